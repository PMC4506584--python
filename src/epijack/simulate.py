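"""Two-locus case-only simulation and marginal-imputation emulation.

Cases are drawn from the joint genotype distribution implied by Bayes rule:
P(G=l, H=m | case) is proportional to penetrance[l,m] * P(G=l) * P(H=m), with
Hardy-Weinberg marginals and linkage equilibrium between the loci in the
general population.  The six classical epistasis penetrance models (unions
and intersections of dominant/recessive conditions at the two loci, high
risk f and low risk g < f) all produce one-signed local log odds ratios
among cases; the multiplicative model (mu * alpha_l * gamma_m) is the
no-interaction null and yields an exactly rank-1 case distribution.

Marginal imputation is emulated with a single typed tag SNP per target
marker.  Target and tag alleles sit on haplotypes with frequencies set by
the allele frequencies (p, q) and a haplotype correlation r; a finite
reference panel of R haplotypes is drawn to estimate those frequencies
(imputation-model noise), the tag genotype is observed for each case, and
the emitted posterior is P(target genotype | tag genotype) under the
panel-estimated haplotype model.  Posterior rows therefore depend on a case
only through its tag genotype (at most 3 distinct rows per marker), and
imputation of one case never depends on the others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import PosteriorMatrix

__all__ = [
    "EPISTASIS_KINDS",
    "PenetranceModel",
    "ImputationConfig",
    "penetrance_table",
    "case_joint_distribution",
    "sample_cases",
    "hwe_genotype_freqs",
    "haplotype_freqs",
    "emulate_imputation",
    "imputation_info",
    "calibrate_r",
]

logger = logging.getLogger(__name__)

#: union / intersection of dominant (>=1 risk allele) and recessive
#: (2 risk alleles) conditions at the two loci.
EPISTASIS_KINDS = ("DuD", "RuR", "DuR", "RnD", "RnR", "DnD")

_KIND_ALIASES = {
    "D∪D": "DuD", "R∪R": "RuR", "D∪R": "DuR",
    "R∩D": "RnD", "R∩R": "RnR", "D∩D": "DnD",
}


@dataclass(frozen=True)
class PenetranceModel:
    """Two-locus penetrance model.

    ``kind`` is one of the six epistasis kinds (e.g. ``"RnR"`` = recessive AND
    recessive) with penetrances ``f`` (condition holds) and ``g < f``
    (otherwise), or ``"multiplicative"`` with baseline ``mu`` and per-genotype
    marginal multipliers ``alpha`` (locus G) and ``gamma`` (locus H).
    Genotypes count copies of the risk allele.
    """

    kind: str
    f: float = 0.02
    g: float = 0.01
    mu: float = 0.01
    alpha: tuple[float, float, float] = (1.0, 1.0, 1.0)
    gamma: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        kind = _KIND_ALIASES.get(self.kind, self.kind)
        object.__setattr__(self, "kind", kind)
        if kind not in EPISTASIS_KINDS + ("multiplicative",):
            raise ValueError(f"unknown penetrance kind {self.kind!r}")
        if kind != "multiplicative" and not self.g < self.f:
            raise ValueError(f"need g < f, got g={self.g}, f={self.f}")


@dataclass(frozen=True)
class ImputationConfig:
    """Single-tag imputation emulator settings for one marker.

    ``p``: target (risk) allele frequency; ``q``: tag allele frequency;
    ``r``: haplotype (allelic) correlation between target and tag alleles —
    imputed information rises with \\|r\\| (roughly r**2 on the dosage r^2
    scale); ``reference_haplotypes``: size R of the panel used to estimate
    haplotype frequencies (panel noise; 120 matches a HapMap-sized CEU
    reference).
    """

    p: float
    q: float
    r: float
    reference_haplotypes: int = 120

    def __post_init__(self) -> None:
        if not 0 < self.p <= 0.5:
            raise ValueError(f"target MAF p={self.p} must be in (0, 0.5]")
        if not 0 < self.q < 1:
            raise ValueError(f"tag allele frequency q={self.q} must be in (0, 1)")
        if not -1 <= self.r <= 1:
            raise ValueError(f"haplotype correlation r={self.r} must be in [-1, 1]")
        if self.reference_haplotypes < 4:
            raise ValueError("reference_haplotypes must be >= 4")
        haplotype_freqs(self.p, self.q, self.r)  # feasibility check


def penetrance_table(model: PenetranceModel) -> np.ndarray:
    """3x3 penetrance table, rows = genotype at G, columns = genotype at H."""
    if model.kind == "multiplicative":
        table = model.mu * np.outer(model.alpha, model.gamma)
    else:
        locus = {"D": np.array([False, True, True]), "R": np.array([False, False, True])}
        cond_g = locus[model.kind[0]]
        cond_h = locus[model.kind[2]]
        if model.kind[1] == "u":
            hit = cond_g[:, None] | cond_h[None, :]
        else:
            hit = cond_g[:, None] & cond_h[None, :]
        table = np.where(hit, model.f, model.g)
    if np.any(table <= 0) or np.any(table > 1):
        raise ValueError("penetrance table entries must lie in (0, 1]")
    return table


def hwe_genotype_freqs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype frequencies for risk-allele frequency ``maf``."""
    if not 0 < maf <= 0.5:
        raise ValueError(f"MAF {maf} must be in (0, 0.5]")
    return np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])


def case_joint_distribution(
    model: PenetranceModel, maf_G: float, maf_H: float
) -> np.ndarray:
    """Joint genotype distribution among cases (Bayes rule, HWE + LE)."""
    pen = penetrance_table(model)
    joint = pen * np.outer(hwe_genotype_freqs(maf_G), hwe_genotype_freqs(maf_H))
    return joint / joint.sum()


def sample_cases(
    dist: np.ndarray, n: int, seed: Optional[int] = None, rng=None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n i.i.d. case genotype pairs from a 3x3 joint distribution."""
    if n < 1:
        raise ValueError("n must be >= 1")
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (3, 3) or np.any(dist < 0):
        raise ValueError("dist must be a non-negative 3x3 table")
    rng = np.random.default_rng(seed) if rng is None else rng
    cells = rng.choice(9, size=n, p=dist.ravel() / dist.sum())
    return cells // 3, cells % 3


def haplotype_freqs(p: float, q: float, r: float) -> np.ndarray:
    """Two-SNP haplotype frequencies (h00, h01, h10, h11) from (p, q, r).

    Index order: target allele then tag allele.  h11 = pq + r sqrt(p(1-p)q(1-q));
    raises if any implied frequency is negative (infeasible r for given p, q).
    """
    h11 = p * q + r * np.sqrt(p * (1 - p) * q * (1 - q))
    h = np.array([1 - p - q + h11, q - h11, p - h11, h11])
    if np.any(h < -1e-12):
        raise ValueError(
            f"infeasible haplotype model: p={p}, q={q}, r={r} implies "
            f"negative frequency {h.min():.4g}"
        )
    return np.clip(h, 0.0, None)


def _panel_joint_genotype(h: np.ndarray) -> np.ndarray:
    """Joint (target, tag) genotype distribution from haplotype freqs under HWE."""
    # haplotype classes indexed (a, b): a = target allele, b = tag allele
    hm = h.reshape(2, 2)
    J = np.zeros((3, 3))
    for a1 in range(2):
        for b1 in range(2):
            for a2 in range(2):
                for b2 in range(2):
                    J[a1 + a2, b1 + b2] += hm[a1, b1] * hm[a2, b2]
    return J


def _impute_marker(
    truth: np.ndarray, cfg: ImputationConfig, rng: np.random.Generator,
    max_panel_retries: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Emulated marginal imputation of one marker.

    Returns (posterior rows n x 3, observed tag genotypes).  Steps: draw a
    reference panel of R haplotypes from the true (p, q, r) model and estimate
    haplotype frequencies (redrawn, with logging, if any class is empty so
    that every posterior is well defined); draw each case's tag genotype from
    the true model conditional on its true target genotype; emit
    P(target | tag) under the panel-estimated model.
    """
    h = haplotype_freqs(cfg.p, cfg.q, cfg.r)
    R = cfg.reference_haplotypes
    support = h > 0  # classes with zero true frequency stay empty (e.g. |r| = 1)
    for attempt in range(max_panel_retries):
        panel = rng.multinomial(R, h)
        if np.all(panel[support] > 0):
            break
        logger.info("reference panel had an empty haplotype class; redrawing "
                    "(attempt %d)", attempt + 1)
    else:
        raise RuntimeError(
            f"reference panel of {R} haplotypes kept missing a haplotype class "
            f"after {max_panel_retries} draws; (p, q, r)=({cfg.p}, {cfg.q}, {cfg.r}) "
            "is too extreme for this panel size"
        )
    h_hat = panel / R

    # tag-allele probability per haplotype, conditional on target allele
    tag_given1 = h[3] / (h[2] + h[3])  # target allele present
    tag_given0 = h[1] / (h[0] + h[1])  # target allele absent
    t = np.asarray(truth)
    tag = rng.binomial(t, tag_given1) + rng.binomial(2 - t, tag_given0)

    J = _panel_joint_genotype(h_hat)
    colsum = J.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = np.where(colsum > 0, J / colsum, 0.0)  # P(target | tag), cols = tag
    return cond.T[tag], tag


def emulate_imputation(
    G: np.ndarray,
    H: np.ndarray,
    cfg_G: ImputationConfig,
    cfg_H: ImputationConfig,
    seed: Optional[int] = None,
    rng=None,
) -> PosteriorMatrix:
    """Emulate marginal imputation of both markers independently.

    The true genotypes (G, H) are hidden; each marker's posterior is driven
    by its own tag SNP and reference panel.  Rows depend only on the tag
    genotype, so there are at most 3 distinct rows per marker (9 joint
    groups), which the grouped jackknife exploits.
    """
    G = np.asarray(G)
    H = np.asarray(H)
    if G.shape != H.shape:
        raise ValueError("G and H must have equal length")
    rng = np.random.default_rng(seed) if rng is None else rng
    pG, _ = _impute_marker(G, cfg_G, rng)
    pH, _ = _impute_marker(H, cfg_H, rng)
    return PosteriorMatrix(pG=pG, pH=pH)


def imputation_info(post_rows: np.ndarray, truth: np.ndarray) -> float:
    """Squared correlation between posterior-mean dosage and true genotype.

    A proxy for the information content of the imputation (1 for perfect,
    ~0 for uninformative posteriors); 0 by convention when the dosage has
    zero variance.
    """
    truth = np.asarray(truth, dtype=float)
    if truth.shape[0] != np.asarray(post_rows).shape[0]:
        raise ValueError("length mismatch between posteriors and truth")
    if np.var(truth) == 0:
        raise ValueError("true genotypes are constant; information undefined")
    dosage = np.asarray(post_rows) @ np.array([0.0, 1.0, 2.0])
    if np.var(dosage) == 0:
        return 0.0
    return float(np.corrcoef(dosage, truth)[0, 1] ** 2)


def calibrate_r(
    target_info: float,
    p: float,
    q: float,
    reference_haplotypes: int = 120,
    n: int = 20_000,
    grid: Optional[np.ndarray] = None,
    seed: int = 0,
) -> float:
    """Pick the haplotype correlation r whose realized information is closest
    to ``target_info`` on a simulation grid (HWE draws of the target marker)."""
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = np.linspace(0.05, 0.999, 40)
    freqs = hwe_genotype_freqs(p)
    truth = rng.choice(3, size=n, p=freqs)
    best_r, best_gap = None, np.inf
    for r in grid:
        try:
            cfg = ImputationConfig(p=p, q=q, r=float(r),
                                   reference_haplotypes=reference_haplotypes)
        except ValueError:
            continue
        rows, _ = _impute_marker(truth, cfg, np.random.default_rng(rng.integers(2**31)))
        gap = abs(imputation_info(rows, truth) - target_info)
        if gap < best_gap:
            best_r, best_gap = float(r), gap
    if best_r is None:
        raise ValueError("no feasible r on the grid")
    return best_r
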