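"""Size/power experiment harness for the case-only interaction tests.

Each replicate draws n cases from the configured two-locus model, emulates
marginal imputation, and runs up to three analysis arms on the same data:

* ``WTT`` / ``WTT_c``           — imputed markers, jackknife variance;
* ``naive_dosage_WTT(c)``       — imputed markers, expected table plugged
                                  into the multinomial variance (the flawed
                                  dosage-as-observed baseline);
* ``truth_WTT`` / ``truth_WTTc``— the actual genotypes, analytic variance.

Rejection rates at the configured level are reported with binomial Monte
Carlo standard errors.  Everything is reproducible from the master seed
(per-replicate generators are spawned from one SeedSequence, and methods are
paired within replicate: they see the same data).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

from . import core
from .jackknife import jackknife_variance
from .simulate import (
    ImputationConfig,
    PenetranceModel,
    case_joint_distribution,
    emulate_imputation,
    imputation_info,
    sample_cases,
)

__all__ = [
    "ALL_METHODS",
    "StudyConfig",
    "StudyResult",
    "CalibrationReport",
    "run_study",
    "ks_uniformity",
    "variance_calibration",
    "null_config",
    "power_config",
    "IMPUTATION_PRESETS",
]

ALL_METHODS = (
    "WTT",
    "WTT_c",
    "naive_dosage_WTT",
    "naive_dosage_WTTc",
    "truth_WTT",
    "truth_WTTc",
)

_IMPUTED_METHODS = frozenset(ALL_METHODS[:4])
_JACK_METHODS = frozenset(("WTT", "WTT_c"))
_NAIVE_METHODS = frozenset(("naive_dosage_WTT", "naive_dosage_WTTc"))
_TRUTH_METHODS = frozenset(("truth_WTT", "truth_WTTc"))


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one simulation experiment."""

    model: PenetranceModel
    maf_G: float = 0.3
    maf_H: float = 0.3
    imp_G: Optional[ImputationConfig] = None
    imp_H: Optional[ImputationConfig] = None
    n_cases: int = 5000
    replicates: int = 3000
    alpha: float = 0.01
    methods: tuple[str, ...] = ALL_METHODS
    seed: int = 0
    chibar_draws: int = 20_000
    zero_policy: Literal["error", "haldane"] = "error"
    grouping: bool = True
    max_excluded_frac: float = 0.01

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if set(self.methods) & _IMPUTED_METHODS and (
            self.imp_G is None or self.imp_H is None
        ):
            raise ValueError("imputed-arm methods need imp_G and imp_H configs")


@dataclass(frozen=True)
class StudyResult:
    """Per-method rejection rates and replicate-level p-values."""

    config: StudyConfig
    pvalues: dict[str, np.ndarray]  # NaN where the replicate was excluded
    info_G: np.ndarray
    info_H: np.ndarray
    excluded: int

    @property
    def n_effective(self) -> int:
        return self.config.replicates - self.excluded

    def rejection_rate(self, method: str, alpha: Optional[float] = None) -> float:
        alpha = self.config.alpha if alpha is None else alpha
        p = self.pvalues[method]
        p = p[~np.isnan(p)]
        return float(np.mean(p <= alpha))

    def mc_se(self, method: str, alpha: Optional[float] = None) -> float:
        rate = self.rejection_rate(method, alpha)
        return float(np.sqrt(rate * (1.0 - rate) / max(1, self.n_effective)))

    def summary_rows(self) -> list[dict]:
        rows = []
        for m in self.config.methods:
            rows.append(
                {
                    "method": m,
                    "model": self.config.model.kind,
                    "n": self.config.n_cases,
                    "replicates": self.config.replicates,
                    "alpha": self.config.alpha,
                    "rejection_rate": self.rejection_rate(m),
                    "mc_se": self.mc_se(m),
                    "excluded": self.excluded,
                    "mean_info_G": float(np.nanmean(self.info_G))
                    if self.info_G.size
                    else float("nan"),
                    "mean_info_H": float(np.nanmean(self.info_H))
                    if self.info_H.size
                    else float("nan"),
                }
            )
        return rows


def _replicate_tests(
    G: np.ndarray,
    H: np.ndarray,
    cfg: StudyConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, float], float, float]:
    """All requested tests on one replicate's data; returns p-values and
    the realized imputation information for the two markers."""
    want = set(cfg.methods)
    out: dict[str, float] = {}
    info_g = info_h = float("nan")

    if want & _TRUTH_METHODS:
        tab = core.build_count_table(G, H)
        beta = core.estimate_beta(tab, zero_policy=cfg.zero_policy)
        V = core.analytic_variance(tab)
        if "truth_WTT" in want:
            out["truth_WTT"] = core.wtt(beta, V, method="truth_WTT").pvalue
        if "truth_WTTc" in want:
            out["truth_WTTc"] = core.wtt_c(
                beta, V, mc_draws=cfg.chibar_draws,
                seed=int(rng.integers(2**31)), method="truth_WTTc",
            ).pvalue

    if want & _IMPUTED_METHODS:
        post = emulate_imputation(G, H, cfg.imp_G, cfg.imp_H, rng=rng)
        info_g = imputation_info(post.pG, G)
        info_h = imputation_info(post.pH, H)
        if want & _JACK_METHODS:
            tab_u = core.build_expected_table(post)
            beta_u = core.estimate_beta(tab_u, zero_policy=cfg.zero_policy)
            Vj = jackknife_variance(
                post, grouping=cfg.grouping, zero_policy=cfg.zero_policy
            )
            if "WTT" in want:
                out["WTT"] = core.wtt(beta_u, Vj, method="WTT").pvalue
            if "WTT_c" in want:
                out["WTT_c"] = core.wtt_c(
                    beta_u, Vj, mc_draws=cfg.chibar_draws,
                    seed=int(rng.integers(2**31)),
                ).pvalue
        if "naive_dosage_WTT" in want:
            out["naive_dosage_WTT"] = core.naive_dosage_test(
                post, constrained=False, zero_policy=cfg.zero_policy
            ).pvalue
        if "naive_dosage_WTTc" in want:
            out["naive_dosage_WTTc"] = core.naive_dosage_test(
                post, constrained=True, zero_policy=cfg.zero_policy,
                mc_draws=cfg.chibar_draws, seed=int(rng.integers(2**31)),
            ).pvalue
    return out, info_g, info_h


def run_study(cfg: StudyConfig) -> StudyResult:
    """Run the configured experiment; fails loudly if more than
    ``max_excluded_frac`` of replicates hit the zero-cell policy."""
    dist = case_joint_distribution(cfg.model, cfg.maf_G, cfg.maf_H)
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.replicates)
    pvals = {m: np.full(cfg.replicates, np.nan) for m in cfg.methods}
    info_G = np.full(cfg.replicates, np.nan)
    info_H = np.full(cfg.replicates, np.nan)
    excluded = 0
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        G, H = sample_cases(dist, cfg.n_cases, rng=rng)
        try:
            out, info_G[k], info_H[k] = _replicate_tests(G, H, cfg, rng)
        except ValueError:
            excluded += 1
            continue
        for m, p in out.items():
            pvals[m][k] = p
    if excluded > cfg.max_excluded_frac * cfg.replicates:
        raise RuntimeError(
            f"{excluded}/{cfg.replicates} replicates excluded by the "
            f"zero-cell policy ({cfg.zero_policy!r}); results would be biased"
        )
    return StudyResult(
        config=cfg, pvalues=pvals, info_G=info_G, info_H=info_H, excluded=excluded
    )


def ks_uniformity(pvalues: Sequence[float]) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test of p-values against Uniform(0,1)."""
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size < 10:
        raise ValueError("need at least 10 p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    res = stats.kstest(p, "uniform")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class CalibrationReport:
    """Mean estimated variances vs empirical variance of the estimator,
    per coordinate of beta, across K null replicates."""

    mean_jackknife_diag: np.ndarray
    mean_naive_diag: np.ndarray
    empirical_var: np.ndarray
    K: int

    @property
    def naive_overestimates(self) -> np.ndarray:
        """True where the dosage-as-observed variance exceeds the truth."""
        return self.mean_naive_diag > self.empirical_var


def variance_calibration(cfg: StudyConfig, K: int = 500) -> CalibrationReport:
    """Compare average variance estimates with the empirical variance of the
    imputed-marker estimator across K null replicates.

    The dosage-as-observed (naive) estimator systematically overestimates:
    with imputation uncertainty the dosage is less variable than the genotype
    it replaces, so the plug-in multinomial variance is too large, while the
    jackknife tracks the empirical variance.
    """
    if K < 100:
        raise ValueError("K must be >= 100")
    dist = case_joint_distribution(cfg.model, cfg.maf_G, cfg.maf_H)
    children = np.random.SeedSequence(cfg.seed).spawn(K)
    betas = np.empty((K, 4))
    jdiag = np.empty((K, 4))
    ndiag = np.empty((K, 4))
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        G, H = sample_cases(dist, cfg.n_cases, rng=rng)
        post = emulate_imputation(G, H, cfg.imp_G, cfg.imp_H, rng=rng)
        tab = core.build_expected_table(post)
        betas[k] = core.estimate_beta(tab, zero_policy=cfg.zero_policy).beta
        jdiag[k] = np.diag(
            jackknife_variance(post, grouping=cfg.grouping,
                               zero_policy=cfg.zero_policy).V
        )
        ndiag[k] = np.diag(core.analytic_variance(tab).V)
    return CalibrationReport(
        mean_jackknife_diag=jdiag.mean(axis=0),
        mean_naive_diag=ndiag.mean(axis=0),
        empirical_var=betas.var(axis=0, ddof=1),
        K=K,
    )


# ---------------------------------------------------------------------------
# Preset experiment configurations (the study conditions of the size/power
# design: 5000 cases, 3000 size replicates at level 0.01, 100 power
# replicates at level 0.05, 120 reference haplotypes).

#: tag-SNP correlations chosen so that the realized dosage r^2 information
#: lands near the three regimes studied: high ~0.90, medium ~0.76, low ~0.02.
IMPUTATION_PRESETS: dict[str, ImputationConfig] = {
    "high": ImputationConfig(p=0.3, q=0.3, r=0.950),
    "medium": ImputationConfig(p=0.3, q=0.3, r=0.872),
    "low": ImputationConfig(p=0.3, q=0.3, r=0.150),
}

#: null: multiplicative penetrances with a modest per-allele marginal effect
#: (odds multiplier 1.2 per risk allele) at both loci.
NULL_MODEL = PenetranceModel(
    kind="multiplicative", mu=0.01,
    alpha=(1.0, 1.2, 1.44), gamma=(1.0, 1.2, 1.44),
)

#: default detectable-effect model: recessive-AND-recessive epistasis with a
#: twofold risk in the doubly homozygous cell (beta_11 = log 2).
POWER_MODEL = PenetranceModel(kind="RnR", f=0.02, g=0.01)


def null_config(
    info_G: str = "high",
    info_H: str = "medium",
    replicates: int = 3000,
    seed: int = 0,
    methods: tuple[str, ...] = ALL_METHODS,
    **overrides,
) -> StudyConfig:
    """Null (multiplicative) size experiment at the named information regimes."""
    return StudyConfig(
        model=NULL_MODEL,
        imp_G=IMPUTATION_PRESETS[info_G],
        imp_H=IMPUTATION_PRESETS[info_H],
        replicates=replicates,
        alpha=0.01,
        methods=methods,
        seed=seed,
        **overrides,
    )


def power_config(
    model: PenetranceModel = POWER_MODEL,
    info_G: str = "high",
    info_H: str = "medium",
    replicates: int = 100,
    seed: int = 0,
    methods: tuple[str, ...] = ALL_METHODS,
    **overrides,
) -> StudyConfig:
    """Power experiment at level 0.05 under an epistasis penetrance model."""
    return StudyConfig(
        model=model,
        imp_G=IMPUTATION_PRESETS[info_G],
        imp_H=IMPUTATION_PRESETS[info_H],
        replicates=replicates,
        alpha=0.05,
        methods=methods,
        seed=seed,
        **overrides,
    )
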