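"""Case-only interaction estimators and Wald-type tests for a SNP pair.

The interaction parameter is the vector of four local log odds ratios of the
3x3 joint genotype table among cases,

    beta_lm = log( p_lm p_{l+1,m+1} / (p_{l,m+1} p_{l+1,m}) ),  l,m in {0,1},

which is identically zero iff the two-locus penetrance is multiplicative
(the case-only "no interaction" null under linkage equilibrium).  For typed
markers the table holds hard-call counts; for untyped (imputed) markers it
holds expected counts under the null, built from the product of the two
marginal genotype posteriors.

Two tests are provided: an unconstrained Wald-type test (WTT, chi-square with
4 df) and a sign-constrained Wald-type test (WTT_c) against the union of the
all-nonnegative and all-nonpositive orthants, whose null reference is a
chi-bar-square mixture with Monte Carlo weights.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Union

import numpy as np
from scipy import linalg
from scipy.stats import chi2

__all__ = [
    "BETA_CELLS",
    "JointGenotypeTable",
    "PosteriorMatrix",
    "LocalOdds",
    "Cov4",
    "ChiBarWeights",
    "TestResult",
    "build_count_table",
    "build_expected_table",
    "estimate_beta",
    "analytic_variance",
    "wtt",
    "project_to_cone",
    "chibar_weights",
    "chibar_tail_mc",
    "wtt_c",
    "naive_dosage_test",
]

#: 2x2 sub-block anchors of the four local odds ratios, in beta order
#: (beta00, beta01, beta10, beta11).
BETA_CELLS: tuple[tuple[int, int], ...] = ((0, 0), (0, 1), (1, 0), (1, 1))

# 4x9 contrast matrix K such that beta = K @ log(vec(counts)), row-major vec.
_K = np.zeros((4, 9))
for _k, (_l, _m) in enumerate(BETA_CELLS):
    _K[_k, 3 * _l + _m] += 1.0
    _K[_k, 3 * (_l + 1) + (_m + 1)] += 1.0
    _K[_k, 3 * _l + (_m + 1)] -= 1.0
    _K[_k, 3 * (_l + 1) + _m] -= 1.0

# All subsets of {0,1,2,3}: the faces of a 4-dimensional orthant.
_FACES: tuple[tuple[int, ...], ...] = tuple(
    itertools.chain.from_iterable(
        itertools.combinations(range(4), k) for k in range(5)
    )
)

_PD_TOL = 1e-12  # relative to the largest eigenvalue


@dataclass(frozen=True)
class JointGenotypeTable:
    """3x3 table of (expected) joint genotype counts among cases.

    ``counts[l, m]`` is the (expected) number of cases with genotype ``l`` at
    marker G and ``m`` at marker H, with 0/1/2 counting copies of the coded
    allele.  Entries are integers for hard calls and real for expected counts.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (3, 3):
            raise ValueError(f"counts must be 3x3, got shape {c.shape}")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def n_total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class PosteriorMatrix:
    """Per-individual marginal genotype posteriors for the two markers.

    Row ``i`` of ``pG`` is P(genotype at G = 0,1,2 | observed data) for case
    ``i``, likewise ``pH``.  Under the no-interaction null the joint posterior
    is the outer product of the two marginals, so these rows are the
    sufficient input for every imputed-marker statistic.  Rows are validated
    to sum to one (tolerance 1e-8) and renormalized exactly on construction.
    Hard calls are the degenerate special case with one unit entry per row.
    """

    pG: np.ndarray
    pH: np.ndarray

    def __post_init__(self) -> None:
        for name in ("pG", "pH"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.ndim != 2 or p.shape[1] != 3:
                raise ValueError(f"{name} must be an n x 3 matrix")
            if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
                raise ValueError(f"{name} entries must lie in [0, 1]")
            rowsum = p.sum(axis=1)
            bad = np.flatnonzero(np.abs(rowsum - 1.0) > 1e-8)
            if bad.size:
                raise ValueError(
                    f"{name} row {bad[0]} sums to {rowsum[bad[0]]:.10f}, not 1"
                )
            object.__setattr__(self, name, np.clip(p, 0.0, None) / rowsum[:, None])
        if self.pG.shape[0] != self.pH.shape[0]:
            raise ValueError(
                f"pG has {self.pG.shape[0]} rows but pH has {self.pH.shape[0]}"
            )
        if self.pG.shape[0] == 0:
            raise ValueError("no samples")

    @property
    def n(self) -> int:
        return self.pG.shape[0]

    @classmethod
    def from_calls(cls, g: Sequence[int], h: Sequence[int]) -> "PosteriorMatrix":
        """Encode hard genotype calls as degenerate posteriors."""
        g = _check_genotypes(np.asarray(g), "G")
        h = _check_genotypes(np.asarray(h), "H")
        if g.shape[0] != h.shape[0]:
            raise ValueError(f"length mismatch: {g.shape[0]} vs {h.shape[0]}")
        eye = np.eye(3)
        return cls(pG=eye[g], pH=eye[h])


@dataclass(frozen=True)
class LocalOdds:
    """The 4-vector of local log odds ratios (beta00, beta01, beta10, beta11)."""

    beta: np.ndarray
    haldane: bool = False  # True if +0.5 was added to every cell before logging

    def __post_init__(self) -> None:
        b = np.asarray(self.beta, dtype=float)
        if b.shape != (4,):
            raise ValueError("beta must be a 4-vector")
        if not np.all(np.isfinite(b)):
            raise ValueError("beta has non-finite entries (zero cells?)")
        object.__setattr__(self, "beta", b)


@dataclass(frozen=True)
class Cov4:
    """4x4 covariance of the local log odds ratio estimator."""

    V: np.ndarray
    provenance: Literal["analytic", "jackknife", "naive_dosage"]

    def __post_init__(self) -> None:
        V = np.asarray(self.V, dtype=float)
        if V.shape != (4, 4):
            raise ValueError("V must be 4x4")
        if not np.allclose(V, V.T, atol=1e-10):
            raise ValueError("V must be symmetric (tolerance 1e-10)")
        object.__setattr__(self, "V", 0.5 * (V + V.T))

    @property
    def min_eigenvalue(self) -> float:
        return float(linalg.eigvalsh(self.V)[0])

    def require_pd(self) -> None:
        # tolerance is relative to the matrix scale: covariance magnitudes
        # span many orders (imputed estimators shrink hard at low information)
        eigs = linalg.eigvalsh(self.V)
        if eigs[-1] <= 0 or eigs[0] <= _PD_TOL * eigs[-1]:
            raise np.linalg.LinAlgError(
                f"covariance ({self.provenance}) is not positive definite "
                f"(eigenvalues {eigs[0]:.3e} .. {eigs[-1]:.3e}); check for "
                "zero cells or a degenerate posterior structure"
            )


@dataclass(frozen=True)
class ChiBarWeights:
    """Monte Carlo chi-bar-square mixture weights for the constrained test.

    ``w[l]`` multiplies the upper tail of chi-square with ``l`` df in
    P(WTT_c >= t) ~= sum_{l=1..4} w[l] P(chi2_l >= t); ``w[0]`` is the point
    mass at zero.  For ``cone="nonneg"`` (a single convex orthant) the weights
    are the classical face probabilities and sum to one.  For the default
    two-sided cone (union of the nonnegative and nonpositive orthants) the
    tail weights are the *sum* of the two per-orthant face probabilities —
    the union bound, exact per orthant and accurate in the upper tail — so
    sum(w[1:]) may exceed one and the mixture p-value is clipped at one.
    """

    w: np.ndarray
    mc_draws: int
    seed: int
    cone: Literal["two-sided", "nonneg"] = "two-sided"
    method: Literal["orthant-sum", "winning"] = "orthant-sum"

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.shape != (5,):
            raise ValueError("w must be a 5-vector (w0..w4)")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "w", w)

    def tail(self, t: float) -> float:
        """Mixture upper tail P(statistic >= t); 1 at t <= 0."""
        if t <= 0:
            return 1.0
        p = sum(self.w[l] * chi2.sf(t, l) for l in range(1, 5))
        return float(min(1.0, p))


@dataclass(frozen=True)
class TestResult:
    """Outcome of one interaction test on one SNP pair."""

    statistic: float
    pvalue: float
    method: str
    df_or_weights: Union[str, ChiBarWeights]
    variance_provenance: str

    def __post_init__(self) -> None:
        if not (self.statistic >= 0 and np.isfinite(self.statistic)):
            raise ValueError(f"invalid statistic {self.statistic}")
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"invalid p-value {self.pvalue}")


def _check_genotypes(g: np.ndarray, label: str) -> np.ndarray:
    g = np.asarray(g)
    if g.size == 0:
        raise ValueError("no samples")
    if not np.issubdtype(g.dtype, np.number):
        raise ValueError(f"{label} genotypes must be numeric")
    gi = g.astype(int)
    bad = np.flatnonzero((g != gi) | (gi < 0) | (gi > 2))
    if bad.size:
        raise ValueError(
            f"{label} genotype at index {bad[0]} is {g[bad[0]]!r}, "
            "expected 0, 1 or 2"
        )
    return gi


def build_count_table(
    genotypes_G: Sequence[int], genotypes_H: Sequence[int]
) -> JointGenotypeTable:
    """Tally hard genotype calls into the 3x3 joint count table."""
    g = _check_genotypes(np.asarray(genotypes_G), "G")
    h = _check_genotypes(np.asarray(genotypes_H), "H")
    if g.shape[0] != h.shape[0]:
        raise ValueError(f"length mismatch: {g.shape[0]} vs {h.shape[0]}")
    counts = np.bincount(3 * g + h, minlength=9).reshape(3, 3)
    return JointGenotypeTable(counts=counts.astype(float))


def build_expected_table(post: PosteriorMatrix) -> JointGenotypeTable:
    """Expected joint counts under the null: sum_i pG_i (outer) pH_i.

    The per-individual null joint posterior is the product of the two
    marginal posteriors, so the expected table is simply ``pG.T @ pH``.
    """
    return JointGenotypeTable(counts=post.pG.T @ post.pH)


def estimate_beta(
    tab: JointGenotypeTable,
    zero_policy: Literal["error", "haldane"] = "error",
) -> LocalOdds:
    """Local log odds ratios of a 3x3 (expected) count table.

    ``zero_policy="haldane"`` adds 0.5 to every cell first (flagged on the
    result); with ``"error"`` any non-positive cell raises, naming the cell.
    """
    c = tab.counts
    if zero_policy == "haldane":
        c = c + 0.5
    elif zero_policy == "error":
        zeros = np.argwhere(c <= 0)
        if zeros.size:
            l, m = zeros[0]
            raise ValueError(
                f"cell ({l},{m}) of the joint genotype table is "
                f"{tab.counts[l, m]:g}; local odds ratios are undefined "
                "(use zero_policy='haldane' or inspect allele frequencies)"
            )
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    beta = _K @ np.log(c.ravel())
    return LocalOdds(beta=beta, haldane=(zero_policy == "haldane"))


def analytic_variance(tab: JointGenotypeTable) -> Cov4:
    """Multinomial (delta-method) covariance of the local log odds ratios.

    Equals (1/n) K diag(1/p) K^T with p the cell proportions and K the 4x9
    contrast matrix of the local log odds ratios: the diagonal entry for
    beta_lm is (1/p_lm + 1/p_{l,m+1} + 1/p_{l+1,m} + 1/p_{l+1,m+1}) / n and
    off-diagonals collect the shared cells with their contrast signs.
    """
    n = tab.n_total
    zeros = np.argwhere(tab.counts <= 0)
    if zeros.size:
        l, m = zeros[0]
        raise ValueError(f"cell ({l},{m}) is zero; analytic variance undefined")
    p = tab.counts.ravel() / n
    V = (_K / p) @ _K.T / n
    return Cov4(V=V, provenance="analytic")


def _quad_inv(beta: np.ndarray, V: np.ndarray) -> float:
    """beta^T V^{-1} beta via a symmetric (Cholesky) factorization."""
    cho = linalg.cho_factor(V, lower=True)
    return float(beta @ linalg.cho_solve(cho, beta))


def wtt(beta: LocalOdds, V: Cov4, method: str = "WTT") -> TestResult:
    """Unconstrained Wald-type test: beta^T V^{-1} beta against chi2(4)."""
    V.require_pd()
    stat = max(0.0, _quad_inv(beta.beta, V.V))
    return TestResult(
        statistic=stat,
        pvalue=float(chi2.sf(stat, 4)),
        method=method,
        df_or_weights="chi2_4",
        variance_provenance=V.provenance,
    )


def _face_cache(W: np.ndarray) -> list[tuple[tuple[int, ...], Optional[np.ndarray]]]:
    cache = []
    for S in _FACES:
        if S:
            idx = np.asarray(S)
            cache.append((S, np.linalg.inv(W[np.ix_(idx, idx)])))
        else:
            cache.append((S, None))
    return cache


def _project_batch(
    B: np.ndarray, W: np.ndarray, faces=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Project rows of B onto each orthant in the V^{-1} (= W) metric.

    Exact active-set enumeration: the minimizer over one orthant lies on one
    of the 16 faces (a subset of coordinates fixed at zero); on each face the
    unconstrained optimum solves W_SS x_S = (W b)_S and is kept if it is
    sign-feasible.  Returns per-row (qdist_pos, dim_pos, qdist_neg, dim_neg):
    the attained squared distance and the number of nonzero coordinates of
    the optimum, for the nonnegative and nonpositive orthants.
    """
    if faces is None:
        faces = _face_cache(W)
    k = B.shape[0]
    Y = B @ W
    q = np.einsum("ij,ij->i", B, Y)
    out = {}
    for sign in (+1, -1):
        out[sign] = (np.full(k, np.inf), np.zeros(k, dtype=np.int64))
    for S, Minv in faces:
        if not S:
            f = q
            X = None
        else:
            idx = list(S)
            X = Y[:, idx] @ Minv.T
            f = q - np.einsum("ij,ij->i", X, Y[:, idx])
        for sign in (+1, -1):
            obj, dim = out[sign]
            if X is None:
                feas = np.ones(k, dtype=bool)
                nz = 0
            else:
                feas = np.all(sign * X >= -1e-10, axis=1)
                nz = np.count_nonzero(np.abs(X) > 1e-10, axis=1)
            upd = feas & (f < obj - 1e-12)
            obj[upd] = f[upd]
            dim[upd] = nz[upd] if X is not None else 0
    qp, dp = out[+1]
    qn, dn = out[-1]
    return np.maximum(qp, 0.0), dp, np.maximum(qn, 0.0), dn


def project_to_cone(
    beta: LocalOdds, V: Cov4, cone: Literal["two-sided", "nonneg"] = "two-sided"
) -> tuple[LocalOdds, float, int]:
    """Project beta onto the sign-constraint cone in the V^{-1} metric.

    The constrained alternative is the union of the all-nonnegative and
    all-nonpositive orthants; the projection solves the two orthant quadratic
    programs exactly by enumerating all 16 faces of each and takes the
    smaller, ties broken to the nonnegative orthant.  Returns the projected
    vector, the attained squared V^{-1}-distance, and the number of nonzero
    coordinates of the projection.
    """
    V.require_pd()
    W = np.linalg.inv(V.V)
    W = 0.5 * (W + W.T)
    b = beta.beta
    best = None  # (qdist, x, sign-priority)
    Y = W @ b
    q = float(b @ Y)
    for sign in (+1, -1):
        for S in _FACES:
            x = np.zeros(4)
            if S:
                idx = list(S)
                xs = np.linalg.solve(W[np.ix_(idx, idx)], Y[idx])
                if np.any(sign * xs < -1e-10):
                    continue
                x[idx] = xs
                f = q - float(xs @ Y[idx])
            else:
                f = q
            f = max(f, 0.0)
            if best is None or f < best[0] - 1e-12:
                best = (f, x, sign)
    qdist, x, _ = best
    x = np.where(np.abs(x) > 1e-10, x, 0.0)
    return LocalOdds(beta=x), float(qdist), int(np.count_nonzero(x))


def chibar_weights(
    V: Cov4,
    mc_draws: int = 20_000,
    seed: int = 0,
    cone: Literal["two-sided", "nonneg"] = "two-sided",
    method: Literal["orthant-sum", "winning"] = "orthant-sum",
) -> ChiBarWeights:
    """Monte Carlo chi-bar-square mixture weights for the covariance V.

    Draws Z ~ N(0, V), projects each draw onto the constraint cone, and
    records the dimension (number of nonzero coordinates) of the projection.
    For the single-orthant cone the dimension frequencies are the classical
    chi-bar weights (sum 1).  For the two-sided cone the default
    ``orthant-sum`` method sums the two per-orthant dimension frequencies
    (see ChiBarWeights); ``winning`` records only the closer orthant's
    projection dimension.  Deterministic given the seed; weights depend on V
    only through its correlation structure (scale-invariant).
    """
    if mc_draws < 1000:
        raise ValueError("mc_draws must be >= 1000")
    V.require_pd()
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(V.V)
    W = np.linalg.inv(V.V)
    W = 0.5 * (W + W.T)
    faces = _face_cache(W)
    Z = rng.standard_normal((mc_draws, 4)) @ L.T
    qp, dp, qn, dn = _project_batch(Z, W, faces)
    if cone == "nonneg":
        w = np.bincount(dp, minlength=5) / mc_draws
    elif method == "winning":
        dim = np.where(qn < qp, dn, dp)
        w = np.bincount(dim, minlength=5) / mc_draws
    else:
        w = (np.bincount(dp, minlength=5) + np.bincount(dn, minlength=5)) / mc_draws
        w[0] = max(0.0, 1.0 - w[1:].sum())
    return ChiBarWeights(w=w, mc_draws=mc_draws, seed=seed, cone=cone, method=method)


def chibar_tail_mc(
    V: Cov4,
    t: Union[float, Sequence[float]],
    mc_draws: int = 100_000,
    seed: int = 0,
    cone: Literal["two-sided", "nonneg"] = "two-sided",
) -> np.ndarray:
    """Direct Monte Carlo upper tail of the constrained null statistic.

    Simulates Z ~ N(0, V) and returns the empirical P(statistic >= t) for the
    constrained statistic Z^T V^{-1} Z - qdist(Z).  Cross-check for the
    mixture approximation of :func:`chibar_weights`.
    """
    V.require_pd()
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(V.V)
    W = np.linalg.inv(V.V)
    W = 0.5 * (W + W.T)
    Z = rng.standard_normal((mc_draws, 4)) @ L.T
    q = np.einsum("ij,ij->i", Z @ W, Z)
    qp, _, qn, _ = _project_batch(Z, W)
    qd = qp if cone == "nonneg" else np.minimum(qp, qn)
    stat = q - qd
    t = np.atleast_1d(np.asarray(t, dtype=float))
    return np.array([(stat >= ti).mean() for ti in t])


def wtt_c(
    beta: LocalOdds,
    V: Cov4,
    weights: Optional[ChiBarWeights] = None,
    mc_draws: int = 20_000,
    seed: int = 0,
    method: str = "WTT_c",
) -> TestResult:
    """Sign-constrained Wald-type test against the chi-bar-square mixture.

    The statistic is the unconstrained quadratic form minus the squared
    V^{-1}-distance from beta to the constraint cone; it always lies in
    [0, WTT] with equality to WTT iff beta satisfies the sign constraints.
    """
    V.require_pd()
    if weights is None:
        weights = chibar_weights(V, mc_draws=mc_draws, seed=seed)
    full = max(0.0, _quad_inv(beta.beta, V.V))
    _, qdist, _ = project_to_cone(
        beta, V, cone="nonneg" if weights.cone == "nonneg" else "two-sided"
    )
    stat = max(0.0, full - qdist)
    pvalue = 1.0 if stat <= 0 else weights.tail(stat)
    return TestResult(
        statistic=stat,
        pvalue=pvalue,
        method=method,
        df_or_weights=weights,
        variance_provenance=V.provenance,
    )


def naive_dosage_test(
    post: PosteriorMatrix,
    constrained: bool = False,
    zero_policy: Literal["error", "haldane"] = "error",
    mc_draws: int = 20_000,
    seed: int = 0,
) -> TestResult:
    """Dosage baseline: treat expected counts as observed hard-call counts.

    Builds the expected table, estimates beta, and plugs the expected table
    into the multinomial analytic variance as if it held observed genotypes.
    This ignores imputation uncertainty and overestimates the variance of the
    estimator, making the test conservative; it is included as the standard
    (flawed) downstream-of-imputation comparator.
    """
    tab = build_expected_table(post)
    beta = estimate_beta(tab, zero_policy=zero_policy)
    V = Cov4(V=analytic_variance(tab).V, provenance="naive_dosage")
    if constrained:
        res = wtt_c(beta, V, mc_draws=mc_draws, seed=seed, method="naive_dosage_WTTc")
    else:
        res = wtt(beta, V, method="naive_dosage_WTT")
    return res
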