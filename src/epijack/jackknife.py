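"""Delete-1 jackknife variance estimation for the imputed-marker estimator.

The resampling unit is one case's pair of posterior rows.  Because the
posteriors are produced from an external reference panel, imputing one
individual does not depend on the others, so deleting a case and "re-imputing"
leaves every other row unchanged — the jackknife can be applied directly to
the imputed rows.  The leave-one-out estimate is obtained by subtracting the
individual's outer-product contribution from the full expected table (O(1)
per sample), and individuals with identical posterior rows share a single
leave-one-out computation (the categorical-grouping speedup: emulated
imputation yields at most 9 distinct row pairs).

With the full-sample estimate b_n and leave-one-out estimates b^i_{n-1}, the
pseudo-values are ps_i = n b_n - (n-1) b^i_{n-1} and the variance estimate is

    V = 1/(n(n-1)) sum_i (ps_i - ps_bar)(ps_i - ps_bar)^T,

centered at the pseudo-value mean ps_bar.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import Cov4, JointGenotypeTable, PosteriorMatrix, build_expected_table, estimate_beta

__all__ = [
    "PseudoValueSet",
    "unique_row_groups",
    "jackknife_pseudovalues",
    "jackknife_variance",
    "pseudovalue_covariance",
]


@dataclass(frozen=True)
class PseudoValueSet:
    """Jackknife pseudo-values per group of identical posterior rows."""

    pseudo: np.ndarray  # g x 4, one row per group
    sizes: np.ndarray  # group sizes, sum = n
    n: int

    @property
    def center(self) -> np.ndarray:
        """Pseudo-value mean over individuals (size-weighted over groups)."""
        return self.sizes @ self.pseudo / self.n

    def expand(self) -> np.ndarray:
        """Per-individual n x 4 pseudo-value matrix (group order)."""
        return np.repeat(self.pseudo, self.sizes, axis=0)


def unique_row_groups(
    post: PosteriorMatrix, tol: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Group individuals whose (pG, pH) row pairs agree within ``tol``.

    Returns (group_ids, group_sizes) with ``group_sizes.sum() == n``.  With
    ``tol > 0`` rows are quantized to multiples of ``tol`` before comparison.
    """
    rows = np.hstack([post.pG, post.pH])
    key = np.round(rows / tol) if tol > 0 else rows
    _, ids, sizes = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return ids.ravel(), sizes


def jackknife_pseudovalues(
    post: PosteriorMatrix,
    grouping: bool = True,
    zero_policy: Literal["error", "haldane"] = "error",
) -> PseudoValueSet:
    """Delete-1 pseudo-values of the null local log odds ratio estimator."""
    n = post.n
    if n < 9:
        raise ValueError(f"jackknife requires n >= 9, got {n}")
    tab = build_expected_table(post)
    beta_n = estimate_beta(tab, zero_policy=zero_policy).beta
    if grouping:
        ids, sizes = unique_row_groups(post)
        reps = np.empty(sizes.shape[0], dtype=np.int64)
        reps[ids[::-1]] = np.arange(n - 1, -1, -1)  # first member of each group
    else:
        reps = np.arange(n)
        sizes = np.ones(n, dtype=np.int64)
    pseudo = np.empty((reps.shape[0], 4))
    for g, i in enumerate(reps):
        loo = tab.counts - np.outer(post.pG[i], post.pH[i])
        # contributions cancel to rounding error when a cell is carried by one row
        loo[(loo < 0) & (loo > -1e-9)] = 0.0
        try:
            beta_i = estimate_beta(
                JointGenotypeTable(counts=loo), zero_policy=zero_policy
            ).beta
        except ValueError as err:
            raise ValueError(
                f"leave-one-out table for sample {i} is degenerate: {err}"
            ) from err
        pseudo[g] = n * beta_n - (n - 1) * beta_i
    return PseudoValueSet(pseudo=pseudo, sizes=np.asarray(sizes), n=n)


def pseudovalue_covariance(ps: PseudoValueSet) -> np.ndarray:
    """1/(n(n-1)) sum_i (ps_i - ps_bar)(ps_i - ps_bar)^T over individuals."""
    n = ps.n
    d = ps.pseudo - ps.center
    return (d.T * ps.sizes) @ d / (n * (n - 1))


def jackknife_variance(
    post: PosteriorMatrix,
    grouping: bool = True,
    zero_policy: Literal["error", "haldane"] = "error",
) -> Cov4:
    """Delete-1 jackknife covariance of the imputed-marker estimator.

    ``grouping=True`` shares one leave-one-out computation among individuals
    with identical posterior rows; the result is identical to the ungrouped
    estimator up to floating-point associativity (<= 1e-12).
    """
    ps = jackknife_pseudovalues(post, grouping=grouping, zero_policy=zero_policy)
    return Cov4(V=pseudovalue_covariance(ps), provenance="jackknife")
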