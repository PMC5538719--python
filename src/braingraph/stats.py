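"""Non-parametric permutation comparison of network measures between groups.

Group differences in graph measures have no tractable parametric null, so
significance is assessed by permutation: subjects are randomly reassigned
to two groups of the original sizes, the statistic of interest is
recomputed for each reassignment, and the observed difference is referred
to the resulting null distribution. Longitudinal (paired) designs permute
only within subject — each permutation independently swaps, or not, a
subject's two timepoints — so no permuted dataset ever mixes different
subjects' data.

p-values use the inclusive estimator (k + 1) / (M + 1), which is a valid
test and never returns 0; the plain fraction k / M is available as
``raw_p``. The 95% interval reported is the 2.5-97.5 percentile band of the
permutation null of the difference. Nodal comparisons share the same
permutations across nodes and are corrected across nodes with
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError

__all__ = [
    "ComparisonResult",
    "permutation_compare",
    "permutation_compare_longitudinal",
    "permutation_null",
    "summarize_permutation",
    "fdr_bh",
]

Statistic = Callable[[np.ndarray], Union[float, np.ndarray]]


@dataclass(frozen=True)
class ComparisonResult:
    """Observed group difference with its permutation null and p-values.

    ``observed_diff`` is statistic(group B) - statistic(group A) — scalar
    for global measures, length-R vector for nodal ones. ``null_diffs`` has
    shape (M,) or (M, R).
    """

    name: str
    observed_diff: Union[float, np.ndarray]
    null_diffs: np.ndarray
    p_one: Union[float, np.ndarray]
    p_two: Union[float, np.ndarray]
    raw_p_two: Union[float, np.ndarray]
    ci_low: Union[float, np.ndarray]
    ci_high: Union[float, np.ndarray]
    fdr_adjusted_p: Optional[np.ndarray] = None
    param: object = None
    warnings: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_permutations(self) -> int:
        return self.null_diffs.shape[0]

    def significant(self, alpha: float = 0.05, corrected: bool = True) -> np.ndarray:
        """Boolean rejection mask (FDR-adjusted for nodal results when available)."""
        p = self.fdr_adjusted_p if (corrected and self.fdr_adjusted_p is not None) else self.p_two
        return np.atleast_1d(np.asarray(p) < alpha)


def fdr_bh(p: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR: adjusted p-values and rejections at level q.

    Adjusted values are monotone-enforced; the rejection mask is equivalent
    to the classic step-up rule at level q.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p must be a nonempty 1-D vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    reject, adjusted, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject


def summarize_permutation(
    name: str,
    observed: Union[float, np.ndarray],
    null: np.ndarray,
    nodal: bool,
    warnings: tuple[str, ...] = (),
    param: object = None,
    q: float = 0.05,
) -> ComparisonResult:
    """Turn an observed difference and its permutation null into a result.

    Used directly by workflows that share one set of permutations across
    many measures and then summarise each slice separately; ``nodal``
    selects BH-FDR correction across the vector's entries.
    """
    M = null.shape[0]
    obs = np.asarray(observed, dtype=float)
    ge_abs = (np.abs(null) >= np.abs(obs)).sum(axis=0)
    p_two = (ge_abs + 1) / (M + 1)
    raw_p_two = ge_abs / M
    # one-tailed in the direction of the observed difference
    signed = np.where(obs >= 0, (null >= obs).sum(axis=0), (null <= obs).sum(axis=0))
    p_one = (signed + 1) / (M + 1)
    ci_low = np.percentile(null, 2.5, axis=0)
    ci_high = np.percentile(null, 97.5, axis=0)
    fdr = None
    if nodal:
        fdr, _ = fdr_bh(np.atleast_1d(p_two), q=q)
    if not nodal:
        obs = float(obs)
        p_one, p_two, raw_p_two = float(p_one), float(p_two), float(raw_p_two)
        ci_low, ci_high = float(ci_low), float(ci_high)
    return ComparisonResult(
        name=name,
        observed_diff=obs,
        null_diffs=null,
        p_one=p_one,
        p_two=p_two,
        raw_p_two=raw_p_two,
        ci_low=ci_low,
        ci_high=ci_high,
        fdr_adjusted_p=fdr,
        param=param,
        warnings=warnings,
    )


def permutation_null(
    values_a: np.ndarray,
    values_b: np.ndarray,
    statistic: Statistic,
    n_permutations: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed difference and raw permutation null, without summarising.

    Returns ``(observed, null)`` with ``null`` of shape (M, *observed.shape).
    Lets a caller evaluate one (possibly concatenated) statistic under a
    single stream of label permutations and slice the result per measure.
    """
    A = np.asarray(values_a, dtype=float)
    B = np.asarray(values_b, dtype=float)
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValidationError("both groups must be nonempty")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([A, B], axis=0)
    nA = A.shape[0]
    n = pooled.shape[0]
    observed = np.asarray(statistic(B), dtype=float) - np.asarray(statistic(A), dtype=float)
    null = np.empty((n_permutations,) + observed.shape)
    for i in range(n_permutations):
        idx = rng.permutation(n)
        null[i] = np.asarray(statistic(pooled[idx[nA:]]), dtype=float) - np.asarray(
            statistic(pooled[idx[:nA]]), dtype=float
        )
    return observed, null


def permutation_compare(
    values_a: np.ndarray,
    values_b: np.ndarray,
    statistic: Statistic,
    n_permutations: int = 1000,
    seed: int = 0,
    name: str = "measure",
    param: object = None,
    q: float = 0.05,
) -> ComparisonResult:
    """Two-group permutation test of statistic(B) - statistic(A).

    ``values_a`` / ``values_b`` hold one row (leading axis) per subject —
    raw regional data when the statistic rebuilds the whole pipeline
    (structural mode) or precomputed per-subject measures (functional
    mode). ``statistic`` maps a group's stacked rows to a scalar or nodal
    vector. Group labels are permuted M times preserving group sizes.
    """
    A = np.asarray(values_a, dtype=float)
    B = np.asarray(values_b, dtype=float)
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValidationError("both groups must be nonempty")
    if n_permutations < 1:
        raise ValidationError("need at least one permutation")
    warnings = ()
    if n_permutations < 40:
        warnings = (
            f"M={n_permutations} is too small for stable 95% interval bounds (< 40)",
        )
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([A, B], axis=0)
    nA = A.shape[0]
    n = pooled.shape[0]

    observed = np.asarray(statistic(B), dtype=float) - np.asarray(statistic(A), dtype=float)
    nodal = observed.ndim > 0 and observed.size > 1

    null = np.empty((n_permutations,) + observed.shape)
    for i in range(n_permutations):
        idx = rng.permutation(n)
        pa = pooled[idx[:nA]]
        pb = pooled[idx[nA:]]
        null[i] = np.asarray(statistic(pb), dtype=float) - np.asarray(statistic(pa), dtype=float)
    return summarize_permutation(name, observed, null, nodal, warnings, param, q)


def permutation_compare_longitudinal(
    values_t1: np.ndarray,
    values_t2: np.ndarray,
    statistic: Statistic,
    n_permutations: int = 1000,
    seed: int = 0,
    name: str = "measure",
    param: object = None,
    q: float = 0.05,
) -> ComparisonResult:
    """Paired permutation test of statistic(t2) - statistic(t1).

    Rows of ``values_t1`` and ``values_t2`` are aligned by subject; each
    permutation independently swaps (or not) each subject's pair of
    timepoints, so permuted groups always contain exactly one observation
    per subject.
    """
    T1 = np.asarray(values_t1, dtype=float)
    T2 = np.asarray(values_t2, dtype=float)
    if T1.shape != T2.shape:
        raise ValidationError(
            f"paired designs need matching shapes per timepoint, got {T1.shape} vs {T2.shape}"
        )
    if T1.shape[0] == 0:
        raise ValidationError("no paired subjects")
    warnings = ()
    if n_permutations < 40:
        warnings = (
            f"M={n_permutations} is too small for stable 95% interval bounds (< 40)",
        )
    rng = np.random.default_rng(seed)
    n = T1.shape[0]

    observed = np.asarray(statistic(T2), dtype=float) - np.asarray(statistic(T1), dtype=float)
    nodal = observed.ndim > 0 and observed.size > 1

    null = np.empty((n_permutations,) + observed.shape)
    for i in range(n_permutations):
        flip = rng.random(n) < 0.5
        p1 = np.where(flip[(...,) + (None,) * (T1.ndim - 1)], T2, T1)
        p2 = np.where(flip[(...,) + (None,) * (T1.ndim - 1)], T1, T2)
        null[i] = np.asarray(statistic(p2), dtype=float) - np.asarray(statistic(p1), dtype=float)
    return summarize_permutation(name, observed, null, nodal, warnings, param, q)
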