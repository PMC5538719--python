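"""Association (connectivity) matrices between brain regions.

Edges are statistical associations between regional values: across subjects
for structural data (one group-level matrix per group) or across timepoints
for functional data (one matrix per subject). Supported coefficients are
Pearson, Spearman, Kendall tau-b, and Pearson/Spearman partial correlation;
the diagonal is always zeroed (self-connections are removed), and a
negative-weight rule (keep | abs | zero) is applied afterwards.

Partial correlation for entry (j, k) conditions on all remaining regions,
computed from the inverse correlation matrix (equivalent to correlating the
OLS residuals of j and k on the others); this requires more observations
than regions, enforced with a clear error.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .atlas import BrainAtlas
from .cohort import Cohort, Subject
from .exceptions import (
    ConfigError,
    RankDeficiencyError,
    UndefinedCorrelationError,
    ValidationError,
)

__all__ = [
    "AssociationSpec",
    "ConnectivityMatrix",
    "correlate",
    "partial_correlate",
    "association_matrix",
    "build_group_matrix",
    "build_subject_matrix",
    "save_matrix",
    "load_matrix",
]

_METHODS = ("pearson", "spearman", "kendall", "partial_pearson", "partial_spearman")
_RULES = ("keep", "abs", "zero")


@dataclass(frozen=True)
class AssociationSpec:
    """Correlation method plus the rule for negative coefficients."""

    method: str = "pearson"
    negative_rule: str = "zero"

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ConfigError(f"unknown correlation method {self.method!r}; choose from {_METHODS}")
        if self.negative_rule == "stransform":
            raise ConfigError(
                "the 's-transform' negative rule has no published definition and is "
                "not implemented; use keep, abs, or zero"
            )
        if self.negative_rule not in _RULES:
            raise ConfigError(f"unknown negative rule {self.negative_rule!r}; choose from {_RULES}")


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Square symmetric association matrix with zero diagonal.

    ``provenance`` records whether this is a group-level matrix (structural
    analysis) or a single subject's matrix (functional analysis).
    """

    values: np.ndarray
    atlas: BrainAtlas
    provenance: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError(f"connectivity matrix must be square, got {v.shape}")
        if v.shape[0] != len(self.atlas):
            raise ValidationError(
                f"matrix size {v.shape[0]} does not match atlas size {len(self.atlas)}"
            )
        if not np.all(np.isfinite(v)):
            raise ValidationError("connectivity matrix contains non-finite entries")
        if np.any(np.diag(v) != 0):
            raise ValidationError("connectivity matrix diagonal must be zero")


def _check_variance(X: np.ndarray, labels: Sequence[str] | None = None) -> None:
    """Raise naming the offending column if any column is constant."""
    flat = np.ptp(X, axis=0) == 0
    if np.any(flat):
        idx = int(np.flatnonzero(flat)[0])
        name = labels[idx] if labels is not None else f"column {idx}"
        raise UndefinedCorrelationError(
            f"correlation undefined: {name} has zero variance (constant values)"
        )


def correlate(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> float:
    """Correlation coefficient between two vectors (non-partial methods).

    Kendall is the tie-corrected tau-b variant. Zero variance in either
    input raises :class:`UndefinedCorrelationError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"x and y must be equal-length vectors, got {x.shape}, {y.shape}")
    if x.size < 3:
        raise ValidationError("need n >= 3 observations")
    if method not in ("pearson", "spearman", "kendall"):
        raise ConfigError(f"correlate() supports non-partial methods, not {method!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for zero-variance input")
    if method == "pearson":
        r = sps.pearsonr(x, y).statistic
    elif method == "spearman":
        r = sps.spearmanr(x, y).statistic
    else:
        r = sps.kendalltau(x, y, variant="b").statistic
    return float(r)


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    n = v.shape[0]
    X = np.column_stack([np.ones(n), Z]) if Z.size else np.ones((n, 1))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError("control matrix Z is rank deficient")
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def partial_correlate(
    x: np.ndarray, y: np.ndarray, Z: np.ndarray | None, method: str = "pearson"
) -> float:
    """Partial correlation of x and y controlling for the columns of Z.

    Computed as the plain correlation between the OLS residuals of x and y
    on intercept + Z; for ``spearman`` the inputs are rank-transformed first.
    With Z empty this reduces exactly to :func:`correlate`.
    """
    if method not in ("pearson", "spearman"):
        raise ConfigError(f"partial correlation supports pearson|spearman, not {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.empty((x.shape[0], 0)) if Z is None else np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != x.shape[0]:
        Z = Z.T
    if Z.shape[1] == 0:
        return correlate(x, y, method)
    if x.shape[0] <= Z.shape[1] + 2:
        raise ValidationError(
            f"need n > #controls + 2 observations (n={x.shape[0]}, controls={Z.shape[1]})"
        )
    if method == "spearman":
        x, y = sps.rankdata(x), sps.rankdata(y)
        Z = np.column_stack([sps.rankdata(col) for col in Z.T])
    rx = _residualize(x, Z)
    ry = _residualize(y, Z)
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise UndefinedCorrelationError(
            "partial correlation undefined: residuals have zero variance "
            "(input collinear with controls)"
        )
    return float(sps.pearsonr(rx, ry).statistic)


def _rank_columns(X: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sps.rankdata, 0, X)


def _corr_matrix(X: np.ndarray, method: str, labels: Sequence[str] | None) -> np.ndarray:
    """Full R x R association matrix of the columns of X (n x R)."""
    n, R = X.shape
    _check_variance(X, labels)
    if method == "pearson":
        C = np.corrcoef(X, rowvar=False)
    elif method == "spearman":
        C = np.corrcoef(_rank_columns(X), rowvar=False)
    elif method == "kendall":
        C = np.eye(R)
        for j in range(R):
            for k in range(j + 1, R):
                C[j, k] = C[k, j] = sps.kendalltau(X[:, j], X[:, k], variant="b").statistic
    elif method in ("partial_pearson", "partial_spearman"):
        if n <= R + 2:
            raise ValidationError(
                f"partial correlation over all remaining regions needs n > R + 2 "
                f"(n={n}, R={R}); use a plain correlation or more observations"
            )
        Xm = _rank_columns(X) if method == "partial_spearman" else X
        S = np.corrcoef(Xm, rowvar=False)
        try:
            P = np.linalg.inv(S)
        except np.linalg.LinAlgError:
            raise RankDeficiencyError("correlation matrix singular; partial correlation undefined")
        d = np.sqrt(np.diag(P))
        C = -P / np.outer(d, d)
        np.fill_diagonal(C, 1.0)
    else:  # pragma: no cover - guarded by AssociationSpec
        raise ConfigError(f"unknown method {method!r}")
    C = (C + C.T) / 2.0  # enforce exact symmetry against fp asymmetry
    np.fill_diagonal(C, 0.0)
    return np.clip(C, -1.0, 1.0)


def _apply_negative_rule(C: np.ndarray, rule: str) -> np.ndarray:
    if rule == "keep":
        return C
    if rule == "abs":
        return np.abs(C)
    if rule == "zero":
        return np.where(C < 0, 0.0, C)
    raise ConfigError(f"unknown negative rule {rule!r}")


def association_matrix(
    X: np.ndarray, spec: AssociationSpec, labels: Sequence[str] | None = None
) -> np.ndarray:
    """R x R association matrix of the columns of ``X`` (observations x regions).

    The raw-array workhorse behind the group and subject builders — also
    used by permutation tests that rebuild the matrix for every relabelling.
    Diagonal zeroed, negative rule applied.
    """
    X = np.asarray(X, dtype=float)
    C = _corr_matrix(X, spec.method, labels)
    return _apply_negative_rule(C, spec.negative_rule)


def build_group_matrix(cohort: Cohort, group: str, spec: AssociationSpec) -> ConnectivityMatrix:
    """Group-level matrix for a structural cohort: associations across subjects.

    Entry (j, k) is the association, across the group's subjects, between
    region j's and region k's values.
    """
    if cohort.mode != "structural":
        raise ValidationError("group-level matrices are computed from structural cohorts")
    X = cohort.group_data(group)  # (n_subjects, R)
    if X.shape[0] < 3:
        raise ValidationError(f"group {group!r} needs >= 3 subjects, has {X.shape[0]}")
    C = _corr_matrix(X, spec.method, [f"region {lab!r}" for lab in cohort.atlas.labels])
    C = _apply_negative_rule(C, spec.negative_rule)
    return ConnectivityMatrix(values=C, atlas=cohort.atlas, provenance=f"group:{group}")


def build_subject_matrix(
    subject: Subject, atlas: BrainAtlas, spec: AssociationSpec
) -> ConnectivityMatrix:
    """Subject-level matrix for functional data: associations across timepoints."""
    ts = subject.data
    if ts.ndim != 2:
        raise ValidationError(f"subject {subject.id!r} has no time-series data")
    if ts.shape[0] < 3:
        raise ValidationError(f"subject {subject.id!r}: need T >= 3 timepoints")
    C = _corr_matrix(ts, spec.method, [f"region {lab!r}" for lab in atlas.labels])
    C = _apply_negative_rule(C, spec.negative_rule)
    return ConnectivityMatrix(values=C, atlas=atlas, provenance=f"subject:{subject.id}")


def save_matrix(m: ConnectivityMatrix, path: str | Path) -> Path:
    """Dense CSV with atlas labels as header row and index column."""
    path = Path(path)
    labels = list(m.atlas.labels)
    pd.DataFrame(m.values, index=labels, columns=labels).to_csv(path)
    return path


def load_matrix(path: str | Path, atlas: BrainAtlas, provenance: str = "file") -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.columns) != list(atlas.labels):
        raise ValidationError("matrix CSV columns do not match atlas labels")
    return ConnectivityMatrix(values=df.to_numpy(dtype=float), atlas=atlas, provenance=provenance)
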