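"""Subject cohorts: regional data, group structure, and nuisance regression.

Two acquisition modes are supported:

* ``structural`` — one scalar per region per subject (cortical thickness,
  volume, glucose metabolism, ...): the subject's data is a length-R vector.
* ``functional`` — a regional time series per subject (resting-state BOLD,
  electrophysiology, ...): the subject's data is a T x R matrix.

Cohort files are plain text. Structural mode is a single CSV with columns
``id, group, <covariates...>, <region labels...>`` — region columns are
recognised by matching atlas labels, everything else between ``group`` and
the regions is treated as a numeric covariate. Functional mode is a manifest
CSV (``id, group, path, <covariates...>``) pointing at one whitespace- or
comma-delimited T x R file per subject.

Non-finite values are hard errors everywhere: a single NaN silently
propagates through a correlation matrix, so it is rejected at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import BrainAtlas
from .exceptions import (
    DimensionError,
    ParseError,
    RankDeficiencyError,
    ValidationError,
)

__all__ = ["Subject", "Cohort", "load_cohort", "save_cohort", "regress_nuisance"]

Mode = Literal["structural", "functional"]


@dataclass(frozen=True)
class Subject:
    """One subject: unique ``id``, regional ``data``, named scalar covariates."""

    id: str
    data: np.ndarray  # (R,) structural or (T, R) functional
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", arr)
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"subject {self.id!r}: non-finite values in data")
        for k, v in self.covariates.items():
            if not np.isfinite(v):
                raise ValidationError(f"subject {self.id!r}: covariate {k!r} non-finite")


@dataclass(frozen=True)
class Cohort:
    """Named groups of subjects sharing an atlas and an acquisition mode.

    Groups may overlap (a subject can appear in several groups); subject
    order inside a group is load order and is stable.
    """

    atlas: BrainAtlas
    mode: Mode
    groups: Mapping[str, tuple[Subject, ...]]

    def __post_init__(self) -> None:
        if self.mode not in ("structural", "functional"):
            raise ValidationError(f"unknown cohort mode {self.mode!r}")
        groups = {name: tuple(subs) for name, subs in self.groups.items()}
        object.__setattr__(self, "groups", groups)
        R = len(self.atlas)
        for name, subs in groups.items():
            for s in subs:
                if self.mode == "structural":
                    if s.data.ndim != 1 or s.data.shape[0] != R:
                        raise DimensionError(
                            f"subject {s.id!r} in group {name!r}: expected {R} regional "
                            f"values, got shape {s.data.shape}"
                        )
                else:
                    if s.data.ndim != 2 or s.data.shape[1] != R:
                        raise DimensionError(
                            f"subject {s.id!r} in group {name!r}: expected a T x {R} "
                            f"time series, got shape {s.data.shape}"
                        )
                    if s.data.shape[0] < 3:
                        raise ValidationError(
                            f"subject {s.id!r}: functional mode needs T >= 3 timepoints"
                        )

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(self.groups.keys())

    def group(self, name: str) -> tuple[Subject, ...]:
        try:
            return self.groups[name]
        except KeyError:
            raise KeyError(f"no group {name!r}; have {list(self.groups)}") from None

    def group_data(self, name: str) -> np.ndarray:
        """Stack a group's data: (n_subjects, R) structural, (n, T, R) functional."""
        subs = self.group(name)
        if not subs:
            raise ValidationError(f"group {name!r} is empty")
        return np.stack([s.data for s in subs])

    def subjects(self) -> tuple[Subject, ...]:
        """All distinct subjects in load order (first occurrence wins)."""
        seen: dict[str, Subject] = {}
        for subs in self.groups.values():
            for s in subs:
                seen.setdefault(s.id, s)
        return tuple(seen.values())


def load_cohort(path: str | Path, atlas: BrainAtlas, mode: Mode) -> Cohort:
    """Load a cohort file against ``atlas``.

    Structural: one CSV, one row per subject. Functional: a manifest CSV with
    a ``path`` column naming each subject's T x R time-series file (relative
    paths resolve against the manifest's directory).
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, dtype={"id": str, "group": str})
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path.name}: {exc}") from None
    for col in ("id", "group"):
        if col not in table.columns:
            raise ParseError(f"{path.name}: missing required column {col!r}")

    labels = list(atlas.labels)
    if mode == "structural":
        missing = [lab for lab in labels if lab not in table.columns]
        if missing:
            raise DimensionError(
                f"{path.name}: region columns missing for atlas labels {missing[:5]}"
                f"{'...' if len(missing) > 5 else ''}"
            )
        cov_cols = [c for c in table.columns if c not in ("id", "group", *labels)]
        groups: dict[str, list[Subject]] = {}
        for idx, row in table.iterrows():
            try:
                data = row[labels].to_numpy(dtype=float)
                covs = {c: float(row[c]) for c in cov_cols}
            except (TypeError, ValueError) as exc:
                raise ParseError(f"{path.name}: subject {row['id']!r}: {exc}") from None
            subj = Subject(id=str(row["id"]), data=data, covariates=covs)
            groups.setdefault(str(row["group"]), []).append(subj)
        return Cohort(atlas=atlas, mode="structural", groups=groups)

    if mode == "functional":
        if "path" not in table.columns:
            raise ParseError(f"{path.name}: functional manifest needs a 'path' column")
        cov_cols = [c for c in table.columns if c not in ("id", "group", "path")]
        groups = {}
        for _, row in table.iterrows():
            ts_path = Path(row["path"])
            if not ts_path.is_absolute():
                ts_path = path.parent / ts_path
            try:
                ts = np.loadtxt(ts_path, delimiter=None if "\t" in ts_path.read_text()[:200] else ",")
            except Exception as exc:
                raise ParseError(f"{ts_path.name}: {exc}") from None
            ts = np.atleast_2d(ts)
            if ts.shape[1] != len(labels):
                raise DimensionError(
                    f"subject {row['id']!r}: time series has {ts.shape[1]} columns, "
                    f"atlas has {len(labels)} regions"
                )
            covs = {c: float(row[c]) for c in cov_cols}
            subj = Subject(id=str(row["id"]), data=ts, covariates=covs)
            groups.setdefault(str(row["group"]), []).append(subj)
        return Cohort(atlas=atlas, mode="functional", groups=groups)

    raise ValidationError(f"unknown cohort mode {mode!r}")


def save_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a structural cohort as CSV, or a functional one as manifest + per-subject files."""
    path = Path(path)
    labels = list(cohort.atlas.labels)
    if cohort.mode == "structural":
        rows = []
        for gname, subs in cohort.groups.items():
            for s in subs:
                row = {"id": s.id, "group": gname, **s.covariates}
                row.update(dict(zip(labels, s.data)))
                rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)
        return path
    ts_dir = path.parent / (path.stem + "_timeseries")
    ts_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for gname, subs in cohort.groups.items():
        for s in subs:
            fname = ts_dir / f"{s.id}.tsv"
            np.savetxt(fname, s.data, delimiter="\t")
            rows.append(
                {"id": s.id, "group": gname, "path": str(fname.relative_to(path.parent)), **s.covariates}
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def regress_nuisance(cohort: Cohort, covariate_names: Sequence[str]) -> Cohort:
    """Replace each region's values by OLS residuals on intercept + covariates.

    Nuisance correction for structural cohorts: for every region, the values
    across *all* subjects are regressed on the named covariates (age, gender
    code, scanner site, ...) and the residuals substitute the raw values.
    The design is fit once across the union of subjects so that group
    membership does not leak into the correction.
    """
    if cohort.mode != "structural":
        raise ValidationError("nuisance regression is defined for structural cohorts only")
    covariate_names = list(covariate_names)
    subjects = cohort.subjects()
    n = len(subjects)
    if n <= len(covariate_names) + 1:
        raise ValidationError(
            f"need more subjects ({n}) than covariates+1 ({len(covariate_names) + 1})"
        )
    for s in subjects:
        for c in covariate_names:
            if c not in s.covariates:
                raise ValidationError(f"subject {s.id!r} lacks covariate {c!r}")

    X = np.column_stack(
        [np.ones(n)] + [[s.covariates[c] for s in subjects] for c in covariate_names]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError(
            f"design matrix rank-deficient for covariates {covariate_names} "
            "(constant or collinear covariate?)"
        )
    Y = np.stack([s.data for s in subjects])  # (n, R)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta

    by_id = {s.id: resid[i] for i, s in enumerate(subjects)}
    new_groups = {
        gname: tuple(replace(s, data=by_id[s.id]) for s in subs)
        for gname, subs in cohort.groups.items()
    }
    return Cohort(atlas=cohort.atlas, mode="structural", groups=new_groups)
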