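"""Synthetic cohorts with controllable group effects and modular block structure.

No public brain-imaging cohort is needed to exercise the pipeline: this
module simulates the two data kinds the loaders accept.

Structural mode draws each subject's length-R regional vector from a
multivariate normal whose correlation structure is a block model: regions
in the same block share a latent factor (within-block correlation
``within_corr``), all regions share a weak global factor (``between_corr``).
A group ``effect`` adds a mean shift to chosen regions, and
``coupling_scale`` < 1 weakens a group's block couplings — the effect that
shows up in correlation-based networks.

Functional mode simulates each subject's T x R time series from the same
latent block-factor construction applied over timepoints, yielding planted
modules in every subject's connectivity matrix; ``coupling_scale`` < 1 for
a group globally weakens its couplings, lowering connectivity degrees.

Synthetic atlases place regions on a deterministic 3-D grid; coordinates
carry no meaning beyond exercising the I/O paths.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .atlas import BrainAtlas, RegionDef
from .cohort import Cohort, Subject, save_cohort
from .exceptions import ValidationError

__all__ = [
    "synthetic_atlas",
    "block_assignment",
    "generate_structural_cohort",
    "generate_functional_cohort",
    "generate_fixture_cohort",
]


def synthetic_atlas(R: int) -> BrainAtlas:
    """Deterministic R-region atlas with grid coordinates (synthetic labels r01..)."""
    width = len(str(R))
    regions = [
        RegionDef(
            label=f"r{i + 1:0{width}d}",
            name=f"synthetic region {i + 1}",
            coord=(float(i % 10), float((i // 10) % 10), float(i // 100)),
        )
        for i in range(R)
    ]
    return BrainAtlas(regions)


def block_assignment(R: int, n_blocks: int) -> np.ndarray:
    """Contiguous, near-equal block ids 1..n_blocks over R regions."""
    if n_blocks < 1 or n_blocks > R:
        raise ValidationError(f"need 1 <= n_blocks <= R, got {n_blocks} blocks for R={R}")
    return np.repeat(np.arange(1, n_blocks + 1), np.diff(np.linspace(0, R, n_blocks + 1).astype(int)))


def _block_sample(
    rng: np.random.Generator,
    n_draws: int,
    blocks: np.ndarray,
    within_corr: float,
    between_corr: float,
    coupling_scale: float,
) -> np.ndarray:
    """(n_draws, R) samples with block-factor correlation structure.

    x = sqrt(b)*g + sqrt(w)*f_block + sqrt(1 - b - w)*noise with loadings
    scaled by ``coupling_scale``; the implied correlation matrix is positive
    definite by construction whenever b + w < 1.
    """
    w = within_corr * coupling_scale
    b = between_corr * coupling_scale
    if w < 0 or b < 0 or w + b >= 1:
        raise ValidationError(
            f"infeasible correlation structure: within={w:.3f} + between={b:.3f} must be in [0, 1)"
        )
    R = blocks.shape[0]
    global_f = rng.standard_normal((n_draws, 1))
    block_f = rng.standard_normal((n_draws, int(blocks.max())))
    noise = rng.standard_normal((n_draws, R))
    return (
        np.sqrt(b) * global_f
        + np.sqrt(w) * block_f[:, blocks - 1]
        + np.sqrt(1.0 - w - b) * noise
    )


def generate_structural_cohort(
    R: int = 20,
    n_per_group: int = 20,
    groups: Sequence[str] = ("A", "B"),
    effect: float = 0.0,
    effect_regions: Sequence[int] | None = None,
    module_blocks: int = 2,
    within_corr: float = 0.5,
    between_corr: float = 0.1,
    coupling_scale: Mapping[str, float] | None = None,
    covariates: bool = True,
    seed: int = 0,
) -> Cohort:
    """Structural cohort: one regional vector per subject, MVN block structure.

    ``effect`` shifts the mean of ``effect_regions`` (default: first block)
    in every group after the first; ``coupling_scale[group]`` < 1 weakens
    that group's correlation structure. With effect 0 and no scaling the
    groups are exchangeable by construction.
    """
    rng = np.random.default_rng(seed)
    atlas = synthetic_atlas(R)
    blocks = block_assignment(R, module_blocks)
    if effect_regions is None:
        effect_regions = np.flatnonzero(blocks == 1)
    scale = dict(coupling_scale or {})
    grp: dict[str, list[Subject]] = {}
    for gi, gname in enumerate(groups):
        X = _block_sample(
            rng, n_per_group, blocks, within_corr, between_corr, scale.get(gname, 1.0)
        )
        if gi > 0 and effect != 0.0:
            X[:, list(effect_regions)] += effect
        subs = []
        for si in range(n_per_group):
            cov = (
                {"age": float(rng.uniform(55, 85)), "sex": float(rng.integers(0, 2))}
                if covariates
                else {}
            )
            subs.append(Subject(id=f"{gname}{si + 1:03d}", data=X[si], covariates=cov))
        grp[gname] = subs
    return Cohort(atlas=atlas, mode="structural", groups=grp)


def generate_functional_cohort(
    R: int = 30,
    n_per_group: int = 15,
    T: int = 150,
    groups: Sequence[str] = ("A", "B"),
    module_blocks: int = 3,
    within_corr: float = 0.45,
    between_corr: float = 0.08,
    coupling_scale: Mapping[str, float] | None = None,
    covariates: bool = True,
    seed: int = 0,
) -> Cohort:
    """Functional cohort: T x R time series per subject with planted modules.

    Every subject's series comes from the latent block-factor model, so each
    subject-level correlation matrix carries the same planted modular
    structure; ``coupling_scale[group]`` < 1 globally weakens couplings for
    that group (lower correlations, hence lower degrees/strengths).
    """
    rng = np.random.default_rng(seed)
    atlas = synthetic_atlas(R)
    blocks = block_assignment(R, module_blocks)
    scale = dict(coupling_scale or {})
    grp: dict[str, list[Subject]] = {}
    for gname in groups:
        subs = []
        for si in range(n_per_group):
            ts = _block_sample(rng, T, blocks, within_corr, between_corr, scale.get(gname, 1.0))
            cov = (
                {"age": float(rng.uniform(55, 85)), "sex": float(rng.integers(0, 2))}
                if covariates
                else {}
            )
            subs.append(Subject(id=f"{gname}{si + 1:03d}", data=ts, covariates=cov))
        grp[gname] = subs
    return Cohort(atlas=atlas, mode="functional", groups=grp)


def generate_fixture_cohort(spec: Mapping, out_dir: str | Path) -> Path:
    """Generate a cohort from a parameter dict and write loader-ready files.

    ``spec`` keys: mode (structural|functional), R, n_per_group, T
    (functional), effect, module_blocks, coupling_scale, seed. Returns the
    path of the cohort CSV (structural) or manifest CSV (functional); the
    atlas is written alongside as ``atlas.txt``. Fixed seeds give
    byte-identical files.
    """
    from .atlas import save_atlas

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mode = spec.get("mode", "structural")
    common = dict(
        R=int(spec.get("R", 20)),
        n_per_group=int(spec.get("n_per_group", 20)),
        module_blocks=int(spec.get("module_blocks", 2 if mode == "structural" else 3)),
        coupling_scale=spec.get("coupling_scale"),
        seed=int(spec.get("seed", 0)),
    )
    if mode == "structural":
        cohort = generate_structural_cohort(
            effect=float(spec.get("effect", 0.0)),
            effect_regions=spec.get("effect_regions"),
            **common,
        )
        path = out_dir / "cohort.csv"
    elif mode == "functional":
        cohort = generate_functional_cohort(T=int(spec.get("T", 150)), **common)
        path = out_dir / "manifest.csv"
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    save_atlas(cohort.atlas, out_dir / "atlas.txt")
    save_cohort(cohort, path)
    return path
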