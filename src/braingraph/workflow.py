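"""End-to-end analyses: fit a cohort, get a results object, archive it.

Two reusable recipes, exposed in a Model/Results style (construct the
analysis from data and a config, call :meth:`fit`, inspect or archive the
returned results object):

* :class:`StructuralNetworkAnalysis` — group-level correlation matrices
  (default Pearson, negatives zeroed), binarized at a grid of densities
  (default 5%..25% in 0.5% steps, 41 levels), all configured global and
  nodal measures per group and density, and permutation comparisons between
  every group pair with percentile bands and nodal FDR. Because structural
  matrices are group-level objects, every permutation rebuilds the whole
  matrix -> graph -> measure pipeline from the relabelled subjects.

* :class:`FunctionalNetworkAnalysis` — one weighted undirected graph per
  subject, per-subject nodal degree and strength averaged per group, a
  permutation comparison of the average degree, a seeded modularity
  partition per group (matched across groups by maximum node overlap),
  per-module average-degree comparisons, and nodal comparisons within each
  module with FDR.

Results archive to a directory of CSVs plus the full config and a log —
auditable, and regenerable from the config alone.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .community import Partition, match_modules, modularity_partition
from .connectivity import AssociationSpec, association_matrix, build_subject_matrix
from .exceptions import ConfigError, ValidationError
from .graph import Graph, GraphParam, binarize_density, binarize_threshold, from_connectivity
from .measures import GLOBAL_MEASURES, NODAL_MEASURES, degree, strength
from .stats import permutation_null, summarize_permutation

__all__ = [
    "AnalysisConfig",
    "StructuralNetworkAnalysis",
    "StructuralResults",
    "FunctionalNetworkAnalysis",
    "FunctionalResults",
    "load_archive",
    "default_density_grid",
]


def default_density_grid() -> tuple[float, ...]:
    """Density grid 0.05 .. 0.25 in steps of 0.005 (41 levels)."""
    return tuple(np.round(np.arange(0.05, 0.2501, 0.005), 3))


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything needed to reproduce an analysis, with recipe defaults.

    ``densities`` drives BUD binarization for structural analyses (set
    ``thresholds`` instead for BUT). ``n_permutations`` defaults to 1000;
    raise to 10000 for publication-grade p-values.
    """

    method: str = "pearson"
    negative_rule: str = "zero"
    densities: tuple[float, ...] = field(default_factory=default_density_grid)
    thresholds: Optional[tuple[float, ...]] = None
    global_measures: tuple[str, ...] = (
        "char_path_length",
        "global_efficiency",
        "local_efficiency",
        "clustering",
        "transitivity",
    )
    nodal_measures: tuple[str, ...] = ("degree", "local_efficiency")
    n_permutations: int = 1000
    q: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        AssociationSpec(self.method, self.negative_rule)  # validates both
        if self.thresholds is None:
            if not self.densities:
                raise ConfigError("density grid is empty")
            if any(not (0.0 < d <= 1.0) for d in self.densities):
                raise ConfigError(f"densities must lie in (0, 1], got {self.densities}")
        unknown = [m for m in self.global_measures if m not in GLOBAL_MEASURES]
        unknown += [m for m in self.nodal_measures if m not in NODAL_MEASURES]
        if unknown:
            raise ConfigError(f"unknown measures {unknown}")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")

    @property
    def spec(self) -> AssociationSpec:
        return AssociationSpec(self.method, self.negative_rule)

    @property
    def params(self) -> tuple[GraphParam, ...]:
        if self.thresholds is not None:
            return tuple(GraphParam("threshold", t) for t in self.thresholds)
        return tuple(GraphParam("density", d) for d in self.densities)


def _binarized(wu: Graph, param: GraphParam) -> Graph:
    if param.kind == "density":
        return binarize_density(wu, param.value)
    return binarize_threshold(wu, param.value)


def _log_entry(stage: str, t0: float) -> str:
    import networkx
    import scipy

    return (
        f"{time.strftime('%Y-%m-%dT%H:%M:%S')} {stage} ({time.time() - t0:.2f}s) "
        f"[python {platform.python_version()}, numpy {np.__version__}, "
        f"scipy {scipy.__version__}, pandas {pd.__version__}, networkx {networkx.__version__}]"
    )


class _ResultsBase:
    """Shared archiving/summary plumbing for results objects."""

    config: AnalysisConfig
    measures: pd.DataFrame
    comparisons: pd.DataFrame
    log: list

    def save(self, out_dir: str | Path) -> Path:
        """Archive to a directory of CSVs + config JSON + log."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg = asdict(self.config)
        (out / "config.json").write_text(json.dumps(cfg, indent=2, default=list) + "\n")
        self.measures.to_csv(out / "measures.csv", index=False)
        self.comparisons.to_csv(out / "comparisons.csv", index=False)
        extra = getattr(self, "partitions_frame", None)
        if extra is not None:
            extra.to_csv(out / "partitions.csv", index=False)
        (out / "log.txt").write_text("\n".join(self.log) + "\n")
        return out

    def summary(self) -> str:
        sig = self.comparisons[self.comparisons["significant"]]
        lines = [
            f"{type(self).__name__}",
            "=" * len(type(self).__name__),
            f"groups: {', '.join(self.group_names)}",
            f"measures table: {len(self.measures)} rows; "
            f"comparisons: {len(self.comparisons)} rows "
            f"({len(sig)} significant at alpha={self.config.q})",
            f"permutations per comparison: {self.config.n_permutations}",
        ]
        if len(sig):
            lines.append("significant comparisons (FDR-corrected where nodal):")
            for _, row in sig.head(25).iterrows():
                lines.append(
                    f"  {row['pair']} {row['measure']} [{row['node']}] "
                    f"param={row['param_value']:g}: diff={row['observed_diff']:+.4f} "
                    f"p={row['p_two']:.4f}"
                )
        return "\n".join(lines)


def load_archive(path: str | Path) -> dict:
    """Load an archived analysis back as {'config': dict, '<table>': DataFrame, ...}."""
    path = Path(path)
    out: dict = {"config": json.loads((path / "config.json").read_text())}
    for csv in path.glob("*.csv"):
        out[csv.stem] = pd.read_csv(csv)
    return out


class StructuralNetworkAnalysis:
    """Group-level correlation-network analysis of a structural cohort."""

    def __init__(
        self,
        cohort: Cohort,
        config: AnalysisConfig | None = None,
        groups: Sequence[str] | None = None,
    ) -> None:
        if cohort.mode != "structural":
            raise ValidationError("StructuralNetworkAnalysis needs a structural cohort")
        self.cohort = cohort
        self.config = config or AnalysisConfig()
        self.groups = tuple(groups) if groups else cohort.group_names
        if len(self.groups) < 2:
            raise ValidationError("need at least two groups to compare")

    # -- pipeline pieces ------------------------------------------------
    def _group_graphs(self, X: np.ndarray) -> list[Graph]:
        """Raw subject-by-region data -> WU graph -> one binary graph per param."""
        C = association_matrix(X, self.config.spec, list(self.cohort.atlas.labels))
        wu = Graph(adjacency=C, weighted=True, directed=False, labels=self.cohort.atlas.labels)
        return [_binarized(wu, p) for p in self.config.params]

    def _statistic_vector(self, X: np.ndarray) -> np.ndarray:
        """Concatenated [globals then nodals] x params statistic for permutation reuse."""
        out: list[np.ndarray] = []
        for g in self._group_graphs(X):
            for name in self.config.global_measures:
                out.append(np.atleast_1d(GLOBAL_MEASURES[name](g)))
            for name in self.config.nodal_measures:
                out.append(NODAL_MEASURES[name](g))
        return np.concatenate(out)

    def _slices(self) -> list[tuple[GraphParam, str, str, slice]]:
        R = len(self.cohort.atlas)
        out = []
        pos = 0
        for p in self.config.params:
            for name in self.config.global_measures:
                out.append((p, name, "global", slice(pos, pos + 1)))
                pos += 1
            for name in self.config.nodal_measures:
                out.append((p, name, "nodal", slice(pos, pos + R)))
                pos += R
        return out

    def fit(self) -> "StructuralResults":
        t0 = time.time()
        cfg = self.config
        labels = list(self.cohort.atlas.labels)
        log = [_log_entry(f"fit start (seed={cfg.seed})", t0)]

        mrows = []
        graphs: dict[str, list[Graph]] = {}
        for gname in self.groups:
            X = self.cohort.group_data(gname)
            graphs[gname] = self._group_graphs(X)
            for g in graphs[gname]:
                for name in cfg.global_measures:
                    mrows.append(
                        (gname, g.param.kind, g.param.value, name, "global", "GLOBAL",
                         GLOBAL_MEASURES[name](g))
                    )
                for name in cfg.nodal_measures:
                    for lab, v in zip(labels, NODAL_MEASURES[name](g)):
                        mrows.append((gname, g.param.kind, g.param.value, name, "nodal", lab, float(v)))
        measures = pd.DataFrame(
            mrows, columns=["group", "param_kind", "param_value", "measure", "scope", "node", "value"]
        )
        log.append(_log_entry("group measures", t0))

        crows = []
        slices = self._slices()
        rng = np.random.default_rng(cfg.seed)
        for ga, gb in combinations(self.groups, 2):
            pair_seed = int(rng.integers(0, 2**31 - 1))
            observed, null = permutation_null(
                self.cohort.group_data(ga),
                self.cohort.group_data(gb),
                self._statistic_vector,
                cfg.n_permutations,
                pair_seed,
            )
            for p, name, scope, sl in slices:
                res = summarize_permutation(
                    name, observed[sl] if scope == "nodal" else float(observed[sl][0]),
                    null[:, sl] if scope == "nodal" else null[:, sl][:, 0],
                    nodal=(scope == "nodal"), param=p, q=cfg.q,
                )
                if scope == "global":
                    crows.append(
                        (f"{ga} vs {gb}", p.kind, p.value, name, "GLOBAL", res.observed_diff,
                         res.p_one, res.p_two, res.ci_low, res.ci_high, np.nan,
                         bool(res.p_two < cfg.q))
                    )
                else:
                    for j, lab in enumerate(labels):
                        crows.append(
                            (f"{ga} vs {gb}", p.kind, p.value, name, lab,
                             float(np.asarray(res.observed_diff)[j]),
                             float(np.asarray(res.p_one)[j]), float(np.asarray(res.p_two)[j]),
                             float(np.asarray(res.ci_low)[j]), float(np.asarray(res.ci_high)[j]),
                             float(res.fdr_adjusted_p[j]),
                             bool(res.fdr_adjusted_p[j] < cfg.q))
                        )
            log.append(_log_entry(f"comparison {ga} vs {gb} (M={cfg.n_permutations})", t0))

        comparisons = pd.DataFrame(
            crows,
            columns=["pair", "param_kind", "param_value", "measure", "node", "observed_diff",
                     "p_one", "p_two", "ci_low", "ci_high", "fdr_p", "significant"],
        )
        log.append(_log_entry("fit done", t0))
        return StructuralResults(self, measures, comparisons, graphs, log)


class StructuralResults(_ResultsBase):
    """Measures per group/density and permutation comparisons per group pair."""

    def __init__(self, model, measures, comparisons, graphs, log) -> None:
        self.model = model
        self.config = model.config
        self.group_names = model.groups
        self.measures = measures
        self.comparisons = comparisons
        self.graphs = graphs
        self.log = log

    def global_sweep(self, measure: str, pair: str) -> pd.DataFrame:
        """Difference and percentile band across the density grid for one measure."""
        sel = self.comparisons
        return sel[
            (sel["measure"] == measure) & (sel["pair"] == pair) & (sel["node"] == "GLOBAL")
        ].sort_values("param_value")

    def plot_global_sweep(self, measure: str, pair: str, ax=None):
        """Observed difference vs density with the permutation 95% band."""
        import matplotlib.pyplot as plt

        df = self.global_sweep(measure, pair)
        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(df["param_value"], df["ci_low"], df["ci_high"], alpha=0.3,
                        color="gray", label="permutation 95% band")
        ax.plot(df["param_value"], df["observed_diff"], "o-", color="darkorange",
                label="observed difference")
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xlabel(df["param_kind"].iloc[0])
        ax.set_ylabel(f"difference in {measure}")
        ax.set_title(pair)
        ax.legend()
        return ax


class FunctionalNetworkAnalysis:
    """Subject-level weighted-network analysis of a functional cohort."""

    def __init__(
        self,
        cohort: Cohort,
        config: AnalysisConfig | None = None,
        groups: Sequence[str] | None = None,
    ) -> None:
        if cohort.mode != "functional":
            raise ValidationError("FunctionalNetworkAnalysis needs a functional cohort")
        self.cohort = cohort
        self.config = config or AnalysisConfig()
        self.groups = tuple(groups) if groups else cohort.group_names
        if len(self.groups) < 2:
            raise ValidationError("need at least two groups to compare")

    def fit(self) -> "FunctionalResults":
        t0 = time.time()
        cfg = self.config
        atlas = self.cohort.atlas
        labels = list(atlas.labels)
        R = len(atlas)
        log = [_log_entry(f"fit start (seed={cfg.seed})", t0)]

        # per-subject WU graphs and nodal measures
        nodal_deg: dict[str, np.ndarray] = {}
        nodal_str: dict[str, np.ndarray] = {}
        mean_matrix: dict[str, np.ndarray] = {}
        for gname in self.groups:
            subs = self.cohort.group(gname)
            degs, strs, mats = [], [], []
            for s in subs:
                cm = build_subject_matrix(s, atlas, cfg.spec)
                g = from_connectivity(cm)
                degs.append(degree(g))
                strs.append(strength(g))
                mats.append(cm.values)
            nodal_deg[gname] = np.stack(degs)  # (n_subj, R)
            nodal_str[gname] = np.stack(strs)
            mean_matrix[gname] = np.mean(mats, axis=0)
        log.append(_log_entry("subject matrices", t0))

        mrows = []
        for gname in self.groups:
            for lab, dv, sv in zip(labels, nodal_deg[gname].mean(axis=0),
                                   nodal_str[gname].mean(axis=0)):
                mrows.append((gname, "degree", "nodal", lab, float(dv)))
                mrows.append((gname, "strength", "nodal", lab, float(sv)))
            mrows.append((gname, "average_degree", "global", "GLOBAL",
                          float(nodal_deg[gname].mean(axis=0).mean())))
            mrows.append((gname, "average_strength", "global", "GLOBAL",
                          float(nodal_str[gname].mean(axis=0).mean())))
        measures = pd.DataFrame(mrows, columns=["group", "measure", "scope", "node", "value"])

        # per-group modularity partition on the group-mean WU graph
        partitions: dict[str, Partition] = {}
        for gname in self.groups:
            g_mean = Graph(adjacency=mean_matrix[gname], weighted=True, directed=False,
                           labels=tuple(labels))
            partitions[gname] = modularity_partition(g_mean, seed=cfg.seed)
        ref_group = self.groups[0]
        ref_part = partitions[ref_group]
        module_maps = {
            gname: match_modules(ref_part, partitions[gname]) for gname in self.groups
        }
        log.append(_log_entry("partitions", t0))

        prows = []
        for gname in self.groups:
            for lab, mid in zip(labels, partitions[gname].assignment):
                prows.append((gname, lab, int(mid), partitions[gname].Q))
        partitions_frame = pd.DataFrame(prows, columns=["group", "node", "module", "Q"])

        # comparisons: whole-network average degree/strength, then per module
        crows = []
        rng = np.random.default_rng(cfg.seed)
        for ga, gb in combinations(self.groups, 2):
            for mname, store in (("average_degree", nodal_deg), ("average_strength", nodal_str)):
                observed, null = permutation_null(
                    store[ga].mean(axis=1, keepdims=True),
                    store[gb].mean(axis=1, keepdims=True),
                    lambda v: float(v.mean()),
                    cfg.n_permutations, int(rng.integers(0, 2**31 - 1)),
                )
                res = summarize_permutation(mname, float(observed), null, nodal=False, q=cfg.q)
                crows.append((f"{ga} vs {gb}", mname, "whole", "GLOBAL", res.observed_diff,
                              res.p_one, res.p_two, res.ci_low, res.ci_high, np.nan,
                              bool(res.p_two < cfg.q)))
            # module statistics use the reference partition's node sets so that
            # both groups are measured on the same regions
            for mid in range(1, ref_part.n_modules + 1):
                members = ref_part.members(mid)
                observed, null = permutation_null(
                    nodal_deg[ga][:, members].mean(axis=1, keepdims=True),
                    nodal_deg[gb][:, members].mean(axis=1, keepdims=True),
                    lambda v: float(v.mean()),
                    cfg.n_permutations, int(rng.integers(0, 2**31 - 1)),
                )
                res = summarize_permutation(f"module_{mid}_average_degree", float(observed),
                                            null, nodal=False, q=cfg.q)
                crows.append((f"{ga} vs {gb}", "module_average_degree", f"module {mid}",
                              "GLOBAL", res.observed_diff, res.p_one, res.p_two,
                              res.ci_low, res.ci_high, np.nan, bool(res.p_two < cfg.q)))
                # nodal degree within the module, FDR across the module's nodes
                observed, null = permutation_null(
                    nodal_deg[ga][:, members], nodal_deg[gb][:, members],
                    lambda v: v.mean(axis=0), cfg.n_permutations,
                    int(rng.integers(0, 2**31 - 1)),
                )
                res = summarize_permutation("module_nodal_degree", observed, null,
                                            nodal=True, q=cfg.q)
                for j, node_idx in enumerate(members):
                    crows.append((f"{ga} vs {gb}", "nodal_degree", f"module {mid}",
                                  labels[node_idx],
                                  float(np.asarray(res.observed_diff)[j]),
                                  float(np.asarray(res.p_one)[j]),
                                  float(np.asarray(res.p_two)[j]),
                                  float(np.asarray(res.ci_low)[j]),
                                  float(np.asarray(res.ci_high)[j]),
                                  float(res.fdr_adjusted_p[j]),
                                  bool(res.fdr_adjusted_p[j] < cfg.q)))
            log.append(_log_entry(f"comparison {ga} vs {gb} (M={cfg.n_permutations})", t0))

        comparisons = pd.DataFrame(
            crows,
            columns=["pair", "measure", "param_value", "node", "observed_diff",
                     "p_one", "p_two", "ci_low", "ci_high", "fdr_p", "significant"],
        )
        comparisons.insert(1, "param_kind", "module")
        log.append(_log_entry("fit done", t0))
        return FunctionalResults(self, measures, comparisons, partitions, module_maps,
                                 partitions_frame, log)


class FunctionalResults(_ResultsBase):
    """Per-subject measure summaries, group partitions, and module comparisons."""

    def __init__(self, model, measures, comparisons, partitions, module_maps,
                 partitions_frame, log) -> None:
        self.model = model
        self.config = model.config
        self.group_names = model.groups
        self.measures = measures
        self.comparisons = comparisons
        self.partitions = partitions
        self.module_maps = module_maps
        self.partitions_frame = partitions_frame
        self.log = log

    def average_degree(self, group: str) -> float:
        sel = self.measures
        row = sel[(sel["group"] == group) & (sel["measure"] == "average_degree")]
        return float(row["value"].iloc[0])
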