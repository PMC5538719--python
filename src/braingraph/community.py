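"""Modular structure: Louvain partitions, modularity Q, and module-based nodal roles.

A partition assigns every node to one module (ids 1..M, contiguous). Its
quality is the Newman-Girvan modularity Q — the within-module edge weight in
excess of the degree-matched random expectation:

    Q = (1/2m) * sum_ij [A_ij - k_i k_j / (2m)] * delta(c_i, c_j)

Partitions are found by seeded Louvain maximisation; reruns with the same
seed are bit-reproducible. Two nodal roles characterise hubs relative to a
partition: the within-module degree z-score (provincial hubs) and the
participation coefficient (connector hubs). On weighted graphs all module
statistics use strength in place of degree.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import UndefinedMeasureError, ValidationError
from .graph import Graph
from .measures import degree, strength

__all__ = [
    "Partition",
    "modularity_Q",
    "modularity_partition",
    "within_module_zscore",
    "participation_coefficient",
    "module_average_degree",
    "match_modules",
    "save_partition",
]


@dataclass(frozen=True)
class Partition:
    """Node-to-module assignment (ids 1..M) with its modularity Q."""

    assignment: np.ndarray
    Q: float

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=int)
        object.__setattr__(self, "assignment", a)
        mods = np.unique(a)
        if mods.size == 0 or mods[0] != 1 or not np.array_equal(mods, np.arange(1, mods.size + 1)):
            raise ValidationError("module ids must be contiguous 1..M")
        if not (-1.0 - 1e-12 <= self.Q <= 1.0 + 1e-12):
            raise ValidationError(f"modularity Q={self.Q} outside [-1, 1]")

    @property
    def n_modules(self) -> int:
        return int(self.assignment.max())

    def members(self, module_id: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == module_id)


def _relabel_contiguous(raw: np.ndarray) -> np.ndarray:
    """Map arbitrary module labels to 1..M in order of first appearance."""
    out = np.empty_like(raw)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(raw):
        out[i] = mapping.setdefault(int(lab), len(mapping) + 1)
    return out


def modularity_Q(g: Graph, assignment: np.ndarray) -> float:
    """Newman-Girvan modularity of an assignment (weighted generalisation on WU)."""
    A = g.adjacency
    if g.directed:
        raise ValidationError("modularity implemented for undirected graphs")
    assignment = np.asarray(assignment, dtype=int)
    if assignment.shape[0] != g.n_nodes:
        raise ValidationError("assignment length must equal node count")
    two_m = A.sum()
    if two_m == 0:
        raise UndefinedMeasureError("modularity undefined on an edgeless graph")
    k = A.sum(axis=1)
    same = assignment[:, None] == assignment[None, :]
    return float(((A - np.outer(k, k) / two_m) * same).sum() / two_m)


def modularity_partition(g: Graph, seed: int = 0, restarts: int = 10) -> Partition:
    """Louvain maximisation of Q; deterministic for a given seed.

    Louvain is greedy and its sweep order matters on small graphs, so the
    optimisation restarts ``restarts`` times with seeds derived from
    ``seed`` and keeps the best-Q assignment (ties broken by the earliest
    restart, hence bit-reproducible).
    """
    A = g.adjacency
    if not np.any(A != 0):
        raise UndefinedMeasureError("community detection undefined on an edgeless graph")
    G = nx.from_numpy_array(np.abs(A))
    sub_seeds = np.random.default_rng(int(seed)).integers(0, 2**31 - 1, size=max(1, restarts))
    best: Partition | None = None
    for s in sub_seeds:
        communities = nx.community.louvain_communities(G, weight="weight", seed=int(s))
        raw = np.zeros(g.n_nodes, dtype=int)
        for mid, nodes in enumerate(communities):
            for v in nodes:
                raw[v] = mid
        assignment = _relabel_contiguous(raw)
        cand = Partition(assignment=assignment, Q=modularity_Q(g, assignment))
        if best is None or cand.Q > best.Q:
            best = cand
    return best


def _nodal_k(g: Graph) -> np.ndarray:
    """Degree on binary graphs, strength on weighted ones."""
    return strength(g) if g.weighted else degree(g)


def within_module_zscore(g: Graph, partition: Partition) -> np.ndarray:
    """Within-module degree z-score: standardised within-module connectivity.

    kappa_v is v's connectivity (degree or strength) restricted to its own
    module; z standardises kappa within each module with the population
    standard deviation. Modules with zero spread (including singletons)
    yield z = 0.
    """
    A = g.adjacency
    assignment = partition.assignment
    z = np.zeros(g.n_nodes)
    for mid in range(1, partition.n_modules + 1):
        members = partition.members(mid)
        sub = A[np.ix_(members, members)]
        kappa = sub.sum(axis=1) if g.weighted else (sub != 0).sum(axis=1).astype(float)
        sd = kappa.std()
        if sd > 0:
            z[members] = (kappa - kappa.mean()) / sd
    return z


def participation_coefficient(g: Graph, partition: Partition) -> np.ndarray:
    """P_v = 1 - sum_m (kappa_vm / k_v)^2; 0 for unconnected nodes.

    Near 0 when all of a node's edges stay inside its module; approaches 1
    as its edges spread evenly over many modules.
    """
    A = g.adjacency
    k = _nodal_k(g)
    P = np.zeros(g.n_nodes)
    connected = k > 0
    acc = np.zeros(g.n_nodes)
    for mid in range(1, partition.n_modules + 1):
        members = partition.members(mid)
        km = (
            A[:, members].sum(axis=1)
            if g.weighted
            else (A[:, members] != 0).sum(axis=1).astype(float)
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            acc += np.where(connected, (km / np.where(connected, k, 1.0)) ** 2, 0.0)
    P[connected] = 1.0 - acc[connected]
    return P


def module_average_degree(g: Graph, partition: Partition, module_id: int) -> float:
    """Mean whole-graph connectivity (degree or strength) of a module's nodes."""
    members = partition.members(module_id)
    if members.size == 0:
        raise ValidationError(f"module {module_id} has no members")
    return float(_nodal_k(g)[members].mean())


def match_modules(reference: Partition, other: Partition) -> dict[int, int]:
    """Map each module of ``other`` onto the reference module with maximum node overlap.

    Greedy on overlap size (ties broken by smaller module ids) so that
    cross-group statements like "module III in both groups" are well defined.
    """
    if reference.assignment.shape != other.assignment.shape:
        raise ValidationError("partitions cover different node sets")
    overlaps = []
    for mo in range(1, other.n_modules + 1):
        for mr in range(1, reference.n_modules + 1):
            ov = np.intersect1d(other.members(mo), reference.members(mr)).size
            overlaps.append((-ov, mo, mr))
    overlaps.sort()
    mapping: dict[int, int] = {}
    used: set[int] = set()
    for neg_ov, mo, mr in overlaps:
        if neg_ov == 0:
            continue
        if mo in mapping or mr in used:
            continue
        mapping[mo] = mr
        used.add(mr)
    return mapping


def save_partition(g: Graph, partition: Partition, path: str | Path) -> Path:
    """CSV of (node label, module id) plus a module summary alongside."""
    path = Path(path)
    labels = g.labels or tuple(str(i) for i in range(g.n_nodes))
    pd.DataFrame({"node": labels, "module": partition.assignment}).to_csv(path, index=False)
    summary = pd.DataFrame(
        {
            "module": range(1, partition.n_modules + 1),
            "size": [partition.members(m).size for m in range(1, partition.n_modules + 1)],
            "average_degree": [
                module_average_degree(g, partition, m) for m in range(1, partition.n_modules + 1)
            ],
        }
    )
    summary.to_csv(path.with_name(path.stem + "_modules" + path.suffix), index=False)
    return path
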