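"""Graph taxonomy and threshold/density binarization.

A graph is a square adjacency matrix tagged as weighted/binary and
directed/undirected (WU, BU, WD, BD). The analyses here use undirected
graphs; directed matrices can be symmetrized by one of four entrywise rules
(sum, absolute difference, min, max). A weighted undirected graph becomes
binary either at a fixed threshold (edges strictly above the threshold are
kept — BUT) or at a fixed density (the m strongest edges are kept, with
m = round(d * R(R-1)/2) — BUD). Fixing density equalises the edge count
across groups or subjects, which is why density grids dominate group
comparisons.

Tie and rounding conventions (the field leaves them unstated, so they are
fixed here deterministically): threshold comparison is strict; the density
edge count rounds half up with a minimum of one edge; ties in the density
cut are broken by weight descending, then (row, col) ascending. If negative
weights were kept upstream, both binarizations operate on the signed values
(so a weight of -0.2 ranks below +0.1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import ConfigError, ValidationError

__all__ = [
    "GraphParam",
    "Graph",
    "from_connectivity",
    "symmetrize",
    "density",
    "binarize_threshold",
    "binarize_density",
]


@dataclass(frozen=True)
class GraphParam:
    """The construction parameter a binary graph was obtained at."""

    kind: str  # "threshold" | "density"
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("threshold", "density"):
            raise ConfigError(f"param kind must be threshold|density, got {self.kind!r}")


@dataclass(frozen=True)
class Graph:
    """Adjacency matrix plus its type flags (weighted/directed) and param tag."""

    adjacency: np.ndarray
    weighted: bool = True
    directed: bool = False
    param: Optional[GraphParam] = None
    labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        object.__setattr__(self, "adjacency", A)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValidationError(f"adjacency must be square, got {A.shape}")
        if not np.all(np.isfinite(A)):
            raise ValidationError("adjacency contains non-finite entries")
        if np.any(np.diag(A) != 0):
            raise ValidationError("adjacency diagonal must be zero (no self-loops)")
        if not self.directed and not np.array_equal(A, A.T):
            raise ValidationError("undirected graph requires an exactly symmetric adjacency")
        if not self.weighted and not np.all(np.isin(A, (0.0, 1.0))):
            raise ValidationError("binary graph entries must be 0 or 1")
        if self.labels is not None and len(self.labels) != A.shape[0]:
            raise ValidationError("labels length does not match adjacency size")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def kind(self) -> str:
        """Two-letter type code: WU, BU, WD or BD."""
        return ("W" if self.weighted else "B") + ("D" if self.directed else "U")


def from_connectivity(matrix, param: Optional[GraphParam] = None) -> Graph:
    """Wrap a :class:`~braingraph.connectivity.ConnectivityMatrix` as a WU graph."""
    return Graph(
        adjacency=matrix.values,
        weighted=True,
        directed=False,
        param=param,
        labels=tuple(matrix.atlas.labels),
    )


def symmetrize(g: Graph, rule: str = "max") -> Graph:
    """Make a graph undirected by an entrywise rule on (A, A^T).

    sum: A + A^T; difference: |A - A^T|; min / max: entrywise extremum.
    """
    A = g.adjacency
    if rule == "sum":
        S = A + A.T
    elif rule == "difference":
        S = np.abs(A - A.T)
    elif rule == "min":
        S = np.minimum(A, A.T)
    elif rule == "max":
        S = np.maximum(A, A.T)
    else:
        raise ConfigError(f"unknown symmetrization rule {rule!r}; use sum|difference|min|max")
    return Graph(adjacency=S, weighted=g.weighted, directed=False, param=g.param, labels=g.labels)


def density(g: Graph) -> float:
    """Fraction of possible undirected edges present (nonzero upper triangle)."""
    if g.directed:
        raise ValidationError("density is defined here for undirected graphs")
    R = g.n_nodes
    iu = np.triu_indices(R, k=1)
    possible = R * (R - 1) // 2
    return float(np.count_nonzero(g.adjacency[iu]) / possible)


def binarize_threshold(g: Graph, t: float) -> Graph:
    """Binary graph keeping edges with weight strictly above ``t`` (BUT)."""
    if g.directed or not g.weighted:
        raise ValidationError("threshold binarization applies to weighted undirected graphs")
    B = (g.adjacency > t).astype(float)
    np.fill_diagonal(B, 0.0)
    return Graph(
        adjacency=B,
        weighted=False,
        directed=False,
        param=GraphParam("threshold", float(t)),
        labels=g.labels,
    )


def binarize_density(g: Graph, d: float) -> Graph:
    """Binary graph keeping the m strongest edges, m = round(d * R(R-1)/2) (BUD).

    Rounding is half-up with a floor of one edge; ties are broken by weight
    descending then (row, col) ascending, so repeated calls are identical.
    """
    if g.directed or not g.weighted:
        raise ValidationError("density binarization applies to weighted undirected graphs")
    if not (0.0 < d <= 1.0):
        raise ConfigError(f"density must lie in (0, 1], got {d}")
    R = g.n_nodes
    rows, cols = np.triu_indices(R, k=1)
    w = g.adjacency[rows, cols]
    possible = w.size
    m = max(1, int(math.floor(d * possible + 0.5)))
    # stable sort on (-weight, row, col): lexsort's last key is primary
    order = np.lexsort((cols, rows, -w))
    keep = order[:m]
    B = np.zeros((R, R))
    B[rows[keep], cols[keep]] = 1.0
    B += B.T
    return Graph(
        adjacency=B,
        weighted=False,
        directed=False,
        param=GraphParam("density", float(d)),
        labels=g.labels,
    )
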