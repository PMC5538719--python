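"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — Floyd-Warshall distance relaxation,
exhaustive simple-path enumeration for betweenness, explicit triangle
enumeration, full set-partition search for modularity — so that agreement
with the package's optimized implementations is evidence, not tautology.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

INF = float("inf")


def length_matrix(A: np.ndarray, weighted: bool) -> np.ndarray:
    """Edge lengths (1 binary, 1/w weighted); INF where no edge."""
    n = A.shape[0]
    L = np.full((n, n), INF)
    for i in range(n):
        for j in range(n):
            if i != j and A[i, j] != 0:
                L[i, j] = 1.0 / A[i, j] if weighted else 1.0
    return L


def floyd_warshall(A: np.ndarray, weighted: bool) -> np.ndarray:
    n = A.shape[0]
    D = length_matrix(A, weighted)
    for i in range(n):
        D[i, i] = 0.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def nodal_path_length(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    out = np.full(n, np.nan)
    for i in range(n):
        ds = [D[i, j] for j in range(n) if j != i and np.isfinite(D[i, j])]
        if ds:
            out[i] = sum(ds) / len(ds)
    return out


def closeness(D: np.ndarray) -> np.ndarray:
    pl = nodal_path_length(D)
    return np.array([0.0 if (np.isnan(v) or v == 0) else 1.0 / v for v in pl])


def nodal_efficiency(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    if n < 2:
        return np.zeros(n)
    out = np.zeros(n)
    for i in range(n):
        out[i] = sum(
            (1.0 / D[i, j]) if np.isfinite(D[i, j]) and D[i, j] > 0 else 0.0
            for j in range(n)
            if j != i
        ) / (n - 1)
    return out


def _all_paths(L: np.ndarray, s: int, t: int):
    """All simple paths s->t with their total lengths (DFS enumeration)."""
    n = L.shape[0]
    paths = []

    def dfs(v, visited, length, path):
        if v == t:
            paths.append((length, list(path)))
            return
        for w in range(n):
            if np.isfinite(L[v, w]) and w not in visited:
                visited.add(w)
                path.append(w)
                dfs(w, visited, length + L[v, w], path)
                path.pop()
                visited.remove(w)

    dfs(s, {s}, 0.0, [s])
    return paths


def betweenness(A: np.ndarray, weighted: bool, normalized: bool = True) -> np.ndarray:
    """Exhaustive shortest-path enumeration betweenness (undirected)."""
    n = A.shape[0]
    L = length_matrix(A, weighted)
    bc = np.zeros(n)
    for s, t in combinations(range(n), 2):
        paths = _all_paths(L, s, t)
        if not paths:
            continue
        dmin = min(p[0] for p in paths)
        shortest = [p for l, p in paths if l <= dmin * (1 + 1e-12) + 1e-15]
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p)
            bc[v] += through / len(shortest)
    if normalized and n > 2:
        bc /= (n - 1) * (n - 2) / 2.0
    return bc


def clustering(A: np.ndarray, weighted: bool) -> np.ndarray:
    """Triangle enumeration clustering; Onnela weighting on weighted graphs."""
    n = A.shape[0]
    W = A / A.max() if (weighted and A.max() > 0) else A
    out = np.zeros(n)
    for v in range(n):
        nbrs = [u for u in range(n) if A[v, u] != 0]
        k = len(nbrs)
        if k < 2:
            continue
        tri = 0.0
        for a, b in combinations(nbrs, 2):
            if A[a, b] != 0:
                if weighted:
                    tri += (W[v, a] * W[a, b] * W[b, v]) ** (1.0 / 3.0)
                else:
                    tri += 1.0
        out[v] = 2.0 * tri / (k * (k - 1))
    return out


def transitivity(A: np.ndarray, weighted: bool) -> float:
    n = A.shape[0]
    W = A / A.max() if (weighted and A.max() > 0) else A
    closed = 0.0
    paths2 = 0
    for v in range(n):
        nbrs = [u for u in range(n) if A[v, u] != 0]
        paths2 += len(nbrs) * (len(nbrs) - 1)
        for a, b in combinations(nbrs, 2):
            if A[a, b] != 0:
                if weighted:
                    closed += 2.0 * (W[v, a] * W[a, b] * W[b, v]) ** (1.0 / 3.0)
                else:
                    closed += 2.0
    return closed / paths2 if paths2 else 0.0


def local_efficiency(A: np.ndarray, weighted: bool) -> np.ndarray:
    n = A.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nbrs = [u for u in range(n) if A[v, u] != 0]
        if len(nbrs) < 2:
            continue
        sub = A[np.ix_(nbrs, nbrs)]
        D = floyd_warshall(sub, weighted)
        out[v] = nodal_efficiency(D).mean()
    return out


def pairwise_corr_matrix(X: np.ndarray, corr_fn) -> np.ndarray:
    """Entry-by-entry loop over column pairs with a scalar correlation function."""
    R = X.shape[1]
    C = np.zeros((R, R))
    for j in range(R):
        for k in range(j + 1, R):
            C[j, k] = C[k, j] = corr_fn(X[:, j], X[:, k])
    return C


def modularity_Q(A: np.ndarray, assignment: np.ndarray) -> float:
    """Hand-summed e_ii - a_i^2 form of Newman-Girvan Q."""
    two_m = A.sum()
    Q = 0.0
    for mod in np.unique(assignment):
        members = np.flatnonzero(assignment == mod)
        e_ii = A[np.ix_(members, members)].sum() / two_m
        a_i = A[members, :].sum() / two_m
        Q += e_ii - a_i**2
    return Q


def set_partitions(items):
    """All set partitions of a list (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def best_partition_Q(A: np.ndarray) -> float:
    """Exhaustive-search optimum of Q over all set partitions."""
    n = A.shape[0]
    best = -np.inf
    for part in set_partitions(range(n)):
        assignment = np.zeros(n, dtype=int)
        for mid, block in enumerate(part):
            for v in block:
                assignment[v] = mid
        best = max(best, modularity_Q(A, assignment))
    return best


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Hand step-up BH adjustment."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def random_binary_graph(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    A = (rng.random((n, n)) < p).astype(float)
    A = np.triu(A, k=1)
    A = A + A.T
    return A


def random_weighted_graph(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    A = random_binary_graph(rng, n, p)
    W = np.triu(rng.uniform(0.05, 1.0, (n, n)), k=1)
    W = (W + W.T) * (A != 0)
    return W
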