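"""Independent brute-force oracles used to pin expected values.

These implementations deliberately share no code with the package: NODF by
literal pairwise overlap enumeration, centralities by explicit shortest-path
enumeration, and entropy extrema by exhaustive enumeration of all integer
matrices with fixed marginals.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def nodf_bruteforce(binary: np.ndarray) -> float:
    """NODF by direct enumeration of all row and column pairs."""
    b = (np.asarray(binary) > 0).astype(int)
    p, a = b.shape

    def axis_terms(mat):
        fills = mat.sum(axis=1)
        total = 0.0
        for i in range(mat.shape[0]):
            for k in range(mat.shape[0]):
                if i == k:
                    continue
                if fills[i] > fills[k] and fills[k] > 0:
                    shared = int(np.logical_and(mat[i], mat[k]).sum())
                    total += 100.0 * shared / fills[k]
        return total

    pairs = p * (p - 1) / 2 + a * (a - 1) / 2
    return (axis_terms(b) + axis_terms(b.T)) / pairs


def all_shortest_paths(adj: dict, src):
    """BFS shortest paths: returns (distance, path count, paths) per node."""
    dist = {src: 0}
    paths = {src: [[src]]}
    frontier = [src]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    paths[v] = [p + [v] for p in paths[u]]
                    nxt.append(v)
                elif dist[v] == dist[u] + 1:
                    paths[v].extend(p + [v] for p in paths[u])
        frontier = nxt
    return dist, paths


def betweenness_bruteforce(nodes, edges) -> dict:
    """Betweenness by enumerating every shortest path of every pair."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    bc = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(nodes, 2):
        _, paths = all_shortest_paths(adj, s)
        if t not in paths:
            continue
        st_paths = paths[t]
        for path in st_paths:
            for mid in path[1:-1]:
                bc[mid] += 1.0 / len(st_paths)
    return bc


def closeness_bruteforce(nodes, edges) -> dict:
    """Closeness (n_comp - 1) / sum of within-component distances."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    cc = {}
    for n in nodes:
        dist, _ = all_shortest_paths(adj, n)
        total = sum(d for d in dist.values())
        cc[n] = (len(dist) - 1) / total if total > 0 else 0.0
    return cc


def enumerate_matrices(row_tot, col_tot):
    """Every nonnegative integer matrix with the given marginals."""
    row_tot = [int(x) for x in row_tot]
    col_tot = [int(x) for x in col_tot]
    n_rows, n_cols = len(row_tot), len(col_tot)

    def rows(remaining_cols, i):
        if i == n_rows:
            if all(c == 0 for c in remaining_cols):
                yield []
            return

        def cells(j, rem, row):
            if j == n_cols - 1:
                if rem <= remaining_cols[j]:
                    yield row + [rem]
                return
            for v in range(min(rem, remaining_cols[j]) + 1):
                yield from cells(j + 1, rem - v, row + [v])

        for row in cells(0, row_tot[i], []):
            newcols = [c - v for c, v in zip(remaining_cols, row)]
            for rest in rows(newcols, i + 1):
                yield [row] + rest

    for mat in rows(list(col_tot), 0):
        yield np.array(mat)


def entropy(weights: np.ndarray) -> float:
    m = weights.sum()
    p = weights[weights > 0] / m
    return float(-(p * np.log(p)).sum())


def entropy_extrema_bruteforce(row_tot, col_tot) -> tuple[float, float]:
    """(min, max) Shannon entropy over all matrices with the marginals."""
    ents = [entropy(m) for m in enumerate_matrices(row_tot, col_tot)]
    return min(ents), max(ents)


def kl_min_bruteforce(total: int, q: np.ndarray) -> float:
    """Minimum KL divergence of an integer allocation of *total* toward q."""
    best = math.inf
    n = len(q)

    def rec(j, rem, counts):
        nonlocal best
        if j == n - 1:
            counts = counts + [rem]
            p = np.array(counts, dtype=float) / total
            mask = p > 0
            best = min(best, float((p[mask] * np.log(p[mask] / q[mask])).sum()))
            return
        for v in range(rem + 1):
            rec(j + 1, rem - v, counts + [v])

    rec(0, total, [])
    return best
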