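"""Structural and specialization metrics for weighted bipartite webs.

Implements the standard flower-visitation network statistics: connectance,
web asymmetry, weighted/unweighted mean degrees, NODF nestedness, the
two-dimensional Shannon specialization index H2' with its marginal-
constrained extremes, species-level specialization d' (Kullback-Leibler
divergence from partner availability, rescaled), specialization asymmetry,
and the Good-Turing sample-coverage estimator.

Notation: ``a_ij`` visit counts, row totals ``A_i``, column totals ``B_j``,
grand total ``m``, link count ``L``, plant richness ``P``, visitor
richness ``A``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .network import BipartiteNetwork, UndefinedMetricError

__all__ = [
    "connectance",
    "web_asymmetry",
    "asymmetry_from_richness",
    "mean_degrees",
    "nodf",
    "shannon_H2",
    "h2_extrema",
    "h2_prime",
    "d_prime",
    "specialization_asymmetry",
    "sample_coverage",
    "CoverageEstimate",
    "MetricReport",
    "metric_report",
]


# ---------------------------------------------------------------------------
# structural metrics

def connectance(net: BipartiteNetwork) -> float:
    """Realized fraction of possible links, C = L / (P * A)."""
    return net.link_count / (net.n_plants * net.n_visitors)


def asymmetry_from_richness(n_plants: int, n_visitors: int) -> float:
    """Web asymmetry W = (A - P) / (A + P) from the two richness counts.

    Positive when visitor species outnumber plant species (the typical
    pattern in flower-visitor webs); negative when plants dominate.
    """
    if n_plants + n_visitors <= 0:
        raise UndefinedMetricError("richness totals must be positive")
    return (n_visitors - n_plants) / (n_visitors + n_plants)


def web_asymmetry(net: BipartiteNetwork) -> float:
    return asymmetry_from_richness(net.n_plants, net.n_visitors)


def mean_degrees(net: BipartiteNetwork) -> dict:
    """Mean weighted and unweighted degrees for each guild.

    Weighted degree of a species is its marginal visit total; unweighted
    degree is its number of distinct partners.
    """
    b = net.binary()
    return {
        "plant_weighted": float(net.plant_totals.mean()),
        "plant_unweighted": float(b.sum(axis=1).mean()),
        "visitor_weighted": float(net.visitor_totals.mean()),
        "visitor_unweighted": float(b.sum(axis=0).mean()),
    }


def _nodf_axis(binary: np.ndarray) -> float:
    """Sum of paired NODF terms over ordered row pairs of *binary*."""
    fills = binary.sum(axis=1)
    overlap = binary @ binary.T  # shared presences per row pair
    total = 0.0
    n = binary.shape[0]
    for i in range(n):
        for k in range(n):
            if i != k and fills[i] > fills[k] > 0:
                total += 100.0 * overlap[i, k] / fills[k]
    return total


def nodf(net: BipartiteNetwork) -> float:
    """NODF nestedness (0-100), strict decreasing fill, presence = w > 0.

    For every pair of rows whose fills strictly decrease, the paired term
    is the percentage of the sparser row's presences shared with the
    fuller row; ties contribute zero.  Same over column pairs; the sum is
    divided by the number of row plus column pairs.
    """
    if net.n_plants < 2 or net.n_visitors < 2:
        raise UndefinedMetricError("NODF needs at least 2 rows and 2 columns")
    b = net.binary()
    p, a = b.shape
    pairs = p * (p - 1) / 2 + a * (a - 1) / 2
    return (_nodf_axis(b) + _nodf_axis(b.T)) / pairs


# ---------------------------------------------------------------------------
# specialization: H2'

def _entropy(weights: np.ndarray) -> float:
    """Two-dimensional Shannon entropy of visit frequencies p_ij = a_ij/m."""
    m = weights.sum()
    p = weights[weights > 0] / m
    return float(-(p * np.log(p)).sum())


def shannon_H2(net: BipartiteNetwork) -> float:
    return _entropy(net.weights)


def _max_entropy_matrix(row_tot: np.ndarray, col_tot: np.ndarray) -> np.ndarray:
    """Most even integer matrix with the given marginals (greedy spreading).

    Entropy depends only on the multiset of cell counts, so each unit goes
    to the eligible cell (remaining row and column capacity) with the
    lowest current count; ties prefer the cell with the largest remaining
    marginal product, which keeps later units from being forced onto
    already-filled cells.
    """
    m = int(row_tot.sum())
    target = np.outer(row_tot, col_tot) / m
    a = np.floor(target).astype(np.int64)  # never overshoots a marginal
    rem_r = row_tot - a.sum(axis=1)
    rem_c = col_tot - a.sum(axis=0)
    deficit = m - int(a.sum())
    if deficit * a.size <= 2_000_000:
        # place remaining units one by one on the least-filled eligible cell
        big = float(m + 1)
        for _ in range(deficit):
            score = a * big - (target - a)
            score[rem_r <= 0, :] = np.inf
            score[:, rem_c <= 0] = np.inf
            i, j = np.unravel_index(np.argmin(score), a.shape)
            a[i, j] += 1
            rem_r[i] -= 1
            rem_c[j] -= 1
    else:
        # very sparse expectation: allocate row-by-row proportionally
        for i in np.argsort(-rem_r, kind="stable"):
            ri = int(rem_r[i])
            if ri == 0:
                continue
            tgt = ri * rem_c / rem_c.sum()
            row = np.minimum(np.floor(tgt).astype(np.int64), rem_c)
            frac = tgt - row
            frac[row >= rem_c] = -np.inf
            for j in np.argsort(-frac, kind="stable")[: ri - int(row.sum())]:
                row[j] += 1
            a[i] += row
            rem_c -= row
    return _refine_entropy(a, maximize=True)


def _nlogn(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    pos = x > 0
    out[pos] = x[pos] * np.log(x[pos])
    return out


_LOCAL_SEARCH_CELLS = 2500  # refine only webs up to ~50x50


def _negative_cycle(w: np.ndarray):
    """A negative cycle in the dense weighted digraph *w*, or None.

    Vectorized Bellman-Ford from an implicit all-zeros source; returns the
    cycle as a list of edges (u, v).
    """
    n = w.shape[0]
    dist = np.zeros(n)
    pred = np.full(n, -1)
    x = -1
    for _ in range(n + 1):
        cand = dist[:, None] + w
        best = cand.min(axis=0)
        improved = best < dist - 1e-9
        if not improved.any():
            return None
        arg = cand.argmin(axis=0)
        dist = np.where(improved, best, dist)
        pred = np.where(improved, arg, pred)
        x = int(np.flatnonzero(improved)[0])
    for _ in range(n):  # walk back onto the cycle itself
        x = pred[x]
    edges, v = [], x
    while True:
        edges.append((int(pred[v]), int(v)))
        v = int(pred[v])
        if v == x:
            break
    return edges


def _refine_entropy(a: np.ndarray, maximize: bool, max_iter: int | None = None) -> np.ndarray:
    """Exact entropy-extremum refinement by negative-cycle cancellation.

    Entropy extremization under fixed marginals is a transportation
    problem with separable convex cost Σ f(a_ij), f(n) = n ln n (negated
    to minimize entropy).  A matrix is optimal iff the residual graph over
    columns — edge j->l costing min_i [f(a_ij - 1) - f(a_ij) + f(a_il + 1)
    - f(a_il)] — has no negative cycle; each found cycle shifts one unit
    per edge and strictly improves.  Skipped for very large matrices,
    where the construction greedy stands alone.
    """
    if a.size > _LOCAL_SEARCH_CELLS or a.shape[1] < 2 or not maximize:
        return a
    a = a.copy()
    if max_iter is None:
        max_iter = 10 * int(a.sum()) + 100
    for _ in range(max_iter):
        af = a.astype(float)
        rem = _nlogn(af - 1) - _nlogn(af)
        add = _nlogn(af + 1) - _nlogn(af)
        rem = np.where(a > 0, rem, np.inf)  # cannot remove from empty cells
        t = rem[:, :, None] + add[:, None, :]  # (i, j, l)
        w = t.min(axis=0)
        rows = t.argmin(axis=0)
        np.fill_diagonal(w, np.inf)
        cycle = _negative_cycle(w)
        if cycle is None or sum(w[j, l] for j, l in cycle) > -1e-9:
            break
        for j, l in cycle:
            i = rows[j, l]
            a[i, j] -= 1
            a[i, l] += 1
    return a


_MIN_DP_TOTAL = 24
_MIN_DP_SIDE = 6


def _min_entropy_sum(row_tot: tuple, col_tot: tuple) -> float | None:
    """Exact max of Σ n·ln n over integer matrices with the marginals.

    Entropy minimization maximizes a convex function, so the optimum sits
    at a vertex of the transportation polytope; every vertex is reachable
    by repeatedly shipping min(r_i, c_j) for some pair order.  Dynamic
    programming over the multisets of remaining marginals explores all
    such orders; feasible only for small webs (returns None beyond the
    size bounds).
    """
    if sum(row_tot) > _MIN_DP_TOTAL or max(len(row_tot), len(col_tot)) > _MIN_DP_SIDE:
        return None
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(rows: tuple, cols: tuple) -> float:
        if not rows:
            return 0.0
        out = -np.inf
        for r in set(rows):
            for c in set(cols):
                t = min(r, c)
                rows2 = list(rows)
                rows2.remove(r)
                cols2 = list(cols)
                cols2.remove(c)
                if r - t:
                    rows2.append(r - t)
                if c - t:
                    cols2.append(c - t)
                val = t * np.log(t) + best(tuple(sorted(rows2)), tuple(sorted(cols2)))
                out = max(out, val)
        return out

    return best(tuple(sorted(int(r) for r in row_tot)),
                tuple(sorted(int(c) for c in col_tot)))


def _min_entropy_matrix(row_tot: np.ndarray, col_tot: np.ndarray) -> np.ndarray:
    """Most concentrated integer matrix with the given marginals (greedy).

    Repeatedly ships min(r_i, c_j) into the cell of the pair maximizing
    that transferable amount, preferring pairs that annihilate both
    marginals at once (r_i == c_j), so mass ends up in as few, as large
    cells as the marginals allow.
    """
    rem_r = row_tot.astype(np.int64).copy()
    rem_c = col_tot.astype(np.int64).copy()
    a = np.zeros((len(rem_r), len(rem_c)), dtype=np.int64)
    while rem_r.sum() > 0:
        x = np.minimum(rem_r[:, None], rem_c[None, :])
        exact = (rem_r[:, None] == rem_c[None, :]) & (x > 0)
        best = x * 2 + exact  # primary: largest x; tie-break: exact annihilation
        i, j = np.unravel_index(np.argmax(best), a.shape)
        amt = min(rem_r[i], rem_c[j])
        a[i, j] += amt
        rem_r[i] -= amt
        rem_c[j] -= amt
    # no cycle refinement here: minimizing entropy maximizes a convex
    # function, where the linearized cycle test is not a valid certificate
    return a


def h2_extrema(net: BipartiteNetwork) -> tuple[float, float]:
    """(H2_min, H2_max): extreme entropies achievable under the marginals.

    Small webs use exact search (vertex DP for the minimum, convex-flow
    refinement for the maximum); large webs fall back to the greedy
    constructions.
    """
    r, c = net.plant_totals, net.visitor_totals
    m = int(r.sum())
    s = _min_entropy_sum(tuple(r), tuple(c))
    if s is not None:
        h2min = float(np.log(m) - s / m)
    else:
        h2min = _entropy(_min_entropy_matrix(r, c))
    return h2min, _entropy(_max_entropy_matrix(r, c))


def h2_prime(net: BipartiteNetwork) -> float:
    """Network-level specialization H2' in [0, 1].

    H2' = (H2_max - H2) / (H2_max - H2_min): 0 when interactions are as
    proportional to the marginals as integer counts allow, 1 when they are
    maximally specialized.
    """
    h2min, h2max = h2_extrema(net)
    if h2max - h2min < 1e-12:
        raise UndefinedMetricError("marginals force a unique distribution")
    return float(np.clip((h2max - shannon_H2(net)) / (h2max - h2min), 0.0, 1.0))


# ---------------------------------------------------------------------------
# specialization: d'

def _kl_from_counts(counts: np.ndarray, q: np.ndarray) -> float:
    tot = counts.sum()
    mask = counts > 0
    p = counts[mask] / tot
    return float((p * np.log(p / q[mask])).sum())


def _min_kl_counts(total: int, q: np.ndarray) -> np.ndarray:
    """Integer allocation of *total* units closest (in KL) to proportions q."""
    base = np.floor(total * q).astype(np.int64)
    for _ in range(total - int(base.sum())):
        b = base.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            cur = np.where(b > 0, b * np.log(b / (total * q)), 0.0)
            nxt = (b + 1) * np.log((b + 1) / (total * q))
        base[int(np.argmin(nxt - cur))] += 1
    return base


def d_prime(net: BipartiteNetwork, guild: str = "plants") -> dict:
    """Species-level specialization d' in [0, 1] per species of one guild.

    d_i is the Kullback-Leibler divergence of species i's partner-use
    frequencies from overall partner availability q_j = B_j/m; d' rescales
    it between the integer-feasible minimum (greedy allocation toward q)
    and the maximum ln(m/A_i).  Species whose marginals leave no room
    (d_max = d_min) map to None.
    """
    w = net.weights if guild == "plants" else net.weights.T
    labels = net.plant_labels if guild == "plants" else net.visitor_labels
    m = w.sum()
    q = w.sum(axis=0) / m  # availability of partners
    out = {}
    for i, label in enumerate(labels):
        tot = int(w[i].sum())
        d_obs = _kl_from_counts(w[i], q)
        d_max = np.log(m / tot)
        d_min = _kl_from_counts(_min_kl_counts(tot, q), q)
        if d_max - d_min < 1e-12:
            out[label] = None
        else:
            out[label] = float(np.clip((d_obs - d_min) / (d_max - d_min), 0.0, 1.0))
    return out


def specialization_asymmetry(net: BipartiteNetwork) -> float:
    """Mean visitor d' minus mean plant d' (defined species only)."""
    dv = [v for v in d_prime(net, "visitors").values() if v is not None]
    dp = [v for v in d_prime(net, "plants").values() if v is not None]
    if not dv or not dp:
        raise UndefinedMetricError("d' undefined for an entire guild")
    return float(np.mean(dv) - np.mean(dp))


# ---------------------------------------------------------------------------
# sample coverage

@dataclass(frozen=True)
class CoverageEstimate:
    n: int
    f1: int
    f2: int
    coverage: float


def sample_coverage(abundances: Sequence[int]) -> CoverageEstimate:
    """Good-Turing sample-coverage estimate from species abundances.

    C_hat = 1 - (f1/n) * (n-1) f1 / ((n-1) f1 + 2 f2), where f1 and f2 are
    the singleton and doubleton counts; complete coverage when there are
    no singletons.
    """
    ab = np.asarray(list(abundances), dtype=np.int64)
    ab = ab[ab > 0]
    n = int(ab.sum())
    if n <= 0:
        raise UndefinedMetricError("coverage needs at least one individual")
    f1 = int((ab == 1).sum())
    f2 = int((ab == 2).sum())
    if f1 == 0:
        c = 1.0
    else:
        denom = (n - 1) * f1 + 2 * f2
        c = 1.0 - (f1 / n) * ((n - 1) * f1 / denom) if denom > 0 else 1.0 - f1 / n
    return CoverageEstimate(n=n, f1=f1, f2=f2, coverage=float(c))


# ---------------------------------------------------------------------------
# report assembly

@dataclass(frozen=True)
class MetricReport:
    """The standard per-network metric row (one table column per web).

    Metrics that are undefined for the web are carried as None, never as
    silent zeros.
    """

    tag: str
    plant_richness: int
    visitor_richness: int
    link_count: int
    total_visits: int
    plant_weighted_degree: float
    plant_unweighted_degree: float
    visitor_weighted_degree: float
    visitor_unweighted_degree: float
    connectance: float
    nodf: float | None
    asymmetry: float
    h2: float
    h2_prime: float | None
    plant_d_prime_mean: float | None
    visitor_d_prime_mean: float | None
    specialization_asymmetry: float | None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def _maybe(fn, *args):
    try:
        return fn(*args)
    except UndefinedMetricError:
        return None


def metric_report(net: BipartiteNetwork) -> MetricReport:
    """Compute the full metric suite for one web."""
    deg = mean_degrees(net)
    dp = _maybe(lambda: [v for v in d_prime(net, "plants").values() if v is not None])
    dv = _maybe(lambda: [v for v in d_prime(net, "visitors").values() if v is not None])
    return MetricReport(
        tag=str(net.metadata.get("tag", "")),
        plant_richness=net.n_plants,
        visitor_richness=net.n_visitors,
        link_count=net.link_count,
        total_visits=net.total_visits,
        plant_weighted_degree=deg["plant_weighted"],
        plant_unweighted_degree=deg["plant_unweighted"],
        visitor_weighted_degree=deg["visitor_weighted"],
        visitor_unweighted_degree=deg["visitor_unweighted"],
        connectance=connectance(net),
        nodf=_maybe(nodf, net),
        asymmetry=web_asymmetry(net),
        h2=shannon_H2(net),
        h2_prime=_maybe(h2_prime, net),
        plant_d_prime_mean=float(np.mean(dp)) if dp else None,
        visitor_d_prime_mean=float(np.mean(dv)) if dv else None,
        specialization_asymmetry=_maybe(specialization_asymmetry, net),
    )
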