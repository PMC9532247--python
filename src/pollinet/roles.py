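"""Species-role metrics, 0-1 scaling, rankings, and group contrasts.

Per-species measures: weighted and unweighted degree, visitation rate
(visits per unit floral display), node longevity (weeks of activity),
betweenness and closeness centrality in the unweighted one-mode
projection, and a leave-one-out functional-complementarity contribution.
Each is min-max scaled to [0, 1] so different measures carry equal weight
in rankings; top-k unions, plant-family preference summaries, and
native/non-native permutation contrasts are built on top.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from scipy import stats as _sps

from .network import BipartiteNetwork, EmptyNetworkError, UndefinedMetricError
from .records import InteractionRecord, build_network

__all__ = [
    "one_mode_projection",
    "centrality",
    "node_longevity",
    "visitation_rate",
    "functional_complementarity",
    "feature_scale",
    "species_role_table",
    "top_k_union",
    "family_preference",
    "native_contrast",
    "loglog_attraction_slope",
    "RANKING_METRICS",
]

#: Default ranking metric columns (the raw visit total is available as an
#: optional extra via the ``metrics`` argument of :func:`top_k_union`).
RANKING_METRICS = (
    "visitation_rate",
    "weighted_degree",
    "unweighted_degree",
    "longevity",
    "betweenness",
    "closeness",
    "fc",
)


def one_mode_projection(net: BipartiteNetwork, guild: str = "plants") -> nx.Graph:
    """Unweighted one-mode projection: two species join iff they share a partner."""
    b = net.binary() if guild == "plants" else net.binary().T
    labels = net.plant_labels if guild == "plants" else net.visitor_labels
    shared = b @ b.T
    g = nx.Graph()
    g.add_nodes_from(labels)
    n = len(labels)
    for i in range(n):
        for k in range(i + 1, n):
            if shared[i, k] > 0:
                g.add_edge(labels[i], labels[k])
    return g


def centrality(graph: nx.Graph) -> dict:
    """Betweenness (raw pair counts) and closeness per node.

    Betweenness counts shortest paths between other node pairs passing
    through the node, each unordered pair once, with fractional credit
    split over tied paths.  Closeness is (n_comp - 1) / sum of distances
    within the node's component; isolated nodes get 0.
    """
    return {
        "betweenness": nx.betweenness_centrality(graph, normalized=False),
        "closeness": nx.closeness_centrality(graph, wf_improved=False),
    }


def node_longevity(
    records: Iterable[InteractionRecord], dimension: str = "plant"
) -> dict:
    """Inclusive ISO-week span of each species' activity, pooling years.

    longevity = last active week - first active week + 1, where a species
    is active in any week it was recorded interacting.
    """
    weeks: dict[str, list[int]] = {}
    for rec in records:
        if rec.visits <= 0:
            continue
        taxon = rec.plant_taxon if dimension == "plant" else rec.insect_taxon
        weeks.setdefault(taxon, []).append(rec.iso_week)
    return {t: max(w) - min(w) + 1 for t, w in weeks.items()}


def _plant_totals(records) -> tuple[dict, dict, dict]:
    """Per-plant total visits, total floral display, and survey count.

    Display is a property of the plant on a survey, so it is counted once
    per (site, date, transect, plant) even though several insect records
    from the same survey repeat it.
    """
    visits: dict[str, float] = {}
    display: dict[str, float] = {}
    n_surveys: dict[str, int] = {}
    seen: set = set()
    for rec in records:
        visits[rec.plant_taxon] = visits.get(rec.plant_taxon, 0.0) + rec.visits
        d = rec.display
        key = (rec.site_id, rec.date, rec.transect_id, rec.plant_taxon)
        if d is not None and key not in seen:
            seen.add(key)
            display[rec.plant_taxon] = display.get(rec.plant_taxon, 0.0) + d
            n_surveys[rec.plant_taxon] = n_surveys.get(rec.plant_taxon, 0) + 1
    return visits, display, n_surveys


def visitation_rate(records: Iterable[InteractionRecord]) -> dict:
    """Visits per unit floral display, per plant.

    v = total visits / total floral display (floral units x inflorescence
    size, summed over the plant's surveys); None (excluded from ranking)
    when no survey carries a positive known display.
    """
    visits, display, _ = _plant_totals(records)
    return {
        t: (visits[t] / display[t]) if display.get(t, 0.0) > 0 else None
        for t in visits
    }


def _tree_height(rows: np.ndarray) -> float:
    """Total branch length of the average-linkage dendrogram (sum of merge
    heights) over Euclidean distances between interaction-frequency rows."""
    if rows.shape[0] < 2:
        return 0.0
    return float(linkage(pdist(rows), method="average")[:, 2].sum())


def functional_complementarity(
    net: BipartiteNetwork, guild: str = "plants"
) -> tuple[float, dict]:
    """Network FC and per-species leave-one-out contributions.

    FC is the total branch length of the average-linkage dendrogram of
    species' interaction-frequency rows; fc_i = max(FC - FC without
    species i, 0) quantifies how much unique partner structure species i
    adds.
    """
    rows = net.weights.astype(float) if guild == "plants" else net.weights.T.astype(float)
    labels = net.plant_labels if guild == "plants" else net.visitor_labels
    n = rows.shape[0]
    if n < 2:
        raise UndefinedMetricError("functional complementarity needs >= 2 species")
    fc_all = _tree_height(rows)
    contrib = {}
    for i, label in enumerate(labels):
        sub = np.delete(rows, i, axis=0)
        contrib[label] = max(fc_all - _tree_height(sub), 0.0)
    return fc_all, contrib


def feature_scale(values: Sequence) -> np.ndarray:
    """Min-max scale to [0, 1]; constant vectors map to all zeros.

    NaNs (undefined metric values) are preserved and ignored for the
    extremes.
    """
    x = np.asarray(values, dtype=float)
    finite = x[~np.isnan(x)]
    if finite.size == 0:
        return x
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        return np.where(np.isnan(x), np.nan, 0.0)
    return (x - lo) / (hi - lo)


def species_role_table(
    records: Sequence[InteractionRecord],
    guild: str = "plants",
    insect_subgroup: str | None = None,
    include: Sequence[str] = RANKING_METRICS,
) -> pd.DataFrame:
    """Assemble the per-species role table for one guild.

    For plants, *insect_subgroup* restricts the web to visits by one
    insect group (bee / syrphid / lepidopteran) before recomputing every
    metric, the per-subgroup recalculation used in ranking.  Raw columns
    are paired with ``scaled_*`` min-max counterparts.  *include* selects
    which ranking metrics to compute (the expensive centralities and
    functional complementarity can be skipped for large communities).
    """
    net = build_network(records, guild=insect_subgroup)
    dimension = "plant" if guild == "plants" else "insect"
    labels = list(net.plant_labels if guild == "plants" else net.visitor_labels)
    w = net.weights if guild == "plants" else net.weights.T
    include = tuple(include)

    sub_records = records
    if insect_subgroup is not None:
        sub_records = [r for r in records if r.insect_guild == insect_subgroup]

    longevity = node_longevity(sub_records, dimension)
    if "betweenness" in include or "closeness" in include:
        cent = centrality(one_mode_projection(net, guild))
    else:
        cent = {"betweenness": {}, "closeness": {}}
    fc = {}
    if "fc" in include:
        try:
            _, fc = functional_complementarity(net, guild)
        except UndefinedMetricError:
            pass
    vrate = visitation_rate(sub_records) if guild == "plants" else {}

    df = pd.DataFrame(index=labels)
    df.index.name = "species"
    df["weighted_degree"] = w.sum(axis=1)
    df["unweighted_degree"] = (w > 0).sum(axis=1)
    df["total_visits"] = w.sum(axis=1)
    df["visitation_rate"] = [
        np.nan if guild != "plants" else
        (np.nan if vrate.get(s) is None else vrate.get(s)) for s in labels
    ]
    df["longevity"] = [longevity.get(s, np.nan) for s in labels]
    df["betweenness"] = [cent["betweenness"].get(s, np.nan) for s in labels]
    df["closeness"] = [cent["closeness"].get(s, np.nan) for s in labels]
    df["fc"] = [fc.get(s, np.nan) for s in labels]

    if guild == "plants":
        fam, nat = {}, {}
        for rec in records:
            fam.setdefault(rec.plant_taxon, rec.plant_family)
            nat.setdefault(rec.plant_taxon, rec.plant_native)
        df["plant_family"] = [fam.get(s, "") for s in labels]
        df["plant_native"] = [nat.get(s, "unknown") for s in labels]
    else:
        g = {}
        for rec in records:
            g.setdefault(rec.insect_taxon, rec.insect_guild)
        df["insect_guild"] = [g.get(s, "") for s in labels]

    for col in RANKING_METRICS + ("total_visits",):
        df["scaled_" + col] = feature_scale(df[col].to_numpy())
    return df


def top_k_union(
    table: pd.DataFrame, k: int = 10, metrics: Sequence[str] = RANKING_METRICS
) -> pd.DataFrame:
    """Union of the top-k species per ranking metric, with membership flags.

    Ties break by descending value then ascending species label; undefined
    (NaN) values never rank.  With fewer than k species all are returned.
    """
    members: dict[str, set] = {}
    for metric in metrics:
        col = table[metric].dropna()
        ranked = sorted(col.items(), key=lambda kv: (-kv[1], kv[0]))
        members[metric] = {s for s, _ in ranked[:k]}
    union = sorted(set().union(*members.values())) if members else []
    out = pd.DataFrame(index=union)
    out.index.name = "species"
    for metric in metrics:
        out[metric] = [s in members[metric] for s in union]
    out["n_metrics"] = out[list(metrics)].sum(axis=1)
    return out


def family_preference(
    table: pd.DataFrame,
    records: Sequence[InteractionRecord],
    k: int = 10,
    metrics: Sequence[str] = RANKING_METRICS,
) -> dict:
    """Signed family preference: top-rank share minus floral-display share.

    delta_f = (fraction of the top-ranked plant species in family f) -
    (family f's share of the total floral display).  Values sum to zero
    across families.
    """
    top = top_k_union(table, k=k, metrics=metrics)
    if len(top) == 0:
        raise UndefinedMetricError("no top-ranked species")
    fam_of = table["plant_family"].to_dict()
    display: dict[str, float] = {}
    for rec in records:
        d = rec.display
        if d is not None and d > 0:
            f = rec.plant_family
            display[f] = display.get(f, 0.0) + d
    total_display = sum(display.values())
    families = sorted(set(display) | {fam_of.get(s, "") for s in top.index})
    top_count = {f: 0 for f in families}
    for s in top.index:
        top_count[fam_of.get(s, "")] = top_count.get(fam_of.get(s, ""), 0) + 1
    n_top = len(top)
    return {
        f: top_count.get(f, 0) / n_top - display.get(f, 0.0) / total_display
        for f in families
    }


def native_contrast(
    table: pd.DataFrame,
    metrics: Sequence[str] = RANKING_METRICS,
    n_perm: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.007,
) -> pd.DataFrame:
    """Native vs non-native group means with permutation p-values.

    Species of unknown status are excluded.  For each metric the observed
    difference (non-native minus native mean) is compared to a two-sided
    label-permutation distribution; flags apply the Bonferroni-adjusted
    threshold (0.05 over seven role metrics ~= 0.007).
    """
    sub = table[table["plant_native"].isin(["native", "non-native"])]
    is_nn = (sub["plant_native"] == "non-native").to_numpy()
    if is_nn.all() or not is_nn.any():
        raise UndefinedMetricError("both status groups must be nonempty")
    rng = np.random.default_rng(seed)
    rows = []
    for metric in metrics:
        x = sub[metric].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        xv, grp = x[ok], is_nn[ok]
        if not grp.any() or grp.all():
            rows.append((metric, np.nan, np.nan, np.nan, np.nan, False))
            continue
        obs = xv[grp].mean() - xv[~grp].mean()
        n_nn = int(grp.sum())
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(xv)) < n_nn
            diff = xv[perm].mean() - xv[~perm].mean()
            if abs(diff) >= abs(obs) - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
        rows.append((metric, xv[~grp].mean(), xv[grp].mean(), obs, p, p < alpha))
    return pd.DataFrame(
        rows,
        columns=["metric", "native_mean", "nonnative_mean", "difference", "p_value", "significant"],
    ).set_index("metric")


def loglog_attraction_slope(
    records: Sequence[InteractionRecord], offset: float = 1.0
):
    """OLS slope of log visitor abundance on log floral display, per species.

    Each plant contributes one point: its average visitor abundance per
    survey, log((total visits + offset) / n surveys), against its average
    floral display, log(total display / n surveys).  Normalizing by the
    plant's survey count keeps unequal survey effort (long- vs short-
    blooming species) from masquerading as an attraction effect.  Species
    without a positive known display are excluded.  Returns the scipy
    linregress result (slope, intercept, rvalue, pvalue, stderr).  A
    diagnostic for the background size-of-display attraction relationship,
    used for synthetic parameter recovery.
    """
    visits, display, n_surveys = _plant_totals(records)
    species = [s for s in visits if display.get(s, 0.0) > 0]
    if len(species) < 3:
        raise UndefinedMetricError("need >= 3 plant species with positive display")
    x = np.log([display[s] / n_surveys[s] for s in species])
    y = np.log([(visits[s] + offset) / n_surveys[s] for s in species])
    if np.ptp(x) == 0:
        raise UndefinedMetricError("no variance in log display")
    return _sps.linregress(x, y)
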