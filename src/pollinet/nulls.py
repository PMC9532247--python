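"""Connectance-preserving null models and z-score comparisons.

The randomization follows the two-phase scheme that keeps a web's
dimensions, grand total m, and link count L fixed: first L distinct cells
are drawn with probability proportional to the product of the observed
row and column marginal frequencies (resampling until every row and
column is covered), each chosen link gets one visit, and the remaining
m - L visits are spread multinomially over the chosen links with the same
product probabilities.  Observed specialization statistics are compared
to the ensemble with z = (observed - mu_null) / sigma_null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import BipartiteNetwork, UndefinedMetricError
from . import metrics as _metrics

__all__ = [
    "InfeasibleNullError",
    "vaznull_sample",
    "NullEnsemble",
    "null_ensemble",
    "z_score",
]

RESAMPLE_CAP = 10_000


class InfeasibleNullError(ValueError):
    """No randomized web can satisfy the coverage constraint."""


def vaznull_sample(net: BipartiteNetwork, rng: np.random.Generator) -> np.ndarray:
    """Draw one randomized matrix preserving dimensions, m, and L.

    Raises
    ------
    InfeasibleNullError
        If L < max(P, A) (some row or column could never hold a link) or
        the coverage constraint is not met within the resampling cap.
    """
    p, a = net.n_plants, net.n_visitors
    m, L = net.total_visits, net.link_count
    if L < max(p, a):
        raise InfeasibleNullError(
            f"link count {L} cannot cover {p} rows and {a} columns"
        )
    probs = np.outer(net.plant_totals / m, net.visitor_totals / m).ravel()
    probs = probs / probs.sum()
    n_cells = p * a

    for _ in range(RESAMPLE_CAP):
        if L == n_cells:
            chosen = np.arange(n_cells)
        else:
            # weighted sampling without replacement via the Gumbel trick
            keys = np.log(probs) + rng.gumbel(size=n_cells)
            chosen = np.argpartition(-keys, L - 1)[:L]
        rows, cols = np.unravel_index(chosen, (p, a))
        if len(np.unique(rows)) == p and len(np.unique(cols)) == a:
            break
    else:
        raise InfeasibleNullError("row/column coverage not achieved within cap")

    w = np.zeros((p, a), dtype=np.int64)
    w[rows, cols] = 1
    if m > L:
        link_p = probs[chosen] / probs[chosen].sum()
        extra = rng.multinomial(m - L, link_p)
        w[rows, cols] += extra
    return w


@dataclass
class NullEnsemble:
    """Per-replicate specialization statistics for one observed web."""

    observed: dict
    replicates: dict  # stat name -> ndarray of per-replicate values
    seed: int | None
    n_reps: int
    matrices: list = field(default_factory=list, repr=False)

    def mean(self, stat: str) -> float:
        return float(np.nanmean(self.replicates[stat]))

    def sd(self, stat: str) -> float:
        return float(np.nanstd(self.replicates[stat], ddof=1))

    def z(self, stat: str) -> float:
        """z-score of the observed statistic against the null ensemble."""
        return z_score(self.observed[stat], self.replicates[stat])

    def summary(self) -> dict:
        out = {}
        for stat in self.replicates:
            try:
                z = self.z(stat)
            except UndefinedMetricError:
                z = None
            out[stat] = {
                "observed": self.observed[stat],
                "null_mean": self.mean(stat),
                "null_sd": self.sd(stat),
                "z": z,
            }
        return out


_STAT_FUNCS = {
    "h2_prime": _metrics.h2_prime,
    "h2": _metrics.shannon_H2,
    "delta_d_prime": _metrics.specialization_asymmetry,
}


def null_ensemble(
    net: BipartiteNetwork,
    n_reps: int = 1000,
    seed: int | None = None,
    stats: tuple = ("h2_prime", "delta_d_prime"),
    keep_matrices: bool = False,
) -> NullEnsemble:
    """Generate a null ensemble and evaluate specialization statistics.

    Replicate r draws from the deterministic substream (seed, r), so
    ensembles are reproducible and order-independent.
    """
    observed = {}
    for stat in stats:
        try:
            observed[stat] = _STAT_FUNCS[stat](net)
        except UndefinedMetricError:
            observed[stat] = None
    reps = {stat: np.full(n_reps, np.nan) for stat in stats}
    matrices = []
    for r in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(r,)))
        w = vaznull_sample(net, rng)
        null_net = BipartiteNetwork.from_weights(
            w, net.plant_labels, net.visitor_labels, prune=False
        )
        if keep_matrices:
            matrices.append(w)
        for stat in stats:
            try:
                reps[stat][r] = _STAT_FUNCS[stat](null_net)
            except UndefinedMetricError:
                pass
    return NullEnsemble(
        observed=observed, replicates=reps, seed=seed, n_reps=n_reps, matrices=matrices
    )


def z_score(observed: float, null_values) -> float:
    """z = (observed - mu_null) / sigma_null, undefined when sigma is 0."""
    if observed is None:
        raise UndefinedMetricError("observed statistic is undefined")
    vals = np.asarray(null_values, dtype=float)
    vals = vals[~np.isnan(vals)]
    sd = vals.std(ddof=1)
    if not sd > 0:
        raise UndefinedMetricError("null ensemble has zero spread")
    return float((observed - vals.mean()) / sd)
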