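"""Weighted bipartite interaction webs.

The central container is :class:`BipartiteNetwork`: a labelled nonnegative
integer matrix of visit counts with plants on the rows and flower-visiting
insects on the columns, the convention used by public interaction-web
databases.  All structural and specialization metrics consume this object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BipartiteNetwork",
    "EmptyNetworkError",
    "UndefinedMetricError",
]


class EmptyNetworkError(ValueError):
    """Raised when an operation needs a nonempty web and gets none."""


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given web.

    Degenerate inputs (single-row webs for NODF, marginals that force a
    unique distribution for H2', ...) raise this rather than returning a
    silent zero, so that report assembly can carry an explicit marker.
    """


@dataclass(frozen=True)
class BipartiteNetwork:
    """A labelled plant x visitor visit-count matrix.

    Parameters
    ----------
    plant_labels : sequence of str
        Row labels (plant taxa).
    visitor_labels : sequence of str
        Column labels (insect taxa).
    weights : ndarray of shape (P, A)
        Nonnegative integer visit counts ``a_ij``.
    metadata : mapping
        Free-form tags (habitat, month, guild, ...).
    """

    plant_labels: tuple
    visitor_labels: tuple
    weights: np.ndarray
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        w = np.asarray(self.weights)
        if w.ndim != 2:
            raise ValueError("weights must be a 2-D matrix")
        if w.size == 0:
            raise EmptyNetworkError("empty interaction matrix")
        if np.any(w < 0):
            raise ValueError("visit counts must be nonnegative")
        if not np.issubdtype(w.dtype, np.integer):
            if not np.allclose(w, np.round(w)):
                raise ValueError("visit counts must be integers")
            w = np.round(w).astype(np.int64)
        else:
            w = w.astype(np.int64)
        if len(self.plant_labels) != w.shape[0]:
            raise ValueError("plant_labels length must match row count")
        if len(self.visitor_labels) != w.shape[1]:
            raise ValueError("visitor_labels length must match column count")
        if w.sum() == 0:
            raise EmptyNetworkError("interaction matrix has no visits")
        object.__setattr__(self, "plant_labels", tuple(self.plant_labels))
        object.__setattr__(self, "visitor_labels", tuple(self.visitor_labels))
        object.__setattr__(self, "weights", w)
        w.setflags(write=False)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_weights(
        cls,
        weights,
        plant_labels: Sequence[str] | None = None,
        visitor_labels: Sequence[str] | None = None,
        metadata: Mapping[str, Any] | None = None,
        prune: bool = True,
    ) -> "BipartiteNetwork":
        """Build a network, by default pruning all-zero rows and columns."""
        w = np.asarray(weights)
        if w.size == 0 or w.sum() == 0:
            raise EmptyNetworkError("cannot build a network without visits")
        if plant_labels is None:
            plant_labels = [f"plant_{i}" for i in range(w.shape[0])]
        if visitor_labels is None:
            visitor_labels = [f"visitor_{j}" for j in range(w.shape[1])]
        plant_labels = list(plant_labels)
        visitor_labels = list(visitor_labels)
        if prune:
            keep_r = w.sum(axis=1) > 0
            keep_c = w.sum(axis=0) > 0
            w = w[np.ix_(keep_r, keep_c)]
            plant_labels = [l for l, k in zip(plant_labels, keep_r) if k]
            visitor_labels = [l for l, k in zip(visitor_labels, keep_c) if k]
        return cls(tuple(plant_labels), tuple(visitor_labels), w, metadata or {})

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, metadata=None, prune=True):
        return cls.from_weights(
            df.to_numpy(), list(df.index), list(df.columns), metadata, prune
        )

    # -- basic quantities --------------------------------------------------
    @property
    def n_plants(self) -> int:
        """Plant richness P."""
        return self.weights.shape[0]

    @property
    def n_visitors(self) -> int:
        """Visitor richness A."""
        return self.weights.shape[1]

    @property
    def total_visits(self) -> int:
        """Grand total m = sum of all a_ij."""
        return int(self.weights.sum())

    @property
    def link_count(self) -> int:
        """Number of realized links L (nonzero cells)."""
        return int(np.count_nonzero(self.weights))

    @property
    def plant_totals(self) -> np.ndarray:
        """Row marginals A_i (total visits received per plant)."""
        return self.weights.sum(axis=1)

    @property
    def visitor_totals(self) -> np.ndarray:
        """Column marginals B_j (total visits made per visitor)."""
        return self.weights.sum(axis=0)

    def binary(self) -> np.ndarray:
        """Presence/absence matrix (any positive weight counts)."""
        return (self.weights > 0).astype(np.int64)

    def transpose(self) -> "BipartiteNetwork":
        return BipartiteNetwork(
            self.visitor_labels, self.plant_labels, self.weights.T, dict(self.metadata)
        )

    def subset_visitors(self, labels: Sequence[str]) -> "BipartiteNetwork":
        """Restrict to the given visitor columns, pruning emptied rows."""
        keep = [j for j, l in enumerate(self.visitor_labels) if l in set(labels)]
        if not keep:
            raise EmptyNetworkError("no matching visitor columns")
        return BipartiteNetwork.from_weights(
            self.weights[:, keep],
            self.plant_labels,
            [self.visitor_labels[j] for j in keep],
            dict(self.metadata),
        )

    # -- I/O ---------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weights, index=list(self.plant_labels), columns=list(self.visitor_labels)
        )

    def to_csv(self, path, sep: str = ",") -> None:
        """Write the labelled matrix plus a JSON metadata sidecar."""
        path = Path(path)
        self.to_dataframe().to_csv(path, sep=sep)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(dict(self.metadata), indent=2, default=str))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        tag = self.metadata.get("tag", "")
        return (
            f"BipartiteNetwork({self.n_plants} plants x {self.n_visitors} visitors, "
            f"m={self.total_visits}, L={self.link_count}{', ' + tag if tag else ''})"
        )
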