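"""Cross-network comparison of published interaction webs.

Reads interaction-web matrices in the public-database convention (rows =
plants, labelled delimited text), tabulates the nine standard measures
across networks, and flags where a focal network lies more than two
(sample) standard deviations from the mean of the reference set.  Ships a
compiled table of summary statistics for ten published flower-visitor
networks plus the Irish national web.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .network import BipartiteNetwork, UndefinedMetricError
from . import metrics as _metrics

__all__ = [
    "load_matrix",
    "summary_row",
    "ComparisonTable",
    "comparison_table",
    "two_sd_flags",
    "richness_ratio_stats",
    "load_reference_table",
    "load_irish_table",
]

#: Metric columns of the comparison grid.
COMPARISON_METRICS = (
    "pollinator_richness",
    "plant_richness",
    "pollinator_weighted_degree",
    "plant_weighted_degree",
    "pollinator_unweighted_degree",
    "plant_unweighted_degree",
    "connectance",
    "nodf",
    "asymmetry",
)


def load_matrix(path, orientation: str = "plants_rows", sep: str = ",") -> BipartiteNetwork:
    """Read a labelled interaction matrix from delimited text.

    Parameters
    ----------
    orientation : {"plants_rows", "visitors_rows"}
        Transposed inputs are flipped so rows are always plants.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    arr = np.empty(df.shape, dtype=float)
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            try:
                arr[i, j] = float(df.iat[i, j])
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r}"
                ) from None
    if np.any(arr < 0):
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"negative count at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("visit counts must be integers")
    if orientation == "visitors_rows":
        df = df.T
        arr = arr.T
    elif orientation != "plants_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        warnings.warn(f"{path.name}: pruning all-zero rows/columns", stacklevel=2)
    return BipartiteNetwork.from_weights(
        np.round(arr).astype(np.int64), list(df.index), list(df.columns),
        {"tag": path.stem},
    )


def summary_row(net: BipartiteNetwork) -> dict:
    """The nine comparison measures for one web."""
    deg = _metrics.mean_degrees(net)
    try:
        ndf = _metrics.nodf(net)
    except UndefinedMetricError:
        ndf = np.nan
    return {
        "pollinator_richness": net.n_visitors,
        "plant_richness": net.n_plants,
        "pollinator_weighted_degree": deg["visitor_weighted"],
        "plant_weighted_degree": deg["plant_weighted"],
        "pollinator_unweighted_degree": deg["visitor_unweighted"],
        "plant_unweighted_degree": deg["plant_unweighted"],
        "connectance": _metrics.connectance(net),
        "nodf": ndf,
        "asymmetry": _metrics.web_asymmetry(net),
    }


@dataclass
class ComparisonTable:
    """Networks x metrics grid with reference statistics and focal flags."""

    table: pd.DataFrame
    focal: str | None
    ref_stats: pd.DataFrame  # mean / sd per metric over the reference set
    flags: pd.Series | None  # focal metric flagged beyond 2 SD (NaN sd -> NA)

    def to_json_dict(self) -> dict:
        out = {
            "focal": self.focal,
            "table": self.table.to_dict(orient="index"),
            "reference": self.ref_stats.to_dict(orient="index"),
        }
        if self.flags is not None:
            out["flags"] = {
                k: (None if pd.isna(v) else bool(v)) for k, v in self.flags.items()
            }
        return out


def comparison_table(
    summaries: pd.DataFrame, focal: str | None = None, min_references: int = 3
) -> ComparisonTable:
    """Build the comparison grid; reference set excludes the focal network."""
    cols = [c for c in COMPARISON_METRICS if c in summaries.columns]
    table = summaries[cols].astype(float)
    ref = table.drop(index=focal) if focal is not None else table
    if focal is not None and len(ref) < min_references:
        raise ValueError(f"need >= {min_references} reference networks")
    ref_stats = pd.DataFrame({"mean": ref.mean(), "sd": ref.std(ddof=1)})
    flags = None
    if focal is not None:
        flags = two_sd_flags(table, focal, ref_stats)
    return ComparisonTable(table=table, focal=focal, ref_stats=ref_stats, flags=flags)


def two_sd_flags(
    table: pd.DataFrame, focal: str, ref_stats: pd.DataFrame | None = None
) -> pd.Series:
    """Flag each metric where the focal value is > 2 sample SD from the
    reference mean; undefined (NA) where the reference SD is zero."""
    if ref_stats is None:
        ref = table.drop(index=focal)
        ref_stats = pd.DataFrame({"mean": ref.mean(), "sd": ref.std(ddof=1)})
    gap = (table.loc[focal] - ref_stats["mean"]).abs()
    flags = (gap > 2 * ref_stats["sd"]).astype("boolean")
    flags[~(ref_stats["sd"] > 0)] = pd.NA
    return flags


def richness_ratio_stats(
    summaries: pd.DataFrame, direction: str = "visitors_per_plant"
) -> tuple[float, float, pd.Series]:
    """Mean and standard error of per-network richness ratios.

    direction "visitors_per_plant" computes A_k / P_k; "plants_per_visitor"
    the inverse.  Networks with a zero denominator are excluded with a
    warning.  SE = sample SD / sqrt(n).
    """
    if direction == "visitors_per_plant":
        num, den = summaries["pollinator_richness"], summaries["plant_richness"]
    elif direction == "plants_per_visitor":
        num, den = summaries["plant_richness"], summaries["pollinator_richness"]
    else:
        raise ValueError(f"unknown direction {direction!r}")
    ok = den > 0
    if not ok.all():
        warnings.warn("excluding networks with zero denominator", stacklevel=2)
    ratios = (num[ok] / den[ok]).astype(float)
    if len(ratios) < 2:
        raise ValueError("need >= 2 networks for ratio statistics")
    return float(ratios.mean()), float(ratios.std(ddof=1) / np.sqrt(len(ratios))), ratios


def _load_packaged(name: str) -> pd.DataFrame:
    with resources.files("pollinet.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, index_col=0)


def load_reference_table() -> pd.DataFrame:
    """Summary measures of the Irish web and ten published networks."""
    return _load_packaged("reference_networks.csv")


def load_irish_table() -> pd.DataFrame:
    """Per-habitat and per-month summary measures of the Irish web."""
    return _load_packaged("irish_networks.csv")
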