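"""Survey-record data model, filtering rules, and network construction.

A record is one plant x insect observation within one transect survey,
carrying effort and trait context (floral units counted, inflorescence
size, native status, habitat classification).  Records are filtered for
taxonomic resolution and single-habitat surveys, then aggregated into
weighted bipartite webs by habitat, month, insect guild, or the full pool.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import BipartiteNetwork, EmptyNetworkError

__all__ = [
    "InteractionRecord",
    "SurveyEvent",
    "SchemaError",
    "RowParseError",
    "read_interaction_table",
    "filter_records",
    "floral_display",
    "build_network",
    "build_networks",
    "DEFAULT_HABITAT_MAP",
    "DEFAULT_STOP_WORDS",
    "is_resolved",
]

GUILDS = ("bee", "syrphid", "lepidopteran")

#: Level-2 habitat subcategory -> level-1 broad class (Fossitt-style typology).
DEFAULT_HABITAT_MAP: dict[str, str] = {
    "agriculture": "intensively-managed",
    "urban": "intensively-managed",
    "coastal dune": "coastal",
    "seminatural grassland": "grassland",
    "amenity grassland": "grassland",
    "hedgerow": "woodland-shrub",
    "scrub": "woodland-shrub",
}

#: Tokens marking a taxon name as unresolved below genus.
DEFAULT_STOP_WORDS = frozenset({"unknown", "unidentified", "indet", "indet."})


class SchemaError(ValueError):
    """A mandatory column is missing from the input table."""


class RowParseError(ValueError):
    """A row-level parse failure (e.g. a bad date), with its line number."""


@dataclass(frozen=True)
class InteractionRecord:
    """One plant x insect observation within one survey."""

    site_id: str
    date: _dt.date
    habitat_l2: str
    plant_taxon: str
    insect_taxon: str
    insect_guild: str
    visits: int
    floral_units: int = 0
    inflorescence_size: float | None = None  # mm^2 per floral unit
    plant_family: str = ""
    plant_native: str = "unknown"  # native | non-native | unknown
    habitat_l1: str = ""
    transect_id: str = ""
    n_habitats: int = 1  # habitat types the surveyor tagged on this survey

    def __post_init__(self):
        if self.visits < 0 or self.floral_units < 0:
            raise ValueError("visits and floral_units must be nonnegative")
        if self.inflorescence_size is not None and not self.inflorescence_size > 0:
            raise ValueError("inflorescence_size must be positive when known")
        if not self.habitat_l1:
            l1 = DEFAULT_HABITAT_MAP.get(self.habitat_l2, "")
            object.__setattr__(self, "habitat_l1", l1)

    @property
    def iso_week(self) -> int:
        """ISO-8601 week-of-year (pooled across years downstream)."""
        return self.date.isocalendar()[1]

    @property
    def month(self) -> int:
        return self.date.month

    @property
    def display(self) -> float | None:
        """Total floral display, or None when inflorescence size is unknown."""
        if self.inflorescence_size is None:
            return None
        return floral_display(self.floral_units, self.inflorescence_size)


@dataclass(frozen=True)
class SurveyEvent:
    """One transect survey: where, when, for how long, over what area."""

    site_id: str
    date: _dt.date
    duration_min: float
    area_m2: float
    habitat_l2: tuple = ()

    def __post_init__(self):
        if not self.duration_min > 0:
            raise ValueError("duration must be positive")
        if not self.area_m2 > 0:
            raise ValueError("area must be positive")


# ---------------------------------------------------------------------------
# parsing

MANDATORY_COLUMNS = (
    "site_id",
    "date",
    "habitat_l2",
    "plant_taxon",
    "insect_taxon",
    "insect_guild",
    "visits",
)

OPTIONAL_COLUMNS = (
    "floral_units",
    "inflorescence_size",
    "plant_family",
    "plant_native",
    "transect_id",
    "n_habitats",
)


def read_interaction_table(
    path,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> list[InteractionRecord]:
    """Read survey records from a delimited text file.

    Parameters
    ----------
    path : path-like
        UTF-8 delimited file with a header row; comma by default, tab
        accepted (autodetected when *sep* is None).
    dialect : mapping, optional
        Maps canonical column names to the file's column names, e.g.
        ``{"plant_taxon": "Plant species"}``.
    """
    path = Path(path)
    if sep is None:
        head = path.open(encoding="utf-8").readline()
        sep = "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    colmap = {k: (dialect or {}).get(k, k) for k in MANDATORY_COLUMNS + OPTIONAL_COLUMNS}
    missing = [colmap[k] for k in MANDATORY_COLUMNS if colmap[k] not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    records = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        raw_date = row[colmap["date"]]
        try:
            date = _dt.date.fromisoformat(raw_date.strip())
        except ValueError as exc:
            raise RowParseError(f"line {line_no}: unparseable date {raw_date!r}") from exc

        def get(key, default=""):
            col = colmap[key]
            return row[col].strip() if col in df.columns else default

        size = get("inflorescence_size")
        native = get("plant_native") or "unknown"
        if native not in ("native", "non-native", "unknown"):
            native = "unknown"
        try:
            rec = InteractionRecord(
                site_id=get("site_id"),
                date=date,
                habitat_l2=get("habitat_l2"),
                plant_taxon=get("plant_taxon"),
                insect_taxon=get("insect_taxon"),
                insect_guild=get("insect_guild"),
                visits=int(float(get("visits") or 0)),
                floral_units=int(float(get("floral_units") or 0)),
                inflorescence_size=float(size) if size else None,
                plant_family=get("plant_family"),
                plant_native=native,
                transect_id=get("transect_id"),
                n_habitats=int(float(get("n_habitats") or 1)),
            )
        except ValueError as exc:
            raise RowParseError(f"line {line_no}: {exc}") from exc
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# filtering

def is_resolved(name: str, stop_words: frozenset = DEFAULT_STOP_WORDS) -> bool:
    """Whether a taxon name is resolved to at least genus.

    A name counts as resolved if it is nonempty and none of its tokens is a
    stop word ("unknown", "unidentified", "indet.").  Aggregate names such
    as ``Taraxacum agg.`` are single taxa and count as resolved.
    """
    tokens = name.strip().lower().split()
    if not tokens:
        return False
    return not any(t.strip(".") in {w.strip(".") for w in stop_words} for t in tokens)


def filter_records(
    records: Iterable[InteractionRecord],
    require_resolved: bool = True,
    require_single_habitat: bool = False,
    stop_words: frozenset = DEFAULT_STOP_WORDS,
) -> tuple[list[InteractionRecord], list[tuple[InteractionRecord, str]]]:
    """Apply inclusion rules; return (kept records, exclusion log).

    Rules: both taxa must be resolved to at least genus; when a habitat
    comparison is requested, surveys tagged with more than one habitat
    type are dropped entirely.  Every dropped record gets exactly one
    logged reason; kept + dropped = input.
    """
    kept, dropped = [], []
    for rec in records:
        if require_resolved and not is_resolved(rec.plant_taxon, stop_words):
            dropped.append((rec, "unresolved plant taxon"))
        elif require_resolved and not is_resolved(rec.insect_taxon, stop_words):
            dropped.append((rec, "unresolved insect taxon"))
        elif require_single_habitat and rec.n_habitats > 1:
            dropped.append((rec, "multiple habitat types in one survey"))
        else:
            kept.append(rec)
    return kept, dropped


def floral_display(floral_units: int, inflorescence_size: float) -> float:
    """Total floral display: floral abundance x inflorescence size (mm^2)."""
    if floral_units < 0:
        raise ValueError("floral_units must be nonnegative")
    if not inflorescence_size > 0:
        raise ValueError("inflorescence_size must be positive")
    return float(floral_units) * float(inflorescence_size)


# ---------------------------------------------------------------------------
# aggregation into webs

def _partition_key(rec: InteractionRecord, partition: str):
    if partition == "full":
        return "full"
    if partition == "habitat_l1":
        return rec.habitat_l1
    if partition == "habitat_l2":
        return rec.habitat_l2
    if partition == "month":
        return rec.month  # pooled across years
    if partition == "guild":
        return rec.insect_guild
    raise ValueError(f"unknown partition {partition!r}")


def build_networks(
    records: Sequence[InteractionRecord],
    partition: str = "full",
    guild: str | None = None,
) -> dict:
    """Aggregate records into one weighted web per partition cell.

    Cell (i, j) sums visits of insect j on plant i within the cell.
    Records with zero visits (plant present but unvisited) never enter a
    web.  Empty partition cells are simply absent from the result.

    Parameters
    ----------
    partition : {"full", "habitat_l1", "habitat_l2", "month", "guild"}
    guild : str, optional
        Restrict to one insect guild before partitioning (the per-subgroup
        recalculation used for plant rankings).
    """
    if guild is not None:
        records = [r for r in records if r.insect_guild == guild]
    cells: dict = {}
    for rec in records:
        if rec.visits <= 0:
            continue
        key = _partition_key(rec, partition)
        cells.setdefault(key, {})
        cell = cells[key]
        pair = (rec.plant_taxon, rec.insect_taxon)
        cell[pair] = cell.get(pair, 0) + rec.visits

    out = {}
    for key, cell in sorted(cells.items(), key=lambda kv: str(kv[0])):
        plants = sorted({p for p, _ in cell})
        insects = sorted({i for _, i in cell})
        w = np.zeros((len(plants), len(insects)), dtype=np.int64)
        p_ix = {p: i for i, p in enumerate(plants)}
        a_ix = {a: j for j, a in enumerate(insects)}
        for (p, a), v in cell.items():
            w[p_ix[p], a_ix[a]] = v
        meta = {"partition": partition, "tag": str(key)}
        if guild:
            meta["guild"] = guild
        out[key] = BipartiteNetwork.from_weights(w, plants, insects, meta)
    return out


def build_network(
    records: Sequence[InteractionRecord], guild: str | None = None
) -> BipartiteNetwork:
    """Pool all records into one web (the "full" partition)."""
    nets = build_networks(records, partition="full", guild=guild)
    if "full" not in nets:
        raise EmptyNetworkError("no positive-visit records to build a network from")
    return nets["full"]
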