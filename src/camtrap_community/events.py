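"""Capture-event processing: independence filtering, survey effort, and
detection matrices.

Raw camera-trap records (one row per photograph burst) are reduced to
independent events with a rolling time window, combined with deployment
tables to account for trap-nights lost to malfunctions, and collapsed into
the species-by-station detection matrix that the occupancy model consumes.
Per-species descriptive summaries (trapping rate, naive occupancy,
elevation range, IUCN status) mirror the standard camera-trap report table.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionData",
    "EffortTable",
    "filter_independent_events",
    "compute_effort",
    "trapping_rate",
    "naive_occupancy",
    "build_detection_matrix",
    "species_elevation_range",
    "tag_conservation_status",
    "species_summary_table",
]


@dataclass
class DetectionData:
    """Species-by-station detection counts with per-station effort.

    ``y[i, j]`` is the number of sampling occasions (trap-nights) at station
    ``j`` on which species ``i`` was detected at least once; ``K[j]`` is the
    number of occasions station ``j`` was active.
    """

    species: list[str]
    stations: list[str]
    y: np.ndarray  # (n_species, n_stations) int
    K: np.ndarray  # (n_stations,) int

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        self.K = np.asarray(self.K, dtype=int)
        if self.y.shape != (len(self.species), len(self.stations)):
            raise ValueError(
                f"y has shape {self.y.shape}, expected "
                f"({len(self.species)}, {len(self.stations)})"
            )
        if self.K.shape != (len(self.stations),):
            raise ValueError("K length must match the station list")
        if np.any(self.K < 0):
            raise ValueError("occasion counts K must be nonnegative")
        if np.any(self.y < 0) or np.any(self.y > self.K[None, :]):
            raise ValueError("detection counts must satisfy 0 <= y_ij <= K_j")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_stations(self) -> int:
        return len(self.stations)

    def to_frame(self) -> pd.DataFrame:
        """Detection matrix as a DataFrame: one row per species, a final
        ``K`` row with per-station occasion counts."""
        df = pd.DataFrame(self.y, index=self.species, columns=self.stations)
        df.loc["K"] = self.K
        df.index.name = "species"
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DetectionData":
        df = pd.read_csv(path, index_col=0)
        if "K" not in df.index:
            raise ValueError("detection matrix file must contain a final 'K' row")
        K = df.loc["K"].to_numpy(dtype=int)
        body = df.drop(index="K")
        return cls(
            species=list(body.index),
            stations=list(df.columns),
            y=body.to_numpy(dtype=int),
            K=K,
        )


@dataclass
class EffortTable:
    """Per-station survey effort.

    ``table`` has one row per station with columns ``station_id``,
    ``trap_nights`` (active nights, i.e. deployment nights minus malfunction
    nights) and ``K`` (sampling occasions; equal to ``trap_nights`` under the
    one-night-per-occasion convention). ``active_nights`` maps each station
    to its set of active calendar dates, used to place events on occasions.
    """

    table: pd.DataFrame
    active_nights: dict[str, set] = field(repr=False)

    @property
    def total_trap_nights(self) -> int:
        return int(self.table["trap_nights"].sum())

    @property
    def stations(self) -> list[str]:
        return list(self.table["station_id"])

    def K(self) -> np.ndarray:
        return self.table["K"].to_numpy(dtype=int)


def _parse_timestamps(records: pd.DataFrame, column: str) -> pd.DataFrame:
    ts = pd.to_datetime(records[column], errors="coerce")
    bad = ts.isna() & records[column].notna()
    if bad.any():
        for idx in records.index[bad]:
            logger.warning(
                "dropping record at line %s: unparseable timestamp %r",
                idx,
                records.loc[idx, column],
            )
    out = records.loc[~ts.isna()].copy()
    out[column] = ts.loc[~ts.isna()]
    return out


def filter_independent_events(
    records: pd.DataFrame,
    window_minutes: float = 30,
    timestamp_col: str = "timestamp",
) -> pd.DataFrame:
    """Reduce raw capture records to independent events.

    Within each (station, species) stream, ordered by time, a record is kept
    iff it is at least ``window_minutes`` after the last *kept* record of
    that stream; the first record of a stream is always kept. Streams at
    different stations, or of different species, never suppress each other.

    Records with unparseable timestamps are dropped with a logged warning.
    Returns the kept records, sorted by station, species, time.
    """
    required = {"station_id", "species", timestamp_col}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    records = _parse_timestamps(records, timestamp_col)
    if records.empty:
        return records

    window = pd.Timedelta(minutes=window_minutes)
    kept_idx: list = []
    for _, grp in records.sort_values(timestamp_col).groupby(
        ["station_id", "species"], sort=True
    ):
        last_kept = None
        for idx, ts in zip(grp.index, grp[timestamp_col]):
            if last_kept is None or ts - last_kept >= window:
                kept_idx.append(idx)
                last_kept = ts
    out = records.loc[kept_idx].sort_values(
        ["station_id", "species", timestamp_col]
    )
    return out.reset_index(drop=True)


def _parse_malfunction_nights(value) -> list[date]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return []
    text = str(value).strip()
    if not text:
        return []
    return [date.fromisoformat(tok.strip()) for tok in text.split(";") if tok.strip()]


def compute_effort(deployments: pd.DataFrame) -> EffortTable:
    """Derive per-station trap-nights from a deployment table.

    Expects columns ``station_id``, ``start_date``, ``end_date`` and
    optionally ``malfunction_nights`` (semicolon-separated ISO dates).
    A trap-night is one night in ``[start_date, end_date)``; malfunction
    nights inside the deployment are subtracted, those outside it are
    ignored with a warning.
    """
    rows = []
    active: dict[str, set] = {}
    for rec in deployments.to_dict("records"):
        sid = str(rec["station_id"])
        start = pd.Timestamp(rec["start_date"]).date()
        end = pd.Timestamp(rec["end_date"]).date()
        if end < start:
            raise ValueError(f"station {sid}: end_date precedes start_date")
        nights = {start + timedelta(days=k) for k in range((end - start).days)}
        for night in _parse_malfunction_nights(rec.get("malfunction_nights")):
            if night in nights:
                nights.discard(night)
            else:
                warnings.warn(
                    f"station {sid}: malfunction night {night} outside "
                    "deployment interval, ignored",
                    stacklevel=2,
                )
        active[sid] = nights
        rows.append(
            {"station_id": sid, "trap_nights": len(nights), "K": len(nights)}
        )
    return EffortTable(table=pd.DataFrame(rows), active_nights=active)


def trapping_rate(n_events: int, trap_nights: int) -> float:
    """Independent events per 100 trap-nights (relative activity index)."""
    if trap_nights <= 0:
        raise ValueError("trapping rate undefined for zero trap-nights")
    return 100.0 * n_events / trap_nights


def naive_occupancy(events: pd.DataFrame, stations: list[str]) -> pd.Series:
    """Fraction of stations with at least one event, per species.

    Uncorrected for imperfect detection; species absent from ``events`` get
    0.0 only if listed there — callers wanting a full species list should
    reindex the result.
    """
    if not stations:
        raise ValueError("station list is empty")
    J = len(stations)
    known = set(stations)
    ev = events[events["station_id"].astype(str).isin(known)]
    counts = ev.groupby("species")["station_id"].nunique()
    return (counts / J).rename("naive_occupancy")


def build_detection_matrix(
    events: pd.DataFrame, effort: EffortTable
) -> DetectionData:
    """Collapse independent events into occasion-level detection counts.

    The occasion is one trap-night (calendar date); multiple same-night
    events of a species at a station contribute a single detection. Events
    dated outside a station's active nights (unknown station, malfunction
    night, or outside the deployment) are excluded with a warning.
    """
    stations = effort.stations
    K = effort.K()
    species = sorted(events["species"].unique())
    y = np.zeros((len(species), len(stations)), dtype=int)
    sp_ix = {s: i for i, s in enumerate(species)}
    st_ix = {s: j for j, s in enumerate(stations)}

    n_excluded = 0
    seen: set[tuple[int, int, date]] = set()
    ts = pd.to_datetime(events["timestamp"])
    for sid, sp, stamp in zip(events["station_id"].astype(str), events["species"], ts):
        night = stamp.date()
        if sid not in st_ix or night not in effort.active_nights[sid]:
            n_excluded += 1
            continue
        key = (sp_ix[sp], st_ix[sid], night)
        if key not in seen:
            seen.add(key)
            y[key[0], key[1]] += 1
    if n_excluded:
        warnings.warn(
            f"{n_excluded} event(s) outside the effort window were excluded",
            stacklevel=2,
        )
    # drop species that lost all their events to effort exclusions
    nonzero = y.sum(axis=1) > 0
    return DetectionData(
        species=[s for s, keep in zip(species, nonzero) if keep],
        stations=stations,
        y=y[nonzero],
        K=K,
    )


def species_elevation_range(events: pd.DataFrame) -> pd.DataFrame:
    """Min and max capture elevation per species (NaN when unavailable)."""
    if "elevation_m" not in events.columns:
        raise ValueError("events table has no elevation_m column")
    grp = events.groupby("species")["elevation_m"]
    out = pd.DataFrame(
        {"elev_min_m": grp.min(), "elev_max_m": grp.max()}
    )
    return out


THREATENED_CATEGORIES = ("EN", "VU", "NT")


def tag_conservation_status(
    summaries: pd.DataFrame, lookup: pd.DataFrame | dict
) -> pd.DataFrame:
    """Attach IUCN Red List categories to a per-species summary table.

    ``lookup`` maps species name to category code (EN/VU/NT/LC); a DataFrame
    with columns ``species`` and ``iucn_status`` is also accepted. Species
    missing from the lookup are labelled ``unknown`` with a warning. The
    result carries the count of threatened-or-near-threatened species
    (EN/VU/NT) in ``df.attrs["n_threatened"]``.
    """
    if isinstance(lookup, pd.DataFrame):
        mapping = dict(zip(lookup["species"], lookup["iucn_status"]))
    else:
        mapping = dict(lookup)
    out = summaries.copy()
    status = [mapping.get(sp, "unknown") for sp in out["species"]]
    n_missing = sum(1 for s in status if s == "unknown")
    if n_missing:
        warnings.warn(
            f"{n_missing} species missing from the IUCN lookup, labelled 'unknown'",
            stacklevel=2,
        )
    out["iucn_status"] = status
    out.attrs["n_threatened"] = int(
        sum(s in THREATENED_CATEGORIES for s in status)
    )
    return out


def species_summary_table(
    events: pd.DataFrame,
    effort: EffortTable,
    iucn_lookup: pd.DataFrame | dict | None = None,
) -> pd.DataFrame:
    """Per-species descriptive summary from independent events.

    Columns: species, n_events, trapping_rate (events / 100 trap-nights,
    1 decimal), naive_occupancy (2 decimals), elev_min_m, elev_max_m and,
    when a lookup is given, iucn_status.
    """
    total_tn = effort.total_trap_nights
    counts = events.groupby("species").size().rename("n_events")
    occ = naive_occupancy(events, effort.stations)
    out = pd.DataFrame({"n_events": counts}).reset_index()
    out["trapping_rate"] = out["n_events"].map(
        lambda n: round(trapping_rate(int(n), total_tn), 1)
    )
    out["naive_occupancy"] = (
        out["species"].map(occ).fillna(0.0).round(2)
    )
    if "elevation_m" in events.columns:
        rng = species_elevation_range(events)
        out = out.merge(rng, left_on="species", right_index=True, how="left")
    if iucn_lookup is not None:
        out = tag_conservation_status(out, iucn_lookup)
    return out
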