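"""Elevation-distribution summaries and physiographic-zone classification.

Capture elevations are summarised with Tukey box-plot statistics and
classified into Nepal's physiographic zones (Terai below 300 m, Churia
300-700 m, middle mountain 700-2000 m, high mountain 2000-2500 m, high
Himal above). Zone bounds are half-open [lower, upper) so the zones
partition the elevation axis; elevations above 2000 m additionally flag
the high-altitude range used to characterise mountain tiger habitat.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ZoneScheme",
    "DEFAULT_ZONES",
    "COLLAPSED_ZONES",
    "ElevationSummary",
    "boxplot_stats",
    "classify_zone",
    "zone_percentages",
    "refugia_overlap",
    "point_in_polygon",
]

HIGH_ALTITUDE_CUTOFF_M = 2000.0


@dataclass(frozen=True)
class ZoneScheme:
    """Ordered half-open elevation bands covering the whole axis."""

    zones: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        prev_hi = None
        for name, lo, hi in self.zones:
            if not lo < hi:
                raise ValueError(f"zone {name}: lower bound must be below upper")
            if prev_hi is not None and lo != prev_hi:
                raise ValueError("zones must tile the axis without gaps or overlap")
            prev_hi = hi
        if self.zones[0][1] != -np.inf or self.zones[-1][2] != np.inf:
            raise ValueError("zones must cover (-inf, inf)")

    @property
    def names(self) -> list[str]:
        return [z[0] for z in self.zones]


DEFAULT_ZONES = ZoneScheme(
    zones=(
        ("terai", -np.inf, 300.0),
        ("churia", 300.0, 700.0),
        ("middle_mountain", 700.0, 2000.0),
        ("high_mountain", 2000.0, 2500.0),
        ("high_himal", 2500.0, np.inf),
    )
)

#: collapsed three-band scheme (<300, 300-700, >700) used for range-wide
#: tiger capture summaries
COLLAPSED_ZONES = ZoneScheme(
    zones=(
        ("below_300", -np.inf, 300.0),
        ("300_to_700", 300.0, 700.0),
        ("above_700", 700.0, np.inf),
    )
)


@dataclass
class ElevationSummary:
    """Tukey box-plot statistics of one group's capture elevations."""

    group: str
    n: int
    min: float
    q1: float
    median: float
    mean: float
    q3: float
    max: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def boxplot_stats(elevations, group: str = "") -> ElevationSummary:
    """Quartiles by linear interpolation, whiskers at the most extreme
    points within 1.5 IQR of the quartiles, values beyond flagged as
    outliers."""
    x = np.asarray(elevations, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) == 0:
        raise ValueError("no elevations to summarise")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = x[(x < lo_fence) | (x > hi_fence)]
    return ElevationSummary(
        group=group,
        n=len(x),
        min=float(x.min()),
        q1=float(q1),
        median=float(med),
        mean=float(x.mean()),
        q3=float(q3),
        max=float(x.max()),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=np.sort(outliers),
    )


def classify_zone(
    elevation_m: float, scheme: ZoneScheme = DEFAULT_ZONES
) -> tuple[str, bool]:
    """Zone label for one elevation, plus the high-altitude-range flag
    (elevation above 2000 m)."""
    if not np.isfinite(elevation_m):
        raise ValueError("elevation must be finite")
    if elevation_m < 0:
        warnings.warn(
            f"negative elevation {elevation_m} m classified anyway", stacklevel=2
        )
    for name, lo, hi in scheme.zones:
        if lo <= elevation_m < hi:
            return name, elevation_m > HIGH_ALTITUDE_CUTOFF_M
    raise AssertionError("zone scheme does not cover the axis")  # pragma: no cover


def zone_percentages(
    elevations, scheme: ZoneScheme = DEFAULT_ZONES
) -> pd.Series:
    """Percentage of captures per zone (sums to 100).

    Missing elevations are excluded; their count is reported in
    ``attrs['n_missing']``.
    """
    x = np.asarray(pd.Series(elevations, dtype=float))
    missing = int(np.isnan(x).sum())
    x = x[~np.isnan(x)]
    if len(x) == 0:
        raise ValueError("no non-missing elevations")
    counts = {name: 0 for name in scheme.names}
    for v in x:
        counts[classify_zone(float(v), scheme)[0]] += 1
    pct = pd.Series(counts, dtype=float) / len(x) * 100.0
    pct.attrs["n_missing"] = missing
    return pct


def point_in_polygon(x: float, y: float, ring: np.ndarray) -> bool:
    """Even-odd ray casting; ``ring`` is an (n, 2) array of vertices."""
    ring = np.asarray(ring, dtype=float)
    inside = False
    n = len(ring)
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x < x_cross:
                inside = not inside
    return inside


def refugia_overlap(
    points: pd.DataFrame,
    station_mask: dict | pd.Series | None = None,
    polygons: list[np.ndarray] | None = None,
) -> float:
    """Percentage of capture locations falling inside mapped refugia.

    Either ``station_mask`` (station_id -> bool, from a precomputed refugia
    attribute) or ``polygons`` (list of (n, 2) lon/lat rings; even-odd rule)
    must be supplied. ``points`` needs ``station_id`` or ``lon``/``lat``
    columns accordingly.
    """
    if station_mask is None and polygons is None:
        raise ValueError(
            "supply a per-station boolean mask or refugia polygons; the "
            "refugia layer itself is an input, not computed here"
        )
    if len(points) == 0:
        raise ValueError("no points")
    if station_mask is not None:
        mask = pd.Series(station_mask)
        flags = points["station_id"].astype(str).map(mask.astype(bool))
        if flags.isna().any():
            missing = sorted(points.loc[flags.isna(), "station_id"].unique())
            raise ValueError(f"stations missing from the refugia mask: {missing}")
        inside = int(flags.sum())
    else:
        inside = 0
        for _, row in points.iterrows():
            hit = any(
                point_in_polygon(float(row["lon"]), float(row["lat"]), ring)
                for ring in polygons
            )
            inside += hit
    return 100.0 * inside / len(points)
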