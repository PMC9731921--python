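"""Circular statistics for diel activity patterns.

Times of day are mapped to angles (midnight = 0 rad, angle = 2*pi *
seconds-since-midnight / 86400) and summarised by a fitted von Mises
distribution, a Rayleigh uniformity test, clock-based day/night/twilight
fractions and a four-way activity classification (diurnal, nocturnal,
crepuscular, cathemeral). Day is 06:00-17:59, night 18:00-05:59; twilight
is the union of 05:00-07:00 and 17:00-19:00.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import i0e, i1e

__all__ = [
    "ActivitySample",
    "VonMisesFit",
    "ActivitySummary",
    "ClassThresholds",
    "to_circular",
    "fit_von_mises",
    "rayleigh_test",
    "day_night_partition",
    "twilight_fraction",
    "classify_activity",
    "hourly_histogram",
    "summarize_activity",
    "compare_activity_tables",
]

TWO_PI = 2.0 * np.pi
SECONDS_PER_DAY = 86400
KAPPA_CAP = 500.0

DAY_WINDOW = (6.0, 18.0)                      # [06:00, 18:00)
TWILIGHT_WINDOWS = ((5.0, 7.0), (17.0, 19.0))  # dawn and dusk


@dataclass
class ActivitySample:
    """Circular times-of-day for one species."""

    species: str
    angles: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.mod(np.asarray(self.angles, dtype=float), TWO_PI)

    @property
    def n(self) -> int:
        return len(self.angles)

    @property
    def hours(self) -> np.ndarray:
        return self.angles / TWO_PI * 24.0


def to_circular(timestamps, species: str = "") -> ActivitySample:
    """Map timestamps (or datetime-likes) to angles in [0, 2*pi).

    Entries without a parseable time component are dropped with a warning.
    """
    ts = pd.to_datetime(pd.Series(timestamps), errors="coerce")
    bad = ts.isna()
    if bad.any():
        warnings.warn(
            f"dropped {int(bad.sum())} record(s) without a parseable time",
            stacklevel=2,
        )
        ts = ts[~bad]
    secs = ts.dt.hour * 3600 + ts.dt.minute * 60 + ts.dt.second
    angles = secs.to_numpy(dtype=float) / SECONDS_PER_DAY * TWO_PI
    return ActivitySample(species=species, angles=angles)


@dataclass(frozen=True)
class VonMisesFit:
    mu: float          # mean direction, radians in [0, 2*pi)
    kappa: float
    rbar: float        # mean resultant length
    degenerate: bool = False  # rbar ~ 0: mean direction undefined

    @property
    def mean_time(self) -> str:
        """Mean direction as hh:mm."""
        mins = int(round(self.mu / TWO_PI * 24 * 60)) % (24 * 60)
        return f"{mins // 60:02d}:{mins % 60:02d}"


def _a1(kappa: float) -> float:
    """A(kappa) = I1(kappa) / I0(kappa)."""
    return i1e(kappa) / i0e(kappa)


def _a1_inv(rbar: float) -> float:
    """Invert the Bessel ratio: Best-Fisher start + Newton refinement."""
    if rbar <= 0:
        return 0.0
    # A(k) ~ 1 - 1/(2k), so rbar this close to 1 is already past the cap
    if rbar >= 1.0 - 1.0 / (2.0 * KAPPA_CAP):
        return KAPPA_CAP
    if rbar < 0.53:
        k = 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    elif rbar < 0.85:
        k = -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    else:
        k = 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)
    for _ in range(50):
        a = _a1(k)
        if abs(a - rbar) < 1e-9:
            break
        # A'(k) = 1 - A^2 - A/k
        deriv = 1 - a * a - a / k if k > 0 else 0.5
        step = (a - rbar) / deriv
        k = k - step
        if k <= 0:
            k = 1e-8
        if k > KAPPA_CAP:
            return KAPPA_CAP
    return min(k, KAPPA_CAP)


def fit_von_mises(sample: ActivitySample | np.ndarray) -> VonMisesFit:
    """Maximum-likelihood von Mises fit by trigonometric moments.

    mu = atan2(sum sin, sum cos); rbar = |resultant| / n; kappa solves
    A(kappa) = rbar where A = I1/I0 (capped at 500). With rbar = 0
    (e.g. antipodal data) the mean direction is undefined; the atan2(0, 0)
    convention of 0 is reported with ``degenerate=True``.
    """
    angles = sample.angles if isinstance(sample, ActivitySample) else np.asarray(sample)
    if len(angles) == 0:
        raise ValueError("cannot fit a circular distribution to an empty sample")
    C = float(np.sum(np.cos(angles)))
    S = float(np.sum(np.sin(angles)))
    n = len(angles)
    rbar = float(np.hypot(C, S) / n)
    degenerate = rbar < 1e-12
    mu = 0.0 if degenerate else float(np.mod(np.arctan2(S, C), TWO_PI))
    kappa = 0.0 if degenerate else _a1_inv(rbar)
    return VonMisesFit(mu=mu, kappa=kappa, rbar=rbar, degenerate=degenerate)


def rayleigh_test(sample: ActivitySample | np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity.

    Z = n * rbar^2; the p-value uses the standard fourth-order series
    approximation, clamped to [0, 1]. Requires n >= 4.
    """
    angles = sample.angles if isinstance(sample, ActivitySample) else np.asarray(sample)
    n = len(angles)
    if n < 4:
        raise ValueError("Rayleigh test requires at least 4 observations")
    rbar = fit_von_mises(angles).rbar
    Z = n * rbar**2
    p = np.exp(-Z) * (
        1
        + (2 * Z - Z**2) / (4 * n)
        - (24 * Z - 132 * Z**2 + 76 * Z**3 - 9 * Z**4) / (288 * n**2)
    )
    return float(Z), float(np.clip(p, 0.0, 1.0))


def day_night_partition(
    sample: ActivitySample | np.ndarray,
) -> tuple[float, float]:
    """Fractions of events in the day (06:00-17:59) and night windows.

    The two fractions sum to 1 exactly.
    """
    hours = (
        sample.hours
        if isinstance(sample, ActivitySample)
        else np.mod(np.asarray(sample), TWO_PI) / TWO_PI * 24.0
    )
    if len(hours) == 0:
        raise ValueError("empty sample")
    day = float(np.mean((hours >= DAY_WINDOW[0]) & (hours < DAY_WINDOW[1])))
    return day, 1.0 - day


def twilight_fraction(sample: ActivitySample | np.ndarray) -> float:
    """Fraction of events at twilight (05:00-07:00 or 17:00-19:00)."""
    hours = (
        sample.hours
        if isinstance(sample, ActivitySample)
        else np.mod(np.asarray(sample), TWO_PI) / TWO_PI * 24.0
    )
    mask = np.zeros(len(hours), dtype=bool)
    for lo, hi in TWILIGHT_WINDOWS:
        mask |= (hours >= lo) & (hours < hi)
    return float(np.mean(mask))


@dataclass(frozen=True)
class ClassThresholds:
    """Cutoffs of the four-way activity classification.

    Crepuscular wins first when the twilight fraction reaches
    ``crepuscular``; otherwise diurnal/nocturnal need the corresponding
    fraction to reach their cutoffs; anything else is cathemeral. Samples
    below ``min_n`` events are labelled ``insufficient-data``.
    """

    crepuscular: float = 0.50
    diurnal: float = 0.60
    nocturnal: float = 0.60
    min_n: int = 5


def classify_activity(
    sample: ActivitySample | np.ndarray,
    thresholds: ClassThresholds = ClassThresholds(),
) -> str:
    angles = sample.angles if isinstance(sample, ActivitySample) else np.asarray(sample)
    if len(angles) < thresholds.min_n:
        return "insufficient-data"
    twil = twilight_fraction(angles)
    day, night = day_night_partition(angles)
    if twil >= thresholds.crepuscular:
        return "crepuscular"
    if day >= thresholds.diurnal:
        return "diurnal"
    if night >= thresholds.nocturnal:
        return "nocturnal"
    return "cathemeral"


def hourly_histogram(sample: ActivitySample | np.ndarray) -> np.ndarray:
    """Proportion of events per clock hour (24 half-open bins [h, h+1))."""
    hours = (
        sample.hours
        if isinstance(sample, ActivitySample)
        else np.mod(np.asarray(sample), TWO_PI) / TWO_PI * 24.0
    )
    if len(hours) == 0:
        raise ValueError("empty sample")
    counts, _ = np.histogram(hours, bins=np.arange(25))
    return counts / counts.sum()


@dataclass
class ActivitySummary:
    species: str
    n: int
    mean_direction: float
    mean_time: str
    rbar: float
    kappa: float
    rayleigh_z: float | None
    rayleigh_p: float | None
    day_fraction: float
    night_fraction: float
    twilight_fraction: float
    activity_class: str
    hourly_props: np.ndarray = field(repr=False)
    thresholds: ClassThresholds = field(default_factory=ClassThresholds)


def summarize_activity(
    sample: ActivitySample, thresholds: ClassThresholds = ClassThresholds()
) -> ActivitySummary:
    """Full circular summary of one species' event times."""
    fit = fit_von_mises(sample)
    z, p = (None, None) if sample.n < 4 else rayleigh_test(sample)
    day, night = day_night_partition(sample)
    return ActivitySummary(
        species=sample.species,
        n=sample.n,
        mean_direction=fit.mu,
        mean_time=fit.mean_time,
        rbar=fit.rbar,
        kappa=fit.kappa,
        rayleigh_z=z,
        rayleigh_p=p,
        day_fraction=day,
        night_fraction=night,
        twilight_fraction=twilight_fraction(sample),
        activity_class=classify_activity(sample, thresholds),
        hourly_props=hourly_histogram(sample),
        thresholds=thresholds,
    )


def compare_activity_tables(
    summaries: pd.DataFrame, reference: pd.DataFrame
) -> pd.DataFrame:
    """Side-by-side comparison of activity classes against a reference table.

    Both frames need ``species`` and ``activity_class`` columns; the
    reference classes are supplied data (e.g. published results), never
    recomputed. The result lists every species from either table with an
    ``agree`` flag (NaN where one side is missing) and carries the counts
    in ``attrs``: ``n_compared``, ``n_agree``, ``unmatched``.
    """
    left = summaries[["species", "activity_class"]].rename(
        columns={"activity_class": "class_study"}
    )
    right = reference[["species", "activity_class"]].rename(
        columns={"activity_class": "class_reference"}
    )
    merged = left.merge(right, on="species", how="outer")
    both = merged["class_study"].notna() & merged["class_reference"].notna()
    merged["agree"] = np.where(
        both, merged["class_study"] == merged["class_reference"], np.nan
    )
    merged.attrs["n_compared"] = int(both.sum())
    merged.attrs["n_agree"] = int(merged.loc[both, "agree"].sum())
    merged.attrs["unmatched"] = sorted(merged.loc[~both, "species"])
    return merged
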