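"""GPS track ingest, filtering, regularization and step metrics.

A :class:`Trip` is one night-time foraging trip: a timestamped planar
track with a nominal 15 s fix interval. From each trip a
:class:`StepSeries` is derived — per-location step length, speed and
turn angle — which is the common input to all segmentation methods.

Conventions (fixed so that per-method "omitted point" counts are
well defined):

* the speed/step of the pair (i-1, i) is assigned to the *later*
  location i, so location 0 has no speed;
* the turn angle is assigned to the *vertex* location, so locations 0
  and n-1 have no turn angle (n-2 turn angles for n locations);
* a method needing both metrics therefore omits exactly 2 locations
  per trip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .projection import utm_forward

MOVEBANK_COLUMNS = {
    "id": "individual-local-identifier",
    "timestamp": "timestamp",
    "lon": "location-long",
    "lat": "location-lat",
}


class TrackFormatError(ValueError):
    """Raised when a track table is missing required columns."""


class TrackDataError(ValueError):
    """Raised when a track table's contents are invalid (duplicates, empty...)."""


@dataclass
class Trip:
    """Timestamped planar track (meters), times in seconds since trip start."""

    trip_id: str
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    nominal_dt: float = 15.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.times) == len(self.x) == len(self.y)):
            raise TrackDataError("times, x, y must have equal length")
        if len(self.times) < 2:
            raise TrackDataError("a trip needs at least 2 locations")
        if not np.all(np.isfinite(self.x)) or not np.all(np.isfinite(self.y)):
            raise TrackDataError("non-finite coordinates")
        if np.any(np.diff(self.times) <= 0):
            raise TrackDataError("times must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.times)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def positions(self) -> np.ndarray:
        return np.column_stack((self.x, self.y))


@dataclass
class FilterConfig:
    """Spatial pre-filter: drop near-roost locations, reject short tracks."""

    exclusion_radius: float = 250.0   # m around the roost/island
    min_locations: int = 100

    def __post_init__(self) -> None:
        if self.exclusion_radius <= 0:
            raise ValueError("exclusion_radius must be > 0")
        if self.min_locations < 2:
            raise ValueError("min_locations must be >= 2")


@dataclass
class StepSeries:
    """Per-location movement metrics; NaN marks undefined entries.

    ``speed``/``step_length`` are undefined at location 0; ``turn_*`` at
    locations 0 and n-1 (and at vertices touching a zero-length step,
    where heading is indeterminate).
    """

    step_length: np.ndarray   # m, assigned to the step's end location
    speed: np.ndarray         # m/s
    heading: np.ndarray       # rad, heading of the incoming step
    turn_signed: np.ndarray   # rad in (-pi, pi], assigned to the vertex
    turn_abs: np.ndarray      # degrees in [0, 180]
    dt: float = 15.0
    trip_id: str = ""

    def __len__(self) -> int:
        return len(self.speed)

    @property
    def speed_defined(self) -> np.ndarray:
        return ~np.isnan(self.speed)

    @property
    def turn_defined(self) -> np.ndarray:
        return ~np.isnan(self.turn_signed)

    @property
    def both_defined(self) -> np.ndarray:
        return self.speed_defined & self.turn_defined


def read_track(
    path,
    columns: dict | None = None,
    utm_zone: int = 12,
    northern: bool = True,
    nominal_dt: float = 15.0,
) -> Trip:
    """Read a track CSV (Movebank dialect or pre-projected x/y) into a Trip.

    Accepts either ``location-long``/``location-lat`` (projected to UTM at
    ingest) or planar ``x``/``y`` columns in meters. Times may be ISO-8601
    timestamps (``timestamp``) or numeric seconds (``time_s``). Rows are
    sorted by time; duplicate timestamps are rejected.

    Parameters
    ----------
    columns
        Optional mapping overriding column names, keys among
        ``{"id", "timestamp", "lon", "lat", "x", "y", "time_s"}``.
    """
    df = pd.read_csv(path)
    cols = dict(MOVEBANK_COLUMNS)
    cols.setdefault("x", "x")
    cols.setdefault("y", "y")
    cols.setdefault("time_s", "time_s")
    if columns:
        cols.update(columns)

    # --- time axis
    if cols["timestamp"] in df.columns:
        ts = pd.to_datetime(df[cols["timestamp"]], utc=True, format="mixed")
        t = (ts - ts.min()).dt.total_seconds().to_numpy()
    elif cols["time_s"] in df.columns:
        t = df[cols["time_s"]].to_numpy(dtype=float)
        t = t - t.min()
    else:
        raise TrackFormatError(
            f"no time column: expected '{cols['timestamp']}' or '{cols['time_s']}'"
        )

    # --- coordinates
    if cols["x"] in df.columns and cols["y"] in df.columns:
        x = df[cols["x"]].to_numpy(dtype=float)
        y = df[cols["y"]].to_numpy(dtype=float)
    elif cols["lon"] in df.columns and cols["lat"] in df.columns:
        x, y = utm_forward(
            df[cols["lon"]].to_numpy(dtype=float),
            df[cols["lat"]].to_numpy(dtype=float),
            zone=utm_zone,
            northern=northern,
        )
    else:
        raise TrackFormatError(
            f"no coordinate columns: expected ('{cols['x']}','{cols['y']}') "
            f"or ('{cols['lon']}','{cols['lat']}')"
        )

    id_col = cols["id"] if cols["id"] in df.columns else (
        "trip_id" if "trip_id" in df.columns else None
    )
    if id_col is not None:
        ids = df[id_col].astype(str).unique()
        if len(ids) > 1:
            raise TrackDataError(f"multiple individuals in one track file: {ids}")
        trip_id = str(ids[0])
    else:
        trip_id = "track"

    order = np.argsort(t, kind="stable")
    t, x, y = t[order], x[order], y[order]
    if np.any(np.diff(t) == 0):
        raise TrackDataError("duplicate timestamps")
    return Trip(trip_id=trip_id, times=t, x=x, y=y, nominal_dt=nominal_dt)


def write_track(trip: Trip, path) -> None:
    """Write a Trip to CSV (``trip_id, time_s, x, y``), full float precision."""
    pd.DataFrame(
        {"trip_id": trip.trip_id, "time_s": trip.times, "x": trip.x, "y": trip.y}
    ).to_csv(path, index=False)


def read_labels(path) -> pd.DataFrame:
    """Read a labels CSV (``trip_id, time_s, state``)."""
    df = pd.read_csv(path)
    need = {"trip_id", "time_s", "state"}
    if not need.issubset(df.columns):
        raise TrackFormatError(f"labels CSV needs columns {sorted(need)}")
    return df


def filter_track(trip: Trip, origin, cfg: FilterConfig | None = None) -> Trip | None:
    """Drop locations within ``cfg.exclusion_radius`` of ``origin``.

    Returns None (track rejected) if fewer than ``cfg.min_locations``
    survive — short tracks and near-roost circling carry no usable
    foraging signal. Idempotent.
    """
    cfg = cfg or FilterConfig()
    ox, oy = float(origin[0]), float(origin[1])
    d = np.hypot(trip.x - ox, trip.y - oy)
    keep = d > cfg.exclusion_radius
    if int(keep.sum()) < cfg.min_locations:
        return None
    return Trip(
        trip_id=trip.trip_id,
        times=trip.times[keep],
        x=trip.x[keep],
        y=trip.y[keep],
        nominal_dt=trip.nominal_dt,
    )


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap radians to (-pi, pi]."""
    out = np.mod(a + np.pi, 2.0 * np.pi) - np.pi
    # np.mod maps odd multiples of pi to -pi; convention here is (-pi, pi]
    out[out == -np.pi] = np.pi
    return out


def compute_steps(trip: Trip) -> StepSeries:
    """Step length, speed and turn angle for each pair of successive locations.

    Zero-length steps leave the heading — and hence the turn angles at
    both adjacent vertices — undefined (NaN).
    """
    n = trip.n
    dx = np.diff(trip.x)
    dy = np.diff(trip.y)
    dtv = np.diff(trip.times)
    L = np.hypot(dx, dy)

    step_length = np.full(n, np.nan)
    speed = np.full(n, np.nan)
    heading = np.full(n, np.nan)
    step_length[1:] = L
    speed[1:] = L / dtv
    h = np.where(L > 0, np.arctan2(dy, dx), np.nan)
    heading[1:] = h

    turn_signed = np.full(n, np.nan)
    if n >= 3:
        turn_signed[1:-1] = _wrap_angle(h[1:] - h[:-1])
    turn_abs = np.degrees(np.abs(turn_signed))

    return StepSeries(
        step_length=step_length,
        speed=speed,
        heading=heading,
        turn_signed=turn_signed,
        turn_abs=turn_abs,
        dt=float(trip.nominal_dt),
        trip_id=trip.trip_id,
    )


def regularize(
    trip: Trip, dt: float | None = None, max_gap_s: float = 600.0
) -> list[Trip]:
    """Resample a trip onto an arithmetic time grid by linear interpolation.

    Positions inside gaps are linearly interpolated; nothing is
    extrapolated beyond the endpoints. Gaps longer than ``max_gap_s``
    (default 10 min) are not bridged: the trip is split there and each
    piece regularized separately, so the result is a list (a single
    element for gap-free input).
    """
    if dt is None:
        dt = trip.nominal_dt
    if dt <= 0:
        raise ValueError("dt must be > 0")

    gaps = np.nonzero(np.diff(trip.times) > max_gap_s)[0]
    bounds = np.concatenate(([0], gaps + 1, [trip.n]))
    out: list[Trip] = []
    for k, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        if b - a < 2:
            continue
        t = trip.times[a:b]
        n_grid = int(np.floor((t[-1] - t[0]) / dt)) + 1
        grid = t[0] + dt * np.arange(n_grid)
        x = np.interp(grid, t, trip.x[a:b])
        y = np.interp(grid, t, trip.y[a:b])
        tid = trip.trip_id if len(bounds) == 2 else f"{trip.trip_id}#{k}"
        if n_grid >= 2:
            out.append(Trip(trip_id=tid, times=grid, x=x, y=y, nominal_dt=dt))
    if len(bounds) > 2:
        warnings.warn(
            f"trip {trip.trip_id}: {len(bounds) - 2} gap(s) > {max_gap_s:g} s; "
            f"split into {len(out)} pieces",
            stacklevel=2,
        )
    if not out:
        raise TrackDataError("regularization left no usable piece")
    return out


def subsample(trip: Trip, interval: float) -> Trip:
    """Keep every k-th fix, k = interval / nominal_dt (must be integral)."""
    k = interval / trip.nominal_dt
    if abs(k - round(k)) > 1e-9 or round(k) < 1:
        raise ValueError(
            f"interval {interval} is not a positive multiple of nominal_dt "
            f"{trip.nominal_dt}"
        )
    k = int(round(k))
    if k == 1:
        return trip
    return Trip(
        trip_id=trip.trip_id,
        times=trip.times[::k],
        x=trip.x[::k],
        y=trip.y[::k],
        nominal_dt=trip.nominal_dt * k,
    )
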