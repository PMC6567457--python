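"""Synthetic bat foraging trips with known states, buzzes and call trains.

The generator emulates the movement and acoustics of a trawling bat's
night trip as a two-state semi-Markov kinematic model:

* **commuting** — fast (~5.3 m/s), nearly straight flight (von Mises
  heading increments with high concentration);
* **foraging** — slow (~3.4 m/s), tortuous area-restricted search (low
  heading concentration), in bouts of minutes-scale exponential
  duration, during which feeding buzzes are emitted as a Poisson
  process (exponential inter-buzz gaps, hence the exponentially
  decreasing inter-buzz-interval tail seen in clustered prey attacks).

Fixes are taken every 15 s, perturbed by isotropic Gaussian GPS error
(~8 m per axis); audio is duty-cycled (0.5 s of every 5 s), which is
what makes buzz-positive fixes sparse even inside foraging bouts.

Movement is deliberately generated by a switching kinematic model
rather than by any of the models the segmentation methods assume
(HMM-with-gamma-steps or Ornstein-Uhlenbeck velocities), so that no
method is evaluated on data drawn from its own assumptions. A separate
OU simulator lives in :mod:`batseg.cvcp` for that model's oracles.

All randomness flows from a single integer seed through
``numpy.random.default_rng`` spawning: trip k of a suite uses
``default_rng([seed, k])``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .acoustics import Call, DutyCycle
from .states import COMMUTING, FORAGING, StateSequence
from .tracks import Trip


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults follow the field study being emulated: 15 s fixes, trip
    durations 3.4 +/- 1.8 h, commuting at 5.3 +/- 0.4 m/s with heading
    concentration ~11 (mean absolute turn ~19 deg), foraging at
    3.4 +/- 0.5 m/s with concentration ~0.2 (near-uniform turns),
    foraging bouts of ~5 min, ~8 m planar GPS noise, and a 10% audio
    duty cycle. The commute-phase buzz rate is small but non-zero
    (stray attacks on outbound flight are occasionally recorded).
    """

    dt: float = 15.0                      # s between fixes
    trip_hours_mean: float = 3.4
    trip_hours_sd: float = 1.8
    trip_hours_range: tuple[float, float] = (0.9, 6.4)
    commute_speed_mean: float = 5.3       # m/s
    commute_speed_sd: float = 0.4
    forage_speed_mean: float = 3.4        # m/s
    forage_speed_sd: float = 0.5
    commute_kappa: float = 11.0           # von Mises heading-increment concentration
    forage_kappa: float = 0.2
    forage_bout_mean_s: float = 300.0     # mean foraging bout, 5 min
    commute_bout_mean_s: float = 600.0    # mean commuting stretch, 10 min
    buzz_rate_foraging: float = 5.0       # buzzes / min while foraging
    buzz_rate_commute: float = 0.05       # buzzes / min while commuting
    gps_noise_sd: float = 8.0             # m per axis
    duty_on: float = 0.5                  # s of audio per period
    duty_period: float = 5.0              # s

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.forage_speed_mean >= self.commute_speed_mean:
            raise ValueError("foraging must be slower than commuting")
        for r in (self.buzz_rate_foraging, self.buzz_rate_commute):
            if r < 0:
                raise ValueError("buzz rates must be >= 0")

    @property
    def duty_cycle(self) -> DutyCycle:
        return DutyCycle(on_window=self.duty_on, period=self.duty_period)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        """Load a configuration from a YAML mapping of field names."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "trip_hours_range" in data:
            data["trip_hours_range"] = tuple(data["trip_hours_range"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        data = asdict(self)
        data["trip_hours_range"] = list(data["trip_hours_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class SimTruth:
    """Ground truth accompanying a generated trip."""

    states: np.ndarray                    # per-fix true state (FORAGING/COMMUTING)
    bouts: list[tuple[float, float]]      # true foraging intervals (s)
    buzz_times: np.ndarray                # all emitted buzzes (s), pre duty cycle
    true_x: np.ndarray                    # noiseless positions
    true_y: np.ndarray
    true_speeds: np.ndarray               # per-fix commanded speed (m/s)

    def state_sequence(self, dt: float, trip_id: str = "") -> StateSequence:
        return StateSequence(self.states, dt=dt, trip_id=trip_id, method="truth")


def _dwell_states(rng: np.random.Generator, n_fix: int, cfg: SimConfig) -> np.ndarray:
    """Alternating exponential dwells, starting in commute (leaving the roost)."""
    states = np.empty(n_fix, dtype=np.int8)
    i = 0
    state = COMMUTING
    while i < n_fix:
        mean = cfg.commute_bout_mean_s if state == COMMUTING else cfg.forage_bout_mean_s
        dwell = max(cfg.dt, rng.exponential(mean))
        k = max(1, int(round(dwell / cfg.dt)))
        states[i : i + k] = state
        i += k
        state = FORAGING if state == COMMUTING else COMMUTING
    return states


def _foraging_intervals(states: np.ndarray, dt: float) -> list[tuple[float, float]]:
    out = []
    n = len(states)
    i = 0
    while i < n:
        if states[i] == FORAGING:
            j = i
            while j < n and states[j] == FORAGING:
                j += 1
            out.append((i * dt, j * dt))
            i = j
        else:
            i += 1
    return out


def generate_trip(
    cfg: SimConfig | None = None,
    seed: int | np.random.Generator = 0,
    trip_id: str = "sim",
    n_fix: int | None = None,
) -> tuple[Trip, SimTruth]:
    """Generate one synthetic foraging trip and its ground truth.

    Headings evolve by state-specific von Mises increments, per-fix
    speeds are truncated-normal draws, positions are integrated at
    ``cfg.dt`` and then perturbed by GPS noise. Buzzes are emitted at the
    state-specific Poisson rate; ``SimTruth.buzz_times`` holds the full
    (pre-duty-cycle) emission record.

    ``n_fix`` overrides the random trip duration (useful for tests).
    """
    cfg = cfg or SimConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if n_fix is None:
        lo, hi = cfg.trip_hours_range
        hours = float(np.clip(rng.normal(cfg.trip_hours_mean, cfg.trip_hours_sd), lo, hi))
        n_fix = max(10, int(round(hours * 3600.0 / cfg.dt)))
    states = _dwell_states(rng, n_fix, cfg)

    speed_mean = np.where(
        states == FORAGING, cfg.forage_speed_mean, cfg.commute_speed_mean
    )
    speed_sd = np.where(states == FORAGING, cfg.forage_speed_sd, cfg.commute_speed_sd)
    speeds = rng.normal(speed_mean, speed_sd)
    speeds = np.clip(speeds, 0.5, None)  # truncate: bats keep flying

    kappa = np.where(states == FORAGING, cfg.forage_kappa, cfg.commute_kappa)
    increments = rng.vonmises(0.0, kappa[1:])
    headings = np.empty(n_fix)
    headings[0] = rng.uniform(-np.pi, np.pi)
    headings[1:] = headings[0] + np.cumsum(increments)

    # integrate: the step leaving fix i uses fix i's state/speed/heading
    tx = np.zeros(n_fix)
    ty = np.zeros(n_fix)
    step = speeds[:-1] * cfg.dt
    tx[1:] = np.cumsum(step * np.cos(headings[:-1]))
    ty[1:] = np.cumsum(step * np.sin(headings[:-1]))

    x = tx + rng.normal(0.0, cfg.gps_noise_sd, n_fix)
    y = ty + rng.normal(0.0, cfg.gps_noise_sd, n_fix)
    times = cfg.dt * np.arange(n_fix)

    bouts = _foraging_intervals(states, cfg.dt)
    duration = n_fix * cfg.dt
    buzz_times = _emit_buzzes(rng, states, bouts, duration, cfg)

    trip = Trip(trip_id=trip_id, times=times, x=x, y=y, nominal_dt=cfg.dt)
    truth = SimTruth(
        states=states,
        bouts=bouts,
        buzz_times=buzz_times,
        true_x=tx,
        true_y=ty,
        true_speeds=speeds,
    )
    return trip, truth


def _emit_buzzes(
    rng: np.random.Generator,
    states: np.ndarray,
    bouts: list[tuple[float, float]],
    duration: float,
    cfg: SimConfig,
) -> np.ndarray:
    """Poisson buzz emission: clustered inside foraging bouts, sparse otherwise."""
    times: list[float] = []
    rate_f = cfg.buzz_rate_foraging / 60.0   # per second
    for a, b in bouts:
        if rate_f <= 0:
            break
        t = a + rng.exponential(1.0 / rate_f)
        while t < b:
            times.append(t)
            t += rng.exponential(1.0 / rate_f)
    rate_c = cfg.buzz_rate_commute / 60.0
    if rate_c > 0:
        t = rng.exponential(1.0 / rate_c)
        while t < duration:
            idx = min(int(t / cfg.dt), len(states) - 1)
            if states[idx] == COMMUTING:
                times.append(t)
            t += rng.exponential(1.0 / rate_c)
    return np.sort(np.array(times))


def apply_duty_cycle(
    buzz_times: np.ndarray, dc: DutyCycle | None = None, shift: float = 0.0
) -> np.ndarray:
    """Keep buzzes audible to a duty-cycled recorder with the given phase.

    A buzz at time t survives when ``t mod period`` lies in
    ``[shift, shift + on_window)``.
    """
    dc = dc or DutyCycle()
    if not 0 <= shift < dc.period:
        raise ValueError("need 0 <= shift < period")
    t = np.asarray(buzz_times, dtype=float)
    phase = np.mod(t, dc.period)
    return t[(phase >= shift) & (phase < shift + dc.on_window)]


# ------------------------------------------------------------- call trains

#: search-phase call shape: 6 ms calls, 200 ms inter-pulse interval
SEARCH_CALL_DURATION = 0.006
SEARCH_IPI = 0.200
#: buzz call shape: short calls at ~7 ms IPI; 25 calls span ~0.22 s,
#: inside the 0.2-0.25 s span of a natural terminal buzz
BUZZ_CALL_DURATION = 0.002
BUZZ_IPI = 0.007
BUZZ_N_CALLS = 25


def generate_call_train(
    kind: str,
    n_calls: int | None = None,
    t0: float = 0.0,
    peak_db: float = 20.0,
    schedule: list[tuple[str, float]] | None = None,
) -> list[Call]:
    """Construct a synthetic call train of the given kind.

    ``search``: ``n_calls`` (default 10) calls of 6 ms at 200 ms IPI.
    ``buzz``: ``n_calls`` (default 25) calls of 2 ms at 7 ms IPI — the
    train spans ~0.22 s, a natural terminal-buzz length.
    ``mixed``: concatenation following ``schedule`` = list of
    ``(kind, start_time)`` entries.
    """
    if kind == "mixed":
        if not schedule:
            raise ValueError("mixed trains need a schedule")
        calls: list[Call] = []
        for k, t in schedule:
            calls.extend(generate_call_train(k, t0=t, peak_db=peak_db))
        return sorted(calls, key=lambda c: c.start)
    if kind == "search":
        n = n_calls if n_calls is not None else 10
        dur, ipi = SEARCH_CALL_DURATION, SEARCH_IPI
    elif kind == "buzz":
        n = n_calls if n_calls is not None else BUZZ_N_CALLS
        dur, ipi = BUZZ_CALL_DURATION, BUZZ_IPI
    else:
        raise ValueError(f"unknown train kind: {kind!r}")
    calls = []
    t = t0
    for _ in range(n):
        calls.append(Call(start=t, end=t + dur, peak_amp=peak_db))
        t += dur + ipi
    return calls


def calls_to_envelope(
    calls: list[Call],
    fs: float = 20_000.0,
    floor_db: float = 0.0,
    pad: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Render calls as a log-amplitude envelope on a noise floor.

    Each call becomes a triangular pulse whose -5 dB crossings coincide
    with the call's start/end, so envelope-based detection recovers the
    constructed endpoints.
    """
    if not calls:
        raise ValueError("need at least one call")
    t0 = calls[0].start - pad
    t1 = max(c.end for c in calls) + pad
    t = t0 + np.arange(int(np.ceil((t1 - t0) * fs))) / fs
    amp = np.full(t.size, floor_db)
    for c in calls:
        peak = c.peak_amp
        mid = 0.5 * (c.start + c.end)
        half = 0.5 * c.duration
        # linear flanks: peak at mid, peak-5 at start/end, down to floor beyond
        slope = 5.0 / half
        rise_span = (peak - floor_db) / slope
        sel = (t > mid - rise_span) & (t < mid + rise_span)
        pulse = peak - slope * np.abs(t[sel] - mid)
        amp[sel] = np.maximum(amp[sel], pulse)
    return t, amp


# ------------------------------------------------------------ benchmark suite

@dataclass
class TripRecord:
    """One generated trip with its truth and duty-cycled observed buzzes."""

    trip: Trip
    truth: SimTruth
    observed_buzz_times: np.ndarray


def make_benchmark_suite(
    cfg: SimConfig | None = None,
    n_trips: int = 15,
    seed: int = 0,
    outdir: str | Path | None = None,
    duty_shift: float = 0.0,
) -> list[TripRecord]:
    """Generate a study-sized suite of trips (default 15, matching the field design).

    Each trip's buzzes are passed through the audio duty cycle (phase
    ``duty_shift``) to produce the observed buzz record. With ``outdir``
    set, writes per-trip track/truth/buzz CSVs plus a seed manifest; the
    same seed reproduces the bundle byte for byte.
    """
    cfg = cfg or SimConfig()
    records: list[TripRecord] = []
    for k in range(n_trips):
        rng = np.random.default_rng([seed, k])
        trip, truth = generate_trip(cfg, seed=rng, trip_id=f"sim{k:02d}")
        observed = apply_duty_cycle(truth.buzz_times, cfg.duty_cycle, shift=duty_shift)
        records.append(TripRecord(trip=trip, truth=truth, observed_buzz_times=observed))

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        from .tracks import write_track

        for rec in records:
            tid = rec.trip.trip_id
            write_track(rec.trip, outdir / f"{tid}_track.csv")
            pd.DataFrame(
                {
                    "trip_id": tid,
                    "time_s": rec.trip.times,
                    "state": list(rec.truth.state_sequence(cfg.dt, tid).iter_names()),
                }
            ).to_csv(outdir / f"{tid}_truth.csv", index=False)
            pd.DataFrame(
                {"trip_id": tid, "time_s": rec.observed_buzz_times}
            ).to_csv(outdir / f"{tid}_buzzes.csv", index=False)
        manifest = {
            "seed": seed,
            "n_trips": n_trips,
            "duty_shift": duty_shift,
            "config": asdict(cfg),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return records
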