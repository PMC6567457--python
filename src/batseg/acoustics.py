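"""Echolocation-call processing: feeding-buzz detection and duty-cycle loss.

An insect- or fish-hunting bat emits search-phase calls (~6 ms long,
~200 ms apart) while cruising and compresses the inter-pulse interval
(IPI) to a few milliseconds in the terminal "feeding buzz" of a prey
capture attempt. A buzz — terminal or aborted — is therefore the
acoustic ground truth that the animal was foraging at that moment.

This module works on amplitude envelopes and call tables, not raw
waveforms: calls are local maxima of the (log-)amplitude envelope, with
endpoints placed where the envelope first falls 5 dB below the peak on
each side; buzzes are maximal runs of >= 3 consecutive calls whose IPIs
are all below 10 ms. Detected buzzes are snapped to the nearest GPS fix,
which makes fixes "buzz-positive" for evaluation.

The on-board recorder samples 0.5 s of audio every 5 s (10% duty
cycle); :func:`duty_cycle_detection` quantifies how many foraging bouts
such a schedule captures by exhaustively enumerating all window shifts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .tracks import Trip

#: IPI threshold below which consecutive calls belong to a buzz (s).
DEFAULT_IPI_THRESHOLD = 0.010
#: Minimum number of consecutive sub-threshold-IPI calls forming a buzz.
DEFAULT_MIN_CALLS = 3
#: Endpoint criterion: amplitude drop from the call peak (dB).
ENDPOINT_DROP_DB = 5.0


@dataclass
class Call:
    """One detected echolocation call (times in s, amplitude in dB re arbitrary)."""

    start: float
    end: float
    peak_amp: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("call end must be after start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class BuzzEvent:
    """A feeding buzz: a run of >= min_calls calls with sub-threshold IPIs.

    ``aborted`` marks buzzes followed by further search-phase calls in
    the same recording (the bat broke off the attack); both kinds count
    as foraging evidence.
    """

    time: float            # time of the first call in the run (s)
    n_calls: int
    aborted: bool = False
    fix_index: int = -1    # GPS location index, set by assign_buzzes_to_fixes

    def __post_init__(self) -> None:
        if self.n_calls < 2:
            raise ValueError("a buzz needs at least 2 calls")


@dataclass
class DutyCycle:
    """Recorder schedule: ``on_window`` seconds of audio every ``period`` seconds."""

    on_window: float = 0.5
    period: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.on_window <= self.period:
            raise ValueError("need 0 < on_window <= period")

    @property
    def fraction(self) -> float:
        return self.on_window / self.period

    @property
    def n_shifts(self) -> int:
        return int(round(self.period / self.on_window))


def detect_calls(
    times: np.ndarray,
    amp_db: np.ndarray,
    min_peak_db: float,
    min_sep: float = 0.002,
) -> list[Call]:
    """Detect calls in a log-amplitude envelope by peak picking.

    One call per local maximum exceeding ``min_peak_db``, with maxima
    closer than ``min_sep`` merged into the larger peak. Endpoints sit
    where the envelope first crosses 5 dB below the peak on each side
    (linearly interpolated between samples).
    """
    times = np.asarray(times, dtype=float)
    amp = np.asarray(amp_db, dtype=float)
    if times.size != amp.size:
        raise ValueError("times and amp_db must have equal length")
    if times.size < 3:
        return []
    fs = 1.0 / np.median(np.diff(times))
    distance = max(1, int(round(min_sep * fs)))
    peaks, _ = find_peaks(amp, height=min_peak_db, distance=distance)

    calls: list[Call] = []
    for p in peaks:
        level = amp[p] - ENDPOINT_DROP_DB
        # walk left to the first sample below the -5 dB level
        i = p
        while i > 0 and amp[i - 1] > level:
            i -= 1
        if i == 0:
            start = times[0]
        else:
            frac = (level - amp[i - 1]) / (amp[i] - amp[i - 1])
            start = times[i - 1] + frac * (times[i] - times[i - 1])
        j = p
        while j < amp.size - 1 and amp[j + 1] > level:
            j += 1
        if j == amp.size - 1:
            end = times[-1]
        else:
            frac = (level - amp[j + 1]) / (amp[j] - amp[j + 1])
            end = times[j + 1] - frac * (times[j + 1] - times[j])
        calls.append(Call(start=float(start), end=float(end), peak_amp=float(amp[p])))
    return calls


def compute_ipis(calls: list[Call]) -> np.ndarray:
    """Inter-pulse intervals: end of one call to start of the next (s).

    Length is ``len(calls) - 1`` (empty for < 2 calls). Overlapping calls
    would make an IPI negative and are rejected.
    """
    if len(calls) < 2:
        return np.empty(0)
    starts = np.array([c.start for c in calls])
    ends = np.array([c.end for c in calls])
    if np.any(np.diff(starts) < 0):
        raise ValueError("calls must be sorted by start time")
    ipi = starts[1:] - ends[:-1]
    if np.any(ipi < 0):
        raise ValueError("overlapping calls produce negative IPIs")
    return ipi


def detect_buzzes(
    calls: list[Call],
    ipi_threshold: float = DEFAULT_IPI_THRESHOLD,
    min_calls: int = DEFAULT_MIN_CALLS,
) -> list[BuzzEvent]:
    """Find feeding buzzes: maximal runs of calls with all IPIs < threshold.

    A run of ``m`` calls has ``m - 1`` consecutive IPIs; it is a buzz when
    ``m >= min_calls`` and every internal IPI is below ``ipi_threshold``.
    A buzz followed by further (search-phase) calls is flagged aborted.
    """
    if min_calls < 2:
        raise ValueError("min_calls must be >= 2")
    if len(calls) < min_calls:
        return []
    ipis = compute_ipis(calls)
    fast = ipis < ipi_threshold

    buzzes: list[BuzzEvent] = []
    i = 0
    n_ipi = fast.size
    while i < n_ipi:
        if not fast[i]:
            i += 1
            continue
        j = i
        while j < n_ipi and fast[j]:
            j += 1
        run_calls = (j - i) + 1      # calls spanned by IPIs i..j-1
        if run_calls >= min_calls:
            buzzes.append(
                BuzzEvent(
                    time=calls[i].start,
                    n_calls=run_calls,
                    aborted=(j < n_ipi),  # at least one later call after the run
                )
            )
        i = j
    return buzzes


def assign_buzzes_to_fixes(
    buzzes: list[BuzzEvent], trip: Trip, max_outside: float = 5.0
) -> list[BuzzEvent]:
    """Assign each buzz to the nearest-in-time GPS fix of ``trip``.

    Equidistant ties go to the earlier fix. Buzzes falling outside the
    trip's time span by more than ``max_outside`` seconds (one recorder
    period) are dropped with a warning. Returns new BuzzEvent objects.
    """
    out: list[BuzzEvent] = []
    t = trip.times
    n_dropped = 0
    for b in buzzes:
        if b.time < t[0] - max_outside or b.time > t[-1] + max_outside:
            n_dropped += 1
            continue
        k = int(np.searchsorted(t, b.time))
        if k == 0:
            idx = 0
        elif k == len(t):
            idx = len(t) - 1
        else:
            # earlier fix wins on a tie
            idx = k - 1 if (b.time - t[k - 1]) <= (t[k] - b.time) else k
        out.append(
            BuzzEvent(time=b.time, n_calls=b.n_calls, aborted=b.aborted, fix_index=idx)
        )
    if n_dropped:
        warnings.warn(
            f"{n_dropped} buzz(es) outside trip time span dropped", stacklevel=2
        )
    return out


def buzz_positive_fixes(buzzes: list[BuzzEvent]) -> set[int]:
    """Indices of GPS fixes with at least one assigned buzz."""
    return {b.fix_index for b in buzzes if b.fix_index >= 0}


def group_bouts(buzz_times: np.ndarray, max_gap: float = 60.0) -> list[tuple[float, float]]:
    """Group buzz times into foraging bouts: maximal sets with gaps < max_gap."""
    t = np.sort(np.asarray(buzz_times, dtype=float))
    if t.size == 0:
        return []
    breaks = np.nonzero(np.diff(t) >= max_gap)[0]
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks, [t.size - 1]))
    return [(float(t[a]), float(t[b])) for a, b in zip(starts, stops)]


def duty_cycle_detection(
    buzz_times: np.ndarray,
    bouts: list[tuple[float, float]],
    dc: DutyCycle | None = None,
) -> tuple[np.ndarray, float, float]:
    """Fraction of foraging bouts a duty-cycled recorder would detect.

    For each of the ``period / on_window`` possible recorder phases
    (all shifts of the on-window within the period), a bout counts as
    detected when at least one of its buzzes falls inside an on-window.
    Returns ``(per-shift fractions, mean, SD)``.
    """
    dc = dc or DutyCycle()
    if not bouts:
        raise ValueError("duty-cycle detection needs at least one bout")
    t = np.asarray(buzz_times, dtype=float)
    shifts = dc.on_window * np.arange(dc.n_shifts)
    phase = np.mod(t, dc.period)
    fractions = np.empty(dc.n_shifts)
    for si, s in enumerate(shifts):
        audible = (phase >= s) & (phase < s + dc.on_window)
        n_det = 0
        for a, b in bouts:
            in_bout = (t >= a) & (t <= b)
            if np.any(in_bout & audible):
                n_det += 1
        fractions[si] = n_det / len(bouts)
    return fractions, float(fractions.mean()), float(fractions.std(ddof=1))


# ---------------------------------------------------------------- CSV dialects

def read_calls(path) -> list[Call]:
    """Read a call CSV (``rec_id, start_s, end_s, peak_db``), sorted by start."""
    df = pd.read_csv(path).sort_values("start_s")
    return [
        Call(start=r.start_s, end=r.end_s, peak_amp=r.peak_db)
        for r in df.itertuples()
    ]


def write_buzzes(buzzes: list[BuzzEvent], trip_id: str, path) -> None:
    pd.DataFrame(
        {
            "trip_id": trip_id,
            "time_s": [b.time for b in buzzes],
            "n_calls": [b.n_calls for b in buzzes],
            "aborted": [b.aborted for b in buzzes],
            "fix_index": [b.fix_index for b in buzzes],
        }
    ).to_csv(path, index=False)


def read_buzzes(path) -> dict[str, list[BuzzEvent]]:
    """Read a buzz CSV back into per-trip BuzzEvent lists."""
    df = pd.read_csv(path)
    out: dict[str, list[BuzzEvent]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.trip_id), []).append(
            BuzzEvent(
                time=r.time_s,
                n_calls=int(r.n_calls),
                aborted=bool(r.aborted),
                fix_index=int(r.fix_index),
            )
        )
    return out
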