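"""Correlated-velocity movement models and change-point segmentation.

A correlated-velocity movement (CVM) model describes a track whose
velocity follows an Ornstein-Uhlenbeck process: each velocity
coordinate relaxes toward a mean with timescale tau (the velocity
autocorrelation time) and stationary variance nu^2/2, so that the
stationary root-mean-squared speed is nu. The unbiased model (UCVM) has
zero mean velocity — localized, tortuous movement typical of
area-restricted search — while the advective model (ACVM) adds a
non-zero mean velocity mu, producing directed commuting flight.

Fitting uses the exact discrete OU transition of the finite-difference
velocity series: an AR(1) Gaussian likelihood with autoregression
coefficient rho = exp(-dt/tau), plus the stationary density of the
first velocity (so that likelihoods of a split segment pair are
comparable with the unsplit segment). Given rho, the advective mean and
innovation variance have closed forms; the fit reduces to a 1-D search
over tau.

Change points are proposed by sliding a short window (default 8
locations, stepped by 5) along the track and profiling the gain in
split log-likelihood over interior split points. Proposals are then
thinned by recursive binary segmentation under the Bayesian
Information Criterion: within each segment the BIC-best candidate
split is accepted only when it lowers the segment's BIC (the
segmented likelihood keeps the velocity transition across each
boundary, so the unsplit model is nested in the split model and the
BIC comparison is well calibrated), recursing into both halves;
change points may not fall closer together than a minimum separation
(default 30 s). Accepted boundaries are finally polished to the
locally BIC-optimal split position. Each resulting segment is
classified by refitting both models: UCVM-preferred segments are
labeled foraging, ACVM-preferred segments commuting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .states import COMMUTING, FORAGING, StateSequence
from .tracks import Trip

_TAU_LO_FACTOR = 0.01    # tau search bounds as multiples of dt
_TAU_HI_FACTOR = 1000.0


@dataclass
class CvmFit:
    """Maximum-likelihood fit of one CVM model to one track segment."""

    model: str               # "UCVM" or "ACVM"
    nu: float                # stationary RMS speed (m/s)
    tau: float               # velocity autocorrelation timescale (s)
    mu: np.ndarray           # advective velocity (m/s, 2-vector; zero for UCVM)
    loglik: float
    bic: float
    n: int                   # number of velocity observations
    tau_pinned: bool = False

    @property
    def k(self) -> int:
        return 2 if self.model == "UCVM" else 4


@dataclass
class ChangePointSet:
    """Candidate and accepted change-point times for one trip."""

    candidates: np.ndarray
    accepted: np.ndarray
    min_separation: float = 30.0


def simulate_cvm(
    nu: float,
    tau: float,
    mu=(0.0, 0.0),
    dt: float = 15.0,
    n: int = 1000,
    seed: int = 0,
    x0=(0.0, 0.0),
    trip_id: str = "cvm",
) -> Trip:
    """Simulate a track whose velocity is an exact discretely sampled OU process.

    Per coordinate: v_{t+dt} = mu + rho (v_t - mu) + e,
    rho = exp(-dt/tau), Var e = (nu^2/2)(1 - rho^2), v_0 stationary.
    Positions accumulate v dt, so finite-difference velocities of the
    returned track reproduce the OU series exactly (no Euler error).
    """
    if nu <= 0 or tau <= 0 or dt <= 0:
        raise ValueError("nu, tau, dt must be > 0")
    rng = np.random.default_rng(seed)
    mu = np.asarray(mu, dtype=float)
    rho = np.exp(-dt / tau)
    s_st = nu / np.sqrt(2.0)
    s_inn = s_st * np.sqrt(1.0 - rho**2)
    v = np.empty((n, 2))
    v[0] = mu + rng.normal(0.0, s_st, 2)
    noise = rng.normal(0.0, s_inn, (n - 1, 2))
    for t in range(1, n):
        v[t] = mu + rho * (v[t - 1] - mu) + noise[t - 1]
    pos = np.zeros((n + 1, 2))
    pos[0] = np.asarray(x0, dtype=float)
    pos[1:] = pos[0] + np.cumsum(v * dt, axis=0)
    times = dt * np.arange(n + 1)
    return Trip(trip_id=trip_id, times=times, x=pos[:, 0], y=pos[:, 1], nominal_dt=dt)


def _velocities(trip: Trip) -> tuple[np.ndarray, float]:
    dts = np.diff(trip.times)
    dt = float(np.median(dts))
    if np.any(np.abs(dts - dt) > 0.01 * dt):
        raise ValueError("CVM fitting needs a (near-)regular fix interval")
    v = np.column_stack((np.diff(trip.x), np.diff(trip.y))) / dt
    return v, dt


def _loglik_given_rho(v: np.ndarray, rho: float, advective: bool):
    """Profile likelihood at fixed rho: closed-form mu and innovation variance.

    Returns (loglik, nu, mu). The likelihood is the AR(1) conditional
    density of v_1..v_{m-1} given v_0 plus the stationary density of
    v_0, evaluated at the conditional-MLE mu and variance (quasi-MLE;
    exact as m grows).
    """
    m = len(v)
    if advective:
        mu = (v[1:].sum(axis=0) - rho * v[:-1].sum(axis=0)) / ((m - 1) * (1.0 - rho))
    else:
        mu = np.zeros(2)
    e = (v[1:] - mu) - rho * (v[:-1] - mu)
    s2 = float(np.mean(e**2))          # innovation variance per coordinate
    s2 = max(s2, 1e-300)
    s2_st = s2 / (1.0 - rho**2)        # stationary variance per coordinate
    n_cond = 2 * (m - 1)
    ll = -0.5 * n_cond * (np.log(2.0 * np.pi * s2) + 1.0)
    ll += -0.5 * (2.0 * np.log(2.0 * np.pi * s2_st) + float(np.sum((v[0] - mu) ** 2)) / s2_st)
    nu = float(np.sqrt(2.0 * s2_st))
    return ll, nu, mu


def fit_cvm(segment: Trip | np.ndarray, model: str = "UCVM", dt: float | None = None) -> CvmFit:
    """Maximum-likelihood CVM fit to a track segment.

    ``segment`` is a Trip (>= 4 locations) or an (m, 2) array of
    velocities sampled at ``dt``. ``model`` is ``"UCVM"`` (mu = 0,
    k = 2 parameters) or ``"ACVM"`` (free mu, k = 4). A tau estimate
    pinned at the search bounds is flagged.
    """
    model = model.upper()
    if model not in ("UCVM", "ACVM"):
        raise ValueError("model must be UCVM or ACVM")
    if isinstance(segment, Trip):
        if segment.n < 4:
            raise ValueError("CVM fit needs at least 4 locations")
        v, dt = _velocities(segment)
    else:
        v = np.asarray(segment, dtype=float)
        if dt is None:
            raise ValueError("dt required with raw velocities")
        if len(v) < 3:
            raise ValueError("CVM fit needs at least 3 velocities")
    advective = model == "ACVM"

    lo, hi = np.log(_TAU_LO_FACTOR * dt), np.log(_TAU_HI_FACTOR * dt)

    def neg(log_tau: float) -> float:
        rho = np.exp(-dt / np.exp(log_tau))
        return -_loglik_given_rho(v, rho, advective)[0]

    res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    log_tau = float(res.x)
    tau = float(np.exp(log_tau))
    pinned = log_tau < lo + 0.01 or log_tau > hi - 0.01
    rho = float(np.exp(-dt / tau))
    ll, nu, mu = _loglik_given_rho(v, rho, advective)
    k = 4 if advective else 2
    m = len(v)
    bic = k * np.log(m) - 2.0 * ll
    return CvmFit(
        model=model, nu=nu, tau=tau, mu=np.asarray(mu, dtype=float),
        loglik=float(ll), bic=float(bic), n=m, tau_pinned=pinned,
    )


# ------------------------------------------------------------- change points

def _split_gain(v: np.ndarray, s: int, dt: float) -> float:
    """Gain in UCVM log-likelihood from splitting the velocity series at s."""
    full = fit_cvm(v, "UCVM", dt=dt).loglik
    left = fit_cvm(v[:s], "UCVM", dt=dt).loglik
    right = fit_cvm(v[s:], "UCVM", dt=dt).loglik
    return left + right - full


class _SegmentScorer:
    """Memoized best-model (UCVM vs ACVM) segment likelihoods for thinning.

    The log-likelihood of velocities a..b-1 keeps the transition density
    across the left boundary (the first velocity of an interior segment
    is conditioned on its predecessor under the segment's own
    parameters); only the very first segment of the track pays a
    stationary initial-density term. Splitting a segment therefore
    repartitions exactly the same likelihood terms, which makes
    merged-vs-split BIC comparisons properly nested.
    """

    def __init__(self, v: np.ndarray, dt: float):
        self.v = v
        self.dt = dt
        self._cache: dict[tuple[int, int], tuple[float, int]] = {}

    def ll_k(self, a: int, b: int) -> tuple[float, int]:
        key = (a, b)
        if key in self._cache:
            return self._cache[key]
        v, dt = self.v, self.dt
        vv = v[a:b]
        if len(vv) < 3:
            out = (-np.inf, 2)
        else:
            best = None
            for model in ("UCVM", "ACVM"):
                f = fit_cvm(vv, model, dt=dt)
                rho = np.exp(-dt / f.tau)
                s2 = (f.nu**2 / 2.0) * (1.0 - rho**2)
                lo = 1 if a == 0 else a
                e = (v[lo:b] - f.mu) - rho * (v[lo - 1 : b - 1] - f.mu)
                ll = -0.5 * float(np.sum(np.log(2.0 * np.pi * s2) + e**2 / s2))
                if a == 0:
                    s2_st = s2 / (1.0 - rho**2)
                    ll += -0.5 * (
                        2.0 * np.log(2.0 * np.pi * s2_st)
                        + float(np.sum((v[0] - f.mu) ** 2)) / s2_st
                    )
                bic = f.k * np.log(len(vv)) - 2.0 * ll
                if best is None or bic < best[2]:
                    best = (ll, f.k, bic)
            out = (best[0], best[1])
        self._cache[key] = out
        return out

    def bic_single(self, a: int, c: int) -> float:
        ll, k = self.ll_k(a, c)
        return k * np.log(c - a) - 2.0 * ll

    def bic_pair(self, a: int, b: int, c: int) -> float:
        ll1, k1 = self.ll_k(a, b)
        ll2, k2 = self.ll_k(b, c)
        return (k1 + k2) * np.log(c - a) - 2.0 * (ll1 + ll2)


def scan_changepoints(
    trip: Trip,
    window: int = 8,
    step: int = 5,
    min_side: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window change-point proposal scan.

    Each window of ``window`` locations is profiled over interior split
    points (each side keeping >= ``min_side`` velocities); the window's
    best split — the local maximum of the concatenated split-likelihood
    profile — becomes a candidate when its gain is positive. Returns
    ``(candidate_times, candidate_gains)``; candidates are deliberately
    permissive, BIC thinning decides which survive. If a window cannot
    be fit, the scan retries with a window of ``window + 2`` locations
    (2.5 min at 15 s fixes) for this trip.
    """
    n = trip.n
    if n < window + 1:
        return np.empty(0), np.empty(0)
    v, dt = _velocities(trip)

    try:
        best_t, best_g = _scan(v, trip.times, dt, window, step, min_side)
    except (ValueError, FloatingPointError):
        warnings.warn(
            f"window of {window} failed for trip {trip.trip_id}; "
            f"retrying with {window + 2}",
            stacklevel=2,
        )
        best_t, best_g = _scan(v, trip.times, dt, window + 2, step, min_side)
    if not best_t:
        return np.empty(0), np.empty(0)
    t = np.array(best_t)
    g = np.array(best_g)
    keep = g > 0
    return t[keep], g[keep]


def _scan(v, times, dt, window, step, min_side):
    m = len(v)  # velocities
    best_t: list[float] = []
    best_g: list[float] = []
    # a window of `window` locations spans `window - 1` velocities
    wv = window - 1
    for a in range(0, m - wv + 1, step):
        chunk = v[a : a + wv]
        g_best, s_best = -np.inf, None
        for s in range(min_side, wv - min_side + 1):
            g = _split_gain(chunk, s, dt)
            if g > g_best:
                g_best, s_best = g, s
        if s_best is None:
            continue
        # split between velocities s-1 and s = at location index a + s
        best_t.append(float(times[a + s_best]))
        best_g.append(g_best)
    return best_t, best_g


def thin_changepoints(
    trip: Trip,
    candidates: np.ndarray,
    min_sep: float = 30.0,
    gains: np.ndarray | None = None,
    refine_window: int = 12,
    max_refine_iter: int = 6,
) -> ChangePointSet:
    """Recursive BIC selection of supported change points, with refinement.

    Within each segment (initially the whole track), the candidate that
    minimizes the two-segment BIC is accepted when that BIC undercuts
    the unsplit segment's BIC, and the procedure recurses into both
    halves; candidates closer than ``min_sep`` to a segment edge are
    unavailable there, which enforces the minimum change-point
    separation. Accepted boundaries are then iteratively slid to the
    BIC-optimal split position within ``refine_window`` locations
    (candidate positions from the coarse window scan are grid-limited).
    ``gains`` is accepted for API symmetry with the scan but unused:
    the BIC decides.
    """
    cand = np.sort(np.asarray(candidates, dtype=float))
    times = trip.times
    v, dt = _velocities(trip)
    scorer = _SegmentScorer(v, dt)
    cidx = sorted({int(np.searchsorted(times, t)) for t in cand})
    cidx = [b for b in cidx if 0 < b < trip.n - 1]

    accepted: list[int] = []

    def recurse(a: int, c: int) -> None:
        inner = [
            b
            for b in cidx
            if a < b < c
            and times[b] - times[a] >= min_sep
            and times[c] - times[b] >= min_sep
        ]
        if not inner:
            return
        best_bic, best_b = min((scorer.bic_pair(a, b, c), b) for b in inner)
        if best_bic < scorer.bic_single(a, c):
            accepted.append(best_b)
            recurse(a, best_b)
            recurse(best_b, c)

    recurse(0, trip.n - 1)
    acc = sorted(accepted)

    for _ in range(max_refine_iter):
        edges = [0] + acc + [trip.n - 1]
        new_acc = []
        for i in range(1, len(edges) - 1):
            a, b, c = edges[i - 1], edges[i], edges[i + 1]
            lo = max(a + 1, b - refine_window)
            hi = min(c - 1, b + refine_window)
            pos = [
                bb
                for bb in range(lo, hi + 1)
                if times[bb] - times[a] >= min_sep and times[c] - times[bb] >= min_sep
            ]
            if pos:
                _, bb = min((scorer.bic_pair(a, bb, c), bb) for bb in pos)
                new_acc.append(bb)
            else:
                new_acc.append(b)
        new_acc = sorted(set(new_acc))
        if new_acc == acc:
            break
        acc = new_acc

    return ChangePointSet(
        candidates=cand, accepted=times[np.array(acc, dtype=int)] if acc else np.empty(0),
        min_separation=min_sep,
    )


def segment_cvcp(
    trip: Trip, cps: ChangePointSet, min_segment: int = 4
) -> tuple[StateSequence, list[CvmFit]]:
    """Classify inter-change-point segments: UCVM -> foraging, ACVM -> commuting.

    Segments shorter than ``min_segment`` locations are merged into the
    neighboring segment with the closer mean speed before fitting. Every
    location is labeled (a boundary location opens the following
    segment).
    """
    times = trip.times
    bounds = [int(np.searchsorted(times, t)) for t in np.sort(cps.accepted)]
    edges = [0] + [b for b in bounds if 0 < b < trip.n - 1] + [trip.n]
    # merge too-short segments into the neighbor with closer mean speed
    v, dt = _velocities(trip)
    speed = np.hypot(v[:, 0], v[:, 1])

    def mean_speed(a, b):
        return float(np.mean(speed[a : max(b - 1, a + 1)]))

    changed = True
    while changed and len(edges) > 2:
        changed = False
        for i in range(len(edges) - 1):
            a, b = edges[i], edges[i + 1]
            if b - a < min_segment:
                left_ok = i > 0
                right_ok = i < len(edges) - 2
                if left_ok and right_ok:
                    dl = abs(mean_speed(edges[i - 1], a) - mean_speed(a, b))
                    dr = abs(mean_speed(b, edges[i + 2]) - mean_speed(a, b))
                    drop = i if dl <= dr else i + 1
                elif left_ok:
                    drop = i
                else:
                    drop = i + 1
                del edges[drop]
                changed = True
                break

    labels = np.empty(trip.n, dtype=np.int8)
    fits: list[CvmFit] = []
    for a, b in zip(edges[:-1], edges[1:]):
        vv = v[a : max(b - 1, a + 1)]
        if len(vv) < 3:  # degenerate remnant: inherit commuting
            labels[a:b] = COMMUTING
            continue
        u = fit_cvm(vv, "UCVM", dt=dt)
        adv = fit_cvm(vv, "ACVM", dt=dt)
        win = u if u.bic <= adv.bic else adv
        fits.append(win)
        labels[a:b] = FORAGING if win.model == "UCVM" else COMMUTING
    return (
        StateSequence(labels, dt=trip.nominal_dt, trip_id=trip.trip_id, method="CVCP"),
        fits,
    )


def segment_cvcp_pipeline(
    trip: Trip,
    window: int = 8,
    step: int = 5,
    min_sep: float = 30.0,
) -> tuple[StateSequence, list[CvmFit], ChangePointSet]:
    """Full per-trip change-point pipeline: scan, thin, classify."""
    cand, gains = scan_changepoints(trip, window=window, step=step)
    cps = thin_changepoints(trip, cand, min_sep=min_sep, gains=gains)
    seq, fits = segment_cvcp(trip, cps)
    return seq, fits, cps
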