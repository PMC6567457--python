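"""Hidden Markov model segmentation on step length and turn angle.

The movement HMM assumes the animal switches between hidden behavioral
states, each emitting step lengths from a gamma distribution and turn
angles from a von Mises distribution (mean 0). For a two-state model
the short-step / near-uniform-turn state is area-restricted search
(foraging) and the long-step / concentrated-turn state is commuting.

Fitting maximizes the exact forward-algorithm likelihood over all
emission and transition parameters by quasi-Newton optimization (the
same strategy as the standard movement-HMM tools), with the initial
state distribution tied to the stationary distribution of the
transition matrix. Initial step-length parameters come from a
two-component normal mixture of the pooled step lengths; turn
concentrations start at 0.1. Decoding uses the global Viterbi path by
default; one-step-ahead pseudo-residuals with a Jarque-Bera normality
test provide goodness-of-fit diagnostics.

The model is n-state capable; defaults and naming rules are two-state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, i0, logsumexp, ndtri
from scipy.stats import gamma as gamma_dist
from scipy.stats import jarque_bera as _jb
from scipy.stats import linregress, vonmises

from .states import COMMUTING, FORAGING, StateSequence
from .tracks import StepSeries, Trip, regularize, subsample, compute_steps

__all__ = [
    "HmmInit",
    "HmmModel",
    "hmm_init",
    "hmm_fit",
    "hmm_decode",
    "hmm_pseudo_residuals",
    "hmm_subsampling_experiment",
    "simulate_hmm",
    "forward_loglik",
]


@dataclass
class HmmInit:
    """Starting values for the HMM optimizer (state 0 = smaller step mean)."""

    step_means: np.ndarray
    step_sds: np.ndarray
    turn_kappas: np.ndarray
    fallback_used: bool = False

    def __post_init__(self) -> None:
        order = np.argsort(self.step_means)
        self.step_means = np.asarray(self.step_means, float)[order]
        self.step_sds = np.asarray(self.step_sds, float)[order]
        self.turn_kappas = np.asarray(self.turn_kappas, float)[order]


@dataclass
class HmmModel:
    """Fitted movement HMM (gamma step lengths, zero-mean von Mises turns)."""

    n_states: int
    step_means: np.ndarray
    step_sds: np.ndarray
    turn_kappas: np.ndarray
    trans: np.ndarray            # row-stochastic (K, K)
    init_probs: np.ndarray       # stationary distribution of trans
    loglik: float
    converged: bool = True
    n_obs: int = 0

    @property
    def foraging_state(self) -> int:
        """Foraging = the state with the smaller step mean (and, in a
        well-separated fit, the lower turn concentration)."""
        by_step = int(np.argmin(self.step_means))
        if int(np.argmin(self.turn_kappas)) != by_step:
            warnings.warn(
                "smallest-step and lowest-concentration states disagree; "
                "using step length",
                stacklevel=2,
            )
        return by_step


# ------------------------------------------------------------------ emissions

def _gamma_logpdf(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    shape = (mean / sd) ** 2
    rate = mean / sd**2
    return shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(x) - rate * x


def _vonmises_logpdf(theta: np.ndarray, kappa: float) -> np.ndarray:
    return kappa * np.cos(theta) - np.log(2.0 * np.pi * i0(kappa))


def _emission_logprobs(
    steps: np.ndarray, turns: np.ndarray, model_params: tuple
) -> np.ndarray:
    """(T, K) log emission matrix; NaN observations are marginalized out."""
    means, sds, kappas = model_params
    K = len(means)
    T = len(steps)
    logB = np.zeros((T, K))
    ok_s = ~np.isnan(steps)
    ok_t = ~np.isnan(turns)
    for k in range(K):
        logB[ok_s, k] += _gamma_logpdf(steps[ok_s], means[k], sds[k])
        logB[ok_t, k] += _vonmises_logpdf(turns[ok_t], kappas[k])
    return logB


# ---------------------------------------------------------------- forward etc.

def forward_loglik(logB: np.ndarray, trans: np.ndarray, init: np.ndarray) -> float:
    """Log-likelihood of one observation sequence via the scaled forward pass."""
    T, K = logB.shape
    # scale emissions per time step to avoid under/overflow
    m = logB.max(axis=1)
    B = np.exp(logB - m[:, None])
    alpha = init * B[0]
    c = alpha.sum()
    ll = np.log(c) + m[0]
    alpha /= c
    for t in range(1, T):
        alpha = (alpha @ trans) * B[t]
        c = alpha.sum()
        if not np.isfinite(c) or c <= 0:
            return -np.inf
        ll += np.log(c) + m[t]
        alpha /= c
    return float(ll)


def _viterbi(logB: np.ndarray, trans: np.ndarray, init: np.ndarray) -> np.ndarray:
    T, K = logB.shape
    log_trans = np.log(trans)
    delta = np.log(init) + logB[0]
    back = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + log_trans
        back[t] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + logB[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(delta.argmax())
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def _stationary(trans: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(trans.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, k])
    v = np.abs(v)
    return v / v.sum()


# ------------------------------------------------------------------- plumbing

def _as_obs_list(steps) -> list[tuple[np.ndarray, np.ndarray]]:
    """Normalize input to a list of (step_lengths, signed_turns) arrays.

    Accepts a StepSeries, a list of StepSeries, or raw (steps, turns)
    tuples. Observation t of a StepSeries pairs the step ending at
    location t+1 with the turn angle at that vertex; zero step lengths
    are displaced to half the smallest positive step (GPS jitter makes
    exact zeros artifacts, and the gamma density needs x > 0).
    """
    if isinstance(steps, StepSeries):
        steps = [steps]
    out = []
    for s in steps:
        if isinstance(s, StepSeries):
            st = s.step_length[1:].astype(float).copy()
            tu = s.turn_signed[1:].astype(float).copy()
        else:
            st, tu = np.asarray(s[0], float).copy(), np.asarray(s[1], float).copy()
        pos = st[np.isfinite(st) & (st > 0)]
        if pos.size == 0:
            raise ValueError("no positive step lengths")
        st[np.isfinite(st) & (st <= 0)] = pos.min() / 2.0
        out.append((st, tu))
    return out


def hmm_init(step_lengths: np.ndarray, seed: int = 0) -> HmmInit:
    """Initial values from a 2-component normal mixture of pooled step lengths.

    If the data are effectively unimodal — the Bayesian Information
    Criterion prefers a single Gaussian over the two-component mixture,
    or a component's weight vanishes — falls back to a 30th/70th
    percentile split with a warning.
    """
    from scipy.stats import norm as _norm

    from .fpt import fit_gauss_mixture  # 1-D mixture EM lives with the FPT tools

    x = np.asarray(step_lengths, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if x.size < 100:
        raise ValueError("need at least 100 step lengths to initialize")
    fallback = False
    try:
        mix = fit_gauss_mixture(x, seed=seed)
        single_ll = float(np.sum(_norm.logpdf(x, x.mean(), x.std())))
        # mixture adds 3 parameters over the single Gaussian
        unimodal = (
            2.0 * (mix.loglik - single_ll) < 3.0 * np.log(x.size)
            or np.min(mix.weights) < 0.02
        )
    except (RuntimeError, ValueError):
        unimodal = True
        mix = None
    if unimodal:
        warnings.warn(
            "step-length mixture unimodal; falling back to 30th/70th percentile split",
            stacklevel=2,
        )
        fallback = True
        q30, q70 = np.percentile(x, [30, 70])
        sd = float(np.std(x)) / 2.0
        means = np.array([q30, q70])
        sds = np.array([sd, sd])
    else:
        means = mix.means.copy()
        sds = mix.sds.copy()
    return HmmInit(
        step_means=means,
        step_sds=sds,
        turn_kappas=np.full(len(means), 0.1),
        fallback_used=fallback,
    )


def _pack(means, sds, kappas, trans) -> np.ndarray:
    K = len(means)
    off = []
    for i in range(K):
        for j in range(K):
            if i != j:
                off.append(np.log(trans[i, j] / trans[i, i]))
    return np.concatenate([np.log(means), np.log(sds), np.log(kappas), off])


def _unpack(theta: np.ndarray, K: int):
    means = np.exp(theta[:K])
    sds = np.exp(theta[K : 2 * K])
    kappas = np.exp(theta[2 * K : 3 * K])
    off = theta[3 * K :]
    trans = np.zeros((K, K))
    p = 0
    for i in range(K):
        row = np.zeros(K)
        for j in range(K):
            if i != j:
                row[j] = off[p]
                p += 1
        e = np.exp(row - row.max())
        trans[i] = e / e.sum()
    return means, sds, kappas, trans


def hmm_fit(
    steps,
    init: HmmInit | None = None,
    n_states: int = 2,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int = 0,
) -> HmmModel:
    """Maximize the joint forward likelihood over all trips.

    ``steps`` may be a StepSeries, a list of StepSeries (pooled fit with
    a shared parameter set; trips enter as independent chains, so the
    likelihood is invariant to trip order), or raw (steps, turns)
    tuples. The final log-likelihood is guaranteed >= the starting
    value; states are reordered by step mean (ascending) on return.
    """
    obs = _as_obs_list(steps)
    K = n_states
    if init is None:
        pooled = np.concatenate([o[0] for o in obs])
        if K == 2:
            init = hmm_init(pooled, seed=seed)
        else:
            qs = np.percentile(pooled, np.linspace(20, 80, K))
            init = HmmInit(
                step_means=qs,
                step_sds=np.full(K, np.std(pooled) / K),
                turn_kappas=np.full(K, 0.1),
            )
    if len(init.step_means) != K:
        raise ValueError("init size does not match n_states")

    trans0 = np.full((K, K), 0.1 / max(K - 1, 1))
    np.fill_diagonal(trans0, 0.9)
    theta0 = _pack(init.step_means, init.step_sds, init.turn_kappas, trans0)

    def nll(theta: np.ndarray) -> float:
        means, sds, kappas, trans = _unpack(theta, K)
        if np.any(kappas > 700):  # i0 overflow guard
            return 1e12
        pi = _stationary(trans)
        total = 0.0
        for st, tu in obs:
            logB = _emission_logprobs(st, tu, (means, sds, kappas))
            ll = forward_loglik(logB, trans, pi)
            if not np.isfinite(ll):
                return 1e12
            total += ll
        return -total

    nll0 = nll(theta0)
    if not np.isfinite(nll0) or nll0 >= 1e12:
        raise RuntimeError("non-finite likelihood at the initial parameters")
    res = minimize(
        nll,
        theta0,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-7},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError(f"non-finite likelihood during optimization: {res.message}")
    theta = res.x if res.fun <= nll0 else theta0
    means, sds, kappas, trans = _unpack(theta, K)

    order = np.argsort(means)
    means, sds, kappas = means[order], sds[order], kappas[order]
    trans = trans[np.ix_(order, order)]
    pi = _stationary(trans)

    diag = np.diag(trans)
    if np.any(diag > 0.999):
        warnings.warn(
            "transition matrix nearly degenerate (a state is almost absorbing); "
            "the data may contain a single behavioral state",
            stacklevel=2,
        )
    n_obs = sum(len(o[0]) for o in obs)
    return HmmModel(
        n_states=K,
        step_means=means,
        step_sds=sds,
        turn_kappas=kappas,
        trans=trans,
        init_probs=pi,
        loglik=float(-min(res.fun, nll0)),
        converged=bool(res.success),
        n_obs=n_obs,
    )


def hmm_decode(
    model: HmmModel, steps, posterior: bool = False
) -> StateSequence | list[StateSequence]:
    """Viterbi-decode per-location behavioral labels (0 omitted).

    Observation t informs location t+1; location 0 inherits the state of
    the first step, so every location is labeled. ``posterior=True``
    switches to local (forward-backward marginal) decoding.
    """
    single = isinstance(steps, StepSeries)
    steps_list = [steps] if single else list(steps)
    obs = _as_obs_list(steps_list)
    params = (model.step_means, model.step_sds, model.turn_kappas)
    fstate = model.foraging_state
    out = []
    for s, (st, tu) in zip(steps_list, obs):
        logB = _emission_logprobs(st, tu, params)
        if posterior:
            path = _posterior_decode(logB, model.trans, model.init_probs)
        else:
            path = _viterbi(logB, model.trans, model.init_probs)
        lab = np.empty(len(st) + 1, dtype=np.int8)
        lab[1:] = np.where(path == fstate, FORAGING, COMMUTING)
        lab[0] = lab[1]
        dt = s.dt if isinstance(s, StepSeries) else 15.0
        tid = s.trip_id if isinstance(s, StepSeries) else ""
        out.append(StateSequence(lab, dt=dt, trip_id=tid, method="HMM"))
    return out[0] if single else out


def _posterior_decode(logB, trans, init) -> np.ndarray:
    T, K = logB.shape
    m = logB.max(axis=1)
    B = np.exp(logB - m[:, None])
    alpha = np.zeros((T, K))
    a = init * B[0]
    alpha[0] = a / a.sum()
    for t in range(1, T):
        a = (alpha[t - 1] @ trans) * B[t]
        alpha[t] = a / a.sum()
    beta = np.ones(K)
    post = np.zeros((T, K))
    post[-1] = alpha[-1]
    for t in range(T - 2, -1, -1):
        beta = trans @ (B[t + 1] * beta)
        beta /= beta.sum()
        p = alpha[t] * beta
        post[t] = p / p.sum()
    return post.argmax(axis=1)


# ----------------------------------------------------------------- diagnostics

def hmm_pseudo_residuals(model: HmmModel, steps) -> dict:
    """One-step-ahead pseudo-residuals and Jarque-Bera normality tests.

    For each observation the forecast CDF under the fitted model,
    u_t = P(X_t <= x_t | x_{1:t-1}), is mapped through the standard
    normal quantile; under a correct model the residuals are iid
    standard normal. Returns a dict with ``step_residuals``,
    ``turn_residuals`` and per-stream ``(stat, df, p)`` Jarque-Bera
    results (JB = n/6 (S^2 + (K-3)^2 / 4), df = 2).
    """
    obs = _as_obs_list(steps)
    params = (model.step_means, model.step_sds, model.turn_kappas)
    K = model.n_states
    shapes = (model.step_means / model.step_sds) ** 2
    scales = model.step_sds**2 / model.step_means

    res_step: list[float] = []
    res_turn: list[float] = []
    clipped = 0
    eps = 1e-12
    for st, tu in obs:
        logB = _emission_logprobs(st, tu, params)
        T = len(st)
        w = model.init_probs.copy()
        m = logB.max(axis=1)
        B = np.exp(logB - m[:, None])
        alpha = None
        for t in range(T):
            if t > 0:
                w = alpha @ model.trans
            if np.isfinite(st[t]):
                u = float(
                    np.sum(w * gamma_dist.cdf(st[t], a=shapes, scale=scales))
                )
                if u <= eps or u >= 1 - eps:
                    clipped += 1
                    u = float(np.clip(u, eps, 1 - eps))
                res_step.append(ndtri(u))
            if np.isfinite(tu[t]):
                u = float(
                    np.sum(
                        w * np.array([vonmises.cdf(tu[t], kappa=k) for k in model.turn_kappas])
                    )
                )
                if u <= eps or u >= 1 - eps:
                    clipped += 1
                    u = float(np.clip(u, eps, 1 - eps))
                res_turn.append(ndtri(u))
            a = w * B[t]
            alpha = a / a.sum()
    if clipped:
        warnings.warn(f"{clipped} residual probabilities clipped to ({eps}, 1-{eps})",
                      stacklevel=2)

    def jb(z: list[float]):
        z = np.asarray(z)
        stat, p = _jb(z)
        return float(stat), 2, float(p)

    return {
        "step_residuals": np.asarray(res_step),
        "turn_residuals": np.asarray(res_turn),
        "step_jb": jb(res_step),
        "turn_jb": jb(res_turn),
    }


# ------------------------------------------------------------------ simulation

def simulate_hmm(
    step_means,
    step_sds,
    turn_kappas,
    trans,
    n: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample (steps, turns, states) from a gamma/von-Mises HMM (oracle data)."""
    rng = np.random.default_rng(seed)
    trans = np.asarray(trans, dtype=float)
    K = trans.shape[0]
    pi = _stationary(trans)
    states = np.empty(n, dtype=np.int64)
    states[0] = rng.choice(K, p=pi)
    for t in range(1, n):
        states[t] = rng.choice(K, p=trans[states[t - 1]])
    means = np.asarray(step_means, float)[states]
    sds = np.asarray(step_sds, float)[states]
    shapes = (means / sds) ** 2
    scales = sds**2 / means
    steps = rng.gamma(shape=shapes, scale=scales)
    turns = rng.vonmises(0.0, np.asarray(turn_kappas, float)[states])
    return steps, turns, states


# ------------------------------------------------- subsampling sensitivity

def hmm_subsampling_experiment(
    trips: list[Trip],
    buzz_times: list[np.ndarray],
    intervals: np.ndarray | None = None,
    seed: int = 0,
    min_locations: int = 50,
) -> tuple[pd.DataFrame, float]:
    """Median balanced accuracy of the HMM pipeline vs GPS sampling interval.

    For each interval the trips are subsampled, regularized, refitted
    (pooled), decoded and scored against their buzz records; the
    ordinary-least-squares slope of median balanced accuracy (fraction)
    against interval (s) quantifies the degradation. Trips left with
    fewer than ``min_locations`` fixes at an interval are skipped there.
    """
    from .acoustics import BuzzEvent, assign_buzzes_to_fixes, buzz_positive_fixes
    from .evaluate import score_trip

    if intervals is None:
        intervals = np.arange(15.0, 601.0, 15.0)
    rows = []
    for interval in intervals:
        sub: list[Trip] = []
        sub_buzz: list[np.ndarray] = []
        for trip, bt in zip(trips, buzz_times):
            s = subsample(trip, interval)
            if s.n < min_locations:
                continue
            s = regularize(s, dt=interval)[0]
            sub.append(s)
            sub_buzz.append(np.asarray(bt))
        if not sub:
            continue
        steps_list = [compute_steps(t) for t in sub]
        model = hmm_fit(steps_list, seed=seed)
        labels = hmm_decode(model, steps_list)
        bas = []
        for trip, lab, bt in zip(sub, labels, sub_buzz):
            events = [BuzzEvent(time=float(t), n_calls=3) for t in bt]
            assigned = assign_buzzes_to_fixes(events, trip, max_outside=interval)
            fixes = buzz_positive_fixes(assigned)
            if not fixes:
                continue
            bas.append(score_trip(lab, fixes).balanced_accuracy)
        if bas:
            rows.append({"interval_s": float(interval),
                         "median_ba": float(np.median(bas)),
                         "n_trips": len(bas)})
    table = pd.DataFrame(rows)
    if len(table) >= 2:
        slope = float(linregress(table["interval_s"], table["median_ba"]).slope)
    else:
        slope = np.nan
    return table, slope
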