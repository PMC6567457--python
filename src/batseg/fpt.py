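"""First-passage-time (FPT) segmentation.

The first-passage time at a track location is the time the animal takes
to cross a virtual circle of radius r centered there — the forward time
to first exit plus the backward time to first exit, with crossing times
linearly interpolated between fixes. Slow tortuous area-restricted
search inflates FPT; straight commuting flight at speed v gives
FPT ~ 2r/v. Locations whose path never exits the circle in one
direction (trip ends) have undefined FPT and are omitted.

The analysis scale is chosen by scanning radii and picking the one
maximizing the across-trip mean variance of ln(FPT) (variance peaks at
the scale of area-restricted search). A two-component Gaussian mixture
on ln(FPT) then separates the commuting and foraging modes, and the
threshold between them defaults to the 95th percentile of the lower
(commuting) component, clamped between the two component means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .states import COMMUTING, FORAGING, OMITTED, StateSequence
from .tracks import Trip

DEFAULT_RADII = np.arange(100.0, 5001.0, 25.0)


@dataclass
class GaussMix2:
    """Two-component univariate normal mixture, components ordered by mean."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    n: int

    def __post_init__(self) -> None:
        if self.means[0] > self.means[1]:
            order = np.argsort(self.means)
            self.weights = self.weights[order]
            self.means = self.means[order]
            self.sds = self.sds[order]

    @property
    def separation(self) -> float:
        """Mean separation in units of the pooled SD."""
        pooled = float(np.sqrt(np.mean(self.sds**2)))
        return float((self.means[1] - self.means[0]) / pooled)


@dataclass
class FptProfile:
    """Variance-of-ln(FPT) scan over candidate radii."""

    radii: np.ndarray
    mean_var: np.ndarray          # across-trip mean of per-trip var(ln FPT)
    per_trip_var: np.ndarray      # (n_trips, n_radii)
    selected_radius: float


def _dist_matrix(trip: Trip) -> np.ndarray:
    P = trip.positions()
    d = P[:, None, :] - P[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))


def _first_exit_times(times: np.ndarray, D: np.ndarray, radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Forward and backward time-to-first-exit for every location (NaN if none)."""
    n = times.size
    B = D > radius

    fwd = np.full(n, np.nan)
    Bu = np.triu(B, k=1)
    has = Bu.any(axis=1)
    j = Bu.argmax(axis=1)
    i_idx = np.nonzero(has)[0]
    jj = j[i_idx]
    d_in = D[i_idx, jj - 1]     # last fix inside (could be the center itself)
    d_out = D[i_idx, jj]
    frac = (radius - d_in) / (d_out - d_in)
    t_exit = times[jj - 1] + frac * (times[jj] - times[jj - 1])
    fwd[i_idx] = t_exit - times[i_idx]

    bwd = np.full(n, np.nan)
    Bl = np.tril(B, k=-1)
    has_b = Bl.any(axis=1)
    # first exit going backwards = last True column before the diagonal
    rev = Bl[:, ::-1]
    j_rev = rev.argmax(axis=1)
    jb = n - 1 - j_rev
    i_idx = np.nonzero(has_b)[0]
    jj = jb[i_idx]
    d_in = D[i_idx, jj + 1]
    d_out = D[i_idx, jj]
    frac = (radius - d_in) / (d_out - d_in)
    t_exit = times[jj + 1] - frac * (times[jj + 1] - times[jj])
    bwd[i_idx] = times[i_idx] - t_exit
    return fwd, bwd


def compute_fpt(trip: Trip, radius: float, _D: np.ndarray | None = None) -> np.ndarray:
    """Per-location first-passage time (s) for one radius; NaN where undefined."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    D = _dist_matrix(trip) if _D is None else _D
    fwd, bwd = _first_exit_times(trip.times, D, radius)
    return fwd + bwd


def select_radius(
    trips: list[Trip], radii: np.ndarray = DEFAULT_RADII
) -> tuple[float, FptProfile]:
    """Scan radii, returning the one maximizing mean across-trip var(ln FPT).

    The variance is computed per trip over its defined FPT values, then
    averaged across trips (trips with < 2 defined values at a radius
    contribute nothing there).
    """
    radii = np.asarray(radii, dtype=float)
    if radii.size == 0:
        raise ValueError("empty radius grid")
    if not trips:
        raise ValueError("need at least one trip")
    per_trip = np.full((len(trips), radii.size), np.nan)
    for ti, trip in enumerate(trips):
        D = _dist_matrix(trip)
        for ri, r in enumerate(radii):
            fpt = compute_fpt(trip, r, _D=D)
            ok = np.isfinite(fpt) & (fpt > 0)
            if ok.sum() >= 2:
                per_trip[ti, ri] = np.var(np.log(fpt[ok]), ddof=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean_var = np.nanmean(per_trip, axis=0)
    if np.all(~np.isfinite(mean_var)):
        raise ValueError("no radius yielded any defined FPT values")
    spread = np.nanmax(mean_var) - np.nanmin(mean_var)
    if spread < 1e-12:
        warnings.warn("flat variance curve; selecting smallest radius", stacklevel=2)
        best = float(radii[0])
    else:
        best = float(radii[np.nanargmax(mean_var)])
    return best, FptProfile(
        radii=radii, mean_var=mean_var, per_trip_var=per_trip, selected_radius=best
    )


def fit_gauss_mixture(
    values: np.ndarray,
    k: int = 2,
    max_iter: int = 500,
    tol: float = 1e-7,
    seed: int = 0,
    n_starts: int = 10,
) -> GaussMix2:
    """EM fit of a k=2 univariate normal mixture (multiple restarts)."""
    v = np.asarray(values, dtype=float).reshape(-1, 1)
    v = v[np.isfinite(v[:, 0])].reshape(-1, 1)
    if len(v) < 10:
        raise ValueError("need at least 10 values")
    if k != 2:
        raise ValueError("only k=2 supported")
    if np.std(v) == 0.0:
        raise ValueError("values have no variation; mixture undefined")
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        max_iter=max_iter,
        tol=tol,
        n_init=n_starts,
        random_state=seed,
        reg_covar=1e-10,
    )
    gm.fit(v)
    sds = np.sqrt(gm.covariances_.reshape(2))
    if np.any(sds < 1e-8 * max(1.0, float(np.std(v)))):
        raise RuntimeError("degenerate mixture component (sd -> 0)")
    loglik = float(gm.score(v) * len(v))
    return GaussMix2(
        weights=gm.weights_.copy(),
        means=gm.means_.reshape(2).copy(),
        sds=sds,
        loglik=loglik,
        n=len(v),
    )


def fpt_threshold(mix: GaussMix2, level: float = 0.95) -> float:
    """FPT threshold (seconds) separating commuting from foraging.

    Default rule: the ``level`` (95th) percentile of the lower-mean
    (commuting) component of the ln(FPT) mixture, clamped to lie between
    the two component means, exponentiated back to seconds. Requires a
    bimodal mixture (means separated by more than one pooled SD).
    """
    if mix.separation <= 1.0:
        raise ValueError(
            f"mixture not bimodal (separation {mix.separation:.2f} pooled SDs); "
            "set a threshold manually"
        )
    q = mix.means[0] + norm.ppf(level) * mix.sds[0]
    q = float(np.clip(q, mix.means[0], mix.means[1]))
    return float(np.exp(q))


def segment_fpt(
    fpt: np.ndarray, threshold: float, dt: float = 15.0, trip_id: str = ""
) -> StateSequence:
    """Label locations: foraging where FPT > threshold, commuting where <=,
    omitted where FPT is undefined."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    fpt = np.asarray(fpt, dtype=float)
    lab = np.full(fpt.size, OMITTED, dtype=np.int8)
    ok = np.isfinite(fpt)
    lab[ok & (fpt > threshold)] = FORAGING
    lab[ok & (fpt <= threshold)] = COMMUTING
    return StateSequence(lab, dt=dt, trip_id=trip_id, method="FPT")
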