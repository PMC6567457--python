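"""Pattern-description segmentation: k-means and binary-clustering (EMbC-style).

Both methods work in the (speed, |turn angle|) plane, unstandardized
(m/s and degrees). Because turn angle spans [0, 180] while speed spans a
few m/s, the k-means decision boundary is dominated by turn angle — the
empirical behavior for trawling-bat trips, where the foraging/commuting
boundary is approximately a turn-angle threshold.

The binary-clustering method fits a 4-component Gaussian mixture and
reduces it to axis-aligned low/high delimiters per variable, yielding
the four canonical labels LL (rest/slow travel), LH (intensive search),
HL (commute), HH (extensive search); LH and HH aggregate to foraging.
This is a deliberate approximation of the full likelihood-weighted
binary-clustering algorithm: delimiters here come from a weighted
two-group split of the component means on each axis, and every location
is then labeled by simple threshold comparison, which makes the
label/delimiter consistency exact by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .states import COMMUTING, FORAGING, OMITTED, StateSequence
from .tracks import StepSeries

EMBC_LABELS = ("LL", "LH", "HL", "HH")
#: default aggregation: both search regimes count as foraging
DEFAULT_FORAGING_LABELS = frozenset({"LH", "HH"})


@dataclass
class ClusterModel:
    """Fitted k-means partition of (speed, turn) points."""

    k: int
    centers: np.ndarray          # (k, 2): speed m/s, |turn| deg
    assignment: np.ndarray       # per-point cluster id
    inertia: float               # within-cluster sum of squares
    variance_explained: float    # 1 - WCSS / TSS


@dataclass
class EmbcLabels:
    """Axis-aligned four-region labeling of (speed, turn) points.

    ``labels`` holds one of ``LL/LH/HL/HH`` per location, or ``omitted``
    never occurs here: locations with an undefined metric get the nearest
    defined value filled in, so the labeling is total (the reference
    algorithm also labels every point).
    """

    labels: np.ndarray           # array of 2-char strings per location
    speed_cut: float             # m/s: L below, H at/above
    turn_cut: float              # degrees
    means: np.ndarray            # (4, 2) component means
    weights: np.ndarray
    converged: bool = True

    def __len__(self) -> int:
        return len(self.labels)


def _tss(X: np.ndarray) -> float:
    return float(np.sum((X - X.mean(axis=0)) ** 2))


def kmeans_fit(points: np.ndarray, k: int, n_starts: int = 10, seed: int = 0) -> ClusterModel:
    """Lloyd's k-means on (speed, turn) points, best of ``n_starts`` restarts."""
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("points must be (n, 2): speed, |turn|")
    if k < 1 or k > len(np.unique(X, axis=0)):
        raise ValueError(f"k={k} incompatible with {len(X)} points")
    km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(X)
    tss = _tss(X)
    ve = 1.0 - km.inertia_ / tss if tss > 0 else 0.0
    return ClusterModel(
        k=k,
        centers=km.cluster_centers_,
        assignment=labels,
        inertia=float(km.inertia_),
        variance_explained=float(ve),
    )


def elbow_select(
    points: np.ndarray,
    k_range: range = range(2, 11),
    seed: int = 0,
    n_starts: int = 10,
    collapse_ratio: float = 0.25,
) -> tuple[int, np.ndarray]:
    """Pick the cluster count at the elbow of the variance-explained curve.

    The elbow is the smallest candidate k after which the marginal gain
    in variance explained collapses: gain(k -> k+1) falls below
    ``collapse_ratio`` times gain(k-1 -> k). (A raw max-second-difference
    rule degenerates to the first candidate, because the first gain over
    the k=1 baseline always dominates the curvature.) The curve is
    returned for inspection as rows ``(k, variance_explained)``,
    including k-1 below and k+1 above the candidate range; variance
    explained at k=1 is 0 by definition. When no gain ever collapses —
    a structureless single cloud yields a smoothly decaying curve —
    the smallest candidate k is returned with a warning.
    """
    ks = list(k_range)
    if ks != sorted(ks) or len(ks) == 0:
        raise ValueError("k_range must be ascending and non-empty")
    ext = [ks[0] - 1] + ks + [ks[-1] + 1]
    ve = {}
    for k in ext:
        if k <= 1:
            ve[k] = 0.0
        else:
            ve[k] = kmeans_fit(points, k, n_starts=n_starts, seed=seed).variance_explained
    curve = np.array([(k, ve[k]) for k in ext])
    for k in ks:
        gain_in = ve[k] - ve[k - 1]
        gain_out = ve[k + 1] - ve[k]
        if gain_in > 0 and gain_out < collapse_ratio * gain_in:
            return k, curve
    warnings.warn(
        "no elbow in the variance-explained curve; returning smallest k",
        stacklevel=2,
    )
    return ks[0], curve


def _pooled_points(steps_list: list[StepSeries]) -> tuple[np.ndarray, list[np.ndarray]]:
    """Stack defined (speed, turn_abs) rows across trips; keep per-trip masks."""
    masks = [s.both_defined for s in steps_list]
    X = np.vstack(
        [
            np.column_stack((s.speed[m], s.turn_abs[m]))
            for s, m in zip(steps_list, masks)
        ]
    )
    return X, masks


def segment_kmc(
    steps: StepSeries | list[StepSeries],
    seed: int = 0,
    n_starts: int = 10,
    standardize: bool = False,
) -> StateSequence | list[StateSequence]:
    """Two-cluster k-means segmentation on (speed, |turn|).

    Foraging is the cluster with the higher mean turn angle (when the
    lowest-speed and highest-turn criteria disagree, turn angle decides,
    consistent with the turn-dominated boundary). A list of StepSeries
    is pooled into one clustering — one partition for the whole study —
    and per-trip label sequences are returned. Locations lacking speed
    or turn angle (2 per trip) are omitted.

    Features are unstandardized by default, which lets turn angle
    dominate the boundary; ``standardize=True`` z-scores both features
    first, giving speed equal leverage.
    """
    single = isinstance(steps, StepSeries)
    steps_list = [steps] if single else list(steps)
    X, masks = _pooled_points(steps_list)
    if standardize:
        X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    if len(np.unique(X, axis=0)) < 2:
        warnings.warn("degenerate input: all points identical; labeling all commuting",
                      stacklevel=2)
        out = []
        for s, m in zip(steps_list, masks):
            lab = np.full(len(s), OMITTED, dtype=np.int8)
            lab[m] = COMMUTING
            out.append(StateSequence(lab, dt=s.dt, trip_id=s.trip_id, method="kmC"))
        return out[0] if single else out

    model = kmeans_fit(X, k=2, n_starts=n_starts, seed=seed)
    # turn angle decides which cluster is foraging
    foraging_cluster = int(np.argmax(model.centers[:, 1]))
    if np.argmin(model.centers[:, 0]) != foraging_cluster:
        warnings.warn(
            "lowest-speed and highest-turn clusters disagree; using turn angle",
            stacklevel=2,
        )
    out = []
    pos = 0
    for s, m in zip(steps_list, masks):
        k = int(m.sum())
        assign = model.assignment[pos : pos + k]
        pos += k
        lab = np.full(len(s), OMITTED, dtype=np.int8)
        lab[m] = np.where(assign == foraging_cluster, FORAGING, COMMUTING)
        out.append(StateSequence(lab, dt=s.dt, trip_id=s.trip_id, method="kmC"))
    return out[0] if single else out


def _binary_cut(component_means: np.ndarray, weights: np.ndarray) -> float:
    """Low/high delimiter for one variable from mixture component means.

    The sorted component means are split into two contiguous groups
    minimizing the weight-weighted within-group sum of squares (a
    weighted two-means over the component means — weighting prevents a
    small stray component from hijacking the cut); the delimiter is the
    midpoint between the groups' facing means.
    """
    order = np.argsort(component_means)
    m = np.asarray(component_means, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    best_ss, best_cut = np.inf, None
    for s in range(1, len(m)):
        ss = 0.0
        for grp_m, grp_w in ((m[:s], w[:s]), (m[s:], w[s:])):
            c = np.average(grp_m, weights=grp_w)
            ss += float(np.sum(grp_w * (grp_m - c) ** 2))
        if ss < best_ss:
            best_ss = ss
            best_cut = 0.5 * (m[s - 1] + m[s])
    return float(best_cut)


def _fill_nearest(values: np.ndarray) -> np.ndarray:
    """Fill NaNs with the nearest defined value along the sequence."""
    v = values.copy()
    n = len(v)
    idx = np.arange(n)
    ok = ~np.isnan(v)
    if not ok.any():
        raise ValueError("no defined values to fill from")
    v[~ok] = np.interp(idx[~ok], idx[ok], v[ok])
    return v


def embc_fit(
    steps: StepSeries | list[StepSeries],
    max_iter: int = 1000,
    tol: float = 1e-5,
    seed: int = 0,
    n_starts: int = 5,
) -> EmbcLabels | list[EmbcLabels]:
    """Four-component Gaussian-mixture fit with binary low/high delimitation.

    Fits a full-covariance 4-component bivariate mixture to the pooled
    (speed, |turn|) points, derives one low/high cut per variable at the
    largest gap between the sorted component means, and labels every
    location by threshold comparison (axis-aligned regions). Trip-end
    locations with an undefined metric inherit the nearest defined value,
    so no location is omitted.
    """
    single = isinstance(steps, StepSeries)
    steps_list = [steps] if single else list(steps)
    X, _ = _pooled_points(steps_list)
    if len(np.unique(X, axis=0)) < 4:
        raise RuntimeError("EM degenerate: fewer than 4 distinct points")
    gm = GaussianMixture(
        n_components=4,
        covariance_type="full",
        max_iter=max_iter,
        tol=tol,
        n_init=n_starts,
        random_state=seed,
        reg_covar=1e-6,
    )
    gm.fit(X)
    if not gm.converged_:
        raise RuntimeError(
            f"EM did not converge in {max_iter} iterations "
            f"(last lower bound {gm.lower_bound_:.6g})"
        )
    speed_cut = _binary_cut(gm.means_[:, 0], gm.weights_)
    turn_cut = _binary_cut(gm.means_[:, 1], gm.weights_)

    out = []
    for s in steps_list:
        sp = _fill_nearest(s.speed)
        tu = _fill_nearest(s.turn_abs)
        hi_s = sp >= speed_cut
        hi_t = tu >= turn_cut
        lab = np.empty(len(s), dtype=object)
        lab[~hi_s & ~hi_t] = "LL"
        lab[~hi_s & hi_t] = "LH"
        lab[hi_s & ~hi_t] = "HL"
        lab[hi_s & hi_t] = "HH"
        out.append(
            EmbcLabels(
                labels=lab,
                speed_cut=speed_cut,
                turn_cut=turn_cut,
                means=gm.means_.copy(),
                weights=gm.weights_.copy(),
                converged=bool(gm.converged_),
            )
        )
    return out[0] if single else out


def segment_embc(
    labels: EmbcLabels,
    foraging_labels: frozenset[str] | set[str] = DEFAULT_FORAGING_LABELS,
    dt: float = 15.0,
    trip_id: str = "",
) -> StateSequence:
    """Aggregate four-region labels into foraging/commuting states.

    Default grouping: the two search regimes LH and HH become foraging,
    LL and HL commuting. Alternative groupings (e.g. LH only) are
    accepted for sensitivity analyses.
    """
    bad = set(foraging_labels) - set(EMBC_LABELS)
    if bad:
        raise ValueError(f"unknown labels in aggregation: {bad}")
    codes = np.where(
        np.isin(labels.labels.astype(str), sorted(foraging_labels)), FORAGING, COMMUTING
    ).astype(np.int8)
    return StateSequence(codes, dt=dt, trip_id=trip_id, method="EMbC")
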