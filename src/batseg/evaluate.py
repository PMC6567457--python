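"""Acoustic validation of segmentations: balanced accuracy and method comparison.

Feeding buzzes are the ground truth: a GPS fix is a positive when at
least one buzz was assigned to it, a negative otherwise. For a given
labeling,

* TPR (sensitivity) = buzz-positive fixes labeled foraging / all
  buzz-positive fixes,
* TNR (specificity) = non-buzz fixes labeled commuting / all non-buzz
  fixes,
* balanced accuracy = (TPR + TNR) / 2,

with method-omitted fixes excluded from both denominators. Balanced
accuracy equals 100% only for a labeling that separates buzz-positive
from buzz-free fixes perfectly, and 50% in expectation for random
labels, which makes it robust to the heavy class imbalance of rare
buzzes.

Method comparison across trips uses a tie-corrected Friedman test, with
paired Wilcoxon signed-rank tests (Bonferroni-corrected) as post hoc
contrasts; the same machinery compares each method's foraging movement
parameters against the speeds and turn angles measured at buzz fixes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import friedmanchisquare, wilcoxon

from .states import COMMUTING, FORAGING, OMITTED, StateSequence
from .tracks import StepSeries


@dataclass
class EvalResult:
    """Per-trip, per-method validation scores."""

    trip_id: str
    method: str
    tpr: float
    tnr: float
    balanced_accuracy: float
    n_buzz_fixes: int
    n_nonbuzz_fixes: int
    omitted: int


@dataclass
class SegmentSummary:
    """Descriptive statistics of the foraging segments of one labeling."""

    percent_foraging: float
    n_segments: int                  # number of foraging segments
    mean_segment_duration: float     # s
    mean_segment_locations: float


def score_trip(
    labels: StateSequence,
    buzz_fixes: set[int],
    buzz_counts: dict[int, int] | None = None,
) -> EvalResult:
    """Score one labeling against the trip's buzz-positive fix set.

    By default a fix with several buzzes counts once in the TPR; pass
    ``buzz_counts`` (fix index -> number of buzzes) to weight each
    buzz-positive fix by its buzz count instead. Raises ValueError when
    no non-omitted buzz-positive fix exists (TPR undefined; the trip
    should be flagged and excluded).
    """
    lab = labels.labels
    n = len(lab)
    is_buzz = np.zeros(n, dtype=bool)
    idx = [i for i in buzz_fixes if 0 <= i < n]
    is_buzz[idx] = True
    ok = lab != OMITTED

    pos = ok & is_buzz
    neg = ok & ~is_buzz
    n_pos = int(pos.sum())
    n_neg = int(neg.sum())
    if n_pos == 0:
        raise ValueError(
            f"trip {labels.trip_id!r}: no scoreable buzz-positive fixes; TPR undefined"
        )
    if buzz_counts is None:
        tpr = float(np.sum(lab[pos] == FORAGING)) / n_pos
    else:
        w = np.zeros(n)
        for i, c in buzz_counts.items():
            if 0 <= i < n:
                w[i] = c
        tpr = float(np.sum(w[pos & (lab == FORAGING)])) / float(np.sum(w[pos]))
    tnr = float(np.sum(lab[neg] == COMMUTING)) / n_neg if n_neg else np.nan
    ba = (tpr + tnr) / 2.0
    return EvalResult(
        trip_id=labels.trip_id,
        method=labels.method,
        tpr=tpr,
        tnr=tnr,
        balanced_accuracy=ba,
        n_buzz_fixes=n_pos,
        n_nonbuzz_fixes=n_neg,
        omitted=labels.n_omitted,
    )


def summarize_segments(labels: StateSequence, dt: float | None = None) -> SegmentSummary:
    """Foraging percentage and segment counts/durations of one labeling.

    Segments are maximal runs of identical non-omitted labels (omitted
    locations are transparent); percent foraging is over non-omitted
    locations; durations are run length x dt.
    """
    if dt is None:
        dt = labels.dt
    segs = labels.segments()
    ok = labels.labels != OMITTED
    n_ok = int(ok.sum())
    if n_ok == 0:
        raise ValueError("all locations omitted")
    pct = 100.0 * float(np.sum(labels.labels[ok] == FORAGING)) / n_ok
    f_segs = [s for s in segs if s.label == FORAGING]
    if f_segs:
        locs = np.array([s.n_locations for s in f_segs], dtype=float)
        return SegmentSummary(
            percent_foraging=pct,
            n_segments=len(f_segs),
            mean_segment_duration=float(np.mean(locs) * dt),
            mean_segment_locations=float(np.mean(locs)),
        )
    return SegmentSummary(pct, 0, 0.0, 0.0)


def friedman_test(scores: np.ndarray) -> tuple[float, int, float]:
    """Tie-corrected Friedman test on a (trips x methods) score matrix.

    Returns (chi2, df = n_methods - 1, p). Missing cells are an error:
    the test needs a complete block design.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("scores must be a (>=2 trips) x (>=2 methods) matrix")
    if np.any(~np.isfinite(X)):
        raise ValueError("missing cells; Friedman test needs a complete matrix")
    if np.all(np.ptp(X, axis=1) == 0):
        # every trip ranks all methods identically: no evidence of differences
        return 0.0, X.shape[1] - 1, 1.0
    stat, p = friedmanchisquare(*(X[:, j] for j in range(X.shape[1])))
    return float(stat), X.shape[1] - 1, float(p)


def wilcoxon_paired(
    x: np.ndarray, y: np.ndarray, m_comparisons: int = 1
) -> tuple[float, float, float]:
    """Paired Wilcoxon signed-rank test with Bonferroni adjustment.

    Zero differences are dropped before ranking (Wilcoxon's original
    rule); the null distribution is enumerated exactly for n <= 25
    distinct-magnitude differences and approximated normally (with tie
    correction) otherwise. Returns (V, p_raw, p_adj = min(1, m * p_raw)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if m_comparisons < 1:
        raise ValueError("m_comparisons must be >= 1")
    d = x - y
    d = d[d != 0.0]
    if d.size == 0:
        return 0.0, 1.0, 1.0
    has_ties = len(np.unique(np.abs(d))) < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = wilcoxon(d, zero_method="wilcox", method=method, correction=False)
    p_raw = float(res.pvalue)
    return float(res.statistic), p_raw, min(1.0, m_comparisons * p_raw)


def results_table(results: list[EvalResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trip_id": r.trip_id,
                "method": r.method,
                "tpr": r.tpr,
                "tnr": r.tnr,
                "balanced_accuracy": r.balanced_accuracy,
                "n_buzz_fixes": r.n_buzz_fixes,
                "n_nonbuzz_fixes": r.n_nonbuzz_fixes,
                "omitted": r.omitted,
            }
            for r in results
        ]
    )


def buzz_movement_params(
    steps: StepSeries, buzz_fixes: set[int]
) -> tuple[float, float]:
    """Mean speed (m/s) and |turn| (deg) at a trip's buzz-positive fixes."""
    idx = np.array(sorted(i for i in buzz_fixes if 0 <= i < len(steps)), dtype=int)
    if idx.size == 0:
        return np.nan, np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sp = float(np.nanmean(steps.speed[idx]))
        tu = float(np.nanmean(steps.turn_abs[idx]))
    return sp, tu


def state_movement_params(
    steps: StepSeries, labels: StateSequence, state: int = FORAGING
) -> tuple[float, float]:
    """Mean speed and |turn| over a trip's locations labeled ``state``."""
    sel = labels.labels == state
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sp = float(np.nanmean(steps.speed[sel])) if sel.any() else np.nan
        tu = float(np.nanmean(steps.turn_abs[sel])) if sel.any() else np.nan
    return sp, tu


def compare_foraging_params(
    buzz_params: pd.DataFrame, method_params: pd.DataFrame
) -> pd.DataFrame:
    """Compare per-method foraging movement parameters against buzz-fix values.

    ``buzz_params``: one row per trip with columns ``trip_id, speed,
    turn``. ``method_params``: rows ``trip_id, method, state, speed,
    turn`` (state in {"foraging", "commuting"}). For each method, paired
    Wilcoxon tests of the per-trip foraging speed and turn against the
    buzz-fix values, Bonferroni-corrected over methods; trips lacking
    buzzes are excluded pairwise. Returns one row per method with
    mean +/- SD summaries and adjusted p-values.
    """
    methods = sorted(method_params["method"].unique())
    m = len(methods)
    rows = []
    bp = buzz_params.set_index("trip_id")
    for meth in methods:
        sub = method_params[method_params["method"] == meth]
        fora = sub[sub["state"] == "foraging"].set_index("trip_id")
        comm = sub[sub["state"] == "commuting"].set_index("trip_id")
        common = [t for t in fora.index if t in bp.index]
        xs = fora.loc[common, "speed"].to_numpy()
        bs = bp.loc[common, "speed"].to_numpy()
        xt = fora.loc[common, "turn"].to_numpy()
        bt = bp.loc[common, "turn"].to_numpy()
        ok = np.isfinite(xs) & np.isfinite(bs) & np.isfinite(xt) & np.isfinite(bt)
        _, _, p_speed = wilcoxon_paired(xs[ok], bs[ok], m_comparisons=m)
        _, _, p_turn = wilcoxon_paired(xt[ok], bt[ok], m_comparisons=m)
        rows.append(
            {
                "method": meth,
                "foraging_speed_mean": float(np.nanmean(fora["speed"])),
                "foraging_speed_sd": float(np.nanstd(fora["speed"], ddof=1)),
                "foraging_turn_mean": float(np.nanmean(fora["turn"])),
                "foraging_turn_sd": float(np.nanstd(fora["turn"], ddof=1)),
                "commuting_speed_mean": float(np.nanmean(comm["speed"])),
                "commuting_speed_sd": float(np.nanstd(comm["speed"], ddof=1)),
                "commuting_turn_mean": float(np.nanmean(comm["turn"])),
                "commuting_turn_sd": float(np.nanstd(comm["turn"], ddof=1)),
                "p_speed_vs_buzz": p_speed,
                "p_turn_vs_buzz": p_turn,
            }
        )
    buzz_row = {
        "method": "Buzz",
        "foraging_speed_mean": float(np.nanmean(bp["speed"])),
        "foraging_speed_sd": float(np.nanstd(bp["speed"], ddof=1)),
        "foraging_turn_mean": float(np.nanmean(bp["turn"])),
        "foraging_turn_sd": float(np.nanstd(bp["turn"], ddof=1)),
    }
    return pd.DataFrame(rows + [buzz_row])
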