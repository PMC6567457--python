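# Methods

This note records the models, conventions, defaults and known limits of
`batseg`. It documents what the code does and why; every number quoted
here is computed by the test suite or the example scripts.

## Tracks and step metrics

Tracks are planar (meters). Longitude/latitude input is projected once
at ingest with a transverse-Mercator (UTM) forward projection written
in-package (Snyder's series; an independent Krüger-series formulation
is kept as an internal cross-check and the two agree below 1 mm). The
default zone is 12 N; all downstream geometry is Euclidean.

Step metrics follow fixed assignment conventions, because they decide
which fixes a method can classify: the speed of the pair (i−1, i)
belongs to the *later* fix i, the turn angle to the *vertex* fix, so a
method needing both metrics omits exactly the first and last fix of a
trip. Zero-length steps have indeterminate heading; the turn angles at
both adjacent vertices are left undefined rather than invented.
Clustering methods use |θ| in degrees, the HMM uses signed θ in
radians — the two usages serve different models and are kept distinct.

Pre-filtering drops fixes within 250 m of the roost (near-roost
circling is neither foraging nor commuting) and rejects tracks left
with fewer than 100 fixes. Regularization linearly interpolates onto
the 15 s grid inside gaps of up to 10 min; longer gaps are not bridged
— the trip is split there, since interpolating tens of minutes of
flight would fabricate movement. Both radii (island / trip start) are
exposed in `FilterConfig`.

## Acoustics

Calls are local maxima of a log-amplitude envelope above a threshold,
with endpoints at the first −5 dB crossings on each side (linearly
interpolated between samples). The inter-pulse interval (IPI) runs
from the end of one call to the start of the next. A feeding buzz is a
maximal run of ≥ 3 consecutive calls whose IPIs are all < 10 ms; a run
followed by further search-phase calls is an *aborted* buzz, and both
kinds count as foraging evidence. The "at least three consecutive
calls" rule is read as ≥ 3 calls (i.e. ≥ 2 sub-threshold IPIs); the
alternative ≥ 3-IPI reading is available via `min_calls=4`.

Buzzes snap to the nearest GPS fix in time; an exact tie goes to the
earlier fix (deterministic and order-independent). Evaluation counts a
fix once however many buzzes map to it (a per-buzz weighting exists
behind a flag).

Duty-cycle analysis enumerates all `period / on_window` phases of the
recorder schedule (10 for 0.5 s of every 5 s) and reports, per phase,
the fraction of foraging bouts containing at least one audible buzz.
Bouts are ground-truth foraging intervals where available; for purely
acoustic data a bout is a maximal buzz cluster with gaps < 60 s
(configurable — the boundary value is a modeling choice, not a
measurement).

## k-means and the elbow

kmC clusters (speed, |turn|) *unstandardized*. This is deliberate:
turn angle spans [0, 180] while speed spans a few m/s, so the fitted
boundary is essentially a turn-angle threshold — the geometry observed
for trawling bats. A z-scoring option exists but is off by default.
With two clusters, foraging is the higher-mean-turn cluster; when the
lowest-speed and highest-turn criteria disagree, turn decides.

The cluster count comes from the variance-explained curve. A raw
maximum-second-difference rule degenerates (the gain from k=1 to k=2
always dominates the curvature), so the elbow is defined as the
smallest k after which the marginal gain collapses below a quarter of
the preceding gain; curves that never collapse (a single structureless
cloud) return the smallest candidate k with a warning.

## First-passage time

FPT at a fix is the forward plus backward time to first exit a circle
of radius r centered there, with crossing times linearly interpolated
along the straight segment between fixes — this matches the
closed form FPT = 2r/v on a straight constant-speed path and is the
continuous-path convention. Fixes whose path never exits in one
direction (trip ends) are undefined and omitted.

The analysis radius maximizes the across-trip *mean* of the per-trip
variance of ln(FPT) (per-trip first, then averaged — not pooled) over
a 100–5000 m grid in 25 m steps. The foraging/commuting threshold
comes from a two-component normal mixture on ln(FPT): by default the
95th percentile of the lower (commuting) component, clamped between
the two component means, exponentiated back to seconds. "The upper
confidence limit between the peaks" admits several estimators, so the
quantile level is a parameter and `segment_fpt` accepts any externally
chosen threshold; the default is the most literal rule that is
well-defined from the mixture alone. It requires component means more
than one pooled SD apart; otherwise the threshold must be set manually.

## Hidden Markov model

Two states (n-state capable); emissions are gamma step lengths
(parameterized by mean/SD) and von Mises turn angles with mean fixed
at 0 — in this system both states' turn distributions are centered on
0 and freeing the means buys nothing but variance. The likelihood is
the exact scaled-forward recursion, maximized directly with L-BFGS
over log-transformed emission parameters and transition logits (the
same strategy as the standard movement-HMM tools; the optimizer's
result is kept only if it improves on the start, so the final
log-likelihood never falls below the initial one). The initial state
distribution is tied to the stationary distribution of the transition
matrix. Trips pool into one model as independent chains, making the
fit invariant to trip order.

Starting values: a 2-component normal mixture of pooled step lengths
(means/SDs), κ = 0.1 per state. If BIC prefers a single Gaussian over
the mixture — or a component weight vanishes — initialization falls
back to a 30th/70th percentile split with a warning. Zero step lengths
are displaced to half the smallest positive step (GPS jitter makes
exact zeros artifacts; the gamma needs x > 0). Undefined turn angles
at trip ends are marginalized out of the emission product.

Decoding is global (Viterbi) by default, posterior decoding behind a
flag. The short-step state is foraging. Observation t informs location
t+1 and location 0 inherits the first step's state, so no fix is
omitted. Goodness of fit uses one-step-ahead probability-integral
pseudo-residuals mapped through the normal quantile, tested with
Jarque-Bera (df = 2); forecast probabilities at 0 or 1 are clipped
with a warning.

The subsampling experiment refits the whole pipeline at intervals from
15 s upward (trips left with < 50 fixes are skipped per interval) and
reports the OLS slope of median balanced accuracy against interval.

## Correlated-velocity change points

Velocities are finite differences of a regular track. Per coordinate
they follow an Ornstein–Uhlenbeck process: autoregression
ρ = exp(−dt/τ), stationary variance ν²/2 (so ν is the stationary RMS
speed), advective mean μ (zero for UCVM, free for ACVM). The fit is an
exact AR(1) Gaussian likelihood — given ρ, μ and the innovation
variance have closed forms, leaving a 1-D search over τ (bounds
0.01–1000 × dt; estimates pinned there are flagged). The reported
likelihood adds the stationary density of the segment's first velocity
evaluated at those estimates. BIC uses k = 2 (UCVM) or 4 (ACVM) and
n = the number of velocities.

Change points: a window of 8 fixes, stepped by 5, profiles the
UCVM split log-likelihood over interior split points (≥ 3 velocities
per side); each window's best split with positive gain is a candidate.
Candidates are then thinned by recursive binary segmentation: within a
segment, the candidate minimizing the two-segment BIC is accepted only
if it beats the unsplit segment's BIC, recursing into both halves. For
this comparison the segmented likelihood keeps the velocity transition
*across* each boundary (an interior segment's first velocity is
conditioned on its predecessor under the segment's own parameters), so
the unsplit model is exactly nested in the split model and the BIC
test is calibrated — without this, splitting always gains likelihood
and false positives proliferate. Accepted boundaries are finally slid
to their locally BIC-optimal position (the scan's candidate grid is
coarse). Change points may not fall within 30 s of each other or of a
segment edge. A window that cannot be fit triggers a retry with a
10-fix (2.5 min) window for that trip.

Segments shorter than 4 fixes are merged into the neighbor with the
closer mean speed; each final segment is refit with both models and
the lower BIC labels it: UCVM → foraging, ACVM → commuting.

On simulated single-switch tracks (advective commute μ = 5 m/s,
ν = 1.5, τ = 60 s vs unbiased search ν = 3.4, τ = 10 s, 100 fixes per
side) the accepted change point falls within one window of the truth
in 50/50 seeded replicates, with ~0.05 false positives per
homogeneous 200-fix track.

## Evaluation

Positives are buzz-positive fixes, negatives all other fixes;
TPR/TNR/balanced accuracy are computed per trip with method-omitted
fixes excluded from both denominators (omissions are reported
separately, not silently absorbed). A trip with no scoreable
buzz-positive fix has undefined TPR and is flagged rather than scored.
Segment summaries treat omitted fixes as transparent: they neither
form segments nor break a run whose flanking labels agree.

Friedman (tie-corrected) compares methods across trips; identical
rankings short-circuit to χ² = 0, p = 1. Paired Wilcoxon tests drop
zero differences before ranking (Wilcoxon's rule), use the exact null
for ≤ 25 distinct-magnitude differences and the tie-corrected normal
approximation otherwise, with Bonferroni multiplication by the number
of comparisons actually performed in the family.

## Synthetic generator

The generator is a two-state semi-Markov *kinematic* model, not any of
the models the segmentation methods assume: headings evolve by von
Mises increments (κ ≈ 11 commuting, ≈ 0.2 foraging), per-fix speeds
are truncated-normal draws (5.3 ± 0.4 m/s commuting, 3.4 ± 0.5
foraging), dwell times are exponential (10 min commuting, 5 min
foraging bouts), positions integrate at 15 s and get isotropic 8 m
Gaussian GPS noise. Buzzes are Poisson at 5/min inside foraging bouts
and 0.05/min otherwise (stray commute attacks do occur in real
recordings; their rate is a modeling choice). Trip durations are
3.4 ± 1.8 h clipped to 0.9–6.4 h. Audio duty cycling keeps buzzes
whose time modulo 5 s falls in a 0.5 s on-window. All randomness flows
from one seed via `default_rng([seed, trip_index])`, so suites are
byte-reproducible. A separate exact-transition OU simulator
(`simulate_cvm`) exists for the change-point module's oracles, keeping
that method from being tested only on its own generative model.

What the generator does *not* emulate: rest/drift states, wind or
current advection, prey-patch depletion, heading goal-persistence over
long commutes (commute heading random-walks, so very long commute
segments slowly turn — which degrades the constant-advection CVCP
model more than the other methods and is the main reason CVCP ranks
lower here than a goal-directed commuter would suggest), GPS dropouts
(tests delete fixes explicitly), and raw 184 kHz waveforms (call
trains are synthesized at the envelope level). Passing tests therefore
demonstrate algorithmic correctness and qualitative behavior under
study-like conditions, not field performance.

## Numerical choices

- k-means: 10 restarts; mixtures: full covariance, up to 1000 EM
  iterations at tolerance 1e-5 (the pooled 4-component fit needs a few
  hundred); degenerate components (zero variance) raise rather than
  return nonsense.
- HMM optimizer: L-BFGS-B, ftol 1e-8, κ capped at 700 (Bessel
  overflow), states reordered by step mean after fitting.
- CVM τ search: bounded scalar minimization on log τ, xatol 1e-6.
- FPT uses a per-trip distance matrix (O(n²) memory, ~5 MB at 800
  fixes) so the 197-radius scale scan stays vectorized.
- Wilcoxon switches from exact to normal approximation at n > 25 or on
  tied magnitudes.

## Problem sizes

The test suite and examples run everything at the study's own scale:
15 trips of ~3.4 h at 15 s fixes (~12,000 fixes total) for the
benchmark; 5000 observations for HMM recovery; 2000 velocities for CVM
recovery; 100 replicates for BIC selection frequencies; 50 replicates
for change-point localization; 10,000 relabelings for the
random-classifier anchor. The full suite completes in about two
minutes on one CPU.

## Known limitations

- The EMbC-style method is an axis-aligned approximation (GMM +
  weighted two-group delimiters), not the cited likelihood-weighted
  algorithm; its labels agree with it in the well-separated regime the
  delimiters assume.
- The FPT threshold rule is one member of a family; with the deposited
  field data a different estimator of "the upper confidence limit
  between peaks" could shift the threshold by tens of seconds.
- CVCP assumes piecewise-constant OU parameters; gradual behavioral
  drift produces extra change points or late boundaries.
- The HMM assumes serial independence of emissions given the state;
  pseudo-residual diagnostics on real tracks should be expected to
  flag autocorrelation, as they do mildly on generator output.
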