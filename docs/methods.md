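# Methods

This note documents the models, parameter choices and numerical conventions
behind `phenoroi`, and what the synthetic-scene tests do and do not show
about real webcam archives.

## Signal model

The vegetation signal is the green chromatic coordinate
`gcc = g / (r + g + b)` per pixel, with channels normalised to [0, 1].
gcc is invariant to overall brightness scaling, which removes much of the
day-to-day exposure variation in uncontrolled webcam imagery; it does not
remove white-balance shifts, snow, fog or shadows, none of which are
modelled here.  A fully black pixel (r+g+b = 0) carries no chromatic
information and is treated as missing.

All series live on a fixed day-of-year axis 1..365.  Multiple frames on
one DOY are averaged into a single daily value, because every downstream
window (the 240-day OC1 window, the DOY 30..210 candidate range, the
template knots) counts calendar days.  Missing days stay missing — nothing
is interpolated — and every operation restricts itself to observed days.
Frames on DOY 366 (the leap-day-shifted year end) are excluded with a
warning rather than folded into day 365.  ROI series average pixel gcc
within each frame first and daily afterwards; candidate scoring in the
sROI/uROI search instead averages rows of the precomputed per-pixel daily
matrix, which is identical whenever pixel missingness is day-aligned (true
for rendered scenes and for real frames without fully black pixels) and
avoids re-touching the frame data for every one of hundreds of candidates.

## OC1 — supF structural change

For observed days t ≤ 240 (window configurable), each candidate change day
s ∈ [30, 210] splits the series into regimes t < s and t ≥ s.  A straight
line (k = 2 parameters, residual sum RSS0) is compared with two
independent lines (RSS1(s)) via

    F(s) = ((RSS0 − RSS1(s)) / k) / (RSS1(s) / (n − 2k)),

and OC1 = max F(s) with its argmax as the change day.  Conventions:

- `n` counts the observed days actually used, so gappy open-access series
  remain scoreable; when all 240 days are present this equals the fixed
  window length.
- Candidates need at least 5 observations strictly on each side; boundary
  candidates would make the segmented fit singular.
- Exact fits: RSS1 ≈ 0 with RSS0 > 0 gives F = +∞, flagged `exact_fit`
  and still comparable as a maximum; RSS0 ≈ RSS1 ≈ 0 (a perfect single
  line) gives F = 0.  "≈ 0" means below 1e-9 of the series' total sum of
  squares, which absorbs float cancellation in the closed forms.
- Ties in F break toward the earliest candidate day, for determinism.

Segment RSS values come from moment-sum closed forms
(RSS = Syy − Sxy²/Sxx after centring t and y), evaluated for all split
points at once from prefix sums.  The tests verify this against explicit
per-candidate design-matrix least squares at relative tolerance 1e-8.
F is used purely as a ranking score; no p-value calibration is attempted,
and none is needed for ROI selection.

OC1 is misfit-dominated on large, low-noise ROIs: its residual is then the
two-line model's lack of fit to the curved seasonal shape, which scales
with the seasonal amplitude exactly as the "signal" does.  Diluting a pure
deciduous mask with near-constant pixels therefore barely changes F and
can even raise it slightly.  This is why OC2 is the default selection
criterion (below); OC1 remains useful as a change-day estimator and as a
secondary score.

## OC2 — template-bank correlation

The expected deciduous annual curve is a piecewise-linear template: winter
level 0 up to spring onset `a`, linear rise to 1 at the peak `c`, small
decline to a summer plateau (level 0.7) between `d` and `e`, decline back
to 0 at season end `b`, flat afterwards.  Only `a` and `b` are scanned —
the default bank is the full grid a ∈ {50..150} × b ∈ {265..365}, 10201
templates — with shape defaults c = a + 20, d = c + 20, e = b − 60.  All
five shape parameters are configurable; because Pearson correlation is
affine-invariant, only the relative geometry matters, and the defaults
place a mid-April onset about three weeks before peak greenness and a
two-month autumn decline, a typical temperate-deciduous shape.

OC2 is the maximum Pearson correlation between the series and the bank,
computed over the observed days only; templates that are constant on the
observed window are excluded.  Ties break toward lexicographically
smallest (a, b).  The winning (a, b) double as rough SOS/EOS2 estimates.
Bank rows are standardised once per observation pattern and cached, so
scoring many candidates against the same gappy series costs one
matrix-vector product each.

## sROI

A pinprick is a 6 × 6 px seed square; its series is the mean gcc over its
36 pixels.  The correlation image holds each pixel's Pearson correlation
with the pinprick series over their shared observed days (undefined below
3 shared days or at zero variance).  Thresholding at τ keeps pixels with
r ≥ τ; the default grid τ ∈ {0.05, 0.10, …, 0.95} (m = 19) spans the unit
interval, and masks are nested in τ by construction.  Candidates smaller
than max(25 px, 0.05 % of the image) are dropped by default — tiny ROIs
make criterion scores noisy.  The best (pinprick, τ) under the criterion
(ties: larger mask, then smaller τ) is the sROI.  In the automated mode,
q pinprick centres are drawn uniformly without replacement on a coarse
grid with stride equal to the pinprick side, which prevents near-duplicate
seeds; degenerate pinpricks (constant series, e.g. on buildings) are
skipped with a log note.

## uROI

The stack becomes the centred 3n × T matrix X with row blocks
(r₁..r_n, g₁..g_n, b₁..b_n).  Only available frames enter; day gaps affect
the criteria, not the decomposition.  The first p left singular vectors
are computed by dense LAPACK SVD and truncated by slicing — exact,
deterministic, and faster than iterative truncated solvers at the stack
sizes this package targets; each singular pair's sign is fixed so the
largest-magnitude entry of the left vector is positive.  U is rearranged
to the n × 3p per-pixel feature matrix U* (p loadings per colour channel,
channel-blocked), clustered with k-means (k-means++ seeding, 10 restarts,
max 300 iterations, seeded).  Features are raw U* rows without
singular-value weighting; weighting is available as an option.  Every
cluster of every (p, k) partition is scored with both criteria; the
default grid p ∈ {12, 24} × k ∈ {4..10} yields 14 partitions and 98
candidate clusters, ranked in the output table by the selection criterion.
Cluster size filtering is off by default (min_size = 0): small clusters
are still scored, they just rarely win.

## Season dates

`dates_from_template` returns SOS = â and EOS2 = b̂ from the OC2 winner —
rough estimates by construction (grid resolution 1 day, template shape
fixed).

`segment_dates` fits the full annual series with a multiple-change-point
model: piecewise-linear regimes with free intercept and slope, each at
least 5 observations long, minimising total RSS.  The partition for every
change-point count K ≤ 4 is solved exactly by dynamic programming over
segment-RSS tables (O(K·n²), well under a second for daily series).
Greedy binary segmentation was considered first — it reuses the supF scan
directly — but a greedy split of a segment that still contains several
kinks lands between them, and later refinement cannot always escape that
(a mis-placed split pins the scan window next to a true kink); the exact
DP has no such failure mode and recovers noise-free piecewise-linear
fixtures to the day.  The change-point count is chosen stepwise: the K-th
change is accepted while

    F_K = ((RSS_{K−1} − RSS_K) / 2) / (RSS_K / (n − 2(K+1))) ≥ 20,

with the same exact-fit conventions as OC1.  The floor of 20 corresponds
to a strongly significant two-parameter improvement and stops spurious
splits in flat winter stretches; it is configurable.  Ties in RSS break
toward the earliest days.  Change days are labelled positionally
(1st → SOS, 2nd → MAX, 3rd → EOS1, 4th → EOS2); no semantic check of
greenness direction at each break is made, so on series with atypical
shapes the labels may not match their ecological meaning — a documented
limitation.  Fractional change days are out of scope: estimates are whole
days.

## Synthetic scenes

`render_scene` builds RGB stacks whose gcc inverts the planted profile
exactly at zero noise: g = gcc·s and r = b = (1 − gcc)·s/2 with base
brightness s = 0.9, so g/(r+g+b) = gcc analytically.  Gaussian channel
noise (sd 0.02 by default, clipped to [0, 1]) sits on top; 0.02 of an
8-bit channel range is a realistic clear-day exposure jitter for an
outdoor camera, and propagates to roughly the same sd in gcc.

The default scene is a 64 × 64 grid with 365 daily frames and four
rectangular regions: sky (level 0.30 plus daily jitter sd 0.01), evergreen
(level 0.42 plus a +0.05 May-shoot bump on days 120–170, so the criteria
must discriminate degrees of seasonality rather than merely detect any),
deciduous (template with a = 105, b = 308, winter gcc 0.25, summer 0.60 —
onset and end in mid-April and early November, typical for temperate
beech), and building (constant 0.33).  The deciduous block is 37.5 % of
the image.  All randomness derives from the scene seed in a fixed order,
so rendering is bit-reproducible.

What passing on this scene shows: the full pipeline — loading, gcc
aggregation, correlation growth, SVD features, clustering, both criteria,
date estimation — recovers planted structure through realistic pixel
noise.  What it does not show: robustness to illumination drift,
shadows, snow, fog, camera shake or field-of-view shifts, mixed-species
regions with overlapping phenologies, or exposure artefacts; real
archives also have irregular gaps far larger than any modelled here.
Image registration for drifting cameras is explicitly out of scope.

## Problem sizes

The test suite and the acceptance script run everything at desk scale:
the 64 × 64 × 365 default scene (n = 4096 pixels, data matrix
12288 × 365), the full 14-partition uROI grid on that scene, 10201-template
banks, 100-replicate date-recovery experiments, and 8 × 8 stacks for the
SVD oracle checks.  These sizes exercise every code path; the algorithms
scale to webcam-native resolutions linearly in n for everything except the
dense SVD, whose cost grows with n·T² — for megapixel archives an
iterative truncated solver would be the natural swap behind
`svd_features`.
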