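# Methods

## The phantom: what it emulates, and what it does not

Each synthetic slice models a left-ventricular short-axis section as a
circular annulus (endocardial radius `r_endo`, epicardial radius
`r_epi`) containing an infarct shaped as an annular sector anchored at
the endocardium and extending outward through a fraction
`transmural_depth` of the wall. This matches the morphology of 2-week
reperfused infarcts, which grow from the subendocardium toward the
epicardium. Rasterization follows a single rule used everywhere: a
pixel belongs to a region iff its center lies inside the analytic
boundary (pixel centers at integer grid coordinates, x right, y down,
positions in mm = index × spacing). Ground-truth size is therefore an
exact pixel ratio, `100 · |infarct| / |myocardium|`, and converges to
the closed-form annulus-sector area fraction as spacing shrinks (tested
at 1.4, 0.7 and 0.35 mm).

Pixel values are independent Gaussians around the pixel's true-class
mean. Defaults are the cohort-average tissue statistics of a 2-week
swine infarct model at 1.5 T: remote myocardium 995 ± 48 ms native T1
and 21 ± 8.4 a.u. LGE signal intensity; infarct 1347 ± 89 ms and
112.6 ± 17 a.u. Default in-plane spacing is 1.4 mm (both modalities are
generated on the T1 grid; LGE-resolution grids can be requested
explicitly). There is no partial-volume mixing at the infarct border by
default, which keeps the ground truth exact; an optional `smooth_edge`
flag linearly blends class means across a ±1.5-pixel band while leaving
the ground-truth masks crisp. The phantom deliberately omits MR physics
(off-resonance banding, motion, heart-rate-dependent TI scheduling,
surface-coil shading) and anatomic irregularity (non-circular contours,
papillary muscles). Passing tests therefore demonstrate correctness of
the measurement pipeline under its stated statistical model, not
robustness to real-acquisition artifacts.

Cohorts are `n_animals × (basal, mid, apical)` with basal slices
infarct-free by default (basal planes typically escape an LAD
occlusion infarct). Per-animal tissue means are jittered around the
cohort averages with between-animal SDs estimated from the observed
inter-animal spread of per-animal means (T1: 38 ms remote, 76 ms
infarct; LGE remote: 5.8 a.u.). The LGE infarct mean is jittered
lognormally (σ_log = 0.34) because enhancement ratios are positive and
right-skewed across animals; Gaussian jitter at the observed spread
occasionally produces non-physical near-zero contrast. Infarct geometry
varies mildly per animal: sector 120° ± 15°, transmural depth
0.80 ± 0.05, center angle 60° ± 15° — choices that put slice infarct
sizes in the 25–30 % range and transmurality near 80 %, the regime the
method is meant for. Wall radii (basal 13/21, mid 12/20, apical
9/16 mm) are plausible for a 30 kg swine but not calibrated to measured
anatomy; all are configurable.

## MOLLI simulation and fitting

Simulated series follow the three-parameter Look-Locker model
`S(TI) = A − B·exp(−TI/T1*)` with `B/A = 2` (ideal inversion) by
default, so `T1* = T1` and the Look-Locker correction
`T1 = T1*·(B/A − 1)` is the identity; the default TI schedule is the
3(3)5 two-inversion pattern (3 images one RR apart, a 3-beat pause,
5 more), at RR = 800 ms with first TIs of 100 and 180 ms. Signals are
signed by default; magnitude mode is an explicit flag recorded in the
series metadata, and fitting then enables polarity restoration (refit
with the first j samples negated for every split, keep the lowest
residual).

Fitting is nonlinear least squares (trust-region reflective) on
(A, B, T1\*), initialized at `A₀ = max(S)`, `B₀ = 2A₀`,
`T1*₀ = TI_min|S| / ln 2`, bounded to `T1* > 0`, relative tolerance
1e−10, at most 200 function evaluations. Non-converged, degenerate
(constant-signal) or non-physical (`A ≤ 0`, `T1 ≤ 0`) fits are flagged
and surface as missing (NaN) pixels in the map — never as silent
values. An independent oracle used in the tests exploits that the model
is linear in (A, B) for fixed T1\*: solving that 2-parameter problem
exactly over a dense T1\* grid bounds the fit error by the grid step.

## Segmentation conventions

Remote-ROI statistics use the sample SD (n − 1); the default minimum
ROI size is 20 pixels (a 60°-wide full-wall sector at 1.4 mm gives
~68). The threshold test is strictly `value > mean + k·sd` — ties are
excluded — with `k = 3` for T1 and `k = 5` for LGE. No connectivity or
minimum-island cleanup is applied by default (an optional
`remove_islands` parameter exists but is off in every shipped
analysis). "Percentage of slice area" is interpreted with the slice's
myocardial area as denominator (blood pool excluded): reported sizes
near 26–29 % together with ~80 % transmurality and ~100 mm² absolute
areas are only mutually consistent under a myocardium denominator. The
denominator choice is a parameter of `infarct_size` callers in the
sense that any mask may be passed as the reference.

## Transmural extent

The infarct's circumferential span is the 1st–99th percentile of its
mask-pixel angles about the LV center, computed circularly (recentered
on the circular mean direction) so spans crossing the ±180° cut work;
the percentile trim makes the span robust to stray suprathreshold
pixels. Ten rays (span endpoints included) are placed equidistantly
across the span; each is sampled endocardium→epicardium at 0.1 pixel
per step with nearest-pixel lookup, at wall-interval midpoints. Samples
whose nearest pixel is not myocardium (blood pool or beyond the
epicardium under rasterization) are excluded from the wall length —
without this, the half-pixel rasterized boundary bands depress a fully
transmural infarct's reading by ~2 pp at 0.35 mm spacing and ~7 pp at
1.4 mm. Infarct-classified length is counted wherever it occurs along
the ray (not restricted to a contiguous subendocardial run). A span
within 2 % of the maximum attainable percentile span switches to
full-ring mode with rays equidistant over 360°. On rays through the
circular-annulus phantom this construction is exactly the perpendicular
endo-to-epi chord; for arbitrary contours, rays through the centroid
approximate the clinical centerline construction.

## AHA segments and positivity

Basal and mid slices are split into six 60° sectors, apical into four
90° sectors, with boundaries at `anchor + i·width` anchored on the
anterior RV insertion angle; ids follow the standard numbering (basal
1–6, mid 7–12, apical 13–16; the apical cap, segment 17, has no
short-axis extent). Segment positivity is "any infarct pixel inside the
segment" — presence/absence is all the reference recording provides —
and the continuous diagnostic score of a segment is its mean T1 (not
the pixel maximum). A segment with no usable pixels is flagged
`excluded` and dropped from ROC analysis.

## Statistics

The empirical ROC uses cutoffs at midpoints between adjacent distinct
scores plus ±∞, strict `>` positivity, and trapezoidal AUC; this equals
the normalized Mann-Whitney statistic with ties counted ½. A
dichotomous test (LGE) yields the single-operating-point polygon whose
AUC is `(sens + spec)/2`, which is what makes the continuous-vs-binary
AUC comparison well defined. AUC standard errors and the paired AUC
z-test use the DeLong placement-value covariance estimator; a zero
variance of the difference (e.g. identical scores) returns z = 0,
p = 1. The Youden-optimal cutoff maximizes `J` over the finite ROC
cutoff set with ties broken toward the smaller cutoff. Bland-Altman
reports bias, SD of differences and both limits `bias ± 1.96·SD`
explicitly. Regression is ordinary least squares with `r²` the squared
Pearson correlation; p-values come from the normal/t approximations,
with no small-sample exact options.

## Pipeline

`run_study` is deterministic given the config seed (the config hash is
written to the run log; reports are byte-identical across runs). The
remote ROI is placed automatically 180° from the infarct's center angle
(60°-wide full-wall sector); a second observer is emulated by repeating
the T1 analysis with the ROI rotated a further 25°, and the two
observers' per-slice sizes and transmural extents feed the
inter-observer Bland-Altman block. Animal-level agreement/regression
blocks average infarcted slices per animal (basal slices, infarct-free,
drop out of those summaries but remain in the segment tables). By
default the phantom's T1 map is analyzed directly; `fit_molli = true`
inserts the full simulate-MOLLI → fit-T1-map step instead, which is
exact on noise-free series.

## Problem sizes in shipped analyses

The default study is 10 animals × 3 slices at 1.4 mm spacing (~400
myocardial pixels per mid slice, 160 AHA segments). Sub-pixel accuracy
checks (transmurality, rotation invariance, size convergence) run at
0.35 mm. Monte-Carlo checks use 200 replicate cohorts (generator
unbiasedness), 1000 replicates (MOLLI noise), 500 simulated datasets
(DeLong null calibration and the cohort-level AUC/cutoff consistency
check).

## Known limitations

- Circular-annulus geometry only; arbitrary contours are accepted by
  the measurement functions but are not exercised by the generator.
- Independent Gaussian pixel noise; no spatial correlation, Rician
  magnitude bias, or partial-volume mixing (unless `smooth_edge`).
- The transmurality span estimate assumes one dominant infarct;
  multiple disconnected infarcts in distinct sectors would be spanned
  jointly.
- DeLong p-values use the normal approximation, adequate at the
  ~150-segment scale but not for very small samples.
- The segment-level reference is the exact ground-truth mask, so
  reference misclassification (histology/registration error in real
  studies) is absent; measured specificities are correspondingly
  optimistic.
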