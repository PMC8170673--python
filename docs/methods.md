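# Methods

## Reconstruction chain

A digitized ultrasound pixel `(u, v)` (0-based; `u` lateral along the
39 mm probe face, `v` axial depth away from the probe) is scaled to
image-plane millimetres, corrected for speed of sound, and mapped
through two rigid transforms:

```
p_world = T_world<-probe ∘ T_probe<-image ( u·s_lat, v·s_ax·(c/c_cal), 0 )
```

Only the axial spacing is rescaled by `c/c_cal`: time-of-flight
miscalibration affects reconstructed depth, not lateral geometry. For
water-bath work `c(T)` comes from the quadratic model
`c = 1405.03 + 4.624·T − 3.83e-2·T²` (T in °C, valid 10–40 °C); the
coefficients live in `WaterSpeedModel` and can be overridden when a
different calibration of the same form is preferred.

Rigid transforms are validated to orthonormality at 1e-9; inputs within
1e-6 of a rotation (accumulated round-off) are repaired by polar
decomposition, anything worse is an error — silent repair of genuinely
broken poses would hide calibration faults.

**Marker-cluster frames.** A cluster of ≥3 labeled markers defines a
frame by convention: origin at the first marker, x-axis toward the
second, z-axis along the least-squares plane normal (sign fixed by the
first three markers, right-handed), y = z × x. The convention is
arbitrary but deterministic, which is what a shared test/retest
reference requires. The sacrum cluster's axes carry declared anatomical
labels (default: x medio-lateral, y anterior-posterior, z
superior-inferior; anterior/left/superior positive). All reported
per-axis statistics use these labels; they are configuration, not
anatomy inferred from data.

## Hip joint center: MSAC sphere fit

The inner estimator is the algebraic least-squares sphere (linearizing
`|p|² = 2c·p + (R² − |c|²)`), exact on noiseless data; coplanarity is
detected by the design-matrix condition number (threshold 1e8). The
MSAC loop samples minimal 4-point hypotheses, rejects radii outside
(10, 60) mm — plausible femoral-head sizes, also suppressing giant-
sphere degeneracies — and scores with the truncated squared residual
`Σ min(r², t²)`. Defaults: inlier threshold t = 2.0 mm (≈4× the
digitization noise scale), 2000 iterations with adaptive early stopping
at 99% confidence, fixed seed, first-encountered winner on cost ties.
The final model is an unweighted algebraic refit on the consensus set;
a Gauss-Newton geometric refinement is available behind
`MsacConfig.geometric_refine` but off by default so the robust loop and
the refit share one estimator. All loop parameters are reported in the
fit's JSON metadata because no canonical values exist for this
application.

Sweeps should contribute roughly 10–50 digitized frames; fewer (or
more) triggers a warning, an empty sweep is an error.

## ASIS selection

The ASIS is the most anterior point of the pooled sweep in the pelvic
frame (ties: lowest input index). Pooling across frames, rather than
selecting per image, yields the single 3D landmark that test-retest
statistics need; per-image selection would require a second reduction
step anyway.

## Reliability statistics

Legs are treated as independent rows. For each method × group × axis an
n × 2 (sessions) matrix feeds a two-way ANOVA (rows, columns, residual
by direct summation — the residual sum of squares is computed from
residuals, not by subtraction, so perfect-agreement data gives exactly
zero):

* ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n), the
  single-measure absolute-agreement form; 95% CI by the standard
  F-based interval with a Satterthwaite df approximation. Ratings:
  < 0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, > 0.9 excellent
  (boundaries resolve downward: 0.90 is "good"). A matrix with no
  variability yields a flagged undefined ICC, not an error.
* SEm = √MS_error (the measurement-error SD, not the standard error of
  the mean); the alternative SD·√(1−ICC) is exposed as a labeled
  secondary output.
* Friedman across methods (within-row average ranks, tie-corrected,
  χ² with m−1 df) per group; pairwise two-sided Mann-Whitney follow-ups
  (tie-corrected normal approximation, no continuity correction by
  default, uncorrected for multiplicity, α = 0.05). Mann-Whitney is the
  default follow-up even though the compared samples are paired by leg;
  a Wilcoxon-style paired alternative can be obtained by differencing
  externally — the unpaired test is kept as the primary because it is
  the conventional companion to the Friedman screen here.
* Pearson r between per-leg Euclidean test-retest distance and torso
  fat mass (FMT, % body mass), two-sided p via the t transform, n
  reported; zero-variance inputs yield a flagged undefined result.
* Variation table: SD (ddof = 1) of signed per-axis differences and of
  Euclidean distances per group; contrast columns are
  `obese_SD − lean_SD` (rounded to 0.1 mm) and `100·obese/lean`
  (rounded to integer percent).

Rows missing a session are excluded and counted, never imputed.

## Accuracy evaluation

Minimal Euclidean distances of each reconstructed point to the
reference: nearest neighbour via k-d tree in cloud mode (the default,
matching a dense laser scan at sub-resolution spacing), or exact
nearest-surface point in mesh mode (centroid-pruned point-triangle
distances; the pruning radius provably contains the nearest face).
Outliers: beyond 1.5 × IQR outside Q1/Q3, quartiles by linear
interpolation between order statistics (recorded in output metadata;
strict inequalities, so zero-IQR samples have no outliers). Summaries
(mean, SD, range, quartiles) cover **all** points with the outlier
fraction reported alongside; an outlier-excluded summary is a flag
away. Heatmap export writes an ASCII PLY with a blue→red ramp and bakes
the color scale into the returned metadata.

## Synthetic phantom and cohort

The phantom is an abstraction, not an anatomical mesh: a superellipsoid
body (semi-axes 110/70/80 mm, exponent 2.5), two spherical femoral
heads (radius 24 mm — pediatric scale), a 4-marker sacrum cluster, and
two ASIS protrusions modelled as Gaussian bumps (amplitude 15 mm, width
5 mm) on a locally flat anterior plateau. The flat base makes the bump
apex the strict anterior maximum of the patch, so the "most anterior
point" rule and the analytic ground truth coincide by construction —
the property the tests need to be exact.

Simulated sweeps are parallel image planes across a structure; pixels
are computed by inverting the true probe pose, so with zero noise the
back-projection lands on the analytic surface to machine precision.
Noise parameters: pixel noise (mm, on u and v), gross blunders
(spurious *shallow* echoes 10–30 mm above the bone — soft-tissue
interfaces; modelled shallow rather than deep because a deeper
displacement can pass through the head sphere and land near its far
surface, which is not a gross outlier), and tracking noise applied to
the stored pose only (pixels stay consistent with the true pose).

The cohort generator emulates the study conditions: 32 lean + 38 obese
legs (two legs per subject share the subject's FMT), FMT from truncated
normals 14.9 (10.0) % and 43.3 (7.9) %, per-subject anatomical offsets
(SD 10 mm/axis — without between-subject variance the zero-error ICC
would be undefined), and per-axis session error SD = a + b·FMT with
method-specific illustrative coefficients (MMP 0.5 + 0.20·FMT, IPT
0.5 + 0.18·FMT, ultrasound ASIS 3.5 + 0.12·FMT, ultrasound HJC
2.0 + 0.15·FMT mm) chosen so lean/obese SEm magnitudes fall in
plausible few-to-teens-of-mm ranges; they are not fitted to any data.
Optionally, hip-center rows are dropped when a simulated head depth
(35.5 + 0.6·FMT + N(0, 5) mm) exceeds the 65 mm penetration limit,
which removes mostly obese trials. Note one estimand subtlety: with
FMT-heteroscedastic error the ANOVA MSE estimates `E[(a + b·FMT)²]`,
so SEm recovery is checked against √E[(a+b·FMT)²], which exceeds
`a + b·E[FMT]` by Jensen's inequality.

What the generator does **not** emulate: acoustic image formation
(speckle, attenuation, refraction), correlated per-axis errors, probe
pressure effects, assessor learning, or subject-specific anatomy.
Passing tests therefore demonstrate the correctness and robustness of
the estimators under the stated error model, not in-vivo performance.

## Problem sizes and determinism

Unit and acceptance runs use 15–21 frames × 15 points per sweep
(~300 points per fit), 50–100 Monte-Carlo replicates, cohorts of 70
legs (1000 rows only for variance-component recovery), and 27 simulated
accuracy trials against a ~0.3 points/mm² reference cloud — sizes at
which every check is stable yet the whole suite runs in seconds. All
generators are bit-reproducible for a fixed seed; every report embeds
seed, config hash, and package version.

## Known limitations

* The phantom's analytic convenience (flat ASIS plateau, perfect
  spheres) makes recovery bounds optimistic relative to irregular bone.
* Cloud-mode accuracy against a sampled reference upper-bounds the true
  surface distance by the sampling spacing.
* The ICC CI uses the standard F/Satterthwaite approximation; exact
  small-sample coverage is not claimed.
* Marker trajectories are assumed pre-filtered by the motion-capture
  pipeline; no trajectory smoothing is implemented here.
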