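# fus3d

Toolkit for 3D freehand ultrasound (3DFUS) localization of pelvic
anatomical landmarks and the hip joint center, with the full test-retest
reliability and point-cloud accuracy analysis around it.

In clinical 3D gait analysis the anterior superior iliac spines (ASIS)
define the pelvic coordinate system and, via pelvic width, the estimated
hip joint center (HJC). Palpation-based marker placement degrades with
subcutaneous fat. A tracked 2D ultrasound probe offers an alternative:
each image pixel `(u, v)` maps through a calibrated chain

```
p_world = T_world<-probe · T_probe<-image · (u·s_lat, v·s_ax·c/c_cal, 0)ᵀ
```

where `s_lat`, `s_ax` are pixel spacings (mm/px), and the axial spacing
is rescaled by the ratio of the actual speed of sound `c` to the
calibration speed `c_cal` (in water baths, `c(T)` from the quadratic
temperature model). Pooled over a sweep and expressed in the
sacrum-cluster frame, the digitized bone-surface points feed:

* **HJC estimation** — an MSAC (M-estimator Sample Consensus) sphere
  fit: minimal 4-point algebraic hypotheses scored by the truncated cost
  `Σ min(r_i², t²)` with `r_i = | ‖p_i − c‖ − R |`, refit on the
  consensus set; the center `c` is the HJC.
* **ASIS extraction** — the most anterior point of the pooled sweep in
  the pelvic frame.
* **Test-retest reliability** — ICC(2,1) (single-measure, absolute
  agreement, from the two-way ANOVA mean squares) with F-based 95% CIs,
  SEm = √MS_error, Friedman + Mann-Whitney comparisons across methods,
  and Pearson correlation of test-retest distances against torso fat
  mass (FMT).
* **Accuracy** — minimal Euclidean distances of a reconstructed cloud to
  a ground-truth laser-scan cloud or mesh, with the 1.5 × IQR outlier
  rule and descriptive summaries.

A synthetic phantom/cohort generator (`fus3d.phantom`) provides every
input with analytic ground truth: a superellipsoid pelvis with Gaussian
ASIS protrusions and spherical femoral heads, tracked sweeps whose
noiseless digitizations back-project exactly onto the surface, and a
two-session lean/obese cohort whose landmark error grows linearly with
FMT.

## Worked example

The numbered drivers under `analysis/` run the full study on synthetic
data (optional argument: a seed, default 0) and write their tables under
`results/`:

```
$ python analysis/01_build_phantom.py
phantom: HJC error 5.02e-14 mm, ASIS error 0.00e+00 mm (noiseless)

$ python analysis/03_cohort_reliability.py
cohort: 267 rows, 13 hip-center trials dropped
  Friedman lean: chi2(3) = 19.57, p = 0.000
  Friedman obese: chi2(3) = 3.67, p = 0.299
  Pearson r(distance, FMT) MMP: r = 0.83, p = 0.000, n = 70
  Pearson r(distance, FMT) IPT: r = 0.73, p = 0.000, n = 70
  Pearson r(distance, FMT) 3DFUS: r = 0.44, p = 0.000, n = 70
  Pearson r(distance, FMT) 3DFUS-HJC: r = 0.59, p = 0.000, n = 57

$ python analysis/04_accuracy_water_bath.py
pooled: mean 1.96 (2.36) mm, range 0.1-16.5 mm, 6.6% outliers
```

Reading the output: a noiseless sweep recovers the ground-truth HJC and
ASIS to machine precision, validating the reconstruction chain. In the
simulated cohort the method differences in test-retest error are
significant for the lean group but not the obese group, and the
distance-FMT correlation is strong for palpation/pointer methods but
weak for ultrasound — ultrasound-based localization is less sensitive
to body fat by construction of the generator's error model. The
water-bath study summarizes reconstruction error against the reference
scan with the share of IQR-rule outliers.

`analysis/02_hjc_recovery.py` tabulates Monte-Carlo HJC recovery across
noise levels and outlier fractions (`results/hjc_recovery.csv`): at
0.5 mm digitization noise and up to 20% gross blunders the median center
error stays below 0.5 mm.

A `fus3d` command-line interface wraps the same library for file-based
pipelines (`simulate`, `reconstruct`, `fit-hjc`, `reliability`,
`accuracy`, `report`); run `fus3d --help`.

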