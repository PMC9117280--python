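# Methods

This document records the mathematical model, the numerical choices, the
synthetic-data generator, and the design decisions behind `petsrtm`.

## 1. Kinetic model

### 1.1 SRTM

The simplified reference tissue model (Lammertsma & Hume, 1996) describes a
target-region PET concentration C_T(t) in terms of a reference-region
concentration C_R(t) devoid of specific binding:

    C_T(t) = R1 · C_R(t) + (k2 − R1·k2a) · [C_R ⊗ e^{−k2a t}](t)

Parameters:

| symbol | units | meaning |
| --- | --- | --- |
| R1 | — | relative tracer delivery, K1/K1' |
| k2 | 1/min | target-region clearance rate |
| k2a | 1/min | apparent clearance, k2 / (1 + BP_ND) |

The quantity of interest is the non-displaceable binding potential

    BP_ND = k2 / k2a − 1 .

Model assumptions: both regions are well described by one-tissue-compartment
kinetics; the reference region has negligible specific binding; the
non-displaceable distribution volume is the same in both regions; blood volume
contributions are negligible. These are the standard SRTM assumptions; the
package neither checks nor relaxes them.

### 1.2 Basis-function fit

`SRTM.fit()` uses the basis-function method (Gunn et al., 1997). For each
candidate k2a on a fixed grid, the model is linear in (R1, φ) with
φ = k2 − R1·k2a:

    C_T = R1 · C_R + φ · B(k2a),   B(k2a) = C_R ⊗ e^{−k2a t}

so each grid point costs one 2×2 weighted normal-equation solve (vectorised
across the whole grid). The grid point minimising the weighted residual sum of
squares wins; k2 = φ + R1·k2a and BP_ND = k2/k2a − 1 follow.

Defaults (all overridable):

- **k2a grid**: 100 log-spaced points in [0.006, 0.6] /min. The range covers
  BP_ND from ~0 to >50 for striatal-range k2; log spacing gives ~4.8% relative
  resolution per step. Fits landing on the first or last grid point set
  `edge_of_grid=True`.
- **weights**: `uniform` (default) or `duration` (frame-duration weights).
- **uncertainty**: the delta-method %CV of BP_ND from the conditional linear
  covariance at the winning grid point, with gradient g = (∂BP/∂R1, ∂BP/∂φ) =
  (1, 1/k2a) applied to cov(R1, φ) = σ̂² (XᵀWX)⁻¹. This conditions on k2a and
  therefore slightly understates total variance; with 100 grid points the
  quantisation term is small against the noise term at realistic noise.

Grid quantisation of k2a largely cancels in BP_ND because k2 = φ + R1·k2a
moves with the chosen k2a; on noiseless data the basis fit agrees with an
unconstrained nonlinear least-squares fit to < 0.5% (verified against an
independent oracle in the acceptance tests).

### 1.3 Convolution numerics

The basis functions require [C_R ⊗ e^{−k2a t}]. The reference curve is modelled
as piecewise linear through (0, 0) and the frame mid-times, resampled on a fine
grid (0.05 min default). On that grid the convolution satisfies the exact
recursion

    y[n+1] = E · y[n] + a_n · g + b_n · (Δ − g)/k2a,
    E = e^{−k2a Δ}, g = (1 − E)/k2a

where a_n, b_n are the local linear coefficients of C_R. The recursion is a
first-order IIR filter evaluated with `scipy.signal.lfilter`; it is exact for
piecewise-linear input, so the only discretisation error is the linear
interpolation of C_R itself. Model predictions are frame **averages**, not
point samples: the fine-grid curve is integrated (cumulative trapezoid),
interpolated at frame boundaries and differenced. Unit tests pin this pipeline
against an ODE integration (`scipy.integrate.solve_ivp`) of
dC_T/dt = R1·dC_R/dt + k2·C_R − k2a·C_T with an analytic reference input
(relative error < 1e-3) and against brute-force trapezoid convolution.

## 2. Challenge pharmacodynamics

For each subject, region and post-challenge scan:

    ΔBP  = 100 · (1 − BP_post / BP_baseline)                      (percent displacement)
    ΔΔBP = 100 · (1 − ΔBP_drug+amph / ΔBP_amph)
         = 100 · (BP_drug+amph − BP_amph) / (BP_baseline − BP_amph)  (percent attenuation)

Aggregation is per-subject-first: the statistic is computed for every subject,
then averaged within the group; SDs use n−1. A zero denominator (no baseline
binding, or no amphetamine displacement for ΔΔBP) yields NaN with a
`RuntimeWarning`, and such subjects drop out of the group mean (the reported n
tracks this).

Hypothesis tests, per region:

1. **Displacement**: paired two-tailed t test, baseline vs amphetamine BP_ND.
2. **Attenuation**: paired two-tailed t test on the two ΔBP series
   (amphetamine-only vs drug+amphetamine).
3. **Dose effect**: one-tailed two-sample t test that the higher dose yields
   greater ΔΔBP, pooled-variance Student t by default (df = n1+n2−2), Welch
   optional.

t statistics and degenerate-case handling (identical series, zero variance)
are implemented directly; `scipy.stats.t` supplies the distribution function,
and the tests cross-check against `scipy.stats.ttest_rel`/`ttest_ind`.

### 2.1 Input-rounding sensitivity

The packaged clinical per-subject BP_ND values are published to two decimals.
`ChallengeResults.input_rounding_bound()` propagates a worst-case ±0.005
perturbation of every input through the two statistics analytically:

    |δΔBP|  ≤ 100·δ·(1/b + a/b²)
    |δΔΔBP| ≤ 100·δ·( 1/|b−a| + |t−b|/(b−a)² + |t−a|/(b−a)² )

summed per subject and averaged per cell (b, a, t: baseline, amphetamine,
drug+amphetamine BP_ND). For ΔBP the bound is ~0.3 points; for ΔΔBP in regions
with small displacement (caudate, substantia nigra) the ratio amplifies
rounding to 4–9 points. This explains why two non-headline ΔΔBP cells of the
published table recompute 0.7–0.8 points away from the printed values while
all headline quantities agree to ±0.2: the original authors computed their
table from unrounded inputs. `reproduce-paper` and the acceptance tests hold
every cell to its analytic bound and the headline cells to ±0.5 points.

## 3. Synthetic-data generator

`simulate_cohort` produces a three-scan (baseline, amphetamine,
drug+amphetamine), two-dose-group cohort with full ground truth. The chain:

1. **Plasma input**: Feng tri-exponential model
   C_p(t) = (A₁t − A₂ − A₃)e^{−λ₁t} + A₂e^{−λ₂t} + A₃e^{−λ₃t} with the
   published default coefficients — a standard bolus-injection shape.
2. **Reference TAC**: one-tissue-compartment response
   C_R = K1 · [C_p ⊗ e^{−k2't}] with ref_k1 = 0.1 mL/min/mL and
   ref_k2' = 0.35 /min, computed with the same exact piecewise-linear
   convolution at 0.02 min, frame-averaged, and peak-scaled to 30 kBq/mL. With
   these defaults the cerebellar curve peaks at ≈4.5 min — early, as expected
   for a bolus study.
3. **Target TACs**: SRTM forward model per region with per-subject parameters.
4. **Noise**: zero-mean Gaussian frame noise with the count-statistics
   heuristic σ(t) = noise_scale · sqrt(max(C,0)/Δt). Applied independently to
   reference and target curves of every scan.
5. **Effects**: per subject and region, baseline BP_ND ~ N(base_mean,
   base_sd²); amphetamine displacement ΔBP ~ truncated N(dbp_mean, dbp_sd²)
   on (−50, 80)%; attenuation ΔΔBP ~ N per dose group (redrawn if > 100%).
   The three scan-level BP_ND values are obtained by inverting the ΔBP/ΔΔBP
   definitions, so the generator's ground truth is exactly consistent with
   the analysis-side statistics.

All randomness flows from a single `numpy.random.default_rng(seed)`; the same
seed reproduces the cohort bit-for-bit. `SimConfig` is YAML round-trippable
and fully documented in its docstring.

### 3.1 Calibration and scope

Default region means/SDs and effect sizes mirror the published study's group
table, the frame schedule is 26 frames over 90 min
(4×15 s, 4×30 s, 4×1 min, 4×2 min, 5×5 min, 5×10 min), and group sizes are
5+5.

`noise_scale` defaults to 0.2, giving region-level BP_ND precision of ≈1%
(delta-method CV ≈1%). Two constraints pin this choice: the study reports its
regional BP_ND estimates as well determined (CV < 10%), which is only an upper
bound; and the published between-subject SD of ΔΔBP (e.g. 7.7 points in the
40 mg putamen, n = 5) upper-bounds the per-subject measurement component of
that statistic. Because ΔΔBP is a ratio with a small numerator, BP_ND noise of
~4% would already produce a ~20-point measurement component — larger than the
printed total SD, hence inconsistent with the study's own variability. Since
the generator draws *true* effects with the printed between-subject SDs (which
already include measurement error), it deliberately takes those as a
worst-case spread and keeps the added measurement noise small.

What the generator does **not** emulate: image reconstruction and ROI
extraction (the pipeline starts at regional TACs), subject motion, scanner
resolution and partial-volume effects, radioactive decay (curves are assumed
decay-corrected), correlated noise between regions, and within-subject
parameter drift between scans other than the modelled challenge effects.

## 4. Design decisions

- **Repository shape**: statsmodels-style — model classes (`SRTM`,
  `ChallengeStudy`) whose `fit()` returns results objects (`SRTMResults`,
  `ChallengeResults`) with `summary()`; simulation and plotting hang off
  these. Thin functional wrappers (`fit_srtm_basis`, `summarize_challenge`)
  cover one-shot use.
- **Problem sizes** (package's own choices): 100-point default k2a grid,
  0.05 min basis fine step, 0.02 min simulator fine step, 26-frame/90-min
  default schedule. One basis fit costs ~1.5 ms; a full default cohort
  simulate + fit runs in ~0.3 s.
- **Data formats**: plain delimited text only (CSV default, TSV accepted);
  row order immaterial, schema violations raise `ParseError` naming the
  offending rows. Packaged fixtures are SHA-256 integrity-checked on load.
- **Determinism**: same seed → byte-identical simulator output; fits are
  deterministic; BP-table round trips through disk are bit-exact
  (`%.17g` + `float_precision="round_trip"`).

## 5. Limitations

- The basis fit conditions the BP_ND uncertainty on the selected k2a; at very
  low noise the grid quantisation can dominate the reported CV.
- The SRTM itself biases BP_ND when the one-tissue approximation fails in the
  target region (notably for very slow kinetics); no two-tissue fallback is
  provided.
- Pooled-variance dose comparison assumes equal group variances; Welch is
  available but not the default, matching the original analysis.
- The generator's truncated-normal effect distributions are a pragmatic
  choice, not a mechanistic receptor-occupancy model.
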