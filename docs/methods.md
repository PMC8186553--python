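# Methods

This note documents the models, estimators, parameter choices and known
limitations behind `aehydro`, the way a maintainer would want them written
down — not as a results report (every number quoted here is recomputed by
the test suite or the analysis scripts).

## The measurement problem

During bench-top dehydration an excised cereal shoot dries under tension.
Each embolism event — air abruptly filling a xylem vessel — releases a
burst of ultrasonic energy that a point-contact sensor records as a
discrete acoustic emission (AE) hit with an amplitude (dB_AE) and a peak
frequency (kHz).  In parallel, a dendrometer logs radial shrinkage, a
balance logs mass, and a pressure chamber provides occasional point
readings of xylem water potential Ψ_xylem (negative MPa).  The pipeline
turns these four streams into:

* an **acoustic vulnerability curve** (VC_AE): percent loss of conductivity
  (PLC, %) against Ψ, with the thresholds AE_12/AE_50/AE_88/AE_100 and the
  time to full embolism t_100%;
* a **desorption curve** (DC): cumulative water loss (g) against Ψ, with
  two phase breakpoints and the elastic/inelastic hydraulic capacitances
  C_el, C_inel (g MPa⁻¹);
* **anatomical trait summaries** (d_h, CWR, V_g, vessel/parenchyma areas)
  from per-vessel measurement tables.

## Acoustic processing

1. **Filtering.** Events are retained when amplitude ≥ 28 dB_AE and peak
   frequency lies in the inclusive 20–1000 kHz band.  Both boundaries are
   closed: "at the noise floor" keeps the event, which makes the filter a
   deterministic predicate.  The filter is applied in software to event
   records; in the original instrumentation it is an acquisition-hardware
   setting.
2. **Cumulation.** Retained events are counted in 5-min bins and summed
   cumulatively on the bin edges, anchored at 0 at excision.
3. **Activity.** The AE activity curve (hits h⁻¹) is the first finite
   difference of cumulative AE over a 15-min span.
4. **Endpoint.** Embolism formation ends where activity decreases most
   strongly after its peak — the first post-peak local maximum of the
   third derivative of cumulative AE.  The third derivative is computed by
   applying the spanning central difference three times (window default
   2.5 h, configurable 2–3 h; one-sided stencils at the edges).  When
   several post-peak local maxima exist, the first one reaching at least
   50% of the strongest is chosen (a prominence guard against noise
   wiggles), ties resolving to the earliest bin.
5. **PLC.** Cumulative AE is rescaled from zero to the endpoint:
   PLC(t) = 100·cum(t)/cum(endpoint), truncated at the endpoint.

**Numerical behaviour of the endpoint detector.**  The iterated wide-window
central difference is a smoothed third derivative.  On an asymmetric curve
(a logistic is asymmetric around the post-peak third-derivative maximum)
symmetric smoothing shifts the detected maximum late by roughly
`3·(w/2)²·c/τ` seconds (w the window, τ the logistic time scale, c ≈ 0.3),
i.e. up to ~1 h for w = 2.5 h and τ = 1.5 h.  In the small-window limit the
detector agrees with a dense numeric third derivative to within one 5-min
bin (tested).  On noisy event streams the prominence rule tends to select a
slightly earlier local maximum, which in practice offsets most of the
smoothing bias; the recovered t_100% on calibrated synthetic data is
unbiased to within ~0.3 h.  The 2.5-h default is kept because shrinking the
window on real (counting-noise) data makes the third derivative useless.

## The continuous Ψ axis

Pressure-chamber readings are sparse; the dendrometer is continuous.  The
bridge is the stress–strain relation: relative radial shrinkage
Δd/d_i (μm mm⁻¹) against Ψ shows an elastic phase and an inelastic phase
separated by one breakpoint.  We fit Ψ as a one-breakpoint segmented-linear
function of shrinkage (orientation chosen because Ψ is what the axis must
predict), pairing each reading with the shrinkage value at the nearest
5-min grid time (≤ 2.5 min offset; readings outside the trace are
dropped).  The fitted map is evaluated on the whole shrinkage trace and
projected onto non-increasing sequences (L2 isotonic regression via
scikit-learn's pool-adjacent-violators), because Ψ cannot rise during
bench dehydration and noise-induced inversions would otherwise corrupt
threshold interpolation.  If the segmented fit is unidentifiable (readings
on one side of every candidate breakpoint, or an effectively straight
relation) it falls back to ordinary least squares with a warning flag.

## Segmented least squares

All breakpoint estimation uses one in-package primitive: continuous
piecewise-linear least squares.  The design matrix is
`[1, x, (x−b₁)₊, …, (x−bₖ)₊]`, so continuity at the breakpoints is built
in.  Breakpoint positions are found by exhaustive search over midpoints of
consecutive distinct x (assembled from precomputed cross-sums, so the
two-breakpoint pair grid stays O(n²) cheap), followed by Nelder–Mead
refinement of the continuous positions.  Constraints: every segment must
contain ≥ 3 points (identifiable slopes); ties break toward the smallest
breakpoints; the refined fit is accepted only when it improves on the grid
optimum, so the result is never worse than the exhaustive grid.  With zero
breakpoints the primitive reduces exactly to OLS.  No dependency on the
external segmented-regression package the field commonly uses: the
primitive is oracle-tested against brute force instead.  Confidence
intervals for breakpoints, robust losses and smoothing splines are out of
scope.

## Desorption curves and capacitances

ΔWC(t) = mass(0) − mass(t) is resampled to the Ψ-axis grid (the
gravimetric shoots carry no dendrometer, so they borrow the cultivar-mean
axis of the paired acoustic shoots, time-aligned at excision), cleaned to
non-decreasing by isotonic projection, and fitted with a two-breakpoint
segmented regression: a flat pre-phase, elastic phase I, inelastic phase
II.  The fit is truncated at the cultivar AE_100 because the phase model is
defined only down to full embolism — including the tail beyond it lets
Ψ-axis distortion there consume a breakpoint.  C_el and C_inel are the
magnitudes of the OLS slopes of water loss vs Ψ restricted to
[bp2, bp1] and [AE_100, bp2] respectively, reported positive in g MPa⁻¹
(capacitance per tissue volume is not computed).  A curve with no phase
structure (single straight line) raises a degenerate-phase error rather
than returning arbitrary breakpoints.

**Identifiability limit.**  When the true C_el is indistinguishable from
zero (one published cultivar's elastic capacitance is smaller than its own
standard error), the pre-phase and phase I have essentially the same slope
and the first breakpoint is unidentifiable; the fit then spends it inside
phase II and the reported C_el is meaningless.  This is a property of the
data, not of the estimator, and shows up in the analysis campaign for that
cultivar.

## Anatomy

* d = 2√(A/π) assumes circular vessels.
* d_h = (Σd⁴/n)^¼, the hydraulically weighted mean; by the power-mean
  inequality d_h ≥ mean(d) with equality iff all diameters are equal.
* CWR = (t/b)² with the ratio averaged over vessels whose diameter lies
  within ±10% of d_h (nearest measured vessel as fallback), then squared —
  mean-then-square, matching the formula's subscript reading "evaluated at
  d_h".  The selection window is a choice; the sources give no rule.
* V_g = vessels / distinct groupings (≥ 1, = 1 iff all solitary).
* Traits are computed per organ (stem / leaf sheath) or combined; both
  protoxylem and metaxylem records are included.

## The synthetic experiment generator

No raw bench-dehydration data are deposited, so validation rests on
virtual experiments with known truth:

* **Ψ(t)** declines linearly from ψ₀ = −0.5 MPa.  Linearity is a modelling
  choice (the true trajectory shape is unreported) that keeps every
  downstream quantity analytic.
* **PLC(Ψ)** is a symmetric logistic `100/(1+exp(s·(Ψ−p50)))`, the standard
  sigmoid vulnerability curve; symmetry puts the Ψ of maximum acoustic
  activity exactly at p50, which is what makes the near-unit
  AE_50-vs-max-activity regression testable.
* **Events** form an inhomogeneous Poisson stream with intensity
  `n_events·d/dt[PLC/100]` (most acoustic energy where most embolism
  forms), drawn by thinning; amplitudes uniform 28–60 dB_AE, frequencies
  uniform 20–1000 kHz.  Noise events are homogeneous in time with
  amplitudes uniform 20–27.9 dB_AE — strictly below the noise floor, so
  the amplitude filter removes exactly them.  Real amplitude/frequency
  distributions are unreported; uniform draws are a stand-in, and nothing
  downstream uses amplitudes beyond the threshold.
* **Dendrometer**: two-segment stress–strain law (slopes 8 then
  3 μm mm⁻¹ MPa⁻¹, breakpoint at the cultivar's embolism onset),
  displacement = −strain·d_i with d_i = 2.5 mm, Gaussian noise 0.3 μm,
  1-min logging.
* **Balance**: flat pre-phase above bp1 = ψ₀ − 0.2 MPa, then slopes C_el
  and C_inel below bp2 (tied to the shrinkage breakpoint, mirroring the
  observed coupling of stress–strain and DC breakpoints), noise 0.01 g
  (the balance's stated accuracy), 1-min logging.
* **Pressure chamber**: readings every 30 min with N(0, 0.05 MPa) noise,
  clipped to ≤ 0.

**Cultivar calibration.**  The five published cultivar rows (AE thresholds,
t_100%, capacitances) are translated into generator truth: p50 = AE_50;
steepness s = ln(88/12)/(AE_12 − AE_50); drying rate set so that the
analytic endpoint of the logistic — the post-peak third-derivative maximum,
which sits ln(p/(1−p)) ≈ 2.292 logistic units after the midpoint, at
p = ½ + 1/√6 — lands exactly on the published t_100%.  For the wheat
cultivar used in endpoint validation this calibration independently
reproduces the published AE_100 to 0.01 MPa (−0.5 − rate·t_100% ≈ −2.35),
a strong internal-consistency check.  The published threshold sets of the
other cultivars are not perfectly symmetric-logistic (their AE_50→AE_88
spacing is narrower than AE_12→AE_50), so for them the implied AE_100 is
0.1–0.15 MPa more negative than print; recovery tests for those cultivars
therefore target AE_50 and t_100%, not AE_100.

**What passing tests do and do not show.**  The generator reproduces the
stochastic structure the estimators rely on (counting noise, sensor noise,
phase structure, coupled breakpoints) but not drift, temperature effects,
sensor decoupling, non-logistic vulnerability shapes or embolism refilling.
Recovery within published standard errors on synthetic data demonstrates
estimator correctness under the stated model, not field accuracy.

## Problem sizes and defaults

| parameter | default | why |
|---|---|---|
| AE bin | 300 s | the 5-min cumulation/averaging interval |
| activity window | 900 s | the 15-min first-derivative interval |
| third-derivative window | 9000 s (2–3 h valid) | consistent endpoint detection |
| amplitude threshold | 28 dB_AE (inclusive) | sensor noise floor |
| frequency band | 20–1000 kHz (inclusive) | acquisition band-pass |
| replicate Ψ grid | 0.01 MPa | below pressure-chamber precision |
| CWR window | ±10% of d_h | selection rule for "(t/b) at d_h" |
| expected embolism events | 3000 | realistic per-shoot AE yield |
| noise event rate | 5 h⁻¹ | sparse sub-threshold background |
| Ψ reading noise | 0.05 MPa | pressure-chamber repeatability |
| virtual shoots per recovery test | 4 | matches the bench protocol (4 acoustic + 4 gravimetric shoots) |

Recovery experiments use 4 seeds and 30–45 h virtual recordings; the whole
validation suite and the acceptance script run in well under a minute each
on one core.
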