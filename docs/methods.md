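# Methods

## The digital hindlimb phantom

The phantom is a 128×128×7 voxel stack (2.0×2.0 cm field of view, 1 mm
slices; voxel 0.156×0.156×1 mm³) containing a posterior muscle ellipse, an
anterior muscle ellipse and a subcutaneous fat annulus, each scaled per
slice by a tapering profile (0.45, 0.62, 0.866, 1.0, 0.866, 0.62, 0.45 on
the linear scale) so the stack has a well defined largest slice, as a real
limb does. Geometry was chosen so the largest-slice muscle area is
≈ 37.2 mm² and the 4-slice volume ≈ 107 mm³ — typical wild-type mouse
values — but only ROI-level statistics matter; the anatomy is otherwise
schematic. Group presets carry the tissue truth values: muscle fat fraction
0.09 % (WT) / 0.19 % (Tg), T2 18.8 / 19.8 ms, tensor eigenvalues
(1.95, 1.45, 1.07) / (1.88, 1.34, 1.00) ×10⁻³ mm²/s.

Every simulator is a pure function of (ground truth, acquisition
parameters, seed); seeds are mandatory and no global RNG state is used.
Noise is independent complex Gaussian per channel, so magnitude images are
Rician; at the signal-to-noise ratios used for validation (≥ 50) the
Gaussian approximation of the magnitude noise holds and no Rician bias
correction is applied.

### Signal models

* **Dixon:** Sₙ = (W + F·e^{iθₙ})·e^{i2πψ·TEₙ} with θ = 0, π, 2π for the
  in/opposed/in echoes and ψ the per-compartment static field offset (Hz).
  The water–fat phase is idealized at exact multiples of π rather than
  derived from the literal echo spacing of a high-field protocol
  (1.5/1.8/2.1 ms), because the analyzer — like the standard 3-point
  method — is defined against the in/opposed-phase model. The field-offset
  ramp does use the nominal echo times.
* **T2:** |S₀·e^{−TE/T2} + complex noise| at TE = 8, 12, 16, 20, 24 ms.
* **DTI:** Stejskal–Tanner S = S₀·e^{−b·gᵀDg} at b = 0 and 450 s/mm² along
  a fixed 12-direction electrostatically spread set (frozen in
  `phantom/directions.py`; tensor design condition number 1.58). Fat signal
  is omitted, emulating fat-suppressed echo-planar readouts.
* **³¹P-MRS:** each protocol bin is a 2048-point, 8 kHz complex FID, a sum
  of damped sinusoids: PCr (0 ppm), Pi at the pH-dependent shift, γ/α-ATP
  1:1 doublets (−2.48 / −7.52 ppm) and the β-ATP 1:2:1 triplet
  (−16.26 ppm), J = 16.5 Hz, 81.08 MHz spectrometer frequency. PCr falls
  monoexponentially during stimulation toward a 55 % plateau (depletion
  time constant 60 s) and recovers monoexponentially with τPCr (preset
  148 s WT / 159 s Tg); Pi mirrors PCr exactly so PCr + Pi is conserved;
  pH ramps linearly from 7.06 to 6.80 during stimulation and relaxes back
  exponentially. Bin amplitudes are the kinetic model averaged analytically
  over each bin's acquisition window and scaled by the number of summed
  FIDs; bin noise scales with √n as a coherent sum of noisy FIDs would.
  Generator linewidths (9–28 Hz) deliberately differ from the fitter's
  initial guesses so recovery is a genuine fit.
* **Force:** tetani rise as F_plateau·(1−e^{−kt}) during the 0.75 s train
  and relax as F_peak·e^{−t/τ_rel}; per-train plateau follows a Hill curve
  (defaults F_max = 300 mN, f50 = 40 Hz, n = 3, k = 10.5 s⁻¹,
  τ_rel = 262 ms/ln 2). Twitches are scaled fast pulses (20 ms rise, 40 ms
  relaxation, 60 mN), declining during the 6-min 1.7 Hz fatigue bout along
  a configurable per-bin schedule (default: exponential decline to a 50 %
  plateau with a 60 s time constant — the decline is reported but not
  mechanistically modelled).

## Analysis choices

* **Dixon separation** assumes the per-voxel field phase per echo spacing
  lies within (−π/2, π/2]; no spatial unwrapping is performed (phantom
  offsets are tens of Hz). Negative W/F solutions are clamped to zero in
  the output maps and the clamped fraction reported, but the regional fat
  percentage averages the *signed* solutions: truncating negative noise
  excursions before averaging would bias a near-zero fat fraction upward
  by roughly the half-normal mean of the noise (at SNR 200 this bias is
  ~0.1 percentage points, larger than the quantity itself).
* **Anatomy** thresholds the water image at 50 % of the median foreground
  intensity (configurable) and keeps the largest connected component.
  Volume uses the 4 consecutive largest slices × 1 mm; the historical
  "four CSAs of the five consecutive largest slices" phrasing is
  internally inconsistent, so the slice count is a parameter defaulting
  to 4.
* **T2 mapping** is the log-linear estimator (unweighted OLS), matching
  field practice for single-component muscle T2; a nonlinear
  Levenberg–Marquardt refit serves as the oracle in tests only. Voxels
  with any nonpositive echo or a nonnegative slope are flagged invalid,
  never filled.
* **DTI** uses unweighted log-linear least squares — deterministic and
  sufficient at b = 450 s/mm². Negative noise eigenvalues are retained in
  the metric formulas (clamping would bias ROI means) but counted.
  Eigenvalues are sorted by value; no orientation tracking.
* **Spectral fitting** imposes prior knowledge by parameterization: one
  amplitude/damping/frequency per multiplet, fixed internal ratios and
  J-spacing, frequency windows of ±0.2 ppm (±1.2 ppm for Pi, which moves
  with pH), one shared zero-order phase. Starting values come from a
  linear projection on the nominal basis; optimization restarts from 3
  perturbed initializations (deterministic given the seed) and the best
  residual wins. Non-convergence yields a flagged result, not an
  exception. Time-course normalization divides bin amplitudes by the
  packet size before referencing the rest bin, since bins sum different
  numbers of FIDs.
* **pH calibration:** pH = 6.75 + log₁₀((δ−3.27)/(5.69−δ)), the standard
  Henderson–Hasselbalch calibration of the Pi–PCr shift; inputs outside
  the open interval (3.27, 5.69) ppm are rejected. The inverse is exact to
  machine precision over pH 6.4–7.4.
* **τPCr** is fitted as PCr(t) = PCr_end − ΔPCr·e^{−(t−t₀)/τ} on the
  recovery-bin time courses (% of rest; equivalent to raw amplitudes for
  τ), with bin timestamps at packet midpoints — unbiased for a
  monoexponential at these bin widths to within ~0.1 %. A flat course
  makes τ unidentifiable and is flagged.
* **Force metrics:** baseline is the median of the 50 ms before each
  train. The maximum rate of force development uses a 21 ms local-cubic
  (Savitzky–Golay) derivative: a raw centred difference at 10 kHz
  amplifies noise by the sample rate, while the cubic window tracks the
  onset curvature (noiseless bias < 1 %, unbiased under 1 % noise). The
  half-relaxation reference peak is searched only after the last stimulus
  of the train on a 5 ms smoothed copy — a global argmax on a noisy
  plateau would start the relaxation clock mid-train. The Hill fit is
  zero-offset with free exponent, so F(f50) = F_max/2 holds by
  construction.
* **Cohort statistics** use the equal-variance Student t-test (the
  unpaired test conventionally reported in this literature) and report
  percent differences rounded to integers. Repeated-measures ANOVA and
  post-hoc procedures are out of scope; the pipeline emits tidy per-bin
  tables suitable for external tools instead.

## Validation strategy and problem sizes

Noiseless simulator/analyzer round trips are exact (< 10⁻⁶ relative) for
every pair, and closed-form signal values, grid-search oracles (Hill fit,
τ fit, two-peak spectral amplitudes), quadrature oracles (bin averaging)
and an independent nonlinear T2 refit back the estimators. Stochastic
recoveries run at the study conditions: T2 at SNR 100 (2 % tolerance),
Dixon fat at SNR 200 (0.02 percentage points), PCr/ATP at SNR 50 (3 %),
τPCr at 2 % amplitude noise over 50 seeds (5 %), half-relaxation at 1 %
noise (2 %). Monte-Carlo repetition counts (10–50 seeds) and the single
full-resolution phantom per test keep the whole suite under a minute on
one CPU while leaving comfortable statistical margins.

## What the phantom does not capture

No k-space or EPI artifacts (ghosting, distortion), no B1 inhomogeneity,
no multi-peak fat spectrum or T2* decay across Dixon echoes, no
partial-volume mixing beyond voxel-centre rasterization, no saturation
correction for the dynamic ³¹P bins (quantities are % of rest acquired at
the same TR; PCr/ATP uses only the fully relaxed spectrum), and no
motion. Passing recovery tests therefore demonstrates correctness of the
estimators under the stated signal models, not robustness to scanner
artifacts; real-data use would add spatial phase unwrapping (Dixon),
eddy/motion correction (DTI) and lineshape handling (MRS) upstream of
these modules. In-vivo group contrasts (e.g. the transgenic force deficit)
are represented only as generator presets and are not claims reproduced by
simulation.
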