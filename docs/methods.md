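# Methods

This note documents the models, numerical choices and limitations of the
`srssoct` package: what the synthetic generator emulates, how the
reconstruction and biomarkers are computed, and which design decisions
were genuinely open.

## Forward model

One acquisition ("M-scan") is a stack of spectrometer frames
`I(λ, t)`, recorded at a fixed lateral position while the Stokes beam is
gated by the unit waveform `m(t)` (raised sine by default; square wave
available — the demodulator computes the waveform's fundamental
coefficient numerically, so no separate 4/π bookkeeping is needed). The
frame model is first order in the nonlinear perturbation:

    I(λ, t) = I₀(λ) · ( 1 + 2 Re{ S₀(λ) + m(t) · S₁(λ) } ),
    S₀(λ)   = Σ_j r̃_j e^(−μ (z_j − z_s)) e^(i 2 k n₀ z_j),
    S₁(λ)   = G(λ) Σ_j r̃_j e^(−μ (z_j − z_s)) p(z_j) e^(i 2 k n₀ z_j),
    G(λ)    = s_int · I_S · (ν/ν_c) · ( Im{χ⁽³⁾(Ω(λ))}/2 − i Re{χ⁽³⁾(Ω(λ))} ),

with `k = 2π/λ`, `Ω(λ)` the Raman shift of pixel λ against the fixed
Stokes line, and the phase coefficient twice the gain coefficient
(matching the ω/2c vs ω/c prefactors of the perturbed pump field). The
first-order expansion is consistent with the weak-perturbation regime in
which the amplitude/phase split of the demodulated signal is defined; at
the default interaction scale the exponents are O(10⁻²), so the truncation
error is O(10⁻⁴).

Modelling choices:

* **Speckle.** `r̃_j` are circular-Gaussian draws per depth sample of the
  phantom grid (4 μm spacing), scaled by the deterministic reflectivity
  envelope. Each lateral position gets an independent realization;
  columns of a B-scan are therefore independent speckle draws of the same
  column phantom.
* **Attenuation.** The fringe amplitude carries `exp(−μ (z − z_s))` with
  μ in mm⁻¹, so the reconstructed OCT *magnitude* decays at rate μ — the
  scale on which tissue decay coefficients are conventionally reported.
  μ is therefore directly the generative truth for the decay-recovery
  experiments.
* **SRS depth profile.** The phantom's interaction profile `p(z)`
  multiplies the nonlinear response of each scatterer. The default is
  `p(z) = exp(−μ_srs (z − z_s))` inside the tissue, which makes the
  reconstructed nonlinear-phase channel a single exponential with rate
  `μ_srs` — the generative truth for the phase-channel decay experiments.
  Absolute χ⁽³⁾ units are not modelled; all constants (interaction length,
  β = 3/(2 n₀² c ε₀), powers) are lumped into one dimensionless
  `interaction_scale`, and the SRS channels are meaningful only relative
  to their noise background.
* **Raman lines.** χ⁽³⁾ is a sum of complex Lorentzians (automatically
  Kramers–Kronig consistent); the default tissue composition uses a lipid
  CH₂ line (2850 cm⁻¹, HWHM 40 cm⁻¹) and a protein CH₃ line (2940 cm⁻¹,
  HWHM 45 cm⁻¹). Healthy (white-matter-like) phantoms are lipid-dominant
  with strong backscatter; tumor phantoms are protein-dominant with
  reduced backscatter. No electronic (non-resonant) background is
  modelled.
* **Noise.** Shot noise is Gaussian with variance proportional to the
  local mean intensity (large-photon-count limit); pump relative intensity
  noise (RIN) is a per-frame multiplicative factor. The default shot
  scale (1e-4) puts the nonlinear-phase channel's surface SNR at the
  10²-level — the clean-image regime of a working instrument — so the fit
  windows are limited by physics (signal decay and 1/carrier phase-noise
  growth) rather than by the first pixels.
* **Refractive index.** Default n₀ = 1 so the reconstructed (optical-path)
  depth axis and the geometric axis coincide and decay rates are per
  geometric mm; n₀ ≠ 1 is supported, with rates then per optical mm.

### Cohort generator

`make_cohort(n_tumor, n_healthy, …)` draws per-region phantom parameters
from truncated normal distributions (±2.5 σ). The group means of the
decay coefficients are the generative truths of the recovery experiments:
OCT 3.73 (tumor) / 8.17 (healthy) mm⁻¹, SRS phase 3.14 / 7.83 mm⁻¹. The
between-region spreads are free parameters of the generator (the source
measurements report only group summaries); the default SD of 0.4 mm⁻¹
keeps the cohort-mean standard error near 2% at n = 34 — small enough
that a 5% recovery tolerance tests the pipeline rather than the draw —
while leaving the groups visibly dispersed. Surface depths vary
(150 ± 25 μm), as do composition amplitudes and reflectivity scales.

Acquisition presets: `full` scale is 2048 spectral pixels × 2048 frames ×
200 A-scans per B-scan over 480 μm; `test` scale (1024 × 512 × 20) keeps
a 54-region cohort analysis to ~2 minutes on one CPU and is used by the
test suite and the acceptance script. The spectrometer spans 80 nm around
the 790 nm pump center (~2 mm depth range at test scale, ~4 μm axial
pixel).

## Reconstruction

1. **k-linearization.** Cubic-spline interpolation of each frame from the
   wavelength grid to a uniform `k = 2π/λ` grid (same pixel count,
   spanning the native support).
2. **Reference subtraction.** The reference spectrum is estimated as the
   temporal-mean frame smoothed along the spectral axis (Gaussian,
   σ = n_pixels/40) with one Richardson extrapolation step
   (`2·G[x] − G[G[x]]`) to cancel the smoother's curvature bias; this
   removes the source pedestal while leaving the static sample fringes
   intact. Band-filtered reconstructions reuse the *broadband* reference
   (identically windowed): estimating a reference on an already windowed
   spectrum cannot separate the narrow pedestal from fringes. An
   instrument with a recorded reference arm would use that instead; the
   estimate is this package's stand-in and is accurate to ~10⁻⁴ of the
   pedestal.
3. **Depth transform.** Hann apodization along k, then an rFFT keeping
   the positive-depth half-space. Without apodization, sidelobes of the
   truncated spectral support leak bright shallow structure into the
   depth tail and visibly flatten decay profiles.
4. **Lock-in demodulation.** The complex depth profiles `A(z, t)` are
   projected onto *both* modulation sidebands with a Hann window (the
   15 kHz line falls between FFT bins of the 2048 × 50 kHz record, so
   explicit projection avoids scalloping). With
   `c₊ = ⟨w (m − m̄) e^(−i2πf t)⟩` the same projection applied to the
   waveform,

       u(z) = ( X₊/c₊ + X₋/c₊* ) / 2 = a₀(z) · G_eff(z),

   and the carrier is recovered as `a₀ = ⟨w A⟩ − m̄·u`. For a real gating
   waveform, any real multiplicative disturbance — pump intensity noise —
   has conjugate coefficients at ±f and therefore folds entirely into the
   in-phase quadrature of `u/a₀`: the phase quadrature is structurally
   immune to RIN. This is the package's formalization of the phase
   channel's SNR robustness, and it makes the corresponding test a strict
   inequality rather than a statistical one.
5. **Perturbation ratio.** `q(z) = ⟨u·conj(a₀)⟩_w / ⟨|a₀|²⟩_w` with a
   2-pixel Gaussian axial kernel (amplitude-weighted, Kasai-style). The
   naive per-pixel ratio `u/a₀` diverges at speckle nulls of the carrier
   and makes the phase channel heavy-tailed. Channels:
   `oct = |a₀|`, `srs_amp = Re{q}·|a₀|`, `srs_phase = Im{q}`.
6. **Noise normalization.** Both SRS channels are divided by a scalar
   noise floor: the median over carrier-valid depths of the RMS of the
   same demodulation evaluated at nine guard frequencies spread over
   18–22 kHz (spectrally local, away from DC and the modulation). The
   per-depth noise profiles are kept alongside for fit censoring; masked
   depths (carrier below 10⁻³ of its maximum) carry infinite noise.

## Spectral (molecular) metrics

The two Raman bands (2861 / 2947 cm⁻¹, 80 cm⁻¹ wide) are imposed as
multiplicative order-4 Butterworth magnitude windows over the Raman-shift
axis of the k-linearized spectra — zero-phase by construction, ≥ 40 dB
power rejection one bandwidth outside the passband edge. Filtering acts
on the interferometric spectra before the depth transform. Per A-scan the
noise-normalized `srs_amp` and `srs_phase` of each band are averaged over
100–150 μm below the detected surface; the amplitude ratio (high/low) and
phase difference (high − low) are averaged across the B-scan's A-scans.
The ratio cancels pump power, Stokes power and reflectivity exactly; the
phase difference cancels band-independent phase offsets. With the two
band floors differing, the phase difference is in (band-wise) noise-floor
units; only group contrasts are meaningful.

## Spatial (structural) metrics

* **Surface detection:** first depth (≥ 40 μm, excluding the DC-residual
  region) where the OCT magnitude exceeds both 5× the additive noise
  (median of the deepest 15% of the record) and 10% of the A-scan peak,
  for ≥ 3 consecutive samples. The peak-relative term rejects the
  reference-subtraction residual; accuracy is one axial resolution
  element (~2 pixels at test scale), set by the apodized PSF.
* **Decay fitting:** log-linear least squares of the channel magnitude
  over [surface + 50 μm, surface + 700 μm] (the 700 μm extent mirrors the
  usable tissue penetration), truncated where the median-smoothed signal
  drops below 3× the (per-depth, for the phase channel) noise estimate.
  The cutoff is a single contiguous truncation: thresholding individual
  samples deeper down would selection-bias the tail. No additive offset
  term is fitted (the channels are reference-subtracted; an offset would
  absorb the noise floor and bias shallow decays). Fits are flagged
  invalid below 10 usable samples or above 1.5 log-RMS residual.
* **Region-level decay:** fitted on the lateral-mean (B-scan averaged)
  profiles. Per-column fits of the speckled phase channel are heavy
  tailed and biased 15–20% low near the noise floor; coherent lateral
  averaging over the independent speckle realizations recovers the
  generative rates within ~2%. (The per-A-scan `fit_decay` +
  `region_average` route remains available.)
* **AUC ratio:** trapezoidal integral of |channel| over the first 100 μm
  below the surface divided by the integral to the end of the record;
  strictly increasing in the decay rate for single exponentials and
  invariant to amplitude scaling.

## Discrimination

Student's pooled two-sample t test (two-sided; Welch behind a flag) for
group comparisons; the midpoint of the group means as the 1D decay-rate
threshold (which reproduces the ≈ 6 mm⁻¹ operating point from the OCT
group means); Fisher's linear discriminant
`w ∝ Σ_pooled⁻¹ (μ_t − μ_h)` (Tikhonov-regularized at 10⁻⁹ of the mean
eigenvalue) for the combined (OCT decay, SRS-phase AUC ratio) feature
pair, with projections min–max rescaled to [0, 1] (the minimum-projection
point is the reference at 0). In-sample, the projected coordinate's |t|
is at least that of either feature axis, so the combined metric never
separates worse — the test asserts exactly that. Box-plot summaries use
the linear-interpolation quantile rule and 1.5×IQR whiskers.

## What passing tests do and do not show

The generator reproduces the acquisition geometry, speckle statistics of
discrete random scatterers, exponential signal decay, the cumulative
weak SRS perturbation, shot noise and pump RIN. It does **not** model
dispersion mismatch, galvo distortion, thermal-lensing contributions
(the modulation is taken to be above the thermal bandwidth), detector
saturation, multiple scattering, or laterally structured tissue. Recovery
of the generative decay coefficients therefore validates the processing
chain — resampling, demodulation, surface detection, censored fitting —
under controlled conditions; it does not certify accuracy on real tissue,
where the exponential-decay and isolated-line assumptions are
approximations. The spectral-metric group contrasts are directional
reproductions (orderings and significance), not calibrated effect sizes:
the phase-difference scale depends on the arbitrary interaction scale and
noise normalization.

## Problem sizes and runtime

The test suite runs mostly at a reduced scale (512 pixels × 256 frames,
4–12 A-scans) with the full 34/20-region cohort exercised once at test
scale for the recovery checks (~2 minutes); `scripts/acceptance.py`
repeats that cohort from scratch plus a 2048-frame lock-in measurement
(~1.5 minutes). All randomness flows from explicit seeds; noiseless
simulations are bit-reproducible.
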