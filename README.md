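# srssoct

Simulation and analysis pipeline for **stimulated Raman scattering
spectroscopic optical coherence tomography (SRS-SOCT)** — a label-free
imaging modality that combines the depth-resolved, spectrally multiplexed
detection of Fourier-domain OCT with the molecular (vibrational) contrast
of stimulated Raman scattering. The package is aimed at researchers
developing SRS-SOCT instrumentation and processing: it provides a
physics-based generator of raw spectral-interferogram stacks from tissue
phantoms, the lock-in reconstruction of the OCT / SRS-amplitude /
SRS-phase channels, and the structural and molecular biomarkers that
separate brain-tumor tissue from healthy tissue.

## The measurement and the model

A broadband pump (790 nm center, ~40 nm FWHM) doubles as the OCT source; a
fixed 1040 nm Stokes beam, amplitude-modulated at 15 kHz, drives the SRS
interaction. At Raman shift Ω = ν_pump − ν_Stokes (cm⁻¹) the complex
third-order susceptibility of the tissue, modelled as a sum of Lorentzian
lines,

    χ⁽³⁾(Ω) = Σ_j A_j Γ_j / (Ω_j − Ω − iΓ_j),

perturbs the recorded spectral interferogram: per Stokes gating cycle the
oscillating term acquires a gain ∝ Im{χ⁽³⁾}·I_Stokes (stimulated Raman
loss/gain) and a phase shift ∝ Re{χ⁽³⁾}·I_Stokes. For each lateral
position 2048 spectra are recorded at 50 kHz; after interpolation to a
uniform wavenumber grid and a spectral→depth Fourier transform, a second
Fourier analysis along the frame axis isolates the 15 kHz component
(lock-in detection), yielding per depth z

* `oct(z)` — conventional FD-OCT magnitude,
* `srs_amp(z)` ∝ r·I₀·Im{χ⁽³⁾} — in-phase sideband amplitude,
* `srs_phase(z)` ∝ Re{χ⁽³⁾} — quadrature nonlinear phase, independent of
  reflectivity and pump power (and structurally immune to pump intensity
  noise: see `docs/methods.md`).

Downstream biomarkers:

* **band metrics** — Butterworth windows (80 cm⁻¹ ≈ 5 nm) centered on the
  lipid (2861 cm⁻¹) and protein (2947 cm⁻¹) CH-stretch bands; the
  amplitude ratio and phase difference of the two bands, extracted
  100–150 μm below the surface, report relative protein/lipid content;
* **decay coefficients** — log-linear exponential fits of the OCT and
  SRS-phase A-scans starting 50 μm below the surface, in mm⁻¹ (tumor
  scatters less: lower decay);
* **AUC ratio** — fraction of the depth-integrated signal within the first
  100 μm below the surface (tumor: weak, long-tailed profiles → lower);
* **2D discriminant** — Fisher's linear discriminant of (OCT decay,
  SRS-phase AUC ratio), with per-region coordinates along the
  discriminant direction rescaled to [0, 1], and the midpoint-of-means
  decision threshold for the 1D decay-rate rule.

## Worked example

Simulate a small labeled cohort at test scale, run the full analysis, and
compare the groups:

```python
import numpy as np
from srssoct import (AcquisitionConfig, CohortConfig, analyze_cohort,
                     discrimination_report, make_cohort)
from srssoct.pipeline import AnalysisConfig

config = CohortConfig(acquisition=AcquisitionConfig.test_scale(ascans_per_bscan=12))
plan = make_cohort(n_tumor=4, n_healthy=3, config=config, seed=42)
metrics = analyze_cohort(plan, AnalysisConfig())
print(metrics[["region_id", "label", "oct_decay_mm", "srsphase_decay_mm",
               "srsphase_auc_ratio", "phase_difference"]].round(3).to_string(index=False))

report = discrimination_report(metrics)
print(f"\nOCT decay: tumor {report['per_feature']['oct_decay_mm']['tumor_mean']:.2f} "
      f"vs healthy {report['per_feature']['oct_decay_mm']['healthy_mean']:.2f} mm^-1, "
      f"threshold {report['threshold_mm']:.2f} mm^-1")
print(f"Fisher direction {np.round(report['direction'], 3)}, "
      f"projected-coordinate p = {report['projected']['p_value']:.2e}")
```

Output:

```
  region_id   label  oct_decay_mm  srsphase_decay_mm  srsphase_auc_ratio  phase_difference
  tumor_000   tumor         3.273              3.165               0.308            38.863
  tumor_001   tumor         3.871              3.031               0.234            29.030
  tumor_002   tumor         4.086              2.724               0.214            40.095
  tumor_003   tumor         3.447              3.488               0.281            29.585
healthy_004 healthy         8.172              7.556               0.297             6.615
healthy_005 healthy         8.362              8.542               0.330             6.642
healthy_006 healthy         8.570              7.460               0.297             4.969

OCT decay: tumor 3.67 vs healthy 8.37 mm^-1, threshold 6.02 mm^-1
Fisher direction [-0.125 -0.992], projected-coordinate p = 1.53e-07
```

Tumor regions show the expected contrasts: OCT decay coefficients near the
generative tumor mean of 3.73 mm⁻¹ versus ~8.2 mm⁻¹ for healthy regions
(midpoint threshold ≈ 6 mm⁻¹), lower SRS-phase AUC ratios, and a much
higher dual-band phase difference (protein-rich composition). The
`phase_difference` column is in noise-floor units of the phase channel.

A command-line interface mirrors the library
(`srssoct simulate | reconstruct | metrics | discriminate | run-full`);
`srssoct run-full --out OUTDIR` runs the whole chain and writes the
metrics CSV, the discrimination report and a run manifest.

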