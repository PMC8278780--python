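"""Forward model: raw spectrometer-frame stacks from tissue phantoms.

One acquisition ("M-scan") is a stack of spectrometer frames recorded at a
fixed lateral position while the Stokes beam is amplitude-modulated.  Each
frame is a spectral interferogram

    I(lambda, t) = I0(lambda) * (1 + 2 Re{ S0(lambda) + m(t) S1(lambda) }),

where ``S0`` is the static fringe field of the scatterers,

    S0(lambda) = sum_j r_j exp(-mu (z_j - z_s)/1000) exp(i 2 k n0 z_j),

and ``S1`` carries the Stokes-synchronous nonlinear perturbation,

    S1(lambda) = G(lambda) * sum_j r_j exp(-mu .../1000) p(z_j) exp(i 2 k n0 z_j),
    G(lambda)  = s_int * I_Stokes * (nu/nu_c) * (Im{chi3}/2 - i Re{chi3}),

with ``m(t)`` the unit modulation waveform, ``p(z)`` the phantom's
depth-resolved interaction profile and ``chi3`` evaluated at the Raman
shift of each pump wavelength against the fixed Stokes line.  The imaginary
part of chi3 produces stimulated Raman gain (an intensity change), the real
part a nonlinear phase shift, and the phase coefficient is twice the gain
coefficient, matching the single- vs half-accumulation of the two
exponents in the perturbed pump field.  The expansion is first order in the
perturbation (weak-interaction regime; exponents are O(1e-2) at the
defaults).

Attenuation is parameterized so that the reconstructed OCT *magnitude*
A-scan of a homogeneous phantom decays as ``exp(-mu z)`` with ``mu`` in
mm^-1 — the scale on which tissue decay coefficients are reported.
Speckle arises from circular-Gaussian draws of the per-depth scatterer
amplitudes; each lateral position gets an independent realization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .physics import LaserConfig, RamanLine, SpectralAxis, chi3_eval, raman_shift

__all__ = [
    "AcquisitionConfig",
    "Phantom",
    "RawMScan",
    "PhantomPopulation",
    "CohortConfig",
    "CohortPlan",
    "RegionSpec",
    "layered_phantom",
    "make_phantom",
    "modulation_waveform",
    "simulate_mscan",
    "simulate_bscan",
    "make_cohort",
    "TUMOR_OCT_DECAY_MM",
    "HEALTHY_OCT_DECAY_MM",
    "TUMOR_SRS_DECAY_MM",
    "HEALTHY_SRS_DECAY_MM",
]

# Group-mean generative decay coefficients (mm^-1) used as cohort defaults.
TUMOR_OCT_DECAY_MM = 3.73
HEALTHY_OCT_DECAY_MM = 8.17
TUMOR_SRS_DECAY_MM = 3.14
HEALTHY_SRS_DECAY_MM = 7.83

#: per-depth-sample baseline scatterer amplitude (sets fringe contrast)
SCATTERER_AMPLITUDE = 0.01

#: lipid CH2 / protein CH3 stretch resonances (cm^-1): center, HWHM
LIPID_LINE_CENTER = 2850.0
LIPID_LINE_WIDTH = 40.0
PROTEIN_LINE_CENTER = 2940.0
PROTEIN_LINE_WIDTH = 45.0


class ConfigurationError(ValueError):
    pass


@dataclass
class AcquisitionConfig:
    """Spectrometer/scan settings.

    ``test`` scale (1024 pixels, 512 frames, 20 A-scans per B-scan) keeps
    cohort-level runs to minutes; ``full`` scale reproduces the acquisition
    geometry of the emulated system (2048 x 2048 x 200).
    """

    frames_per_ascan: int = 2048
    frame_rate_khz: float = 50.0
    n_pixels: int = 2048
    ascans_per_bscan: int = 200
    lateral_span_um: float = 480.0
    spectral_span_nm: float = 80.0
    modulation_waveform: str = "sine"
    shot_noise_scale: float = 1e-4
    pump_rin: float = 0.005

    def __post_init__(self):
        if self.frames_per_ascan < 2:
            raise ConfigurationError("frames_per_ascan must be >= 2")
        if self.frame_rate_khz <= 0 or self.n_pixels < 8:
            raise ConfigurationError("invalid acquisition settings")
        if self.modulation_waveform not in ("sine", "square"):
            raise ConfigurationError(f"unknown waveform {self.modulation_waveform!r}")

    @classmethod
    def test_scale(cls, **overrides) -> "AcquisitionConfig":
        kw = dict(frames_per_ascan=512, n_pixels=1024, ascans_per_bscan=20)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def full_scale(cls, **overrides) -> "AcquisitionConfig":
        return cls(**overrides)

    def wavelength_grid(self, laser: LaserConfig) -> np.ndarray:
        half = self.spectral_span_nm / 2.0
        return np.linspace(
            laser.pump_center_nm - half, laser.pump_center_nm + half, self.n_pixels
        )

    def spectral_axis(self, laser: LaserConfig) -> SpectralAxis:
        return SpectralAxis(self.wavelength_grid(laser))


@dataclass
class Phantom:
    """Depth-resolved tissue column.

    ``reflectivity`` is the deterministic backscatter-amplitude envelope
    r(z) >= 0 (zero above the surface); speckle is drawn per A-scan at
    simulation time.  ``interaction_profile`` p(z) >= 0 is the
    depth-resolved SRS interaction strength; the reconstructed nonlinear
    phase channel is proportional to p(z), so an exponential profile makes
    the phase channel decay at the configured SRS decay rate.
    ``interaction_scale`` lumps the constants of the coupling (z0, beta,
    absolute powers) into one dimensionless gain.
    """

    depth_axis_um: np.ndarray
    reflectivity: np.ndarray
    attenuation_mm: float
    surface_depth_um: float
    chi_lines: list
    interaction_profile: np.ndarray
    interaction_scale: float = 1.0
    srs_decay_mm: float = 0.0
    n0: float = 1.0
    label: str = "custom"

    def __post_init__(self):
        z = np.asarray(self.depth_axis_um, dtype=float)
        if z.ndim != 1 or z[0] < 0 or np.any(np.diff(z) <= 0):
            raise ValueError("depth_axis_um must be strictly increasing from >= 0")
        self.depth_axis_um = z
        self.reflectivity = np.asarray(self.reflectivity, dtype=float)
        self.interaction_profile = np.asarray(self.interaction_profile, dtype=float)
        if self.reflectivity.shape != z.shape or self.interaction_profile.shape != z.shape:
            raise ValueError("per-depth arrays must match depth_axis_um")
        if np.any(self.reflectivity < 0) or np.any(self.interaction_profile < 0):
            raise ValueError("reflectivity and interaction_profile must be >= 0")
        if np.any(self.reflectivity[z < self.surface_depth_um] != 0):
            raise ValueError("reflectivity must vanish above the surface")
        if self.attenuation_mm < 0:
            raise ValueError("attenuation must be >= 0")


@dataclass
class RawMScan:
    """time x wavelength stack of spectrometer frames for one lateral
    position, with axes and acquisition metadata."""

    frames: np.ndarray
    spectral_axis: SpectralAxis
    acquisition: AcquisitionConfig
    laser: LaserConfig
    stokes_on: bool = True
    lateral_position_um: float = 0.0
    truth: Phantom | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2:
            raise ValueError("frames must be 2D (time x wavelength)")
        if self.frames.shape[1] != self.spectral_axis.n_pixels:
            raise ValueError("frames and spectral axis disagree on pixel count")
        if np.any(self.frames < 0):
            raise ValueError("frame intensities must be >= 0")


def modulation_waveform(t_ms, f_khz: float, kind: str = "sine") -> np.ndarray:
    """Unit Stokes gating waveform m(t) in [0, 1]."""
    phase = 2.0 * np.pi * f_khz * np.asarray(t_ms, dtype=float)
    if kind == "sine":
        return 0.5 * (1.0 + np.sin(phase))
    if kind == "square":
        return (np.sin(phase) >= 0).astype(float)
    raise ConfigurationError(f"unknown waveform {kind!r}")


def layered_phantom(
    surface_depth_um: float = 150.0,
    thickness_um: float = 1000.0,
    attenuation_mm: float = HEALTHY_OCT_DECAY_MM,
    srs_decay_mm: float = HEALTHY_SRS_DECAY_MM,
    reflectivity_scale: float = 1.0,
    lipid_amplitude: float = 1.0,
    protein_amplitude: float = 0.6,
    interaction_scale: float = 0.05,
    n0: float = 1.0,
    depth_extent_um: float = 1600.0,
    depth_step_um: float = 4.0,
    label: str = "custom",
) -> Phantom:
    """Homogeneous single-layer tissue column.

    The interaction profile decays as ``exp(-srs_decay_mm * (z - z_s))``
    inside the tissue so the reconstructed nonlinear-phase channel decays at
    ``srs_decay_mm``.
    """
    z = np.arange(0.0, depth_extent_um + depth_step_um / 2, depth_step_um)
    in_tissue = (z >= surface_depth_um) & (z <= surface_depth_um + thickness_um)
    refl = np.where(in_tissue, reflectivity_scale * SCATTERER_AMPLITUDE, 0.0)
    rel = np.clip(z - surface_depth_um, 0.0, None) * 1e-3  # mm below surface
    profile = np.where(in_tissue, np.exp(-srs_decay_mm * rel), 0.0)
    lines = [
        RamanLine(LIPID_LINE_CENTER, LIPID_LINE_WIDTH, lipid_amplitude),
        RamanLine(PROTEIN_LINE_CENTER, PROTEIN_LINE_WIDTH, protein_amplitude),
    ]
    return Phantom(
        depth_axis_um=z,
        reflectivity=refl,
        attenuation_mm=attenuation_mm,
        surface_depth_um=surface_depth_um,
        chi_lines=lines,
        interaction_profile=profile,
        interaction_scale=interaction_scale,
        srs_decay_mm=srs_decay_mm,
        n0=n0,
        label=label,
    )


@dataclass
class PhantomPopulation:
    """Between-region parameter distribution for one tissue class.

    Means of the decay coefficients are the group-level generative truths;
    spreads are normal draws truncated at +/- 2.5 sigma (and floored at
    physical bounds).  Tumor tissue is protein-rich with reduced
    backscatter; healthy (white-matter-like) tissue is lipid-rich with
    stronger backscatter and faster decay.
    """

    label: str
    attenuation_mean_mm: float
    attenuation_sd_mm: float = 0.4
    srs_decay_mean_mm: float = 0.0
    srs_decay_sd_mm: float = 0.4
    reflectivity_mean: float = 1.0
    reflectivity_sd: float = 0.1
    lipid_mean: float = 1.0
    lipid_sd: float = 0.1
    protein_mean: float = 0.6
    protein_sd: float = 0.08
    surface_mean_um: float = 150.0
    surface_sd_um: float = 25.0
    interaction_scale: float = 0.05

    @classmethod
    def tumor(cls, **overrides) -> "PhantomPopulation":
        kw = dict(
            label="tumor",
            attenuation_mean_mm=TUMOR_OCT_DECAY_MM,
            srs_decay_mean_mm=TUMOR_SRS_DECAY_MM,
            reflectivity_mean=0.5,
            reflectivity_sd=0.05,
            lipid_mean=0.5,
            lipid_sd=0.08,
            protein_mean=1.0,
            protein_sd=0.1,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def healthy(cls, **overrides) -> "PhantomPopulation":
        kw = dict(
            label="healthy",
            attenuation_mean_mm=HEALTHY_OCT_DECAY_MM,
            srs_decay_mean_mm=HEALTHY_SRS_DECAY_MM,
            reflectivity_mean=1.0,
            reflectivity_sd=0.1,
            lipid_mean=1.0,
            lipid_sd=0.1,
            protein_mean=0.6,
            protein_sd=0.08,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def for_label(cls, label: str, **overrides) -> "PhantomPopulation":
        if label == "tumor":
            return cls.tumor(**overrides)
        if label == "healthy":
            return cls.healthy(**overrides)
        raise ValueError(f"unknown phantom label {label!r}")


def _truncated_normal(rng, mean, sd, lo=None, n_sigma=2.5):
    if sd == 0:
        return mean
    lo_t = mean - n_sigma * sd
    hi_t = mean + n_sigma * sd
    x = float(np.clip(rng.normal(mean, sd), lo_t, hi_t))
    if lo is not None:
        x = max(x, lo)
    return x


def make_phantom(label: str, config: PhantomPopulation | None = None, seed=0, rng=None,
                 **phantom_kwargs) -> Phantom:
    """Draw one region phantom from a tissue-class population."""
    pop = config if config is not None else PhantomPopulation.for_label(label)
    if pop.label != label:
        raise ValueError("population label does not match requested label")
    rng = rng if rng is not None else np.random.default_rng(seed)
    return layered_phantom(
        surface_depth_um=_truncated_normal(rng, pop.surface_mean_um, pop.surface_sd_um, lo=40.0),
        attenuation_mm=_truncated_normal(rng, pop.attenuation_mean_mm, pop.attenuation_sd_mm, lo=0.2),
        srs_decay_mm=_truncated_normal(rng, pop.srs_decay_mean_mm, pop.srs_decay_sd_mm, lo=0.2),
        reflectivity_scale=_truncated_normal(rng, pop.reflectivity_mean, pop.reflectivity_sd, lo=0.05),
        lipid_amplitude=_truncated_normal(rng, pop.lipid_mean, pop.lipid_sd, lo=0.0),
        protein_amplitude=_truncated_normal(rng, pop.protein_mean, pop.protein_sd, lo=0.0),
        interaction_scale=pop.interaction_scale,
        label=label,
        **phantom_kwargs,
    )


# cache of the scatterer phase matrix exp(i 2 k n0 z); shared across an
# entire cohort when the spectral/depth grids coincide
_PHASE_CACHE: dict = {}


def _phase_matrix(k_rad_um: np.ndarray, opl_um: np.ndarray) -> np.ndarray:
    key = (
        k_rad_um.shape[0],
        k_rad_um[0],
        k_rad_um[-1],
        opl_um.shape[0],
        opl_um[0],
        opl_um[-1],
    )
    cached = _PHASE_CACHE.get(key)
    if cached is None:
        cached = np.exp(2j * np.outer(k_rad_um, opl_um))
        if len(_PHASE_CACHE) > 8:
            _PHASE_CACHE.clear()
        _PHASE_CACHE[key] = cached
    return cached


def simulate_mscan(
    phantom: Phantom,
    laser: LaserConfig | None = None,
    acq: AcquisitionConfig | None = None,
    stokes_on: bool = True,
    seed=0,
    rng=None,
    lateral_position_um: float = 0.0,
) -> RawMScan:
    """Simulate one raw frame stack (M-scan) at a lateral position."""
    laser = laser if laser is not None else LaserConfig()
    acq = acq if acq is not None else AcquisitionConfig.test_scale()
    if laser.modulation_frequency_khz >= acq.frame_rate_khz / 2.0:
        raise ConfigurationError("modulation frequency at or above Nyquist")
    rng = rng if rng is not None else np.random.default_rng(seed)

    axis = acq.spectral_axis(laser)
    lam = axis.wavelengths_nm
    k = 2e3 * np.pi / lam  # rad/um
    i0 = laser.pump_spectrum(lam)

    z = phantom.depth_axis_um
    sel = phantom.reflectivity > 0
    if np.any(sel):
        zs = z[sel]
        rel_mm = np.clip(zs - phantom.surface_depth_um, 0.0, None) * 1e-3
        amp = phantom.reflectivity[sel] * np.exp(-phantom.attenuation_mm * rel_mm)
        speckle = (rng.standard_normal(zs.size) + 1j * rng.standard_normal(zs.size)) / np.sqrt(2.0)
        r = amp * speckle
        phase = _phase_matrix(k, phantom.n0 * zs)
        s0 = phase @ r
        shifts = raman_shift(lam, laser.stokes_wavelength_nm)
        chi = chi3_eval(phantom.chi_lines, shifts)
        gain = (
            phantom.interaction_scale
            * laser.stokes_intensity
            * (laser.pump_center_nm / lam)
            * (0.5 * chi.imag - 1j * chi.real)
        )
        s1 = (phase @ (r * phantom.interaction_profile[sel])) * gain
    else:
        s0 = np.zeros(lam.size, dtype=complex)
        s1 = np.zeros(lam.size, dtype=complex)

    t_ms = np.arange(acq.frames_per_ascan) / acq.frame_rate_khz
    if stokes_on:
        m = modulation_waveform(t_ms, laser.modulation_frequency_khz, acq.modulation_waveform)
    else:
        m = np.zeros(acq.frames_per_ascan)

    frames = i0[None, :] * (1.0 + 2.0 * s0.real)[None, :] + np.outer(
        2.0 * m, i0 * s1.real
    )
    if acq.pump_rin > 0:
        frames = frames * (1.0 + acq.pump_rin * rng.standard_normal(acq.frames_per_ascan))[:, None]
    if acq.shot_noise_scale > 0:
        sigma = acq.shot_noise_scale * np.sqrt(
            np.clip(frames, 0.0, None) * laser.pump_power_scale
        )
        frames = frames + sigma * rng.standard_normal(frames.shape)
    np.clip(frames, 0.0, None, out=frames)

    return RawMScan(
        frames=frames,
        spectral_axis=axis,
        acquisition=acq,
        laser=laser,
        stokes_on=stokes_on,
        lateral_position_um=lateral_position_um,
        truth=phantom,
    )


def simulate_bscan(
    phantom,
    laser: LaserConfig | None = None,
    acq: AcquisitionConfig | None = None,
    seed=0,
    stokes_on: bool = True,
) -> list:
    """Simulate an ordered list of M-scans across the lateral span.

    ``phantom`` may be a single ``Phantom`` (laterally homogeneous column)
    or a callable ``(column_index, lateral_um) -> Phantom``.
    """
    acq = acq if acq is not None else AcquisitionConfig.test_scale()
    laser = laser if laser is not None else LaserConfig()
    n = acq.ascans_per_bscan
    positions = (
        np.linspace(0.0, acq.lateral_span_um, n) if n > 1 else np.array([0.0])
    )
    rng = np.random.default_rng(seed)
    columns = []
    for i, x in enumerate(positions):
        col_phantom = phantom(i, x) if callable(phantom) else phantom
        columns.append(
            simulate_mscan(
                col_phantom,
                laser=laser,
                acq=acq,
                stokes_on=stokes_on,
                rng=rng,
                lateral_position_um=float(x),
            )
        )
    return columns


@dataclass
class RegionSpec:
    """Ground-truth record for one cohort region."""

    region_id: str
    label: str
    phantom: Phantom
    seed: int


@dataclass
class CohortConfig:
    """Cohort-level settings: acquisition scale, laser, and the per-class
    phantom populations."""

    laser: LaserConfig = field(default_factory=LaserConfig)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig.test_scale)
    tumor_population: PhantomPopulation = field(default_factory=PhantomPopulation.tumor)
    healthy_population: PhantomPopulation = field(default_factory=PhantomPopulation.healthy)


@dataclass
class CohortPlan:
    """Labeled cohort of regions with embedded ground truth.

    Phantom parameters are drawn eagerly (the manifest is available without
    simulating); the heavy frame stacks are simulated lazily per region via
    :meth:`simulate_region` or by iterating :meth:`iter_regions`.
    """

    regions: list
    config: CohortConfig

    def __len__(self) -> int:
        return len(self.regions)

    def manifest(self):
        import pandas as pd

        rows = []
        for spec in self.regions:
            ph = spec.phantom
            rows.append(
                {
                    "region_id": spec.region_id,
                    "label": spec.label,
                    "seed": spec.seed,
                    "true_oct_decay_mm": ph.attenuation_mm,
                    "true_srs_decay_mm": ph.srs_decay_mm,
                    "surface_um": ph.surface_depth_um,
                    "reflectivity_scale": float(np.max(ph.reflectivity)) / SCATTERER_AMPLITUDE
                    if np.any(ph.reflectivity)
                    else 0.0,
                    "lipid_amplitude": ph.chi_lines[0].amplitude,
                    "protein_amplitude": ph.chi_lines[1].amplitude,
                }
            )
        return pd.DataFrame(rows)

    def simulate_region(self, index: int) -> list:
        spec = self.regions[index]
        return simulate_bscan(
            spec.phantom,
            laser=self.config.laser,
            acq=self.config.acquisition,
            seed=spec.seed,
        )

    def iter_regions(self):
        for i, spec in enumerate(self.regions):
            yield spec, self.simulate_region(i)


def make_cohort(
    n_tumor: int,
    n_healthy: int,
    config: CohortConfig | None = None,
    seed=0,
) -> CohortPlan:
    """Plan a labeled cohort of ``n_tumor + n_healthy`` regions with
    independent per-region parameter draws."""
    if n_tumor < 0 or n_healthy < 0:
        raise ValueError("region counts must be >= 0")
    config = config if config is not None else CohortConfig()
    rng = np.random.default_rng(seed)
    regions = []
    labels = ["tumor"] * n_tumor + ["healthy"] * n_healthy
    for i, label in enumerate(labels):
        pop = (
            config.tumor_population if label == "tumor" else config.healthy_population
        )
        phantom = make_phantom(label, pop, rng=rng)
        region_seed = int(rng.integers(0, 2**31 - 1))
        regions.append(
            RegionSpec(
                region_id=f"{label}_{i:03d}",
                label=label,
                phantom=phantom,
                seed=region_seed,
            )
        )
    return CohortPlan(regions=regions, config=config)
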