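"""Forward model: phantom populations, frame-stack simulation, cohorts."""

import numpy as np
import pytest

from srssoct import (
    AcquisitionConfig,
    LaserConfig,
    Phantom,
    PhantomPopulation,
    RamanLine,
    make_cohort,
    make_phantom,
    reconstruct_mscan,
    simulate_bscan,
    simulate_mscan,
)
from srssoct.simulate import ConfigurationError

from conftest import TINY_KW, tiny_phantom


def zero_spread(label):
    pop = PhantomPopulation.for_label(label)
    for name in (
        "attenuation_sd_mm",
        "srs_decay_sd_mm",
        "reflectivity_sd",
        "lipid_sd",
        "protein_sd",
        "surface_sd_um",
    ):
        setattr(pop, name, 0.0)
    return pop


class TestMakePhantom:
    def test_tumor_defaults(self):
        ph = make_phantom("tumor", zero_spread("tumor"), seed=3)
        assert ph.attenuation_mm == pytest.approx(3.73)
        assert ph.srs_decay_mm == pytest.approx(3.14)
        lipid, protein = ph.chi_lines
        assert protein.amplitude > lipid.amplitude

    def test_healthy_defaults(self):
        ph = make_phantom("healthy", zero_spread("healthy"), seed=3)
        assert ph.attenuation_mm == pytest.approx(8.17)
        assert ph.srs_decay_mm == pytest.approx(7.83)
        lipid, protein = ph.chi_lines
        assert lipid.amplitude >= protein.amplitude
        healthy_refl = np.max(ph.reflectivity)
        tumor_refl = np.max(make_phantom("tumor", zero_spread("tumor")).reflectivity)
        assert tumor_refl < healthy_refl

    def test_zero_spread_is_seed_independent(self):
        a = make_phantom("tumor", zero_spread("tumor"), seed=1)
        b = make_phantom("tumor", zero_spread("tumor"), seed=99)
        np.testing.assert_array_equal(a.reflectivity, b.reflectivity)
        assert a.attenuation_mm == b.attenuation_mm
        assert a.surface_depth_um == b.surface_depth_um

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            make_phantom("necrotic")

    def test_phantom_invariants_enforced(self):
        z = np.arange(0.0, 100.0, 4.0)
        with pytest.raises(ValueError):  # reflectivity above surface
            Phantom(
                depth_axis_um=z,
                reflectivity=np.ones_like(z),
                attenuation_mm=5.0,
                surface_depth_um=50.0,
                chi_lines=[RamanLine(2900.0, 40.0, 1.0)],
                interaction_profile=np.ones_like(z),
            )


class TestSimulateMScan:
    def test_frames_nonnegative(self, healthy_scan):
        assert np.all(healthy_scan.frames >= 0)
        assert healthy_scan.frames.shape == (TINY_KW["frames_per_ascan"], TINY_KW["n_pixels"])

    def test_zero_reflectivity_gives_reference_spectrum(self, tiny_acq_noiseless, laser):
        ph = tiny_phantom(reflectivity_scale=0.0)
        ph.reflectivity[:] = 0.0
        raw = simulate_mscan(ph, laser=laser, acq=tiny_acq_noiseless, seed=0)
        i0 = laser.pump_spectrum(raw.spectral_axis.wavelengths_nm)
        np.testing.assert_allclose(raw.frames, np.broadcast_to(i0, raw.frames.shape), rtol=1e-12)

    def test_noiseless_simulation_is_bit_reproducible(self, tiny_acq_noiseless):
        a = simulate_mscan(tiny_phantom(), acq=tiny_acq_noiseless, seed=5)
        b = simulate_mscan(tiny_phantom(), acq=tiny_acq_noiseless, seed=5)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_modulation_above_nyquist_rejected(self, tiny_acq):
        laser = LaserConfig(modulation_frequency_khz=26.0)
        with pytest.raises(ConfigurationError):
            simulate_mscan(tiny_phantom(), laser=laser, acq=tiny_acq, seed=0)

    def test_doubling_reflectivity_doubles_amp_not_phase(self, tiny_acq_noiseless):
        """Eq.-(4)/(5) contract: SRS amplitude scales with backscatter, the
        nonlinear phase does not."""
        ph1 = tiny_phantom(reflectivity_scale=0.5)
        ph2 = tiny_phantom(reflectivity_scale=1.0)
        ch1 = reconstruct_mscan(simulate_mscan(ph1, acq=tiny_acq_noiseless, seed=3))
        ch2 = reconstruct_mscan(simulate_mscan(ph2, acq=tiny_acq_noiseless, seed=3))
        z = ch1.depth_axis_um
        sel = (z > 170.0) & (z < 400.0)
        amp1 = ch1.srs_amp * ch1.noise_floor["srs_amp"]
        amp2 = ch2.srs_amp * ch2.noise_floor["srs_amp"]
        ratio_amp = np.median(amp2[sel] / amp1[sel])
        assert ratio_amp == pytest.approx(2.0, rel=0.02)
        ph_1 = ch1.srs_phase * ch1.noise_floor["srs_phase"]
        ph_2 = ch2.srs_phase * ch2.noise_floor["srs_phase"]
        assert np.median(ph_2[sel] / ph_1[sel]) == pytest.approx(1.0, rel=0.01)

    def test_srs_channels_linear_in_stokes_intensity(self, tiny_acq_noiseless):
        """Demodulated amplitude and phase are linear in I_Stokes over an
        8x range (weak-perturbation regime)."""
        ref = None
        for scale in (1.0, 8.0):
            laser = LaserConfig(stokes_intensity=scale)
            ph = tiny_phantom(interaction_scale=0.01)
            ch = reconstruct_mscan(simulate_mscan(ph, laser=laser, acq=tiny_acq_noiseless, seed=3))
            z = ch.depth_axis_um
            sel = (z > 170.0) & (z < 400.0)
            vec = np.concatenate(
                [
                    ch.srs_amp[sel] * ch.noise_floor["srs_amp"],
                    ch.srs_phase[sel] * ch.noise_floor["srs_phase"],
                ]
            )
            if ref is None:
                ref = vec
            else:
                # relative to the channel scale (entries near zero crossings
                # carry no meaningful relative error of their own)
                assert np.max(np.abs(vec - 8.0 * ref)) <= 0.01 * 8.0 * np.max(np.abs(ref))

    def test_phase_invariant_to_pump_power(self, tiny_acq_noiseless):
        chans = []
        for power in (1.0, 4.0):
            laser = LaserConfig(pump_power_scale=power)
            chans.append(
                reconstruct_mscan(
                    simulate_mscan(tiny_phantom(), laser=laser, acq=tiny_acq_noiseless, seed=3)
                )
            )
        z = chans[0].depth_axis_um
        sel = (z > 170.0) & (z < 400.0)
        p1 = chans[0].srs_phase * chans[0].noise_floor["srs_phase"]
        p2 = chans[1].srs_phase * chans[1].noise_floor["srs_phase"]
        np.testing.assert_allclose(p2[sel], p1[sel], rtol=0.01)
        a1 = chans[0].srs_amp * chans[0].noise_floor["srs_amp"]
        a2 = chans[1].srs_amp * chans[1].noise_floor["srs_amp"]
        assert np.median(a2[sel] / a1[sel]) == pytest.approx(4.0, rel=0.02)

    def test_single_scatterer_peaks_at_its_depth(self, tiny_acq_noiseless, laser):
        z = np.arange(0.0, 900.0, 4.0)
        refl = np.zeros_like(z)
        refl[np.argmin(np.abs(z - 200.0))] = 0.01
        ph = Phantom(
            depth_axis_um=z,
            reflectivity=refl,
            attenuation_mm=0.0,
            surface_depth_um=196.0,
            chi_lines=[RamanLine(2900.0, 40.0, 1.0)],
            interaction_profile=np.zeros_like(z),
        )
        raw = simulate_mscan(ph, laser=laser, acq=tiny_acq_noiseless, seed=0)
        ch = reconstruct_mscan(raw)
        peak = ch.depth_axis_um[np.argmax(ch.oct)]
        pixel = ch.depth_axis_um[1] - ch.depth_axis_um[0]
        assert abs(peak - 200.0) <= pixel


class TestBScanAndCohort:
    def test_bscan_column_count_and_spacing(self, tiny_acq):
        cols = simulate_bscan(tiny_phantom(), acq=tiny_acq, seed=0)
        assert len(cols) == tiny_acq.ascans_per_bscan
        xs = [c.lateral_position_um for c in cols]
        np.testing.assert_allclose(np.diff(xs), xs[1] - xs[0])
        assert xs[-1] == pytest.approx(tiny_acq.lateral_span_um)

    def test_single_column_bscan(self, laser):
        acq = AcquisitionConfig(ascans_per_bscan=1, **{k: v for k, v in TINY_KW.items() if k != "ascans_per_bscan"})
        cols = simulate_bscan(tiny_phantom(), laser=laser, acq=acq, seed=0)
        assert len(cols) == 1

    def test_columns_have_independent_speckle(self, tiny_acq):
        cols = simulate_bscan(tiny_phantom(), acq=tiny_acq, seed=0)
        assert not np.array_equal(cols[0].frames, cols[1].frames)

    def test_cohort_counts(self):
        plan = make_cohort(34, 20, seed=0)
        assert len(plan) == 54
        labels = [r.label for r in plan.regions]
        assert labels.count("tumor") == 34 and labels.count("healthy") == 20

    def test_empty_cohort(self):
        assert len(make_cohort(0, 0, seed=0)) == 0

    def test_cohort_manifest_records_truth(self):
        plan = make_cohort(2, 2, seed=1)
        m = plan.manifest()
        assert len(m) == 4
        assert set(m["label"]) == {"tumor", "healthy"}
        assert np.all(m["true_oct_decay_mm"] > 0)
        assert m["region_id"].is_unique

    def test_cohort_draws_vary_between_regions(self):
        plan = make_cohort(3, 0, seed=2)
        rates = [r.phantom.attenuation_mm for r in plan.regions]
        assert len(set(rates)) == 3
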