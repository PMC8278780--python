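"""k-linearization, depth transform, and lock-in demodulation."""

import numpy as np
import pytest

from srssoct import (
    ComplexAScanStack,
    Phantom,
    RamanLine,
    SpectralAxis,
    assemble_bscan,
    demodulate,
    peak_modulation_frequency_khz,
    reconstruct_mscan,
    resample_to_linear_k,
    simulate_mscan,
)
from srssoct.reconstruct import ascan_transform, estimate_reference
from srssoct.simulate import modulation_waveform

from conftest import tiny_phantom


class TestResample:
    def test_constant_spectrum_preserved(self):
        axis = SpectralAxis(np.linspace(750.0, 830.0, 256))
        out, k = resample_to_linear_k(np.full(256, 3.5), axis)
        np.testing.assert_allclose(out, 3.5, rtol=1e-12)
        assert np.all(np.diff(k) > 0)
        np.testing.assert_allclose(np.diff(k), k[1] - k[0], rtol=1e-9)

    def test_linear_in_k_exactly_recovered(self):
        axis = SpectralAxis(np.linspace(750.0, 830.0, 256))
        k_native = 2e3 * np.pi / axis.wavelengths_nm
        out, k = resample_to_linear_k(3.0 * k_native + 1.0, axis)
        np.testing.assert_allclose(out, 3.0 * k + 1.0, rtol=1e-6)

    def test_fringe_sampled_in_wavelength_maps_to_depth(self):
        """cos(2 k z0) sampled on a wavelength grid must transform to a
        depth peak at z0 after k-linearization."""
        z0 = 300.0
        axis = SpectralAxis(np.linspace(750.0, 830.0, 1024))
        k_native = 2e3 * np.pi / axis.wavelengths_nm
        frames = np.cos(2.0 * k_native * z0)[None, :]
        frames_k, k = resample_to_linear_k(frames, axis)
        stack = ascan_transform(frames_k, k, frame_rate_khz=50.0)
        peak = stack.depth_axis_um[np.argmax(np.abs(stack.values[0]))]
        pixel = stack.depth_axis_um[1] - stack.depth_axis_um[0]
        assert abs(peak - z0) <= pixel

    def test_nonmonotonic_axis_rejected(self):
        with pytest.raises(ValueError):
            SpectralAxis(np.array([800.0, 790.0, 795.0]))


class TestAScanTransform:
    def test_all_zero_frames_transform_to_zero(self):
        k = np.linspace(7.5, 8.3, 128)
        stack = ascan_transform(np.zeros((4, 128)), k, frame_rate_khz=50.0)
        np.testing.assert_array_equal(stack.values, 0)

    def test_two_scatterers_50um_apart_resolved(self, tiny_acq_noiseless, laser):
        z = np.arange(0.0, 900.0, 4.0)
        refl = np.zeros_like(z)
        for zc in (300.0, 350.0):
            refl[np.argmin(np.abs(z - zc))] = 0.01
        ph = Phantom(
            depth_axis_um=z,
            reflectivity=refl,
            attenuation_mm=0.0,
            surface_depth_um=296.0,
            chi_lines=[RamanLine(2900.0, 40.0, 1.0)],
            interaction_profile=np.zeros_like(z),
        )
        ch = reconstruct_mscan(simulate_mscan(ph, laser=laser, acq=tiny_acq_noiseless, seed=0))
        zax = ch.depth_axis_um
        near = lambda zc: np.max(ch.oct[np.abs(zax - zc) < 15.0])
        trough = np.min(ch.oct[(zax > 315.0) & (zax < 335.0)])
        assert trough < 0.5 * min(near(300.0), near(350.0))

    def test_reference_estimate_tracks_smooth_envelope(self):
        k = np.linspace(7.5, 8.3, 512)
        envelope = np.exp(-0.5 * ((k - 7.9) / 0.15) ** 2)
        fringe = 0.3 * envelope * np.cos(2 * k * 400.0)
        ref = estimate_reference((envelope + fringe)[None, :])
        inner = slice(32, -32)
        assert np.max(np.abs(ref[inner] - envelope[inner])) < 0.02


def synthetic_stack(g=0.01, phi=0.02, n_frames=256, fs=50.0, f_mod=15.0, n_depth=32, a0=1.0):
    """Carrier with a known multiplicative modulation response."""
    t = np.arange(n_frames) / fs
    m = modulation_waveform(t, f_mod)
    values = a0 * (1.0 + np.outer((g + 1j * phi) * m, np.ones(n_depth)))
    return ComplexAScanStack(
        values=values,
        depth_axis_um=np.arange(n_depth, dtype=float),
        frame_rate_khz=fs,
        modulation_frequency_khz=f_mod,
    )


class TestDemodulate:
    def test_constructed_modulation_recovers_quadratures(self):
        """a(t) = a0 (1 + (0.01 + 0.02 i) m(t)) must demodulate to
        srs_amp ∝ 0.01 and srs_phase ∝ 0.02 (exact 2.0 ratio before
        noise normalization)."""
        ch = demodulate(synthetic_stack())
        amp_raw = ch.srs_amp * ch.noise_floor["srs_amp"]
        phase_raw = ch.srs_phase * ch.noise_floor["srs_phase"]
        np.testing.assert_allclose(amp_raw, 0.01, rtol=1e-6)
        np.testing.assert_allclose(phase_raw, 0.02, rtol=1e-6)
        np.testing.assert_allclose(phase_raw / amp_raw, 2.0, rtol=1e-9)

    def test_complex_carrier_phase_does_not_leak(self):
        ch = demodulate(synthetic_stack(a0=0.7 * np.exp(1.3j)))
        amp_raw = ch.srs_amp * ch.noise_floor["srs_amp"]
        phase_raw = ch.srs_phase * ch.noise_floor["srs_phase"]
        np.testing.assert_allclose(amp_raw, 0.7 * 0.01, rtol=1e-6)
        np.testing.assert_allclose(phase_raw, 0.02, rtol=1e-6)

    def test_square_wave_fundamental_correction(self):
        t = np.arange(256) / 50.0
        m = modulation_waveform(t, 15.0, "square")
        values = 1.0 + np.outer((0.01 + 0.02j) * m, np.ones(8))
        stack = ComplexAScanStack(
            values=values,
            depth_axis_um=np.arange(8.0),
            frame_rate_khz=50.0,
            modulation_frequency_khz=15.0,
            modulation_waveform="square",
        )
        ch = demodulate(stack)
        phase_raw = ch.srs_phase * ch.noise_floor["srs_phase"]
        np.testing.assert_allclose(phase_raw, 0.02, rtol=5e-3)

    def test_stokes_off_is_null(self, tiny_acq):
        raw = simulate_mscan(tiny_phantom(), acq=tiny_acq, stokes_on=False, seed=4)
        ch = reconstruct_mscan(raw)
        z = ch.depth_axis_um
        sel = (z > 170.0) & (z < 400.0)
        # noise-normalized channels stay at the noise floor (O(1))
        assert np.median(np.abs(ch.srs_amp[sel])) < 3.0
        assert np.median(np.abs(ch.srs_phase[sel])) < 3.0

    def test_modulation_peak_at_15_khz(self, healthy_scan):
        frames_k, k = resample_to_linear_k(healthy_scan.frames, healthy_scan.spectral_axis)
        stack = ascan_transform(frames_k, k, frame_rate_khz=50.0)
        f = peak_modulation_frequency_khz(stack)
        bin_width = 50.0 / stack.values.shape[0]
        assert abs(f - 15.0) <= bin_width

    def test_wrong_demodulation_frequency_sees_noise(self, healthy_scan):
        ch = reconstruct_mscan(healthy_scan, f_mod_khz=11.0)
        z = ch.depth_axis_um
        sel = (z > 170.0) & (z < 400.0)
        assert np.median(np.abs(ch.srs_amp[sel])) < 3.0
        assert np.median(np.abs(ch.srs_phase[sel])) < 3.0

    def test_oct_matches_conventional_fdoct_of_mean_frame(self, tiny_acq_noiseless):
        """Two-path consistency: the demodulator's carrier magnitude must
        coincide with conventional FD-OCT reconstruction of the
        temporal-mean frame.  Compared Stokes-off, where the mean frame
        carries no modulation energy (Stokes-on, the mean frame retains the
        DC of m(t) which the carrier estimator removes)."""
        raw = simulate_mscan(tiny_phantom(), acq=tiny_acq_noiseless, stokes_on=False, seed=7)
        ch = reconstruct_mscan(raw)
        frames_k, k = resample_to_linear_k(raw.frames, raw.spectral_axis)
        mean_frame = frames_k.mean(axis=0)
        conventional = ascan_transform(mean_frame[None, :], k, frame_rate_khz=50.0)
        oct_conv = np.abs(conventional.values[0])
        sel = ch.oct > 1e-4 * ch.oct.max()
        np.testing.assert_allclose(ch.oct[sel], oct_conv[sel], rtol=1e-9)

    def test_end_to_end_linearity_in_interaction_scale(self, tiny_acq_noiseless):
        chans = []
        for s in (0.02, 0.04):
            ch = reconstruct_mscan(
                simulate_mscan(tiny_phantom(interaction_scale=s), acq=tiny_acq_noiseless, seed=3)
            )
            z = ch.depth_axis_um
            sel = (z > 170.0) & (z < 400.0)
            chans.append(
                np.concatenate(
                    [
                        ch.srs_amp[sel] * ch.noise_floor["srs_amp"],
                        ch.srs_phase[sel] * ch.noise_floor["srs_phase"],
                    ]
                )
            )
        assert np.max(np.abs(chans[1] - 2.0 * chans[0])) <= 0.01 * 2.0 * np.max(np.abs(chans[0]))

    def test_rin_degrades_amplitude_more_than_phase(self, tiny_acq):
        """Pump intensity noise is common-mode real and multiplicative, so
        it folds into the in-phase (amplitude) quadrature and largely
        spares the phase quadrature."""
        from srssoct import AcquisitionConfig
        from conftest import TINY_KW

        base = AcquisitionConfig(shot_noise_scale=0.0, pump_rin=0.0, **TINY_KW)
        rin = AcquisitionConfig(shot_noise_scale=0.0, pump_rin=0.05, **TINY_KW)
        ph = tiny_phantom()
        ch0 = reconstruct_mscan(simulate_mscan(ph, acq=base, seed=6))
        ch1 = reconstruct_mscan(simulate_mscan(ph, acq=rin, seed=6))
        amp_degradation = ch1.noise_floor["srs_amp"] / ch0.noise_floor["srs_amp"]
        phase_degradation = ch1.noise_floor["srs_phase"] / ch0.noise_floor["srs_phase"]
        assert amp_degradation > 3.0 * phase_degradation


class TestAssemble:
    def test_column_stacking_order(self, healthy_scan):
        ch = reconstruct_mscan(healthy_scan)
        b = assemble_bscan([ch, ch, ch])
        assert b.n_columns == 3
        assert b.oct.shape == (ch.oct.size, 3)

    def test_permutation_co_registration(self, tiny_acq):
        import srssoct

        cols = srssoct.simulate_bscan(tiny_phantom(), acq=tiny_acq, seed=2)[:3]
        chans = [reconstruct_mscan(c) for c in cols]
        fwd = assemble_bscan(chans)
        rev = assemble_bscan(chans[::-1])
        for attr in ("oct", "srs_amp", "srs_phase"):
            np.testing.assert_array_equal(getattr(fwd, attr)[:, ::-1], getattr(rev, attr))

    def test_mismatched_depth_axes_rejected(self, healthy_scan):
        ch = reconstruct_mscan(healthy_scan)
        import copy

        other = copy.deepcopy(ch)
        other.depth_axis_um = other.depth_axis_um + 1.0
        with pytest.raises(ValueError):
            assemble_bscan([ch, other])
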