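"""Spectral estimation: periodograms, normalization, attenuation, fits."""

import numpy as np
import pytest

from qushab.spectral import (
    NormalizedSpectrum,
    PhantomSpec,
    RFFrame,
    correct_attenuation,
    estimate_ace,
    fit_form_factor,
    fit_linear_spectral_params,
    gaussian_form_factor_db,
    generate_parametric_maps,
    make_margin,
    normalize_spectrum,
    windowed_power_spectrum,
)
from qushab.synthetic import (
    FrameGeometry,
    GaussianPulse,
    random_scatterer_field,
    simulate_rf_frame,
)

F_GRID = np.linspace(3.0, 8.0, 60)


def _sine_frame(freq_mhz=5.0, fs=40.0, n=2048, n_lines=30):
    t = np.arange(n) / (fs * 1e6)
    line = np.sin(2 * np.pi * freq_mhz * 1e6 * t)
    return RFFrame(samples=np.tile(line[:, None], (1, n_lines)),
                   sampling_rate=fs, lateral_spacing=0.1)


class TestWindowedPowerSpectrum:
    def test_sinusoid_peaks_at_its_frequency(self):
        frame = _sine_frame(5.0)
        freqs, ps = windowed_power_spectrum(frame, (20.0, 1.5))
        assert freqs[np.argmax(ps)] == pytest.approx(5.0, abs=0.25)

    def test_zero_window_gives_zero_spectrum(self):
        frame = _sine_frame()
        frame.samples[:] = 0.0
        _, ps = windowed_power_spectrum(frame, (20.0, 1.5))
        assert np.all(ps == 0)

    def test_window_outside_frame_rejected(self):
        frame = _sine_frame()
        with pytest.raises(ValueError, match="outside"):
            windowed_power_spectrum(frame, (0.5, 1.5))

    def test_single_line_window_rejected(self):
        # 3 mm line pitch: a 2 mm window covers at most one scan line
        frame = RFFrame(samples=np.zeros((2048, 10)), sampling_rate=40.0,
                        lateral_spacing=3.0)
        with pytest.raises(ValueError, match="lines"):
            windowed_power_spectrum(frame, (20.0, 5.0))

    def test_white_noise_spectrum_flat_in_band(self, rng):
        """Averaged periodogram of white noise is flat (within 1 dB in-band)."""
        acc = None
        n_windows = 120
        for _ in range(n_windows):
            frame = RFFrame(samples=rng.normal(size=(128, 25)),
                            sampling_rate=40.0, lateral_spacing=0.1)
            freqs, ps = windowed_power_spectrum(frame, (1.2, 1.2))
            acc = ps if acc is None else acc + ps
        band = (freqs >= 3) & (freqs <= 8)
        db = 10 * np.log10(acc[band] / n_windows)
        assert db.max() - db.min() < 1.0


class TestNormalizeSpectrum:
    def test_self_reference_is_zero_db(self, rng):
        ps = rng.random(100) + 0.1
        f = np.linspace(0, 20, 100)
        ns = normalize_spectrum(f, ps, ps)
        assert np.allclose(ns.values, 0.0)

    def test_tenfold_sample_is_plus_ten_db(self, rng):
        ps = rng.random(100) + 0.1
        f = np.linspace(0, 20, 100)
        ns = normalize_spectrum(f, 10 * ps, ps)
        assert np.allclose(ns.values, 10.0)

    def test_zero_reference_rejected(self):
        f = np.linspace(0, 20, 100)
        with pytest.raises(ValueError, match="positive"):
            normalize_spectrum(f, np.ones(100), np.zeros(100))

    def test_pulse_shift_cancels_under_shared_pulse(self):
        """System cancellation: normalized spectrum insensitive to pulse detuning."""
        geom = FrameGeometry(axial_extent=25.0, lateral_extent=4.0,
                             lateral_spacing=0.1)
        results = []
        for fc in (5.5, 6.0, 6.5):
            pulse = GaussianPulse(center_frequency=fc, fractional_bandwidth=5.0 / fc)
            acc_s = acc_r = None
            for s in range(40):
                fs_field = random_scatterer_field(geom, concentration=100,
                                                  mean_amplitude=2.0, seed=100 + s)
                fr_field = random_scatterer_field(geom, concentration=100,
                                                  seed=5000 + s)
                sf = simulate_rf_frame(fs_field, pulse, geom)
                rf = simulate_rf_frame(fr_field, pulse, geom)
                f, ps = windowed_power_spectrum(sf, (12.0, 2.0))
                _, pr = windowed_power_spectrum(rf, (12.0, 2.0))
                acc_s = ps if acc_s is None else acc_s + ps
                acc_r = pr if acc_r is None else acc_r + pr
            ns = normalize_spectrum(f, acc_s, acc_r, band=(4.0, 7.0))
            results.append(ns.values.mean())
        assert max(results) - min(results) < 1.0


class TestEstimateACE:
    def test_depth_independent_spectra_give_zero(self):
        ns = NormalizedSpectrum(F_GRID, np.full_like(F_GRID, -3.0))
        pairs = [(1.0, ns), (1.5, ns), (2.0, ns)]
        ace, clipped = estimate_ace(pairs, phantom_attenuation=0.0)
        assert ace == 0.0 and not clipped

    def test_identical_media_recover_phantom_attenuation(self):
        ns = NormalizedSpectrum(F_GRID, np.zeros_like(F_GRID))
        ace, _ = estimate_ace([(1.0, ns), (2.0, ns)], phantom_attenuation=0.576)
        assert ace == pytest.approx(0.576)

    def test_known_excess_attenuation_recovered_exactly_on_ideal_spectra(self):
        alpha_s, alpha_p = 1.0, 0.576
        pairs = []
        for d in (1.0, 1.4, 1.8):
            vals = -4.0 * (alpha_s - alpha_p) * F_GRID * d
            pairs.append((d, NormalizedSpectrum(F_GRID, vals)))
        ace, _ = estimate_ace(pairs, phantom_attenuation=alpha_p)
        assert ace == pytest.approx(alpha_s, rel=1e-10)

    def test_insufficient_depth_span_rejected(self):
        ns = NormalizedSpectrum(F_GRID, np.zeros_like(F_GRID))
        with pytest.raises(ValueError, match="span"):
            estimate_ace([(1.0, ns), (1.02, ns)], 0.576)

    def test_simulated_medium_recovery(self):
        """ACE within 15% for a 1.0 dB/MHz·cm medium vs the 0.576 phantom."""
        geom = FrameGeometry(axial_extent=30.0, lateral_extent=3.0,
                             lateral_spacing=0.1)
        pulse = GaussianPulse()
        depths_mm = np.array([8.0, 13.0, 18.0, 23.0])
        acc_s = {d: None for d in depths_mm}
        acc_r = {d: None for d in depths_mm}
        for s in range(50):
            f_s = random_scatterer_field(geom, concentration=100, attenuation=1.0,
                                         seed=300 + s)
            f_r = random_scatterer_field(geom, concentration=100, attenuation=0.576,
                                         seed=9000 + s)
            sf = simulate_rf_frame(f_s, pulse, geom)
            rf = simulate_rf_frame(f_r, pulse, geom)
            for d in depths_mm:
                fr, ps = windowed_power_spectrum(sf, (d, 1.5))
                _, pr = windowed_power_spectrum(rf, (d, 1.5))
                acc_s[d] = ps if acc_s[d] is None else acc_s[d] + ps
                acc_r[d] = pr if acc_r[d] is None else acc_r[d] + pr
        pairs = []
        for d in depths_mm:
            ns = normalize_spectrum(fr, acc_s[d], acc_r[d], band=(4.0, 7.0))
            pairs.append((d / 10.0, ns))
        ace, _ = estimate_ace(pairs, phantom_attenuation=0.576)
        assert ace == pytest.approx(1.0, rel=0.15)


class TestCorrectAttenuation:
    def test_zero_paths_unchanged(self):
        ns = NormalizedSpectrum(F_GRID, np.sin(F_GRID))
        out = correct_attenuation(ns, ace=0.8, depth_in_tumor=0.0,
                                  intervening_path=0.0)
        np.testing.assert_allclose(out.values, ns.values)

    def test_matched_attenuations_unchanged(self):
        ns = NormalizedSpectrum(F_GRID, np.sin(F_GRID))
        out = correct_attenuation(ns, ace=0.576, depth_in_tumor=2.0,
                                  intervening_path=0.0, phantom_attenuation=0.576)
        np.testing.assert_allclose(out.values, ns.values, atol=1e-12)

    def test_compensation_restores_depth_invariance(self):
        """Ideal attenuated spectra become depth-independent after correction."""
        alpha_s, alpha_p = 1.2, 0.576
        mids = []
        for d in (0.5, 1.0, 1.5, 2.0):
            vals = -4.0 * (alpha_s - alpha_p) * F_GRID * d
            ns = NormalizedSpectrum(F_GRID, vals)
            out = correct_attenuation(ns, ace=alpha_s, depth_in_tumor=d,
                                      intervening_path=0.0,
                                      phantom_attenuation=alpha_p)
            mids.append(out.values[len(F_GRID) // 2])
        assert max(mids) - min(mids) < 1e-9


class TestLinearSpectralParams:
    def test_exact_linear_spectrum(self):
        ns = NormalizedSpectrum(F_GRID, -20.0 + 1.5 * F_GRID)
        mbf, ss, si = fit_linear_spectral_params(ns, band=(3.0, 8.0))
        assert si == pytest.approx(-20.0, abs=1e-9)
        assert ss == pytest.approx(1.5, abs=1e-9)
        assert mbf == pytest.approx(-20.0 + 1.5 * 5.5, abs=1e-9)

    def test_flat_spectrum(self):
        ns = NormalizedSpectrum(F_GRID, np.full_like(F_GRID, -7.0))
        mbf, ss, si = fit_linear_spectral_params(ns)
        assert ss == pytest.approx(0.0, abs=1e-12)
        assert mbf == pytest.approx(-7.0) and si == pytest.approx(-7.0)

    def test_slope_estimator_unbiased(self, rng):
        """OLS slope bias under additive noise is < 1% of the true slope."""
        true_ss = 1.5
        est = []
        for _ in range(1000):
            vals = -10.0 + true_ss * F_GRID + rng.normal(0, 1.0, F_GRID.size)
            _, ss, _ = fit_linear_spectral_params(NormalizedSpectrum(F_GRID, vals))
            est.append(ss)
        assert abs(np.mean(est) - true_ss) < 0.01 * true_ss

    def test_mbf_identity(self, rng):
        vals = rng.normal(size=F_GRID.size)
        mbf, ss, si = fit_linear_spectral_params(NormalizedSpectrum(F_GRID, vals))
        assert mbf == pytest.approx(si + ss * 5.5, abs=1e-12)


class TestFormFactor:
    def test_self_inversion_noiseless(self):
        vals = gaussian_form_factor_db(F_GRID, 100.0) + 12.0
        esd, eac, ok = fit_form_factor(NormalizedSpectrum(F_GRID, vals))
        assert ok
        assert esd == pytest.approx(100.0, rel=0.01)
        assert eac == pytest.approx(12.0, abs=0.05)

    def test_amplitude_scale_separates_into_eac(self):
        vals = gaussian_form_factor_db(F_GRID, 80.0)
        e1 = fit_form_factor(NormalizedSpectrum(F_GRID, vals))
        e2 = fit_form_factor(NormalizedSpectrum(F_GRID, vals + 10.0))
        assert e2[0] == pytest.approx(e1[0], abs=1e-6)
        assert e2[1] - e1[1] == pytest.approx(10.0, abs=1e-9)

    def test_recovery_is_monotone_in_true_esd(self):
        ests = []
        for true in (40.0, 80.0, 120.0, 160.0, 200.0):
            vals = gaussian_form_factor_db(F_GRID, true)
            ests.append(fit_form_factor(NormalizedSpectrum(F_GRID, vals))[0])
        assert np.all(np.diff(ests) >= 0)

    def test_edge_fit_flagged_invalid(self):
        # steeply rising spectrum drives the fit to the small-ESD bound
        vals = 60.0 * np.log10(F_GRID)
        _, _, ok = fit_form_factor(NormalizedSpectrum(F_GRID, vals))
        assert not ok


class TestMakeMargin:
    def test_annulus_area(self):
        yy, xx = np.mgrid[:400, :400]
        core = (yy - 200.0) ** 2 + (xx - 200.0) ** 2 <= (10.0 / 0.1) ** 2
        roi = make_margin(core, thickness_mm=5.0, spacing=(0.1, 0.1))
        area = roi.margin.sum() * 0.1 * 0.1
        assert area == pytest.approx(np.pi * (15.0**2 - 10.0**2), rel=0.02)

    def test_clipped_at_frame_edge(self):
        core = np.zeros((50, 50), bool)
        core[:10, :10] = True
        roi = make_margin(core, thickness_mm=2.0, spacing=(0.1, 0.1))
        assert roi.margin.shape == core.shape
        assert not (roi.core & roi.margin).any()

    def test_zero_thickness_empty_margin(self):
        core = np.zeros((20, 20), bool)
        core[5:15, 5:15] = True
        roi = make_margin(core, thickness_mm=0.0)
        assert roi.margin.sum() == 0

    def test_empty_core_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            make_margin(np.zeros((10, 10), bool))


@pytest.fixture(scope="module")
def simulated_pair():
    geom = FrameGeometry(axial_extent=24.0, lateral_extent=10.0,
                         lateral_spacing=0.1)
    pulse = GaussianPulse()
    sample = simulate_rf_frame(
        random_scatterer_field(geom, concentration=150, attenuation=0.7,
                               mean_amplitude=3.0, seed=42),
        pulse, geom)
    phantom_frames = [
        simulate_rf_frame(
            random_scatterer_field(geom, concentration=150, attenuation=0.576,
                                   seed=7000 + i),
            pulse, geom)
        for i in range(6)
    ]
    phantom = PhantomSpec(frames=phantom_frames)
    return sample, phantom, geom


class TestParametricMaps:
    def test_step_is_five_percent_of_window(self, simulated_pair):
        sample, phantom, geom = simulated_pair
        core = np.zeros((240, 100), bool)
        core[80:125, 30:65] = True  # 0.1 mm grid
        roi = make_margin(core, thickness_mm=1.0, spacing=(0.1, 0.1))
        maps = generate_parametric_maps(sample, roi, phantom, overlap=0.95)
        step_ax = np.diff(maps.axial_centers)
        step_lat = np.diff(maps.lateral_centers)
        assert np.allclose(step_ax, 0.1) and np.allclose(step_lat, 0.1)

    def test_homogeneous_medium_low_variation(self, simulated_pair):
        sample, phantom, geom = simulated_pair
        core = np.zeros((240, 100), bool)
        core[60:180, 20:80] = True
        roi = make_margin(core, thickness_mm=2.0, spacing=(0.1, 0.1))
        maps = generate_parametric_maps(sample, roi, phantom, overlap=0.5)
        assert maps.valid.sum() > 20
        esd = maps.channels["ESD"][maps.valid]
        assert np.std(esd) / np.mean(esd) < 0.20
        mbf = maps.channels["MBF"][maps.valid]
        assert np.std(mbf) / abs(np.mean(mbf)) < 0.20

    def test_channels_share_registration(self, simulated_pair):
        sample, phantom, geom = simulated_pair
        core = np.zeros((240, 100), bool)
        core[80:160, 30:70] = True
        roi = make_margin(core, thickness_mm=2.0, spacing=(0.1, 0.1))
        maps = generate_parametric_maps(sample, roi, phantom, overlap=0.5)
        shapes = {arr.shape for arr in maps.channels.values()}
        assert shapes == {maps.valid.shape}
        # MBF = SI + SS * f_center identity at every valid pixel
        v = maps.valid
        lhs = maps.channels["MBF"][v]
        rhs = maps.channels["SI"][v] + maps.channels["SS"][v] * 5.5
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_roi_smaller_than_window_rejected(self, simulated_pair):
        sample, phantom, geom = simulated_pair
        core = np.zeros((240, 100), bool)
        core[100:105, 50:55] = True  # 0.5 mm square < 2 mm window
        roi = ROIMask_like(core)
        with pytest.raises(ValueError, match="too small"):
            generate_parametric_maps(sample, roi, phantom)

    def test_phantom_against_itself_yields_null_parameters(self, simulated_pair):
        """Processing the phantom as the sample gives ~0 dB spectra and SS≈SI≈MBF≈0."""
        sample, phantom, geom = simulated_pair
        ph_frame = phantom.frames[0]
        f, ps = windowed_power_spectrum(ph_frame, (12.0, 5.0))
        ns = normalize_spectrum(f, ps, ps)
        assert np.allclose(ns.values, 0.0, atol=1e-9)
        ns = correct_attenuation(ns, ace=phantom.attenuation, depth_in_tumor=1.2,
                                 intervening_path=0.0,
                                 phantom_attenuation=phantom.attenuation)
        mbf, ss, si = fit_linear_spectral_params(ns)
        assert abs(mbf) < 1e-9 and abs(ss) < 1e-9 and abs(si) < 1e-9


def ROIMask_like(core):
    from qushab.spectral import ROIMask

    return ROIMask(core=core, margin=np.zeros_like(core), spacing=(0.1, 0.1))
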