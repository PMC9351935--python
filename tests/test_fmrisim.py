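import warnings

import numpy as np
import pandas as pd
import pytest

from naturakit.core import DegenerateDataWarning, ValidationError, VolumeGeometry
from naturakit.fmrisim import (
    DesignTable,
    NoiseProfile,
    apply_signal,
    convolve_hrf,
    double_gamma_hrf,
    generate_noise,
    generate_stimfunction,
    measure_noise,
    volume_to_timeseries,
)


def design_from(rows):
    return DesignTable(
        pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "amplitude"])
    )


class TestStimfunction:
    def test_single_event_sample_count(self):
        d = design_from([(10.0, 5.0, "a", 1.0)])
        tc = generate_stimfunction(d, 60.0, 1.0, upsample_factor=10)["a"]
        assert (tc.values > 0).sum() == 50
        assert len(tc.values) == 600

    def test_empty_design(self):
        d = design_from([(0.0, 1.0, "a", 1.0)])
        out = generate_stimfunction(d, 20.0, 2.0)
        assert (out["a"].values >= 0).all()
        d2 = DesignTable(
            pd.DataFrame(columns=["onset", "duration", "trial_type", "amplitude"])
        )
        assert generate_stimfunction(d2, 20.0, 2.0) == {}

    def test_overlap_sums_with_warning(self):
        d = design_from([(0.0, 4.0, "a", 1.0), (2.0, 4.0, "a", 1.0)])
        with pytest.warns(DegenerateDataWarning):
            tc = generate_stimfunction(d, 10.0, 1.0, upsample_factor=2)["a"]
        assert tc.values.max() == pytest.approx(2.0)

    def test_onset_beyond_scan_rejected(self):
        d = design_from([(30.0, 1.0, "a", 1.0)])
        with pytest.raises(ValidationError):
            generate_stimfunction(d, 20.0, 1.0)


class TestHRF:
    def test_peak_time_is_shape_minus_one_times_dispersion(self):
        h = double_gamma_hrf(dt=0.1)
        assert h.argmax() * 0.1 == pytest.approx(4.5, abs=0.1)
        assert h.max() == pytest.approx(1.0)

    def test_impulse_response_proportional_to_hrf(self):
        d = design_from([(0.0, 0.1, "a", 1.0)])
        tcs = generate_stimfunction(d, 40.0, 1.0, upsample_factor=10)
        out = convolve_hrf(tcs["a"])
        h = double_gamma_hrf(dt=0.1)[::10]
        lag = out.argmax() - h.argmax()
        assert abs(lag) <= 1

    def test_linearity_in_amplitude(self):
        d1 = design_from([(5.0, 3.0, "a", 1.0)])
        d2 = design_from([(5.0, 3.0, "a", 2.0)])
        t1 = convolve_hrf(generate_stimfunction(d1, 60.0, 1.0)["a"])
        t2 = convolve_hrf(generate_stimfunction(d2, 60.0, 1.0)["a"])
        np.testing.assert_allclose(t2, 2 * t1, atol=1e-12)


class TestGenerateMeasure:
    def test_round_trip_matches_profile(self, cube_geometry):
        profile = NoiseProfile()
        vol = generate_noise(cube_geometry, 200, 1.0, profile, seed=42)
        measured = measure_noise(vol, cube_geometry, 1.0)
        assert abs(measured.sfnr - profile.sfnr) / profile.sfnr < 0.10
        assert abs(measured.ar_rho - profile.ar_rho) < 0.10

    def test_same_seed_bit_identical(self, cube_geometry):
        a = generate_noise(cube_geometry, 100, 1.0, seed=5)
        b = generate_noise(cube_geometry, 100, 1.0, seed=5)
        c = generate_noise(cube_geometry, 100, 1.0, seed=6)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_unstructured_profile_gives_flat_spectrum(self, cube_geometry):
        profile = NoiseProfile(
            ar_rho=1e-9, drift_sd_pct=0.0, physio_freqs_hz=[], spatial_fwhm_mm=0.0
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vol = generate_noise(cube_geometry, 500, 1.0, profile, seed=1)
        ts = volume_to_timeseries(vol, cube_geometry, 1.0)
        from scipy.signal import welch

        # averaged (Welch, all voxels) spectrum: flat means no bin stands
        # out beyond chi-square wiggle
        _, power = welch(ts.data - ts.data.mean(axis=0), axis=0, nperseg=125)
        mean_power = power.mean(axis=1)[1:]
        assert mean_power.max() < 3 * np.median(mean_power)

    def test_physio_component_peaks_at_requested_frequency(self, cube_geometry):
        profile = NoiseProfile(physio_freqs_hz=[0.2], ar_rho=0.2, drift_sd_pct=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vol = generate_noise(cube_geometry, 500, 1.0, profile, seed=3)
        ts = volume_to_timeseries(vol, cube_geometry, 1.0)
        # average the per-voxel spectra: random phases cancel in the mean
        # time series but not in the mean spectrum
        x = ts.data - ts.data.mean(axis=0)
        power = (np.abs(np.fft.rfft(x, axis=0)) ** 2).mean(axis=1)
        freqs = np.fft.rfftfreq(500, d=1.0)
        band = (freqs > 0.15) & (freqs < 0.25)
        outside = (freqs > 0.05) & ~band
        assert power[band].max() > 2 * np.median(power[outside])

    def test_measure_on_known_construction(self, cube_geometry):
        rng = np.random.default_rng(0)
        t = 300
        vol = np.zeros(cube_geometry.dims + (t,))
        flat = vol.reshape(-1, t, order="F")
        m = cube_geometry.mask.ravel(order="F")
        flat[m] = 100.0 + rng.standard_normal((m.sum(), t))
        flat[~m] = rng.standard_normal(((~m).sum(), t))
        vol = flat.reshape(cube_geometry.dims + (t,), order="F")
        prof = measure_noise(vol, cube_geometry, 1.0)
        assert abs(prof.sfnr - 100) / 100 < 0.10
        assert abs(prof.ar_rho) < 0.15
        assert abs(prof.snr - 100) / 100 < 0.15

    def test_ar_coefficient_estimation(self, cube_geometry):
        rng = np.random.default_rng(1)
        t, rho = 2000, 0.5
        base = np.zeros(t)
        for i in range(1, t):
            base[i] = rho * base[i - 1] + np.sqrt(1 - rho**2) * rng.standard_normal()
        vol = np.zeros(cube_geometry.dims + (t,))
        flat = vol.reshape(-1, t, order="F")
        m = cube_geometry.mask.ravel(order="F")
        flat[m] = 100.0 + base  # identical AR series in every voxel
        vol = flat.reshape(cube_geometry.dims + (t,), order="F")
        prof = measure_noise(vol, cube_geometry, 1.0)
        assert 0.4 <= prof.ar_rho <= 0.6

    def test_constant_volume_reports_infinite_sfnr(self, cube_geometry):
        vol = np.full(cube_geometry.dims + (20,), 50.0)
        with pytest.warns(DegenerateDataWarning):
            prof = measure_noise(vol, cube_geometry, 1.0)
        assert np.isinf(prof.sfnr)


class TestApplySignal:
    def _noise(self, geom, t=100, seed=2):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return generate_noise(geom, t, 1.0, seed=seed)

    def test_zero_scale_is_identity(self, cube_geometry):
        vol = self._noise(cube_geometry)
        tc = {"a": np.ones(100)}
        pat = {"a": np.ones(cube_geometry.n_voxels)}
        out = apply_signal(vol, cube_geometry, cube_geometry.mask, pat, tc, 0.0)
        np.testing.assert_array_equal(out, vol)

    def test_boxcar_raises_event_mean_by_one_percent(self, cube_geometry):
        vol = self._noise(cube_geometry)
        tc = np.zeros(100)
        tc[40:60] = 1.0
        out = apply_signal(
            vol, cube_geometry, cube_geometry.mask,
            {"a": np.ones(cube_geometry.n_voxels)}, {"a": tc}, 1.0,
        )
        ts_in = volume_to_timeseries(vol, cube_geometry, 1.0).data
        ts_out = volume_to_timeseries(out, cube_geometry, 1.0).data
        lift = (ts_out - ts_in)[40:60].mean()
        baseline = ts_in.mean()
        assert lift / baseline == pytest.approx(0.01, rel=1e-6)

    def test_roi_outside_mask_rejected(self, cube_geometry):
        vol = self._noise(cube_geometry, t=20)
        roi = np.ones(cube_geometry.dims, bool)  # larger than the mask
        with pytest.raises(ValidationError, match="outside the mask"):
            apply_signal(vol, cube_geometry, roi, {"a": np.ones(roi.sum())},
                         {"a": np.zeros(20)}, 1.0)

    def test_signal_and_noise_combine_linearly(self, cube_geometry):
        vol = self._noise(cube_geometry)
        tc = {"a": np.sin(np.linspace(0, 6, 100)) ** 2}
        pat = {"a": np.linspace(-1, 1, cube_geometry.n_voxels)}
        out = apply_signal(vol, cube_geometry, cube_geometry.mask, pat, tc, 2.0)
        zero = apply_signal(vol, cube_geometry, cube_geometry.mask, pat, tc, 0.0)
        signal = out - zero
        doubled = apply_signal(vol, cube_geometry, cube_geometry.mask, pat, tc, 4.0)
        np.testing.assert_allclose(doubled - zero, 2 * signal, atol=1e-9)

    def test_two_condition_patterns_are_classifiable(self, cube_geometry):
        """The simulator's intended use: insert condition-specific patterns
        and verify a classifier can separate the event-evoked responses."""
        from sklearn.svm import LinearSVC

        t = 200
        vol = self._noise(cube_geometry, t=t, seed=11)
        events = []
        onset = 10.0
        for i in range(12):
            events.append((onset, 8.0, "A" if i % 2 == 0 else "B", 1.0))
            onset += 15.0
        design = design_from(events)
        stims = generate_stimfunction(design, t * 1.0, 1.0)
        tcs = {c: convolve_hrf(s) for c, s in stims.items()}
        rng = np.random.default_rng(11)
        n = cube_geometry.n_voxels
        pat_a = rng.choice([-1.0, 1.0], n)
        out = apply_signal(
            vol, cube_geometry, cube_geometry.mask,
            {"A": pat_a, "B": -pat_a}, tcs, 2.0,
        )
        ts = volume_to_timeseries(out, cube_geometry, 1.0).data
        x, y = [], []
        for _, r in design.events.iterrows():
            lo, hi = int(r["onset"] + 4), int(r["onset"] + r["duration"] + 4)
            x.append(ts[lo:hi].mean(axis=0))
            y.append(0 if r["trial_type"] == "A" else 1)
        x, y = np.array(x), np.array(y)
        correct = 0
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            clf = LinearSVC(max_iter=20000).fit(x[keep], y[keep])
            correct += int(clf.predict(x[i : i + 1])[0] == y[i])
        assert correct / len(y) > 0.9
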