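"""Signal conditioning and lock-in feature extraction."""

import dataclasses
import math

import numpy as np
import pytest

import dipalp as d

TWO_PI = 2.0 * math.pi


def _sine(f, fs, n, amp=1.0, phase=0.0, offset=0.0):
    t = np.arange(n) / fs
    return offset + amp * np.sin(TWO_PI * f * t + phase), t


class TestDetrendStrain:
    def test_pure_sinusoid_untouched_in_interior(self):
        fs, f = 1000.0, 5.0
        x, _ = _sine(f, fs, 4000)
        window = 601  # three periods, odd
        detrended, trend = d.detrend_strain(x, window)
        half = window // 2
        gain = 1.0 - d.moving_average_attenuation(window, f, fs)
        np.testing.assert_allclose(detrended[half:-half], gain * x[half:-half],
                                   atol=1e-10)
        # trend of a zero-mean sinusoid is (nearly) zero
        assert np.abs(trend[half:-half]).max() < 0.005

    def test_ramp_removed_amplitude_preserved(self):
        """Compare against a least-squares sinusoid+ramp oracle."""
        fs, f, amp = 1000.0, 5.0, 0.7
        n = 6000
        x, t = _sine(f, fs, n, amp=amp, phase=0.3)
        x = x + 0.05 * t  # linear drift
        window = 601
        detrended, _ = d.detrend_strain(x, window)
        half = window // 2
        interior = detrended[half:-half]
        assert abs(interior.mean()) < 1e-3

        # oracle: direct least-squares fit of sin + cos + ramp + offset
        design = np.column_stack([np.sin(TWO_PI * f * t), np.cos(TWO_PI * f * t),
                                  t, np.ones(n)])
        coef, *_ = np.linalg.lstsq(design, x, rcond=None)
        amp_oracle = math.hypot(coef[0], coef[1])

        gain = 1.0 - d.moving_average_attenuation(window, f, fs)
        ti = t[half:-half]
        proj_s = 2 * np.mean(interior * np.sin(TWO_PI * f * ti))
        proj_c = 2 * np.mean(interior * np.cos(TWO_PI * f * ti))
        amp_est = math.hypot(proj_s, proj_c) / gain
        assert amp_est == pytest.approx(amp_oracle, rel=5e-3)
        assert amp_est == pytest.approx(amp, rel=5e-3)

    def test_per_block_scope_removes_block_settles(self):
        """A settle transient restarting at each block needs per-block
        averaging; a single global window leaves residual trend at the
        boundary."""
        fs, f = 1000.0, 5.0
        nb = 4000
        x = np.concatenate([
            _sine(f, fs, nb)[0] + 0.5 * np.exp(-np.arange(nb) / fs / 0.5),
            _sine(f, fs, nb)[0] + 0.5 * np.exp(-np.arange(nb) / fs / 0.5),
        ])
        blocks = [slice(0, nb), slice(nb, 2 * nb)]
        _, trend_block = d.detrend_strain(x, 601, scope="per_block", blocks=blocks)
        # per-block trend tracks each settle: residual after subtraction is
        # below the settle amplitude everywhere in the interior
        for sl in blocks:
            interior = (x - trend_block)[sl][300:-300]
            assert np.abs(interior).max() < 1.1  # sinusoid + tiny residual
            assert abs(interior.mean()) < 0.01

    def test_window_validation(self):
        x = np.zeros(100)
        with pytest.raises(ValueError, match="odd"):
            d.detrend_strain(x, 10)
        with pytest.raises(ValueError, match="period"):
            d.detrend_strain(np.zeros(5000), 101, min_window=200)
        with pytest.raises(ValueError, match="scope"):
            d.detrend_strain(np.zeros(100), 11, scope="bogus")


class TestExtractFundamental:
    @pytest.mark.parametrize("amp,phase,offset", [
        (1.0, 0.0, 0.0), (0.3, 1.2, -2.0), (2.5, -2.0, 5.0),
    ])
    def test_exact_on_integer_periods(self, amp, phase, offset):
        fs, f = 1000.0, 5.0
        x, _ = _sine(f, fs, 2000, amp=amp, phase=phase, offset=offset)
        mean, a, ph = d.extract_fundamental(x, f, fs)
        assert mean == pytest.approx(offset, abs=1e-12)
        assert a == pytest.approx(amp, rel=1e-12)
        assert math.remainder(ph - phase, TWO_PI) == pytest.approx(0.0, abs=1e-12)

    def test_matches_fft_bin_exactly(self):
        fs, f = 1000.0, 4.0
        rng = np.random.default_rng(1)
        x, _ = _sine(f, fs, 5000, amp=0.8, phase=0.7, offset=1.0)
        x = x + rng.normal(0, 0.1, x.size)  # equality must hold even w/ noise
        mean, amp, phase = d.extract_fundamental(x, f, fs)
        n_per = int(fs / f)
        k = 5000 // n_per
        n = k * n_per
        spectrum = np.fft.rfft(x[:n])
        assert amp == pytest.approx(2.0 * abs(spectrum[k]) / n, rel=1e-10)
        # X[k] = (N/2) (b - i a) for x = a sin + b cos
        assert phase == pytest.approx(
            math.atan2(spectrum[k].real, -spectrum[k].imag), abs=1e-10)
        assert mean == pytest.approx(spectrum[0].real / n, rel=1e-10)

    def test_two_tone_reports_only_fundamental(self):
        fs, f = 1000.0, 5.0
        x, t = _sine(f, fs, 3000, amp=1.0)
        x = x + 0.5 * np.sin(TWO_PI * 3 * f * t)
        _, amp, _ = d.extract_fundamental(x, f, fs)
        assert amp == pytest.approx(1.0, rel=1e-10)

    def test_noise_amplitude_error_below_2pct(self):
        """Monte-Carlo at 20 dB SNR, 10 s at 1000 Hz, 100 seeds."""
        fs, f, amp = 1000.0, 5.0, 1.0
        sigma = amp * 10 ** (-20 / 20)
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x, _ = _sine(f, fs, 10000, amp=amp, phase=0.4)
            x = x + rng.normal(0, sigma, x.size)
            _, a, _ = d.extract_fundamental(x, f, fs)
            errs.append(abs(a - amp) / amp)
        assert max(errs) < 0.02

    def test_too_few_periods_rejected(self):
        x, _ = _sine(5.0, 1000.0, 400)  # 2 periods
        with pytest.raises(ValueError, match="period"):
            d.extract_fundamental(x, 5.0, 1000.0)

    def test_unresolvable_frequency_rejected(self):
        with pytest.raises(ValueError, match="resolvable"):
            d.extract_fundamental(np.zeros(1000), 600.0, 1000.0)


class TestRatios:
    def test_mean_ratio(self):
        assert d.compute_mr(2.0, -0.5, 1.0) == pytest.approx(4.0)
        assert d.compute_mr(2.0, -0.5, 2.0) == pytest.approx(8.0)

    def test_amplitude_ratio(self):
        assert d.compute_ar(1.0, 0.25, 1.0) == pytest.approx(4.0)

    def test_no_contact_rejected(self):
        with pytest.raises(ValueError, match="contact"):
            d.compute_mr(1.0, 0.0, 1.0)

    def test_mr_matches_hertz_secant_oracle(self, geometry):
        """Noise-free elastic point: MR equals the Hertz secant slope at the
        operating point (closed-form oracle)."""
        e = 20.0
        rec = d.synthesize_recording(d.ViscoParams(e), geometry,
                                     d.ActuationProtocol(), "firm")
        df = d.extract_features(rec, geometry)
        d0 = d.indentation_depth(e, geometry, 1.5)
        secant = d.hertz_force(e, geometry, d0) / d0
        assert df.mr_n_per_mm.iloc[0] == pytest.approx(secant, rel=1e-3)
        # and 1.5x the secant is the tangent the modulus inversion expects
        assert d.SECANT_TO_TANGENT * df.mr_n_per_mm.iloc[0] == pytest.approx(
            d.hertz_tangent_stiffness(e, geometry, d0), rel=1e-3)

    def test_ar_over_elastic_ar_equals_dynamic_ratio(self, geometry):
        """Kelvin-Voigt point at 5 Hz: AR / AR_elastic = |E*| / E'."""
        f = 5.0
        eta = 20.0 * math.tan(0.6) / (TWO_PI * f)
        kv = d.ViscoParams(20.0, eta=eta)
        rec_kv = d.synthesize_recording(kv, geometry, d.ActuationProtocol(), "firm")
        rec_el = d.synthesize_recording(d.ViscoParams(20.0), geometry,
                                        d.ActuationProtocol(), "firm")
        ar_kv = d.extract_features(rec_kv, geometry).ar_n_per_mm.iloc[0]
        ar_el = d.extract_features(rec_el, geometry).ar_n_per_mm.iloc[0]
        cm = d.complex_modulus(kv, f)
        assert ar_kv / ar_el == pytest.approx(cm.magnitude / cm.storage, rel=1e-2)


class TestExtractFeatures:
    @pytest.mark.parametrize("f", [1.0, 5.0])
    @pytest.mark.parametrize("dt", [0.005, 0.02, 0.04])
    @pytest.mark.parametrize("e", [5.0, 20.0, 50.0])
    def test_noise_free_parameter_recovery_grid(self, geometry, e, dt, f):
        """Headline features recover to <1% over the working grid."""
        eta = e * math.tan(TWO_PI * f * dt) / (TWO_PI * f)
        visco = d.ViscoParams(e, eta=eta)
        rec = d.synthesize_recording(visco, geometry,
                                     d.ActuationProtocol(frequencies=(f,)), "firm")
        row = d.extract_features(rec, geometry).iloc[0]
        assert row.e_static_kpa == pytest.approx(e, rel=0.01)
        assert row.e_dynamic_kpa == pytest.approx(
            d.complex_modulus(visco, f).magnitude, rel=0.01)
        assert row.dt_s == pytest.approx(dt, rel=0.01)

    def test_phase_estimate_unbiased_under_noise(self, geometry):
        """Mean lag over 200 noisy replicates within 2 SE of truth (20 dB)."""
        f, dt, e = 5.0, 0.0175, 25.0
        eta = e * math.tan(TWO_PI * f * dt) / (TWO_PI * f)
        visco = d.ViscoParams(e, eta=eta)
        proto = d.ActuationProtocol(frequencies=(f,), block_duration_s=10.0)
        lags = []
        for seed in range(200):
            rec = d.synthesize_recording(
                visco, geometry, proto, "firm", snr_strain_db=20.0,
                rng=np.random.default_rng(seed))
            lags.append(d.extract_features(rec, geometry).dt_s.iloc[0])
        lags = np.array(lags)
        se = lags.std(ddof=1) / math.sqrt(len(lags))
        assert abs(lags.mean() - dt) < 2 * se + 1e-12

    def test_invariance_to_offset_and_slow_drift(self, geometry):
        """Dynamic features (AR, PD, dt) are unchanged by a strain offset and
        by drift much slower than the detrend window."""
        f = 5.0
        eta = 20.0 * math.tan(0.5) / (TWO_PI * f)
        rec = d.synthesize_recording(d.ViscoParams(20.0, eta=eta), geometry,
                                     d.ActuationProtocol(), "firm")
        base = d.extract_features(rec, geometry).iloc[0]
        shifted = dataclasses.replace(rec) if False else rec
        rec2 = d.RawRecording(time=rec.time, force=rec.force,
                              strain=rec.strain - 0.2 + 1e-4 * rec.time,
                              meta=rec.meta, truth=rec.truth)
        mod = d.extract_features(rec2, geometry).iloc[0]
        assert mod.ar_n_per_mm == pytest.approx(base.ar_n_per_mm, rel=1e-6)
        assert mod.pd_rad == pytest.approx(base.pd_rad, abs=1e-6)

    def test_short_block_flagged_and_excluded(self, geometry):
        proto = d.ActuationProtocol(frequencies=(1.0,), block_duration_s=2.0)
        rec = d.synthesize_recording(d.ViscoParams(20.0), geometry, proto, "firm")
        df = d.extract_features(rec, geometry)
        assert df.empty
        assert len(df.attrs["excluded"]) == 1

    def test_elastic_point_zero_lag(self, geometry):
        rec = d.synthesize_recording(d.ViscoParams(30.0), geometry,
                                     d.ActuationProtocol(), "firm")
        df = d.extract_features(rec, geometry)
        assert len(df) == 1
        assert abs(df.dt_s.iloc[0]) <= 1e-3

    def test_default_cohort_static_recovery_within_5pct(self, default_features):
        """Stochastic round trip: extracted per-class medians track the
        generator's calibrated medians."""
        firm = default_features[default_features.pressure == "firm"]
        for label in ("C", "NC"):
            med = firm[firm.label == label].e_static_kpa.median()
            target = d.IN_VIVO_PROFILE.static[label].median
            assert med == pytest.approx(target, rel=0.05)
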