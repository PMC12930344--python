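"""Closed-form and oracle checks for the ten acoustic features."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from korosound.features import (
    FeatureConfig,
    amplitude_stats,
    envelope_moments,
    extract_features,
    spectral_features,
)
from korosound.preprocess import BeatSegment, KorotkoffWindow
from korosound.synth import GroundTruthParams, generate_recording

FS = 1000.0


def _beats(times, amps, fs=FS):
    """Build minimal BeatSegments at given peak times/amplitudes."""
    out = []
    for t, a in zip(times, amps):
        i = int(t * fs)
        out.append(
            BeatSegment(
                onset=i - 1, peak=i, end=i + 1, amplitude=float(a),
                peak_time=float(t), cuff_pressure=float("nan"),
            )
        )
    return out


def _moments_bruteforce(times, amps, t_mid):
    """Independent weighted-moment oracle by direct summation."""
    w = np.asarray(amps, float) / np.sum(amps)
    t = np.asarray(times, float)
    mu = np.sum(w * t)
    m2 = np.sum(w * (t - mu) ** 2)
    m3 = np.sum(w * (t - mu) ** 3)
    return t_mid - mu, m3 / m2**1.5 if m2 > 0 else 0.0


class TestAmplitudeStats:
    def test_sinusoid_closed_forms(self):
        """Whole periods of a unit sine: crest sqrt(2), form pi/(2 sqrt 2),
        impulse pi/2, kurtosis 1.5."""
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * 32.0 * t)
        max_amp, kurt, peak, pulse, form = amplitude_stats(x)
        assert peak == pytest.approx(np.sqrt(2), rel=1e-3)
        assert form == pytest.approx(np.pi / (2 * np.sqrt(2)), rel=1e-3)
        assert pulse == pytest.approx(np.pi / 2, rel=1e-3)
        assert kurt == pytest.approx(1.5, rel=1e-3)
        assert max_amp == pytest.approx(1.0, rel=1e-4)

    def test_unit_impulse_sequence(self):
        """(0,0,1,0,0): RMS = 1/sqrt(5), mean|x| = 1/5 by hand."""
        _, _, peak, pulse, form = amplitude_stats(np.array([0, 0, 1, 0, 0.0]))
        assert pulse == pytest.approx(5.0, abs=1e-12)
        assert peak == pytest.approx(np.sqrt(5), abs=1e-12)
        assert form == pytest.approx(np.sqrt(5), abs=1e-12)

    def test_scale_law(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        base = amplitude_stats(x)
        scaled = amplitude_stats(3.7 * x)
        assert scaled[0] == pytest.approx(3.7 * base[0], rel=1e-12)
        for i in (1, 2, 3, 4):
            assert scaled[i] == pytest.approx(base[i], rel=1e-12)

    def test_zero_energy_rejected(self):
        with pytest.raises(ValueError):
            amplitude_stats(np.zeros(100))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_pulse_equals_peak_times_form(self, seed):
        x = np.random.default_rng(seed).normal(size=200)
        _, _, peak, pulse, form = amplitude_stats(x)
        assert pulse == pytest.approx(peak * form, rel=1e-12)
        assert peak >= 1.0 and form >= 1.0


class TestEnvelopeMoments:
    def test_symmetric_beats_give_zero(self):
        win = KorotkoffWindow(0, 4000, "annotated")
        com, skew = envelope_moments(
            _beats([1.0, 2.0, 3.0], [1.0, 2.0, 1.0]), win, FS
        )
        assert com == pytest.approx(0.0, abs=1e-12)
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_mass_early_toy_example(self):
        """Beats at (1,2,3) s, amplitudes (3,1,1), 4-s window: weighted mean
        1.6 s, so the deflation-direction center of mass is +0.4 s; the
        weighted third moment gives skewness 0.432/0.512 = +0.84375."""
        win = KorotkoffWindow(0, 4000, "annotated")
        com, skew = envelope_moments(_beats([1, 2, 3], [3, 1, 1]), win, FS)
        assert com == pytest.approx(0.4, abs=1e-12)
        assert skew == pytest.approx(0.84375, abs=1e-12)

    def test_time_reversal_negates_both(self):
        win = KorotkoffWindow(0, 4000, "annotated")
        times, amps = [0.5, 1.1, 2.0, 3.1], [4.0, 2.0, 1.0, 0.5]
        com, skew = envelope_moments(_beats(times, amps), win, FS)
        rev_times = [4.0 - t for t in times][::-1]
        com_r, skew_r = envelope_moments(_beats(rev_times, amps[::-1]), win, FS)
        assert com_r == pytest.approx(-com, abs=1e-10)
        assert skew_r == pytest.approx(-skew, abs=1e-10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 11)
        times = np.sort(rng.uniform(0.1, 9.9, n))
        times += np.arange(n) * 1e-3  # ensure distinct
        amps = rng.uniform(0.1, 5.0, n)
        win = KorotkoffWindow(0, 10000, "annotated")
        com, skew = envelope_moments(_beats(times, amps), win, FS)
        com_o, skew_o = _moments_bruteforce(times, amps, 5.0)
        assert com == pytest.approx(com_o, abs=1e-10)
        assert skew == pytest.approx(skew_o, abs=1e-10)

    def test_too_few_beats_and_zero_amplitude(self):
        win = KorotkoffWindow(0, 4000, "annotated")
        with pytest.raises(ValueError, match="3 beats"):
            envelope_moments(_beats([1, 2], [1, 1]), win, FS)
        with pytest.raises(ValueError, match="zero"):
            envelope_moments(_beats([1, 2, 3], [0, 0, 0]), win, FS)


class TestSpectralFeatures:
    def test_single_tone(self):
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * 32.0 * t)
        peak, centroid, msf = spectral_features(x, FS, segment_s=1.0)
        df = 1.0  # 1-s segments -> 1 Hz bins
        assert abs(peak - 32.0) <= df
        assert abs(centroid - 32.0) <= df
        assert abs(msf - 32.0**2) <= 2 * 32.0 * df + df**2

    def test_two_equal_tones(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 20 * t) + np.sin(2 * np.pi * 40 * t)
        _, centroid, msf = spectral_features(x, FS, segment_s=1.0)
        assert centroid == pytest.approx(30.0, abs=1.5)
        assert msf == pytest.approx((400 + 1600) / 2, rel=0.05)

    def test_scale_invariance(self):
        x = np.random.default_rng(3).normal(size=4000)
        a = spectral_features(x, FS)
        b = spectral_features(5.0 * x, FS)
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_energy_rejected(self):
        with pytest.raises(ValueError):
            spectral_features(np.zeros(4000), FS)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_jensen_inequality(self, seed):
        x = np.random.default_rng(seed).normal(size=2048)
        _, centroid, msf = spectral_features(x, FS)
        assert msf >= centroid**2 - 1e-9


class TestExtractFeatures:
    def test_deterministic(self, young_recording):
        rec = young_recording[0]
        a = extract_features(rec)
        b = extract_features(rec)
        assert a == b

    def test_feature_identities_on_synthetic_recordings(self):
        for seed in range(5):
            p = GroundTruthParams(envelope_skew=0.3 * (seed - 2) / 2, seed=seed)
            rec, _, _ = generate_recording(p)
            fv = extract_features(rec)
            assert fv.pulse_factor == pytest.approx(
                fv.peak_factor * fv.form_factor, rel=1e-12
            )
            assert fv.mean_square_frequency >= fv.centroid_frequency**2
            assert fv.peak_factor >= 1.0 and fv.form_factor >= 1.0
            assert 0 <= fv.peak_frequency <= FS / 2

    def test_young_pattern_positive_moments(self):
        """Mass-early recordings give positive skewness and center of mass
        in >= 8/10 seeds; mass-late give the mirror image."""
        good = 0
        for seed in range(10):
            p = GroundTruthParams(envelope_skew=0.55, beat_center_freq=40, seed=seed)
            rec, _, _ = generate_recording(p)
            fv = extract_features(rec)
            good += fv.skewness > 0 and fv.center_of_mass > 0
        assert good >= 8

    def test_group_peak_frequency_ordering(self):
        """Stiff-preset recordings sit below the compliant band in >= 8/10."""
        below = 0
        for seed in range(10):
            p = GroundTruthParams(envelope_skew=-0.55, beat_center_freq=29, seed=seed)
            rec, _, _ = generate_recording(p)
            below += extract_features(rec).peak_frequency < 40.0
        assert below >= 8

    def test_stage_labelled_errors(self):
        from korosound.features import StageError
        from korosound.io import Recording

        silent = Recording(
            np.random.default_rng(0).normal(0, 1e-9, 30000),
            np.linspace(150, 70, 30000),
            FS,
        )
        with pytest.raises(StageError) as err:
            extract_features(silent)
        assert err.value.stage in ("detect_window", "segment_beats")

    def test_bad_config_stage_label(self, young_recording):
        rec = young_recording[0]
        from korosound.features import StageError

        with pytest.raises(StageError) as err:
            extract_features(rec, FeatureConfig(wavelet="nosuch9"))
        assert err.value.stage == "wavelet_denoise"
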