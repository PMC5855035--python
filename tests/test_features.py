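"""The 44-feature layer: per-modality formulas against hand arithmetic,
assembly contracts, and coupling to the generator's latent workload."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from cogload.features import (FEATURE_NAMES, SENSOR_GROUPS, assemble,
                              ecg_features, eda_features, eeg_features,
                              extract_features, hr_features, phasic_features,
                              prepare_signals, standardize, temp_features)
from cogload.simulate import SimulationConfig, simulate_session
from cogload.windowing import Window, session_windows


def test_feature_partition_is_2_6_2_3_3_28():
    assert len(FEATURE_NAMES) == 44
    sizes = {g: len(v) for g, v in SENSOR_GROUPS.items()}
    assert sizes == {"pupil": 2, "EDA": 6, "T": 2, "ECG": 3, "PPG": 3,
                     "EEG": 28}


class TestStandardize:
    def test_hand_arithmetic(self):
        out = standardize(np.array([1.0, 2.0, 3.0]))
        assert np.allclose(out, [-1.0, 0.0, 1.0])  # sd(n-1) of [1,2,3] is 1

    def test_constant_gives_zeros(self):
        assert np.allclose(standardize(np.full(5, 4.2)), 0.0)

    def test_idempotent(self, rng):
        x = rng.standard_normal(100)
        once = standardize(x)
        assert np.allclose(standardize(once), once)


class TestEdaFeatures:
    def test_constant_signal_forced_values(self):
        w = np.full(40, 3.0)
        acc, avg, power = eda_features(w, grand_mean=3.0)
        assert acc == pytest.approx(40.0)   # normalized == 1 summed over n
        assert avg == pytest.approx(1.0)
        assert power == pytest.approx(0.0)

    def test_scale_invariance(self, rng):
        w = 400 + rng.standard_normal(50)
        a1 = eda_features(w, w.mean())
        a2 = eda_features(7 * w, 7 * w.mean())
        assert np.allclose(a1, a2)

    def test_spectral_power_excludes_dc(self, rng):
        fs = 10.0
        t = np.arange(100) / fs
        w = np.sin(2 * np.pi * 1.0 * t) + 5.0
        _, _, p1 = eda_features(w, np.mean(w))
        _, _, p2 = eda_features(w + 100.0, np.mean(w + 100.0))
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_zero_grand_mean_is_error(self):
        with pytest.raises(ValueError):
            eda_features(np.ones(10), 0.0)


class TestPhasicFeatures:
    def test_zero_series(self):
        assert phasic_features(np.zeros(50)) == (0, 0.0, 0.0)

    def test_single_spike(self):
        x = np.zeros(20)
        x[10] = 0.5
        n, mx, mean = phasic_features(x)
        assert (n, mx) == (1, 0.5)
        assert mean == pytest.approx(0.5 / 20)

    def test_negative_trough_not_a_peak_but_counts_in_modulus(self):
        x = np.zeros(30)
        x[10] = 0.3
        x[20] = -0.4
        n, mx, _ = phasic_features(x)
        assert n == 1          # maxima only
        assert mx == pytest.approx(0.4)


class TestEcgMad:
    def test_three_sample_brute_force(self):
        # window [1,2,3]: deviations from median 2 are [1,0,1]
        mean, med, var = ecg_features(np.array([1.0, 2.0, 3.0]))
        assert mean == pytest.approx(2.0 / 3.0)
        assert med == pytest.approx(1.0)  # sorted deviations [0,1,1]
        assert var == pytest.approx(np.var([1.0, 0.0, 1.0], ddof=1))

    def test_symmetric_window(self):
        a = 2.5
        mean, _, _ = ecg_features(np.array([-a, 0.0, a]))
        assert mean == pytest.approx(2 * a / 3)

    def test_constant_window(self):
        assert ecg_features(np.full(7, 1.3)) == (0.0, 0.0, 0.0)


class TestHrFeatures:
    def test_constant_rate(self):
        assert hr_features(np.full(6, 60.0)) == (60.0, 0.0, 60.0)

    def test_two_values_rms(self):
        mean, sd, rms = hr_features(np.array([60.0, 80.0]))
        assert mean == pytest.approx(70.0)
        assert rms == pytest.approx(np.sqrt(5000.0))

    def test_empty_window_is_nan(self):
        assert all(np.isnan(v) for v in hr_features(np.array([])))


def test_temp_features_skew_and_shuffle(rng):
    assert temp_features(np.array([0.0, 0.0, 3.0])) == (1.0, 0.0)
    x = rng.standard_normal(50)
    shuffled = rng.permutation(x)
    assert temp_features(x) == pytest.approx(temp_features(shuffled))


class TestEegFeatures:
    def test_pure_inband_tone_power(self):
        fs = 128.0
        t = np.arange(int(20 * fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        power, _ = eeg_features(x[len(x) // 4: -len(x) // 4], fs)
        # envelope of a unit tone is 1, power |a|^2 ~ 1
        assert power == pytest.approx(1.0, rel=0.02)

    def test_out_of_band_tone_rejected(self):
        fs = 128.0
        t = np.arange(int(20 * fs)) / fs
        x = np.sin(2 * np.pi * 30.0 * t)
        power, _ = eeg_features(x, fs)
        assert power < 0.01

    def test_amplitude_modulated_tone(self):
        fs = 128.0
        t = np.arange(int(40 * fs)) / fs
        a = 1 + 0.5 * np.cos(2 * np.pi * 0.5 * t)
        x = a * np.sin(2 * np.pi * 10.0 * t)
        sl = slice(len(x) // 4, -len(x) // 4)
        power, _ = eeg_features(x[sl], fs)
        assert power == pytest.approx(np.mean(a[sl] ** 2), rel=0.05)


@pytest.fixture(scope="module")
def signals(small_session):
    s, _ = small_session
    return s, prepare_signals(s)


class TestAssemble:
    def test_all_modalities_present_gives_44_numbers(self, signals):
        s, sig = signals
        ws = session_windows(s)
        vec = assemble(ws[0], sig)
        assert len(vec) == 44
        assert list(vec.index) == list(FEATURE_NAMES)
        assert vec.notna().all()

    def test_absent_eeg_leaves_16_numeric_28_nan(self, signals):
        s, sig = signals
        ws = session_windows(s)
        import dataclasses
        no_eeg = dataclasses.replace(sig, eeg_analytic=None)
        vec = assemble(ws[0], no_eeg)
        assert int(vec.notna().sum()) == 16
        assert int(vec.isna().sum()) == 28

    def test_field_order_stable(self, signals):
        s, sig = signals
        ws = session_windows(s)
        v1 = assemble(ws[0], sig)
        v2 = assemble(ws[0], sig)
        assert list(v1.index) == list(v2.index)
        assert np.allclose(v1.to_numpy(), v2.to_numpy(), equal_nan=True)


class TestWorkloadCoupling:
    def test_pupil_feature_monotone_in_level(self):
        cfg = SimulationConfig(seed=21, session_duration_s=240.0,
                               channels=(), transition_effect=0.0,
                               level_spread=0.05)
        s, truth = simulate_session(cfg, 0)
        ws = session_windows(s)
        sig = prepare_signals(s)
        tab = extract_features(ws, sig, "P01")
        # match each recovered window to the truth window covering its centre
        centres = (tab["t_start"] + tab["t_end"]) / 2
        idx = np.searchsorted(truth.windows["t_start"].to_numpy(), centres,
                              side="right") - 1
        tab["level"] = truth.windows["level"].to_numpy()[idx]
        means = tab.groupby("level")["pupil_mean_area"].mean()
        rho = sst.spearmanr(means.index, means.to_numpy()).statistic
        assert rho > 0.9

    def test_alpha_suppression_lowers_eeg_power_across_levels(self):
        # per-participant z-scoring fixes the session's total variance, so
        # the alpha-suppression signature lives within the session: windows
        # at higher workload levels carry less 2–15 Hz envelope power
        cfg = SimulationConfig(seed=31, session_duration_s=120.0,
                               channels=("EEG",), eeg_theta_mod=0.0,
                               eeg_noise_uv=2.0, eeg_alpha_mod=0.8)
        s, truth = simulate_session(cfg, 0)
        ws = session_windows(s)
        sig = prepare_signals(s)
        tab = extract_features(ws, sig, "x")
        cols = [c for c in FEATURE_NAMES if c.startswith("eeg_power")]
        centres = (tab["t_start"] + tab["t_end"]) / 2
        idx = np.searchsorted(truth.windows["t_start"].to_numpy(), centres,
                              side="right") - 1
        lvl = truth.windows["level"].to_numpy()[idx]
        power = tab[cols].mean(axis=1).to_numpy()
        assert sst.spearmanr(lvl, power).statistic < -0.5
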