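"""Signal-conditioning chains: filter responses, artifact handling, HR
recovery and the scaling invariances every chain must satisfy."""

import numpy as np
import pandas as pd
import pytest

from cogload import preprocess as pp
from cogload.session import SensorChannel
from cogload.simulate import SimulationConfig, simulate_session


def tone(freq, fs, seconds=30.0, amp=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def gain_at(y, x):
    """Amplitude ratio measured on the central half of the signals."""
    n = len(x)
    sl = slice(n // 4, 3 * n // 4)
    return np.sqrt(np.mean(y[sl] ** 2) / np.mean(x[sl] ** 2))


class TestSelectPupil:
    @pytest.mark.parametrize("vl,vr,expected", [
        (0, 2, 3.1), (3, 1, 3.4), (2, 2, 3.1),  # lower code wins; tie -> left
    ])
    def test_validity_selection(self, vl, vr, expected):
        g = pd.DataFrame({
            "pupil_left_mm": [3.1], "pupil_right_mm": [3.4],
            "validity_left": [vl], "validity_right": [vr],
        })
        assert pp.select_pupil(g)[0] == expected

    def test_both_eyes_lost_gives_nan(self):
        g = pd.DataFrame({
            "pupil_left_mm": [np.nan], "pupil_right_mm": [np.nan],
            "validity_left": [4], "validity_right": [4],
        })
        assert np.isnan(pp.select_pupil(g)[0])


class TestPupilChain:
    def test_constant_series_with_blink_gap_unchanged(self):
        fs = 120.0
        n = 1200
        x = np.full(n, 3.5)
        x[500:520] = np.nan
        ev = np.array(["fixation"] * n, dtype=object)
        ev[500:520] = "blink"
        t = np.arange(n) * 1000.0 / fs
        out = pp.clean_pupil(x, ev, t, fs)
        assert np.allclose(out.values, 3.5, atol=1e-9)

    def test_low_pass_attenuates_5hz_and_passes_05hz(self):
        fs = 120.0
        n = int(60 * fs)
        ev = np.array(["fixation"] * n, dtype=object)
        t = np.arange(n) * 1000.0 / fs
        hi = pp.clean_pupil(tone(5.0, fs, 60), ev, t, fs)
        lo = pp.clean_pupil(tone(0.5, fs, 60), ev, t, fs)
        assert gain_at(hi.values, tone(5.0, fs, 60)) < 0.1  # >= 20 dB down
        assert abs(gain_at(lo.values, tone(0.5, fs, 60)) - 1) < 0.05

    def test_long_gap_is_flagged(self):
        fs = 120.0
        n = 600
        x = np.full(n, 3.0)
        x[100:350] = np.nan  # > 2 s gap
        ev = np.array(["fixation"] * n, dtype=object)
        t = np.arange(n) * 1000.0 / fs
        out = pp.clean_pupil(x, ev, t, fs, max_gap_ms=1000.0)
        assert "gap_exceeds_max" in out.flags
        assert out.stages["long_gap_mask"][200]

    def test_area_baseline_arithmetic(self):
        # d=4 mm against a 2 mm baseline: area difference = 4π − π = 3π
        fs = 120.0
        clean = pp.CleanSignal("pupil", fs, np.full(100, 4.0))
        out = pp.pupil_area_baseline(clean, np.full(60, 2.0))
        assert np.allclose(out.stages["area_corrected"], 3 * np.pi)

    def test_self_baseline_is_zero_and_zscore_contract(self):
        fs = 120.0
        vals = 3.0 + 0.1 * np.sin(np.arange(600) / 30.0)
        clean = pp.CleanSignal("pupil", fs, vals)
        out = pp.pupil_area_baseline(clean, vals[:60])
        assert abs(out.values.mean()) < 1e-9
        assert abs(out.values.std(ddof=1) - 1) < 1e-9

    def test_missing_baseline_is_error(self):
        clean = pp.CleanSignal("pupil", 120.0, np.full(10, 3.0))
        with pytest.raises(ValueError):
            pp.pupil_area_baseline(clean, np.array([]))


def make_channel(name, fs, values, baseline=None):
    if baseline is None:
        baseline = np.full(int(0.5 * fs), float(np.mean(values)))
    units = {"EDA": "kΩ", "PPG": "mV", "TEMP": "°C", "ECG": "mV"}.get(
        name.split(":")[0], "µV")
    return SensorChannel(name, fs, units, values, baseline)


class TestEda:
    def test_output_rate_is_ten_hz(self):
        seconds = 20
        ch = make_channel("EDA", 120.0, 400 + tone(0.2, 120.0, seconds))
        out = pp.clean_eda(ch)
        assert out.rate_hz == 10.0
        assert abs(len(out.values) - 10 * seconds) <= 1

    def test_dc_gain_unity_and_20hz_stopband(self):
        fs = 120.0
        dc = make_channel("EDA", fs, np.full(int(30 * fs), 7.0))
        assert np.allclose(pp.clean_eda(dc).stages["filtered_decimated"], 7.0,
                           atol=1e-6)
        hi = make_channel("EDA", fs, tone(20.0, fs, 30))
        filt = pp.lowpass(tone(20.0, fs, 30), 5.0, fs)
        assert gain_at(filt, tone(20.0, fs, 30)) < 0.1

    def test_phasic_of_slow_ramp_is_negligible(self):
        ramp = np.linspace(0, 1, 200)
        clean = pp.CleanSignal("EDA", 10.0, ramp)
        phasic = pp.eda_phasic(clean)
        step = ramp[1] - ramp[0]
        assert np.all(np.abs(phasic.values) < step * 4 + 1e-12)

    def test_phasic_isolates_single_sample_spike(self):
        x = np.zeros(50)
        x[25] = 0.8
        clean = pp.CleanSignal("EDA", 10.0, x)
        phasic = pp.eda_phasic(clean)
        assert phasic.values[25] == pytest.approx(0.8)
        assert np.allclose(np.delete(phasic.values, 25), 0.0)

    def test_phasic_of_constant_is_zero_and_short_series_flagged(self):
        const = pp.eda_phasic(pp.CleanSignal("EDA", 10.0, np.full(30, 2.0)))
        assert np.allclose(const.values, 0.0)
        short = pp.eda_phasic(pp.CleanSignal("EDA", 10.0, np.arange(5.0)))
        assert "too_short_for_phasic" in short.flags
        assert np.allclose(short.values, 0.0)


class TestEcg:
    def test_fft_filter_pass_and_stop(self):
        fs = 1000.0
        lo, hi = tone(10.0, fs, 10), tone(150.0, fs, 10)
        assert abs(gain_at(pp.fft_lowpass(lo, 100.0, fs), lo) - 1) < 0.05
        assert gain_at(pp.fft_lowpass(hi, 100.0, fs), hi) < 0.1

    def test_r_peak_times_preserved(self):
        cfg = SimulationConfig(seed=2, session_duration_s=20.0,
                               channels=("ECG",))
        s, truth = simulate_session(cfg, 0)
        ch = s.channel("ECG")
        clean = pp.clean_ecg(ch)
        from scipy.signal import find_peaks
        raw_pk, _ = find_peaks(ch.values, height=0.5, distance=400)
        cln_pk, _ = find_peaks(clean.values,
                               height=0.5 * clean.values.max(), distance=400)
        # every raw R peak has a filtered peak within 2 ms
        for p in raw_pk:
            assert np.min(np.abs(cln_pk - p)) <= 2


class TestPpgHeartRate:
    @pytest.mark.parametrize("dt_cs,expected", [(100.0, 60.0), (80.0, 75.0)])
    def test_rate_formula(self, dt_cs, expected):
        # beats exactly dt_cs hundredths of a second apart
        fs = 120.0
        period_s = dt_cs / 100.0
        n = int(20 * fs)
        t = np.arange(n) / fs
        x = np.maximum(np.cos(2 * np.pi * t / period_s), 0.0) ** 3
        # one sharp pulse per period
        hr = pp.ppg_to_hr(make_channel("PPG", fs, x))
        assert np.median(hr.hr_bpm) == pytest.approx(expected, abs=0.8)

    def test_simulated_72bpm_recovered_within_1bpm(self):
        cfg = SimulationConfig(seed=4, session_duration_s=60.0,
                               channels=("PPG",), hr_level_gain_bpm=0.0)
        s, truth = simulate_session(cfg, 0)
        hr = pp.ppg_to_hr(s.channel("PPG"))
        assert abs(np.mean(hr.hr_bpm) - 72.0) < 1.0

    def test_too_few_peaks_flagged_empty(self):
        flat = make_channel("PPG", 120.0, np.zeros(240))
        hr = pp.ppg_to_hr(flat)
        assert len(hr.hr_bpm) == 0


class TestTempAndEeg:
    def test_temp_chain_constants_and_stopband(self):
        fs = 50.0
        const = make_channel("TEMP", fs, np.full(int(30 * fs), 36.5))
        out = pp.clean_temp(const)
        assert np.allclose(out.values, 0.0)  # constant minus its baseline
        five = tone(5.0, fs, 30)
        assert gain_at(pp.lowpass(five, 1.0, fs), five) < 0.1

    def test_eeg_chain_removes_dc_and_mains(self):
        fs = 128.0
        dc = make_channel("EEG:AF3", fs, np.full(int(40 * fs), 100.0),
                          baseline=np.zeros(64))
        out = pp.clean_eeg(dc)
        assert np.all(np.abs(out.stages["filtered"]) < 1.0)
        mains = tone(50.0, fs, 40)
        assert gain_at(pp.lowpass(mains, 40.0, fs), mains) < 0.1

    def test_hampel_replaces_spike_against_direct_oracle(self, rng):
        fs = 128.0
        x = tone(10.0, fs, 4, amp=50.0)
        x[200] += 500.0
        out = pp.hampel(x, 3, 3.0)

        def oracle(v, half=3, nsig=3.0):
            res = v.copy()
            vp = np.pad(v, half, mode="edge")
            for i in range(len(v)):
                w = vp[i:i + 2 * half + 1]
                med = np.median(w)
                mad = np.median(np.abs(w - med))
                if abs(v[i] - med) > nsig * 1.4826 * mad:
                    res[i] = med
            return res

        assert np.allclose(out, oracle(x))
        # the 500 µV excursion is gone: the sample sits at its local median
        assert abs(out[200] - x[200]) > 400.0
        assert np.max(np.abs(out)) <= 50.0 * 1.01


class TestInvariances:
    @pytest.mark.parametrize("fn", [
        lambda x: pp.lowpass(x, 5.0, 120.0),
        lambda x: pp.highpass(x, 0.5, 128.0),
        lambda x: pp.fft_lowpass(x, 100.0, 1000.0),
    ])
    def test_filters_are_linear(self, fn, rng):
        x = rng.standard_normal(4000)
        assert np.allclose(fn(3.7 * x), 3.7 * fn(x), atol=1e-9)

    def test_baseline_plus_zscore_is_affine_invariant(self, rng):
        vals = 400 + rng.standard_normal(3000)
        base = 400 + rng.standard_normal(60)
        a = pp.clean_temp(make_channel("TEMP", 50.0, vals, base))
        b = pp.clean_temp(make_channel("TEMP", 50.0, 5 * vals + 20,
                                       5 * base + 20))
        assert np.allclose(a.values, b.values, atol=1e-8)
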