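"""Per-signal conditioning chains.

Each raw channel passes through its own chain — artifact handling, a
Blackman-window FIR filter at the stated cutoff, pre-stimulus baseline
subtraction and per-participant z-scoring — producing a :class:`CleanSignal`
whose provenance records every step with its parameters.

Filter conventions
------------------
All FIR filters use a Blackman window with the order chosen so the
transition band is at most 25% of the cutoff (for the 0.5 Hz EEG high-pass
the transition band equals the cutoff, keeping the kernel much shorter than
a session). Symmetric kernels are applied centred (reflect padding), which
is zero-phase: event timing is preserved. The ECG chain filters in the
frequency domain instead, with a raised-cosine band edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import maximum_filter1d

from .session import SensorChannel


@dataclass
class CleanSignal:
    """A conditioned channel plus named intermediate stages.

    ``values`` is the final baseline-corrected, z-scored series;
    ``stages`` holds raw-scale intermediates some feature computations need
    (e.g. the filtered, decimated EDA before normalisation).
    """

    name: str
    rate_hz: float
    values: np.ndarray
    provenance: list[dict] = field(default_factory=list)
    stages: dict[str, np.ndarray] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


@dataclass
class HeartRateSeries:
    beat_times_ms: np.ndarray   # strictly increasing
    hr_bpm: np.ndarray          # one value per inter-beat interval

    def in_window(self, t_start: float, t_end: float) -> np.ndarray:
        """HR values whose defining interval ends inside [t_start, t_end)."""
        t = self.beat_times_ms[1:]
        return self.hr_bpm[(t >= t_start) & (t < t_end)]


# ---------------------------------------------------------------------------
# FIR design and application


def blackman_fir(cutoff_hz, fs: float, kind: str = "lowpass",
                 transition_hz: float | None = None,
                 max_taps: int | None = None) -> np.ndarray:
    """Blackman-window FIR taps for a lowpass/highpass/bandpass response."""
    lo = np.atleast_1d(cutoff_hz).min()
    if transition_hz is None:
        transition_hz = 0.25 * float(lo) if kind != "highpass" else float(lo)
    numtaps = int(np.ceil(5.5 * fs / transition_hz))
    if max_taps is not None:
        numtaps = min(numtaps, max_taps)
    numtaps |= 1  # odd length -> symmetric, integer group delay
    pass_zero = {"lowpass": True, "highpass": False, "bandpass": False}[kind]
    return sps.firwin(numtaps, cutoff_hz, window="blackman",
                      pass_zero=pass_zero, fs=fs)


def apply_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Zero-phase application of a symmetric FIR kernel (reflect padding)."""
    x = np.asarray(x, dtype=float)
    half = len(taps) // 2
    if half == 0:
        return x * taps[0]
    if len(x) <= 1:
        return x.copy()
    mode = "reflect" if half <= len(x) - 1 else "edge"
    xp = np.pad(x, half, mode=mode)
    return np.convolve(xp, taps, mode="valid")


def lowpass(x: np.ndarray, cutoff_hz: float, fs: float) -> np.ndarray:
    taps = blackman_fir(cutoff_hz, fs, "lowpass", max_taps=2 * len(x) + 1)
    return apply_fir(x, taps)


def highpass(x: np.ndarray, cutoff_hz: float, fs: float) -> np.ndarray:
    taps = blackman_fir(cutoff_hz, fs, "highpass", max_taps=2 * len(x) + 1)
    return apply_fir(x, taps)


def bandpass(x: np.ndarray, lo_hz: float, hi_hz: float, fs: float) -> np.ndarray:
    taps = blackman_fir([lo_hz, hi_hz], fs, "bandpass",
                        transition_hz=0.25 * lo_hz, max_taps=2 * len(x) + 1)
    return apply_fir(x, taps)


def fft_lowpass(x: np.ndarray, cutoff_hz: float, fs: float,
                transition_frac: float = 0.1) -> np.ndarray:
    """Frequency-domain low-pass with a raised-cosine edge (zero phase)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n == 0:
        return x.copy()
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    lo = cutoff_hz * (1 - transition_frac)
    hi = cutoff_hz * (1 + transition_frac)
    gain = np.ones_like(freqs)
    ramp = (freqs > lo) & (freqs < hi)
    gain[ramp] = 0.5 * (1 + np.cos(np.pi * (freqs[ramp] - lo) / (hi - lo)))
    gain[freqs >= hi] = 0.0
    return np.fft.irfft(np.fft.rfft(x) * gain, n=n)


def zscore(x: np.ndarray, ddof: int = 1) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=ddof) if len(x) > ddof else 0.0
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def hampel(x: np.ndarray, half_window: int = 3, n_sigmas: float = 3.0) -> np.ndarray:
    """Hampel outlier replacement: samples further than ``n_sigmas`` scaled
    MADs from the local median are replaced by that median."""
    x = np.asarray(x, dtype=float)
    w = 2 * half_window + 1
    if len(x) < w:
        return x.copy()
    xp = np.pad(x, half_window, mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(xp, w)
    med = np.median(windows, axis=1)
    mad = np.median(np.abs(windows - med[:, None]), axis=1)
    thresh = n_sigmas * 1.4826 * mad
    out = x.copy()
    bad = np.abs(x - med) > thresh
    out[bad] = med[bad]
    return out


# ---------------------------------------------------------------------------
# pupil


def select_pupil(gaze: pd.DataFrame) -> np.ndarray:
    """Per-sample diameter of the eye with the better (lower) validity code.

    Ties go to the left eye. Samples where neither eye was captured are NaN.
    """
    pl = gaze["pupil_left_mm"].to_numpy(float)
    pr = gaze["pupil_right_mm"].to_numpy(float)
    vl = gaze["validity_left"].to_numpy()
    vr = gaze["validity_right"].to_numpy()
    # a missing diameter counts as unusable regardless of the code
    vl = np.where(np.isnan(pl), 5, vl)
    vr = np.where(np.isnan(pr), 5, vr)
    out = np.where(vl <= vr, pl, pr)
    out[np.minimum(vl, vr) >= 5] = np.nan
    return out


def _interp_gaps(x: np.ndarray, t_ms: np.ndarray,
                 max_gap_ms: float) -> tuple[np.ndarray, np.ndarray, bool]:
    """Linear interpolation over NaN gaps; returns (filled, long_gap_mask)."""
    x = np.asarray(x, dtype=float)
    nan = np.isnan(x)
    if not nan.any():
        return x.copy(), np.zeros(len(x), dtype=bool), False
    if nan.all():
        return np.zeros_like(x), np.ones(len(x), dtype=bool), True
    idx = np.arange(len(x))
    filled = x.copy()
    filled[nan] = np.interp(idx[nan], idx[~nan], x[~nan])
    # flag gaps longer than the interpolation limit
    long_mask = np.zeros(len(x), dtype=bool)
    flagged = False
    i = 0
    while i < len(x):
        if nan[i]:
            j = i
            while j < len(x) and nan[j]:
                j += 1
            t0 = t_ms[i - 1] if i > 0 else t_ms[i]
            t1 = t_ms[j] if j < len(x) else t_ms[j - 1]
            if t1 - t0 > max_gap_ms:
                long_mask[i:j] = True
                flagged = True
            i = j
        else:
            i += 1
    return filled, long_mask, flagged


def clean_pupil(series: np.ndarray, events: np.ndarray, t_ms: np.ndarray,
                rate_hz: float, cutoff_hz: float = 2.0,
                max_gap_ms: float = 1000.0) -> CleanSignal:
    """Excise saccade samples, bridge blink gaps linearly, low-pass at 2 Hz.

    Gaps longer than ``max_gap_ms`` are bridged too but flagged in
    ``stages['long_gap_mask']`` so downstream windows can be marked unusable.
    """
    x = np.asarray(series, dtype=float).copy()
    x[np.asarray(events) == "saccade"] = np.nan  # excised, bridged linearly
    filled, long_mask, flagged = _interp_gaps(x, np.asarray(t_ms, float),
                                              max_gap_ms)
    out = lowpass(filled, cutoff_hz, rate_hz)
    cs = CleanSignal(
        name="pupil", rate_hz=rate_hz, values=out,
        provenance=[
            {"step": "excise_saccades"},
            {"step": "interpolate_gaps", "max_gap_ms": max_gap_ms},
            {"step": "blackman_lowpass", "cutoff_hz": cutoff_hz},
        ],
        stages={"long_gap_mask": long_mask},
    )
    if flagged:
        cs.flags.append("gap_exceeds_max")
    return cs


def pupil_area_baseline(clean: CleanSignal,
                        baseline_diameter_mm: np.ndarray) -> CleanSignal:
    """Diameter -> circular area, baseline-area subtraction, z-score."""
    base = np.asarray(baseline_diameter_mm, dtype=float)
    base = base[~np.isnan(base)]
    if len(base) == 0:
        raise ValueError("pupil baseline segment is empty")
    area = np.pi * (clean.values / 2.0) ** 2
    base_area = float(np.mean(np.pi * (base / 2.0) ** 2))
    corrected = area - base_area
    out = CleanSignal(
        name="pupil_area", rate_hz=clean.rate_hz, values=zscore(corrected),
        provenance=clean.provenance + [
            {"step": "area_from_diameter"},
            {"step": "baseline_subtract", "baseline_area_mm2": base_area},
            {"step": "zscore"},
        ],
        stages={**clean.stages, "area_corrected": corrected},
        flags=list(clean.flags),
    )
    return out


# ---------------------------------------------------------------------------
# EDA


def clean_eda(channel: SensorChannel, cutoff_hz: float = 5.0,
              target_rate_hz: float = 10.0) -> CleanSignal:
    """Low-pass at 5 Hz, decimate to 10 Hz, baseline-correct, z-score.

    ``stages['filtered_decimated']`` keeps the raw-scale (kΩ) series the
    normalized-EDA features are computed from.
    """
    x = np.asarray(channel.values, dtype=float)
    filt = lowpass(x, cutoff_hz, channel.rate_hz)
    prov = [{"step": "blackman_lowpass", "cutoff_hz": cutoff_hz}]
    ratio = channel.rate_hz / target_rate_hz
    if abs(ratio - round(ratio)) < 1e-9:
        dec = filt[:: int(round(ratio))]
        prov.append({"step": "decimate", "factor": int(round(ratio))})
    else:
        up, down = np.round(
            [target_rate_hz * 100, channel.rate_hz * 100]).astype(int)
        g = np.gcd(up, down)
        dec = sps.resample_poly(filt, up // g, down // g)
        prov.append({"step": "resample_poly", "up": int(up // g),
                     "down": int(down // g)})
    base_mean = float(np.mean(channel.baseline)) if len(channel.baseline) else 0.0
    corrected = dec - base_mean
    prov += [{"step": "baseline_subtract", "baseline_mean": base_mean},
             {"step": "zscore"}]
    return CleanSignal(
        name="EDA", rate_hz=target_rate_hz, values=zscore(corrected),
        provenance=prov,
        stages={"filtered_decimated": dec},
    )


def eda_phasic(clean: CleanSignal, half_window: int = 4) -> CleanSignal:
    """Phasic component: signal minus a running median (±4 samples).

    The tonic level is the running median over a 9-sample window (window
    shrinks at the edges); what rides on top of it is the phasic component.
    """
    x = np.asarray(clean.values, dtype=float)
    w = 2 * half_window + 1
    flags = []
    if len(x) < w:
        phasic = np.zeros_like(x)
        flags.append("too_short_for_phasic")
        tonic = x.copy()
    else:
        tonic = np.empty_like(x)
        for i in range(len(x)):
            lo = max(0, i - half_window)
            hi = min(len(x), i + half_window + 1)
            tonic[i] = np.median(x[lo:hi])
        phasic = x - tonic
    return CleanSignal(
        name="EDA_phasic", rate_hz=clean.rate_hz, values=phasic,
        provenance=clean.provenance + [
            {"step": "running_median_tonic", "half_window": half_window,
             "interpretation": "signal minus running median"},
        ],
        stages={"tonic": tonic},
        flags=flags,
    )


# ---------------------------------------------------------------------------
# ECG, PPG, temperature, EEG


def clean_ecg(channel: SensorChannel, cutoff_hz: float = 100.0) -> CleanSignal:
    x = np.asarray(channel.values, dtype=float)
    filt = fft_lowpass(x, cutoff_hz, channel.rate_hz)
    base_mean = float(np.mean(channel.baseline)) if len(channel.baseline) else 0.0
    return CleanSignal(
        name="ECG", rate_hz=channel.rate_hz, values=zscore(filt - base_mean),
        provenance=[
            {"step": "fft_lowpass", "cutoff_hz": cutoff_hz},
            {"step": "baseline_subtract", "baseline_mean": base_mean},
            {"step": "zscore"},
        ],
        stages={"filtered": filt},
    )


def ppg_to_hr(channel: SensorChannel, cutoff_hz: float = 16.0,
              refractory_ms: float = 250.0,
              threshold_frac: float = 0.5) -> HeartRateSeries:
    """Peak-to-peak heart rate from the PPG pulse wave.

    The filtered signal's local maxima above an adaptive threshold
    (``threshold_frac`` × rolling 2 s maximum) and at least ``refractory_ms``
    apart become beats; HR per inter-beat interval is 6000/Δt with Δt in
    hundredths of a second.
    """
    fs = channel.rate_hz
    x = lowpass(np.asarray(channel.values, dtype=float), cutoff_hz, fs)
    x = x - np.median(x)
    win = max(int(2.0 * fs), 1)
    roll_max = maximum_filter1d(x, size=win, mode="nearest")
    peaks, _ = sps.find_peaks(x, distance=max(int(refractory_ms / 1000 * fs), 1))
    peaks = peaks[x[peaks] >= threshold_frac * roll_max[peaks]]
    beat_times = peaks / fs * 1000.0
    if len(beat_times) < 2:
        return HeartRateSeries(beat_times_ms=beat_times,
                               hr_bpm=np.empty(0))
    dt_cs = np.diff(beat_times) / 10.0  # ms -> hundredths of a second
    hr = 6000.0 / dt_cs
    return HeartRateSeries(beat_times_ms=beat_times, hr_bpm=hr)


def clean_temp(channel: SensorChannel, cutoff_hz: float = 1.0) -> CleanSignal:
    x = np.asarray(channel.values, dtype=float)
    filt = lowpass(x, cutoff_hz, channel.rate_hz)
    base_mean = float(np.mean(channel.baseline)) if len(channel.baseline) else 0.0
    return CleanSignal(
        name="TEMP", rate_hz=channel.rate_hz, values=zscore(filt - base_mean),
        provenance=[
            {"step": "blackman_lowpass", "cutoff_hz": cutoff_hz},
            {"step": "baseline_subtract", "baseline_mean": base_mean},
            {"step": "zscore"},
        ],
        stages={"filtered": filt},
    )


def clean_eeg(channel: SensorChannel, hp_hz: float = 0.5, lp_hz: float = 40.0,
              hampel_half_window: int = 3,
              hampel_sigmas: float = 3.0) -> CleanSignal:
    x = np.asarray(channel.values, dtype=float)
    filt = highpass(x, hp_hz, channel.rate_hz)
    filt = lowpass(filt, lp_hz, channel.rate_hz)
    filt = hampel(filt, hampel_half_window, hampel_sigmas)
    base_mean = float(np.mean(channel.baseline)) if len(channel.baseline) else 0.0
    return CleanSignal(
        name=channel.name, rate_hz=channel.rate_hz,
        values=zscore(filt - base_mean),
        provenance=[
            {"step": "blackman_highpass", "cutoff_hz": hp_hz},
            {"step": "blackman_lowpass", "cutoff_hz": lp_hz},
            {"step": "hampel", "half_window": hampel_half_window,
             "n_sigmas": hampel_sigmas},
            {"step": "baseline_subtract", "baseline_mean": base_mean},
            {"step": "zscore"},
        ],
        stages={"filtered": filt},
    )
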