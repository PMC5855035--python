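"""Per-window feature extraction: 44 features across six modalities.

The canonical feature vector is partitioned as
2 (pupil) + 6 (EDA incl. phasic) + 2 (temperature) + 3 (ECG) + 3 (PPG-HR)
+ 28 (14 EEG channels × power & phase). Signals are standardized
(``(x − μ)/σ``, sample sd) before spectral features; variance-type features
use the sample (n−1) denominator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import preprocess as pp
from .preprocess import CleanSignal, HeartRateSeries, bandpass
from .session import EEG_LABELS, Session
from .windowing import Window

PUPIL_FEATURES = ("pupil_mean_area", "pupil_var_area")
EDA_FEATURES = ("eda_accumulated", "eda_average", "eda_spectral_power",
                "phasic_mean", "phasic_max_abs", "phasic_n_peaks")
TEMP_FEATURES = ("temp_mean", "temp_median")
ECG_FEATURES = ("ecgmad_mean", "ecgmad_median", "ecgmad_var")
HR_FEATURES = ("hr_mean", "hr_sd", "hr_rms")
EEG_FEATURES = tuple(
    f"eeg_{kind}_{ch}" for ch in EEG_LABELS for kind in ("power", "phase"))

FEATURE_NAMES: tuple[str, ...] = (
    PUPIL_FEATURES + EDA_FEATURES + TEMP_FEATURES + ECG_FEATURES
    + HR_FEATURES + EEG_FEATURES
)
assert len(FEATURE_NAMES) == 44

#: feature names by sensor group, as used for per-sensor ablations
SENSOR_GROUPS: dict[str, tuple[str, ...]] = {
    "pupil": PUPIL_FEATURES,
    "EDA": EDA_FEATURES,
    "T": TEMP_FEATURES,
    "ECG": ECG_FEATURES,
    "PPG": HR_FEATURES,
    "EEG": EEG_FEATURES,
}


def standardize(x: np.ndarray) -> np.ndarray:
    """Classical (x − μ)/σ with the sample sd; constant input -> zeros."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return np.zeros_like(x)
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# modality features


def eda_features(window_raw: np.ndarray, grand_mean: float) -> tuple[float, float, float]:
    """Normalized-EDA accumulation, time-average and AC spectral power.

    ``window_raw`` is the filtered, decimated raw-scale EDA inside the
    window; ``grand_mean`` is the mean of that series over all task
    segments of the session. The normalized signal is EDA(t)/grand_mean, so
    the features are invariant to linear rescaling of the raw channel.
    Spectral power is the periodogram sum of the standardized window with
    the zero-frequency bin excluded.
    """
    if grand_mean == 0:
        raise ValueError("grand mean of EDA is zero — unphysical input")
    w = np.asarray(window_raw, dtype=float)
    if len(w) == 0:
        return (np.nan, np.nan, np.nan)
    normalized = w / grand_mean
    accumulated = float(np.sum(normalized))
    average = accumulated / len(w)
    if len(w) < 2:
        power = 0.0
    else:
        _, pxx = sps.periodogram(standardize(w))
        power = float(np.sum(pxx[1:]))
    return accumulated, average, power


def phasic_features(phasic_window: np.ndarray,
                    peak_threshold: float = 0.01) -> tuple[int, float, float]:
    """(number of peaks, maximum modulus, mean) of the phasic component."""
    w = np.asarray(phasic_window, dtype=float)
    if len(w) == 0:
        return (0, np.nan, np.nan)
    peaks, _ = sps.find_peaks(w, height=peak_threshold)
    return int(len(peaks)), float(np.max(np.abs(w))), float(np.mean(w))


def ecg_features(window: np.ndarray) -> tuple[float, float, float]:
    """Mean, median and variance of the per-sample absolute deviation of the
    ECG from its window median."""
    w = np.asarray(window, dtype=float)
    if len(w) == 0:
        return (np.nan, np.nan, np.nan)
    mad = np.abs(w - np.median(w))
    var = float(mad.var(ddof=1)) if len(mad) > 1 else 0.0
    return float(np.mean(mad)), float(np.median(mad)), var


def hr_features(hr_values: np.ndarray) -> tuple[float, float, float]:
    """Mean, sample sd and root mean square of per-interval heart rate.

    Fewer than two beats in the window leave the heart rate undefined; the
    features are NaN and the window is flagged by the caller.
    """
    v = np.asarray(hr_values, dtype=float)
    if len(v) < 1:
        return (np.nan, np.nan, np.nan)
    sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
    return float(v.mean()), sd, float(np.sqrt(np.mean(v ** 2)))


def temp_features(window: np.ndarray) -> tuple[float, float]:
    w = np.asarray(window, dtype=float)
    if len(w) == 0:
        return (np.nan, np.nan)
    return float(np.mean(w)), float(np.median(w))


def eeg_analytic(values: np.ndarray, rate_hz: float,
                 band: tuple[float, float] = (2.0, 15.0)) -> np.ndarray:
    """Band-limited analytic signal (2–15 Hz band, Hilbert transform)."""
    x = bandpass(np.asarray(values, dtype=float), band[0], band[1], rate_hz)
    return sps.hilbert(x)


def eeg_features_from_analytic(analytic_window: np.ndarray) -> tuple[float, float]:
    """Mean squared envelope and circular-mean instantaneous phase."""
    a = np.asarray(analytic_window)
    if len(a) == 0:
        return (np.nan, np.nan)
    power = float(np.mean(np.abs(a) ** 2))
    phase = float(np.angle(np.mean(np.exp(1j * np.angle(a)))))
    return power, phase


def eeg_features(window_values: np.ndarray, rate_hz: float,
                 band: tuple[float, float] = (2.0, 15.0)) -> tuple[float, float]:
    """Power and phase of the analytic signal of one EEG window."""
    return eeg_features_from_analytic(eeg_analytic(window_values, rate_hz, band))


# ---------------------------------------------------------------------------
# assembly


@dataclass
class SessionSignals:
    """Everything the feature layer needs for one session."""

    pupil: CleanSignal | None = None     # z-scored baseline-corrected area
    pupil_t_ms: np.ndarray | None = None
    eda: CleanSignal | None = None       # with stage "filtered_decimated"
    phasic: CleanSignal | None = None
    temp: CleanSignal | None = None
    ecg: CleanSignal | None = None
    hr: HeartRateSeries | None = None
    eeg_analytic: dict[str, np.ndarray] | None = None  # label -> analytic
    eeg_rate_hz: float = 128.0


def prepare_signals(session: Session) -> SessionSignals:
    """Run every available channel through its conditioning chain."""
    sig = SessionSignals()

    task = session.gaze_task()
    if len(task):
        series = pp.select_pupil(task)
        rate = 1000.0 / float(np.median(np.diff(task["t"].to_numpy())))
        clean = pp.clean_pupil(series, task["event"].to_numpy(),
                               task["t"].to_numpy(), rate)
        base = pp.select_pupil(session.gaze_baseline())
        sig.pupil = pp.pupil_area_baseline(clean, base)
        sig.pupil_t_ms = task["t"].to_numpy(float)

    ch = session.channel("EDA")
    if ch is not None:
        sig.eda = pp.clean_eda(ch)
        sig.phasic = pp.eda_phasic(sig.eda)
    ch = session.channel("TEMP")
    if ch is not None:
        sig.temp = pp.clean_temp(ch)
    ch = session.channel("ECG")
    if ch is not None:
        sig.ecg = pp.clean_ecg(ch)
    ch = session.channel("PPG")
    if ch is not None:
        sig.hr = pp.ppg_to_hr(ch)
    eeg = session.eeg_channels
    if eeg:
        sig.eeg_analytic = {}
        for c in eeg:
            label = c.name.split(":", 1)[1]
            cleaned = pp.clean_eeg(c)
            sig.eeg_analytic[label] = eeg_analytic(cleaned.values, c.rate_hz)
            sig.eeg_rate_hz = c.rate_hz
    return sig


def _slice_rate(values: np.ndarray, rate_hz: float, w: Window) -> np.ndarray:
    i0 = int(np.ceil(w.t_start * rate_hz / 1000.0))
    i1 = int(np.ceil(w.t_end * rate_hz / 1000.0))
    return values[max(i0, 0):max(i1, 0)]


def assemble(window: Window, signals: SessionSignals,
             phasic_peak_threshold: float = 0.01) -> pd.Series:
    """The 44-entry feature vector of one window (absent modalities NaN)."""
    out: dict[str, float] = dict.fromkeys(FEATURE_NAMES, np.nan)

    if signals.pupil is not None:
        t = signals.pupil_t_ms
        m = (t >= window.t_start) & (t < window.t_end)
        w = signals.pupil.values[m]
        if len(w):
            out["pupil_mean_area"] = float(np.mean(w))
            out["pupil_var_area"] = float(w.var(ddof=1)) if len(w) > 1 else 0.0

    if signals.eda is not None:
        raw = signals.eda.stages["filtered_decimated"]
        grand_mean = float(np.mean(raw))
        acc, avg, power = eda_features(
            _slice_rate(raw, signals.eda.rate_hz, window), grand_mean)
        out["eda_accumulated"], out["eda_average"] = acc, avg
        out["eda_spectral_power"] = power
    if signals.phasic is not None:
        n, mx, mean = phasic_features(
            _slice_rate(signals.phasic.values, signals.phasic.rate_hz, window),
            phasic_peak_threshold)
        out["phasic_n_peaks"], out["phasic_max_abs"], out["phasic_mean"] = n, mx, mean

    if signals.temp is not None:
        out["temp_mean"], out["temp_median"] = temp_features(
            _slice_rate(signals.temp.values, signals.temp.rate_hz, window))

    if signals.ecg is not None:
        m_, md, var = ecg_features(
            _slice_rate(signals.ecg.values, signals.ecg.rate_hz, window))
        out["ecgmad_mean"], out["ecgmad_median"], out["ecgmad_var"] = m_, md, var

    if signals.hr is not None:
        out["hr_mean"], out["hr_sd"], out["hr_rms"] = hr_features(
            signals.hr.in_window(window.t_start, window.t_end))

    if signals.eeg_analytic is not None:
        for label, analytic in signals.eeg_analytic.items():
            p, ph = eeg_features_from_analytic(
                _slice_rate(analytic, signals.eeg_rate_hz, window))
            out[f"eeg_power_{label}"] = p
            out[f"eeg_phase_{label}"] = ph

    return pd.Series(out, index=list(FEATURE_NAMES), dtype=float)


def extract_features(windows: list[Window], signals: SessionSignals,
                     participant_id: str = "",
                     phasic_peak_threshold: float = 0.01) -> pd.DataFrame:
    """One row of window metadata + 44 features per window."""
    rows = []
    for i, w in enumerate(windows):
        vec = assemble(w, signals, phasic_peak_threshold)
        meta = pd.Series({
            "participant_id": participant_id, "window_index": i,
            "kind": w.kind, "t_start": w.t_start, "t_end": w.t_end,
            "aoi_id": w.aoi_id,
        })
        rows.append(pd.concat([meta, vec]))
    cols = ["participant_id", "window_index", "kind", "t_start", "t_end",
            "aoi_id"] + list(FEATURE_NAMES)
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
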