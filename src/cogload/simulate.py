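"""Synthetic multi-sensor browsing sessions with known workload structure.

The generator emulates the study conditions the pipeline is built for: a
participant freely browsing a news-page layout while six streams are
recorded — gaze/pupillometry at 120 Hz, EDA at 120 Hz (kΩ), PPG at 120 Hz
(mV), axillary temperature at 50 Hz (°C), ECG at 1000 Hz (mV) and 14 EEG
channels at 128 Hz (µV) — each preceded by a 500 ms pre-stimulus baseline.

Latent structure: the session is tiled by alternating *active* windows
(fixations inside one area of interest) and *transition* windows (gaze
between elements). Each window carries a workload level k in 1..K_true.
The level drives

* a standardized pupil-diameter shift (level means, within-level spread),
  with a configurable decrement during transition windows,
* EEG alpha suppression and theta enhancement,
* phasic EDA event rate,
* heart-rate modulation shared by ECG and PPG.

Everything is deterministic given ``(seed, participant_index)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session import (
    AoI,
    DEFAULT_RATES,
    DEFAULT_UNITS,
    EEG_LABELS,
    GAZE_COLUMNS,
    SensorChannel,
    Session,
)

ALL_CHANNELS = ("EDA", "PPG", "TEMP", "ECG", "EEG")


def default_layout(width: int = 1280, height: int = 1024) -> tuple[AoI, ...]:
    """Seven news items, four advertisements and a menu bar on one screen.

    Rectangles are separated by gutters so that between-element gaze points
    fall outside every AoI.
    """
    aois = [AoI("menu", (20.0, 10.0, width - 20.0, 70.0))]
    # news in two columns on the left 2/3 of the page
    col_w, row_h = 360.0, 200.0
    k = 0
    for row in range(4):
        for col in range(2):
            if k >= 7:
                break
            x0 = 30.0 + col * (col_w + 40.0)
            y0 = 100.0 + row * (row_h + 30.0)
            aois.append(AoI(f"news{k + 1}", (x0, y0, x0 + col_w, y0 + row_h)))
            k += 1
    # ads stacked on the right
    for j in range(4):
        y0 = 100.0 + j * (190.0 + 35.0)
        aois.append(AoI(f"ad{j + 1}", (860.0, y0, 1240.0, y0 + 190.0)))
    return tuple(aois)


@dataclass
class SimulationConfig:
    """Generator parameters. Defaults mirror the emulated study conditions."""

    seed: int = 0
    n_participants: int = 53
    session_duration_s: float = 3600.0
    layout: tuple[AoI, ...] = field(default_factory=default_layout)
    screen: tuple[int, int] = (1280, 1024)
    channels: tuple[str, ...] = ALL_CHANNELS  # empty tuple -> gaze only

    # latent workload structure
    level_shifts: tuple[float, ...] = (-1.5, -0.5, 0.5, 1.5)  # standardized
    level_spread: float = 0.25      # within-level per-window sd (standardized)
    transition_effect: float = 0.5  # standardized pupil decrement in transitions

    # gaze stream
    gaze_rate_hz: float = 120.0
    active_duration_s: tuple[float, float] = (2.5, 1.0)   # lognormal mean, sd
    transition_duration_s: tuple[float, float] = (1.0, 0.4)
    fixation_duration_ms: tuple[float, float] = (300.0, 100.0)
    saccade_duration_ms: tuple[float, float] = (40.0, 10.0)
    blink_rate_hz: float = 0.1
    blink_duration_ms: tuple[float, float] = (100.0, 300.0)
    p_eye_degraded: float = 0.01    # per-sample chance of a worse validity code

    # pupil signal
    pupil_base_mm: tuple[float, float] = (3.5, 0.3)  # cohort mean, between-subject sd
    pupil_scale_mm: float = 0.25    # mm per standardized unit
    pupil_noise_mm: float = 0.05    # smooth physiological noise (sd)
    pupil_lag_ms: float = 300.0     # low-pass lag of the pupil response
    eye_noise_mm: float = 0.01      # independent per-eye measurement noise

    # cardiovascular
    hr_base_bpm: float = 72.0
    hr_level_gain_bpm: float = 5.0  # bpm swing from lowest to highest level
    ibi_jitter: float = 0.02        # multiplicative inter-beat jitter (sd)

    # electrodermal
    eda_base_kohm: float = 400.0
    eda_tonic_drift: float = 20.0   # kΩ span of the slow tonic drift
    phasic_event_rate: float = 0.05  # base events/s, scaled up with level
    phasic_amp_kohm: tuple[float, float] = (2.0, 8.0)
    eda_noise_kohm: float = 0.2

    # temperature
    temp_base_c: float = 36.5
    temp_drift_c: float = 0.3
    temp_noise_c: float = 0.01

    # EEG
    eeg_alpha_uv: float = 20.0
    eeg_theta_uv: float = 10.0
    eeg_alpha_mod: float = 0.5      # fractional alpha suppression at top level
    eeg_theta_mod: float = 0.5      # fractional theta increase at top level
    eeg_noise_uv: float = 10.0

    baseline_ms: float = 500.0

    def __post_init__(self) -> None:
        if len(self.level_shifts) < 2:
            raise ValueError("need K_true >= 2 workload levels")
        if self.transition_effect < 0:
            raise ValueError("transition_effect must be >= 0")
        if self.session_duration_s <= 0 or self.gaze_rate_hz <= 0:
            raise ValueError("durations and rates must be > 0")

    @property
    def k_true(self) -> int:
        return len(self.level_shifts)


@dataclass
class GroundTruth:
    """Latent state underlying one simulated session."""

    windows: pd.DataFrame          # t_start, t_end, kind, aoi_id, level
    beat_times_ms: np.ndarray      # true heartbeat instants
    eda_event_times_ms: np.ndarray  # true phasic-event onsets


def _smooth(x: np.ndarray, rate_hz: float, tau_s: float,
            rng_pad: float = 0.0) -> np.ndarray:
    """Gaussian smoothing used for drifts and the pupil response lag."""
    if tau_s <= 0:
        return x
    sigma = max(tau_s * rate_hz, 1e-9)
    half = int(np.ceil(4 * sigma))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
    k /= k.sum()
    xp = np.pad(x, half, mode="edge")
    return np.convolve(xp, k, mode="valid")


def _window_schedule(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Alternating active/transition windows tiling [0, duration)."""
    total_ms = cfg.session_duration_s * 1000.0
    rows = []
    t = 0.0
    active = bool(rng.integers(0, 2))
    aoi_ids = [a.id for a in cfg.layout]
    k_true = cfg.k_true
    level = int(rng.integers(1, k_true + 1))
    while t < total_ms:
        if active:
            mu, sd = cfg.active_duration_s
        else:
            mu, sd = cfg.transition_duration_s
        # lognormal with the requested mean/sd, floored at 600 ms so that
        # windows survive the 500 ms validity rule
        s2 = np.log(1 + (sd / mu) ** 2)
        dur = float(rng.lognormal(np.log(mu) - s2 / 2, np.sqrt(s2))) * 1000.0
        dur = max(dur, 600.0)
        t_end = min(t + dur, total_ms)
        rows.append({
            "t_start": t, "t_end": t_end,
            "kind": "active" if active else "transition",
            "aoi_id": rng.choice(aoi_ids) if active else "",
            "level": level,
        })
        t = t_end
        active = not active
        # levels persist across the active/transition pair with prob 1/2
        if rng.random() < 0.5:
            level = int(rng.integers(1, k_true + 1))
    return pd.DataFrame(rows)


def _point_in_aoi(rng: np.random.Generator, aoi: AoI) -> tuple[float, float]:
    x0, y0, x1, y1 = aoi.rect
    mx, my = 0.1 * (x1 - x0), 0.1 * (y1 - y0)
    return (float(rng.uniform(x0 + mx, x1 - mx)),
            float(rng.uniform(y0 + my, y1 - my)))


def _point_outside(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[float, float]:
    w, h = cfg.screen
    for _ in range(200):
        x, y = float(rng.uniform(0, w)), float(rng.uniform(0, h))
        if not any(a.contains(x, y) for a in cfg.layout):
            return x, y
    return 0.0, float(h - 1)  # layouts always leave the bottom strip free


def _trunc_normal(rng: np.random.Generator, mu: float, sd: float,
                  lo: float) -> float:
    return max(float(rng.normal(mu, sd)), lo)


def _gaze_stream(cfg: SimulationConfig, windows: pd.DataFrame,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Fixation/saccade alternation consistent with the window schedule."""
    period = 1000.0 / cfg.gaze_rate_hz
    n_base = int(round(cfg.baseline_ms / period))
    total_ms = cfg.session_duration_s * 1000.0
    n_task = int(round(total_ms / period))
    t_ms = np.round((np.arange(-n_base, n_task)) * period).astype(np.int64)

    n = len(t_ms)
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    event = np.array(["unknown"] * n, dtype=object)
    aoi_hit = np.array(["off-screen"] * n, dtype=object)

    aoi_by_id = {a.id: a for a in cfg.layout}

    # fixation targets laid out window by window (baseline treated as one
    # outside-AoI dwell)
    segs = [(-cfg.baseline_ms, 0.0, "transition", "")]
    segs += [(r.t_start, r.t_end, r.kind, r.aoi_id)
             for r in windows.itertuples(index=False)]

    events_list: list[tuple[float, float, float, float, str]] = []
    for t0, t1, kind, aoi_id in segs:
        t = t0
        while t < t1:
            fdur = _trunc_normal(rng, *cfg.fixation_duration_ms, 80.0)
            fdur = min(fdur, t1 - t)
            if kind == "active":
                px, py = _point_in_aoi(rng, aoi_by_id[aoi_id])
            else:
                px, py = _point_outside(cfg, rng)
            events_list.append((t, min(t + fdur, t1), px, py, "fixation"))
            t += fdur
            if t >= t1:
                break
            sdur = _trunc_normal(rng, *cfg.saccade_duration_ms, 15.0)
            if t + sdur + 80.0 >= t1:
                # leave no room for a truncated saccade or a sliver of a
                # fixation at the boundary: extend the final fixation instead
                t0_, _, px_, py_, kind_ = events_list[-1]
                events_list[-1] = (t0_, t1, px_, py_, kind_)
                break
            events_list.append((t, t + sdur, px, py, "saccade"))
            t += sdur

    # rasterize fixations/saccades onto the sample grid (vectorized)
    ev_t0 = np.array([e[0] for e in events_list])
    ev_t1 = np.array([e[1] for e in events_list])
    ev_px = np.array([e[2] for e in events_list])
    ev_py = np.array([e[3] for e in events_list])
    ev_kind = np.array([e[4] for e in events_list], dtype=object)
    idx = np.clip(np.searchsorted(ev_t0, t_ms, side="right") - 1, 0,
                  len(events_list) - 1)
    x[:] = ev_px[idx]
    y[:] = ev_py[idx]
    event[:] = ev_kind[idx]
    event[t_ms >= ev_t1[idx]] = "saccade"  # truncated tails
    # saccade samples travel linearly towards the next fixation point
    sac = np.flatnonzero(event == "saccade")
    if len(sac):
        j = idx[sac]
        nxt = np.minimum(j + 1, len(events_list) - 1)
        t0 = ev_t0[j]
        t1 = np.where(nxt > j, ev_t0[nxt], ev_t1[j])
        frac = np.clip((t_ms[sac] - t0) / np.maximum(t1 - t0, 1e-9), 0.0, 1.0)
        x[sac] = ev_px[j] + frac * (ev_px[nxt] - ev_px[j])
        y[sac] = ev_py[j] + frac * (ev_py[nxt] - ev_py[j])

    # blinks: gaps with missing coordinates and pupils
    blink = np.zeros(n, dtype=bool)
    t_cursor = float(t_ms[0])
    end = float(t_ms[-1])
    while True:
        t_cursor += rng.exponential(1000.0 / max(cfg.blink_rate_hz, 1e-12))
        if t_cursor >= end:
            break
        bdur = rng.uniform(*cfg.blink_duration_ms)
        blink |= (t_ms >= t_cursor) & (t_ms < t_cursor + bdur)
        t_cursor += bdur

    # latent standardized pupil drive, sampled on the gaze grid
    w_start = windows["t_start"].to_numpy()
    shifts = np.asarray(cfg.level_shifts)
    wi = np.clip(np.searchsorted(w_start, t_ms, side="right") - 1, 0,
                 len(windows) - 1)
    lvl = windows["level"].to_numpy()[wi]
    kind_arr = windows["kind"].to_numpy()[wi]
    drive = shifts[lvl - 1].astype(float)
    drive[kind_arr == "transition"] -= cfg.transition_effect
    drive[t_ms < 0] = 0.0  # neutral pre-stimulus pupil
    # per-window random offset (within-level spread)
    offsets = rng.normal(0.0, cfg.level_spread, size=len(windows))
    drive = drive + offsets[wi] * (t_ms >= 0)

    d0 = _trunc_normal(rng, *cfg.pupil_base_mm, 2.0)
    lagged = _smooth(drive, cfg.gaze_rate_hz, cfg.pupil_lag_ms / 1000.0 / 2.0)
    noise = _smooth(rng.standard_normal(n), cfg.gaze_rate_hz, 0.2)
    noise *= cfg.pupil_noise_mm / max(noise.std(), 1e-12)
    diam = d0 + cfg.pupil_scale_mm * lagged + noise

    pl = diam + rng.normal(0.0, cfg.eye_noise_mm, n)
    pr = diam + rng.normal(0.0, cfg.eye_noise_mm, n)
    vl = np.zeros(n, dtype=np.int64)
    vr = np.zeros(n, dtype=np.int64)
    for v in (vl, vr):
        bad = rng.random(n) < cfg.p_eye_degraded
        v[bad] = rng.integers(1, 5, bad.sum())
    pl[vl == 4] = np.nan
    pr[vr == 4] = np.nan

    x[blink] = np.nan
    y[blink] = np.nan
    pl[blink] = np.nan
    pr[blink] = np.nan
    vl[blink] = 4
    vr[blink] = 4
    event[blink] = "blink"

    # AoI hit column, as the eye-tracker software would export it
    on = ~np.isnan(x)
    aoi_hit[on] = "outside"
    for a in cfg.layout:
        x0, y0, x1, y1 = a.rect
        inside = on & (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
        aoi_hit[inside] = a.id

    return pd.DataFrame({
        "t": t_ms, "x": x, "y": y,
        "pupil_left_mm": pl, "validity_left": vl,
        "pupil_right_mm": pr, "validity_right": vr,
        "event": event, "aoi_hit": aoi_hit,
    }, columns=list(GAZE_COLUMNS))


def _level_series(cfg: SimulationConfig, windows: pd.DataFrame,
                  rate_hz: float, n_base: int, n_task: int) -> np.ndarray:
    """Per-sample workload intensity u in [0, 1] on an arbitrary grid."""
    t = (np.arange(-n_base, n_task)) / rate_hz * 1000.0
    w_start = windows["t_start"].to_numpy()
    wi = np.clip(np.searchsorted(w_start, t, side="right") - 1, 0,
                 len(windows) - 1)
    lvl = windows["level"].to_numpy()[wi].astype(float)
    u = (lvl - 1.0) / max(cfg.k_true - 1, 1)
    u[t < 0] = 0.5
    return u


def _beats(cfg: SimulationConfig, windows: pd.DataFrame,
           rng: np.random.Generator) -> np.ndarray:
    """Heartbeat times (ms) from -baseline to session end."""
    t = -cfg.baseline_ms
    end = cfg.session_duration_s * 1000.0
    w_start = windows["t_start"].to_numpy()
    lvl = windows["level"].to_numpy().astype(float)
    u_of = lambda tt: 0.5 if tt < 0 else (
        (lvl[min(max(np.searchsorted(w_start, tt, side="right") - 1, 0),
                 len(lvl) - 1)] - 1.0) / max(cfg.k_true - 1, 1))
    beats = []
    while t < end:
        hr = cfg.hr_base_bpm + cfg.hr_level_gain_bpm * (u_of(t) - 0.5)
        ibi = 60000.0 / hr * float(np.exp(rng.normal(0.0, cfg.ibi_jitter)))
        t += ibi
        if t < end:
            beats.append(t)
    return np.asarray(beats)


def _pulse_train(beats_ms: np.ndarray, rate_hz: float, n_base: int,
                 n_task: int, width_ms: float, amp: float) -> np.ndarray:
    """Sum of raised-cosine pulses centred on the beat times."""
    t = (np.arange(-n_base, n_task)) / rate_hz * 1000.0
    out = np.zeros(len(t))
    half = width_ms / 2.0
    step = 1000.0 / rate_hz
    for b in beats_ms:
        i0 = int(np.floor((b - half - t[0]) / step))
        i1 = int(np.ceil((b + half - t[0]) / step)) + 1
        i0, i1 = max(i0, 0), min(i1, len(t))
        if i0 >= i1:
            continue
        phase = (t[i0:i1] - b) / half
        out[i0:i1] += amp * 0.5 * (1 + np.cos(np.pi * np.clip(phase, -1, 1)))
    return out


def simulate_session(cfg: SimulationConfig,
                     participant_index: int) -> tuple[Session, GroundTruth]:
    """Generate one participant's session plus its latent ground truth."""
    rng = np.random.default_rng(
        np.random.SeedSequence((int(cfg.seed), int(participant_index))))
    windows = _window_schedule(cfg, rng)
    gaze = _gaze_stream(cfg, windows, rng)

    channels: dict[str, SensorChannel] = {}
    beats = np.empty(0)
    eda_events = np.empty(0)
    want = set(cfg.channels)

    if want & {"ECG", "PPG"}:
        beats = _beats(cfg, windows, rng)

    dur = cfg.session_duration_s

    if "EDA" in want:
        rate = DEFAULT_RATES["EDA"]
        n_base = int(round(cfg.baseline_ms / 1000.0 * rate))
        n_task = int(round(dur * rate))
        n = n_base + n_task
        drift = _smooth(np.cumsum(rng.standard_normal(n)), rate, 10.0)
        drift = (drift - drift.mean())
        drift *= cfg.eda_tonic_drift / max(np.ptp(drift), 1e-12) if np.ptp(drift) else 0.0
        u = _level_series(cfg, windows, rate, n_base, n_task)
        # phasic events: Poisson thinning, rate grows with workload level
        t_axis = (np.arange(-n_base, n_task)) / rate * 1000.0
        lam_max = cfg.phasic_event_rate * 2.0
        t_cursor, ev = -cfg.baseline_ms, []
        while True:
            t_cursor += rng.exponential(1000.0 / max(lam_max, 1e-12))
            if t_cursor >= dur * 1000.0:
                break
            i = min(int((t_cursor + cfg.baseline_ms) / 1000.0 * rate), n - 1)
            if rng.random() < (0.5 + u[i]) / 1.5:
                ev.append(t_cursor)
        eda_events = np.asarray(ev)
        phasic = np.zeros(n)
        tau_r, tau_d = 700.0, 3000.0
        for t0 in eda_events:
            amp = rng.uniform(*cfg.phasic_amp_kohm)
            rel = t_axis - t0
            m = rel >= 0
            shape = np.exp(-rel[m] / tau_d) - np.exp(-rel[m] / tau_r)
            phasic[m] -= amp * shape / max(shape.max(), 1e-12)
        vals = (cfg.eda_base_kohm + drift + phasic
                + rng.normal(0.0, cfg.eda_noise_kohm, n))
        channels["EDA"] = SensorChannel("EDA", rate, DEFAULT_UNITS["EDA"],
                                        vals[n_base:], vals[:n_base])

    if "PPG" in want:
        rate = DEFAULT_RATES["PPG"]
        n_base = int(round(cfg.baseline_ms / 1000.0 * rate))
        n_task = int(round(dur * rate))
        vals = _pulse_train(beats, rate, n_base, n_task, 320.0, 1.0)
        vals = vals + rng.normal(0.0, 0.02, len(vals))
        channels["PPG"] = SensorChannel("PPG", rate, DEFAULT_UNITS["PPG"],
                                        vals[n_base:], vals[:n_base])

    if "ECG" in want:
        rate = DEFAULT_RATES["ECG"]
        n_base = int(round(cfg.baseline_ms / 1000.0 * rate))
        n_task = int(round(dur * rate))
        vals = _pulse_train(beats, rate, n_base, n_task, 24.0, 1.0)
        vals = vals - 0.15 * _pulse_train(beats, rate, n_base, n_task, 90.0, 1.0)
        vals = vals + rng.normal(0.0, 0.01, len(vals))
        channels["ECG"] = SensorChannel("ECG", rate, DEFAULT_UNITS["ECG"],
                                        vals[n_base:], vals[:n_base])

    if "TEMP" in want:
        rate = DEFAULT_RATES["TEMP"]
        n_base = int(round(cfg.baseline_ms / 1000.0 * rate))
        n_task = int(round(dur * rate))
        n = n_base + n_task
        drift = _smooth(np.cumsum(rng.standard_normal(n)), rate, 30.0)
        drift -= drift[0]
        span = np.ptp(drift)
        if span > 0:
            drift *= cfg.temp_drift_c / span
        vals = (cfg.temp_base_c + drift
                + _smooth(rng.normal(0.0, cfg.temp_noise_c * 3, n), rate, 0.5))
        channels["TEMP"] = SensorChannel("TEMP", rate, DEFAULT_UNITS["TEMP"],
                                         vals[n_base:], vals[:n_base])

    if "EEG" in want:
        rate = DEFAULT_RATES["EEG"]
        n_base = int(round(cfg.baseline_ms / 1000.0 * rate))
        n_task = int(round(dur * rate))
        n = n_base + n_task
        u = _level_series(cfg, windows, rate, n_base, n_task)
        t_s = (np.arange(-n_base, n_task)) / rate
        for label in EEG_LABELS:
            pa = float(rng.uniform(0, 2 * np.pi))
            pt = float(rng.uniform(0, 2 * np.pi))
            alpha = (cfg.eeg_alpha_uv * (1.0 - cfg.eeg_alpha_mod * u)
                     * np.sin(2 * np.pi * 10.0 * t_s + pa))
            theta = (cfg.eeg_theta_uv * (1.0 + cfg.eeg_theta_mod * u)
                     * np.sin(2 * np.pi * 6.0 * t_s + pt))
            noise = _smooth(rng.standard_normal(n), rate, 0.01)
            noise *= cfg.eeg_noise_uv / max(noise.std(), 1e-12)
            vals = alpha + theta + noise
            channels[f"EEG:{label}"] = SensorChannel(
                f"EEG:{label}", rate, DEFAULT_UNITS["EEG"],
                vals[n_base:], vals[:n_base])

    session = Session(
        participant_id=f"P{participant_index + 1:02d}",
        gaze=gaze,
        channels=channels,
        layout=cfg.layout,
        task_segments=1,
    )
    truth = GroundTruth(windows=windows, beat_times_ms=beats,
                        eda_event_times_ms=eda_events)
    return session, truth


def simulate_cohort(cfg: SimulationConfig) -> list[tuple[Session, GroundTruth]]:
    """One session per participant, each with its own derived seed."""
    return [simulate_session(cfg, i) for i in range(cfg.n_participants)]


def config_with(cfg: SimulationConfig, **overrides) -> SimulationConfig:
    return dataclasses.replace(cfg, **overrides)
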