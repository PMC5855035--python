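"""Statistical validation and experimental-control checks.

* Repeated-measures ANOVA on the window-type factor (active vs transition)
  applied to participant-mean standardized pupil, testing whether workload
  drops while the gaze travels between page elements.
* Per-participant baseline-correction validation (Shapiro on the paired
  differences, Wilcoxon signed-rank when normality fails).
* Frame-brightness percentage and the EDA variation-rate arousal check used
  to rule out confounds of pupil dilation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sst


@dataclass
class WindowTypeTest:
    f_stat: float
    p_value: float
    group_means: dict[str, float]
    group_sds: dict[str, float]
    n_participants: int
    excluded: list[str] = field(default_factory=list)
    per_participant: pd.DataFrame | None = None


@dataclass
class BaselineCheck:
    shapiro_p: dict[str, float]
    wilcoxon_p: dict[str, float]
    indistinguishable: list[str]    # participants where correction changed nothing
    flags: dict[str, str] = field(default_factory=dict)


def anova_rm_window_type(window_table: pd.DataFrame) -> WindowTypeTest:
    """One-way RM-ANOVA, within factor = window type (active/transition).

    ``window_table`` has one row per window with columns ``participant_id``,
    ``kind`` and ``pupil_mean`` (the window's mean standardized pupil).
    Windows are aggregated to per-participant means per type — the classical
    paired design; participants missing a type are excluded and listed.
    """
    agg = (window_table.groupby(["participant_id", "kind"])["pupil_mean"]
           .mean().reset_index())
    counts = agg.groupby("participant_id")["kind"].nunique()
    excluded = sorted(counts[counts < 2].index.tolist())
    agg = agg[~agg["participant_id"].isin(excluded)]
    wide = agg.pivot(index="participant_id", columns="kind",
                     values="pupil_mean")
    if len(wide) < 2:
        raise ValueError("need at least 2 participants with both window types")

    diffs = wide["active"] - wide["transition"]
    if np.allclose(diffs.var(ddof=1), 0.0):
        if np.allclose(diffs, 0.0):
            f, p = 0.0, 1.0
        else:
            f, p = np.inf, 0.0
    else:
        res = pg.rm_anova(data=agg, dv="pupil_mean", within="kind",
                          subject="participant_id", detailed=True)
        pcol = "p_unc" if "p_unc" in res.columns else "p-unc"
        f = float(res.loc[0, "F"])
        p = float(res.loc[0, pcol])

    means = window_table.groupby("kind")["pupil_mean"].mean().to_dict()
    sds = window_table.groupby("kind")["pupil_mean"].std(ddof=1).to_dict()
    return WindowTypeTest(
        f_stat=f, p_value=p,
        group_means={k: float(v) for k, v in means.items()},
        group_sds={k: float(v) for k, v in sds.items()},
        n_participants=len(wide), excluded=excluded,
        per_participant=wide.reset_index(),
    )


def window_type_permutation(window_table: pd.DataFrame, n_perm: int = 2000,
                            seed: int = 0) -> float:
    """Window-level alternative: permutation p-value for the mean difference
    of standardized pupil between active and transition windows, permuting
    window types within participants."""
    rng = np.random.default_rng(seed)
    obs = (window_table.loc[window_table["kind"] == "active", "pupil_mean"].mean()
           - window_table.loc[window_table["kind"] == "transition",
                              "pupil_mean"].mean())
    count = 0
    groups = [g for _, g in window_table.groupby("participant_id")]
    for _ in range(n_perm):
        parts = []
        for g in groups:
            kinds = g["kind"].to_numpy().copy()
            rng.shuffle(kinds)
            parts.append(pd.DataFrame({"kind": kinds,
                                       "pupil_mean": g["pupil_mean"].to_numpy()}))
        perm = pd.concat(parts)
        stat = (perm.loc[perm["kind"] == "active", "pupil_mean"].mean()
                - perm.loc[perm["kind"] == "transition", "pupil_mean"].mean())
        if abs(stat) >= abs(obs):
            count += 1
    return (count + 1) / (n_perm + 1)


def baseline_validation(raw: dict[str, np.ndarray],
                        corrected: dict[str, np.ndarray],
                        alpha: float = 0.05) -> BaselineCheck:
    """Did baseline correction actually change each participant's signal?

    For every participant the paired differences raw − corrected are tested
    for normality (Shapiro); since correction is a level shift the
    differences are rarely normal-and-centred, so a Wilcoxon signed-rank
    test on the pairs decides whether the two series share a location.
    Participants where the null is retained are listed as indistinguishable.
    """
    shapiro_p: dict[str, float] = {}
    wilcoxon_p: dict[str, float] = {}
    indist: list[str] = []
    flags: dict[str, str] = {}
    for pid in raw:
        a = np.asarray(raw[pid], dtype=float)
        b = np.asarray(corrected[pid], dtype=float)
        d = a - b
        if len(d) < 3:
            flags[pid] = "too_few_samples"
            continue
        sub = d if len(d) <= 5000 else d[:: int(np.ceil(len(d) / 5000))]
        shapiro_p[pid] = float(sst.shapiro(sub).pvalue)
        if np.allclose(d, d[0]):
            if d[0] == 0:
                flags[pid] = "identical_series"
                indist.append(pid)
            else:
                # constant nonzero shift: Wilcoxon defined, p -> 0 as n grows
                wilcoxon_p[pid] = float(
                    sst.wilcoxon(np.full(len(d), d[0])).pvalue)
            continue
        wilcoxon_p[pid] = float(sst.wilcoxon(d).pvalue)
        if wilcoxon_p[pid] >= alpha:
            indist.append(pid)
    return BaselineCheck(shapiro_p=shapiro_p, wilcoxon_p=wilcoxon_p,
                         indistinguishable=sorted(indist), flags=flags)


def frame_brightness(frames: np.ndarray | list[np.ndarray]) -> np.ndarray:
    """Per-frame brightness: mean grayscale pixel / 255 × 100 (%)."""
    out = []
    for f in frames:
        f = np.asarray(f, dtype=float)
        if f.size == 0:
            raise ValueError("empty frame")
        if f.min() < 0 or f.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")
        out.append(f.mean() / 255.0 * 100.0)
    return np.asarray(out)


def eda_variation_rate(clean_eda: np.ndarray, rate_hz: float,
                       window_ms: float = 500.0,
                       arousal_band: tuple[float, float] = (3.0, 4.5),
                       ) -> tuple[float, float, bool]:
    """Percent change of mean EDA between consecutive 500 ms windows.

    Returns (mean %, sd %, arousal_flag); the flag raises when the mean
    rate magnitude reaches the 3–4.5% band associated with genuinely
    arousing content.
    """
    x = np.asarray(clean_eda, dtype=float)
    n_win = max(int(rate_hz * window_ms / 1000.0), 1)
    n_blocks = len(x) // n_win
    if n_blocks < 2:
        raise ValueError("EDA series shorter than two windows")
    means = x[: n_blocks * n_win].reshape(n_blocks, n_win).mean(axis=1)
    prev = means[:-1]
    if np.any(prev == 0):
        raise ValueError("zero-mean EDA window; variation rate undefined")
    rates = (means[1:] - prev) / prev * 100.0
    mean_rate = float(rates.mean())
    sd_rate = float(rates.std(ddof=1)) if len(rates) > 1 else 0.0
    flag = abs(mean_rate) >= arousal_band[0]
    return mean_rate, sd_rate, flag
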