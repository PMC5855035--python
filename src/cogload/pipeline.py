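"""End-to-end orchestration: simulate → window → features → label →
classify → stats, reproducibly, from a single config.

A master seed deterministically derives one sub-seed per stage so the whole
run — including the repeated evaluation protocol — is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cl
from . import features as ft
from . import labeling as lb
from . import simulate as sim
from . import stats as st
from . import windowing as wd
from .session import write_session

log = logging.getLogger("cogload")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    seed: int = 7
    out_dir: str = "run"
    n_participants: int = 8
    session_duration_s: float = 120.0
    channels: tuple[str, ...] = sim.ALL_CHANNELS
    transition_effect: float = 0.5
    level_shifts: tuple[float, ...] = (-1.5, -0.5, 0.5, 1.5)
    level_spread: float = 0.25
    k_max: int = 10
    n_boot: int = 100
    use_pupil_variance: bool = False
    models: tuple[str, ...] = ("m-LR", "m-SVM", "MLP")
    mlp_units: int = 1000
    mlp_epochs: int = 500
    repetitions: int = 100
    folds: int = 10
    run_cv: bool = True
    include_pupil_features: bool = False
    write_sessions: bool = False

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("channels", "level_shifts", "models"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return RunConfig(**raw)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2^31."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage, writing artifacts + a provenance manifest.

    Returns the run directory. Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    config.to_yaml(out / "config.yaml")

    def run_stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise PipelineError(name, str(exc)) from exc
        manifest["stages"][name] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "seed": stage_seed(config.seed, name),
        }
        log.info("stage %s done in %.2fs", name,
                 time.perf_counter() - t0)
        return result

    # --- simulate ---------------------------------------------------------
    def _simulate():
        cfg = sim.SimulationConfig(
            seed=stage_seed(config.seed, "simulate"),
            n_participants=config.n_participants,
            session_duration_s=config.session_duration_s,
            channels=config.channels,
            transition_effect=config.transition_effect,
            level_shifts=config.level_shifts,
            level_spread=config.level_spread,
        )
        cohort = sim.simulate_cohort(cfg)
        if config.write_sessions:
            for s, _ in cohort:
                write_session(s, out / "sessions" / s.participant_id)
        truth = pd.concat(
            [t.windows.assign(participant_id=s.participant_id)
             for s, t in cohort], ignore_index=True)
        _write_tsv(truth, out / "ground_truth.tsv")
        return cohort

    cohort = run_stage("simulate", _simulate)

    # --- windows + features ----------------------------------------------
    def _features():
        tables = []
        window_rows = []
        for s, _ in cohort:
            windows = wd.session_windows(s)
            if not windows:
                continue
            signals = ft.prepare_signals(s)
            tables.append(ft.extract_features(windows, signals,
                                              s.participant_id))
            window_rows.append(wd.windows_frame(windows).assign(
                participant_id=s.participant_id))
        if not tables:
            raise ValueError("no valid windows in the whole cohort")
        _write_tsv(pd.concat(window_rows, ignore_index=True),
                   out / "windows.tsv")
        table = pd.concat(tables, ignore_index=True)
        _write_tsv(table, out / "features.tsv")
        return table

    feature_table = run_stage("features", _features)

    # --- label ------------------------------------------------------------
    def _label():
        table = feature_table.dropna(
            subset=["pupil_mean_area"]).reset_index(drop=True)
        report = lb.cluster_pupil_windows(
            table, k_max=config.k_max,
            seed=stage_seed(config.seed, "label"),
            use_variance=config.use_pupil_variance, n_boot=config.n_boot)
        labeled = lb.label_dataset(table, report)
        _write_tsv(labeled, out / "labeled.tsv")
        with open(out / "clustering.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
        return labeled, report

    labeled, report = run_stage("label", _label)

    # --- classify ---------------------------------------------------------
    def _classify():
        # usable numeric features: drop all-NaN modalities, then NaN rows
        cols = [c for c in ft.FEATURE_NAMES
                if not labeled[c].isna().all()]
        if not config.include_pupil_features:
            cols = [c for c in cols if not c.startswith("pupil_")]
        data = labeled.dropna(subset=cols).reset_index(drop=True)
        protocol = cl.EvaluationProtocol(
            repetitions=config.repetitions, folds=config.folds,
            run_cv=config.run_cv,
            seed=stage_seed(config.seed, "classify"))
        reports = {}
        for kind in config.models:
            spec = {"m-LR": cl.ModelSpec.mlr(),
                    "m-SVM": cl.ModelSpec.msvm(),
                    "MLP": cl.ModelSpec.mlp(config.mlp_units,
                                            config.mlp_epochs)}[kind]
            reports[kind] = cl.train_eval(
                data[cols], data["level"].to_numpy(), spec, protocol)
        with open(out / "eval.json", "w") as fh:
            json.dump({k: r.to_dict() for k, r in reports.items()}, fh,
                      indent=1)
        return reports

    run_stage("classify", _classify)

    # --- stats ------------------------------------------------------------
    def _stats():
        table = labeled.rename(columns={"pupil_mean_area": "pupil_mean"})
        test = st.anova_rm_window_type(
            table[["participant_id", "kind", "pupil_mean"]])
        payload = {
            "anova_rm": {"F": test.f_stat, "p": test.p_value,
                         "group_means": test.group_means,
                         "group_sds": test.group_sds,
                         "n_participants": test.n_participants,
                         "excluded": test.excluded},
        }
        with open(out / "stats.json", "w") as fh:
            json.dump(payload, fh, indent=1)
        return test

    run_stage("stats", _stats)

    for name in ("windows.tsv", "features.tsv", "labeled.tsv",
                 "clustering.json", "eval.json", "stats.json"):
        manifest[name] = _sha256(out / name)
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
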