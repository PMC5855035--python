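"""Canonical session data model and plain-text persistence.

A recording session bundles one participant's gaze stream (a Tobii-Studio-like
export: timestamps, gaze point, per-eye pupil diameter and validity, event
type, AoI hit) with uniformly sampled sensor channels (EDA, PPG, TEMP, ECG and
14 EEG electrodes) plus a pre-stimulus baseline segment per channel.

Conventions
-----------
* Timestamps are integer milliseconds relative to stimulus onset (t = 0);
  baseline samples carry negative timestamps.
* Screen coordinates are pixels, origin top-left; AoI rectangles are
  half-open ``[min, max)`` so hit-testing is unambiguous at shared edges.
* On disk a session is a directory: a YAML manifest, a tab-separated gaze
  table and one CSV per sensor channel. All numeric formatting uses
  shortest-round-trip ``repr`` so that read(write(s)) == s exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

EEG_LABELS = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: canonical sampling rates (Hz) of the hardware being emulated
DEFAULT_RATES = {"EDA": 120.0, "PPG": 120.0, "TEMP": 50.0, "ECG": 1000.0, "EEG": 128.0}
DEFAULT_UNITS = {"EDA": "kΩ", "PPG": "mV", "TEMP": "°C", "ECG": "mV", "EEG": "µV"}

# ASCII-safe unit tokens used on disk
_UNIT_TO_ASCII = {"kΩ": "kOhm", "mV": "mV", "°C": "degC", "µV": "uV"}
_ASCII_TO_UNIT = {v: k for k, v in _UNIT_TO_ASCII.items()}

GAZE_COLUMNS = (
    "t", "x", "y", "pupil_left_mm", "validity_left",
    "pupil_right_mm", "validity_right", "event", "aoi_hit",
)

EVENTS = ("fixation", "saccade", "blink", "unknown")


class FormatError(ValueError):
    """Raised when a session directory is structurally unreadable."""


class ValidationError(ValueError):
    """Raised when parsed session data violates a model invariant."""


@dataclass(frozen=True)
class AoI:
    """A rectangular area of interest in screen pixels, half-open [min, max)."""

    id: str
    rect: tuple[float, float, float, float]  # x_min, y_min, x_max, y_max

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.rect
        if not (x0 < x1 and y0 < y1):
            raise ValidationError(f"AoI {self.id!r}: degenerate rect {self.rect}")

    def contains(self, x: float, y: float) -> bool:
        x0, y0, x1, y1 = self.rect
        return x0 <= x < x1 and y0 <= y < y1


@dataclass
class SensorChannel:
    """A uniformly sampled sensor series with its pre-stimulus baseline."""

    name: str
    rate_hz: float
    units: str
    values: np.ndarray
    baseline: np.ndarray  # samples covering >=500 ms before t=0

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValidationError(f"channel {self.name}: rate_hz must be > 0")
        self.values = np.asarray(self.values, dtype=float)
        self.baseline = np.asarray(self.baseline, dtype=float)
        base = self.name.split(":", 1)[0]
        if base == "EEG":
            label = self.name.split(":", 1)[1]
            if label not in EEG_LABELS:
                raise ValidationError(f"unknown EEG electrode label {label!r}")
        elif base not in DEFAULT_RATES:
            raise ValidationError(f"unknown channel name {self.name!r}")

    @property
    def baseline_ms(self) -> float:
        return len(self.baseline) / self.rate_hz * 1000.0


@dataclass
class Session:
    """One participant's synchronized gaze stream and sensor channels.

    ``gaze`` is a DataFrame with :data:`GAZE_COLUMNS`; rows with ``t < 0``
    form the pupil baseline segment. ``task_segments`` is the number m of
    task segments used by the EDA normalization (default 1).
    """

    participant_id: str
    gaze: pd.DataFrame
    channels: dict[str, SensorChannel] = field(default_factory=dict)
    layout: tuple[AoI, ...] = ()
    task_segments: int = 1

    def __post_init__(self) -> None:
        self.gaze = self.gaze.reindex(columns=list(GAZE_COLUMNS))
        validate_gaze(self.gaze)
        ids = [a.id for a in self.layout]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate AoI ids in layout")
        if self.task_segments < 1:
            raise ValidationError("task_segments must be >= 1")

    def channel(self, name: str) -> SensorChannel | None:
        return self.channels.get(name)

    @property
    def eeg_channels(self) -> list[SensorChannel]:
        return [c for n, c in self.channels.items() if n.startswith("EEG:")]

    def gaze_task(self) -> pd.DataFrame:
        """Gaze samples from stimulus onset onwards (t >= 0)."""
        return self.gaze[self.gaze["t"] >= 0].reset_index(drop=True)

    def gaze_baseline(self) -> pd.DataFrame:
        """Pre-stimulus gaze samples (t < 0), covering the 500 ms baseline."""
        return self.gaze[self.gaze["t"] < 0].reset_index(drop=True)


def validate_gaze(gaze: pd.DataFrame) -> None:
    t = gaze["t"].to_numpy()
    if len(t) and np.any(np.diff(t) < 0):
        row = int(np.argmax(np.diff(t) < 0)) + 1
        raise ValidationError(f"gaze timestamps not non-decreasing at row {row}")
    for col in ("validity_left", "validity_right"):
        v = gaze[col].to_numpy()
        bad = (v < 0) | (v > 4)
        if bad.any():
            row = int(np.argmax(bad))
            raise ValidationError(
                f"gaze {col}={v[row]} outside [0, 4] at row {row}"
            )
    ev = gaze["event"]
    if len(ev) and not ev.isin(EVENTS).all():
        bad = ev[~ev.isin(EVENTS)].iloc[0]
        raise ValidationError(f"unknown gaze event type {bad!r}")


# ---------------------------------------------------------------------------
# persistence


def _fmt(x: float) -> str:
    if isinstance(x, float) and math.isnan(x):
        return ""
    return repr(float(x))


def write_session(session: Session, path: str | Path) -> None:
    """Write ``session`` as a manifest + gaze TSV + per-channel CSVs.

    Formatting is bit-stable: writing, reading and writing again produces
    byte-identical files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    gaze_file = "gaze.tsv"
    with open(path / gaze_file, "w", newline="") as fh:
        fh.write("\t".join(GAZE_COLUMNS) + "\n")
        for row in session.gaze.itertuples(index=False):
            fields = [
                str(int(row.t)),
                _fmt(row.x), _fmt(row.y),
                _fmt(row.pupil_left_mm), str(int(row.validity_left)),
                _fmt(row.pupil_right_mm), str(int(row.validity_right)),
                str(row.event), str(row.aoi_hit),
            ]
            fh.write("\t".join(fields) + "\n")

    channels_meta = []
    for name, ch in session.channels.items():
        fname = name.replace(":", "_") + ".csv"
        with open(path / fname, "w", newline="") as fh:
            fh.write(f"# channel={name} rate_hz={_fmt(ch.rate_hz)} "
                     f"units={_UNIT_TO_ASCII.get(ch.units, ch.units)}\n")
            fh.write("segment,value\n")
            for v in ch.baseline:
                fh.write(f"baseline,{_fmt(v)}\n")
            for v in ch.values:
                fh.write(f"task,{_fmt(v)}\n")
        channels_meta.append({
            "name": name,
            "file": fname,
            "rate_hz": float(ch.rate_hz),
            "units": _UNIT_TO_ASCII.get(ch.units, ch.units),
            "n_samples": int(len(ch.values)),
            "n_baseline": int(len(ch.baseline)),
        })

    manifest = {
        "participant_id": session.participant_id,
        "task_segments": int(session.task_segments),
        "gaze_file": gaze_file,
        "layout": [
            {"id": a.id, "rect": [float(v) for v in a.rect]}
            for a in session.layout
        ],
        "channels": channels_meta,
    }
    with open(path / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_session(path: str | Path) -> Session:
    """Read a session directory written by :func:`write_session`.

    Raises :class:`FormatError` if the manifest is missing and
    :class:`ValidationError` when the data violate model invariants (bad
    validity codes, non-monotone timestamps, channel length mismatching the
    manifest declaration).
    """
    path = Path(path)
    mpath = path / "manifest.yaml"
    if not mpath.exists():
        raise FormatError(f"no manifest.yaml in {path}")
    with open(mpath) as fh:
        manifest = yaml.safe_load(fh)

    gaze = pd.read_csv(
        path / manifest["gaze_file"], sep="\t",
        dtype={"event": str, "aoi_hit": str},
        keep_default_na=False, na_values=[""],
        float_precision="round_trip",
    )
    n_raw = len(gaze)
    gaze["t"] = gaze["t"].astype(np.int64)
    for col in ("validity_left", "validity_right"):
        gaze[col] = gaze[col].astype(np.int64)
    for col in ("x", "y", "pupil_left_mm", "pupil_right_mm"):
        gaze[col] = gaze[col].astype(float)
    gaze["aoi_hit"] = gaze["aoi_hit"].fillna("off-screen")
    if len(gaze) != n_raw:
        raise ValidationError("gaze rows were dropped during parsing")

    channels: dict[str, SensorChannel] = {}
    for meta in manifest.get("channels", []):
        fpath = path / meta["file"]
        if not fpath.exists():
            raise FormatError(f"channel {meta['name']}: file {meta['file']} missing")
        tab = pd.read_csv(fpath, comment="#", float_precision="round_trip")
        vals = tab.loc[tab["segment"] == "task", "value"].to_numpy(float)
        base = tab.loc[tab["segment"] == "baseline", "value"].to_numpy(float)
        if len(vals) != meta["n_samples"]:
            raise ValidationError(
                f"channel {meta['name']}: manifest declares {meta['n_samples']} "
                f"samples at {meta['rate_hz']} Hz but file holds {len(vals)}"
            )
        channels[meta["name"]] = SensorChannel(
            name=meta["name"],
            rate_hz=float(meta["rate_hz"]),
            units=_ASCII_TO_UNIT.get(meta["units"], meta["units"]),
            values=vals,
            baseline=base,
        )

    layout = tuple(
        AoI(id=a["id"], rect=tuple(float(v) for v in a["rect"]))
        for a in manifest.get("layout", [])
    )
    return Session(
        participant_id=str(manifest["participant_id"]),
        gaze=gaze,
        channels=channels,
        layout=layout,
        task_segments=int(manifest.get("task_segments", 1)),
    )


def sessions_equal(a: Session, b: Session) -> bool:
    """Field-by-field equality of two sessions (NaN == NaN for data)."""
    if a.participant_id != b.participant_id or a.task_segments != b.task_segments:
        return False
    if a.layout != b.layout:
        return False
    if set(a.channels) != set(b.channels):
        return False
    for name, ch in a.channels.items():
        other = b.channels[name]
        if ch.rate_hz != other.rate_hz or ch.units != other.units:
            return False
        if not (np.array_equal(ch.values, other.values, equal_nan=True)
                and np.array_equal(ch.baseline, other.baseline, equal_nan=True)):
            return False
    try:
        pd.testing.assert_frame_equal(
            a.gaze.reset_index(drop=True), b.gaze.reset_index(drop=True),
            check_dtype=False,
        )
    except AssertionError:
        return False
    return True
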