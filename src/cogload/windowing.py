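"""Gaze-contingent segmentation into active and transition windows.

An *active* window is a maximal span in which the participant fixates inside
one area of interest; a *transition* window is on-screen gaze outside every
AoI (including fixations that hit no AoI and the saccades between elements).
Off-screen or missing gaze is *inactive* and never becomes a window.

Validity rule: only windows lasting at least 500 ms are kept. Sub-threshold
runs are deleted, and when the runs on either side of a deleted stretch
belong to the same element (the same AoI, or both transition), they are
joined into one longer window whose span includes the deleted gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session import AoI, Session

MIN_WINDOW_MS = 500.0

ACTIVE = "active"
TRANSITION = "transition"
INACTIVE = "inactive"


@dataclass(frozen=True)
class Window:
    kind: str               # "active" | "transition"
    t_start: float          # ms
    t_end: float            # ms
    aoi_id: str = ""        # active windows only

    @property
    def duration_ms(self) -> float:
        return self.t_end - self.t_start


def label_samples(gaze: pd.DataFrame, layout: tuple[AoI, ...]) -> pd.DataFrame:
    """Per-sample gaze state.

    Returns a frame with columns ``t``, ``state`` and ``aoi`` where state is
    active/transition/inactive. Fixation coordinates are hit-tested against
    the layout; saccade samples count as transition; samples with missing
    coordinates (blinks, tracking loss) are inactive.
    """
    t = gaze["t"].to_numpy()
    x = gaze["x"].to_numpy(float)
    y = gaze["y"].to_numpy(float)
    event = gaze["event"].to_numpy()

    state = np.array([INACTIVE] * len(t), dtype=object)
    aoi = np.array([""] * len(t), dtype=object)

    on_screen = ~(np.isnan(x) | np.isnan(y))
    state[on_screen] = TRANSITION
    fix = on_screen & (event == "fixation")
    for a in layout:
        x0, y0, x1, y1 = a.rect
        inside = fix & (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
        state[inside] = ACTIVE
        aoi[inside] = a.id
    return pd.DataFrame({"t": t, "state": state, "aoi": aoi})


def _runs(states: pd.DataFrame, sample_period_ms: float) -> list[dict]:
    """Maximal runs of identical (state, aoi), with end = next run's start."""
    t = states["t"].to_numpy(float)
    s = states["state"].to_numpy()
    a = states["aoi"].to_numpy()
    if len(t) == 0:
        return []
    change = np.flatnonzero((s[1:] != s[:-1]) | (a[1:] != a[:-1])) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(t)]])
    runs = []
    for i0, i1 in zip(starts, ends):
        t_end = t[i1] if i1 < len(t) else t[i1 - 1] + sample_period_ms
        runs.append({"state": s[i0], "aoi": a[i0],
                     "t_start": float(t[i0]), "t_end": float(t_end)})
    return runs


def _sample_period(states: pd.DataFrame) -> float:
    t = states["t"].to_numpy(float)
    if len(t) < 2:
        return 1000.0 / 120.0
    return float(np.median(np.diff(t)))


def segment_windows(states: pd.DataFrame,
                    min_window_ms: float = MIN_WINDOW_MS) -> list[Window]:
    """Runs -> deletion of sub-threshold runs -> joining -> valid windows.

    Deletion happens first; surviving same-element neighbours across deleted
    stretches are then merged (sub-threshold pieces participate in merging,
    so e.g. 300 ms + deleted 200 ms + 300 ms of the same AoI yields one
    800 ms window). The merged duration spans the deleted gap and is
    re-checked against the threshold.
    """
    period = _sample_period(states)
    runs = _runs(states, period)
    merged = merge_after_deletion(runs, min_window_ms)
    return [w for w in merged if w.duration_ms >= min_window_ms]


def merge_after_deletion(runs: list[dict],
                         min_window_ms: float = MIN_WINDOW_MS) -> list[Window]:
    """Join same-element runs separated only by sub-threshold (deleted) runs.

    Inactive runs never carry a window; the deletion rule applies to both
    active and transition runs. The output still contains sub-threshold
    merged windows — the caller applies the final duration check — so that
    the joining logic is observable on its own.
    """
    import heapq

    segs = [dict(r) for r in runs]
    n = len(segs)
    if n == 0:
        return []

    def element(i: int) -> tuple:
        return (segs[i]["state"], segs[i]["aoi"])

    def deleted(i: int) -> bool:
        return segs[i]["t_end"] - segs[i]["t_start"] < min_window_ms

    nxt = list(range(1, n)) + [-1]
    prv = [-1] + list(range(0, n - 1))
    alive = [True] * n          # still present in the linked list
    del_flag = [deleted(i) for i in range(n)]
    # long inactive runs are barriers: present, never deleted, never merge

    def partner(i: int) -> int:
        """First later same-element segment reachable across deleted ones."""
        if segs[i]["state"] == INACTIVE:
            return -1
        j = nxt[i]
        while j != -1:
            if element(j) == element(i):
                return j
            if not del_flag[j]:
                return -1
            j = nxt[j]
        return -1

    heap: list[tuple[float, int, int]] = []

    def push(i: int) -> None:
        j = partner(i)
        if j != -1:
            gap = segs[j]["t_start"] - segs[i]["t_end"]
            heapq.heappush(heap, (gap, i, j))

    for i in range(n):
        push(i)

    # innermost-first joining: the pair with the smallest deleted gap merges
    # first, so fixation runs stitch across their own micro-saccades before
    # any outer bridge can span the whole element
    while heap:
        gap, i, j = heapq.heappop(heap)
        if not (alive[i] and alive[j]):
            continue
        if partner(i) != j:  # stale entry
            continue
        # consume everything between i and j into i
        k = nxt[i]
        while k != j:
            alive[k] = False
            k = nxt[k]
        segs[i]["t_end"] = segs[j]["t_end"]
        alive[j] = False
        nxt[i] = nxt[j]
        if nxt[j] != -1:
            prv[nxt[j]] = i
        del_flag[i] = segs[i]["t_end"] - segs[i]["t_start"] < min_window_ms
        push(i)
        # a predecessor whose bridge crossed this region must be re-examined
        p = prv[i]
        while p != -1 and del_flag[p]:
            p = prv[p]
        if p != -1:
            push(p)

    return [
        _to_window(segs[i])
        for i in range(n)
        if alive[i] and not del_flag[i] and segs[i]["state"] != INACTIVE
    ]


def _to_window(run: dict) -> Window:
    return Window(kind=run["state"], t_start=run["t_start"],
                  t_end=run["t_end"], aoi_id=run["aoi"])


def session_windows(session: Session,
                    min_window_ms: float = MIN_WINDOW_MS) -> list[Window]:
    """Full chain on a session's task-phase gaze stream."""
    states = label_samples(session.gaze_task(), session.layout)
    return segment_windows(states, min_window_ms)


def windows_frame(windows: list[Window]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"kind": w.kind, "t_start": w.t_start, "t_end": w.t_end,
          "aoi_id": w.aoi_id} for w in windows],
        columns=["kind", "t_start", "t_end", "aoi_id"],
    )
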