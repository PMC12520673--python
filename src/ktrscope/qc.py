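"""Benchmark metrics against simulated ground truth.

Detection scoring matches detections to true positions one-to-one within a
radius; tracking is scored by purity (detections per track from a single
true cell) and completeness (fraction of a true cell's frames covered by
its best track); division recall matches called mitoses to true events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .tracker import CellTrack, MitosisEvent


@dataclass
class DetectionScores:
    n_true: int
    n_detected: int
    n_matched: int

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_true if self.n_true else float("nan")

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else float("nan")


def match_points(detected_xy: np.ndarray, true_xy: np.ndarray,
                 max_dist_um: float) -> list[tuple[int, int]]:
    """Globally optimal one-to-one matching of detections to truth."""
    detected_xy = np.asarray(detected_xy, float).reshape(-1, 2)
    true_xy = np.asarray(true_xy, float).reshape(-1, 2)
    if len(detected_xy) == 0 or len(true_xy) == 0:
        return []
    diff = detected_xy[:, None, :] - true_xy[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    cost = np.where(dist <= max_dist_um, dist, 1e9)
    ri, ci = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(ri, ci) if dist[i, j] <= max_dist_um]


def detection_scores(detected_xy: np.ndarray, true_xy: np.ndarray,
                     max_dist_um: float) -> DetectionScores:
    matches = match_points(detected_xy, true_xy, max_dist_um)
    return DetectionScores(n_true=len(np.atleast_2d(true_xy)),
                           n_detected=len(np.atleast_2d(detected_xy)),
                           n_matched=len(matches))


@dataclass
class TrackingScores:
    purity: float
    completeness: float
    n_tracks: int
    n_true_cells: int


def tracking_scores(tracks: list[CellTrack], truth_frames: pd.DataFrame,
                    max_dist_um: float = 10.0) -> TrackingScores:
    """Score tracks against a truth table (cell_id, frame, x_um, y_um).

    Each track detection is attributed to the nearest true cell in its
    frame (within ``max_dist_um``); purity is the detection-weighted mean
    of each track's majority-cell fraction, completeness the mean over true
    cells of the best single track's coverage of their lifetime.
    """
    truth_by_frame = {int(f): g for f, g in truth_frames.groupby("frame")}
    assign_counts: dict[int, dict[int, int]] = {}
    total_attributed = 0
    pure = 0.0
    for tr in tracks:
        counts: dict[int, int] = {}
        for f, x, y in zip(tr.frames, tr.x_um, tr.y_um):
            g = truth_by_frame.get(int(f))
            if g is None or g.empty:
                continue
            d = np.hypot(g["x_um"].to_numpy() - x, g["y_um"].to_numpy() - y)
            j = int(np.argmin(d))
            if d[j] <= max_dist_um:
                cid = int(g["cell_id"].iloc[j])
                counts[cid] = counts.get(cid, 0) + 1
        if counts:
            n_att = sum(counts.values())
            pure += max(counts.values())
            total_attributed += n_att
            assign_counts[tr.track_id] = counts
    purity = pure / total_attributed if total_attributed else float("nan")

    lifetimes = truth_frames.groupby("cell_id")["frame"].size()
    best_cover: dict[int, int] = {cid: 0 for cid in lifetimes.index}
    for counts in assign_counts.values():
        for cid, n in counts.items():
            best_cover[cid] = max(best_cover.get(cid, 0), n)
    completeness = float(np.mean([
        best_cover[cid] / lifetimes[cid] for cid in lifetimes.index]))
    return TrackingScores(purity=float(purity), completeness=completeness,
                          n_tracks=len(tracks), n_true_cells=len(lifetimes))


def division_recall(events: list[MitosisEvent], tracks: list[CellTrack],
                    truth_divisions: pd.DataFrame, truth_frames: pd.DataFrame,
                    max_dist_um: float = 25.0,
                    frame_tolerance: int = 1) -> float:
    """Fraction of true division events matched by a called mitosis.

    A call matches a true event when the daughter birth frames agree within
    ``frame_tolerance`` and the called parent's last position lies within
    ``max_dist_um`` of the true parent's position at its final frame.
    """
    if truth_divisions.empty:
        return float("nan")
    by_id = {t.track_id: t for t in tracks}
    calls = [(e.frame, by_id[e.parent_track].x_um[-1],
              by_id[e.parent_track].y_um[-1]) for e in events]
    matched = 0
    used = set()
    for row in truth_divisions.itertuples():
        parent_last = truth_frames[
            (truth_frames["cell_id"] == row.parent_id)
            & (truth_frames["frame"] == row.frame - 1)]
        if parent_last.empty:
            continue
        px = float(parent_last["x_um"].iloc[0])
        py = float(parent_last["y_um"].iloc[0])
        best = None
        for k, (f, x, y) in enumerate(calls):
            if k in used or abs(f - row.frame) > frame_tolerance:
                continue
            d = np.hypot(x - px, y - py)
            if d <= max_dist_um and (best is None or d < best[1]):
                best = (k, d)
        if best is not None:
            used.add(best[0])
            matched += 1
    return matched / len(truth_divisions)


def trace_recovery_error(traces, truth_frames: pd.DataFrame,
                         tracks: list[CellTrack], key: str = "cdk2",
                         max_dist_um: float = 10.0) -> float:
    """Max abs error between extracted traces and true trajectories.

    Tracks are attributed to true cells by nearest position per frame;
    only valid, non-interpolated trace points are compared.
    """
    truth_by_frame = {int(f): g for f, g in truth_frames.groupby("frame")}
    by_id = {t.track_id: t for t in tracks}
    worst = 0.0
    for tid in traces.track_ids:
        tr = traces.track(tid)
        track = by_id[int(tid)]
        pos = {int(f): (x, y) for f, x, y in zip(track.frames, track.x_um,
                                                 track.y_um)}
        for row in tr.itertuples():
            if not row.valid or row.interpolated or int(row.frame) not in pos:
                continue
            g = truth_by_frame.get(int(row.frame))
            if g is None:
                continue
            x, y = pos[int(row.frame)]
            d = np.hypot(g["x_um"].to_numpy() - x, g["y_um"].to_numpy() - y)
            j = int(np.argmin(d))
            if d[j] > max_dist_um:
                continue
            true_val = float(g[key].iloc[j])
            worst = max(worst, abs(getattr(row, key) - true_val))
    return worst
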