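"""Frame-to-frame linking of nuclei into lineages.

Linking is a globally optimal one-to-one assignment per frame pair
(Hungarian algorithm on centroid distance), followed by gap closing of
track ends onto later track starts. Because the assignment is global, a
continuing track is never "deflected" by a newborn daughter claiming its
detection — the assignment minimising total displacement wins. Mitoses are
called afterwards from newborn-track geometry and intensity conservation:
two daughters adjacent to a track end whose combined nuclear intensity is
comparable to the parent's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

_INF_COST = 1e9


@dataclass
class CellTrack:
    """One tracked cell: per-frame records plus lineage annotations.

    Frames are strictly increasing; they are contiguous except across
    bridged detection gaps. ``parent_id`` is 0 for root tracks.
    """

    track_id: int
    frames: np.ndarray
    t_h: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    label: np.ndarray
    h2b_int: np.ndarray
    parent_id: int = 0
    divided: bool = False

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError("a track needs at least one record")
        if not np.all(np.diff(self.frames) > 0):
            raise ValueError("frames must be strictly increasing")

    @property
    def start_frame(self) -> int:
        return int(self.frames[0])

    @property
    def end_frame(self) -> int:
        return int(self.frames[-1])

    @property
    def n_records(self) -> int:
        return len(self.frames)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "track_id": self.track_id, "parent_id": self.parent_id,
            "frame": self.frames, "t_h": self.t_h,
            "x_um": self.x_um, "y_um": self.y_um,
            "label": self.label, "h2b_int": self.h2b_int,
        })


def tracks_to_dataframe(tracks: list[CellTrack]) -> pd.DataFrame:
    if not tracks:
        return pd.DataFrame(columns=["track_id", "parent_id", "frame", "t_h",
                                     "x_um", "y_um", "label", "h2b_int"])
    return pd.concat([t.to_dataframe() for t in tracks], ignore_index=True)


def _split_frames(detections: pd.DataFrame) -> dict[int, pd.DataFrame]:
    return {int(f): g.reset_index(drop=True)
            for f, g in detections.groupby("frame", sort=True)}


def _assign(pos_a: np.ndarray, pos_b: np.ndarray, max_dist: float):
    """Globally optimal one-to-one matching within ``max_dist``."""
    if len(pos_a) == 0 or len(pos_b) == 0:
        return []
    diff = pos_a[:, None, :] - pos_b[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    cost = np.where(dist <= max_dist, dist, _INF_COST)
    ri, ci = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(ri, ci) if dist[i, j] <= max_dist]


def link_frames(detections: pd.DataFrame | list[pd.DataFrame],
                max_step_um: float = 40.0, max_gap_frames: int = 2,
                frame_interval_h: float = 0.2) -> list[CellTrack]:
    """Link per-frame detections into tracks with gap bridging.

    ``detections`` is a table with columns frame, label, x_um, y_um and
    optionally t_h and h2b_int (or a list of per-frame tables without the
    frame column). Unmatched track ends may bridge over up to
    ``max_gap_frames`` missing frames onto unmatched track starts within
    ``max_step_um * (gap + 1)``.
    """
    if max_step_um <= 0:
        raise ValueError("max_step_um must be > 0")
    if isinstance(detections, list):
        parts = []
        for f, df in enumerate(detections):
            df = df.copy()
            df["frame"] = f
            parts.append(df)
        detections = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
    if detections.empty:
        return []
    detections = detections.copy()
    if "t_h" not in detections:
        detections["t_h"] = detections["frame"] * frame_interval_h
    if "h2b_int" not in detections:
        detections["h2b_int"] = np.nan
    frames = _split_frames(detections)
    empty = detections.iloc[0:0]
    # iterate every frame in the span; frames absent from the table are empty
    frame_ids = list(range(min(frames), max(frames) + 1))
    frames = {f: frames.get(f, empty) for f in frame_ids}

    # growing track store: list of dict(records=list of row dicts)
    open_tracks: list[dict] = []
    closed: list[dict] = []

    def records_of(df: pd.DataFrame, idx: int) -> dict:
        row = df.iloc[idx]
        return dict(frame=int(row["frame"]), t_h=float(row["t_h"]),
                    x_um=float(row["x_um"]), y_um=float(row["y_um"]),
                    label=int(row["label"]), h2b_int=float(row["h2b_int"]))

    first = frame_ids[0]
    for i in range(len(frames[first])):
        open_tracks.append(dict(records=[records_of(frames[first], i)]))

    for prev_f, cur_f in zip(frame_ids[:-1], frame_ids[1:]):
        cur = frames[cur_f]
        active = [t for t in open_tracks if t["records"][-1]["frame"] == prev_f]
        inactive = [t for t in open_tracks if t["records"][-1]["frame"] != prev_f]
        pos_a = np.array([[t["records"][-1]["x_um"], t["records"][-1]["y_um"]]
                          for t in active]).reshape(-1, 2)
        pos_b = cur[["x_um", "y_um"]].to_numpy().reshape(-1, 2)
        matches = _assign(pos_a, pos_b, max_step_um)
        matched_tracks = set()
        matched_dets = set()
        for i, j in matches:
            active[i]["records"].append(records_of(cur, j))
            matched_tracks.add(i)
            matched_dets.add(j)
        for j in range(len(cur)):
            if j not in matched_dets:
                inactive.append(dict(records=[records_of(cur, j)]))
        open_tracks = active + inactive

    closed = open_tracks
    closed = _close_gaps(closed, max_step_um, max_gap_frames)

    closed.sort(key=lambda t: (t["records"][0]["frame"],
                               t["records"][0]["y_um"], t["records"][0]["x_um"]))
    tracks = []
    for tid, t in enumerate(closed, start=1):
        rec = pd.DataFrame(t["records"])
        tracks.append(CellTrack(
            track_id=tid,
            frames=rec["frame"].to_numpy(int),
            t_h=rec["t_h"].to_numpy(float),
            x_um=rec["x_um"].to_numpy(float),
            y_um=rec["y_um"].to_numpy(float),
            label=rec["label"].to_numpy(int),
            h2b_int=rec["h2b_int"].to_numpy(float),
        ))
    return tracks


def _close_gaps(tracks: list[dict], max_step_um: float,
                max_gap_frames: int) -> list[dict]:
    """Bridge unmatched ends onto unmatched starts (global assignment)."""
    if max_gap_frames < 1 or len(tracks) < 2:
        return tracks
    changed = True
    while changed:
        changed = False
        ends = []
        starts = []
        for i, t in enumerate(tracks):
            ends.append((i, t["records"][-1]))
            starts.append((i, t["records"][0]))
        n = len(tracks)
        cost = np.full((n, n), _INF_COST)
        for a, (i, e) in enumerate(ends):
            for b, (j, s) in enumerate(starts):
                if i == j:
                    continue
                gap = s["frame"] - e["frame"] - 1
                if not 1 <= gap <= max_gap_frames:
                    continue
                d = np.hypot(s["x_um"] - e["x_um"], s["y_um"] - e["y_um"])
                if d <= max_step_um * (gap + 1):
                    cost[a, b] = d
        if not (cost < _INF_COST).any():
            break
        ri, ci = linear_sum_assignment(cost)
        merges = [(a, b) for a, b in zip(ri, ci) if cost[a, b] < _INF_COST]
        if not merges:
            break
        # apply merges; earlier (by end frame) first so chains resolve
        merges.sort(key=lambda ab: tracks[ab[0]]["records"][-1]["frame"])
        drop = set()
        for a, b in merges:
            if a in drop or b in drop:
                continue
            tracks[a]["records"].extend(tracks[b]["records"])
            tracks[b]["records"] = tracks[a]["records"]  # alias for chains
            drop.add(b)
            changed = True
        tracks = [t for i, t in enumerate(tracks) if i not in drop]
        # de-alias: distinct dicts may share record lists after chaining
        seen = set()
        unique = []
        for t in tracks:
            if id(t["records"]) not in seen:
                seen.add(id(t["records"]))
                unique.append(t)
        tracks = unique
    return tracks


@dataclass
class MitosisEvent:
    parent_track: int
    daughter_tracks: tuple[int, int]
    frame: int  # first frame of the daughters
    intensity_mismatch: float


def _index_of_frame(track: CellTrack, frame: int) -> int | None:
    idx = np.searchsorted(track.frames, frame)
    if idx < track.n_records and track.frames[idx] == frame:
        return int(idx)
    return None


def _slice_track(track: CellTrack, start: int, stop: int, track_id: int,
                 parent_id: int = 0) -> CellTrack:
    return CellTrack(track_id=track_id, parent_id=parent_id,
                     frames=track.frames[start:stop], t_h=track.t_h[start:stop],
                     x_um=track.x_um[start:stop], y_um=track.y_um[start:stop],
                     label=track.label[start:stop],
                     h2b_int=track.h2b_int[start:stop])


def detect_mitosis(tracks: list[CellTrack], max_pair_distance_um: float = 25.0,
                   intensity_tolerance: float = 0.3
                   ) -> tuple[list[CellTrack], list[MitosisEvent]]:
    """Annotate divisions and return the (possibly re-split) track set.

    A division at frame ``t + 1`` is two daughter nuclei appearing close to
    a parent present at frame ``t``, with combined nuclear intensity
    comparable to the parent's (relative mismatch within
    ``intensity_tolerance``). Two geometries are recognised: the parent
    track ends at ``t`` and two unlinked tracks are born at ``t + 1``; or —
    the common case under distance-only linking — the parent track runs on
    into one daughter while the other appears as a newborn, in which case
    the continuing track is split at the division. Competing candidates
    resolve by minimum intensity mismatch, then by summed distance.
    """
    tracks = list(tracks)
    by_id = {t.track_id: t for t in tracks}
    last_frame = max(t.end_frame for t in tracks) if tracks else 0
    newborn_by_frame: dict[int, list[CellTrack]] = {}
    for t in tracks:
        if t.parent_id == 0 and t.start_frame > 0:
            newborn_by_frame.setdefault(t.start_frame, []).append(t)

    # candidate tuples: (mismatch, sum_dist, kind, parent_id, d1_id, d2_id, frame)
    candidates: list[tuple] = []
    for p in tracks:
        # geometry 1: parent ends, two newborns appear
        if p.end_frame < last_frame:
            born = [d for d in newborn_by_frame.get(p.end_frame + 1, [])
                    if d.track_id != p.track_id]
            px, py = p.x_um[-1], p.y_um[-1]
            ip = p.h2b_int[-1]
            near = [d for d in born
                    if np.hypot(d.x_um[0] - px, d.y_um[0] - py)
                    <= max_pair_distance_um]
            if np.isfinite(ip) and ip > 0:
                for i in range(len(near)):
                    for j in range(i + 1, len(near)):
                        d1, d2 = near[i], near[j]
                        isum = d1.h2b_int[0] + d2.h2b_int[0]
                        if not np.isfinite(isum):
                            continue
                        mismatch = abs(isum - ip) / ip
                        if mismatch <= intensity_tolerance:
                            sd = (np.hypot(d1.x_um[0] - px, d1.y_um[0] - py)
                                  + np.hypot(d2.x_um[0] - px, d2.y_um[0] - py))
                            candidates.append((mismatch, sd, "pair",
                                               p.track_id, d1.track_id,
                                               d2.track_id, p.end_frame + 1))
    # geometry 2: parent continues into one daughter; split candidate
    for frame, born in newborn_by_frame.items():
        for d2 in born:
            bx, by = d2.x_um[0], d2.y_um[0]
            i2 = d2.h2b_int[0]
            if not np.isfinite(i2):
                continue
            for p in tracks:
                if p.track_id == d2.track_id:
                    continue
                k_prev = _index_of_frame(p, frame - 1)
                k_cur = _index_of_frame(p, frame)
                if k_prev is None or k_cur is None:
                    continue
                px, py = p.x_um[k_prev], p.y_um[k_prev]
                if np.hypot(bx - px, by - py) > max_pair_distance_um:
                    continue
                ip = p.h2b_int[k_prev]
                i1 = p.h2b_int[k_cur]
                if not (np.isfinite(ip) and ip > 0 and np.isfinite(i1)):
                    continue
                mismatch = abs(i1 + i2 - ip) / ip
                if mismatch <= intensity_tolerance:
                    sd = (np.hypot(p.x_um[k_cur] - px, p.y_um[k_cur] - py)
                          + np.hypot(bx - px, by - py))
                    candidates.append((mismatch, sd, "split", p.track_id,
                                       d2.track_id, None, frame))

    candidates.sort(key=lambda c: (c[0], c[1], c[2], c[3]))
    events: list[MitosisEvent] = []
    used_parents: set[int] = set()
    used_daughters: set[int] = set()
    next_id = max(by_id) + 1 if by_id else 1
    for cand in candidates:
        mismatch, _sd, kind = cand[0], cand[1], cand[2]
        if kind == "pair":
            _, _, _, pid, did1, did2, frame = cand
            if (pid in used_parents or did1 in used_daughters
                    or did2 in used_daughters or pid in used_daughters):
                continue
            by_id[pid].divided = True
            by_id[did1].parent_id = pid
            by_id[did2].parent_id = pid
            used_parents.add(pid)
            used_daughters.update((did1, did2))
            events.append(MitosisEvent(pid, (did1, did2), frame, mismatch))
        else:
            _, _, _, pid, did2, _none, frame = cand
            if pid in used_parents or did2 in used_daughters:
                continue
            p = by_id[pid]
            k = _index_of_frame(p, frame)
            if k is None or k == 0:
                continue
            daughter1 = _slice_track(p, k, p.n_records, next_id, parent_id=pid)
            parent = _slice_track(p, 0, k, pid)
            parent.divided = True
            by_id[pid] = parent
            by_id[next_id] = daughter1
            tracks[tracks.index(p)] = parent
            tracks.append(daughter1)
            by_id[did2].parent_id = pid
            used_parents.add(pid)
            used_daughters.update((did2, next_id))
            events.append(MitosisEvent(pid, (next_id, did2), frame, mismatch))
            next_id += 1
    tracks.sort(key=lambda t: t.track_id)
    return tracks, events


def track_movie(detections: pd.DataFrame | list[pd.DataFrame],
                max_step_um: float = 40.0, max_gap_frames: int = 2,
                max_pair_distance_um: float = 25.0,
                intensity_tolerance: float = 0.3,
                frame_interval_h: float = 0.2) -> tuple[list[CellTrack], list[MitosisEvent]]:
    """Convenience: link frames then annotate mitoses."""
    tracks = link_frames(detections, max_step_um, max_gap_frames,
                         frame_interval_h)
    return detect_mitosis(tracks, max_pair_distance_um, intensity_tolerance)
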