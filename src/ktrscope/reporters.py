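"""Per-cell sensor readouts: KTR C/N ratios, degron intensities, traces.

The cytoplasm of each cell is approximated as a ring extending 2–10 um
outward from its nuclear mask. Ring pixels contested between two cells, or
lying inside/within the inner ring distance of any other nucleus, are
excluded from both. The activity readout is the median cytoplasmic over
median nuclear intensity, optionally after subtracting a scalar background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .frames import FrameStack
from .imgproc import LabelMask
from .tracker import CellTrack

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ring quantification


def _label_distance_maps(mask: LabelMask, reach_um: float):
    """Yield (label, slices, distance_um) limited to an expanded bounding box."""
    labels = mask.labels
    px = mask.pixel_size_um
    pad = int(np.ceil(reach_um / px)) + 2
    objects = ndi.find_objects(labels)
    for lab in mask.label_ids:
        sl = objects[lab - 1]
        rs = slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, labels.shape[0]))
        cs = slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, labels.shape[1]))
        sub = labels[rs, cs]
        d = ndi.distance_transform_edt(sub != lab) * px
        yield int(lab), (rs, cs), d


def cn_ratio(sensor_image: np.ndarray, mask: LabelMask,
             ring_inner_um: float = 2.0, ring_outer_um: float = 10.0,
             min_ring_px: int = 30, background: float | str = 0.0) -> pd.DataFrame:
    """Cytoplasm-to-nucleus ratio per label.

    A pixel belongs to the cytoplasm ring of label L when its Euclidean
    distance to L's mask lies in ``[ring_inner_um, ring_outer_um]`` and it
    is neither claimed by another label's ring nor inside / within
    ``ring_inner_um`` of any other mask. ``background`` is subtracted from
    both medians before dividing; ``'auto'`` estimates it as the median of
    pixels farther than ``ring_outer_um`` from every mask. Labels with fewer
    than ``min_ring_px`` usable ring pixels are flagged invalid (NaN ratio).
    """
    if ring_inner_um >= ring_outer_um:
        raise ValueError("ring_inner_um must be < ring_outer_um")
    img = np.asarray(sensor_image, dtype=float)
    if img.shape != mask.labels.shape:
        raise ValueError("sensor image and mask shapes differ")
    ring_count = np.zeros(img.shape, dtype=np.int16)
    near_count = np.zeros(img.shape, dtype=np.int16)
    for _lab, (rs, cs), d in _label_distance_maps(mask, ring_outer_um):
        ring_count[rs, cs] += (d >= ring_inner_um) & (d <= ring_outer_um)
        near_count[rs, cs] += d < ring_inner_um  # includes the mask itself

    if background == "auto":
        far = ring_count == 0
        if mask.n_labels:
            far &= ndi.distance_transform_edt(mask.labels == 0) * mask.pixel_size_um > ring_outer_um
        bg = float(np.median(img[far])) if far.any() else 0.0
    else:
        bg = float(background)

    rows = []
    for lab, (rs, cs), d in _label_distance_maps(mask, ring_outer_um):
        in_ring = (d >= ring_inner_um) & (d <= ring_outer_um)
        usable = in_ring & (ring_count[rs, cs] == 1) & (near_count[rs, cs] == 0)
        nuc_vals = img[mask.labels == lab]
        cyto_vals = img[rs, cs][usable]
        n_ring = int(usable.sum())
        valid = n_ring >= min_ring_px and nuc_vals.size > 0
        nuc_med = float(np.median(nuc_vals)) - bg if nuc_vals.size else np.nan
        cyto_med = float(np.median(cyto_vals)) - bg if n_ring else np.nan
        ratio = cyto_med / nuc_med if valid and nuc_med != 0 else np.nan
        rows.append(dict(label=lab, cn_ratio=ratio, nucleus_median=nuc_med,
                         cytoplasm_median=cyto_med, n_ring_px=n_ring,
                         valid=bool(valid and np.isfinite(ratio))))
    return pd.DataFrame(rows, columns=["label", "cn_ratio", "nucleus_median",
                                       "cytoplasm_median", "n_ring_px", "valid"])


def nuclear_intensity(reporter_image: np.ndarray, mask: LabelMask,
                      background: float = 0.0) -> pd.DataFrame:
    """Median intensity within each label's nuclear mask."""
    img = np.asarray(reporter_image, dtype=float)
    rows = [dict(label=int(lab),
                 median=float(np.median(img[mask.labels == lab])) - background)
            for lab in mask.label_ids]
    return pd.DataFrame(rows, columns=["label", "median"])


def quantify_movie(stack: FrameStack, masks: list[LabelMask],
                   cdk46_channel: str = "cdk46_sensor",
                   cdk2_channel: str = "cdk2_sensor",
                   degron_channel: str = "degron",
                   ring_inner_um: float = 2.0, ring_outer_um: float = 10.0,
                   min_ring_px: int = 30,
                   background: float | str = "auto") -> pd.DataFrame:
    """Per-frame per-label readouts for trace assembly.

    Returns columns frame, label, cdk46, cdk2, degron, valid.
    """
    rows = []
    for f, mask in enumerate(masks):
        r46 = cn_ratio(stack.frame(cdk46_channel, f), mask, ring_inner_um,
                       ring_outer_um, min_ring_px, background)
        r2 = cn_ratio(stack.frame(cdk2_channel, f), mask, ring_inner_um,
                      ring_outer_um, min_ring_px, background)
        deg = nuclear_intensity(stack.frame(degron_channel, f), mask)
        merged = r46[["label", "cn_ratio", "valid"]].rename(
            columns={"cn_ratio": "cdk46", "valid": "valid46"})
        merged = merged.merge(
            r2[["label", "cn_ratio", "valid"]].rename(
                columns={"cn_ratio": "cdk2", "valid": "valid2"}), on="label")
        merged = merged.merge(deg.rename(columns={"median": "degron"}),
                              on="label", how="left")
        merged["frame"] = f
        merged["valid"] = merged["valid46"] & merged["valid2"]
        rows.append(merged[["frame", "label", "cdk46", "cdk2", "degron", "valid"]])
    if not rows:
        return pd.DataFrame(columns=["frame", "label", "cdk46", "cdk2",
                                     "degron", "valid"])
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# trace assembly


@dataclass
class TraceSet:
    """Per-track activity traces on the frame grid.

    ``data`` columns: track_id, frame, t_h (relative to treatment), cdk46,
    cdk2, degron, valid, interpolated. Invalid frames are flagged, never
    silently filled beyond the interpolation gap limit.
    """

    data: pd.DataFrame
    frame_interval_h: float
    min_duration_h: float = 18.0

    @property
    def track_ids(self) -> np.ndarray:
        return self.data["track_id"].unique()

    def track(self, track_id: int) -> pd.DataFrame:
        return self.data[self.data["track_id"] == track_id]

    def durations_h(self) -> pd.Series:
        counts = self.data.groupby("track_id")["t_h"]
        return counts.max() - counts.min()

    def for_analysis(self) -> "TraceSet":
        """Subset of traces long enough for persister analysis."""
        dur = self.durations_h()
        keep = dur[dur >= self.min_duration_h].index
        if len(keep) == 0:
            logger.warning("no traces reach min_duration_h=%.1f h",
                           self.min_duration_h)
        sub = self.data[self.data["track_id"].isin(keep)].reset_index(drop=True)
        return TraceSet(sub, self.frame_interval_h, self.min_duration_h)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_interval_h: float = 0.2) -> "TraceSet":
        return cls(pd.read_csv(path), frame_interval_h)


def build_traces(tracks: list[CellTrack], readouts: pd.DataFrame,
                 treatment_time_h: float = 0.0, frame_interval_h: float = 0.2,
                 max_gap: int = 2, min_duration_h: float = 18.0) -> TraceSet:
    """Assemble per-track traces from tracked cells and per-frame readouts.

    Gaps (bridged frames, or invalid readouts) of at most ``max_gap``
    interior frames are linearly interpolated and flagged; longer runs stay
    invalid. Times are reported relative to ``treatment_time_h``.
    """
    if tracks:
        movie_end = max(t.t_h[-1] for t in tracks)
        if treatment_time_h > movie_end:
            raise ValueError("treatment_time_h beyond the movie span")
    lut = readouts.set_index(["frame", "label"])
    rows = []
    for track in tracks:
        f0, f1 = track.start_frame, track.end_frame
        grid = np.arange(f0, f1 + 1)
        n = grid.size
        vals = {k: np.full(n, np.nan) for k in ("cdk46", "cdk2", "degron")}
        valid = np.zeros(n, dtype=bool)
        present = np.zeros(n, dtype=bool)
        for f, lab in zip(track.frames, track.label):
            i = f - f0
            present[i] = True
            try:
                row = lut.loc[(f, lab)]
            except KeyError:
                continue
            if bool(row["valid"]):
                for k in vals:
                    vals[k][i] = row[k]
                valid[i] = True
        interpolated = np.zeros(n, dtype=bool)
        fillable = _interior_gap_mask(valid, max_gap)
        if fillable.any():
            xi = np.nonzero(valid)[0]
            for k in vals:
                vals[k][fillable] = np.interp(np.nonzero(fillable)[0], xi,
                                              vals[k][xi])
            interpolated = fillable
            valid = valid | fillable
        rows.append(pd.DataFrame({
            "track_id": track.track_id, "frame": grid,
            "t_h": grid * frame_interval_h - treatment_time_h,
            "cdk46": vals["cdk46"], "cdk2": vals["cdk2"],
            "degron": vals["degron"], "valid": valid,
            "interpolated": interpolated,
        }))
    data = (pd.concat(rows, ignore_index=True) if rows else
            pd.DataFrame(columns=["track_id", "frame", "t_h", "cdk46", "cdk2",
                                  "degron", "valid", "interpolated"]))
    return TraceSet(data, frame_interval_h, min_duration_h)


def _interior_gap_mask(valid: np.ndarray, max_gap: int) -> np.ndarray:
    """Invalid runs of length <= max_gap strictly between valid frames."""
    out = np.zeros_like(valid)
    if valid.sum() < 2:
        return out
    idx = np.nonzero(valid)[0]
    for a, b in zip(idx[:-1], idx[1:]):
        gap = b - a - 1
        if 1 <= gap <= max_gap:
            out[a + 1:b] = True
    return out


# ---------------------------------------------------------------------------
# degron phase calling


@dataclass
class PhaseCalls:
    """Cell-cycle transition times (h) and phase intervals from a degron trace."""

    reporter: str
    transitions: dict[str, float] = field(default_factory=dict)
    intervals: list[tuple[str, float, float]] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.transitions


def call_phase_transitions(times_h: np.ndarray, degron: np.ndarray,
                           reporter: str, frac_low: float = 0.5,
                           frac_high: float = 0.7, k: float = 3.0,
                           sustain_frames: int = 3) -> PhaseCalls:
    """Call cell-cycle transitions from a degron intensity trace.

    Cdt1 mode: the Cdt1 degron is degraded during S phase, so a sustained
    drop below ``frac_low`` of the running maximum marks G1/S (timed at the
    steepest drop) and a subsequent sustained recovery above ``frac_high``
    of the pre-drop level marks S/G2. Geminin mode: geminin accumulates in
    S/G2, so a sustained rise above baseline + ``k`` * MAD marks S entry.
    Returns empty calls when no transition qualifies.
    """
    t = np.asarray(times_h, dtype=float)
    v = np.asarray(degron, dtype=float)
    ok = np.isfinite(v)
    t, v = t[ok], v[ok]
    calls = PhaseCalls(reporter=reporter)
    if v.size < 2 * sustain_frames + 1:
        return calls
    if reporter == "cdt1":
        run_max = np.maximum.accumulate(v)
        below = v < frac_low * run_max
        start = _first_sustained(below, sustain_frames)
        if start is None:
            return calls
        lo = max(start - sustain_frames, 1)
        dv = np.diff(v)
        drop_i = lo + int(np.argmin(dv[lo - 1:start])) if start > lo - 1 else start
        t_g1s = float(t[drop_i])
        pre = run_max[drop_i]
        above = np.zeros_like(below)
        above[drop_i + 1:] = v[drop_i + 1:] > frac_high * pre
        rise = _first_sustained(above, sustain_frames)
        calls.transitions["G1/S"] = t_g1s
        intervals = [("G1", float(t[0]), t_g1s)]
        if rise is not None:
            t_sg2 = float(t[rise])
            calls.transitions["S/G2"] = t_sg2
            intervals += [("S", t_g1s, t_sg2), ("G2M", t_sg2, float(t[-1]))]
        else:
            intervals += [("S", t_g1s, float(t[-1]))]
        calls.intervals = intervals
    elif reporter == "geminin":
        n0 = max(sustain_frames, v.size // 4, 3)
        base = np.median(v[:n0])
        mad = np.median(np.abs(v[:n0] - base))
        thr = base + k * mad + 1e-9 * max(abs(base), 1.0)
        above = v > thr
        rise = _first_sustained(above, sustain_frames)
        if rise is not None:
            t_s = float(t[rise])
            calls.transitions["S-entry"] = t_s
            calls.intervals = [("G1", float(t[0]), t_s),
                               ("S", t_s, float(t[-1]))]
    else:
        raise ValueError(f"unknown reporter {reporter!r}")
    return calls


def _first_sustained(flags: np.ndarray, sustain: int) -> int | None:
    """Index of the first run of at least ``sustain`` consecutive True."""
    count = 0
    for i, f in enumerate(flags):
        count = count + 1 if f else 0
        if count >= sustain:
            return i - sustain + 1
    return None
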