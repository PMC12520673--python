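"""Illumination correction and nuclear segmentation.

Two segmentation paths mirror the two imaging modes: fixed-cell fields
(DNA-stain histogram thresholding with watershed splitting of touching
nuclei) and live-cell movies (multi-scale Laplacian-of-Gaussian blob
detection on the H2B channel, with masks grown from the detected seeds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import feature, filters, measure, segmentation

from .frames import FrameStack

#: LoG blob radius ~ sigma * sqrt(2) for a solid disk
_SQRT2 = np.sqrt(2.0)


@dataclass
class LabelMask:
    """Integer label image (0 = background) with physical calibration.

    Labels are positive, unique and 4-connected. ``properties`` summarises
    per-label geometry (centroid in um, area in um^2) and intensity in any
    requested channels.
    """

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2-D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_labels(self) -> int:
        return self.label_ids.size

    def properties(self, channels: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
        """Per-label table: centroid (um), area (um^2), intensity stats."""
        px = self.pixel_size_um
        if self.n_labels == 0:
            cols = ["label", "x_um", "y_um", "area_um2"]
            for name in (channels or {}):
                cols += [f"mean_{name}", f"median_{name}", f"integrated_{name}"]
            return pd.DataFrame(columns=cols)
        props = measure.regionprops_table(
            self.labels, properties=("label", "centroid", "area"))
        out = pd.DataFrame({
            "label": props["label"],
            "x_um": props["centroid-1"] * px,
            "y_um": props["centroid-0"] * px,
            "area_um2": props["area"] * px**2,
        })
        for name, img in (channels or {}).items():
            means, medians, integrated = [], [], []
            for lab in out["label"]:
                vals = np.asarray(img)[self.labels == lab]
                means.append(vals.mean())
                medians.append(np.median(vals))
                integrated.append(vals.sum())
            out[f"mean_{name}"] = means
            out[f"median_{name}"] = medians
            out[f"integrated_{name}"] = integrated
        return out


# ---------------------------------------------------------------------------
# flat-field correction


def _poly2_design(rows: np.ndarray, cols: np.ndarray, shape) -> np.ndarray:
    r = 2.0 * rows / max(shape[0] - 1, 1) - 1.0
    c = 2.0 * cols / max(shape[1] - 1, 1) - 1.0
    return np.column_stack([np.ones_like(r), r, c, r * c, r**2, c**2])


def estimate_flatfield(image: np.ndarray) -> np.ndarray:
    """Estimate a smooth multiplicative bias field from background pixels.

    Background pixels (below an Otsu threshold on log intensity) are fitted
    with a low-order 2-D polynomial surface; the returned field is
    normalised to mean 1.
    """
    image = np.asarray(image, dtype=float)
    logimg = np.log1p(np.clip(image, 0, None))
    try:
        thr = filters.threshold_otsu(logimg)
    except ValueError:  # constant image
        thr = np.inf
    bgmask = logimg < thr
    if bgmask.sum() < 64:
        bgmask = np.ones_like(bgmask)
    rows, cols = np.nonzero(bgmask)
    design = _poly2_design(rows, cols, image.shape)
    coef, *_ = np.linalg.lstsq(design, image[bgmask], rcond=None)
    gr, gc = np.mgrid[0:image.shape[0], 0:image.shape[1]]
    field = _poly2_design(gr.ravel(), gc.ravel(), image.shape) @ coef
    field = field.reshape(image.shape)
    field = np.clip(field, 1e-6 * max(field.mean(), 1e-12), None)
    return field / field.mean()


def flatfield_correct(stack: FrameStack, reference: str = "from_background",
                      field: np.ndarray | None = None) -> FrameStack:
    """Divide out a multiplicative illumination bias.

    ``reference='provided_field'`` divides every channel by the given field
    (mean-normalised); ``'from_background'`` estimates one field per channel
    from the temporal median image's background.
    """
    if reference == "provided_field":
        if field is None:
            raise ValueError("provided_field requires a field array")
        field = np.asarray(field, dtype=float)
        if field.shape != stack.shape:
            raise ValueError(
                f"field shape {field.shape} != image shape {stack.shape}")
        if (field <= 0).any():
            raise ValueError("flat-field must be strictly positive")
        norm = field / field.mean()
        channels = {name: img / norm for name, img in stack.channels.items()}
    elif reference == "from_background":
        channels = {}
        for name, img in stack.channels.items():
            ref = np.median(img, axis=0)
            norm = estimate_flatfield(ref)
            channels[name] = img / norm
    else:
        raise ValueError(f"unknown reference mode {reference!r}")
    return FrameStack(channels, pixel_size_um=stack.pixel_size_um,
                      frame_interval_h=stack.frame_interval_h)


# ---------------------------------------------------------------------------
# fixed-cell segmentation


def segment_fixed(dna_image: np.ndarray, pixel_size_um: float,
                  min_area_um2: float = 30.0, max_area_um2: float = 800.0,
                  threshold: float | None = None) -> LabelMask:
    """Segment nuclei in a DNA-stain image by histogram thresholding.

    The global threshold defaults to Otsu on log intensity. Connected
    components are filtered by area; components larger than ``max_area_um2``
    are split by watershed on the distance transform.
    """
    img = np.asarray(dna_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("dna_image must be 2-D")
    px2 = pixel_size_um**2
    if threshold is None:
        logimg = np.log1p(np.clip(img, 0, None))
        try:
            thr = filters.threshold_otsu(logimg)
        except ValueError:
            return LabelMask(np.zeros(img.shape, np.int32), pixel_size_um)
        binary = logimg > thr
    else:
        binary = img > threshold
    binary = ndi.binary_fill_holes(binary)
    labels, _ = ndi.label(binary)  # 4-connectivity
    if labels.max() == 0:
        return LabelMask(np.zeros(img.shape, np.int32), pixel_size_um)

    areas = np.bincount(labels.ravel())
    out = np.zeros(img.shape, dtype=np.int32)
    next_id = 1
    min_px = min_area_um2 / px2
    max_px = max_area_um2 / px2
    peak_sep = max(int(round(np.sqrt(min_area_um2 / np.pi) / pixel_size_um)), 1)
    for lab in range(1, labels.max() + 1):
        if areas[lab] < min_px:
            continue
        comp = labels == lab
        if areas[lab] <= max_px:
            out[comp] = next_id
            next_id += 1
            continue
        dist = ndi.distance_transform_edt(comp)
        peaks = feature.peak_local_max(dist, min_distance=peak_sep, labels=comp,
                                       exclude_border=False)
        if len(peaks) < 2:
            out[comp] = next_id
            next_id += 1
            continue
        markers = np.zeros(img.shape, dtype=np.int32)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        split = segmentation.watershed(-dist, markers, mask=comp,
                                       connectivity=1)
        for sub in range(1, split.max() + 1):
            part = split == sub
            if part.sum() >= min_px:
                out[part] = next_id
                next_id += 1
    return LabelMask(out, pixel_size_um)


# ---------------------------------------------------------------------------
# live-cell segmentation (LoG blob detection)


def log_blobs(image: np.ndarray, pixel_size_um: float,
              radius_range_um: tuple[float, float],
              detection_threshold: float = 0.5) -> pd.DataFrame:
    """Multi-scale LoG blob detection with a robust-SNR threshold.

    The image is centred and scaled by its median / MAD before detection, so
    ``detection_threshold`` is expressed in robust-SNR response units and the
    result is invariant to multiplying the image by a positive constant.
    Returns (row_px, col_px, radius_um, snr) sorted by position.
    """
    rmin, rmax = radius_range_um
    if rmin <= 0 or rmin >= rmax:
        raise ValueError("require 0 < rmin < rmax")
    img = np.asarray(image, dtype=float)
    med = np.median(img)
    mad = np.median(np.abs(img - med))
    scale = 1.4826 * mad
    if scale <= 0:
        scale = img.std() or 1.0
    norm = (img - med) / scale
    sigma_min = rmin / _SQRT2 / pixel_size_um
    sigma_max = rmax / _SQRT2 / pixel_size_um
    blobs = feature.blob_log(norm, min_sigma=sigma_min, max_sigma=sigma_max,
                             num_sigma=8, log_scale=True,
                             threshold=detection_threshold,
                             exclude_border=max(1, int(np.ceil(sigma_min))))
    if blobs.size == 0:
        return pd.DataFrame(columns=["row_px", "col_px", "radius_um", "snr"])
    rows = blobs[:, 0]
    cols = blobs[:, 1]
    radii = blobs[:, 2] * _SQRT2 * pixel_size_um
    snr = norm[rows.astype(int), cols.astype(int)]
    df = pd.DataFrame({"row_px": rows, "col_px": cols, "radius_um": radii,
                       "snr": snr})
    df = df.sort_values(["row_px", "col_px"], kind="mergesort").reset_index(drop=True)
    # merge blobs closer than rmin into the brighter seed
    keep = np.ones(len(df), dtype=bool)
    pts = df[["row_px", "col_px"]].to_numpy() * pixel_size_um
    tree = cKDTree(pts)
    for i, j in sorted(tree.query_pairs(rmin)):
        if keep[i] and keep[j]:
            drop = i if df["snr"].iloc[i] < df["snr"].iloc[j] else j
            keep[drop] = False
    return df[keep].reset_index(drop=True)


def segment_live(h2b_image: np.ndarray, pixel_size_um: float,
                 radius_range_um: tuple[float, float] = (5.0, 12.0),
                 detection_threshold: float = 0.5) -> LabelMask:
    """Segment nuclei in a live-cell H2B image via LoG blob detection.

    Accepted blobs become seeds; masks are grown from each seed by a local
    Otsu threshold in a (4 x rmax)^2 window, limited to 2 x rmax from the
    seed. Contested pixels go to the nearer seed (ties to the lower label).
    """
    img = np.asarray(h2b_image, dtype=float)
    seeds = log_blobs(img, pixel_size_um, radius_range_um, detection_threshold)
    out = np.zeros(img.shape, dtype=np.int32)
    if seeds.empty:
        return LabelMask(out, pixel_size_um)
    rmax_px = radius_range_um[1] / pixel_size_um
    win = int(round(2 * rmax_px))
    grow = 2 * rmax_px
    best_d = np.full(img.shape, np.inf)
    for lab, row in enumerate(seeds.itertuples(), start=1):
        r0 = int(round(row.row_px))
        c0 = int(round(row.col_px))
        rmin_ = max(r0 - win, 0)
        rmax_ = min(r0 + win + 1, img.shape[0])
        cmin_ = max(c0 - win, 0)
        cmax_ = min(c0 + win + 1, img.shape[1])
        window = img[rmin_:rmax_, cmin_:cmax_]
        try:
            thr = filters.threshold_otsu(window)
        except ValueError:
            continue
        gr, gc = np.mgrid[rmin_:rmax_, cmin_:cmax_]
        d = np.hypot(gr - row.row_px, gc - row.col_px)
        cand = (window >= thr) & (d <= grow)
        closer = cand & (d < best_d[rmin_:rmax_, cmin_:cmax_])
        sub_out = out[rmin_:rmax_, cmin_:cmax_]
        sub_out[closer] = lab
        best_d[rmin_:rmax_, cmin_:cmax_][closer] = d[closer]
    # enforce 4-connected coherence: keep the component containing each seed
    final = np.zeros_like(out)
    for lab, row in enumerate(seeds.itertuples(), start=1):
        comp, _ = ndi.label(out == lab)
        r0 = int(round(np.clip(row.row_px, 0, img.shape[0] - 1)))
        c0 = int(round(np.clip(row.col_px, 0, img.shape[1] - 1)))
        seed_comp = comp[r0, c0]
        if seed_comp == 0:
            sizes = np.bincount(comp.ravel())
            if sizes.size <= 1:
                continue
            seed_comp = int(np.argmax(sizes[1:]) + 1)
        final[comp == seed_comp] = lab
    return LabelMask(final, pixel_size_um)


def segment_movie(stack: FrameStack, channel: str = "h2b",
                  radius_range_um: tuple[float, float] = (5.0, 12.0),
                  detection_threshold: float = 0.5) -> list[LabelMask]:
    """Per-frame live-cell segmentation of a movie channel."""
    return [segment_live(stack.channel(channel)[f], stack.pixel_size_um,
                         radius_range_um, detection_threshold)
            for f in range(stack.n_frames)]


def detections_table(masks: list[LabelMask],
                     intensity: np.ndarray | None = None,
                     frame_interval_h: float = 0.2) -> pd.DataFrame:
    """Stack per-frame label properties into one detection table for tracking."""
    rows = []
    for f, mask in enumerate(masks):
        channels = {"h2b": intensity[f]} if intensity is not None else None
        props = mask.properties(channels)
        props.insert(0, "frame", f)
        props.insert(1, "t_h", f * frame_interval_h)
        if intensity is not None:
            props = props.rename(columns={"integrated_h2b": "h2b_int"})
        else:
            props["h2b_int"] = np.nan
        rows.append(props)
    if not rows:
        return pd.DataFrame(columns=["frame", "t_h", "label", "x_um", "y_um",
                                     "area_um2", "h2b_int"])
    out = pd.concat(rows, ignore_index=True)
    cols = ["frame", "t_h", "label", "x_um", "y_um", "area_um2", "h2b_int"]
    return out[[c for c in cols if c in out.columns]]
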