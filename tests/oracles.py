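"""Independent brute-force oracles used to validate the implementations.

These deliberately avoid the package's algorithmic shortcuts: runs are
enumerated window by window, ring pixels are classified by exhaustive
distance to every mask pixel, and distance fields by an all-pairs minimum.
"""

from __future__ import annotations

import numpy as np


def longest_run_oracle(times_h: np.ndarray, values: np.ndarray,
                       threshold: float = 1.0,
                       window: tuple[float, float] = (30.0, 48.0)) -> float:
    """Longest span (h) of consecutive frames above threshold inside window,
    found by enumerating every candidate start frame and extending."""
    t = np.asarray(times_h, float)
    v = np.asarray(values, float)
    eps = 1e-9
    ok = (t >= window[0] - eps) & (t <= window[1] + eps) & (v > threshold)
    best = 0.0
    i = 0
    n = t.size
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and ok[j + 1]:
            j += 1
        best = max(best, t[j] - t[i])
        i = j + 1
    return best


def cn_ratio_oracle(image: np.ndarray, labels: np.ndarray, pixel_size_um: float,
                    ring_inner_um: float = 2.0, ring_outer_um: float = 10.0,
                    background: float = 0.0) -> dict[int, float]:
    """Per-pixel re-derivation of the C/N ratio.

    Every pixel's distance to every label's mask is the exhaustive all-pairs
    minimum over that label's pixels (no distance transform); a pixel is
    cytoplasm of exactly one label when it lies in that label's ring, in no
    other ring, and not within the inner distance of any other mask.
    """
    ids = sorted(int(x) for x in np.unique(labels) if x > 0)
    shape = labels.shape
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    coords = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    dist = {}
    for lab in ids:
        pts = np.argwhere(labels == lab).astype(float)
        diff_r = coords[:, 0:1] - pts[None, :, 0]
        diff_c = coords[:, 1:2] - pts[None, :, 1]
        dist[lab] = np.sqrt(diff_r**2 + diff_c**2).min(axis=1) * pixel_size_um
    in_ring = {lab: (dist[lab] >= ring_inner_um) & (dist[lab] <= ring_outer_um)
               for lab in ids}
    near = {lab: dist[lab] < ring_inner_um for lab in ids}
    ring_count = np.sum([in_ring[lab] for lab in ids], axis=0)
    near_count = np.sum([near[lab] for lab in ids], axis=0)
    flat = np.asarray(image, float).ravel()
    out = {}
    for lab in ids:
        member = in_ring[lab] & (ring_count == 1) & (near_count - near[lab] == 0)
        nuc = np.median(image[labels == lab]) - background
        if member.any() and nuc != 0:
            out[lab] = (float(np.median(flat[member])) - background) / nuc
        else:
            out[lab] = float("nan")
    return out


def distance_field_oracle(mask: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """All-pairs minimum distance from in-mask pixels to background pixels."""
    mask = np.asarray(mask, bool)
    bg = np.argwhere(~mask)
    out = np.full(mask.shape, -1.0)
    for r, c in np.argwhere(mask):
        out[r, c] = np.min(np.hypot(bg[:, 0] - r, bg[:, 1] - c)) * pixel_size_um
    return out
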