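"""Tumor-section morphometry: margin distances and immune-cell densities.

The tumor is segmented from its stain channel; every in-mask pixel gets a
Euclidean distance (um) to the nearest background pixel; CD8+ cells are
detected as LoG spots and assigned to the periphery (margin distance up to
500 um) or the core (beyond 500 um). Densities are cells/mm^2 per region.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters, morphology

from .frames import SectionImage
from .imgproc import log_blobs

#: distance sentinel for pixels outside the tumor mask
OUTSIDE = -1.0


def segment_tumor(section_image: np.ndarray, pixel_size_um: float,
                  closing_radius_um: float = 50.0) -> np.ndarray:
    """Segment the tumor region from its stain channel.

    Otsu threshold, morphological closing, largest connected component,
    hole filling. Returns a boolean mask (empty, with a warning, when the
    image has no foreground).
    """
    img = np.asarray(section_image, dtype=float)
    try:
        thr = filters.threshold_otsu(img)
    except ValueError:
        warnings.warn("blank section image: empty tumor mask", stacklevel=2)
        return np.zeros(img.shape, dtype=bool)
    binary = img > thr
    if not binary.any():
        warnings.warn("no foreground in section image", stacklevel=2)
        return binary
    radius_px = max(int(round(closing_radius_um / pixel_size_um)), 1)
    binary = ndi.binary_closing(binary, structure=morphology.disk(radius_px))
    labels, n = ndi.label(binary)
    if n == 0:
        warnings.warn("no foreground after closing", stacklevel=2)
        return np.zeros(img.shape, dtype=bool)
    largest = int(np.argmax(np.bincount(labels.ravel())[1:]) + 1)
    mask = labels == largest
    return ndi.binary_fill_holes(mask)


def margin_distance(mask: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Euclidean distance (um) from each in-mask pixel to the margin.

    Pixels outside the mask carry the sentinel ``OUTSIDE`` (-1).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty tumor mask")
    dist = ndi.distance_transform_edt(mask) * pixel_size_um
    dist[~mask] = OUTSIDE
    return dist


def detect_cd8(stain_image: np.ndarray, mask: np.ndarray, pixel_size_um: float,
               radius_range_um: tuple[float, float] = (3.0, 6.0),
               detection_threshold: float = 2.0,
               search_margin_um: float = 50.0) -> pd.DataFrame:
    """Detect CD8+ cells as LoG spots within a dilated tumor neighborhood.

    Returns centroids (x_um, y_um) of spots inside the dilated mask.
    """
    blobs = log_blobs(np.asarray(stain_image, dtype=float), pixel_size_um,
                      radius_range_um, detection_threshold)
    if blobs.empty:
        return pd.DataFrame(columns=["x_um", "y_um"])
    dilate_px = max(int(round(search_margin_um / pixel_size_um)), 1)
    neighborhood = ndi.binary_dilation(np.asarray(mask, bool),
                                       iterations=dilate_px)
    rows = blobs["row_px"].round().astype(int).clip(0, mask.shape[0] - 1)
    cols = blobs["col_px"].round().astype(int).clip(0, mask.shape[1] - 1)
    keep = neighborhood[rows, cols]
    return pd.DataFrame({
        "x_um": blobs["col_px"][keep] * pixel_size_um,
        "y_um": blobs["row_px"][keep] * pixel_size_um,
    }).reset_index(drop=True)


@dataclass
class SectionMorphometry:
    """Morphometric summary of one tumor section.

    ``cells`` carries one row per detected CD8+ cell with its margin
    distance and region label in {periphery, core, outside}. Periphery and
    core partition the mask (boundary distance exactly at the cutoff is
    periphery); in-mask counts are conserved by construction.
    """

    mask: np.ndarray = field(repr=False)
    distance_um: np.ndarray = field(repr=False)
    cells: pd.DataFrame
    pixel_size_um: float
    periphery_um: float
    areas_mm2: dict[str, float]
    counts: dict[str, int]
    densities_per_mm2: dict[str, float]
    core_undefined: bool = False

    def to_json(self, path=None) -> str:
        payload = dict(periphery_um=self.periphery_um,
                       areas_mm2=self.areas_mm2, counts=self.counts,
                       densities_per_mm2=self.densities_per_mm2,
                       core_undefined=self.core_undefined)
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def region_densities(mask: np.ndarray, distance_um: np.ndarray,
                     centroids: pd.DataFrame, pixel_size_um: float,
                     periphery_um: float = 500.0) -> SectionMorphometry:
    """Assign cells to periphery/core and compute densities (cells/mm^2).

    Periphery is the in-mask band with margin distance up to
    ``periphery_um`` (a cell exactly at the cutoff counts as periphery,
    mirroring the strict ``> 500 um`` definition of the core); the core is
    everything deeper. A thin tumor with no core pixels reports the core
    density as NaN with ``core_undefined=True``.
    """
    mask = np.asarray(mask, dtype=bool)
    periph_px = mask & (distance_um <= periphery_um)
    core_px = mask & (distance_um > periphery_um)
    mm2 = (pixel_size_um / 1000.0) ** 2
    areas = {"periphery": float(periph_px.sum() * mm2),
             "core": float(core_px.sum() * mm2),
             "tumor": float(mask.sum() * mm2)}

    cells = centroids.copy()
    if cells.empty:
        cells = pd.DataFrame(columns=["x_um", "y_um"])
    rows = (cells["y_um"] / pixel_size_um).round().astype(int).clip(
        0, mask.shape[0] - 1) if len(cells) else pd.Series([], dtype=int)
    cols = (cells["x_um"] / pixel_size_um).round().astype(int).clip(
        0, mask.shape[1] - 1) if len(cells) else pd.Series([], dtype=int)
    region = []
    d_vals = []
    for r, c in zip(rows, cols):
        if not mask[r, c]:
            region.append("outside")
            d_vals.append(OUTSIDE)
        else:
            d = distance_um[r, c]
            d_vals.append(float(d))
            region.append("core" if d > periphery_um else "periphery")
    cells["d_um"] = d_vals
    cells["region"] = region

    counts = {"periphery": int((cells["region"] == "periphery").sum()),
              "core": int((cells["region"] == "core").sum()),
              "outside": int((cells["region"] == "outside").sum())}
    core_undefined = areas["core"] == 0
    if core_undefined:
        warnings.warn("no core pixels: core density undefined", stacklevel=2)
    densities = {
        "periphery": counts["periphery"] / areas["periphery"]
        if areas["periphery"] > 0 else float("nan"),
        "core": counts["core"] / areas["core"]
        if not core_undefined else float("nan"),
    }
    return SectionMorphometry(mask=mask, distance_um=distance_um, cells=cells,
                              pixel_size_um=pixel_size_um,
                              periphery_um=periphery_um, areas_mm2=areas,
                              counts=counts, densities_per_mm2=densities,
                              core_undefined=core_undefined)


def analyze_section(image: SectionImage, tumor_channel: str = "tumor",
                    cd8_channel: str = "cd8", periphery_um: float = 500.0,
                    radius_range_um: tuple[float, float] = (3.0, 6.0),
                    detection_threshold: float = 2.0) -> SectionMorphometry:
    """Full morphometry chain: segment, distance field, detect, densities."""
    mask = segment_tumor(image.channel(tumor_channel), image.pixel_size_um)
    dist = margin_distance(mask, image.pixel_size_um)
    cells = detect_cd8(image.channel(cd8_channel), mask, image.pixel_size_um,
                       radius_range_um, detection_threshold)
    return region_densities(mask, dist, cells, image.pixel_size_um,
                            periphery_um)
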