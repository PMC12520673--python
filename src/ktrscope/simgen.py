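"""Synthetic microscopy generator with known ground truth.

Emulates the data the downstream analysis assumes: H2B-marked nuclei moving
and dividing in a widefield field of view; CDK4/6 and CDK2 kinase
translocation reporters (KTRs) whose cytoplasm/nucleus partitioning follows
ground-truth activity trajectories; a cell-cycle degron channel; Hill-curve
dose–response checkerboards; and tumor sections with CD8+ cell point
patterns enriched at the periphery.

Scenarios
---------
``untreated``
    Both CDK4/6 and CDK2 activity high and cycling; cells divide.
``cdk46i``
    CDK4/6 activity suppressed; cells arrest (CDK2 ~ 0.5 plateau) but a
    configurable fraction re-activate CDK2 through a sigmoidal rise crossing
    1.0 inside a 24–36 h window — the drug-persister phenotype.
``cdk46i_plus_cdk7i``
    As ``cdk46i`` with a smaller re-activation fraction.

All outputs are pure functions of their configuration, including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .frames import FrameStack, SectionImage
from .pharm import DoseMatrix

Scenario = Literal["untreated", "cdk46i", "cdk46i_plus_cdk7i"]

#: rendered mean nuclear signal, arbitrary units
NUCLEAR_LEVEL = 1000.0
#: Gaussian blur applied to rendered frames (px), emulating the PSF
RENDER_BLUR_PX = 0.7

# persister fractions emulating the reported single-cell movie proportions
_SCENARIO_PERSISTER_FRACTION = {
    "untreated": 0.0,
    "cdk46i": 0.48,
    "cdk46i_plus_cdk7i": 0.10,
}


class PlacementError(ValueError):
    """Requested cells cannot be placed without full overlap."""


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the time-lapse simulator.

    Defaults reflect live-cell imaging of adherent breast-cancer cells at a
    12-minute cadence over 48 h.
    """

    rng_seed: int = 0
    field_size_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 1.0
    frame_interval_h: float = 0.2
    duration_h: float = 48.0
    n_cells: int = 20
    nucleus_radius_um: float = 8.0
    cytoplasm_width_um: float = 10.0
    motion_sigma_um_per_frame: float = 1.0
    division_rate_per_h: float = 0.04
    snr: float | None = 10.0
    illumination_bias_amplitude: float = 0.0
    background_level: float = 0.05
    persister_fraction: float | None = None
    rise_window_h: tuple[float, float] = (24.0, 36.0)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.frame_interval_h <= 0:
            raise ValueError("pixel_size_um and frame_interval_h must be > 0")
        if self.duration_h <= 0 or self.n_cells < 1:
            raise ValueError("duration_h must be > 0 and n_cells >= 1")
        if self.division_rate_per_h < 0:
            raise ValueError("division_rate_per_h must be >= 0")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be > 0 (or None for noiseless)")
        if not 0 <= self.illumination_bias_amplitude < 1:
            raise ValueError("illumination_bias_amplitude must be in [0, 1)")
        field_um = min(self.field_size_px) * self.pixel_size_um
        if 2 * self.nucleus_radius_um >= field_um:
            raise ValueError("nucleus diameter exceeds the field of view")
        if self.persister_fraction is not None and not 0 <= self.persister_fraction <= 1:
            raise ValueError("persister_fraction must be in [0, 1]")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_h / self.frame_interval_h))

    @property
    def times_h(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_h


@dataclass
class GroundTruth:
    """Ground truth accompanying a simulated movie.

    ``cells`` has one row per cell (lineage and persister label);
    ``frames`` one row per cell-frame (position and true signal values);
    ``divisions`` one row per division event, with ``frame`` the first frame
    of the daughters.
    """

    cells: pd.DataFrame
    frames: pd.DataFrame
    divisions: pd.DataFrame
    config: SimConfig
    scenario: str

    @property
    def n_persisters(self) -> int:
        return int(self.cells["is_persister"].sum())

    @property
    def persister_fraction(self) -> float:
        return float(self.cells["is_persister"].mean())

    def true_label_stack(self) -> np.ndarray:
        """Render per-frame label images (cell_id as label) from true geometry."""
        shape = self.config.field_size_px
        px = self.config.pixel_size_um
        out = np.zeros((self.config.n_frames, *shape), dtype=np.int32)
        for row in self.frames.itertuples():
            rr, cc = _disk_coords(row.y_um / px, row.x_um / px,
                                  row.radius_um / px, shape)
            out[row.frame, rr, cc] = row.cell_id
        return out


# ---------------------------------------------------------------------------
# activity trajectories


def _persister_rise_times(rng: np.random.Generator, n: int,
                          window: tuple[float, float]) -> np.ndarray:
    return rng.uniform(window[0], window[1], size=n)


def _treated_cdk2(t: np.ndarray, t_rise: float | None,
                  lo: float = 0.5, hi: float = 1.6, tau: float = 1.2) -> np.ndarray:
    """Arrest plateau with optional sigmoidal persister rise crossing 1.0 at t_rise."""
    base = lo + 0.65 * np.exp(-t / 3.0)
    if t_rise is None:
        return base
    # shift so the sigmoid crosses 1.0 exactly at t_rise
    s0 = (1.0 - lo) / (hi - lo)
    t50 = t_rise - tau * math.log(s0 / (1.0 - s0))
    rise = (hi - lo) / (1.0 + np.exp(-(t - t50) / tau))
    return np.maximum(base, lo + rise)


def _cell_trajectories(scenario: str, t: np.ndarray, birth_h: float,
                       t_rise: float | None, phase_offset: float) -> dict[str, np.ndarray]:
    """True CDK4/6, CDK2, degron and phase series for one cell on grid ``t``."""
    if scenario == "untreated":
        age = t - birth_h
        cdk46 = 0.85 + 0.1 * np.sin(2 * np.pi * age / 20.0 + phase_offset)
        cdk2 = 0.45 + 1.1 * (1.0 - np.exp(-age / 6.0))
        g1_len, s_len = 8.0, 8.0
        degron = 0.1 + 0.9 * np.clip((age - g1_len) / s_len, 0.0, 1.0)
        phase = np.where(age < g1_len, "G1", np.where(age < g1_len + s_len, "S", "G2M"))
    else:
        cdk46 = 0.2 + 0.7 * np.exp(-t / 3.0)
        cdk2 = _treated_cdk2(t, t_rise)
        if t_rise is None:
            degron = np.full_like(t, 1.0)  # Cdt1-type: high in G1 arrest
            phase = np.full(t.shape, "G1", dtype=object)
        else:
            s_entry = t_rise + 3.0
            degron = 1.0 - 0.85 / (1.0 + np.exp(-(t - s_entry) / 1.5))
            phase = np.where(t < s_entry, "G1", "S")
    return {"cdk46": cdk46, "cdk2": cdk2, "degron": degron,
            "phase": np.asarray(phase, dtype=object)}


def _effective_persister_fraction(cfg: SimConfig, scenario: str) -> float:
    if cfg.persister_fraction is not None:
        return cfg.persister_fraction
    return _SCENARIO_PERSISTER_FRACTION[scenario]


def _true_persister_label(t: np.ndarray, cdk2: np.ndarray,
                          frame_interval_h: float) -> bool:
    """Sliding-window persister rule on the true trajectory.

    Longest contiguous run of frames with CDK2 activity > 1.0 inside the
    30–48 h window must exceed 4 h (run length counted as span between first
    and last frame of the run).
    """
    from .pheno import longest_supra_threshold_run_h

    run = longest_supra_threshold_run_h(t, cdk2, threshold=1.0,
                                        window=(30.0, 48.0),
                                        frame_interval_h=frame_interval_h)
    return run > 4.0


# ---------------------------------------------------------------------------
# trace-level simulation (no imaging)


def simulate_trace_set(cfg: SimConfig, scenario: Scenario = "cdk46i",
                       noise_sd: float = 0.0):
    """Simulate per-cell activity traces directly (no image rendering).

    Returns ``(TraceSet, GroundTruth)`` where the TraceSet carries measured
    (optionally noisy) traces and the ground truth records the noiseless
    trajectories and persister labels. Cells neither move nor divide here;
    every trace spans the full movie.
    """
    from .reporters import TraceSet

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(cfg.rng_seed)
    t = cfg.times_h
    frac = _effective_persister_fraction(cfg, scenario)
    n_pers = int(round(frac * cfg.n_cells)) if scenario != "untreated" else 0
    pers_ids = set(rng.permutation(cfg.n_cells)[:n_pers] + 1)
    rises = iter(_persister_rise_times(rng, n_pers, cfg.rise_window_h))
    offsets = rng.uniform(0, 2 * np.pi, cfg.n_cells)

    cell_rows, trace_rows = [], []
    for cid in range(1, cfg.n_cells + 1):
        t_rise = float(next(rises)) if cid in pers_ids else None
        traj = _cell_trajectories(scenario, t, 0.0, t_rise, offsets[cid - 1])
        is_pers = _true_persister_label(t, traj["cdk2"], cfg.frame_interval_h)
        cell_rows.append(dict(cell_id=cid, parent_id=0, birth_frame=0,
                              end_frame=cfg.n_frames - 1,
                              is_persister=is_pers,
                              t_rise_h=t_rise if t_rise is not None else np.nan))
        noisy46 = traj["cdk46"] + rng.normal(0, noise_sd, t.size) if noise_sd else traj["cdk46"]
        noisy2 = traj["cdk2"] + rng.normal(0, noise_sd, t.size) if noise_sd else traj["cdk2"]
        trace_rows.append(pd.DataFrame({
            "track_id": cid, "frame": np.arange(t.size), "t_h": t,
            "cdk46": noisy46, "cdk2": noisy2, "degron": traj["degron"],
            "valid": True, "interpolated": False,
        }))

    traces = TraceSet(pd.concat(trace_rows, ignore_index=True),
                      frame_interval_h=cfg.frame_interval_h)
    truth = GroundTruth(cells=pd.DataFrame(cell_rows), frames=pd.DataFrame(),
                        divisions=pd.DataFrame(columns=["parent_id", "frame",
                                                        "daughter1", "daughter2"]),
                        config=cfg, scenario=scenario)
    return traces, truth


# ---------------------------------------------------------------------------
# spatial simulation and rendering


def _place_cells(rng: np.random.Generator, n: int, shape: tuple[int, int],
                 px: float, margin_um: float, min_sep_um: float) -> np.ndarray:
    lo = margin_um
    hi_x = shape[1] * px - margin_um
    hi_y = shape[0] * px - margin_um
    if hi_x <= lo or hi_y <= lo:
        raise PlacementError("field too small for requested margin")
    pts: list[tuple[float, float]] = []
    for _ in range(20000 * n):
        x = rng.uniform(lo, hi_x)
        y = rng.uniform(lo, hi_y)
        if all((x - qx) ** 2 + (y - qy) ** 2 >= min_sep_um**2 for qx, qy in pts):
            pts.append((x, y))
            if len(pts) == n:
                return np.asarray(pts)
    raise PlacementError(
        f"could not place {n} cells at min separation {min_sep_um:.1f} um")


def _reflect(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    v = np.mod(v - lo, 2 * span)
    v = np.where(v > span, 2 * span - v, v)
    return v + lo


def _disk_coords(r0: float, c0: float, radius_px: float, shape):
    from skimage.draw import disk

    return disk((r0, c0), radius_px, shape=shape)


def _patch_masks(r0: float, c0: float, r_nuc_px: float, r_out_px: float, shape):
    """Global index arrays for nucleus disk and cytoplasm annulus of one cell."""
    size = int(math.ceil(r_out_px)) + 2
    rmin = max(int(math.floor(r0)) - size, 0)
    rmax = min(int(math.ceil(r0)) + size + 1, shape[0])
    cmin = max(int(math.floor(c0)) - size, 0)
    cmax = min(int(math.ceil(c0)) + size + 1, shape[1])
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    d = np.hypot(rr - r0, cc - c0)
    nuc = d <= r_nuc_px
    cyto = (d > r_nuc_px) & (d <= r_out_px)
    return (rr[nuc], cc[nuc]), (rr[cyto], cc[cyto])


def illumination_bias_field(shape: tuple[int, int], amplitude: float) -> np.ndarray:
    """Smooth multiplicative vignetting; 1 at the center, 1 - amplitude at corners."""
    r = np.linspace(-1.0, 1.0, shape[0])[:, None]
    c = np.linspace(-1.0, 1.0, shape[1])[None, :]
    return 1.0 - amplitude * (r**2 + c**2) / 2.0


def _apply_noise(img: np.ndarray, snr: float | None,
                 rng: np.random.Generator) -> np.ndarray:
    if snr is None:
        return img
    # Poisson shot noise scaled so nuclear-level signal has the requested SNR,
    # plus a small Gaussian read-noise floor.
    scale = snr**2 / NUCLEAR_LEVEL
    shot = rng.poisson(np.clip(img, 0, None) * scale) / scale
    return shot + rng.normal(0.0, 0.005 * NUCLEAR_LEVEL, img.shape)


def simulate_timelapse(cfg: SimConfig,
                       scenario: Scenario = "cdk46i") -> tuple[FrameStack, GroundTruth]:
    """Simulate a 4-channel movie (H2B, CDK4/6 sensor, CDK2 sensor, degron).

    Nuclei are Gaussian-blurred disks; each cell's KTR channels place
    ``NUCLEAR_LEVEL`` in the nucleus and ``NUCLEAR_LEVEL x activity`` in a
    surrounding cytoplasm annulus, so the background-subtracted C/N ratio of
    rendered pixels equals the true activity up to shot noise. Motion is a
    reflected Gaussian random walk; divisions (untreated scenario only) spawn
    two daughters one nucleus radius apart, each with ~half the parent H2B
    intensity.
    """
    if scenario not in _SCENARIO_PERSISTER_FRACTION:
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(cfg.rng_seed)
    shape = cfg.field_size_px
    px = cfg.pixel_size_um
    t_grid = cfg.times_h
    n_frames = cfg.n_frames
    r_um = cfg.nucleus_radius_um
    margin = r_um + cfg.cytoplasm_width_um
    frac = _effective_persister_fraction(cfg, scenario)
    n_pers = int(round(frac * cfg.n_cells)) if scenario != "untreated" else 0

    starts = _place_cells(rng, cfg.n_cells, shape, px, margin,
                          min_sep_um=2.5 * r_um)
    pers_ids = set(rng.permutation(cfg.n_cells)[:n_pers] + 1)
    rises = iter(_persister_rise_times(rng, n_pers, cfg.rise_window_h))

    divide = scenario == "untreated" and cfg.division_rate_per_h > 0
    p_div = cfg.division_rate_per_h * cfg.frame_interval_h

    # cell registry -------------------------------------------------------
    cells: list[dict] = []

    def new_cell(parent_id: int, birth_frame: int, pos, h2b_factor: float) -> dict:
        cid = len(cells) + 1
        t_rise = None
        if parent_id == 0 and cid in pers_ids:
            t_rise = float(next(rises))
        cell = dict(cell_id=cid, parent_id=parent_id, birth_frame=birth_frame,
                    end_frame=n_frames - 1, pos=np.asarray(pos, float),
                    h2b_factor=h2b_factor, t_rise=t_rise,
                    phase_offset=rng.uniform(0, 2 * np.pi),
                    traj=None, positions=np.full((n_frames, 2), np.nan))
        cell["traj"] = _cell_trajectories(
            scenario, t_grid, birth_frame * cfg.frame_interval_h,
            t_rise, cell["phase_offset"])
        cells.append(cell)
        return cell

    for i in range(cfg.n_cells):
        new_cell(0, 0, starts[i], 1.0)

    divisions: list[dict] = []
    lo = margin
    hi = (shape[1] * px - margin, shape[0] * px - margin)  # (x, y)

    min_sep = 2.1 * r_um  # excluded volume: nuclei are solid

    def _resolve_overlaps(alive: list[dict]) -> None:
        for _ in range(8):
            moved = False
            for i in range(len(alive)):
                for j in range(i + 1, len(alive)):
                    delta = alive[i]["pos"] - alive[j]["pos"]
                    d = float(np.hypot(*delta))
                    if d < min_sep:
                        if d < 1e-9:
                            delta = np.array([1.0, 0.0])
                            d = 1.0
                        push = (min_sep - d) / 2 * delta / d
                        alive[i]["pos"] = np.clip(alive[i]["pos"] + push, lo, hi)
                        alive[j]["pos"] = np.clip(alive[j]["pos"] - push, lo, hi)
                        moved = True
            if not moved:
                break

    for f in range(n_frames):
        alive = [c for c in cells if c["birth_frame"] <= f <= c["end_frame"]]
        for c in alive:
            if f > c["birth_frame"]:
                step = rng.normal(0.0, cfg.motion_sigma_um_per_frame, 2)
                c["pos"] = c["pos"] + step
                c["pos"][0] = _reflect(c["pos"][0:1], lo, hi[0])[0]
                c["pos"][1] = _reflect(c["pos"][1:2], lo, hi[1])[0]
        _resolve_overlaps(alive)
        for c in alive:
            c["positions"][f] = c["pos"]
        if divide and f < n_frames - 1:
            for c in alive:
                age_h = (f - c["birth_frame"]) * cfg.frame_interval_h
                if age_h > 10.0 and rng.uniform() < p_div:
                    c["end_frame"] = f
                    axis = rng.uniform(0, 2 * np.pi)
                    offset = r_um * np.array([math.cos(axis), math.sin(axis)])
                    f1 = float(np.clip(rng.normal(0.5, 0.02), 0.4, 0.6))
                    f2 = float(np.clip(rng.normal(0.5, 0.02), 0.4, 0.6))
                    d1 = new_cell(c["cell_id"], f + 1,
                                  np.clip(c["pos"] + offset, lo, hi), c["h2b_factor"] * f1)
                    d2 = new_cell(c["cell_id"], f + 1,
                                  np.clip(c["pos"] - offset, lo, hi), c["h2b_factor"] * f2)
                    divisions.append(dict(parent_id=c["cell_id"], frame=f + 1,
                                          daughter1=d1["cell_id"],
                                          daughter2=d2["cell_id"]))

    # ground-truth tables -------------------------------------------------
    frame_rows = []
    for c in cells:
        idx = np.arange(c["birth_frame"], c["end_frame"] + 1)
        frame_rows.append(pd.DataFrame({
            "cell_id": c["cell_id"], "frame": idx,
            "t_h": t_grid[idx],
            "x_um": c["positions"][idx, 0], "y_um": c["positions"][idx, 1],
            "radius_um": r_um, "h2b_factor": c["h2b_factor"],
            "cdk46": c["traj"]["cdk46"][idx], "cdk2": c["traj"]["cdk2"][idx],
            "degron": c["traj"]["degron"][idx],
            "phase": c["traj"]["phase"][idx],
        }))
    frames_df = pd.concat(frame_rows, ignore_index=True)
    cells_df = pd.DataFrame([
        dict(cell_id=c["cell_id"], parent_id=c["parent_id"],
             birth_frame=c["birth_frame"], end_frame=c["end_frame"],
             is_persister=_true_persister_label(
                 t_grid[c["birth_frame"]:c["end_frame"] + 1],
                 c["traj"]["cdk2"][c["birth_frame"]:c["end_frame"] + 1],
                 cfg.frame_interval_h),
             t_rise_h=c["t_rise"] if c["t_rise"] is not None else np.nan)
        for c in cells])
    divisions_df = pd.DataFrame(divisions, columns=["parent_id", "frame",
                                                    "daughter1", "daughter2"])

    # rendering -----------------------------------------------------------
    bias = illumination_bias_field(shape, cfg.illumination_bias_amplitude)
    bg = cfg.background_level * NUCLEAR_LEVEL
    r_px = r_um / px
    r_out_px = (r_um + cfg.cytoplasm_width_um) / px
    names = ["h2b", "cdk46_sensor", "cdk2_sensor", "degron"]
    stacks = {n: np.zeros((n_frames, *shape), dtype=np.float64) for n in names}

    by_frame: dict[int, list[dict]] = {f: [] for f in range(n_frames)}
    for c in cells:
        for f in range(c["birth_frame"], c["end_frame"] + 1):
            by_frame[f].append(c)

    for f in range(n_frames):
        imgs = {n: np.full(shape, bg, dtype=np.float64) for n in names}
        patches = []
        nuc_any = np.zeros(shape, dtype=bool)
        for c in by_frame[f]:
            x, y = c["positions"][f]
            nuc, cyto = _patch_masks(y / px, x / px, r_px, r_out_px, shape)
            patches.append((c, nuc, cyto))
            nuc_any[nuc] = True
        for c, nuc, cyto in patches:
            # cytoplasm never overlays a nucleus (confluent-monolayer tiling)
            free = ~nuc_any[cyto]
            cyto = (cyto[0][free], cyto[1][free])
            imgs["h2b"][nuc] += NUCLEAR_LEVEL * c["h2b_factor"]
            for ch, key in (("cdk46_sensor", "cdk46"), ("cdk2_sensor", "cdk2")):
                act = c["traj"][key][f]
                imgs[ch][nuc] += NUCLEAR_LEVEL
                imgs[ch][cyto] += NUCLEAR_LEVEL * act
            imgs["degron"][nuc] += NUCLEAR_LEVEL * c["traj"]["degron"][f]
        for n in names:
            img = ndi.gaussian_filter(imgs[n], RENDER_BLUR_PX) * bias
            stacks[n][f] = _apply_noise(img, cfg.snr, rng)

    stack = FrameStack({n: stacks[n] for n in names}, pixel_size_um=px,
                       frame_interval_h=cfg.frame_interval_h)
    truth = GroundTruth(cells=cells_df, frames=frames_df,
                        divisions=divisions_df, config=cfg, scenario=scenario)
    return stack, truth


def simulate_nuclei_field(n_cells: int = 50, field_size_px: tuple[int, int] = (512, 512),
                          pixel_size_um: float = 1.0, nucleus_radius_um: float = 8.0,
                          radius_jitter: float = 0.1, snr: float | None = 10.0,
                          illumination_bias_amplitude: float = 0.0,
                          background_level: float = 0.05,
                          rng_seed: int = 0) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a single fixed-cell DNA-stain field of non-overlapping nuclei.

    Returns the image and a truth table (cell_id, x_um, y_um, radius_um).
    """
    rng = np.random.default_rng(rng_seed)
    r_max = nucleus_radius_um * (1 + radius_jitter)
    pts = _place_cells(rng, n_cells, field_size_px, pixel_size_um,
                       margin_um=2 * r_max, min_sep_um=2.6 * r_max)
    radii = nucleus_radius_um * rng.uniform(1 - radius_jitter, 1 + radius_jitter,
                                            n_cells)
    img = np.full(field_size_px, background_level * NUCLEAR_LEVEL)
    rows = []
    for i, ((x, y), r) in enumerate(zip(pts, radii), start=1):
        rr, cc = _disk_coords(y / pixel_size_um, x / pixel_size_um,
                              r / pixel_size_um, field_size_px)
        img[rr, cc] += NUCLEAR_LEVEL
        rows.append(dict(cell_id=i, x_um=x, y_um=y, radius_um=r))
    img = ndi.gaussian_filter(img, RENDER_BLUR_PX)
    img *= illumination_bias_field(field_size_px, illumination_bias_amplitude)
    img = _apply_noise(img, snr, rng)
    return img, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dose-response checkerboards


def hill_inhibition(dose: np.ndarray, ic50: float, hill: float,
                    emax: float = 1.0) -> np.ndarray:
    """Fractional inhibition of a single agent (0 at dose 0, -> emax)."""
    dose = np.asarray(dose, dtype=float)
    out = np.zeros_like(dose)
    pos = dose > 0
    out[pos] = emax * dose[pos] ** hill / (dose[pos] ** hill + ic50**hill)
    return out


def interaction_bump(ya: np.ndarray, yb: np.ndarray) -> np.ndarray:
    """Smooth bump, zero on the single-agent margins, peaking mid-surface."""
    return 16.0 * np.outer(ya * (1 - ya), yb * (1 - yb))


def simulate_dose_matrix(ic50_a: float, hill_a: float, ic50_b: float, hill_b: float,
                         interaction: float = 0.0,
                         doses_a: np.ndarray | None = None,
                         doses_b: np.ndarray | None = None,
                         noise_sd: float = 0.0, n_replicates: int = 1,
                         rng_seed: int = 0, emax_a: float = 1.0,
                         emax_b: float = 1.0) -> DoseMatrix:
    """Simulate a checkerboard of inhibition fractions.

    The noiseless surface is ``clamp(ya + yb - ya*yb + interaction * g, 0, 1)``
    where ``ya``, ``yb`` are Hill-curve inhibitions and ``g`` the
    margin-vanishing bump of :func:`interaction_bump`; ``interaction = 0``
    yields exact Bliss independence.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if doses_a is None:
        doses_a = np.concatenate([[0.0], np.geomspace(ic50_a / 16, ic50_a * 16, 7)])
    if doses_b is None:
        doses_b = np.concatenate([[0.0], np.geomspace(ic50_b / 16, ic50_b * 16, 7)])
    doses_a = np.asarray(doses_a, float)
    doses_b = np.asarray(doses_b, float)
    if (doses_a < 0).any() or (doses_b < 0).any():
        raise ValueError("doses must be >= 0")
    rng = np.random.default_rng(rng_seed)
    ya = hill_inhibition(doses_a, ic50_a, hill_a, emax_a)
    yb = hill_inhibition(doses_b, ic50_b, hill_b, emax_b)
    surface = (ya[:, None] + yb[None, :] - np.outer(ya, yb)
               + interaction * interaction_bump(ya, yb))
    reps = []
    for _ in range(n_replicates):
        noisy = surface + (rng.normal(0, noise_sd, surface.shape) if noise_sd else 0.0)
        reps.append(np.clip(noisy, 0.0, 1.0))
    truth = dict(ic50_a=ic50_a, hill_a=hill_a, ic50_b=ic50_b, hill_b=hill_b,
                 emax_a=emax_a, emax_b=emax_b, interaction=interaction,
                 noise_sd=noise_sd, surface=np.clip(surface, 0.0, 1.0))
    return DoseMatrix(doses_a=doses_a, doses_b=doses_b,
                      inhibition=np.stack(reps), truth=truth)


# ---------------------------------------------------------------------------
# tumor sections


@dataclass
class SectionTruth:
    """Ground truth for a simulated tumor section."""

    mask: np.ndarray
    distance_um: np.ndarray
    points: pd.DataFrame  # x_um, y_um, d_um, region
    pixel_size_um: float
    params: dict = field(default_factory=dict)


def simulate_section(field_mm: tuple[float, float] = (4.0, 4.0),
                     tumor_shape_seed: int = 0, n_cd8: int = 400,
                     periphery_enrichment: float = 3.0, rng_seed: int = 0,
                     pixel_size_um: float = 2.0, tumor_radius_mm: float = 1.5,
                     irregularity: float = 0.1, periphery_um: float = 500.0,
                     snr: float | None = 20.0,
                     spot_sigma_um: float = 2.5) -> tuple[SectionImage, SectionTruth]:
    """Simulate a tumor section with CD8+ cells enriched at the periphery.

    CD8 points are placed inside the tumor with a periphery:core density
    ratio equal to ``periphery_enrichment`` (``1`` = uniform; ``np.inf``
    places none in the core). Region labels use the 500 um margin-distance
    rule (periphery: ``0 < d <= periphery_um``; core: ``d > periphery_um``).
    """
    if periphery_enrichment < 0:
        raise ValueError("periphery_enrichment must be >= 0")
    w_mm, h_mm = field_mm
    shape = (int(round(h_mm * 1000 / pixel_size_um)),
             int(round(w_mm * 1000 / pixel_size_um)))
    shape_rng = np.random.default_rng(tumor_shape_seed)
    harmonics = np.arange(2, 6)
    amps = shape_rng.normal(0, 1, harmonics.size)
    amps = irregularity * amps / (np.abs(amps).sum() + 1e-12) if irregularity else amps * 0
    phases = shape_rng.uniform(0, 2 * np.pi, harmonics.size)

    r_max_mm = tumor_radius_mm * (1 + np.abs(amps).sum())
    if 2 * r_max_mm >= min(field_mm):
        raise ValueError("tumor does not fit strictly inside the field")

    cy = shape[0] / 2.0
    cx = shape[1] / 2.0
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    dy = (rr - cy) * pixel_size_um / 1000.0
    dx = (cc - cx) * pixel_size_um / 1000.0
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    radius = tumor_radius_mm * (1.0 + sum(
        a * np.cos(k * theta + p) for a, k, p in zip(amps, harmonics, phases)))
    mask = r <= radius

    dist_um = ndi.distance_transform_edt(mask) * pixel_size_um

    rng = np.random.default_rng(rng_seed)
    periph_px = mask & (dist_um <= periphery_um)
    core_px = mask & (dist_um > periphery_um)
    weights = np.zeros(shape)
    if np.isinf(periphery_enrichment):
        weights[periph_px] = 1.0
    else:
        weights[periph_px] = periphery_enrichment
        weights[core_px] = 1.0
    placeable = int((weights > 0).sum())
    if n_cd8 > placeable:
        raise PlacementError(f"cannot place {n_cd8} cells on {placeable} pixels")
    flat = weights.ravel()
    idx = rng.choice(flat.size, size=n_cd8, replace=True, p=flat / flat.sum())
    prow, pcol = np.unravel_index(idx, shape)
    jit = rng.uniform(-0.5, 0.5, (2, n_cd8))
    x_um = (pcol + jit[0]) * pixel_size_um
    y_um = (prow + jit[1]) * pixel_size_um
    d_um = dist_um[prow, pcol]
    region = np.where(d_um > periphery_um, "core", "periphery")
    points = pd.DataFrame(dict(x_um=x_um, y_um=y_um, d_um=d_um, region=region))

    # render ---------------------------------------------------------------
    tumor_ch = ndi.gaussian_filter(mask.astype(float), 3.0) + 0.05
    cd8_ch = np.zeros(shape)
    sig_px = spot_sigma_um / pixel_size_um
    half = max(int(math.ceil(4 * sig_px)), 2)
    for x, y in zip(x_um / pixel_size_um, y_um / pixel_size_um):
        r0 = int(round(y))
        c0 = int(round(x))
        rmin, rmax_ = max(r0 - half, 0), min(r0 + half + 1, shape[0])
        cmin, cmax_ = max(c0 - half, 0), min(c0 + half + 1, shape[1])
        gr, gc = np.mgrid[rmin:rmax_, cmin:cmax_]
        cd8_ch[rmin:rmax_, cmin:cmax_] += np.exp(
            -((gr - y) ** 2 + (gc - x) ** 2) / (2 * sig_px**2))
    cd8_ch += 0.02
    if snr is not None:
        tumor_ch = tumor_ch + rng.normal(0, 1.0 / snr, shape)
        cd8_ch = cd8_ch + rng.normal(0, 1.0 / snr, shape)

    image = SectionImage({"tumor": tumor_ch, "cd8": cd8_ch},
                         pixel_size_um=pixel_size_um)
    truth = SectionTruth(mask=mask, distance_um=dist_um, points=points,
                         pixel_size_um=pixel_size_um,
                         params=dict(field_mm=field_mm, n_cd8=n_cd8,
                                     periphery_enrichment=periphery_enrichment,
                                     tumor_radius_mm=tumor_radius_mm,
                                     periphery_um=periphery_um))
    return image, truth


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Convenience: same configuration, different seed."""
    return replace(cfg, rng_seed=seed)
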