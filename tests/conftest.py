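"""Shared fixtures: simulated movies and their pipeline products.

The expensive simulations are session-scoped so that unit tests and the
end-to-end acceptance checks reuse the same data.
"""

from __future__ import annotations

import numpy as np
import pytest

from ktrscope import imgproc, qc, reporters, simgen, tracker


@pytest.fixture(scope="session")
def noiseless_movie():
    """20-cell noiseless CDK4/6i movie with a constructed 50% persister mix."""
    cfg = simgen.SimConfig(rng_seed=1, n_cells=20, snr=None,
                           persister_fraction=0.5, division_rate_per_h=0.0)
    stack, truth = simgen.simulate_timelapse(cfg, "cdk46i")
    return cfg, stack, truth


@pytest.fixture(scope="session")
def noiseless_pipeline(noiseless_movie):
    """Masks, tracks and traces extracted from the noiseless movie."""
    cfg, stack, truth = noiseless_movie
    masks = imgproc.segment_movie(stack)
    dets = imgproc.detections_table(masks, stack.channel("h2b"),
                                    stack.frame_interval_h)
    tracks, events = tracker.track_movie(dets)
    readouts = reporters.quantify_movie(stack, masks)
    traces = reporters.build_traces(tracks, readouts, 0.0,
                                    cfg.frame_interval_h)
    return dict(cfg=cfg, stack=stack, truth=truth, masks=masks,
                tracks=tracks, events=events, traces=traces)


@pytest.fixture(scope="session")
def untreated_movie():
    """Cycling, dividing cells at SNR 10 — the tracking/mitosis benchmark."""
    cfg = simgen.SimConfig(rng_seed=3, n_cells=25, field_size_px=(360, 360),
                           snr=10.0, duration_h=24.0, division_rate_per_h=0.04)
    stack, truth = simgen.simulate_timelapse(cfg, "untreated")
    return cfg, stack, truth


@pytest.fixture(scope="session")
def untreated_pipeline(untreated_movie):
    cfg, stack, truth = untreated_movie
    masks = imgproc.segment_movie(stack)
    dets = imgproc.detections_table(masks, stack.channel("h2b"),
                                    stack.frame_interval_h)
    tracks, events = tracker.track_movie(dets)
    return dict(cfg=cfg, stack=stack, truth=truth, masks=masks,
                tracks=tracks, events=events)


@pytest.fixture(scope="session")
def nuclei_field():
    """50 non-overlapping nuclei, SNR 10, with ground-truth centroids."""
    img, truth = simgen.simulate_nuclei_field(rng_seed=5)
    return img, truth


@pytest.fixture(scope="session")
def simulated_section():
    """Tumor section with 3x periphery-enriched CD8 point pattern."""
    return simgen.simulate_section(rng_seed=2, n_cd8=400,
                                   periphery_enrichment=3.0)


def per_frame_detection_scores(masks, truth_frames, match_radius_um=8.0):
    recalls, precisions = [], []
    for f, mask in enumerate(masks):
        g = truth_frames[truth_frames["frame"] == f]
        props = mask.properties()
        sc = qc.detection_scores(props[["x_um", "y_um"]].to_numpy(),
                                 g[["x_um", "y_um"]].to_numpy(),
                                 match_radius_um)
        recalls.append(sc.recall)
        precisions.append(sc.precision)
    return np.asarray(recalls), np.asarray(precisions)
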