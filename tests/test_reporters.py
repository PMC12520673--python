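"""C/N ring quantification, trace assembly and degron phase calling."""

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk

from ktrscope import reporters
from ktrscope.imgproc import LabelMask
from ktrscope.tracker import CellTrack


def _two_region_image(labels, nucleus=100.0, cytoplasm=200.0, bg=0.0,
                      reach_um=10.0):
    """Nucleus value inside masks, cytoplasm value in a band around them."""
    from scipy import ndimage as ndi

    img = np.full(labels.shape, bg)
    d = ndi.distance_transform_edt(labels == 0)
    img[labels > 0] = nucleus
    img[(d > 0) & (d <= reach_um)] = cytoplasm
    return img


def _mask_with_disks(centers, radius=8, shape=(128, 128)):
    labels = np.zeros(shape, np.int32)
    for i, (r, c) in enumerate(centers, start=1):
        rr, cc = disk((r, c), radius, shape=shape)
        labels[rr, cc] = i
    return LabelMask(labels, 1.0)


class TestCnRatio:
    def test_uniform_compartments_give_exact_ratio(self):
        mask = _mask_with_disks([(64, 64)])
        img = _two_region_image(mask.labels, nucleus=100.0, cytoplasm=200.0)
        table = reporters.cn_ratio(img, mask)
        assert table["cn_ratio"].iloc[0] == pytest.approx(2.0)
        assert table["valid"].iloc[0]

    def test_constant_image_gives_unit_ratio(self):
        mask = _mask_with_disks([(40, 40), (90, 90)])
        table = reporters.cn_ratio(np.full((128, 128), 7.0), mask)
        np.testing.assert_allclose(table["cn_ratio"], 1.0)

    def test_scale_invariance(self):
        mask = _mask_with_disks([(64, 64)])
        img = _two_region_image(mask.labels, 100.0, 150.0)
        r1 = reporters.cn_ratio(img, mask)["cn_ratio"].iloc[0]
        r2 = reporters.cn_ratio(img * 13.7, mask)["cn_ratio"].iloc[0]
        assert r1 == pytest.approx(r2)

    def test_overlapping_rings_match_bruteforce_oracle(self):
        from oracles import cn_ratio_oracle

        mask = _mask_with_disks([(50, 50), (50, 65)], radius=6, shape=(100, 110))
        rng = np.random.default_rng(1)
        img = rng.uniform(50, 150, (100, 110))
        table = reporters.cn_ratio(img, mask).set_index("label")
        expected = cn_ratio_oracle(img, mask.labels, 1.0)
        for lab, ref in expected.items():
            got = table.loc[lab, "cn_ratio"]
            if np.isnan(ref):
                assert not table.loc[lab, "valid"]
            else:
                assert got == pytest.approx(ref)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_fixtures_match_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 5)
        shape = (96, 96)
        centers = rng.uniform(16, 80, (n, 2))
        mask = _mask_with_disks([tuple(c) for c in centers],
                                radius=int(rng.integers(4, 8)), shape=shape)
        if mask.n_labels == 0:
            pytest.skip("degenerate fixture")
        img = rng.uniform(10, 300, shape)
        from oracles import cn_ratio_oracle

        table = reporters.cn_ratio(img, mask, min_ring_px=1).set_index("label")
        for lab, ref in cn_ratio_oracle(img, mask.labels, 1.0).items():
            got = table.loc[lab, "cn_ratio"]
            assert (np.isnan(got) and np.isnan(ref)) or got == pytest.approx(ref)

    def test_fully_excluded_ring_flagged_invalid_not_error(self):
        # two masks so close that every ring pixel is contested
        mask = _mask_with_disks([(50, 48), (50, 60)], radius=10, shape=(100, 108))
        img = np.full((100, 108), 5.0)
        table = reporters.cn_ratio(img, mask, min_ring_px=10**6)
        assert not table["valid"].any()

    def test_invalid_ring_geometry_rejected(self):
        mask = _mask_with_disks([(20, 20)])
        with pytest.raises(ValueError):
            reporters.cn_ratio(np.zeros((128, 128)), mask, ring_inner_um=10,
                               ring_outer_um=2)


class TestNuclearIntensity:
    def test_constant_image_returns_constant(self):
        mask = _mask_with_disks([(30, 30), (70, 70)])
        table = reporters.nuclear_intensity(np.full((128, 128), 42.0), mask)
        np.testing.assert_allclose(table["median"], 42.0)

    def test_empty_mask_empty_table(self):
        mask = LabelMask(np.zeros((32, 32), np.int32), 1.0)
        assert reporters.nuclear_intensity(np.zeros((32, 32)), mask).empty

    def test_degron_series_recovered_from_noiseless_movie(self, noiseless_movie):
        cfg, stack, truth = noiseless_movie
        labels = truth.true_label_stack()
        f = 100
        mask = LabelMask(labels[f], cfg.pixel_size_um)
        table = reporters.nuclear_intensity(stack.frame("degron", f), mask,
                                            background=0.05 * 1000.0)
        g = truth.frames[truth.frames["frame"] == f].rename(
            columns={"cell_id": "label"})
        merged = table.merge(g[["label", "degron"]], on="label")
        rel = (merged["median"] / 1000.0 - merged["degron"]).abs()
        assert rel.max() < 0.01


def _track(track_id, frames, x=50.0, y=50.0, label=1):
    frames = np.asarray(frames)
    return CellTrack(track_id=track_id, frames=frames,
                     t_h=frames * 0.2, x_um=np.full(frames.size, x),
                     y_um=np.full(frames.size, y),
                     label=np.full(frames.size, label, int),
                     h2b_int=np.full(frames.size, 100.0))


def _readouts(frames, label=1, cdk2=1.2, valid=True):
    return pd.DataFrame({
        "frame": frames, "label": label, "cdk46": 0.5, "cdk2": cdk2,
        "degron": 1.0, "valid": valid,
    })


class TestBuildTraces:
    def test_full_track_has_full_unflagged_trace(self):
        track = _track(1, range(10))
        traces = reporters.build_traces([track], _readouts(range(10)))
        tr = traces.track(1)
        assert len(tr) == 10
        assert tr["valid"].all() and not tr["interpolated"].any()

    def test_bridged_gap_is_interpolated_and_flagged(self):
        frames = [f for f in range(10) if f != 4]
        track = _track(1, frames)
        readouts = _readouts(frames)
        readouts.loc[readouts["frame"] == 3, "cdk2"] = 1.0
        readouts.loc[readouts["frame"] == 5, "cdk2"] = 2.0
        traces = reporters.build_traces([track], readouts)
        tr = traces.track(1).set_index("frame")
        assert bool(tr.loc[4, "interpolated"])
        assert tr.loc[4, "cdk2"] == pytest.approx(1.5)

    def test_long_invalid_runs_stay_invalid(self):
        track = _track(1, range(12))
        readouts = _readouts(range(12))
        readouts.loc[readouts["frame"].isin([4, 5, 6, 7]), "valid"] = False
        traces = reporters.build_traces([track], readouts, max_gap=2)
        tr = traces.track(1).set_index("frame")
        assert not tr.loc[[4, 5, 6, 7], "valid"].any()

    def test_short_traces_excluded_from_analysis_set(self, caplog):
        track = _track(1, range(10))  # 1.8 h << 18 h minimum
        traces = reporters.build_traces([track], _readouts(range(10)))
        assert traces.for_analysis().data.empty

    def test_treatment_time_beyond_span_rejected(self):
        track = _track(1, range(10))
        with pytest.raises(ValueError):
            reporters.build_traces([track], _readouts(range(10)),
                                   treatment_time_h=100.0)


class TestPhaseTransitions:
    def test_cdt1_step_trace_called_at_step_times(self):
        t = np.arange(0, 40, 0.2)
        v = np.where(t < 10, 1.0, np.where(t < 20, 0.15, 0.95))
        calls = reporters.call_phase_transitions(t, v, "cdt1")
        assert calls.transitions["G1/S"] == pytest.approx(10.0, abs=0.2)
        assert calls.transitions["S/G2"] == pytest.approx(20.0, abs=0.2)
        assert [p for p, *_ in calls.intervals] == ["G1", "S", "G2M"]

    def test_constant_trace_has_no_transitions(self):
        t = np.arange(0, 30, 0.2)
        for reporter in ("cdt1", "geminin"):
            assert reporters.call_phase_transitions(
                t, np.full(t.size, 0.5), reporter).empty

    def test_geminin_ramp_onset_called_within_one_frame(self):
        t = np.arange(0, 30, 0.2)
        v = np.where(t < 10, 0.1, 0.1 + 0.05 * (t - 10))
        calls = reporters.call_phase_transitions(t, v, "geminin")
        assert calls.transitions["S-entry"] == pytest.approx(10.0, abs=0.21)

    def test_unknown_reporter_rejected(self):
        with pytest.raises(ValueError):
            reporters.call_phase_transitions(np.arange(10.0), np.ones(10),
                                             "fucci")
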