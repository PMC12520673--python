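"""Generator contracts: determinism, construction guarantees, geometry."""

import numpy as np
import pytest

from ktrscope import pharm, simgen
from ktrscope.simgen import PlacementError, SimConfig


class TestSimConfig:
    def test_rejects_invalid_values(self):
        with pytest.raises(ValueError):
            SimConfig(pixel_size_um=0)
        with pytest.raises(ValueError):
            SimConfig(illumination_bias_amplitude=1.0)
        with pytest.raises(ValueError):
            SimConfig(snr=-1)
        with pytest.raises(ValueError):
            SimConfig(nucleus_radius_um=200, field_size_px=(64, 64))

    def test_frame_grid_matches_cadence(self):
        cfg = SimConfig(duration_h=48.0, frame_interval_h=0.2)
        assert cfg.n_frames == 240
        assert cfg.times_h[1] - cfg.times_h[0] == pytest.approx(0.2)


class TestTimelapse:
    def test_seeded_determinism_bit_identical(self):
        cfg = SimConfig(rng_seed=11, n_cells=5, duration_h=2.0, snr=8.0)
        s1, t1 = simgen.simulate_timelapse(cfg, "cdk46i")
        s2, t2 = simgen.simulate_timelapse(cfg, "cdk46i")
        for name in s1.channel_names:
            assert np.array_equal(s1.channel(name), s2.channel(name))
        assert t1.frames.equals(t2.frames)

    def test_persister_count_forced_by_construction(self, noiseless_movie):
        _, _, truth = noiseless_movie
        assert truth.n_persisters == 10
        assert len(truth.cells) == 20

    def test_persister_labels_match_sliding_window_oracle(self, noiseless_movie):
        from oracles import longest_run_oracle

        cfg, _, truth = noiseless_movie
        traces, t2 = simgen.simulate_trace_set(cfg, "cdk46i")
        for tid in traces.track_ids:
            tr = traces.track(tid)
            run = longest_run_oracle(tr["t_h"].to_numpy(), tr["cdk2"].to_numpy())
            expected = bool(t2.cells.set_index("cell_id")["is_persister"][tid])
            assert (run > 4.0) == expected

    def test_combination_scenario_reduces_persisters(self):
        cfg = SimConfig(rng_seed=2, n_cells=50)
        _, mono = simgen.simulate_trace_set(cfg, "cdk46i")
        _, combo = simgen.simulate_trace_set(cfg, "cdk46i_plus_cdk7i")
        assert combo.persister_fraction < mono.persister_fraction
        assert mono.n_persisters == 24  # 0.48 x 50

    def test_illumination_bias_corner_to_center_ratio(self):
        """The analytic bias field dims corners to 1 - amplitude; measured
        background patches must follow it to within 2%."""
        field = simgen.illumination_bias_field((256, 256), 0.3)
        assert field[0, 0] == pytest.approx(0.7)
        assert field[-1, -1] == pytest.approx(0.7)

        cfg = SimConfig(rng_seed=6, n_cells=3, duration_h=0.4, snr=None,
                        illumination_bias_amplitude=0.3)
        stack, truth = simgen.simulate_timelapse(cfg, "cdk46i")
        img = stack.frame("h2b", 0)
        labels = truth.true_label_stack()[0]
        from scipy import ndimage as ndi

        far = ndi.distance_transform_edt(labels == 0) > 25
        corner_sel = np.zeros_like(far)
        corner_sel[:24, :24] = True
        center_sel = np.zeros_like(far)
        center_sel[116:140, 116:140] = True
        measured = (img[far & corner_sel].mean() / img[far & center_sel].mean())
        expected = (field[far & corner_sel].mean()
                    / field[far & center_sel].mean())
        assert measured == pytest.approx(expected, abs=0.02)

    def test_daughters_start_at_division_frame(self, untreated_movie):
        _, _, truth = untreated_movie
        assert len(truth.divisions) > 0
        births = truth.cells.set_index("cell_id")["birth_frame"]
        for row in truth.divisions.itertuples():
            assert births[row.daughter1] == row.frame
            assert births[row.daughter2] == row.frame

    def test_placement_error_when_overcrowded(self):
        cfg = SimConfig(n_cells=500, field_size_px=(64, 64), duration_h=0.4)
        with pytest.raises(PlacementError):
            simgen.simulate_timelapse(cfg, "cdk46i")

    def test_rendered_cn_matches_truth_with_true_masks(self, noiseless_movie):
        """Rendered-trace fidelity: true-mask extraction recovers activity."""
        from ktrscope import reporters
        from ktrscope.imgproc import LabelMask

        cfg, stack, truth = noiseless_movie
        labels = truth.true_label_stack()
        for f in (0, 120, 239):
            mask = LabelMask(labels[f], cfg.pixel_size_um)
            table = reporters.cn_ratio(stack.frame("cdk2_sensor", f), mask,
                                       background="auto")
            g = truth.frames[truth.frames["frame"] == f].rename(
                columns={"cell_id": "label"})
            merged = table[table["valid"]].merge(g[["label", "cdk2"]],
                                                 on="label")
            err = (merged["cn_ratio"] - merged["cdk2"]).abs()
            assert err.max() < 0.01 * merged["cdk2"].max()


class TestTraceSetSimulation:
    def test_noise_free_traces_equal_truth_trajectories(self):
        cfg = SimConfig(rng_seed=9, n_cells=10, persister_fraction=0.3)
        traces, truth = simgen.simulate_trace_set(cfg, "cdk46i", noise_sd=0.0)
        assert truth.n_persisters == 3
        assert traces.data["cdk2"].notna().all()
        assert (traces.data["valid"]).all()

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simgen.simulate_trace_set(SimConfig(), "cdk46i", noise_sd=-0.1)


class TestDoseMatrix:
    def test_independence_has_zero_bliss_excess(self):
        m = simgen.simulate_dose_matrix(100, 1.0, 10, 1.5, interaction=0.0,
                                        noise_sd=0.0)
        res = pharm.bliss_synergy(m, n_boot=0)
        assert np.abs(res.excess).max() == 0.0
        assert res.score == 0.0

    def test_zero_partner_doses_reduce_to_single_agent_hill(self):
        doses_a = np.concatenate([[0.0], np.geomspace(1, 1000, 6)])
        m = simgen.simulate_dose_matrix(100, 1.2, 10, 1.0, doses_a=doses_a,
                                        doses_b=np.zeros(4), noise_sd=0.0)
        ya = simgen.hill_inhibition(doses_a, 100, 1.2)
        for j in range(4):
            np.testing.assert_allclose(m.inhibition[0, :, j], ya, atol=1e-12)

    def test_mean_excess_equals_interaction_times_bump(self):
        m = simgen.simulate_dose_matrix(100, 1.0, 10, 1.0, interaction=0.1,
                                        noise_sd=0.0)
        ya = simgen.hill_inhibition(m.doses_a, 100, 1.0)
        yb = simgen.hill_inhibition(m.doses_b, 10, 1.0)
        bliss = ya[:, None] + yb[None, :] - np.outer(ya, yb)
        expected_excess = np.clip(
            bliss + 0.1 * simgen.interaction_bump(ya, yb), 0, 1) - bliss
        res = pharm.bliss_synergy(m, n_boot=0)
        np.testing.assert_allclose(res.excess.mean(), expected_excess.mean(),
                                   atol=1e-12)

    def test_negative_noise_sd_rejected(self):
        with pytest.raises(ValueError):
            simgen.simulate_dose_matrix(10, 1, 10, 1, noise_sd=-1)


class TestSection:
    def test_uniform_enrichment_gives_equal_densities(self):
        from ktrscope import morpho

        img, truth = simgen.simulate_section(rng_seed=3, n_cd8=4000,
                                             periphery_enrichment=1.0,
                                             irregularity=0.0)
        m = morpho.region_densities(truth.mask, truth.distance_um,
                                    truth.points.rename(columns={}),
                                    truth.pixel_size_um)
        dp = m.densities_per_mm2["periphery"]
        dc = m.densities_per_mm2["core"]
        # binomial sampling error at n=4000
        assert abs(dp - dc) / dp < 0.12

    def test_infinite_enrichment_empties_core(self):
        _, truth = simgen.simulate_section(rng_seed=4, n_cd8=300,
                                           periphery_enrichment=np.inf)
        assert (truth.points["region"] == "core").sum() == 0

    def test_circular_tumor_core_area_fraction(self):
        """500 um offset of a 1.5 mm disk leaves a 1.0 mm core: (1/1.5)^2."""
        _, truth = simgen.simulate_section(rng_seed=5, n_cd8=10,
                                           irregularity=0.0,
                                           tumor_radius_mm=1.5)
        core = truth.mask & (truth.distance_um > 500.0)
        frac = core.sum() / truth.mask.sum()
        assert frac == pytest.approx((1.0 / 1.5) ** 2, rel=0.02)

    def test_placement_error_when_no_room(self):
        with pytest.raises(PlacementError):
            simgen.simulate_section(rng_seed=0, n_cd8=10_000_000)

    def test_seeded_determinism(self):
        i1, t1 = simgen.simulate_section(rng_seed=8, n_cd8=50)
        i2, t2 = simgen.simulate_section(rng_seed=8, n_cd8=50)
        assert np.array_equal(i1.channel("cd8"), i2.channel("cd8"))
        assert t1.points.equals(t2.points)
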