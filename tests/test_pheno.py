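"""Persister classification and population readouts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ktrscope import pheno, simgen
from oracles import longest_run_oracle

# 48 h of imaging at 12-minute cadence, inclusive of the final time point
T_GRID = np.arange(241) * 0.2


class TestClassifyPersister:
    def test_constant_high_activity_is_persister(self):
        call = pheno.classify_persister(T_GRID, np.full(T_GRID.size, 1.2))
        assert call.is_persister
        assert call.longest_run_h == pytest.approx(18.0)

    def test_constant_low_activity_is_not(self):
        call = pheno.classify_persister(T_GRID, np.full(T_GRID.size, 0.5))
        assert not call.is_persister
        assert call.longest_run_h == 0.0

    def test_exactly_four_hours_is_not_persister(self):
        """Strict 'over 4 h': a run spanning exactly 4.0 h does not count."""
        v = np.full(T_GRID.size, 0.5)
        v[(T_GRID >= 30.0) & (T_GRID <= 34.0 + 1e-9)] = 1.2  # 21 frames
        call = pheno.classify_persister(T_GRID, v)
        assert call.longest_run_h == pytest.approx(4.0)
        assert not call.is_persister
        assert longest_run_oracle(T_GRID, v) == pytest.approx(4.0)

    def test_one_extra_frame_tips_the_call(self):
        v = np.full(T_GRID.size, 0.5)
        v[(T_GRID >= 30.0) & (T_GRID <= 34.2 + 1e-9)] = 1.2
        assert pheno.classify_persister(T_GRID, v).is_persister

    def test_activity_outside_window_ignored(self):
        v = np.full(T_GRID.size, 0.5)
        v[T_GRID < 20.0] = 1.5  # long run, but before the window
        assert not pheno.classify_persister(T_GRID, v).is_persister

    def test_low_coverage_excluded_with_reason(self):
        t = T_GRID[:160]  # ends at 31.8 h: covers ~10% of the window
        call = pheno.classify_persister(t, np.full(t.size, 1.2))
        assert call.excluded and "coverage" in call.reason

    def test_invalid_frames_break_runs(self):
        v = np.full(T_GRID.size, 1.2)
        valid = np.ones(T_GRID.size, bool)
        valid[(T_GRID > 38.0) & (T_GRID < 40.0)] = False
        call = pheno.classify_persister(T_GRID, v, valid=valid)
        ref = v.copy()
        ref[~valid] = 0.0
        assert call.longest_run_h == pytest.approx(
            longest_run_oracle(T_GRID, ref))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_agrees_with_bruteforce_oracle_on_random_traces(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0.6, 1.4, T_GRID.size)
        call = pheno.classify_persister(T_GRID, v)
        run = longest_run_oracle(T_GRID, v)
        assert call.longest_run_h == pytest.approx(run)
        assert call.is_persister == (run > 4.0 + 1e-9)

    def test_fraction_invariant_to_trace_order(self):
        cfg = simgen.SimConfig(rng_seed=5, n_cells=40, persister_fraction=0.4)
        traces, _ = simgen.simulate_trace_set(cfg, "cdk46i", noise_sd=0.02)
        calls = pheno.classify_traces(traces)
        shuffled = traces.data.sample(frac=1.0, random_state=0)
        traces.data = shuffled
        calls2 = pheno.classify_traces(traces)
        assert pheno.persister_fraction(calls) == pheno.persister_fraction(calls2)


class TestPopulationSummary:
    def test_ci_contains_point_estimate(self):
        cfg = simgen.SimConfig(rng_seed=2, n_cells=60, persister_fraction=0.5)
        traces, _ = simgen.simulate_trace_set(cfg, "cdk46i", noise_sd=0.05)
        calls = pheno.classify_traces(traces)
        s = pheno.summarize_population(calls, "cdk46i")
        assert s.ci_low <= s.persister_fraction <= s.ci_high
        assert 0.0 <= s.persister_fraction <= 1.0


class TestEdUFraction:
    def _bimodal(self, n_high=300, n_low=700, seed=0):
        rng = np.random.default_rng(seed)
        return np.concatenate([10 ** rng.normal(2.0, 0.15, n_low),
                               10 ** rng.normal(3.2, 0.15, n_high)])

    @pytest.mark.parametrize("method", ["otsu_log", "gmm2"])
    def test_recovers_constructed_positive_fraction(self, method):
        frac, calls, _ = pheno.edu_positive_fraction(self._bimodal(), method)
        assert frac == pytest.approx(0.30, abs=0.02)
        assert calls.sum() == pytest.approx(300, abs=20)

    def test_unimodal_input_falls_back_with_warning(self):
        rng = np.random.default_rng(1)
        x = 10 ** rng.normal(2.0, 0.1, 500)
        with pytest.warns(UserWarning, match="falling back"):
            frac, _, _ = pheno.edu_positive_fraction(x, "gmm2")
        assert 0.0 <= frac <= 1.0

    def test_fixed_threshold_below_minimum_calls_everything(self):
        x = np.full(60, 100.0)
        frac, _, _ = pheno.edu_positive_fraction(x, "fixed", fixed_threshold=1.0)
        assert frac == 1.0

    def test_too_few_cells_for_automatic_threshold(self):
        with pytest.raises(ValueError, match="50"):
            pheno.edu_positive_fraction(np.ones(10), "otsu_log")


class TestEUSummary:
    def test_exact_sample_size_uses_full_set(self):
        x = np.arange(1000.0)
        s = pheno.eu_summarize(x, sample_n=1000, rng_seed=0)
        assert s.n == 1000 and s.mean == pytest.approx(x.mean())

    def test_constant_input_zero_sd(self):
        s = pheno.eu_summarize(np.full(2000, 5.0), rng_seed=1)
        assert s.mean == 5.0 and s.sd == 0.0

    def test_seeded_resample_is_deterministic(self):
        x = np.random.default_rng(3).uniform(0, 1, 5000)
        s1 = pheno.eu_summarize(x, rng_seed=42)
        s2 = pheno.eu_summarize(x, rng_seed=42)
        np.testing.assert_array_equal(s1.sample, s2.sample)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pheno.eu_summarize(np.array([]))


class TestDoseResponseTable:
    def _table(self):
        import pandas as pd

        doses = [0, 0, 1, 10, 100]
        resp = [1.0, 1.1, 0.9, 0.5, 0.1]
        return pd.DataFrame({"dose": doses, "response": resp})

    def test_vehicle_normalisation(self):
        out = pheno.dose_response_table(self._table())
        assert out.loc[out["dose"] == 0, "response_norm"].iloc[0] == 1.0
        assert out.loc[out["dose"] == 0, "n"].iloc[0] == 2

    def test_missing_vehicle_rejected(self):
        import pandas as pd

        df = pd.DataFrame({"dose": [1, 10, 100, 1000],
                           "response": [1, 0.8, 0.5, 0.2]})
        with pytest.raises(ValueError, match="vehicle"):
            pheno.dose_response_table(df)

    def test_simulated_hill_data_reproduced_exactly_at_zero_noise(self):
        import pandas as pd

        from ktrscope import pharm

        doses = np.concatenate([[0.0], np.geomspace(1, 1000, 7)])
        resp = pharm.hill4(doses, 0.2, 1.0, 30.0, 1.2)
        out = pheno.dose_response_table(
            pd.DataFrame({"dose": doses, "response": resp}))
        np.testing.assert_allclose(out["response_norm"], resp, atol=1e-12)
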