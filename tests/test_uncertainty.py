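"""Moment matching, tornado analysis, PSA, CEAC and EVPI."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from survcea.cea_outcomes import CEAResult
from survcea.uncertainty import (ParamSpec, PSAResult, ceac, evpi,
                                 moment_match, one_way_dsa, run_psa,
                                 sample_param)


class _ToyModel:
    """Linear toy: cost1 = a + k * price, everything else fixed.

    Accepts any parameter name; parameters other than "price" and
    "inert" are rejected to exercise per-row error recording.
    """

    def __init__(self, a=1000.0, k=10.0, d_qaly=0.5):
        self.a, self.k, self.d_qaly = a, k, d_qaly
        self.params = {"price": 100.0, "inert": 1.0}

    def cea(self, wtp, overrides=None):
        p = dict(self.params)
        if overrides:
            unknown = set(overrides) - set(p)
            if unknown:
                raise KeyError(str(sorted(unknown)))
            p.update(overrides)
        cost1 = self.a + self.k * p["price"]
        return CEAResult(cost0=0.0, qaly0=1.0, cost1=cost1,
                         qaly1=1.0 + self.d_qaly, wtp=wtp)


class TestMomentMatch:
    def test_gamma_matching_for_drug_cost(self):
        spec = ParamSpec("durvalumab", 7631.74, 6105.39, 9158.09, "gamma")
        assert spec.se == pytest.approx(3052.70 / 3.92, abs=0.01)
        mm = moment_match(spec)
        assert mm["shape"] / mm["rate"] == pytest.approx(7631.74, rel=1e-12)

    def test_beta_sampled_mean_matches_base(self):
        spec = ParamSpec("utility_pfs", 0.673, 0.528, 0.808, "beta")
        draws = sample_param(spec, np.random.default_rng(0), 100_000)
        assert draws.mean() == pytest.approx(0.673, rel=0.01)
        assert np.all((draws >= 0) & (draws <= 1))

    def test_scaled_beta_respects_support_and_mean(self):
        spec = ParamSpec("discount_rate", 0.05, 0.0, 0.08, "scaled-beta")
        draws = sample_param(spec, np.random.default_rng(1), 100_000)
        assert np.all((draws >= 0.0) & (draws <= 0.08))
        assert draws.mean() == pytest.approx(0.05, rel=0.02)

    def test_degenerate_spec_flags_point_mass(self):
        spec = ParamSpec("fixed", 5.0, 5.0, 5.0, "gamma")
        assert moment_match(spec)["dist"] == "degenerate"

    def test_alternative_se_rule(self):
        spec = ParamSpec("x", 10.0, 8.0, 12.0, "gamma")
        mm = moment_match(spec, se_rule="prop20")
        assert mm["shape"] == pytest.approx(10.0 ** 2 / 2.0 ** 2)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ParamSpec("bad", 1.0, 2.0, 3.0, "gamma")
        with pytest.raises(ValueError):
            ParamSpec("bad", 1.0, 0.0, 2.0, "cauchy")


class TestOneWayDSA:
    def _specs(self):
        return {
            "price": ParamSpec("price", 100.0, 80.0, 120.0, "gamma"),
            "inert": ParamSpec("inert", 1.0, 0.5, 1.5, "gamma"),
        }

    def test_inert_parameter_has_zero_range_and_sorts_last(self):
        tbl = one_way_dsa(_ToyModel(), self._specs(), wtp=10_000.0)
        assert tbl.iloc[-1]["parameter"] == "inert"
        assert tbl.iloc[-1]["range"] == 0.0

    def test_price_pass_through_matches_direct_reruns(self):
        model = _ToyModel()
        tbl = one_way_dsa(model, self._specs(), wtp=10_000.0)
        row = tbl[tbl["parameter"] == "price"].iloc[0]
        assert row["icer_low"] == pytest.approx(
            model.cea(10_000.0, {"price": 80.0}).icer, abs=1e-9)
        assert row["icer_high"] == pytest.approx(
            model.cea(10_000.0, {"price": 120.0}).icer, abs=1e-9)
        # linear pass-through: range = k * (high - low) / d_qaly
        assert row["range"] == pytest.approx(10.0 * 40.0 / 0.5, abs=1e-6)

    def test_output_covers_every_parameter(self, preset_model, param_specs,
                                           wtp_3x):
        tbl = one_way_dsa(preset_model, param_specs, wtp_3x)
        assert sorted(tbl["parameter"]) == sorted(param_specs)
        assert (tbl["error"] == "").all()
        assert tbl["range"].is_monotonic_decreasing

    def test_model_failure_recorded_per_row(self):
        specs = {"ghost": ParamSpec("ghost", 1.0, 0.5, 1.5, "gamma"),
                 "price": ParamSpec("price", 100.0, 80.0, 120.0, "gamma")}
        tbl = one_way_dsa(_ToyModel(), specs, wtp=10_000.0)
        ghost = tbl[tbl["parameter"] == "ghost"].iloc[0]
        assert "KeyError" in ghost["error"]
        assert len(tbl) == 2  # not fatal


class TestRunPSA:
    def test_degenerate_specs_reproduce_base_case(self, preset_model):
        specs = {name: ParamSpec(name, v, v, v, "gamma")
                 for name, v in preset_model.params.items()}
        psa = run_psa(preset_model, specs, n_draws=5, seed=0)
        base = preset_model.evaluate()
        assert np.allclose(psa.samples["cost1"],
                           base["intervention"].cost, rtol=1e-12)
        assert psa.samples["qaly0"].nunique() == 1

    def test_draws_reproducible_and_prefix_stable(self, preset_model,
                                                  param_specs):
        a = run_psa(preset_model, param_specs, n_draws=40, seed=123)
        b = run_psa(preset_model, param_specs, n_draws=40, seed=123)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        longer = run_psa(preset_model, param_specs, n_draws=80, seed=123)
        pd.testing.assert_frame_equal(longer.samples.iloc[:40], a.samples)

    def test_intervention_costlier_and_more_effective(self, preset_model,
                                                      param_specs):
        psa = run_psa(preset_model, param_specs, n_draws=200, seed=7)
        q = psa.quadrant_counts()
        assert q["NE"] >= 0.99 * psa.n_draws
        assert sum(q.values()) == psa.n_draws


def _manual_psa(nmb_pairs, wtp=1.0):
    """PSAResult with prescribed (nmb0, nmb1) at the given WTP."""
    rows = [{"draw": i, "cost0": -n0, "qaly0": 0.0, "cost1": -n1, "qaly1": 0.0}
            for i, (n0, n1) in enumerate(nmb_pairs)]
    return PSAResult(samples=pd.DataFrame(rows), seed=0)


class TestCEAC:
    def test_single_positive_draw_gives_unit_curve(self):
        psa = _manual_psa([(0.0, 1.0)])
        curve = ceac(psa, [0.0, 10.0, 100.0])
        assert (curve["p_cost_effective"] == 1.0).all()

    def test_boundary_at_zero_wtp_is_fraction_cheaper(self, preset_model,
                                                      param_specs):
        psa = run_psa(preset_model, param_specs, n_draws=100, seed=3)
        curve = ceac(psa, [0.0])
        d_cost = psa.samples["cost1"] - psa.samples["cost0"]
        assert curve["p_cost_effective"][0] == (d_cost < 0).mean()

    def test_monotone_when_all_draws_gain_qalys(self, preset_model,
                                                param_specs):
        psa = run_psa(preset_model, param_specs, n_draws=100, seed=3)
        assert (psa.samples["qaly1"] > psa.samples["qaly0"]).all()
        curve = ceac(psa, np.linspace(0, 1e6, 40))
        assert curve["p_cost_effective"].is_monotonic_increasing \
            or curve["p_cost_effective"].diff().dropna().ge(-1e-12).all()


class TestEVPI:
    def test_zero_variance_means_zero_value(self):
        psa = _manual_psa([(1.0, 2.0)] * 10)
        assert (evpi(psa, [0.0, 1.0, 5.0])["evpi"] == 0.0).all()

    def test_two_draw_hand_case(self):
        # draws with strategy NMBs (1,0) and (0,1):
        # E[max] = 1, max(E) = 0.5, EVPI = 0.5
        psa = _manual_psa([(1.0, 0.0), (0.0, 1.0)])
        assert evpi(psa, [0.0])["evpi"][0] == pytest.approx(0.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-1e6, 1e6), st.floats(-1e6, 1e6)),
                    min_size=1, max_size=30))
    def test_nonnegative_on_arbitrary_samples(self, pairs):
        psa = _manual_psa(pairs)
        assert (evpi(psa, [0.0])["evpi"] >= 0.0).all()

    def test_empty_samples_rejected(self):
        psa = PSAResult(samples=pd.DataFrame(
            columns=["draw", "cost0", "qaly0", "cost1", "qaly1"]), seed=0)
        with pytest.raises(ValueError):
            evpi(psa, [0.0])
        with pytest.raises(ValueError):
            ceac(psa, [0.0])
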