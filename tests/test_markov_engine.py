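"""Cohort trace construction and discounted cost/QALY accounting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from survcea.markov_engine import (ArmCostModel, ArmTotals, CohortTrace,
                                   UtilityModel, accumulate, build_trace,
                                   discount_factor, discount_vector,
                                   trace_from_survival)
from survcea.survival_models import SurvivalFit


def _exp_fit(median):
    rate = math.log(2) / median
    return SurvivalFit("exponential", {"rate": rate}, 0.0, 2.0, 2.0, 100)


def _flat_trace(cycles):
    return CohortTrace(pfs=np.ones(cycles), pd=np.zeros(cycles),
                       death=np.zeros(cycles))


def _unit_costs(**kw):
    base = dict(drug_cost_per_cycle=100.0, lab_per_cycle=10.0,
                imaging_per_cycle=10.0, rechallenge_per_cycle=50.0,
                topotecan_per_cycle=20.0, bsc_per_cycle=30.0,
                palliative_per_death=500.0,
                ae_costs={"rash": 400.0}, ae_incidence={"rash": 0.05})
    base.update(kw)
    return ArmCostModel(**base)


class TestBuildTrace:
    def test_everyone_progression_free_at_start(self):
        tr = build_trace(_exp_fit(24), _exp_fit(12), cycles=60)
        assert (tr.pfs[0], tr.pd[0], tr.death[0]) == (1.0, 0.0, 0.0)

    def test_identical_curves_leave_pd_empty(self):
        f = _exp_fit(18)
        tr = build_trace(f, f, cycles=60)
        assert np.allclose(tr.pd, 0.0, atol=1e-12)

    def test_closed_form_exponential_occupancy(self):
        # OS median 24, PFS median 12: at t=12 months occupancy is
        # (0.5, 2^-0.5 - 0.5, 1 - 2^-0.5)
        tr = build_trace(_exp_fit(24), _exp_fit(12), cycles=60)
        s_os_12 = 2.0 ** -0.5
        assert tr.pfs[12] == pytest.approx(0.5, abs=1e-12)
        assert tr.pd[12] == pytest.approx(s_os_12 - 0.5, abs=1e-12)
        assert tr.death[12] == pytest.approx(1 - s_os_12, abs=1e-12)

    def test_pfs_clamped_when_curves_cross(self):
        # "PFS" curve above "OS" forces pd = 0, not negative
        tr = build_trace(_exp_fit(12), _exp_fit(24), cycles=60)
        assert np.all(tr.pd >= 0)
        assert np.allclose(tr.pfs, 1.0 - tr.death, atol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(m_os=st.floats(6.0, 60.0), ratio=st.floats(0.2, 1.0),
           mode=st.sampled_from(["partitioned", "transition"]))
    def test_conservation_and_monotonicity(self, m_os, ratio, mode):
        tr = build_trace(_exp_fit(m_os), _exp_fit(m_os * ratio),
                         cycles=120, mode=mode)
        tr.validate()  # sums to 1, pfs down, death up, all in [0, 1]

    def test_transition_mode_matches_partitioned_for_exponentials(self):
        # with a common death hazard both realizations read off the same OS
        p = build_trace(_exp_fit(24), _exp_fit(12), cycles=60)
        t = build_trace(_exp_fit(24), _exp_fit(12), cycles=60,
                        mode="transition")
        assert np.allclose(p.death, t.death, atol=5e-3)


class TestDiscounting:
    def test_zero_rate_is_unity(self):
        assert discount_factor(0.0, 0) == 1.0
        assert discount_factor(0.0, 57) == 1.0

    def test_hand_checked_values(self):
        assert discount_factor(0.05, 12) == pytest.approx(1 / 1.05, rel=1e-9)
        assert discount_factor(0.05, 120) == pytest.approx(1.05 ** -10,
                                                           rel=1e-9)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-0.01, 1)


class TestAccumulate:
    def test_qaly_equals_ly_with_unit_utilities(self):
        tr = build_trace(_exp_fit(24), _exp_fit(12), cycles=120)
        utils = UtilityModel(u_pfs=1.0, u_pd=1.0)
        totals = accumulate(tr, _unit_costs(ae_incidence={}), utils, 0.0)
        assert totals.qaly == pytest.approx(totals.ly, abs=1e-12)

    def test_year_in_pfs_at_utility_0673(self):
        utils = UtilityModel(u_pfs=0.673, u_pd=0.473)
        totals = accumulate(_flat_trace(12), _unit_costs(ae_incidence={}),
                            utils, 0.0)
        assert totals.qaly == pytest.approx(0.673, abs=1e-12)

    def test_cost_homogeneity(self):
        tr = build_trace(_exp_fit(24), _exp_fit(12), cycles=120)
        utils = UtilityModel(u_pfs=0.7, u_pd=0.5)
        c1 = accumulate(tr, _unit_costs(), utils, 0.05).cost
        doubled = _unit_costs(
            drug_cost_per_cycle=200.0, lab_per_cycle=20.0,
            imaging_per_cycle=20.0, rechallenge_per_cycle=100.0,
            topotecan_per_cycle=40.0, bsc_per_cycle=60.0,
            palliative_per_death=1000.0, ae_costs={"rash": 800.0})
        c2 = accumulate(tr, doubled, utils, 0.05).cost
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_zero_discount_equals_undiscounted_sum(self):
        tr = build_trace(_exp_fit(24), _exp_fit(12), cycles=60)
        utils = UtilityModel(u_pfs=0.673, u_pd=0.473)
        totals = accumulate(tr, _unit_costs(ae_incidence={}), utils, 0.0)
        manual = (tr.pfs * 0.673 + tr.pd * 0.473).sum() / 12.0
        assert totals.qaly == pytest.approx(manual, abs=1e-12)
        assert np.all(discount_vector(0.0, 60) == 1.0)

    def test_qaly_never_exceeds_ly(self):
        tr = build_trace(_exp_fit(30), _exp_fit(10), cycles=120)
        utils = UtilityModel(u_pfs=0.673, u_pd=0.473,
                             ae_disutility={"rash": 0.03},
                             ae_incidence={"rash": 0.05})
        totals = accumulate(tr, _unit_costs(), utils, 0.05)
        assert totals.qaly <= totals.ly

    def test_cost_strictly_increasing_in_drug_price(self):
        tr = build_trace(_exp_fit(24), _exp_fit(12), cycles=120)
        utils = UtilityModel(u_pfs=0.7, u_pd=0.5)
        costs = [accumulate(tr, _unit_costs(drug_cost_per_cycle=p), utils,
                            0.05).cost for p in (100.0, 200.0, 300.0)]
        assert costs[0] < costs[1] < costs[2]

    def test_treatment_cap_reduces_drug_exposure(self):
        tr = build_trace(_exp_fit(40), _exp_fit(30), cycles=120)
        utils = UtilityModel(u_pfs=0.7, u_pd=0.5)
        uncapped = accumulate(tr, _unit_costs(), utils, 0.0).cost
        capped = accumulate(tr, _unit_costs(treatment_cap_cycles=24),
                            utils, 0.0).cost
        assert capped < uncapped

    def test_half_cycle_correction_stays_between_endpoints(self):
        tr = build_trace(_exp_fit(24), _exp_fit(12), cycles=120)
        utils = UtilityModel(u_pfs=1.0, u_pd=1.0)
        plain = accumulate(tr, _unit_costs(ae_incidence={}), utils, 0.0)
        hc = accumulate(tr, _unit_costs(ae_incidence={}), utils, 0.0,
                        half_cycle=True)
        assert hc.ly < plain.ly  # occupancy is non-increasing


class TestTraceValidation:
    def test_bad_traces_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CohortTrace(np.array([0.5]), np.array([0.2]),
                        np.array([0.1])).validate()
        with pytest.raises(ValueError, match="non-increasing"):
            CohortTrace(np.array([0.5, 0.6]), np.array([0.3, 0.2]),
                        np.array([0.2, 0.2])).validate()

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            trace_from_survival(np.ones(5), np.ones(4))
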