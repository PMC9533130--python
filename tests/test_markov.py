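"""Cohort trace construction and discounted cost/QALY accumulation."""

import dataclasses
import math

import numpy as np
import pytest

from alkcea.markov import (
    accumulate_costs,
    accumulate_qalys,
    build_trace,
    discount_factor,
    evaluate_all,
    evaluate_strategy,
)
from alkcea.synthetic import perturb_config

from conftest import comparator, make_minimal_config, with_conventions


class TestTrace:
    def test_cohort_starts_progression_free(self, baseline_config):
        trace = build_trace(baseline_config.strategy("crizotinib"), baseline_config)
        assert tuple(trace.occupancy[0]) == (1.0, 0.0, 0.0)

    def test_first_cycle_boundary_matches_curves(self, baseline_config):
        # both printed Weibulls evaluated at t=1
        trace = build_trace(baseline_config.strategy("crizotinib"), baseline_config)
        pfs, pd_, dead = trace.occupancy[1]
        assert pfs == pytest.approx(math.exp(-0.08242))
        assert dead == pytest.approx(1 - math.exp(-0.02092))
        assert pd_ == pytest.approx(math.exp(-0.02092) - math.exp(-0.08242))

    def test_unit_hazard_ratios_reproduce_reference(self, baseline_config):
        twin = comparator("twin", 1.0, 1.0)
        cfg = dataclasses.replace(
            baseline_config, strategies=baseline_config.strategies + (twin,)
        )
        t_ref = build_trace(cfg.reference_strategy, cfg)
        t_twin = build_trace(cfg.strategy("twin"), cfg)
        assert np.allclose(t_ref.occupancy, t_twin.occupancy)

    @pytest.mark.parametrize("mode", ["partitioned", "state_transition"])
    def test_invariants_all_strategies(self, baseline_config, mode):
        for s in baseline_config.strategies:
            trace = build_trace(s, baseline_config, mode=mode)
            trace.validate()  # row conservation, monotone death, start state

    @pytest.mark.parametrize("seed", range(5))
    def test_invariants_under_config_jitter(self, baseline_config, seed):
        cfg = perturb_config(baseline_config, seed=seed, magnitude=0.5)
        for s in cfg.strategies:
            build_trace(s, cfg).validate()

    def test_modes_agree(self, baseline_config):
        # alive fraction identical by construction; QALYs within 2%
        for s in baseline_config.strategies:
            tp = build_trace(s, baseline_config, mode="partitioned")
            ts = build_trace(s, baseline_config, mode="state_transition")
            assert np.allclose(tp.occupancy[:, 2], ts.occupancy[:, 2], atol=1e-12)
            qp = accumulate_qalys(tp, baseline_config.utilities, s, baseline_config)
            qs = accumulate_qalys(ts, baseline_config.utilities, s, baseline_config)
            assert qs == pytest.approx(qp, rel=0.02)

    def test_pd_clamped_when_pfs_curve_crosses_os(self):
        # hr_os far above hr_pfs pushes S_OS below S_PFS -> PD floor at 0
        cfg = make_minimal_config(
            extra_strategies=(comparator("crossed", hr_os=4.0, hr_pfs=0.2),)
        )
        trace = build_trace(cfg.strategy("crossed"), cfg)
        assert trace.clamped_cycles  # warning path exercised
        trace.validate()
        assert np.all(trace.occupancy[:, 1] >= 0)


class TestDiscounting:
    def test_reference_values(self, baseline_config):
        assert discount_factor(0, baseline_config) == 1.0
        assert discount_factor(65, baseline_config) == pytest.approx(
            1.05 ** (-65 * 56 / 365.25)
        )
        assert discount_factor(65, baseline_config) == pytest.approx(0.615, abs=0.001)

    def test_zero_rate_is_unity(self):
        cfg = make_minimal_config(discount=0.0)
        assert np.all(discount_factor(np.arange(66), cfg) == 1.0)


class TestQALYs:
    def test_extinct_cohort_accrues_nothing(self, baseline_config):
        s = baseline_config.strategy("crizotinib")
        trace = build_trace(s, baseline_config)
        dead = dataclasses.replace(
            trace, occupancy=np.tile([0.0, 0.0, 1.0], (trace.n_cycles + 1, 1))
        )
        assert accumulate_qalys(dead, baseline_config.utilities, s, baseline_config) == 0.0

    def test_reduces_to_life_years(self):
        # full utilities, no disutility, no discounting: QALYs == life-years
        cfg = make_minimal_config(u_pfs=1.0, u_pd=1.0, discount=0.0)
        res = evaluate_strategy(cfg.strategies[0], cfg)
        assert res.total_qalys == pytest.approx(res.life_years)

    def test_negative_on_treatment_utility_rejected(self):
        cfg = make_minimal_config(u_pfs=0.1, u_pd=0.05, disutility=0.5)
        s = cfg.strategies[0]
        trace = build_trace(s, cfg)
        with pytest.raises(ValueError, match="utility"):
            accumulate_qalys(trace, cfg.utilities, s, cfg)

    def test_qaly_ordering_follows_os_hazard(self):
        # lower death hazard must not reduce QALYs, all else equal
        cfg = make_minimal_config(
            extra_strategies=(
                comparator("better", 0.5, 0.8),
                comparator("worse", 1.5, 0.8),
            )
        )
        res = evaluate_all(cfg)
        assert res["better"].total_qalys >= res["reference"].total_qalys
        assert res["worse"].total_qalys <= res["reference"].total_qalys


class TestCosts:
    def test_single_cycle_drug_cost_only(self):
        # ~zero hazards freeze the cohort in PFS; one undiscounted cycle
        cfg = make_minimal_config(
            drug_cost=59.29,
            horizon_years=56.0 / 365.25,
            os_params=dataclasses.replace(
                make_minimal_config().base_survival["os"], scale_lambda=1e-12
            ),
            pfs_params=dataclasses.replace(
                make_minimal_config().base_survival["pfs"], scale_lambda=1e-12
            ),
        )
        assert cfg.horizon_cycles == 1
        res = evaluate_strategy(cfg.strategies[0], cfg)
        assert res.total_cost == pytest.approx(56 * 59.29, rel=1e-6)

    def test_linearity_in_cost_inputs(self, baseline_config):
        s = baseline_config.strategy("ensartinib")
        doubled = dataclasses.replace(
            s,
            drug_cost_per_day=dataclasses.replace(
                s.drug_cost_per_day, value=2 * s.drug_cost_per_day.value
            ),
            ae_cost_once=dataclasses.replace(s.ae_cost_once, value=2 * s.ae_cost_once.value),
        )
        sc = baseline_config.shared_costs
        shared2 = dataclasses.replace(
            sc,
            **{
                f.name: dataclasses.replace(
                    getattr(sc, f.name), value=2 * getattr(sc, f.name).value
                )
                for f in dataclasses.fields(sc)
            },
        )
        trace = build_trace(s, baseline_config)
        c1 = accumulate_costs(trace, s, sc, baseline_config)
        c2 = accumulate_costs(trace, doubled, shared2, baseline_config)
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_negative_component_rejected(self, baseline_config):
        s = baseline_config.strategy("ensartinib")
        bad = dataclasses.replace(
            s, drug_cost_per_day=dataclasses.replace(s.drug_cost_per_day, value=-1.0)
        )
        trace = build_trace(s, baseline_config)
        with pytest.raises(ValueError, match="drug"):
            accumulate_costs(trace, bad, baseline_config.shared_costs, baseline_config)


class TestEvaluation:
    def test_zero_horizon_only_entry_costs(self, baseline_config):
        cfg = dataclasses.replace(baseline_config, horizon_years=0.0)
        res = evaluate_strategy(cfg.strategy("ensartinib"), cfg)
        assert res.total_qalys == 0.0
        assert res.total_cost == cfg.strategy("ensartinib").ae_cost_once.value

    def test_rerun_bit_identical(self, baseline_config):
        s = baseline_config.strategy("lorlatinib")
        r1 = evaluate_strategy(s, baseline_config)
        r2 = evaluate_strategy(s, baseline_config)
        assert r1 == r2

    def test_result_invariants(self, baseline_results):
        for res in baseline_results.values():
            res.validate()  # discounted <= undiscounted, QALYs <= life-years
            assert res.total_cost > 0
            assert 0 < res.total_qalys < res.life_years

    @pytest.mark.parametrize(
        "switches",
        [
            {"half_cycle": False},
            {"palliative_timing": "per_final_cycle"},
            {"ae_cost_timing": "amortized"},
            {"trace_mode": "state_transition"},
        ],
    )
    def test_convention_switches_small_perturbations(self, baseline_config, switches):
        # every switch is auditable and moves totals only modestly
        base = evaluate_all(baseline_config)
        alt = evaluate_all(with_conventions(baseline_config, **switches))
        for name in base:
            assert alt[name].total_cost == pytest.approx(base[name].total_cost, rel=0.05)
            assert alt[name].total_qalys == pytest.approx(base[name].total_qalys, rel=0.05)
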