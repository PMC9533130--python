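"""Tornado DSA, threshold search, moment matching, PSA, and CEAC."""

import dataclasses

import numpy as np
import pytest

from alkcea.config import iter_parameters
from alkcea.economics import net_monetary_benefit
from alkcea.markov import evaluate_all, evaluate_strategy
from alkcea.sensitivity import (
    ceac,
    moment_match,
    one_way_dsa,
    pairwise_ceac,
    run_psa,
    threshold_search,
)

WTP = 37654.0


@pytest.fixture(scope="module")
def small_psa(baseline_config):
    return run_psa(baseline_config, n=500, seed=42)


@pytest.fixture(scope="module")
def entries(baseline_config):
    return one_way_dsa(baseline_config, "alectinib", "ensartinib")


class TestTornado:

    def test_covers_exactly_the_varied_parameters(self, baseline_config, entries):
        varied = {r.label for r in iter_parameters(baseline_config) if r.varied_in_dsa}
        assert {e.parameter for e in entries} == varied
        # the fixed base Weibull curves never appear
        assert not any("scale" in e.parameter or "shape" in e.parameter for e in entries)

    def test_sorted_by_descending_swing(self, entries):
        swings = [e.swing for e in entries]
        assert swings == sorted(swings, reverse=True)

    def test_degenerate_bounds_give_zero_swing(self, baseline_config):
        # pin one parameter's range to its baseline: swing must vanish
        s = baseline_config.strategy("crizotinib")
        pinned = dataclasses.replace(
            s, ae_cost_once=dataclasses.replace(s.ae_cost_once, low=566.40, high=566.40)
        )
        cfg = dataclasses.replace(
            baseline_config,
            strategies=tuple(pinned if x.name == "crizotinib" else x
                             for x in baseline_config.strategies),
        )
        entries = one_way_dsa(cfg, "alectinib", "ensartinib")
        entry = next(e for e in entries if e.parameter == "ae_cost_once[crizotinib]")
        assert entry.swing == 0.0

    def test_irrelevant_parameter_has_zero_swing(self, entries):
        # crizotinib's drug price cannot move an alectinib-vs-ensartinib ICER
        entry = next(e for e in entries if e.parameter == "drug_cost_per_day[crizotinib]")
        assert entry.swing == pytest.approx(0.0, abs=1e-6)


class TestThresholdSearch:
    def test_flip_price_below_baseline_exists(self, baseline_config):
        x = threshold_search(
            baseline_config, "drug_cost_per_day[alectinib]",
            "alectinib", "ensartinib", lo=0.0, hi=84.32,
        )
        assert x is not None
        assert 0 < x < 84.32

    def test_agrees_with_grid_scan_oracle(self, baseline_config):
        lo, hi = 0.0, 84.32
        x = threshold_search(
            baseline_config, "drug_cost_per_day[alectinib]",
            "alectinib", "ensartinib", lo=lo, hi=hi,
        )
        ref = next(
            r for r in iter_parameters(baseline_config)
            if r.label == "drug_cost_per_day[alectinib]"
        )
        grid = np.linspace(lo, hi, 1000)
        signs = []
        for v in grid:
            cfg = ref.set(baseline_config, v)
            diff = net_monetary_benefit(
                evaluate_strategy(cfg.strategy("alectinib"), cfg), WTP
            ) - net_monetary_benefit(evaluate_strategy(cfg.strategy("ensartinib"), cfg), WTP)
            signs.append(np.sign(diff))
        flips = np.flatnonzero(np.diff(signs))
        assert len(flips) == 1
        step = grid[1] - grid[0]
        assert abs(x - grid[flips[0]]) <= step

    def test_zero_influence_parameter_returns_none(self, baseline_config):
        assert (
            threshold_search(
                baseline_config, "drug_cost_per_day[crizotinib]",
                "alectinib", "ensartinib",
            )
            is None
        )


class TestMomentMatch:
    def test_beta_round_trips_published_utility(self):
        dist = moment_match("beta", 0.856, 0.718, 0.994)
        sd = (0.994 - 0.718) / (2 * 1.959963984540054)
        assert sd == pytest.approx(0.0704, abs=2e-4)
        assert dist.mean() == pytest.approx(0.856, rel=1e-9)
        assert dist.std() == pytest.approx(sd, rel=1e-9)

    def test_symmetric_normal_bounds_are_95_percentiles(self):
        dist = moment_match("normal", 50.0, 30.0, 70.0)
        assert dist.ppf(0.025) == pytest.approx(30.0, rel=1e-9)
        assert dist.ppf(0.975) == pytest.approx(70.0, rel=1e-9)

    def test_gamma_monte_carlo_mean(self):
        dist = moment_match("gamma", 383.63, 306.91, 460.36)
        draws = dist.rvs(size=100_000, random_state=np.random.default_rng(0))
        assert draws.mean() == pytest.approx(383.63, rel=0.01)
        assert draws.std() == pytest.approx(dist.std(), rel=0.02)

    def test_infeasible_beta_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            moment_match("beta", 0.99, 0.0, 1.0)  # variance too large for mean

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            moment_match("normal", 1.0, 1.0, 1.0)


class TestPSA:
    def test_seed_reproducibility(self, baseline_config):
        a = run_psa(baseline_config, n=20, seed=7)
        b = run_psa(baseline_config, n=20, seed=7)
        assert a.params.equals(b.params)
        assert a.costs.equals(b.costs)
        assert a.qalys.equals(b.qalys)

    def test_draws_respect_supports(self, small_psa):
        p = small_psa.params
        for col in p.columns:
            if col.startswith("hr_"):
                assert (p[col] > 0).all()
            elif col.startswith(("drug_", "ae_cost", "bsc", "followup", "subsequent", "palliative")):
                assert (p[col] >= 0).all()
            elif col.startswith(("u_", "ae_disutility")):
                assert p[col].between(0, 1).all()

    def test_point_masses_reproduce_baseline(self, baseline_config):
        # strip every distribution tag: the PSA collapses to the base case
        doc_cfg = baseline_config

        def fix_param(p):
            return dataclasses.replace(p, dist="fixed")

        strategies = tuple(
            dataclasses.replace(
                s,
                drug_cost_per_day=fix_param(s.drug_cost_per_day),
                ae_cost_once=fix_param(s.ae_cost_once),
                ae_disutility=fix_param(s.ae_disutility),
                hr_os=dataclasses.replace(s.hr_os, dist="fixed") if s.hr_os else None,
                hr_pfs=dataclasses.replace(s.hr_pfs, dist="fixed") if s.hr_pfs else None,
            )
            for s in doc_cfg.strategies
        )
        sc = doc_cfg.shared_costs
        cfg = dataclasses.replace(
            doc_cfg,
            strategies=strategies,
            shared_costs=dataclasses.replace(
                sc,
                **{f.name: fix_param(getattr(sc, f.name)) for f in dataclasses.fields(sc)},
            ),
            utilities=dataclasses.replace(
                doc_cfg.utilities,
                u_pfs=fix_param(doc_cfg.utilities.u_pfs),
                u_pd=fix_param(doc_cfg.utilities.u_pd),
            ),
        )
        psa = run_psa(cfg, n=5, seed=1)
        base = evaluate_all(cfg)
        for name, res in base.items():
            assert np.allclose(psa.costs[name], res.total_cost)
            assert np.allclose(psa.qalys[name], res.total_qalys)

    def test_mean_matches_baseline_for_reference_arm(self, baseline_config, small_psa):
        # crizotinib depends linearly on its drawn inputs, so the Monte Carlo
        # mean must sit on the deterministic base case (within sampling error);
        # HR-driven arms are convex in the HR draws and are biased upward.
        base = evaluate_all(baseline_config)["crizotinib"]
        q = small_psa.qalys["crizotinib"]
        c = small_psa.costs["crizotinib"]
        assert abs(q.mean() - base.total_qalys) < 3 * q.std() / np.sqrt(len(q))
        assert abs(c.mean() - base.total_cost) < 3 * c.std() / np.sqrt(len(c))


class TestCEAC:
    def test_single_sample_gives_indicator_probabilities(self, baseline_config):
        psa = run_psa(baseline_config, n=1, seed=3)
        curve = ceac(psa, [0.0, WTP, 10 * WTP])
        assert set(np.unique(curve.probabilities.to_numpy())) <= {0.0, 1.0}

    def test_probabilities_partition(self, small_psa):
        curve = ceac(small_psa, np.linspace(0, 150_000, 16))
        sums = curve.probabilities.sum(axis=1)
        assert np.allclose(sums, 1.0)
        assert ((curve.probabilities >= 0) & (curve.probabilities <= 1)).all().all()

    def test_pairwise_monotone_where_intervention_more_effective(self, small_psa):
        # in every draw where alectinib buys QALYs over ensartinib, raising
        # the WTP can only make it more attractive; restrict to those draws
        # (draws losing QALYs flip the other way, so the full curve need not
        # be monotone)
        keep = (
            small_psa.qalys["alectinib"] - small_psa.qalys["ensartinib"] > 0
        ).to_numpy()
        assert keep.sum() > 100
        sub = dataclasses.replace(
            small_psa,
            params=small_psa.params[keep].reset_index(drop=True),
            costs=small_psa.costs[keep].reset_index(drop=True),
            qalys=small_psa.qalys[keep].reset_index(drop=True),
        )
        grid = np.linspace(0, 300_000, 31)
        pw = pairwise_ceac(sub, "alectinib", "ensartinib", grid)
        probs = pw["p_alectinib_preferred"].to_numpy()
        assert np.all(np.diff(probs) >= -1e-12)
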