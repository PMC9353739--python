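"""Cost/QALY accrual, discounting, and incremental cost-effectiveness."""

import dataclasses
import math

import numpy as np
import pytest

from nsclc_cea import (
    ModelSettings,
    accrue,
    compute_icer,
    cycle_cost,
    discount_factor,
    evaluate_model,
    expected_ae_cost,
    trace_summary,
)


class TestDiscounting:
    def test_cycle_zero_undiscounted(self, bundle):
        assert discount_factor(0, bundle.settings) == 1.0

    def test_one_cycle(self, bundle):
        assert discount_factor(1, bundle.settings) == pytest.approx(
            1.05 ** (-21 / 365.25)
        )
        assert discount_factor(1, bundle.settings) == pytest.approx(0.99720, abs=1e-5)

    def test_zero_rate_flat(self):
        s = ModelSettings(annual_discount_rate=0.0)
        assert all(discount_factor(u, s) == 1.0 for u in (0, 10, 174))


class TestCycleCost:
    def test_combo_induction_cycle(self, strategies):
        # camrelizumab + pemetrexed + carboplatin + pretreatment + admin + dm
        assert cycle_cost(strategies["combo"], "pfs", 2) == pytest.approx(
            424.51 + 393.99 + 11.96 + 1.52 + 72.54 + 60.64
        )

    def test_combo_phase_boundaries(self, strategies):
        combo = strategies["combo"]
        maintenance = 424.51 + 393.99 + 1.52 + 66.27 + 60.64
        post_cap = 393.99 + 1.52 + 65.58 + 48.68
        assert cycle_cost(combo, "pfs", 5) == pytest.approx(maintenance)
        assert cycle_cost(combo, "pfs", 34) == pytest.approx(maintenance - 60.64 + 48.68)
        assert cycle_cost(combo, "pfs", 35) == pytest.approx(post_cap)

    def test_chemo_phases(self, strategies):
        chemo = strategies["chemo"]
        assert cycle_cost(chemo, "pfs", 4) == pytest.approx(
            393.99 + 11.96 + 1.52 + 71.85 + 60.64
        )
        assert cycle_cost(chemo, "pfs", 5) == pytest.approx(
            393.99 + 1.52 + 56.36 + 60.64
        )

    def test_pd_accrues_full_second_line_schedule(self, strategies):
        # both arms: docetaxel + immunotherapy components + disease management
        for arm in strategies.values():
            assert cycle_cost(arm, "pd", 20) == pytest.approx(
                392.61 + 698.77 + 48.68
            )
            assert cycle_cost(arm, "pd", 18) == pytest.approx(392.61 + 698.77 + 60.64)

    def test_death_costs_nothing(self, strategies):
        assert cycle_cost(strategies["combo"], "dead", 3) == 0.0

    def test_unknown_state(self, strategies):
        with pytest.raises(ValueError):
            cycle_cost(strategies["combo"], "limbo", 1)


class TestAccrual:
    def test_qalys_reduce_to_life_years_without_weighting(self, bundle, traces):
        s = dataclasses.replace(bundle.settings, annual_discount_rate=0.0)
        arm = dataclasses.replace(
            bundle.strategies()[0], utility_pfs=1.0, utility_pd=1.0
        )
        _, qalys = accrue(traces["combo"], arm, s)
        life_years = trace_summary(traces["combo"]).life_cycles * 21 / 365.25
        assert qalys == pytest.approx(life_years, rel=1e-12)

    def test_discounting_is_contractive(self, bundle, traces, strategies):
        s0 = dataclasses.replace(bundle.settings, annual_discount_rate=0.0)
        for arm in ("combo", "chemo"):
            c0, q0 = accrue(traces[arm], strategies[arm], s0)
            c5, q5 = accrue(traces[arm], strategies[arm], bundle.settings)
            assert c5 < c0 and q5 < q0
            assert q5 >= 0.0

    def test_raising_a_cost_raises_the_total(self, bundle, traces):
        base_cost, _ = accrue(traces["chemo"], bundle.strategies()[1], bundle.settings)
        bumped = bundle.strategies({"cost_pemetrexed": 500.0})[1]
        up_cost, _ = accrue(traces["chemo"], bumped, bundle.settings)
        assert up_cost > base_cost

    def test_mismatched_horizon_rejected(self, bundle, traces, strategies):
        s = dataclasses.replace(bundle.settings, horizon_cycles=10)
        with pytest.raises(ValueError):
            accrue(traces["combo"], strategies["combo"], s)

    def test_base_case_totals(self, base_result):
        """Discounted totals reproduce the published results table closely."""
        assert base_result.chemo_cost == pytest.approx(30575.23, rel=0.01)
        assert base_result.chemo_qalys == pytest.approx(1.10, abs=0.02)
        assert base_result.combo_cost == pytest.approx(45393.28, rel=0.01)
        assert base_result.combo_qalys == pytest.approx(1.44, abs=0.02)


class TestICER:
    def test_identity_and_flags(self, base_result):
        r = base_result
        assert r.delta_cost == r.combo_cost - r.chemo_cost
        assert r.delta_qalys == r.combo_qalys - r.chemo_qalys
        assert r.icer * r.delta_qalys == pytest.approx(r.delta_cost, rel=1e-12)
        assert r.icer > r.wtp_per_qaly and not r.cost_effective

    def test_simple_ratio(self):
        r = compute_icer((100.0, 2.0), (0.0, 0.0), wtp=60.0)
        assert r.icer == pytest.approx(50.0)
        assert r.cost_effective

    def test_dominant_combination(self):
        r = compute_icer((50.0, 2.0), (100.0, 1.0), wtp=10.0)
        assert r.cost_effective
        assert r.icer < 0
        assert "dominant" in r.dominance

    def test_zero_delta_qaly_flagged_not_raised(self):
        r = compute_icer((10.0, 1.0), (5.0, 1.0), wtp=100.0)
        assert not r.icer_defined
        assert math.isnan(r.icer)
        assert not r.cost_effective
        assert "undefined" in r.verdict()

    def test_first_quadrant_at_defaults(self, base_result):
        assert base_result.delta_cost > 0 and base_result.delta_qalys > 0

    def test_huge_wtp_flips_verdict(self, bundle):
        r = evaluate_model(bundle, wtp=1e9)
        assert r.cost_effective


class TestExpectedAECost:
    def test_zero_costs(self):
        inc = [("anemia", 0.19), ("asthenia", 0.03)]
        assert expected_ae_cost(inc, [("anemia", 0.0), ("asthenia", 0.0)]) == 0.0

    def test_single_product(self):
        assert expected_ae_cost([("x", 0.38)], [("x", 100.0)]) == pytest.approx(38.0)

    def test_uniform_cost_sums_rates(self):
        from nsclc_cea import trae_fixture

        df = trae_fixture()
        inc = list(zip(df["event"], df["combo_rate"]))
        costs = [(e, 10.0) for e in df["event"]]
        assert expected_ae_cost(inc, costs) == pytest.approx(
            10.0 * df["combo_rate"].sum()
        )

    def test_unmatched_event_named(self):
        with pytest.raises(KeyError, match="anemia"):
            expected_ae_cost([("anemia", 0.19)], [("asthenia", 5.0)])
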