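"""The four feasibility conditions."""

import dataclasses

import numpy as np
import pytest

from abpsim import (
    CashflowStream,
    EconomicSpec,
    PaymentScheme,
    TruncationPolicy,
    build_abp_stream,
    build_upfront_stream,
    condition1,
    condition2a,
    condition2b,
    condition3,
    condition4,
    discount_stream,
    evaluate_all,
    patient_flow,
)

from conftest import make_flow


def scheme(price=1e6, rate=0.03, n=5, kind="health_impact"):
    return PaymentScheme(
        price=price, modality="annuity", n_payments=n, bond_rate=rate, bond_type=kind
    )


def disc(values):
    return CashflowStream(values=np.asarray(values, dtype=float), basis="discounted")


class TestCondition1:
    def test_lca_defaults_pass(self, lca_config):
        flow = patient_flow(lca_config.epidemiology, 25)
        r = lca_config.economics.social_discount_rate
        upfront = discount_stream(build_upfront_stream(flow, lca_config.price), r)
        abp = discount_stream(build_abp_stream(flow, scheme(n=5)), r)
        exceeds, within = condition1(upfront, abp, lca_config.economics)
        assert exceeds and within

    def test_cap_above_both_maxima_fails_on_upfront(self):
        econ = EconomicSpec(budget_cap=1000.0)
        exceeds, within = condition1(disc([500.0]), disc([100.0]), econ)
        assert (exceeds, within) == (False, True)

    def test_cap_below_both_maxima_fails_on_abp(self):
        econ = EconomicSpec(budget_cap=50.0)
        exceeds, within = condition1(disc([500.0]), disc([100.0]), econ)
        assert (exceeds, within) == (True, False)

    def test_nominal_streams_rejected(self):
        econ = EconomicSpec(budget_cap=1.0)
        nominal = CashflowStream(values=np.array([1.0]))
        with pytest.raises(ValueError, match="discounted"):
            condition1(nominal, disc([1.0]), econ)


class TestCondition2a:
    def test_single_annuity_ratio_exactly_one(self):
        flow = make_flow([4.0, 1.0, 0.0, 2.0])
        upfront = build_upfront_stream(flow, 1e6)
        abp = build_abp_stream(flow, scheme(n=1), TruncationPolicy.FULL_LEDGER)
        assert condition2a(upfront, abp, 0.03) == 1.0

    def test_bond_rate_equal_social_rate_is_cost_equivalent(self):
        """At i = r under full-ledger accounting every patient's annuity
        NPV equals the upfront price, so the ratio is identically 1."""
        flow = make_flow([10.0, 3.0, 5.5, 0.0, 2.0])
        upfront = build_upfront_stream(flow, 1e6)
        for n in (2, 5, 15):
            abp = build_abp_stream(flow, scheme(rate=0.03, n=n), TruncationPolicy.FULL_LEDGER)
            assert condition2a(upfront, abp, 0.03) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("rate, expected_side", [(0.08, 1), (0.01, -1)])
    def test_ratio_sign_tracks_rate_gap(self, rate, expected_side):
        flow = make_flow([10.0, 3.0, 5.5])
        upfront = build_upfront_stream(flow, 1e6)
        abp = build_abp_stream(flow, scheme(rate=rate, n=5), TruncationPolicy.FULL_LEDGER)
        ratio = condition2a(upfront, abp, 0.03)
        assert np.sign(ratio - 1.0) == expected_side

    def test_monotone_in_bond_rate(self):
        flow = make_flow([10.0, 3.0, 5.5])
        upfront = build_upfront_stream(flow, 1e6)
        ratios = [
            condition2a(
                upfront,
                build_abp_stream(flow, scheme(rate=i, n=5), TruncationPolicy.FULL_LEDGER),
                0.03,
            )
            for i in (0.0, 0.02, 0.03, 0.05, 0.10)
        ]
        assert all(b > a for a, b in zip(ratios, ratios[1:]))

    def test_zero_upfront_npv_rejected(self):
        zero = CashflowStream(values=np.zeros(3))
        with pytest.raises(ValueError, match="zero NPV"):
            condition2a(zero, zero, 0.03)


class TestCondition2b:
    def test_single_annuity_ratio_is_one(self):
        flow = make_flow([4.0, 1.0])
        upfront = discount_stream(build_upfront_stream(flow, 1e6), 0.03)
        abp = discount_stream(
            build_abp_stream(flow, scheme(n=1), TruncationPolicy.FULL_LEDGER), 0.03
        )
        assert condition2b(upfront, abp) == 1.0

    def test_prevalence_dominant_ratio_is_annuity_over_price(self, lca_config):
        """With the backlog treated at launch both maxima fall in year 0,
        so the ratio reduces to A/P ~ 0.212 at 3% over 5 years."""
        flow = patient_flow(lca_config.epidemiology, 25)
        upfront = discount_stream(build_upfront_stream(flow, 1e6), 0.03)
        abp = discount_stream(build_abp_stream(flow, scheme(n=5)), 0.03)
        assert condition2b(upfront, abp) == pytest.approx(0.212, abs=5e-4)

    def test_six_scheme_range_for_prevalence_dominant(self, lca_config):
        """Across {3%, 10%} x {5, 10, 15}y the peak-budget ratio stays
        between 8% and 24% of the upfront peak."""
        flow = patient_flow(lca_config.epidemiology, 25)
        upfront = discount_stream(build_upfront_stream(flow, 1e6), 0.03)
        ratios = []
        for rate in (0.03, 0.10):
            for n in (5, 10, 15):
                abp = discount_stream(build_abp_stream(flow, scheme(rate=rate, n=n)), 0.03)
                ratios.append(condition2b(upfront, abp))
        assert 0.08 <= min(ratios) and max(ratios) <= 0.24

    def test_zero_upfront_maximum_rejected(self):
        with pytest.raises(ValueError, match="zero maximum"):
            condition2b(disc([0.0]), disc([1.0]))


class TestCondition3:
    @pytest.mark.parametrize("rate, n", [(0.0, 1), (0.03, 5), (0.10, 15), (0.25, 30)])
    def test_npv_metric_is_identity(self, rate, n):
        assert condition3(scheme(rate=rate, n=n)) == pytest.approx(1.0, rel=1e-12)

    def test_nominal_sum_premium(self):
        # five payments of ~EUR 211,995 on a EUR 1M principal
        assert condition3(scheme(rate=0.03, n=5), "nominal_sum") == pytest.approx(
            1.06, abs=5e-3
        )

    def test_nominal_sum_at_zero_rate_is_one(self):
        assert condition3(scheme(rate=0.0, n=7), "nominal_sum") == pytest.approx(
            1.0, rel=1e-12
        )

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="unknown condition-3 metric"):
            condition3(scheme(), "profit")


class TestCondition4:
    @pytest.mark.parametrize(
        "n, durability, expected",
        [
            (15, 75.0, True),   # lifelong benefit, 15-year bond
            (10, 2.5, False),   # short-durability cancer therapy
            (2, 2.5, True),     # annuities capped at whole years of effect
            (3, 2.99, False),
        ],
    )
    def test_annuity_count_capped_by_durability(self, n, durability, expected):
        assert condition4(scheme(n=n), durability) is expected

    def test_nonpositive_durability_rejected(self):
        with pytest.raises(ValueError):
            condition4(scheme(), 0.0)


class TestEvaluateAll:
    def test_lca_health_impact_ten_year_feasible(self, lca_config):
        flow = patient_flow(lca_config.epidemiology, 25)
        report = evaluate_all(
            flow,
            scheme(rate=0.03, n=10),
            lca_config.economics,
            lca_config.durability_years,
        )
        assert report.overall_feasible

    def test_dlbcl_corporate_bond_infeasible(self, dlbcl_config):
        flow = patient_flow(dlbcl_config.epidemiology, 25)
        report = evaluate_all(
            flow,
            scheme(price=dlbcl_config.price, rate=0.10, n=10, kind="corporate"),
            dlbcl_config.economics,
            dlbcl_config.durability_years,
        )
        assert not report.overall_feasible
        assert not report.c4_pass

    def test_single_annuity_behaves_as_upfront(self, lca_config):
        flow = patient_flow(lca_config.epidemiology, 25)
        report = evaluate_all(
            flow, scheme(n=1), lca_config.economics, lca_config.durability_years
        )
        assert report.c2a_ratio == 1.0
        assert report.c2b_ratio == 1.0
        assert not report.c1_pass  # spreading over one year relieves nothing

    def test_ratios_scale_invariant_in_population(self, lca_config):
        epi = lca_config.epidemiology
        scaled = dataclasses.replace(
            epi,
            population_size=epi.population_size * 3,
            births_per_year=epi.births_per_year * 3,
        )
        econ = lca_config.economics
        s = scheme(rate=0.10, n=10)
        r1 = evaluate_all(patient_flow(epi, 25), s, econ, 75.0)
        r2 = evaluate_all(patient_flow(scaled, 25), s, econ, 75.0)
        assert r1.c2a_ratio == pytest.approx(r2.c2a_ratio, rel=1e-12)
        assert r1.c2b_ratio == pytest.approx(r2.c2b_ratio, rel=1e-12)
        assert r1.c3_ratio == pytest.approx(r2.c3_ratio, rel=1e-12)

    def test_repeated_evaluation_identical(self, lca_config):
        flow = patient_flow(lca_config.epidemiology, 25)
        args = (flow, scheme(n=10), lca_config.economics, 75.0)
        assert evaluate_all(*args) == evaluate_all(*args)

    def test_horizon_mismatch_rejected(self, lca_config):
        flow = patient_flow(lca_config.epidemiology, 10)
        with pytest.raises(ValueError, match="does not match"):
            evaluate_all(flow, scheme(), lca_config.economics, 75.0)
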