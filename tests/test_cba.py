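"""Cost streams, benefit monetisation, NPV/BCR and accounting identities."""

import math

import pytest

from oohcba import (CostInputs, build_cost_ledger, compute_npv_bcr,
                    industry_profit_loss, loaded_wage, monetise_benefits,
                    payer_shares, run_pipeline, ConfigError)
from oohcba.cba import (annual_govt_revenue_loss, annual_monitoring_cost,
                        policy_development_cost, CostLedger, CostEntry,
                        GOVERNMENT, INDUSTRY)


@pytest.mark.parametrize("base, oncost, loading, expected", [
    # 100000 x 1.14 x (1 + 0.175 x 4/52)
    (100_000, 0.14, 0.175, 115_534.6154),
    (100_000, 0.0, 0.0, 100_000.0),
    (0, 0.14, 0.175, 0.0),
])
def test_loaded_wage(base, oncost, loading, expected):
    assert loaded_wage(base, oncost, loading) == pytest.approx(expected,
                                                               abs=0.005)


def test_policy_development_cost_sums_grades():
    costs = CostInputs(policy_dev_fte_years={"a": 1.0, "b": 2.0},
                       grade_wage_multipliers={"a": 1.0, "b": 1.5},
                       base_wage=100_000, oncost_rate=0.0,
                       leave_loading_rate=0.0)
    assert policy_development_cost(costs) == pytest.approx(400_000.0)


def test_monitoring_is_half_national_floored_at_officer_wage():
    high = CostInputs(national_monitoring_cost=1_000_000)
    assert annual_monitoring_cost(high) == pytest.approx(500_000.0)
    low = CostInputs(national_monitoring_cost=0.0, base_wage=100_000)
    officer = loaded_wage(100_000, 0.14, 0.175)
    assert annual_monitoring_cost(low) == pytest.approx(officer)


def test_pta_revenue_loss_share():
    # billboard share zero isolates the PTA component
    costs = CostInputs(pta_food_ad_revenue=1_000_000, unhealthy_share_pta=0.55,
                       billboard_share=0.0)
    assert annual_govt_revenue_loss(costs) == pytest.approx(550_000.0)


def test_main_roads_imputation_uses_billboard_ratio():
    costs = CostInputs(pta_food_ad_revenue=1_000_000, unhealthy_share_pta=0.55,
                       billboard_share=0.58)
    want = 550_000 * (1 + 0.58 / 0.42)
    assert annual_govt_revenue_loss(costs) == pytest.approx(want)
    direct = costs.model_copy(update={"main_roads_revenue_loss": 123.0})
    assert annual_govt_revenue_loss(direct) == pytest.approx(550_123.0)


def test_zero_unhealthy_share_drops_revenue_entries():
    costs = CostInputs(unhealthy_share_pta=0.0)
    ledger = build_cost_ledger(costs, horizon=5)
    assert not [e for e in ledger.entries
                if e.category == "govt_revenue_loss"]


def test_legislation_cost_in_year_zero_when_enabled():
    ledger = build_cost_ledger(CostInputs(), horizon=5,
                               include_legislation=True)
    leg = [e for e in ledger.entries if e.category == "legislation"]
    assert len(leg) == 1
    assert leg[0].year == 0
    assert leg[0].amount == pytest.approx(1_306_180.0)


@pytest.mark.parametrize("revenue, conc, share, margin, expected", [
    (100_000_000, 0.07, 0.21, 0.13, 191_100.0),
    (100_000_000, 0.07, 0.21, 0.0, 0.0),
])
def test_industry_profit_loss(revenue, conc, share, margin, expected):
    costs = CostInputs(apn_national_transport_revenue=revenue,
                       wa_concentration=conc, unhealthy_ad_share=share,
                       profit_margin=margin)
    assert industry_profit_loss(costs) == pytest.approx(expected)


def test_no_revenue_change_scenario_zeroes_both_streams():
    ledger = build_cost_ledger(CostInputs(), horizon=5,
                               include_govt_revenue_loss=False,
                               include_industry_profit_loss=False)
    cats = {e.category for e in ledger.entries}
    assert "govt_revenue_loss" not in cats
    assert "industry_profit_loss" not in cats


def test_replacement_recovers_losses_from_year_two():
    ledger = build_cost_ledger(CostInputs(), horizon=5,
                               replacement_fraction=1.0)
    by_year = {}
    for e in ledger.entries:
        if e.category in ("govt_revenue_loss", "industry_profit_loss"):
            by_year.setdefault(e.year, 0.0)
            by_year[e.year] += e.amount
    assert by_year.get(1, 0.0) > 0
    assert all(y == 1 for y in by_year)  # nothing from year 2 onward


def test_monetise_benefits_headline_arithmetic():
    monetised, total = monetise_benefits(5906, 213_000, 116e6)
    assert monetised == pytest.approx(5906 * 213_000)
    assert total / 1e6 == pytest.approx(1374, abs=0.5)


def test_monetise_benefits_zero_and_alternative_vsly():
    assert monetise_benefits(0.0, 213_000, 0.0) == (0.0, 0.0)
    monetised, _ = monetise_benefits(1000, 314_772, 0.0)
    assert monetised == pytest.approx(314_772_000.0)


def test_npv_bcr():
    npv, bcr = compute_npv_bcr(1374e6, 28e6)
    assert npv == pytest.approx(1346e6)
    assert bcr == pytest.approx(1374 / 28, rel=1e-12)
    npv, bcr = compute_npv_bcr(0.0, 28e6)
    assert npv == pytest.approx(-28e6)
    assert bcr == 0.0
    npv, bcr = compute_npv_bcr(10.0, 0.0)
    assert math.isinf(bcr) and npv == 10.0


def test_payer_shares():
    def ledger(g, i):
        entries = []
        if g:
            entries.append(CostEntry(GOVERNMENT, "monitoring", 0, g))
        if i:
            entries.append(CostEntry(INDUSTRY, "industry_profit_loss", 0, i))
        return CostLedger(entries)

    shares = payer_shares(ledger(20e6, 8e6))
    assert shares[GOVERNMENT] == pytest.approx(20 / 28)
    assert round(100 * shares[GOVERNMENT]) == 71
    assert sum(shares.values()) == pytest.approx(1.0)
    assert payer_shares(ledger(5.0, 0))[GOVERNMENT] == 1.0
    equal = payer_shares(ledger(7.0, 7.0))
    assert equal[GOVERNMENT] == equal[INDUSTRY] == 0.5
    with pytest.raises(ConfigError):
        payer_shares(CostLedger([]))


def test_negative_amounts_rejected():
    with pytest.raises(ConfigError):
        CostEntry(GOVERNMENT, "monitoring", 1, -5.0)


def test_result_identities_on_real_run(bundle):
    res = run_pipeline(bundle)
    assert res.npv == pytest.approx(res.total_benefits - res.total_costs,
                                    rel=1e-15)
    assert res.total_benefits == pytest.approx(
        res.monetised_halys + res.hc_savings, rel=1e-15)
    assert res.total_costs == pytest.approx(
        res.govt_costs + res.industry_costs, rel=1e-15)
    assert res.bcr == pytest.approx(res.total_benefits / res.total_costs,
                                    rel=1e-15)


def test_dominance_flag(bundle):
    res = run_pipeline(bundle)
    assert res.dominant == (res.hc_savings > res.total_costs)


def test_discount_rate_monotonicity(bundle):
    ledger = build_cost_ledger(bundle.costs, horizon=10)
    # recurring entries sit after year 0, so a higher rate lowers their PV
    low = ledger.discounted_total(0.03)
    high = ledger.discounted_total(0.10)
    assert high < low
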