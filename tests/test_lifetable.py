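"""Lifetable model: PIFs, disease recursions, cohort simulation,
discounting.  The cohort model is checked against an independently coded
brute-force yearly state enumeration."""

import numpy as np
import pytest
from scipy import integrate, stats

from oohcba import (adjust_incidence, compute_pif, discount_stream, pif_table,
                    run_disease_model, run_lifetable, apply_effect_pathway,
                    EffectSpec, ModelError)
from oohcba.lifetable import compute_pif_categorical

from conftest import make_disease, make_population


# ---------------------------------------------------------------------------
# potential impact fractions

def quad_pif(mu, sd, delta, rr, tmrel):
    """Independent PIF oracle via adaptive quadrature."""
    def integrand(x, shift):
        return stats.norm.pdf(x, mu, sd) * rr ** max(0.0, x + shift - tmrel)

    hi = mu + 12 * sd
    num, _ = integrate.quad(integrand, tmrel, hi, args=(delta,), limit=400)
    den, _ = integrate.quad(integrand, tmrel, hi, args=(0.0,), limit=400)
    return 1.0 - num / den


def test_pif_flat_risk_is_zero():
    assert compute_pif(30.0, 4.0, -1.0, 1.0, 21.0) == 0.0


def test_pif_zero_shift_is_zero():
    assert compute_pif(30.0, 4.0, 0.0, 1.2, 21.0) == 0.0


def test_pif_point_mass_closed_form():
    # all mass at BMI 30; a -1 shift scales RR by 1/1.2
    got = compute_pif(30.0, 0.0, -1.0, 1.2, 21.0)
    assert got == pytest.approx(1.0 - 1.0 / 1.2, abs=1e-12)


@pytest.mark.parametrize("mu, sd, delta, rr", [
    (27.0, 4.5, -0.2, 1.12),
    (30.0, 4.0, -1.0, 1.05),
    (24.0, 3.5, -0.05, 1.2),
    (27.0, 4.5, 0.5, 1.08),     # weight gain: PIF goes negative
])
def test_pif_matches_quadrature_oracle(mu, sd, delta, rr):
    got = compute_pif(mu, sd, delta, rr, 21.0)
    want = quad_pif(mu, sd, delta, rr, 21.0)
    assert got == pytest.approx(want, rel=1e-6)
    if delta > 0:
        assert got < 0
    # categorical (BMI-band) mode agrees to its discretisation error
    cat = compute_pif_categorical(mu, sd, delta, rr, 21.0, bin_width=0.02)
    assert cat == pytest.approx(want, rel=1e-3, abs=1e-5)


def test_pif_table_shapes_and_zero_rows(bundle):
    deltas = apply_effect_pathway(bundle.population, bundle.consumption,
                                  EffectSpec())
    pifs = pif_table(bundle.population, bundle.diseases, deltas["delta_bmi"])
    assert pifs.shape == (len(bundle.diseases), len(bundle.population))
    assert (pifs.to_numpy() < 1).all()
    # zero BMI change in a stratum forces zero PIF there
    zero = pif_table(bundle.population, bundle.diseases,
                     np.zeros(len(bundle.population)))
    assert (zero.to_numpy() == 0).all()


@pytest.mark.parametrize("incidence, pif, expected", [
    (0.01, 1.0 - 1.0 / 1.2, 0.01 / 1.2),
    (0.01, 0.0, 0.01),
    (0.0, 0.5, 0.0),
])
def test_adjust_incidence(incidence, pif, expected):
    assert adjust_incidence(incidence, pif) == pytest.approx(expected,
                                                             rel=1e-9)


def test_adjust_incidence_rejects_out_of_range():
    with pytest.raises(ModelError):
        adjust_incidence(0.9, -0.5)   # 0.9 * 1.5 > 1


# ---------------------------------------------------------------------------
# single-disease recursion

def test_disease_model_closed_form_no_fatality():
    i = 0.03
    prev, mort = run_disease_model(np.full(10, i), np.zeros(10), np.zeros(10))
    want = 1.0 - (1.0 - i) ** np.arange(1, 11)
    np.testing.assert_allclose(prev, want, rtol=1e-12)
    assert (mort == 0).all()


def test_disease_model_zero_incidence_stays_zero():
    prev, mort = run_disease_model(np.zeros(5), np.full(5, 0.1),
                                   np.zeros(5))
    assert (prev == 0).all() and (mort == 0).all()


def test_disease_model_full_remission_bounds_prevalence():
    i = 0.02
    prev, _ = run_disease_model(np.full(8, i), np.zeros(8), np.ones(8))
    assert (prev <= i + 1e-12).all()   # only the current year's cases remain


def test_disease_model_rejects_probability_overflow():
    with pytest.raises(ModelError):
        run_disease_model(np.full(3, 0.1), np.full(3, 0.7), np.full(3, 0.5))


# ---------------------------------------------------------------------------
# cohort lifetable vs brute-force oracle

def oracle_lifetable(pop, diseases, pifs, horizon, onset_year=1):
    """Independent scalar enumeration of the two-arm cohort model.

    Valid for cohorts whose rates stay constant over the run (single band
    per sex in the population table).
    """
    out = {}
    for s, sid in enumerate(pop.index):
        N = {"base": float(pop.loc[sid, "count"]),
             "intv": float(pop.loc[sid, "count"])}
        acm = float(pop.loc[sid, "acm_rate"])
        st = {}
        for d in diseases:
            p0 = float(d.rates.loc[sid, "prevalence"])
            st[d.name] = {arm: {"h": 1 - p0, "c": p0} for arm in ("base",
                                                                  "intv")}
        hist = {arm: {"alive": [], "haly": [], "cost": [], "prev": []}
                for arm in ("base", "intv")}
        for t in range(1, horizon + 1):
            morts = {"base": {}, "intv": {}}
            prevs = {"base": {}, "intv": {}}
            for k, d in enumerate(diseases):
                i0 = float(d.rates.loc[sid, "incidence"])
                f = float(d.rates.loc[sid, "case_fatality"])
                r = float(d.rates.loc[sid, "remission"])
                for arm in ("base", "intv"):
                    i = i0
                    if arm == "intv" and t > onset_year:
                        i = i0 * (1.0 - pifs[k][s])
                    h, c = st[d.name][arm]["h"], st[d.name][arm]["c"]
                    alive = h + c
                    morts[arm][d.name] = c * f / alive if alive else 0.0
                    h2 = h * (1 - i) + c * r
                    c2 = c * (1 - f - r) + h * i
                    st[d.name][arm] = {"h": h2, "c": c2}
                    prevs[arm][d.name] = c2 / (h2 + c2) if h2 + c2 else 0.0
            other = acm - sum(morts["base"].values())
            for arm in ("base", "intv"):
                q = other + sum(morts[arm].values())
                N[arm] = N[arm] * (1 - q)
                burden = min(sum(prevs[arm][d.name] * d.disability_weight
                                 for d in diseases), 1.0)
                hist[arm]["alive"].append(N[arm])
                hist[arm]["haly"].append(N[arm] * (1 - burden))
                hist[arm]["cost"].append(N[arm] * sum(
                    prevs[arm][d.name] * d.unit_cost for d in diseases))
                hist[arm]["prev"].append(
                    [prevs[arm][d.name] for d in diseases])
        out[sid] = hist
    return out


def _tiny_setup():
    pop = make_population([
        {"age_lo": 40, "sex": "F", "count": 1000, "acm_rate": 0.01},
        {"age_lo": 60, "sex": "F", "count": 800, "acm_rate": 0.03},
        {"age_lo": 40, "sex": "M", "count": 900, "acm_rate": 0.015},
    ])
    diseases = [
        make_disease("type 2 diabetes", pop, incidence=0.01,
                     case_fatality=0.004, remission=0.0, prevalence=0.05,
                     disability_weight=0.07, unit_cost=3500.0),
        make_disease("stroke", pop, incidence=0.004, case_fatality=0.02,
                     remission=0.001, prevalence=0.02,
                     disability_weight=0.18, unit_cost=7500.0),
    ]
    pifs = np.array([[0.10, 0.08, 0.12], [0.05, 0.04, 0.06]])
    return pop, diseases, pifs


def test_lifetable_matches_bruteforce_oracle():
    pop, diseases, pifs = _tiny_setup()
    T = 5
    base, intv, _ = run_lifetable(pop, diseases, pifs, horizon=T,
                                  discount_rate=0.0)
    want = oracle_lifetable(pop, diseases, pifs, T)
    for s, sid in enumerate(pop.index):
        for arm, traj in (("base", base), ("intv", intv)):
            np.testing.assert_allclose(traj.alive[s, 1:],
                                       want[sid][arm]["alive"], rtol=1e-9)
            np.testing.assert_allclose(traj.haly[s],
                                       want[sid][arm]["haly"], rtol=1e-9)
            np.testing.assert_allclose(traj.hc_cost[s],
                                       want[sid][arm]["cost"], rtol=1e-9)
            np.testing.assert_allclose(
                traj.prevalence[:, s, :].T, want[sid][arm]["prev"],
                rtol=1e-9)


def test_lifetable_haly_hand_example():
    # 100 person-years, one disease at prevalence 0.1 with weight 0.2 -> 98
    pop = make_population([{"age_lo": 40, "sex": "F", "count": 100,
                            "acm_rate": 0.0}])
    dis = make_disease("stroke", pop, incidence=0.0, prevalence=0.1,
                       disability_weight=0.2, unit_cost=1000.0)
    base, _, _ = run_lifetable(pop, [dis], np.zeros((1, 1)), horizon=1,
                               discount_rate=0.0)
    assert base.person_years[0, 0] == pytest.approx(100.0)
    assert base.haly[0, 0] == pytest.approx(98.0)
    assert base.hc_cost[0, 0] == pytest.approx(0.1 * 100 * 1000.0)


def test_null_intervention_is_bitwise_identical(bundle):
    pifs = np.zeros((len(bundle.diseases), len(bundle.population)))
    base, intv, outcome = run_lifetable(bundle.population, bundle.diseases,
                                        pifs, horizon=10)
    assert np.array_equal(base.alive, intv.alive)
    assert np.array_equal(base.haly, intv.haly)
    assert np.array_equal(base.hc_cost, intv.hc_cost)
    assert outcome.halys_gained == 0.0
    assert outcome.hc_savings == 0.0


def test_conservation_of_persons(bundle):
    pifs = np.zeros((len(bundle.diseases), len(bundle.population)))
    base, _, _ = run_lifetable(bundle.population, bundle.diseases, pifs,
                               horizon=30)
    total_deaths = (base.deaths_disease.sum(axis=(0, 2))
                    + base.deaths_other.sum(axis=1))
    initial = bundle.population["count"].to_numpy(float)
    np.testing.assert_allclose(base.alive[:, -1] + total_deaths, initial,
                               rtol=1e-9)
    assert (base.alive >= 0).all()
    assert ((base.prevalence >= 0) & (base.prevalence <= 1)).all()
    assert (base.haly <= base.person_years + 1e-12).all()


def test_monotonic_in_bmi_reduction(bundle):
    deltas = apply_effect_pathway(bundle.population, bundle.consumption,
                                  EffectSpec())
    args = (bundle.population, bundle.diseases)
    p1 = pif_table(*args, deltas["delta_bmi"])
    p2 = pif_table(*args, 2.0 * deltas["delta_bmi"])
    _, _, o1 = run_lifetable(*args, p1, horizon=20)
    _, _, o2 = run_lifetable(*args, p2, horizon=20)
    assert o2.halys_gained >= o1.halys_gained > 0
    assert o2.hc_savings >= o1.hc_savings > 0


def test_negative_other_cause_mortality_raises():
    pop = make_population([{"age_lo": 40, "sex": "F", "count": 100,
                            "acm_rate": 0.001}])
    dis = make_disease("stroke", pop, incidence=0.0, prevalence=0.5,
                       case_fatality=0.5)
    with pytest.raises(ModelError, match="40-44F.*year 1"):
        run_lifetable(pop, [dis], np.zeros((1, 1)), horizon=3)


def test_phase_in_delays_the_effect():
    pop, diseases, pifs = _tiny_setup()
    _, _, now = run_lifetable(pop, diseases, pifs, horizon=10,
                              discount_rate=0.0)
    _, _, later = run_lifetable(pop, diseases, pifs, horizon=10,
                                discount_rate=0.0, start_year=5)
    assert later.halys_gained < now.halys_gained
    # nothing happens before the delayed onset
    assert np.allclose(later.halys_gained_stream[:6], 0.0)


# ---------------------------------------------------------------------------
# discounting

def test_discount_three_year_stream():
    assert discount_stream([100.0] * 3, 0.07) == pytest.approx(262.43,
                                                               abs=0.005)


def test_discount_zero_rate_is_sum():
    assert discount_stream([5.0, 7.0, 11.0], 0.0) == 23.0


def test_discount_single_step():
    assert discount_stream([107.0], 0.07) == pytest.approx(100.0)


def test_discount_rejects_negative_rate():
    with pytest.raises(ModelError):
        discount_stream([1.0], -0.1)
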