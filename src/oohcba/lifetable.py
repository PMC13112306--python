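"""Proportional multi-state lifetable Markov cohort model.

Each age/sex stratum is a closed cohort followed in annual cycles over the
analysis horizon.  Every obesity-related disease runs as its own
three-state Markov process (healthy -> diseased -> dead-from-disease, with
optional remission) on a unit cohort; diseases are independent conditional
on survival (the "proportional" assumption), and their mortality is summed
with an other-cause remainder to drive the survival curve:

    other-cause(t) = all-cause(t) - sum_d disease-mortality_d(t)

recomputed every year from the *baseline* disease models, so that baseline
all-cause mortality reproduces the input rates exactly.

BMI shifts act on disease incidence through potential impact fractions
(PIFs): with BMI ~ Normal(mu, sigma) truncated below the theoretical
minimum-risk exposure level (TMREL) and a log-linear relative risk
RR(x) = rr^max(0, x - tmrel),

    PIF = 1 - E[RR(B + dBMI)] / E[RR(B)],

evaluated by Gauss-Legendre quadrature split at the RR kink.  Intervention
incidence is incidence x (1 - PIF) from the cycle after the weight change
is realised (end of year 1 by default).

Outputs are health-adjusted life years, HALY(t) = person-years(t) x
(1 - sum_d prevalence_d(t) x disability-weight_d, capped at 1), and
healthcare costs, cost(t) = sum_d prevalence_d(t) x alive(t) x unit-cost_d.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ModelError
from .strata import band_index_of_age, N_BANDS
from .synthetic import DiseaseDefinition

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)


# ---------------------------------------------------------------------------
# potential impact fractions

def _expected_rr(mu: np.ndarray, sd: np.ndarray, shift: np.ndarray,
                 log_rr: np.ndarray, tmrel: np.ndarray) -> np.ndarray:
    """E[rr^max(0, B + shift - tmrel) * 1{B >= tmrel}] (unnormalised),
    B ~ Normal(mu, sd), broadcast over the leading shape.

    The integrand kinks where B + shift = tmrel; the integral is split
    there so each Gauss-Legendre segment is smooth.
    """
    mu, sd, shift, log_rr, tmrel = np.broadcast_arrays(
        np.asarray(mu, float), np.asarray(sd, float), np.asarray(shift, float),
        np.asarray(log_rr, float), np.asarray(tmrel, float))
    lo = tmrel
    hi = np.maximum(mu + 12.0 * sd, tmrel + 1.0)
    kink = np.clip(tmrel - shift, lo, hi)

    def segment(a, b):
        half = (b - a) / 2.0
        mid = (b + a) / 2.0
        x = mid[..., None] + half[..., None] * _GL_NODES   # (..., K)
        pdf = np.exp(-0.5 * ((x - mu[..., None]) / sd[..., None]) ** 2) \
            / (sd[..., None] * np.sqrt(2.0 * np.pi))
        rrv = np.exp(log_rr[..., None]
                     * np.maximum(0.0, x + shift[..., None] - tmrel[..., None]))
        return (half[..., None] * _GL_WEIGHTS * pdf * rrv).sum(axis=-1)

    return segment(lo, kink) + segment(kink, hi)


def compute_pif(bmi_mean: float, bmi_sd: float, delta_bmi: float,
                rr_per_bmi_unit: float, tmrel_bmi: float) -> float:
    """PIF for one stratum/disease; positive values reduce incidence."""
    if bmi_sd < 0:
        raise ModelError(f"bmi_sd must be >= 0, got {bmi_sd}")
    if rr_per_bmi_unit < 1:
        raise ModelError(f"rr_per_bmi_unit must be >= 1, got {rr_per_bmi_unit}")
    if rr_per_bmi_unit == 1.0 or delta_bmi == 0.0:
        return 0.0
    log_rr = np.log(rr_per_bmi_unit)
    if bmi_sd == 0.0:
        rr0 = np.exp(log_rr * max(0.0, bmi_mean - tmrel_bmi))
        rr1 = np.exp(log_rr * max(0.0, bmi_mean + delta_bmi - tmrel_bmi))
        return float(1.0 - rr1 / rr0)
    num = _expected_rr(bmi_mean, bmi_sd, delta_bmi, log_rr, tmrel_bmi)
    den = _expected_rr(bmi_mean, bmi_sd, 0.0, log_rr, tmrel_bmi)
    return float(1.0 - num / den)


def compute_pif_categorical(bmi_mean: float, bmi_sd: float, delta_bmi: float,
                            rr_per_bmi_unit: float, tmrel_bmi: float,
                            bin_width: float = 0.25) -> float:
    """Cross-check PIF using discrete BMI bands instead of quadrature."""
    if rr_per_bmi_unit == 1.0 or delta_bmi == 0.0 or bmi_sd == 0.0:
        return compute_pif(bmi_mean, bmi_sd, delta_bmi, rr_per_bmi_unit,
                           tmrel_bmi)
    edges = np.arange(tmrel_bmi, bmi_mean + 12 * bmi_sd + bin_width, bin_width)
    mids = (edges[:-1] + edges[1:]) / 2.0
    p = np.exp(-0.5 * ((mids - bmi_mean) / bmi_sd) ** 2)
    lrr = np.log(rr_per_bmi_unit)
    rr0 = np.exp(lrr * np.maximum(0.0, mids - tmrel_bmi))
    rr1 = np.exp(lrr * np.maximum(0.0, mids + delta_bmi - tmrel_bmi))
    return float(1.0 - (p * rr1).sum() / (p * rr0).sum())


def pif_table(population: pd.DataFrame, diseases: Sequence[DiseaseDefinition],
              delta_bmi: pd.Series | np.ndarray) -> pd.DataFrame:
    """PIF per (disease, stratum); rows = diseases, columns = strata."""
    mu = population["bmi_mean"].to_numpy(float)
    sd = population["bmi_sd"].to_numpy(float)
    delta = np.asarray(delta_bmi, float)
    out = np.zeros((len(diseases), len(population)))
    for k, dis in enumerate(diseases):
        if dis.rr_per_bmi_unit == 1.0:
            continue
        log_rr = np.log(dis.rr_per_bmi_unit)
        num = _expected_rr(mu, sd, delta, log_rr, dis.tmrel_bmi)
        den = _expected_rr(mu, sd, 0.0, log_rr, dis.tmrel_bmi)
        pif = 1.0 - num / den
        out[k] = np.where(delta == 0.0, 0.0, pif)
    return pd.DataFrame(out, index=[d.name for d in diseases],
                        columns=population.index)


def adjust_incidence(incidence: float | np.ndarray, pif: float | np.ndarray
                     ) -> float | np.ndarray:
    """Apply a PIF to an incidence rate: i' = i x (1 - PIF)."""
    out = np.asarray(incidence) * (1.0 - np.asarray(pif))
    if np.any(out < 0) or np.any(out > 1):
        raise ModelError("PIF-adjusted incidence left [0, 1]")
    if np.isscalar(incidence) or np.ndim(incidence) == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# disease process

def run_disease_model(incidence: np.ndarray, case_fatality: np.ndarray,
                      remission: np.ndarray, prevalence0: float = 0.0,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Three-state Markov recursion for one disease on a unit cohort.

    Rates are per-year arrays of length T.  Returns (prevalence, mortality)
    where prevalence[t] is the diseased proportion among this model's
    survivors at the *end* of year t, and mortality[t] the disease death
    probability during year t among survivors at the start of the year.
    """
    incidence = np.asarray(incidence, float)
    T = len(incidence)
    h, c = 1.0 - prevalence0, prevalence0
    prev = np.empty(T)
    mort = np.empty(T)
    for t in range(T):
        i, f, r = incidence[t], case_fatality[t], remission[t]
        if f + r > 1.0 or i > 1.0:
            raise ModelError(f"transition probabilities exceed 1 in year {t + 1}")
        alive = h + c
        mort[t] = c * f / alive if alive > 0 else 0.0
        h, c = h * (1.0 - i) + c * r, c * (1.0 - f - r) + h * i
        alive = h + c
        prev[t] = c / alive if alive > 0 else 0.0
    return prev, mort


# ---------------------------------------------------------------------------
# lifetable

@dataclasses.dataclass
class CohortTrajectory:
    """Year-by-year state of every stratum cohort (arrays, year axis last).

    ``alive`` has shape (S, T+1): survivors at the start of each year plus
    the end of the horizon.  ``prevalence`` (D, S, T) is measured at year
    end; ``person_years`` are end-of-year survivors (half-cycle correction
    off).
    """

    stratum_ids: list[str]
    disease_names: list[str]
    alive: np.ndarray
    deaths_disease: np.ndarray    # (D, S, T)
    deaths_other: np.ndarray      # (S, T)
    prevalence: np.ndarray        # (D, S, T)
    person_years: np.ndarray      # (S, T)
    haly: np.ndarray              # (S, T)
    hc_cost: np.ndarray           # (S, T)

    @property
    def horizon(self) -> int:
        return self.person_years.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy (stratum, year, metric, value) view of the scalar streams."""
        S, T = self.person_years.shape
        rows = []
        for s, sid in enumerate(self.stratum_ids):
            for t in range(T):
                rows.extend([
                    (sid, t + 1, "alive", self.alive[s, t + 1]),
                    (sid, t + 1, "person_years", self.person_years[s, t]),
                    (sid, t + 1, "haly", self.haly[s, t]),
                    (sid, t + 1, "hc_cost", self.hc_cost[s, t]),
                    (sid, t + 1, "deaths_other", self.deaths_other[s, t]),
                ])
        return pd.DataFrame(rows, columns=["stratum_id", "year", "metric",
                                           "value"])


@dataclasses.dataclass
class HealthOutcome:
    """Intervention-minus-baseline health streams and their totals."""

    halys_gained_stream: np.ndarray   # per year, undiscounted
    hc_savings_stream: np.ndarray     # per year, undiscounted, A$
    discount_rate: float
    halys_gained: float = dataclasses.field(init=False)
    hc_savings: float = dataclasses.field(init=False)
    halys_gained_undiscounted: float = dataclasses.field(init=False)
    hc_savings_undiscounted: float = dataclasses.field(init=False)

    def __post_init__(self):
        self.halys_gained = discount_stream(self.halys_gained_stream,
                                            self.discount_rate)
        self.hc_savings = discount_stream(self.hc_savings_stream,
                                          self.discount_rate)
        self.halys_gained_undiscounted = float(self.halys_gained_stream.sum())
        self.hc_savings_undiscounted = float(self.hc_savings_stream.sum())


def discount_stream(stream: Sequence[float], rate: float, t0: int = 1) -> float:
    """Present value of a per-year stream with end-of-year convention:
    sum_t stream[t] / (1 + rate)^(t0 + t)."""
    if rate < 0:
        raise ModelError(f"discount rate must be >= 0, got {rate}")
    stream = np.asarray(stream, float)
    t = t0 + np.arange(len(stream))
    return float((stream / (1.0 + rate) ** t).sum())


def _row_map(population: pd.DataFrame, horizon: int) -> np.ndarray:
    """row_map[s, t] = stratum row whose rates cohort s faces in year t+1.

    Cohorts start at their band midpoint age and age one year per cycle;
    ages past the last band keep using it.
    """
    sids = list(population.index)
    start_age = ((population["age_lo"] + population["age_hi"] - 1) // 2
                 ).to_numpy(int)
    sex_of = population["sex"].to_numpy()
    lookup: dict[str, dict[int, int]] = {"F": {}, "M": {}}
    for k, sid in enumerate(sids):
        b = band_index_of_age(int(population.loc[sid, "age_lo"]))
        lookup[population.loc[sid, "sex"]][b] = k
    out = np.empty((len(sids), horizon), dtype=int)
    for s in range(len(sids)):
        table = lookup[sex_of[s]]
        for t in range(horizon):
            b = band_index_of_age(min(start_age[s] + t, 99))
            # fall back to the oldest band present for this sex
            while b not in table and b > 0:
                b -= 1
            out[s, t] = table[b]
    return out


def run_lifetable(population: pd.DataFrame,
                  diseases: Sequence[DiseaseDefinition],
                  pifs: pd.DataFrame | np.ndarray,
                  horizon: int = 30,
                  discount_rate: float = 0.07,
                  onset_year: int = 1,
                  start_year: int = 0,
                  dw_combination: str = "additive",
                  ) -> tuple[CohortTrajectory, CohortTrajectory, HealthOutcome]:
    """Run baseline and intervention cohorts and difference the outcomes.

    The BMI change is realised at the end of year ``start_year +
    onset_year``; PIF-adjusted incidence applies to all later cycles.
    ``start_year`` delays the whole intervention (phase-in scenarios).
    Raises :class:`ModelError` if modelled disease mortality exceeds
    all-cause mortality in any stratum-year.
    """
    S = len(population)
    D = len(diseases)
    T = int(horizon)
    pif = np.asarray(pifs, float).reshape(D, S)
    rows = _row_map(population, T)

    inc0 = np.stack([d.rates["incidence"].to_numpy(float) for d in diseases])
    cf0 = np.stack([d.rates["case_fatality"].to_numpy(float) for d in diseases])
    rem0 = np.stack([d.rates["remission"].to_numpy(float) for d in diseases])
    prev0 = np.stack([d.rates["prevalence"].to_numpy(float) for d in diseases])
    dw = np.array([d.disability_weight for d in diseases])
    ucost = np.array([d.unit_cost for d in diseases])
    acm0 = population["acm_rate"].to_numpy(float)
    n0 = population["count"].to_numpy(float)
    onset = start_year + onset_year

    def empty():
        return CohortTrajectory(
            stratum_ids=list(population.index),
            disease_names=[d.name for d in diseases],
            alive=np.empty((S, T + 1)),
            deaths_disease=np.empty((D, S, T)),
            deaths_other=np.empty((S, T)),
            prevalence=np.empty((D, S, T)),
            person_years=np.empty((S, T)),
            haly=np.empty((S, T)),
            hc_cost=np.empty((S, T)),
        )

    base, intv = empty(), empty()
    for traj in (base, intv):
        traj.alive[:, 0] = n0

    # disease-model state, shape (D, S); cohorts start at their own stratum
    hb = 1.0 - prev0
    cb = prev0.copy()
    hi_ = hb.copy()
    ci = cb.copy()

    for t in range(1, T + 1):
        cols = rows[:, t - 1]
        inc = inc0[:, cols]
        cf = cf0[:, cols]
        rem = rem0[:, cols]
        acm = acm0[cols]
        if np.any(cf + rem > 1.0) or np.any(inc > 1.0):
            raise ModelError(f"transition probabilities exceed 1 in year {t}")
        inc_int = inc * (1.0 - pif) if t > onset else inc

        def step(h, c, i):
            alive = h + c
            mort = np.where(alive > 0, c * cf / np.where(alive > 0, alive, 1.0),
                            0.0)
            h2 = h * (1.0 - i) + c * rem
            c2 = c * (1.0 - cf - rem) + h * i
            alive2 = h2 + c2
            prev = np.where(alive2 > 0, c2 / np.where(alive2 > 0, alive2, 1.0),
                            0.0)
            return h2, c2, prev, mort

        hb, cb, prev_b, mort_b = step(hb, cb, inc)
        hi_, ci, prev_i, mort_i = step(hi_, ci, inc_int)

        other = acm - mort_b.sum(axis=0)
        if np.any(other < -1e-12):
            s_bad = int(np.argmin(other))
            raise ModelError(
                f"modelled disease mortality exceeds all-cause mortality "
                f"(stratum {population.index[s_bad]}, year {t})")
        other = np.maximum(other, 0.0)

        for traj, prev, mort in ((base, prev_b, mort_b), (intv, prev_i, mort_i)):
            n_start = traj.alive[:, t - 1]
            d_dis = n_start * mort
            d_oth = n_start * other
            n_end = n_start - d_dis.sum(axis=0) - d_oth
            traj.alive[:, t] = n_end
            traj.deaths_disease[:, :, t - 1] = d_dis
            traj.deaths_other[:, t - 1] = d_oth
            traj.prevalence[:, :, t - 1] = prev
            traj.person_years[:, t - 1] = n_end
            if dw_combination == "additive":
                burden = np.minimum((prev * dw[:, None]).sum(axis=0), 1.0)
            elif dw_combination == "multiplicative":
                burden = 1.0 - np.prod(1.0 - prev * dw[:, None], axis=0)
            else:
                raise ModelError(
                    f"unknown dw_combination {dw_combination!r}")
            traj.haly[:, t - 1] = n_end * (1.0 - burden)
            traj.hc_cost[:, t - 1] = (prev * n_end * ucost[:, None]).sum(axis=0)

    outcome = HealthOutcome(
        halys_gained_stream=(intv.haly - base.haly).sum(axis=0),
        hc_savings_stream=(base.hc_cost - intv.hc_cost).sum(axis=0),
        discount_rate=discount_rate,
    )
    return base, intv, outcome


__all__ = [
    "compute_pif", "compute_pif_categorical", "pif_table", "adjust_incidence",
    "run_disease_model", "run_lifetable", "discount_stream",
    "CohortTrajectory", "HealthOutcome", "N_BANDS",
]
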