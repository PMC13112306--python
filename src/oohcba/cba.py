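"""Societal cost-benefit accounting: cost streams, benefit monetisation,
net present value and benefit-cost ratio.

Government bears policy development (year 0), annual monitoring and the
advertising revenue forgone on public-transport and Main Roads assets;
industry bears the profit lost on unhealthy-food advertising.  Health
gains (HALYs) are monetised with the value of a statistical life year and
added to healthcare cost savings on the benefit side.  All amounts are
2019 A$ discounted at the configured real social discount rate with an
end-of-year convention (year 0 undiscounted).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable

from .errors import ConfigError
from .synthetic import CostInputs

GOVERNMENT = "government"
INDUSTRY = "industry"

CATEGORIES = ("policy_development", "legislation", "monitoring",
              "govt_revenue_loss", "industry_profit_loss")


@dataclasses.dataclass(frozen=True)
class CostEntry:
    payer: str
    category: str
    year: int
    amount: float

    def __post_init__(self):
        if self.amount < 0:
            raise ConfigError(f"cost amounts must be >= 0, got {self.amount} "
                              f"({self.payer}/{self.category}, year {self.year})")
        if self.payer not in (GOVERNMENT, INDUSTRY):
            raise ConfigError(f"unknown payer {self.payer!r}")
        if self.category not in CATEGORIES:
            raise ConfigError(f"unknown cost category {self.category!r}")


@dataclasses.dataclass
class CostLedger:
    entries: list[CostEntry]

    def discounted_total(self, rate: float, payer: str | None = None) -> float:
        return sum(e.amount / (1.0 + rate) ** e.year for e in self.entries
                   if payer is None or e.payer == payer)

    def undiscounted_total(self, payer: str | None = None) -> float:
        return sum(e.amount for e in self.entries
                   if payer is None or e.payer == payer)


def loaded_wage(base_wage: float, oncost_rate: float,
                leave_loading_rate: float, leave_weeks: float = 4.0) -> float:
    """Annual wage inclusive of salary oncosts and annual leave loading
    (loading paid on ``leave_weeks`` of a 52-week year)."""
    return base_wage * (1.0 + oncost_rate) \
        * (1.0 + leave_loading_rate * leave_weeks / 52.0)


def policy_development_cost(costs: CostInputs) -> float:
    """Year-0 policy development cost: FTE-years by grade at loaded wages."""
    total = 0.0
    for grade, fte in costs.policy_dev_fte_years.items():
        mult = costs.grade_wage_multipliers.get(grade, 1.0)
        total += fte * loaded_wage(costs.base_wage * mult, costs.oncost_rate,
                                   costs.leave_loading_rate)
    return total


def annual_monitoring_cost(costs: CostInputs) -> float:
    """State policy monitoring: half the national monitoring cost, floored
    at one full-time compliance officer's loaded wage."""
    officer = loaded_wage(costs.base_wage, costs.oncost_rate,
                          costs.leave_loading_rate)
    return max(costs.national_monitoring_cost / 2.0, officer)


def annual_govt_revenue_loss(costs: CostInputs) -> float:
    """Advertising revenue forgone by government, per year.

    PTA component: food/drink advertising income scaled by the unhealthy
    share.  Main Roads component: imputed from the billboard share of
    out-of-home advertising (billboard:non-billboard ratio applied to the
    PTA loss) unless a direct amount is supplied.
    """
    pta_loss = costs.pta_food_ad_revenue * costs.unhealthy_share_pta
    if costs.main_roads_revenue_loss is not None:
        main_roads = costs.main_roads_revenue_loss
    elif costs.billboard_share < 1.0:
        main_roads = pta_loss * costs.billboard_share / (1.0 - costs.billboard_share)
    else:
        raise ConfigError("billboard_share = 1 leaves the Main Roads "
                          "imputation undefined; supply main_roads_revenue_loss")
    return pta_loss + main_roads


def industry_profit_loss(costs: CostInputs) -> float:
    """Annual profit loss to outdoor advertisers: national transport
    advertising revenue x WA concentration x unhealthy-ad share x margin."""
    return (costs.apn_national_transport_revenue * costs.wa_concentration
            * costs.unhealthy_ad_share * costs.profit_margin)


def build_cost_ledger(costs: CostInputs, horizon: int,
                      include_legislation: bool = False,
                      include_govt_revenue_loss: bool = True,
                      include_industry_profit_loss: bool = True,
                      replacement_fraction: float = 0.0,
                      replacement_start_year: int = 2,
                      start_year: int = 0) -> CostLedger:
    """Assemble the full cost ledger for one scenario.

    Development (and legislation, if enabled) fall in ``start_year``;
    recurring items run from ``start_year + 1`` to ``horizon``.  A
    replacement fraction f recovers f of the revenue/profit losses from
    ``replacement_start_year`` (relative to start) onward.
    """
    if not 0.0 <= replacement_fraction <= 1.0:
        raise ConfigError(f"replacement_fraction must be in [0, 1], "
                          f"got {replacement_fraction}")
    entries: list[CostEntry] = []
    entries.append(CostEntry(GOVERNMENT, "policy_development", start_year,
                             policy_development_cost(costs)))
    if include_legislation:
        entries.append(CostEntry(GOVERNMENT, "legislation", start_year,
                                 costs.legislation_cost))
    monitoring = annual_monitoring_cost(costs)
    revenue = annual_govt_revenue_loss(costs) if include_govt_revenue_loss else 0.0
    profit = industry_profit_loss(costs) if include_industry_profit_loss else 0.0
    for year in range(start_year + 1, horizon + 1):
        entries.append(CostEntry(GOVERNMENT, "monitoring", year, monitoring))
        replaced = (replacement_fraction
                    if year - start_year >= replacement_start_year else 0.0)
        if revenue * (1.0 - replaced) > 0:
            entries.append(CostEntry(GOVERNMENT, "govt_revenue_loss", year,
                                     revenue * (1.0 - replaced)))
        if profit * (1.0 - replaced) > 0:
            entries.append(CostEntry(INDUSTRY, "industry_profit_loss", year,
                                     profit * (1.0 - replaced)))
    return CostLedger(entries)


def monetise_benefits(halys_gained: float, vsly: float,
                      hc_savings: float) -> tuple[float, float]:
    """(monetised HALYs, total benefits): HALYs x VSLY plus healthcare
    savings, all already discounted."""
    if vsly <= 0:
        raise ConfigError(f"vsly must be > 0, got {vsly}")
    monetised = halys_gained * vsly
    return monetised, monetised + hc_savings


def compute_npv_bcr(total_benefits: float, total_costs: float
                    ) -> tuple[float, float]:
    """NPV = benefits - costs; BCR = benefits / costs (inf when costs are
    zero, signalled rather than raised)."""
    npv = total_benefits - total_costs
    bcr = total_benefits / total_costs if total_costs > 0 else math.inf
    return npv, bcr


def payer_shares(ledger: CostLedger, rate: float = 0.0) -> dict[str, float]:
    """Discounted share of total costs borne by each payer; sums to 1."""
    total = ledger.discounted_total(rate)
    if total <= 0:
        raise ConfigError("payer shares undefined for an empty/zero ledger")
    return {payer: ledger.discounted_total(rate, payer) / total
            for payer in (GOVERNMENT, INDUSTRY)}


@dataclasses.dataclass
class CBAResult:
    """Discounted totals of one pipeline run (2019 A$)."""

    halys_gained: float
    hc_savings: float
    monetised_halys: float
    total_benefits: float
    govt_costs: float
    industry_costs: float
    total_costs: float
    npv: float
    bcr: float
    mean_weight_change: float
    dominant: bool

    def as_dict(self) -> dict[str, float]:
        return {k: (float(v) if not isinstance(v, bool) else v)
                for k, v in dataclasses.asdict(self).items()}


def assemble_result(halys_gained: float, hc_savings: float, vsly: float,
                    ledger: CostLedger, discount_rate: float,
                    mean_weight_change: float = 0.0) -> CBAResult:
    """Combine health outcomes and the cost ledger into a CBAResult.

    A run is flagged *dominant* when healthcare savings alone exceed total
    costs (the policy saves money even before health gains are monetised).
    """
    monetised, benefits = monetise_benefits(halys_gained, vsly, hc_savings)
    govt = ledger.discounted_total(discount_rate, GOVERNMENT)
    industry = ledger.discounted_total(discount_rate, INDUSTRY)
    total = govt + industry
    npv, bcr = compute_npv_bcr(benefits, total)
    return CBAResult(
        halys_gained=halys_gained,
        hc_savings=hc_savings,
        monetised_halys=monetised,
        total_benefits=benefits,
        govt_costs=govt,
        industry_costs=industry,
        total_costs=total,
        npv=npv,
        bcr=bcr,
        mean_weight_change=mean_weight_change,
        dominant=hc_savings > total,
    )


def iter_categories(ledger: CostLedger) -> Iterable[tuple[str, str, float]]:
    """(payer, category, undiscounted total) triples, for reporting."""
    seen: dict[tuple[str, str], float] = {}
    for e in ledger.entries:
        seen[(e.payer, e.category)] = seen.get((e.payer, e.category), 0.0) \
            + e.amount
    for (payer, cat), amount in sorted(seen.items()):
        yield payer, cat, amount
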