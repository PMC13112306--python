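"""Intervention effect pathway: purchasing change -> energy intake -> body
weight -> BMI, per population stratum.

The seed effect is the relative change in unhealthy-food energy purchased
observed after Transport for London's 2019 advertising restriction
(-6.7 %, 95 % CI -10.1 to -3.2).  Multiplicative effectiveness adjustments
(e.g. a 20 % reduction for lower out-of-home advertising exposure in Perth,
or an 18 % reduction for the absent bus-shelter coverage) scale this effect
before it is applied, 1:1, to stratum-level unhealthy food consumption.
Energy changes convert to steady-state weight changes via a per-age-band
energy-balance coefficient (kJ/day per kg), realised at the end of year 1
and maintained thereafter; BMI change is weight change over height squared.
"""

from __future__ import annotations

import math
from typing import Mapping

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigError
from .strata import parse_stratum_id

#: kJ/day of sustained intake change per kg of steady-state weight change
#: (widely used adult energy-balance approximation).
EPSILON_ADULT_KJ_PER_KG = 94.0
#: child bands use a growth-adjusted coefficient; overridable per run.
EPSILON_CHILD_KJ_PER_KG = 420.0
ADULT_AGE = 18


class EffectSpec(BaseModel):
    """Relative change in unhealthy-food energy purchased, with CI and an
    ordered list of multiplicative effectiveness reductions."""

    relative_change: float = -0.067
    ci_low: float = -0.101
    ci_high: float = -0.032
    adjustments: tuple[float, ...] = (0.20,)
    #: None means one effect applied to the unhealthy-category total;
    #: otherwise a map of category -> relative change (Scenario 5 shape).
    by_category: dict[str, float] | None = None

    @model_validator(mode="after")
    def _check(self):
        if not self.ci_low <= self.relative_change <= self.ci_high:
            raise ValueError(
                f"CI must bracket relative_change: "
                f"{self.ci_low} <= {self.relative_change} <= {self.ci_high}")
        for a in self.adjustments:
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"adjustment {a} outside [0, 1]")
        return self


class EnergyBalance(BaseModel):
    """Energy-to-weight conversion coefficients, kJ/day per kg."""

    epsilon_adult: float = EPSILON_ADULT_KJ_PER_KG
    epsilon_child: float = EPSILON_CHILD_KJ_PER_KG
    adult_age: int = ADULT_AGE
    overrides: dict[int, float] = Field(default_factory=dict)  # band age_lo -> eps

    def epsilon(self, age_lo: int) -> float:
        eps = self.overrides.get(
            age_lo,
            self.epsilon_adult if age_lo >= self.adult_age else self.epsilon_child,
        )
        if eps <= 0:
            raise ConfigError(f"energy-balance epsilon must be > 0, got {eps} "
                              f"for band starting at age {age_lo}")
        return eps


def adjusted_effect(spec: EffectSpec) -> float:
    """Effect size after all effectiveness adjustments.

    Each adjustment a_i multiplies the effect by (1 - a_i); the product is
    order-independent.
    """
    out = spec.relative_change
    for a in spec.adjustments:
        out *= 1.0 - a
    return out


def coverage_adjustment(shelter_coverage: float, shelter_asset_share: float
                        ) -> float:
    """Effectiveness reduction attributable to media assets the policy does
    not cover (bus shelters), assuming equal advertising exposure per asset.

    ``shelter_coverage`` is the fraction of shelters the reference (TfL)
    policy covered; ``shelter_asset_share`` the fraction of local media
    assets that are shelters.
    """
    for name, v in (("shelter_coverage", shelter_coverage),
                    ("shelter_asset_share", shelter_asset_share)):
        if not 0.0 <= v <= 1.0:
            raise ConfigError(f"{name} must be in [0, 1], got {v}")
    return shelter_coverage * shelter_asset_share


def intake_change(consumption: pd.DataFrame,
                  effect: float | Mapping[str, float]) -> pd.DataFrame:
    """Change in mean daily energy intake per stratum (kJ/person/day).

    A scalar ``effect`` applies to the stratum's total across unhealthy
    categories; a mapping applies category-specific effects (categories not
    named get zero).  No dietary substitution term is added.
    """
    if isinstance(effect, Mapping):
        known = set(consumption["category"].unique())
        unknown = sorted(set(effect) - known)
        if unknown:
            raise ConfigError(
                f"unknown categories {unknown}; table has {sorted(known)}")
        eff = consumption["category"].map(effect).fillna(0.0)
        delta = consumption["mean_kj_per_day"] * eff
    else:
        delta = consumption["mean_kj_per_day"] * float(effect)
    out = (
        consumption.assign(delta_kj_per_day=delta)
        .groupby("stratum_id", sort=False)["delta_kj_per_day"]
        .sum()
        .reset_index()
    )
    return out


def weight_change(delta_kj: float, age_lo: int,
                  balance: EnergyBalance | None = None) -> float:
    """Steady-state weight change (kg) from a sustained intake change
    (kJ/day), linear in the intake change."""
    balance = balance or EnergyBalance()
    return delta_kj / balance.epsilon(age_lo)


def bmi_change(delta_weight: float, mean_height: float) -> float:
    """BMI change (kg/m2) from a weight change at fixed height."""
    if mean_height <= 0 or math.isnan(mean_height):
        raise ConfigError(f"mean_height must be > 0, got {mean_height}")
    return delta_weight / mean_height**2


def apply_effect_pathway(population: pd.DataFrame,
                         consumption: pd.DataFrame,
                         spec: EffectSpec,
                         balance: EnergyBalance | None = None,
                         ) -> pd.DataFrame:
    """Run the whole pathway; returns per-stratum deltas indexed by stratum.

    Columns: delta_kj_per_day, delta_weight (kg), delta_bmi (kg/m2),
    realized_at (year index, 1).  The population-weighted mean weight change
    is attached as ``DataFrame.attrs['mean_weight_change']``.
    """
    balance = balance or EnergyBalance()
    effect = spec.by_category if spec.by_category is not None \
        else adjusted_effect(spec)
    if isinstance(effect, dict) and spec.adjustments:
        scale = 1.0
        for a in spec.adjustments:
            scale *= 1.0 - a
        effect = {k: v * scale for k, v in effect.items()}
    deltas = intake_change(consumption, effect).set_index("stratum_id")
    deltas = deltas.reindex(population.index, fill_value=0.0)

    age_lo = population["age_lo"]
    eps = age_lo.map(balance.epsilon)
    deltas["delta_weight"] = deltas["delta_kj_per_day"] / eps
    deltas["delta_bmi"] = [
        bmi_change(w, h)
        for w, h in zip(deltas["delta_weight"], population["mean_height"])
    ]
    deltas["realized_at"] = 1
    w = population["count"].to_numpy(dtype=float)
    total = w.sum()
    deltas.attrs["mean_weight_change"] = float(
        (deltas["delta_weight"].to_numpy() * w).sum() / total) if total else 0.0
    return deltas


# parse_stratum_id re-exported for convenience of callers building tables
__all__ = [
    "EffectSpec", "EnergyBalance", "adjusted_effect", "coverage_adjustment",
    "intake_change", "weight_change", "bmi_change", "apply_effect_pathway",
    "parse_stratum_id",
]
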