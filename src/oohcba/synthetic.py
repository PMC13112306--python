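"""Synthetic Perth-like model inputs.

No public microdata back this analysis, so every downstream stage is
exercised on internally consistent synthetic tables: a closed age/sex
stratified population with all-cause mortality and BMI distributions,
epidemiological rates for ten obesity-related disease states, mean daily
energy intake from unhealthy food categories, and the cost/revenue
parameters of the policy.  Magnitudes are loosely calibrated to
public-knowledge ranges (Greater Perth ~2.1 M people, adult BMI mean ~27
kg/m2) but carry no claim of realism.

The generator is deterministic under a fixed seed, and the ground-truth
parameters (true effect size, RR per BMI unit, ...) are recorded in the
bundle manifest so that downstream parameter-recovery tests have a known
answer.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .errors import BundleParseError, ConfigError
from .strata import stratum_frame

# The nine obesity-related diseases; osteoarthritis is split into hip and
# knee states, giving ten modelled disease processes.
DISEASE_NAMES: tuple[str, ...] = (
    "type 2 diabetes",
    "hypertensive heart disease",
    "ischaemic heart disease",
    "stroke",
    "osteoarthritis hip",
    "osteoarthritis knee",
    "kidney cancer",
    "colorectal cancer",
    "endometrial cancer",
    "breast cancer",
)

# Female-only disease states in this model.
SEX_SPECIFIC: dict[str, str] = {"endometrial cancer": "F", "breast cancer": "F"}

CANCERS = ("kidney cancer", "colorectal cancer", "endometrial cancer",
           "breast cancer")

UNHEALTHY_CATEGORIES: tuple[str, ...] = (
    "chocolate and confectionery",
    "puddings and biscuits",
    "sugary drinks",
    "savoury snacks",
    "fast food",
)

RATE_COLUMNS = ("incidence", "prevalence", "case_fatality", "remission")


class CostInputs(BaseModel):
    """Cost and revenue parameters of the policy, all in 2019 A$.

    Defaults follow the published derivation: wages carry 14 % salary
    oncosts and 17.5 % annual leave loading; government advertising revenue
    loss is the unhealthy share (55 %) of food/drink advertising income on
    public-transport assets plus a billboard-derived Main Roads component
    (58 % of out-of-home advertising is on billboards); industry profit loss
    scales a national transport-advertising revenue by WA concentration
    (7 %), the unhealthy-ad share (21 %) and a 13 % profit margin.
    """

    policy_dev_fte_years: dict[str, float] = Field(
        default={"project_officer": 2.0, "senior_policy_officer": 1.5,
                 "director": 0.25})
    # wage multiplier per grade relative to base_wage (synthetic default)
    grade_wage_multipliers: dict[str, float] = Field(
        default={"project_officer": 1.0, "senior_policy_officer": 1.3,
                 "director": 1.8})
    base_wage: float = 85_000.0
    oncost_rate: float = 0.14
    leave_loading_rate: float = 0.175
    national_monitoring_cost: float = 200_000.0
    pta_food_ad_revenue: float = 1_200_000.0
    unhealthy_share_pta: float = 0.55
    billboard_share: float = 0.58
    main_roads_revenue_loss: float | None = None  # overrides the imputation
    apn_national_transport_revenue: float = 320_000_000.0
    wa_concentration: float = 0.07
    unhealthy_ad_share: float = 0.21
    profit_margin: float = 0.13
    legislation_cost: float = 1_306_180.0
    vsly: float = 213_000.0

    @field_validator("oncost_rate", "leave_loading_rate", "unhealthy_share_pta",
                     "billboard_share", "wa_concentration", "unhealthy_ad_share",
                     "profit_margin")
    @classmethod
    def _fraction(cls, v: float, info):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{info.field_name} must be in [0, 1], got {v}")
        return v

    @field_validator("base_wage", "national_monitoring_cost",
                     "pta_food_ad_revenue", "apn_national_transport_revenue",
                     "legislation_cost", "vsly")
    @classmethod
    def _nonneg(cls, v: float, info):
        if v < 0:
            raise ValueError(f"{info.field_name} must be >= 0, got {v}")
        return v


@dataclasses.dataclass
class DiseaseDefinition:
    """One obesity-related disease process.

    ``rates`` is indexed by stratum_id with columns incidence, prevalence,
    case_fatality and remission (annual probabilities / proportions).
    ``rr_per_bmi_unit`` is the log-linear relative risk per +1 kg/m2 of BMI
    above ``tmrel_bmi``; ``unit_cost`` is the annual healthcare cost of one
    prevalent case-year.
    """

    name: str
    rates: pd.DataFrame
    disability_weight: float
    rr_per_bmi_unit: float
    tmrel_bmi: float
    unit_cost: float

    def __post_init__(self):
        if self.name not in DISEASE_NAMES:
            raise ConfigError(
                f"unknown disease {self.name!r}; allowed: {list(DISEASE_NAMES)}")
        if not 0.0 <= self.disability_weight < 1.0:
            raise ConfigError(f"disability_weight must be in [0,1): "
                              f"{self.disability_weight}")
        if self.rr_per_bmi_unit < 1.0:
            raise ConfigError(f"rr_per_bmi_unit must be >= 1: "
                              f"{self.rr_per_bmi_unit}")
        for col in RATE_COLUMNS:
            vals = self.rates[col].to_numpy()
            if ((vals < 0) | (vals > 1)).any():
                raise ConfigError(f"{self.name}: {col} outside [0, 1]")
        sex = SEX_SPECIFIC.get(self.name)
        if sex is not None:
            other = self.rates.index.str[-1] != sex
            if self.rates.loc[other, ["incidence", "prevalence"]].to_numpy().any():
                raise ConfigError(
                    f"{self.name} is {sex}-specific but has nonzero rates in "
                    f"the other sex")

    def __eq__(self, other):
        if not isinstance(other, DiseaseDefinition):
            return NotImplemented
        return (self.name == other.name
                and self.rates.equals(other.rates)
                and self.disability_weight == other.disability_weight
                and self.rr_per_bmi_unit == other.rr_per_bmi_unit
                and self.tmrel_bmi == other.tmrel_bmi
                and self.unit_cost == other.unit_cost)


class GeneratorConfig(BaseModel):
    """Settings for the synthetic-input generator."""

    population_size: int = 2_100_000
    seed: int = 1
    true_effect: float = -0.067          # ground-truth relative purchasing change
    diseases: tuple[str, ...] = DISEASE_NAMES
    merge_osteoarthritis: bool = False   # collapse hip+knee into one state
    cancer_remission: float = 0.10       # annual "cured" probability
    noncancer_remission: float = 0.0
    tmrel_bmi: float = 21.0
    rr_override: float | None = None     # force one RR per BMI unit everywhere

    @field_validator("rr_override")
    @classmethod
    def _rr_ok(cls, v):
        if v is not None and v < 1.0:
            raise ValueError(f"rr_override must be >= 1, got {v}")
        return v

    @field_validator("population_size")
    @classmethod
    def _pos_pop(cls, v: int):
        if v <= 0:
            raise ValueError(f"population_size must be positive, got {v}")
        return v

    @field_validator("diseases")
    @classmethod
    def _known(cls, v):
        bad = [d for d in v if d not in DISEASE_NAMES]
        if bad:
            raise ValueError(f"unknown diseases {bad}; allowed {DISEASE_NAMES}")
        return tuple(v)

    @field_validator("cancer_remission", "noncancer_remission")
    @classmethod
    def _prob(cls, v: float, info):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{info.field_name} must be in [0,1], got {v}")
        return v


@dataclasses.dataclass
class InputBundle:
    """Everything one pipeline run consumes."""

    population: pd.DataFrame          # index stratum_id
    diseases: list[DiseaseDefinition]
    consumption: pd.DataFrame         # columns stratum_id, category, mean_kj_per_day
    costs: CostInputs
    manifest: dict

    def __eq__(self, other):
        if not isinstance(other, InputBundle):
            return NotImplemented
        mine = sorted(self.diseases, key=lambda d: d.name)
        theirs = sorted(other.diseases, key=lambda d: d.name)
        return (self.population.equals(other.population)
                and mine == theirs
                and self.consumption.equals(other.consumption)
                and self.costs == other.costs
                and self.manifest == other.manifest)


# ---------------------------------------------------------------------------
# generation

# per-disease calibration: (incidence at age 40, age slope /yr, incidence cap,
# case fatality at 40, cf cap, disability weight, RR per BMI unit, unit cost A$)
_DISEASE_CALIBRATION: dict[str, tuple] = {
    "type 2 diabetes":            (1.5e-3, 0.055, 1.2e-2, 1.0e-3, 8e-3, 0.07, 1.12, 3_500),
    "hypertensive heart disease": (4.0e-4, 0.075, 8.0e-3, 2.0e-3, 2e-2, 0.09, 1.09, 4_200),
    "ischaemic heart disease":    (8.0e-4, 0.080, 1.0e-2, 4.0e-3, 3e-2, 0.12, 1.05, 6_800),
    "stroke":                     (4.0e-4, 0.085, 8.0e-3, 5.0e-3, 3e-2, 0.18, 1.04, 7_500),
    "osteoarthritis hip":         (6.0e-4, 0.050, 7.0e-3, 0.0,    0.0,  0.06, 1.03, 2_100),
    "osteoarthritis knee":        (9.0e-4, 0.050, 9.0e-3, 0.0,    0.0,  0.06, 1.04, 2_100),
    "kidney cancer":              (8.0e-5, 0.060, 1.2e-3, 6.0e-3, 2e-2, 0.20, 1.06, 9_500),
    "colorectal cancer":          (2.0e-4, 0.065, 2.5e-3, 6.0e-3, 2e-2, 0.20, 1.03, 9_800),
    "endometrial cancer":         (1.0e-4, 0.050, 1.2e-3, 4.0e-3, 1.5e-2, 0.18, 1.10, 9_000),
    "breast cancer":              (6.0e-4, 0.035, 3.0e-3, 4.0e-3, 1.5e-2, 0.18, 1.02, 9_200),
}

# mean daily kJ per category at the adult peak (ages 15-34), before the
# age/sex shaping below
_CATEGORY_KJ: dict[str, float] = {
    "chocolate and confectionery": 350.0,
    "puddings and biscuits": 380.0,
    "sugary drinks": 420.0,
    "savoury snacks": 260.0,
    "fast food": 590.0,
}


def _age_share(mid: float) -> float:
    """Relative population weight of an age band (roughly Perth-shaped)."""
    return float(np.exp(-((mid - 32.0) ** 2) / (2 * 33.0 ** 2)) + 0.05)


def _acm_rate(mid: float, sex: str) -> float:
    """Gompertz-like all-cause mortality, male excess ~1.4x."""
    base = 2.2e-5 * np.exp(0.095 * mid)
    base = max(base, 1.0e-4)
    return float(min(base * (1.4 if sex == "M" else 1.0), 0.5))


def _generate_population(cfg: GeneratorConfig, rng: np.random.Generator
                         ) -> pd.DataFrame:
    frame = stratum_frame()
    mids = (frame.age_lo + frame.age_hi - 1) / 2.0
    shares = np.array([_age_share(m) for m in mids])
    shares = shares / shares.sum()
    counts = np.floor(cfg.population_size * shares
                      * rng.uniform(0.97, 1.03, size=len(shares))).astype(int)
    height = np.where(
        mids >= 18,
        np.where(frame.sex == "M", 1.76, 1.63),
        0.85 + (np.minimum(mids, 18) - 2) * (0.9 / 16.0),
    ) + rng.normal(0, 0.01, size=len(mids))
    bmi_mean = np.where(
        mids >= 18,
        26.0 + np.minimum(mids - 18, 40) * 0.05 + np.where(frame.sex == "M", 0.6, 0.0),
        16.0 + (np.minimum(mids, 18) - 2) * 0.45,
    ) + rng.normal(0, 0.3, size=len(mids))
    bmi_sd = np.clip(rng.normal(4.5, 0.3, size=len(mids)), 3.0, 6.0)
    acm = np.array([_acm_rate(m, s) for m, s in zip(mids, frame.sex)])
    return pd.DataFrame(
        {
            "age_lo": frame.age_lo,
            "age_hi": frame.age_hi,
            "sex": frame.sex,
            "count": counts,
            "acm_rate": np.round(acm, 8),
            "mean_height": np.round(height, 4),
            "bmi_mean": np.round(bmi_mean, 3),
            "bmi_sd": np.round(bmi_sd, 3),
        },
        index=pd.Index(frame.stratum_id, name="stratum_id"),
    )


def _generate_disease(name: str, cfg: GeneratorConfig, population: pd.DataFrame,
                      rng: np.random.Generator) -> DiseaseDefinition:
    i40, slope, icap, f40, fcap, dw, rr, cost = _DISEASE_CALIBRATION[name]
    if cfg.rr_override is not None:
        rr = cfg.rr_override
    mids = (population["age_lo"] + population["age_hi"] - 1) / 2.0
    jitter = rng.uniform(0.9, 1.1, size=len(population))
    inc = np.minimum(i40 * np.exp(slope * (mids - 40.0)), icap) * jitter
    inc = np.where(mids < 20, 0.0, inc)  # childhood incidence negligible
    cf = np.minimum(f40 * np.exp(0.04 * (mids - 40.0)), fcap) if f40 > 0 else \
        np.zeros(len(population))
    rem = cfg.cancer_remission if name in CANCERS else cfg.noncancer_remission
    remv = np.full(len(population), rem)
    # initial prevalence ~ 60% of the demographic steady state, with a 0.05/yr
    # turnover floor so young-age prevalent pools stay small (case duration
    # effectively capped at ~20 years)
    denom = inc + cf + remv + 0.05
    prev = np.minimum(0.6 * inc / denom, 0.25)
    sex = SEX_SPECIFIC.get(name)
    if sex is not None:
        mask = (population["sex"] != sex).to_numpy()
        inc = np.where(mask, 0.0, inc)
        prev = np.where(mask, 0.0, prev)
    rates = pd.DataFrame(
        {
            "incidence": np.round(inc, 8),
            "prevalence": np.round(prev, 8),
            "case_fatality": np.round(cf, 8),
            "remission": remv,
        },
        index=population.index,
    )
    return DiseaseDefinition(
        name=name, rates=rates, disability_weight=dw,
        rr_per_bmi_unit=rr, tmrel_bmi=cfg.tmrel_bmi, unit_cost=float(cost),
    )


def _merge_osteoarthritis(hip: DiseaseDefinition, knee: DiseaseDefinition
                          ) -> DiseaseDefinition:
    """Collapse the two osteoarthritis sites into one knee-labelled state."""
    rates = hip.rates.copy()
    for col in ("incidence", "prevalence"):
        rates[col] = np.minimum(hip.rates[col] + knee.rates[col], 1.0)
    return DiseaseDefinition(
        name="osteoarthritis knee", rates=rates,
        disability_weight=(hip.disability_weight + knee.disability_weight) / 2,
        rr_per_bmi_unit=max(hip.rr_per_bmi_unit, knee.rr_per_bmi_unit),
        tmrel_bmi=hip.tmrel_bmi,
        unit_cost=(hip.unit_cost + knee.unit_cost) / 2,
    )


def _generate_consumption(population: pd.DataFrame, rng: np.random.Generator
                          ) -> pd.DataFrame:
    rows = []
    mids = ((population["age_lo"] + population["age_hi"] - 1) / 2.0).to_numpy()
    for cat in UNHEALTHY_CATEGORIES:
        peak = _CATEGORY_KJ[cat]
        # intake ramps up through childhood, peaks in young adulthood, declines
        shape = np.where(
            mids < 15, 0.35 + 0.043 * (mids - 2),
            np.where(mids < 35, 1.0, np.maximum(1.0 - 0.008 * (mids - 35), 0.4)),
        )
        sexf = np.where(population["sex"] == "M", 1.15, 0.9)
        kj = peak * shape * sexf * rng.uniform(0.9, 1.1, size=len(mids))
        for sid, v in zip(population.index, kj):
            rows.append((sid, cat, round(float(v), 2)))
    return pd.DataFrame(rows, columns=["stratum_id", "category",
                                       "mean_kj_per_day"])


def generate_inputs(config: GeneratorConfig | None = None, *,
                    seed: int | None = None) -> InputBundle:
    """Generate a full synthetic input bundle.

    Identical (config, seed) yields bit-identical tables.  ``seed``
    overrides ``config.seed`` when given.
    """
    if config is None:
        config = GeneratorConfig()
    if seed is not None:
        config = config.model_copy(update={"seed": seed})
    rng = np.random.default_rng(config.seed)
    population = _generate_population(config, rng)

    names = list(config.diseases)
    defs = {n: _generate_disease(n, config, population, rng) for n in names}
    if (config.merge_osteoarthritis and "osteoarthritis hip" in defs
            and "osteoarthritis knee" in defs):
        merged = _merge_osteoarthritis(defs.pop("osteoarthritis hip"),
                                       defs["osteoarthritis knee"])
        defs["osteoarthritis knee"] = merged
    diseases = list(defs.values())

    consumption = _generate_consumption(population, rng)
    costs = CostInputs()
    manifest = {
        "generator_config": json.loads(config.model_dump_json()),
        "ground_truth": {
            "true_effect": config.true_effect,
            "rr_per_bmi_unit": {d.name: d.rr_per_bmi_unit for d in diseases},
            "tmrel_bmi": config.tmrel_bmi,
        },
    }
    return InputBundle(population=population, diseases=diseases,
                       consumption=consumption, costs=costs, manifest=manifest)


# ---------------------------------------------------------------------------
# bundle IO (one CSV per table + manifest.json)

def _disease_filename(name: str) -> str:
    return "disease_" + name.replace(" ", "_") + ".csv"


def write_bundle(bundle: InputBundle, directory: str | Path) -> list[Path]:
    """Write the bundle as UTF-8 CSVs plus ``manifest.json``; returns paths."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    written = []

    p = d / "population.csv"
    bundle.population.to_csv(p)
    written.append(p)

    for dis in bundle.diseases:
        p = d / _disease_filename(dis.name)
        out = dis.rates.copy()
        out.insert(0, "disease", dis.name)
        out["disability_weight"] = dis.disability_weight
        out["rr_per_bmi_unit"] = dis.rr_per_bmi_unit
        out["tmrel_bmi"] = dis.tmrel_bmi
        out["unit_cost"] = dis.unit_cost
        out.to_csv(p)
        written.append(p)

    p = d / "consumption.csv"
    bundle.consumption.to_csv(p, index=False)
    written.append(p)

    p = d / "costs.json"
    p.write_text(bundle.costs.model_dump_json(indent=2), encoding="utf-8")
    written.append(p)

    p = d / "manifest.json"
    p.write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True),
                 encoding="utf-8")
    written.append(p)
    return written


def _check_range(df: pd.DataFrame, column: str, lo: float, hi: float,
                 file: str) -> None:
    vals = df[column].to_numpy(dtype=float)
    bad = np.where((vals < lo) | (vals > hi))[0]
    if bad.size:
        raise BundleParseError(
            f"{column}={vals[bad[0]]} outside [{lo}, {hi}]",
            file=file, column=column, row=int(bad[0]),
        )


def _read_disease_csv(path: Path) -> DiseaseDefinition:
    df = pd.read_csv(path, index_col="stratum_id")
    fname = path.name
    required = ["disease", *RATE_COLUMNS, "disability_weight",
                "rr_per_bmi_unit", "tmrel_bmi", "unit_cost"]
    for col in required:
        if col not in df.columns:
            raise BundleParseError("missing column", file=fname, column=col)
    name = df["disease"].iloc[0]
    if name not in DISEASE_NAMES or df["disease"].nunique() != 1:
        raise BundleParseError(
            f"unknown disease name {name!r}; allowed names (osteoarthritis "
            f"split into hip/knee): {list(DISEASE_NAMES)}",
            file=fname, column="disease", row=0,
        )
    for col in RATE_COLUMNS:
        _check_range(df, col, 0.0, 1.0, fname)
    for col in ("disability_weight", "rr_per_bmi_unit", "tmrel_bmi",
                "unit_cost"):
        if df[col].nunique() != 1:
            raise BundleParseError("per-disease scalar column is not constant",
                                   file=fname, column=col)
    try:
        return DiseaseDefinition(
            name=name,
            rates=df[list(RATE_COLUMNS)].copy(),
            disability_weight=float(df["disability_weight"].iloc[0]),
            rr_per_bmi_unit=float(df["rr_per_bmi_unit"].iloc[0]),
            tmrel_bmi=float(df["tmrel_bmi"].iloc[0]),
            unit_cost=float(df["unit_cost"].iloc[0]),
        )
    except ConfigError as exc:
        raise BundleParseError(str(exc), file=fname) from exc


def read_bundle(directory: str | Path) -> InputBundle:
    """Read a bundle written by :func:`write_bundle`, validating invariants."""
    d = Path(directory)
    pop_path = d / "population.csv"
    if not pop_path.exists():
        raise BundleParseError("missing file", file="population.csv")
    population = pd.read_csv(pop_path, index_col="stratum_id")
    for col in ("age_lo", "age_hi", "sex", "count", "acm_rate", "mean_height",
                "bmi_mean", "bmi_sd"):
        if col not in population.columns:
            raise BundleParseError("missing column", file="population.csv",
                                   column=col)
    _check_range(population, "acm_rate", 0.0, 1.0 - 1e-12, "population.csv")
    _check_range(population, "mean_height", 0.8, 2.1, "population.csv")
    _check_range(population, "count", 0, np.inf, "population.csv")
    if (population["bmi_sd"] <= 0).any():
        row = int(np.where(population["bmi_sd"] <= 0)[0][0])
        raise BundleParseError("bmi_sd must be > 0", file="population.csv",
                               column="bmi_sd", row=row)

    diseases = [
        _read_disease_csv(p) for p in sorted(d.glob("disease_*.csv"))
    ]

    cons_path = d / "consumption.csv"
    consumption = pd.read_csv(cons_path)
    for col in ("stratum_id", "category", "mean_kj_per_day"):
        if col not in consumption.columns:
            raise BundleParseError("missing column", file="consumption.csv",
                                   column=col)
    _check_range(consumption, "mean_kj_per_day", 0.0, np.inf, "consumption.csv")

    costs = CostInputs.model_validate_json(
        (d / "costs.json").read_text(encoding="utf-8"))
    manifest = json.loads((d / "manifest.json").read_text(encoding="utf-8"))
    return InputBundle(population=population, diseases=diseases,
                       consumption=consumption, costs=costs, manifest=manifest)


def steady_state_prevalence(disease: DiseaseDefinition) -> pd.Series:
    """Prevalence implied by (incidence, case fatality, remission) at
    demographic equilibrium; used as an internal-consistency check."""
    i = disease.rates["incidence"]
    f = disease.rates["case_fatality"]
    r = disease.rates["remission"]
    denom = (i + f + r).replace(0.0, np.nan)
    return (i / denom).fillna(0.0)
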