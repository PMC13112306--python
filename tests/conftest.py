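import numpy as np
import pandas as pd
import pytest

from oohcba import GeneratorConfig, generate_inputs
from oohcba.synthetic import DiseaseDefinition


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic Perth-like bundle, shared across tests."""
    return generate_inputs(GeneratorConfig(seed=1))


def make_population(specs):
    """Tiny population table for hand-checkable lifetable runs.

    ``specs`` is a list of dicts with keys age_lo, sex, count, acm_rate and
    optional bmi/height fields.
    """
    rows = {}
    for s in specs:
        age_lo = s["age_lo"]
        age_hi = age_lo + (3 if age_lo == 2 else 5)
        sid = f"{age_lo:02d}-{age_hi - 1:02d}{s['sex']}"
        rows[sid] = {
            "age_lo": age_lo,
            "age_hi": age_hi,
            "sex": s["sex"],
            "count": s["count"],
            "acm_rate": s["acm_rate"],
            "mean_height": s.get("mean_height", 1.7),
            "bmi_mean": s.get("bmi_mean", 27.0),
            "bmi_sd": s.get("bmi_sd", 4.0),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "stratum_id"
    return df


def make_disease(name, population, incidence, case_fatality=0.0,
                 remission=0.0, prevalence=0.0, disability_weight=0.1,
                 rr=1.1, tmrel=21.0, unit_cost=1000.0):
    """DiseaseDefinition with constant rates across strata."""
    n = len(population)
    rates = pd.DataFrame(
        {
            "incidence": np.full(n, incidence, float),
            "prevalence": np.full(n, prevalence, float),
            "case_fatality": np.full(n, case_fatality, float),
            "remission": np.full(n, remission, float),
        },
        index=population.index,
    )
    return DiseaseDefinition(name=name, rates=rates,
                             disability_weight=disability_weight,
                             rr_per_bmi_unit=rr, tmrel_bmi=tmrel,
                             unit_cost=unit_cost)
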