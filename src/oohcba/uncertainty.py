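"""Probabilistic sensitivity analysis.

Uncertain parameters are declared as distributions (normal reconstructed
from a 95 % CI, Pert with +/-25 % bounds for expert-judgement values,
general Pert, lognormal, or fixed), sampled independently, and the full
deterministic pipeline is rerun per draw.  Summaries are means with
empirical 95 % uncertainty intervals (2.5th/97.5th percentiles, linear
interpolation between order statistics).

Each parameter gets its own RNG stream derived from the master seed and
the parameter's name, so adding or removing one parameter does not perturb
the draws of the others.
"""

from __future__ import annotations

import dataclasses
import zlib
from typing import Callable, Literal, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

from .errors import ConfigError, ModelError

Z975 = 1.959964  # two-sided 95 % normal quantile

PERT_LAMBDA = 4.0


class DistributionSpec(BaseModel):
    """One uncertain parameter's sampling distribution."""

    name: Literal["normal_from_ci", "pert_pm25", "pert", "lognormal", "fixed"]
    mean: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    min: float | None = None
    mode: float | None = None
    max: float | None = None
    sigma: float | None = None         # lognormal scale (of log values)
    lam: float = PERT_LAMBDA           # Pert shape

    @model_validator(mode="after")
    def _check(self):
        if self.name == "normal_from_ci":
            if None in (self.mean, self.ci_low, self.ci_high) \
                    or not self.ci_low < self.ci_high:
                raise ValueError("normal_from_ci needs mean and ci_low < ci_high")
        elif self.name == "pert_pm25":
            if self.mean is None:
                raise ValueError("pert_pm25 needs a mean")
        elif self.name == "pert":
            if None in (self.min, self.mode, self.max) \
                    or not self.min <= self.mode <= self.max:
                raise ValueError("pert needs min <= mode <= max")
        elif self.name == "lognormal":
            if self.mean is None or self.sigma is None or self.mean <= 0 \
                    or self.sigma <= 0:
                raise ValueError("lognormal needs mean > 0 and sigma > 0")
        elif self.name == "fixed":
            if self.mean is None:
                raise ValueError("fixed needs a mean")
        return self


def _pert(rng: np.random.Generator, lo: float, mode: float, hi: float,
          lam: float, size: int) -> np.ndarray:
    """Classic Pert via its Beta reparameterisation."""
    if hi == lo:
        return np.full(size, lo)
    alpha = 1.0 + lam * (mode - lo) / (hi - lo)
    beta = 1.0 + lam * (hi - mode) / (hi - lo)
    return lo + rng.beta(alpha, beta, size=size) * (hi - lo)


def sample(spec: DistributionSpec, rng: np.random.Generator,
           size: int = 1) -> np.ndarray:
    """Draw ``size`` values from a distribution spec."""
    if spec.name == "fixed":
        return np.full(size, spec.mean)
    if spec.name == "normal_from_ci":
        sd = (spec.ci_high - spec.ci_low) / (2.0 * Z975)
        return rng.normal(spec.mean, sd, size=size)
    if spec.name == "pert_pm25":
        m = spec.mean
        lo, hi = sorted((0.75 * m, 1.25 * m))
        return _pert(rng, lo, m, hi, spec.lam, size)
    if spec.name == "pert":
        return _pert(rng, spec.min, spec.mode, spec.max, spec.lam, size)
    if spec.name == "lognormal":
        return rng.lognormal(np.log(spec.mean), spec.sigma, size=size)
    raise ConfigError(f"unknown distribution family {spec.name!r}")


def normal_from_ci_sd(ci_low: float, ci_high: float) -> float:
    """Standard deviation implied by a 95 % CI width."""
    return (ci_high - ci_low) / (2.0 * Z975)


def parameter_rng(master_seed: int, name: str) -> np.random.Generator:
    """Independent, name-keyed RNG stream for one parameter."""
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, zlib.crc32(name.encode())]))


@dataclasses.dataclass
class DrawSet:
    """Per-draw parameter vectors and pipeline outputs."""

    parameters: pd.DataFrame   # n_draws x n_parameters
    outputs: pd.DataFrame      # n_draws x n_metrics
    seed: int
    n_errors: int = 0


def draw_parameters(specs: Mapping[str, DistributionSpec], n_draws: int,
                    seed: int) -> pd.DataFrame:
    """Draw all parameters up front, one independent stream per name."""
    cols = {name: sample(spec, parameter_rng(seed, name), n_draws)
            for name, spec in specs.items()}
    return pd.DataFrame(cols)


def run_monte_carlo(pipeline: Callable[[Mapping[str, float]],
                                       Mapping[str, float]],
                    specs: Mapping[str, DistributionSpec],
                    n_draws: int = 2000,
                    seed: int = 0,
                    max_error_fraction: float = 0.001) -> DrawSet:
    """Rerun ``pipeline`` once per parameter draw.

    ``pipeline`` maps a parameter dict to a metric dict and must be
    deterministic given its inputs.  Draws that raise :class:`ModelError`
    are recorded; the run fails if more than ``max_error_fraction`` of
    draws error out.
    """
    if n_draws < 1:
        raise ConfigError(f"n_draws must be >= 1, got {n_draws}")
    params = draw_parameters(specs, n_draws, seed)
    rows: list[dict[str, float]] = []
    errors = 0
    for i in range(n_draws):
        vec = {k: float(params.iloc[i][k]) for k in params.columns}
        try:
            rows.append(dict(pipeline(vec)))
        except ModelError:
            errors += 1
            rows.append({})
    if errors > max_error_fraction * n_draws:
        raise ModelError(
            f"{errors}/{n_draws} Monte Carlo draws failed "
            f"(> {max_error_fraction:.1%} allowed)")
    outputs = pd.DataFrame(rows)
    return DrawSet(parameters=params, outputs=outputs, seed=seed,
                   n_errors=errors)


def summarise(draws: DrawSet | pd.DataFrame) -> pd.DataFrame:
    """Mean and 95 % uncertainty interval per output metric.

    Percentiles use linear interpolation between order statistics
    (``numpy.percentile`` default), so summaries are bit-reproducible.
    """
    df = draws.outputs if isinstance(draws, DrawSet) else draws
    if len(df) < 1:
        raise ConfigError("cannot summarise an empty draw set")
    rows = {}
    for col in df.columns:
        vals = df[col].dropna().to_numpy(float)
        rows[col] = {
            "mean": float(vals.mean()),
            "p2.5": float(np.percentile(vals, 2.5)),
            "p97.5": float(np.percentile(vals, 97.5)),
        }
    return pd.DataFrame(rows).T[["mean", "p2.5", "p97.5"]]
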