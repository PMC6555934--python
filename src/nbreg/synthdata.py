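"""Synthetic two-arm cost-effectiveness trials with known truth.

Person-level trial data suitable for net-benefit analysis are rarely
shareable, so the package ships a generator that emulates their structure: a
randomized two-arm trial with right-skewed costs, approximately normal QALY
effects, within-patient cost-effect correlation, and an optional biomarker
subgroup whose strata have different incremental costs and effects (a
treatment-by-subgroup interaction).

Costs and effects are driven by a shared latent standard-normal factor:

    a_e = sqrt(|rho|) z + sqrt(1 - |rho|) u
    a_c = sign(rho) sqrt(|rho|) z + sqrt(1 - |rho|) v

with z, u, v independent N(0,1), so corr(a_e, a_c) = rho on the latent scale.
Effects are ``mean + effect_sd * a_e``. Costs transform ``a_c`` through the
chosen family with the arm/stratum mean preserved exactly in expectation:
lognormal (dispersion = SD of log cost), gamma (dispersion = coefficient of
variation, Gaussian-copula transform) or normal (dispersion = coefficient of
variation). For the non-normal families the observed-scale cost-effect
correlation is therefore approximate (attenuated by the monotone transform);
the latent rho is what is specified.

The CO.17-like preset mirrors the structure of a two-stratum biomarker trial:
stratum sizes 150 (mutant-like) and 216 (wild-type-like) split evenly across
arms, incremental costs $13,787 / $30,843 and incremental effects -0.0172 /
0.1769 QALYs. Control-arm baselines, dispersions and the latent correlation
are package choices of plausible magnitude (the source trial reports only
increments); see docs/methods.md.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy import stats

from .ce_data import CEDataset
from .exceptions import ValidationError


class CovariateEffect(BaseModel):
    """A numeric covariate x ~ N(mean, sd) adding centered linear shifts
    ``coef_cost * (x - mean)`` and ``coef_effect * (x - mean)``, so arm and
    stratum means are untouched."""

    mean: float = 0.0
    sd: float = Field(1.0, gt=0)
    coef_cost: float = 0.0
    coef_effect: float = 0.0


class StratumSpec(BaseModel):
    """One subgroup stratum: arm sizes, control-arm baselines and truths."""

    name: str
    n_control: int = Field(..., ge=2)
    n_treated: int = Field(..., ge=2)
    control_mean_cost: float = Field(..., gt=0)
    control_mean_effect: float
    delta_cost: float
    delta_effect: float

    @model_validator(mode="after")
    def _positive_treated_cost(self) -> "StratumSpec":
        if self.control_mean_cost + self.delta_cost <= 0:
            raise ValueError(
                f"stratum {self.name!r}: treated-arm mean cost must be positive"
            )
        return self


class SyntheticConfig(BaseModel):
    """Full description of a synthetic trial; serializable as JSON."""

    strata: list[StratumSpec] = Field(..., min_length=1)
    cost_distribution: Literal["lognormal", "gamma", "normal"] = "lognormal"
    cost_dispersion: float = Field(0.7, ge=0)
    effect_sd: float = Field(0.18, ge=0)
    cost_effect_correlation: float = 0.3
    covariate_effects: dict[str, CovariateEffect] = Field(default_factory=dict)
    subgroup_column: str = "subgroup"
    seed: Optional[int] = None

    @field_validator("cost_effect_correlation")
    @classmethod
    def _rho_open_interval(cls, v: float) -> float:
        if not -1.0 < v < 1.0:
            raise ValueError("cost_effect_correlation must be strictly inside (-1, 1)")
        return v

    @model_validator(mode="after")
    def _unique_names(self) -> "SyntheticConfig":
        names = [s.name for s in self.strata]
        if len(set(names)) != len(names):
            raise ValueError("stratum names must be unique")
        return self

    def n_total(self) -> int:
        return sum(s.n_control + s.n_treated for s in self.strata)


def co17_like_preset(seed: int | None = None) -> SyntheticConfig:
    """Two-stratum biomarker-trial preset (mutant-like and wild-type-like).

    Stratum sizes 150 and 216 with even arm splits; incremental truths
    dC = $13,787 / $30,843 and dE = -0.0172 / 0.1769 QALYs. The implied
    whole-sample truths at 216/366 prevalence are dE ~ 0.0773 QALYs and
    dC ~ $23,854 — close to, but deliberately not equal to, a trial ALL-row
    that also pools patients with unknown biomarker status; only the two
    known strata are modeled.
    """
    return SyntheticConfig(
        strata=[
            StratumSpec(
                name="MUT",
                n_control=75,
                n_treated=75,
                control_mean_cost=12_000.0,
                control_mean_effect=0.28,
                delta_cost=13_787.0,
                delta_effect=-0.0172,
            ),
            StratumSpec(
                name="WT",
                n_control=108,
                n_treated=108,
                control_mean_cost=12_000.0,
                control_mean_effect=0.28,
                delta_cost=30_843.0,
                delta_effect=0.1769,
            ),
        ],
        cost_distribution="lognormal",
        cost_dispersion=0.7,
        effect_sd=0.18,
        cost_effect_correlation=0.3,
        seed=seed,
    )


def generate(config: SyntheticConfig, seed: int | None = None) -> CEDataset:
    """Draw one synthetic trial; fully reproducible from the seed.

    ``seed`` overrides ``config.seed``; one of them must be set (silent
    nondeterminism is never allowed).
    """
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValidationError(
            "an explicit integer seed is required (config.seed or seed=)"
        )
    rng = np.random.default_rng(seed)
    rho = config.cost_effect_correlation
    sr = np.sqrt(abs(rho))
    sc = np.sign(rho) if rho != 0 else 0.0
    tail = np.sqrt(1.0 - abs(rho))

    ids, txs, costs, effects, subgroups = [], [], [], [], []
    cov_values: dict[str, list[np.ndarray]] = {k: [] for k in config.covariate_effects}

    for stratum in config.strata:
        for arm, n in ((0, stratum.n_control), (1, stratum.n_treated)):
            mean_cost = stratum.control_mean_cost + arm * stratum.delta_cost
            mean_effect = stratum.control_mean_effect + arm * stratum.delta_effect
            z = rng.standard_normal(n)
            u = rng.standard_normal(n)
            v = rng.standard_normal(n)
            a_e = sr * z + tail * u
            a_c = sc * sr * z + tail * v

            effect = mean_effect + config.effect_sd * a_e
            cost = _cost_from_latent(
                a_c, mean_cost, config.cost_distribution, config.cost_dispersion
            )
            for name, eff in config.covariate_effects.items():
                x = eff.mean + eff.sd * rng.standard_normal(n)
                cost = cost + eff.coef_cost * (x - eff.mean)
                effect = effect + eff.coef_effect * (x - eff.mean)
                cov_values[name].append(x)

            ids.extend(f"{stratum.name}-{arm}-{i + 1}" for i in range(n))
            txs.append(np.full(n, arm, dtype=int))
            costs.append(cost)
            effects.append(effect)
            subgroups.extend([stratum.name] * n)

    covariates = {
        name: np.concatenate(chunks) for name, chunks in cov_values.items()
    } or None
    return CEDataset.from_arrays(
        tx=np.concatenate(txs),
        cost=np.concatenate(costs),
        effect=np.concatenate(effects),
        ids=ids,
        subgroup=subgroups,
        covariates=covariates,
        allow_negative_cost=True,  # covariate shifts may produce rare credits
    )


def _cost_from_latent(
    a: np.ndarray, mean: float, family: str, dispersion: float
) -> np.ndarray:
    if dispersion == 0.0:
        return np.full(a.shape, mean)
    if family == "lognormal":
        sigma = dispersion  # SD of log cost
        mu = np.log(mean) - sigma**2 / 2.0
        return np.exp(mu + sigma * a)
    if family == "gamma":
        shape = 1.0 / dispersion**2  # dispersion = coefficient of variation
        scale = mean / shape
        return stats.gamma.ppf(stats.norm.cdf(a), shape, scale=scale)
    # normal: dispersion = coefficient of variation
    return mean + (dispersion * mean) * a
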