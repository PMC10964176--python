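"""Probabilistic sensitivity analysis and value-of-information analysis.

Parameter uncertainty is propagated through the lifetime Markov model by
Monte Carlo: each uncertain model input gets a distribution from the
conventional family for its type (normal for effect sizes, lognormal for
hazard ratios, beta for utilities, gamma for costs), draws are pushed through
the deterministic model, and the per-draw incremental costs and QALYs feed
the cost-effectiveness plane, CEAC, and expected-value-of-information
summaries.

EVPI is the per-person value of resolving *all* parameter uncertainty at a
willingness-to-pay threshold: ``E[max(0, INB)] - max(0, E[INB])`` with the
comparator's net benefit normalised to zero.  EVPPI for a single parameter
uses the regression (single-level) method: a smooth fit of INB on the
parameter's draws estimates the conditional expectation, and the EVPI
formula is applied to the fitted values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, fields as dc_fields

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .healthecon import HEParameters, HEResult, run_deterministic

__all__ = [
    "Dist",
    "normal",
    "lognormal",
    "beta_dist",
    "gamma_dist",
    "fixed",
    "sample_parameters",
    "run_psa",
    "PSAResults",
    "summarise_psa",
    "ceac",
    "evpi",
    "evppi",
    "population_value",
    "Scenario",
    "scenario_run",
]


@dataclass(frozen=True)
class Dist:
    """Sampling distribution for one model parameter.

    family ∈ {normal, lognormal, beta, gamma, fixed}; ``a``/``b`` are the
    family's natural parameters except for lognormal and gamma, which are
    parameterised by the *target* mean and SD for convenience.
    """

    family: str
    a: float
    b: float = 0.0

    def sample(self, k: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "normal":
            return rng.normal(self.a, self.b, k)
        if self.family == "lognormal":
            # a = mean, b = sd on the natural scale
            if self.b == 0:
                return np.full(k, self.a)
            sigma2 = np.log1p((self.b / self.a) ** 2)
            mu = np.log(self.a) - sigma2 / 2
            return rng.lognormal(mu, np.sqrt(sigma2), k)
        if self.family == "beta":
            if self.a == 0 and self.b == 0:
                raise ValueError("beta needs positive shape parameters")
            return rng.beta(self.a, self.b, k)
        if self.family == "gamma":
            # a = mean, b = sd
            if self.b == 0:
                return np.full(k, self.a)
            shape = (self.a / self.b) ** 2
            scale = self.b**2 / self.a
            return rng.gamma(shape, scale, k)
        if self.family == "fixed":
            return np.full(k, self.a)
        raise ValueError(f"unknown family {self.family!r}")


def normal(mean: float, sd: float) -> Dist:
    return Dist("normal", mean, sd)


def lognormal(mean: float, sd: float) -> Dist:
    """Lognormal with the given mean/SD on the natural (hazard-ratio) scale."""
    return Dist("lognormal", mean, sd)


def beta_dist(alpha: float, beta: float) -> Dist:
    return Dist("beta", alpha, beta)


def gamma_dist(mean: float, sd: float) -> Dist:
    return Dist("gamma", mean, sd)


def fixed(value: float) -> Dist:
    return Dist("fixed", value)


def sample_parameters(
    dists: dict[str, Dist], k: int, seed: int
) -> pd.DataFrame:
    """Draw ``k`` independent samples per parameter, reproducibly by seed."""
    if k < 1:
        raise ValueError("need at least one draw")
    rng = np.random.default_rng(seed)
    return pd.DataFrame({name: d.sample(k, rng) for name, d in dists.items()})


@dataclass(frozen=True)
class PSAResults:
    """Per-draw incremental outcomes aligned with the sampled inputs."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    samples: pd.DataFrame
    n_rejected: int = 0

    def __post_init__(self) -> None:
        if not (len(self.delta_cost) == len(self.delta_qaly) == len(self.samples)):
            raise ValueError("results and samples must be row-aligned")

    def __len__(self) -> int:
        return len(self.delta_cost)

    def inb(self, wtp: float) -> np.ndarray:
        return wtp * self.delta_qaly - self.delta_cost


_HE_FIELDS = {f.name for f in dc_fields(HEParameters)}


def _valid_row(p: HEParameters) -> bool:
    return (
        0 <= p.utility_baseline <= 1
        and p.cancer_excess_hazard >= 0
        and p.hr_cancer_per_methr > 0
        and p.hr_other_per_methr > 0
        and p.intervention_cost >= 0
    )


def run_psa(base_params: HEParameters, samples: pd.DataFrame) -> PSAResults:
    """Push each sampled parameter row through the deterministic model.

    Sample columns must name ``HEParameters`` fields; each row overrides
    those fields on ``base_params``.  Rows violating parameter domains
    (e.g. utility outside [0,1]) are rejected and counted, not silently
    clipped.
    """
    unknown = set(samples.columns) - _HE_FIELDS
    if unknown:
        raise ValueError(f"sample columns not in HEParameters: {sorted(unknown)}")
    dcost, dqaly, keep = [], [], []
    for i, row in enumerate(samples.itertuples(index=False)):
        try:
            p = replace(base_params, **row._asdict())
        except ValueError:
            continue
        if not _valid_row(p):
            continue
        res = run_deterministic(p)
        dcost.append(res.delta_cost)
        dqaly.append(res.delta_qaly)
        keep.append(i)
    return PSAResults(
        delta_cost=np.asarray(dcost),
        delta_qaly=np.asarray(dqaly),
        samples=samples.iloc[keep].reset_index(drop=True),
        n_rejected=len(samples) - len(keep),
    )


def summarise_psa(results: PSAResults) -> pd.DataFrame:
    """Means and percentile 95% credible intervals of the incremental outcomes."""
    if len(results) < 40:
        raise ValueError("need at least 40 draws for a percentile interval")
    rows = []
    for name, x in (("delta_cost", results.delta_cost), ("delta_qaly", results.delta_qaly)):
        lo, hi = np.percentile(x, [2.5, 97.5])
        rows.append({"quantity": name, "mean": float(np.mean(x)), "ci_lower": lo, "ci_upper": hi})
    return pd.DataFrame(rows)


def ceac(results: PSAResults, wtp_grid: np.ndarray) -> pd.DataFrame:
    """Probability the intervention is cost-effective at each threshold.

    Per threshold λ: the fraction of draws with positive incremental net
    benefit λ·ΔQALY − ΔCost.
    """
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    probs = [float(np.mean(results.inb(l) > 0)) for l in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "prob_cost_effective": probs})


def evpi(results: PSAResults, wtp: float) -> float:
    """Per-person expected value of perfect information at threshold ``wtp``."""
    if len(results) < 100:
        raise ValueError("need at least 100 draws for EVPI")
    inb = results.inb(wtp)
    return float(np.mean(np.maximum(inb, 0.0)) - max(np.mean(inb), 0.0))


def evppi(
    results: PSAResults, parameter: str, wtp: float, frac: float = 0.3
) -> float:
    """Single-parameter EVPPI by the regression method.

    A lowess smoother of per-draw INB on the parameter's draws estimates
    E[INB | parameter]; applying the EVPI formula to the fitted values gives
    the value of learning that parameter alone.  ``frac`` is the lowess
    bandwidth.
    """
    if len(results) < 1000:
        raise ValueError("need at least 1000 draws for regression EVPPI")
    if parameter not in results.samples.columns:
        raise KeyError(parameter)
    x = results.samples[parameter].to_numpy(dtype=float)
    inb = results.inb(wtp)
    if np.ptp(x) == 0:  # degenerate parameter carries no information
        return 0.0
    fitted = lowess(inb, x, frac=frac, return_sorted=False)
    return float(np.mean(np.maximum(fitted, 0.0)) - max(np.mean(fitted), 0.0))


def evppi_nested(
    base_params: HEParameters,
    dists: dict[str, Dist],
    parameter: str,
    wtp: float,
    n_outer: int = 50,
    n_inner: int = 200,
    seed: int = 0,
) -> float:
    """Nested Monte-Carlo EVPPI (slow verification mode).

    Outer loop fixes the parameter of interest at a fresh draw; the inner
    loop averages INB over the remaining parameters.
    """
    rng = np.random.default_rng(seed)
    outer_vals = dists[parameter].sample(n_outer, rng)
    cond_means = np.empty(n_outer)
    for j, v in enumerate(outer_vals):
        inner = {
            name: (fixed(v) if name == parameter else d) for name, d in dists.items()
        }
        samples = sample_parameters(inner, n_inner, int(rng.integers(2**31)))
        res = run_psa(base_params, samples)
        cond_means[j] = float(np.mean(res.inb(wtp)))
    return float(np.mean(np.maximum(cond_means, 0.0)) - max(np.mean(cond_means), 0.0))


def population_value(
    per_person: float,
    annual_patients: float,
    years: int = 1,
    discount_rate: float = 0.035,
) -> float:
    """Scale a per-person value to the decision-affected population.

    Default is single-year scaling (per_person × annual incident patients);
    a discounted multi-year horizon is available via ``years``.
    """
    if per_person < 0 or annual_patients < 0:
        raise ValueError("inputs must be non-negative")
    if years == 1:
        return per_person * annual_patients
    disc = sum((1 + discount_rate) ** -t for t in range(years))
    return per_person * annual_patients * disc


@dataclass(frozen=True)
class Scenario:
    """A named perturbation of the base-case model for scenario analysis.

    Multipliers default to 1 (no change); overrides default to None.
    """

    name: str
    effect_multiplier: float = 1.0
    effect_duration: float | None = None
    cost_scaling: float = 1.0
    annual_resource_offset: float | None = None
    mortality_multiplier: float = 1.0

    def apply(self, params: HEParameters) -> HEParameters:
        updates: dict = {
            "delta_met": params.delta_met * self.effect_multiplier,
            "intervention_cost": params.intervention_cost * self.cost_scaling,
            "cancer_excess_hazard": params.cancer_excess_hazard * self.mortality_multiplier,
        }
        if self.effect_duration is not None:
            updates["effect_duration"] = self.effect_duration
        if self.annual_resource_offset is not None:
            updates["annual_resource_offset"] = self.annual_resource_offset
        return replace(params, **updates)


def scenario_run(
    base_params: HEParameters,
    scenarios: list[Scenario],
    dists: dict[str, Dist],
    k: int,
    seed: int,
    wtp: float = 20_000.0,
) -> pd.DataFrame:
    """One PSA per scenario with common random numbers (shared seed).

    Sampled parameters are drawn once; scenario perturbations are applied to
    the base parameters before each run, so between-scenario differences are
    not confounded by sampling noise.  Sampled columns that a scenario also
    perturbs are perturbed *after* sampling (the scenario wins).
    """
    from .healthecon import icer as _icer

    samples = sample_parameters(dists, k, seed)
    rows = []
    for sc in scenarios:
        p = sc.apply(base_params)
        sc_samples = samples.copy()
        if "delta_met" in sc_samples:
            sc_samples["delta_met"] *= sc.effect_multiplier
        if "intervention_cost" in sc_samples:
            sc_samples["intervention_cost"] *= sc.cost_scaling
        if "cancer_excess_hazard" in sc_samples:
            sc_samples["cancer_excess_hazard"] *= sc.mortality_multiplier
        res = run_psa(p, sc_samples)
        dc, dq = float(np.mean(res.delta_cost)), float(np.mean(res.delta_qaly))
        rows.append(
            {
                "scenario": sc.name,
                "delta_cost": dc,
                "delta_qaly": dq,
                "icer": _icer(dc, dq),
                "nmb": wtp * dq - dc,
                "ceac_at_wtp": float(np.mean(res.inb(wtp) > 0)),
            }
        )
    return pd.DataFrame(rows)
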