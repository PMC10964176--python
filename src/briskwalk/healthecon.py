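"""Lifetime Markov cohort model for the brisk-walking intervention.

A three-state cohort model (alive, dead of cancer, dead of other causes) run
in annual cycles from the cohort's start age to a lifetime cap.  The
intervention's effect enters as an activity volume change in MET-hours per
week which multiplies the cause-specific mortality hazards through a
log-linear dose-response, ``h -> h * hr ** delta_met``, for as long as the
effect is assumed to persist.  Discounted quality-adjusted life years are
accumulated from a baseline EQ-5D utility with a multiplicative age
decrement; costs take a health-service perspective with a one-off
intervention cost at cycle 0 and an optional annual resource-use offset.

The model structure is deliberately minimal: mortality is the only pathway
by which activity affects outcomes, matching the evidence base the pilot
economic analysis drew on.  Richer disease states (recurrence, progression)
are an extension point, not implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Gompertz",
    "LifeTable",
    "HEParameters",
    "CostBreakdown",
    "HEResult",
    "met_conversion",
    "build_intervention_cost",
    "paper_intervention_cost",
    "survival_trace",
    "qaly",
    "life_years",
    "cost",
    "run_deterministic",
    "icer",
    "nmb",
    "PAPER_INTERVENTION_COST",
    "DEFAULT_MET_MAP",
]

#: Per-person intervention cost from the trial micro-costing (materials,
#: nurse delivery time and amortised training).  Stored as a constant because
#: its components are not individually published.
PAPER_INTERVENTION_COST = 62.52

#: Placeholder MET intensities for stepping above/below the 100 steps/min
#: cadence threshold.  Configurable; the compendium values for brisk vs
#: usual-pace walking are a reasonable default.
DEFAULT_MET_MAP = {"brisk": 4.3, "slow": 3.0}


@dataclass(frozen=True)
class Gompertz:
    """Background (other-cause) mortality hazard ``b * exp(c * age)``.

    b is the hazard at age 0 (per year); c the log-hazard slope per year of
    age.  Defaults give a hazard of ~1% at age 63 and ~6% at age 80 —
    an illustrative adult schedule, not a published lifetable.
    """

    b: float = 2.0e-5
    c: float = 0.098

    def hazard(self, age: np.ndarray | float) -> np.ndarray | float:
        return self.b * np.exp(self.c * np.asarray(age, dtype=float))


@dataclass(frozen=True)
class LifeTable:
    """Background mortality as annual death probabilities by age."""

    table: pd.DataFrame  # columns: age, annual_death_probability

    def __post_init__(self) -> None:
        t = self.table
        if not {"age", "annual_death_probability"} <= set(t.columns):
            raise ValueError("lifetable needs columns age, annual_death_probability")
        q = t["annual_death_probability"].to_numpy(dtype=float)
        if ((q < 0) | (q > 1)).any():
            raise ValueError("annual death probabilities must lie in [0, 1]")
        ages = t["age"].to_numpy(dtype=float)
        if (np.diff(ages) <= 0).any():
            raise ValueError("lifetable ages must be strictly increasing")

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        return cls(pd.read_csv(path))

    def hazard(self, age: np.ndarray | float) -> np.ndarray:
        """Annual hazard rate -ln(1-q) at each age (step interpolation)."""
        ages = self.table["age"].to_numpy(dtype=float)
        q = self.table["annual_death_probability"].to_numpy(dtype=float)
        idx = np.clip(np.searchsorted(ages, np.asarray(age, dtype=float), "right") - 1, 0, len(q) - 1)
        qa = q[idx]
        return -np.log1p(-np.clip(qa, 0.0, 1.0 - 1e-12))


@dataclass(frozen=True)
class HEParameters:
    """All inputs of the lifetime cost-effectiveness model.

    delta_met is the intervention-minus-control activity change in MET-hours
    per week; hr_cancer_per_methr / hr_other_per_methr are hazard ratios per
    unit MET-h/week applied while the effect persists (effect_duration
    years).  Utilities are EQ-5D index values; utility_age_decrement is the
    multiplicative factor applied per decade of ageing.
    """

    start_age: float = 63.0
    horizon_age: float = 100.0
    cycle_length: float = 1.0
    discount_rate_costs: float = 0.035
    discount_rate_qalys: float = 0.035
    other_cause_mortality: Gompertz | LifeTable = field(default_factory=Gompertz)
    cancer_excess_hazard: float = 0.02
    hr_cancer_per_methr: float = 0.97
    hr_other_per_methr: float = 0.99
    delta_met: float = 0.0
    effect_duration: float = 5.0
    utility_baseline: float = 0.8
    utility_age_decrement: float = 0.97
    annual_resource_offset: float = 0.0
    intervention_cost: float = PAPER_INTERVENTION_COST
    wtp_thresholds: tuple = (20_000.0, 30_000.0)

    def __post_init__(self) -> None:
        if self.cancer_excess_hazard < 0:
            raise ValueError("hazards must be non-negative")
        if not (0 <= self.utility_baseline <= 1):
            raise ValueError("utility must lie in [0, 1]")
        if self.discount_rate_costs < 0 or self.discount_rate_qalys < 0:
            raise ValueError("discount rates must be non-negative")
        if self.effect_duration < 0:
            raise ValueError("effect_duration must be non-negative")
        if self.horizon_age <= self.start_age:
            raise ValueError("horizon_age must exceed start_age")
        if self.hr_cancer_per_methr <= 0 or self.hr_other_per_methr <= 0:
            raise ValueError("hazard ratios must be positive")

    @property
    def n_cycles(self) -> int:
        return int(np.ceil((self.horizon_age - self.start_age) / self.cycle_length))


@dataclass(frozen=True)
class CostBreakdown:
    materials: float
    delivery_nurse_time: float
    training_amortised: float

    @property
    def total_per_person(self) -> float:
        return self.materials + self.delivery_nurse_time + self.training_amortised


def met_conversion(
    delta_brisk: float, delta_slow: float, met_map: dict | None = None
) -> float:
    """Convert walking-minute changes into a MET-h/week change.

    delta_brisk / delta_slow are min/week changes in walking above/below the
    cadence threshold; the MET map gives the intensity of each.
    """
    met_map = dict(DEFAULT_MET_MAP if met_map is None else met_map)
    if met_map["brisk"] <= 0 or met_map["slow"] <= 0:
        raise ValueError("MET values must be positive")
    return (delta_brisk * met_map["brisk"] + delta_slow * met_map["slow"]) / 60.0


def build_intervention_cost(
    materials: float,
    nurse_rate_per_min: float,
    delivery_minutes: float = 55.0,
    training_day_cost: float = 0.0,
    nurses_trained: int = 10,
    patients_per_nurse_year: int = 200,
    training_valid_years: int = 3,
) -> CostBreakdown:
    """Micro-cost the intervention per person.

    Delivery is nurse time (55 min per patient by default); a training day
    for a cohort of nurses is amortised over every patient those nurses see
    while the training remains valid.
    """
    if min(materials, nurse_rate_per_min, training_day_cost) < 0:
        raise ValueError("costs must be non-negative")
    base = nurses_trained * patients_per_nurse_year * training_valid_years
    if base <= 0:
        raise ValueError("training amortisation base must be positive")
    return CostBreakdown(
        materials=materials,
        delivery_nurse_time=delivery_minutes * nurse_rate_per_min,
        training_amortised=training_day_cost / base,
    )


def paper_intervention_cost() -> float:
    """The trial's published per-person intervention cost (GBP)."""
    return PAPER_INTERVENTION_COST


def _hazards(params: HEParameters, arm: str) -> tuple[np.ndarray, np.ndarray]:
    t = np.arange(params.n_cycles)
    ages = params.start_age + t * params.cycle_length
    h_other = np.asarray(params.other_cause_mortality.hazard(ages), dtype=float).copy()
    h_cancer = np.full(params.n_cycles, params.cancer_excess_hazard, dtype=float)
    if arm == "intervention" and params.delta_met != 0.0:
        active = ages - params.start_age < params.effect_duration
        h_cancer[active] *= params.hr_cancer_per_methr**params.delta_met
        h_other[active] *= params.hr_other_per_methr**params.delta_met
    elif arm not in ("intervention", "control"):
        raise ValueError(f"unknown arm {arm!r}")
    if (h_cancer < 0).any() or (h_other < 0).any():
        raise ValueError("negative hazard after effect modification")
    return h_cancer, h_other


def survival_trace(params: HEParameters, arm: str) -> pd.DataFrame:
    """Per-cycle state occupancy for one arm.

    Cause-specific annual hazards are combined competing-risk style: rates
    are summed, the cycle death probability is ``1 - exp(-h_total)``, and
    deaths are partitioned in proportion to the cause-specific rates.
    Row t gives occupancy at the *start* of cycle t (t=0 is the start of the
    model); a final row gives occupancy at the horizon.
    """
    h_cancer, h_other = _hazards(params, arm)
    n = params.n_cycles
    alive = np.empty(n + 1)
    dead_c = np.zeros(n + 1)
    dead_o = np.zeros(n + 1)
    alive[0] = 1.0
    h_tot = h_cancer + h_other
    p_die = -np.expm1(-h_tot * params.cycle_length)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_c = np.where(h_tot > 0, h_cancer / np.where(h_tot > 0, h_tot, 1.0), 0.0)
    for t in range(n):
        d = alive[t] * p_die[t]
        alive[t + 1] = alive[t] - d
        dead_c[t + 1] = dead_c[t] + d * frac_c[t]
        dead_o[t + 1] = dead_o[t] + d * (1 - frac_c[t])
    ages = params.start_age + np.arange(n + 1) * params.cycle_length
    return pd.DataFrame(
        {"age": ages, "alive": alive, "dead_cancer": dead_c, "dead_other": dead_o}
    )


def _mid_cycle(trace: pd.DataFrame) -> np.ndarray:
    alive = trace["alive"].to_numpy()
    return 0.5 * (alive[:-1] + alive[1:])


def qaly(trace: pd.DataFrame, params: HEParameters) -> float:
    """Discounted QALYs for one arm's trace (half-cycle corrected).

    Each cycle contributes ``utility(age_mid) * mean(alive) * (1+r)^-(t-0.5)``
    where utility decays multiplicatively per decade of ageing from the
    baseline EQ-5D index.
    """
    mid = _mid_cycle(trace)
    t = np.arange(1, len(mid) + 1, dtype=float) * params.cycle_length
    age_mid = params.start_age + t - 0.5 * params.cycle_length
    util = params.utility_baseline * params.utility_age_decrement ** (
        (age_mid - params.start_age) / 10.0
    )
    disc = (1.0 + params.discount_rate_qalys) ** -(t - 0.5 * params.cycle_length)
    return float(np.sum(util * mid * disc) * params.cycle_length)


def life_years(trace: pd.DataFrame, params: HEParameters) -> float:
    """Undiscounted life-years (half-cycle corrected)."""
    return float(np.sum(_mid_cycle(trace)) * params.cycle_length)


def cost(trace: pd.DataFrame, params: HEParameters, arm: str) -> float:
    """Discounted costs for one arm.

    The intervention arm incurs the per-person intervention cost at cycle 0
    (undiscounted); the intervention arm additionally accrues the annual
    resource-use offset per alive person-year, discounted and half-cycle
    corrected.  The offset is the between-arm difference in annual resource
    use, so the control arm's recurring costs are normalised to zero.
    """
    total = 0.0
    mid = _mid_cycle(trace)
    t = np.arange(1, len(mid) + 1, dtype=float) * params.cycle_length
    disc = (1.0 + params.discount_rate_costs) ** -(t - 0.5 * params.cycle_length)
    if arm == "intervention":
        total += params.intervention_cost
        total += float(np.sum(params.annual_resource_offset * mid * disc) * params.cycle_length)
    elif arm != "control":
        raise ValueError(f"unknown arm {arm!r}")
    return total


@dataclass(frozen=True)
class HEResult:
    cost_control: float
    cost_intervention: float
    qaly_control: float
    qaly_intervention: float
    trace_control: pd.DataFrame
    trace_intervention: pd.DataFrame

    @property
    def delta_cost(self) -> float:
        return self.cost_intervention - self.cost_control

    @property
    def delta_qaly(self) -> float:
        return self.qaly_intervention - self.qaly_control


def run_deterministic(params: HEParameters) -> HEResult:
    """Run both arms and return discounted costs, QALYs and their deltas."""
    tc = survival_trace(params, "control")
    ti = survival_trace(params, "intervention")
    return HEResult(
        cost_control=cost(tc, params, "control"),
        cost_intervention=cost(ti, params, "intervention"),
        qaly_control=qaly(tc, params),
        qaly_intervention=qaly(ti, params),
        trace_control=tc,
        trace_intervention=ti,
    )


def icer(delta_cost: float, delta_qaly: float) -> float | str:
    """Incremental cost-effectiveness ratio, or a dominance label.

    Cheaper-and-better is "dominant", costlier-and-no-better "dominated";
    in the trade-off quadrants the plain ratio is returned.
    """
    if delta_qaly > 0:
        return "dominant" if delta_cost < 0 else delta_cost / delta_qaly
    if delta_cost > 0:
        return "dominated"
    if delta_qaly < 0:
        return delta_cost / delta_qaly
    return "dominant" if delta_cost < 0 else float("nan")


def nmb(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Net monetary benefit at willingness-to-pay ``wtp`` per QALY."""
    return wtp * delta_qaly - delta_cost
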