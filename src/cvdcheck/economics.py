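"""Cost accumulation, ICERs and the deterministic scenario grid.

Costs are nominal Australian dollars from the health-system perspective.
The intervention arm carries the per-attendee direct cost of the health
check (a one-off discounted lump in cycle 1 by default); both arms carry
acute hospitalisation costs for first CVD events and ongoing post-event
care costed as a fraction ``f`` of the acute cost per year (base 0.15).
Usual care carries no primary-care cost.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .markov import (
    IDX_EVENT,
    IDX_POST,
    SUBTYPES,
    MarkovParameters,
    StateTrace,
    UtilitySet,
    life_years,
    qalys,
    run_cohort,
)

__all__ = [
    "CostSet",
    "HealthCheckCostModel",
    "CohortOutcome",
    "ICERResult",
    "ScenarioSpec",
    "expected_direct_cost",
    "accumulate_costs",
    "arm_outcome",
    "compute_icer",
    "run_scenarios",
    "BASE_SCENARIOS",
]

CONTROL_ARM = "usual_care"
INTERVENTION_ARM = "health_check"


@dataclass(frozen=True)
class CostSet:
    """All monetary inputs for one sex."""

    acute: dict[str, float]  # subtype -> acute hospitalisation cost (AUD)
    acute_range_fraction: float = 0.25  # +/- bound on acute costs
    post_event_fraction: float = 0.15  # f: annual post-event cost as share of acute
    direct_cost: float = 0.0  # health-check direct cost per attendee (mean)
    direct_cost_min: float = 0.0
    direct_cost_max: float = 0.0
    discount_rate: float = 0.05
    # The check is delivered at cohort entry (time zero), so its cost is not
    # discounted by default; set a cycle count to instead spread it over the
    # first cycles with discounting (sensitivity mode).
    direct_cost_at_entry: bool = True
    direct_cost_cycles: int = 1

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.acute.values()) or self.direct_cost < 0:
            raise ValueError("costs must be non-negative")
        if not (0.0 <= self.post_event_fraction <= 1.0):
            raise ValueError("post-event cost fraction must lie in [0, 1]")
        if self.direct_cost and not (
            self.direct_cost_min <= self.direct_cost <= self.direct_cost_max
        ):
            raise ValueError("direct cost mean must lie within its (min, max) range")


@dataclass(frozen=True)
class ServiceBundle:
    """Annual follow-up service bundle for one detected risk condition."""

    condition: str
    annual_cost: float  # visits + pathology + medication, AUD/year
    uptake: float  # probability the detected patient starts management
    compliance: float  # probability the patient completes the year

    def __post_init__(self) -> None:
        for name in ("uptake", "compliance"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class HealthCheckCostModel:
    """Direct health-check cost: base check plus risk-condition follow-up.

    The minimum cost assumes no follow-up at all (the check visits only);
    the maximum assumes every detected condition is managed with full
    uptake and compliance; the mean applies the configured uptake and
    compliance rates to the sex-specific condition prevalences.
    """

    base_cost: float  # the check itself (visits + standard pathology)
    bundles: tuple[ServiceBundle, ...]
    prevalence: dict[str, dict[str, float]]  # sex -> condition -> prevalence

    def __post_init__(self) -> None:
        for sex, prev in self.prevalence.items():
            for cond, p in prev.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"{sex}/{cond}: prevalence {p} outside [0, 1]")


def expected_direct_cost(
    model: HealthCheckCostModel, sex: str
) -> tuple[float, float, float]:
    """(mean, min, max) per-attendee direct cost of the health check, AUD."""
    if sex not in model.prevalence:
        raise ValueError(f"no prevalence data for sex {sex!r}")
    prev = model.prevalence[sex]
    mean = model.base_cost
    maximum = model.base_cost
    for b in model.bundles:
        p = prev.get(b.condition, 0.0)
        mean += p * b.uptake * b.compliance * b.annual_cost
        maximum += p * b.annual_cost
    return mean, model.base_cost, maximum


def accumulate_costs(trace: StateTrace, costs: CostSet, arm: str) -> float:
    """Discounted lifetime cost of one arm's trace.

    Per cycle: tunnel-state occupancy x acute cost + post-state occupancy x
    f x acute cost; the intervention arm additionally carries the direct
    health-check cost, undiscounted at entry by default (or discounted and
    spread over ``direct_cost_cycles`` when ``direct_cost_at_entry`` is off).
    """
    t = np.arange(1, trace.cycles + 1)
    disc = (1.0 + costs.discount_rate) ** (-t)
    total = 0.0
    for s in SUBTYPES:
        acute = costs.acute[s]
        ev = trace.occupancy[:, IDX_EVENT[s]]
        post = trace.occupancy[:, IDX_POST[s]]
        total += float(np.sum(disc * (ev * acute + post * costs.post_event_fraction * acute)))
    if arm == INTERVENTION_ARM and costs.direct_cost > 0:
        if costs.direct_cost_at_entry:
            total += costs.direct_cost
        else:
            k = max(1, costs.direct_cost_cycles)
            total += float(np.sum(disc[:k] * (costs.direct_cost / k)))
    return total


@dataclass(frozen=True)
class CohortOutcome:
    """Discounted cost / QALY and (undiscounted by convention) LY for one arm."""

    arm: str
    sex: str
    life_years: float
    qalys: float
    cost: float

    def __post_init__(self) -> None:
        if min(self.life_years, self.qalys, self.cost) < 0:
            raise ValueError("outcomes must be non-negative")


def arm_outcome(
    params: MarkovParameters,
    utilities: UtilitySet,
    costs: CostSet,
    arm: str,
    ly_discount_rate: float = 0.0,
) -> CohortOutcome:
    """Run the Markov model for one arm and summarise LY, QALY and cost.

    Life-years are reported undiscounted (``ly_discount_rate=0``) following
    the reporting convention of the analysis; QALYs and costs are discounted
    at the rate carried by ``costs.discount_rate``.
    """
    trace = run_cohort(params, arm)
    return CohortOutcome(
        arm=arm,
        sex=params.sex,
        life_years=life_years(trace, ly_discount_rate),
        qalys=qalys(trace, utilities, costs.discount_rate),
        cost=accumulate_costs(trace, costs, arm),
    )


@dataclass(frozen=True)
class ICERResult:
    """Incremental outcomes and cost-effectiveness ratios between two arms."""

    sex: str
    delta_ly: float
    delta_qaly: float
    delta_cost: float
    icer_per_ly: float | None
    icer_per_qaly: float | None
    classification: str  # trade-off | dominant | dominated | undefined


def _classify(delta_cost: float, delta_effect: float) -> str:
    if delta_effect == 0.0:
        return "undefined" if delta_cost != 0.0 else "trade-off"
    if delta_cost <= 0.0 and delta_effect > 0.0:
        return "dominant"
    if delta_cost >= 0.0 and delta_effect < 0.0:
        return "dominated"
    return "trade-off"


def compute_icer(control: CohortOutcome, intervention: CohortOutcome) -> ICERResult:
    """Incremental cost-effectiveness of intervention vs control.

    Ratios are computed on unrounded values. A zero effect difference with a
    non-zero cost difference is flagged undefined rather than raising.
    """
    if control.sex != intervention.sex:
        raise ValueError("arms must share one sex")
    if control.arm == intervention.arm:
        raise ValueError("need two distinct arms")
    d_cost = intervention.cost - control.cost
    d_ly = intervention.life_years - control.life_years
    d_qaly = intervention.qalys - control.qalys
    return ICERResult(
        sex=control.sex,
        delta_ly=d_ly,
        delta_qaly=d_qaly,
        delta_cost=d_cost,
        icer_per_ly=(d_cost / d_ly) if d_ly != 0.0 else None,
        icer_per_qaly=(d_cost / d_qaly) if d_qaly != 0.0 else None,
        classification=_classify(d_cost, d_qaly),
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """One deterministic scenario: a named variation of (r, f, discount)."""

    name: str
    post_event_disutility_reduction: float = 0.5
    post_event_cost_fraction: float = 0.15
    discount_rate: float = 0.05
    is_base_case: bool = False


#: The published scenario grid: one-at-a-time variations around the base case.
BASE_SCENARIOS: tuple[ScenarioSpec, ...] = (
    ScenarioSpec("base_case", is_base_case=True),
    ScenarioSpec("disutility_reduction_0", post_event_disutility_reduction=0.0),
    ScenarioSpec("disutility_reduction_25", post_event_disutility_reduction=0.25),
    ScenarioSpec("disutility_reduction_75", post_event_disutility_reduction=0.75),
    ScenarioSpec("disutility_reduction_100", post_event_disutility_reduction=1.0),
    ScenarioSpec("post_event_cost_10", post_event_cost_fraction=0.10),
    ScenarioSpec("post_event_cost_20", post_event_cost_fraction=0.20),
    ScenarioSpec("discount_3_5", discount_rate=0.035),
)


def run_scenarios(
    specs: list[ScenarioSpec] | tuple[ScenarioSpec, ...],
    params: dict[str, MarkovParameters],
    utilities: dict[str, UtilitySet],
    costs: dict[str, CostSet],
) -> pd.DataFrame:
    """Evaluate the deterministic model once per scenario per sex.

    Returns a table with incremental LY/QALY/cost and both ICERs, mirroring
    a one-way scenario analysis (only the scenario's parameters move).
    """
    if not any(s.is_base_case for s in specs):
        raise ValueError("scenario list must include the base case")
    rows = []
    for spec in specs:
        for sex in params:
            util = replace(
                utilities[sex],
                post_event_disutility_reduction=spec.post_event_disutility_reduction,
            )
            cost = replace(
                costs[sex],
                post_event_fraction=spec.post_event_cost_fraction,
                discount_rate=spec.discount_rate,
            )
            control = arm_outcome(params[sex], util, cost, CONTROL_ARM)
            interv = arm_outcome(params[sex], util, cost, INTERVENTION_ARM)
            icer = compute_icer(control, interv)
            rows.append(
                {
                    "scenario": spec.name,
                    "sex": sex,
                    "r": spec.post_event_disutility_reduction,
                    "f": spec.post_event_cost_fraction,
                    "discount_rate": spec.discount_rate,
                    "diff_ly": icer.delta_ly,
                    "diff_qaly": icer.delta_qaly,
                    "diff_cost": icer.delta_cost,
                    "cost_per_ly": icer.icer_per_ly,
                    "cost_per_qaly": icer.icer_per_qaly,
                }
            )
    return pd.DataFrame(rows)
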