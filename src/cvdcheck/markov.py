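"""Annual-cycle Markov cohort model for lifetime CVD outcome extrapolation.

Twelve health states: alive with no CVD; five one-cycle tunnel states
marking the *first* event of each CVD subtype (unstable angina UA, stable
angina SA, myocardial infarction MI, stroke, transient ischaemic attack
TIA); five corresponding post-event states occupied for the remainder of
life (repeat events are not modelled); and dead. The cohort enters at the
lower edge of the 45-49 eligibility band in the no-CVD state and is
propagated for 50 one-year cycles (to age 94), so that cycles 1-5 cover
ages 45-49 under the arm-specific risk-equation incidence and cycle 6
lands exactly on the 50-54 registry incidence band.

First-event probabilities come from the risk-equation microsimulation for
the first five cycles (arm-specific) and from registry-style age-band
incidence tables thereafter (identical across arms). Mortality from CVD
states is background CVD-free mortality multiplied by a per-subtype
standardised mortality ratio (SMR), capped at 1.

Reward accounting follows the conventions of the reported analysis:
life-years may be discounted or not via the ``discount_rate`` argument
(the headline life-year outcomes are undiscounted), QALYs weight each
alive cycle by a state utility, and all rewards are counted at cycle end
with the first cycle discounted (no half-cycle correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SUBTYPES",
    "STATES",
    "MarkovParameters",
    "UtilitySet",
    "StateTrace",
    "annualize",
    "split_by_subtype",
    "build_transition_matrix",
    "propagate",
    "run_cohort",
    "life_years",
    "qalys",
]

#: CVD subtype identifiers, fixed order used throughout the package.
SUBTYPES = ("UA", "SA", "MI", "Stroke", "TIA")

#: The 12 model states. Index 0 = event-free, 1-5 = first-event tunnels,
#: 6-10 = post-event states, 11 = dead (absorbing).
STATES = (
    ("NoCVD",)
    + tuple(f"Event_{s}" for s in SUBTYPES)
    + tuple(f"Post_{s}" for s in SUBTYPES)
    + ("Dead",)
)
N_STATES = len(STATES)
IDX_NOCVD = 0
IDX_EVENT = {s: 1 + i for i, s in enumerate(SUBTYPES)}
IDX_POST = {s: 6 + i for i, s in enumerate(SUBTYPES)}
IDX_DEAD = 11

AgeBand = tuple[int, int]


def _lookup_band(table: dict[AgeBand, object], age: float):
    """Value for the band containing ``age``; ages beyond the last band reuse it."""
    bands = sorted(table)
    for lo, hi in bands:
        if lo <= age <= hi:
            return table[(lo, hi)]
    if age > bands[-1][1]:
        return table[bands[-1]]
    return table[bands[0]]


def annualize(p5: float) -> float:
    """Constant annual probability equivalent to a 5-year probability.

    Returns ``1 - (1 - p5)**(1/5)``; applying the result over five one-year
    cycles reproduces the 5-year probability exactly.
    """
    if not (0.0 <= p5 < 1.0):
        raise ValueError(f"5-year probability must lie in [0, 1), got {p5}")
    return 1.0 - (1.0 - p5) ** 0.2


def split_by_subtype(p: float, allocation: dict[str, float]) -> dict[str, float]:
    """Allocate an annual first-event probability over the five CVD subtypes."""
    total = sum(allocation.values())
    if total <= 0:
        raise ValueError("allocation fractions must sum to a positive value")
    if abs(total - 1.0) > 1e-6:
        allocation = {k: v / total for k, v in allocation.items()}
    return {s: p * allocation.get(s, 0.0) for s in SUBTYPES}


@dataclass(frozen=True)
class MarkovParameters:
    """Sex-specific transition inputs of the cohort model.

    ``arm_incidence_5yr`` holds the 5-year first-event probability per arm
    (from the risk-factor microsimulation); it drives cycles 1-5 after
    annualisation. ``incidence`` holds age-band annual probabilities per
    subtype for cycles 6 onwards, identical across arms (benefits of the
    check are assumed to last five years only).
    """

    sex: str
    arm_incidence_5yr: dict[str, float]
    allocation: dict[str, float]
    incidence: dict[AgeBand, dict[str, float]]
    mortality: dict[AgeBand, float]
    smr: dict[str, float]
    start_age: int = 45
    cycles: int = 50
    fre_cycles: int = 5

    def age_at(self, cycle: int) -> int:
        return self.start_age + cycle - 1

    def background_mortality(self, age: float) -> float:
        return float(_lookup_band(self.mortality, age))

    def annual_event_probs(self, cycle: int, arm: str) -> dict[str, float]:
        """Per-subtype annual first-event probabilities for one cycle/arm."""
        if cycle <= self.fre_cycles:
            p5 = self.arm_incidence_5yr[arm]
            return split_by_subtype(annualize(p5), self.allocation)
        return dict(_lookup_band(self.incidence, self.age_at(cycle)))


@dataclass(frozen=True)
class UtilitySet:
    """Utility weights: age-band population norms and CVD event weights.

    The per-subtype CVD weights are multipliers on the age- and sex-matched
    population utility: an acute event year is valued ``u_pop * w``, so the
    acute decrement is ``u_pop * (1 - w)`` (TIA has w = 1 and never carries
    a decrement). ``post_event_disutility_reduction`` (r) scales the
    lifelong decrement carried by post-event states: the acute decrement is
    reduced by the fraction r, so r = 1 restores post-event utility to the
    population norm and r = 0 carries the full acute decrement for life
    (base case r = 0.5).
    """

    sex: str
    population: dict[AgeBand, float]
    acute: dict[str, float]
    post_event_disutility_reduction: float = 0.5

    def population_at(self, age: float) -> float:
        return float(_lookup_band(self.population, age))

    def state_utilities(self, age: float) -> np.ndarray:
        """Utility of each of the 12 states at a given cohort age."""
        u_pop = self.population_at(age)
        r = self.post_event_disutility_reduction
        u = np.zeros(N_STATES)
        u[IDX_NOCVD] = u_pop
        for s in SUBTYPES:
            w = self.acute[s]
            u[IDX_EVENT[s]] = u_pop * w
            u[IDX_POST[s]] = u_pop * (1.0 - (1.0 - r) * (1.0 - w))
        u[IDX_DEAD] = 0.0
        return u


@dataclass
class StateTrace:
    """State occupancy per cycle (rows: cycles 1..n, columns: the 12 states)."""

    occupancy: np.ndarray
    ages: np.ndarray
    sex: str = ""
    arm: str = ""

    def __post_init__(self) -> None:
        sums = self.occupancy.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("state occupancy must sum to 1 every cycle")
        dead = self.occupancy[:, IDX_DEAD]
        if np.any(np.diff(dead) < -1e-12):
            raise ValueError("dead-state occupancy must be non-decreasing")

    @property
    def cycles(self) -> int:
        return self.occupancy.shape[0]

    def alive(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, IDX_DEAD]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", np.arange(1, self.cycles + 1))
        return df


def build_transition_matrix(
    cycle: int, params: MarkovParameters, arm: str
) -> np.ndarray:
    """Row-stochastic 12x12 transition matrix for one cycle.

    Competing risks are composed death-first: from the event-free state the
    background death probability d applies, first-event probabilities apply
    to the survivors (scaled by 1 - d), and the remainder stays event-free.
    From tunnel and post-event states death occurs with probability
    min(1, SMR x d) and the remainder moves to (or stays in) the post-event
    state. Dead is absorbing.
    """
    if not (1 <= cycle <= params.cycles):
        raise ValueError(f"cycle {cycle} outside [1, {params.cycles}]")
    age = params.age_at(cycle)
    d = params.background_mortality(age)
    events = params.annual_event_probs(cycle, arm)

    m = np.zeros((N_STATES, N_STATES))
    total_event = sum(events.values())
    m[IDX_NOCVD, IDX_DEAD] = d
    for s in SUBTYPES:
        m[IDX_NOCVD, IDX_EVENT[s]] = (1.0 - d) * events[s]
    m[IDX_NOCVD, IDX_NOCVD] = (1.0 - d) * (1.0 - total_event)

    for s in SUBTYPES:
        dx = min(1.0, params.smr[s] * d)
        m[IDX_EVENT[s], IDX_DEAD] = dx
        m[IDX_EVENT[s], IDX_POST[s]] = 1.0 - dx
        m[IDX_POST[s], IDX_DEAD] = dx
        m[IDX_POST[s], IDX_POST[s]] = 1.0 - dx

    m[IDX_DEAD, IDX_DEAD] = 1.0

    rows = m.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-12):
        raise RuntimeError(f"transition rows do not sum to 1: {rows}")
    return m


def propagate(initial: np.ndarray, matrices: list[np.ndarray]) -> np.ndarray:
    """Propagate an occupancy vector through a sequence of transition matrices.

    Returns one row per cycle (occupancy *after* each transition).
    """
    occ = np.asarray(initial, dtype=float)
    out = np.empty((len(matrices), occ.shape[0]))
    for t, m in enumerate(matrices):
        occ = occ @ m
        out[t] = occ
    return out


def run_cohort(
    params: MarkovParameters,
    arm: str,
    initial: np.ndarray | None = None,
) -> StateTrace:
    """Run the cohort model for one arm and return its occupancy trace."""
    if initial is None:
        initial = np.zeros(N_STATES)
        initial[IDX_NOCVD] = 1.0
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (N_STATES,) or abs(initial.sum() - 1.0) > 1e-9:
        raise ValueError("initial occupancy must be a 12-element probability vector")
    matrices = [
        build_transition_matrix(c, params, arm) for c in range(1, params.cycles + 1)
    ]
    occ = propagate(initial, matrices)
    ages = params.start_age + np.arange(params.cycles)
    return StateTrace(occupancy=occ, ages=ages, sex=params.sex, arm=arm)


def _discount_factors(cycles: int, rate: float) -> np.ndarray:
    t = np.arange(1, cycles + 1)
    return (1.0 + rate) ** (-t)


def life_years(trace: StateTrace, discount_rate: float = 0.0) -> float:
    """(Optionally discounted) life-years: alive occupancy summed over cycles."""
    return float(np.sum(trace.alive() * _discount_factors(trace.cycles, discount_rate)))


def qalys(trace: StateTrace, utilities: UtilitySet, discount_rate: float = 0.05) -> float:
    """Discounted quality-adjusted life-years over the trace."""
    disc = _discount_factors(trace.cycles, discount_rate)
    total = 0.0
    for t in range(trace.cycles):
        u = utilities.state_utilities(trace.ages[t])
        total += disc[t] * float(trace.occupancy[t] @ u)
    return total
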