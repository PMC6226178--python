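"""Probabilistic sensitivity analysis.

Every uncertain input of the cohort model is given a prior matching its
reported uncertainty: lognormal for relative risks and SMRs (parameterised
from the mean's 95% CI on the log scale), beta for utilities (moment-matched
from mean and SE), and uniform for costs and incidence-type quantities
(printed ranges where available, otherwise a configurable +/- fraction,
default 25%). One joint independent draw is taken per iteration, the full
Markov-plus-costing model is evaluated per sex and arm, and the incremental
cost / incremental QALY pairs form the cost-effectiveness plane. The
acceptability curve reports, per willingness-to-pay threshold, the fraction
of draws with non-negative net monetary benefit.

Arm-specific 5-year incidence is sampled uniformly within its simulated
2.5/97.5 percentile interval; by default both arms share one quantile per
draw (positively correlated arms), which avoids spurious reversals of the
between-arm effect that independent sampling of two overlapping intervals
would create.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .config import SEXES, ModelConfig
from .economics import CONTROL_ARM, INTERVENTION_ARM, CostSet, arm_outcome, compute_icer
from .markov import SUBTYPES, MarkovParameters, UtilitySet

__all__ = [
    "ParameterPrior",
    "fit_prior",
    "run_psa",
    "ceac",
    "default_thresholds",
]


@dataclass(frozen=True)
class ParameterPrior:
    """Distributional assumption for one uncertain parameter.

    families: ``lognormal`` (args: mean, ci_lower, ci_upper), ``beta``
    (args: mean, se), ``uniform`` (args: low, high — or mean, fraction).
    """

    name: str
    family: str
    args: dict


class PriorFitError(ValueError):
    """The stated moments are incompatible with the requested family."""


def fit_prior(prior: ParameterPrior) -> Callable[[np.random.Generator, int | None], np.ndarray]:
    """Return a sampler ``f(rng, size=None)`` for the prior."""
    fam = prior.family
    a = prior.args
    if fam == "lognormal":
        lo, hi = float(a["ci_lower"]), float(a["ci_upper"])
        if not (0 < lo <= hi):
            raise PriorFitError(f"{prior.name}: lognormal CI must be positive")
        if lo == hi:
            return lambda rng, size=None: _const(lo, size)
        mu = 0.5 * (np.log(lo) + np.log(hi))
        sigma = (np.log(hi) - np.log(lo)) / (2 * 1.96)
        return lambda rng, size=None: rng.lognormal(mu, sigma, size)
    if fam == "beta":
        m, se = float(a["mean"]), float(a["se"])
        if not (0.0 < m < 1.0):
            if se == 0.0:
                return lambda rng, size=None: _const(m, size)
            raise PriorFitError(f"{prior.name}: beta mean {m} outside (0, 1)")
        if se == 0.0:
            return lambda rng, size=None: _const(m, size)
        nu = m * (1.0 - m) / se**2 - 1.0
        if nu <= 0:
            raise PriorFitError(
                f"{prior.name}: SE {se} implies variance >= mean(1-mean); "
                "beta moment matching impossible"
            )
        alpha, beta = m * nu, (1.0 - m) * nu
        return lambda rng, size=None: rng.beta(alpha, beta, size)
    if fam == "uniform":
        if "low" in a:
            lo, hi = float(a["low"]), float(a["high"])
        else:
            m, frac = float(a["mean"]), float(a["fraction"])
            lo, hi = m * (1.0 - frac), m * (1.0 + frac)
        if lo > hi:
            raise PriorFitError(f"{prior.name}: uniform bounds reversed")
        if lo == hi:
            return lambda rng, size=None: _const(lo, size)
        return lambda rng, size=None: rng.uniform(lo, hi, size)
    raise PriorFitError(f"{prior.name}: unknown family {fam!r}")


def _const(v: float, size):
    return float(v) if size is None else np.full(size, float(v))


def _uniform_in(rng: np.random.Generator, lo: float, hi: float, q: float | None = None) -> float:
    if q is None:
        q = rng.uniform()
    return lo + q * (hi - lo)


@dataclass
class _PriorSet:
    """All fitted samplers for one configuration."""

    smr: dict[str, dict[str, Callable]]  # sex -> subtype
    pop_util: dict[str, dict[tuple, Callable]]
    acute_util: dict[str, Callable]
    hosp_cost: dict[str, Callable]
    direct_cost: dict[str, Callable]
    incidence_intervals: dict[str, dict[str, tuple[float, float]]]
    range_fraction: float


def _build_priors(config: ModelConfig) -> _PriorSet:
    frac = float(config.psa.get("range_fraction", 0.25))
    smr = {
        sex: {
            s: fit_prior(
                ParameterPrior(
                    f"smr_{sex}_{s}",
                    "lognormal",
                    {
                        "ci_lower": config.smr_ci[sex][s][0],
                        "ci_upper": config.smr_ci[sex][s][1],
                    },
                )
            )
            for s in SUBTYPES
        }
        for sex in SEXES
    }
    pop_util = {
        sex: {
            band: fit_prior(
                ParameterPrior(
                    f"pop_util_{sex}_{band}",
                    "beta",
                    {"mean": m, "se": config.population_utility_se[sex][band]},
                )
            )
            for band, m in config.population_utilities[sex].items()
        }
        for sex in SEXES
    }
    acute_util = {
        s: fit_prior(
            ParameterPrior(
                f"acute_util_{s}",
                "beta",
                {"mean": config.acute_utilities[s], "se": config.acute_utility_se[s]},
            )
        )
        for s in SUBTYPES
    }
    hosp_cost = {
        s: fit_prior(
            ParameterPrior(
                f"cost_{s}",
                "uniform",
                {"mean": config.hospitalization_costs[s], "fraction": config.cost_range_fraction},
            )
        )
        for s in SUBTYPES
    }
    direct_cost = {}
    for sex in SEXES:
        mean, lo, hi = config.direct_costs[sex]
        direct_cost[sex] = fit_prior(
            ParameterPrior(f"direct_cost_{sex}", "uniform", {"low": lo, "high": hi})
        )

    intervals_raw = config.psa.get("incidence_intervals")
    if intervals_raw is None:
        raise ValueError(
            "psa.incidence_intervals missing: provide per-sex per-arm 2.5/97.5 "
            "percentile intervals of the 5-year incidence"
        )
    intervals = {
        sex: {arm: (float(v[0]), float(v[1])) for arm, v in entry.items()}
        for sex, entry in intervals_raw.items()
    }
    return _PriorSet(
        smr=smr,
        pop_util=pop_util,
        acute_util=acute_util,
        hosp_cost=hosp_cost,
        direct_cost=direct_cost,
        incidence_intervals=intervals,
        range_fraction=frac,
    )


def run_psa(
    config: ModelConfig,
    n_draws: int = 1000,
    seed: int = 1,
    sexes: tuple[str, ...] = SEXES,
    correlated_arms: bool | None = None,
) -> pd.DataFrame:
    """Joint Monte Carlo over all uncertain parameters.

    Returns one row per (draw, sex) with incremental cost, QALYs and
    life-years of the health check versus usual care. Identical seeds give
    bitwise identical results.
    """
    if n_draws < 1:
        raise ValueError("need at least one draw")
    if correlated_arms is None:
        correlated_arms = bool(config.psa.get("correlated_arm_incidence", True))
    priors = _build_priors(config)
    frac = priors.range_fraction
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    rows = []
    for draw in range(n_draws):
        for sex in sexes:
            # --- joint parameter draw ---------------------------------
            smr = {s: float(priors.smr[sex][s](rng)) for s in SUBTYPES}
            pop_util = {b: float(f(rng)) for b, f in priors.pop_util[sex].items()}
            acute_util = {s: float(priors.acute_util[s](rng)) for s in SUBTYPES}
            hosp = {s: float(priors.hosp_cost[s](rng)) for s in SUBTYPES}
            direct = float(priors.direct_cost[sex](rng))

            alloc = {
                s: config.allocation[sex][s] * rng.uniform(1 - frac, 1 + frac)
                for s in SUBTYPES
            }
            tot = sum(alloc.values())
            alloc = {s: v / tot for s, v in alloc.items()}

            incid = {
                band: {
                    s: p * rng.uniform(1 - frac, 1 + frac) for s, p in probs.items()
                }
                for band, probs in config.incidence[sex].items()
            }
            mort = {
                band: min(0.999, p * rng.uniform(1 - frac, 1 + frac))
                for band, p in config.mortality[sex].items()
            }

            iv = priors.incidence_intervals[sex]
            q = rng.uniform()
            arm_inc = {}
            for arm in (CONTROL_ARM, INTERVENTION_ARM):
                lo, hi = iv[arm]
                arm_inc[arm] = _uniform_in(rng, lo, hi, q if correlated_arms else None)

            params = MarkovParameters(
                sex=sex,
                arm_incidence_5yr=arm_inc,
                allocation=alloc,
                incidence=incid,
                mortality=mort,
                smr=smr,
                start_age=config.entry_age,
                cycles=config.cycles,
            )
            utils = UtilitySet(
                sex=sex,
                population=pop_util,
                acute=acute_util,
                post_event_disutility_reduction=config.post_event_disutility_reduction,
            )
            mean, lo_d, hi_d = config.direct_costs[sex]
            costset = CostSet(
                acute=hosp,
                post_event_fraction=config.post_event_cost_fraction,
                direct_cost=direct,
                direct_cost_min=min(lo_d, direct),
                direct_cost_max=max(hi_d, direct),
                discount_rate=config.discount_rate,
            )

            control = arm_outcome(params, utils, costset, CONTROL_ARM)
            interv = arm_outcome(params, utils, costset, INTERVENTION_ARM)
            icer = compute_icer(control, interv)
            rows.append(
                {
                    "draw": draw,
                    "sex": sex,
                    "delta_qaly": icer.delta_qaly,
                    "delta_cost": icer.delta_cost,
                    "delta_ly": icer.delta_ly,
                }
            )
    return pd.DataFrame(rows)


def default_thresholds(config: ModelConfig | None = None) -> np.ndarray:
    """Willingness-to-pay grid: $0-150,000 in $1,000 steps plus key anchors."""
    cfg = (config.psa if config else {}).get("thresholds", {})
    lo = float(cfg.get("min", 0))
    hi = float(cfg.get("max", 150_000))
    step = float(cfg.get("step", 1_000))
    grid = np.arange(lo, hi + step / 2, step)
    anchors = np.asarray(cfg.get("always_include", [28_000, 50_000]), dtype=float)
    return np.unique(np.concatenate([grid, anchors]))


def ceac(draws: pd.DataFrame, thresholds) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve per sex.

    At each threshold lambda the probability of cost-effectiveness is the
    fraction of draws with net monetary benefit
    ``lambda * delta_QALY - delta_cost >= 0``.
    """
    if draws.empty:
        raise ValueError("no PSA draws supplied")
    thresholds = np.asarray(thresholds, dtype=float)
    rows = []
    for sex, group in draws.groupby("sex", sort=True):
        dq = group["delta_qaly"].to_numpy()
        dc = group["delta_cost"].to_numpy()
        for lam in thresholds:
            nmb = lam * dq - dc
            rows.append(
                {
                    "sex": sex,
                    "threshold": float(lam),
                    "probability": float(np.mean(nmb >= 0.0)),
                }
            )
    return pd.DataFrame(rows)
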