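"""End-to-end orchestration: base case, scenarios, PSA, validation, exports.

Everything is driven by one configuration file and one master seed; the seed
fans out to per-stage streams through ``numpy.random.SeedSequence`` spawning,
so stages are independently reproducible and the whole pipeline is
deterministic given (config, seed).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ARMS, SEXES, ModelConfig
from .economics import (
    BASE_SCENARIOS,
    CONTROL_ARM,
    INTERVENTION_ARM,
    arm_outcome,
    compute_icer,
    run_scenarios,
)
from .psa import ceac, default_thresholds, run_psa
from .risk import simulate_arms

__all__ = [
    "BaseCaseReport",
    "run_base_case",
    "run_scenario_grid",
    "run_probabilistic",
    "simulate_incidence",
    "validate_incidence",
    "RunManifest",
]

# The master seed splits into fixed per-stage streams.
_STAGE_STREAM = {"incidence": 0, "psa": 1}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2**31)."""
    child = np.random.SeedSequence(master_seed, spawn_key=(_STAGE_STREAM[stage],))
    return int(child.generate_state(1, np.uint32)[0] % (2**31))


@dataclass
class BaseCaseReport:
    """Per-sex deterministic outcomes, Table-style."""

    results: pd.DataFrame  # one row per sex x arm
    increments: pd.DataFrame  # one row per sex

    def rounded(self) -> pd.DataFrame:
        """Display rounding: LY/QALY to 3 decimals, currency to whole dollars."""
        out = self.increments.copy()
        for col in ("diff_ly", "diff_qaly"):
            out[col] = out[col].round(3)
        for col in ("diff_cost", "cost_per_ly", "cost_per_qaly"):
            out[col] = out[col].round(0)
        return out


def run_base_case(config: ModelConfig) -> BaseCaseReport:
    """Deterministic lifetime run for both sexes and arms.

    Cycles 1-5 use the arm-specific 5-year incidences (exact expectations of
    the risk equation under the configured distributions, or the configured
    override), annualised; cycles 6+ use the age-band incidence table.
    Life-years are reported undiscounted; QALYs and costs discounted.
    """
    arm_rows, inc_rows = [], []
    for sex in SEXES:
        params = config.markov_parameters(sex)
        utils = config.utility_set(sex)
        costs = config.cost_set(sex)
        outcomes = {}
        for arm in ARMS:
            o = arm_outcome(params, utils, costs, arm)
            outcomes[arm] = o
            arm_rows.append(
                {
                    "sex": sex,
                    "arm": arm,
                    "ly": o.life_years,
                    "qaly": o.qalys,
                    "cost": o.cost,
                }
            )
        icer = compute_icer(outcomes[CONTROL_ARM], outcomes[INTERVENTION_ARM])
        inc_rows.append(
            {
                "sex": sex,
                "diff_ly": icer.delta_ly,
                "diff_qaly": icer.delta_qaly,
                "diff_cost": icer.delta_cost,
                "cost_per_ly": icer.icer_per_ly,
                "cost_per_qaly": icer.icer_per_qaly,
                "classification": icer.classification,
            }
        )
    return BaseCaseReport(results=pd.DataFrame(arm_rows), increments=pd.DataFrame(inc_rows))


def run_scenario_grid(config: ModelConfig, specs=BASE_SCENARIOS) -> pd.DataFrame:
    """The deterministic scenario table (one evaluation per scenario per sex)."""
    params = {sex: config.markov_parameters(sex) for sex in SEXES}
    utils = {sex: config.utility_set(sex) for sex in SEXES}
    costs = {sex: config.cost_set(sex) for sex in SEXES}
    return run_scenarios(list(specs), params, utils, costs)


def simulate_incidence(
    config: ModelConfig,
    n: int | None = None,
    reps: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Repeated-cohort microsimulation of 5-year incidence per sex and arm."""
    n = n or config.cohort_size
    reps = reps or config.repetitions
    seed = seed if seed is not None else stage_seed(config.seed, "incidence")
    rows = []
    for sex in SEXES:
        dists = {
            CONTROL_ARM: config.distributions[sex],
            INTERVENTION_ARM: config.intervention_distribution(sex),
        }
        comp = simulate_arms(dists, n=n, reps=reps, seed=seed)
        for arm, est in comp.estimates.items():
            rows.append(
                {
                    "sex": sex,
                    "arm": arm,
                    "mean": est.mean,
                    "p2_5": est.p2_5,
                    "p97_5": est.p97_5,
                    "reps": reps,
                    "n": n,
                    "seed": seed,
                    "rr_mean": comp.rr_mean,
                    "rr_p2_5": comp.rr_p2_5,
                    "rr_p97_5": comp.rr_p97_5,
                }
            )
    return pd.DataFrame(rows)


def run_probabilistic(
    config: ModelConfig,
    n_draws: int | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PSA draws (cost-effectiveness plane) and acceptability curves."""
    n_draws = n_draws or int(config.psa.get("draws", 1000))
    seed = seed if seed is not None else stage_seed(config.seed, "psa")
    draws = run_psa(config, n_draws=n_draws, seed=seed)
    curves = ceac(draws, default_thresholds(config))
    return draws, curves


def model_annual_incidence(config: ModelConfig, sex: str) -> pd.DataFrame:
    """First-cycle annual incidence per subtype implied by the usual-care arm."""
    params = config.markov_parameters(sex)
    probs = params.annual_event_probs(1, CONTROL_ARM)
    return pd.DataFrame(
        [{"sex": sex, "subtype": s, "annual_incidence": p} for s, p in probs.items()]
    )


def validate_incidence(
    model_incidence: pd.DataFrame, reference: pd.DataFrame
) -> pd.DataFrame:
    """Side-by-side comparison with a user-supplied national reference table.

    ``reference`` needs columns sex, subtype, incidence, ci_lower, ci_upper.
    The result adds a ``within_ci`` flag per row; the comparison is
    informational only.
    """
    required = {"sex", "subtype", "incidence", "ci_lower", "ci_upper"}
    if reference is None or reference.empty:
        raise ValueError("reference table is empty")
    missing = required - set(reference.columns)
    if missing:
        raise ValueError(f"reference table missing columns: {sorted(missing)}")
    merged = model_incidence.merge(reference, on=["sex", "subtype"], how="inner")
    if merged.empty:
        raise ValueError("reference table shares no (sex, subtype) rows with the model")
    merged["within_ci"] = (merged["annual_incidence"] >= merged["ci_lower"]) & (
        merged["annual_incidence"] <= merged["ci_upper"]
    )
    return merged


@dataclass
class RunManifest:
    """Provenance record for a pipeline invocation."""

    config_digest: str
    seed: int
    package_version: str
    timestamp: str
    outputs: list[str]

    @classmethod
    def create(cls, config: ModelConfig, seed: int, outputs: list[Path]) -> "RunManifest":
        from . import __version__

        return cls(
            config_digest=config.digest(),
            seed=seed,
            package_version=__version__,
            timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
            outputs=[str(p) for p in outputs],
        )

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
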