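"""Configuration loading and validation.

All model inputs -- risk-factor bin distributions, intervention relative
risks, event allocation, age-band incidence and mortality tables, SMRs,
utilities, and costs -- live in one YAML document. The package ships an
annotated default (``data/defaults.yaml``) whose risk-factor distributions
are a calibrated emulation of the 2011 Australian National Health Survey
categories for 45-49 year olds, not source survey data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .economics import CostSet, HealthCheckCostModel, ServiceBundle, expected_direct_cost
from .markov import SUBTYPES, MarkovParameters, UtilitySet
from .population import (
    InterventionEffect,
    RiskBin,
    RiskFactorDistribution,
    SchemaError,
)

__all__ = ["ModelConfig", "load_config", "default_config_path", "SchemaError"]

SEXES = ("male", "female")
ARMS = ("usual_care", "health_check")


def default_config_path() -> Path:
    return Path(str(resources.files("cvdcheck") / "data" / "defaults.yaml"))


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise SchemaError(f"{context}: missing required key {key!r}")
    return mapping[key]


def _parse_band(text: str | int, context: str) -> tuple[int, int]:
    s = str(text)
    if s.endswith("+"):
        return (int(s[:-1]), 200)
    parts = s.split("-")
    if len(parts) != 2:
        raise SchemaError(f"{context}: cannot parse age band {text!r}")
    return (int(parts[0]), int(parts[1]))


def _parse_distribution(sex: str, raw: dict) -> RiskFactorDistribution:
    bins: dict[str, tuple[RiskBin, ...]] = {}
    for factor, entries in raw.items():
        fb = []
        for e in entries:
            fb.append(
                RiskBin(
                    factor=factor,
                    label=str(_require(e, "label", f"{sex}/{factor}")),
                    lower=float(_require(e, "lower", f"{sex}/{factor}")),
                    upper=float(_require(e, "upper", f"{sex}/{factor}")),
                    value=float(_require(e, "value", f"{sex}/{factor}")),
                    mass=float(_require(e, "mass", f"{sex}/{factor}")),
                )
            )
        total = sum(b.mass for b in fb)
        if abs(total - 1.0) > 1e-6:
            raise SchemaError(
                f"{sex}/{factor}: bin masses sum to {total:.9f}, expected 1"
            )
        bins[factor] = tuple(fb)
    return RiskFactorDistribution(sex=sex, age_band=(45, 49), bins=bins).normalized()


@dataclass
class ModelConfig:
    """Validated, assembled model inputs ready for the engines."""

    raw: dict
    distributions: dict[str, RiskFactorDistribution]
    effects: list[InterventionEffect]
    allocation: dict[str, dict[str, float]]
    incidence: dict[str, dict[tuple[int, int], dict[str, float]]]
    mortality: dict[str, dict[tuple[int, int], float]]
    smr: dict[str, dict[str, float]]  # sex -> subtype -> mean
    smr_ci: dict[str, dict[str, tuple[float, float]]]
    population_utilities: dict[str, dict[tuple[int, int], float]]
    population_utility_se: dict[str, dict[tuple[int, int], float]]
    acute_utilities: dict[str, float]
    acute_utility_se: dict[str, float]
    hospitalization_costs: dict[str, float]
    cost_range_fraction: float
    post_event_cost_fraction: float
    discount_rate: float
    post_event_disutility_reduction: float
    direct_costs: dict[str, tuple[float, float, float]]  # sex -> (mean, min, max)
    cost_model: HealthCheckCostModel
    cohort_size: int
    repetitions: int
    fre_age: int
    entry_age: int
    cycles: int
    seed: int
    incidence_override: dict[str, dict[str, float]] | None
    psa: dict

    # -- derived caches -------------------------------------------------
    _arm_incidence: dict[str, dict[str, float]] = field(default_factory=dict, repr=False)

    def intervention_distribution(self, sex: str) -> RiskFactorDistribution:
        from .population import apply_intervention

        return apply_intervention(self.distributions[sex], self.effects)

    def arm_incidence(self, sex: str) -> dict[str, float]:
        """Deterministic 5-year first-event probability per arm.

        Uses the explicit override from the config when present, otherwise
        the exact expectation of the risk equation under the shipped bins
        (the infinite-cohort limit of the microsimulation).
        """
        if sex in self._arm_incidence:
            return self._arm_incidence[sex]
        if self.incidence_override and sex in self.incidence_override:
            result = dict(self.incidence_override[sex])
        else:
            from .risk import expected_risk

            result = {
                "usual_care": expected_risk(self.distributions[sex], age=self.fre_age),
                "health_check": expected_risk(
                    self.intervention_distribution(sex), age=self.fre_age
                ),
            }
        self._arm_incidence[sex] = result
        return result

    def markov_parameters(self, sex: str) -> MarkovParameters:
        return MarkovParameters(
            sex=sex,
            arm_incidence_5yr=self.arm_incidence(sex),
            allocation=self.allocation[sex],
            incidence=self.incidence[sex],
            mortality=self.mortality[sex],
            smr=self.smr[sex],
            start_age=self.entry_age,
            cycles=self.cycles,
        )

    def utility_set(self, sex: str) -> UtilitySet:
        return UtilitySet(
            sex=sex,
            population=self.population_utilities[sex],
            acute=self.acute_utilities,
            post_event_disutility_reduction=self.post_event_disutility_reduction,
        )

    def cost_set(self, sex: str) -> CostSet:
        mean, lo, hi = self.direct_costs[sex]
        return CostSet(
            acute=self.hospitalization_costs,
            acute_range_fraction=self.cost_range_fraction,
            post_event_fraction=self.post_event_cost_fraction,
            direct_cost=mean,
            direct_cost_min=lo,
            direct_cost_max=hi,
            discount_rate=self.discount_rate,
        )

    def digest(self) -> str:
        """Stable hash of the semantic config content."""
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _per_sex_or_shared(raw: dict, context: str) -> dict[str, float]:
    """Accept either ``{mean: x}`` (shared) or ``{male: {...}, female: {...}}``."""
    if "mean" in raw:
        return {sex: float(raw["mean"]) for sex in SEXES}
    return {sex: float(_require(raw, sex, context)["mean"]) for sex in SEXES}


def load_config(path: str | Path | None = None) -> ModelConfig:
    """Parse and validate a model configuration file (default: shipped YAML)."""
    cfg_path = Path(path) if path is not None else default_config_path()
    if not cfg_path.exists():
        raise FileNotFoundError(cfg_path)
    raw = yaml.safe_load(cfg_path.read_text())
    if not isinstance(raw, dict):
        raise SchemaError("configuration root must be a mapping")

    dist_raw = _require(raw, "risk_distributions", "config")
    distributions = {
        sex: _parse_distribution(sex, _require(dist_raw, sex, "risk_distributions"))
        for sex in SEXES
    }

    effects = []
    for e in _require(raw, "intervention_effects", "config"):
        ci = e.get("ci", [e["rr"], e["rr"]])
        effects.append(
            InterventionEffect(
                factor=_require(e, "factor", "intervention_effects"),
                threshold=float(_require(e, "threshold", "intervention_effects")),
                rr=float(_require(e, "rr", "intervention_effects")),
                ci_lower=float(ci[0]),
                ci_upper=float(ci[1]),
            )
        )

    alloc_raw = _require(raw, "event_allocation", "config")
    allocation = {}
    for sex in SEXES:
        a = {s: float(v) for s, v in _require(alloc_raw, sex, "event_allocation").items()}
        unknown = set(a) - set(SUBTYPES)
        if unknown:
            raise SchemaError(f"event_allocation/{sex}: unknown subtypes {sorted(unknown)}")
        total = sum(a.values())
        if total <= 0:
            raise SchemaError(f"event_allocation/{sex}: fractions must be positive")
        allocation[sex] = {s: a.get(s, 0.0) / total for s in SUBTYPES}

    inc_raw = _require(raw, "annual_incidence", "config")
    incidence = {}
    for sex in SEXES:
        table = {}
        for band, probs in _require(inc_raw, sex, "annual_incidence").items():
            key = _parse_band(band, f"annual_incidence/{sex}")
            table[key] = {s: float(probs.get(s, 0.0)) for s in SUBTYPES}
            if sum(table[key].values()) >= 1:
                raise SchemaError(f"annual_incidence/{sex}/{band}: probabilities sum >= 1")
        incidence[sex] = table

    mort_raw = _require(raw, "mortality", "config")
    mortality = {}
    for sex in SEXES:
        mortality[sex] = {
            _parse_band(band, f"mortality/{sex}"): float(p)
            for band, p in _require(mort_raw, sex, "mortality").items()
        }
        for band, p in mortality[sex].items():
            if not (0.0 < p < 1.0):
                raise SchemaError(f"mortality/{sex}/{band}: probability {p} outside (0, 1)")

    smr_raw = _require(raw, "smr", "config")
    smr: dict[str, dict[str, float]] = {sex: {} for sex in SEXES}
    smr_ci: dict[str, dict[str, tuple[float, float]]] = {sex: {} for sex in SEXES}
    for subtype in SUBTYPES:
        entry = _require(smr_raw, subtype, "smr")
        if "mean" in entry:
            per_sex = {sex: entry for sex in SEXES}
        else:
            per_sex = {sex: _require(entry, sex, f"smr/{subtype}") for sex in SEXES}
        for sex in SEXES:
            smr[sex][subtype] = float(per_sex[sex]["mean"])
            ci = per_sex[sex].get("ci", [smr[sex][subtype]] * 2)
            smr_ci[sex][subtype] = (float(ci[0]), float(ci[1]))

    pu_raw = _require(raw, "population_utilities", "config")
    pop_util, pop_util_se = {}, {}
    for sex in SEXES:
        pop_util[sex], pop_util_se[sex] = {}, {}
        for band, entry in _require(pu_raw, sex, "population_utilities").items():
            key = _parse_band(band, f"population_utilities/{sex}")
            pop_util[sex][key] = float(_require(entry, "mean", f"population_utilities/{sex}/{band}"))
            pop_util_se[sex][key] = float(entry.get("se", 0.0))

    au_raw = _require(raw, "acute_utilities", "config")
    acute_util = {s: float(_require(au_raw, s, "acute_utilities")["mean"]) for s in SUBTYPES}
    acute_se = {s: float(au_raw[s].get("se", 0.0)) for s in SUBTYPES}
    for s, u in acute_util.items():
        if not (0.0 <= u <= 1.0):
            raise SchemaError(f"acute_utilities/{s}: utility {u} outside [0, 1]")

    costs_raw = _require(raw, "costs", "config")
    hosp = {
        s: float(_require(costs_raw["hospitalization"], s, "costs/hospitalization"))
        for s in SUBTYPES
    }

    hc_raw = _require(raw, "health_check_cost_model", "config")
    bundles = tuple(
        ServiceBundle(
            condition=_require(b, "condition", "health_check_cost_model/bundles"),
            annual_cost=float(_require(b, "annual_cost", "health_check_cost_model/bundles")),
            uptake=float(_require(b, "uptake", "health_check_cost_model/bundles")),
            compliance=float(_require(b, "compliance", "health_check_cost_model/bundles")),
        )
        for b in _require(hc_raw, "bundles", "health_check_cost_model")
    )
    cost_model = HealthCheckCostModel(
        base_cost=float(_require(hc_raw, "base_cost", "health_check_cost_model")),
        bundles=bundles,
        prevalence={
            sex: {c: float(p) for c, p in _require(hc_raw["prevalence"], sex, "prevalence").items()}
            for sex in SEXES
        },
    )
    direct_costs = {sex: expected_direct_cost(cost_model, sex) for sex in SEXES}

    analysis = raw.get("analysis", {})
    cohort = raw.get("cohort", {})
    psa = raw.get("psa", {})

    incidence_override = None
    if "five_year_incidence" in raw.get("base_case", {}):
        incidence_override = {
            sex: {arm: float(v) for arm, v in entry.items()}
            for sex, entry in raw["base_case"]["five_year_incidence"].items()
        }

    return ModelConfig(
        raw=raw,
        distributions=distributions,
        effects=effects,
        allocation=allocation,
        incidence=incidence,
        mortality=mortality,
        smr=smr,
        smr_ci=smr_ci,
        population_utilities=pop_util,
        population_utility_se=pop_util_se,
        acute_utilities=acute_util,
        acute_utility_se=acute_se,
        hospitalization_costs=hosp,
        cost_range_fraction=float(costs_raw.get("range_fraction", 0.25)),
        post_event_cost_fraction=float(costs_raw.get("post_event_fraction", 0.15)),
        discount_rate=float(costs_raw.get("discount_rate", 0.05)),
        post_event_disutility_reduction=float(
            analysis.get("post_event_disutility_reduction", 0.5)
        ),
        direct_costs=direct_costs,
        cost_model=cost_model,
        cohort_size=int(cohort.get("size_per_sex", 5000)),
        repetitions=int(cohort.get("repetitions", 1000)),
        fre_age=int(cohort.get("fre_age", 47)),
        entry_age=int(cohort.get("entry_age", 45)),
        cycles=int(cohort.get("cycles", 50)),
        seed=int(raw.get("seed", 1)),
        incidence_override=incidence_override,
        psa=psa,
    )
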