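"""Synthetic risk-factor populations for the 45-49 year old health-check model.

The target population is 'healthy' Australians aged 45-49 entering a one-off
general-practice health check. Each individual carries four cardiovascular
risk factors -- systolic blood pressure (SBP, mmHg), total cholesterol
(TC, mmol/L), HDL cholesterol (mmol/L) and current-smoking status -- drawn
independently from sex-specific categorical (binned) distributions emulating
national health-survey data. The health-check arm is modelled at the
*distribution* level: meta-analytic relative risks of remaining above a
clinical threshold (SBP > 140 mmHg, TC > 6 mmol/L, current smoking) shrink
the above-threshold probability mass, and the reallocated mass is spread over
the below-threshold bins in proportion to their existing masses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FACTORS",
    "RiskBin",
    "RiskFactorDistribution",
    "RiskProfile",
    "InterventionEffect",
    "Cohort",
    "SchemaError",
    "sample_cohort",
    "apply_intervention",
]

#: Canonical factor identifiers, in the order they appear in exports.
FACTORS = ("sbp", "tc", "hdl", "smoking")

_MASS_TOL = 1e-9

#: Admissible ranges for sampled profiles (physiological plausibility).
PROFILE_BOUNDS = {"sbp": (70.0, 260.0), "tc": (1.0, 15.0), "hdl": (0.3, 4.0)}


class SchemaError(ValueError):
    """A configuration block failed structural validation."""


@dataclass(frozen=True)
class RiskBin:
    """One category of a binned risk-factor distribution.

    ``value`` is the representative value assigned to every individual
    sampled into the bin (the survey bins are categorical; the risk equation
    needs a number). For smoking the bins are {non-smoker, smoker} with
    values 0 and 1.
    """

    factor: str
    label: str
    lower: float
    upper: float
    value: float
    mass: float

    def __post_init__(self) -> None:
        if self.factor not in FACTORS:
            raise SchemaError(f"unknown risk factor {self.factor!r}")
        if not (0.0 <= self.mass <= 1.0):
            raise SchemaError(
                f"{self.factor} bin {self.label!r}: mass {self.mass} outside [0, 1]"
            )
        if not (self.lower <= self.value <= self.upper):
            raise SchemaError(
                f"{self.factor} bin {self.label!r}: representative value "
                f"{self.value} outside [{self.lower}, {self.upper}]"
            )


@dataclass(frozen=True)
class RiskFactorDistribution:
    """Per-sex categorical risk-factor distribution for one age band."""

    sex: str
    age_band: tuple[int, int]
    bins: dict[str, tuple[RiskBin, ...]]

    def __post_init__(self) -> None:
        for factor in FACTORS:
            if factor not in self.bins or not self.bins[factor]:
                raise SchemaError(f"missing bins for factor {factor!r} ({self.sex})")
        for factor, fbins in self.bins.items():
            total = sum(b.mass for b in fbins)
            if abs(total - 1.0) > 1e-6:
                raise SchemaError(
                    f"{factor} bin masses for {self.sex} sum to {total:.9f}, not 1"
                )
            ordered = sorted(fbins, key=lambda b: b.lower)
            for lo, hi in zip(ordered, ordered[1:]):
                if abs(lo.upper - hi.lower) > 1e-9:
                    raise SchemaError(
                        f"{factor} bins for {self.sex} do not partition the support "
                        f"({lo.label!r} ends at {lo.upper}, {hi.label!r} starts at {hi.lower})"
                    )

    def normalized(self) -> "RiskFactorDistribution":
        """Return a copy with each factor's masses rescaled to sum exactly to 1."""
        bins = {}
        for factor, fbins in self.bins.items():
            total = sum(b.mass for b in fbins)
            bins[factor] = tuple(replace(b, mass=b.mass / total) for b in fbins)
        return RiskFactorDistribution(self.sex, self.age_band, bins)

    def masses(self, factor: str) -> np.ndarray:
        return np.array([b.mass for b in self.bins[factor]], dtype=float)

    def values(self, factor: str) -> np.ndarray:
        return np.array([b.value for b in self.bins[factor]], dtype=float)

    def above_threshold_mass(self, factor: str, threshold: float) -> float:
        return sum(b.mass for b in self.bins[factor] if b.lower >= threshold)


@dataclass(frozen=True)
class RiskProfile:
    """One simulated individual, carrying the risk-equation covariates.

    Diabetes and left-ventricular hypertrophy are fixed absent: the modelled
    cohort is healthy adults with no diagnosed chronic disease.
    """

    sex: str
    age: float
    sbp: float
    tc: float
    hdl: float
    smoker: bool
    diabetic: bool = False
    lvh: bool = False

    def __post_init__(self) -> None:
        for name in ("sbp", "tc", "hdl"):
            lo, hi = PROFILE_BOUNDS[name]
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside physiological range [{lo}, {hi}]")


@dataclass(frozen=True)
class InterventionEffect:
    """Relative risk of remaining above a risk-factor threshold after the check.

    ``threshold`` is the clinical high-risk boundary (140 mmHg for SBP,
    6 mmol/L for TC, smoker status for smoking). ``rr`` multiplies the
    above-threshold probability mass in the health-check arm.
    """

    factor: str
    threshold: float
    rr: float
    ci_lower: float
    ci_upper: float

    def __post_init__(self) -> None:
        if not (0.0 < self.rr <= 1.0):
            raise SchemaError(f"{self.factor}: relative risk {self.rr} outside (0, 1]")
        if not (self.ci_lower <= self.rr <= self.ci_upper):
            raise SchemaError(f"{self.factor}: CI does not bracket the mean RR")


@dataclass
class Cohort:
    """A sampled cohort as parallel arrays (one entry per individual)."""

    sex: str
    age: np.ndarray
    sbp: np.ndarray
    tc: np.ndarray
    hdl: np.ndarray
    smoker: np.ndarray  # boolean
    diabetic: np.ndarray = field(default=None)  # type: ignore[assignment]
    lvh: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.sbp)
        if self.diabetic is None:
            self.diabetic = np.zeros(n, dtype=bool)
        if self.lvh is None:
            self.lvh = np.zeros(n, dtype=bool)

    def __len__(self) -> int:
        return len(self.sbp)

    def profiles(self) -> list[RiskProfile]:
        return [
            RiskProfile(self.sex, a, s, t, h, bool(sm))
            for a, s, t, h, sm in zip(self.age, self.sbp, self.tc, self.hdl, self.smoker)
        ]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sex": self.sex,
                "age": self.age,
                "sbp": self.sbp,
                "tc": self.tc,
                "hdl": self.hdl,
                "smoker": self.smoker.astype(int),
                "diabetic": self.diabetic.astype(int),
                "lvh": self.lvh.astype(int),
            }
        )


def sample_cohort(
    dist: RiskFactorDistribution,
    n: int,
    seed: int | np.random.Generator,
    age: float = 47.0,
) -> Cohort:
    """Draw ``n`` individuals, each factor sampled independently from its bins.

    All individuals are assigned the cohort entry age (default 47, the
    midpoint of the 45-49 eligibility band). Identical seeds give bitwise
    identical cohorts.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def draw(factor: str) -> np.ndarray:
        masses = dist.masses(factor)
        idx = rng.choice(len(masses), size=n, p=masses / masses.sum())
        return dist.values(factor)[idx]

    return Cohort(
        sex=dist.sex,
        age=np.full(n, float(age)),
        sbp=draw("sbp"),
        tc=draw("tc"),
        hdl=draw("hdl"),
        smoker=draw("smoking") > 0.5,
    )


def apply_intervention(
    dist: RiskFactorDistribution, effects: list[InterventionEffect]
) -> RiskFactorDistribution:
    """Derive the health-check arm's distribution from the usual-care one.

    For each treated factor, the total above-threshold mass is multiplied by
    the factor's relative risk; the removed mass is redistributed over the
    below-threshold bins proportionally to their existing masses. Untreated
    factors (HDL) are returned unchanged. Total mass per factor is conserved.
    """
    new_bins = dict(dist.bins)
    for eff in effects:
        if eff.factor not in dist.bins:
            raise SchemaError(f"effect references unknown factor {eff.factor!r}")
        fbins = dist.bins[eff.factor]
        above = [b for b in fbins if b.lower >= eff.threshold]
        below = [b for b in fbins if b.upper <= eff.threshold]
        if len(above) + len(below) != len(fbins):
            straddlers = [
                b.label for b in fbins if b not in above and b not in below
            ]
            raise SchemaError(
                f"{eff.factor}: threshold {eff.threshold} does not align with bin "
                f"boundaries (bins {straddlers} straddle it)"
            )
        above_mass = sum(b.mass for b in above)
        below_mass = sum(b.mass for b in below)
        removed = (1.0 - eff.rr) * above_mass
        if removed > 0 and below_mass <= 0:
            raise SchemaError(
                f"{eff.factor}: no below-threshold mass to receive reallocated "
                f"individuals"
            )
        scale = 1.0 + removed / below_mass if removed > 0 else 1.0
        updated = []
        for b in fbins:
            if b in above:
                updated.append(replace(b, mass=b.mass * eff.rr))
            else:
                updated.append(replace(b, mass=b.mass * scale))
        new_bins[eff.factor] = tuple(updated)
    return RiskFactorDistribution(dist.sex, dist.age_band, new_bins)
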