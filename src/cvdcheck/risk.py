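"""Five-year cardiovascular risk via the Framingham parametric equation.

Implements the sex-combined accelerated-failure-time (Weibull) equation for
incident cardiovascular disease of Anderson, Odell, Wilson & Kannel (1991),
"Cardiovascular disease risk profiles", Am Heart J 121:293-298. The model
gives the probability of a first CVD event (stable/unstable angina, MI,
stroke or TIA) within ``t`` years from age, systolic blood pressure, the
total/HDL cholesterol ratio, smoking, diabetes and ECG left-ventricular
hypertrophy:

    p(t) = 1 - exp(-exp(u)),   u = (ln t - mu) / sigma
    mu    = linear predictor in the covariates (below)
    sigma = exp(theta0 + theta1 * mu)

Larger ``mu`` means a longer expected event-free time, hence lower risk.

The module also aggregates individual risks to arm-level incidence across
repeated cohort simulations and derives the between-arm relative risk, as
used to quantify the short-term effect of the health check.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .population import Cohort, RiskFactorDistribution, RiskProfile, sample_cohort

__all__ = [
    "FraminghamCoefficients",
    "ANDERSON_1991_CVD",
    "five_year_cvd_risk",
    "cvd_risk",
    "cohort_incidence",
    "expected_risk",
    "IncidenceEstimate",
    "ArmComparison",
    "simulate_arms",
]

#: Admissible covariate domain for the risk equation.
AGE_RANGE = (30.0, 74.0)
SBP_RANGE = (70.0, 260.0)
TC_RANGE = (1.0, 15.0)
HDL_RANGE = (0.3, 4.0)


@dataclass(frozen=True)
class FraminghamCoefficients:
    """Coefficient set of the parametric (Weibull) CVD risk equation.

    ``mu = intercept + female*I(F) + ln_age*ln(age) + female_ln_age*I(F)ln(age)
    + ln_sbp*ln(SBP) + smoker*I(smk) + ln_tc_hdl*ln(TC/HDL) + diabetes*I(dm)
    + female_diabetes*I(F)I(dm) + lvh*I(LVH)``; ``sigma = exp(theta0 + theta1*mu)``.
    """

    intercept: float
    female: float
    ln_age: float
    female_ln_age: float
    ln_sbp: float
    smoker: float
    ln_tc_hdl: float
    diabetes: float
    female_diabetes: float
    lvh: float
    theta0: float
    theta1: float


#: Published coefficients for the "CVD" endpoint (Anderson et al. 1991, Table).
ANDERSON_1991_CVD = FraminghamCoefficients(
    intercept=18.8144,
    female=-1.2146,
    ln_age=-1.8443,
    female_ln_age=0.3668,
    ln_sbp=-1.4032,
    smoker=-0.3899,
    ln_tc_hdl=-0.5390,
    diabetes=-0.3036,
    female_diabetes=-0.1697,
    lvh=-0.3362,
    theta0=0.6536,
    theta1=-0.2402,
)


def _validate_domain(age, sbp, tc, hdl) -> None:
    for name, val, (lo, hi) in (
        ("age", age, AGE_RANGE),
        ("SBP", sbp, SBP_RANGE),
        ("TC", tc, TC_RANGE),
        ("HDL", hdl, HDL_RANGE),
    ):
        val = np.asarray(val, dtype=float)
        if np.any(val < lo) or np.any(val > hi):
            raise ValueError(f"{name} outside admissible range [{lo}, {hi}]")


def cvd_risk(
    sex,
    age,
    sbp,
    tc,
    hdl,
    smoker,
    diabetic=False,
    lvh=False,
    years: float = 5.0,
    coef: FraminghamCoefficients = ANDERSON_1991_CVD,
) -> np.ndarray | float:
    """Vectorised ``years``-year first-CVD-event probability.

    ``sex`` is ``"male"``/``"female"`` or a boolean array (True = female);
    the remaining covariates are scalars or broadcastable arrays.
    """
    _validate_domain(age, sbp, tc, hdl)
    if isinstance(sex, str):
        female = 1.0 if sex == "female" else 0.0
    else:
        female = np.asarray(sex, dtype=float)
    age = np.asarray(age, dtype=float)
    sbp = np.asarray(sbp, dtype=float)
    ratio = np.asarray(tc, dtype=float) / np.asarray(hdl, dtype=float)
    smoker = np.asarray(smoker, dtype=float)
    diabetic = np.asarray(diabetic, dtype=float)
    lvh = np.asarray(lvh, dtype=float)

    ln_age = np.log(age)
    mu = (
        coef.intercept
        + coef.female * female
        + coef.ln_age * ln_age
        + coef.female_ln_age * female * ln_age
        + coef.ln_sbp * np.log(sbp)
        + coef.smoker * smoker
        + coef.ln_tc_hdl * np.log(ratio)
        + coef.diabetes * diabetic
        + coef.female_diabetes * female * diabetic
        + coef.lvh * lvh
    )
    sigma = np.exp(coef.theta0 + coef.theta1 * mu)
    u = (np.log(years) - mu) / sigma
    p = 1.0 - np.exp(-np.exp(u))
    return float(p) if np.isscalar(p) or p.ndim == 0 else p


def five_year_cvd_risk(
    profile: RiskProfile, coef: FraminghamCoefficients = ANDERSON_1991_CVD
) -> float:
    """Five-year first-CVD-event probability for one individual."""
    return float(
        cvd_risk(
            profile.sex,
            profile.age,
            profile.sbp,
            profile.tc,
            profile.hdl,
            profile.smoker,
            profile.diabetic,
            profile.lvh,
            years=5.0,
            coef=coef,
        )
    )


def _cohort_risks(cohort: Cohort, coef: FraminghamCoefficients) -> np.ndarray:
    return np.asarray(
        cvd_risk(
            np.full(len(cohort), cohort.sex == "female"),
            cohort.age,
            cohort.sbp,
            cohort.tc,
            cohort.hdl,
            cohort.smoker,
            cohort.diabetic,
            cohort.lvh,
            coef=coef,
        )
    )


def cohort_incidence(
    cohort: Cohort | list[RiskProfile], coef: FraminghamCoefficients = ANDERSON_1991_CVD
) -> float:
    """Mean individual 5-year risk = expected 5-year CVD incidence of the cohort."""
    if isinstance(cohort, Cohort):
        if len(cohort) == 0:
            raise ValueError("empty cohort")
        return float(_cohort_risks(cohort, coef).mean())
    if not cohort:
        raise ValueError("empty cohort")
    return float(np.mean([five_year_cvd_risk(p, coef) for p in cohort]))


def expected_risk(
    dist: RiskFactorDistribution,
    coef: FraminghamCoefficients = ANDERSON_1991_CVD,
    age: float = 47.0,
) -> float:
    """Exact expected 5-year risk under a binned distribution.

    Because factors are independent and each bin maps to one representative
    value, the population mean risk is a finite sum over the product of the
    four bin sets. This is the infinite-cohort limit of ``cohort_incidence``
    on sampled cohorts, and parameterises the deterministic base case.
    """
    female = dist.sex == "female"
    total = 0.0
    for bs, bt, bh, bk in product(
        dist.bins["sbp"], dist.bins["tc"], dist.bins["hdl"], dist.bins["smoking"]
    ):
        w = bs.mass * bt.mass * bh.mass * bk.mass
        if w == 0.0:
            continue
        p = cvd_risk(female, age, bs.value, bt.value, bh.value, bk.value > 0.5, coef=coef)
        total += w * float(p)
    return total


@dataclass(frozen=True)
class IncidenceEstimate:
    """Arm-level 5-year incidence summarised over repeated cohort simulations."""

    arm: str
    sex: str
    mean: float
    p2_5: float
    p97_5: float
    reps: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p2_5 <= self.mean <= self.p97_5 <= 1.0):
            raise ValueError("percentiles must bracket the mean within [0, 1]")


@dataclass(frozen=True)
class ArmComparison:
    """Incidence per arm plus the per-repetition relative risk summary."""

    sex: str
    estimates: dict[str, IncidenceEstimate]
    rr_mean: float
    rr_p2_5: float
    rr_p97_5: float
    diff_mean: float
    reps: int
    n: int
    seed: int


def simulate_arms(
    dists: dict[str, RiskFactorDistribution],
    n: int,
    reps: int,
    seed: int,
    coef: FraminghamCoefficients = ANDERSON_1991_CVD,
    control_arm: str = "usual_care",
    intervention_arm: str = "health_check",
    paired: bool = False,
) -> ArmComparison:
    """Repeatedly sample fresh cohorts per arm and summarise incidence and RR.

    Each repetition draws an independent ``n``-person cohort in every arm,
    computes its mean 5-year risk, and records the intervention/control
    incidence ratio. Means and 2.5/97.5 percentiles are taken across
    repetitions. With ``paired=True`` both arms reuse the same random stream
    per repetition (common random numbers), reducing Monte Carlo variance of
    the ratio; the default is fully independent arms.
    """
    if reps < 2:
        raise ValueError("need at least 2 repetitions")
    sexes = {d.sex for d in dists.values()}
    if len(sexes) != 1:
        raise ValueError("all arms must share one sex")
    sex = sexes.pop()

    ss = np.random.SeedSequence(seed)
    arm_names = list(dists)
    incid = {arm: np.empty(reps) for arm in arm_names}
    for r, child in enumerate(ss.spawn(reps)):
        if paired:
            states = [child] * len(arm_names)
        else:
            states = child.spawn(len(arm_names))
        for arm, state in zip(arm_names, states):
            rng = np.random.default_rng(state)
            cohort = sample_cohort(dists[arm], n, rng)
            incid[arm][r] = _cohort_risks(cohort, coef).mean()

    rr = incid[intervention_arm] / incid[control_arm]
    diff = incid[intervention_arm] - incid[control_arm]
    estimates = {
        arm: IncidenceEstimate(
            arm=arm,
            sex=sex,
            mean=float(v.mean()),
            p2_5=float(np.percentile(v, 2.5)),
            p97_5=float(np.percentile(v, 97.5)),
            reps=reps,
        )
        for arm, v in incid.items()
    }
    return ArmComparison(
        sex=sex,
        estimates=estimates,
        rr_mean=float(rr.mean()),
        rr_p2_5=float(np.percentile(rr, 2.5)),
        rr_p97_5=float(np.percentile(rr, 97.5)),
        diff_mean=float(diff.mean()),
        reps=reps,
        n=n,
        seed=seed,
    )
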