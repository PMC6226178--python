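"""Risk-factor distributions, cohort sampling and the intervention reallocation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cvdcheck.population import (
    FACTORS,
    InterventionEffect,
    RiskBin,
    RiskFactorDistribution,
    SchemaError,
    apply_intervention,
    sample_cohort,
)


def _dist(sex="male", smoking=0.2, sbp_masses=(0.5, 0.3, 0.15, 0.05)):
    bins = {
        "sbp": tuple(
            RiskBin("sbp", lab, lo, hi, v, m)
            for (lab, lo, hi, v), m in zip(
                [("<120", 90, 120, 110), ("120-139", 120, 140, 130),
                 ("140-159", 140, 160, 150), ("160+", 160, 200, 170)],
                sbp_masses,
            )
        ),
        "tc": (
            RiskBin("tc", "<6", 2.5, 6.0, 5.0, 0.8),
            RiskBin("tc", "6+", 6.0, 9.0, 6.8, 0.2),
        ),
        "hdl": (RiskBin("hdl", "all", 0.6, 2.5, 1.3, 1.0),),
        "smoking": (
            RiskBin("smoking", "non-smoker", 0.0, 0.5, 0.0, 1 - smoking),
            RiskBin("smoking", "smoker", 0.5, 1.0, 1.0, smoking),
        ),
    }
    return RiskFactorDistribution(sex, (45, 49), bins)


def _point_mass():
    bins = {
        "sbp": (RiskBin("sbp", "all", 90, 200, 128.0, 1.0),),
        "tc": (RiskBin("tc", "all", 2.5, 9.0, 5.2, 1.0),),
        "hdl": (RiskBin("hdl", "all", 0.6, 2.5, 1.4, 1.0),),
        "smoking": (RiskBin("smoking", "non-smoker", 0.0, 1.0, 0.0, 1.0),),
    }
    return RiskFactorDistribution("female", (45, 49), bins)


class TestValidation:
    def test_masses_must_sum_to_one(self):
        with pytest.raises(SchemaError, match="smoking"):
            bins = dict(_dist().bins)
            bins["smoking"] = (
                RiskBin("smoking", "non-smoker", 0.0, 0.5, 0.0, 0.6),
                RiskBin("smoking", "smoker", 0.5, 1.0, 1.0, 0.5),
            )
            RiskFactorDistribution("male", (45, 49), bins)

    def test_missing_factor_is_named(self):
        bins = {f: _dist().bins[f] for f in FACTORS if f != "hdl"}
        with pytest.raises(SchemaError, match="hdl"):
            RiskFactorDistribution("male", (45, 49), bins)

    def test_bins_must_partition_support(self):
        bins = dict(_dist().bins)
        bins["tc"] = (
            RiskBin("tc", "<5", 2.5, 5.0, 4.0, 0.5),
            RiskBin("tc", "6+", 6.0, 9.0, 6.8, 0.5),  # gap (5, 6)
        )
        with pytest.raises(SchemaError, match="partition"):
            RiskFactorDistribution("male", (45, 49), bins)

    def test_representative_value_within_bounds(self):
        with pytest.raises(SchemaError, match="representative"):
            RiskBin("sbp", "bad", 120, 140, 150, 0.5)

    def test_mass_outside_unit_interval(self):
        with pytest.raises(SchemaError):
            RiskBin("sbp", "bad", 120, 140, 130, 1.2)


class TestSampling:
    def test_point_mass_gives_identical_profiles(self):
        cohort = sample_cohort(_point_mass(), 10, seed=3)
        assert len(cohort) == 10
        assert np.all(cohort.sbp == 128.0)
        assert np.all(cohort.tc == 5.2)
        assert np.all(cohort.hdl == 1.4)
        assert not cohort.smoker.any()

    def test_seed_reproducibility_is_bitwise(self):
        a = sample_cohort(_dist(), 500, seed=11)
        b = sample_cohort(_dist(), 500, seed=11)
        for field in ("sbp", "tc", "hdl", "smoker"):
            assert np.array_equal(getattr(a, field), getattr(b, field))

    def test_different_seeds_differ(self):
        a = sample_cohort(_dist(), 500, seed=11)
        b = sample_cohort(_dist(), 500, seed=12)
        assert not np.array_equal(a.sbp, b.sbp)

    def test_empirical_frequencies_converge(self):
        # binomial 4-sigma band at n = 1e5
        n = 100_000
        cohort = sample_cohort(_dist(smoking=0.2), n, seed=29)
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(cohort.smoker.mean() - 0.2) < 4 * se
        sbp_frac = (cohort.sbp == 110.0).mean()
        se = np.sqrt(0.5 * 0.5 / n)
        assert abs(sbp_frac - 0.5) < 4 * se

    def test_invalid_cohort_size(self):
        with pytest.raises(ValueError):
            sample_cohort(_dist(), 0, seed=1)

    def test_profiles_roundtrip(self):
        cohort = sample_cohort(_dist(), 7, seed=5)
        profiles = cohort.profiles()
        assert len(profiles) == 7
        assert profiles[0].sbp == cohort.sbp[0]


class TestIntervention:
    def test_smoking_prevalence_scales_by_rr(self):
        d = _dist(smoking=0.20)
        out = apply_intervention(d, [InterventionEffect("smoking", 0.5, 0.90, 0.84, 0.97)])
        smoker = [b for b in out.bins["smoking"] if b.value == 1.0][0]
        assert smoker.mass == pytest.approx(0.18)

    def test_sbp_reallocation_conserves_mass(self):
        # above-140 mass 0.10, RR 0.71 -> 0.071; below bins scaled by 0.929/0.90
        d = _dist(sbp_masses=(0.55, 0.35, 0.07, 0.03))
        out = apply_intervention(d, [InterventionEffect("sbp", 140.0, 0.71, 0.55, 0.90)])
        above = sum(b.mass for b in out.bins["sbp"] if b.lower >= 140)
        assert above == pytest.approx(0.071)
        scale = (1 - 0.071) / 0.90
        assert out.bins["sbp"][0].mass == pytest.approx(0.55 * scale)
        assert sum(b.mass for b in out.bins["sbp"]) == pytest.approx(1.0, abs=1e-9)

    def test_identity_when_rr_is_one(self):
        d = _dist()
        out = apply_intervention(d, [
            InterventionEffect("sbp", 140.0, 1.0, 1.0, 1.0),
            InterventionEffect("smoking", 0.5, 1.0, 1.0, 1.0),
        ])
        for f in FACTORS:
            for b0, b1 in zip(d.bins[f], out.bins[f]):
                assert b1.mass == pytest.approx(b0.mass)

    def test_untreated_factor_unchanged(self):
        d = _dist()
        out = apply_intervention(d, [InterventionEffect("tc", 6.0, 0.63, 0.50, 0.79)])
        assert out.bins["hdl"] == d.bins["hdl"]
        assert out.bins["sbp"] == d.bins["sbp"]

    def test_threshold_must_align_with_bin_boundary(self):
        d = _dist()
        with pytest.raises(SchemaError, match="threshold"):
            apply_intervention(d, [InterventionEffect("sbp", 145.0, 0.71, 0.55, 0.90)])

    @given(
        above=st.floats(0.01, 0.6),
        rr=st.floats(0.05, 1.0),
        split=st.floats(0.05, 0.95),
    )
    def test_mass_conservation_property(self, above, rr, split):
        below = 1.0 - above
        masses = (below * split, below * (1 - split), above * 0.7, above * 0.3)
        d = _dist(sbp_masses=masses)
        out = apply_intervention(d, [InterventionEffect("sbp", 140.0, rr, rr, rr)])
        total = sum(b.mass for b in out.bins["sbp"])
        assert total == pytest.approx(1.0, abs=1e-9)
        new_above = sum(b.mass for b in out.bins["sbp"] if b.lower >= 140)
        assert new_above <= above + 1e-12  # monotone benefit
        assert new_above == pytest.approx(above * rr)

    def test_effect_on_unknown_factor(self):
        with pytest.raises(SchemaError, match="unknown"):
            apply_intervention(_dist(), [InterventionEffect("bmi", 30.0, 0.9, 0.8, 1.0)])
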