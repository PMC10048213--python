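"""Allelic-model effect extraction, HWE testing, and quality gating."""

import math
import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drmeta.effects import (
    alleles_from_genotypes,
    dedupe_one_record_per_study,
    effect_from_genotype_counts,
    hwe_test,
    or_from_table,
    quality_gate,
    read_genotype_counts,
    read_reported_effects,
    se_from_ci,
)
from drmeta.types import (
    AlleleTable,
    EffectSource,
    GenotypeCounts,
    QualityRule,
    ValidationError,
)

from conftest import make_estimate
from reference_impl import hwe_chi2_exact_reference, hwe_exact_reference


class TestAllelesFromGenotypes:
    @pytest.mark.parametrize(
        "cases, expected_a, expected_b",
        [
            ((10, 20, 70), 40, 160),
            ((0, 0, 50), 0, 100),  # monomorphic
            ((25, 50, 25), 100, 100),  # frequency 0.5
        ],
    )
    def test_allele_collapse(self, cases, expected_a, expected_b):
        g = GenotypeCounts("S", case_counts=cases, control_counts=(1, 1, 1))
        t = alleles_from_genotypes(g)
        assert (t.a, t.b) == (expected_a, expected_b)

    def test_zero_total_arm_rejected(self):
        with pytest.raises(ValidationError):
            GenotypeCounts("S", case_counts=(0, 0, 0), control_counts=(1, 1, 1))

    @given(
        st.tuples(
            st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)
        ).filter(lambda t: sum(t) > 0),
        st.tuples(
            st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)
        ).filter(lambda t: sum(t) > 0),
    )
    @settings(max_examples=100, deadline=None)
    def test_chromosomes_conserved(self, cases, controls):
        g = GenotypeCounts("S", case_counts=cases, control_counts=controls)
        t = alleles_from_genotypes(g)
        assert t.a + t.b == 2 * sum(cases)
        assert t.c + t.d == 2 * sum(controls)


class TestOrFromTable:
    def test_null_or(self):
        e = or_from_table(AlleleTable(10, 10, 10, 10))
        assert e.beta == pytest.approx(0.0)
        assert e.se == pytest.approx(math.sqrt(0.4))
        assert not e.continuity_corrected

    def test_hand_arithmetic(self):
        e = or_from_table(AlleleTable(40, 160, 20, 180))
        assert math.exp(e.beta) == pytest.approx(2.25)
        assert e.beta == pytest.approx(math.log(2.25))
        # sqrt(1/40 + 1/160 + 1/20 + 1/180)
        assert e.se == pytest.approx(0.2946278, abs=1e-6)

    def test_haldane_correction_on_zero_cell(self):
        e = or_from_table(AlleleTable(0, 100, 10, 90), correction="haldane")
        assert e.continuity_corrected
        expected = (0.5 * 90.5) / (100.5 * 10.5)
        assert math.exp(e.beta) == pytest.approx(expected)
        assert math.exp(e.beta) == pytest.approx(0.0429, abs=1e-4)

    def test_strict_policy_raises_on_zero_cell(self):
        with pytest.raises(ValidationError):
            or_from_table(AlleleTable(0, 100, 10, 90), correction="strict")

    def test_nonzero_tables_never_corrected(self):
        e = or_from_table(AlleleTable(1, 1, 1, 1), correction="haldane")
        assert not e.continuity_corrected

    @given(
        st.tuples(*[st.integers(1, 1000)] * 4),
    )
    @settings(max_examples=100, deadline=None)
    def test_allele_swap_negates_beta_preserves_se(self, cells):
        a, b, c, d = cells
        e = or_from_table(AlleleTable(a, b, c, d))
        swapped = or_from_table(AlleleTable(b, a, d, c))
        assert swapped.beta == pytest.approx(-e.beta, abs=1e-12)
        assert swapped.se == pytest.approx(e.se, abs=1e-15)


class TestSeFromCi:
    def test_printed_formula(self):
        e = se_from_ci(1.5, 1.2)
        assert e.se == pytest.approx((math.log(1.5) - math.log(1.2)) / 1.96)
        assert e.se == pytest.approx(0.11385, abs=1e-5)
        assert e.source is EffectSource.REPORTED_CI

    def test_algebraic_inversion(self):
        e = se_from_ci(1.0, math.exp(-1.96 * 0.1))
        assert e.se == pytest.approx(0.1, rel=1e-12)

    def test_degenerate_ci_rejected(self):
        with pytest.raises(ValidationError):
            se_from_ci(2.0, 2.0)
        with pytest.raises(ValidationError):
            se_from_ci(2.0, 2.5)

    def test_asymmetric_reported_ci_warns(self):
        with pytest.warns(UserWarning, match="asymmetric"):
            se_from_ci(1.5, 1.2, ci_upper=2.5)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            se_from_ci(1.5, 1.2, ci_upper=1.5**2 / 1.2)  # symmetric on log scale

    @given(
        st.floats(min_value=0.05, max_value=20.0),
        st.floats(min_value=1e-4, max_value=2.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_lower_ci_reconstruction(self, or_value, spread):
        ci_lower = or_value * math.exp(-spread)
        e = se_from_ci(or_value, ci_lower)
        assert math.exp(e.beta - 1.96 * e.se) == pytest.approx(ci_lower, rel=1e-12)


class TestHweTest:
    @pytest.mark.parametrize("counts", [(81, 18, 1), (25, 50, 25)])
    def test_perfect_hwe_proportions(self, counts):
        res = hwe_test(counts)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_chi2(self):
        res = hwe_test((30, 40, 30))
        assert res.chi2 == pytest.approx(4.0)
        assert res.p_value == pytest.approx(0.0455, abs=1e-4)

    def test_monomorphic_flagged(self):
        res = hwe_test((0, 0, 50))
        assert res.monomorphic
        assert res.p_value == 1.0

    def test_exact_matches_enumeration_reference(self):
        for counts in [(30, 40, 30), (5, 20, 75), (12, 36, 52), (1, 8, 91)]:
            res = hwe_test(counts, method="exact")
            assert res.p_value == pytest.approx(
                hwe_exact_reference(*counts), rel=1e-9
            )

    @pytest.mark.parametrize(
        "n, maf, seed", [(250, 0.25, 0), (250, 0.25, 1), (400, 0.15, 2), (400, 0.25, 3)]
    )
    def test_chi2_close_to_exact_enumeration_for_large_counts(self, n, maf, seed):
        # asymptotic p tracks the exact statistic-ordered enumeration for
        # control totals >= 200 and common alleles
        import numpy as np

        rng = np.random.default_rng(seed)
        p, q = maf, 1 - maf
        counts = tuple(int(x) for x in rng.multinomial(n, [p * p, 2 * p * q, q * q]))
        chi2_p = hwe_test(counts, method="chi2").p_value
        exact_p = hwe_chi2_exact_reference(*counts)
        assert abs(chi2_p - exact_p) < 0.02


class TestQualityGate:
    def test_nos_threshold_is_inclusive(self):
        e = quality_gate(make_estimate(nos_stars=6))
        assert e.high_risk_nos is True
        e7 = quality_gate(make_estimate(nos_stars=7, hwe_p=0.5))
        assert e7.high_risk_nos is False
        assert e7.hwe_deviation is False

    def test_hwe_alpha_boundary(self):
        assert quality_gate(make_estimate(hwe_p=0.049)).hwe_deviation is True
        assert quality_gate(make_estimate(hwe_p=0.05)).hwe_deviation is False

    def test_missing_inputs_leave_flags_unset(self):
        e = quality_gate(make_estimate())
        assert e.high_risk_nos is None
        assert e.hwe_deviation is None


class TestLoaders:
    def test_genotype_counts_round_trip(self, tmp_path):
        path = tmp_path / "counts.csv"
        path.write_text(
            "study_id,snp,arm,n_EE,n_EO,n_OO\n"
            "A,rs1,case,10,20,70\n"
            "A,rs1,control,5,25,70\n"
        )
        cohorts = read_genotype_counts(path)
        assert len(cohorts) == 1
        assert cohorts[0].case_counts == (10, 20, 70)
        e = effect_from_genotype_counts(cohorts[0])
        assert e.hwe_p is not None and e.se > 0

    def test_reported_effects_loader(self, tmp_path):
        path = tmp_path / "reported.csv"
        path.write_text(
            "study_id,snp,or,ci_lower,ci_upper,nos_stars\n"
            "B,rs1,1.5,1.2,1.88,7\n"
        )
        ests = read_reported_effects(path)
        assert len(ests) == 1
        assert ests[0].nos_stars == 7
        assert ests[0].beta == pytest.approx(math.log(1.5))

    def test_dedupe_prefers_reported_ci(self):
        counts_based = make_estimate(study="A", snp="rs1")
        reported = make_estimate(
            study="A", snp="rs1", source=EffectSource.REPORTED_CI, beta=0.5
        )
        kept = dedupe_one_record_per_study([counts_based, reported])
        assert len(kept) == 1
        assert kept[0].source is EffectSource.REPORTED_CI
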