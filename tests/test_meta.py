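"""Random-effects pooling, heterogeneity, sensitivity, and funnel outputs."""

import math
import shutil
import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drmeta.meta import (
    classify_heterogeneity,
    dersimonian_laird,
    fixed_effect,
    funnel_data,
    is_significant,
    leave_one_out,
    meta_table,
)
from drmeta.types import MetaResult, QualityRule, ValidationError

from conftest import make_estimate
from reference_impl import dl_reference


def random_estimates(rng, k):
    return [
        make_estimate(
            study=f"S{i}",
            beta=float(rng.normal(0, 0.5)),
            se=float(rng.uniform(0.05, 0.5)),
        )
        for i in range(k)
    ]


class TestFixedEffect:
    def test_identical_estimates(self):
        ests = [make_estimate(study="a"), make_estimate(study="b")]
        beta, se, q = fixed_effect(ests)
        assert beta == pytest.approx(0.3)
        assert se == pytest.approx(0.1 / math.sqrt(2))
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic(self):
        ests = [make_estimate(study="a", beta=0.0), make_estimate(study="b", beta=0.4)]
        beta, se, q = fixed_effect(ests)
        assert beta == pytest.approx(0.2)
        assert q == pytest.approx(8.0)

    def test_single_study_rejected(self):
        with pytest.raises(ValidationError):
            fixed_effect([make_estimate()])


class TestDerSimonianLaird:
    def test_identical_estimates_no_heterogeneity(self):
        ests = [make_estimate(study="a"), make_estimate(study="b")]
        r = dersimonian_laird(ests)
        assert r.tau2 == 0.0
        assert r.i2 == 0.0
        assert r.beta_random == pytest.approx(r.beta_fixed)
        assert r.se_random == pytest.approx(r.se_fixed)

    def test_hand_worked_two_study_pool(self):
        ests = [make_estimate(study="a", beta=0.0), make_estimate(study="b", beta=0.4)]
        r = dersimonian_laird(ests)
        assert r.q_stat == pytest.approx(8.0)
        assert r.tau2 == pytest.approx(0.07)  # (8-1)/(200-100)
        assert r.beta_random == pytest.approx(0.2)
        assert r.i2 == pytest.approx(87.5)

    def test_q_below_df_truncates_tau2(self):
        ests = [
            make_estimate(study="a", beta=0.10, se=0.2),
            make_estimate(study="b", beta=0.11, se=0.2),
        ]
        r = dersimonian_laird(ests)
        assert r.tau2 == 0.0
        assert r.beta_random == pytest.approx(r.beta_fixed)
        assert r.se_random == pytest.approx(r.se_fixed)
        assert r.i2 == 0.0

    def test_ci_brackets_pooled_or(self):
        ests = [make_estimate(study="a", beta=0.0), make_estimate(study="b", beta=0.4)]
        r = dersimonian_laird(ests)
        lo, hi = r.ci_random
        assert lo < r.or_random < hi
        assert lo == pytest.approx(math.exp(r.beta_random - 1.96 * r.se_random))

    def test_matches_reference_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            k = int(rng.integers(2, 11))
            ests = random_estimates(rng, k)
            r = dersimonian_laird(ests)
            ref = dl_reference([e.beta for e in ests], [e.se for e in ests])
            assert r.beta_random == pytest.approx(ref["beta_random"], abs=1e-8)
            assert r.tau2 == pytest.approx(ref["tau2"], abs=1e-8)
            assert r.i2 == pytest.approx(ref["i2"], abs=1e-8)
            assert r.ci_random[0] == pytest.approx(ref["ci_lower"], abs=1e-8)
            assert r.ci_random[1] == pytest.approx(ref["ci_upper"], abs=1e-8)

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_pooled_beta_is_convex_combination(self, data):
        k = data.draw(st.integers(2, 8))
        betas = data.draw(
            st.lists(
                st.floats(-2, 2, allow_nan=False), min_size=k, max_size=k
            )
        )
        ses = data.draw(
            st.lists(st.floats(0.01, 1.0), min_size=k, max_size=k)
        )
        ests = [
            make_estimate(study=f"S{i}", beta=b, se=s)
            for i, (b, s) in enumerate(zip(betas, ses))
        ]
        r = dersimonian_laird(ests)
        assert min(betas) - 1e-12 <= r.beta_random <= max(betas) + 1e-12

    def test_i2_invariant_under_common_rescale(self):
        rng = np.random.default_rng(3)
        ests = random_estimates(rng, 6)
        r1 = dersimonian_laird(ests)
        scaled = [
            make_estimate(study=e.study_id, beta=3.7 * e.beta, se=3.7 * e.se)
            for e in ests
        ]
        r2 = dersimonian_laird(scaled)
        assert r2.i2 == pytest.approx(r1.i2, abs=1e-9)

    def test_tau2_zero_iff_random_equals_fixed(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            ests = random_estimates(rng, int(rng.integers(2, 8)))
            r = dersimonian_laird(ests)
            if r.tau2 == 0.0:
                assert r.beta_random == r.beta_fixed
                assert r.se_random == r.se_fixed
            else:
                assert r.se_random > r.se_fixed


def test_metafor_cross_check(tmp_path):
    """DL output agrees with R metafor (method='DL') on a 5-study fixture."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript not available for the independent cross-check")
    betas = [0.10, 0.35, -0.05, 0.50, 0.22]
    ses = [0.12, 0.20, 0.15, 0.30, 0.10]
    script = tmp_path / "dl.R"
    script.write_text(
        textwrap.dedent(
            f"""
            suppressMessages(library(metafor))
            yi <- c({', '.join(map(str, betas))})
            sei <- c({', '.join(map(str, ses))})
            fit <- rma(yi = yi, sei = sei, method = "DL")
            cat(sprintf("%.12f %.12f %.12f\\n", fit$b[1], fit$tau2, fit$I2))
            """
        )
    )
    out = subprocess.run(
        ["Rscript", "--vanilla", str(script)],
        capture_output=True,
        text=True,
        check=True,
    )
    b_ref, tau2_ref, i2_ref = map(float, out.stdout.split())
    ests = [
        make_estimate(study=f"S{i}", beta=b, se=s)
        for i, (b, s) in enumerate(zip(betas, ses))
    ]
    r = dersimonian_laird(ests)
    assert r.beta_random == pytest.approx(b_ref, abs=1e-6)
    assert r.tau2 == pytest.approx(tau2_ref, abs=1e-6)
    assert r.i2 == pytest.approx(i2_ref, abs=1e-4)


class TestClassifyHeterogeneity:
    @pytest.mark.parametrize(
        "i2, expected", [(0.0, "low"), (49.9, "low"), (50.0, "high"), (87.5, "high")]
    )
    def test_strict_fifty_percent_cutoff(self, i2, expected):
        r = MetaResult(
            k=2,
            beta_fixed=0.1,
            se_fixed=0.1,
            q_stat=1.0,
            tau2=0.0,
            beta_random=0.1,
            se_random=0.1,
            or_random=math.exp(0.1),
            ci_random=(math.exp(0.1 - 0.196), math.exp(0.1 + 0.196)),
            i2=i2,
            z=1.0,
            p_summary=0.3,
        )
        assert classify_heterogeneity(r) == expected


class TestLeaveOneOut:
    def test_identical_studies_never_flip(self):
        ests = [make_estimate(study=f"S{i}", beta=0.5, se=0.1) for i in range(3)]
        results = leave_one_out(ests)
        assert len(results) == 3
        assert not any(r.significance_flipped for r in results)
        assert all(r.result_without.k == 2 for r in results)

    def test_only_dominating_study_flips_significance(self):
        # one precise study carries the evidence; the imprecise rest point the
        # same way but cannot reach significance on their own
        dominant = make_estimate(study="DOMINANT", beta=0.5, se=0.1)
        others = [
            make_estimate(study="S1", beta=0.30, se=0.45),
            make_estimate(study="S2", beta=0.28, se=0.45),
            make_estimate(study="S3", beta=0.32, se=0.45),
        ]
        ests = [dominant] + others
        assert is_significant(dersimonian_laird(ests))
        results = leave_one_out(ests)
        flipped = [r.omitted_study_id for r in results if r.significance_flipped]
        assert flipped == ["DOMINANT"]

    def test_k2_returns_empty_with_warning(self):
        ests = [make_estimate(study="a"), make_estimate(study="b")]
        with pytest.warns(UserWarning, match="k = 2"):
            assert leave_one_out(ests) == []

    def test_restricted_mode_with_no_flags_is_empty(self):
        ests = [
            make_estimate(study=f"S{i}", beta=0.5, se=0.1, nos_stars=8, hwe_p=0.9,
                          high_risk_nos=False, hwe_deviation=False)
            for i in range(3)
        ]
        assert leave_one_out(ests, restrict_to_flagged=True) == []

    def test_restricted_mode_omits_only_flagged(self):
        ests = [
            make_estimate(study="GOOD1", beta=0.5, se=0.1, high_risk_nos=False),
            make_estimate(study="BAD", beta=0.5, se=0.1, high_risk_nos=True),
            make_estimate(study="GOOD2", beta=0.5, se=0.1, high_risk_nos=False),
        ]
        results = leave_one_out(ests, restrict_to_flagged=True)
        assert [r.omitted_study_id for r in results] == ["BAD"]


class TestFunnelData:
    def test_rows_and_guides(self):
        ests = [make_estimate(study="a"), make_estimate(study="b", beta=0.4)]
        rows, guides = funnel_data(ests)
        assert len(rows) == 2
        assert (rows.se > 0).all()
        assert guides["z"] == 1.96

    def test_symmetric_fixture_centers_on_pooled_beta(self):
        # betas mirrored around 0.3 with equal SEs: signed deviations cancel
        ests = [
            make_estimate(study=f"S{i}", beta=0.3 + d, se=0.2)
            for i, d in enumerate([-0.2, -0.1, 0.0, 0.1, 0.2])
        ]
        rows, guides = funnel_data(ests)
        deviations = rows.beta - guides["center_beta"]
        assert deviations.mean() == pytest.approx(0.0, abs=1e-12)


class TestMetaTable:
    def test_significance_boundary_strict(self):
        def result_with_p(p):
            return MetaResult(
                k=3,
                beta_fixed=0.1,
                se_fixed=0.05,
                q_stat=1.0,
                tau2=0.0,
                beta_random=0.1,
                se_random=0.05,
                or_random=math.exp(0.1),
                ci_random=(math.exp(0.002), math.exp(0.198)),
                i2=0.0,
                z=2.0,
                p_summary=p,
            )
        table = meta_table({"rsA": result_with_p(0.001), "rsB": result_with_p(0.05)})
        assert bool(table[table.snp == "rsA"].significant.iloc[0]) is True
        assert bool(table[table.snp == "rsB"].significant.iloc[0]) is False

    def test_empty_mapping_gives_empty_report_with_header(self):
        table = meta_table({})
        assert len(table) == 0
        assert "or" in table.columns and "i2" in table.columns
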