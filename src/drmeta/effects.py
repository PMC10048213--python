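"""Per-study effect extraction under the allelic model.

Each replication study contributes one log odds ratio (beta) with a standard
error, either computed from genotype counts via the allelic 2x2 table or
recovered from a reported OR with its 95% CI lower limit using

    SE = (ln OR - ln lower) / 1.96.

Hardy-Weinberg deviation in controls and Newcastle-Ottawa quality are
attached as flags here; removal only ever happens downstream, in the
meta-analysis sensitivity step.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd
from scipy import stats

from .types import (
    AlleleTable,
    EffectEstimate,
    EffectSource,
    GenotypeCounts,
    GenotypeTriple,
    QualityRule,
    ValidationError,
)

Z_95 = 1.96  # normal quantile used throughout (RevMan convention)


def alleles_from_genotypes(g: GenotypeCounts) -> AlleleTable:
    """Collapse genotype triples to allele counts (each subject = 2 alleles).

    Cases: a = 2*n_EE + n_EO effect alleles, b = 2*n_OO + n_EO other
    alleles; likewise c, d for controls.  Conserves chromosomes: a + b is
    exactly twice the case sample size.
    """
    cee, ceo, coo = g.case_counts
    kee, keo, koo = g.control_counts
    return AlleleTable(
        a=2 * cee + ceo,
        b=2 * coo + ceo,
        c=2 * kee + keo,
        d=2 * koo + keo,
    )


def or_from_table(
    t: AlleleTable,
    correction: str = "haldane",
    study_id: str = "",
    snp: Optional[str] = None,
) -> EffectEstimate:
    """Allelic odds ratio OR = (a*d)/(b*c) with Woolf standard error.

    beta = ln OR; se = sqrt(1/a + 1/b + 1/c + 1/d).  If any cell is zero and
    ``correction="haldane"``, 0.5 is added to all four cells first
    (Haldane-Anscombe); nonzero tables are never touched.
    ``correction="strict"`` raises on a zero cell instead.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    corrected = False
    if min(a, b, c, d) == 0:
        if correction == "haldane":
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            corrected = True
        elif correction == "strict":
            raise ValidationError(
                f"{study_id or 'table'}: zero cell with strict continuity policy"
            )
        else:
            raise ValueError(f"unknown continuity policy {correction!r}")
    beta = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(
        study_id=study_id,
        beta=beta,
        se=se,
        source=EffectSource.COUNTS,
        continuity_corrected=corrected,
        snp=snp,
    )


def se_from_ci(
    or_value: float,
    ci_lower: float,
    ci_upper: Optional[float] = None,
    study_id: str = "",
    snp: Optional[str] = None,
    nos_stars: Optional[int] = None,
    asymmetry_warn: float = 0.05,
) -> EffectEstimate:
    """Recover beta and SE from a reported OR and its 95% CI lower limit.

    se = (ln OR - ln lower) / 1.96.  Only the lower limit enters the
    estimate; when the upper limit is supplied it is used for a symmetry
    consistency check (a warning if |ln upper + ln lower - 2 beta| exceeds
    ``asymmetry_warn``), catching transcription errors in reported CIs.
    """
    if or_value <= 0 or ci_lower <= 0:
        raise ValidationError(f"{study_id}: OR and CI limits must be positive")
    if ci_lower > or_value:
        raise ValidationError(f"{study_id}: ci_lower exceeds the odds ratio")
    if ci_lower == or_value:
        raise ValidationError(f"{study_id}: degenerate CI (lower equals OR)")
    beta = math.log(or_value)
    se = (beta - math.log(ci_lower)) / Z_95
    if ci_upper is not None:
        gap = abs(math.log(ci_upper) + math.log(ci_lower) - 2 * beta)
        if gap > asymmetry_warn:
            warnings.warn(
                f"{study_id or 'estimate'}: reported CI asymmetric on the log "
                f"scale (|ln U + ln L - 2 beta| = {gap:.4f})",
                stacklevel=2,
            )
    return EffectEstimate(
        study_id=study_id,
        beta=beta,
        se=se,
        source=EffectSource.REPORTED_CI,
        snp=snp,
        nos_stars=nos_stars,
    )


@dataclass(frozen=True)
class HweResult:
    p_value: float
    chi2: float
    monomorphic: bool
    method: str


def hwe_test(control_counts: GenotypeTriple, method: str = "chi2") -> HweResult:
    """Hardy-Weinberg deviation test in controls.

    ``method="chi2"`` is a 1-df goodness-of-fit chi-square against the
    expected p^2 / 2pq / q^2 proportions at the observed allele frequency.
    ``method="exact"`` enumerates the conditional distribution of
    heterozygote counts given the allele counts (preferable for small or
    sparse tables).  Monomorphic controls return p = 1 with a flag.
    """
    n_ee, n_eo, n_oo = control_counts
    n = n_ee + n_eo + n_oo
    if n <= 0:
        raise ValidationError("control arm total must be > 0")
    n_e = 2 * n_ee + n_eo
    if n_e == 0 or n_e == 2 * n:
        return HweResult(p_value=1.0, chi2=0.0, monomorphic=True, method=method)
    if method == "chi2":
        p = n_e / (2 * n)
        q = 1.0 - p
        expected = (n * p * p, 2 * n * p * q, n * q * q)
        chi2 = sum(
            (obs - exp) ** 2 / exp
            for obs, exp in zip((n_ee, n_eo, n_oo), expected)
        )
        return HweResult(
            p_value=float(stats.chi2.sf(chi2, df=1)),
            chi2=float(chi2),
            monomorphic=False,
            method="chi2",
        )
    if method == "exact":
        return HweResult(
            p_value=_hwe_exact_p(n_ee, n_eo, n_oo),
            chi2=float("nan"),
            monomorphic=False,
            method="exact",
        )
    raise ValueError(f"unknown HWE test method {method!r}")


def _hwe_exact_p(n_ee: int, n_eo: int, n_oo: int) -> float:
    """Exact HWE p: sum of conditional probabilities <= the observed one.

    Enumerates P(n_het | allele counts) over all heterozygote counts of the
    right parity, in log space for numerical stability.
    """
    n = n_ee + n_eo + n_oo
    n_e = 2 * n_ee + n_eo
    rare = min(n_e, 2 * n - n_e)

    def log_prob(het: int) -> float:
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        return (
            math.lgamma(n + 1)
            - math.lgamma(hom_rare + 1)
            - math.lgamma(het + 1)
            - math.lgamma(hom_common + 1)
            + het * math.log(2)
            + math.lgamma(rare + 1)
            + math.lgamma(2 * n - rare + 1)
            - math.lgamma(2 * n + 1)
        )

    hets = range(rare % 2, rare + 1, 2)
    log_ps = {h: log_prob(h) for h in hets}
    m = max(log_ps.values())
    total = sum(math.exp(lp - m) for lp in log_ps.values())
    observed = log_ps[n_eo]
    # <= with a relative tolerance so the observed outcome always counts
    tail = sum(
        math.exp(lp - m)
        for lp in log_ps.values()
        if lp <= observed + 1e-12
    )
    return min(1.0, tail / total)


def quality_gate(e: EffectEstimate, rule: QualityRule = QualityRule()) -> EffectEstimate:
    """Attach high-risk-NOS and HWE-deviation flags; never removes a study.

    ``high_risk_nos`` is true when nos_stars <= nos_fail_max (inclusive);
    ``hwe_deviation`` when hwe_p < hwe_alpha.  Flags stay ``None`` when the
    underlying datum is absent.  Removal happens only in the meta-analysis
    sensitivity step.
    """
    high_risk = None if e.nos_stars is None else (e.nos_stars <= rule.nos_fail_max)
    hwe_dev = None if e.hwe_p is None else (e.hwe_p < rule.hwe_alpha)
    return replace(e, high_risk_nos=high_risk, hwe_deviation=hwe_dev)


def effect_from_genotype_counts(
    g: GenotypeCounts,
    correction: str = "haldane",
    hwe_method: str = "chi2",
    rule: QualityRule = QualityRule(),
    nos_stars: Optional[int] = None,
) -> EffectEstimate:
    """Counts -> allele table -> OR, with the control HWE p attached and gated."""
    table = alleles_from_genotypes(g)
    est = or_from_table(table, correction=correction, study_id=g.study_id, snp=g.snp)
    hwe = hwe_test(g.control_counts, method=hwe_method)
    est = replace(est, hwe_p=hwe.p_value, nos_stars=nos_stars)
    return quality_gate(est, rule)


# ---------------------------------------------------------------------------
# File loaders


def read_genotype_counts(path: Union[str, Path]) -> List[GenotypeCounts]:
    """CSV loader: columns study_id, snp, arm (case|control), n_EE, n_EO, n_OO."""
    df = pd.read_csv(path)
    required = {"study_id", "snp", "arm", "n_EE", "n_EO", "n_OO"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"genotype counts file missing columns: {sorted(missing)}")
    out: List[GenotypeCounts] = []
    for (study_id, snp), grp in df.groupby(["study_id", "snp"], sort=True):
        arms: Dict[str, GenotypeTriple] = {}
        for _, row in grp.iterrows():
            arms[str(row["arm"]).strip().lower()] = (
                int(row["n_EE"]),
                int(row["n_EO"]),
                int(row["n_OO"]),
            )
        if "case" not in arms or "control" not in arms:
            raise ValidationError(
                f"{study_id}/{snp}: both case and control arms are required"
            )
        out.append(
            GenotypeCounts(
                study_id=str(study_id),
                snp=str(snp),
                case_counts=arms["case"],
                control_counts=arms["control"],
            )
        )
    return out


def read_reported_effects(path: Union[str, Path]) -> List[EffectEstimate]:
    """CSV loader: columns study_id, snp, or, ci_lower, ci_upper[, nos_stars]."""
    df = pd.read_csv(path)
    required = {"study_id", "snp", "or", "ci_lower"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"reported effects file missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        nos = row.get("nos_stars")
        ci_upper = row.get("ci_upper")
        out.append(
            se_from_ci(
                or_value=float(row["or"]),
                ci_lower=float(row["ci_lower"]),
                ci_upper=None if pd.isna(ci_upper) else float(ci_upper),
                study_id=str(row["study_id"]),
                snp=str(row["snp"]),
                nos_stars=None if nos is None or pd.isna(nos) else int(nos),
            )
        )
    return out


def dedupe_one_record_per_study(
    estimates: Sequence[EffectEstimate],
) -> List[EffectEstimate]:
    """Enforce one estimate per (study, SNP), preferring reported (adjusted) CIs.

    Adjusted estimates enter via reported CIs; when both a counts-based and a
    reported estimate exist for the same study and SNP, the reported one wins
    so that the two never co-enter a pool.
    """
    best: Dict[Tuple[str, Optional[str]], EffectEstimate] = {}
    for e in estimates:
        key = (e.study_id, e.snp)
        prev = best.get(key)
        if prev is None:
            best[key] = e
        elif (
            prev.source is EffectSource.COUNTS
            and e.source is EffectSource.REPORTED_CI
        ):
            best[key] = e
    return list(best.values())
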