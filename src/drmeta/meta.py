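"""Random-effects meta-analysis with heterogeneity and sensitivity diagnostics.

The pooling model is the DerSimonian-Laird moment estimator, the
random-effects default of RevMan: fixed-effect inverse-variance weights give
Cochran's Q, the between-study variance tau^2 is estimated as
max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) and the pooled log-OR is the
tau^2-damped weighted mean.  Confidence intervals use the normal 1.96
quantile (no Hartung-Knapp adjustment), I^2 = max(0, (Q - (k-1))/Q) * 100,
and summary significance is a strict p < 0.05 with no multiple-testing
correction.  Publication-bias assessment is visual only: funnel coordinates
and pseudo-95% guide lines are emitted, never an asymmetry statistic.
"""

from __future__ import annotations

import math
import warnings
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    EffectEstimate,
    MetaResult,
    QualityRule,
    SensitivityResult,
    ValidationError,
)

Z_95 = 1.96
ALPHA_SUMMARY = 0.05  # strict "<" summary significance
I2_LOW_CUTOFF = 50.0  # I2 strictly below this is "low" heterogeneity


def fixed_effect(
    estimates: Sequence[EffectEstimate],
) -> Tuple[float, float, float]:
    """Inverse-variance fixed-effect pool: (beta_fixed, se_fixed, Q).

    w_i = 1/se_i^2; beta = sum(w b)/sum(w); se = 1/sqrt(sum w);
    Q = sum w (b - beta)^2.
    """
    k = len(estimates)
    if k < 2:
        raise ValidationError(f"meta-analysis requires k >= 2 studies, got {k}")
    beta = np.array([e.beta for e in estimates], dtype=float)
    w = np.array([1.0 / e.se**2 for e in estimates], dtype=float)
    sw = w.sum()
    beta_fixed = float((w * beta).sum() / sw)
    se_fixed = float(1.0 / math.sqrt(sw))
    q = float((w * (beta - beta_fixed) ** 2).sum())
    return beta_fixed, se_fixed, q


def dersimonian_laird(estimates: Sequence[EffectEstimate]) -> MetaResult:
    """DerSimonian-Laird random-effects pool of per-study log odds ratios."""
    beta_fixed, se_fixed, q = fixed_effect(estimates)
    k = len(estimates)
    beta = np.array([e.beta for e in estimates], dtype=float)
    w = np.array([1.0 / e.se**2 for e in estimates], dtype=float)
    sw = w.sum()
    denom = sw - (w**2).sum() / sw
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (np.array([e.se**2 for e in estimates]) + tau2)
    sws = w_star.sum()
    beta_random = float((w_star * beta).sum() / sws)
    se_random = float(1.0 / math.sqrt(sws))
    i2 = 0.0 if q <= 0 else max(0.0, (q - (k - 1)) / q) * 100.0
    z = beta_random / se_random
    p_summary = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult(
        k=k,
        beta_fixed=beta_fixed,
        se_fixed=se_fixed,
        q_stat=q,
        tau2=tau2,
        beta_random=beta_random,
        se_random=se_random,
        or_random=math.exp(beta_random),
        ci_random=(
            math.exp(beta_random - Z_95 * se_random),
            math.exp(beta_random + Z_95 * se_random),
        ),
        i2=i2,
        z=float(z),
        p_summary=p_summary,
    )


def classify_heterogeneity(result: MetaResult) -> str:
    """``"low"`` iff I^2 is strictly below 50%, else ``"high"``."""
    return "low" if result.i2 < I2_LOW_CUTOFF else "high"


def is_significant(result: MetaResult, alpha: float = ALPHA_SUMMARY) -> bool:
    return result.p_summary < alpha


def leave_one_out(
    estimates: Sequence[EffectEstimate],
    rule: QualityRule = QualityRule(),
    restrict_to_flagged: bool = False,
) -> List[SensitivityResult]:
    """Re-pool after omitting each study in turn.

    ``significance_flipped`` marks omissions that move the summary p across
    0.05 in either direction.  With ``restrict_to_flagged`` only studies
    flagged high-risk (NOS <= threshold) or HWE-deviating are omitted —
    the protocol's targeted sensitivity analysis.  k = 2 inputs return an
    empty list with a warning, since omission would leave a single study.
    """
    k = len(estimates)
    if k < 2:
        raise ValidationError("sensitivity analysis requires k >= 2 studies")
    if k == 2:
        warnings.warn(
            "k = 2: leave-one-out omission would leave a single study; "
            "returning no sensitivity results",
            stacklevel=2,
        )
        return []
    parent = dersimonian_laird(estimates)
    parent_sig = is_significant(parent)
    results = []
    for i, omitted in enumerate(estimates):
        if restrict_to_flagged and not (
            omitted.high_risk_nos or omitted.hwe_deviation
        ):
            continue
        rest = [e for j, e in enumerate(estimates) if j != i]
        sub = dersimonian_laird(rest)
        results.append(
            SensitivityResult(
                omitted_study_id=omitted.study_id,
                result_without=sub,
                significance_flipped=parent_sig != is_significant(sub),
            )
        )
    return results


def funnel_data(
    estimates: Sequence[EffectEstimate],
    result: Optional[MetaResult] = None,
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Plot-ready funnel coordinates plus pseudo-95% guide-line parameters.

    Returns per-study rows (study_id, beta, se) and the guide geometry: at
    each se the guides run beta_random +/- 1.96 * se, from se = 0 down to the
    largest observed se.  No asymmetry statistic is computed; assessment is
    visual.
    """
    if len(estimates) < 2:
        raise ValidationError("funnel data requires k >= 2 studies")
    if result is None:
        result = dersimonian_laird(estimates)
    rows = pd.DataFrame(
        {
            "study_id": [e.study_id for e in estimates],
            "beta": [e.beta for e in estimates],
            "se": [e.se for e in estimates],
        }
    )
    guides = {
        "center_beta": result.beta_random,
        "se_max": float(max(e.se for e in estimates)),
        "halfwidth_at_se_max": Z_95 * float(max(e.se for e in estimates)),
        "z": Z_95,
    }
    return rows, guides


def meta_table(results: Mapping[str, MetaResult]) -> pd.DataFrame:
    """Summary table: one row per SNP with pooled OR, CI, p, I^2 and flags.

    ORs and CIs are rounded to 2 decimals for display (stored results keep
    full precision); significance is strict p < 0.05.
    """
    rows = []
    for snp, r in results.items():
        rows.append(
            {
                "snp": snp,
                "k": r.k,
                "or": round(r.or_random, 2),
                "ci_lower": round(r.ci_random[0], 2),
                "ci_upper": round(r.ci_random[1], 2),
                "p": float(f"{r.p_summary:.3g}"),
                "i2": round(r.i2, 1),
                "heterogeneity": classify_heterogeneity(r),
                "significant": is_significant(r),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "snp",
            "k",
            "or",
            "ci_lower",
            "ci_upper",
            "p",
            "i2",
            "heterogeneity",
            "significant",
        ],
    )
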