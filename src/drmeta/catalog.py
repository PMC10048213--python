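"""Signal-catalog ingestion, validation, and significance tiering.

Reads GWAS signal tables (TSV) through a column-mapping *dialect*, validates
every row into a :class:`~drmeta.types.Signal`, and collects rows that fail
validation into a rejects report instead of dropping them silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

from .types import (
    BackgroundDisease,
    GwasStudy,
    PhenotypeGroup,
    Signal,
    SignificanceTier,
    ValidationError,
    normalize_chrom,
)

#: Canonical column names used by the package's own TSV output.
CANONICAL_DIALECT: Dict[str, str] = {
    "study_id": "study_id",
    "rsid": "rsid",
    "chrom": "chrom",
    "pos": "pos",
    "p_value": "p_value",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "odds_ratio": "odds_ratio",
    "ci_lower": "ci_lower",
    "ci_upper": "ci_upper",
    "locus": "locus",
    "phenotype_group": "phenotype_group",
}

#: Column names as exported by the GWAS Catalog association download.
GWAS_CATALOG_DIALECT: Dict[str, str] = {
    "study_id": "STUDY ACCESSION",
    "rsid": "SNPS",
    "chrom": "CHR_ID",
    "pos": "CHR_POS",
    "p_value": "P-VALUE",
    "odds_ratio": "OR or BETA",
    "ci_lower": "95% CI (TEXT)",
    "locus": "MAPPED_GENE",
    "phenotype_group": "DISEASE/TRAIT",
}

DIALECTS: Dict[str, Dict[str, str]] = {
    "canonical": CANONICAL_DIALECT,
    "gwas_catalog": GWAS_CATALOG_DIALECT,
}

MANDATORY_FIELDS = ("study_id", "rsid", "chrom", "pos", "p_value")

#: Default mapping from free-text trait labels to the three phenotype strata.
#: Severe/sight-threatening retinopathy folds into the PDR stratum and
#: maculopathy into the DME stratum; everything else is plain DR.
DEFAULT_TRAIT_MAP: Dict[str, PhenotypeGroup] = {
    "dr": PhenotypeGroup.DR,
    "diabetic retinopathy": PhenotypeGroup.DR,
    "npdr": PhenotypeGroup.DR,
    "pdr": PhenotypeGroup.PDR_SIGHT_THREATENING,
    "proliferative diabetic retinopathy": PhenotypeGroup.PDR_SIGHT_THREATENING,
    "severe dr": PhenotypeGroup.PDR_SIGHT_THREATENING,
    "sight-threatening dr": PhenotypeGroup.PDR_SIGHT_THREATENING,
    "severe diabetic retinopathy": PhenotypeGroup.PDR_SIGHT_THREATENING,
    "dme": PhenotypeGroup.DME_MACULOPATHY,
    "diabetic macular edema": PhenotypeGroup.DME_MACULOPATHY,
    "diabetic maculopathy": PhenotypeGroup.DME_MACULOPATHY,
    "pdr_sight_threatening": PhenotypeGroup.PDR_SIGHT_THREATENING,
    "dme_maculopathy": PhenotypeGroup.DME_MACULOPATHY,
}


class ConfigurationError(ValueError):
    """The file cannot be read with the given dialect (e.g. missing column)."""


@dataclass(frozen=True)
class RejectedRow:
    """One input row that failed validation, with its 1-based row number."""

    row_number: int
    reason: str
    raw: Mapping[str, object] = field(default_factory=dict)


@dataclass
class CatalogReadResult:
    signals: List[Signal]
    studies: List[GwasStudy]
    rejects: List[RejectedRow]


def resolve_phenotype_group(trait: object) -> PhenotypeGroup:
    key = str(trait).strip().lower()
    if key in DEFAULT_TRAIT_MAP:
        return DEFAULT_TRAIT_MAP[key]
    if "maculopathy" in key or "macular" in key:
        return PhenotypeGroup.DME_MACULOPATHY
    if "proliferative" in key or "severe" in key or "sight" in key:
        return PhenotypeGroup.PDR_SIGHT_THREATENING
    return PhenotypeGroup.DR


def _opt_float(value: object) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s == "" or s.lower() in {"na", "nan", "none", "nr"}:
        return None
    return float(s)


def read_signal_catalog(
    path: Union[str, Path],
    dialect: Union[str, Mapping[str, str]] = "canonical",
    studies: Optional[Sequence[GwasStudy]] = None,
) -> CatalogReadResult:
    """Read a TSV signal table into validated :class:`Signal` records.

    Parameters
    ----------
    path:
        TSV file with one row per reported SNP-trait association.
    dialect:
        Either the name of a shipped dialect (``"canonical"``,
        ``"gwas_catalog"``) or a mapping from canonical field names to the
        file's column names.  ``study_id``, ``rsid``, ``chrom``, ``pos`` and
        ``p_value`` must be resolvable.
    studies:
        Optional pre-built study records; otherwise minimal ``GwasStudy``
        stubs are derived from the distinct study ids seen.

    Returns
    -------
    CatalogReadResult
        Validated signals, study records, and per-row rejects with reasons.
        Accepted rows plus rejected rows always partition the input rows.
    """
    if isinstance(dialect, str):
        try:
            dialect = DIALECTS[dialect]
        except KeyError as exc:
            raise ConfigurationError(f"unknown dialect {dialect!r}") from exc

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    for fld in MANDATORY_FIELDS:
        col = dialect.get(fld)
        if col is None:
            raise ConfigurationError(f"dialect does not map mandatory field {fld!r}")
        if col not in df.columns:
            raise ConfigurationError(
                f"mandatory column {col!r} (field {fld!r}) missing from {path.name}"
            )

    signals: List[Signal] = []
    rejects: List[RejectedRow] = []
    for idx, row in enumerate(df.to_dict(orient="records"), start=1):
        def get(fieldname: str) -> object:
            col = dialect.get(fieldname)
            return row.get(col) if col is not None else None

        try:
            p_raw = get("p_value")
            try:
                p_value = float(str(p_raw).strip())
            except (TypeError, ValueError):
                raise ValidationError(f"unparseable p-value {p_raw!r}")
            pos_raw = get("pos")
            try:
                pos = int(str(pos_raw).strip())
            except (TypeError, ValueError):
                raise ValidationError(f"unparseable position {pos_raw!r}")
            chrom_raw = str(get("chrom"))
            locus = get("locus")
            signal = Signal(
                rsid=str(get("rsid")).strip(),
                chrom=normalize_chrom(chrom_raw),
                chrom_original=chrom_raw,
                pos=pos,
                p_value=p_value,
                study_id=str(get("study_id")).strip(),
                phenotype_group=resolve_phenotype_group(get("phenotype_group") or "DR"),
                effect_allele=(str(get("effect_allele")).strip() or None)
                if get("effect_allele") is not None
                else None,
                other_allele=(str(get("other_allele")).strip() or None)
                if get("other_allele") is not None
                else None,
                odds_ratio=_opt_float(get("odds_ratio")),
                ci_lower=_opt_float(get("ci_lower")),
                ci_upper=_opt_float(get("ci_upper")),
                locus=(str(locus).strip() or None) if locus is not None else None,
            )
        except (ValidationError, ValueError) as exc:
            rejects.append(RejectedRow(row_number=idx, reason=str(exc), raw=row))
            continue
        signals.append(signal)

    if studies is None:
        seen = sorted({s.study_id for s in signals})
        studies = [GwasStudy(study_id=sid) for sid in seen]
    return CatalogReadResult(signals=signals, studies=list(studies), rejects=rejects)


def write_signal_catalog(signals: Iterable[Signal], path: Union[str, Path]) -> None:
    """Write signals as a canonical-dialect TSV (round-trips with the reader)."""
    rows = []
    for s in signals:
        rows.append(
            {
                "study_id": s.study_id,
                "rsid": s.rsid,
                "chrom": s.chrom,
                "pos": s.pos,
                "p_value": repr(s.p_value),
                "effect_allele": s.effect_allele or "",
                "other_allele": s.other_allele or "",
                "odds_ratio": "" if s.odds_ratio is None else repr(s.odds_ratio),
                "ci_lower": "" if s.ci_lower is None else repr(s.ci_lower),
                "ci_upper": "" if s.ci_upper is None else repr(s.ci_upper),
                "locus": s.locus or "",
                "phenotype_group": s.phenotype_group.value,
            }
        )
    pd.DataFrame(rows, columns=list(CANONICAL_DIALECT)).to_csv(
        path, sep="\t", index=False
    )


def write_rejects_report(rejects: Sequence[RejectedRow], path: Union[str, Path]) -> None:
    pd.DataFrame(
        [{"row_number": r.row_number, "reason": r.reason} for r in rejects],
        columns=["row_number", "reason"],
    ).to_csv(path, sep="\t", index=False)


def filter_by_tier(
    signals: Sequence[Signal],
    tier: SignificanceTier = SignificanceTier(),
    level: str = "genome_wide",
) -> List[Signal]:
    """Signals with p strictly below the selected threshold, order preserved.

    ``level`` is ``"genome_wide"`` (default gate 1e-7) or ``"suggestive"``
    (default 5e-5).  Boundary equality is excluded.
    """
    if level == "genome_wide":
        threshold = tier.genome_wide_threshold
    elif level == "suggestive":
        threshold = tier.suggestive_threshold
    else:
        raise ValueError(f"unknown tier level {level!r}")
    return [s for s in signals if s.p_value < threshold]


def count_distinct_loci(
    signals: Sequence[Signal], locus_labels: Mapping[str, str]
) -> int:
    """Number of distinct gene-locus labels among the signals.

    Every rsid must be present in ``locus_labels``; missing ids raise a
    ``KeyError`` listing all of them.
    """
    missing = sorted({s.rsid for s in signals if s.rsid not in locus_labels})
    if missing:
        raise KeyError(f"no locus label for rsids: {', '.join(missing)}")
    return len({locus_labels[s.rsid] for s in signals})


def exclude_population_control_studies(
    signals: Sequence[Signal], studies: Sequence[GwasStudy]
) -> List[Signal]:
    """Drop signals from studies that used nondiabetic population controls.

    Such studies stay in the catalog but are excluded from overlap and
    meta-analysis by default (override by simply not calling this filter).
    """
    excluded = {s.study_id for s in studies if s.uses_population_controls}
    return [s for s in signals if s.study_id not in excluded]
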