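"""LD-proxy selection and local functional-annotation joining.

Proxies are SNPs in high linkage disequilibrium with an index SNP, gated
conjunctively and inclusively: D' >= 0.8 AND r^2 >= 0.8.  Annotation values
(SIFT, PolyPhen, CADD, RegulomeDB rank, eQTL gene/p) are inputs read from
local tables, never computed or fetched from a web service.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from .types import AnnotationRecord, LdRecord, ValidationError, normalize_rsid

D_PRIME_MIN = 0.8
R2_MIN = 0.8


def select_proxies(
    index_rsid: str,
    ld: Sequence[LdRecord],
    d_min: float = D_PRIME_MIN,
    r2_min: float = R2_MIN,
) -> List[str]:
    """SNPs with D' >= d_min AND r^2 >= r2_min relative to the index.

    LD records are treated as symmetric; the index itself is never returned.
    An index absent from the table yields an empty list with a warning.
    Raising either threshold can only shrink the result (monotonicity).
    """
    idx = normalize_rsid(index_rsid)
    selected: Dict[str, str] = {}  # normalized -> original casing
    seen_index = False
    for rec in ld:
        a, b = normalize_rsid(rec.rsid_a), normalize_rsid(rec.rsid_b)
        if idx == a:
            other, raw = b, rec.rsid_b
        elif idx == b:
            other, raw = a, rec.rsid_a
        else:
            continue
        seen_index = True
        if other == idx:
            continue
        if rec.d_prime >= d_min and rec.r2 >= r2_min:
            selected[other] = str(raw).strip()
    if not seen_index:
        warnings.warn(
            f"index SNP {index_rsid} absent from the LD table", stacklevel=2
        )
        return []
    return sorted(selected.values())


def read_ld_table(path: Union[str, Path]) -> List[LdRecord]:
    """PLINK-.ld-style TSV loader: columns SNP_A, SNP_B, R2 plus DP (D')."""
    df = pd.read_csv(path, sep="\t")
    required = {"SNP_A", "SNP_B", "R2", "DP"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"LD table missing columns: {sorted(missing)}")
    pop_col = "POP" if "POP" in df.columns else None
    return [
        LdRecord(
            rsid_a=str(row["SNP_A"]),
            rsid_b=str(row["SNP_B"]),
            d_prime=float(row["DP"]),
            r2=float(row["R2"]),
            population=str(row[pop_col]) if pop_col else "",
        )
        for _, row in df.iterrows()
    ]


ANNOTATION_COLUMNS = [
    "rsid",
    "location_class",
    "nearest_gene",
    "sift",
    "polyphen",
    "cadd",
    "regulomedb_rank",
    "eqtl_gene",
    "eqtl_p",
    "unannotated",
]


def _parse_optional(value: object) -> Optional[float]:
    s = str(value).strip().lower()
    if s in {"", "na", "nan", "none"}:
        return None
    return float(s)


def read_annotation_table(path: Union[str, Path]) -> List[AnnotationRecord]:
    """TSV loader for local annotation tables (one row per SNP)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "rsid" not in df.columns:
        raise ValidationError("annotation table must have an 'rsid' column")
    records = []
    for _, row in df.iterrows():
        records.append(
            AnnotationRecord(
                rsid=str(row["rsid"]).strip(),
                location_class=str(row.get("location_class", "other")).strip()
                or "other",
                nearest_gene=str(row.get("nearest_gene", "")).strip(),
                sift=_parse_optional(row.get("sift", "na")),
                polyphen=_parse_optional(row.get("polyphen", "na")),
                cadd=_parse_optional(row.get("cadd", "na")),
                regulomedb_rank=str(row.get("regulomedb_rank", "")).strip(),
                eqtl_gene=(str(row.get("eqtl_gene", "")).strip() or None),
                eqtl_p=_parse_optional(row.get("eqtl_p", "na")),
            )
        )
    return records


def join_annotations(
    rsids: Sequence[str],
    table: Sequence[AnnotationRecord],
) -> pd.DataFrame:
    """Total left join: exactly one output row per input rsid.

    SNPs missing from the table get an all-"na" row with the ``unannotated``
    flag set, so the join never loses or invents rows.
    """
    by_rsid = {normalize_rsid(r.rsid): r for r in table}
    rows = []
    for rsid in rsids:
        rec = by_rsid.get(normalize_rsid(rsid))
        if rec is None:
            rows.append(
                {
                    "rsid": rsid,
                    "location_class": "na",
                    "nearest_gene": "na",
                    "sift": "na",
                    "polyphen": "na",
                    "cadd": "na",
                    "regulomedb_rank": "na",
                    "eqtl_gene": "na",
                    "eqtl_p": "na",
                    "unannotated": True,
                }
            )
        else:
            fmt = lambda v: "na" if v is None else v
            rows.append(
                {
                    "rsid": rsid,
                    "location_class": rec.location_class,
                    "nearest_gene": rec.nearest_gene or "na",
                    "sift": fmt(rec.sift),
                    "polyphen": fmt(rec.polyphen),
                    "cadd": fmt(rec.cadd),
                    "regulomedb_rank": rec.regulomedb_rank or "na",
                    "eqtl_gene": fmt(rec.eqtl_gene),
                    "eqtl_p": fmt(rec.eqtl_p),
                    "unannotated": False,
                }
            )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def annotate_index_snps(
    index_rsids: Sequence[str],
    ld: Sequence[LdRecord],
    table: Sequence[AnnotationRecord],
    d_min: float = D_PRIME_MIN,
    r2_min: float = R2_MIN,
) -> Dict[str, object]:
    """Per-index proxy counts plus the joined annotation report.

    The report covers each index SNP and all of its high-LD proxies;
    ``proxy_counts`` records how many high-LD SNPs back each index.
    """
    proxy_counts: Dict[str, int] = {}
    all_rsids: List[str] = []
    for idx in index_rsids:
        proxies = select_proxies(idx, ld, d_min=d_min, r2_min=r2_min)
        proxy_counts[idx] = len(proxies)
        all_rsids.append(idx)
        all_rsids.extend(proxies)
    report = join_annotations(all_rsids, table)
    return {"proxy_counts": proxy_counts, "report": report}
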