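"""Published headline GWAS signal lists and small local annotation fixtures.

These are the curated inputs the pipeline is exercised on: the genome-wide
significant SNPs reported for diabetic retinopathy (DR), proliferative
DR/sight-threatening DR (PDR), and diabetic macular edema/maculopathy (DME)
by published discovery GWASs, with their published p-values and gene loci.

Genomic positions: only three positions are carried over from published
annotation (rs4462262 chr10:59,189,178; rs7903146 chr10:114,758,349;
rs7074440 chr10:114,785,424).  All other positions are synthetic
placeholders, spaced far apart so they do not fabricate proximity — the
tiering and counting computations use only the p-values.

The DME list is known to contain 12 suggestive SNPs of which exactly one
(rs9966620, p = 7e-8) is genome-wide significant; only that p-value is
published, so the remaining 11 entries here are synthetic fillers with
p-values drawn in the suggestive band (1e-7, 5e-5).
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, List

from .annotate import AnnotationRecord, LdRecord, read_annotation_table, read_ld_table
from .types import PhenotypeGroup, Signal


def _sig(rsid, chrom, pos, p, study, group, locus):
    return Signal(
        rsid=rsid,
        chrom=chrom,
        pos=pos,
        p_value=p,
        study_id=study,
        phenotype_group=group,
        locus=locus,
    )


def dr_top_signals() -> List[Signal]:
    """The seven genome-wide significant DR signals (published p-values)."""
    g = PhenotypeGroup.DR
    return [
        _sig("rs17376456", "5", 102_300_000, 3.0e-15, "HUANG2011", g, "KIAA0825/C5orf36"),
        _sig("rs2038823", "13", 97_100_000, 5.0e-11, "HUANG2011", g, "HS6ST3"),
        _sig("rs12630354", "3", 31_600_000, 7.0e-10, "IMAMURA2021", g, "THRAP3P1-STT3B"),
        _sig("rs4838605", "10", 49_600_000, 2.0e-9, "HUANG2011", g, "ARHGAP22"),
        _sig("rs12219125", "10", 20_100_000, 9.0e-9, "HUANG2011", g, "AMD1P1-PLXDC2"),
        _sig("rs202069793", "9", 107_300_000, 6.0e-8, "POLLACK2018", g, "OR13D3P-OR13D1"),
        _sig("rs4462262", "10", 59_189_178, 9.0e-8, "HUANG2011", g, "ZWINT-MRPS35P3"),
    ]


def pdr_top_signals() -> List[Signal]:
    """The eight genome-wide significant PDR signals (published p-values)."""
    g = PhenotypeGroup.PDR_SIGHT_THREATENING
    return [
        _sig("rs3081219", "15", 53_900_000, 1.0e-9, "PDR_GWAS1", g, "WDR72"),
        _sig("rs3913535", "11", 89_300_000, 4.0e-9, "PDR_GWAS2", g, "NOX4"),
        _sig("rs11018670", "11", 49_200_000, 1.0e-8, "PDR_GWAS3", g, "FOLH1B"),
        _sig("rs72740408", "4", 26_700_000, 2.0e-8, "PDR_GWAS4", g, "HNRNPA1P46"),
        _sig("rs184340784", "21", 30_500_000, 4.0e-8, "PDR_GWAS5", g, "LINC01646"),
        _sig("rs1065386", "6", 31_300_000, 5.0e-8, "PDR_GWAS6", g, "HLA-B"),
        _sig("rs4726066", "7", 151_500_000, 5.0e-8, "PDR_GWAS2", g, "PRKAG2"),
        _sig("rs200295620", "3", 167_700_000, 7.0e-8, "PDR_GWAS5", g, "GOLIM4-EGFEM1P"),
    ]


def dme_signals(include_synthetic_fill: bool = True) -> List[Signal]:
    """The DME signal list: one published hit plus synthetic suggestive fillers.

    Only rs9966620 (p = 7e-8) reached genome-wide significance among the 12
    DME SNPs; the 11 fillers are synthetic stand-ins with suggestive-band
    p-values so the list has the documented shape (12 suggestive, 1
    genome-wide).
    """
    g = PhenotypeGroup.DME_MACULOPATHY
    signals = [_sig("rs9966620", "18", 41_200_000, 7.0e-8, "DME_GWAS1", g, "SCN4A-AS1")]
    if include_synthetic_fill:
        # synthetic: evenly spread across the suggestive band (1e-7, 5e-5)
        filler_p = [2e-7, 5e-7, 1e-6, 2e-6, 4e-6, 7e-6, 1e-5, 2e-5, 3e-5, 4e-5, 4.5e-5]
        for i, p in enumerate(filler_p, start=1):
            signals.append(
                _sig(
                    f"rs88000{i:02d}",
                    str(1 + (i % 20)),
                    10_000_000 + i * 5_000_000,
                    p,
                    "DME_GWAS1" if i % 2 else "DME_GWAS2",
                    g,
                    f"SYN_LOCUS_{i}",
                )
            )
    return signals


def headline_pooled_ors() -> Dict[str, float]:
    """Published pooled replication odds ratios for the confirmed DR SNPs."""
    return {"rs4462262": 1.38, "rs7903146": 1.30, "rs12219125": 1.24}


def annotation_table() -> List[AnnotationRecord]:
    """Published functional annotations for the two confirmed loci and the
    rs7074440 proxy (SIFT/PolyPhen unavailable for all three)."""
    with resources.as_file(
        resources.files("drmeta.data").joinpath("annotations.tsv")
    ) as path:
        return read_annotation_table(path)


def ld_table() -> List[LdRecord]:
    """European-population LD fixture around the confirmed loci.

    The rs7903146-rs7074440 (D' 0.95, r2 0.91) and rs7903146-rs34872471
    (r2 0.99) values are published; the remaining rows are synthetic filler
    pairs below or above the proxy thresholds for testing.
    """
    with resources.as_file(
        resources.files("drmeta.data").joinpath("ld_eur_synthetic.tsv")
    ) as path:
        return read_ld_table(path)
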