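"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The cohort generator emulates case-control allelic replication studies: a
per-study log odds ratio is drawn around ln(true OR) with between-study SD
tau, the case-arm effect-allele frequency is derived from the control
frequency by exact inversion of the allelic odds ratio,

    p_case = OR * p / (1 + p * (OR - 1)),

and genotypes in each arm are multinomial draws from Hardy-Weinberg
proportions at the arm frequency.  The simulated estimand is therefore the
allelic OR itself — not a logistic-model approximation — matching the
analysis model downstream.  Cohorts are independent; no within-locus LD
structure is simulated.

The catalog generator plants identical and proximal cross-study clusters at
known positions, with background signals laid out so they can never collide
into accidental clusters, and emits the ground truth alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .catalog import write_signal_catalog
from .types import (
    GenotypeCounts,
    PhenotypeGroup,
    Signal,
    SimSpec,
    ValidationError,
)


def case_frequency(true_or: float, control_freq: float) -> float:
    """Exact case-arm effect-allele frequency implied by an allelic OR.

    Inverts OR = [q/(1-q)] / [p/(1-p)]: q = OR*p / (1 + p*(OR-1)).
    """
    q = true_or * control_freq / (1.0 + control_freq * (true_or - 1.0))
    if not (0.0 < q < 1.0):
        raise ValidationError(
            f"derived case frequency {q} outside (0,1) for OR={true_or}, "
            f"p={control_freq}"
        )
    return q


def _genotype_probs(freq: float, inbreeding_f: float = 0.0) -> np.ndarray:
    """HWE genotype probabilities (EE, EO, OO), optionally F-distorted.

    With inbreeding coefficient F the heterozygote deficit model applies:
    P(EE) = p^2 + F p q, P(EO) = 2 p q (1 - F), P(OO) = q^2 + F p q.
    """
    p, q = freq, 1.0 - freq
    return np.array(
        [
            p * p + inbreeding_f * p * q,
            2.0 * p * q * (1.0 - inbreeding_f),
            q * q + inbreeding_f * p * q,
        ]
    )


def simulate_study(
    spec: SimSpec,
    rng: Optional[np.random.Generator] = None,
    study_id: str = "SIM1",
    snp: str = "rs0",
) -> GenotypeCounts:
    """One synthetic replication cohort as case/control genotype triples.

    The study-level log-OR is ln(true_or) + Normal(0, tau^2); controls are
    drawn from HWE at control_maf (or the F-distorted proportions when
    hwe_in_controls is False); cases from HWE at the derived case frequency.
    Bit-reproducible for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    study_or = math.exp(math.log(spec.true_or) + rng.normal(0.0, spec.tau))
    p_case = case_frequency(study_or, spec.control_maf)
    f = 0.0 if spec.hwe_in_controls else spec.inbreeding_f
    control = rng.multinomial(spec.n_control, _genotype_probs(spec.control_maf, f))
    case = rng.multinomial(spec.n_case, _genotype_probs(p_case))
    return GenotypeCounts(
        study_id=study_id,
        snp=snp,
        case_counts=tuple(int(x) for x in case),
        control_counts=tuple(int(x) for x in control),
    )


def simulate_meta(
    spec: SimSpec,
    rng: Optional[np.random.Generator] = None,
    snp: str = "rs0",
) -> List[GenotypeCounts]:
    """k independent cohorts sharing true_or and tau.

    Per-cohort arm sizes are jittered uniformly by +/-20% unless
    ``spec.jitter_sizes`` is False.
    """
    if spec.k_studies < 2:
        raise ValidationError("simulate_meta requires k_studies >= 2")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    cohorts = []
    for i in range(spec.k_studies):
        if spec.jitter_sizes:
            jc = rng.uniform(0.8, 1.2)
            jn = rng.uniform(0.8, 1.2)
            n_case = max(1, int(round(spec.n_case * jc)))
            n_control = max(1, int(round(spec.n_control * jn)))
        else:
            n_case, n_control = spec.n_case, spec.n_control
        sub = replace(spec, n_case=n_case, n_control=n_control)
        cohorts.append(
            simulate_study(sub, rng=rng, study_id=f"SIM{i + 1}", snp=snp)
        )
    return cohorts


@dataclass(frozen=True)
class PlantedCluster:
    kind: str  # "identical" | "proximal"
    rsids: Tuple[str, ...]
    chrom: str
    positions: Tuple[int, ...]
    studies: Tuple[str, ...]


@dataclass
class SyntheticCatalog:
    signals: List[Signal]
    truth: List[PlantedCluster]


_CHROMS = [str(c) for c in range(1, 23)]


def simulate_catalog(
    n_studies: int = 4,
    n_signals: int = 50,
    planted_identical: int = 0,
    planted_proximal: int = 0,
    window: int = 100_000,
    seed: int = 0,
    phenotype_group: PhenotypeGroup = PhenotypeGroup.DR,
    proximal_distance: Optional[int] = None,
    out_path: Optional[Union[str, Path]] = None,
) -> SyntheticCatalog:
    """Random signal catalog with planted cross-study overlap clusters.

    Background signals are placed on a per-chromosome grid with spacing
    greater than twice the window, each from a single study, so they can
    never form a cluster by accident; planted clusters occupy reserved slots
    on that grid.  ``proximal_distance`` (default: the window itself, the
    inclusive boundary) is the separation of planted proximal pairs.  The
    ground-truth cluster list is returned (and written as TSV next to
    ``out_path`` when given).
    """
    if planted_identical + planted_proximal > n_signals:
        raise ValidationError("planted clusters cannot exceed n_signals")
    if n_studies < 2 and (planted_identical or planted_proximal):
        raise ValidationError("planted overlaps need >= 2 studies")
    rng = np.random.default_rng(seed)
    studies = [f"GWAS{i + 1}" for i in range(n_studies)]
    spacing = 2 * window + 100_000
    # pre-compute grid slots: (chrom, base position)
    slots = [
        (chrom, 1_000_000 + k * spacing) for chrom in _CHROMS for k in range(60)
    ]
    rng.shuffle(slots)
    signals: List[Signal] = []
    truth: List[PlantedCluster] = []
    serial = 0

    def new_rsid() -> str:
        nonlocal serial
        serial += 1
        return f"rs{900000 + serial}"

    def random_p() -> float:
        return float(10.0 ** rng.uniform(-12, -5))

    slot_iter = iter(slots)
    for _ in range(planted_identical):
        chrom, pos = next(slot_iter)
        rsid = new_rsid()
        pair = rng.choice(n_studies, size=2, replace=False)
        chosen = [studies[i] for i in pair]
        for sid in chosen:
            signals.append(
                Signal(
                    rsid=rsid,
                    chrom=chrom,
                    pos=pos,
                    p_value=random_p(),
                    study_id=sid,
                    phenotype_group=phenotype_group,
                )
            )
        truth.append(
            PlantedCluster(
                kind="identical",
                rsids=(rsid,),
                chrom=chrom,
                positions=(pos, pos),
                studies=tuple(chosen),
            )
        )
    dist = window if proximal_distance is None else proximal_distance
    for _ in range(planted_proximal):
        chrom, pos = next(slot_iter)
        rs1, rs2 = new_rsid(), new_rsid()
        pair = rng.choice(n_studies, size=2, replace=False)
        chosen = [studies[i] for i in pair]
        for rsid, sid, p in ((rs1, chosen[0], pos), (rs2, chosen[1], pos + dist)):
            signals.append(
                Signal(
                    rsid=rsid,
                    chrom=chrom,
                    pos=p,
                    p_value=random_p(),
                    study_id=sid,
                    phenotype_group=phenotype_group,
                )
            )
        truth.append(
            PlantedCluster(
                kind="proximal",
                rsids=(rs1, rs2),
                chrom=chrom,
                positions=(pos, pos + dist),
                studies=tuple(chosen),
            )
        )
    n_background = n_signals - planted_identical - planted_proximal
    for _ in range(n_background):
        chrom, pos = next(slot_iter)
        signals.append(
            Signal(
                rsid=new_rsid(),
                chrom=chrom,
                pos=pos,
                p_value=random_p(),
                study_id=studies[int(rng.integers(n_studies))],
                phenotype_group=phenotype_group,
            )
        )

    catalog = SyntheticCatalog(signals=signals, truth=truth)
    if out_path is not None:
        out_path = Path(out_path)
        write_signal_catalog(signals, out_path)
        truth_rows = [
            {
                "kind": t.kind,
                "chrom": t.chrom,
                "rsids": ",".join(t.rsids),
                "positions": ",".join(map(str, t.positions)),
                "studies": ",".join(t.studies),
            }
            for t in truth
        ]
        pd.DataFrame(
            truth_rows, columns=["kind", "chrom", "rsids", "positions", "studies"]
        ).to_csv(out_path.with_suffix(".truth.tsv"), sep="\t", index=False)
    return catalog


def counts_to_frame(cohorts: Sequence[GenotypeCounts]) -> pd.DataFrame:
    """Genotype counts in the pipeline's CSV layout (one row per arm)."""
    rows = []
    for g in cohorts:
        for arm, triple in (("case", g.case_counts), ("control", g.control_counts)):
            rows.append(
                {
                    "study_id": g.study_id,
                    "snp": g.snp or "rs0",
                    "arm": arm,
                    "n_EE": triple[0],
                    "n_EO": triple[1],
                    "n_OO": triple[2],
                }
            )
    return pd.DataFrame(rows, columns=["study_id", "snp", "arm", "n_EE", "n_EO", "n_OO"])
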