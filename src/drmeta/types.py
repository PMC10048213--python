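"""Shared domain types for the DR GWAS evidence-synthesis pipeline.

Everything downstream (overlap clustering, effect extraction, pooling,
annotation) works on these validated containers.  Validation raises
:class:`ValidationError` with a human-readable reason so that ingestion code
can collect per-row rejects instead of aborting.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple


class ValidationError(ValueError):
    """A domain invariant was violated."""


class PhenotypeGroup(str, enum.Enum):
    """The three separately analysed retinopathy phenotype strata."""

    DR = "DR"
    PDR_SIGHT_THREATENING = "PDR_sight_threatening"
    DME_MACULOPATHY = "DME_maculopathy"


class BackgroundDisease(str, enum.Enum):
    T1D = "T1D"
    T2D = "T2D"
    BOTH = "both"
    DM_UNSPECIFIED = "DM-unspecified"


def normalize_chrom(label: str) -> str:
    """Canonical un-prefixed chromosome label: 'chr10' -> '10', 'chrx' -> 'X'."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.lower() in {"x", "y", "mt", "m"}:
        return "MT" if s.lower() in {"mt", "m"} else s.upper()
    return s


def normalize_rsid(rsid: str) -> str:
    """Identity for overlap purposes: lowercased, whitespace-stripped."""
    return str(rsid).strip().lower()


@dataclass(frozen=True)
class GwasStudy:
    """One discovery GWAS (provenance record for its reported signals)."""

    study_id: str
    first_author: str = ""
    year: int = 0
    trait: str = ""
    background_disease: BackgroundDisease = BackgroundDisease.DM_UNSPECIFIED
    ancestry: str = ""
    n_case: int = 0
    n_control: int = 0
    has_internal_replication: bool = False
    uses_population_controls: bool = False

    def __post_init__(self) -> None:
        if self.n_case < 0 or self.n_control < 0:
            raise ValidationError(
                f"study {self.study_id}: sample sizes must be nonnegative"
            )


@dataclass(frozen=True)
class Signal:
    """One reported SNP-trait association from a discovery GWAS."""

    rsid: str
    chrom: str
    pos: int
    p_value: float
    study_id: str
    phenotype_group: PhenotypeGroup = PhenotypeGroup.DR
    effect_allele: Optional[str] = None
    other_allele: Optional[str] = None
    odds_ratio: Optional[float] = None
    ci_lower: Optional[float] = None
    ci_upper: Optional[float] = None
    locus: Optional[str] = None
    chrom_original: Optional[str] = None  # label as found in the source file

    def __post_init__(self) -> None:
        if not self.rsid or not str(self.rsid).strip():
            raise ValidationError("rsid must be non-empty")
        if not isinstance(self.pos, int) or self.pos < 1:
            raise ValidationError(f"{self.rsid}: pos must be an integer >= 1")
        if not (isinstance(self.p_value, float) and math.isfinite(self.p_value)):
            raise ValidationError(f"{self.rsid}: p-value must be a finite number")
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"{self.rsid}: p-value must lie in (0, 1]")
        if self.odds_ratio is not None and self.odds_ratio <= 0:
            raise ValidationError(f"{self.rsid}: odds ratio must be positive")
        if self.ci_lower is not None and self.ci_upper is not None:
            if self.odds_ratio is not None and not (
                self.ci_lower <= self.odds_ratio <= self.ci_upper
            ):
                raise ValidationError(
                    f"{self.rsid}: CI must bracket the odds ratio"
                )


@dataclass(frozen=True)
class SignificanceTier:
    """Two-level significance gate for GWAS signals.

    The genome-wide gate defaults to 1e-7 (the curation protocol's gate, not
    the conventional 5e-8); the suggestive gate to 5e-5.  Comparison is
    strict ``<`` at both levels.
    """

    suggestive_threshold: float = 5e-5
    genome_wide_threshold: float = 1e-7

    def __post_init__(self) -> None:
        if not (self.genome_wide_threshold < self.suggestive_threshold):
            raise ValidationError(
                "genome-wide threshold must be below the suggestive threshold"
            )


@dataclass(frozen=True)
class WindowSpec:
    """Symmetric proximity window: |pos1 - pos2| <= half_width, inclusive."""

    half_width: int = 100_000

    def __post_init__(self) -> None:
        if self.half_width < 0:
            raise ValidationError("half_width must be >= 0")


@dataclass(frozen=True)
class OverlapCluster:
    """Signals for one locus reported by two or more independent studies."""

    cluster_id: int
    kind: str  # "identical" | "proximal"
    members: Tuple[Signal, ...]
    n_studies: int
    span: Tuple[str, int, int]  # (chrom, min pos, max pos)

    def __post_init__(self) -> None:
        if self.n_studies < 2:
            raise ValidationError("a cluster requires >= 2 distinct studies")
        chroms = {m.chrom for m in self.members}
        if len(chroms) != 1:
            raise ValidationError("cluster members must share one chromosome")
        groups = {m.phenotype_group for m in self.members}
        if len(groups) != 1:
            raise ValidationError("cluster members must share a phenotype group")


GenotypeTriple = Tuple[int, int, int]  # (n_EE, n_EO, n_OO)


@dataclass(frozen=True)
class GenotypeCounts:
    """Case/control genotype triples for one replication study at one SNP.

    Triples are ordered (effect-homozygote, heterozygote, other-homozygote).
    """

    study_id: str
    case_counts: GenotypeTriple
    control_counts: GenotypeTriple
    snp: Optional[str] = None

    def __post_init__(self) -> None:
        for arm, triple in (("case", self.case_counts), ("control", self.control_counts)):
            if len(triple) != 3 or any(c < 0 for c in triple):
                raise ValidationError(
                    f"{self.study_id}: {arm} counts must be three nonnegative integers"
                )
            if sum(triple) <= 0:
                raise ValidationError(f"{self.study_id}: {arm} arm total must be > 0")


@dataclass(frozen=True)
class AlleleTable:
    """Allelic 2x2 table: effect/other allele counts in cases and controls.

    ``a``/``b`` are effect/other alleles in cases, ``c``/``d`` in controls.
    Cells may be half-integers after a continuity correction.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if any(x < 0 for x in (self.a, self.b, self.c, self.d)):
            raise ValidationError("allele counts must be nonnegative")


class EffectSource(str, enum.Enum):
    COUNTS = "counts"
    REPORTED_CI = "reported_ci"


@dataclass(frozen=True)
class EffectEstimate:
    """Per-study log odds ratio with its standard error."""

    study_id: str
    beta: float
    se: float
    source: EffectSource
    continuity_corrected: bool = False
    hwe_p: Optional[float] = None
    nos_stars: Optional[int] = None
    snp: Optional[str] = None
    high_risk_nos: Optional[bool] = None
    hwe_deviation: Optional[bool] = None

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise ValidationError(f"{self.study_id}: se must be > 0")
        if self.nos_stars is not None and not (0 <= self.nos_stars <= 9):
            raise ValidationError(f"{self.study_id}: NOS stars must be in 0..9")


@dataclass(frozen=True)
class QualityRule:
    """Quality flags: NOS <= nos_fail_max is high-risk; HWE p < hwe_alpha deviates."""

    nos_fail_max: int = 6
    hwe_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.nos_fail_max <= 9):
            raise ValidationError("nos_fail_max must be in 0..9")
        if not (0 < self.hwe_alpha < 1):
            raise ValidationError("hwe_alpha must be in (0, 1)")


@dataclass(frozen=True)
class MetaResult:
    """Pooled random-effects result for one SNP."""

    k: int
    beta_fixed: float
    se_fixed: float
    q_stat: float
    tau2: float
    beta_random: float
    se_random: float
    or_random: float
    ci_random: Tuple[float, float]
    i2: float
    z: float
    p_summary: float

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValidationError("meta-analysis requires k >= 2 studies")
        if self.tau2 < 0:
            raise ValidationError("tau2 must be >= 0")
        if not (0.0 <= self.i2 <= 100.0):
            raise ValidationError("I2 must lie in [0, 100]")
        lo, hi = self.ci_random
        if not (lo <= self.or_random <= hi):
            raise ValidationError("CI must bracket the pooled OR")


@dataclass(frozen=True)
class SensitivityResult:
    """Leave-one-out re-pooling after omitting one study."""

    omitted_study_id: str
    result_without: MetaResult
    significance_flipped: bool


@dataclass(frozen=True)
class LdRecord:
    """One pairwise linkage-disequilibrium measurement; (a, b) is unordered."""

    rsid_a: str
    rsid_b: str
    d_prime: float
    r2: float
    population: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.d_prime <= 1.0):
            raise ValidationError("D' must lie in [0, 1]")
        if not (0.0 <= self.r2 <= 1.0):
            raise ValidationError("r2 must lie in [0, 1]")


@dataclass(frozen=True)
class AnnotationRecord:
    """Local functional annotation for one SNP (scores are inputs, not computed)."""

    rsid: str
    location_class: str = "other"  # intergenic | intronic | exonic | other
    nearest_gene: str = ""
    sift: Optional[float] = None
    polyphen: Optional[float] = None
    cadd: Optional[float] = None
    regulomedb_rank: str = ""
    eqtl_gene: Optional[str] = None
    eqtl_p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cadd is not None and self.cadd < 0:
            raise ValidationError(f"{self.rsid}: CADD must be >= 0")
        if self.eqtl_p is not None and not (0.0 < self.eqtl_p <= 1.0):
            raise ValidationError(f"{self.rsid}: eQTL p must lie in (0, 1]")


@dataclass(frozen=True)
class SimSpec:
    """Parameters of the synthetic case-control replication cohort generator.

    ``true_or`` is the allelic odds ratio of the effect allele;
    ``control_maf`` its frequency in controls; ``tau`` the between-study SD of
    the log odds ratio.  When ``hwe_in_controls`` is False, control genotype
    probabilities are distorted by an inbreeding-style coefficient
    ``inbreeding_f``.
    """

    true_or: float = 1.38
    control_maf: float = 0.30
    n_case: int = 500
    n_control: int = 500
    k_studies: int = 3
    tau: float = 0.0
    hwe_in_controls: bool = True
    seed: int = 0
    inbreeding_f: float = 0.15
    jitter_sizes: bool = True

    def __post_init__(self) -> None:
        if self.true_or <= 0:
            raise ValidationError("true_or must be positive")
        if not (0.0 < self.control_maf <= 0.5):
            raise ValidationError("control_maf must lie in (0, 0.5]")
        if self.n_case < 1 or self.n_control < 1:
            raise ValidationError("per-arm sample sizes must be >= 1")
        if self.k_studies < 1:
            raise ValidationError("k_studies must be >= 1")
        if self.tau < 0:
            raise ValidationError("tau must be >= 0")
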