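# Methods

## Scope and shape

`drmeta` implements a GWAS evidence-synthesis protocol for diabetic
retinopathy as five analysis stages over validated in-memory records:
catalog curation and significance tiering, cross-study overlap detection,
per-study allelic effect extraction, DerSimonian–Laird random-effects
pooling with diagnostics, and LD-proxy/functional annotation. A seeded
synthetic-data generator supplies inputs with the statistical structure the
analysis assumes, so the full pipeline runs and is testable offline. The
literature search itself, live queries to web services (GWAS Catalog, GTEx,
RegulomeDB, 1000 Genomes), and quality scoring of publications are out of
scope: study lists, NOS stars, LD values and functional scores are inputs.

## Curation and tiering

Signals are ingested from TSV through a column-mapping dialect (a
GWAS-Catalog-export dialect ships alongside the canonical one). Every row
is validated — `pos ≥ 1`, `p ∈ (0, 1]`, CI brackets the OR when present —
and failing rows are collected into a rejects report with row numbers and
reasons; accepted plus rejected rows always partition the input. Chromosome
labels are normalized to un-prefixed form on ingest with the original
retained for output.

Both significance gates use strict `<`: genome-wide at `1e-7` (the
protocol's gate, deliberately not the conventional `5e-8`) and suggestive at
`5e-5`. Both are configurable; nesting (genome-wide ⊆ suggestive) is a
tested invariant. Trait labels map onto three strata — DR,
PDR/sight-threatening, DME/maculopathy — via a configurable mapping;
severe/sight-threatening retinopathy folds into the PDR stratum. Studies
flagged as using nondiabetic population controls stay in the catalog but are
excluded from overlap and pooling by a default filter.

## Overlap detection

Within one stratum, *identical* overlap groups string-equal rsIDs
(lowercased, stripped; merge history not resolved) reported by ≥ 2 distinct
studies. *Proximal* overlap links cross-study pairs on the same chromosome
with `|pos₁ − pos₂| ≤ 100,000` (inclusive, 1-based; the ±100 kb window read
as half-width). Clusters are connected components of that graph (union-find
over position-sorted signals): the goal is locus-level grouping, so two
signals more than a window apart may co-cluster through a chain, and the
reported span makes chained extents visible. Because the window-vs-pair
question is genuinely open, a `pairwise` mode emits each qualifying
cross-study pair as its own cluster instead. Same-study pairs never create
links. Cross-stratum overlap is never computed. Empty results are emitted as
explicit "0 clusters" rows — absence of overlap is a finding, not missing
output. Cluster spans are also emitted as 0-based half-open BED.

## Per-study effects

The allelic model contrasts effect vs other allele counts, two per subject:
`a = 2·n_EE + n_EO` etc. The OR is `ad/bc` with Woolf SE
`√(1/a+1/b+1/c+1/d)`. The Haldane–Anscombe +0.5 continuity correction is
applied to all four cells only when some cell is zero (a `strict` policy
raises instead); nonzero tables are never perturbed. Swapping the allele
labels negates β exactly and preserves the SE — a property test.

Reported-OR studies enter through `SE = (ln OR − ln L)/1.96` using the lower
95% limit only, exactly as the protocol's formula; a supplied upper limit
is used for a log-scale symmetry check that warns beyond 0.05, catching
transcribed CIs that do not match their point estimate. One estimate per
(study, SNP) is enforced, preferring the reported (covariate-adjusted) form
over counts when both exist, so the two can never co-enter a pool.

Hardy–Weinberg deviation is tested in controls with a 1-df χ² against
`p², 2pq, q²` at the observed allele frequency (monomorphic arms return
p = 1, flagged). An optional exact test enumerates the conditional
distribution of heterozygote counts given the allele counts in log space,
with the conventional sum-of-≤-probable-outcomes p. The χ² flavor at
α = 0.05 is the default because the test flavor was an open choice; both
knobs are exposed. NOS stars ≤ 6 mark a study high-risk. Flags never remove
a study at this stage — removal is the meta stage's sensitivity analysis.

## Pooling

The DerSimonian–Laird moment estimator was chosen to match the
random-effects default of the mainstream systematic-review software this
protocol family uses; REML and Hartung–Knapp adjustments are deliberately
out of scope, and the 95% CI uses the normal 1.96 quantile. τ² truncates at
0; `Q = 0` defines `I² = 0`; `I²` is reported as a percentage in [0, 100]
with `< 50%` classed as low heterogeneity (strict). Summary significance is
strict `p < 0.05` with no multiple-testing correction across SNPs (the
report footer says so). Identities that hold exactly — τ² = 0 ⟺ random
equals fixed bitwise; β_R within [min βᵢ, max βᵢ]; I² invariant to common
rescaling of β and SE — are property-tested, and the whole estimator is
cross-checked to 1e-8 against a loop-coded reference and to 1e-6 against R's
`metafor (method="DL")`.

Leave-one-out sensitivity re-pools after omitting each study (optionally
only flagged studies) and marks omissions that move the summary p across
0.05 in either direction. k = 2 pools return an empty sensitivity list with
a warning, since omission would leave a single study. Funnel output is
per-study (β, SE) plus pseudo-95% guide-line geometry around the pooled β —
no asymmetry statistic, because assessment in this protocol is visual.

## Annotation

LD proxies require `D′ ≥ 0.8` and `r² ≥ 0.8` jointly, inclusive; LD records
are symmetric and the index is never its own proxy. Raising either
threshold can only shrink the proxy set (tested). The annotation join is
total: one row per requested rsID, with all-"na" rows flagged
`unannotated`. The shipped fixtures carry the published annotation rows for
rs4462262, rs7903146 and rs7074440 and the published rs7903146–rs7074440
(D′ 0.95, r² 0.91) and rs7903146–rs34872471 (r² 0.99) LD values; the other
LD rows are synthetic filler (so the fixture exercises both sides of the
gate), and the file name says so.

## Synthetic data

`simulate_study` draws a study-level log-OR as `ln(OR_true) + N(0, τ²)`,
derives the case-arm effect-allele frequency by exact inversion of the
allelic OR — `p_case = OR·p/(1 + p(OR−1))` — and draws each arm's genotypes
as a multinomial from Hardy–Weinberg proportions at the arm frequency. The
inversion (rather than a logistic approximation) makes the simulated
allelic OR the estimand, matching the analysis model. HWE violation mode
distorts control genotype probabilities with an inbreeding-style coefficient
(`P(het) = 2pq(1−F)`, default F = 0.15). `simulate_meta` produces k
independent cohorts with per-arm sizes jittered ±20% unless fixed. Default
conditions (OR 1.38, control MAF 0.30, 400–500 per arm, k = 3, τ = 0) mirror
the scale of the replication cohorts behind the protocol's confirmed DR
SNPs. What the generator does *not* emulate: within-locus LD, shared
controls between cohorts, covariate adjustment, ancestry structure, or
genotyping error — so passing tests demonstrate correctness of the
synthesis machinery under the stated sampling model, not robustness to
those real-data complications.

`simulate_catalog` plants identical and proximal clusters at known
positions and lays background signals on a per-chromosome grid spaced more
than two windows apart, so accidental clusters are impossible by
construction and recovery can be asserted exactly; the ground truth is
emitted alongside. Catalogs meant to stress the overlap scan with
collisions are generated with unconstrained random positions in the tests,
where a brute-force O(n²) oracle provides the expected clustering.

## Numerical choices and problem sizes

All arithmetic is double precision; no tolerance is applied to the
truncations at 0 (τ², I²) because the expressions are exact. The exact HWE
enumeration works in log space with a 1e-12 slack when comparing outcome
probabilities so the observed outcome always counts in the tail. Report
tables round ORs to 2 decimals and p to 3 significant figures for display;
stored values keep full precision.

Calibration checks use 500 replicates at k = 50 and 2,000 per arm for bias
and CI coverage of the pooled estimator (observed |bias| ~1e-4, coverage
~95–96%), 200 replicates for the null-model mean, and 60-replicate batches
for the τ-monotonicity of I²; these sizes give sampling error comfortably
inside the asserted bands while keeping the default run short.

## Known limitations

Genome builds are not harmonized: one declared build per catalog file is
assumed, and no liftover is attempted. rsID merge history is not resolved.
The pooling CI has the usual DerSimonian–Laird undercoverage for very small
k with large τ²; the protocol's pools (k = 2–4, low I²) sit in the regime
where the normal approximation is standard practice. The published pooled
ORs for the confirmed SNPs (1.38, 1.30, 1.24) are reproducible by the
pipeline only from the per-study counts in the cited replication
publications, which are external inputs; the shipped drivers demonstrate
the machinery on synthetic cohorts generated at those effect sizes instead.
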