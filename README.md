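# drmeta

Evidence synthesis for diabetic-retinopathy (DR) GWAS signals: curate
reported SNP–trait associations, tier them by significance, detect
cross-study overlap, extract per-study allelic effects, pool them with a
random-effects meta-analysis, and annotate the surviving loci with
LD proxies and local functional scores.

## The scientific problem

Genome-wide association studies of DR and its subphenotypes — proliferative
DR (PDR) and diabetic macular edema/maculopathy (DME) — have reported over a
hundred loci with strikingly little agreement between studies. Confirming
which signals are real therefore means (1) collecting the reported signals
under a common significance standard, (2) asking whether independent GWASs
ever hit the same locus, and (3) pooling whatever independent replication
data exist for the top hits. This package implements that protocol as a
reusable, fully offline pipeline, with a seeded synthetic-data generator so
every stage can be exercised and tested without any external download.

## The model

**Tiering.** A signal is genome-wide significant when `p < 1e-7` and
suggestive when `p < 5e-5` (both strict, both configurable).

**Overlap.** Within one phenotype stratum, two signals from different
studies overlap if they share an rsID, or lie within a ±100 kb window
(`|pos₁ − pos₂| ≤ 100,000`, inclusive). Proximal clusters are connected
components of the cross-study proximity graph.

**Per-study effects (allelic model).** Genotype counts collapse to an
allelic 2×2 table (`a,b` effect/other alleles in cases, `c,d` in controls):

    OR = ad / bc,   β = ln OR,   SE(β) = √(1/a + 1/b + 1/c + 1/d)

with a Haldane–Anscombe +0.5 correction only when a cell is zero. When a
study reports only OR and 95% CI, the SE is recovered as
`SE = (β − ln L)/1.96` where `L` is the lower limit. Control-arm
Hardy–Weinberg deviation (χ², 1 df; exact test optional) and
Newcastle–Ottawa stars (≤ 6 = high risk) are attached as flags.

**Pooling (DerSimonian–Laird random effects).** With fixed-effect weights
`wᵢ = 1/SEᵢ²`:

    Q = Σwᵢ(βᵢ − β_F)²,   τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))
    wᵢ* = 1/(SEᵢ² + τ²),  β_R = Σwᵢ*βᵢ / Σwᵢ*,   I² = max(0, (Q−(k−1))/Q)·100

Summary OR = exp(β_R) with a normal 95% CI; summary significance is
`p < 0.05`; `I² < 50%` counts as low heterogeneity. Sensitivity is
leave-one-out re-pooling; publication bias is assessed visually from emitted
funnel coordinates.

**Annotation.** LD proxies require `D′ ≥ 0.8` **and** `r² ≥ 0.8`
(inclusive); functional scores (SIFT, PolyPhen, CADD, RegulomeDB, eQTL) are
joined from local tables, never computed.

## Worked example

```python
from drmeta import SimSpec
from drmeta.synthetic import simulate_meta
from drmeta.effects import effect_from_genotype_counts
from drmeta.meta import dersimonian_laird, meta_table

cohorts = simulate_meta(SimSpec(true_or=1.38, control_maf=0.3,
                                n_case=400, n_control=400,
                                k_studies=3, tau=0.0, seed=20230306),
                        snp="rs4462262")
ests = [effect_from_genotype_counts(g) for g in cohorts]
print(meta_table({"rs4462262": dersimonian_laird(ests)}).to_string(index=False))
```

prints

```
      snp  k   or  ci_lower  ci_upper       p  i2 heterogeneity  significant
rs4462262  3 1.24       1.1       1.4 0.000449 0.0           low         True
```

Three synthetic cohorts generated at a true allelic OR of 1.38 pool to an
OR of 1.24 (95% CI 1.10–1.40, p = 4.5×10⁻⁴) — significant, with no
between-study heterogeneity (I² = 0); the gap between 1.24 and 1.38 is the
sampling noise of three 400-per-arm cohorts.

The same stages run as numbered drivers (`analysis/01_curate_signals.py` …
`analysis/05_annotate_loci.py`, writing tables under `results/`) and as a
CLI (`drmeta curate|overlap|effects|meta|annotate|simulate|run`).

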