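#!/usr/bin/env python
"""Random-effects meta-analysis of the synthetic replication cohorts.

Pools the per-study allelic log odds ratios from 03_simulate_replication.py
with the DerSimonian-Laird estimator, classifies heterogeneity (I^2 < 50%
is low), runs leave-one-out sensitivity, and writes the summary table plus
funnel-plot coordinates.

Finding: each SNP's pooled OR is consistent with its generating value given
the sampling noise of three few-hundred-per-arm cohorts, with low I^2
throughout (the true pooled estimates require the per-study counts from the
replication literature; these cohorts are synthetic stand-ins at the same
effect sizes).
"""

from pathlib import Path

import pandas as pd

from drmeta.effects import effect_from_genotype_counts, read_genotype_counts
from drmeta.meta import dersimonian_laird, funnel_data, leave_one_out, meta_table

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    counts_path = RESULTS / "synthetic_replication_counts.csv"
    if not counts_path.exists():
        raise SystemExit("run 03_simulate_replication.py first")
    cohorts = read_genotype_counts(counts_path)
    by_snp = {}
    for g in cohorts:
        by_snp.setdefault(g.snp, []).append(effect_from_genotype_counts(g))

    results = {snp: dersimonian_laird(ests) for snp, ests in sorted(by_snp.items())}
    table = meta_table(results)
    table.to_csv(RESULTS / "meta_table.tsv", sep="\t", index=False)
    print(table.to_string(index=False))

    funnel_frames = []
    sens_rows = []
    for snp, ests in sorted(by_snp.items()):
        rows, _ = funnel_data(ests, results[snp])
        rows.insert(0, "snp", snp)
        funnel_frames.append(rows)
        for s in leave_one_out(ests):
            sens_rows.append(
                {
                    "snp": snp,
                    "omitted": s.omitted_study_id,
                    "or_without": round(s.result_without.or_random, 3),
                    "p_without": float(f"{s.result_without.p_summary:.3g}"),
                    "significance_flipped": s.significance_flipped,
                }
            )
    pd.concat(funnel_frames).to_csv(RESULTS / "funnel.csv", index=False)
    sens = pd.DataFrame(sens_rows)
    sens.to_csv(RESULTS / "sensitivity.tsv", sep="\t", index=False)
    n_flips = int(sens.significance_flipped.sum()) if len(sens) else 0
    print(f"\nleave-one-out: {len(sens)} omissions, {n_flips} significance flips")
    print(f"wrote {RESULTS / 'meta_table.tsv'}")


if __name__ == "__main__":
    main()
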