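#!/usr/bin/env python
"""Cross-study occurrence meta-analysis on a synthetic aging cohort.

Generates six synthetic expression studies with AMP genes planted at
+2 log2 per age step (all other immune classes flat), binarizes per-sample
fold changes into occurrences of high expression, and reports class-level
rate differences plus per-gene Mantel-Haenszel pooled odds ratios for the
three age contrasts. Writes results/class_rd.tsv and results/forest_*.tsv.
"""

from pathlib import Path

from immunoccur.catalog import load_catalog
from immunoccur.dataset_io import filter_eligible
from immunoccur.occurrence import DEFAULT_GROUP_PAIRS, run_meta_analysis
from immunoccur.simulate import CohortSpec, generate_aging_cohort, write_cohort

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20200106


def main() -> None:
    catalog = load_catalog("default")
    cohort, truth = generate_aging_cohort(CohortSpec(seed=SEED), catalog)
    cohort = filter_eligible(cohort)
    OUT.mkdir(exist_ok=True)
    write_cohort(cohort, truth, OUT / "synthetic_cohort")

    meta = run_meta_analysis(cohort, catalog)
    meta.class_rates.to_csv(OUT / "class_rd.tsv", sep="\t", index=False)
    for older, younger in DEFAULT_GROUP_PAIRS:
        meta.forest_table(older, younger).to_csv(
            OUT / f"forest_{older}_vs_{younger}.tsv", sep="\t", index=False
        )

    rates = meta.class_rates
    old_young = rates[
        (rates.older_group == "old") & (rates.younger_group == "young")
    ].set_index("immune_class")
    print(f"old-vs-young AMP rate difference: {old_young.loc['AMP', 'RD']:.3f}")
    print("non-AMP classes max |RD|: "
          f"{old_young.drop('AMP')['RD'].abs().max():.3f}")
    res = meta.gene_results[("AttA", "old", "young")]
    print(f"AttA pooled OR (old vs young): {res.pooled_or:.1f} "
          f"[{res.ci_low:.1f}, {res.ci_high:.1f}], p = {res.p_value:.2e}")
    print("finding: only the AMP class departs from RD ~ 0; per-gene pooled "
          "ORs for AMPs exceed 1 with CIs excluding 1.")


if __name__ == "__main__":
    main()
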