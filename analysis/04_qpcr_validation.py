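#!/usr/bin/env python
"""qPCR-style validation of the time-course contrast.

Takes the synthetic Ct table (panel genes + RpL32 reference), quantifies
relative expression by 2^-ddCt with the WT arm as calibrator, and tests each
gene x timepoint AD-vs-WT difference with the exact Mann-Whitney U test.
Writes results/qpcr_results.tsv.
"""

from pathlib import Path

from immunoccur.catalog import load_catalog
from immunoccur.qpcr import qpcr_summary
from immunoccur.simulate import AdTimecourseSpec, generate_ad_timecourse

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20200106


def main() -> None:
    catalog = load_catalog("default")
    bundle = generate_ad_timecourse(AdTimecourseSpec(seed=SEED), catalog)
    summary = qpcr_summary(bundle.ct_records)
    OUT.mkdir(exist_ok=True)
    summary.to_csv(OUT / "qpcr_results.tsv", sep="\t", index=False)

    lyss = summary[summary.gene == "LysS"].set_index("timepoint_days")
    print("LysS qPCR log2FC (AD vs WT) by day:",
          {tp: round(v, 2) for tp, v in lyss["log2FC"].items()})
    day10 = summary[summary.timepoint_days == 10]
    n_down = (day10[day10.gene != "LysS"]["log2FC"] < 0).sum()
    print(f"day 10: {n_down}/14 AMP genes below WT levels "
          "(qPCR recapitulates the RNA-seq dip).")
    print(f"minimum exact Mann-Whitney p at triplicate scale: "
          f"{summary.p_value.min():.2f} (floor for n=3 per arm is 0.1)")


if __name__ == "__main__":
    main()
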