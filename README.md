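# immunoccur

Analysis pipeline for innate-immunity gene expression in the head of aging
*Drosophila melanogaster* — normal aging versus an amyloid-β42 (Aβ42)
transgenic model of Alzheimer's disease (AD).

Public expression studies of fly head tissue span incompatible microarray and
RNA-seq platforms, so raw signal cannot be compared across them. This package
implements a cross-study statistic that sidesteps the problem: within each
study, every sample is compared with the mean of a reference age group on
log2 scale, and a sample with log2 fold change > 1 counts as one *occurrence
of high expression*. Occurrences k out of samples n give a response rate
P = k/n per arm, class-level contrasts are summarized as a rate difference

    RD = P_older − P_younger,

and per-gene 2×2 occurrence tables are pooled across studies by the
Mantel–Haenszel fixed-effect odds ratio

    OR_MH = Σᵢ (aᵢdᵢ/Nᵢ) / Σᵢ (bᵢcᵢ/Nᵢ),

with 95% CIs from the Robins–Breslow–Greenland variance of log OR_MH.
Around this core the package provides the age binning and eligibility rules
for assembling cohorts (young < 10 d, middle-aged 10–29 d, old ≥ 30 d; a
study must span ≥ 2 bins), a WT-vs-AD time-course differential-expression
contrast (median-of-ratios normalization, Welch's t on log2 counts,
Benjamini–Hochberg FDR; significant ⇔ |log2FC| > 1 and q < 0.05), 2^−ΔΔCt
qPCR quantification against the RpL32 reference with exact Mann–Whitney
tests, trajectory-shape classification (the V-shaped AD AMP profile with its
minimum at day 10), and Pearson correlation of expression with Aβ42/apoptosis
phenotype series. A synthetic-data module generates every input with planted
ground truth, so the whole pipeline is testable offline.

It is aimed at researchers doing cross-platform expression meta-analysis in
model organisms, particularly around innate immunity (antimicrobial peptides,
lysozymes, PGRP/GNBP receptors, Toll/IMD/JAK-STAT signaling).

## Layout

- `src/immunoccur/` — the library: `catalog` (immune gene classes),
  `dataset_io` (matrices, metadata, age bins, census), `occurrence`
  (occurrence statistic, RD, Mantel–Haenszel meta-analysis), `timecourse`
  (DE contrast, BH FDR, trajectory shapes), `qpcr` (2^−ΔΔCt), `correlation`
  (Pearson, ANOVA + Bonferroni), `simulate` (synthetic cohorts and
  time courses), `pipeline`/`cli` (orchestration).
- `analysis/` — numbered narrative drivers (`01_study_census.py` …
  `05_correlation_panel.py`), each a thin script over the library that
  prints what it found and writes tables under `results/`.
- The `immunoccur` console command exposes the same stages
  (`census`, `de`, `qpcr`, `correlate`, `synth`, `run`).

## Worked example

```sh
$ python analysis/02_aging_meta_analysis.py
old-vs-young AMP rate difference: 1.000
non-AMP classes max |RD|: 0.069
AttA pooled OR (old vs young): 81.0 [15.0, 437.6], p = 3.29e-07
finding: only the AMP class departs from RD ~ 0; per-gene pooled ORs for
AMPs exceed 1 with CIs excluding 1.
```

Six synthetic studies carry a +2 log2-per-age-step shift on the 14
antimicrobial peptide (AMP) genes and nothing on the other immune classes.
The analysis recovers exactly that structure: every old sample is an
occurrence relative to the young arm (AMP RD = 1.0), the other classes stay
near RD = 0, and the per-gene pooled odds ratios are large with confidence
intervals far from 1. On the AD side:

```sh
$ python analysis/03_ad_timecourse_de.py
AMP panel mean log2FC (AD vs WT) by day: {3: -0.39, 10: -2.19, 20: 0.0, 30: 0.5}
day-10 AMP mean log2FC: -2.19 (planted -2)
LysS log2FC by day: {3: 2.65, 10: 4.11, 20: 3.64, 30: 3.97}
finding: 13/14 AMP genes classified V-shaped; LysS positive at every timepoint.
```

The AD AMP trajectory dips to its minimum at day 10 and recovers (the
V shape that distinguishes the disease model from the monotone rise of
normal aging), while lysozyme S stays overexpressed throughout.

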