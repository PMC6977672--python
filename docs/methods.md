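# Methods

## The occurrence-of-high-expression statistic

Cross-study comparison of expression levels between heterogeneous microarray
and RNA-seq platforms is confounded by platform, protocol and normalization
differences. The pipeline therefore never compares signal between studies;
it compares *within-study statistics* across studies. Within one study, for
a gene g and an (older, younger) age-group pair:

1. All values are put on log2 scale. Datasets declare `linear` or `log2`;
   linear values become log2(x + 1). The +1 pseudocount keeps zeros finite
   and is applied uniformly, so within-study differences are unaffected for
   well-expressed genes.
2. Each older-arm sample's log2 fold change is its log2 value minus the
   mean (configurable: median) of the younger arm's log2 values. A fold
   change strictly greater than the cutoff (default 1, i.e. > 2-fold) is one
   occurrence of high expression. The younger arm is counted symmetrically
   against the older arm's mean, so the 2×2 table is well formed in both
   directions and reduces to one-sided counting when younger events are
   zero.
3. The table per study is (k_older, n_older − k_older; k_younger,
   n_younger − k_younger).

Class-level summaries pool raw events with no weighting — P_arm = Σk/Σn
over all genes, samples and studies of the class — and report
RD = P_older − P_younger. Gene-level summaries pool the per-study tables
with the Mantel–Haenszel fixed-effect odds ratio; the 95% CI and two-sided p
come from the Robins–Breslow–Greenland variance of log OR_MH. Any table with
a zero cell gets the Haldane–Anscombe +0.5 added to all four of its cells
(only that table). A DerSimonian–Laird random-effects pooling is available
behind `model="random"` but is not the default: the fixed-effect MH
estimator is the standard default for sparse dichotomous tables, where
per-study variances are poorly estimated.

Assumptions worth stating: samples within an arm are treated as independent
Bernoulli units; the symmetric younger-arm construction is a design choice
(the one-sided description of occurrence counting does not determine the
younger arm's event definition), and whether the per-sample comparison runs
against the opposing group's summary rather than sample-by-sample pairs is
likewise a choice — we use sample-vs-group-mean, which makes n equal the arm
size. No cross-gene multiplicity correction is applied at this stage;
significance is α = 0.05 two-sided per gene.

## Age binning, eligibility, census

Ages in days post eclosion are binned young < 10, middle-aged 10–29,
old ≥ 30. A study enters the cohort only if it spans ≥ 2 bins, so an
older-vs-younger contrast exists within the study. Studies with more than
two bins contribute one table per realized (older, younger) pair; distinct
ages within a bin (e.g. day 30 and day 45) are pooled under the bin label.

The packaged census fixture lists the per-GSM ages of the 18 eligible GEO
series of normal fly head samples. A GSM accession reused by two series
(GSM12770/GSM12772 under both GSE6430 and GSE826) counts once per series
membership, since each series is an independent experiment. Recounting the
fixture gives 18 series and 52 young / 56 middle-aged / 74 old samples. The
source table's own text reports 57 middle-aged and 75 old; the per-row
arithmetic does not support those two figures, so this package asserts only
the dataset count and the young count as fixed values and documents the
recounts for the other two bins.

## WT-vs-AD time-course contrast

The per-timepoint AD-vs-WT contrast is a deliberately transparent pipeline:
median-of-ratios size factors (computed over genes expressed in every
sample, rescaled to unit geometric mean, which makes normalization exactly
idempotent), log2(normalized count + 1), Welch's two-sample t per gene, and
Benjamini–Hochberg FDR across genes within the timepoint. Significance is
declared at |log2FC| > 1 and q < 0.05. This is not a negative-binomial GLM
with dispersion shrinkage and does not try to be: the downstream biology
rides on the sign and approximate magnitude of log2FC, which this contrast
preserves. The cost is power — with triplicate arms, Welch's t has 2–4
degrees of freedom, and at the generator's default dispersion (0.1) even a
2-log2-unit planted effect rarely clears the BH threshold at n = 3. The
recovery contract is therefore stated on the estimated log2FC (within ±0.5
of the planted value) and on the p-value ranking, not on the significance
flag; at realistic per-gene power the flag needs larger n or a
dispersion-sharing model. No dispersion information is shared across
timepoints; each timepoint's contrast is its own BH family, matching
per-timepoint reporting.

Trajectory shapes classify a gene's per-timepoint profile (we use the
AD-vs-WT log2FC series): `flat` if the total range is ≤ 0.25 log2 units;
`V_shaped(min_at)` if the minimum is interior and both endpoints exceed it
by a margin (default 1 log2 unit — configurable, since "declined then rose
sharply" has no canonical numeric definition); otherwise `monotone_up` /
`monotone_down` for non-decreasing / non-increasing profiles; else `other`.
The checks run in that order; a profile cannot satisfy both the V and
monotone rules.

## qPCR quantification

Relative expression is 2^−ΔΔCt with amplification efficiency exactly 2 and
RpL32 as reference: ΔCt = Ct(target) − Ct(RpL32) within a sample, ΔΔCt
subtracts the calibrator's ΔCt. For AD-vs-WT contrasts the calibrator is
the WT arm's mean ΔCt at the same timepoint, so WT replicates scatter
around 1 and log2FC = mean ΔCt(WT) − mean ΔCt(AD) is directly comparable to
the RNA-seq contrast; a day-3 calibrator gives within-genotype aging trends
instead. Technical replicates are averaged on the Ct scale before ΔCt;
biological replicates stay separate for testing. Arm differences use the
exact two-sided Mann–Whitney U for untied small samples (the exact null
floor for 3-vs-3 is p = 0.1), falling back to the tie-corrected normal
approximation when ties occur.

## Phenotype statistics

Time trends use one-way ANOVA with Bonferroni-adjusted pairwise two-sample
comparisons (p × number of pairs, capped at 1). Associations between gene
expression, Aβ42 concentration (pg/mL) and apoptotic DNA fragmentation
(absorbance) are Pearson correlations over observations aligned by
(condition × timepoint × replicate) — the alignment unit is a design choice
that maximizes usable n from a triplicate design; expression enters as log2
normalized values. Zero-variance or n < 3 pairs are reported as undefined,
never as r = 0. No multiplicity correction is applied across the panel by
default (a BH option exists). "CecA" in correlation gene lists is ambiguous
between CecA1/CecA2; the default catalog maps the alias `CecA` to CecA1 and
both genes are available.

## The gene catalog

The default catalog carries the 14 canonical head-expressed AMP genes
(AttA–D, CecA1/A2/B/C, DptA/B, Drs, Def, Dro, Mtk), LysS and sibling
lysozymes, PGRP-LC/-SA/-SD and other common PGRPs, GNBP1–3, four lectins,
and core Toll (Tl, spz, Myd88, pll, tub, cact, Dif, dl), IMD (imd, Rel, key,
Dredd, Fadd, Tak1) and JAK-STAT (hop, dome, Stat92E, upd1–3) members. Only
the AMP panel and the named LysS/PGRP entries are load-bearing for the
analyses; the remaining class panels are reasonable defaults and explicitly
user-extensible — class statistics operate on whatever members a user's
catalog provides. Lookup is case-insensitive with alias support because GEO
platforms use inconsistent casing and synonyms.

## Synthetic data: what it emulates and what it does not

`generate_aging_cohort` emulates the multi-study mining input: six studies,
4 samples per age group, per-gene global baselines N(6, 1.5²) on log2 scale,
per-study platform offsets N(0, 1²), i.i.d. sample noise sd 0.5, and a
planted +2 log2 shift per age step on AMPs only. `generate_ad_timecourse`
emulates a WT/AD design at days 3/10/20/30 in triplicate:
negative-binomial counts (var = μ + 0.1 μ²; gene baselines log-normal around
2^7) with planted AD-vs-WT log2FC trajectories — AMPs (−0.5, −2, 0, +0.5)
(the −2 at day 10 on the scale of the reported day-10 declines) and LysS
(+2.9, +3.9, +3.4, +4.6) (rounded from the reported 2.891/3.929/3.412/4.576)
— plus a WT aging rise on AMPs (0, +0.5, +1, +1.5). Ct values are
back-computed as Ct = 34 − log2(expression) + N(0, 0.15²) with RpL32 flat at
16. Aβ42 stays near 8 pg/mL in WT and rises in AD (means 15/40/150/160,
largest jump and sharpest group separation at day 20); apoptosis absorbance
behaves analogously (0.12 flat vs 0.25/0.6/1.4/1.5). A standard-normal
latent factor per AD (timepoint, replicate) drives Aβ42 exactly and
apoptosis at loading 0.8, and adds 0.5 log2 units per sd to the designated
coupled genes (AttB, AttC, CecA1, Drs, Mtk, LysS), producing positive
gene–Aβ42 correlations on top of the shared time structure.

Every stochastic quantity draws from a named substream
(`default_rng([seed, k])`), so outputs are byte-identical under a fixed seed
and adding a table never perturbs the others. Planted truths are returned as
sidecar tables.

What the generator does **not** model: probe-level microarray artifacts,
batch/library-size confounding beyond a global size factor, gene–gene
correlation within classes (genes are conditionally independent given the
latent factor), dropout/zero inflation, or qPCR efficiency ≠ 2. Passing
recovery tests on this data therefore shows the statistics are implemented
correctly and are calibrated under their own assumptions — not that those
assumptions hold in any particular real dataset.

## Problem sizes and numerical choices

The replicate experiments run at 20 cohort replicates (recovery) and 50
replicates (null calibration of the DE rule at 200 genes, and of the
correlation panel at 28 pairs), sizes at which binomial noise on the
reported rates is a fraction of the margins being checked while the whole
analysis reruns in seconds. Ties in Mann–Whitney switch the method to the
corrected normal approximation; BH is computed with statsmodels and checked
against a definitional sweep; the MH pooling is checked against both an
independent direct-formula evaluation and statsmodels' StratifiedTable.
Degenerate DE genes (zero variance in both arms, zero fold change) are
assigned p = 1 rather than NaN; genes with under two replicates in an arm
get NaN statistics rather than aborting the contrast.

## Known limitations

- The DE substitute trades power for transparency (see above); per-gene
  significance at triplicate scale is conservative.
- The symmetric younger-arm event construction and the sample-vs-group-mean
  comparison are documented choices among defensible readings of the
  occurrence procedure, not uniquely determined by it.
- Class-level RD pools raw events, so large studies dominate small ones;
  this matches unweighted event counting but is not a variance-optimal
  estimator.
- The correlation panel mixes WT and AD observations by default; much of the
  gene–phenotype correlation is then carried by the shared condition/time
  structure. Restricting to one condition isolates the replicate-level
  coupling.
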