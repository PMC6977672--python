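"""Time-trend ANOVA and Pearson correlation of expression with phenotypes.

Molecular phenotypes — Abeta42 concentration (pg/mL, ELISA) and apoptotic
DNA fragmentation (absorbance) — are measured per (condition, timepoint,
replicate). Gene expression enters as log2 normalized values aligned on the
same design tuples, and all pairwise associations are summarized as a
symmetric Pearson correlation matrix with per-pair two-sided p-values
(t transform, n-2 df). Time trends within a condition use one-way ANOVA
with Bonferroni-adjusted pairwise comparisons.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = ("condition", "timepoint_days", "replicate", "analyte", "value")
ANALYTES = ("Abeta42", "apoptosis_abs")


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p_value: float
    n: int


def pearson(x: Sequence[float], y: Sequence[float]) -> Optional[PearsonResult]:
    """Pearson's r with two-sided p; None when undefined (n < 3 or a
    zero-variance vector), never silently r = 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired (equal length)")
    if x.size < 3:
        return None
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    res = stats.pearsonr(x, y)
    return PearsonResult(r=float(res.statistic), p_value=float(res.pvalue), n=int(x.size))


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    pairwise: dict[tuple, float]  # (group_i, group_j) -> Bonferroni-adjusted p


def anova_trend(groups: Mapping[int, Sequence[float]]) -> AnovaResult:
    """One-way ANOVA across timepoint groups plus Bonferroni post-hoc.

    Pairwise comparisons are two-sample t tests with p multiplied by the
    number of pairs, capped at 1.
    """
    keys = sorted(groups)
    if len(keys) < 2:
        raise ValueError("need >= 2 groups")
    for k in keys:
        if len(groups[k]) < 2:
            raise ValueError(f"group at timepoint {k} has < 2 values")
    arrays = [np.asarray(groups[k], dtype=float) for k in keys]
    f, p = stats.f_oneway(*arrays)
    pairs = list(itertools.combinations(range(len(keys)), 2))
    m = len(pairs)
    pairwise = {}
    for i, j in pairs:
        p_raw = float(stats.ttest_ind(arrays[i], arrays[j]).pvalue)
        pairwise[(keys[i], keys[j])] = min(1.0, m * p_raw)
    return AnovaResult(f_statistic=float(f), p_value=float(p), pairwise=pairwise)


@dataclass
class CorrelationMatrix:
    """Symmetric pairwise Pearson results over matched observations."""

    labels: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.labels):
            for b in self.labels[i + 1 :]:
                rows.append(
                    {
                        "var_a": a,
                        "var_b": b,
                        "r": self.r.loc[a, b],
                        "p_value": self.p.loc[a, b],
                        "n": self.n.loc[a, b],
                    }
                )
        return pd.DataFrame(rows, columns=["var_a", "var_b", "r", "p_value", "n"])


def phenotype_wide(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long phenotype table to one column per analyte, indexed by
    (condition, timepoint_days, replicate)."""
    missing = set(PHENOTYPE_COLUMNS) - set(phenotypes.columns)
    if missing:
        raise ValueError(f"phenotype table missing column(s): {sorted(missing)}")
    if (phenotypes["value"] < 0).any():
        raise ValueError("phenotype values must be >= 0")
    return phenotypes.pivot_table(
        index=["condition", "timepoint_days", "replicate"],
        columns="analyte",
        values="value",
    )


def correlate_panel(
    gene_expression: pd.DataFrame,
    phenotypes: pd.DataFrame,
) -> CorrelationMatrix:
    """Full pairwise Pearson matrix over genes and analytes.

    ``gene_expression`` is indexed by (condition, timepoint_days, replicate)
    with one column per gene (log2 values); ``phenotypes`` is the long table.
    Observations present in one input but not the other are dropped (count
    logged). Cells with < 3 matched pairs or zero variance are NaN.
    """
    pheno = phenotype_wide(phenotypes)
    shared = gene_expression.index.intersection(pheno.index)
    dropped = (len(gene_expression.index) - len(shared)) + (len(pheno.index) - len(shared))
    if dropped:
        logger.info("correlate_panel: dropped %d unmatched observation rows", dropped)
    if len(shared) == 0:
        raise ValueError("no matched (condition, timepoint, replicate) observations")
    data = pd.concat([gene_expression.loc[shared], pheno.loc[shared]], axis=1)
    labels = list(data.columns)
    k = len(labels)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        r[i, i] = 1.0
        p[i, i] = 0.0
        n[i, i] = data.iloc[:, i].notna().sum()
        for j in range(i + 1, k):
            pair = data.iloc[:, [i, j]].dropna()
            res = pearson(pair.iloc[:, 0], pair.iloc[:, 1])
            if res is not None:
                r[i, j] = r[j, i] = res.r
                p[i, j] = p[j, i] = res.p_value
            n[i, j] = n[j, i] = len(pair)
    return CorrelationMatrix(
        labels=labels,
        r=pd.DataFrame(r, index=labels, columns=labels),
        p=pd.DataFrame(p, index=labels, columns=labels),
        n=pd.DataFrame(n, index=labels, columns=labels),
    )
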