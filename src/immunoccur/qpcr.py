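"""2^-ddCt relative quantification for qPCR with RpL32 as reference gene.

dCt = Ct(target) - Ct(reference) within a sample; ddCt subtracts a
calibrator's dCt; relative expression is 2^-ddCt (amplification efficiency
exactly 2). For the AD-vs-WT contrast at a timepoint, the calibrator is the
WT arm's mean dCt, so WT replicates scatter around 1 and the AD/WT log2 fold
change is directly comparable to RNA-seq contrasts. Group significance uses
the exact two-sided Mann-Whitney U test (normal approximation with tie
correction when ties are present).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

REFERENCE_GENE = "RpL32"

CT_COLUMNS = ("sample_id", "gene", "Ct", "condition", "timepoint_days", "replicate")


def read_ct(path: str | Path) -> pd.DataFrame:
    """Read a Ct table TSV; technical replicates of a (sample, gene) pair are
    averaged on the Ct scale."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing column(s): {sorted(missing)}")
    if (df["Ct"] <= 0).any():
        bad = df.loc[df["Ct"] <= 0, "sample_id"].tolist()
        raise ValueError(f"non-positive Ct values for sample(s) {bad}")
    group_cols = [c for c in df.columns if c != "Ct"]
    return df.groupby(group_cols, as_index=False, sort=False)["Ct"].mean()


def ddct_relative_expression(
    target_ct: float,
    reference_ct: float,
    calibrator_target_ct: float,
    calibrator_reference_ct: float,
) -> float:
    """2^-[(Ct_target - Ct_ref)_sample - (Ct_target - Ct_ref)_calibrator]."""
    ddct = (target_ct - reference_ct) - (calibrator_target_ct - calibrator_reference_ct)
    return float(2.0 ** (-ddct))


def mann_whitney_exact(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value, exact for untied small samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "asymptotic" if ties else "exact"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


@dataclass
class GroupExpressionResult:
    """AD-vs-WT relative expression of one gene at one timepoint."""

    gene: str
    timepoint_days: int
    rel_expr: dict[str, list[float]]  # condition -> per-replicate 2^-ddCt
    log2fc: float
    p_value: float

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.rel_expr)


def _delta_ct(
    records: pd.DataFrame, gene: str, reference_gene: str
) -> pd.DataFrame:
    """Per-sample dCt = Ct(gene) - Ct(reference); errors name the sample."""
    target = records[records["gene"] == gene]
    ref = records[records["gene"] == reference_gene].set_index("sample_id")["Ct"]
    rows = []
    for row in target.itertuples(index=False):
        if row.sample_id not in ref.index:
            raise ValueError(
                f"sample {row.sample_id!r} has no {reference_gene} reference record"
            )
        rows.append(
            {
                "sample_id": row.sample_id,
                "condition": row.condition,
                "timepoint_days": row.timepoint_days,
                "replicate": row.replicate,
                "delta_ct": row.Ct - float(ref.loc[row.sample_id]),
            }
        )
    return pd.DataFrame(rows)


def group_relative_expression(
    records: pd.DataFrame,
    gene: str,
    timepoint_days: int,
    condition_pair: tuple[str, str] = ("AD", "WT"),
    reference_gene: str = REFERENCE_GENE,
) -> GroupExpressionResult:
    """Relative expression of *gene* in two arms at one timepoint.

    The calibrator is the mean dCt of the second condition in the pair
    (default WT). Returns per-replicate 2^-ddCt values per arm, the log2
    AD/WT geometric-mean ratio, and the Mann-Whitney two-sided p.
    """
    test_cond, cal_cond = condition_pair
    dct = _delta_ct(records, gene, reference_gene)
    dct = dct[dct["timepoint_days"] == timepoint_days]
    arms = {
        cond: dct.loc[dct["condition"] == cond, "delta_ct"].to_numpy()
        for cond in condition_pair
    }
    for cond, values in arms.items():
        if len(values) < 2:
            raise ValueError(
                f"gene {gene}, day {timepoint_days}: condition {cond!r} has "
                f"{len(values)} replicate(s); need >= 2"
            )
    calibrator = float(arms[cal_cond].mean())
    rel = {
        cond: [float(2.0 ** (-(d - calibrator))) for d in values]
        for cond, values in arms.items()
    }
    # log2 of the geometric-mean ratio == difference of mean -dCt's
    log2fc = float(arms[cal_cond].mean() - arms[test_cond].mean())
    p = mann_whitney_exact(rel[test_cond], rel[cal_cond])
    return GroupExpressionResult(
        gene=gene,
        timepoint_days=int(timepoint_days),
        rel_expr=rel,
        log2fc=log2fc,
        p_value=p,
    )


def qpcr_summary(
    records: pd.DataFrame,
    genes: Optional[Sequence[str]] = None,
    reference_gene: str = REFERENCE_GENE,
    condition_pair: tuple[str, str] = ("AD", "WT"),
) -> pd.DataFrame:
    """AD-vs-WT log2FC and Mann-Whitney p for every gene x timepoint."""
    if genes is None:
        genes = [g for g in records["gene"].unique() if g != reference_gene]
    rows = []
    for gene in genes:
        tps = sorted(records.loc[records["gene"] == gene, "timepoint_days"].unique())
        for tp in tps:
            res = group_relative_expression(
                records, gene, int(tp), condition_pair, reference_gene
            )
            rows.append(
                {
                    "gene": gene,
                    "timepoint_days": int(tp),
                    "log2FC": res.log2fc,
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(rows, columns=["gene", "timepoint_days", "log2FC", "p_value"])
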