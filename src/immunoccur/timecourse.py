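"""WT-vs-AD time-course differential expression on RNA-seq counts.

The contrast at each timepoint (days 3/10/20/30 post eclosion) is a
deliberately transparent substitute for a negative-binomial GLM pipeline:
median-of-ratios size factors, log2(normalized count + 1), Welch's t per
gene, and Benjamini-Hochberg FDR across genes within the timepoint. It
preserves the quantities the downstream biology rides on — the sign and
approximate magnitude of the AD-vs-WT log2 fold change — without modelling
dispersion shrinkage. A gene is called significant when |log2FC| > 1 and
q < 0.05.

Per-gene time profiles (e.g. log2FC trajectories in the AD group) are
classified into shapes; the V shape — an interior minimum with both flanks
at least one log2 unit above it — is the disease-specific AMP signature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SIG_LOG2FC = 1.0
SIG_FDR = 0.05
TIMEPOINTS = (3, 10, 20, 30)


@dataclass
class CountMatrix:
    """Genes x samples integer counts with per-sample design metadata.

    ``meta`` must carry sample_id, condition (WT|AD), timepoint_days and
    replicate, one row per counts column.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        required = {"sample_id", "condition", "timepoint_days", "replicate"}
        missing = required - set(self.meta.columns)
        if missing:
            raise ValueError(f"metadata missing column(s): {sorted(missing)}")
        meta_ids = set(self.meta["sample_id"])
        absent = [c for c in self.counts.columns if c not in meta_ids]
        if absent:
            raise ValueError(f"counts columns missing from metadata: {absent}")

    def samples_at(self, condition: str, timepoint: int) -> list[str]:
        m = self.meta
        sel = m[(m["condition"] == condition) & (m["timepoint_days"] == timepoint)]
        return [s for s in sel["sample_id"] if s in self.counts.columns]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Per sample, the median over all-sample-expressed genes of
    count / geometric-mean-across-samples. Factors are strictly positive.
    """
    if counts.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns)
    expressed = (counts > 0).all(axis=1)
    if not expressed.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; add a pseudocount "
            "or filter samples before normalization"
        )
    sub = counts.loc[expressed].to_numpy(dtype=float)
    log_geo_mean = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_geo_mean)
    factors = np.median(ratios, axis=0)
    # rescale to unit geometric mean so normalization is exactly idempotent
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)


def normalize(counts: pd.DataFrame, factors: Optional[pd.Series] = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_contrast(
    counts: CountMatrix,
    timepoint: int,
    conditions: tuple[str, str] = ("AD", "WT"),
) -> pd.DataFrame:
    """Per-gene AD-vs-WT contrast at one timepoint.

    log2FC is the difference of group means of log2(normalized count + 1);
    p is Welch's two-sample t; q is BH across genes. Genes with fewer than
    two replicates in an arm get NaN statistics rather than failing the run.
    Returns a DataFrame with columns gene, log2FC, p_value, q_value,
    significant.
    """
    test_cond, ref_cond = conditions
    test_samples = counts.samples_at(test_cond, timepoint)
    ref_samples = counts.samples_at(ref_cond, timepoint)
    if len(test_samples) < 2 or len(ref_samples) < 2:
        raise ValueError(
            f"timepoint {timepoint}: need >= 2 replicates per arm "
            f"({test_cond}: {len(test_samples)}, {ref_cond}: {len(ref_samples)})"
        )
    norm = normalize(counts.counts[test_samples + ref_samples])
    log2 = np.log2(norm + 1.0)
    x = log2[test_samples].to_numpy()
    y = log2[ref_samples].to_numpy()
    log2fc = x.mean(axis=1) - y.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_res = stats.ttest_ind(x, y, axis=1, equal_var=False)
    p = np.asarray(t_res.pvalue, dtype=float)
    # zero variance in both arms: identical groups are unambiguously null
    degenerate = np.isnan(p)
    p[degenerate & np.isclose(log2fc, 0.0)] = 1.0
    valid = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    if valid.any():
        q[valid] = bh_fdr(p[valid])
    out = pd.DataFrame(
        {
            "gene": counts.counts.index,
            "log2FC": log2fc,
            "p_value": p,
            "q_value": q,
        }
    )
    out["significant"] = (out["log2FC"].abs() > SIG_LOG2FC) & (out["q_value"] < SIG_FDR)
    return out


@dataclass(frozen=True)
class ShapeLabel:
    kind: str  # monotone_up | monotone_down | V_shaped | flat | other
    min_at: Optional[int] = None

    def __str__(self) -> str:
        if self.kind == "V_shaped":
            return f"V_shaped(min_at={self.min_at})"
        return self.kind


def classify_profile(
    values: Sequence[float],
    timepoints: Sequence[int] = TIMEPOINTS,
    margin: float = 1.0,
    flat_tol: float = 0.25,
) -> ShapeLabel:
    """Classify one gene's time profile.

    flat: total range <= flat_tol. V_shaped: an interior minimum with both
    endpoints at least ``margin`` log2 units above it. monotone_up/down:
    non-decreasing / non-increasing. Everything else: other.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need >= 3 timepoints to classify a profile")
    if v.max() - v.min() <= flat_tol:
        return ShapeLabel("flat")
    i_min = int(np.argmin(v))
    if 0 < i_min < v.size - 1 and v[0] - v[i_min] >= margin and v[-1] - v[i_min] >= margin:
        return ShapeLabel("V_shaped", min_at=int(timepoints[i_min]))
    if np.all(np.diff(v) >= 0):
        return ShapeLabel("monotone_up")
    if np.all(np.diff(v) <= 0):
        return ShapeLabel("monotone_down")
    return ShapeLabel("other")


def trajectory_shape(
    profiles: pd.DataFrame,
    gene_set: Optional[Sequence[str]] = None,
    margin: float = 1.0,
    flat_tol: float = 0.25,
) -> pd.DataFrame:
    """Classify per-gene profiles (genes x timepoint columns).

    ``profiles`` columns are timepoints (ints) in ascending order; rows are
    genes. Returns gene, shape, min_at.
    """
    tps = sorted(int(c) for c in profiles.columns)
    if gene_set is not None:
        present = [g for g in gene_set if g in profiles.index]
        profiles = profiles.loc[present]
    rows = []
    for gene, row in profiles.iterrows():
        label = classify_profile([row[t] for t in tps], tps, margin, flat_tol)
        rows.append({"gene": gene, "shape": label.kind, "min_at": label.min_at})
    return pd.DataFrame(rows, columns=["gene", "shape", "min_at"])
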