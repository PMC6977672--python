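"""Occurrence-of-high-expression statistics and Mantel-Haenszel meta-analysis.

The cross-study analysis avoids comparing raw signal between heterogeneous
platforms. Within each study, every sample is compared against the mean of a
reference age group on log2 scale; a sample whose log2 fold change exceeds a
cutoff (default 1, i.e. two-fold) is one *occurrence of high expression*.
Occurrences (k) out of samples (n) give a response rate P = k/n per arm.

Class-level results are rate differences RD = P_older - P_younger with events
pooled across genes, samples and datasets of a class. Gene-level results are
2x2 odds ratios per study, pooled across studies with the Mantel-Haenszel
fixed-effect estimator; the 95% CI uses the Robins-Breslow-Greenland variance
of log(OR_MH). Tables with a zero cell get the Haldane-Anscombe +0.5 applied
to all four of that table's cells.

The 2x2 table per gene, study and (older, younger) group pair is::

                 occurrence   no occurrence
    older arm        a=k_o      b=n_o-k_o
    younger arm      c=k_y      d=n_y-k_y

with the younger arm's events counted symmetrically (high expression relative
to the older group's mean), so the table is well-formed in both directions and
reduces to one-sided counting when younger events are zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import GeneCatalog
from .dataset_io import AGE_GROUP_ORDER, AGE_GROUPS, Cohort, ExpressionDataset

#: The three older-vs-younger age-group contrasts, in reporting order.
DEFAULT_GROUP_PAIRS = (
    ("middle_aged", "young"),
    ("old", "middle_aged"),
    ("old", "young"),
)

Baseline = Literal["mean", "median"]


@dataclass(frozen=True)
class OccurrenceTable:
    """Per gene, per study 2x2 occurrence counts for one group pair."""

    gene: str
    dataset_id: str
    older_group: str
    younger_group: str
    k_older: int
    n_older: int
    k_younger: int
    n_younger: int

    def __post_init__(self) -> None:
        if AGE_GROUP_ORDER[self.older_group] <= AGE_GROUP_ORDER[self.younger_group]:
            raise ValueError(
                f"older_group {self.older_group!r} must be strictly later than "
                f"younger_group {self.younger_group!r}"
            )
        for k, n, arm in (
            (self.k_older, self.n_older, "older"),
            (self.k_younger, self.n_younger, "younger"),
        ):
            if n < 1:
                raise ValueError(f"{arm} arm has n={n} < 1")
            if not 0 <= k <= n:
                raise ValueError(f"{arm} arm has k={k} outside [0, {n}]")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        """(a, b, c, d) = (k_o, n_o-k_o, k_y, n_y-k_y)."""
        return (
            self.k_older,
            self.n_older - self.k_older,
            self.k_younger,
            self.n_younger - self.k_younger,
        )

    def swapped(self) -> "OccurrenceTable":
        """The same data with the arms' roles exchanged (for symmetry checks)."""
        return OccurrenceTable(
            gene=self.gene,
            dataset_id=self.dataset_id,
            older_group=self.older_group,
            younger_group=self.younger_group,
            k_older=self.k_younger,
            n_older=self.n_younger,
            k_younger=self.k_older,
            n_younger=self.n_older,
        )


@dataclass(frozen=True)
class ClassRateResult:
    """Pooled response rates and rate difference for one immune class."""

    immune_class: str
    older_group: str
    younger_group: str
    k_older: int
    n_older: int
    k_younger: int
    n_younger: int

    @property
    def p_older(self) -> float:
        return self.k_older / self.n_older

    @property
    def p_younger(self) -> float:
        return self.k_younger / self.n_younger

    @property
    def rd(self) -> float:
        return self.p_older - self.p_younger


@dataclass(frozen=True)
class MetaResult:
    """Mantel-Haenszel pooled odds ratio for one gene across studies."""

    gene: str
    older_group: str
    younger_group: str
    tables: tuple[OccurrenceTable, ...]
    dataset_ors: tuple[float, ...]
    pooled_or: float
    ci_low: float
    ci_high: float
    p_value: float
    model: str = "fixed"

    @property
    def n_datasets(self) -> int:
        return len(self.tables)

    def ci_excludes_one(self) -> bool:
        return self.ci_low > 1.0 or self.ci_high < 1.0


def sample_log2fc(
    dataset: ExpressionDataset,
    gene: str,
    sample_id: str,
    reference_group: str,
    baseline: Baseline = "mean",
) -> float:
    """log2 expression of one sample minus the reference group's summary.

    Values are taken from the dataset's log2 matrix (linear data gets the +1
    pseudocount); the reference summary is the mean (default) or median of
    the reference group's log2 values for the gene.
    """
    ref_samples = dataset.group_samples(reference_group)
    if not ref_samples:
        raise ValueError(
            f"reference group {reference_group!r} empty in dataset {dataset.dataset_id}"
        )
    if gene not in dataset.matrix.index:
        raise KeyError(f"gene {gene!r} absent from dataset {dataset.dataset_id}")
    log2 = dataset.log2_matrix().loc[gene]
    ref = log2[ref_samples]
    summary = float(ref.mean()) if baseline == "mean" else float(ref.median())
    return float(log2[sample_id]) - summary


def is_occurrence(log2fc: float, cutoff: float = 1.0) -> bool:
    """True iff the log2 fold change strictly exceeds the cutoff."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    return log2fc > cutoff


def build_occurrence_table(
    dataset: ExpressionDataset,
    gene: str,
    older_group: str,
    younger_group: str,
    cutoff: float = 1.0,
    baseline: Baseline = "mean",
) -> Optional[OccurrenceTable]:
    """Count occurrences in both arms of one study's group pair.

    Returns None (skip marker) if either group has no samples in the study.
    Older-arm events are samples high relative to the younger group's summary
    and vice versa (symmetric construction).
    """
    older = dataset.group_samples(older_group)
    younger = dataset.group_samples(younger_group)
    if not older or not younger:
        return None
    if gene not in dataset.matrix.index:
        return None
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    log2 = dataset.log2_matrix().loc[gene]
    older_vals = log2[older].to_numpy(dtype=float)
    younger_vals = log2[younger].to_numpy(dtype=float)
    summarize = np.mean if baseline == "mean" else np.median
    # vectorized equivalent of is_occurrence(sample_log2fc(...)) per sample
    k_older = int(np.sum(older_vals - summarize(younger_vals) > cutoff))
    k_younger = int(np.sum(younger_vals - summarize(older_vals) > cutoff))
    return OccurrenceTable(
        gene=gene,
        dataset_id=dataset.dataset_id,
        older_group=older_group,
        younger_group=younger_group,
        k_older=int(k_older),
        n_older=len(older),
        k_younger=int(k_younger),
        n_younger=len(younger),
    )


def class_rate_difference(
    tables: Sequence[OccurrenceTable],
    immune_class: str = "",
) -> Optional[ClassRateResult]:
    """Pool events over all tables of a class: P_arm = sum(k)/sum(n).

    Raw events are summed across genes, samples and datasets with no
    weighting. Returns None when either arm has no samples at all.
    """
    if not tables:
        return None
    pairs = {(t.older_group, t.younger_group) for t in tables}
    if len(pairs) != 1:
        raise ValueError(f"tables mix group pairs: {sorted(pairs)}")
    older_group, younger_group = next(iter(pairs))
    n_o = sum(t.n_older for t in tables)
    n_y = sum(t.n_younger for t in tables)
    if n_o == 0 or n_y == 0:
        return None
    return ClassRateResult(
        immune_class=immune_class,
        older_group=older_group,
        younger_group=younger_group,
        k_older=sum(t.k_older for t in tables),
        n_older=n_o,
        k_younger=sum(t.k_younger for t in tables),
        n_younger=n_y,
    )


def _corrected_cells(
    table: OccurrenceTable, zero_cell_correction: float = 0.5
) -> tuple[float, float, float, float]:
    a, b, c, d = table.cells
    if min(a, b, c, d) == 0:
        return (
            a + zero_cell_correction,
            b + zero_cell_correction,
            c + zero_cell_correction,
            d + zero_cell_correction,
        )
    return (float(a), float(b), float(c), float(d))


def dataset_odds_ratio(
    table: OccurrenceTable, zero_cell_correction: float = 0.5
) -> float:
    """Cross-product odds ratio of one study's 2x2 table.

    OR = (k_o * (n_y - k_y)) / ((n_o - k_o) * k_y); any zero cell triggers
    the Haldane-Anscombe correction on all four cells of this table.
    """
    a, b, c, d = _corrected_cells(table, zero_cell_correction)
    return (a * d) / (b * c)


def mantel_haenszel(
    tables: Sequence[OccurrenceTable], zero_cell_correction: float = 0.5
) -> tuple[float, float, float, float]:
    """Mantel-Haenszel fixed-effect pooled OR with RBG variance.

    Returns (pooled_or, ci_low, ci_high, two-sided p) with the 95% CI and p
    computed from the Robins-Breslow-Greenland standard error of log(OR_MH)
    via the normal approximation.
    """
    cells = [_corrected_cells(t, zero_cell_correction) for t in tables]
    R = S = 0.0
    sum_PR = sum_PSQR = sum_QS = 0.0
    for a, b, c, d in cells:
        n = a + b + c + d
        P = (a + d) / n
        Q = (b + c) / n
        Ri = a * d / n
        Si = b * c / n
        R += Ri
        S += Si
        sum_PR += P * Ri
        sum_PSQR += P * Si + Q * Ri
        sum_QS += Q * Si
    pooled = R / S
    var = sum_PR / (2 * R * R) + sum_PSQR / (2 * R * S) + sum_QS / (2 * S * S)
    se = math.sqrt(var)
    log_or = math.log(pooled)
    z = stats.norm.ppf(0.975)
    ci_low = math.exp(log_or - z * se)
    ci_high = math.exp(log_or + z * se)
    p = 2.0 * stats.norm.sf(abs(log_or) / se) if se > 0 else float(log_or != 0.0)
    return pooled, ci_low, ci_high, p


def _dersimonian_laird(
    tables: Sequence[OccurrenceTable], zero_cell_correction: float = 0.5
) -> tuple[float, float, float, float]:
    """DerSimonian-Laird random-effects pooled OR (inverse-variance weights)."""
    cells = [_corrected_cells(t, zero_cell_correction) for t in tables]
    y = np.array([math.log((a * d) / (b * c)) for a, b, c, d in cells])
    v = np.array([1 / a + 1 / b + 1 / c + 1 / d for a, b, c, d in cells])
    w = 1.0 / v
    ybar = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - ybar) ** 2))
    df = len(y) - 1
    c_const = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / c_const) if df > 0 and c_const > 0 else 0.0
    w_star = 1.0 / (v + tau2)
    mu = float(np.sum(w_star * y) / np.sum(w_star))
    se = math.sqrt(1.0 / float(np.sum(w_star)))
    z = stats.norm.ppf(0.975)
    p = 2.0 * stats.norm.sf(abs(mu) / se) if se > 0 else float(mu != 0.0)
    return math.exp(mu), math.exp(mu - z * se), math.exp(mu + z * se), p


def pooled_odds_ratio(
    tables: Sequence[OccurrenceTable],
    model: Literal["fixed", "random"] = "fixed",
    zero_cell_correction: float = 0.5,
) -> Optional[MetaResult]:
    """Pool one gene's 2x2 tables across studies.

    Fixed effect (default) is Mantel-Haenszel with RBG CI; ``model="random"``
    selects DerSimonian-Laird. Returns None for an empty table list.
    """
    if not tables:
        return None
    genes = {t.gene for t in tables}
    pairs = {(t.older_group, t.younger_group) for t in tables}
    if len(genes) != 1 or len(pairs) != 1:
        raise ValueError("tables must share one gene and one group pair")
    pool = mantel_haenszel if model == "fixed" else _dersimonian_laird
    pooled, lo, hi, p = pool(tables, zero_cell_correction)
    return MetaResult(
        gene=next(iter(genes)),
        older_group=tables[0].older_group,
        younger_group=tables[0].younger_group,
        tables=tuple(tables),
        dataset_ors=tuple(dataset_odds_ratio(t, zero_cell_correction) for t in tables),
        pooled_or=pooled,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        model=model,
    )


@dataclass
class MetaAnalysis:
    """Bundle of class-level RD rows and per-gene meta results."""

    class_rates: pd.DataFrame
    gene_results: dict[tuple[str, str, str], MetaResult]  # (gene, older, younger)
    skipped: list[tuple[str, str, str]] = field(default_factory=list)

    def forest_table(self, older: str, younger: str) -> pd.DataFrame:
        rows = []
        for (gene, o, y), res in sorted(self.gene_results.items()):
            if (o, y) != (older, younger):
                continue
            for t, or_i in zip(res.tables, res.dataset_ors):
                rows.append(
                    {
                        "gene": gene,
                        "dataset_id": t.dataset_id,
                        "k_older": t.k_older,
                        "n_older": t.n_older,
                        "k_younger": t.k_younger,
                        "n_younger": t.n_younger,
                        "dataset_or": or_i,
                        "pooled_or": res.pooled_or,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "p_value": res.p_value,
                        "n_datasets": res.n_datasets,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "gene", "dataset_id", "k_older", "n_older", "k_younger",
                "n_younger", "dataset_or", "pooled_or", "ci_low", "ci_high",
                "p_value", "n_datasets",
            ],
        )


def run_meta_analysis(
    cohort: Cohort,
    catalog: Optional[GeneCatalog] = None,
    group_pairs: Sequence[tuple[str, str]] = DEFAULT_GROUP_PAIRS,
    cutoff: float = 1.0,
    baseline: Baseline = "mean",
    model: Literal["fixed", "random"] = "fixed",
) -> MetaAnalysis:
    """Run the full cross-study analysis for every catalog gene and class.

    For each (older, younger) pair, builds per-study occurrence tables for
    every catalog gene present in a study, pools them per gene into a
    Mantel-Haenszel odds ratio, and pools raw events per immune class into
    a rate difference. Output ordering is deterministic (class/gene, pair).
    """
    catalog = catalog or cohort.catalog
    if catalog is None:
        raise ValueError("a GeneCatalog is required (cohort.catalog or argument)")
    class_rows: list[dict] = []
    gene_results: dict[tuple[str, str, str], MetaResult] = {}
    skipped: list[tuple[str, str, str]] = []
    class_index = catalog.class_index
    for older, younger in group_pairs:
        tables_by_gene: dict[str, list[OccurrenceTable]] = {}
        for ds in cohort.datasets:
            for rec in catalog.records:
                t = build_occurrence_table(ds, rec.symbol, older, younger, cutoff, baseline)
                if t is not None:
                    tables_by_gene.setdefault(rec.symbol, []).append(t)
        for rec in catalog.records:
            tabs = tables_by_gene.get(rec.symbol)
            if not tabs:
                skipped.append((rec.symbol, older, younger))
                continue
            res = pooled_odds_ratio(tabs, model=model)
            if res is not None:
                gene_results[(rec.symbol, older, younger)] = res
        for immune_class in sorted(class_index):
            class_tabs = [
                t
                for g in class_index[immune_class]
                for t in tables_by_gene.get(g, [])
            ]
            rate = class_rate_difference(class_tabs, immune_class)
            if rate is None:
                skipped.append((f"class:{immune_class}", older, younger))
                continue
            class_rows.append(
                {
                    "immune_class": immune_class,
                    "older_group": older,
                    "younger_group": younger,
                    "P_older": rate.p_older,
                    "P_younger": rate.p_younger,
                    "RD": rate.rd,
                    "k_older": rate.k_older,
                    "n_older": rate.n_older,
                    "k_younger": rate.k_younger,
                    "n_younger": rate.n_younger,
                }
            )
    class_rates = pd.DataFrame(
        class_rows,
        columns=[
            "immune_class", "older_group", "younger_group", "P_older",
            "P_younger", "RD", "k_older", "n_older", "k_younger", "n_younger",
        ],
    )
    return MetaAnalysis(class_rates=class_rates, gene_results=gene_results, skipped=skipped)
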