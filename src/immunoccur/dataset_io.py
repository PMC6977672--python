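"""Expression-matrix / sample-metadata I-O, age binning, and cohort assembly.

A cohort is a set of independent GEO-style expression studies over Drosophila
head tissue. Samples are binned into three age groups (young < 10 days,
middle-aged 10-29 days, old >= 30 days) and a study is eligible for the
cross-study analysis only if it covers at least two of those groups, so that
an older-vs-younger contrast exists within the study.

Expression matrices are genes-in-rows TSV; each dataset declares whether its
values are linear or already log2. Linear values are harmonized internally as
log2(value + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import GeneCatalog

logger = logging.getLogger(__name__)

AGE_GROUPS = ("young", "middle_aged", "old")
AGE_GROUP_ORDER = {g: i for i, g in enumerate(AGE_GROUPS)}

METADATA_COLUMNS = ("sample_id", "dataset_id", "age_days")
_TABLE1_RESOURCE = "table1_metadata.tsv"


def bin_age(age_days: int) -> str:
    """Bin an age in days post eclosion into young/middle_aged/old.

    young: < 10 days; middle_aged: 10-29 days; old: >= 30 days.
    """
    if age_days < 0:
        raise ValueError(f"age_days must be >= 0, got {age_days}")
    if age_days < 10:
        return "young"
    if age_days <= 29:
        return "middle_aged"
    return "old"


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample annotation: accession, study, age, and derived age group."""

    sample_id: str
    dataset_id: str
    age_days: int
    condition: Optional[str] = None
    timepoint_days: Optional[int] = None

    @property
    def age_group(self) -> str:
        return bin_age(self.age_days)


@dataclass
class ExpressionDataset:
    """One study's expression matrix plus its per-sample metadata.

    ``matrix`` is a genes x samples DataFrame indexed by gene symbol with
    sample ids as columns; ``scale`` declares whether values are 'linear'
    or 'log2'.
    """

    dataset_id: str
    matrix: pd.DataFrame
    scale: str
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError(f"duplicate sample ids in dataset {self.dataset_id}")
        missing = [c for c in self.matrix.columns if c not in set(sample_ids)]
        if missing:
            raise ValueError(
                f"dataset {self.dataset_id}: matrix samples missing from "
                f"metadata: {missing}"
            )
        extra = [s for s in sample_ids if s not in set(self.matrix.columns)]
        if extra:
            raise ValueError(
                f"dataset {self.dataset_id}: metadata samples absent from "
                f"matrix: {extra}"
            )
        if self.scale == "linear" and (self.matrix.to_numpy() < 0).any():
            raise ValueError(f"dataset {self.dataset_id}: negative linear values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def sample_by_id(self) -> dict[str, SampleMeta]:
        return {s.sample_id: s for s in self.samples}

    def log2_matrix(self) -> pd.DataFrame:
        """The matrix on log2 scale; linear values get a +1 pseudocount."""
        if self.scale == "log2":
            return self.matrix
        return np.log2(self.matrix + 1.0)

    def group_samples(self, age_group: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.age_group == age_group]

    def age_groups_present(self) -> set[str]:
        return {s.age_group for s in self.samples}


@dataclass
class Cohort:
    """A collection of expression datasets analyzed against one gene catalog."""

    datasets: list[ExpressionDataset]
    catalog: Optional[GeneCatalog] = None

    def __post_init__(self) -> None:
        ids = [d.dataset_id for d in self.datasets]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate dataset_ids in cohort")

    def metadata(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": s.sample_id,
                "dataset_id": d.dataset_id,
                "age_days": s.age_days,
                "age_group": s.age_group,
            }
            for d in self.datasets
            for s in d.samples
        ]
        return pd.DataFrame(rows, columns=["sample_id", "dataset_id", "age_days", "age_group"])


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata TSV and derive the age_group column."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "dataset_id": str})
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata file missing column(s): {sorted(missing)}")
    df["age_days"] = df["age_days"].astype(int)
    df["age_group"] = df["age_days"].map(bin_age)
    return df


def load_table1_metadata() -> pd.DataFrame:
    """The packaged study-census fixture: per-GSM ages for the 18 GEO series."""
    from importlib import resources

    with resources.as_file(resources.files("immunoccur.data") / _TABLE1_RESOURCE) as p:
        return read_metadata(p)


def read_dataset(
    matrix_path: str | Path,
    metadata_path: str | Path,
    scale: str,
    dataset_id: Optional[str] = None,
) -> ExpressionDataset:
    """Read one study: a genes x samples TSV plus its metadata TSV."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    bad = matrix.columns[~matrix.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(bad):
        raise ValueError(f"non-numeric expression values in column(s) {list(bad)}")
    meta = read_metadata(metadata_path)
    if dataset_id is None:
        ids = meta["dataset_id"].unique()
        if len(ids) != 1:
            raise ValueError(
                f"metadata contains {len(ids)} dataset ids; pass dataset_id explicitly"
            )
        dataset_id = str(ids[0])
    meta = meta[meta["dataset_id"] == dataset_id]
    known = set(meta["sample_id"])
    missing = [c for c in matrix.columns if c not in known]
    if missing:
        raise ValueError(
            f"samples in matrix but not metadata for {dataset_id}: {missing}"
        )
    samples = [
        SampleMeta(
            sample_id=row.sample_id,
            dataset_id=dataset_id,
            age_days=int(row.age_days),
            condition=getattr(row, "condition", None),
            timepoint_days=(
                int(row.timepoint_days)
                if "timepoint_days" in meta.columns and pd.notna(row.timepoint_days)
                else None
            ),
        )
        for row in meta.itertuples(index=False)
        if row.sample_id in set(matrix.columns)
    ]
    return ExpressionDataset(dataset_id=dataset_id, matrix=matrix, scale=scale, samples=samples)


def write_dataset(dataset: ExpressionDataset, matrix_path: str | Path, metadata_path: str | Path) -> None:
    dataset.matrix.to_csv(matrix_path, sep="\t", index_label="gene_id")
    rows = [
        {
            "sample_id": s.sample_id,
            "dataset_id": s.dataset_id,
            "age_days": s.age_days,
            "condition": s.condition if s.condition is not None else "",
            "timepoint_days": s.timepoint_days if s.timepoint_days is not None else "",
        }
        for s in dataset.samples
    ]
    pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)


def filter_eligible(cohort: Cohort) -> Cohort:
    """Keep only datasets spanning >= 2 distinct age groups; log the rest."""
    kept, dropped = [], []
    for ds in cohort.datasets:
        (kept if len(ds.age_groups_present()) >= 2 else dropped).append(ds)
    if dropped:
        logger.info(
            "dropped %d ineligible dataset(s) (single age group): %s",
            len(dropped),
            [d.dataset_id for d in dropped],
        )
    if not kept:
        logger.warning("no eligible datasets remain after filtering")
    return Cohort(datasets=kept, catalog=cohort.catalog)


@dataclass(frozen=True)
class Census:
    n_datasets: int
    young: int
    middle_aged: int
    old: int

    def as_dict(self) -> dict[str, int]:
        return {
            "n_datasets": self.n_datasets,
            "young": self.young,
            "middle_aged": self.middle_aged,
            "old": self.old,
        }


def census(metadata: pd.DataFrame) -> Census:
    """Count datasets and samples per age group.

    A sample is counted once per dataset membership: a GSM reused by two
    series (GSM12770/GSM12772 appear under both GSE6430 and GSE826)
    contributes to each series' count, since each series is an independent
    experiment in the cross-study analysis.
    """
    if "age_group" not in metadata.columns:
        metadata = metadata.assign(age_group=metadata["age_days"].map(bin_age))
    counts = metadata["age_group"].value_counts()
    return Census(
        n_datasets=int(metadata["dataset_id"].nunique()),
        young=int(counts.get("young", 0)),
        middle_aged=int(counts.get("middle_aged", 0)),
        old=int(counts.get("old", 0)),
    )


def cohort_census(cohort: Cohort) -> Census:
    return census(cohort.metadata())
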