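import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from immunoccur.catalog import load_catalog
from immunoccur.dataset_io import ExpressionDataset, SampleMeta
from immunoccur.simulate import (
    AdTimecourseSpec,
    CohortSpec,
    generate_ad_timecourse,
    generate_aging_cohort,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    return load_catalog("default")


def make_dataset(values, ages, dataset_id="DS1", scale="log2", genes=None):
    """Build a small ExpressionDataset from a genes x samples array."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i + 1}" for i in range(n_genes)]
    sample_ids = [f"s{i + 1}" for i in range(n_samples)]
    matrix = pd.DataFrame(values, index=genes, columns=sample_ids)
    samples = [
        SampleMeta(sample_id=s, dataset_id=dataset_id, age_days=int(a))
        for s, a in zip(sample_ids, ages)
    ]
    return ExpressionDataset(
        dataset_id=dataset_id, matrix=matrix, scale=scale, samples=samples
    )


@pytest.fixture
def dataset_factory():
    return make_dataset


@pytest.fixture(scope="session")
def aging_cohort(catalog):
    cohort, truth = generate_aging_cohort(CohortSpec(seed=7), catalog)
    return cohort, truth


@pytest.fixture(scope="session")
def ad_bundle(catalog):
    return generate_ad_timecourse(AdTimecourseSpec(seed=7), catalog)
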