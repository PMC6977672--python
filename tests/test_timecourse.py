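import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from immunoccur.timecourse import (
    CountMatrix,
    bh_fdr,
    classify_profile,
    de_contrast,
    normalize,
    size_factors,
    trajectory_shape,
)

from oracles import bh_oracle


def make_counts(values, conditions, timepoints, genes=None):
    values = np.atleast_2d(np.asarray(values))
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    sample_ids = [f"s{i + 1}" for i in range(values.shape[1])]
    counts = pd.DataFrame(values, index=genes, columns=sample_ids)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "condition": conditions,
            "timepoint_days": timepoints,
            "replicate": range(1, len(sample_ids) + 1),
        }
    )
    return CountMatrix(counts=counts, meta=meta)


class TestSizeFactors:
    def test_doubled_column_splits_geometrically(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        f = size_factors(counts)
        assert f["a"] == pytest.approx(1 / math.sqrt(2))
        assert f["b"] == pytest.approx(math.sqrt(2))

    def test_identical_columns_are_unit(self):
        counts = pd.DataFrame({"a": [5, 9, 2], "b": [5, 9, 2]})
        assert size_factors(counts).tolist() == pytest.approx([1.0, 1.0])

    def test_single_sample_is_unit(self):
        assert size_factors(pd.DataFrame({"a": [3, 4]})).tolist() == [1.0]

    def test_no_commonly_expressed_gene_is_error(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="pseudocount"):
            size_factors(counts)

    def test_normalization_idempotent(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.poisson(50, size=(40, 6)) + 1)
        once = normalize(counts)
        twice = normalize(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)


class TestBhFdr:
    def test_worked_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    @pytest.mark.parametrize("p,expected", [([0.2], [0.2]), ([1.0, 1.0], [1.0, 1.0])])
    def test_edge_inputs(self, p, expected):
        assert bh_fdr(p).tolist() == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_definitional_oracle_and_dominates_p(self, p):
        q = bh_fdr(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert q.tolist() == pytest.approx(bh_oracle(p))


class TestDeContrast:
    def test_quartered_expression_gives_minus_two(self):
        eps = [0, 1, -1]
        ad = [25 + e for e in eps]
        wt = [100 + e for e in eps]
        rng = np.random.default_rng(0)
        background = rng.poisson(60, size=(9, 6)) + 1  # flat genes anchor factors
        values = np.vstack([[ad + wt], background])
        cm = make_counts(
            values, conditions=["AD"] * 3 + ["WT"] * 3, timepoints=[10] * 6
        )
        res = de_contrast(cm, 10)
        assert res.loc[0, "log2FC"] == pytest.approx(-2.0, abs=0.15)

    def test_identical_groups_are_null(self):
        cm = make_counts(
            [[50, 50, 50, 50, 50, 50], [10, 11, 9, 10, 11, 9]],
            conditions=["AD"] * 3 + ["WT"] * 3,
            timepoints=[10] * 6,
        )
        res = de_contrast(cm, 10)
        assert res.loc[0, "log2FC"] == pytest.approx(0.0)
        assert res.loc[0, "p_value"] == pytest.approx(1.0)
        assert not res["significant"].any()

    def test_too_few_replicates_is_error(self):
        cm = make_counts(
            [[5, 5, 5]], conditions=["AD", "WT", "WT"], timepoints=[10] * 3
        )
        with pytest.raises(ValueError, match="replicates"):
            de_contrast(cm, 10)

    def test_invariant_to_global_sample_scaling(self):
        rng = np.random.default_rng(8)
        base = rng.poisson(200, size=(30, 6)) + 1
        scaled = (base * np.array([1, 2, 4, 1, 3, 2])).astype(int)
        conditions = ["AD"] * 3 + ["WT"] * 3
        r1 = de_contrast(make_counts(base, conditions, [10] * 6), 10)
        r2 = de_contrast(make_counts(scaled, conditions, [10] * 6), 10)
        # size factors absorb the scaling up to the +1 pseudocount effect
        assert np.allclose(r1["log2FC"], r2["log2FC"], atol=0.05)

    def test_recovers_planted_effect(self, ad_bundle, catalog):
        res = de_contrast(ad_bundle.counts, 10).set_index("gene")
        amps = list(catalog.members("AMP"))
        assert res.loc[amps, "log2FC"].mean() == pytest.approx(-2.0, abs=0.5)
        assert res.loc["LysS", "log2FC"] == pytest.approx(3.9, abs=1.0)
        # planted genes dominate the p-value ranking even at triplicate power
        top = set(res.nsmallest(10, "p_value").index)
        assert len(top & (set(amps) | {"LysS"})) >= 8

    def test_counts_must_be_nonnegative_integers(self):
        with pytest.raises(ValueError):
            make_counts([[1.5, 2.0]], ["AD", "WT"], [10, 10])
        with pytest.raises(ValueError):
            make_counts([[-1, 2]], ["AD", "WT"], [10, 10])


class TestTrajectoryShape:
    @pytest.mark.parametrize(
        "profile,kind,min_at",
        [
            ((0, -3, 0.5, 1), "V_shaped", 10),
            ((0, 1, 2, 3), "monotone_up", None),
            ((3, 2, 1, 0), "monotone_down", None),
            ((0, 0, 0, 0), "flat", None),
            ((0, 2, 0.5, -3), "other", None),
        ],
    )
    def test_classification(self, profile, kind, min_at):
        label = classify_profile(profile, (3, 10, 20, 30))
        assert label.kind == kind
        assert label.min_at == min_at

    def test_margin_gates_v_shape(self):
        shallow = (0, -0.5, 0.4, 0.5)
        assert classify_profile(shallow, margin=1.0).kind != "V_shaped"
        assert classify_profile(shallow, margin=0.3, flat_tol=0.1).kind == "V_shaped"

    def test_needs_three_timepoints(self):
        with pytest.raises(ValueError):
            classify_profile([0, 1], timepoints=(3, 10))

    def test_dataframe_interface(self):
        prof = pd.DataFrame(
            {3: [0.0, 0.0], 10: [-3.0, 1.0], 20: [0.5, 2.0], 30: [1.0, 3.0]},
            index=["AttA", "LysS"],
        )
        out = trajectory_shape(prof).set_index("gene")
        assert out.loc["AttA", "shape"] == "V_shaped"
        assert out.loc["AttA", "min_at"] == 10
        assert out.loc["LysS", "shape"] == "monotone_up"
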