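import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from immunoccur.occurrence import (
    OccurrenceTable,
    build_occurrence_table,
    class_rate_difference,
    dataset_odds_ratio,
    is_occurrence,
    mantel_haenszel,
    pooled_odds_ratio,
    run_meta_analysis,
    sample_log2fc,
)
from immunoccur.dataset_io import Cohort

from oracles import mh_pooled_or_oracle


def table(k_o, n_o, k_y, n_y, gene="g", ds="D", older="old", younger="young"):
    return OccurrenceTable(
        gene=gene, dataset_id=ds, older_group=older, younger_group=younger,
        k_older=k_o, n_older=n_o, k_younger=k_y, n_younger=n_y,
    )


class TestSampleLog2FC:
    def test_difference_of_logs(self, dataset_factory):
        ds = dataset_factory([[9.5, 7.0, 8.0]], ages=[40, 3, 3])
        assert sample_log2fc(ds, "g1", "s1", "young") == pytest.approx(2.0)

    def test_sample_at_reference_mean_is_zero(self, dataset_factory):
        ds = dataset_factory([[7.5, 7.0, 8.0]], ages=[40, 3, 3])
        assert sample_log2fc(ds, "g1", "s1", "young") == pytest.approx(0.0)

    def test_linear_scale_uses_pseudocount(self, dataset_factory):
        ds = dataset_factory([[8.0, 2.0, 2.0]], ages=[40, 3, 3], scale="linear")
        # log2(8+1) - log2(2+1) = log2(3)
        assert sample_log2fc(ds, "g1", "s1", "young") == pytest.approx(math.log2(3))

    def test_empty_reference_group_is_domain_error(self, dataset_factory):
        ds = dataset_factory([[8.0, 2.0]], ages=[40, 40])
        with pytest.raises(ValueError, match="young"):
            sample_log2fc(ds, "g1", "s1", "young")


class TestIsOccurrence:
    @pytest.mark.parametrize(
        "fc,expected", [(1.2, True), (1.0, False), (-3.0, False), (1.000001, True)]
    )
    def test_strict_cutoff(self, fc, expected):
        assert is_occurrence(fc) is expected

    def test_cutoff_must_be_positive(self):
        with pytest.raises(ValueError):
            is_occurrence(2.0, cutoff=0.0)


class TestBuildOccurrenceTable:
    def test_counts_match_per_sample_rule(self, dataset_factory):
        # old samples at log2fc {1.5, 0.4, 2.1} vs young mean 0
        ds = dataset_factory(
            [[1.5, 0.4, 2.1, 0.1, -0.2, 0.0]], ages=[40, 40, 40, 3, 3, 3]
        )
        # shift so young mean is 0 by construction: young values 0.1,-0.2,0.0
        t = build_occurrence_table(ds, "g1", "old", "young", cutoff=1.0)
        young_mean = np.mean([0.1, -0.2, 0.0])
        assert t.k_older == sum(v - young_mean > 1.0 for v in [1.5, 0.4, 2.1]) == 2
        assert (t.n_older, t.k_younger, t.n_younger) == (3, 0, 3)

    def test_agrees_with_scalar_path(self, dataset_factory):
        rng = np.random.default_rng(3)
        values = rng.normal(7, 2, size=(1, 8))
        ds = dataset_factory(values, ages=[3, 3, 3, 3, 40, 40, 40, 40])
        t = build_occurrence_table(ds, "g1", "old", "young")
        k_older = sum(
            is_occurrence(sample_log2fc(ds, "g1", s, "young"))
            for s in ds.group_samples("old")
        )
        assert t.k_older == k_older

    def test_identical_samples_give_no_occurrences(self, dataset_factory):
        ds = dataset_factory([[5.0] * 4], ages=[3, 3, 40, 40])
        t = build_occurrence_table(ds, "g1", "old", "young")
        assert (t.k_older, t.k_younger) == (0, 0)

    def test_singleton_older_arm(self, dataset_factory):
        ds = dataset_factory([[10.0, 5.0, 5.0]], ages=[40, 3, 3])
        t = build_occurrence_table(ds, "g1", "old", "young")
        assert (t.k_older, t.n_older) == (1, 1)

    def test_absent_group_returns_skip_marker(self, dataset_factory):
        ds = dataset_factory([[5.0, 5.0]], ages=[3, 3])
        assert build_occurrence_table(ds, "g1", "old", "young") is None

    def test_invalid_group_order_rejected(self):
        with pytest.raises(ValueError, match="strictly later"):
            table(1, 2, 1, 2, older="young", younger="old")


class TestClassRateDifference:
    def test_pooled_arithmetic(self):
        res = class_rate_difference([table(2, 4, 0, 4), table(1, 4, 1, 4)], "AMP")
        assert res.p_older == pytest.approx(3 / 8)
        assert res.p_younger == pytest.approx(1 / 8)
        assert res.rd == pytest.approx(0.25)

    def test_all_zero_occurrences(self):
        assert class_rate_difference([table(0, 4, 0, 4)]).rd == 0.0

    def test_maximal_difference(self):
        assert class_rate_difference([table(4, 4, 0, 4)]).rd == 1.0

    def test_empty_input_is_undefined(self):
        assert class_rate_difference([]) is None


class TestDatasetOddsRatio:
    def test_cross_product(self):
        assert dataset_odds_ratio(table(5, 10, 1, 10)) == pytest.approx(9.0)

    def test_equal_rates_is_one(self):
        assert dataset_odds_ratio(table(2, 4, 2, 4)) == pytest.approx(1.0)

    def test_haldane_anscombe_on_zero_cell(self):
        # (5.5 * 10.5) / (5.5 * 0.5) = 21
        assert dataset_odds_ratio(table(5, 10, 0, 10)) == pytest.approx(21.0)


class TestPooledOddsRatio:
    def test_single_table_is_identity(self):
        res = pooled_odds_ratio([table(5, 10, 1, 10)])
        assert res.pooled_or == pytest.approx(9.0)
        assert res.ci_low <= res.pooled_or <= res.ci_high

    def test_identical_tables_pool_to_same_or(self):
        tabs = [table(5, 10, 1, 10, ds=f"D{i}") for i in range(4)]
        assert pooled_odds_ratio(tabs).pooled_or == pytest.approx(9.0)

    def test_matches_direct_formula_oracle(self):
        tabs = [table(3, 5, 1, 5, ds="A"), table(4, 10, 2, 10, ds="B")]
        cells = [t.cells for t in tabs]
        exp_or, exp_lo, exp_hi, exp_p = mh_pooled_or_oracle(cells)
        res = pooled_odds_ratio(tabs)
        assert res.pooled_or == pytest.approx(exp_or, rel=1e-12)
        assert res.ci_low == pytest.approx(exp_lo, rel=1e-12)
        assert res.ci_high == pytest.approx(exp_hi, rel=1e-12)
        assert res.p_value == pytest.approx(exp_p, rel=1e-9)

    def test_matches_statsmodels_stratified_table(self):
        from statsmodels.stats.contingency_tables import StratifiedTable

        tabs = [table(3, 5, 1, 5, ds="A"), table(4, 10, 2, 10, ds="B")]
        strata = np.array([[[t.k_older, t.n_older - t.k_older],
                            [t.k_younger, t.n_younger - t.k_younger]] for t in tabs])
        st_tab = StratifiedTable(list(strata))
        res = pooled_odds_ratio(tabs)
        assert res.pooled_or == pytest.approx(st_tab.oddsratio_pooled, rel=1e-12)
        lo, hi = st_tab.oddsratio_pooled_confint(0.05)
        assert res.ci_low == pytest.approx(lo, rel=1e-9)
        assert res.ci_high == pytest.approx(hi, rel=1e-9)

    def test_random_effects_matches_fixed_when_homogeneous(self):
        tabs = [table(5, 10, 1, 10, ds=f"D{i}") for i in range(3)]
        res = pooled_odds_ratio(tabs, model="random")
        assert res.pooled_or == pytest.approx(9.0, rel=1e-9)

    def test_empty_input_is_undefined(self):
        assert pooled_odds_ratio([]) is None


@st.composite
def occurrence_tables(draw, max_tables=5, max_n=20):
    k = draw(st.integers(1, max_tables))
    tabs = []
    for i in range(k):
        n_o = draw(st.integers(1, max_n))
        n_y = draw(st.integers(1, max_n))
        tabs.append(
            table(
                draw(st.integers(0, n_o)), n_o,
                draw(st.integers(0, n_y)), n_y,
                ds=f"D{i}",
            )
        )
    return tabs


class TestProperties:
    @given(occurrence_tables())
    def test_rd_and_rates_bounded(self, tabs):
        res = class_rate_difference(tabs)
        assert 0.0 <= res.p_older <= 1.0
        assert 0.0 <= res.p_younger <= 1.0
        assert -1.0 <= res.rd <= 1.0

    @given(occurrence_tables())
    def test_arm_swap_inverts_or_and_rd_sign(self, tabs):
        swapped = [t.swapped() for t in tabs]
        direct = class_rate_difference(tabs)
        flipped = class_rate_difference(swapped)
        assert flipped.rd == pytest.approx(-direct.rd)
        or_d, *_ = mantel_haenszel(tabs)
        or_s, *_ = mantel_haenszel(swapped)
        assert or_s == pytest.approx(1.0 / or_d, rel=1e-9)

    @given(occurrence_tables(max_tables=1), st.integers(2, 6))
    def test_pooling_m_identical_tables_is_invariant(self, tabs, m):
        t = tabs[0]
        copies = [table(t.k_older, t.n_older, t.k_younger, t.n_younger, ds=f"D{i}")
                  for i in range(m)]
        single, *_ = mantel_haenszel([t])
        pooled, *_ = mantel_haenszel(copies)
        assert pooled == pytest.approx(single, rel=1e-9)

    def test_raising_cutoff_never_increases_k(self, dataset_factory):
        rng = np.random.default_rng(11)
        ds = dataset_factory(rng.normal(6, 2, (3, 10)), ages=[3] * 5 + [40] * 5)
        for gene in ds.gene_ids:
            ks = [
                build_occurrence_table(ds, gene, "old", "young", cutoff=c).k_older
                for c in (0.5, 1.0, 2.0, 4.0)
            ]
            assert ks == sorted(ks, reverse=True)


class TestRunMetaAnalysis:
    def test_recovers_planted_amp_signal(self, aging_cohort):
        cohort, _ = aging_cohort
        meta = run_meta_analysis(cohort, group_pairs=[("old", "young")])
        rates = meta.class_rates.set_index("immune_class")
        assert rates.loc["AMP", "RD"] > 0.5
        non_amp = rates.drop("AMP")
        assert non_amp["RD"].abs().max() < 0.2
        amp_or = meta.gene_results[("AttA", "old", "young")]
        assert amp_or.pooled_or > 1.0 and amp_or.ci_excludes_one()

    def test_single_dataset_pooled_equals_dataset_or(self, dataset_factory):
        rng = np.random.default_rng(5)
        ds = dataset_factory(
            rng.normal(6, 2, (1, 8)), ages=[3, 3, 3, 3, 40, 40, 40, 40],
            genes=["Drs"],
        )
        from immunoccur.catalog import load_catalog

        meta = run_meta_analysis(
            Cohort([ds]), load_catalog("default"), group_pairs=[("old", "young")]
        )
        res = meta.gene_results[("Drs", "old", "young")]
        assert res.pooled_or == pytest.approx(res.dataset_ors[0])

    def test_infinite_cutoff_zeroes_everything(self, aging_cohort):
        cohort, _ = aging_cohort
        sub = Cohort(cohort.datasets[:2], cohort.catalog)
        meta = run_meta_analysis(sub, cutoff=1e9, group_pairs=[("old", "young")])
        assert (meta.class_rates["RD"] == 0).all()
        assert (meta.class_rates[["k_older", "k_younger"]] == 0).all().all()

    def test_output_ordering_deterministic(self, aging_cohort):
        cohort, _ = aging_cohort
        sub = Cohort(cohort.datasets[:2], cohort.catalog)
        a = run_meta_analysis(sub, group_pairs=[("old", "young")])
        b = run_meta_analysis(sub, group_pairs=[("old", "young")])
        assert a.class_rates.equals(b.class_rates)
        assert list(a.gene_results) == list(b.gene_results)
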