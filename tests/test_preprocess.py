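import numpy as np
import pandas as pd
import pytest

from envim.errors import (
    DegenerateSampleError,
    EmptyResultError,
    ImputationError,
    MatchingError,
    ParameterError,
)
from envim.preprocess import (
    FilterSpec,
    drop_high_missing,
    filter_features,
    filter_metabolites_by_pathway,
    impute_qrilc,
    match_and_combine,
    censored_normal_fit,
    split_train_test,
    to_relative_abundance,
)
from envim.tables import FeatureMap

from conftest import make_table


class TestRelativeAbundance:
    def test_simple_row(self):
        t = to_relative_abundance(make_table([[2, 3, 5]]))
        np.testing.assert_allclose(t.values, [[0.2, 0.3, 0.5]])
        assert t.unit.value == "RELATIVE"

    def test_already_normalized_row_is_fixed_point(self):
        t = to_relative_abundance(make_table([[0.2, 0.3, 0.5], [1, 1, 2]]))
        np.testing.assert_allclose(t.values[0], [0.2, 0.3, 0.5])

    def test_zero_sum_row_names_sample(self):
        with pytest.raises(DegenerateSampleError, match="s1"):
            to_relative_abundance(make_table([[1, 2], [0, 0]]))

    def test_row_sums_one(self, rng):
        t = to_relative_abundance(make_table(rng.uniform(0.1, 5, (10, 20))))
        np.testing.assert_allclose(t.values.sum(axis=1), 1.0, atol=1e-12)


class TestFilterFeatures:
    GENE_SPEC = FilterSpec(5e-5, 0.9)

    def _table(self):
        # f0 mean 4e-5 (too rare), f1 abundant, f2 zero in 95% of samples
        vals = np.full((20, 3), 0.0)
        vals[:, 0] = 4e-5
        vals[:, 1] = 0.5
        vals[0, 2] = 0.2
        rest = 1.0 - vals.sum(axis=1)
        df = pd.DataFrame(
            np.column_stack([vals, rest]),
            index=[f"s{i}" for i in range(20)],
            columns=["f0", "f1", "f2", "fill"],
        )
        from envim.tables import AbundanceTable

        return AbundanceTable(df, "RELATIVE", "DNA")

    def test_low_abundance_and_low_prevalence_removed(self):
        out = filter_features(self._table(), self.GENE_SPEC)
        assert out.feature_ids == ["f1", "fill"]

    def test_vacuous_spec_is_identity(self):
        t = self._table()
        out = filter_features(t, FilterSpec(0.0, 1.0))
        pd.testing.assert_frame_equal(out.data, t.data)

    def test_idempotent(self):
        once = filter_features(self._table(), self.GENE_SPEC)
        twice = filter_features(once, self.GENE_SPEC)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_everything_removed_raises(self):
        with pytest.raises(EmptyResultError):
            filter_features(self._table(), FilterSpec(0.9, 0.0))


class TestDropHighMissing:
    def _table(self):
        vals = np.ones((20, 2))
        vals[:19, 0] = np.nan  # 95% missing
        return make_table(vals, modality="METABOLITE")

    def test_feature_above_threshold_dropped(self):
        out = drop_high_missing(self._table(), 0.9, axis="features")
        assert out.feature_ids == ["f1"]

    def test_fully_observed_unchanged(self):
        t = make_table(np.ones((5, 3)), modality="METABOLITE")
        out = drop_high_missing(t, 0.9)
        pd.testing.assert_frame_equal(out.data, t.data)

    def test_all_missing_sample_dropped(self):
        vals = np.ones((4, 3))
        vals[2, :] = np.nan
        out = drop_high_missing(make_table(vals, modality="METABOLITE"), 0.9, axis="samples")
        assert out.sample_ids == ["s0", "s1", "s3"]


class TestQrilc:
    def _censored(self, seed, n=200, frac=0.3):
        r = np.random.default_rng(seed)
        x = np.exp(r.normal(0.0, 1.0, (n, 3)))
        df = pd.DataFrame(x, index=[f"s{i}" for i in range(n)],
                          columns=["m0", "m1", "m2"])
        for c in df.columns:
            df.loc[df[c] < df[c].quantile(frac), c] = np.nan
        return make_table(df.to_numpy(), modality="METABOLITE")

    def test_no_missing_is_identity(self):
        t = make_table(np.ones((5, 2)) * 2.0, modality="METABOLITE")
        out = impute_qrilc(t, seed=1)
        pd.testing.assert_frame_equal(out.data, t.data)

    def test_imputed_below_observed_minimum(self):
        t = self._censored(seed=11)
        out = impute_qrilc(t, seed=5)
        for j in range(t.n_features):
            miss = np.isnan(t.values[:, j])
            assert out.values[miss, j].max() < t.values[~miss, j].min()

    def test_observed_entries_untouched_and_deterministic(self):
        t = self._censored(seed=12)
        a = impute_qrilc(t, seed=9)
        b = impute_qrilc(t, seed=9)
        miss = np.isnan(t.values)
        np.testing.assert_array_equal(a.values[~miss], t.values[~miss])
        np.testing.assert_array_equal(a.values, b.values)

    def test_sigma_recovery_under_censoring(self):
        # 30% left-censoring of a log-normal: the log-scale sd estimate from
        # the quantile regression should track the true sd
        errs = []
        for s in range(10):
            r = np.random.default_rng(1000 + s)
            x = r.normal(1.0, 0.8, 200)
            y = x.copy()
            y[x < np.quantile(x, 0.3)] = np.nan
            _, sigma, _ = censored_normal_fit(y)
            errs.append(abs(sigma - 0.8) / 0.8)
        assert np.mean(errs) < 0.25

    def test_too_few_observed_values(self):
        vals = np.full((10, 1), np.nan)
        vals[:2, 0] = 1.0
        with pytest.raises(ImputationError, match="f0"):
            impute_qrilc(make_table(vals, modality="METABOLITE"), seed=0)


class TestPathwayFilter:
    FMAP = FeatureMap(
        [("f0", "p1"), ("f1", "p2"), ("f1", "p3")], kind="METABOLITE_TO_PATHWAY"
    )

    def test_membership(self):
        t = make_table(np.ones((3, 3)), modality="METABOLITE")
        out = filter_metabolites_by_pathway(t, self.FMAP, {"p1", "p3"})
        assert out.feature_ids == ["f0", "f1"]  # f2 unmapped -> dropped

    def test_all_mapped_unchanged(self):
        t = make_table(np.ones((3, 2)), modality="METABOLITE")
        out = filter_metabolites_by_pathway(t, self.FMAP, {"p1", "p2"})
        assert out.feature_ids == ["f0", "f1"]

    def test_empty_observed_set(self):
        t = make_table(np.ones((3, 2)), modality="METABOLITE")
        with pytest.raises(EmptyResultError):
            filter_metabolites_by_pathway(t, self.FMAP, set())


class TestMatchAndCombine:
    def _tables(self):
        dna = make_table(np.arange(10.0).reshape(5, 2), modality="DNA")
        rna = make_table(np.arange(8.0).reshape(4, 2) + 1, modality="RNA")
        metab = make_table(np.ones((4, 3)) + 1, modality="METABOLITE")
        return dna, rna, metab

    def test_intersection_and_suffixes(self):
        dna, rna, metab = self._tables()
        genes, m = match_and_combine([dna, rna], metab)
        assert genes.n_samples == m.n_samples == 4
        assert genes.sample_ids == m.sample_ids
        assert genes.feature_ids == ["f0|DNA", "f1|DNA", "f0|RNA", "f1|RNA"]
        assert genes.modality.value == "BOTH"

    def test_single_table_keeps_modality(self):
        dna, _, metab = self._tables()
        genes, _ = match_and_combine([dna], metab)
        assert genes.modality.value == "DNA"
        assert genes.feature_ids == ["f0", "f1"]

    def test_empty_intersection(self):
        dna = make_table(np.ones((3, 2)), prefix=("a", "f"))
        metab = make_table(np.ones((3, 2)), modality="METABOLITE", prefix=("b", "m"))
        with pytest.raises(MatchingError):
            match_and_combine([dna], metab)


class TestSplit:
    def test_75_25(self):
        ids = [f"s{i}" for i in range(100)]
        sp = split_train_test(ids, 0.25, seed=1)
        assert len(sp.train_sample_ids) == 75 and len(sp.test_sample_ids) == 25
        assert set(sp.train_sample_ids) | set(sp.test_sample_ids) == set(ids)
        assert not set(sp.train_sample_ids) & set(sp.test_sample_ids)

    def test_seed_reproducible_and_distinct(self):
        ids = [f"s{i}" for i in range(60)]
        a = split_train_test(ids, 0.25, seed=1)
        b = split_train_test(ids, 0.25, seed=1)
        c = split_train_test(ids, 0.25, seed=2)
        assert a == b
        assert a.test_sample_ids != c.test_sample_ids

    def test_bad_fraction(self):
        with pytest.raises(ParameterError):
            split_train_test([f"s{i}" for i in range(10)], 1.5, seed=0)
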