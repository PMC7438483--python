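import numpy as np
import pandas as pd
import pytest

from oracles import wc_fst_oracle
from polyburden import differentiation as diff
from polyburden import synthetic_data as sd
from conftest import make_matrix


class TestWcFst:
    def test_fixed_difference_is_one(self):
        res = diff.wc_fst_counts((0, 0, 10), (10, 0, 0))
        assert res.defined
        assert res.theta == pytest.approx(1.0, abs=1e-15)

    def test_identical_counts_nonpositive(self):
        res = diff.wc_fst_counts((5, 5, 5), (5, 5, 5))
        assert res.defined
        assert res.theta <= 0

    def test_matches_oracle_on_example(self):
        res = diff.wc_fst_counts((2, 2, 1), (4, 1, 0))
        theta, a, b, c = wc_fst_oracle([(2, 2, 1), (4, 1, 0)])
        assert res.theta == pytest.approx(theta, abs=1e-12)
        assert res.a == pytest.approx(a, abs=1e-12)
        assert res.b == pytest.approx(b, abs=1e-12)
        assert res.c == pytest.approx(c, abs=1e-12)

    def test_matches_oracle_on_random_configurations(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            c1 = tuple(rng.integers(0, 30, size=3))
            c2 = tuple(rng.integers(0, 30, size=3))
            if sum(c1) < 2 or sum(c2) < 2:
                continue
            res = diff.wc_fst_counts(c1, c2)
            theta, *_ = wc_fst_oracle([c1, c2])
            if np.isnan(theta):
                assert not res.defined
            else:
                assert res.theta == pytest.approx(theta, abs=1e-12)

    def test_symmetric_in_population_order(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            c1 = tuple(rng.integers(1, 20, size=3))
            c2 = tuple(rng.integers(1, 20, size=3))
            r12 = diff.wc_fst_counts(c1, c2)
            r21 = diff.wc_fst_counts(c2, c1)
            if r12.defined:
                assert r12.theta == pytest.approx(r21.theta, abs=1e-12)

    def test_monomorphic_same_allele_undefined(self):
        res = diff.wc_fst_counts((10, 0, 0), (10, 0, 0))
        assert not res.defined

    def test_too_few_samples_flagged_not_crash(self):
        res = diff.wc_fst_counts((1, 0, 0), (5, 5, 5))
        assert not res.defined

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            diff.wc_fst_counts((-1, 0, 5), (1, 1, 1))


class TestPairwiseFst:
    def test_vectorized_matches_per_snp_counts(self):
        rng = np.random.default_rng(23)
        dosages = rng.integers(0, 3, size=(40, 10)).astype(float)
        pops = ["A"] * 18 + ["B"] * 22
        gt = make_matrix(dosages, populations=pops)
        frame = diff.pairwise_fst(gt, "A", "B")
        for j, row in frame.iterrows():
            da = dosages[:18, j]
            db = dosages[18:, j]
            counts = lambda d: ((d == 0).sum(), (d == 1).sum(), (d == 2).sum())
            single = diff.wc_fst_counts(counts(da), counts(db))
            if single.defined:
                assert row.theta == pytest.approx(single.theta, abs=1e-12)
            else:
                assert not row.defined

    def test_monotone_in_divergence(self):
        means = []
        for c in (0.01, 0.05, 0.1, 0.2):
            cfg = sd.SimConfig(
                n_snps=500, n_risk_snps=5, seed=31,
                populations=(
                    sd.PopulationSpec("A", 150, c),
                    sd.PopulationSpec("B", 150, c),
                ),
            )
            freqs = sd.population_frequency_table(cfg)
            gt = sd.simulate_genotypes(freqs, cfg)
            means.append(diff.mean_fst(diff.pairwise_fst(gt, "A", "B")).mean_of_ratios)
        assert means == sorted(means)


class TestMeanFst:
    def make_frame(self, thetas):
        return pd.DataFrame(
            {
                "snp_id": [f"rs{i}" for i in range(len(thetas))],
                "pop_a": "A", "pop_b": "B",
                "theta": thetas, "a": thetas, "b": 0.0, "c": 0.0,
                "defined": [not np.isnan(t) for t in thetas],
            }
        ).assign(a=lambda d: d.theta, b=lambda d: 1 - d.theta, c=0.0)

    def test_simple_mean(self):
        assert diff.mean_fst(self.make_frame([0.1, 0.3])).mean_of_ratios == pytest.approx(0.2)

    def test_single_value(self):
        assert diff.mean_fst(self.make_frame([0.25])).mean_of_ratios == pytest.approx(0.25)

    def test_undefined_excluded(self):
        out = diff.mean_fst(self.make_frame([0.1, np.nan, 0.3]))
        assert out.mean_of_ratios == pytest.approx(0.2)
        assert out.n_defined == 2

    def test_all_undefined_raises(self):
        with pytest.raises(ValueError):
            diff.mean_fst(self.make_frame([np.nan]))

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(6)
        thetas = rng.uniform(-0.05, 0.8, size=100).tolist()
        out = diff.mean_fst(self.make_frame(thetas))
        assert out.mean_of_ratios == pytest.approx(sum(thetas) / 100)


class TestFrequencyMatching:
    def test_pool_equals_target_gives_permutation(self):
        target = pd.Series({f"t{i}": f for i, f in enumerate(np.linspace(0.05, 0.95, 20))})
        chosen = diff.sample_frequency_matched(target, target.copy(), seed=1)
        assert sorted(chosen) == sorted(target.index)

    def test_matching_constraint_respected(self):
        target = pd.Series({f"t{i}": 0.5 for i in range(10)})
        pool = pd.Series(
            {f"a{i}": 0.5 for i in range(10)} | {f"b{i}": 0.05 for i in range(10)}
        )
        chosen = diff.sample_frequency_matched(target, pool, seed=2)
        assert all(c.startswith("a") for c in chosen)

    def test_per_bin_histogram_identical(self):
        rng = np.random.default_rng(9)
        target = pd.Series(rng.uniform(0, 1, 1000), index=[f"t{i}" for i in range(1000)])
        pool = pd.Series(rng.uniform(0, 1, 5000), index=[f"p{i}" for i in range(5000)])
        bw = 0.02
        chosen = diff.sample_frequency_matched(target, pool, bin_width=bw, seed=3)
        assert len(chosen) == len(target)
        tgt_bins = np.floor(target.to_numpy() / bw).astype(int)
        got_bins = np.floor(pool[chosen].to_numpy() / bw).astype(int)
        assert np.bincount(tgt_bins, minlength=60).tolist() == np.bincount(
            got_bins, minlength=60
        ).tolist()

    def test_ks_distance_bounded_by_bin_width(self):
        rng = np.random.default_rng(10)
        target = pd.Series(rng.beta(2, 5, 500), index=[f"t{i}" for i in range(500)])
        pool = pd.Series(rng.uniform(0, 1, 4000), index=[f"p{i}" for i in range(4000)])
        from scipy.stats import ks_2samp

        chosen = diff.sample_frequency_matched(target, pool, bin_width=0.02, seed=4)
        stat = ks_2samp(target.to_numpy(), pool[chosen].to_numpy()).statistic
        assert stat <= 0.02 + 1e-9

    def test_exhausted_bin_falls_back_with_warning(self):
        target = pd.Series({"t0": 0.5, "t1": 0.5})
        pool = pd.Series({"p0": 0.5, "p1": 0.1})
        with pytest.warns(UserWarning, match="exhausted"):
            chosen = diff.sample_frequency_matched(target, pool, seed=5)
        assert sorted(chosen) == ["p0", "p1"]

    def test_exhausted_pool_raises(self):
        target = pd.Series({"t0": 0.5, "t1": 0.5})
        pool = pd.Series({"p0": 0.5})
        with pytest.raises(ValueError):
            diff.sample_frequency_matched(target, pool, seed=6)

    def test_seeded_reproducible(self):
        rng = np.random.default_rng(11)
        target = pd.Series(rng.uniform(0, 1, 50), index=[f"t{i}" for i in range(50)])
        pool = pd.Series(rng.uniform(0, 1, 500), index=[f"p{i}" for i in range(500)])
        a = diff.sample_frequency_matched(target, pool, seed=7)
        b = diff.sample_frequency_matched(target, pool, seed=7)
        assert a == b


class TestSelectionTest:
    def test_identical_sets_null(self):
        vals = pd.Series(np.linspace(0, 0.3, 100))
        res = diff.high_fst_selection_test(vals, vals.copy())
        assert res.chi2 == 0.0
        assert res.pvalue == 1.0

    def test_printed_statistic_p_value_relation(self):
        assert diff.chi2_upper_tail(0.178, 1) == pytest.approx(0.67, abs=0.005)

    def test_statistic_matches_oracle_on_counts(self):
        # independently coded Pearson chi-square on the 2x2 high/not x set table
        n_t, n_r, n = 109, 120, 2302
        table = np.array([[n_t, n - n_t], [n_r, n - n_r]], dtype=float)
        grand = table.sum()
        expected = table.sum(1)[:, None] * table.sum(0)[None, :] / grand
        stat_oracle = ((table - expected) ** 2 / expected).sum()
        stat, p = diff.pearson_chi2_2x2(table)
        assert stat == pytest.approx(stat_oracle, rel=1e-12)
        assert 0 <= p <= 1

    def test_size_mismatch_raises(self):
        with pytest.raises(ValueError):
            diff.high_fst_selection_test(pd.Series([0.1]), pd.Series([0.1, 0.2]))

    def test_floor_and_quantile_conjunction(self):
        # all values below the floor -> nothing is "high" even above the quantile
        t = pd.Series(np.full(100, 0.04))
        r = pd.Series(np.full(100, 0.01))
        res = diff.high_fst_selection_test(t, r, fst_floor=0.05)
        assert res.n_high_fst_t2d == 0 and res.n_high_fst_random == 0


class TestGenotypePca:
    def test_two_populations_separate_on_pc1(self):
        cfg = sd.SimConfig(
            n_snps=300, n_risk_snps=5, seed=13,
            populations=(
                sd.PopulationSpec("A", 100, 0.1),
                sd.PopulationSpec("B", 100, 0.1),
            ),
        )
        freqs = sd.population_frequency_table(cfg)
        gt = sd.simulate_genotypes(freqs, cfg)
        res = diff.genotype_pca(gt, n_components=4)
        pc1 = res.scores.PC1
        a = pc1.iloc[:100]
        b = pc1.iloc[100:]
        pooled_sd = np.sqrt((a.var() + b.var()) / 2)
        assert abs(a.mean() - b.mean()) > 3 * pooled_sd

    def test_duplicate_samples_get_identical_scores(self):
        rng = np.random.default_rng(15)
        dosages = rng.integers(0, 3, size=(20, 30)).astype(float)
        doubled = np.vstack([dosages, dosages])
        gt = make_matrix(doubled)
        res = diff.genotype_pca(gt, n_components=3)
        np.testing.assert_allclose(
            res.scores.iloc[:20].to_numpy(), res.scores.iloc[20:].to_numpy(), atol=1e-8
        )

    def test_null_structure_low_pc1_share(self):
        cfg = sd.SimConfig(
            n_snps=400, n_risk_snps=5, seed=19,
            populations=(sd.PopulationSpec("A", 200, 0.0),),
        )
        freqs = sd.population_frequency_table(cfg)
        gt = sd.simulate_genotypes(freqs, cfg)
        res = diff.genotype_pca(gt, n_components=2)
        baseline = 1.0 / min(gt.n_samples, res.n_snps_used)
        assert res.explained_variance_ratio[0] < 5 * baseline

    def test_scores_orthogonal(self, small_genotypes):
        res = diff.genotype_pca(small_genotypes, n_components=5)
        s = res.scores.to_numpy()
        gram = s.T @ s
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_explained_variance_fractions_sum_below_one(self, small_genotypes):
        res = diff.genotype_pca(small_genotypes, n_components=5)
        assert res.explained_variance_ratio.sum() <= 1 + 1e-12

    def test_all_monomorphic_raises(self):
        gt = make_matrix(np.zeros((10, 5)))
        with pytest.raises(ValueError):
            diff.genotype_pca(gt)

    def test_missing_dosages_mean_imputed(self):
        rng = np.random.default_rng(20)
        dosages = rng.integers(0, 3, size=(30, 20)).astype(float)
        dosages[rng.uniform(size=dosages.shape) < 0.1] = np.nan
        gt = make_matrix(dosages)
        res = diff.genotype_pca(gt, n_components=2)
        assert np.isfinite(res.scores.to_numpy()).all()
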