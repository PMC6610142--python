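import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from enterokit import SyntheticConfig, generate_cohort, to_relative_abundance
from enterokit.discriminant import (bh_adjust, differential_genera,
                                    fisher_exact_2x2, mann_whitney_u,
                                    plsda_fit, sparse_kmeans, sparse_plsda_cv)

from oracles import fisher_exact_brute, mannwhitney_exact_brute


class TestMannWhitney:
    def test_extreme_separation_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/C(6,3) tails

    def test_against_enumeration_oracle(self, rng):
        for _ in range(10):
            nx, ny = rng.integers(3, 9, size=2)
            x = rng.normal(size=nx)
            y = rng.normal(loc=0.5, size=ny)
            _, p = mann_whitney_u(x, y)
            assert p == pytest.approx(mannwhitney_exact_brute(x, y), abs=1e-10)

    def test_monotone_transform_invariance(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=9)
        u1, p1 = mann_whitney_u(x, y)
        u2, p2 = mann_whitney_u(np.exp(x), np.exp(y))
        assert u1 == u2 and p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestFisher:
    def test_independent_table(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_perfect_association(self):
        from scipy.special import comb
        p = fisher_exact_2x2([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_against_hypergeometric_oracle(self, rng):
        for _ in range(20):
            t = rng.integers(0, 12, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            assert fisher_exact_2x2(t) == pytest.approx(
                fisher_exact_brute(t), abs=1e-9)

    def test_zero_margin_convention(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_and_equal_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), 0.3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_monotone_and_dominates_raw(self, ps):
        q = bh_adjust(ps)
        assert (q >= np.asarray(ps) - 1e-12).all()
        assert (q <= 1.0).all()
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-12).all()  # order-preserving

    def test_bad_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


@pytest.fixture(scope="module")
def result():
    cohort = generate_cohort(SyntheticConfig(seed=1))
    genus = to_relative_abundance(cohort.otu_table.genus_table())
    return cohort, differential_genera(genus, cohort.true_labels)


class TestDifferentialGenera:

    def test_exclusive_genus_flagged(self, result):
        cohort, res = result
        prof = cohort.expected_genus_profiles
        exclusive = prof.index[(prof["role"] == "exclusive") & (prof[2] == 0)]
        sub = res.table.loc[[g for g in exclusive if g in res.table.index]]
        observed = sub[sub["prevalence_2"] == 0]
        assert (observed["exclusive_to"] == "1").all()
        assert observed["significant"].any()

    def test_spiked_genera_recovered(self, result):
        cohort, res = result
        prof = cohort.expected_genus_profiles
        spiked = prof.index[prof["role"] == "discriminant"]
        rate = res.table.loc[spiked, "significant"].mean()
        assert rate >= 0.9

    def test_adjusted_dominates_raw(self, result):
        _, res = result
        t = res.table
        assert (t["q_mw"] >= t["p_mw"] - 1e-12).all()
        assert (t["q_fisher"] >= t["p_fisher"] - 1e-12).all()

    def test_identical_distributions_not_significant(self, rng):
        x = pd.DataFrame(rng.dirichlet(np.ones(5), size=20),
                         columns=list("abcde"),
                         index=[f"s{i}" for i in range(20)])
        labels = pd.Series([1] * 10 + [2] * 10, index=x.index)
        res = differential_genera(x, labels)
        assert not res.table["significant"].any()


class TestPlsda:
    def test_separating_column_ranks_first(self, rng):
        n = 40
        labels = pd.Series([1] * 20 + [2] * 20,
                           index=[f"s{i}" for i in range(n)])
        x = pd.DataFrame(rng.normal(size=(n, 10)),
                         columns=[f"g{j}" for j in range(10)],
                         index=labels.index)
        x["g3"] = np.where(labels == 1, 5.0, -5.0) + rng.normal(scale=0.1, size=n)
        model = plsda_fit(x, labels)
        assert model.ranking[0] == "g3"

    def test_scores_orthogonal(self, genus_relabund, default_cohort):
        model = plsda_fit(genus_relabund, default_cohort.true_labels, n_components=3)
        t = model.scores.to_numpy()
        gram = t.T @ t
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() / np.abs(np.diag(gram)).max() < 1e-8

    def test_matches_sklearn_pls(self, rng):
        """Dense NIPALS agrees with sklearn's PLSRegression scores up to
        sign on the same centered/scaled problem."""
        from sklearn.cross_decomposition import PLSRegression
        n = 30
        labels = pd.Series(rng.integers(1, 3, n), index=[f"s{i}" for i in range(n)])
        x = pd.DataFrame(rng.normal(size=(n, 8)), index=labels.index,
                         columns=[f"g{j}" for j in range(8)])
        x.iloc[:, 0] += (labels == 1) * 2.0
        mine = plsda_fit(x, labels, n_components=2, scale=True)
        y = np.column_stack([(labels == c).to_numpy(float) for c in (1, 2)])
        ref = PLSRegression(n_components=2, scale=True).fit(x.to_numpy(), y)
        for comp in range(2):
            a = mine.scores.iloc[:, comp].to_numpy()
            b = ref.x_scores_[:, comp]
            cos = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
            assert cos > 1 - 1e-6

    def test_permuted_labels_near_chance_auc(self, rng, genus_relabund,
                                             default_cohort):
        perm = pd.Series(rng.permutation(default_cohort.true_labels.to_numpy()),
                         index=default_cohort.true_labels.index)
        sel = sparse_plsda_cv(genus_relabund, perm, sparsity_grid=(5, 10),
                              folds=5, seed=0)
        assert max(sel.auc_by_sparsity.values()) < 0.75


class TestSparsePlsda:
    def test_perfectly_separable_genus_auc_one(self, rng):
        n = 30
        labels = pd.Series([1] * 15 + [2] * 15, index=[f"s{i}" for i in range(n)])
        x = pd.DataFrame(rng.normal(size=(n, 6)), index=labels.index,
                         columns=[f"g{j}" for j in range(6)])
        x["g0"] = np.where(labels == 1, 10.0, -10.0)
        sel = sparse_plsda_cv(x, labels, sparsity_grid=(1, 2), folds=5, seed=1)
        assert sel.cv_auc == pytest.approx(1.0)
        assert "g0" in sel.selected

    def test_selection_recovery(self, rng):
        """5 informative genera among 200 noise: selection concentrates on
        the informative ones with high AUC."""
        n = 50
        labels = pd.Series([1] * 20 + [2] * 30, index=[f"s{i}" for i in range(n)])
        informative = [f"inf{j}" for j in range(5)]
        x = pd.DataFrame(rng.normal(size=(n, 200)), index=labels.index,
                         columns=[f"noise{j}" for j in range(200)])
        for g in informative:
            x[g] = np.where(labels == 1, 1.5, -1.5) + rng.normal(size=n)
        sel = sparse_plsda_cv(x, labels, sparsity_grid=(1, 2, 3, 5, 8),
                              folds=5, seed=2)
        assert sel.cv_auc >= 0.95
        noise_picked = [g for g in sel.selected if g.startswith("noise")]
        assert len(noise_picked) <= 1
        assert set(sel.selected) - set(noise_picked) <= set(informative)


class TestSparseKmeans:
    def test_constraints_feasible(self, rng):
        x = pd.DataFrame(rng.normal(size=(30, 12)))
        res = sparse_kmeans(x, k=2, l1_bound=2.0, seed=0)
        w = res.weights.to_numpy()
        assert (w >= 0).all()
        assert np.linalg.norm(w) <= 1 + 1e-9
        assert np.abs(w).sum() <= 2.0 + 1e-9

    def test_loose_bound_matches_plain_kmeans(self, rng):
        from sklearn.cluster import KMeans
        from sklearn.metrics import adjusted_rand_score
        centers = np.array([[0] * 6, [6] * 6])
        x = np.vstack([c + rng.normal(size=(15, 6)) for c in centers])
        xd = pd.DataFrame(x)
        sd = x.std(axis=0)
        xs = (x - x.mean(axis=0)) / sd
        plain = KMeans(2, n_init=10, random_state=0).fit_predict(xs)
        res = sparse_kmeans(xd, k=2, l1_bound=np.sqrt(6), seed=0)
        assert adjusted_rand_score(plain, res.labels.to_numpy()) == 1.0

    def test_informative_feature_recovery(self, rng):
        """3 informative features among 100: weights concentrate on them
        and the partition matches truth."""
        from sklearn.metrics import adjusted_rand_score
        n = 60
        truth = np.array([0] * 30 + [1] * 30)
        x = rng.normal(size=(n, 100))
        for j in range(3):
            x[:, j] += np.where(truth == 0, 2.5, -2.5)
        res = sparse_kmeans(pd.DataFrame(x), k=2, l1_bound=1.5, seed=1)
        w = res.weights.to_numpy()
        assert w[:3].sum() / w.sum() > 0.9
        assert adjusted_rand_score(truth, res.labels.to_numpy()) > 0.9

    def test_bad_arguments(self, rng):
        x = pd.DataFrame(rng.normal(size=(10, 4)))
        with pytest.raises(ValueError):
            sparse_kmeans(x, k=1, l1_bound=2)
        with pytest.raises(ValueError):
            sparse_kmeans(x, k=2, l1_bound=0.5)
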