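import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from enterokit.association import (envfit, fisher_exact_2xc, permanova,
                                   pq_normalize, screen_variables,
                                   two_way_anova)
from enterokit.beta import DistanceMatrix, Ordination


def euclid_dm(x):
    x = np.asarray(x, dtype=float)
    ids = [f"s{i}" for i in range(len(x))]
    return DistanceMatrix(ids, squareform(pdist(x)))


class TestPermanova:
    def test_hand_ss_decomposition(self):
        """4-sample toy: pseudo-F agrees with the direct within/between
        sum-of-squared-distances partition."""
        x = np.array([[0.0], [1.0], [10.0], [11.0]])
        dm = euclid_dm(x)
        g = pd.Series(["a", "a", "b", "b"], index=dm.ids)
        res = permanova(dm, g, n_perm=99, seed=0)
        d2 = dm.data ** 2
        ss_total = d2[np.triu_indices(4, 1)].sum() / 4
        ss_within = (d2[0, 1] + d2[2, 3]) / 2
        f_hand = ((ss_total - ss_within) / 1) / (ss_within / 2)
        assert res.pseudo_f == pytest.approx(f_hand, rel=1e-10)

    def test_extreme_separation_minimal_p(self, rng):
        x = np.vstack([rng.normal(0, 0.1, (8, 2)),
                       rng.normal(100, 0.1, (8, 2))])
        dm = euclid_dm(x)
        g = pd.Series(["a"] * 8 + ["b"] * 8, index=dm.ids)
        res = permanova(dm, g, n_perm=199, seed=1)
        assert res.p_value == pytest.approx(1 / 200)

    def test_matches_skbio_single_factor(self, rng):
        """Cross-check pseudo-F against scikit-bio's PERMANOVA."""
        import skbio
        x = rng.normal(size=(18, 3))
        dm = euclid_dm(x)
        g = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        res = permanova(dm, pd.Series(g, index=dm.ids), n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.data, dm.ids), grouping=g, permutations=0)
        assert res.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-8)

    def test_sequential_terms_sum_to_model_ss(self, rng):
        x = rng.normal(size=(20, 2))
        dm = euclid_dm(x)
        design = pd.DataFrame({
            "g": ["a", "b"] * 10,
            "z": rng.normal(size=20),
        }, index=dm.ids)
        res = permanova(dm, design, n_perm=99, seed=0)
        assert len(res.table) == 2
        assert (res.table["ss"] > 0).all()

    def test_constant_design_rejected(self, rng):
        dm = euclid_dm(rng.normal(size=(6, 2)))
        with pytest.raises(ValueError):
            permanova(dm, pd.Series(["a"] * 6, index=dm.ids), n_perm=99)


class TestEnvfit:
    @pytest.fixture()
    def ordination(self, rng):
        coords = pd.DataFrame(rng.normal(size=(30, 2)),
                              index=[f"s{i}" for i in range(30)],
                              columns=["A1", "A2"])
        return Ordination(coords=coords)

    def test_axis_variable_perfect_fit(self, ordination):
        v = pd.DataFrame({"ax1": ordination.coords["A1"]})
        out = envfit(ordination, v, n_perm=199, seed=0)
        assert out.loc["ax1", "r2"] == pytest.approx(1.0)
        assert out.loc["ax1", "p"] == pytest.approx(1 / 200)

    def test_diagonal_direction(self, ordination):
        # decorrelate axes first so the LS direction is exactly (1,1)/sqrt(2)
        c = ordination.coords - ordination.coords.mean()
        q, _ = np.linalg.qr(c.to_numpy())
        coords = pd.DataFrame(q, index=c.index, columns=c.columns)
        ordn = Ordination(coords=coords)
        v = pd.DataFrame({"diag": coords["A1"] + coords["A2"]})
        out = envfit(ordn, v, n_perm=99, seed=0)
        np.testing.assert_allclose(np.abs(out.loc["diag", "direction"]),
                                   1 / np.sqrt(2), atol=1e-9)

    def test_constant_variable(self, ordination):
        out = envfit(ordination, pd.DataFrame({"c": np.ones(30)},
                                              index=ordination.coords.index),
                     n_perm=99, seed=0)
        assert out.loc["c", "r2"] == 0.0 and out.loc["c", "p"] == 1.0

    def test_null_p_roughly_uniform(self, ordination, rng):
        ps = []
        for i in range(100):
            v = pd.DataFrame({"noise": rng.normal(size=30)},
                             index=ordination.coords.index)
            ps.append(envfit(ordination, v, n_perm=99, seed=i).loc["noise", "p"])
        from scipy import stats
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestTwoWayAnova:
    def test_constructed_main_effect(self, rng):
        n = 60
        a = pd.Series(rng.choice(["c1", "c2"], n))
        b = pd.Series(rng.choice(["d90", "d120", "d160"], n))
        y = pd.Series(np.where(a == "c1", 3.0, 0.0) + rng.normal(size=n))
        p = two_way_anova(y, a, b)
        assert p["factor_a"] < 0.001
        assert p["factor_b"] > 0.01

    def test_balanced_type2_equals_type1(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        a = pd.Series(["x", "y"] * 12)
        b = pd.Series((["u"] * 2 + ["v"] * 2) * 6)
        y = pd.Series(rng.normal(size=24))
        df = pd.DataFrame({"y": y, "a": a, "b": b})
        fit = smf.ols("y ~ C(a) + C(b)", data=df).fit()
        t1 = sm.stats.anova_lm(fit, typ=1)
        t2 = sm.stats.anova_lm(fit, typ=2)
        assert t1.loc["C(a)", "sum_sq"] == pytest.approx(t2.loc["C(a)", "sum_sq"])
        p = two_way_anova(y, a, b)
        assert p["factor_a"] == pytest.approx(t2.loc["C(a)", "PR(>F)"])

    def test_single_level_rejected(self, rng):
        with pytest.raises(ValueError):
            two_way_anova(pd.Series(rng.normal(size=6)),
                          pd.Series(["a"] * 6), pd.Series(["u", "v"] * 3))


class TestPqNormalize:
    def test_double_of_reference_halved(self, rng):
        ref = np.abs(rng.normal(5, 1, 40)) + 0.1
        spectra = pd.DataFrame(np.vstack([ref, ref, 2 * ref]))
        out = pq_normalize(spectra)
        np.testing.assert_allclose(out.iloc[2], ref, rtol=1e-12)

    def test_identical_spectra_unchanged(self, rng):
        ref = np.abs(rng.normal(5, 1, 30)) + 0.1
        spectra = pd.DataFrame(np.vstack([ref] * 4))
        np.testing.assert_allclose(pq_normalize(spectra), spectra, rtol=1e-12)

    def test_dilution_series_collapses(self, rng):
        """Dilutions (1, 2, 4) of one spectrum map onto a common spectrum
        and the quotient factors recover the dilution ratios."""
        base = np.abs(rng.normal(5, 1, 50)) + 0.1
        spectra = pd.DataFrame(np.vstack([base, 2 * base, 4 * base]))
        out = pq_normalize(spectra).to_numpy()
        np.testing.assert_allclose(out[0], out[1], rtol=1e-12)
        np.testing.assert_allclose(out[0], out[2], rtol=1e-12)
        ref = np.median(spectra.to_numpy(), axis=0)
        factors = [np.median(row[ref > 0] / ref[ref > 0])
                   for row in spectra.to_numpy()]
        np.testing.assert_allclose(np.array(factors) / factors[0], [1, 2, 4],
                                   rtol=1e-12)

    def test_all_zero_spectrum_rejected(self):
        with pytest.raises(ValueError):
            pq_normalize(pd.DataFrame([[0.0, 0.0], [1.0, 2.0]]))


def test_fisher_2xc_enumeration_matches_2x2(rng):
    t = np.array([[4, 6], [7, 2]])
    from enterokit.discriminant import fisher_exact_2x2
    assert fisher_exact_2xc(t) == pytest.approx(fisher_exact_2x2(t))


class TestScreenVariables:
    def test_generated_diet_effect_detected(self, default_cohort):
        c = default_cohort
        rep = screen_variables(c.true_labels, c.metadata)
        row = rep.table.loc["fiber_intake_kg"]
        assert row["significant"]
        assert row["direction"] == "higher in 2"

    def test_community_independent_age_not_significant(self, default_cohort):
        c = default_cohort
        rep = screen_variables(c.true_labels, c.metadata)
        assert not rep.table.loc["age", "significant"]

    def test_delta_pairs_tested_as_difference(self, default_cohort):
        c = default_cohort
        meta = c.metadata.copy()
        rng = np.random.default_rng(0)
        meta["lact_t0"] = rng.normal(1.0, 0.1, len(meta))
        meta["lact_t1"] = meta["lact_t0"] + np.where(
            c.true_labels == 1, 2.0, 0.0) + rng.normal(0, 0.1, len(meta))
        rep = screen_variables(c.true_labels, meta,
                               delta_pairs={"d_lact": ("lact_t1", "lact_t0")})
        assert "lact_t1" not in rep.table.index
        assert rep.table.loc["d_lact", "significant"]

    def test_families_adjusted_separately(self, default_cohort):
        c = default_cohort
        fams = {v: ("diet" if "intake" in v else "host")
                for v in c.metadata.columns}
        rep = screen_variables(c.true_labels, c.metadata, families=fams)
        diet = rep.table[rep.table["family"] == "diet"]
        from enterokit.discriminant import bh_adjust
        np.testing.assert_allclose(diet["q"],
                                   bh_adjust(diet["p"].to_numpy()))
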