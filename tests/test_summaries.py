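"""Posterior genetic-parameter summaries and DIC model comparison."""

import numpy as np
import pytest

from mtme import (
    ModelComparison,
    PosteriorChain,
    RunConfig,
    assemble,
    build_model_spec,
    coefficient_of_variation,
    compare_models,
    dic,
    genetic_correlation_samples,
    genotype_values,
    heritability_samples,
    relative_variation_index,
    run_gibbs,
    summary_table,
)
from mtme.gibbs import gaussian_deviance


def manual_chain(
    sigma_g, sigma_gxe=None, sigma_r=1.0, sigma_e=1.0, S=120,
    traits=("a", "b"), envs=("1",), variant="full", cross_g=0.0,
):
    """Chain whose covariance samples are constant and fully specified."""
    T, E = len(traits), len(envs)
    g = np.full((T, T), cross_g) + np.diag(np.atleast_1d(sigma_g) * np.ones(T) - cross_g)
    cov = {
        "genotype": np.tile(g, (S, 1, 1)),
        "block": np.tile(np.eye(T) * sigma_r, (S, E, 1, 1)),
        "residual": np.tile(np.eye(T) * sigma_e, (S, E, 1, 1)),
    }
    if sigma_gxe is not None:
        cov["gxe"] = np.tile(np.eye(T) * sigma_gxe, (S, E, 1, 1))
    return PosteriorChain(
        traits=tuple(traits),
        environments=tuple(envs),
        variant=variant,
        beta=np.zeros((S, E, T)),
        cov=cov,
        deviance=np.zeros(S),
        effect_means={},
        effect_levels={},
        effects=None,
        seed=0,
        config={},
        data_fingerprint="x",
    )


class TestHeritability:
    def test_arithmetic(self):
        # sigma_g = 2, sigma_r = 1, sigma_e = 1 -> h2 = 0.5 (null: no gxe)
        chain = manual_chain(sigma_g=2.0, sigma_r=1.0, sigma_e=1.0, variant="null")
        h2 = heritability_samples(chain, "a", "1")
        np.testing.assert_allclose(h2, 0.5)

    def test_zero_genetic_variance(self):
        chain = manual_chain(sigma_g=1e-300, sigma_r=1.0, sigma_e=1.0)
        np.testing.assert_allclose(heritability_samples(chain, "a", "1"), 0.0, atol=1e-12)

    def test_full_model_adds_interaction_variance(self):
        chain = manual_chain(sigma_g=2.0, sigma_gxe=1.0, sigma_r=0.5, sigma_e=0.5)
        np.testing.assert_allclose(heritability_samples(chain, "a", "1"), 3.0 / 4.0)

    def test_bounds_on_real_fit(self, rice_fit):
        chain, _ = rice_fit
        for e in chain.environments:
            for t in chain.traits:
                h2 = heritability_samples(chain, t, e)
                assert np.all((h2 >= 0) & (h2 <= 1))

    def test_unknown_labels_rejected(self, rice_fit):
        chain, _ = rice_fit
        with pytest.raises(KeyError):
            heritability_samples(chain, "nope", "1")
        with pytest.raises(KeyError):
            heritability_samples(chain, "GY", "9")


class TestGeneticCorrelation:
    def test_diagonal_covariance_gives_zero(self):
        chain = manual_chain(sigma_g=2.0, variant="null", cross_g=0.0)
        rho, excluded = genetic_correlation_samples(chain, "a", "b", "1")
        np.testing.assert_allclose(rho, 0.0)
        assert excluded == 0

    def test_known_covariance(self):
        # genetic covariance [[4, 3], [3, 9]] -> rho = 3 / sqrt(36) = 0.5
        chain = manual_chain(sigma_g=1.0, variant="null")
        S = chain.n_samples
        chain.cov["genotype"] = np.tile(
            np.array([[4.0, 3.0], [3.0, 9.0]]), (S, 1, 1)
        )
        rho, _ = genetic_correlation_samples(chain, "a", "b", "1")
        np.testing.assert_allclose(rho, 0.5)

    def test_bounds_on_real_fit(self, rice_fit):
        chain, _ = rice_fit
        for e in chain.environments:
            rho, excluded = genetic_correlation_samples(chain, "FL", "GY", e)
            assert np.all((rho >= -1) & (rho <= 1))
            assert excluded == 0

    def test_same_trait_rejected(self, rice_fit):
        chain, _ = rice_fit
        with pytest.raises(ValueError):
            genetic_correlation_samples(chain, "GY", "GY", "1")


class TestCoefficientOfVariation:
    def test_ratio_of_equal_cvs_is_one(self):
        assert relative_variation_index(2.5, 2.5) == 1.0

    def test_nonpositive_cve_rejected(self):
        with pytest.raises(ValueError):
            relative_variation_index(1.0, 0.0)

    def test_real_fit_values_positive(self, rice_fit, rice_table):
        chain, _ = rice_fit
        cvg, cve, ratio = coefficient_of_variation(chain, rice_table, "GY", "1")
        assert cvg > 0 and cve > 0
        assert ratio == pytest.approx(cvg / cve)


class TestDic:
    def test_point_mass_chain_has_zero_pd(self, tiny_table):
        model = assemble(tiny_table, build_model_spec("null", ["yield"]))
        chain = run_gibbs(model, RunConfig(n_iter=300, burn_in=100, thin=1, seed=0))
        # collapse to a point-mass chain at the posterior means
        S = chain.n_samples
        chain.beta = np.tile(chain.beta.mean(axis=0), (S, 1, 1))
        for name in chain.cov:
            m = chain.cov[name].mean(axis=0)
            chain.cov[name] = np.tile(m, (S,) + (1,) * m.ndim)
        resid = model.Y - chain.beta[0][model.env_of_plot]
        for name, means in chain.effect_means.items():
            resid = resid - means[model.terms[name].plot_level]
        d_bar = gaussian_deviance(resid, chain.cov["residual"][0], model.env_of_plot)
        chain.deviance = np.full(S, d_bar)
        dic_val, pd_val = dic(chain, model, deviance="conditional")
        assert pd_val == pytest.approx(0.0, abs=1e-8)
        assert dic_val == pytest.approx(d_bar, abs=1e-8)
        # marginal route: a point-mass chain likewise has zero pD
        dic_m, pd_m = dic(chain, model, deviance="marginal")
        assert pd_m == pytest.approx(0.0, abs=1e-6)

    def test_identity_dic_equals_mean_deviance_plus_pd(self, rice_fit):
        chain, model = rice_fit
        dic_val, pd_val = dic(chain, model, deviance="conditional")
        assert dic_val == pytest.approx(chain.deviance.mean() + pd_val)
        assert pd_val > 0  # fitted effects use up effective parameters
        dic_m, pd_m = dic(chain, model)  # marginal default
        assert np.isfinite(dic_m) and pd_m > 0

    def test_thinning_self_consistency(self, rice_fit):
        """DIC from every second retained draw agrees within MC error."""
        chain, model = rice_fit
        full_dic, _ = dic(chain, model)
        import copy

        half = copy.copy(chain)
        half.beta = chain.beta[::2]
        half.cov = {k: v[::2] for k, v in chain.cov.items()}
        half.deviance = chain.deviance[::2]
        half_dic, _ = dic(half, model)
        assert half_dic == pytest.approx(full_dic, abs=0.05 * abs(full_dic) + 10)


class TestCompareModels:
    @pytest.mark.parametrize(
        "dic_full,dic_null,expected",
        [(100.0, 110.0, "full"), (100.0, 101.0, "indistinguishable"),
         (110.0, 100.0, "null")],
    )
    def test_decision_rule(self, dic_full, dic_null, expected):
        cmp_ = ModelComparison(
            dic_full=dic_full, dic_null=dic_null, pd_full=5.0, pd_null=4.0
        )
        assert cmp_.preferred == expected
        assert cmp_.delta == dic_null - dic_full

    def test_self_comparison_indistinguishable(self, rice_fit):
        chain, model = rice_fit
        cmp_ = compare_models((chain, model), (chain, model))
        assert cmp_.delta == 0.0
        assert cmp_.preferred == "indistinguishable"

    def test_mismatched_data_rejected(self, rice_fit, tiny_table):
        chain, model = rice_fit
        other_model = assemble(tiny_table, build_model_spec("null", ["yield"]))
        other = run_gibbs(
            other_model, RunConfig(n_iter=300, burn_in=100, thin=1, seed=1)
        )
        with pytest.raises(ValueError, match="identical data"):
            compare_models((chain, model), (other, other_model))


class TestGenotypeValues:
    def test_requires_stored_effects(self, rice_table):
        model = assemble(rice_table, build_model_spec("full", rice_table.traits))
        chain = run_gibbs(model, RunConfig(n_iter=300, burn_in=100, thin=1, seed=2))
        with pytest.raises(ValueError, match="store_effects"):
            genotype_values(chain, "1", "GY")

    def test_ranking_descending_with_hpd(self, rice_fit):
        chain, _ = rice_fit
        df = genotype_values(chain, "1", "GY")
        assert len(df) == 25
        vals = df["genetic_value"].to_numpy()
        assert np.all(np.diff(vals) <= 0)
        assert np.all(df["hpd_lower"] <= df["hpd_upper"])

    def test_null_model_ranking_identical_across_environments(self, rice_table):
        model = assemble(rice_table, build_model_spec("null", rice_table.traits))
        chain = run_gibbs(
            model,
            RunConfig(n_iter=600, burn_in=100, thin=1, seed=3, store_effects=True),
        )
        r1 = genotype_values(chain, "1", "GY")["genotype"].tolist()
        r2 = genotype_values(chain, "2", "GY")["genotype"].tolist()
        assert r1 == r2

    def test_manual_effects_rank_exactly(self):
        chain = manual_chain(sigma_g=1.0, variant="null", S=100)
        G = 4
        base = np.array([0.5, -1.0, 2.0, 0.0])
        chain.effects = {"genotype": np.tile(base[:, None], (100, 1, 2))}
        chain.effect_levels = {"genotype": [f"g{i}" for i in range(G)]}
        df = genotype_values(chain, "1", "a")
        assert df["genotype"].tolist() == ["g2", "g0", "g3", "g1"]


class TestSummaryTable:
    def test_layout_and_bounds(self, rice_fit):
        chain, _ = rice_fit
        df = summary_table(chain)
        beta_rows = df[df["parameter"].str.startswith("beta")]
        assert len(beta_rows) == 4  # 2 env x 2 traits
        h2 = df[df["parameter"].str.startswith("h2")]
        assert len(h2) == 4
        assert (h2["hpd_lower"] >= 0).all() and (h2["hpd_upper"] <= 1).all()
        rho = df[df["parameter"].str.startswith("rho")]
        assert len(rho) == 2
        assert (rho["hpd_lower"] >= -1).all() and (rho["hpd_upper"] <= 1).all()
        assert (df["hpd_lower"] <= df["hpd_upper"]).all()
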