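import numpy as np
import pytest
from scipy.special import expit, logit
from scipy.stats import binom, norm, t as student_t

from phyloprev import (
    MCMCConfig,
    ModelSpec,
    PrevalenceDataset,
    PriorConfig,
    SimulationConfig,
    fit_all_specs,
    log_likelihood,
    log_prior,
    sample_posterior,
    simulate_dataset,
    simulate_yule_tree,
)
from phyloprev.model import design_matrix, _structure_matrix_factory, _align_species

from conftest import make_dataset


class TestLogLikelihood:
    def test_single_species_zero_cases(self):
        ds = PrevalenceDataset(
            species=["a", "b", "c", "d", "e"],
            n_necropsies=[20, 10, 10, 10, 10],
            k_cases={"neoplasia": [0, 0, 0, 0, 0]},
            log10_mass=[0.0] * 5,
            log10_longevity=[0.0] * 5,
        )
        spec = ModelSpec(predictors=("log10_mass",))
        eta = logit(0.1)
        # only species 0 contributes if the others have eta -> -inf? instead
        # isolate by subtracting the others analytically
        u = np.array([eta, 0, 0, 0, 0], dtype=float)
        ll = log_likelihood(np.zeros(2), u, ds, spec)
        others = sum(n * np.log(0.5) for n in [10, 10, 10, 10])
        assert ll - others == pytest.approx(20 * np.log(0.9), abs=1e-10)

    def test_beta_zero_u_zero_closed_form(self):
        ds = make_dataset(S=8, seed=1)
        spec = ModelSpec(predictors=("log10_mass", "log10_longevity"))
        ll = log_likelihood(np.zeros(3), np.zeros(8), ds, spec)
        from scipy.special import comb

        k, n = ds.k_cases["neoplasia"], ds.n_necropsies
        expected = sum(
            np.log(comb(int(ni), int(ki), exact=True)) - ni * np.log(2)
            for ki, ni in zip(k, n)
        )
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_matches_scipy_pmf_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            S = int(rng.integers(3, 12))
            ds = PrevalenceDataset(
                species=[f"s{i}" for i in range(S)],
                n_necropsies=rng.integers(1, 200, S),
                k_cases={"neoplasia": np.zeros(S, dtype=int)},
                log10_mass=rng.normal(size=S),
                log10_longevity=rng.normal(size=S),
            )
            ds.k_cases["neoplasia"] = rng.binomial(ds.n_necropsies, 0.2)
            interact = bool(rng.integers(2))
            spec = ModelSpec(
                predictors=("log10_mass", "log10_longevity"),
                include_interaction=interact,
            )
            p = 3 + interact
            beta = rng.normal(scale=0.8, size=p)
            u = rng.normal(scale=0.5, size=S)
            eta = design_matrix(ds, spec) @ beta + u
            oracle = float(
                binom.logpmf(
                    ds.k_cases["neoplasia"], ds.n_necropsies, expit(eta)
                ).sum()
            )
            assert log_likelihood(beta, u, ds, spec) == pytest.approx(
                oracle, abs=1e-10
            )

    def test_dimension_mismatch(self):
        ds = make_dataset(S=6)
        spec = ModelSpec(predictors=("log10_mass",))
        with pytest.raises(ValueError):
            log_likelihood(np.zeros(3), np.zeros(6), ds, spec)
        with pytest.raises(ValueError):
            log_likelihood(np.zeros(2), np.zeros(5), ds, spec)


class TestLogPrior:
    def test_scipy_density_oracle_at_origin(self):
        spec = ModelSpec(predictors=("log10_mass",), structure_family="OU")
        pri = PriorConfig()
        got = log_prior(np.zeros(2), 0.0, 0.0, spec, pri)
        expected = (
            2 * norm.logpdf(0.0, scale=10.0)
            + np.log(2) + student_t.logpdf(0.0, df=3, scale=2.5)
            + np.log(2) + norm.logpdf(0.0, scale=5.0)
        )
        assert got == pytest.approx(float(expected), abs=1e-12)

    def test_lambda_uniform_support(self):
        spec = ModelSpec(predictors=("log10_mass",), structure_family="LAMBDA")
        assert log_prior(np.zeros(2), 1.0, 1.2, spec) == -np.inf
        assert log_prior(np.zeros(2), 1.0, -0.01, spec) == -np.inf
        inside = log_prior(np.zeros(2), 1.0, 0.4, spec)
        assert np.isfinite(inside)
        # Uniform(0,1): lambda value does not change the density
        assert inside == pytest.approx(log_prior(np.zeros(2), 1.0, 0.9, spec))

    def test_negative_sigma_and_alpha(self):
        spec = ModelSpec(predictors=("log10_mass",))
        assert log_prior(np.zeros(2), -0.1, 1.0, spec) == -np.inf
        assert log_prior(np.zeros(2), 0.5, -1.0, spec) == -np.inf

    def test_sigma_scale_changes_only_sigma_term(self):
        spec = ModelSpec(predictors=("log10_mass",))
        a = PriorConfig(sigma_scale=2.5)
        b = PriorConfig(sigma_scale=5.0)
        delta = log_prior(np.ones(2), 1.0, 1.0, spec, a) - log_prior(
            np.ones(2), 1.0, 1.0, spec, b
        )
        expected = float(
            student_t.logpdf(1.0, df=3, scale=2.5)
            - student_t.logpdf(1.0, df=3, scale=5.0)
        )
        assert delta == pytest.approx(expected, abs=1e-12)


class TestDatasetValidation:
    def test_k_exceeds_n(self):
        with pytest.raises(ValueError, match="out of range"):
            PrevalenceDataset(
                species=["a", "b"],
                n_necropsies=[20, 20],
                k_cases={"neoplasia": [21, 0]},
                log10_mass=[0, 0],
                log10_longevity=[0, 0],
            )

    def test_duplicate_species(self):
        with pytest.raises(ValueError, match="duplicate"):
            PrevalenceDataset(
                species=["a", "a"],
                n_necropsies=[20, 20],
                k_cases={"neoplasia": [0, 0]},
                log10_mass=[0, 0],
                log10_longevity=[0, 0],
            )

    def test_from_frame_drops_missing(self, caplog):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "species": ["a", "b", "c"],
                "n_necropsies": [20, 30, 40],
                "k_neoplasia": [1, 2, 3],
                "body_mass_kg": [1.0, np.nan, 10.0],
                "max_longevity_months": [100.0, 200.0, 300.0],
            }
        )
        ds = PrevalenceDataset.from_frame(frame)
        assert ds.n_species == 2
        assert ds.meta["n_dropped_missing"] == 1


class TestModelSpec:
    def test_interaction_needs_two_predictors(self):
        with pytest.raises(ValueError):
            ModelSpec(predictors=("log10_mass",), include_interaction=True)

    def test_fixed_needs_value(self):
        with pytest.raises(ValueError):
            ModelSpec(predictors=("log10_mass",), structure_mode="fixed")

    def test_mcmc_invariants(self):
        with pytest.raises(ValueError):
            MCMCConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            MCMCConfig(chains=1)


class TestSamplePosterior:
    def test_retained_draw_count(self, small_sim, fast_mcmc, mass_spec):
        tree, ds, _ = small_sim
        fit = sample_posterior(ds, tree, mass_spec, fast_mcmc)
        expected = fast_mcmc.chains * (
            (fast_mcmc.iterations - fast_mcmc.burn_in) // fast_mcmc.thin
        )
        assert fit.stacked("log10_mass").shape == (expected,)
        assert fit.loglik_matrix().shape == (expected, ds.n_species)

    def test_support_invariants(self, small_sim, fast_mcmc, mass_spec):
        tree, ds, _ = small_sim
        fit = sample_posterior(ds, tree, mass_spec, fast_mcmc)
        assert (fit.stacked("sigma_phylo") >= 0).all()
        assert (fit.stacked("alpha") >= 0).all()

    def test_lambda_draws_in_unit_interval(self, small_sim, fast_mcmc):
        tree, ds, _ = small_sim
        spec = ModelSpec(predictors=("log10_mass",), structure_family="LAMBDA")
        fit = sample_posterior(ds, tree, spec, fast_mcmc)
        lam = fit.stacked("lambda")
        assert ((lam >= 0) & (lam <= 1)).all()

    def test_same_seed_identical_draws(self, small_sim, fast_mcmc, mass_spec):
        tree, ds, _ = small_sim
        a = sample_posterior(ds, tree, mass_spec, fast_mcmc,
                             compute_diagnostics=False)
        b = sample_posterior(ds, tree, mass_spec, fast_mcmc,
                             compute_diagnostics=False)
        for name in a.draws:
            assert np.array_equal(a.draws[name], b.draws[name])

    def test_all_zero_counts_tight_prior_gives_tiny_prevalence(self):
        tree = simulate_yule_tree(10, seed=2)
        ds = PrevalenceDataset(
            species=list(tree.tips),
            n_necropsies=np.full(10, 30),
            k_cases={"neoplasia": np.zeros(10, dtype=int)},
            log10_mass=np.random.default_rng(0).normal(size=10),
            log10_longevity=np.random.default_rng(1).normal(size=10),
        )
        spec = ModelSpec(predictors=("log10_mass",))
        priors = PriorConfig(beta_loc=(-6.0, 0.0), beta_scale=(0.01, 0.01))
        mcmc = MCMCConfig(iterations=500, burn_in=200, thin=1, chains=2, seed=3)
        fit = sample_posterior(ds, tree, spec, mcmc, priors)
        X = design_matrix(ds, spec)
        beta = np.column_stack([fit.stacked(n) for n in spec.coef_names])
        prev = expit(beta @ X.T + fit.stacked("u"))
        assert prev.mean(axis=0).max() < 0.01

    def test_too_few_species(self, fast_mcmc, mass_spec):
        tree = simulate_yule_tree(4, seed=0)
        ds = make_dataset(S=4)
        ds.species = list(tree.tips)
        with pytest.raises(ValueError, match="at least 5"):
            sample_posterior(ds, tree, mass_spec, fast_mcmc)

    def test_zero_variance_predictor(self, fast_mcmc, mass_spec):
        tree = simulate_yule_tree(8, seed=0)
        ds = PrevalenceDataset(
            species=list(tree.tips),
            n_necropsies=np.full(8, 30),
            k_cases={"neoplasia": np.full(8, 2)},
            log10_mass=np.zeros(8),
            log10_longevity=np.zeros(8),
        )
        with pytest.raises(ValueError, match="zero-variance"):
            sample_posterior(ds, tree, mass_spec, fast_mcmc)

    def test_species_missing_from_tree(self, fast_mcmc, mass_spec):
        tree = simulate_yule_tree(8, seed=0)
        ds = make_dataset(S=8)  # species named sp001.. but shuffled labels exist
        ds.species = [f"zz{i}" for i in range(8)]
        with pytest.raises(ValueError, match="absent from tree"):
            sample_posterior(ds, tree, mass_spec, fast_mcmc)

    def test_sigma_near_zero_matches_unstructured_glm(self):
        """With the phylogenetic SD forced to ~0 the posterior mean of beta
        matches an independent-binomial GLM fit (statsmodels oracle)."""
        import statsmodels.api as sm

        cfg = SimulationConfig(
            n_species=40,
            beta_mass=0.7,
            sigma_phylo=0.0,
            necropsy_mean_extra=80.0,
            seed=21,
        )
        tree, ds, _ = simulate_dataset(cfg)
        spec = ModelSpec(predictors=("log10_mass",))
        priors = PriorConfig(sigma_scale=1e-4)
        mcmc = MCMCConfig(iterations=2500, burn_in=500, thin=2, chains=2, seed=9)
        fit = sample_posterior(ds, tree, spec, mcmc, priors)

        X = design_matrix(ds, spec)
        k, n = ds.k_cases["neoplasia"], ds.n_necropsies
        glm = sm.GLM(
            np.column_stack([k, n - k]), X, family=sm.families.Binomial()
        ).fit()
        assert fit.stacked("intercept").mean() == pytest.approx(
            glm.params[0], abs=0.05
        )
        assert fit.stacked("log10_mass").mean() == pytest.approx(
            glm.params[1], abs=0.05
        )


class TestStructureFactory:
    def test_lambda_zero_gives_identity(self, small_sim):
        tree, ds, _ = small_sim
        spec = ModelSpec(
            predictors=("log10_mass",),
            structure_family="LAMBDA",
            structure_mode="fixed",
            structure_value=0.0,
        )
        idx = _align_species(ds, tree)
        build = _structure_matrix_factory(tree, spec, idx)
        assert np.allclose(build(0.0), np.eye(ds.n_species))

    def test_submatrix_matches_full_matrix(self, small_sim):
        from phyloprev import ou_correlation

        tree, ds, _ = small_sim
        spec = ModelSpec(predictors=("log10_mass",))
        idx = _align_species(ds, tree)
        build = _structure_matrix_factory(tree, spec, idx)
        full = ou_correlation(tree, 1.7).matrix
        assert np.allclose(build(1.7), full[np.ix_(idx, idx)], atol=1e-12)


class TestFitAllSpecs:
    @pytest.fixture()
    def tiny(self):
        cfg = SimulationConfig(n_species=8, seed=5, sigma_phylo=0.3)
        tree, ds, _ = simulate_dataset(cfg)
        ds.k_cases["malignant"] = (ds.k_cases["neoplasia"] // 2).astype(int)
        return tree, ds

    def test_counts_one_response(self, tiny):
        tree, ds = tiny
        mcmc = MCMCConfig(iterations=120, burn_in=40, thin=1, chains=2, seed=0)
        fits = fit_all_specs(ds, tree, ["neoplasia"], mcmc)
        assert len(fits) == 4

    def test_counts_two_responses(self, tiny):
        tree, ds = tiny
        mcmc = MCMCConfig(iterations=120, burn_in=40, thin=1, chains=2, seed=0)
        fits = fit_all_specs(ds, tree, ["neoplasia", "malignant"], mcmc)
        assert len(fits) == 8
        labels = {f.spec.label() for f in fits}
        assert len(labels) == 8
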