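import numpy as np
import pytest

from phylotraits.exceptions import DesignError, PhyloTraitsError
from phylotraits.io import SiteDesign, TraitTable
from phylotraits.pglmm import (
    ModelFrame,
    PGLMMParams,
    PhylogeneticMixedLM,
    _fractions,
    hdi,
    marginal_loglik,
    prepare_response,
)
from phylotraits.simulate import (
    SyntheticConfig,
    TraitParams,
    default_trait_params,
    simulate_dataset,
)

from conftest import make_tiny_frame


def random_frame(seed=3, n=12, J=3, S=4, p=2):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n)] + [rng.integers(0, 2, n) for _ in range(p - 1)])
    return ModelFrame(
        y=rng.normal(size=n),
        X=X,
        plot_idx=rng.integers(0, J, n),
        species_idx=rng.integers(0, S, n),
        species=[f"s{i}" for i in range(S)],
        plots=[f"p{i}" for i in range(J)],
        x_names=["alpha0"] + [f"x{i}" for i in range(1, p)],
    )


def random_rho(seed=5, S=4):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(S, S))
    C = A @ A.T
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


class TestPrepareResponse:
    def test_log_round_trip(self, sim_data):
        frame = prepare_response(sim_data.table, "sla")
        raw = sim_data.table.data["sla"].to_numpy()
        np.testing.assert_allclose(np.exp(frame.y), raw, rtol=1e-12)

    def test_missing_cell_counted(self):
        df = make_tiny_frame()
        df.loc[0, "sla"] = np.nan
        frame = prepare_response(TraitTable(df), "sla")
        assert frame.n_dropped == 1
        assert frame.n_obs == 2

    def test_single_site_is_design_error(self):
        df = make_tiny_frame()
        df["site"] = 1000
        df["plot"] = "P1000_1"
        with pytest.raises(DesignError):
            prepare_response(TraitTable(df), "sla")

    def test_treatment_coding_reference_first(self, sim_data):
        frame = prepare_response(sim_data.table, "n")
        assert frame.x_names == ["alpha0", "site_2000", "site_3000"]
        ref_rows = frame.site_of_obs == 1000
        assert np.all(frame.X[ref_rows, 1:] == 0)


class TestMarginalLoglik:
    def test_single_observation_standard_normal(self):
        frame = ModelFrame(
            y=[0.0], X=[[1.0]], plot_idx=[0], species_idx=[0],
            species=["a"], plots=["p"], x_names=["alpha0"],
        )
        ll = marginal_loglik(PGLMMParams(0.0, [], 0, 0, 0, 1.0), frame, np.eye(1))
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-6)

    def test_star_tree_tau_swap_symmetry(self):
        frame = random_frame()
        a = marginal_loglik(PGLMMParams(0.3, [0.2], 0.2, 0.5, 0.3, 0.3), frame, np.eye(4))
        b = marginal_loglik(PGLMMParams(0.3, [0.2], 0.2, 0.3, 0.5, 0.3), frame, np.eye(4))
        assert a == pytest.approx(b, abs=1e-10)

    def test_permutation_invariance(self):
        frame = random_frame(seed=9, n=20)
        rho = random_rho()
        params = PGLMMParams(0.1, [0.4], 0.3, 0.2, 0.4, 0.5)
        ll = marginal_loglik(params, frame, rho)
        rng = np.random.default_rng(1)
        perm = rng.permutation(20)
        frame2 = ModelFrame(
            y=frame.y[perm], X=frame.X[perm], plot_idx=frame.plot_idx[perm],
            species_idx=frame.species_idx[perm], species=frame.species,
            plots=frame.plots, x_names=frame.x_names,
        )
        assert marginal_loglik(params, frame2, rho) == pytest.approx(ll, abs=1e-9)

    def test_beta_dimension_checked(self):
        frame = random_frame()
        with pytest.raises(PhyloTraitsError):
            marginal_loglik(PGLMMParams(0.0, [0.1, 0.2], 0.1, 0.1, 0.1, 1.0), frame, np.eye(4))


class TestHdi:
    def test_uniform_grid(self):
        draws = np.arange(1, 101, dtype=float)
        lo, hi = hdi(draws, 0.95)
        assert (hi - lo) == pytest.approx(0.95 * 99, rel=0.02)

    def test_identical_draws_zero_width(self):
        lo, hi = hdi(np.full(500, 3.3))
        assert lo == hi == 3.3

    def test_too_few_draws(self):
        with pytest.raises(PhyloTraitsError):
            hdi(np.arange(50), 0.95)

    def test_standard_normal_endpoints(self):
        draws = np.random.default_rng(123).standard_normal(100_000)
        lo, hi = hdi(draws, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)


class TestVariancePartition:
    def test_equal_components(self):
        # fixed-effect variance 1 via identity design covariance and unit theta
        f = _fractions(np.array([[1.0]]), np.array([1.0]), 1.0, 1.0, 1.0, 1.0)
        np.testing.assert_allclose(f, 0.2)

    def test_no_random_effects_site_plus_resid(self):
        f = _fractions(np.array([[2.0]]), np.array([1.0]), 0.0, 0.0, 0.0, 1.0)
        assert f[0] + f[4] == pytest.approx(1.0, abs=1e-12)
        assert f[1:4].sum() == 0

    def test_fractions_sum_to_one_on_fit(self, small_sim_data):
        model = PhylogeneticMixedLM.from_trait_table(
            small_sim_data.table, "toughness", small_sim_data.tree
        )
        vp = model.fit(seed=0).variance_partition()
        assert vp.to_series().sum() == pytest.approx(1.0, abs=1e-10)
        assert ((vp.to_series() >= 0) & (vp.to_series() <= 1)).all()


@pytest.fixture(scope="module")
def recovery_data():
    params = {
        k: TraitParams(v.alpha0, v.beta, 0.2, 0.5, 0.3, 0.3)
        for k, v in default_trait_params().items()
    }
    cfg = SyntheticConfig(
        seed=77,
        design=SiteDesign(individuals_min=9, individuals_max=9),
        params=params,
    )
    return simulate_dataset(cfg)


class TestFitML:
    def test_degenerate_simulation_taus_near_zero(self):
        """All random SDs zero in the generator: the fitted SDs vanish on
        average (single fits carry chi-square noise of order sigma/sqrt(n))."""
        params = {
            k: TraitParams(v.alpha0, v.beta, 0.0, 0.0, 0.0, 0.3)
            for k, v in default_trait_params().items()
        }
        taus = []
        for seed in range(5):
            cfg = SyntheticConfig(
                seed=seed, design=SiteDesign(individuals_min=8, individuals_max=8),
                params=params,
            )
            data = simulate_dataset(cfg)
            res = PhylogeneticMixedLM.from_trait_table(
                data.table, "dmc", data.tree
            ).fit(seed=1)
            taus.append(
                [res.params.tau_plot, res.params.tau_phyl, res.params.tau_ind]
            )
        assert np.all(np.mean(taus, axis=0) < 0.05), np.mean(taus, axis=0)

    def test_optimum_beats_truth(self, recovery_data):
        model = PhylogeneticMixedLM.from_trait_table(
            recovery_data.table, "sla", recovery_data.tree
        )
        res = model.fit(seed=0)
        tp = recovery_data.truth["params"]["sla"]
        truth = PGLMMParams(tp.alpha0, np.array(tp.beta), tp.tau_plot, tp.tau_phyl,
                            tp.tau_ind, tp.sigma)
        assert res.llf >= model.loglike(truth) - 1e-6

    def test_fixed_effects_consistent_with_reported_se(self):
        """Across replicates, fixed-effect errors are on the scale of the
        reported GLS standard errors (mean |z| well below 2)."""
        zs = []
        for rep in range(5):
            params = {
                k: TraitParams(v.alpha0, v.beta, 0.2, 0.5, 0.3, 0.3)
                for k, v in default_trait_params().items()
            }
            cfg = SyntheticConfig(
                seed=500 + rep,
                design=SiteDesign(individuals_min=9, individuals_max=9),
                params=params,
            )
            data = simulate_dataset(cfg)
            res = PhylogeneticMixedLM.from_trait_table(
                data.table, "n", data.tree
            ).fit(seed=rep)
            tp = data.truth["params"]["n"]
            truth_theta = np.array([tp.alpha0, *tp.beta])
            zs.extend(np.abs(res.params.theta - truth_theta) / res.bse_theta)
        assert np.mean(zs) < 2.0, zs

    def test_shift_invariance_of_variances(self, recovery_data):
        """Adding a constant to the response shifts the intercept and leaves
        the variance estimates unchanged (checked away from the tau = 0
        boundary, where log-scale estimates are indeterminate)."""
        model = PhylogeneticMixedLM.from_trait_table(
            recovery_data.table, "toughness", recovery_data.tree
        )
        res1 = model.fit(seed=0)
        frame2 = prepare_response(recovery_data.table, "toughness")
        frame2.y = frame2.y + 3.0
        res2 = PhylogeneticMixedLM(frame2, model.rho).fit(seed=0)
        assert res2.params.alpha0 - res1.params.alpha0 == pytest.approx(3.0, abs=1e-6)
        for name in ("tau_plot", "tau_phyl", "tau_ind", "sigma"):
            assert getattr(res2.params, name) == pytest.approx(
                getattr(res1.params, name), abs=1e-6
            )

    def test_star_phylogeny_total_species_variance_identified(self, recovery_data):
        """Under rho = I only tau_phyl^2 + tau_ind^2 is identified; the summed
        phylogeny+species fraction is still recovered."""
        frame = prepare_response(recovery_data.table, "p")
        res = PhylogeneticMixedLM(frame, np.eye(len(frame.species))).fit(seed=0)
        est = res.params.tau_phyl**2 + res.params.tau_ind**2
        vp = res.variance_partition()
        truth_fr = recovery_data.truth["fractions"]["p"]
        assert est == pytest.approx(0.5**2 + 0.3**2, rel=0.6)
        assert vp.f_phyl + vp.f_species == pytest.approx(
            truth_fr["phylogeny"] + truth_fr["species"], abs=0.15
        )


class TestFitMCMC:
    def test_determinism_and_summary(self, small_sim_data):
        model = PhylogeneticMixedLM.from_trait_table(
            small_sim_data.table, "ca", small_sim_data.tree
        )
        r1 = model.fit_mcmc(chains=2, iters=60, warmup=60, seed=9)
        r2 = model.fit_mcmc(chains=2, iters=60, warmup=60, seed=9)
        for k in r1.draws:
            np.testing.assert_array_equal(r1.draws[k], r2.draws[k])
        assert "Rhat" in r1.summary() or "rhat" in r1.summary().lower()
        assert isinstance(r1.converged, bool)
        tab = r1.param_table()
        assert (tab["hdi_low"] <= tab["mean"]).all()
        assert (tab["mean"] <= tab["hdi_high"]).all()

    def test_posterior_location_matches_conjugate_mean(self):
        """With negligible random-effect variance in the data, the posterior
        mean of the intercept approaches the (weak-prior) conjugate normal
        posterior mean, i.e. essentially the sample mean."""
        rng = np.random.default_rng(4)
        n, S, J = 240, 12, 8
        y = rng.normal(2.0, 0.4, size=n)
        frame = ModelFrame(
            y=y,
            X=np.ones((n, 1)),
            plot_idx=rng.integers(0, J, n),
            species_idx=rng.integers(0, S, n),
            species=[f"s{i}" for i in range(S)],
            plots=[f"p{j}" for j in range(J)],
            x_names=["alpha0"],
        )
        res = PhylogeneticMixedLM(frame, np.eye(S)).fit_mcmc(
            chains=2, iters=300, warmup=300, seed=0
        )
        assert res.posterior_mean("alpha0") == pytest.approx(y.mean(), abs=0.15)

    def test_chains_requirement(self, small_sim_data):
        model = PhylogeneticMixedLM.from_trait_table(
            small_sim_data.table, "ca", small_sim_data.tree
        )
        with pytest.raises(PhyloTraitsError):
            model.fit_mcmc(chains=1, iters=50, warmup=50, seed=0)
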