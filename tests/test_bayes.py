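import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from bystander_rl.bayes import (
    MCMCConfig,
    PosteriorDraws,
    PriorSpec,
    _stick_breaking,
    beta_binomial_logpmf,
    derived_probabilities,
    fit_action_model,
    fit_model_a,
    fit_model_b,
    inv_logit,
    point_biserial,
    posterior_predictive_resp,
    posterior_summary,
    prior_interval,
    rhat,
)
from bystander_rl.participants import (
    BetaBinomGenSpec,
    generate_action_effect_dataset,
    generate_beta_binomial_dataset,
)


class TestInvLogit:
    def test_symmetry_point(self):
        assert inv_logit(0.0) == 0.5

    def test_worked_values(self):
        assert round(inv_logit(-0.31), 2) == 0.42
        assert round(inv_logit(-0.31 + 1.16), 2) == 0.70

    def test_extreme_negative_stable(self):
        v = inv_logit(-750.0)
        assert 0.0 <= v < 1e-300

    def test_extreme_positive_stable(self):
        assert inv_logit(750.0) == 1.0  # saturates without overflow

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            inv_logit(float("nan"))

    def test_vectorised(self):
        out = inv_logit(np.array([-1.0, 0.0, 1.0]))
        np.testing.assert_allclose(out, special.expit([-1.0, 0.0, 1.0]))


class TestBetaBinomialLogpmf:
    def test_phi_two_is_uniform(self):
        # alpha = beta = 1 mixes Binomial with Beta(1,1): uniform on 0..13
        for k in (0, 5, 13):
            assert beta_binomial_logpmf(k, 13, 0.5, 2.0) == pytest.approx(np.log(1 / 14))

    def test_normalises(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            N = int(rng.integers(1, 21))
            p = float(rng.uniform(0.05, 0.95))
            phi = float(rng.uniform(0.2, 50))
            total = np.exp([beta_binomial_logpmf(k, N, p, phi) for k in range(N + 1)]).sum()
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_binomial_limit(self):
        for k in range(14):
            bb = beta_binomial_logpmf(k, 13, 0.3, 1e7)
            bn = stats.binom.logpmf(k, 13, 0.3)
            assert bb == pytest.approx(bn, abs=1e-4)

    def test_mean_by_direct_summation(self):
        # E[resp] = N * p for the mean/scale parameterisation
        N, p, phi = 13, 0.3, 1.17
        pmf = np.exp([beta_binomial_logpmf(k, N, p, phi) for k in range(N + 1)])
        assert (np.arange(N + 1) * pmf).sum() == pytest.approx(N * p, abs=1e-10)

    @pytest.mark.parametrize("kwargs", [
        {"k": 14, "N": 13, "p": 0.5, "phi": 1.0},
        {"k": -1, "N": 13, "p": 0.5, "phi": 1.0},
        {"k": 3, "N": 13, "p": 0.5, "phi": 0.0},
        {"k": 3, "N": 13, "p": 1.0, "phi": 1.0},
    ])
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            beta_binomial_logpmf(**kwargs)


class TestPriorInterval:
    def test_wide_normal(self):
        lo, hi = prior_interval(PriorSpec("normal", mean=0, sd=10), 0.95)
        assert round(lo, 1) == -19.6
        assert round(hi, 1) == 19.6
        assert round(lo) == -20 and round(hi) == 20

    def test_diffuse_gamma(self):
        lo, hi = prior_interval(PriorSpec("gamma", shape=2, rate=0.1), 0.95)
        assert round(lo, 1) == 2.4
        assert round(hi, 1) == 55.7

    def test_interval_widens_with_mass(self):
        prior = PriorSpec("normal", mean=1, sd=2)
        widths = [
            np.diff(prior_interval(prior, m))[0]
            for m in (0.5, 0.8, 0.95, 0.999)
        ]
        assert all(b > a for a, b in zip(widths, widths[1:]))

    def test_dirichlet_marginals(self):
        pairs = prior_interval(PriorSpec("dirichlet", concentrations=(1, 1, 1)), 0.95)
        assert len(pairs) == 3
        for lo, hi in pairs:
            # Beta(1, 2) marginal quantiles: 1 - (1 - q)^(1/2) inverted
            assert lo == pytest.approx(1 - np.sqrt(0.975), abs=1e-9)
            assert hi == pytest.approx(1 - np.sqrt(0.025), abs=1e-9)

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec("normal", sd=0)
        with pytest.raises(ValueError):
            PriorSpec("cauchy")


class TestStickBreaking:
    def test_maps_to_simplex(self):
        rng = np.random.default_rng(0)
        y = rng.normal(scale=3.0, size=(500, 2))
        x, logj = _stick_breaking(y)
        assert np.all(x >= 0)
        np.testing.assert_allclose(x.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.isfinite(logj))

    def test_origin_maps_to_barycentre(self):
        x, _ = _stick_breaking(np.zeros((1, 2)))
        np.testing.assert_allclose(x[0], [1 / 3, 1 / 3, 1 / 3], atol=1e-12)

    def test_jacobian_gives_uniform_simplex(self):
        """Sampling the unconstrained density exp(log|J|) must produce a
        uniform distribution over the simplex: each component then has a
        Beta(1, 2) marginal."""
        rng = np.random.default_rng(1)
        # importance-sample: propose y ~ wide normal, weight by J / proposal
        y = rng.normal(scale=6.0, size=(200_000, 2))
        x, logj = _stick_breaking(y)
        logq = stats.norm.logpdf(y, scale=6.0).sum(axis=1)
        w = np.exp(logj - logq)
        w /= w.sum()
        mean = (w[:, None] * x).sum(axis=0)
        np.testing.assert_allclose(mean, [1 / 3, 1 / 3, 1 / 3], atol=0.01)
        second = (w[:, None] * x**2).sum(axis=0)
        np.testing.assert_allclose(second, 1 / 6, atol=0.01)  # E[X^2] of Beta(1,2)


def make_draws(arrays, **meta):
    return PosteriorDraws({k: np.asarray(v, dtype=float) for k, v in arrays.items()}, meta)


class TestPosteriorSummary:
    def test_constant_draws(self):
        d = make_draws({"a": [[2.0, 2.0, 2.0, 2.0]] * 2})
        row = posterior_summary(d, thresholds={"a": 2.0}).iloc[0]
        assert row["mean"] == 2.0
        assert row["sd"] == 0.0
        assert row["prob_gt"] == 0.0  # strict inequality: ties do not count

    def test_small_example(self):
        d = make_draws({"a": [[-1.0, 1.0], [1.0, 1.0]]})
        row = posterior_summary(d).iloc[0]
        assert row["prob_gt"] == 0.75

    def test_standard_normal_prob_positive(self):
        rng = np.random.default_rng(0)
        d = make_draws({"z": rng.standard_normal((4, 25_000))})
        row = posterior_summary(d).iloc[0]
        assert abs(row["prob_gt"] - 0.5) < 0.005


class TestDerivedProbabilities:
    def test_zero_draw(self):
        d = make_draws({"gamma0": [[0.0]], "gamma1": [[0.0]], "gamma2": [[0.0]]})
        out = derived_probabilities(d)
        assert out.flat("p_none")[0] == 0.5
        assert out.flat("p_medium")[0] == 0.5
        assert out.flat("p_high")[0] == 0.5

    def test_worked_single_draw(self):
        d = make_draws({"gamma0": [[-0.31]], "gamma1": [[0.79]], "gamma2": [[1.16]]})
        out = derived_probabilities(d)
        assert round(out.flat("p_none")[0], 2) == 0.42
        assert round(out.flat("p_high")[0], 2) == 0.70

    def test_range_and_per_draw_vs_plug_in(self):
        rng = np.random.default_rng(2)
        d = make_draws({
            "gamma0": rng.normal(0, 2, (2, 500)),
            "gamma1": rng.normal(1, 2, (2, 500)),
            "gamma2": rng.normal(2, 2, (2, 500)),
        })
        out = derived_probabilities(d)
        for name in ("p_none", "p_medium", "p_high"):
            v = out.flat(name)
            assert np.all((v > 0) & (v < 1))
        # Jensen's gap: mean of transformed draws != transform of means
        plug_in = special.expit(d.flat("gamma0").mean())
        assert abs(out.flat("p_none").mean() - plug_in) > 1e-4


class TestPointBiserial:
    def test_identical_vectors(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        r, _ = point_biserial(y, y.astype(float))
        assert r == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # Pearson by hand: cov = 0.9/6, sy = sqrt(1.5/6), sx = sqrt(0.58/6)
        y = [1, 1, 1, 0, 0, 0]
        x = [0.9, 0.8, 0.7, 0.3, 0.2, 0.1]
        r, (lo, hi) = point_biserial(y, x)
        assert r == pytest.approx(0.9 / np.sqrt(1.5 * 0.58), abs=1e-12)
        assert round(r, 3) == 0.965
        assert lo < r < hi

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 10_000)
        x = rng.normal(size=10_000)
        r, (lo, hi) = point_biserial(y, x)
        assert abs(r) < 0.03
        assert lo < 0 < hi

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            point_biserial([1, 1, 1, 1], [0.1, 0.2, 0.3, 0.4])


class TestRhat:
    def test_identical_white_noise_chains(self):
        rng = np.random.default_rng(0)
        d = make_draws({"a": rng.standard_normal((4, 2000))})
        assert rhat(d)["a"] < 1.01

    def test_gross_nonconvergence(self):
        d = make_draws({"a": np.vstack([np.random.default_rng(1).normal(0, 1, 500),
                                        np.random.default_rng(2).normal(100, 1, 500)])})
        assert rhat(d)["a"] > 1.1

    def test_constant_draws_sentinel(self):
        d = make_draws({"a": np.ones((2, 100))})
        assert np.isnan(rhat(d)["a"])

    def test_single_chain_rejected(self):
        d = make_draws({"a": np.zeros((1, 100))})
        with pytest.raises(ValueError):
            rhat(d)


@pytest.fixture(scope="module")
def small_dataset():
    rng = np.random.default_rng(77)
    x = np.concatenate([np.ones(15), rng.uniform(0.4, 0.95, 15), rng.uniform(0.05, 0.5, 15)])
    spec = BetaBinomGenSpec(beta0=1.34, beta1=-1.45, phi=1.17, proprandom_values=x)
    return generate_beta_binomial_dataset(spec, rng)


class TestFitModelA:
    def test_posterior_matches_grid_oracle(self, small_dataset):
        """The sampled posterior must agree with a deterministic dense-grid
        integration of the same log posterior (independent route)."""
        data = small_dataset
        resp = data["resp"].to_numpy()
        x = data["proprandom"].to_numpy()
        b0 = np.linspace(-2, 6, 81)
        b1 = np.linspace(-7, 3, 81)
        lphi = np.linspace(np.log(0.05), np.log(30), 61)
        phi = np.exp(lphi)
        ll = np.zeros((81, 81, 61))
        for i, v0 in enumerate(b0):
            eta = v0 + np.outer(b1, x)  # (81, 45)
            p = special.expit(eta)
            a = p[:, :, None] * phi[None, None, :]
            b = (1 - p)[:, :, None] * phi[None, None, :]
            k = resp[None, :, None]
            ll[i] = (
                special.gammaln(14) - special.gammaln(k + 1) - special.gammaln(14 - k)
                + special.betaln(k + a, 13 - k + b) - special.betaln(a, b)
            ).sum(axis=1)
        lp = (
            ll
            + stats.norm.logpdf(b0, 0, 10)[:, None, None]
            + stats.norm.logpdf(b1, 0, 10)[None, :, None]
            + (stats.gamma.logpdf(phi, 2, scale=10) + lphi)[None, None, :]
        )
        w = np.exp(lp - lp.max())
        w /= w.sum()
        grid_means = {
            "beta0": (w.sum(axis=(1, 2)) * b0).sum(),
            "beta1": (w.sum(axis=(0, 2)) * b1).sum(),
            "phi": (w.sum(axis=(0, 1)) * phi).sum(),
        }
        grid_sds = {
            "beta0": np.sqrt((w.sum(axis=(1, 2)) * (b0 - grid_means["beta0"]) ** 2).sum()),
            "beta1": np.sqrt((w.sum(axis=(0, 2)) * (b1 - grid_means["beta1"]) ** 2).sum()),
            "phi": np.sqrt((w.sum(axis=(0, 1)) * (phi - grid_means["phi"]) ** 2).sum()),
        }
        draws = fit_model_a(data, config=MCMCConfig(iterations=2000, seed=123))
        for name in ("beta0", "beta1", "phi"):
            v = draws.flat(name)
            assert v.mean() == pytest.approx(grid_means[name], abs=0.12 * max(1, abs(grid_means[name])))
            assert v.std() == pytest.approx(grid_sds[name], rel=0.15)

    def test_draw_count_matches_config(self, small_dataset):
        cfg = MCMCConfig(iterations=400, chains=4, warmup=200, seed=0)
        draws = fit_model_a(small_dataset, config=cfg)
        assert draws.n_chains == 4
        assert draws.params["beta0"].shape == (4, 200)
        assert draws.n_draws == 4 * (400 - 200)

    def test_prior_only_fit_reverts_to_prior(self):
        """With no data the posterior is the prior: the sampled 95% interval
        of a coefficient approximates (-19.6, 19.6) and phi's approximates
        (2.4, 55.7)."""
        empty = pd.DataFrame({"resp": [], "proprandom": []})
        draws = fit_model_a(empty, config=MCMCConfig(iterations=6000, seed=4))
        lo, hi = np.percentile(draws.flat("beta0"), [2.5, 97.5])
        assert lo == pytest.approx(-19.6, abs=2.5)
        assert hi == pytest.approx(19.6, abs=2.5)
        plo, phi_hi = np.percentile(draws.flat("phi"), [2.5, 97.5])
        assert plo == pytest.approx(2.4, abs=1.0)
        assert phi_hi == pytest.approx(55.7, rel=0.25)

    def test_out_of_range_resp_rejected(self):
        bad = pd.DataFrame({"resp": [14], "proprandom": [0.5]})
        with pytest.raises(ValueError):
            fit_model_a(bad)


class TestFitModelB:
    def test_equal_groups_centre_contrasts_near_zero(self):
        """If all three groups share one response rate, the Medium and High
        contrasts should concentrate around zero."""
        rng = np.random.default_rng(8)
        from bystander_rl.participants import generate_rllevel_dataset

        data = generate_rllevel_dataset(0.3, 0.0, 0.0, 2.0, n_per_group=60, rng=rng)
        draws = fit_model_b(data, config=MCMCConfig(iterations=1500, seed=5))
        for name in ("gamma1", "gamma2"):
            v = draws.flat(name)
            lo, hi = np.percentile(v, [2.5, 97.5])
            assert lo < 0 < hi
            assert abs(v.mean()) < 0.5

    def test_mixed_dummies_rejected(self):
        bad = pd.DataFrame({"resp": [3], "M": [1], "H": [1]})
        with pytest.raises(ValueError):
            fit_model_b(bad)


class TestFitActionModel:
    def test_one_hot_violation_rejected(self):
        df = generate_action_effect_dataset(n_participants=3, N=4,
                                            rng=np.random.default_rng(0))
        df.loc[2, ["vl", "pl", "bu"]] = [1, 1, 0]
        with pytest.raises(ValueError, match="one-hot"):
            fit_action_model(df)

    def test_simplex_constraint_holds_per_draw(self):
        rng = np.random.default_rng(5)
        df = generate_action_effect_dataset(n_participants=10, N=13, rng=rng)
        draws = fit_action_model(df, config=MCMCConfig(iterations=300, seed=6))
        b = np.stack([draws.flat(n) for n in ("b_vl", "b_pl", "b_bu")])
        assert np.all(b >= 0)
        np.testing.assert_allclose(b.sum(axis=0), 1.0, atol=1e-9)

    def test_subject_effect_columns_present(self):
        rng = np.random.default_rng(6)
        df = generate_action_effect_dataset(n_participants=7, N=6, rng=rng)
        draws = fit_action_model(df, config=MCMCConfig(iterations=200, seed=7))
        assert {f"u_{k}" for k in range(1, 8)} <= set(draws.names)


class TestPosteriorPredictive:
    def test_empty_simulation(self, small_dataset):
        draws = make_draws({"beta0": [[1.0, 1.0], [1.0, 1.0]],
                            "beta1": [[0.0, 0.0], [0.0, 0.0]],
                            "phi": [[2.0, 2.0], [2.0, 2.0]]})
        out = posterior_predictive_resp(draws, "a", small_dataset, n_sims=0)
        assert len(out) == 0

    def test_degenerate_posterior_saturates(self, small_dataset):
        draws = make_draws({"beta0": [[40.0], [40.0]],
                            "beta1": [[0.0], [0.0]],
                            "phi": [[1e6], [1e6]]})
        out = posterior_predictive_resp(
            draws, "a", small_dataset, n_sims=200, rng=np.random.default_rng(0)
        )
        assert np.all(out == 13)

    def test_beta_binomial_fits_overdispersion_better_than_binomial(self):
        """On strongly overdispersed counts, the Beta-Binomial posterior
        predictive histogram must be closer (total variation on 0..13) to
        the observed histogram than the Binomial plug-in predictive."""
        rng = np.random.default_rng(10)
        n = 90
        spec = BetaBinomGenSpec(
            n_participants=n, beta0=0.3, beta1=0.0, phi=0.8,
            proprandom_values=np.full(n, 0.5),
        )
        data = generate_beta_binomial_dataset(spec, rng)
        draws = fit_model_a(data, config=MCMCConfig(iterations=1200, seed=11))
        obs_hist = np.bincount(data["resp"], minlength=14) / n

        def tv(sim):
            h = np.bincount(sim, minlength=14) / len(sim)
            return 0.5 * np.abs(h - obs_hist).sum()

        sim_bb = posterior_predictive_resp(draws, "a", data, 4000,
                                           rng=np.random.default_rng(1))
        sim_bin = posterior_predictive_resp(draws, "a", data, 4000,
                                            rng=np.random.default_rng(1),
                                            binomial_only=True)
        assert tv(sim_bb) < tv(sim_bin)


def test_generator_and_likelihood_agree_by_profile():
    """Data from the Beta-Binomial generator maximise the model's average
    log likelihood near the generating parameters (grid profile in beta1)."""
    rng = np.random.default_rng(21)
    n = 1200
    x = rng.uniform(0, 1, n)
    truth = dict(beta0=1.0, beta1=-1.5, phi=1.5)
    spec = BetaBinomGenSpec(
        n_participants=n, proprandom_values=x, **truth
    )
    data = generate_beta_binomial_dataset(spec, rng)
    grid = np.linspace(-3.5, 0.5, 17)
    ll = []
    for b1 in grid:
        p = special.expit(truth["beta0"] + b1 * x)
        ll.append(
            np.mean(
                [
                    beta_binomial_logpmf(k, 13, pi, truth["phi"])
                    for k, pi in zip(data["resp"], p)
                ]
            )
        )
    best = grid[int(np.argmax(ll))]
    assert abs(best - truth["beta1"]) <= 0.3


def test_mcmc_config_validation():
    with pytest.raises(ValueError):
        MCMCConfig(chains=1)
    with pytest.raises(ValueError):
        MCMCConfig(iterations=100, warmup=100)
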