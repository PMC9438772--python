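"""Bayesian machinery: observations, collapsed likelihood, fit, diagnostics."""

import numpy as np
import pytest
import arviz as az
from scipy.integrate import quad
from scipy.special import logit
from scipy.stats import beta as beta_dist
from scipy.stats import norm

import pcrbias as pb
from pcrbias.inference import (
    IdentifiabilityError,
    ObservationSet,
    Posterior,
    PriorConfig,
    SamplerConfig,
    _CollapsedModel,
    bias_summary,
    build_observations,
    diagnostics,
    fit,
    posterior_predictive_compositions,
)

FAST = SamplerConfig(tune=300, draws=512, thin=16, walkers=48)


def small_dataset(n=5, seed=0, sigma_scale=0.05):
    truth = pb.make_truth(n=n, seed=seed, a_scale=1.0, sigma_scale=sigma_scale)
    exp = pb.simulate_experiment(truth)
    obs = build_observations(exp, truth.basis, counts=pb.zero_replace(exp))
    return truth, exp, obs


def synthetic_posterior(basis, lam, a, sigma, n_draws=400):
    """A degenerate Posterior with constant draws, for predictive tests."""
    n, m = basis.n_leaves, basis.n_balances
    shape = (2, n_draws // 2)
    idata = az.from_dict(
        posterior={
            "lam": np.broadcast_to(lam, (*shape, n)).copy(),
            "a": np.broadcast_to(a, (*shape, m)).copy(),
            "sigma": np.broadcast_to(sigma, (*shape, m)).copy(),
        },
        coords={"template": list(basis.leaf_order),
                "balance": [f"b{i}" for i in range(m)]},
        dims={"lam": ["template"], "a": ["balance"], "sigma": ["balance"]},
    )
    return Posterior(
        idata=idata, template_ids=basis.leaf_order,
        priors=PriorConfig(), sampler=FAST, seed=0,
    )


class TestBuildObservations:
    def test_scale_invariance_between_samples(self, basis4):
        counts = np.array([[10.0, 100.0], [20.0, 200.0],
                           [5.0, 50.0], [65.0, 650.0]])
        exp = pb.CountExperiment(
            counts=counts.astype(int), cycles=[22, 22], replicates=[1, 2],
            template_ids=list("ABCD"), sample_ids=["s1", "s2"],
        )
        obs = build_observations(exp, basis4)
        np.testing.assert_allclose(obs.balances[0], obs.balances[1],
                                   atol=1e-10)

    def test_uniform_counts_zero_balances(self, basis4):
        exp = pb.CountExperiment(
            counts=np.full((4, 1), 7), cycles=[22], replicates=[1],
            template_ids=list("ABCD"), sample_ids=["s1"],
        )
        np.testing.assert_allclose(
            build_observations(exp, basis4).balances, 0.0, atol=1e-12
        )

    def test_matches_matrix_product_oracle(self, basis4, rng):
        mat = rng.uniform(1.0, 50.0, size=(4, 6))
        exp = pb.CountExperiment(
            counts=np.ones((4, 6), int), cycles=[22] * 6,
            replicates=list(range(6)), template_ids=list("ABCD"),
            sample_ids=[f"s{j}" for j in range(6)],
        )
        obs = build_observations(exp, basis4, counts=mat)
        expected = np.log(mat.T) @ basis4.contrast_matrix.T
        np.testing.assert_allclose(obs.balances, expected, atol=1e-12)

    def test_zeros_direct_to_zero_replace(self, basis4):
        exp = pb.CountExperiment(
            counts=np.array([[0, 5], [3, 3], [4, 4], [9, 9]]),
            cycles=[22, 23], replicates=[1, 1],
            template_ids=list("ABCD"), sample_ids=["s1", "s2"],
        )
        with pytest.raises(pb.coda.CodaError, match="zero_replace"):
            build_observations(exp, basis4)

    def test_row_alignment_to_basis_order(self, basis4, rng):
        mat = rng.uniform(1.0, 9.0, size=(4, 2))
        shuffled = ["C", "A", "D", "B"]
        exp = pb.CountExperiment(
            counts=np.ones((4, 2), int), cycles=[22, 23], replicates=[1, 1],
            template_ids=shuffled, sample_ids=["s1", "s2"],
        )
        obs = build_observations(exp, basis4, counts=mat)
        order = [shuffled.index(t) for t in basis4.leaf_order]
        expected = np.log(mat[order].T) @ basis4.contrast_matrix.T
        np.testing.assert_allclose(obs.balances, expected, atol=1e-12)


class TestCollapsedLikelihood:
    def test_matches_quadrature_oracle(self):
        """The analytically marginalised posterior equals brute-force
        1-D integration of the intercept, balance by balance."""
        truth, _, obs = small_dataset(n=4, seed=6)
        basis = truth.basis
        priors = PriorConfig()
        model = _CollapsedModel(obs, basis, priors)
        rng = np.random.default_rng(1)
        lam = rng.uniform(0.3, 0.95, 4)
        sigma = rng.uniform(0.05, 0.4, 3)
        u = np.concatenate([logit(lam), np.log(sigma)])[None]
        got = model.log_prob(u)[0]

        t = obs.cycles.astype(float)
        b = obs.balances
        psi_t = basis.contrast_matrix.T
        slope = np.log1p(lam) @ psi_t
        w = np.log(lam) @ psi_t
        lp = beta_dist(4, 1).logpdf(lam).sum() + np.log(lam * (1 - lam)).sum()
        lp += (np.log(2) + norm(0, 1).logpdf(sigma) + np.log(sigma)).sum()
        S = len(t)
        for i in range(3):
            ybar = (b[:, i] - t * slope[i]).mean()
            sd_post = sigma[i] / np.sqrt(S)
            ll_max = norm(t * slope[i] + ybar, sigma[i]).logpdf(b[:, i]).sum()

            def f(c, i=i, ll_max=ll_max):
                ll = norm(t * slope[i] + c, sigma[i]).logpdf(b[:, i]).sum()
                return np.exp(ll - ll_max + norm(-w[i], 2.0).logpdf(c))

            val, _ = quad(f, ybar - 15 * sd_post, ybar + 15 * sd_post,
                          limit=400)
            lp += np.log(val) + ll_max
        assert got == pytest.approx(lp, abs=1e-8)

    def test_sample_order_invariance(self):
        """Exchangeable likelihood: permuting samples leaves the posterior
        density unchanged at identical parameter values."""
        truth, _, obs = small_dataset(n=5, seed=8)
        perm = np.random.default_rng(0).permutation(obs.n_samples)
        obs_p = ObservationSet(
            balances=obs.balances[perm], cycles=obs.cycles[perm],
            replicates=obs.replicates[perm],
        )
        model = _CollapsedModel(obs, truth.basis, PriorConfig())
        model_p = _CollapsedModel(obs_p, truth.basis, PriorConfig())
        u = np.concatenate([logit(np.full(5, 0.7)), np.log(np.full(4, 0.1))])
        np.testing.assert_allclose(
            model.log_prob(u[None]), model_p.log_prob(u[None]), atol=1e-9
        )


class TestFit:
    def test_recovers_truth_within_three_sd(self):
        truth, _, obs = small_dataset(n=5, seed=1, sigma_scale=0.02)
        post = fit(obs, truth.basis, sampler=FAST, seed=42)
        true_l1p = np.log1p(truth.params.lambda_)
        est = np.log1p(post.lambda_draws)
        mean, sd = est.mean(axis=0), est.std(axis=0)
        # the common level is prior-identified only, so compare contrasts
        centred_err = (mean - mean.mean()) - (true_l1p - true_l1p.mean())
        assert np.all(np.abs(centred_err) < 3 * np.maximum(sd, 1e-3))

    def test_single_cycle_unidentifiable(self, basis4, rng):
        obs = ObservationSet(
            balances=rng.normal(size=(12, 3)), cycles=[22] * 12,
            replicates=list(range(12)),
        )
        with pytest.raises(IdentifiabilityError):
            fit(obs, basis4, sampler=FAST, seed=0)

    def test_prior_recovery_on_noninformative_data(self, rng):
        """Two nearly pure-noise observations barely update Beta(4,1):
        the lambda marginal mean stays near the prior mean 0.8."""
        basis = pb.simulate_tree(4, seed=0)
        obs = ObservationSet(
            balances=0.01 * rng.normal(size=(2, 3)),
            cycles=[22, 23], replicates=[1, 1],
        )
        post = fit(obs, basis, sampler=FAST, seed=7)
        assert post.lambda_draws.mean() == pytest.approx(0.8, abs=0.1)

    def test_seed_reproducibility(self):
        truth, _, obs = small_dataset(n=4, seed=3)
        p1 = fit(obs, truth.basis, sampler=FAST, seed=5)
        p2 = fit(obs, truth.basis, sampler=FAST, seed=5)
        np.testing.assert_array_equal(p1.lambda_draws, p2.lambda_draws)
        np.testing.assert_array_equal(p1.a_draws, p2.a_draws)


class TestDiagnostics:
    def test_iid_chains_pass(self, rng):
        draws = rng.normal(size=(4, 500))
        idata = az.from_dict(posterior={"x": draws})
        frame = diagnostics(idata)
        assert frame["rhat"].max() < 1.01
        assert frame.attrs["converged"]

    def test_disjoint_chains_flagged(self, rng):
        draws = np.stack([rng.normal(size=500), rng.normal(size=500) + 10.0])
        idata = az.from_dict(posterior={"x": draws})
        frame = diagnostics(idata)
        assert frame["rhat"].max() > 1.1
        assert not frame.attrs["converged"]

    def test_iid_ess_near_length(self, rng):
        draws = rng.normal(size=(4, 1000))
        idata = az.from_dict(posterior={"x": draws})
        frame = diagnostics(idata)
        assert frame["ess_bulk"].iloc[0] == pytest.approx(4000, rel=0.25)

    def test_single_chain_flagged(self, rng):
        idata = az.from_dict(posterior={"x": rng.normal(size=(1, 500))})
        with pytest.warns(UserWarning, match="2 chains"):
            frame = diagnostics(idata)
        assert np.isnan(frame["rhat"]).all()
        assert not frame.attrs["converged"]


class TestPosteriorPredictive:
    def test_compositions_sum_to_one(self):
        truth, _, obs = small_dataset(n=4, seed=3)
        post = fit(obs, truth.basis, sampler=FAST, seed=9)
        preds = posterior_predictive_compositions(
            post, truth.basis, cycles=[0, 22, 35], n_draws=50, seed=1
        )
        for t, comp in preds.items():
            assert comp.shape == (50, 4)
            np.testing.assert_allclose(comp.sum(axis=1), 1.0, atol=1e-10)

    def test_vanishing_noise_collapses_to_reconstruction(self, rng):
        basis = pb.simulate_tree(4, seed=1)
        lam = rng.uniform(0.4, 0.9, 4)
        a = rng.normal(0, 1, 3)
        post = synthetic_posterior(basis, lam, a, sigma=np.full(3, 1e-8))
        params = pb.PCRParams.from_balances(
            a=a, lambda_=lam, sigma=np.full(3, 1e-8), basis=basis
        )
        preds = posterior_predictive_compositions(
            post, basis, cycles=[0, 24], n_draws=20, seed=2
        )
        np.testing.assert_allclose(
            preds[24],
            np.broadcast_to(
                pb.reconstruct_composition(params, basis, 24), (20, 4)
            ),
            atol=1e-6,
        )
        np.testing.assert_allclose(
            preds[0],
            np.broadcast_to(
                pb.reconstruct_composition(params, basis, 0), (20, 4)
            ),
            atol=1e-6,
        )

    def test_nonmonotone_trajectory_exists(self):
        """Heterogeneous efficiencies make some per-template predictive
        trajectories non-monotone over cycles — compositional curvature."""
        basis = pb.ContrastBasis.from_tree("((A,B),C);")
        lam = np.array([1.0, 0.62, 0.6])
        theta_z = np.array([0.01, 0.01, 0.98])
        params = pb.PCRParams.from_theta_z(
            theta_z, lam, np.full(2, 0.05), basis
        )
        traj = np.array(
            [pb.reconstruct_composition(params, basis, t)
             for t in range(0, 36)]
        )
        diffs = np.diff(traj, axis=0)
        non_monotone = [
            i for i in range(3)
            if (diffs[:, i] > 1e-12).any() and (diffs[:, i] < -1e-12).any()
        ]
        assert non_monotone


class TestBiasSummary:
    def test_same_cycle_all_zero(self):
        truth, _, obs = small_dataset(n=4, seed=3)
        post = fit(obs, truth.basis, sampler=FAST, seed=9)
        frame = bias_summary(post, truth.basis, 22, 22, n_draws=50, seed=0)
        np.testing.assert_allclose(frame["median_log_ratio"], 0.0, atol=1e-12)

    def test_homogeneous_lambda_centred_at_zero(self, rng):
        basis = pb.simulate_tree(4, seed=2)
        post = synthetic_posterior(
            basis, np.full(4, 0.7), rng.normal(size=3), np.full(3, 0.05)
        )
        frame = bias_summary(post, basis, 22, 26, n_draws=50, seed=0)
        np.testing.assert_allclose(frame["median_log_ratio"], 0.0, atol=1e-10)

    def test_fast_template_gains_others_lose(self):
        basis = pb.simulate_tree(4, seed=3)
        lam = np.array([1.0, 0.6, 0.6, 0.6])
        a = pb.ilr(np.full(4, 0.25), basis)
        post = synthetic_posterior(basis, lam, a, np.full(3, 0.05))
        frame = bias_summary(post, basis, 22, 26, n_draws=50, seed=0)
        med = frame.set_index("template_id")["median_log_ratio"]
        fast = basis.leaf_order[0]
        assert med[fast] > 0
        assert all(med[t] < 0 for t in basis.leaf_order[1:])
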