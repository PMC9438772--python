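"""Hierarchical Bayesian inference of amplification efficiencies.

The observation model treats the ILR balances of each library (replicate j
sequenced after t cycles) as a draw around the kinetic line::

    b^tj ~ Normal( t log(lambda+1) Psi^T - log(lambda) Psi^T + a, diag(sigma^2) )
    lambda_i ~ Beta(4, 1)
    a_i      ~ Normal(0, 2)          (scale parametrisation, sd = 2)
    sigma_i  ~ HalfNormal(1)

Only the contrast log(lambda+1) Psi^T enters the likelihood slope, so the
common level of log(lambda+1) across templates is informed by the prior
alone; contrasts between templates are what the data identify.  Likewise a,
not theta*z, is the identified initial-profile quantity.

Sampling uses an affine-invariant ensemble MCMC sampler on an unconstrained
reparametrisation (logit lambda, log sigma) with exact Jacobian corrections.
``SamplerConfig.chains`` independent ensembles are run; each ensemble is one
chain for rank-normalised R-hat and ESS diagnostics (arviz), its retained
draws flattened step-major so consecutive draws come from different walkers.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy.special import betaln, expit, logit

from pcrbias.coda import CodaError, ContrastBasis, CountExperiment, ilr, ilr_inverse
from pcrbias.kinetics import PCRParams

logger = logging.getLogger(__name__)


class IdentifiabilityError(ValueError):
    """The design cannot identify the model (e.g. a single distinct cycle)."""


@dataclass
class ObservationSet:
    """ILR balances per library with its cycle number and replicate label."""

    balances: np.ndarray  # (n_samples, n_balances)
    cycles: np.ndarray
    replicates: np.ndarray

    def __post_init__(self) -> None:
        self.balances = np.atleast_2d(np.asarray(self.balances, dtype=float))
        self.cycles = np.asarray(self.cycles, dtype=int)
        self.replicates = np.asarray(self.replicates)
        if self.balances.shape[0] != self.cycles.shape[0]:
            raise ValueError("one cycle label per sample required")
        if self.balances.shape[0] != self.replicates.shape[0]:
            raise ValueError("one replicate label per sample required")

    @property
    def n_samples(self) -> int:
        return self.balances.shape[0]

    @property
    def n_balances(self) -> int:
        return self.balances.shape[1]


def build_observations(
    exp: CountExperiment,
    basis: ContrastBasis,
    counts: np.ndarray | None = None,
) -> ObservationSet:
    """ILR-transform a (zero-replaced) count experiment into balances.

    ``counts`` overrides the experiment's integer matrix with the strictly
    positive pseudo-counts produced by :func:`pcrbias.coda.zero_replace`.
    The unknown per-library scale factor cancels in the transform, so no
    depth normalisation is needed.  Rows are aligned to the basis leaf order.
    """
    mat = exp.counts if counts is None else np.asarray(counts, dtype=float)
    if mat.shape != (exp.n_templates, exp.n_samples):
        raise ValueError("counts matrix shape does not match the experiment")
    if set(exp.template_ids) != set(basis.leaf_order):
        missing = set(exp.template_ids) ^ set(basis.leaf_order)
        raise ValueError(
            f"template ids do not match basis leaves; differing: {sorted(missing)}"
        )
    order = [exp.template_ids.index(name) for name in basis.leaf_order]
    mat = mat[order]
    if np.any(mat == 0):
        raise CodaError(
            "counts contain zeros; apply pcrbias.coda.zero_replace first"
        )
    balances = ilr(mat.T, basis)
    return ObservationSet(
        balances=balances, cycles=exp.cycles, replicates=exp.replicates
    )


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the hierarchical priors."""

    lambda_alpha: float = 4.0
    lambda_beta: float = 1.0
    a_scale: float = 2.0
    sigma_scale: float = 1.0

    def __post_init__(self) -> None:
        if min(self.lambda_alpha, self.lambda_beta, self.a_scale,
               self.sigma_scale) <= 0:
            raise ValueError("prior hyperparameters must be positive")


@dataclass(frozen=True)
class SamplerConfig:
    """Ensemble-MCMC settings.

    ``tune`` burn-in moves and enough further moves to retain ``draws``
    samples per ensemble are run for each of ``chains`` independent
    ensembles of ``walkers`` walkers.  The study-scale analogue of the
    original analysis (5000 tuning / 20000 draws / 4 chains) is available by
    passing those numbers; the default is a desk-scale configuration.
    """

    tune: int = 500
    draws: int = 1000
    chains: int = 2
    walkers: int = 64
    thin: int = 64
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.tune < 1 or self.draws < 1 or self.chains < 1:
            raise ValueError("tune, draws and chains must be positive")
        if self.walkers < 8 or self.walkers % 2:
            raise ValueError("walkers must be an even number >= 8")
        if self.thin < 1:
            raise ValueError("thin must be positive")


class _CollapsedModel:
    """The posterior with the per-balance intercept integrated out.

    Writing the likelihood mean as mu_si = t_s * s_i + c_i with slope
    s = log(lambda+1) Psi^T and intercept c = a - log(lambda) Psi^T, the
    model is linear-Gaussian in c for fixed (lambda, sigma): the N(0,
    a_scale^2) prior on a = c + w(lambda), w = log(lambda) Psi^T, is a
    Gaussian prior on c, so c integrates out in closed form.  The ensemble
    sampler then only has to explore u = [logit(lambda) (n), log(sigma)
    (n-1)] — a far better-conditioned 2n-1-dimensional target — and c (hence
    a) is drawn exactly from its Gaussian conditional for every retained
    draw.  Only sufficient statistics of the regression of b on t enter, so
    evaluation cost is independent of the number of libraries.
    """

    def __init__(self, obs: ObservationSet, basis: ContrastBasis,
                 priors: PriorConfig) -> None:
        self.psi_t = basis.contrast_matrix.T  # (n, m)
        self.n = basis.n_leaves
        self.m = basis.n_balances
        self.priors = priors
        t = obs.cycles.astype(float)
        b = obs.balances
        self.S = b.shape[0]
        self.t_bar = t.mean()
        self.b_bar = b.mean(axis=0)  # (m,)
        tc = t - self.t_bar
        bc = b - self.b_bar
        self.sxx = float((tc ** 2).sum())
        self.sxy = tc @ bc  # (m,)
        self.ssb = (bc ** 2).sum(axis=0)  # (m,)
        self._lbeta = betaln(priors.lambda_alpha, priors.lambda_beta)

    def _blocks(self, u: np.ndarray):
        u = np.atleast_2d(u)
        u_lam = u[:, :self.n]
        log_sigma = u[:, self.n:]
        log_lam = -np.logaddexp(0.0, -u_lam)  # log expit(u), stable
        lam = expit(u_lam)
        sigma2 = np.exp(2.0 * log_sigma)
        slope = np.log1p(lam) @ self.psi_t  # (W, m)
        w = log_lam @ self.psi_t  # (W, m)
        return u_lam, log_lam, lam, log_sigma, sigma2, slope, w

    def _conditional_c(self, sigma2: np.ndarray, slope: np.ndarray,
                       w: np.ndarray):
        """Gaussian conditional of the intercept: mean and variance, (W, m)."""
        tau2 = self.priors.a_scale ** 2
        ybar = self.b_bar - self.t_bar * slope
        v = 1.0 / (self.S / sigma2 + 1.0 / tau2)
        mean = v * (self.S * ybar / sigma2 - w / tau2)
        return mean, v

    def log_prob(self, u: np.ndarray) -> np.ndarray:
        pr = self.priors
        u = np.atleast_2d(u)
        # reject absurd proposals outright (|logit lambda| or |log sigma|
        # beyond 30 carries no posterior mass and would overflow exp)
        bad = np.any(np.abs(u) > 30.0, axis=1)
        if bad.any():
            out = np.full(u.shape[0], -np.inf)
            good = ~bad
            if good.any():
                out[good] = self.log_prob(u[good])
            return out
        u_lam, log_lam, lam, log_sigma, sigma2, slope, w = self._blocks(u)
        log_1m_lam = -np.logaddexp(0.0, u_lam)
        sigma = np.sqrt(sigma2)
        # Beta prior on lambda and half-normal prior on sigma, with the
        # Jacobians of the logit/log transforms folded in
        lp = (pr.lambda_alpha * log_lam + pr.lambda_beta * log_1m_lam
              - self._lbeta).sum(axis=1)
        lp += (math.log(2.0) - 0.5 * (sigma / pr.sigma_scale) ** 2
               - math.log(pr.sigma_scale * math.sqrt(2.0 * math.pi))
               + log_sigma).sum(axis=1)
        # marginal likelihood of each balance with the intercept integrated
        # out against its induced Gaussian prior N(-w, a_scale^2)
        tau2 = pr.a_scale ** 2
        ssw = self.ssb - 2.0 * slope * self.sxy + slope ** 2 * self.sxx
        ybar = self.b_bar - self.t_bar * slope
        c_mean, v = self._conditional_c(sigma2, slope, w)
        quad = (ssw + self.S * ybar ** 2) / sigma2 + w ** 2 / tau2 \
            - c_mean ** 2 / v
        lp += (-0.5 * self.S * np.log(2.0 * math.pi * sigma2)
               - 0.5 * math.log(tau2) + 0.5 * np.log(v)
               - 0.5 * quad).sum(axis=1)
        return lp

    def sample_a(self, u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Exact draw of a = c + w from its conditional for each row of u."""
        _, _, _, _, sigma2, slope, w = self._blocks(u)
        c_mean, v = self._conditional_c(sigma2, slope, w)
        c = c_mean + np.sqrt(v) * rng.standard_normal(c_mean.shape)
        return c + w


def _initial_point(obs: ObservationSet, basis: ContrastBasis) -> np.ndarray:
    """Data-informed centre for the walkers: per-balance OLS of b on t.

    The slope contrast determines log(lambda+1) up to a common level, which
    is pinned at the prior mean efficiency (0.8) for initialisation only.
    """
    t = obs.cycles.astype(float)
    design = np.vstack([t, np.ones_like(t)]).T
    coef, *_ = np.linalg.lstsq(design, obs.balances, rcond=None)
    slope_hat, intercept_hat = coef  # each (m,)
    resid = obs.balances - design @ coef
    psi = basis.contrast_matrix
    clr_log1p = slope_hat @ psi  # centred log(lambda + 1)
    log1p_lam = clr_log1p - clr_log1p.mean() + math.log(1.8)
    lam0 = np.clip(np.expm1(log1p_lam), 1e-3, 1.0 - 1e-3)
    dof = max(obs.n_samples - 2, 1)
    sigma0 = np.clip(np.sqrt((resid ** 2).sum(axis=0) / dof), 1e-3, None)
    return np.concatenate([logit(lam0), np.log(sigma0)])


@dataclass
class Posterior:
    """MCMC draws of (lambda, a, sigma) with chain/draw structure.

    ``idata`` is an :class:`arviz.InferenceData` whose chain dimension
    enumerates every walker of every ensemble.
    """

    idata: az.InferenceData
    template_ids: tuple[str, ...]
    priors: PriorConfig
    sampler: SamplerConfig
    seed: int | None
    acceptance_fraction: float = float("nan")

    def _stacked(self, name: str) -> np.ndarray:
        da = self.idata.posterior[name]
        return da.stack(sample=("chain", "draw")).transpose("sample", ...).values

    @property
    def lambda_draws(self) -> np.ndarray:
        return self._stacked("lam")

    @property
    def a_draws(self) -> np.ndarray:
        return self._stacked("a")

    @property
    def sigma_draws(self) -> np.ndarray:
        return self._stacked("sigma")

    @property
    def n_draws(self) -> int:
        return self.lambda_draws.shape[0]

    def params_at(self, basis: ContrastBasis, index: int) -> PCRParams:
        """The index-th posterior draw as a PCRParams."""
        return PCRParams.from_balances(
            a=self.a_draws[index],
            lambda_=np.clip(self.lambda_draws[index], 1e-12, 1.0),
            sigma=self.sigma_draws[index],
            basis=basis,
        )

    def posterior_mean_params(self, basis: ContrastBasis) -> PCRParams:
        return PCRParams.from_balances(
            a=self.a_draws.mean(axis=0),
            lambda_=np.clip(self.lambda_draws.mean(axis=0), 1e-12, 1.0),
            sigma=self.sigma_draws.mean(axis=0),
            basis=basis,
        )

    def summary_frame(self) -> pd.DataFrame:
        """Posterior means, sds and 95% credible bounds per scalar parameter."""
        rows = []
        for name, draws, labels in (
            ("lambda", self.lambda_draws, self.template_ids),
            ("a", self.a_draws,
             [f"b{i}" for i in range(self.a_draws.shape[1])]),
            ("sigma", self.sigma_draws,
             [f"b{i}" for i in range(self.sigma_draws.shape[1])]),
        ):
            lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
            for j, lab in enumerate(labels):
                rows.append(
                    {
                        "parameter": name,
                        "label": lab,
                        "mean": draws[:, j].mean(),
                        "sd": draws[:, j].std(ddof=1),
                        "ci2.5": lo[j],
                        "ci97.5": hi[j],
                    }
                )
        return pd.DataFrame(rows)


def fit(
    obs: ObservationSet,
    basis: ContrastBasis,
    priors: PriorConfig | None = None,
    sampler: SamplerConfig | None = None,
    seed: int | None = None,
) -> Posterior:
    """Sample the posterior of (lambda, a, sigma) given balance observations.

    Parameters
    ----------
    obs
        Balances with cycle labels; at least two distinct cycles are needed,
        otherwise the slope (hence lambda) is unidentifiable.
    basis
        The phylogenetic ILR basis the balances were computed in.
    priors, sampler
        Hyperparameters and MCMC settings; defaults follow the module
        docstring.
    seed
        Overrides ``sampler.seed``.  All randomness derives from it.
    """
    priors = priors or PriorConfig()
    sampler = sampler or SamplerConfig()
    if seed is None:
        seed = sampler.seed
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % (2 ** 31))
        logger.info("fit: no seed supplied, using generated seed %d", seed)
    if obs.n_balances != basis.n_balances:
        raise ValueError("observation and basis dimensions disagree")
    if np.unique(obs.cycles).size < 2:
        raise IdentifiabilityError(
            "balances span a single PCR cycle; the kinetic slope (and hence "
            "lambda) is unidentifiable — include at least two distinct cycles"
        )

    n, m = basis.n_leaves, basis.n_balances
    ndim = n + m
    n_walkers = max(sampler.walkers, 2 * ndim + 2)
    if n_walkers % 2:
        n_walkers += 1
    keep_steps = max(math.ceil(sampler.draws / n_walkers), 8)
    # retain every thin-th ensemble move so the kept window spans many
    # integrated autocorrelation times (tau ~ 70 moves for this target)
    window = keep_steps * sampler.thin
    model = _CollapsedModel(obs, basis, priors)
    centre = _initial_point(obs, basis)

    chain_blocks = []
    acc = []
    root_seed = np.random.SeedSequence(seed)
    child_seeds = root_seed.spawn(sampler.chains + 1)
    for ss in child_seeds[:-1]:
        rng = np.random.default_rng(ss)
        p0 = centre[None, :] + 0.1 * rng.standard_normal((n_walkers, ndim))
        # the common level of logit(lambda) is identified by the prior only;
        # overdisperse the walkers along it so the ensemble starts with the
        # right spread instead of diffusing into it
        p0[:, :n] += 0.5 * rng.standard_normal((n_walkers, 1))
        ens = emcee.EnsembleSampler(
            n_walkers, ndim, model.log_prob, vectorize=True,
            moves=[(emcee.moves.DEMove(), 0.8),
                   (emcee.moves.DESnookerMove(), 0.2)],
        )
        ens.random_state = np.random.RandomState(
            int(ss.generate_state(1)[0])
        ).get_state()
        ens.run_mcmc(p0, sampler.tune + window, progress=False)
        chain = ens.get_chain(discard=sampler.tune, thin=sampler.thin)
        # flatten step-major: consecutive retained draws come from different
        # walkers, so each ensemble forms one nearly-uncorrelated chain
        chain_blocks.append(chain.reshape(keep_steps * n_walkers, ndim))
        acc.append(ens.acceptance_fraction.mean())
    u = np.stack(chain_blocks, axis=0)  # (chains, draws, ndim)

    mean_acc = float(np.mean(acc))
    if mean_acc < 0.15:
        logger.warning(
            "fit: mean ensemble acceptance fraction %.3f is low; treat the "
            "posterior with caution (analogue of divergent transitions)",
            mean_acc,
        )

    lam = expit(u[..., :n])
    sigma = np.exp(u[..., n:])
    # exact conditional draw of the marginalised intercept, per retained draw
    rng_a = np.random.default_rng(child_seeds[-1])
    a = model.sample_a(u.reshape(-1, ndim), rng_a).reshape(
        u.shape[0], u.shape[1], m
    )
    idata = az.from_dict(
        posterior={"lam": lam, "a": a, "sigma": sigma},
        coords={
            "template": list(basis.leaf_order),
            "balance": [f"b{i}" for i in range(m)],
        },
        dims={"lam": ["template"], "a": ["balance"], "sigma": ["balance"]},
    )
    return Posterior(
        idata=idata,
        template_ids=tuple(basis.leaf_order),
        priors=priors,
        sampler=sampler,
        seed=seed,
        acceptance_fraction=mean_acc,
    )


def diagnostics(
    post: Posterior | az.InferenceData,
    rhat_threshold: float = 1.01,
    ess_threshold: float = 100.0,
) -> pd.DataFrame:
    """Per-scalar-parameter Gelman–Rubin R-hat and bulk ESS with pass flags.

    Accepts a fitted :class:`Posterior` or any arviz ``InferenceData`` with a
    posterior group.  With a single chain R-hat is unavailable and flagged as
    NaN (failing the check).  The frame's ``attrs['converged']`` records the
    overall verdict.
    """
    idata = post.idata if isinstance(post, Posterior) else post
    n_chains = idata.posterior.sizes["chain"]
    single_chain = n_chains < 2
    if single_chain:
        warnings.warn(
            "R-hat requires >= 2 chains; reporting NaN", UserWarning,
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = None if single_chain else az.rhat(idata)
        ess = az.ess(idata, method="bulk")
    rows = []
    for name, da in idata.posterior.items():
        extra_dims = [d for d in da.dims if d not in ("chain", "draw")]
        ess_da = ess[name]
        rhat_da = None if single_chain else rhat[name]
        if extra_dims:
            for j in range(da.sizes[extra_dims[0]]):
                label = str(da[extra_dims[0]].values[j])
                r = float("nan") if single_chain else float(rhat_da.values[j])
                e = float(ess_da.values[j])
                rows.append({"parameter": name, "label": label, "rhat": r,
                             "ess_bulk": e})
        else:
            r = float("nan") if single_chain else float(rhat_da.values)
            rows.append({"parameter": name, "label": "", "rhat": r,
                         "ess_bulk": float(ess_da.values)})
    frame = pd.DataFrame(rows)
    frame["rhat_ok"] = (frame["rhat"] < rhat_threshold).fillna(False)
    frame["ess_ok"] = frame["ess_bulk"] >= ess_threshold
    frame["ok"] = frame["rhat_ok"] & frame["ess_ok"]
    frame.attrs["converged"] = bool(frame["ok"].all())
    return frame


def _predictive_balance_means(
    post: Posterior, basis: ContrastBasis, t: int, idx: np.ndarray
) -> np.ndarray:
    """Mean balances at cycle t for a set of posterior draws.

    Uses the exact reconstruction (closed-form counts), which coincides with
    the fitted linear balance model up to the geometrically vanishing
    (1/(lambda+1))^t term; at t = 0 the initial-profile convention b = a
    applies.
    """
    a = post.a_draws[idx]
    if t == 0:
        return a
    lam = np.clip(post.lambda_draws[idx], 1e-12, 1.0)
    z_hat = ilr_inverse(a, basis)
    unnorm = z_hat / lam * ((lam + 1.0) ** t - 1.0)
    return np.log(unnorm) @ basis.contrast_matrix.T


def posterior_predictive_compositions(
    post: Posterior,
    basis: ContrastBasis,
    cycles: list[int],
    n_draws: int = 500,
    seed: int | None = None,
    include_noise: bool = True,
) -> dict[int, np.ndarray]:
    """Posterior-predictive community compositions at the requested cycles.

    For each cycle t and each of ``n_draws`` posterior draws, a balance
    vector is sampled from Normal(b(t), diag(sigma^2)) and mapped through the
    inverse ILR; ``include_noise=False`` returns the noise-free model
    reconstructions instead.  Returns a mapping cycle -> (n_draws, n) array
    of compositions (rows sum to 1).
    """
    rng = np.random.default_rng(seed)
    total = post.n_draws
    idx = rng.choice(total, size=min(n_draws, total), replace=n_draws > total)
    sigma = post.sigma_draws[idx]
    out: dict[int, np.ndarray] = {}
    for t in cycles:
        if t < 0:
            raise ValueError("cycles must be >= 0")
        b_mean = _predictive_balance_means(post, basis, int(t), idx)
        if include_noise:
            b = b_mean + sigma * rng.standard_normal(b_mean.shape)
        else:
            b = b_mean
        out[int(t)] = ilr_inverse(b, basis)
    return out


def bias_summary(
    post: Posterior,
    basis: ContrastBasis,
    t1: int,
    t2: int,
    n_draws: int = 500,
    seed: int | None = None,
) -> pd.DataFrame:
    """Posterior distribution of per-template log-ratio change t1 -> t2.

    Returns a frame with the median and interquartile range, per template, of
    log( x_i(t2) / x_i(t1) ) across posterior draws — the summary behind
    box-plot views of amplification bias between two cycles.
    """
    rng = np.random.default_rng(seed)
    total = post.n_draws
    idx = rng.choice(total, size=min(n_draws, total), replace=n_draws > total)
    x1 = ilr_inverse(_predictive_balance_means(post, basis, int(t1), idx), basis)
    x2 = ilr_inverse(_predictive_balance_means(post, basis, int(t2), idx), basis)
    change = np.log(x2 / x1)  # (draws, n)
    q25, med, q75 = np.percentile(change, [25, 50, 75], axis=0)
    return pd.DataFrame(
        {
            "template_id": list(post.template_ids),
            "median_log_ratio": med,
            "q25": q25,
            "q75": q75,
            "mean_log_ratio": change.mean(axis=0),
        }
    )
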