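"""Synthetic multi-cycle PCR calibration experiments with ground truth.

Emulates the calibration design the model was built for: a fixed community
amplified for five consecutive cycles (22-26) with 12 replicate reactions
per cycle, sequenced to a common depth (9988 reads after rarefaction).  For
every replicate the generator evaluates the kinetic balance line at its
cycle, adds diagonal Gaussian noise in balance space (the inference model's
own noise), maps back to the simplex, applies an arbitrary per-sample scale
factor (which the ILR provably cancels) and draws multinomial counts at the
configured depth.

An optional misspecified mode perturbs the efficiencies themselves per
replicate instead of the balances, for robustness studies of the inference.

All generators are bit-reproducible from (seed, configuration).
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skbio import TreeNode

from pcrbias.coda import ContrastBasis, CountExperiment, closure, ilr_inverse
from pcrbias.kinetics import PCRParams, balance_trajectory

DEFAULT_CYCLES: tuple[int, ...] = (22, 23, 24, 25, 26)
DEFAULT_REPLICATES: int = 12
DEFAULT_DEPTH: int = 9988

#: Coefficients of the synthetic secondary-structure energy covariate:
#: E = e0 + e_gc * GC + e_loglam * log(lambda) + Normal(0, e_sd), in kcal/mol.
#: e_gc defaults to 0 so GC is a null covariate, while e_loglam links the
#: energy to efficiency (more negative energy <-> lower efficiency).
DEFAULT_ENERGY_COEFS: dict[str, float] = {
    "e0": -40.0,
    "e_gc": 0.0,
    "e_loglam": 15.0,
    "e_sd": 1.0,
}


def simulate_tree(n: int, seed: int | None = None) -> ContrastBasis:
    """Random rooted strictly binary tree with n named leaves and its basis.

    Built by repeatedly joining two uniformly chosen clades, which yields a
    uniform random coalescent-style topology.
    """
    if n < 2:
        raise ValueError("a binary tree needs at least two leaves")
    rng = np.random.default_rng(seed)
    clades = [f"T{i:03d}" for i in range(n)]
    while len(clades) > 1:
        i, j = sorted(rng.choice(len(clades), size=2, replace=False))
        right = clades.pop(j)
        left = clades.pop(i)
        clades.append(f"({left},{right})")
    tree = TreeNode.read(_io.StringIO(clades[0] + ";"))
    return ContrastBasis.from_tree(tree)


def simulate_params(
    basis: ContrastBasis,
    seed: int | None = None,
    lambda_ab: tuple[float, float] = (4.0, 1.0),
    a_scale: float = 2.0,
    sigma_scale: float = 0.05,
) -> PCRParams:
    """Draw kinetic parameters from the generative (prior) distributions.

    lambda ~ Beta(*lambda_ab*), a ~ Normal(0, a_scale) per balance and
    sigma ~ HalfNormal(sigma_scale).  theta_z is the closed composition
    ilr^-1(a).  The default replicate noise (0.05) reflects the tight
    replication of a single-master-mix calibration run rather than the
    weakly-informative inference prior.
    """
    alpha, beta = lambda_ab
    if alpha <= 0 or beta <= 0 or a_scale < 0 or sigma_scale <= 0:
        raise ValueError("invalid hyperparameters")
    rng = np.random.default_rng(seed)
    n = basis.n_leaves
    lam = rng.beta(alpha, beta, size=n)
    lam = np.clip(lam, 1e-6, 1.0)
    a = rng.normal(0.0, a_scale, size=n - 1) if a_scale > 0 else np.zeros(n - 1)
    sigma = np.abs(rng.normal(0.0, sigma_scale, size=n - 1))
    sigma = np.clip(sigma, 1e-6, None)
    return PCRParams.from_balances(a=a, lambda_=lam, sigma=sigma, basis=basis)


@dataclass
class SyntheticTruth:
    """Everything needed to regenerate a synthetic experiment bit-for-bit."""

    params: PCRParams
    basis: ContrastBasis
    cycles: tuple[int, ...]
    n_replicates: int
    depth: int
    seed: int
    scale_factors: np.ndarray  # per sample, in design order
    noise_mode: str = "balance"  # or "efficiency"
    sequences: dict[str, str] | None = None
    energies: np.ndarray | None = None
    energy_coefs: dict[str, float] | None = None

    @property
    def n_samples(self) -> int:
        return len(self.cycles) * self.n_replicates

    def design(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Per-sample cycle, replicate and id arrays in generation order."""
        cyc, rep, sid = [], [], []
        for t in self.cycles:
            for j in range(1, self.n_replicates + 1):
                cyc.append(t)
                rep.append(j)
                sid.append(f"c{t}r{j:02d}")
        return np.array(cyc), np.array(rep), sid

    def noiseless_balances(self) -> np.ndarray:
        """The exact kinetic line evaluated at each design cycle."""
        traj = balance_trajectory(self.params, self.basis)
        cyc, _, _ = self.design()
        return np.array([traj(int(t)) for t in cyc])

    def to_json(self) -> str:
        payload = {
            "lambda": self.params.lambda_.tolist(),
            "theta_z": self.params.theta_z.tolist(),
            "a": self.params.a.tolist(),
            "sigma": self.params.sigma.tolist(),
            "leaf_order": list(self.basis.leaf_order),
            "newick": self.basis.to_newick(),
            "cycles": list(self.cycles),
            "n_replicates": self.n_replicates,
            "depth": self.depth,
            "seed": self.seed,
            "scale_factors": self.scale_factors.tolist(),
            "noise_mode": self.noise_mode,
            "sequences": self.sequences,
            "energies": None if self.energies is None else self.energies.tolist(),
            "energy_coefs": self.energy_coefs,
        }
        return json.dumps(payload, indent=2)


def make_truth(
    n: int = 10,
    seed: int = 0,
    cycles: Sequence[int] = DEFAULT_CYCLES,
    n_replicates: int = DEFAULT_REPLICATES,
    depth: int = DEFAULT_DEPTH,
    sigma_scale: float = 0.05,
    a_scale: float = 2.0,
    lambda_ab: tuple[float, float] = (4.0, 1.0),
    scale_factor_sd: float = 0.5,
    noise_mode: str = "balance",
    with_sequences: bool = False,
    sequence_length: int = 250,
) -> SyntheticTruth:
    """Assemble a complete synthetic truth: tree, parameters and design.

    Per-sample scale factors A are LogNormal(0, scale_factor_sd) — arbitrary
    library sizes that the ILR must (and does) cancel.
    """
    if noise_mode not in ("balance", "efficiency"):
        raise ValueError("noise_mode must be 'balance' or 'efficiency'")
    root = np.random.SeedSequence(seed)
    ss_tree, ss_par, ss_scale, ss_seq, _ = root.spawn(5)
    basis = simulate_tree(n, ss_tree)
    params = simulate_params(
        basis, ss_par, lambda_ab=lambda_ab, a_scale=a_scale,
        sigma_scale=sigma_scale,
    )
    n_samples = len(cycles) * n_replicates
    rng = np.random.default_rng(ss_scale)
    scale = rng.lognormal(0.0, scale_factor_sd, size=n_samples)
    truth = SyntheticTruth(
        params=params,
        basis=basis,
        cycles=tuple(int(t) for t in cycles),
        n_replicates=int(n_replicates),
        depth=int(depth),
        seed=int(seed),
        scale_factors=scale,
        noise_mode=noise_mode,
    )
    if with_sequences:
        rng_seq = np.random.default_rng(ss_seq)
        gc_targets = rng_seq.uniform(0.3, 0.7, size=n)
        seqs, energies, coefs = simulate_sequences(
            n,
            sequence_length,
            gc_targets,
            seed=int(rng_seq.integers(2 ** 31)),
            log_lambda=np.log(params.lambda_),
            names=basis.leaf_order,
        )
        truth.sequences = seqs
        truth.energies = energies
        truth.energy_coefs = coefs
    return truth


def simulate_experiment(truth: SyntheticTruth) -> CountExperiment:
    """Generate the replicated multi-cycle count table implied by a truth.

    For each library: balances on the kinetic line at its cycle, plus
    diagonal Gaussian noise (or, in 'efficiency' mode, a per-replicate
    jittered lambda with noiseless balances), inverse-ILR to proportions,
    scaled by the library's factor A, then multinomial sequencing at the
    configured depth.  The multinomial probabilities are the closure of the
    scaled expected counts, so A demonstrably never reaches the counts.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(truth.seed).spawn(5)[4]
    )
    basis = truth.basis
    params = truth.params
    cyc, rep, sample_ids = truth.design()
    if truth.depth < basis.n_leaves:
        import warnings

        warnings.warn(
            f"depth {truth.depth} below template count {basis.n_leaves}; "
            "expect very sparse counts",
            UserWarning,
            stacklevel=2,
        )
    traj = balance_trajectory(params, basis)
    counts = np.empty((basis.n_leaves, truth.n_samples), dtype=int)
    for s, t in enumerate(cyc):
        if truth.noise_mode == "balance":
            b = traj(int(t)) + params.sigma * rng.standard_normal(
                basis.n_balances
            )
        else:  # per-replicate efficiency jitter, noiseless balances
            lam_j = np.clip(
                params.lambda_
                * np.exp(0.05 * rng.standard_normal(basis.n_leaves)),
                1e-6,
                1.0,
            )
            jittered = PCRParams.from_balances(
                a=params.a, lambda_=lam_j, sigma=params.sigma, basis=basis
            )
            b = balance_trajectory(jittered, basis)(int(t))
        x = ilr_inverse(b, basis)
        expected = truth.scale_factors[s] * truth.depth * x
        counts[:, s] = rng.multinomial(truth.depth, closure(expected))
    return CountExperiment(
        counts=counts,
        cycles=cyc,
        replicates=rep,
        template_ids=basis.leaf_order,
        sample_ids=sample_ids,
    )


def simulate_sequences(
    n: int,
    length: int,
    gc_targets: Sequence[float],
    seed: int | None = None,
    log_lambda: np.ndarray | None = None,
    energy_coefs: dict[str, float] | None = None,
    names: Sequence[str] | None = None,
) -> tuple[dict[str, str], np.ndarray, dict[str, float]]:
    """Random template sequences with controlled GC plus a paired synthetic
    secondary-structure energy covariate.

    The realised GC fraction of each sequence is within 1/(2*length) of its
    target (GC positions are allocated by rounding, then placed at random).
    The energy is E = e0 + e_gc*GC + e_loglam*log(lambda) + Normal(0, e_sd);
    the coefficients used are returned so downstream positive/negative
    controls know the generating truth.  With ``log_lambda=None`` the
    log-lambda term is dropped and the energies carry no efficiency signal.
    """
    gc_targets = np.asarray(gc_targets, dtype=float)
    if gc_targets.shape != (n,):
        raise ValueError("one GC target per sequence required")
    if np.any((gc_targets < 0) | (gc_targets > 1)):
        raise ValueError("GC targets must lie in [0, 1]")
    if length < 1:
        raise ValueError("length must be positive")
    coefs = dict(DEFAULT_ENERGY_COEFS)
    if energy_coefs:
        coefs.update(energy_coefs)
    rng = np.random.default_rng(seed)
    if names is None:
        names = [f"T{i:03d}" for i in range(n)]
    seqs: dict[str, str] = {}
    realised_gc = np.empty(n)
    for i, name in enumerate(names):
        n_gc = int(round(gc_targets[i] * length))
        arr = np.empty(length, dtype="<U1")
        gc_pos = rng.choice(length, size=n_gc, replace=False)
        at_mask = np.ones(length, dtype=bool)
        at_mask[gc_pos] = False
        arr[gc_pos] = rng.choice(list("GC"), size=n_gc)
        arr[at_mask] = rng.choice(list("AT"), size=length - n_gc)
        seqs[name] = "".join(arr)
        realised_gc[i] = n_gc / length
    energy = (
        coefs["e0"]
        + coefs["e_gc"] * realised_gc
        + coefs["e_sd"] * rng.standard_normal(n)
    )
    if log_lambda is not None:
        energy = energy + coefs["e_loglam"] * np.asarray(log_lambda, float)
    return seqs, energy, coefs
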