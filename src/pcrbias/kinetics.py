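"""Deterministic multi-template PCR kinetics in composition space.

For one template with initial amount z, original-template efficiency theta
and product efficiency lambda (both per-cycle rates in (0, 1]), the number of
products at cycle t obeys

    c(t) = theta*z + (lambda + 1) * c(t - 1),    c(1) = theta*z,

whose closed form is c(t) = (theta*z / lambda) * ((lambda + 1)^t - 1).
theta and z only ever appear as the product theta*z and are not separately
identifiable.  For the cycle ranges used in amplicon library preparation
(t > 5) the -1 is negligible and c(t) ~ (theta*z / lambda) * (lambda + 1)^t,
with relative error exactly (1 / (lambda + 1))^t.

Under that approximation the ILR balances of the community are *linear* in
cycle number:

    b(t) = t * log(lambda + 1) Psi^T - log(lambda) Psi^T + a,

where a = ilr(theta*z) is the (biased) initial profile in balance space.
The model holds in the log-linear amplification phase only: efficiencies are
constant per template, with no substrate competition or plateau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pcrbias.coda import ContrastBasis, closure, ilr, ilr_inverse


def _validate_lambda(lambda_: np.ndarray) -> np.ndarray:
    lambda_ = np.asarray(lambda_, dtype=float)
    if np.any(lambda_ <= 0) or np.any(lambda_ > 1):
        raise ValueError("amplification efficiencies must lie in (0, 1]")
    return lambda_


def _validate_cycle(t: int, minimum: int = 1) -> int:
    if not float(t).is_integer() or t < minimum:
        raise ValueError(f"cycle number must be an integer >= {minimum}, got {t!r}")
    return int(t)


def counts_recurrence(theta_z: float, lambda_: float, t: int) -> float:
    """Iterate the product-count recurrence c(tau) = theta*z + (lambda+1) c(tau-1).

    Brute-force reference for :func:`counts_closed_form`.
    """
    t = _validate_cycle(t)
    theta_z = np.asarray(theta_z, dtype=float)
    if np.any(theta_z <= 0):
        raise ValueError("theta*z must be positive")
    lambda_ = _validate_lambda(lambda_)
    c = theta_z.copy() if theta_z.ndim else float(theta_z)
    for _ in range(1, t):
        c = theta_z + (lambda_ + 1.0) * c
    return c


def counts_closed_form(theta_z: float, lambda_: float, t: int) -> float:
    """Closed-form product count (theta*z / lambda) ((lambda+1)^t - 1)."""
    t = _validate_cycle(t)
    theta_z = np.asarray(theta_z, dtype=float)
    if np.any(theta_z <= 0):
        raise ValueError("theta*z must be positive")
    lambda_ = _validate_lambda(lambda_)
    return theta_z / lambda_ * ((lambda_ + 1.0) ** t - 1.0)


def counts_approx(theta_z: float, lambda_: float, t: int) -> float:
    """Large-t approximation (theta*z / lambda) (lambda+1)^t.

    Its relative error against the closed form is exactly
    (1 / (lambda + 1))^t, i.e. below 1e-2 for any lambda >= 0.2 once t > 25.
    """
    t = _validate_cycle(t)
    theta_z = np.asarray(theta_z, dtype=float)
    if np.any(theta_z <= 0):
        raise ValueError("theta*z must be positive")
    lambda_ = _validate_lambda(lambda_)
    return theta_z / lambda_ * (lambda_ + 1.0) ** t


@dataclass
class PCRParams:
    """Per-template kinetic parameters of a multi-template PCR.

    Attributes
    ----------
    lambda_
        Product amplification efficiencies, one per template, in (0, 1].
    theta_z
        The products theta_i * z_i (original-template efficiency times
        initial amount).  Only their composition is identifiable; stored
        closure-normalised is conventional but not required.
    a
        ilr(theta_z) — the identified image of the initial profile.
    sigma
        Per-balance Gaussian noise scales (> 0) of replicate observations.
    """

    lambda_: np.ndarray
    theta_z: np.ndarray
    a: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.lambda_ = _validate_lambda(self.lambda_)
        self.theta_z = np.asarray(self.theta_z, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = self.lambda_.shape[0]
        if self.theta_z.shape != (n,):
            raise ValueError("theta_z must have one entry per template")
        if np.any(self.theta_z <= 0):
            raise ValueError("theta_z must be positive")
        if self.a.shape != (n - 1,) or self.sigma.shape != (n - 1,):
            raise ValueError("a and sigma must have length n - 1")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")

    @classmethod
    def from_theta_z(
        cls,
        theta_z: np.ndarray,
        lambda_: np.ndarray,
        sigma: np.ndarray,
        basis: ContrastBasis,
    ) -> "PCRParams":
        theta_z = np.asarray(theta_z, dtype=float)
        return cls(lambda_=lambda_, theta_z=theta_z, a=ilr(theta_z, basis),
                   sigma=sigma)

    @classmethod
    def from_balances(
        cls,
        a: np.ndarray,
        lambda_: np.ndarray,
        sigma: np.ndarray,
        basis: ContrastBasis,
    ) -> "PCRParams":
        a = np.asarray(a, dtype=float)
        return cls(lambda_=lambda_, theta_z=ilr_inverse(a, basis), a=a,
                   sigma=sigma)

    def check_consistent(self, basis: ContrastBasis, atol: float = 1e-10) -> None:
        if not np.allclose(ilr(self.theta_z, basis), self.a, atol=atol):
            raise ValueError("a and theta_z are inconsistent under ilr")

    @property
    def n_templates(self) -> int:
        return self.lambda_.shape[0]


@dataclass(frozen=True)
class BalanceTrajectory:
    """The straight line b(t) = slope * t + intercept in balance space."""

    slope: np.ndarray
    intercept: np.ndarray

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return t[..., None] * self.slope + self.intercept if t.ndim else (
            t * self.slope + self.intercept
        )


def balance_trajectory(params: PCRParams, basis: ContrastBasis) -> BalanceTrajectory:
    """Slope log(lambda+1) Psi^T and intercept -log(lambda) Psi^T + a.

    Homogeneous efficiencies give a zero slope (the zero-sum rows of Psi
    annihilate constant vectors): unbiased PCR leaves the composition fixed.
    """
    if params.n_templates != basis.n_leaves:
        raise ValueError(
            f"params have {params.n_templates} templates but basis has "
            f"{basis.n_leaves} leaves"
        )
    psi_t = basis.contrast_matrix.T
    slope = np.log1p(params.lambda_) @ psi_t
    intercept = -np.log(params.lambda_) @ psi_t + params.a
    return BalanceTrajectory(slope=slope, intercept=intercept)


def reconstruct_composition(
    params: PCRParams, basis: ContrastBasis, t: int
) -> np.ndarray:
    """Relative amplicon abundances predicted at cycle t.

    For t >= 1 this is the closure of the per-template closed-form counts
    with theta*z replaced by its identified image z_hat = ilr^-1(a):
    closure( z_hat_i / lambda_i * ((lambda_i + 1)^t - 1) ).  At t = 0 the
    closed form vanishes, so by convention the approximated initial
    (efficiency-biased) profile closure(z_hat) is returned.
    """
    t = _validate_cycle(t, minimum=0)
    z_hat = ilr_inverse(params.a, basis)
    if params.n_templates != basis.n_leaves:
        raise ValueError("params/basis dimension mismatch")
    if t == 0:
        return z_hat
    return closure(z_hat / params.lambda_ * ((params.lambda_ + 1.0) ** t - 1.0))


def logratio_change(
    params: PCRParams, basis: ContrastBasis, t1: int, t2: int
) -> np.ndarray:
    """Per-template natural-log ratio of predicted abundances at t2 vs t1."""
    x1 = reconstruct_composition(params, basis, t1)
    x2 = reconstruct_composition(params, basis, t2)
    return np.log(x2 / x1)
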