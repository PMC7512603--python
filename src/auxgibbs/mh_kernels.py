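"""Random-walk and MALA Metropolis-Hastings kernels.

Used inside Gibbs sweeps whose x-conditional has no closed form (the
non-Gaussian wavelet-block conditionals of the multichannel application).
Step sizes are adapted during burn-in by a Robbins-Monro rule toward a
target acceptance rate and frozen afterwards, so the post-burn-in chain is
a valid time-homogeneous MH chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "MHConfig",
    "mh_accept",
    "rw_propose",
    "mala_propose",
    "adapt_stepsize",
    "TARGET_ACCEPT_RW",
    "TARGET_ACCEPT_MALA",
]

# standard optimal-scaling targets
TARGET_ACCEPT_RW = 0.24
TARGET_ACCEPT_MALA = 0.57


@dataclass
class MHConfig:
    """Kernel configuration: step size, preconditioner and adaptation."""

    stepsize: float = 1.0
    target_acceptance: float = TARGET_ACCEPT_RW
    adapt_during_burn_in: bool = True
    preconditioner: np.ndarray | None = None  # SPD matrix; None = identity
    frozen: bool = False
    n_warnings: int = 0

    def __post_init__(self):
        if self.stepsize <= 0:
            raise ValueError("stepsize must be positive")
        if not 0.0 < self.target_acceptance < 1.0:
            raise ValueError("target_acceptance must lie in (0, 1)")

    def freeze(self):
        """Stop adaptation (call at the end of burn-in)."""
        self.frozen = True

    def update_stepsize(self, value: float):
        if self.frozen:
            raise RuntimeError("stepsize is frozen after burn-in")
        self.stepsize = float(value)


def mh_accept(
    neglog_target: Callable[[np.ndarray], float],
    proposal_logdensity_ratio: float,
    current: np.ndarray,
    proposed: np.ndarray,
    rng: np.random.Generator,
    neglog_current: float | None = None,
    config: MHConfig | None = None,
) -> tuple[np.ndarray, bool]:
    """One accept/reject decision.

    Accepts with probability min(1, exp(J(current) - J(proposed)) * g-ratio)
    where ``proposal_logdensity_ratio`` is
    log g(current | proposed) - log g(proposed | current)  (0 for symmetric
    proposals).  A NaN in the target counts as a rejection (with a warning
    counter on the config, if given).
    """
    j_cur = neglog_target(current) if neglog_current is None else neglog_current
    if not np.isfinite(j_cur):
        raise ValueError("neglog target must be finite at the current state")
    j_prop = neglog_target(proposed)
    if np.isnan(j_prop):
        if config is not None:
            config.n_warnings += 1
        return np.asarray(current), False
    log_alpha = (j_cur - j_prop) + proposal_logdensity_ratio
    if np.log(rng.uniform()) < log_alpha:
        return np.asarray(proposed), True
    return np.asarray(current), False


def _precond_noise(eps: float, Q: np.ndarray | None, shape, rng) -> np.ndarray:
    n = rng.standard_normal(shape)
    if Q is None:
        return eps * n
    # covariance eps^2 Q^{-1}: noise = eps * L^{-T} n with Q = L L^T
    chol = np.linalg.cholesky(Q)
    return eps * np.linalg.solve(chol.T, n.T).T


def rw_propose(
    current: np.ndarray,
    eps: float,
    Q: np.ndarray | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Symmetric Gaussian proposal N(current, eps^2 Q^{-1})."""
    current = np.asarray(current, dtype=float)
    return current + _precond_noise(eps, Q, current.shape, rng)


def mala_propose(
    current: np.ndarray,
    grad: Callable[[np.ndarray], np.ndarray],
    eps: float,
    Q: np.ndarray | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Langevin proposal and its detailed-balance correction.

    proposed ~ N(current - (eps^2/2) Q^{-1} grad J(current), eps^2 Q^{-1});
    returns (proposed, log g(current|proposed) - log g(proposed|current)).
    A non-finite gradient falls back to a symmetric RW proposal.
    """
    current = np.asarray(current, dtype=float)
    g_cur = np.asarray(grad(current), dtype=float)
    if not np.all(np.isfinite(g_cur)):
        return rw_propose(current, eps, Q, rng), 0.0

    def qinv(w):
        return w if Q is None else np.linalg.solve(Q, w)

    def qdot(a, b):
        # <a, Q b>
        return float(a @ b) if Q is None else float(a @ (Q @ b))

    drift_cur = current - 0.5 * eps**2 * qinv(g_cur)
    proposed = drift_cur + _precond_noise(eps, Q, current.shape, rng)
    g_prop = np.asarray(grad(proposed), dtype=float)
    if not np.all(np.isfinite(g_prop)):
        # reverse move would be a RW step: correction undefined; auto-reject
        return proposed, -np.inf
    drift_prop = proposed - 0.5 * eps**2 * qinv(g_prop)
    fwd = proposed - drift_cur
    bwd = current - drift_prop
    log_ratio = -(qdot(bwd, bwd) - qdot(fwd, fwd)) / (2.0 * eps**2)
    return proposed, log_ratio


def adapt_stepsize(
    acc_rate: float,
    eps: float,
    target_acceptance: float,
    t: int,
) -> float:
    """Robbins-Monro step-size update (burn-in only):

        log eps' = log eps + gamma_t (acc_rate - target),  gamma_t = t^{-0.6}.
    """
    gamma_t = max(t, 1) ** (-0.6)
    return float(eps * np.exp(gamma_t * (acc_rate - target_acceptance)))
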