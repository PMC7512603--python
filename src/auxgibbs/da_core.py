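"""Data-augmentation constructions and the two-block Gibbs loop.

A data-augmentation (DA) scheme introduces a Gaussian auxiliary variable v
whose conditional law is chosen so that, in the augmented space, only one
source of correlation remains attached to the signal x; the other source
(the noise precision Lambda, or the full coupling H^T Lambda H) is carried
by v.  Alternating draws of v | x and x | v form a two-block Gibbs sampler
whose x-marginal is exactly the original posterior.

Two constructions are provided for the correlated-Gaussian-noise model
z = H x + w, w ~ N(0, Lambda^{-1}):

* Alternative I eliminates the coupling induced by Lambda:
  v ~ N(Gamma H x, Gamma) with Gamma = (1/mu) I - Lambda, mu ||Lambda||_S < 1.
* Alternative II eliminates the coupling induced by H^T Lambda H:
  v ~ N(Gamma x, Gamma) with Gamma = (1/mu) I - H^T Lambda H,
  mu ||H^T Lambda H||_S < 1.

For fully Gaussian posteriors (Gaussian prior N(m_x, G_x^{-1})), four DA
variants give conditionally Gaussian x-draws whose precision is structured
by construction; see :func:`da_gaussian_conditional`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.linalg

from .diagnostics import ChainTrace
from .linops import DiagonalMap, LinearMap, as_dense
from .struct_gauss import (
    PreconditionError,
    sample_aux_three_step,
    sample_dense_cholesky,
)

__all__ = [
    "AuxScheme",
    "sample_aux",
    "cond_neglog_alt1",
    "cond_neglog_alt2",
    "GaussPosteriorDA",
    "da_gaussian_conditional",
    "sample_da_auxiliaries",
    "run_two_block_gibbs",
    "DenseDAGibbsModel",
]

EPSILON_DEFAULT = 0.99


def _as_op_apply(H) -> tuple[Callable, Callable]:
    """(apply, adjoint) callables for a LinearMap or dense array."""
    if isinstance(H, LinearMap):
        return H.apply, H.adjoint
    H = np.asarray(H, dtype=float)
    return (lambda x: H @ x), (lambda y: H.T @ y)


def _lam_apply(Lambda) -> Callable:
    if isinstance(Lambda, DiagonalMap):
        return Lambda.apply
    if isinstance(Lambda, LinearMap):
        return Lambda.apply
    Lambda = np.asarray(Lambda, dtype=float)
    if Lambda.ndim == 1:
        return lambda w: Lambda * w
    return lambda w: Lambda @ w


@dataclass
class AuxScheme:
    """One DA construction: which coupling is eliminated and its step size.

    Parameters
    ----------
    alternative : {"I", "II"}
        "I" eliminates Lambda; "II" eliminates H^T Lambda H.
    H : LinearMap
    Lambda : DiagonalMap
        Noise precision (diagonal; zero entries mark degenerate precisions).
    mu : float, optional
        Step size; defaults to epsilon/||Lambda||_S (I) or
        epsilon/(||H||_S^2 ||Lambda||_S) (II).
    epsilon : float
        Strict-inequality margin in (0, 1).
    """

    alternative: str
    H: LinearMap
    Lambda: DiagonalMap
    mu: float | None = None
    epsilon: float = EPSILON_DEFAULT

    def __post_init__(self):
        if self.alternative not in ("I", "II"):
            raise ValueError("alternative must be 'I' or 'II'")
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must lie in (0, 1)")
        if not isinstance(self.Lambda, DiagonalMap):
            raise TypeError("Lambda must be a DiagonalMap")
        lam_norm = self.Lambda.spectral_norm()
        if lam_norm <= 0:
            raise PreconditionError("Lambda must have a positive entry")
        h_norm2 = self.H.spectral_norm() ** 2
        if self.mu is None:
            if self.alternative == "I":
                self.mu = self.epsilon / lam_norm
            else:
                self.mu = self.epsilon / (h_norm2 * lam_norm)
        if self.alternative == "I":
            if not self.mu * lam_norm < 1.0:
                raise PreconditionError(
                    f"mu*||Lambda||_S = {self.mu * lam_norm:.6g} must be < 1"
                )
        else:
            # mu ||H^T Lambda H||_S <= mu ||H||^2 ||Lambda|| < 1 suffices; the
            # three-step rule additionally needs mu ||H||^2 < beta < 1/||Lambda||
            # strictly: take beta as the geometric mean of the two bounds.
            if not self.mu * h_norm2 * lam_norm < 1.0:
                raise PreconditionError(
                    f"mu*||H||_S^2*||Lambda||_S = "
                    f"{self.mu * h_norm2 * lam_norm:.6g} must be < 1"
                )
            self.beta = float(np.sqrt(self.mu * h_norm2 / lam_norm))


def sample_aux(scheme: AuxScheme, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw the auxiliary variable v given the current signal x.

    Alternative I: v ~ N(Gamma H x, Gamma), Gamma = (1/mu) I - Lambda,
    drawn coordinatewise (Gamma diagonal).  Alternative II:
    v ~ N(Gamma x, Gamma), Gamma = (1/mu) I - H^T Lambda H, drawn exactly
    by the three-step structured rule.
    """
    x = np.asarray(x, dtype=float).ravel()
    if scheme.alternative == "I":
        gamma_diag = 1.0 / scheme.mu - scheme.Lambda.diag
        if np.any(gamma_diag <= 0):
            raise PreconditionError("Gamma = (1/mu) I - Lambda not SPD")
        mean = gamma_diag * scheme.H.apply(x)
        return mean + np.sqrt(gamma_diag) * rng.standard_normal(mean.size)
    return sample_aux_three_step(
        x, scheme.mu, scheme.beta, scheme.H, scheme.Lambda, rng, check=False
    )


def cond_neglog_alt1(x, v, z, mu, Lambda, H, psi=None) -> float:
    """Negative log of P(x | v, z) for Alternative I, up to a constant:

        (1/(2 mu)) ||H x - mu (Lambda z + v)||^2 + Psi(V x).
    """
    apply_H, _ = _as_op_apply(H)
    lam = _lam_apply(Lambda)
    x = np.asarray(x, dtype=float).ravel()
    r = apply_H(x) - mu * (lam(np.asarray(z, dtype=float).ravel()) + np.asarray(v).ravel())
    val = float(r @ r) / (2.0 * mu)
    if psi is not None:
        val += float(psi(x))
    return val


def cond_neglog_alt2(x, v, z, mu, Lambda, H, psi=None) -> float:
    """Negative log of P(x | v, z) for Alternative II, up to a constant:

        (1/(2 mu)) ||x - mu (v + H^T Lambda z)||^2 + Psi(V x).
    """
    _, adj_H = _as_op_apply(H)
    lam = _lam_apply(Lambda)
    x = np.asarray(x, dtype=float).ravel()
    r = x - mu * (np.asarray(v).ravel() + adj_H(lam(np.asarray(z, dtype=float).ravel())))
    val = float(r @ r) / (2.0 * mu)
    if psi is not None:
        val += float(psi(x))
    return val


# ---------------------------------------------------------------------------
# DA variants for fully Gaussian posteriors (dense formulation)
# ---------------------------------------------------------------------------

VARIANTS = ("v1_data", "v1v2_frame", "v1_fullcoupling", "v1v2_full")


@dataclass
class GaussPosteriorDA:
    """A DA construction for the Gaussian posterior N(m, G^{-1}) with

        G = H^T Lambda H + G_x,
        m = G^{-1} (H^T Lambda z + G_x m_x).

    Variants (auxiliaries and resulting conditional precision G-tilde):

    * ``v1_data``        v1 on the data term, Gtilde = (1/mu1) H^T H + G_x
    * ``v1v2_frame``     v1 on data, v2 on the prior factor G_x = V^T Omega V,
                         Gtilde = (1/mu1) H^T H + (1/mu2) V^T V
    * ``v1_fullcoupling`` v1 eliminates H^T Lambda H,
                         Gtilde = (1/mu1) I + G_x
    * ``v1v2_full``      v1 and v2 eliminate both couplings,
                         Gtilde = (1/mu) I with mu = mu1 mu2 / (mu1 + mu2)

    Dense (small-dimension) formulation used for oracle validation; the
    application modules implement the same constructions with structured
    operators.
    """

    variant: str
    H: np.ndarray
    Lambda: np.ndarray
    G_x: np.ndarray | None = None
    m_x: np.ndarray | None = None
    V: np.ndarray | None = None
    Omega: np.ndarray | None = None
    mu1: float | None = None
    mu2: float | None = None
    epsilon: float = EPSILON_DEFAULT

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        self.H = np.atleast_2d(np.asarray(self.H, dtype=float))
        self.Lambda = np.atleast_2d(np.asarray(self.Lambda, dtype=float))
        n, q = self.H.shape
        if self.variant in ("v1v2_frame",):
            if self.V is None or self.Omega is None:
                raise ValueError("v1v2_frame needs V and Omega")
            self.V = np.atleast_2d(np.asarray(self.V, dtype=float))
            self.Omega = np.atleast_2d(np.asarray(self.Omega, dtype=float))
            self.G_x = self.V.T @ self.Omega @ self.V
        if self.G_x is None:
            raise ValueError("G_x (or V, Omega) is required")
        self.G_x = np.atleast_2d(np.asarray(self.G_x, dtype=float))
        if self.m_x is None:
            self.m_x = np.zeros(q)
        self.m_x = np.asarray(self.m_x, dtype=float).ravel()
        lam_norm = np.linalg.norm(self.Lambda, 2)
        if self.variant in ("v1_data", "v1v2_frame"):
            mu1_bound = lam_norm
        else:
            mu1_bound = np.linalg.norm(self.H.T @ self.Lambda @ self.H, 2)
        if self.mu1 is None:
            self.mu1 = self.epsilon / mu1_bound
        if self.mu1 * mu1_bound >= 1.0:
            raise PreconditionError("mu1 violates its spectral bound")
        if self.variant == "v1v2_frame":
            mu2_bound = np.linalg.norm(self.Omega, 2)
        elif self.variant == "v1v2_full":
            mu2_bound = np.linalg.norm(self.G_x, 2)
        else:
            mu2_bound = None
        if mu2_bound is not None:
            if self.mu2 is None:
                self.mu2 = self.epsilon / mu2_bound
            if self.mu2 * mu2_bound >= 1.0:
                raise PreconditionError("mu2 violates its spectral bound")

    # exact posterior (dense oracle target)
    def posterior(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        G = self.H.T @ self.Lambda @ self.H + self.G_x
        m = np.linalg.solve(G, self.H.T @ self.Lambda @ z + self.G_x @ self.m_x)
        return m, G


def _draw_gauss_cov(mean: np.ndarray, cov: np.ndarray, rng) -> np.ndarray:
    chol = scipy.linalg.cholesky(cov, lower=True)
    return mean + chol @ rng.standard_normal(mean.size)


def _aux_factors(da: GaussPosteriorDA):
    """Cached (mean operator, covariance Cholesky) pairs for the variant's
    auxiliary draws; these matrices are fixed along the chain."""
    cached = getattr(da, "_aux_factor_cache", None)
    if cached is not None:
        return cached
    n, q = da.H.shape
    if da.variant in ("v1_data", "v1v2_frame"):
        cov1 = np.eye(n) / da.mu1 - da.Lambda
        op1 = cov1 @ da.H
    else:
        cov1 = np.eye(q) / da.mu1 - da.H.T @ da.Lambda @ da.H
        op1 = cov1
    chol1 = scipy.linalg.cholesky(cov1, lower=True)
    op2 = chol2 = None
    if da.variant == "v1v2_frame":
        cov2 = np.eye(da.V.shape[0]) / da.mu2 - da.Omega
        op2, chol2 = cov2 @ da.V, scipy.linalg.cholesky(cov2, lower=True)
    elif da.variant == "v1v2_full":
        cov2 = np.eye(q) / da.mu2 - da.G_x
        op2, chol2 = cov2, scipy.linalg.cholesky(cov2, lower=True)
    cached = (op1, chol1, op2, chol2)
    da._aux_factor_cache = cached
    return cached


def sample_da_auxiliaries(
    da: GaussPosteriorDA, x: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Draw the variant's auxiliary variables given the current x."""
    x = np.asarray(x, dtype=float).ravel()
    op1, chol1, op2, chol2 = _aux_factors(da)
    out = {"v1": op1 @ x + chol1 @ rng.standard_normal(chol1.shape[0])}
    if op2 is not None:
        out["v2"] = op2 @ x + chol2 @ rng.standard_normal(chol2.shape[0])
    return out


def da_gaussian_conditional(
    da: GaussPosteriorDA,
    z: np.ndarray,
    v1: np.ndarray,
    v2: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional Gaussian parameters (Gtilde, mtilde) of x given z and
    the auxiliaries, per variant.  Gtilde is returned as a dense matrix
    (scalar-times-identity for the fully decoupled variants)."""
    z = np.asarray(z, dtype=float).ravel()
    v1 = np.asarray(v1, dtype=float).ravel()
    n, q = da.H.shape
    rhs = da.H.T @ (da.Lambda @ z) + da.G_x @ da.m_x
    if da.variant == "v1_data":
        G_t = da.H.T @ da.H / da.mu1 + da.G_x
        rhs = rhs + da.H.T @ v1
    elif da.variant == "v1v2_frame":
        if v2 is None:
            raise ValueError("variant v1v2_frame needs v2")
        G_t = da.H.T @ da.H / da.mu1 + da.V.T @ da.V / da.mu2
        rhs = rhs + da.H.T @ v1 + da.V.T @ np.asarray(v2, dtype=float).ravel()
    elif da.variant == "v1_fullcoupling":
        G_t = np.eye(q) / da.mu1 + da.G_x
        rhs = rhs + v1
    else:  # v1v2_full
        if v2 is None:
            raise ValueError("variant v1v2_full needs v2")
        mu = da.mu1 * da.mu2 / (da.mu1 + da.mu2)
        G_t = np.eye(q) / mu
        rhs = rhs + v1 + np.asarray(v2, dtype=float).ravel()
    m_t = np.linalg.solve(G_t, rhs)
    return G_t, m_t


class DenseDAGibbsModel:
    """Two-block Gibbs model for a GaussPosteriorDA instance (dense).

    The conditional precision G-tilde is constant along the chain; its
    Cholesky factor is computed once and reused for every x-draw.
    """

    def __init__(self, da: GaussPosteriorDA, z: np.ndarray):
        self.da = da
        self.z = np.asarray(z, dtype=float).ravel()
        self.q = da.H.shape[1]
        n = da.H.shape[0]
        zero2 = np.zeros(da.V.shape[0] if da.variant == "v1v2_frame" else self.q)
        G_t, _ = da_gaussian_conditional(
            da, self.z, np.zeros(n if da.variant in ("v1_data", "v1v2_frame") else self.q),
            zero2 if da.variant in ("v1v2_frame", "v1v2_full") else None,
        )
        chol = scipy.linalg.cholesky(G_t, lower=True)
        self._Gt_inv = scipy.linalg.cho_solve((chol, True), np.eye(self.q))
        # x = m + L^{-T} n: precompute the inverse transpose factor
        self._cov_factor = scipy.linalg.solve_triangular(
            chol, np.eye(self.q), lower=True, trans="T"
        )
        self._rhs_const = da.H.T @ (da.Lambda @ self.z) + da.G_x @ da.m_x

    def init_x(self, rng: np.random.Generator) -> np.ndarray:
        return rng.standard_normal(self.q)

    def sample_aux(self, x, rng):
        return sample_da_auxiliaries(self.da, x, rng)

    def sample_x(self, aux, rng):
        da = self.da
        v1 = aux["v1"]
        if da.variant == "v1_data":
            rhs = self._rhs_const + da.H.T @ v1
        elif da.variant == "v1v2_frame":
            rhs = self._rhs_const + da.H.T @ v1 + da.V.T @ aux["v2"]
        elif da.variant == "v1_fullcoupling":
            rhs = self._rhs_const + v1
        else:
            rhs = self._rhs_const + v1 + aux["v2"]
        return self._Gt_inv @ rhs + self._cov_factor @ rng.standard_normal(self.q)


def run_two_block_gibbs(
    model,
    n_iter: int,
    burn_in: int,
    rng: np.random.Generator | int,
    x0: np.ndarray | None = None,
) -> ChainTrace:
    """Run the fixed-order two-block Gibbs sweep (aux first, then x).

    ``model`` supplies ``init_x(rng)``, ``sample_aux(x, rng)`` and
    ``sample_x(aux, rng)``.  Every state is recorded; the trace is a
    deterministic function of (model, seed).
    """
    seed = None
    if not isinstance(rng, np.random.Generator):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    x = model.init_x(rng) if x0 is None else np.asarray(x0, dtype=float).ravel()
    xs = np.empty((n_iter, x.size))
    aux_hist: dict[str, list] = {}
    for t in range(n_iter):
        try:
            aux = model.sample_aux(x, rng)
            x = model.sample_x(aux, rng)
        except Exception as exc:
            raise RuntimeError(f"conditional sampler failed at sweep {t}") from exc
        xs[t] = x
        if isinstance(aux, dict):
            for k, v in aux.items():
                aux_hist.setdefault(k, []).append(np.copy(v))
        else:
            aux_hist.setdefault("v", []).append(np.copy(aux))
    histories = {"x": xs}
    for k, v in aux_hist.items():
        histories[k] = np.asarray(v)
    return ChainTrace(histories=histories, burn_in=burn_in, seed=seed)
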