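"""Bayesian image deblurring under two-term mixed Gaussian noise.

Observation model: z = H x + w with H a periodic (circulant) blur and
per-pixel noise w_i ~ N(0, sigma_i^2) where

    sigma_i ~ (1 - beta) delta_{kappa1} + beta delta_{kappa2},

i.e. a two-point scale mixture: each pixel is quiet (std kappa1) with
probability 1 - beta or corrupted by a large-variance component (std
kappa2 >= kappa1) with probability beta — an approximation of mixed
impulse/Gaussian noise.  The image carries a Gaussian smoothness prior

    p(x | gamma) ∝ gamma^{Q/2} exp(-(gamma/2) ||L x||^2),
    L = delta_L I - Laplacian  (circulant, SPD),

and kappa1^2, kappa2^2 get inverse-Gamma priors, beta a uniform prior,
gamma a Gamma prior.  All parameter updates are conjugate; the x-update
uses the DA constructions with an iteration-dependent step size
mu(sigma), inside a partially collapsed Gibbs sweep (sigma is drawn from
its v-collapsed conditional, which must precede the v and x draws).

Two sweep variants are provided: AuxV1 adds one auxiliary variable to the
data term (x-draw exact in the Fourier domain); AuxV2 adds auxiliaries to
both the data and prior terms (x-draw i.i.d. per coordinate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diagnostics import ChainTrace
from .linops import CirculantMap2D, DiagonalMap
from .scale_mixture import GibbsStep, pcgs_schedule
from .struct_gauss import PreconditionError, sample_aux_three_step

__all__ = [
    "MixedNoisePriors",
    "MixedNoiseConfig",
    "build_smoothness_operator",
    "sample_sigma_mixture",
    "sample_beta_weight",
    "sample_kappa",
    "sample_gamma_reg",
    "auxv1_vstep",
    "auxv1_xstep",
    "auxv2_v2step",
    "auxv2_xstep",
    "run_auxv1",
    "run_auxv2",
]

LAPLACIAN_STENCIL = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


def build_smoothness_operator(delta_L: float, image_shape) -> CirculantMap2D:
    """L = delta_L I - Laplacian as a periodic circulant operator.

    The discrete Laplacian has a nonpositive frequency response vanishing
    at DC, so the symbol of L is bounded below by delta_L > 0: L is SPD.
    """
    if delta_L <= 0:
        raise ValueError("delta_L must be positive")
    kernel = -LAPLACIAN_STENCIL.copy()
    kernel[1, 1] += delta_L
    return CirculantMap2D(kernel, image_shape)


@dataclass
class MixedNoisePriors:
    """Weakly informative hyperpriors (inverse-Gamma on kappa^2, Gamma on
    gamma); defaults are small values."""

    a1: float = 1e-3
    b1: float = 1e-3
    a2: float = 1e-3
    b2: float = 1e-3
    a_gamma: float = 1e-3
    b_gamma: float = 1e-3


@dataclass
class MixedNoiseConfig:
    n_iter: int = 6000
    burn_in: int = 4000
    epsilon: float = 0.99
    delta_L: float = 0.01
    priors: MixedNoisePriors = field(default_factory=MixedNoisePriors)

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.n_iter - self.burn_in < 1:
            raise ValueError("need at least one kept sweep")


# ---------------------------------------------------------------------------
# conjugate conditional updates
# ---------------------------------------------------------------------------


def sample_sigma_mixture(
    residual: np.ndarray,
    beta: float,
    kappa1: float,
    kappa2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-pixel component labels from the v-collapsed conditional of sigma.

    Returns a boolean array ``is_large`` (True: sigma_i = kappa2) drawn
    independently per pixel with odds

        eta_i = [beta/(1-beta)] * (kappa1/kappa2)
                * exp(-(1/2)(kappa2^{-2} - kappa1^{-2}) r_i^2),

    r = Hx - z.  The kappa1/kappa2 factor is the ratio of the two Gaussian
    normalizations.
    """
    if not (0.0 < beta < 1.0):
        raise ValueError("beta must lie in (0, 1)")
    if kappa1 <= 0 or kappa2 <= 0:
        raise ValueError("kappa values must be positive")
    r2 = np.asarray(residual, dtype=float).ravel() ** 2
    log_eta = (
        np.log(beta / (1.0 - beta))
        + np.log(kappa1 / kappa2)
        - 0.5 * (kappa2**-2 - kappa1**-2) * r2
    )
    # p = eta/(1+eta) computed stably via the logistic function
    p = 1.0 / (1.0 + np.exp(-log_eta))
    return rng.uniform(size=p.size) < p


def sample_beta_weight(n1: int, n2: int, rng: np.random.Generator) -> float:
    """beta | counts ~ Beta(n2 + 1, n1 + 1) (uniform prior)."""
    if n1 < 0 or n2 < 0:
        raise ValueError("counts must be nonnegative")
    return float(rng.beta(n2 + 1.0, n1 + 1.0))


def sample_kappa(
    residual: np.ndarray,
    assigned: np.ndarray,
    a: float,
    b: float,
    rng: np.random.Generator,
) -> float:
    """kappa_w^2 | ... ~ IG(a + n_w/2, b + (1/2) sum of squared residuals
    over the pixels assigned to component w).  With no assigned pixels the
    draw falls back to the prior (empty-sum convention)."""
    r = np.asarray(residual, dtype=float).ravel()[np.asarray(assigned, dtype=bool).ravel()]
    shape = a + 0.5 * r.size
    scale = b + 0.5 * float(r @ r)
    return float(scale / rng.gamma(shape))  # 1/Gamma(shape, rate=scale) ~ IG


def sample_gamma_reg(
    x: np.ndarray, L: CirculantMap2D, a_gamma: float, b_gamma: float, rng: np.random.Generator
) -> float:
    """gamma | x ~ Gamma(Q/2 + a_gamma, rate (1/2)||L x||^2 + b_gamma)."""
    x = np.asarray(x, dtype=float).ravel()
    lx = L.apply(x)
    rate = 0.5 * float(lx @ lx) + b_gamma
    return float(rng.gamma(x.size / 2.0 + a_gamma) / rate)


# ---------------------------------------------------------------------------
# auxiliary and x draws
# ---------------------------------------------------------------------------


def auxv1_vstep(
    x: np.ndarray,
    D: DiagonalMap,
    mu: float,
    H: CirculantMap2D,
    rng: np.random.Generator,
) -> np.ndarray:
    """v ~ N(Gamma H x, Gamma), Gamma = (1/mu) I - D  (diagonal)."""
    gamma_diag = 1.0 / mu - D.diag
    if np.any(gamma_diag <= 0):
        raise PreconditionError("Gamma = (1/mu)I - D not SPD")
    mean = gamma_diag * H.apply(np.asarray(x, dtype=float).ravel())
    return mean + np.sqrt(gamma_diag) * rng.standard_normal(mean.size)


def auxv1_xstep(
    v: np.ndarray,
    z: np.ndarray,
    D: DiagonalMap,
    gamma: float,
    mu: float,
    H: CirculantMap2D,
    L: CirculantMap2D,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact draw from N(mtilde, Gtilde^{-1}) with

        Gtilde = (1/mu) H^T H + gamma L^T L,
        mtilde = Gtilde^{-1} H^T (D z + v),

    computed entirely in the Fourier domain (both operators circulant)."""
    if not isinstance(H, CirculantMap2D) or not isinstance(L, CirculantMap2D):
        raise TypeError("auxv1_xstep needs circulant H and L")
    shape = H.image_shape
    spec = np.abs(H.frequency_response) ** 2 / mu + gamma * np.abs(L.frequency_response) ** 2
    rhs = H.adjoint(D.apply(np.asarray(z, dtype=float).ravel()) + np.asarray(v).ravel())
    mean = np.fft.ifft2(np.fft.fft2(rhs.reshape(shape)) / spec).real.ravel()
    w = rng.standard_normal(H.in_dim)
    noise = np.fft.ifft2(np.fft.fft2(w.reshape(shape)) / np.sqrt(spec)).real.ravel()
    return mean + noise


def auxv2_v2step(
    x: np.ndarray,
    gamma: float,
    mu2: float,
    L: CirculantMap2D,
    rng: np.random.Generator,
) -> np.ndarray:
    """Prior-side auxiliary: v2 ~ N(((1/mu2) I - L^T L) x,
    (1/gamma) ((1/mu2) I - L^T L)).

    The 1/gamma covariance scaling is what makes the x-conditional precision
    collapse to the printed scalar form (see ``auxv2_xstep``)."""
    x = np.asarray(x, dtype=float).ravel()
    spec = 1.0 / mu2 - np.abs(L.frequency_response) ** 2
    if np.any(spec <= 0):
        raise PreconditionError("(1/mu2) I - L^T L not SPD")
    shape = L.image_shape
    mean = np.fft.ifft2(np.fft.fft2(x.reshape(shape)) * spec).real.ravel()
    w = rng.standard_normal(x.size)
    noise = np.fft.ifft2(np.fft.fft2(w.reshape(shape)) * np.sqrt(spec / gamma)).real.ravel()
    return mean + noise


def auxv2_xstep(
    v1: np.ndarray,
    v2: np.ndarray,
    z: np.ndarray,
    D: DiagonalMap,
    gamma: float,
    mu1: float,
    mu2: float,
    H: CirculantMap2D,
    rng: np.random.Generator,
) -> np.ndarray:
    """i.i.d.-coordinate draw: precision (1/mu1 + gamma/mu2) per coordinate,
    mean (1/mu1 + gamma/mu2)^{-1} (H^T D z + v1 + gamma v2)."""
    prec = 1.0 / mu1 + gamma / mu2
    rhs = (
        H.adjoint(D.apply(np.asarray(z, dtype=float).ravel()))
        + np.asarray(v1).ravel()
        + gamma * np.asarray(v2).ravel()
    )
    mean = rhs / prec
    return mean + rng.standard_normal(mean.size) / np.sqrt(prec)


# ---------------------------------------------------------------------------
# full PCGS sweeps
# ---------------------------------------------------------------------------

_AUXV1_STEPS = [
    GibbsStep("kappa1", ("x", "sigma", "beta", "z")),
    GibbsStep("kappa2", ("x", "sigma", "beta", "z")),
    GibbsStep("beta", ("x", "sigma", "kappa1", "kappa2")),
    GibbsStep("gamma", ("x",)),
    GibbsStep("sigma", ("x", "beta", "kappa1", "kappa2", "z"), collapsed=("v",)),
    GibbsStep("v", ("x", "sigma")),
    GibbsStep("x", ("sigma", "gamma", "v", "z")),
]

_AUXV2_STEPS = [
    GibbsStep("kappa1", ("x", "sigma", "beta", "z")),
    GibbsStep("kappa2", ("x", "sigma", "beta", "z")),
    GibbsStep("beta", ("x", "sigma", "kappa1", "kappa2")),
    GibbsStep("gamma", ("x",)),
    GibbsStep("sigma", ("x", "beta", "kappa1", "kappa2", "z"), collapsed=("v1",)),
    GibbsStep("v2", ("x",)),
    GibbsStep("v1", ("x", "sigma")),
    GibbsStep("x", ("sigma", "gamma", "v1", "v2", "z")),
]


def _init_state(z2d: np.ndarray, H: CirculantMap2D, rng: np.random.Generator):
    """Empirical initialization from the observed image."""
    z = z2d.ravel()
    x = z.copy()
    r = H.apply(x) - z
    s = max(float(np.std(r)), 1e-3)
    kappa1, kappa2 = 0.5 * s, 2.0 * s
    beta = 0.5
    is_large = rng.uniform(size=z.size) < beta
    return x, kappa1, kappa2, beta, is_large


def _run_mixed(
    z: np.ndarray,
    H: CirculantMap2D,
    config: MixedNoiseConfig,
    rng: np.random.Generator | int,
    variant: str,
) -> tuple[np.ndarray, dict, ChainTrace]:
    seed = None
    if not isinstance(rng, np.random.Generator):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    z2d = np.asarray(z, dtype=float)
    if z2d.ndim != 2:
        raise ValueError("z must be a 2-D image")
    if H.image_shape != z2d.shape:
        raise ValueError("blur operator shape does not match image")
    shape = z2d.shape
    Q = z2d.size
    L = build_smoothness_operator(config.delta_L, shape)
    pr = config.priors
    eps = config.epsilon
    steps = _AUXV1_STEPS if variant == "auxv1" else _AUXV2_STEPS
    pcgs_schedule(steps)

    zf = z2d.ravel()
    x, kappa1, kappa2, beta, is_large = _init_state(z2d, H, rng)
    gamma = Q / max(float(np.sum(L.apply(zf) ** 2)), 1e-12)
    h_norm2 = H.spectral_norm() ** 2
    l_norm2 = L.spectral_norm() ** 2
    mu2 = eps / l_norm2  # AuxV2 prior-side step size (fixed)

    n_iter, burn_in = config.n_iter, config.burn_in
    hist = {
        k: np.empty(n_iter)
        for k in ("beta", "kappa1", "kappa2", "gamma", "mu", "n2")
    }
    x_sum = np.zeros(Q)
    x_sq_sum = np.zeros(Q)
    msj_acc = 0.0
    msj_count = 0
    x_prev_kept = None

    for t in range(n_iter):
        residual = H.apply(x) - zf
        # (1)-(2) kappa^2 updates on the current assignment, then relabel
        k1_sq = sample_kappa(residual, ~is_large, pr.a1, pr.b1, rng)
        k2_sq = sample_kappa(residual, is_large, pr.a2, pr.b2, rng)
        kappa1, kappa2 = np.sqrt(k1_sq), np.sqrt(k2_sq)
        if kappa1 > kappa2:  # keep the label ordering kappa1 <= kappa2
            kappa1, kappa2 = kappa2, kappa1
            is_large = ~is_large
        # (3) mixture weight
        n2 = int(np.count_nonzero(is_large))
        beta = sample_beta_weight(Q - n2, n2, rng)
        # (4) regularization precision
        gamma = sample_gamma_reg(x, L, pr.a_gamma, pr.b_gamma, rng)
        # (5) sigma from its v-collapsed conditional
        is_large = sample_sigma_mixture(residual, beta, kappa1, kappa2, rng)
        sigma = np.where(is_large, kappa2, kappa1)
        D = DiagonalMap(sigma**-2.0)
        smin2 = float(np.min(sigma)) ** 2
        # (6)-(7) auxiliaries and x
        if variant == "auxv1":
            mu = eps * smin2
            v = auxv1_vstep(x, D, mu, H, rng)
            x = auxv1_xstep(v, zf, D, gamma, mu, H, L, rng)
        else:
            mu1 = eps * smin2 / h_norm2
            mu = mu1
            v2 = auxv2_v2step(x, gamma, mu2, L, rng)
            # three-step inner bound: mu1 ||H||^2 = eps*smin2 < beta_ts < smin2
            beta_ts = np.sqrt(eps) * smin2
            v1 = sample_aux_three_step(x, mu1, beta_ts, H, D, rng, check=False)
            x = auxv2_xstep(v1, v2, zf, D, gamma, mu1, mu2, H, rng)

        hist["beta"][t] = beta
        hist["kappa1"][t] = kappa1
        hist["kappa2"][t] = kappa2
        hist["gamma"][t] = gamma
        hist["mu"][t] = mu
        hist["n2"][t] = n2
        if t >= burn_in:
            x_sum += x
            x_sq_sum += x**2
            if x_prev_kept is not None:
                msj_acc += float(np.sum((x - x_prev_kept) ** 2))
                msj_count += 1
            x_prev_kept = x.copy()

    kept = n_iter - burn_in
    mmse = (x_sum / kept).reshape(shape)
    trace = ChainTrace(histories=hist, burn_in=burn_in, seed=seed)
    summaries = {
        "variant": variant,
        "beta": {"mean": trace.posterior_mean("beta"), "std": trace.posterior_std("beta")},
        "kappa1": {"mean": trace.posterior_mean("kappa1"), "std": trace.posterior_std("kappa1")},
        "kappa2": {"mean": trace.posterior_mean("kappa2"), "std": trace.posterior_std("kappa2")},
        "gamma": {"mean": trace.posterior_mean("gamma"), "std": trace.posterior_std("gamma")},
        "msj": msj_acc / max(msj_count - 0, 1),
        "kept": kept,
    }
    return mmse, summaries, trace


def run_auxv1(
    z: np.ndarray,
    H: CirculantMap2D,
    config: MixedNoiseConfig | None = None,
    rng: np.random.Generator | int = 0,
) -> tuple[np.ndarray, dict, ChainTrace]:
    """AuxV1 PCGS: single auxiliary on the data term; exact Fourier x-draw.

    Sweep order (fixed; validated against the trimming rule):
    kappa1^2, kappa2^2, beta, gamma, sigma (v-collapsed), mu & v, x.
    Returns (MMSE image, parameter summaries, scalar-parameter trace)."""
    return _run_mixed(z, H, config or MixedNoiseConfig(), rng, "auxv1")


def run_auxv2(
    z: np.ndarray,
    H: CirculantMap2D,
    config: MixedNoiseConfig | None = None,
    rng: np.random.Generator | int = 0,
) -> tuple[np.ndarray, dict, ChainTrace]:
    """AuxV2 PCGS: auxiliaries on both the data and prior terms; i.i.d.
    coordinate x-draw.  Sweep order: kappa1^2, kappa2^2, beta, gamma,
    sigma (v1-collapsed), v2, mu1 & v1, x."""
    return _run_mixed(z, H, config or MixedNoiseConfig(), rng, "auxv2")
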