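"""Synthetic data generation for both restoration applications.

Everything here is a pure function of (configuration, seed) and every
dataset ships with its ground-truth latents, so the full pipeline is
testable without any external image: smooth Gaussian-prior random fields,
wavelet-domain GMEP channel stacks, circulant blur kernels, and white or
two-term mixed Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .app_multichannel import GMEPModel, SubbandPrior, _psi_of_d2
from .app_mixednoise import build_smoothness_operator
from .linops import BlockSelector, CirculantMap2D, FrameMap

__all__ = [
    "gaussian_kernel",
    "uniform_kernel",
    "DegradationSpec",
    "gen_smooth_image",
    "gen_gmep_multichannel",
    "degrade",
]


def uniform_kernel(size: int) -> np.ndarray:
    """Uniform blur kernel of shape (size, size), normalized to sum 1."""
    return np.full((size, size), 1.0 / size**2)


def gaussian_kernel(size: int, std: float) -> np.ndarray:
    """Truncated Gaussian blur kernel of shape (size, size), sum 1."""
    r = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-0.5 * (r / std) ** 2)
    k = np.outer(g, g)
    return k / k.sum()


@dataclass
class DegradationSpec:
    """Blur + noise configuration for the forward model z = H x + w.

    ``noise`` is either ("gaussian", sigma2) or
    ("mixed", beta, kappa1, kappa2).
    """

    kernel: np.ndarray
    noise: tuple

    def __post_init__(self):
        self.kernel = np.asarray(self.kernel, dtype=float)
        if np.any(self.kernel < 0) or not np.isclose(self.kernel.sum(), 1.0):
            raise ValueError("kernel must be nonnegative and sum to 1")
        kind = self.noise[0]
        if kind == "gaussian":
            if self.noise[1] < 0:
                raise ValueError("noise variance must be nonnegative")
        elif kind == "mixed":
            _, beta, k1, k2 = self.noise
            if not 0 < beta < 1 or k1 <= 0 or k2 <= 0:
                raise ValueError("mixed noise needs beta in (0,1), kappas > 0")
        else:
            raise ValueError(f"unknown noise kind {kind!r}")


def gen_smooth_image(
    shape: tuple[int, int],
    gamma: float,
    delta_L: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Exact draw from the Gaussian smoothness prior N(0, (gamma L^T L)^{-1}),
    L = delta_L I - Laplacian, computed in the Fourier domain."""
    if gamma <= 0 or delta_L <= 0:
        raise ValueError("gamma and delta_L must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = build_smoothness_operator(delta_L, shape)
    symbol = L.frequency_response.real  # real positive symmetric symbol
    w = rng.standard_normal(shape)
    x = np.fft.ifft2(np.fft.fft2(w) / (np.sqrt(gamma) * symbol)).real
    return x


def degrade(
    image: np.ndarray,
    spec: DegradationSpec,
    rng: np.random.Generator | int,
) -> tuple[np.ndarray, dict]:
    """Periodic blur followed by per-pixel noise.

    Accepts a single image or a channel stack (leading channel axis).
    Returns (observed, truth) where ``truth`` carries the noise latents
    (for mixed noise: the per-pixel sigma and component labels).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(int(rng))
    x = np.asarray(image, dtype=float)
    single = x.ndim == 2
    stack = x[None] if single else x
    shape = stack.shape[1:]
    H = CirculantMap2D(spec.kernel, shape)
    blurred = np.stack([H.apply(c.ravel()).reshape(shape) for c in stack])
    truth: dict = {"blurred": blurred[0] if single else blurred}
    kind = spec.noise[0]
    if kind == "gaussian":
        sigma2 = spec.noise[1]
        noise = np.sqrt(sigma2) * rng.standard_normal(blurred.shape)
        z = blurred + noise
        truth["sigma2"] = sigma2
    else:
        _, beta, k1, k2 = spec.noise
        is_large = rng.uniform(size=blurred.shape) < beta
        sigma = np.where(is_large, k2, k1)
        z = blurred + sigma * rng.standard_normal(blurred.shape)
        truth.update(
            {
                "sigma": sigma[0] if single else sigma,
                "is_large": is_large[0] if single else is_large,
                "beta": beta,
                "kappa1": k1,
                "kappa2": k2,
            }
        )
    return (z[0] if single else z), truth


def gen_gmep_multichannel(
    frame: FrameMap,
    n_channels: int,
    R: np.ndarray,
    n_weights: np.ndarray,
    gammas: np.ndarray,
    subband_priors: list[SubbandPrior],
    seed: int | np.random.Generator,
    mh_steps: int = 1000,
) -> np.ndarray:
    """Draw a B-channel image stack whose wavelet blocks follow the GMEP
    prior.

    The Gaussian-flagged subband is drawn exactly; the heavy-tailed
    subbands (beta < 1) have no exact sampler, so each cross-channel block
    is run through a long vectorized random-walk MH chain (``mh_steps``
    moves, step size tuned to the marginal scale) started from the matched
    Gaussian approximation.  Channels are then synthesized with F*.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    B = n_channels
    R = np.atleast_2d(np.asarray(R, dtype=float))
    n_weights = np.asarray(n_weights, dtype=float).ravel()
    Rinv = np.linalg.inv(R)
    W = n_weights[:, None] * Rinv * n_weights[None, :]
    chol_cov = np.linalg.cholesky(np.linalg.inv(W))
    selector = BlockSelector(frame, B)
    x = np.zeros(B * frame.in_dim)
    for sb in frame.subbands:
        sp = subband_priors[sb.m - 1]
        gamma = gammas[sb.m - 1]
        scale = gamma ** (-1.0 / (2.0 * sp.beta))  # Sigma^{1/2} overall scale
        K_m = sb.size
        # matched Gaussian start: N(0, scale^2 W^{-1})
        blocks = scale * rng.standard_normal((K_m, B)) @ chol_cov.T
        if not (sp.gaussian or sp.beta == 1.0):
            step = 2.4 * scale / np.sqrt(B)
            j = _gmep_block_neglog(blocks, gamma, sp, W)
            for _ in range(mh_steps):
                prop = blocks + step * rng.standard_normal(blocks.shape)
                j_prop = _gmep_block_neglog(prop, gamma, sp, W)
                accept = np.log(rng.uniform(size=K_m)) < (j - j_prop)
                blocks = np.where(accept[:, None], prop, blocks)
                j = np.where(accept, j_prop, j)
        selector.set_subband(x, sb.m, blocks)
    return np.stack(
        [frame.synthesize(xb) for xb in x.reshape(B, frame.in_dim)]
    )


def _gmep_block_neglog(blocks, gamma, sp, W):
    d2 = np.einsum("kb,bc,kc->k", blocks, W, blocks)
    return _psi_of_d2(d2, gamma, sp)
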