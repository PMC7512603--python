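"""Chain traces, mixing diagnostics and image-quality metrics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["ChainTrace", "msj", "image_metrics", "INF_SENTINEL"]

INF_SENTINEL = float("inf")


@dataclass
class ChainTrace:
    """Seeded sampler output: per-variable histories and the burn-in index.

    ``histories`` maps a variable name to an array whose leading axis is the
    sweep index.  Scalar variables are stored as 1-D arrays.
    """

    histories: dict[str, np.ndarray]
    burn_in: int
    seed: int | None = None
    acceptance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        lengths = {len(v) for v in self.histories.values()}
        if len(lengths) > 1:
            raise ValueError("history lengths differ across variables")
        self.n_sweeps = lengths.pop() if lengths else 0
        if not 0 <= self.burn_in < max(self.n_sweeps, 1):
            raise ValueError(
                f"burn_in {self.burn_in} leaves no kept sweeps "
                f"(total {self.n_sweeps})"
            )

    @property
    def kept(self) -> int:
        return self.n_sweeps - self.burn_in

    def posterior_mean(self, name: str) -> np.ndarray | float:
        h = self.histories[name][self.burn_in :]
        m = h.mean(axis=0)
        return float(m) if np.ndim(m) == 0 else m

    def posterior_std(self, name: str) -> np.ndarray | float:
        h = self.histories[name][self.burn_in :]
        s = h.std(axis=0, ddof=1)
        return float(s) if np.ndim(s) == 0 else s

    def summary(self) -> dict:
        out = {"n_sweeps": self.n_sweeps, "burn_in": self.burn_in, "seed": self.seed}
        for name, h in self.histories.items():
            if h.ndim == 1:
                out[name] = {
                    "mean": float(self.posterior_mean(name)),
                    "std": float(self.posterior_std(name)),
                }
        out["acceptance"] = dict(self.acceptance)
        return out

    def to_frame(self):
        """Scalar histories as a pandas DataFrame (one row per sweep)."""
        import pandas as pd

        cols = {k: v for k, v in self.histories.items() if v.ndim == 1}
        return pd.DataFrame(cols)


def msj(trace: ChainTrace | np.ndarray, t0: int, P: int, variable: str = "x") -> float:
    """Mean squared jump between successive kept samples.

        MSJ = (1/(P-1)) * sum_{t=1}^{P-1} ||x_{t+t0} - x_{t0+t+1}||^2

    computed over the P samples following the burn-in index t0.  A mixing
    diagnostic: larger jumps mean less correlated successive samples.
    """
    if isinstance(trace, ChainTrace):
        hist = trace.histories[variable]
    else:
        hist = np.asarray(trace)
    if P < 2:
        raise ValueError("P must be >= 2")
    if t0 + P > len(hist):
        raise ValueError(
            f"need t0 + P = {t0 + P} samples, chain has {len(hist)}"
        )
    kept = hist[t0 : t0 + P].reshape(P, -1)
    diffs = kept[1:] - kept[:-1]
    return float(np.sum(diffs**2) / (P - 1))


def image_metrics(
    reference: np.ndarray,
    estimate: np.ndarray,
    degraded: np.ndarray | None = None,
    sigma2: float | None = None,
    peak: float = 255.0,
) -> dict[str, float]:
    """SNR / PSNR / BSNR / SSIM between a reference image and an estimate.

    SNR  = 10 log10(||x||^2 / ||x - xhat||^2)
    PSNR = 10 log10(peak^2 * Q / ||x - xhat||^2)      (8-bit peak = 255)
    BSNR = 10 log10(var(blurred reference) / sigma2)  (needs ``degraded``
           interpreted as the noiseless blurred reference, and ``sigma2``)
    SSIM uses a Gaussian 11x11 window, K1 = 0.01, K2 = 0.03, dynamic
    range ``peak``.

    A zero error vector reports the infinity sentinel for the ratios.
    """
    x = np.asarray(reference, dtype=float)
    xhat = np.asarray(estimate, dtype=float)
    if x.shape != xhat.shape:
        raise ValueError("reference/estimate shape mismatch")
    err = float(np.sum((x - xhat) ** 2))
    out: dict[str, float] = {}
    if err == 0.0:
        out["snr"] = INF_SENTINEL
        out["psnr"] = INF_SENTINEL
    else:
        out["snr"] = 10.0 * np.log10(np.sum(x**2) / err)
        out["psnr"] = 10.0 * np.log10(peak**2 * x.size / err)
    out["ssim"] = float(
        structural_similarity(
            x, xhat, data_range=peak, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, channel_axis=0 if x.ndim == 3 else None,
        )
    )
    if degraded is not None and sigma2 is not None and sigma2 > 0:
        out["bsnr"] = 10.0 * np.log10(np.var(np.asarray(degraded, dtype=float)) / sigma2)
    return out
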