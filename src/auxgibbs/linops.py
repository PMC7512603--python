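"""Linear-operator algebra for structured Gaussian sampling.

All samplers and conditional densities in this package are written against a
small operator contract: an operator knows its dimensions, can apply itself
and its adjoint to flattened vectors, and exposes its spectral norm.  Images
are stored as 2-D (or channel-stacked 3-D) arrays; flattening is always
row-major (C order), which fixes an unambiguous correspondence between pixel
grids, FFT eigenbases and cross-channel block selectors.

Concrete structures
-------------------
``CirculantMap2D``
    Periodic 2-D convolution, diagonalized by the 2-D DFT.
``DiagonalMap``
    Elementwise multiplication; zero entries represent degenerate
    (semi-definite) precisions, whose generalized inverse keeps the zeros.
``FrameMap``
    Orthonormal separable wavelet analysis operator (PyWavelets), with a
    subband table mapping flat coefficient indices to (scale, orientation).
``BlockChannelMap``
    Block-diagonal action of per-channel operators on a stacked vector.
``CompositeMap``
    Operator product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pywt

__all__ = [
    "LinearMap",
    "IdentityMap",
    "DenseMap",
    "DiagonalMap",
    "CirculantMap2D",
    "FrameMap",
    "BlockChannelMap",
    "CompositeMap",
    "AdjointMap",
    "build_wavelet_frame",
    "spectral_norm",
    "as_dense",
    "BlockSelector",
    "ShapeError",
    "StructureError",
]


class ShapeError(ValueError):
    """Raised when operator/vector dimensions are inconsistent."""


class StructureError(ValueError):
    """Raised when an operator lacks the structure an algorithm requires."""


class LinearMap:
    """Abstract linear operator from R^in_dim to R^out_dim."""

    structure_tag = "dense"

    def __init__(self, out_dim: int, in_dim: int):
        if out_dim <= 0 or in_dim <= 0:
            raise ShapeError("operator dimensions must be positive")
        self.out_dim = int(out_dim)
        self.in_dim = int(in_dim)

    # -- core contract ----------------------------------------------------
    def apply(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def spectral_norm(self, tol: float = 1e-10) -> float:
        cached = getattr(self, "_spectral_norm_cache", None)
        if cached is None:
            cached = _power_iteration(self, tol)
            self._spectral_norm_cache = cached
        return cached

    # -- helpers ----------------------------------------------------------
    def _check_in(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float).ravel()
        if x.size != self.in_dim:
            raise ShapeError(
                f"expected input of length {self.in_dim}, got {x.size}"
            )
        return x

    def _check_out(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float).ravel()
        if y.size != self.out_dim:
            raise ShapeError(
                f"expected input of length {self.out_dim}, got {y.size}"
            )
        return y

    def gram_apply(self, x: np.ndarray) -> np.ndarray:
        """Apply the Gram operator A^T A."""
        return self.adjoint(self.apply(x))

    def gram_function_apply(self, fn: Callable, x: np.ndarray) -> np.ndarray:
        """Apply f(A^T A) through the operator's diagonalization.

        Only available for operators whose Gram matrix has a known
        orthogonal eigenbasis (circulant, orthonormal frame, diagonal,
        composites thereof).  Used by the structured Gaussian samplers to
        form matrix square roots exactly.
        """
        raise StructureError(
            f"{type(self).__name__} exposes no Gram diagonalization"
        )

    def __matmul__(self, other: "LinearMap") -> "CompositeMap":
        return CompositeMap([self, other])


def _power_iteration(op: LinearMap, tol: float, max_iter: int = 5000) -> float:
    """Spectral norm via power iteration on A^T A."""
    rng = np.random.default_rng(0)
    x = rng.standard_normal(op.in_dim)
    x /= np.linalg.norm(x)
    prev = 0.0
    for _ in range(max_iter):
        y = op.gram_apply(x)
        s = np.linalg.norm(y)
        if s == 0.0:
            return 0.0
        x = y / s
        if abs(s - prev) <= tol * max(s, 1.0):
            return float(np.sqrt(s))
        prev = s
    raise RuntimeError(
        f"power iteration did not converge (last estimate {np.sqrt(prev)})"
    )


class IdentityMap(LinearMap):
    structure_tag = "diagonal"

    def __init__(self, dim: int):
        super().__init__(dim, dim)

    def apply(self, x):
        return self._check_in(x).copy()

    adjoint = apply

    def spectral_norm(self, tol: float = 1e-10) -> float:
        return 1.0

    def gram_function_apply(self, fn, x):
        return fn(1.0) * self._check_in(x)


class DenseMap(LinearMap):
    structure_tag = "dense"

    def __init__(self, matrix: np.ndarray):
        matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
        super().__init__(*matrix.shape)
        self.matrix = matrix

    def apply(self, x):
        return self.matrix @ self._check_in(x)

    def adjoint(self, y):
        return self.matrix.T @ self._check_out(y)

    def spectral_norm(self, tol: float = 1e-10) -> float:
        cached = getattr(self, "_spectral_norm_cache", None)
        if cached is None:
            cached = float(np.linalg.norm(self.matrix, 2))
            self._spectral_norm_cache = cached
        return cached

    def gram_function_apply(self, fn, x):
        x = self._check_in(x)
        cached = getattr(self, "_gram_eig_cache", None)
        if cached is None:
            evals, evecs = np.linalg.eigh(self.matrix.T @ self.matrix)
            cached = (np.clip(evals, 0.0, None), evecs)
            self._gram_eig_cache = cached
        evals, evecs = cached
        return evecs @ (fn(evals) * (evecs.T @ x))


class DiagonalMap(LinearMap):
    """Multiplication by a nonnegative diagonal.

    Zero entries are legal and represent degenerate precisions; the
    generalized inverse inverts the nonzero entries and keeps the zeros.
    """

    structure_tag = "diagonal"

    def __init__(self, diag: np.ndarray):
        diag = np.asarray(diag, dtype=float).ravel()
        if np.any(diag < 0):
            raise ValueError("diagonal entries must be nonnegative")
        super().__init__(diag.size, diag.size)
        self.diag = diag

    def apply(self, x):
        return self.diag * self._check_in(x)

    adjoint = apply

    def spectral_norm(self, tol: float = 1e-10) -> float:
        return float(self.diag.max())

    def generalized_inverse(self) -> "DiagonalMap":
        inv = np.where(self.diag > 0, 1.0 / np.where(self.diag > 0, self.diag, 1.0), 0.0)
        return DiagonalMap(inv)

    def gram_function_apply(self, fn, x):
        return fn(self.diag**2) * self._check_in(x)


class CirculantMap2D(LinearMap):
    """Periodic 2-D convolution with a center-anchored kernel.

    The induced matrix is circulant-block-circulant; its eigenvalues are the
    2-D DFT of the zero-padded kernel rolled so that the kernel center sits
    at the origin.
    """

    structure_tag = "circulant2d"

    def __init__(self, kernel: np.ndarray, image_shape: tuple[int, int]):
        kernel = np.atleast_2d(np.asarray(kernel, dtype=float))
        rows, cols = image_shape
        if kernel.shape[0] > rows or kernel.shape[1] > cols:
            raise ShapeError("kernel larger than image")
        n = rows * cols
        super().__init__(n, n)
        self.kernel = kernel
        self.image_shape = (rows, cols)
        padded = np.zeros(image_shape)
        padded[: kernel.shape[0], : kernel.shape[1]] = kernel
        # anchor the kernel center at pixel (0, 0)
        padded = np.roll(
            padded,
            (-(kernel.shape[0] // 2), -(kernel.shape[1] // 2)),
            axis=(0, 1),
        )
        self.frequency_response = np.fft.fft2(padded)

    def _conv(self, x: np.ndarray, response: np.ndarray) -> np.ndarray:
        X = x.reshape(self.image_shape) if x.ndim == 1 else x
        out = np.fft.ifft2(np.fft.fft2(X) * response).real
        return out.ravel() if x.ndim == 1 else out

    def apply(self, x):
        return self._conv(self._check_in(x), self.frequency_response)

    def adjoint(self, y):
        return self._conv(self._check_out(y), np.conj(self.frequency_response))

    def spectral_norm(self, tol: float = 1e-10) -> float:
        return float(np.abs(self.frequency_response).max())

    def gram_function_apply(self, fn, x):
        x = self._check_in(x)
        resp = fn(np.abs(self.frequency_response) ** 2)
        X = np.fft.fft2(x.reshape(self.image_shape))
        return np.fft.ifft2(X * resp).real.ravel()


@dataclass(frozen=True)
class Subband:
    """One wavelet subband: index m (1-based), orientation, scale, extent."""

    m: int
    orientation: str  # 'a' | 'h' | 'v' | 'd'
    scale: int  # 1 = finest detail level
    size: int
    start: int  # flat index range [start, stop) in the coefficient vector
    stop: int


class FrameMap(LinearMap):
    """Orthonormal separable 2-D wavelet analysis operator F.

    ``apply`` maps a flattened image to the stacked coefficient vector
    (detail subbands finest-first, orientation order h, v, d, approximation
    subband last).  ``adjoint`` is the synthesis F*; for orthonormal wavelets
    F F* = F* F = I.
    """

    structure_tag = "frame"

    def __init__(self, wavelet_name: str, levels: int, image_shape: tuple[int, int]):
        rows, cols = image_shape
        if levels < 1:
            raise ValueError("levels must be >= 1")
        if rows % (2**levels) or cols % (2**levels):
            raise ValueError(
                f"image shape {image_shape} not divisible by 2^{levels}"
            )
        try:
            wavelet = pywt.Wavelet(wavelet_name)
        except ValueError as exc:
            raise ValueError(f"unsupported wavelet {wavelet_name!r}") from exc
        if not wavelet.orthogonal:
            raise ValueError(f"wavelet {wavelet_name!r} is not orthonormal")
        n = rows * cols
        super().__init__(n, n)
        self.wavelet_name = wavelet_name
        self.wavelet = wavelet
        self.levels = levels
        self.image_shape = (rows, cols)
        # build the subband table from a template decomposition
        coeffs = self._wavedec2(np.zeros(image_shape))
        self._template = coeffs
        table: list[Subband] = []
        offset = 0
        m = 1
        # coeffs = [cA_L, (cH_L, cV_L, cD_L), ..., (cH_1, cV_1, cD_1)]
        for j in range(levels, 0, -1):  # scale L (coarsest) .. 1 (finest)
            triple = coeffs[levels - j + 1]
            for orient, arr in zip("hvd", triple):
                table.append(
                    Subband(0, orient, j, arr.size, 0, 0)  # placeholder
                )
        # order subbands finest-first: scale 1 (h,v,d), scale 2, ..., approx
        table.sort(key=lambda s: (s.scale, "hvd".index(s.orientation)))
        final: list[Subband] = []
        for sb in table:
            final.append(
                Subband(m, sb.orientation, sb.scale, sb.size, offset, offset + sb.size)
            )
            offset += sb.size
            m += 1
        approx = coeffs[0]
        final.append(Subband(m, "a", levels, approx.size, offset, offset + approx.size))
        offset += approx.size
        assert offset == n
        self.subbands: tuple[Subband, ...] = tuple(final)
        self.n_subbands = len(final)

    def _wavedec2(self, image: np.ndarray):
        # periodization keeps the decimated transform exactly orthonormal at
        # any level; pywt's boundary-effect warning does not apply
        import warnings

        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="Level value .* too high")
            return pywt.wavedec2(
                image, self.wavelet, mode="periodization", level=self.levels
            )

    # -- coefficient packing ----------------------------------------------
    def _pack(self, coeffs) -> np.ndarray:
        out = np.empty(self.in_dim)
        approx = coeffs[0]
        by_key = {}
        for j in range(self.levels, 0, -1):
            triple = coeffs[self.levels - j + 1]
            for orient, arr in zip("hvd", triple):
                by_key[(j, orient)] = arr
        for sb in self.subbands:
            arr = approx if sb.orientation == "a" else by_key[(sb.scale, sb.orientation)]
            out[sb.start : sb.stop] = arr.ravel()
        return out

    def _unpack(self, x: np.ndarray):
        approx_sb = self.subbands[-1]
        shapes = [c[0].shape if isinstance(c, tuple) else c.shape for c in self._template]
        coeffs = [
            x[approx_sb.start : approx_sb.stop].reshape(self._template[0].shape)
        ]
        by_key = {(sb.scale, sb.orientation): sb for sb in self.subbands[:-1]}
        for j in range(self.levels, 0, -1):
            shape = self._template[self.levels - j + 1][0].shape
            triple = tuple(
                x[by_key[(j, o)].start : by_key[(j, o)].stop].reshape(shape)
                for o in "hvd"
            )
            coeffs.append(triple)
        return coeffs

    def apply(self, x):
        x = self._check_in(x)
        coeffs = self._wavedec2(x.reshape(self.image_shape))
        return self._pack(coeffs)

    def adjoint(self, y):
        y = self._check_out(y)
        img = pywt.waverec2(self._unpack(y), self.wavelet, mode="periodization")
        return img.ravel()

    def spectral_norm(self, tol: float = 1e-10) -> float:
        return 1.0

    def gram_function_apply(self, fn, x):
        # F^T F = I for orthonormal frames
        return fn(1.0) * self._check_in(x)

    # -- analysis/synthesis sugar on images --------------------------------
    def analyze(self, image: np.ndarray) -> np.ndarray:
        return self.apply(np.asarray(image).ravel())

    def synthesize(self, coefs: np.ndarray) -> np.ndarray:
        return self.adjoint(coefs).reshape(self.image_shape)


class AdjointMap(LinearMap):
    """The adjoint of another operator, as an operator."""

    def __init__(self, base: LinearMap):
        super().__init__(base.in_dim, base.out_dim)
        self.base = base
        self.structure_tag = base.structure_tag

    def apply(self, x):
        return self.base.adjoint(x)

    def adjoint(self, y):
        return self.base.apply(y)

    def spectral_norm(self, tol: float = 1e-10) -> float:
        return self.base.spectral_norm(tol)

    def gram_function_apply(self, fn, x):
        # (A^T)^T A^T = A A^T; for orthonormal/ tight structures this equals
        # the Gram function of the base when dimensions agree.
        if isinstance(self.base, (FrameMap, IdentityMap, DiagonalMap, CirculantMap2D)):
            return self.base.gram_function_apply(fn, x)
        raise StructureError("adjoint Gram diagonalization unavailable")


class BlockChannelMap(LinearMap):
    """Block-diagonal operator acting channel-wise on a stacked vector."""

    structure_tag = "block_channel"

    def __init__(self, per_channel_ops: Sequence[LinearMap]):
        ops = list(per_channel_ops)
        if not ops:
            raise ValueError("need at least one channel operator")
        super().__init__(
            sum(op.out_dim for op in ops), sum(op.in_dim for op in ops)
        )
        self.ops = ops

    def _split_in(self, x):
        x = self._check_in(x)
        out, pos = [], 0
        for op in self.ops:
            out.append(x[pos : pos + op.in_dim])
            pos += op.in_dim
        return out

    def apply(self, x):
        return np.concatenate(
            [op.apply(xb) for op, xb in zip(self.ops, self._split_in(x))]
        )

    def adjoint(self, y):
        y = self._check_out(y)
        out, pos = [], 0
        for op in self.ops:
            out.append(op.adjoint(y[pos : pos + op.out_dim]))
            pos += op.out_dim
        return np.concatenate(out)

    def spectral_norm(self, tol: float = 1e-10) -> float:
        return max(op.spectral_norm(tol) for op in self.ops)

    def gram_function_apply(self, fn, x):
        return np.concatenate(
            [
                op.gram_function_apply(fn, xb)
                for op, xb in zip(self.ops, self._split_in(x))
            ]
        )


class CompositeMap(LinearMap):
    """Product of operators: maps[0] @ maps[1] @ ... (applied right-first)."""

    structure_tag = "composite"

    def __init__(self, maps: Sequence[LinearMap]):
        maps = list(maps)
        for outer, inner in zip(maps, maps[1:]):
            if outer.in_dim != inner.out_dim:
                raise ShapeError(
                    f"composition mismatch: {outer.in_dim} != {inner.out_dim}"
                )
        super().__init__(maps[0].out_dim, maps[-1].in_dim)
        self.maps = maps

    def apply(self, x):
        x = self._check_in(x)
        for op in reversed(self.maps):
            x = op.apply(x)
        return x

    def adjoint(self, y):
        y = self._check_out(y)
        for op in self.maps:
            y = op.adjoint(y)
        return y

    def spectral_norm(self, tol: float = 1e-10) -> float:
        # exact shortcut when all but one factor is orthonormal square
        if len(self.maps) == 2:
            outer, inner = self.maps
            if _is_orthonormal_square(inner):
                return outer.spectral_norm(tol)
            if _is_orthonormal_square(outer):
                return inner.spectral_norm(tol)
        return super().spectral_norm(tol)

    def gram_function_apply(self, fn, x):
        # H = M P with P orthonormal square (P^T P = P P^T = I):
        # f(H^T H) = P^T f(M^T M) P.
        if len(self.maps) == 2:
            outer, inner = self.maps
            if _is_orthonormal_square(inner):
                return inner.adjoint(
                    outer.gram_function_apply(fn, inner.apply(self._check_in(x)))
                )
        raise StructureError("composite Gram diagonalization unavailable")


def _is_orthonormal_square(op: LinearMap) -> bool:
    if isinstance(op, (IdentityMap, FrameMap)):
        return True
    if isinstance(op, AdjointMap):
        return _is_orthonormal_square(op.base)
    if isinstance(op, BlockChannelMap):
        return all(_is_orthonormal_square(o) for o in op.ops)
    return False


def build_wavelet_frame(
    wavelet_name: str, levels: int, image_shape: tuple[int, int]
) -> FrameMap:
    """Build an orthonormal wavelet analysis operator with its subband table.

    A separable 2-D decomposition over ``levels`` resolution levels yields
    M = 3*levels + 1 subbands (three oriented detail subbands per level plus
    one approximation subband).
    """
    return FrameMap(wavelet_name, levels, image_shape)


def spectral_norm(op: LinearMap, tol: float = 1e-10) -> float:
    """Spectral norm of an operator (exact for structured maps)."""
    return op.spectral_norm(tol)


class BlockSelector:
    """Cross-channel block selectors P_{m,k} over a stacked coefficient vector.

    For B channels of K coefficients each, stacked as x = [x_1; ...; x_B],
    the selector for subband m and position k extracts the length-B vector of
    coefficients at that subband position across all channels.  Each selector
    consists of B rows of a permutation matrix; the blocks partition x.
    """

    def __init__(self, frame: FrameMap, n_channels: int):
        if n_channels < 1:
            raise ValueError("need at least one channel")
        self.frame = frame
        self.B = int(n_channels)
        self.K = frame.in_dim
        self.Q = self.B * self.K

    def _offsets(self, m: int, k: int) -> np.ndarray:
        try:
            sb = self.frame.subbands[m - 1]
        except IndexError:
            raise IndexError(f"subband index {m} out of range") from None
        if not 0 <= k < sb.size:
            raise IndexError(f"position {k} out of range for subband {m}")
        return sb.start + k + self.K * np.arange(self.B)

    def extract(self, x: np.ndarray, m: int, k: int) -> np.ndarray:
        x = np.asarray(x).ravel()
        if x.size != self.Q:
            raise ShapeError(f"expected stacked vector of length {self.Q}")
        return x[self._offsets(m, k)]

    def scatter(self, block: np.ndarray, m: int, k: int, out: np.ndarray | None = None) -> np.ndarray:
        """Adjoint of extract: place a length-B block back (accumulating)."""
        if out is None:
            out = np.zeros(self.Q)
        out[self._offsets(m, k)] += np.asarray(block).ravel()
        return out

    def subband_view(self, x: np.ndarray, m: int) -> np.ndarray:
        """All K_m blocks of subband m as a (K_m, B) array (a view-copy)."""
        sb = self.frame.subbands[m - 1]
        return np.asarray(x).reshape(self.B, self.K)[:, sb.start : sb.stop].T

    def set_subband(self, x: np.ndarray, m: int, blocks: np.ndarray) -> None:
        sb = self.frame.subbands[m - 1]
        x.reshape(self.B, self.K)[:, sb.start : sb.stop] = np.asarray(blocks).T


def as_dense(op: LinearMap) -> np.ndarray:
    """Materialize an operator as a dense matrix (test/oracle use only)."""
    cols = [op.apply(e) for e in np.eye(op.in_dim)]
    return np.array(cols).T
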