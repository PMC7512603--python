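"""Scale-mixture-of-Gaussian noise machinery.

In the scale-mixture model each observation i carries its own noise standard
deviation sigma_i, itself random (two-point mixtures give impulse-plus-
Gaussian noise; inverse-Gamma mixing gives Cauchy noise, etc.).  Because the
per-pixel precisions D(sigma) change at every sweep, the DA step size mu must
be recomputed from the current support of sigma at every sweep, and the
sigma-update is best drawn from its v-collapsed conditional — a partially
collapsed Gibbs sampler (PCGS), valid only for specific step orderings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .da_core import AuxScheme, cond_neglog_alt1, cond_neglog_alt2, sample_aux
from .linops import DiagonalMap, LinearMap
from .struct_gauss import PreconditionError

__all__ = [
    "MixingState",
    "dmatrix",
    "mu_of_sigma",
    "sample_aux_mixture",
    "cond_neglog_mixture",
    "pcgs_schedule",
    "GibbsStep",
    "ScheduleError",
    "ModelDegeneracyError",
]

SIGMA_FLOOR = 1e-12  # guards mu(sigma) against underflow as min sigma -> 0


class ModelDegeneracyError(ValueError):
    """All mixing variables are zero: the noise model is degenerate."""


@dataclass
class MixingState:
    """Per-observation noise standard deviations and derived quantities.

    ``mode`` selects which coupling the DA step eliminates:
    ``alt_I`` removes D(sigma), ``alt_II`` removes H^T D(sigma) H.
    """

    sigma: np.ndarray
    epsilon: float = 0.99
    mode: str = "alt_I"

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float).ravel()
        if np.any(self.sigma < 0):
            raise ValueError("sigma entries must be nonnegative")
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must lie in (0, 1)")
        if self.mode not in ("alt_I", "alt_II"):
            raise ValueError("mode must be 'alt_I' or 'alt_II'")
        if not np.any(self.sigma > 0):
            raise ModelDegeneracyError("all mixing variables are zero")

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.sigma > 0)


def dmatrix(sigma: np.ndarray) -> DiagonalMap:
    """Diagonal precision D(sigma): 0 where sigma_i = 0, else sigma_i^{-2}."""
    sigma = np.asarray(sigma, dtype=float).ravel()
    if np.any(sigma < 0):
        raise ValueError("sigma entries must be nonnegative")
    if not np.any(sigma > 0):
        raise ModelDegeneracyError("all mixing variables are zero")
    diag = np.where(sigma > 0, 1.0 / np.where(sigma > 0, sigma, 1.0) ** 2, 0.0)
    return DiagonalMap(diag)


def mu_of_sigma(state: MixingState, H: LinearMap | None = None) -> float:
    """Iteration-dependent step size mu(sigma).

    alt_I : mu = epsilon * min_{i in support} sigma_i^2
            (equivalently epsilon / ||D(sigma)||_S)
    alt_II: mu = epsilon * min_{i in support} sigma_i^2 / ||H||_S^2

    Either choice keeps the auxiliary covariance Gamma(sigma) positive
    definite.  min sigma is floored at 1e-12 to avoid underflow when a
    mixing variable collapses toward an exact observation.
    """
    support = state.support
    if support.size == 0:
        raise ModelDegeneracyError("empty support")
    # epsilon / ||D(sigma)||_S == epsilon * (min supported sigma)^2, computed
    # through the spectral norm so the homoscedastic case reduces bitwise to
    # the plain-Gaussian default step size
    d_norm = min(dmatrix(state.sigma).spectral_norm(), SIGMA_FLOOR**-2.0)
    if state.mode == "alt_II":
        if H is None:
            raise ValueError("alt_II needs the operator H")
        if not isinstance(H, LinearMap):
            from .linops import DenseMap

            H = DenseMap(np.asarray(H, dtype=float))
        return state.epsilon / (H.spectral_norm() ** 2 * d_norm)
    return state.epsilon / d_norm


def _scheme_for(state: MixingState, H: LinearMap) -> AuxScheme:
    mu = mu_of_sigma(state, H if state.mode == "alt_II" else None)
    return AuxScheme(
        alternative="I" if state.mode == "alt_I" else "II",
        H=H,
        Lambda=dmatrix(state.sigma),
        mu=mu,
        epsilon=state.epsilon,
    )


def sample_aux_mixture(
    state: MixingState, x: np.ndarray, H: LinearMap, rng: np.random.Generator
) -> np.ndarray:
    """Draw the auxiliary variable for the current mixing state.

    alt_I : v ~ N(Gamma(sigma) H x, Gamma(sigma)),
            Gamma(sigma) = (1/mu(sigma)) I - D(sigma)   (diagonal)
    alt_II: v ~ N(Gamma(sigma) x, Gamma(sigma)),
            Gamma(sigma) = (1/mu(sigma)) I - H^T D(sigma) H (three-step rule)

    With constant sigma this delegates to exactly the plain-Gaussian DA draw
    with Lambda = D(sigma), so shared seeds give identical streams.
    """
    return sample_aux(_scheme_for(state, H), x, rng)


def cond_neglog_mixture(
    x, sigma, v, z, mode: str, H, psi=None, epsilon: float = 0.99
) -> float:
    """Negative log of P(x | sigma, v, z), up to a constant.

    alt_I : (1/(2 mu)) ||H x - mu (v + D(sigma) z)||^2 + Psi(V x)
    alt_II: (1/(2 mu)) ||x - mu (v + H^T D(sigma) z)||^2 + Psi(V x)

    with mu = mu(sigma).  Reduces exactly to the plain-Gaussian conditionals
    when sigma is constant.
    """
    state = MixingState(sigma=sigma, epsilon=epsilon, mode=mode)
    D = dmatrix(state.sigma)
    if mode == "alt_I":
        mu = mu_of_sigma(state)
        return cond_neglog_alt1(x, v, z, mu, D, H, psi)
    mu = mu_of_sigma(state, H)
    return cond_neglog_alt2(x, v, z, mu, D, H, psi)


# ---------------------------------------------------------------------------
# PCGS schedule validation
# ---------------------------------------------------------------------------


class ScheduleError(ValueError):
    """A sweep ordering breaks the marginalize-permute-trim template."""


@dataclass(frozen=True)
class GibbsStep:
    """One step of a sweep: the variable drawn and what it conditions on.

    ``collapsed`` lists variables the *full* conditional would include but
    that this step's conditional deliberately omits (marginalizes over).
    """

    draws: str
    conditions_on: frozenset = frozenset()
    collapsed: frozenset = frozenset()

    def __init__(self, draws, conditions_on=(), collapsed=()):
        object.__setattr__(self, "draws", draws)
        object.__setattr__(self, "conditions_on", frozenset(conditions_on))
        object.__setattr__(self, "collapsed", frozenset(collapsed))


def pcgs_schedule(steps: list[GibbsStep]) -> list[GibbsStep]:
    """Validate a partially collapsed Gibbs sweep ordering.

    Template: a step that collapses (omits) a variable w from its
    conditional is only valid if w is re-drawn *later* in the same sweep —
    the trimmed draw of w must come after every step that marginalized over
    it, otherwise the chain's stationary distribution is unknown.  With no
    collapsed variables any ordering is a standard Gibbs sweep and is
    accepted.

    Returns the validated schedule unchanged; raises ScheduleError naming
    the offending pair otherwise.
    """
    drawn_at = {}
    for idx, step in enumerate(steps):
        drawn_at.setdefault(step.draws, []).append(idx)
    for idx, step in enumerate(steps):
        for omitted in step.collapsed:
            positions = drawn_at.get(omitted, [])
            if not any(p > idx for p in positions):
                raise ScheduleError(
                    f"step {idx} draws {step.draws!r} from a conditional that "
                    f"omits {omitted!r}, but {omitted!r} is not re-drawn later "
                    "in the sweep"
                )
    return list(steps)
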