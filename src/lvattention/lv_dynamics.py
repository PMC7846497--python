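"""The nonautonomous Lotka-Volterra structure behind the logit shares.

When every topic utility f_i is C^2, the logit share trajectories are the
unique global solution of the Cauchy problem

    dS_i/dt = g_i(t) S_i (1 - S_i) - sum_{j != i} g_j(t) S_j S_i,
    g_i(t) = df_i/dt,

an integrable nonautonomous Lotka-Volterra system: logistic growth plus
interaction with competitors. The closed form is exact and cheap, so the
numerical integrator here serves only as an independent test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import AlignmentError, IntegrationError
from .share_model import ShareSystem, logit_shares
from .utility_fit import UtilityFunction

__all__ = [
    "CoefficientSet",
    "solve_shares",
    "lv_rhs",
    "ode_residual",
    "integrate_forward",
]


@dataclass(eq=False)
class CoefficientSet:
    """Per-topic interaction-coefficient functions ``g_i(t)`` (per week)."""

    topics: tuple[str, ...]
    funcs: tuple[Callable[[np.ndarray], np.ndarray], ...]
    provenance: str = "fitted"  # "fitted" | "specified"

    def __post_init__(self) -> None:
        self.topics = tuple(self.topics)
        self.funcs = tuple(self.funcs)
        if len(self.topics) != len(self.funcs):
            raise ValueError("one coefficient function per topic required")

    @classmethod
    def from_utilities(
        cls,
        utilities: Sequence[UtilityFunction],
        topics: Sequence[str],
        provenance: str = "fitted",
    ) -> "CoefficientSet":
        """Differentiate utilities analytically: ``g_i = df_i/dt``."""
        return cls(
            topics=tuple(topics),
            funcs=tuple(u.derivative() for u in utilities),
            provenance=provenance,
        )

    @property
    def n_topics(self) -> int:
        return len(self.topics)

    def values(self, times: np.ndarray) -> np.ndarray:
        """Evaluate all coefficients on a grid; returns shape (T, N)."""
        times = np.asarray(times, dtype=float)
        g = np.column_stack([np.broadcast_to(np.asarray(f(times), float),
                                             times.shape)
                             for f in self.funcs])
        if not np.all(np.isfinite(g)):
            raise ValueError("coefficients must be finite on the grid")
        return g

    def at(self, t: float) -> np.ndarray:
        """Evaluate all coefficients at a single time."""
        return np.array([float(f(t)) for f in self.funcs])


def solve_shares(
    utilities: Sequence[UtilityFunction],
    times: np.ndarray,
    topics: Sequence[str] | None = None,
) -> ShareSystem:
    """Closed-form share trajectories: the logit of the utilities per point."""
    times = np.asarray(times, dtype=float)
    if topics is None:
        topics = tuple(f"topic_{i + 1}" for i in range(len(utilities)))
    f = np.column_stack(
        [np.broadcast_to(np.asarray(u(times), float), times.shape)
         for u in utilities]
    )
    S, S0 = logit_shares(f)
    return ShareSystem(times=times, topics=tuple(topics), S=S, S0=S0)


def lv_rhs(S: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Right-hand side of the LV system at one instant.

    ``dS_i/dt = g_i S_i (1 - S_i) - sum_{j != i} g_j S_j S_i``, which
    simplifies to ``S_i * (g_i - sum_j g_j S_j)``.
    """
    S = np.asarray(S, dtype=float)
    g = np.asarray(g, dtype=float)
    if S.shape != g.shape:
        raise ValueError(f"shape mismatch: S {S.shape} vs g {g.shape}")
    return S * (g - S @ g)


def ode_residual(shares: ShareSystem, coeffs: CoefficientSet) -> np.ndarray:
    """Per-topic residual of the LV equation along a share trajectory.

    ``r_i(t) = dS_i/dt (numerical) - lv_rhs_i(S(t), g(t))`` with centered
    differences in the interior and one-sided differences at the ends.
    For shares produced by :func:`solve_shares` from the utilities whose
    derivatives make up ``coeffs``, the residual is zero up to the
    finite-difference error of the grid.
    """
    if coeffs.n_topics != shares.n_topics or tuple(coeffs.topics) != tuple(
        shares.topics
    ):
        raise AlignmentError("coefficients and shares disagree on topics")
    t = shares.times
    if len(t) < 3:
        raise AlignmentError("need at least 3 grid points for a residual")
    dSdt = np.gradient(shares.S, t, axis=0)
    g = coeffs.values(t)
    rhs = shares.S * (g - np.einsum("tj,tj->t", shares.S, g)[:, None])
    return dSdt - rhs


def integrate_forward(
    coeffs: CoefficientSet,
    S_init: np.ndarray,
    times: np.ndarray,
    *,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> ShareSystem:
    """Numerically integrate the LV system from given initial shares.

    An adaptive Runge-Kutta oracle for the closed form: when ``coeffs`` are
    the exact derivatives of utilities f and ``S_init = logit_shares(f(t0))``,
    the result agrees with :func:`solve_shares` within integrator tolerance.
    """
    times = np.asarray(times, dtype=float)
    S_init = np.asarray(S_init, dtype=float)
    if S_init.shape != (coeffs.n_topics,):
        raise ValueError("S_init must hold one share per topic")
    if np.any(S_init <= 0) or S_init.sum() >= 1.0:
        raise ValueError("initial shares must be positive and sum to < 1")

    def rhs(t: float, S: np.ndarray) -> np.ndarray:
        return lv_rhs(S, coeffs.at(t))

    sol = solve_ivp(
        rhs,
        t_span=(times[0], times[-1]),
        y0=S_init,
        t_eval=times,
        method="RK45",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"ODE integration failed at t={sol.t[-1] if len(sol.t) else '?'}: "
            f"{sol.message}"
        )
    S = sol.y.T
    return ShareSystem(
        times=times,
        topics=coeffs.topics,
        S=S,
        S0=1.0 - S.sum(axis=1),
    )
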