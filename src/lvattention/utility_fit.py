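"""Parametric utility functions, least-squares fitting and fit diagnostics.

Two smooth families are supported: a Fourier series of order n,

    f(t) = a_0 + sum_{r=1..n} [ a_r cos(r pi t / tau) + b_r sin(r pi t / tau) ],

and a plain polynomial. Both are evaluable and twice continuously
differentiable everywhere and carry exact analytic derivatives, so the
interaction coefficients g(t) = df/dt downstream are never finite-differenced.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial import polynomial as P

from .errors import FitRankError
from .share_model import ShareSystem, logit_shares, utilities_from_shares

__all__ = [
    "UtilityFunction",
    "FourierUtility",
    "PolynomialUtility",
    "FitDiagnostics",
    "fit_fourier",
    "fit_polynomial",
    "fit_utilities",
    "mse",
    "AUTO_MAX_ORDER",
]

#: Cap on the automatically selected Fourier order (52 weekly points):
#: higher orders start interpolating observation noise.
AUTO_MAX_ORDER = 6


class UtilityFunction(abc.ABC):
    """A smooth parametric utility: callable on time, with exact derivative."""

    kind: str

    @abc.abstractmethod
    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        """Evaluate the function at time(s) ``t`` (weeks)."""

    @abc.abstractmethod
    def derivative(self) -> "UtilityFunction":
        """Exact analytic derivative, as another evaluable function."""


@dataclass(frozen=True, eq=False)
class FourierUtility(UtilityFunction):
    """Order-n Fourier series on the half-period ``tau``.

    ``a[r-1]`` and ``b[r-1]`` are the cosine and sine coefficients of
    harmonic ``r``; ``a0`` is the constant term.
    """

    a0: float
    a: np.ndarray
    b: np.ndarray
    tau: float
    kind: str = field(default="fourier", init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", np.atleast_1d(np.asarray(self.a, float)))
        object.__setattr__(self, "b", np.atleast_1d(np.asarray(self.b, float)))
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("a and b must be 1-d arrays of equal length")
        if self.order < 1:
            raise ValueError("fourier order must be >= 1")
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")

    @property
    def order(self) -> int:
        return len(self.a)

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        r = np.arange(1, self.order + 1)
        ang = np.pi * np.multiply.outer(t, r) / self.tau  # (..., n)
        out = self.a0 + np.cos(ang) @ self.a + np.sin(ang) @ self.b
        return out if out.shape else float(out)

    def derivative(self) -> "FourierUtility":
        # d/dt[a_r cos(r pi t/tau)] = -(a_r r pi/tau) sin(r pi t/tau)
        # d/dt[b_r sin(r pi t/tau)] = +(b_r r pi/tau) cos(r pi t/tau)
        r = np.arange(1, self.order + 1)
        w = r * np.pi / self.tau
        return FourierUtility(a0=0.0, a=self.b * w, b=-self.a * w, tau=self.tau)

    def coefficients(self) -> np.ndarray:
        """Flat coefficient vector ``[a0, a_1..a_n, b_1..b_n]``."""
        return np.concatenate([[self.a0], self.a, self.b])


@dataclass(frozen=True, eq=False)
class PolynomialUtility(UtilityFunction):
    """Polynomial ``c_0 + c_1 t + ... + c_d t^d`` (power basis)."""

    coef: np.ndarray  # c_0 .. c_d
    kind: str = field(default="polynomial", init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coef", np.atleast_1d(np.asarray(self.coef, float))
        )

    @property
    def degree(self) -> int:
        return len(self.coef) - 1

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        out = P.polyval(t, self.coef)
        return out if out.shape else float(out)

    def derivative(self) -> "PolynomialUtility":
        if self.degree == 0:
            return PolynomialUtility(coef=np.zeros(1))
        return PolynomialUtility(coef=P.polyder(self.coef))


def _fourier_design(t: np.ndarray, order: int, tau: float) -> np.ndarray:
    r = np.arange(1, order + 1)
    ang = np.pi * np.multiply.outer(t, r) / tau
    return np.hstack([np.ones((len(t), 1)), np.cos(ang), np.sin(ang)])


def fit_fourier(
    times: np.ndarray, values: np.ndarray, order: int, tau: float
) -> FourierUtility:
    """Least-squares fit of an order-n Fourier series.

    Solved by SVD-backed least squares; a rank-deficient design raises
    :class:`~lvattention.errors.FitRankError` rather than being silently
    regularized. Requires at least ``2 * order + 1`` samples.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    ncoef = 2 * order + 1
    if len(times) < ncoef:
        raise FitRankError(
            f"{len(times)} samples cannot determine {ncoef} Fourier "
            f"coefficients (order {order})"
        )
    X = _fourier_design(times, order, tau)
    beta, _, rank, _ = np.linalg.lstsq(X, values, rcond=None)
    if rank < ncoef:
        raise FitRankError(
            f"rank-deficient Fourier design (rank {rank} < {ncoef}); "
            "check tau against the sample spacing"
        )
    return FourierUtility(
        a0=float(beta[0]), a=beta[1 : order + 1], b=beta[order + 1 :], tau=tau
    )


def fit_polynomial(
    times: np.ndarray, values: np.ndarray, degree: int = 4
) -> PolynomialUtility:
    """Least-squares polynomial fit (default degree 4).

    Fitted in a scaled domain for conditioning, then converted back to the
    power basis.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if degree < 0:
        raise ValueError(f"degree must be >= 0, got {degree}")
    if len(times) < degree + 1:
        raise FitRankError(
            f"{len(times)} samples cannot determine a degree-{degree} "
            "polynomial"
        )
    if len(np.unique(times)) < degree + 1:
        raise FitRankError("duplicate time points make the fit rank-deficient")
    fitted = np.polynomial.Polynomial.fit(times, values, deg=degree)
    return PolynomialUtility(coef=fitted.convert().coef)


def mse(historical: np.ndarray, predicted: np.ndarray) -> float:
    """Mean squared error ``(1/n) * sum (h_i - p_i)^2``."""
    h = np.asarray(historical, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if h.shape != p.shape:
        raise ValueError(f"length mismatch: {h.shape} vs {p.shape}")
    if h.size == 0:
        raise ValueError("mse of empty series is undefined")
    return float(np.mean((h - p) ** 2))


@dataclass(eq=False)
class FitDiagnostics:
    """Accuracy of the utility fit, measured on the share scale."""

    topics: tuple[str, ...]
    share_mse: np.ndarray  # (N,) per-topic MSE, share^2 scale
    residuals: np.ndarray  # (T, N) observed minus fitted shares
    fitted_shares: ShareSystem
    kind: str
    order: int  # fourier order, or polynomial degree
    tau: float | None  # None for polynomial fits

    def mse_by_topic(self) -> dict[str, float]:
        return dict(zip(self.topics, map(float, self.share_mse)))


def _fit_one(
    times: np.ndarray,
    values: np.ndarray,
    kind: str,
    order: int,
    tau: float | None,
) -> UtilityFunction:
    if kind == "fourier":
        assert tau is not None
        return fit_fourier(times, values, order=order, tau=tau)
    if kind == "polynomial":
        return fit_polynomial(times, values, degree=order)
    raise ValueError(f"unknown fit kind {kind!r}")


def _diagnose(
    shares: ShareSystem,
    utilities: Sequence[UtilityFunction],
    kind: str,
    order: int,
    tau: float | None,
) -> FitDiagnostics:
    f_hat = np.column_stack([u(shares.times) for u in utilities])
    S_hat, S0_hat = logit_shares(f_hat)
    fitted = ShareSystem(
        times=shares.times,
        topics=shares.topics,
        S=S_hat,
        S0=S0_hat,
        dates=shares.dates,
    )
    resid = shares.S - S_hat
    per_topic = np.mean(resid**2, axis=0)
    return FitDiagnostics(
        topics=shares.topics,
        share_mse=per_topic,
        residuals=resid,
        fitted_shares=fitted,
        kind=kind,
        order=order,
        tau=tau,
    )


def _loo_cv_score(times: np.ndarray, F: np.ndarray, order: int, tau: float) -> float:
    """Exact leave-one-out CV error of the order-n Fourier fit, summed over
    topics, using the hat-matrix identity e_loo = e / (1 - h_ii)."""
    X = _fourier_design(times, order, tau)
    H = X @ np.linalg.pinv(X)
    h = np.clip(np.diag(H), 0.0, 1.0 - 1e-8)
    resid = F - H @ F
    return float(np.mean((resid / (1.0 - h)[:, None]) ** 2))


def fit_utilities(
    shares: ShareSystem,
    *,
    kind: str = "fourier",
    order: int | None = None,
    tau_multiple: float = 1.0,
    auto_max_order: int = AUTO_MAX_ORDER,
) -> tuple[tuple[UtilityFunction, ...], FitDiagnostics]:
    """Fit one smooth utility function per topic of a share system.

    Parameters
    ----------
    shares : ShareSystem
        Observed shares; utilities are recovered via the exact logit inverse
        and then smoothed by the parametric fit.
    kind : {"fourier", "polynomial"}
        Basis family.
    order : int, optional
        Fourier order or polynomial degree. If omitted: polynomial degree
        defaults to 4; the Fourier order is chosen automatically by exact
        leave-one-out cross-validation on the utility samples (capped at
        ``auto_max_order``), which balances tracking regime shifts against
        interpolating observation noise.
    tau_multiple : float
        The Fourier half-period is ``tau_multiple`` times the observation
        span (the series are not assumed periodic inside the window).

    Returns
    -------
    (utilities, diagnostics)
        One fitted :class:`UtilityFunction` per topic, plus share-scale
        :class:`FitDiagnostics`.
    """
    samples = utilities_from_shares(shares)
    times = samples.times
    span = float(times[-1] - times[0])
    if span <= 0:
        raise ValueError("need a positive observation span")
    tau = tau_multiple * span if kind == "fourier" else None

    def fit_all(n: int) -> tuple[UtilityFunction, ...]:
        return tuple(
            _fit_one(times, samples.column(i), kind, n, tau)
            for i in range(len(shares.topics))
        )

    if order is not None:
        utilities = fit_all(order)
        return utilities, _diagnose(shares, utilities, kind, order, tau)
    if kind == "polynomial":
        utilities = fit_all(4)
        return utilities, _diagnose(shares, utilities, kind, 4, tau)

    # automatic order selection for the Fourier family (leave-one-out CV)
    assert tau is not None
    candidates = [
        n for n in range(1, auto_max_order + 1) if len(times) >= 2 * n + 1
    ]
    if not candidates:
        raise FitRankError(
            f"{len(times)} samples cannot support even an order-1 Fourier fit"
        )
    scores = {
        n: _loo_cv_score(times, samples.f, n, tau) for n in candidates
    }
    n_best = min(scores, key=scores.__getitem__)
    utilities = fit_all(n_best)
    return utilities, _diagnose(shares, utilities, kind, n_best, tau)
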