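"""Shares with an outside good, and the share <-> utility bijection.

The core discrete-choice identities: topic shares are the multinomial logit
of the topic utilities (with the outside option's utility normalized to 0),

    S_i = exp(f_i) / (1 + sum_j exp(f_j)),      S_0 = 1 / (1 + sum_j exp(f_j)),

and the inverse recovers log-odds utilities from observed shares,

    f_i = ln S_i - ln S_0.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AlignmentError
from .trends_io import AttentionSeries

__all__ = [
    "ShareSystem",
    "UtilitySamples",
    "to_shares",
    "logit_shares",
    "utilities_from_shares",
    "DEFAULT_COVERAGE",
    "DEFAULT_FLOOR",
]

#: Fraction of all search activity the tracked topics are assumed to cover.
#: Arbitrary gauge constant; downstream interaction coefficients are
#: invariant to it (see the alpha-invariance tests).
DEFAULT_COVERAGE = 0.5

#: Floor applied to raw relative-interest values before the share
#: conversion, so the logit never sees ln(0).
DEFAULT_FLOOR = 0.5

_SUM_TOL = 1e-12


@dataclass(eq=False)
class ShareSystem:
    """Joint trajectories of N topic shares plus the outside share.

    Attributes
    ----------
    times : numpy.ndarray
        Week indices (0, 1, 2, ... from the first observation).
    topics : tuple of str
        Topic labels, one per column of ``S``.
    S : numpy.ndarray, shape (T, N)
        Topic share trajectories, each value strictly in (0, 1).
    S0 : numpy.ndarray, shape (T,)
        Outside-share trajectory, strictly in (0, 1).
    dates : tuple of datetime.date, optional
        Calendar dates matching ``times``, carried for reporting only.
    """

    times: np.ndarray
    topics: tuple[str, ...]
    S: np.ndarray
    S0: np.ndarray
    dates: tuple[dt.date, ...] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.topics = tuple(self.topics)
        self.S = np.asarray(self.S, dtype=float)
        self.S0 = np.asarray(self.S0, dtype=float)
        T, N = self.S.shape
        if len(self.topics) != N:
            raise ValueError(f"{len(self.topics)} topics for {N} share columns")
        if self.times.shape != (T,) or self.S0.shape != (T,):
            raise ValueError("times, S and S0 must share the time dimension")
        if np.any(self.S <= 0.0) or np.any(self.S >= 1.0):
            raise ValueError("topic shares must be strictly inside (0, 1)")
        if np.any(self.S0 <= 0.0) or np.any(self.S0 >= 1.0):
            raise ValueError("outside share must be strictly inside (0, 1)")
        total = self.S.sum(axis=1) + self.S0
        if np.max(np.abs(total - 1.0)) > _SUM_TOL:
            raise ValueError(
                "shares must sum to 1 at every time point "
                f"(max deviation {np.max(np.abs(total - 1.0)):.3e})"
            )

    @property
    def n_topics(self) -> int:
        return self.S.shape[1]

    def __len__(self) -> int:
        return self.S.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ShareSystem):
            return NotImplemented
        return (
            self.topics == other.topics
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.S, other.S)
            and np.array_equal(self.S0, other.S0)
        )


@dataclass(eq=False)
class UtilitySamples:
    """Discrete utility values (log-odds vs. the outside search) per topic."""

    times: np.ndarray
    topics: tuple[str, ...]
    f: np.ndarray  # (T, N)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.topics = tuple(self.topics)
        self.f = np.asarray(self.f, dtype=float)
        if self.f.ndim != 2 or self.f.shape != (len(self.times), len(self.topics)):
            raise ValueError("f must have shape (len(times), len(topics))")
        if not np.all(np.isfinite(self.f)):
            raise ValueError("utility samples must be finite")

    def column(self, i: int) -> np.ndarray:
        return self.f[:, i]


def to_shares(
    series: Sequence[AttentionSeries],
    coverage: float = DEFAULT_COVERAGE,
    *,
    floor: float = DEFAULT_FLOOR,
) -> ShareSystem:
    """Convert relative-interest series into a share system with outside good.

    At each week the topic values are normalized within the panel and scaled
    by the coverage constant ``alpha``::

        S_i(t) = alpha * v_i(t) / sum_j v_j(t),        S_0(t) = 1 - alpha

    Parameters
    ----------
    series : sequence of AttentionSeries
        All series must share an identical time axis.
    coverage : float
        The constant ``alpha`` in (0, 1). A pure gauge choice: the
        interaction coefficients computed downstream do not depend on it.
    floor : float
        Values below ``floor`` (including exact zeros) are raised to it
        before the conversion so the subsequent logit is well defined.

    Returns
    -------
    ShareSystem
    """
    if not series:
        raise ValueError("no series given")
    if not 0.0 < coverage < 1.0:
        raise ValueError(f"coverage must be in (0, 1), got {coverage}")
    if floor <= 0.0:
        raise ValueError(f"floor must be positive, got {floor}")
    first = series[0]
    for s in series[1:]:
        if s.times != first.times:
            raise AlignmentError(
                f"series {s.topic!r} and {first.topic!r} are on different "
                "time axes"
            )
    v = np.column_stack([np.maximum(s.values, floor) for s in series])
    S = coverage * v / v.sum(axis=1, keepdims=True)
    T = v.shape[0]
    return ShareSystem(
        times=np.arange(T, dtype=float),
        topics=tuple(s.topic for s in series),
        S=S,
        S0=np.full(T, 1.0 - coverage),
        dates=first.times,
    )


def logit_shares(f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map utility values to shares via the multinomial logit.

    Parameters
    ----------
    f : array-like, shape (..., N)
        Utility values for the N topics (the outside option has utility 0).

    Returns
    -------
    S : numpy.ndarray, shape (..., N)
        Topic shares ``exp(f_i) / (1 + sum_j exp(f_j))``.
    S0 : numpy.ndarray, shape (...)
        Outside share ``1 / (1 + sum_j exp(f_j))``.

    Notes
    -----
    Computed through a shifted softmax including the outside option's zero
    utility, so the result is overflow-safe and sums to 1 exactly up to
    rounding.
    """
    f = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("utilities must be finite")
    z = np.concatenate([f, np.zeros(f.shape[:-1] + (1,))], axis=-1)
    z -= z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    return p[..., :-1], p[..., -1]


def utilities_from_shares(shares: ShareSystem) -> UtilitySamples:
    """Recover utility samples from a share system: ``f_i = ln S_i - ln S_0``.

    Exact inverse of the logit map; ``logit_shares(utilities_from_shares(S))``
    reproduces ``S`` to machine precision.
    """
    f = np.log(shares.S) - np.log(shares.S0)[:, None]
    return UtilitySamples(times=shares.times, topics=shares.topics, f=f)
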