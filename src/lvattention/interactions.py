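"""Pairwise competitive-role classification and interaction intensity.

The sign pattern of the two interaction coefficients determines the role::

    (+, +) competition      (+, -) predator-prey (positive topic = predator)
    (-, -) mutualism        (-, 0) commensalism   (+, 0) amensalism
    (0, 0) neutralism

with "0" meaning within ``eps`` of zero. In the LV equation the term
``-g_j S_j S_i`` shows that a positive-coefficient topic depresses every
competitor's share while a negative-coefficient topic boosts them, which is
why the positive topic is the predator in the mixed-sign case.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .lv_dynamics import CoefficientSet

__all__ = [
    "Role",
    "InteractionReport",
    "classify_pair",
    "classify_system",
    "intensity_profile",
    "detect_intensification",
    "adaptive_eps",
    "EPS_FRACTION",
    "EPS_QUANTILE",
]


class Role:
    """The six pairwise role labels."""

    COMPETITION = "competition"
    PREDATOR_PREY = "predator-prey"
    MUTUALISM = "mutualism"
    COMMENSALISM = "commensalism"
    AMENSALISM = "amensalism"
    NEUTRALISM = "neutralism"

    ALL = (
        COMPETITION,
        PREDATOR_PREY,
        MUTUALISM,
        COMMENSALISM,
        AMENSALISM,
        NEUTRALISM,
    )


#: Defaults for the scale-adaptive zero threshold: eps is EPS_FRACTION times
#: the EPS_QUANTILE-quantile of |g| over the whole run. The quantile is 1.0
#: (the maximum) rather than the median: on records where interactions are
#: weak most of the time the median of |g| is itself noise-level, and a
#: threshold tied to it cannot separate "no interaction" from fit ripple.
EPS_FRACTION = 0.15
EPS_QUANTILE = 1.0


def adaptive_eps(
    g: np.ndarray,
    fraction: float = EPS_FRACTION,
    quantile: float = EPS_QUANTILE,
) -> float:
    """Scale-adaptive zero threshold from the coefficient magnitudes."""
    g = np.asarray(g, dtype=float)
    if g.size == 0:
        raise ValueError("cannot derive eps from an empty coefficient grid")
    return float(fraction * np.quantile(np.abs(g), quantile))


def _sign(g: float, eps: float) -> int:
    if g > eps:
        return 1
    if g < -eps:
        return -1
    return 0


def classify_pair(
    g_a: float, g_b: float, eps: float
) -> tuple[str, int | None]:
    """Classify one topic pair from its two coefficient values.

    Parameters
    ----------
    g_a, g_b : float
        Interaction coefficients of topics A and B at one instant.
    eps : float
        Zero threshold; ``|g| <= eps`` counts as no interaction.

    Returns
    -------
    (role, predator)
        Role label, plus ``0`` (topic A) or ``1`` (topic B) identifying the
        predator when the role is predator-prey, else ``None``. For
        commensalism/amensalism the convention is symmetric in the labels,
        so no identity is attached.
    """
    if eps < 0:
        raise ValueError(f"eps must be >= 0, got {eps}")
    sa, sb = _sign(g_a, eps), _sign(g_b, eps)
    if sa == 1 and sb == 1:
        return Role.COMPETITION, None
    if sa == -1 and sb == -1:
        return Role.MUTUALISM, None
    if {sa, sb} == {1, -1}:
        return Role.PREDATOR_PREY, (0 if sa == 1 else 1)
    if sa == 0 and sb == 0:
        return Role.NEUTRALISM, None
    if -1 in (sa, sb):  # one negative, one zero
        return Role.COMMENSALISM, None
    return Role.AMENSALISM, None  # one positive, one zero


@dataclass(eq=False)
class InteractionReport:
    """Per-time pairwise role labels, coefficients and interaction intensity.

    Attributes
    ----------
    times : numpy.ndarray, shape (T,)
        Week grid.
    topics : tuple of str
    pairs : tuple of (int, int)
        Unordered topic-index pairs, i < j.
    roles : numpy.ndarray of str, shape (T, P)
    predators : numpy.ndarray of str, shape (T, P)
        Predator topic label where the role is predator-prey, else "".
    g : numpy.ndarray, shape (T, N)
        The coefficient values the labels were derived from.
    intensity : numpy.ndarray, shape (T,)
        ``sum_i |g_i(t)|`` over all topics (per week).
    eps : float
        Zero threshold used.
    """

    times: np.ndarray
    topics: tuple[str, ...]
    pairs: tuple[tuple[int, int], ...]
    roles: np.ndarray
    predators: np.ndarray
    g: np.ndarray
    intensity: np.ndarray
    eps: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.topics = tuple(self.topics)
        self.pairs = tuple(tuple(p) for p in self.pairs)
        self.roles = np.asarray(self.roles, dtype=object)
        self.predators = np.asarray(self.predators, dtype=object)
        self.g = np.asarray(self.g, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        T, P = len(self.times), len(self.pairs)
        if self.roles.shape != (T, P) or self.predators.shape != (T, P):
            raise ValueError("roles/predators must have shape (T, n_pairs)")
        bad = set(np.unique(self.roles)) - set(Role.ALL)
        if bad:
            raise ValueError(f"unknown role labels {sorted(bad)}")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be >= 0")
        pp = self.roles == Role.PREDATOR_PREY
        if np.any((self.predators != "") != pp):
            raise ValueError(
                "predator identity must be present iff role is predator-prey"
            )

    def pair_labels(self) -> tuple[str, ...]:
        return tuple(f"{self.topics[i]}|{self.topics[j]}" for i, j in self.pairs)

    def role_counts(self, t_slice: slice | None = None) -> Counter:
        """Histogram of role labels over (a slice of) the grid."""
        block = self.roles if t_slice is None else self.roles[t_slice]
        return Counter(block.ravel().tolist())

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (week, pair)."""
        records = []
        for k, (i, j) in enumerate(self.pairs):
            for n, t in enumerate(self.times):
                records.append(
                    {
                        "week": t,
                        "topic_a": self.topics[i],
                        "topic_b": self.topics[j],
                        "g_a": self.g[n, i],
                        "g_b": self.g[n, j],
                        "role": self.roles[n, k],
                        "predator": self.predators[n, k],
                        "intensity": self.intensity[n],
                        "eps": self.eps,
                    }
                )
        return pd.DataFrame.from_records(records)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "InteractionReport":
        """Rebuild a report from :meth:`to_frame` output (lossless)."""
        if frame.empty:
            raise ValueError("empty report table")
        times = np.asarray(sorted(frame["week"].unique()), dtype=float)
        topics: list[str] = []
        for col in ("topic_a", "topic_b"):
            for name in frame[col]:
                if name not in topics:
                    topics.append(name)
        index = {name: i for i, name in enumerate(topics)}
        pair_keys = list(
            dict.fromkeys(zip(frame["topic_a"], frame["topic_b"]))
        )
        pairs = tuple((index[a], index[b]) for a, b in pair_keys)
        T, P, N = len(times), len(pairs), len(topics)
        roles = np.empty((T, P), dtype=object)
        predators = np.empty((T, P), dtype=object)
        g = np.full((T, N), np.nan)
        intensity = np.full(T, np.nan)
        t_pos = {t: n for n, t in enumerate(times)}
        p_pos = {key: k for k, key in enumerate(pair_keys)}
        for row in frame.itertuples(index=False):
            n = t_pos[float(row.week)]
            k = p_pos[(row.topic_a, row.topic_b)]
            roles[n, k] = row.role
            predators[n, k] = str(row.predator)
            i, j = pairs[k]
            g[n, i] = row.g_a
            g[n, j] = row.g_b
            intensity[n] = row.intensity
        return cls(
            times=times,
            topics=tuple(topics),
            pairs=pairs,
            roles=roles,
            predators=predators,
            g=g,
            intensity=intensity,
            eps=float(frame["eps"].iloc[0]),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionReport):
            return NotImplemented
        return (
            self.topics == other.topics
            and self.pairs == other.pairs
            and self.eps == other.eps
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.roles, other.roles)
            and np.array_equal(self.predators, other.predators)
            and np.array_equal(self.g, other.g)
            and np.array_equal(self.intensity, other.intensity)
        )


def intensity_profile(coeffs: CoefficientSet, times: np.ndarray) -> np.ndarray:
    """Interaction intensity ``sum_i |g_i(t)|`` on a time grid."""
    return np.abs(coeffs.values(times)).sum(axis=1)


def _majority_smooth(roles: np.ndarray, window: int) -> np.ndarray:
    """Majority vote over a centered window per pair; ties keep the original."""
    T, P = roles.shape
    half = window // 2
    out = roles.copy()
    for k in range(P):
        for n in range(T):
            lo, hi = max(0, n - half), min(T, n + half + 1)
            counts = Counter(roles[lo:hi, k].tolist())
            label, votes = counts.most_common(1)[0]
            if votes > (hi - lo) / 2:
                out[n, k] = label
    return out


def classify_system(
    coeffs: CoefficientSet,
    times: np.ndarray,
    eps: float | None = None,
    *,
    smooth_weeks: int = 0,
) -> InteractionReport:
    """Classify every unordered topic pair at every grid point.

    Parameters
    ----------
    coeffs : CoefficientSet
    times : array-like
        Evaluation grid (weeks); must be non-empty.
    eps : float, optional
        Zero threshold. Defaults to the scale-adaptive value from
        :func:`adaptive_eps` over the evaluated coefficients.
    smooth_weeks : int
        Optional majority-vote smoothing window (off when 0) to suppress
        label flicker near sign crossings.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("empty time grid")
    g = coeffs.values(times)
    if eps is None:
        eps = adaptive_eps(g)
    N = coeffs.n_topics
    pairs = tuple((i, j) for i in range(N) for j in range(i + 1, N))
    T, P = len(times), len(pairs)
    roles = np.empty((T, P), dtype=object)
    predators = np.empty((T, P), dtype=object)
    for k, (i, j) in enumerate(pairs):
        for n in range(T):
            role, pred = classify_pair(g[n, i], g[n, j], eps)
            roles[n, k] = role
            predators[n, k] = (
                "" if pred is None else coeffs.topics[(i, j)[pred]]
            )
    if smooth_weeks:
        roles = _majority_smooth(roles, smooth_weeks)
        # predator identity must track the (possibly smoothed) labels
        for k, (i, j) in enumerate(pairs):
            for n in range(T):
                if roles[n, k] == Role.PREDATOR_PREY:
                    if predators[n, k] == "":
                        predators[n, k] = coeffs.topics[
                            i if g[n, i] >= g[n, j] else j
                        ]
                else:
                    predators[n, k] = ""
    return InteractionReport(
        times=times,
        topics=coeffs.topics,
        pairs=pairs,
        roles=roles,
        predators=predators,
        g=g,
        intensity=np.abs(g).sum(axis=1),
        eps=float(eps),
    )


def detect_intensification(intensity: np.ndarray, window: int) -> int:
    """Changepoint index maximizing trailing-/leading-window mean intensity.

    Scans every index ``k`` with a full ``window`` on both sides and returns
    the one maximizing ``mean(x[k:k+window]) / mean(x[k-window:k])``; ties
    break toward the earliest index. On flat series every ratio is 1 and the
    earliest admissible index is returned (degenerate but documented).
    """
    x = np.asarray(intensity, dtype=float)
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if len(x) <= 2 * window:
        raise ValueError(
            f"series of length {len(x)} too short for window {window} "
            "(need length > 2 * window)"
        )
    if np.any(x < 0):
        raise ValueError("intensity must be >= 0")
    tiny = np.finfo(float).tiny
    best_k, best_ratio = -1, -np.inf
    for k in range(window, len(x) - window + 1):
        lead = x[k - window : k].mean()
        trail = x[k : k + window].mean()
        ratio = trail / max(lead, tiny)
        if ratio > best_ratio:
            best_k, best_ratio = k, ratio
    return best_k
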