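"""Trends-like synthetic weekly series from known ground-truth utilities.

Generates multi-topic relative-interest data with a known regime structure
(e.g. weak interactions early, a predator plus mutualists late), so every
pipeline stage can be tested end to end without any download: utilities are
built per regime and blended smoothly at regime boundaries, shares follow
the closed-form logit, and the 0-100 observation scale is produced by joint
normalization so exactly one cell equals 100, as in a Trends multi-topic
comparison.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .lv_dynamics import CoefficientSet, solve_shares
from .share_model import ShareSystem
from .trends_io import AttentionSeries
from .utility_fit import FourierUtility, PolynomialUtility, UtilityFunction

__all__ = [
    "Regime",
    "SyntheticScenario",
    "SyntheticTruth",
    "BlendedUtility",
    "generate",
    "trendsify",
    "pandemic_preset",
    "scenario_to_dict",
    "scenario_from_dict",
    "RAMP_WEEKS",
]

#: Width (weeks) of the smooth ramp blending adjacent regimes. The quintic
#: smootherstep used keeps the blended utilities C^2.
RAMP_WEEKS = 2.0

_DEFAULT_START_DATE = dt.date(2019, 5, 5)


@dataclass(frozen=True)
class Regime:
    """One regime: a start week and one utility function per topic."""

    start: float
    utilities: tuple[UtilityFunction, ...]


@dataclass(frozen=True)
class SyntheticScenario:
    """Generator configuration: regimes, span, noise, seed.

    ``coverage`` records the share-conversion constant a downstream analysis
    is expected to use; it does not affect the generated observations.
    """

    topics: tuple[str, ...]
    regimes: tuple[Regime, ...]
    span: int = 52
    noise_sd: float = 0.0
    seed: int = 0
    round_to_int: bool = True
    coverage: float = 0.5
    area: str = "synthetic"
    start_date: dt.date = _DEFAULT_START_DATE

    def __post_init__(self) -> None:
        object.__setattr__(self, "topics", tuple(self.topics))
        object.__setattr__(self, "regimes", tuple(self.regimes))
        if len(self.topics) < 2:
            raise ValueError("need at least 2 topics")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.regimes:
            raise ValueError("need at least one regime")
        starts = [r.start for r in self.regimes]
        if starts[0] != 0:
            raise ValueError("first regime must start at week 0")
        for a, b in zip(starts, starts[1:]):
            if b <= a:
                raise ValueError(
                    f"regime starts must be strictly increasing, got {starts}"
                )
        if starts[-1] >= self.span:
            raise ValueError("regime starts must lie within [0, span)")
        for r in self.regimes:
            if len(r.utilities) != len(self.topics):
                raise ValueError(
                    "every regime needs one utility per topic"
                )

    @property
    def changepoints(self) -> tuple[float, ...]:
        return tuple(r.start for r in self.regimes[1:])


def _smootherstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u**3 * (10.0 - 15.0 * u + 6.0 * u**2)


def _smootherstep_deriv(u: np.ndarray) -> np.ndarray:
    inside = (u > 0.0) & (u < 1.0)
    uu = np.clip(u, 0.0, 1.0)
    return np.where(inside, 30.0 * uu**2 * (1.0 - uu) ** 2, 0.0)


class BlendedUtility(UtilityFunction):
    """Piecewise utilities blended C^2-smoothly across regime boundaries.

    Between regimes the function cross-fades over a ramp of ``RAMP_WEEKS``
    centered on the boundary, so the result stays twice continuously
    differentiable as the share model requires.
    """

    kind = "blended"

    def __init__(
        self,
        pieces: Sequence[UtilityFunction],
        starts: Sequence[float],
        ramp: float = RAMP_WEEKS,
    ) -> None:
        if len(pieces) != len(starts):
            raise ValueError("one start per piece required")
        self.pieces = tuple(pieces)
        self.starts = tuple(float(s) for s in starts)
        self.ramp = float(ramp)

    def _weights(self, t: np.ndarray) -> list[np.ndarray]:
        return [
            _smootherstep((t - s) / self.ramp + 0.5) for s in self.starts[1:]
        ]

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        out = np.asarray(self.pieces[0](t), dtype=float).copy()
        for k, w in enumerate(self._weights(t), start=1):
            out = out + w * (
                np.asarray(self.pieces[k](t), float)
                - np.asarray(self.pieces[k - 1](t), float)
            )
        return out if out.shape else float(out)

    def derivative(self) -> "_BlendedDerivative":
        return _BlendedDerivative(self)


class _BlendedDerivative:
    """Exact analytic derivative of a :class:`BlendedUtility` (callable)."""

    def __init__(self, parent: BlendedUtility) -> None:
        self._p = parent
        self._piece_derivs = [p.derivative() for p in parent.pieces]

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        p = self._p
        t = np.asarray(t, dtype=float)
        out = np.asarray(self._piece_derivs[0](t), dtype=float).copy()
        for k, s in enumerate(p.starts[1:], start=1):
            u = (t - s) / p.ramp + 0.5
            w = _smootherstep(u)
            dw = _smootherstep_deriv(u) / p.ramp
            gap = np.asarray(p.pieces[k](t), float) - np.asarray(
                p.pieces[k - 1](t), float
            )
            dgap = np.asarray(self._piece_derivs[k](t), float) - np.asarray(
                self._piece_derivs[k - 1](t), float
            )
            out = out + dw * gap + w * dgap
        return out if out.shape else float(out)


@dataclass(eq=False)
class SyntheticTruth:
    """Ground truth accompanying a generated data set."""

    utilities: tuple[BlendedUtility, ...]
    coeffs: CoefficientSet
    shares: ShareSystem
    changepoints: tuple[float, ...]


def blended_utilities(scenario: SyntheticScenario) -> tuple[BlendedUtility, ...]:
    """One blended truth utility per topic of the scenario."""
    starts = [r.start for r in scenario.regimes]
    return tuple(
        BlendedUtility(
            pieces=[r.utilities[i] for r in scenario.regimes], starts=starts
        )
        for i in range(len(scenario.topics))
    )


def trendsify(
    shares: ShareSystem,
    *,
    area: str = "synthetic",
    start_date: dt.date = _DEFAULT_START_DATE,
) -> list[AttentionSeries]:
    """Convert shares to the 0-100 relative-interest scale.

    Joint normalization: ``v_i(t) = 100 * S_i(t) / max_{j,u} S_j(u)``, so
    exactly one cell across all topics and weeks equals 100 (the Trends
    multi-topic convention). Share ratios ``S_i / S_j`` are preserved
    exactly.
    """
    peak = shares.S.max()
    if peak <= 0:
        raise ValueError("all-zero shares cannot be normalized")
    v = 100.0 * shares.S / peak
    if shares.dates is not None:
        dates = shares.dates
    else:
        dates = tuple(
            start_date + dt.timedelta(weeks=int(k))
            for k in range(len(shares.times))
        )
    return [
        AttentionSeries(
            topic=topic, area=area, times=dates, values=v[:, i]
        )
        for i, topic in enumerate(shares.topics)
    ]


def generate(
    scenario: SyntheticScenario,
) -> tuple[list[AttentionSeries], SyntheticTruth]:
    """Generate observed series plus ground truth for a scenario.

    The truth shares follow the closed-form logit of the blended utilities;
    observations are the jointly normalized 0-100 values plus iid Gaussian
    noise on the observation scale (truncated into [0, 100]) and optional
    integer rounding. Identical seeds give identical output.
    """
    utilities = blended_utilities(scenario)
    times = np.arange(scenario.span, dtype=float)
    shares = solve_shares(utilities, times, topics=scenario.topics)
    shares.dates = tuple(
        scenario.start_date + dt.timedelta(weeks=int(k))
        for k in range(scenario.span)
    )
    coeffs = CoefficientSet.from_utilities(
        utilities, scenario.topics, provenance="specified"
    )
    clean = trendsify(shares, area=scenario.area)
    rng = np.random.default_rng(scenario.seed)
    observed = []
    for s in clean:
        v = s.values
        if scenario.noise_sd > 0:
            v = v + rng.normal(0.0, scenario.noise_sd, size=v.shape)
        v = np.clip(v, 0.0, 100.0)
        if scenario.round_to_int:
            v = np.rint(v)
        observed.append(replace(s, values=v))
    truth = SyntheticTruth(
        utilities=utilities,
        coeffs=coeffs,
        shares=shares,
        changepoints=scenario.changepoints,
    )
    return observed, truth


#: Pre-changepoint utility levels (log-odds vs. the outside search) and
#: post-changepoint slopes (per week) of the pandemic-like preset. One topic
#: surges while the other three decline together, so late labels are
#: predator-prey against topic 1 and pairwise mutualism among the rest.
_PRESET_LEVELS = (-2.2, -1.7, -0.7, -1.2)
_PRESET_SLOPES = (0.30, -0.10, -0.10, -0.10)
_PRESET_CHANGE = 44.0


def pandemic_preset(
    *, noise_sd: float = 2.0, seed: int = 0
) -> SyntheticScenario:
    """A 52-week, 4-topic scenario with a week-44 regime change.

    Weeks 0-43: constant utilities (all interaction coefficients 0, weak
    interactions). Weeks 44-51: topic 1 gains utility strongly while topics
    2-4 lose it, so the interaction intensity explodes and topic 1 predates
    every other topic while topics 2-4 are in pairwise mutualism.
    """
    topics = ("unemployment", "symptoms", "news", "porn")
    early = Regime(
        start=0.0,
        utilities=tuple(
            PolynomialUtility(coef=[lvl]) for lvl in _PRESET_LEVELS
        ),
    )
    late = Regime(
        start=_PRESET_CHANGE,
        utilities=tuple(
            PolynomialUtility(coef=[lvl - slope * _PRESET_CHANGE, slope])
            for lvl, slope in zip(_PRESET_LEVELS, _PRESET_SLOPES)
        ),
    )
    return SyntheticScenario(
        topics=topics,
        regimes=(early, late),
        span=52,
        noise_sd=noise_sd,
        seed=seed,
        round_to_int=True,
    )


def _utility_to_dict(u: UtilityFunction) -> dict:
    if isinstance(u, FourierUtility):
        return {
            "kind": "fourier",
            "a0": u.a0,
            "a": u.a.tolist(),
            "b": u.b.tolist(),
            "tau": u.tau,
        }
    if isinstance(u, PolynomialUtility):
        return {"kind": "polynomial", "coef": u.coef.tolist()}
    raise TypeError(f"cannot serialize utility of type {type(u).__name__}")


def _utility_from_dict(d: Mapping) -> UtilityFunction:
    kind = d["kind"]
    if kind == "fourier":
        return FourierUtility(a0=d["a0"], a=d["a"], b=d["b"], tau=d["tau"])
    if kind == "polynomial":
        return PolynomialUtility(coef=d["coef"])
    raise ValueError(f"unknown utility kind {kind!r}")


def scenario_to_dict(scenario: SyntheticScenario) -> dict:
    """JSON/YAML-serializable form of a scenario."""
    return {
        "topics": list(scenario.topics),
        "span": scenario.span,
        "noise_sd": scenario.noise_sd,
        "seed": scenario.seed,
        "round_to_int": scenario.round_to_int,
        "coverage": scenario.coverage,
        "area": scenario.area,
        "start_date": scenario.start_date.isoformat(),
        "regimes": [
            {
                "start": r.start,
                "utilities": {
                    topic: _utility_to_dict(u)
                    for topic, u in zip(scenario.topics, r.utilities)
                },
            }
            for r in scenario.regimes
        ],
    }


def scenario_from_dict(d: Mapping) -> SyntheticScenario:
    """Inverse of :func:`scenario_to_dict`."""
    topics = tuple(d["topics"])
    regimes = tuple(
        Regime(
            start=float(r["start"]),
            utilities=tuple(
                _utility_from_dict(r["utilities"][t]) for t in topics
            ),
        )
        for r in d["regimes"]
    )
    return SyntheticScenario(
        topics=topics,
        regimes=regimes,
        span=int(d.get("span", 52)),
        noise_sd=float(d.get("noise_sd", 0.0)),
        seed=int(d.get("seed", 0)),
        round_to_int=bool(d.get("round_to_int", True)),
        coverage=float(d.get("coverage", 0.5)),
        area=str(d.get("area", "synthetic")),
        start_date=dt.date.fromisoformat(
            d.get("start_date", _DEFAULT_START_DATE.isoformat())
        ),
    )
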