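"""End-to-end orchestration: CSV -> shares -> utilities -> coefficients ->
roles -> diagnostics -> artifacts.

All outputs are deterministic for a fixed config and input; the canonical
artifacts are CSV/JSON tables, with plots as secondary output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .interactions import InteractionReport, classify_system, detect_intensification
from .lv_dynamics import CoefficientSet
from .share_model import (
    DEFAULT_COVERAGE,
    DEFAULT_FLOOR,
    ShareSystem,
    to_shares,
)
from .trends_io import AttentionSeries, read_trends_csv, write_report
from .utility_fit import FitDiagnostics, UtilityFunction, fit_utilities, mse

__all__ = ["RunConfig", "RunResult", "analyze_series", "run", "mse_table"]

#: Default window (weeks) for the intensification changepoint scan.
DEFAULT_WINDOW = 8


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible analysis run depends on."""

    input: str | Path | None = None
    outdir: str | Path | None = None
    coverage: float = DEFAULT_COVERAGE
    floor: float = DEFAULT_FLOOR
    fit_kind: str = "fourier"
    fit_order: int | None = None
    tau_multiple: float = 1.0
    eps: float | None = None
    smooth_weeks: int = 0
    window: int = DEFAULT_WINDOW
    seed: int = 0
    plots: bool = False
    preamble_lines: int | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["input"] = None if self.input is None else str(self.input)
        d["outdir"] = None if self.outdir is None else str(self.outdir)
        return d


@dataclass(eq=False)
class RunResult:
    """In-memory products of one analysis run."""

    config: RunConfig
    shares: ShareSystem
    utilities: tuple[UtilityFunction, ...]
    diagnostics: FitDiagnostics
    coeffs: CoefficientSet
    report: InteractionReport
    changepoint: int | None
    manifest: dict = field(default_factory=dict)


def mse_table(
    observed: ShareSystem, fitted: ShareSystem, label: str = "run"
) -> pd.DataFrame:
    """Per-topic share-scale MSE as a one-row table (columns = topics)."""
    if observed.topics != fitted.topics or len(observed) != len(fitted):
        raise ValueError("observed and fitted share systems do not align")
    row = {
        topic: mse(observed.S[:, i], fitted.S[:, i])
        for i, topic in enumerate(observed.topics)
    }
    return pd.DataFrame([row], index=[label])


def analyze_series(
    series: Sequence[AttentionSeries], config: RunConfig = RunConfig()
) -> RunResult:
    """Run the full analysis on in-memory series (no file I/O)."""
    shares = to_shares(series, config.coverage, floor=config.floor)
    utilities, diagnostics = fit_utilities(
        shares,
        kind=config.fit_kind,
        order=config.fit_order,
        tau_multiple=config.tau_multiple,
    )
    coeffs = CoefficientSet.from_utilities(utilities, shares.topics)
    report = classify_system(
        coeffs, shares.times, eps=config.eps, smooth_weeks=config.smooth_weeks
    )
    changepoint: int | None = None
    if len(report.intensity) > 2 * config.window:
        changepoint = detect_intensification(report.intensity, config.window)
    return RunResult(
        config=config,
        shares=shares,
        utilities=utilities,
        diagnostics=diagnostics,
        coeffs=coeffs,
        report=report,
        changepoint=changepoint,
    )


def _coefficient_frame(result: RunResult) -> pd.DataFrame:
    frame = pd.DataFrame(result.report.g, columns=list(result.shares.topics))
    frame.insert(0, "week", result.shares.times)
    frame["intensity"] = result.report.intensity
    return frame


def _share_frame(shares: ShareSystem) -> pd.DataFrame:
    frame = pd.DataFrame(shares.S, columns=list(shares.topics))
    frame.insert(0, "week", shares.times)
    frame["outside"] = shares.S0
    return frame


def _manifest(result: RunResult, input_path: Path | None) -> dict:
    import scipy

    manifest = {
        "config": result.config.to_dict(),
        "versions": {
            "lvattention": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
        "fit": {
            "kind": result.diagnostics.kind,
            "order": result.diagnostics.order,
            "tau": result.diagnostics.tau,
        },
        "eps": result.report.eps,
        "changepoint_week": result.changepoint,
        "topics": list(result.shares.topics),
    }
    if input_path is not None:
        manifest["input_sha256"] = hashlib.sha256(
            input_path.read_bytes()
        ).hexdigest()
    return manifest


def _write_plots(result: RunResult, plotdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plotdir.mkdir(parents=True, exist_ok=True)
    t = result.shares.times
    fitted = result.diagnostics.fitted_shares

    fig, axes = plt.subplots(
        len(result.shares.topics), 1, figsize=(8, 2.2 * len(result.shares.topics)),
        sharex=True,
    )
    for i, (ax, topic) in enumerate(zip(np.atleast_1d(axes), result.shares.topics)):
        ax.plot(t, result.shares.S[:, i], "o", ms=3, label="observed")
        ax.plot(t, fitted.S[:, i], "-", label="fitted")
        ax.set_ylabel(topic)
    np.atleast_1d(axes)[0].legend(loc="best")
    np.atleast_1d(axes)[-1].set_xlabel("week")
    fig.suptitle("Observed vs fitted shares")
    fig.savefig(plotdir / "fit.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(8, 4))
    for i, topic in enumerate(result.shares.topics):
        ax.plot(t, result.report.g[:, i], label=topic)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("week")
    ax.set_ylabel("interaction coefficient (per week)")
    ax.legend(loc="best")
    fig.savefig(plotdir / "coefficients.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(t, result.report.intensity)
    if result.changepoint is not None:
        ax.axvline(t[result.changepoint], color="r", ls="--", label="changepoint")
        ax.legend(loc="best")
    ax.set_xlabel("week")
    ax.set_ylabel("interaction intensity")
    fig.savefig(plotdir / "intensity.png", dpi=120, bbox_inches="tight")
    plt.close(fig)


def run(config: RunConfig) -> RunResult:
    """Execute a configured run end to end, writing artifacts to ``outdir``.

    Artifacts: ``report.csv`` (role table), ``coefficients.csv``,
    ``shares.csv`` / ``fitted_shares.csv``, ``mse.csv``, ``manifest.json``
    and (optionally) plots. Running twice with the same config and input
    produces identical files.
    """
    if config.input is None:
        raise ValueError("config.input must point to a Trends-style CSV")
    input_path = Path(config.input)
    try:
        series = read_trends_csv(
            input_path, preamble_lines=config.preamble_lines
        )
    except Exception as exc:
        raise type(exc)(f"[stage: read] {exc}") from exc

    result = analyze_series(series, config)
    result.manifest = _manifest(result, input_path)

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_report(result.report, outdir / "report.csv")
        _coefficient_frame(result).to_csv(
            outdir / "coefficients.csv", index=False, float_format="%.17g"
        )
        _share_frame(result.shares).to_csv(
            outdir / "shares.csv", index=False, float_format="%.17g"
        )
        _share_frame(result.diagnostics.fitted_shares).to_csv(
            outdir / "fitted_shares.csv", index=False, float_format="%.17g"
        )
        mse_table(result.shares, result.diagnostics.fitted_shares).to_csv(
            outdir / "mse.csv", float_format="%.17g"
        )
        (outdir / "manifest.json").write_text(
            json.dumps(result.manifest, indent=2, sort_keys=True) + "\n"
        )
        if config.plots:
            _write_plots(result, outdir / "plots")
    return result
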