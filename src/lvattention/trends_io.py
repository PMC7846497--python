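"""Read and write Google-Trends-style CSV files and the pipeline's report tables.

The input dialect is the "multiTimeline" CSV that Google Trends produces for a
multi-topic comparison: an optional two-line preamble (``Category: ...`` plus a
blank line), a header row ``Week,<topic>: (<area>),...`` and then one row per
week with integer cells, where sub-unit interest is exported as ``"<1"``.
"""

from __future__ import annotations

import csv
import datetime as dt
import re
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, TrendsParseError

if TYPE_CHECKING:  # pragma: no cover
    from .interactions import InteractionReport

__all__ = [
    "AttentionSeries",
    "read_trends_csv",
    "write_trends_csv",
    "write_report",
    "read_report",
    "SUB_UNIT_VALUE",
    "MIN_ROWS",
]

#: Replacement for "<1" cells: midpoint of the censored interval (0, 1).
SUB_UNIT_VALUE = 0.5

#: Minimum number of weekly rows required to fit any periodic model.
MIN_ROWS = 9

_WEEK = dt.timedelta(days=7)

_HEADER_RE = re.compile(r"^(?P<topic>.*?):\s*\((?P<area>.*)\)\s*$")


@dataclass(frozen=True, eq=False)
class AttentionSeries:
    """One topic's weekly relative-interest values (0-100 scale) in one area.

    Attributes
    ----------
    topic : str
        Free-text topic label.
    area : str
        Free-text geographic label.
    times : tuple of datetime.date
        Week-start dates, strictly increasing with constant 7-day spacing.
    values : numpy.ndarray
        Relative interest per week, dimensionless, all within [0, 100].
    """

    topic: str
    area: str
    times: tuple[dt.date, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(self.times))
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float)
        )
        if len(self.times) != len(self.values):
            raise ValueError(
                f"times ({len(self.times)}) and values ({len(self.values)}) "
                "must have the same length"
            )
        for prev, nxt in zip(self.times, self.times[1:]):
            if nxt - prev != _WEEK:
                raise ValueError(
                    f"times must be weekly and strictly increasing; "
                    f"gap of {(nxt - prev).days} days between {prev} and {nxt}"
                )
        if self.values.size and (
            self.values.min() < 0.0 or self.values.max() > 100.0
        ):
            raise ValueError("values must lie within [0, 100]")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def week_index(self) -> np.ndarray:
        """Integer week index 0, 1, 2, ... from the first observation."""
        return np.arange(len(self.times), dtype=float)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AttentionSeries):
            return NotImplemented
        return (
            self.topic == other.topic
            and self.area == other.area
            and self.times == other.times
            and np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:  # frozen but array-valued; hash on labels only
        return hash((self.topic, self.area, self.times))


def _parse_date(cell: str) -> dt.date | None:
    try:
        return dt.date.fromisoformat(cell.strip())
    except ValueError:
        return None


def _detect_header(rows: list[list[str]]) -> int:
    """Index of the header row: the first row with >= 2 cells that is
    immediately followed by a row whose first cell parses as a date."""
    for i, row in enumerate(rows[:-1]):
        if len(row) >= 2 and _parse_date(rows[i + 1][0]) is not None:
            return i
    raise TrendsParseError(
        "could not locate a header row followed by dated data rows"
    )


def read_trends_csv(
    path: str | Path,
    *,
    preamble_lines: int | None = None,
    sub_unit_value: float = SUB_UNIT_VALUE,
    min_rows: int = MIN_ROWS,
) -> list[AttentionSeries]:
    """Parse a Google-Trends-style multi-topic CSV into per-topic series.

    Parameters
    ----------
    path : path-like
        CSV file with one date column followed by one column per topic.
    preamble_lines : int, optional
        Number of leading lines to skip before the header. By default the
        header is auto-detected (Trends exports carry a 2-line preamble).
    sub_unit_value : float
        Value substituted for ``"<1"`` cells (default 0.5, the midpoint of
        the censored interval; avoids exact zeros that break the logit).
    min_rows : int
        Minimum number of data rows; fewer raises
        :class:`~lvattention.errors.InsufficientDataError`.

    Returns
    -------
    list of AttentionSeries
        One series per topic column, in column order.
    """
    text = Path(path).read_text(encoding="utf-8-sig")
    rows = [row for row in csv.reader(text.splitlines()) if row]
    if not rows:
        raise TrendsParseError(f"{path}: empty file")

    if preamble_lines is None:
        header_idx = _detect_header(rows)
    else:
        header_idx = preamble_lines
        if header_idx >= len(rows):
            raise TrendsParseError(f"{path}: no header after preamble")
    header = rows[header_idx]
    if len(header) < 2:
        raise TrendsParseError(
            f"{path}: header row must name a date column and >= 1 topic "
            f"columns, got {header!r}"
        )

    labels: list[tuple[str, str]] = []
    for cell in header[1:]:
        m = _HEADER_RE.match(cell)
        if m:
            labels.append((m.group("topic").strip(), m.group("area").strip()))
        else:
            labels.append((cell.strip(), ""))

    dates: list[dt.date] = []
    columns: list[list[float]] = [[] for _ in labels]
    for rownum, row in enumerate(rows[header_idx + 1 :], start=header_idx + 2):
        date = _parse_date(row[0])
        if date is None:
            raise TrendsParseError(
                f"{path}: row {rownum}: cannot parse date {row[0]!r}"
            )
        if len(row) != len(header):
            raise TrendsParseError(
                f"{path}: row {rownum}: expected {len(header)} cells, "
                f"got {len(row)}"
            )
        if dates and date <= dates[-1]:
            raise TrendsParseError(
                f"{path}: row {rownum}: duplicate or out-of-order date {date}"
            )
        if dates and date - dates[-1] != _WEEK:
            raise TrendsParseError(
                f"{path}: row {rownum}: skipped week between "
                f"{dates[-1]} and {date}"
            )
        dates.append(date)
        for col, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell == "<1":
                value = sub_unit_value
            else:
                try:
                    value = float(cell)
                except ValueError:
                    raise TrendsParseError(
                        f"{path}: row {rownum}, column {col + 2}: "
                        f"non-numeric cell {cell!r}"
                    ) from None
            columns[col].append(value)

    if len(dates) < min_rows:
        raise InsufficientDataError(
            f"{path}: {len(dates)} rows < {min_rows} required to fit "
            "any periodic model"
        )

    return [
        AttentionSeries(topic=topic, area=area, times=tuple(dates),
                        values=np.asarray(vals))
        for (topic, area), vals in zip(labels, columns)
    ]


def _format_value(x: float) -> str:
    if float(x).is_integer():
        return str(int(x))
    return format(x, ".17g")


def write_trends_csv(
    series: Sequence[AttentionSeries],
    path: str | Path,
    *,
    preamble: bool = True,
) -> None:
    """Write series back out in the Trends multi-topic CSV dialect.

    Inverse of :func:`read_trends_csv` up to the ``"<1"`` censoring (values
    are written verbatim, so the round trip is lossless).
    """
    if not series:
        raise ValueError("no series to write")
    first = series[0]
    for s in series[1:]:
        if s.times != first.times:
            raise ValueError(
                f"series {s.topic!r} is not on the same time axis as "
                f"{first.topic!r}"
            )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        if preamble:
            fh.write("Category: All categories\n\n")
        header = ["Week"] + [
            f"{s.topic}: ({s.area})" if s.area else s.topic for s in series
        ]
        writer.writerow(header)
        for i, date in enumerate(first.times):
            writer.writerow(
                [date.isoformat()] + [_format_value(s.values[i]) for s in series]
            )


def write_report(report: "InteractionReport", path: str | Path) -> None:
    """Write an interaction report as a flat CSV table.

    One row per (week, unordered topic pair) with the role label, the
    predator identity when applicable, the two coefficient values, the
    system-wide interaction intensity and the zero threshold used.
    """
    frame = report.to_frame()
    if frame.empty:
        raise ValueError("refusing to write an empty report")
    frame.to_csv(path, index=False, float_format="%.17g")


def read_report(path: str | Path) -> "InteractionReport":
    """Read a CSV written by :func:`write_report` back into a report."""
    from .interactions import InteractionReport

    frame = pd.read_csv(
        path, keep_default_na=False, float_precision="round_trip"
    )
    return InteractionReport.from_frame(frame)
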