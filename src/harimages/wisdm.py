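"""Reading and summarizing WISDM-style raw accelerometer streams.

The WISDM v1.1 raw format is a plain-text file with one sample per line::

    user_id,ActivityLabel,timestamp,x,y,z;

Timestamps are integer nanoseconds, accelerations are in m/s^2.  The trailing
semicolon is part of the dialect but files in the wild are inconsistent about
it, so it is tolerated and stripped.  Malformed lines (wrong field count,
non-numeric values) are skipped and counted, never fatal: raw dumps from
phones routinely contain truncated lines.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import math

import pandas as pd

#: The six activity labels used throughout the package, in canonical order.
DEFAULT_ACTIVITIES: tuple[str, ...] = (
    "Jogging",
    "Walking",
    "Upstairs",
    "Downstairs",
    "Sitting",
    "Standing",
)


@dataclass(frozen=True)
class RawSample:
    """One timestamped, labeled tri-axial accelerometer reading."""

    user_id: int
    activity: str
    timestamp: int
    ax: float
    ay: float
    az: float

    def values(self) -> tuple[float, float, float]:
        return (self.ax, self.ay, self.az)


@dataclass
class ParseReport:
    """Outcome of parsing a raw stream: line counts and anomalies."""

    n_lines: int = 0
    n_parsed: int = 0
    n_skipped: int = 0
    unknown_labels: dict[str, int] = field(default_factory=dict)
    skipped_lines: list[int] = field(default_factory=list)


def _parse_line(line: str) -> tuple[int, str, int, float, float, float] | None:
    line = line.strip()
    if line.endswith(";"):
        line = line[:-1]
    if not line:
        return None
    parts = line.split(",")
    if len(parts) != 6:
        return None
    try:
        user = int(parts[0])
        ts = int(parts[2])
        x, y, z = float(parts[3]), float(parts[4]), float(parts[5])
    except ValueError:
        return None
    if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(z)):
        return None
    return user, parts[1].strip(), ts, x, y, z


def read_raw(
    source: str | os.PathLike | IO[str] | Iterable[str],
    known_labels: Sequence[str] = DEFAULT_ACTIVITIES,
) -> tuple[list[RawSample], ParseReport]:
    """Parse a WISDM raw text stream into samples plus a parse report.

    Parameters
    ----------
    source
        Path, open text stream, or iterable of lines.
    known_labels
        Labels considered part of the activity set.  Samples with other
        labels are kept but tallied in ``report.unknown_labels``.

    Returns
    -------
    samples, report
        Samples in input order, and counts of parsed/skipped lines.
    """
    close = False
    if isinstance(source, (str, os.PathLike)):
        stream: Iterable[str] = open(source, "r", encoding="utf-8")
        close = True
    else:
        stream = source
    known = set(known_labels)
    samples: list[RawSample] = []
    report = ParseReport()
    try:
        for lineno, line in enumerate(stream, start=1):
            if not line.strip():
                continue
            report.n_lines += 1
            parsed = _parse_line(line)
            if parsed is None:
                report.n_skipped += 1
                report.skipped_lines.append(lineno)
                continue
            user, label, ts, x, y, z = parsed
            if label not in known:
                report.unknown_labels[label] = report.unknown_labels.get(label, 0) + 1
            samples.append(RawSample(user, label, ts, x, y, z))
            report.n_parsed += 1
    finally:
        if close:
            stream.close()  # type: ignore[union-attr]
    return samples, report


def write_raw(samples: Iterable[RawSample], dest: str | os.PathLike | IO[str]) -> None:
    """Write samples in the WISDM raw dialect (trailing semicolon included).

    Accelerations are written with three decimals, which round-trips through
    :func:`read_raw` at the format's stated precision.
    """
    close = False
    if isinstance(dest, (str, os.PathLike)):
        fh: IO[str] = open(dest, "w", encoding="utf-8")
        close = True
    else:
        fh = dest
    try:
        for s in samples:
            fh.write(
                f"{s.user_id},{s.activity},{s.timestamp},"
                f"{s.ax:.3f},{s.ay:.3f},{s.az:.3f};\n"
            )
    finally:
        if close:
            fh.close()


def eda_filter(samples: Sequence[RawSample]) -> tuple[list[RawSample], int]:
    """Remove samples whose three axes all read exactly zero.

    A resting accelerometer always senses gravity, so an all-zero reading is a
    sensor dropout rather than data.  The test is exact equality on the parsed
    values; nothing else is removed and order is preserved.

    Returns the kept samples and the number removed.
    """
    kept = [s for s in samples if not (s.ax == 0.0 and s.ay == 0.0 and s.az == 0.0)]
    return kept, len(samples) - len(kept)


@dataclass
class DatasetSummary:
    """Per-user/per-activity sample counts with per-activity totals.

    ``counts`` is a user x activity table; ``activity_totals`` and
    ``activity_percent`` describe the column margins (percentages of the
    grand total, summing to 100 within rounding).
    """

    counts: pd.DataFrame
    activity_totals: pd.Series
    activity_percent: pd.Series

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def summarize(
    samples: Sequence[RawSample],
    activities: Sequence[str] | None = None,
) -> DatasetSummary:
    """Tabulate sample counts per (user, activity).

    ``activities`` fixes the column order; by default the activities observed
    in the data are used in canonical order (known labels first).
    """
    if not samples:
        empty = pd.DataFrame()
        return DatasetSummary(empty, pd.Series(dtype=int), pd.Series(dtype=float))
    df = pd.DataFrame(
        {"user_id": [s.user_id for s in samples], "activity": [s.activity for s in samples]}
    )
    observed = set(df["activity"])
    if activities is None:
        cols = [a for a in DEFAULT_ACTIVITIES if a in observed]
        cols += sorted(observed - set(DEFAULT_ACTIVITIES))
    else:
        cols = list(activities)
    counts = (
        df.groupby(["user_id", "activity"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=cols, fill_value=0)
    )
    totals = counts.sum(axis=0)
    percent = 100.0 * totals / totals.sum()
    return DatasetSummary(counts, totals.astype(int), percent)
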