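"""Segmenting streams by activity and extracting fixed-length sliding windows.

A *segment* is a maximal run of consecutive samples sharing one (user,
activity) pair; windows are always taken inside a single segment so that each
window has exactly one ground-truth label.  With a window of ``nu`` samples
(``nu = delta_t * f``; 10 s at 20 Hz = 200 by default) slid with a given
stride, a segment of length D yields ``floor((D - nu)/stride) + 1`` complete
windows.  The ceiling-based count ``ceil((D - nu)/stride + 1)`` — which admits
one final partial window when the stride does not divide ``D - nu`` — is kept
as the separate :func:`sliding_window_count` for cross-checks; the extractor
itself emits complete windows only, since any padding policy for a partial
window would inject invented samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from harimages.wisdm import RawSample

#: Default window length in samples (10 s at 20 Hz).
DEFAULT_WINDOW = 200
#: Default stride between window starts, in samples.
DEFAULT_STRIDE = 10


@dataclass
class Segment:
    """A maximal single-activity run of one user's stream."""

    user_id: int
    activity: str
    data: np.ndarray  # (D, q) float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or len(self.data) < 1:
            raise ValueError("segment data must be a non-empty 2-D array")

    @property
    def n_samples(self) -> int:
        return len(self.data)


@dataclass
class Window:
    """A fixed-length slice of one segment, carrying the segment's label.

    ``origin`` records (user_id, segment index, start offset) for
    provenance; ``data`` is a verbatim contiguous slice of the segment.
    """

    data: np.ndarray  # (nu, q)
    label: str
    origin: tuple[int, int, int]

    @property
    def n_samples(self) -> int:
        return len(self.data)


def segment_stream(samples: Sequence[RawSample]) -> list[Segment]:
    """Split an ordered stream into maximal constant-(user, activity) runs.

    Concatenating the returned segments in order reproduces the input stream.
    """
    segments: list[Segment] = []
    run: list[RawSample] = []

    def flush() -> None:
        if run:
            data = np.array([[s.ax, s.ay, s.az] for s in run], dtype=float)
            segments.append(Segment(run[0].user_id, run[0].activity, data))
            run.clear()

    for s in samples:
        if run and (s.user_id != run[0].user_id or s.activity != run[0].activity):
            flush()
        run.append(s)
    flush()
    return segments


def slide_windows(
    segment: Segment,
    n_samples: int = DEFAULT_WINDOW,
    stride: int = DEFAULT_STRIDE,
    segment_index: int = 0,
) -> list[Window]:
    """Extract complete sliding windows from one segment.

    Windows start at offsets 0, stride, 2*stride, ... and only offsets with
    ``start + n_samples <= D`` are emitted; a segment shorter than the window
    yields an empty list.
    """
    if n_samples < 1:
        raise ValueError("window length must be >= 1")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    D = segment.n_samples
    out: list[Window] = []
    for start in range(0, D - n_samples + 1, stride):
        out.append(
            Window(
                data=segment.data[start : start + n_samples],
                label=segment.activity,
                origin=(segment.user_id, segment_index, start),
            )
        )
    return out


def sliding_window_count(D: int, n_samples: int, stride: int) -> int:
    """Ceiling-form window count for a recording of length ``D``.

    Evaluates ``ceil((D - nu)/stride + 1)`` exactly (integer arithmetic).
    When the stride does not divide ``D - nu`` this counts one final partial
    window that :func:`slide_windows` deliberately does not emit.
    """
    if n_samples < 1 or stride < 1:
        raise ValueError("window length and stride must be >= 1")
    if D < n_samples:
        raise ValueError(f"recording length {D} is shorter than the window {n_samples}")
    return -((-(D - n_samples)) // stride) + 1


def extract_windows(
    samples: Sequence[RawSample],
    n_samples: int = DEFAULT_WINDOW,
    stride: int = DEFAULT_STRIDE,
) -> list[Window]:
    """Segment a stream and slide windows over every segment."""
    windows: list[Window] = []
    for idx, seg in enumerate(segment_stream(samples)):
        windows.extend(slide_windows(seg, n_samples, stride, segment_index=idx))
    return windows
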