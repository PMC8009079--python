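"""HAR-Image construction: quantized 2D co-occurrence histograms per axis pair.

A window of ``nu`` tri-axial samples is turned into an image as follows.  For
each unordered pair of axes (for q = 3: (X,Y), (X,Z), (Y,Z), in that order),
every sample is a dot on the plane whose coordinates are the two axis values.
Both coordinates are quantized into ``mu`` bins over a *global* sensor range
(default [-20, 20] m/s^2, 40 bins, i.e. 1 m/s^2 per bin), and each cell of the
resulting mu x mu channel stores the number of dots that fell into it, capped
at 255 like an 8-bit gray level.  Channels are stacked and divided by 255, so
the classifier sees a (mu, mu, nC) array in [0, 1].

The quantization range is global rather than per-window: a convolutional
classifier needs fixed input geometry, and a shared range keeps pixel
intensities comparable across images.  With the range expressed on a 0-1
normalized scale, a quantization step Q corresponds to mu = 1/Q bins
(Q = 0.025 -> 40); :meth:`QuantizationSpec.from_step` instead applies
mu = eta/Q for a step given in sensor units.  Bins are half-open
[edge, edge + w) with a closed top bin; out-of-range values are clipped to
the border bins by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from harimages.windowing import Window


@dataclass(frozen=True)
class QuantizationSpec:
    """Global quantization grid for co-occurrence histograms.

    ``value_min``/``value_max`` span the sensor range eta; ``n_bins`` is the
    per-axis bin count mu, so each channel is mu x mu.  With clipping enabled
    (default) out-of-range values land in the border bins; otherwise they are
    an error.
    """

    value_min: float = -20.0
    value_max: float = 20.0
    n_bins: int = 40
    clip_out_of_range: bool = True

    def __post_init__(self) -> None:
        if self.value_max <= self.value_min:
            raise ValueError("value_max must exceed value_min")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")

    @property
    def bin_width(self) -> float:
        return (self.value_max - self.value_min) / self.n_bins

    @classmethod
    def from_step(
        cls,
        step: float,
        value_min: float = -20.0,
        value_max: float = 20.0,
        clip_out_of_range: bool = True,
    ) -> "QuantizationSpec":
        """Build a spec from a quantization step in sensor units (mu = eta/step)."""
        if step <= 0:
            raise ValueError("quantization step must be positive")
        eta = value_max - value_min
        n_bins = int(round(eta / step))
        if n_bins < 1:
            raise ValueError(f"step {step} larger than the value range {eta}")
        return cls(value_min, value_max, n_bins, clip_out_of_range)

    @classmethod
    def from_normalized_step(
        cls,
        step: float,
        value_min: float = -20.0,
        value_max: float = 20.0,
        clip_out_of_range: bool = True,
    ) -> "QuantizationSpec":
        """Build a spec from a step on the 0-1 normalized range (mu = 1/step)."""
        if not 0 < step <= 1:
            raise ValueError("normalized step must lie in (0, 1]")
        return cls(value_min, value_max, int(round(1.0 / step)), clip_out_of_range)


@dataclass
class HarImage:
    """A normalized multi-channel co-occurrence image with its label."""

    pixels: np.ndarray  # (mu, mu, nC) float32 in [0, 1]
    label: str
    origin: tuple[int, int, int] | None
    channel_pairs: tuple[tuple[int, int], ...]


def axis_pairs(q: int) -> list[tuple[int, int]]:
    """All unordered axis pairs (a, b) with a < b, lexicographic; nC = q(q-1)/2."""
    if q < 2:
        raise ValueError(f"need at least 2 axes to form a pair, got q={q}")
    return [(a, b) for a in range(q) for b in range(a + 1, q)]


def quantize(values: np.ndarray | float, spec: QuantizationSpec) -> np.ndarray | int:
    """Map sensor values to bin indices in [0, n_bins - 1].

    ``index = floor((v - value_min) / bin_width)`` with the top edge closed
    (v = value_max maps to the last bin).  Out-of-range values are clipped to
    the border bins, or rejected when ``spec.clip_out_of_range`` is off.
    """
    v = np.asarray(values, dtype=float)
    if not spec.clip_out_of_range:
        bad = (v < spec.value_min) | (v > spec.value_max)
        if np.any(bad):
            offending = v[bad].ravel()[0]
            raise ValueError(
                f"value {offending} outside quantization range "
                f"[{spec.value_min}, {spec.value_max}] and clipping is disabled"
            )
    idx = np.floor((v - spec.value_min) / spec.bin_width).astype(np.int64)
    idx = np.clip(idx, 0, spec.n_bins - 1)
    if np.isscalar(values):
        return int(idx)
    return idx


def _window_data(window: Window | np.ndarray) -> np.ndarray:
    data = window.data if isinstance(window, Window) else np.asarray(window, dtype=float)
    if data.ndim != 2 or len(data) < 1:
        raise ValueError("window must be a non-empty (n_samples, q) array")
    return data


def build_channel(
    window: Window | np.ndarray,
    pair: tuple[int, int],
    spec: QuantizationSpec,
) -> np.ndarray:
    """One mu x mu channel: co-occurrence counts for an axis pair, capped at 255.

    Cell (i, j) counts the samples whose first-axis value quantizes to i and
    second-axis value to j (first axis -> row, second -> column).  Before the
    cap the counts over a channel sum to the window length.
    """
    data = _window_data(window)
    rows = quantize(data[:, pair[0]], spec)
    cols = quantize(data[:, pair[1]], spec)
    mu = spec.n_bins
    flat = np.bincount(rows * mu + cols, minlength=mu * mu)
    return np.minimum(flat, 255).astype(np.int64).reshape(mu, mu)


def build_har_image(window: Window | np.ndarray, spec: QuantizationSpec) -> HarImage:
    """Assemble the full HAR-Image for one window: stacked channels over 255."""
    data = _window_data(window)
    pairs = tuple(axis_pairs(data.shape[1]))
    channels = [build_channel(data, pair, spec) for pair in pairs]
    pixels = (np.stack(channels, axis=-1) / 255.0).astype(np.float32)
    if isinstance(window, Window):
        label, origin = window.label, window.origin
    else:
        label, origin = "", None
    return HarImage(pixels, label, origin, pairs)


@dataclass
class ImageDataset:
    """A batch of HAR-Images ready for the classifier."""

    pixels: np.ndarray  # (N, mu, mu, nC) float32
    labels: np.ndarray  # (N,) str
    origins: np.ndarray  # (N, 3) int, -1 where unknown
    spec: QuantizationSpec
    channel_pairs: tuple[tuple[int, int], ...] = field(default=((0, 1), (0, 2), (1, 2)))

    def __len__(self) -> int:
        return len(self.pixels)

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


def build_image_dataset(
    windows: Sequence[Window],
    spec: QuantizationSpec,
) -> ImageDataset:
    """Build one HAR-Image per window, batched.

    Uses a single vectorized histogram pass over all windows; the result is
    identical to mapping :func:`build_har_image` over the windows.
    """
    mu = spec.n_bins
    if not windows:
        return ImageDataset(
            pixels=np.zeros((0, mu, mu, 3), dtype=np.float32),
            labels=np.array([], dtype=str),
            origins=np.zeros((0, 3), dtype=np.int64),
            spec=spec,
        )
    q = windows[0].data.shape[1]
    nu = windows[0].n_samples
    for w in windows:
        if w.data.shape != (nu, q):
            raise ValueError("all windows must share the same shape")
    pairs = tuple(axis_pairs(q))
    data = np.stack([w.data for w in windows])  # (N, nu, q)
    binned = quantize(data, spec)  # (N, nu, q)
    N = len(windows)
    base = np.arange(N, dtype=np.int64)[:, None] * (mu * mu)
    pixels = np.empty((N, mu, mu, len(pairs)), dtype=np.float32)
    for c, (a, b) in enumerate(pairs):
        flat = base + binned[:, :, a] * mu + binned[:, :, b]
        counts = np.bincount(flat.ravel(), minlength=N * mu * mu)
        channel = np.minimum(counts.reshape(N, mu, mu), 255)
        pixels[..., c] = channel / 255.0
    labels = np.array([w.label for w in windows])
    origins = np.array([w.origin for w in windows], dtype=np.int64)
    return ImageDataset(pixels, labels, origins, spec, pairs)


def save_images(dataset: ImageDataset, path: str) -> None:
    """Persist an image dataset to HDF5 (pixels, labels, origins, spec metadata)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("pixels", data=dataset.pixels, compression="gzip", compression_opts=4)
        f.create_dataset(
            "labels", data=np.asarray(dataset.labels, dtype="S32")
        )
        f.create_dataset("origins", data=dataset.origins)
        f.attrs["spec"] = json.dumps(
            {
                "value_min": dataset.spec.value_min,
                "value_max": dataset.spec.value_max,
                "n_bins": dataset.spec.n_bins,
                "clip_out_of_range": dataset.spec.clip_out_of_range,
            }
        )
        f.attrs["channel_pairs"] = json.dumps([list(p) for p in dataset.channel_pairs])


def load_images(path: str) -> ImageDataset:
    """Load an image dataset written by :func:`save_images`."""
    import h5py

    with h5py.File(path, "r") as f:
        spec = QuantizationSpec(**json.loads(f.attrs["spec"]))
        pairs = tuple(tuple(p) for p in json.loads(f.attrs["channel_pairs"]))
        return ImageDataset(
            pixels=f["pixels"][...],
            labels=f["labels"][...].astype(str),
            origins=f["origins"][...],
            spec=spec,
            channel_pairs=pairs,
        )
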