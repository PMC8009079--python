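"""Canned experiments at the package's standard benchmark sizes.

The full-scale evaluation recipe (10-fold cross-validation, 100 epochs at
batch size 5, ~10^5 images) takes hours on a laptop-class CPU; these helpers
define the package's desk-scale benchmark instead: a synthetic cohort of 36
users performing all six activities for 60 s each at 20 Hz, which yields
21,816 images under the default window/stride, evaluated with 3-fold
cross-validation at 10 epochs and batch size 32.  The reduced epoch count and
fold count trade statistical polish for runtime; on well-separated synthetic
classes the classifier saturates well before 10 epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from harimages.dcnn import ModelConfig, TrainingConfig
from harimages.evaluation import CrossValResult, cross_validate
from harimages.images import QuantizationSpec, build_image_dataset
from harimages.synthetic import ACTIVITIES, SyntheticDatasetSpec, generate_dataset
from harimages.windowing import extract_windows

#: Desk-scale benchmark cohort: users x activities x seconds at 20 Hz.
BENCHMARK_USERS = 36
BENCHMARK_SEGMENT_S = 60.0


@dataclass
class BenchmarkResult:
    """Outcome of the desk-scale synthetic cross-validation benchmark."""

    crossval: CrossValResult
    n_images: int
    class_counts: dict[str, int]


def benchmark_dataset(seed: int):
    """Generate the benchmark image set: 36 users x 6 activities x 60 s."""
    spec = SyntheticDatasetSpec(
        n_users=BENCHMARK_USERS, segment_duration_s=BENCHMARK_SEGMENT_S, seed=seed
    )
    samples = generate_dataset(spec)
    windows = extract_windows(samples)
    dataset = build_image_dataset(windows, QuantizationSpec())
    label_to_idx = {a: i for i, a in enumerate(ACTIVITIES)}
    y = np.array([label_to_idx[l] for l in dataset.labels])
    return dataset, y


def run_benchmark(
    seed: int,
    k: int = 3,
    epochs: int = 10,
    batch_size: int = 32,
) -> BenchmarkResult:
    """Run the scaled-down cross-validation benchmark end to end."""
    dataset, y = benchmark_dataset(seed)
    tc = TrainingConfig(epochs=epochs, batch_size=batch_size, seed=seed)
    result = cross_validate(
        dataset.pixels, y, ACTIVITIES, ModelConfig(), tc, k=k, seed=seed
    )
    return BenchmarkResult(result, len(dataset), dataset.class_counts())
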