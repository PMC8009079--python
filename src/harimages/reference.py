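"""Published WISDM evaluation results bundled for cross-checking.

The method this package implements was originally evaluated on the public
WISDM v1.1 accelerometer dataset (36 users, six activities, 20 Hz): 105,205
three-channel 40x40 co-occurrence images were classified in a pooled 10-fold
cross-validation.  The pooled confusion matrix reported for that evaluation
is reproduced here so the metric pipeline can be exercised against published
numbers without downloading the dataset or re-running hours of training.
"""

from __future__ import annotations

import numpy as np

from harimages.evaluation import ConfusionMatrix

#: Activity order used by the published evaluation (and this package).
WISDM_CLASSES: tuple[str, ...] = (
    "Jogging",
    "Walking",
    "Upstairs",
    "Downstairs",
    "Sitting",
    "Standing",
)

#: Number of 40x40x3 co-occurrence images per class in the WISDM evaluation
#: (window 200 samples, stride 10, after dropping all-zero sensor readings).
WISDM_IMAGE_COUNTS: dict[str, int] = {
    "Jogging": 32439,
    "Walking": 41719,
    "Upstairs": 11666,
    "Downstairs": 9428,
    "Sitting": 5562,
    "Standing": 4391,
}

#: Pooled 10-fold cross-validation confusion matrix of the published WISDM
#: evaluation; rows = actual class, columns = predicted, order WISDM_CLASSES.
#: Row sums equal WISDM_IMAGE_COUNTS.
WISDM_POOLED_CONFUSION: np.ndarray = np.array(
    [
        [32425, 7, 7, 0, 0, 0],
        [0, 41648, 27, 44, 0, 0],
        [37, 73, 11483, 73, 0, 0],
        [5, 58, 65, 9300, 0, 0],
        [0, 0, 1, 0, 5542, 19],
        [0, 0, 0, 0, 3, 4388],
    ],
    dtype=np.int64,
)


def reference_confusion() -> ConfusionMatrix:
    """The published pooled WISDM confusion matrix as a ConfusionMatrix."""
    return ConfusionMatrix(WISDM_POOLED_CONFUSION.copy(), WISDM_CLASSES)
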