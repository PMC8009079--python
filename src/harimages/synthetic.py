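"""Synthetic tri-axial accelerometer streams with WISDM-like structure.

Each activity is modeled as a static gravity orientation plus a small number
of sinusoidal oscillations and i.i.d. Gaussian noise, per axis.  This is a
deliberately simple signal model: it reproduces the *structure* real HAR data
has (per-class orientation, dominant step frequency, amplitude, noise floor)
without claiming biomechanical realism.  Axis semantics follow the
phone-in-front-pocket convention: X captures horizontal leg movement, Y the
vertical movement, Z forward/backward movement.

Default profiles give six well-separated classes: jogging is a high-amplitude
~2.5 Hz vertical oscillation, walking ~1.7 Hz with lower amplitude, stair
climbing is walking-like with opposite-sign forward (Z) gravity bias per
direction, and sitting/standing are static postures with distinct gravity
orientations (gravity mostly on Z when sitting, on Y when standing).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from harimages.wisdm import DEFAULT_ACTIVITIES, RawSample

#: Canonical activity set, in the order used for class indices everywhere.
ACTIVITIES: tuple[str, ...] = DEFAULT_ACTIVITIES

#: Nominal sensor saturation range in m/s^2.
SENSOR_RANGE: tuple[float, float] = (-20.0, 20.0)

_NS_PER_S = 1_000_000_000


@dataclass(frozen=True)
class Oscillation:
    """A single sinusoidal component on one axis.

    ``axis`` indexes (X, Y, Z) = (0, 1, 2); ``frequency_hz`` must stay below
    the Nyquist limit of the sampling rate; ``amplitude`` is in m/s^2.
    """

    axis: int
    frequency_hz: float
    amplitude: float
    phase: float = 0.0


@dataclass(frozen=True)
class ActivityProfile:
    """Signal model of one activity: gravity + oscillations + noise."""

    label: str
    gravity: tuple[float, float, float]
    oscillations: tuple[Oscillation, ...] = ()
    noise_sd: float = 0.0

    def validate(
        self,
        rate_hz: float,
        value_range: tuple[float, float] = SENSOR_RANGE,
    ) -> None:
        """Check Nyquist and no-systematic-clipping invariants."""
        if self.noise_sd < 0:
            raise ValueError(f"{self.label}: noise_sd must be >= 0")
        bound = min(abs(value_range[0]), abs(value_range[1]))
        peak = [abs(g) for g in self.gravity]
        for osc in self.oscillations:
            if not 0 <= osc.axis <= 2:
                raise ValueError(f"{self.label}: axis index {osc.axis} out of range")
            if osc.frequency_hz >= rate_hz / 2:
                raise ValueError(
                    f"{self.label}: oscillation at {osc.frequency_hz} Hz violates "
                    f"the Nyquist limit for rate {rate_hz} Hz"
                )
            peak[osc.axis] += abs(osc.amplitude)
        for axis, p in enumerate(peak):
            if p > bound:
                raise ValueError(
                    f"{self.label}: peak signal {p:.2f} m/s^2 on axis {axis} "
                    f"exceeds the sensor bound {bound:.2f} (systematic clipping)"
                )


def default_profiles() -> dict[str, ActivityProfile]:
    """The default per-activity signal models (all parameters overridable)."""
    g = 9.8
    return {
        "Jogging": ActivityProfile(
            "Jogging",
            gravity=(0.0, g, 0.0),
            oscillations=(
                Oscillation(axis=1, frequency_hz=2.5, amplitude=8.0),
                Oscillation(axis=0, frequency_hz=2.5, amplitude=3.0, phase=np.pi / 2),
            ),
            noise_sd=1.5,
        ),
        "Walking": ActivityProfile(
            "Walking",
            gravity=(0.0, g, 0.0),
            oscillations=(
                Oscillation(axis=1, frequency_hz=1.7, amplitude=3.5),
                Oscillation(axis=0, frequency_hz=1.7, amplitude=1.2, phase=np.pi / 2),
            ),
            noise_sd=0.8,
        ),
        "Upstairs": ActivityProfile(
            "Upstairs",
            gravity=(0.0, 9.2, 2.8),
            oscillations=(
                Oscillation(axis=1, frequency_hz=1.4, amplitude=2.2),
                Oscillation(axis=2, frequency_hz=1.4, amplitude=1.0, phase=np.pi / 3),
            ),
            noise_sd=0.8,
        ),
        "Downstairs": ActivityProfile(
            "Downstairs",
            gravity=(0.0, 9.2, -2.8),
            oscillations=(
                Oscillation(axis=1, frequency_hz=1.4, amplitude=4.2),
                Oscillation(axis=2, frequency_hz=1.4, amplitude=1.0, phase=np.pi / 3),
            ),
            noise_sd=0.8,
        ),
        "Sitting": ActivityProfile(
            "Sitting",
            gravity=(0.3, 3.0, 9.3),
            noise_sd=0.3,
        ),
        "Standing": ActivityProfile(
            "Standing",
            gravity=(0.0, g, 0.8),
            noise_sd=0.3,
        ),
    }


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Full description of a synthetic dataset; generation is a pure function of it."""

    n_users: int = 2
    profiles: Mapping[str, ActivityProfile] = field(default_factory=default_profiles)
    segment_duration_s: float = 10.0
    rate_hz: float = 20.0
    value_range: tuple[float, float] = SENSOR_RANGE
    seed: int = 0
    timestamp_jitter_ns: int = 0

    @property
    def samples_per_segment(self) -> int:
        n = self.segment_duration_s * self.rate_hz
        return int(round(n))

    def validate(self) -> None:
        if self.n_users < 1:
            raise ValueError("n_users must be positive")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        n = self.segment_duration_s * self.rate_hz
        if n <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError(
                "segment_duration_s * rate_hz must be a positive integer, "
                f"got {n!r}"
            )
        labels = list(self.profiles)
        if sorted(labels) != sorted(set(labels)):
            raise ValueError("duplicate activity labels in profiles")
        for label, profile in self.profiles.items():
            if profile.label != label:
                raise ValueError(f"profile key {label!r} != profile.label {profile.label!r}")
            profile.validate(self.rate_hz, self.value_range)


def generate_segment(
    profile: ActivityProfile,
    n_samples: int,
    rate_hz: float,
    seed: int,
    value_range: tuple[float, float] = SENSOR_RANGE,
) -> np.ndarray:
    """Generate one contiguous recording segment for a single activity.

    Returns an ``(n_samples, 3)`` float array: gravity + oscillations
    evaluated at each sample time + Gaussian noise, clipped to the sensor
    range.  Deterministic in ``seed``.
    """
    if n_samples <= 0:
        raise ValueError(f"n_samples must be positive, got {n_samples}")
    if rate_hz <= 0:
        raise ValueError(f"rate_hz must be positive, got {rate_hz}")
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / rate_hz
    data = np.tile(np.asarray(profile.gravity, dtype=float), (n_samples, 1))
    for osc in profile.oscillations:
        data[:, osc.axis] += osc.amplitude * np.sin(
            2 * np.pi * osc.frequency_hz * t + osc.phase
        )
    if profile.noise_sd > 0:
        data += rng.normal(0.0, profile.noise_sd, size=data.shape)
    return np.clip(data, value_range[0], value_range[1])


def _segment_seed(spec_seed: int, user_id: int, activity_index: int) -> int:
    ss = np.random.SeedSequence([spec_seed, user_id, activity_index])
    return int(ss.generate_state(1)[0]) % (2**31)


def generate_dataset(spec: SyntheticDatasetSpec) -> list[RawSample]:
    """Generate the full labeled stream described by ``spec``.

    For every user and every activity one contiguous segment is emitted, in
    profile order, with strictly increasing nanosecond timestamps per user at
    exact 1/rate spacing.  Per-(user, activity) sub-seeds are derived
    deterministically from ``spec.seed``, so the stream is a pure function of
    the spec.
    """
    spec.validate()
    n = spec.samples_per_segment
    step_ns = int(round(_NS_PER_S / spec.rate_hz))
    jitter_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2**31]))
    samples: list[RawSample] = []
    for user_id in range(1, spec.n_users + 1):
        ts = 0
        for act_idx, (label, profile) in enumerate(spec.profiles.items()):
            seg = generate_segment(
                profile, n, spec.rate_hz, _segment_seed(spec.seed, user_id, act_idx),
                spec.value_range,
            )
            for row in seg:
                t_out = ts
                if spec.timestamp_jitter_ns:
                    t_out += int(
                        jitter_rng.integers(0, spec.timestamp_jitter_ns)
                    )
                samples.append(
                    RawSample(user_id, label, t_out, float(row[0]), float(row[1]), float(row[2]))
                )
                ts += step_ns
    return samples


def with_profile(
    spec: SyntheticDatasetSpec, profile: ActivityProfile
) -> SyntheticDatasetSpec:
    """Return a copy of ``spec`` with one activity profile replaced."""
    profiles = dict(spec.profiles)
    profiles[profile.label] = profile
    return replace(spec, profiles=profiles)
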