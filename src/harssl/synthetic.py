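"""Seeded synthetic tri-axial accelerometer streams and feature-space blobs.

The signal generator emulates a wrist-worn accelerometer at 20 Hz over three
activity regimes:

* sedentary — a gravity-dominated, near-constant signal with only a slow
  postural drift and small sensor noise (sitting/standing);
* moderately active — a walking-like oscillation around 1.7 Hz of moderate
  amplitude;
* active — a jogging-like oscillation around 2.8 Hz of large amplitude with
  a first harmonic.

Episodes are generated independently (random phase per episode) and
concatenated in a blocked, interleaved or randomly shuffled class order, so
the downstream windowing recovers exactly one activity per episode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import ACTIVITY_CLASSES
from .exceptions import ConfigError
from .preprocess import DEFAULT_SAMPLING_RATE_HZ, DEFAULT_WINDOW_LEN, RawSeries

ARRIVAL_PATTERNS = ("blocked", "interleaved", "random")


@dataclass
class ClassSignal:
    """Per-class signal recipe, in g-units.

    ``baseline`` is the gravity vector seen by the wrist at rest;
    oscillation is applied along ``direction`` at ``frequency_hz`` with the
    given amplitude (plus an optional first harmonic); white Gaussian noise
    of sd ``noise_sd`` is added per axis.
    """

    baseline: tuple[float, float, float]
    amplitude: float
    frequency_hz: float
    noise_sd: float
    harmonic_amplitude: float = 0.0
    direction: tuple[float, float, float] = (1.0, 0.6, 0.3)


def default_class_signals() -> dict[str, ClassSignal]:
    """The default three-regime recipe (separable but overlapping)."""
    return {
        "sedentary": ClassSignal(
            baseline=(0.35, 0.45, 0.82),
            amplitude=0.03,
            frequency_hz=0.3,
            noise_sd=0.0015,
        ),
        "moderately_active": ClassSignal(
            baseline=(0.35, 0.45, 0.82),
            amplitude=0.35,
            frequency_hz=1.7,
            noise_sd=0.04,
        ),
        "active": ClassSignal(
            baseline=(0.35, 0.45, 0.82),
            amplitude=0.9,
            frequency_hz=2.8,
            noise_sd=0.08,
            harmonic_amplitude=0.3,
        ),
    }


@dataclass
class SignalSpec:
    """Specification of a synthetic labelled accelerometer stream."""

    classes: dict[str, ClassSignal] = field(default_factory=default_class_signals)
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    episode_len: int = DEFAULT_WINDOW_LEN
    episodes_per_class: int = 500
    arrival: str = "random"
    seed: int = 0

    def validate(self) -> None:
        if not self.classes:
            raise ConfigError("SignalSpec needs at least one class")
        if self.arrival not in ARRIVAL_PATTERNS:
            raise ConfigError(f"arrival must be one of {ARRIVAL_PATTERNS}")
        if self.sampling_rate_hz <= 0 or self.episode_len < 2:
            raise ConfigError("invalid sampling rate or episode length")
        if self.episodes_per_class < 1:
            raise ConfigError("episodes_per_class must be >= 1")
        nyquist = self.sampling_rate_hz / 2.0
        for name, cs in self.classes.items():
            if cs.frequency_hz >= nyquist:
                raise ConfigError(
                    f"class {name!r}: frequency must be below Nyquist ({nyquist} Hz)"
                )
            if cs.amplitude < 0 or cs.noise_sd < 0 or cs.harmonic_amplitude < 0:
                raise ConfigError(
                    f"class {name!r}: amplitudes and noise sd must be >= 0"
                )

    def interpolated(self, separation: float) -> "SignalSpec":
        """Shrink class differences toward the across-class mean recipe.

        ``separation`` = 1 returns the spec unchanged; 0 makes every class
        identical (a chance-level problem): baselines, amplitudes,
        frequencies and noise levels all move toward their across-class
        means.
        """
        s = float(separation)
        names = list(self.classes)
        mean_of = lambda attr: float(
            np.mean([getattr(self.classes[n], attr) for n in names])
        )
        mean_baseline = np.mean(
            [self.classes[n].baseline for n in names], axis=0
        )
        new = {}
        for n in names:
            cs = self.classes[n]
            new[n] = replace(
                cs,
                baseline=tuple(
                    mean_baseline + s * (np.asarray(cs.baseline) - mean_baseline)
                ),
                amplitude=mean_of("amplitude")
                + s * (cs.amplitude - mean_of("amplitude")),
                frequency_hz=mean_of("frequency_hz")
                + s * (cs.frequency_hz - mean_of("frequency_hz")),
                harmonic_amplitude=mean_of("harmonic_amplitude")
                + s * (cs.harmonic_amplitude - mean_of("harmonic_amplitude")),
                noise_sd=mean_of("noise_sd")
                + s * (cs.noise_sd - mean_of("noise_sd")),
            )
        return replace(self, classes=new)


def _episode_order(spec: SignalSpec, rng: np.random.Generator) -> list[str]:
    names = list(spec.classes)
    if spec.arrival == "blocked":
        order = [n for n in names for _ in range(spec.episodes_per_class)]
    elif spec.arrival == "interleaved":
        order = [n for _ in range(spec.episodes_per_class) for n in names]
    else:  # random
        order = [n for n in names for _ in range(spec.episodes_per_class)]
        rng.shuffle(order)
    return order


def _episode_samples(
    cs: ClassSignal, spec: SignalSpec, rng: np.random.Generator
) -> np.ndarray:
    w = spec.episode_len
    t = np.arange(w) / spec.sampling_rate_hz
    phase = rng.uniform(0.0, 2.0 * np.pi)
    d = np.asarray(cs.direction, dtype=float)
    d = d / np.linalg.norm(d)
    osc = cs.amplitude * np.sin(2 * np.pi * cs.frequency_hz * t + phase)
    if cs.harmonic_amplitude > 0:
        osc = osc + cs.harmonic_amplitude * np.sin(
            2 * np.pi * 2 * cs.frequency_hz * t + 2 * phase
        )
    xyz = np.asarray(cs.baseline, dtype=float)[None, :] + osc[:, None] * d[None, :]
    if cs.noise_sd > 0:
        xyz = xyz + rng.normal(0.0, cs.noise_sd, size=(w, 3))
    return xyz


def generate_signal(spec: SignalSpec) -> RawSeries:
    """Generate a labelled raw stream; deterministic per ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    order = _episode_order(spec, rng)
    blocks = [_episode_samples(spec.classes[name], spec, rng) for name in order]
    xyz = np.vstack(blocks)
    labels = np.asarray(
        [name for name in order for _ in range(spec.episode_len)], dtype=object
    )
    timestamps = np.arange(xyz.shape[0]) / spec.sampling_rate_hz
    return RawSeries(xyz=xyz, timestamps=timestamps, labels=labels)


@dataclass
class BlobSpec:
    """Per-class Gaussian blobs directly in the 6-D feature space, for
    exercising the SSL engine in isolation from signal preprocessing."""

    means: Mapping[str, Sequence[float]]
    covariances: Mapping[str, np.ndarray]
    points_per_class: int = 200
    seed: int = 0

    def validate(self) -> None:
        if not self.means:
            raise ConfigError("BlobSpec needs at least one class")
        if set(self.means) != set(self.covariances):
            raise ConfigError("means and covariances must cover the same classes")
        if self.points_per_class < 1:
            raise ConfigError("points_per_class must be >= 1")
        for name, cov in self.covariances.items():
            c = np.asarray(cov, dtype=float)
            if c.ndim != 2 or c.shape[0] != c.shape[1]:
                raise ConfigError(f"class {name!r}: covariance must be square")
            if not np.allclose(c, c.T, atol=1e-10):
                raise ConfigError(f"class {name!r}: covariance must be symmetric")
            if np.min(np.linalg.eigvalsh(c)) < -1e-10:
                raise ConfigError(
                    f"class {name!r}: covariance must be positive semi-definite"
                )


def isotropic_blob_spec(
    separation: float = 10.0,
    sigma: float = 1.0,
    points_per_class: int = 200,
    classes: Sequence[str] = ACTIVITY_CLASSES,
    n_features: int = 6,
    seed: int = 0,
) -> BlobSpec:
    """Convenience spec: classes spread along orthogonal axes at
    ``separation * sigma`` from the origin, isotropic covariance sigma^2 I."""
    means = {}
    for i, c in enumerate(classes):
        m = np.zeros(n_features)
        m[i % n_features] = separation * sigma
        means[c] = m
    covs = {c: (sigma**2) * np.eye(n_features) for c in classes}
    return BlobSpec(
        means=means,
        covariances=covs,
        points_per_class=points_per_class,
        seed=seed,
    )


def generate_blobs(spec: BlobSpec) -> tuple[np.ndarray, list[str]]:
    """Sample per-class multivariate-normal feature vectors.

    Returns the stacked (n, d) feature matrix and per-point class labels;
    deterministic per ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    X_parts: list[np.ndarray] = []
    labels: list[str] = []
    for name in spec.means:
        mean = np.asarray(spec.means[name], dtype=float)
        cov = np.asarray(spec.covariances[name], dtype=float)
        X_parts.append(
            rng.multivariate_normal(
                mean, cov, size=spec.points_per_class, method="cholesky"
            )
            if np.min(np.linalg.eigvalsh(cov)) > 1e-12
            else rng.multivariate_normal(mean, cov, size=spec.points_per_class)
        )
        labels.extend([name] * spec.points_per_class)
    return np.vstack(X_parts), labels
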