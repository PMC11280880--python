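"""Normalisation, windowing and feature extraction for tri-axial accelerometer streams.

A raw stream is normalised so every sample lies in [-1, +1], cut into
fixed-length episodes (default 40 samples = 2 s at 20 Hz), and each episode is
summarised by six features: the coefficient of variation and the mean-crossing
count of each axis.  The six features can optionally be reduced to their top
three principal components before clustering.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .exceptions import DegenerateDataError, InvalidInputError, NotTrainedError

#: guard below which a mean is treated as zero (coefficient of variation -> 0)
EPS_MEAN = 1e-8
#: guard below which a population standard deviation means "no movement"
EPS_SD = 1e-8

DEFAULT_SAMPLING_RATE_HZ = 20.0
DEFAULT_WINDOW_LEN = 40  # 2 s at 20 Hz

FEATURE_NAMES = ("cov_x", "cov_y", "cov_z", "mcr_x", "mcr_y", "mcr_z")

NORMALIZATION_MODES = ("per_sample_l2", "per_axis_maxabs")


@dataclass
class RawSeries:
    """A tri-axial acceleration time series.

    Parameters
    ----------
    xyz : ndarray of shape (n, 3)
        Acceleration samples (arbitrary units before normalisation).
    timestamps : ndarray of shape (n,), optional
        Sample times in seconds, strictly increasing.
    labels : sequence of length n, optional
        Per-sample ground-truth activity class (``None`` for unlabeled
        samples).
    """

    xyz: np.ndarray
    timestamps: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise InvalidInputError(
                f"xyz must have shape (n, 3), got {self.xyz.shape}"
            )
        if self.xyz.shape[0] < 1:
            raise InvalidInputError("series must contain at least one sample")
        if self.timestamps is not None:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.shape != (self.xyz.shape[0],):
                raise InvalidInputError("timestamps length must match samples")
            if np.any(np.diff(self.timestamps) <= 0):
                raise InvalidInputError("timestamps must strictly increase")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape != (self.xyz.shape[0],):
                raise InvalidInputError("labels length must match samples")

    def __len__(self) -> int:
        return self.xyz.shape[0]


@dataclass
class Episode:
    """One fixed-length window of (normalised) samples — the unit of
    featurisation and classification."""

    samples: np.ndarray  # (window_len, 3)
    index: int
    true_label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise InvalidInputError("episode samples must have shape (w, 3)")


def normalize(raw: RawSeries, mode: str = "per_sample_l2") -> RawSeries:
    """Scale a raw series so every component lies in [-1, +1].

    ``per_sample_l2`` (default) divides each 3-vector sample by its Euclidean
    norm; zero-norm samples map to the zero vector.  ``per_axis_maxabs``
    divides each axis by its maximum absolute value over the whole series.
    """
    if len(raw) < 1:  # pragma: no cover - RawSeries already enforces n >= 1
        raise InvalidInputError("cannot normalize an empty series")
    if mode == "per_sample_l2":
        norms = np.linalg.norm(raw.xyz, axis=1, keepdims=True)
        safe = np.where(norms > 0, norms, 1.0)
        xyz = raw.xyz / safe
    elif mode == "per_axis_maxabs":
        maxabs = np.max(np.abs(raw.xyz), axis=0, keepdims=True)
        safe = np.where(maxabs > 0, maxabs, 1.0)
        xyz = raw.xyz / safe
    else:
        raise InvalidInputError(
            f"unknown normalization mode {mode!r}; expected one of "
            f"{NORMALIZATION_MODES}"
        )
    return RawSeries(xyz=xyz, timestamps=raw.timestamps, labels=raw.labels)


def _majority_label(window_labels: np.ndarray | None) -> str | None:
    """Majority vote over a window's per-sample labels; tie -> None."""
    if window_labels is None:
        return None
    votes = Counter(l for l in window_labels if l is not None)
    if not votes:
        return None
    top = votes.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return None
    return top[0][0]


def segment(
    raw: RawSeries,
    window_len: int = DEFAULT_WINDOW_LEN,
    stride: int | None = None,
) -> list[Episode]:
    """Cut a series into fixed-length episodes.

    Windows start at 0, window_len, ... (``stride`` defaults to
    ``window_len``, i.e. non-overlapping).  Trailing samples that do not fill
    a window are dropped; a series shorter than one window yields no
    episodes.  When the series carries per-sample labels, each episode gets
    the majority label of its samples (tie -> unlabeled).
    """
    if window_len < 2:
        raise InvalidInputError("window_len must be >= 2")
    stride = window_len if stride is None else stride
    if stride < 1:
        raise InvalidInputError("stride must be >= 1")
    n = len(raw)
    episodes: list[Episode] = []
    if n < window_len:
        return episodes
    for k, start in enumerate(range(0, n - window_len + 1, stride)):
        sl = slice(start, start + window_len)
        labels = raw.labels[sl] if raw.labels is not None else None
        episodes.append(
            Episode(
                samples=raw.xyz[sl],
                index=k,
                true_label=_majority_label(labels),
            )
        )
    return episodes


def coefficient_of_variation(
    axis_values: np.ndarray,
    eps_mean: float = EPS_MEAN,
    eps_sd: float = EPS_SD,
) -> float:
    """Population standard deviation over absolute mean of one axis.

    Returns 0 in the degenerate cases |mean| < ``eps_mean`` or
    sd < ``eps_sd`` (no significant movement), so the feature is always
    finite and non-negative.
    """
    v = np.asarray(axis_values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise InvalidInputError("need a 1-D vector of length >= 2")
    mu = float(np.mean(v))
    sd = float(np.std(v))  # population (n-denominator)
    if abs(mu) < eps_mean or sd < eps_sd:
        return 0.0
    return sd / abs(mu)


def mean_crossings(axis_values: np.ndarray, eps_sd: float = EPS_SD) -> int:
    """Number of strict sign changes of one axis about its mean.

    A crossing is a consecutive pair (i, i+1) where v_i - mean and
    v_{i+1} - mean have strictly opposite signs; samples exactly at the mean
    never count as crossing endpoints.  Returns 0 when the population sd is
    below ``eps_sd`` (no movement about the mean position).
    """
    v = np.asarray(axis_values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise InvalidInputError("need a 1-D vector of length >= 2")
    if float(np.std(v)) < eps_sd:
        return 0
    s = np.sign(v - np.mean(v))
    return int(np.sum(s[:-1] * s[1:] < 0))


def extract_features(ep: Episode) -> np.ndarray:
    """Six-feature summary of one episode.

    Order is fixed: (cov_x, cov_y, cov_z, mcr_x, mcr_y, mcr_z).
    """
    covs = [coefficient_of_variation(ep.samples[:, a]) for a in range(3)]
    mcrs = [float(mean_crossings(ep.samples[:, a])) for a in range(3)]
    return np.asarray(covs + mcrs, dtype=float)


def features_matrix(
    episodes: list[Episode],
) -> tuple[np.ndarray, list[str | None]]:
    """Stack per-episode features into an (n, 6) matrix plus labels."""
    if not episodes:
        return np.empty((0, len(FEATURE_NAMES))), []
    X = np.vstack([extract_features(ep) for ep in episodes])
    labels = [ep.true_label for ep in episodes]
    return X, labels


class PcaProjector:
    """Top-3 principal-component projector for the 6-D feature space.

    The component signs are fixed so that the largest-magnitude loading of
    each component is positive, making the projection reproducible across
    runs and platforms.
    """

    n_components: int = 3

    def __init__(self) -> None:
        self.components_: np.ndarray | None = None  # (3, 6)
        self.mean_: np.ndarray | None = None  # (6,)
        self.explained_variance_: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.components_ is not None

    def fit(self, X: np.ndarray) -> "PcaProjector":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 4:
            raise DegenerateDataError(
                "PCA requires at least 4 feature vectors"
            )
        centered = X - X.mean(axis=0)
        if np.linalg.matrix_rank(centered) < self.n_components:
            raise DegenerateDataError(
                "feature covariance is degenerate in fewer than 3 directions"
            )
        p = PCA(n_components=self.n_components, svd_solver="full").fit(X)
        comps = p.components_.copy()
        for i in range(comps.shape[0]):
            j = int(np.argmax(np.abs(comps[i])))
            if comps[i, j] < 0:
                comps[i] = -comps[i]
        self.components_ = comps
        self.mean_ = p.mean_.copy()
        self.explained_variance_ = p.explained_variance_.copy()
        return self

    def _require_fitted(self) -> None:
        if not self.fitted:
            raise NotTrainedError("PcaProjector is not fitted")

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project features onto the top-3 components (mean-centred)."""
        self._require_fitted()
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        Z = (np.atleast_2d(X) - self.mean_) @ self.components_.T
        return Z[0] if single else Z

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        """Map component scores back to the 6-D feature space."""
        self._require_fitted()
        Z = np.asarray(Z, dtype=float)
        single = Z.ndim == 1
        X = np.atleast_2d(Z) @ self.components_ + self.mean_
        return X[0] if single else X


def fit_pca(features: np.ndarray) -> PcaProjector:
    """Fit a :class:`PcaProjector` on an (n, 6) feature matrix."""
    return PcaProjector().fit(features)
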