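"""Iterative semi-supervised learning engine.

Incoming featurised episodes are pooled: most land in the unlabeled pool
(Spool), a small fraction alpha with extreme (or oracle-known) labels lands in
the pre-labelled pool (LSpool).  Every ``train_every`` episodes — provided
Spool holds at least ``n_clusters`` points — the Spool is re-clustered
(k-means or a Gaussian mixture, optionally in PCA space) and each cluster is
assigned a class label by one of two strategies:

* population-based: the unique majority class of the pre-labelled episodes
  assigned to the cluster; ties or absence leave it unlabeled;
* distance-based: the class of the Euclidean-nearest pre-labelled episode;
  every cluster is labelled whenever LSpool is non-empty.

Between trainings, new episodes are classified by the nearest cluster
representative; members of unlabeled clusters stay unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .exceptions import ConfigError, InvalidInputError, NotTrainedError
from .preprocess import (
    DEFAULT_SAMPLING_RATE_HZ,
    DEFAULT_WINDOW_LEN,
    FEATURE_NAMES,
    PcaProjector,
    fit_pca,
)

ACTIVITY_CLASSES = ("sedentary", "moderately_active", "active")

CLUSTERING_METHODS = ("kmeans", "gmm_spherical", "gmm_diag", "gmm_full")
LABELLING_STRATEGIES = ("population", "distance")
PRELABEL_MODES = ("oracle", "threshold")

#: sentinel label for episodes whose nearest cluster carries no class
UNCLASSIFIED = None


@dataclass
class SSLConfig:
    """All tunables of the iterative SSL pipeline.

    alpha is the pre-labelling budget in percent of incoming episodes;
    n_clusters (Nc) the model size; train_every (Ne) the retraining interval
    in episodes.  ``prelabel_mode`` selects between the extreme-feature
    threshold detector and an oracle that pre-labels a seeded random
    alpha-fraction with ground truth (the mode used for quantitative
    experiments, since it controls alpha exactly).
    """

    alpha: float = 10.0
    n_clusters: int = 20
    train_every: int = 100
    clustering_method: str = "kmeans"
    labelling_strategy: str = "distance"
    prelabel_mode: str = "oracle"
    prelabel_thresholds: Mapping[str, Mapping[str, Sequence[float]]] | None = None
    use_pca: bool = True
    pca_refit: str = "per_cycle"  # or "once"
    random_seed: int = 0
    max_pool_size: int | None = None  # optional Spool cap, off by default
    max_fit_retries: int = 3
    kmeans_restarts: int = 10
    gmm_reg_covar: float = 1e-6
    # preprocessing settings carried alongside the learner
    normalization: str = "per_sample_l2"
    window_len: int = DEFAULT_WINDOW_LEN
    stride: int | None = None
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0.0 <= self.alpha <= 100.0):
            raise ConfigError("alpha must be in [0, 100]")
        if self.n_clusters < 2:
            raise ConfigError("n_clusters must be >= 2")
        if self.train_every < 1:
            raise ConfigError("train_every must be >= 1")
        if self.clustering_method not in CLUSTERING_METHODS:
            raise ConfigError(
                f"clustering_method must be one of {CLUSTERING_METHODS}"
            )
        if self.labelling_strategy not in LABELLING_STRATEGIES:
            raise ConfigError(
                f"labelling_strategy must be one of {LABELLING_STRATEGIES}"
            )
        if self.prelabel_mode not in PRELABEL_MODES:
            raise ConfigError(f"prelabel_mode must be one of {PRELABEL_MODES}")
        if self.pca_refit not in ("per_cycle", "once"):
            raise ConfigError("pca_refit must be 'per_cycle' or 'once'")
        if self.max_pool_size is not None and self.max_pool_size < self.n_clusters:
            raise ConfigError("max_pool_size must be >= n_clusters")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "SSLConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["prelabel_thresholds"] is not None:
            d["prelabel_thresholds"] = {
                c: {k: list(map(float, v)) for k, v in pred.items()}
                for c, pred in d["prelabel_thresholds"].items()
            }
        return d


@dataclass
class Prediction:
    """Outcome of classifying one episode: a class (or ``None`` when the
    nearest cluster is unlabeled or no model exists yet), the nearest
    cluster index, and the distance to its representative."""

    label: str | None
    cluster_index: int | None
    distance: float

    @property
    def classified(self) -> bool:
        return self.label is not None


NO_MODEL_PREDICTION = Prediction(UNCLASSIFIED, None, float("nan"))


class DataPools:
    """The two episode pools driving iterative training.

    Spool holds unlabeled feature vectors (the clustering substrate); LSpool
    holds (features, class) pairs used only for cluster labelling.
    """

    def __init__(self, n_features: int = len(FEATURE_NAMES)) -> None:
        self.n_features = n_features
        self._spool: list[np.ndarray] = []
        self._lspool: list[np.ndarray] = []
        self._lspool_labels: list[str] = []

    @property
    def count(self) -> int:
        """Size of the unlabeled pool (the paper's 'count')."""
        return len(self._spool)

    @property
    def lspool_size(self) -> int:
        return len(self._lspool)

    @property
    def total(self) -> int:
        return self.count + self.lspool_size

    def add_unlabeled(self, features: np.ndarray) -> None:
        self._spool.append(np.asarray(features, dtype=float))

    def add_prelabeled(self, features: np.ndarray, label: str) -> None:
        self._lspool.append(np.asarray(features, dtype=float))
        self._lspool_labels.append(label)

    def evict_oldest(self, keep: int) -> None:
        """Drop the oldest Spool entries down to ``keep`` (optional cap)."""
        if self.count > keep:
            self._spool = self._spool[self.count - keep:]

    def spool_matrix(self) -> np.ndarray:
        if not self._spool:
            return np.empty((0, self.n_features))
        return np.vstack(self._spool)

    def lspool_matrix(self) -> tuple[np.ndarray, list[str]]:
        if not self._lspool:
            return np.empty((0, self.n_features)), []
        return np.vstack(self._lspool), list(self._lspool_labels)

    def memory_bytes(self) -> int:
        """Deterministic byte accounting of both pools (float64 features)."""
        return 8 * self.n_features * self.total


@dataclass
class ClusterModel:
    """A trained classifier: Nc cluster representatives plus an optional
    class label per cluster (``None`` = unlabeled)."""

    representatives: np.ndarray  # (Nc, d) in the active feature space
    labels: list[str | None]
    method: str
    cycle_index: int
    projector: PcaProjector | None = None

    @property
    def n_clusters(self) -> int:
        return self.representatives.shape[0]

    def to_model_space(self, features: np.ndarray) -> np.ndarray:
        """Map raw 6-D features into the space the model was trained in."""
        if self.projector is not None:
            return self.projector.transform(features)
        return np.asarray(features, dtype=float)

    def memory_bytes(self) -> int:
        n = self.representatives.nbytes
        if self.projector is not None and self.projector.fitted:
            n += self.projector.components_.nbytes
            n += self.projector.mean_.nbytes
        return n


def default_threshold_predicates(
    calibration_features: np.ndarray,
    classes: Sequence[str] = ACTIVITY_CLASSES,
    q_low: float = 0.10,
    q_high: float = 0.90,
    mid_band: tuple[float, float] = (0.45, 0.55),
) -> dict[str, dict[str, list[float]]]:
    """Derive per-class extreme-value predicates from feature quantiles of a
    calibration stream.

    The lowest class fires when all six features fall at or below the low
    quantile, the highest when all fall at or above the high quantile, and
    middle classes when all features sit inside a narrow mid band — so only
    unambiguously extreme episodes are pre-labelled.
    """
    X = np.asarray(calibration_features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ConfigError("calibration features must be an (n, d) matrix, n >= 2")
    lo = np.quantile(X, q_low, axis=0)
    hi = np.quantile(X, q_high, axis=0)
    mlo = np.quantile(X, mid_band[0], axis=0)
    mhi = np.quantile(X, mid_band[1], axis=0)
    classes = list(classes)
    inf = np.full(X.shape[1], np.inf)
    preds: dict[str, dict[str, list[float]]] = {
        classes[0]: {"low": list(-inf), "high": list(lo)},
        classes[-1]: {"low": list(hi), "high": list(inf)},
    }
    for mid_class in classes[1:-1]:
        preds[mid_class] = {"low": list(mlo), "high": list(mhi)}
    return preds


def prelabel(
    features: np.ndarray,
    cfg: SSLConfig,
    rng: np.random.Generator,
    true_label: str | None = None,
) -> str | None:
    """Decide whether an incoming episode is pre-labelled, and with what.

    Threshold mode fires when the 6-feature vector satisfies a class's
    extreme-value predicate (inclusive elementwise bounds).  Oracle mode
    returns the true label with probability alpha/100 (one uniform draw per
    episode, so the random stream is identical whether or not an episode
    carries ground truth).
    """
    if cfg.prelabel_mode == "oracle":
        fires = float(rng.uniform()) * 100.0 < cfg.alpha
        return true_label if (fires and true_label is not None) else None
    if not cfg.prelabel_thresholds:
        raise ConfigError(
            "prelabel_mode='threshold' requires prelabel_thresholds"
        )
    f = np.asarray(features, dtype=float)
    for cls, pred in cfg.prelabel_thresholds.items():
        lo = np.asarray(pred["low"], dtype=float)
        hi = np.asarray(pred["high"], dtype=float)
        if np.all(f >= lo) and np.all(f <= hi):
            return cls
    return None


def _make_backend(cfg: SSLConfig, seed: int):
    if cfg.clustering_method == "kmeans":
        return KMeans(
            n_clusters=cfg.n_clusters,
            n_init=cfg.kmeans_restarts,
            random_state=seed,
        )
    cov = {
        "gmm_spherical": "spherical",
        "gmm_diag": "diag",
        "gmm_full": "full",
    }[cfg.clustering_method]
    return GaussianMixture(
        n_components=cfg.n_clusters,
        covariance_type=cov,
        reg_covar=cfg.gmm_reg_covar,
        random_state=seed,
    )


def assign_to_nearest(points: np.ndarray, representatives: np.ndarray) -> np.ndarray:
    """Index of the Euclidean-nearest representative for each point
    (ties resolved to the lowest cluster index)."""
    return np.argmin(cdist(np.atleast_2d(points), representatives), axis=1)


def label_clusters_population(
    assignments: np.ndarray,
    n_clusters: int,
    lspool_labels: Sequence[str],
) -> list[str | None]:
    """Population-based cluster labelling.

    ``assignments`` holds, for each pre-labelled episode, the cluster it is
    assigned to (nearest representative).  A cluster takes the class with the
    unique maximum count of its pre-labelled members; a tie among the top
    counts, or no pre-labelled members at all, leaves it unlabeled.
    """
    labels: list[str | None] = []
    assignments = np.asarray(assignments, dtype=int)
    lspool_labels = list(lspool_labels)
    for i in range(n_clusters):
        counts: dict[str, int] = {}
        for a, lab in zip(assignments, lspool_labels):
            if a == i:
                counts[lab] = counts.get(lab, 0) + 1
        if not counts:
            labels.append(None)
            continue
        ranked = sorted(counts.items(), key=lambda kv: -kv[1])
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            labels.append(None)  # no unique max(M)
        else:
            labels.append(ranked[0][0])
    return labels


def label_clusters_distance(
    representatives: np.ndarray,
    lspool_features: np.ndarray,
    lspool_labels: Sequence[str],
) -> list[str | None]:
    """Distance-based cluster labelling.

    Each representative takes the class of its Euclidean-nearest pre-labelled
    episode (ties to the lowest episode index); with an empty LSpool every
    cluster stays unlabeled.
    """
    n_clusters = representatives.shape[0]
    if len(lspool_labels) == 0:
        return [None] * n_clusters
    nearest = np.argmin(cdist(representatives, lspool_features), axis=1)
    lspool_labels = list(lspool_labels)
    return [lspool_labels[j] for j in nearest]


def train(
    pools: DataPools,
    cfg: SSLConfig,
    seed: int,
    cycle_index: int = 1,
    projector: PcaProjector | None = None,
) -> ClusterModel:
    """One SSL training cycle: cluster the Spool and label the clusters.

    The clustering backend is fitted on the unlabeled pool only (in PCA space
    when ``use_pca``; pass ``projector`` to reuse a previously fitted one,
    otherwise PCA is refitted on the current Spool).  Representatives are the
    cluster means; labels come from the configured strategy.  Deterministic
    given (pools, cfg, seed).
    """
    X6 = pools.spool_matrix()
    if X6.shape[0] < cfg.n_clusters:
        raise InvalidInputError(
            f"training requires count >= n_clusters "
            f"({X6.shape[0]} < {cfg.n_clusters})"
        )
    proj: PcaProjector | None = None
    if cfg.use_pca:
        proj = projector if projector is not None else fit_pca(X6)
        X = proj.transform(X6)
    else:
        X = X6

    last_err: Exception | None = None
    est = None
    for attempt in range(cfg.max_fit_retries):
        try:
            est = _make_backend(cfg, (seed + attempt) % (2**31)).fit(X)
            break
        except Exception as err:  # retry with a fresh seeded init
            last_err = err
    if est is None:
        raise InvalidInputError(f"clustering failed to converge: {last_err}")

    reps = (
        est.cluster_centers_
        if cfg.clustering_method == "kmeans"
        else est.means_
    )
    reps = np.asarray(reps, dtype=float)

    L6, llabels = pools.lspool_matrix()
    if len(llabels) == 0:
        labels: list[str | None] = [None] * cfg.n_clusters
    else:
        L = proj.transform(L6) if proj is not None else L6
        if cfg.labelling_strategy == "population":
            assignments = assign_to_nearest(L, reps)
            labels = label_clusters_population(
                assignments, cfg.n_clusters, llabels
            )
        else:
            labels = label_clusters_distance(reps, L, llabels)
    return ClusterModel(
        representatives=reps,
        labels=labels,
        method=cfg.clustering_method,
        cycle_index=cycle_index,
        projector=proj,
    )


def classify(features: np.ndarray, model: ClusterModel) -> Prediction:
    """Nearest-cluster classification of one 6-D feature vector."""
    if model is None:
        raise NotTrainedError("no trained cluster model")
    z = np.atleast_2d(model.to_model_space(np.asarray(features, dtype=float)))
    d = cdist(z, model.representatives)[0]
    k = int(np.argmin(d))  # argmin takes the lowest index on ties
    return Prediction(model.labels[k], k, float(d[k]))


def classify_batch(
    features: np.ndarray, model: ClusterModel
) -> tuple[list[str | None], np.ndarray, np.ndarray]:
    """Vectorised nearest-cluster classification of an (n, 6) matrix."""
    if model is None:
        raise NotTrainedError("no trained cluster model")
    Z = np.atleast_2d(model.to_model_space(np.asarray(features, dtype=float)))
    D = cdist(Z, model.representatives)
    ks = np.argmin(D, axis=1)
    labels = [model.labels[int(k)] for k in ks]
    return labels, ks, D[np.arange(len(ks)), ks]


class SSLStream:
    """Streaming front of the SSL engine.

    Feed featurised episodes one at a time with :meth:`ingest`; the stream
    routes them into the pools, classifies each with the model available at
    arrival time, and retrains when ``train_every`` episodes have arrived
    since the last training and the Spool holds at least ``n_clusters``
    points.
    """

    def __init__(
        self,
        config: SSLConfig,
        classes: Sequence[str] = ACTIVITY_CLASSES,
    ) -> None:
        config.validate()
        self.config = config
        self.classes = tuple(classes)
        self.pools = DataPools()
        self.model: ClusterModel | None = None
        self.n_ingested = 0
        self.cycle_count = 0
        self._since_train = 0
        self._shared_projector: PcaProjector | None = None
        ss = np.random.SeedSequence(config.random_seed)
        c_pre, c_train = ss.spawn(2)
        self._prelabel_rng = np.random.default_rng(c_pre)
        self._train_seed_rng = np.random.default_rng(c_train)

    def ingest(
        self, features: np.ndarray, true_label: str | None = None
    ) -> tuple[Prediction, bool]:
        """Route one episode; return its arrival-time prediction and whether
        this episode triggered a retraining."""
        f = np.asarray(features, dtype=float).ravel()
        if f.size != self.pools.n_features:
            raise InvalidInputError(
                f"expected {self.pools.n_features} features, got {f.size}"
            )
        pred = (
            classify(f, self.model)
            if self.model is not None
            else NO_MODEL_PREDICTION
        )
        lab = prelabel(f, self.config, self._prelabel_rng, true_label)
        if lab is not None:
            self.pools.add_prelabeled(f, lab)
        else:
            self.pools.add_unlabeled(f)
            if self.config.max_pool_size is not None:
                self.pools.evict_oldest(self.config.max_pool_size)
        self.n_ingested += 1
        self._since_train += 1
        retrained = False
        if (
            self._since_train >= self.config.train_every
            and self.pools.count >= self.config.n_clusters
        ):
            self.retrain()
            retrained = True
        return pred, retrained

    def retrain(self) -> ClusterModel:
        """Force a training cycle on the current pools."""
        seed = int(self._train_seed_rng.integers(2**31))
        projector = (
            self._shared_projector
            if self.config.pca_refit == "once"
            else None
        )
        self.model = train(
            self.pools,
            self.config,
            seed,
            cycle_index=self.cycle_count + 1,
            projector=projector,
        )
        if self.config.pca_refit == "once" and self._shared_projector is None:
            self._shared_projector = self.model.projector
        self.cycle_count += 1
        self._since_train = 0
        return self.model

    def memory_bytes(self) -> int:
        """Deterministic byte accounting of pools plus model."""
        n = self.pools.memory_bytes()
        if self.model is not None:
            n += self.model.memory_bytes()
        return n
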