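"""Model/Results front end for the iterative SSL activity classifier.

:class:`ActivitySSL` is built from data (featurised episodes, a raw stream,
or a tidy DataFrame), its :meth:`~ActivitySSL.fit` replays the stream through
the SSL engine, and the returned :class:`ActivitySSLResults` carries the
trained cluster model, the per-cycle metric history, arrival-time
predictions, a ``summary()`` table and plotting helpers.
"""

from __future__ import annotations

import json
import time
from typing import Sequence

import numpy as np
import pandas as pd

from . import evaluation
from .core import (
    ACTIVITY_CLASSES,
    ClusterModel,
    Prediction,
    SSLConfig,
    SSLStream,
    classify_batch,
)
from .exceptions import InvalidInputError, NotTrainedError
from .preprocess import (
    FEATURE_NAMES,
    PcaProjector,
    RawSeries,
    features_matrix,
    normalize,
    segment,
)


class ActivitySSL:
    """Iterative semi-supervised activity classifier.

    Parameters
    ----------
    features : ndarray of shape (n_episodes, 6)
        Per-episode feature vectors in arrival order.
    true_labels : sequence of str or None, optional
        Ground-truth class per episode (``None`` = unknown).  Required for
        oracle pre-labelling and for accuracy metrics.
    config : SSLConfig, optional
        Engine configuration; defaults to :class:`SSLConfig`'s defaults.
    classes : sequence of str
        The fixed class set shared by pools, model and metrics.

    Examples
    --------
    >>> from harssl import ActivitySSL, SSLConfig
    >>> from harssl.synthetic import SignalSpec, generate_signal
    >>> raw = generate_signal(SignalSpec(episodes_per_class=200, seed=7))
    >>> res = ActivitySSL.from_raw(raw, SSLConfig(random_seed=7)).fit()
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(
        self,
        features: np.ndarray,
        true_labels: Sequence[str | None] | None = None,
        config: SSLConfig | None = None,
        classes: Sequence[str] = ACTIVITY_CLASSES,
    ) -> None:
        X = np.asarray(features, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
            raise InvalidInputError(
                f"features must have shape (n, {len(FEATURE_NAMES)})"
            )
        if true_labels is not None and len(true_labels) != X.shape[0]:
            raise InvalidInputError("true_labels length must match features")
        self.features = X
        self.true_labels: list[str | None] = (
            list(true_labels)
            if true_labels is not None
            else [None] * X.shape[0]
        )
        self.config = config if config is not None else SSLConfig()
        self.classes = tuple(classes)

    # ------------------------------------------------------------------
    # constructors
    # ------------------------------------------------------------------
    @classmethod
    def from_raw(
        cls,
        raw: RawSeries,
        config: SSLConfig | None = None,
        classes: Sequence[str] = ACTIVITY_CLASSES,
    ) -> "ActivitySSL":
        """Normalise, window and featurise a raw accelerometer stream."""
        config = config if config is not None else SSLConfig()
        normed = normalize(raw, config.normalization)
        episodes = segment(normed, config.window_len, config.stride)
        X, labels = features_matrix(episodes)
        return cls(X, labels, config=config, classes=classes)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        config: SSLConfig | None = None,
        classes: Sequence[str] = ACTIVITY_CLASSES,
    ) -> "ActivitySSL":
        """Build from a tidy frame with columns timestamp, ax, ay, az
        and optionally label."""
        required = ("timestamp", "ax", "ay", "az")
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise InvalidInputError(f"missing columns: {missing}")
        labels = None
        if "label" in df.columns:
            labels = np.asarray(
                [None if pd.isna(v) or v == "" else str(v) for v in df["label"]],
                dtype=object,
            )
        raw = RawSeries(
            xyz=df[["ax", "ay", "az"]].to_numpy(dtype=float),
            timestamps=df["timestamp"].to_numpy(dtype=float),
            labels=labels,
        )
        return cls.from_raw(raw, config=config, classes=classes)

    # ------------------------------------------------------------------
    @property
    def n_episodes(self) -> int:
        return self.features.shape[0]

    def fit(self) -> "ActivitySSLResults":
        """Replay the episode stream through the SSL engine.

        Episodes are ingested in order; at every training cycle the whole
        pool seen so far is re-classified with the fresh model and scored
        (pool-cumulative metrics), and compute time / memory accounting are
        recorded.
        """
        stream = SSLStream(self.config, self.classes)
        records: list[evaluation.MetricsRecord] = []
        arrival: list[Prediction] = []
        t0 = time.perf_counter()
        for i in range(self.n_episodes):
            pred, retrained = stream.ingest(
                self.features[i], self.true_labels[i]
            )
            arrival.append(pred)
            if retrained:
                elapsed = time.perf_counter() - t0
                labels, _, _ = classify_batch(
                    self.features[: i + 1], stream.model
                )
                rec = evaluation.score(
                    labels,
                    self.true_labels[: i + 1],
                    self.classes,
                    cycle_index=stream.cycle_count,
                )
                rec.cumulative_compute_seconds = elapsed
                rec.pool_memory_bytes = stream.memory_bytes()
                records.append(rec)
        return ActivitySSLResults(self, stream, records, arrival)


class ActivitySSLResults:
    """Results of fitting :class:`ActivitySSL`.

    Attributes
    ----------
    cluster_model : ClusterModel or None
        The model from the final training cycle.
    records : list of MetricsRecord
        Pool-cumulative metrics, one per training cycle.
    arrival_predictions : list of Prediction
        The prediction each episode received at arrival time (with the model
        that existed before any retraining it triggered).
    """

    def __init__(
        self,
        model: ActivitySSL,
        stream: SSLStream,
        records: list[evaluation.MetricsRecord],
        arrival_predictions: list[Prediction],
    ) -> None:
        self.model = model
        self.stream = stream
        self.records = records
        self.arrival_predictions = arrival_predictions

    # ------------------------------------------------------------------
    @property
    def cluster_model(self) -> ClusterModel | None:
        return self.stream.model

    @property
    def n_cycles(self) -> int:
        return len(self.records)

    @property
    def final(self) -> evaluation.MetricsRecord:
        if not self.records:
            raise NotTrainedError("no training cycle completed")
        return self.records[-1]

    @property
    def history(self) -> pd.DataFrame:
        """Per-cycle metrics as a tidy frame (one row per cycle)."""
        return pd.DataFrame([r.to_row() for r in self.records])

    def predict(self, features: np.ndarray) -> list[str | None]:
        """Classify new 6-D feature vectors with the final model."""
        if self.cluster_model is None:
            raise NotTrainedError("no trained cluster model")
        labels, _, _ = classify_batch(np.atleast_2d(features), self.cluster_model)
        return labels

    # ------------------------------------------------------------------
    def summary(self) -> str:
        """Human-readable summary of configuration and final-cycle metrics."""
        cfg = self.model.config
        lines = [
            "Iterative Semi-Supervised Activity Classifier",
            "=" * 61,
            f"episodes ingested      {self.model.n_episodes:>10d}",
            f"training cycles        {self.n_cycles:>10d}",
            f"clustering method      {cfg.clustering_method:>10s}",
            f"labelling strategy     {cfg.labelling_strategy:>10s}",
            f"alpha (% pre-labelled) {cfg.alpha:>10.2f}",
            f"clusters (Nc)          {cfg.n_clusters:>10d}",
            f"retrain interval (Ne)  {cfg.train_every:>10d}",
            f"PCA (top 3 comps)      {str(cfg.use_pca):>10s}",
            "-" * 61,
        ]
        if self.records:
            r = self.final
            lines.append(f"{'class':<22s}{'TP %':>10s}{'FP %':>10s}")
            for c in self.model.classes:
                lines.append(
                    f"{c:<22s}"
                    f"{r.true_positive_pct[c]:>10.2f}"
                    f"{r.false_positive_pct[c]:>10.2f}"
                )
            lines += [
                "-" * 61,
                f"overall accuracy (%)   {r.overall_accuracy_pct:>10.2f}",
                f"classification rate (%){r.classification_rate_pct:>9.2f}",
                f"compute time (s)       {r.cumulative_compute_seconds:>10.3f}",
                f"pool+model memory (B)  {r.pool_memory_bytes:>10d}",
            ]
        else:
            lines.append("no training cycle completed (stream too short?)")
        lines.append("=" * 61)
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def plot_accuracy(self, ax=None):
        """Accuracy and classification rate versus episodes seen."""
        from .plotting import plot_accuracy

        return plot_accuracy(self.history, ax=ax)

    def plot_complexity(self, ax=None):
        """Compute time and memory accounting versus episodes seen."""
        from .plotting import plot_complexity

        return plot_complexity(self.history, ax=ax)

    # ------------------------------------------------------------------
    def save_model(self, path) -> None:
        """Serialise the final cluster model (plus PCA loadings and config)
        to a JSON snapshot for resume and inspection."""
        cm = self.cluster_model
        if cm is None:
            raise NotTrainedError("no trained cluster model to save")
        snap = {
            "representatives": cm.representatives.tolist(),
            "labels": list(cm.labels),
            "method": cm.method,
            "cycle_index": cm.cycle_index,
            "config": self.model.config.to_dict(),
            "classes": list(self.model.classes),
        }
        if cm.projector is not None and cm.projector.fitted:
            snap["pca"] = {
                "components": cm.projector.components_.tolist(),
                "mean": cm.projector.mean_.tolist(),
                "explained_variance": cm.projector.explained_variance_.tolist(),
            }
        with open(path, "w") as fh:
            json.dump(snap, fh, indent=1, sort_keys=True)


def load_cluster_model(path) -> ClusterModel:
    """Load a cluster model saved by :meth:`ActivitySSLResults.save_model`."""
    with open(path) as fh:
        snap = json.load(fh)
    projector = None
    if "pca" in snap:
        projector = PcaProjector()
        projector.components_ = np.asarray(snap["pca"]["components"], dtype=float)
        projector.mean_ = np.asarray(snap["pca"]["mean"], dtype=float)
        projector.explained_variance_ = np.asarray(
            snap["pca"]["explained_variance"], dtype=float
        )
    return ClusterModel(
        representatives=np.asarray(snap["representatives"], dtype=float),
        labels=[l if l is not None else None for l in snap["labels"]],
        method=snap["method"],
        cycle_index=snap["cycle_index"],
        projector=projector,
    )
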