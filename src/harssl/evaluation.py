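"""Accuracy and complexity metrics for the iterative SSL classifier.

Per training cycle the pooled episodes are scored into per-class true/false
positive rates, overall accuracy among classified episodes, and the
classification rate (lambda) — the percent of episodes that received any
class label.  Complexity is tracked as wall-clock compute time and a
deterministic byte-accounting of pools plus model.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, InvalidInputError

#: sentinel for metrics whose denominator is empty
UNDEFINED = float("nan")


@dataclass
class MetricsRecord:
    """Accuracy and complexity figures for one training cycle.

    TP_c is per-class recall among classified episodes; FP_c is the fraction
    of classified other-class episodes predicted as c (fall-out); Acc is
    correct / classified; lambda is classified / total, all in percent over
    the episodes that carry ground truth.  Unclassified episodes appear only
    in lambda's denominator.
    """

    cycle_index: int
    n_total: int
    n_classified: int
    true_positive_pct: dict[str, float]
    false_positive_pct: dict[str, float]
    overall_accuracy_pct: float
    classification_rate_pct: float
    cumulative_compute_seconds: float = UNDEFINED
    pool_memory_bytes: int = 0

    def to_row(self) -> dict[str, float]:
        """Flatten into one CSV-friendly row."""
        row: dict[str, float] = {
            "cycle_index": self.cycle_index,
            "n_total": self.n_total,
            "n_classified": self.n_classified,
            "overall_accuracy_pct": self.overall_accuracy_pct,
            "classification_rate_pct": self.classification_rate_pct,
            "cumulative_compute_seconds": self.cumulative_compute_seconds,
            "pool_memory_bytes": self.pool_memory_bytes,
        }
        for c, v in self.true_positive_pct.items():
            row[f"tp_pct_{c}"] = v
        for c, v in self.false_positive_pct.items():
            row[f"fp_pct_{c}"] = v
        return row


def confusion_table(
    pred_labels: Sequence[str | None],
    true_labels: Sequence[str | None],
    classes: Sequence[str],
) -> pd.DataFrame:
    """k x (k+1) table of true class vs predicted class or UNCLASSIFIED.

    Episodes without ground truth are excluded entirely.
    """
    if len(pred_labels) != len(true_labels):
        raise InvalidInputError("predictions and truths differ in length")
    cols = list(classes) + ["UNCLASSIFIED"]
    tab = pd.DataFrame(0, index=list(classes), columns=cols, dtype=int)
    for p, t in zip(pred_labels, true_labels):
        if t is None:
            continue
        tab.loc[t, p if p is not None else "UNCLASSIFIED"] += 1
    return tab


def score(
    pred_labels: Sequence[str | None],
    true_labels: Sequence[str | None],
    classes: Sequence[str],
    cycle_index: int = 0,
) -> MetricsRecord:
    """Score one cycle's predictions against ground truth.

    With zero classified episodes, TP/FP/Acc are reported as NaN sentinels
    and lambda is 0.
    """
    tab = confusion_table(pred_labels, true_labels, classes)
    n_total = int(tab.to_numpy().sum())
    if n_total < 1:
        raise InvalidInputError("need at least one episode with ground truth")
    classified = tab[list(classes)]
    n_classified = int(classified.to_numpy().sum())
    correct = int(np.trace(classified.loc[list(classes), list(classes)].to_numpy()))

    tp: dict[str, float] = {}
    fp: dict[str, float] = {}
    for c in classes:
        denom_tp = int(classified.loc[c].sum())  # truth-c classified
        tp[c] = 100.0 * classified.loc[c, c] / denom_tp if denom_tp else UNDEFINED
        others = [t for t in classes if t != c]
        denom_fp = int(classified.loc[others].to_numpy().sum())
        fp[c] = (
            100.0 * classified.loc[others, c].sum() / denom_fp
            if denom_fp
            else UNDEFINED
        )
    acc = 100.0 * correct / n_classified if n_classified else UNDEFINED
    lam = 100.0 * n_classified / n_total
    return MetricsRecord(
        cycle_index=cycle_index,
        n_total=n_total,
        n_classified=n_classified,
        true_positive_pct=tp,
        false_positive_pct=fp,
        overall_accuracy_pct=acc,
        classification_rate_pct=lam,
    )


def memory_estimate(pools=None, model=None) -> int:
    """Deterministic byte accounting of pools plus model arrays.

    This is an accounting of the stored float64 features and model matrices,
    not OS-resident memory (which is runtime-dependent); see
    :func:`os_memory_probe` for an opt-in OS-level figure.
    """
    n = 0
    if pools is not None:
        n += pools.memory_bytes()
    if model is not None:
        n += model.memory_bytes()
    return n


def os_memory_probe() -> int:
    """Opt-in OS-level peak-RSS probe (kilobytes -> bytes on Linux)."""
    import resource

    return resource.getrusage(resource.RUSAGE_SELF).ru_maxrss * 1024


def profile_cycle(
    stage: Callable[[], object],
    pools=None,
    model=None,
) -> tuple[float, int]:
    """Run one pipeline stage; return (elapsed wall-clock seconds,
    deterministic memory-bytes estimate of pools + model)."""
    t0 = time.perf_counter()
    stage()
    elapsed = time.perf_counter() - t0
    return elapsed, memory_estimate(pools, model)


def aggregate_runs(histories: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Element-wise mean/sd across runs at matched cycle indices.

    Every run must expose an identical ``cycle_index`` grid; NaN sentinels
    are ignored, with the number of defined values reported per cell.
    Columns come back as ``<metric>_mean``, ``<metric>_sd``, ``<metric>_n``.
    """
    if len(histories) < 1:
        raise InvalidInputError("need at least one run")
    grid = histories[0]["cycle_index"].to_numpy()
    for h in histories[1:]:
        if not np.array_equal(h["cycle_index"].to_numpy(), grid):
            raise AlignmentError("runs have mismatched cycle grids")
    stacked = pd.concat(histories, keys=range(len(histories)), names=["run"])
    metric_cols = [c for c in histories[0].columns if c != "cycle_index"]
    g = stacked.groupby("cycle_index")[metric_cols]
    mean = g.mean()  # skips NaN
    sd = g.std(ddof=0)
    n = g.count()
    out = pd.DataFrame(index=mean.index)
    for c in metric_cols:
        out[f"{c}_mean"] = mean[c]
        out[f"{c}_sd"] = sd[c]
        out[f"{c}_n"] = n[c]
    return out.reset_index()
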