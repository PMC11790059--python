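"""Truth-set comparison metrics and cross-dataset rank analysis.

A call set is scored against the positive set P of true somatic variants:

    TP = |calls ∩ truth|     FN = |truth \\ calls|     FP = |calls \\ truth|
    recall (TPR) = TP/(TP+FN)
    precision (PPV) = TP/(TP+FP)
    F1 = 2·TP/(2·TP+FP+FN)

Accuracy is deliberately not computed: with a genome-scale negative class
it is uninformative for variant calling.  Metrics with a zero denominator
are flagged as undefined (None) rather than coerced to 0; the count-form
F1 is well defined whenever the truth set is non-empty, so an empty call
set scores F1 = 0.

Cross-dataset stability is summarised by ranking callers within each
dataset by F1 (rank 1 = best, average rank for ties) and reporting the
population variance Var(X) = E[(X − E[X])²] of each caller's ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .variants import CallSet, RegionSet, TruthSet, restrict_to_regions


@dataclass(frozen=True)
class MetricSet:
    """TP/FP/FN counts with derived recall, precision and F1."""

    tp: int
    fp: int
    fn: int

    @property
    def recall(self) -> Optional[float]:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def precision(self) -> Optional[float]:
        denom = self.tp + self.fp
        return self.tp / denom if denom else None

    @property
    def f1(self) -> Optional[float]:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else None

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
        }


def compare_to_truth(
    callset: CallSet,
    truthset: TruthSet,
    region_set: Optional[RegionSet] = None,
) -> MetricSet:
    """Score one call set against the truth set, optionally within regions."""
    if (
        callset.variant_class is not None
        and truthset.variant_class is not None
        and callset.variant_class != truthset.variant_class
    ):
        raise ValueError(
            f"variant-class mismatch: call set is {callset.variant_class}, "
            f"truth set is {truthset.variant_class}"
        )
    if region_set is not None:
        callset = restrict_to_regions(callset, region_set)
        truthset = restrict_to_regions(truthset, region_set)
    calls = callset.keys()
    truth = truthset.keys()
    tp = len(calls & truth)
    return MetricSet(tp=tp, fp=len(calls) - tp, fn=len(truth) - tp)


def mean_f1(per_dataset_f1: Sequence[float]) -> float:
    """Unweighted arithmetic mean of per-dataset F1 scores.

    Datasets where the variant class has no truth variants must be
    excluded by the caller before invoking this (their F1 is undefined).
    """
    values = list(per_dataset_f1)
    if not values:
        raise ValueError("mean_f1 requires at least one defined F1 value")
    if any(v is None for v in values):
        raise ValueError("mean_f1 received an undefined F1; exclude that dataset")
    return float(np.mean(values))


@dataclass
class RankTable:
    """Per-dataset caller ranks with per-caller mean and population variance."""

    ranks: pd.DataFrame  # callers x datasets, NaN where a caller is absent
    mean_rank: pd.Series
    rank_variance: pd.Series

    def as_frame(self) -> pd.DataFrame:
        out = self.ranks.copy()
        out["mean_rank"] = self.mean_rank
        out["rank_variance"] = self.rank_variance
        return out


def rank_callers(metric_tables: Mapping[str, Mapping[str, float]]) -> RankTable:
    """Rank callers by F1 within each dataset and summarise rank stability.

    ``metric_tables`` maps dataset_id -> {caller_id: f1}.  Rank 1 is the
    best F1; ties receive the average rank, so ranks within a dataset of k
    callers always sum to k(k+1)/2.  A caller absent from a dataset is
    excluded from that dataset's ranking (with a warning) and its mean and
    variance are computed over the datasets where it is present.  The
    variance is the population form Var(X) = E[(X − E[X])²].
    """
    if not metric_tables:
        raise ValueError("rank_callers requires at least one dataset")
    frame = pd.DataFrame(metric_tables, dtype=float)  # callers x datasets
    for dataset in frame.columns:
        missing = frame.index[frame[dataset].isna()]
        if len(missing):
            warnings.warn(
                f"dataset {dataset}: caller(s) {sorted(missing)} absent from ranking"
            )
    ranks = frame.rank(axis=0, ascending=False, method="average")
    mean_rank = ranks.mean(axis=1)
    rank_variance = ranks.var(axis=1, ddof=0)
    return RankTable(ranks=ranks, mean_rank=mean_rank, rank_variance=rank_variance)


def metrics_frame(records: Sequence[dict]) -> pd.DataFrame:
    """Tidy per-(caller, dataset, class) metric table.

    Each record must carry caller, dataset, variant_class and a MetricSet
    under the key ``metrics``.
    """
    rows = []
    for record in records:
        metrics: MetricSet = record["metrics"]
        rows.append(
            {
                "caller": record["caller"],
                "dataset": record["dataset"],
                "class": str(record["variant_class"]),
                **metrics.as_dict(),
            }
        )
    return pd.DataFrame(rows)


def f1_matrix(frame: pd.DataFrame, variant_class: str) -> pd.DataFrame:
    """Callers x datasets matrix of F1 for one variant class (heatmap-ready)."""
    sub = frame[frame["class"] == variant_class]
    return sub.pivot(index="caller", columns="dataset", values="f1")
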