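"""Exhaustive combination x voting-threshold search with cost-aware selection.

For n eligible callers the search enumerates every combination of size
p_min..p_max (defaults 2..n) and, within each combination of size p,
every voting threshold 1..p:

    combinations            Σ_{p} C(n, p)        (= 2^n − n − 1 over 2..n)
    with thresholds         Σ_{p} p·C(n, p)      (= n·2^{n−1} − n over 2..n)

Each (combination, threshold) is scored per dataset against the truth set
and summarised by the unweighted mean F1 across datasets; the CPU cost of
a combination is the sum of its callers' CPU seconds (serial execution,
the worst case) or optionally the maximum (critical path on a cluster).
The tradeoff selector returns the best-mean-F1 result, the Pareto front
in (mean F1 max, CPU cost min), and the cheapest result whose mean F1 is
within a tolerance of the best.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from collections import Counter
from dataclasses import dataclass
from math import comb
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ensemble import EnsembleSpec
from .evaluation import MetricSet, mean_f1
from .registry import CallerMeta
from .variants import CallSet, RegionSet, TruthSet, restrict_to_regions

logger = logging.getLogger(__name__)

COST_MODES = ("serial", "critical_path")


def count_search_space(
    n: int, p_min: int = 2, p_max: Optional[int] = None, with_thresholds: bool = False
) -> int:
    """Number of combinations (optionally x thresholds) of n callers."""
    p_max = n if p_max is None else p_max
    if not 0 <= p_min <= p_max <= n:
        raise ValueError(f"invalid size range [{p_min}, {p_max}] for n={n}")
    if with_thresholds:
        return sum(p * comb(n, p) for p in range(p_min, p_max + 1))
    return sum(comb(n, p) for p in range(p_min, p_max + 1))


@dataclass
class EnsembleResult:
    """One evaluated (combination, threshold) with per-dataset metrics and cost."""

    spec: EnsembleSpec
    per_dataset_metrics: dict[str, MetricSet]
    mean_f1: float
    cpu_seconds_total: float
    peak_memory_mb_max: float


@dataclass
class TradeoffReport:
    best_by_mean_f1: EnsembleResult
    pareto_front: list[EnsembleResult]
    recommended: EnsembleResult
    f1_tolerance: float


def combination_cost(
    caller_ids: Sequence[str],
    caller_meta: Mapping[str, CallerMeta],
    cost_mode: str = "serial",
) -> tuple[float, float]:
    """(CPU seconds, peak memory MB) for a set of callers, de-duplicated."""
    if cost_mode not in COST_MODES:
        raise ValueError(f"cost_mode must be one of {COST_MODES}")
    unique = sorted(set(caller_ids))
    cpus = [caller_meta[c].cpu_seconds for c in unique]
    mems = [caller_meta[c].peak_memory_mb for c in unique]
    cpu = sum(cpus) if cost_mode == "serial" else max(cpus)
    return float(cpu), float(max(mems))


def run_search(
    callsets: Mapping[str, Mapping[str, CallSet]],
    truthsets: Mapping[str, TruthSet],
    regionsets: Optional[Mapping[str, RegionSet]],
    caller_meta: Mapping[str, CallerMeta],
    callers: Optional[Sequence[str]] = None,
    p_min: int = 2,
    p_max: Optional[int] = None,
    cost_mode: str = "serial",
) -> list[EnsembleResult]:
    """Evaluate every combination x threshold for one variant class.

    ``callsets`` maps caller_id -> dataset_id -> CallSet (already reduced
    to the variant class under study).  Datasets without a truth set are
    skipped with a warning, as are callers missing a call set in some
    dataset.  Datasets whose restricted truth set is empty are excluded
    from the mean (their F1 is undefined).  Output order is deterministic:
    by combination size, then lexicographic caller ids, then threshold.
    """
    datasets = []
    for dataset_id in sorted(truthsets):
        if truthsets[dataset_id] is None:
            warnings.warn(f"dataset {dataset_id}: missing truth set, skipped")
            continue
        datasets.append(dataset_id)

    pool = sorted(callers) if callers is not None else sorted(callsets)
    usable = []
    for caller in pool:
        have = callsets.get(caller, {})
        if all(ds in have for ds in datasets):
            usable.append(caller)
        else:
            warnings.warn(f"caller {caller}: call set missing in some dataset, dropped")

    n = len(usable)
    p_max = n if p_max is None else p_max
    if n == 0 or not 1 <= p_min <= p_max <= n:
        raise ValueError(f"size range [{p_min}, {p_max}] infeasible for {n} callers")

    # Restrict once per dataset, then reduce each call set to its key set.
    truth_keys: dict[str, frozenset] = {}
    call_keys: dict[str, dict[str, frozenset]] = {c: {} for c in usable}
    for ds in datasets:
        truth = truthsets[ds]
        regions = regionsets.get(ds) if regionsets else None
        if regions is not None:
            truth = restrict_to_regions(truth, regions)
        truth_keys[ds] = frozenset(truth.variants)
        for caller in usable:
            cs = callsets[caller][ds]
            if regions is not None:
                cs = restrict_to_regions(cs, regions)
            call_keys[caller][ds] = frozenset(cs.variants)

    scored_datasets = [ds for ds in datasets if truth_keys[ds]]
    for ds in datasets:
        if ds not in scored_datasets:
            logger.info("dataset %s: empty truth set for this class, excluded from mean", ds)

    results: list[EnsembleResult] = []
    for p in range(p_min, p_max + 1):
        for combo in itertools.combinations(usable, p):
            cpu, mem = combination_cost(combo, caller_meta, cost_mode)
            # Per dataset: support histogram over the union of the combo's keys.
            per_ds_counts = {}
            for ds in datasets:
                support: Counter = Counter()
                for caller in combo:
                    support.update(call_keys[caller][ds])
                truth = truth_keys[ds]
                # tp_at[t], calls_at[t]: counts of keys with support >= t
                tp_hist = np.zeros(p + 2, dtype=np.int64)
                call_hist = np.zeros(p + 2, dtype=np.int64)
                for key, count in support.items():
                    call_hist[count] += 1
                    if key in truth:
                        tp_hist[count] += 1
                tp_at = np.cumsum(tp_hist[::-1])[::-1]
                calls_at = np.cumsum(call_hist[::-1])[::-1]
                per_ds_counts[ds] = (tp_at, calls_at, len(truth))
            for t in range(1, p + 1):
                per_dataset = {}
                f1s = []
                for ds in datasets:
                    tp_at, calls_at, n_truth = per_ds_counts[ds]
                    tp = int(tp_at[t])
                    metrics = MetricSet(
                        tp=tp, fp=int(calls_at[t]) - tp, fn=n_truth - tp
                    )
                    per_dataset[ds] = metrics
                    if ds in scored_datasets:
                        f1s.append(metrics.f1)
                results.append(
                    EnsembleResult(
                        spec=EnsembleSpec(combo, t),
                        per_dataset_metrics=per_dataset,
                        mean_f1=mean_f1(f1s),
                        cpu_seconds_total=cpu,
                        peak_memory_mb_max=mem,
                    )
                )
    logger.info(
        "search evaluated %d combination x threshold results over %d datasets",
        len(results),
        len(datasets),
    )
    return results


def _best_key(result: EnsembleResult):
    # Max mean F1; ties -> fewer callers, then lexicographic ids, then lower t.
    return (-result.mean_f1, result.spec.size, result.spec.caller_ids, result.spec.threshold)


def pareto_front(results: Sequence[EnsembleResult]) -> list[EnsembleResult]:
    """Results non-dominated in (mean F1 max, CPU cost min)."""
    front = []
    for candidate in results:
        dominated = False
        for other in results:
            if (
                other.mean_f1 >= candidate.mean_f1
                and other.cpu_seconds_total <= candidate.cpu_seconds_total
                and (
                    other.mean_f1 > candidate.mean_f1
                    or other.cpu_seconds_total < candidate.cpu_seconds_total
                )
            ):
                dominated = True
                break
        if not dominated:
            front.append(candidate)
    return sorted(front, key=lambda r: (r.cpu_seconds_total, -r.mean_f1, _best_key(r)))


def select_tradeoff(
    results: Sequence[EnsembleResult], f1_tolerance: float = 0.001
) -> TradeoffReport:
    """Pick the cheapest result whose mean F1 is within tolerance of the best."""
    if not results:
        raise ValueError("select_tradeoff requires at least one result")
    if f1_tolerance < 0:
        raise ValueError("f1_tolerance must be >= 0")
    best = min(results, key=_best_key)
    cutoff = best.mean_f1 - f1_tolerance
    eligible = [r for r in results if r.mean_f1 >= cutoff]
    recommended = min(
        eligible,
        key=lambda r: (
            r.cpu_seconds_total,
            r.spec.size,
            r.spec.caller_ids,
            r.spec.threshold,
        ),
    )
    return TradeoffReport(
        best_by_mean_f1=best,
        pareto_front=pareto_front(results),
        recommended=recommended,
        f1_tolerance=f1_tolerance,
    )


# ---------------------------------------------------------------------------
# Tabular export


def results_to_frame(results: Sequence[EnsembleResult]) -> pd.DataFrame:
    """One row per (combination, threshold): size, callers, threshold,
    per-dataset F1s, mean F1, cost."""
    rows = []
    for result in results:
        row = {
            "size": result.spec.size,
            "callers": ",".join(result.spec.caller_ids),
            "threshold": result.spec.threshold,
            "mean_f1": result.mean_f1,
            "cpu_seconds_total": result.cpu_seconds_total,
            "peak_memory_mb_max": result.peak_memory_mb_max,
        }
        for ds, metrics in result.per_dataset_metrics.items():
            row[f"f1_{ds}"] = metrics.f1
        rows.append(row)
    return pd.DataFrame(rows)


def _result_payload(result: EnsembleResult) -> dict:
    return {
        "callers": list(result.spec.caller_ids),
        "threshold": result.spec.threshold,
        "mean_f1": result.mean_f1,
        "cpu_seconds_total": result.cpu_seconds_total,
        "peak_memory_mb_max": result.peak_memory_mb_max,
        "per_dataset": {
            ds: m.as_dict() for ds, m in result.per_dataset_metrics.items()
        },
    }


def tradeoff_to_json(report: TradeoffReport, path) -> None:
    payload = {
        "f1_tolerance": report.f1_tolerance,
        "best_by_mean_f1": _result_payload(report.best_by_mean_f1),
        "recommended": _result_payload(report.recommended),
        "pareto_front": [_result_payload(r) for r in report.pareto_front],
    }
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2)
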