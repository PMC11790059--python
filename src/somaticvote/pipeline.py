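"""High-level pipeline stages tying manifests to evaluation and search."""

from __future__ import annotations

import logging
from typing import Optional

import pandas as pd

from .evaluation import compare_to_truth, metrics_frame, rank_callers, RankTable
from .manifest import LoadedManifest
from .registry import CallerMeta, eligible_callers
from .search import EnsembleResult, run_search
from .variants import VariantClass, partition_by_class

logger = logging.getLogger(__name__)

EVALUATED_CLASSES = (VariantClass.SNV, VariantClass.INDEL)


def evaluate_manifest(manifest: LoadedManifest) -> pd.DataFrame:
    """Per-caller, per-dataset, per-class truth-set metrics (tidy frame)."""
    records = []
    for ds_id in sorted(manifest.datasets):
        dataset = manifest.datasets[ds_id]
        truth_parts = partition_by_class(dataset.truth)
        for caller in sorted(dataset.callsets):
            call_parts = partition_by_class(dataset.callsets[caller])
            for vc in EVALUATED_CLASSES:
                metrics = compare_to_truth(
                    call_parts[vc], truth_parts[vc], dataset.regions
                )
                records.append(
                    {
                        "caller": caller,
                        "dataset": ds_id,
                        "variant_class": vc,
                        "metrics": metrics,
                    }
                )
    frame = metrics_frame(records)
    logger.info("evaluated %d (caller, dataset, class) cells", len(frame))
    return frame


def rank_from_metrics(frame: pd.DataFrame, variant_class: VariantClass) -> RankTable:
    """Rank callers by F1 per dataset for one class, skipping undefined F1s."""
    sub = frame[(frame["class"] == variant_class.value) & frame["f1"].notna()]
    tables = {
        ds: dict(zip(group["caller"], group["f1"]))
        for ds, group in sub.groupby("dataset")
    }
    return rank_callers(tables)


def search_manifest(
    manifest: LoadedManifest,
    variant_class: VariantClass,
    p_min: int = 2,
    p_max: Optional[int] = None,
    cost_mode: str = "serial",
    callers: Optional[list[str]] = None,
    caller_meta: Optional[dict[str, CallerMeta]] = None,
) -> list[EnsembleResult]:
    """Exhaustive combination x threshold search for one variant class.

    Eligible callers are those flagged for the ensemble in the resource
    table, supporting the class, and present in the manifest.
    """
    meta = caller_meta if caller_meta is not None else manifest.caller_meta
    if meta is None:
        raise ValueError("search requires a caller resource table")
    available = set(manifest.callers())
    if callers is None:
        callers = [c for c in eligible_callers(variant_class, meta) if c in available]
    if not callers:
        raise ValueError(f"no eligible callers for {variant_class}")

    callsets = {}
    for caller in callers:
        callsets[caller] = {}
        for ds_id, dataset in manifest.datasets.items():
            if caller in dataset.callsets:
                parts = partition_by_class(dataset.callsets[caller])
                callsets[caller][ds_id] = parts[variant_class]
    truthsets = {
        ds_id: partition_by_class(ds.truth)[variant_class]
        for ds_id, ds in manifest.datasets.items()
    }
    regionsets = {ds_id: ds.regions for ds_id, ds in manifest.datasets.items()}
    return run_search(
        callsets,
        truthsets,
        regionsets,
        meta,
        callers=callers,
        p_min=p_min,
        p_max=p_max,
        cost_mode=cost_mode,
    )


def global_mean_f1(snv_mean_f1: float, indel_mean_f1: float) -> float:
    """Joint score across classes: unweighted mean of the two arm means.

    A joint recommendation spanning both arms unions the two caller sets
    for costing (a caller shared by the arms is paid for once).
    """
    return 0.5 * (snv_mean_f1 + indel_mean_f1)
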