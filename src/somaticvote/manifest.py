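"""Dataset manifest loading.

A manifest YAML names, per dataset, the truth VCF, the confidence-region
BED and one VCF per caller, plus a caller resource table; all paths are
resolved relative to the manifest file.

    datasets:
      - id: clonal3
        truth_vcf: clonal3.truth.vcf
        regions_bed: clonal3.regions.bed
        callers:
          alpha: clonal3.alpha.vcf
    resources_tsv: resources.tsv
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from . import vcfio
from .registry import CallerMeta, load_resource_table
from .variants import CallSet, RegionSet, TruthSet


@dataclass
class LoadedDataset:
    dataset_id: str
    truth: TruthSet
    regions: RegionSet
    callsets: dict[str, CallSet]


@dataclass
class LoadedManifest:
    datasets: dict[str, LoadedDataset]
    caller_meta: Optional[dict[str, CallerMeta]]

    def callers(self) -> list[str]:
        names = set()
        for ds in self.datasets.values():
            names.update(ds.callsets)
        return sorted(names)


def load_manifest(path, filter_policy: str = "pass_only") -> LoadedManifest:
    path = Path(path)
    with open(path) as handle:
        doc = yaml.safe_load(handle)
    base = path.parent

    def resolve(rel) -> Path:
        p = Path(rel)
        full = p if p.is_absolute() else base / p
        if not full.exists():
            raise FileNotFoundError(f"manifest references missing file: {full}")
        return full

    datasets = {}
    for entry in doc.get("datasets", []):
        ds_id = entry["id"]
        truth = vcfio.read_truthset(resolve(entry["truth_vcf"]), ds_id)
        regions = RegionSet.from_bed(resolve(entry["regions_bed"]))
        callsets = {
            caller: vcfio.read_callset(
                resolve(vcf_path), caller, ds_id, filter_policy=filter_policy
            )
            for caller, vcf_path in sorted(entry.get("callers", {}).items())
        }
        datasets[ds_id] = LoadedDataset(ds_id, truth, regions, callsets)
    caller_meta = None
    if doc.get("resources_tsv"):
        caller_meta = load_resource_table(resolve(doc["resources_tsv"]))
    return LoadedManifest(datasets=datasets, caller_meta=caller_meta)
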