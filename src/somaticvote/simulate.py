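"""Synthetic truth sets, correlated caller call sets, regions and resources.

The generator emulates the statistical structure the benchmark measures,
so every pipeline stage is testable without any sequencing data:

* truth sets with dataset-like sizes and VAF profiles — a clonal-mixture
  dataset (subclones at 50/33/20% VAF), two low-VAF datasets (median 10%
  and median 20%, the latter truncated to 2–60%), and one SNV-only set;
* caller call sets with a sensitivity-vs-VAF curve (logistic by default:
  low-VAF variants are the hard ones), a Poisson false-positive rate per
  megabase of region, and a *shared artifact pool* from which a
  configurable fraction of each caller's false positives is drawn — the
  knob controlling inter-caller FP correlation, which is what makes
  voting informative or not;
* BED confidence regions on two synthetic 5-Mb contigs;
* a per-caller CPU/memory resource table.

All randomness flows from a single seeded generator; the same seed
reproduces byte-identical VCF/BED/TSV outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import yaml

from . import vcfio
from .registry import CallerMeta, save_resource_table
from .variants import (
    CallSet,
    RegionSet,
    TruthSet,
    VariantClass,
    VariantKey,
)

_BASES = np.array(list("ACGT"))

DEFAULT_CONTIGS = {"syn1": 5_000_000, "syn2": 5_000_000}


# ---------------------------------------------------------------------------
# VAF models


@dataclass(frozen=True)
class ClonalMixtureVaf:
    """Discrete subclone VAFs (e.g. 50/33/20%), optionally weighted."""

    fractions: tuple[float, ...]
    weights: Optional[tuple[float, ...]] = None

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        probs = None
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            probs = w / w.sum()
        return rng.choice(np.asarray(self.fractions), size=n, p=probs)


@dataclass(frozen=True)
class BetaVaf:
    """Beta-distributed VAFs centred near ``median`` with optional truncation.

    Parameterised as Beta(median*concentration, (1-median)*concentration);
    for moderate concentration the distribution's median tracks the
    requested value closely.
    """

    median: float
    concentration: float = 8.0
    vmin: float = 0.0
    vmax: float = 1.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        a = self.median * self.concentration
        b = (1.0 - self.median) * self.concentration
        draws = rng.beta(a, b, size=n)
        return np.clip(draws, self.vmin, self.vmax)


# ---------------------------------------------------------------------------
# Profiles


@dataclass(frozen=True)
class DatasetProfile:
    dataset_id: str
    n_snv: int
    n_indel: int
    vaf_model: object
    contigs: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CONTIGS))


def bundled_profiles() -> dict[str, DatasetProfile]:
    """Four profiles mirroring the reference datasets' truth sizes and VAFs.

    clonal3 : 474 SNVs / 464 indels, three subclones at 50/33/20% VAF
    deep_lowvaf : 1160 SNVs / 50 indels, median VAF 10%
    clinical : 175 SNVs / 38 indels, VAF 2-60% with median 20%
    snv_only : 257 SNVs, no indels, median VAF 10%
    """
    return {
        "clonal3": DatasetProfile(
            "clonal3", 474, 464, ClonalMixtureVaf((0.50, 0.33, 0.20))
        ),
        "deep_lowvaf": DatasetProfile("deep_lowvaf", 1160, 50, BetaVaf(0.10)),
        "clinical": DatasetProfile(
            "clinical", 175, 38, BetaVaf(0.20, vmin=0.02, vmax=0.60)
        ),
        "snv_only": DatasetProfile("snv_only", 257, 0, BetaVaf(0.10)),
    }


# ---------------------------------------------------------------------------
# Sensitivity curves and caller error models


@dataclass(frozen=True)
class LogisticSensitivity:
    """Monotone logistic sensitivity-vs-VAF curve with a ceiling."""

    ceiling: float = 0.95
    midpoint: float = 0.02
    scale: float = 0.01

    def __call__(self, vaf: float) -> float:
        return self.ceiling / (1.0 + np.exp(-(vaf - self.midpoint) / self.scale))


@dataclass(frozen=True)
class ConstantSensitivity:
    """VAF-independent sensitivity (useful for closed-form checks)."""

    value: float

    def __call__(self, vaf: float) -> float:
        return self.value


@dataclass(frozen=True)
class CallerErrorModel:
    """Error behaviour of one synthetic caller.

    ``artifact_pool_affinity`` is the fraction of this caller's false
    positives drawn from the dataset's shared artifact pool; 0 gives
    independent FPs, 1 makes all FPs shared sites.
    """

    caller_id: str
    sensitivity: Callable[[float], float]
    fp_rate_per_mb: float
    artifact_pool_affinity: float
    supports: tuple[VariantClass, ...] = (VariantClass.SNV, VariantClass.INDEL)
    cpu_seconds: float = 3600.0
    peak_memory_mb: float = 4000.0

    def meta(self, eligible: bool = True) -> CallerMeta:
        return CallerMeta(
            caller_id=self.caller_id,
            supports=frozenset(self.supports),
            eligible_for_ensemble=eligible,
            cpu_seconds=self.cpu_seconds,
            peak_memory_mb=self.peak_memory_mb,
        )


# ---------------------------------------------------------------------------
# Generators


def generate_regions(
    contigs: Mapping[str, int],
    rng: np.random.Generator,
    n_intervals: int = 200,
    min_len: int = 1_000,
    max_len: int = 10_000,
) -> RegionSet:
    """Non-overlapping confidence intervals spread uniformly over the contigs."""
    names = sorted(contigs)
    per_contig = {name: [] for name in names}
    sizes = np.array([contigs[n] for n in names], dtype=float)
    for _ in range(n_intervals):
        contig = rng.choice(names, p=sizes / sizes.sum())
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, contigs[contig] - length))
        per_contig[contig].append((start, start + length))
    intervals = [
        (contig, start, end)
        for contig in names
        for start, end in per_contig[contig]
    ]
    return RegionSet.from_intervals(intervals)


def _positions_in_regions(
    regions: RegionSet, rng: np.random.Generator, n: int, margin: int = 10
) -> list[tuple[str, int]]:
    """Draw n distinct 1-based positions inside the regions (margin from edges)."""
    spans = [
        (contig, start + margin, end - margin)
        for contig, start, end in regions.intervals()
        if end - start > 2 * margin
    ]
    lengths = np.array([end - start for _, start, end in spans], dtype=np.int64)
    total = int(lengths.sum())
    if total < n * 2:
        raise ValueError(
            f"region space ({total} bp) too small for {n} distinct sites"
        )
    offsets = np.cumsum(lengths) - lengths
    chosen: set[tuple[str, int]] = set()
    out: list[tuple[str, int]] = []
    while len(out) < n:
        draw = int(rng.integers(0, total))
        idx = int(np.searchsorted(offsets, draw, side="right") - 1)
        contig, start, _end = spans[idx]
        pos = start + (draw - int(offsets[idx])) + 1  # 1-based
        site = (contig, pos)
        if site not in chosen:
            chosen.add(site)
            out.append(site)
    return out


def _random_snv_key(contig: str, pos: int, rng: np.random.Generator) -> VariantKey:
    ref, alt = rng.choice(_BASES, size=2, replace=False)
    return VariantKey(contig, pos, str(ref), str(alt))


def _random_indel_key(contig: str, pos: int, rng: np.random.Generator) -> VariantKey:
    anchor = str(rng.choice(_BASES))
    tail = "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
    if rng.random() < 0.5:
        return VariantKey(contig, pos, anchor, anchor + tail)  # insertion
    return VariantKey(contig, pos, anchor + tail, anchor)  # deletion


def generate_truth(
    profile: DatasetProfile,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    regions: Optional[RegionSet] = None,
) -> tuple[dict[VariantClass, TruthSet], RegionSet]:
    """Generate per-class truth sets and the confidence regions for one dataset."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if regions is None:
        regions = generate_regions(profile.contigs, rng)
    n_total = profile.n_snv + profile.n_indel
    sites = _positions_in_regions(regions, rng, n_total)
    vafs = profile.vaf_model.sample(rng, n_total)
    snv: dict[VariantKey, float] = {}
    indel: dict[VariantKey, float] = {}
    for i, (contig, pos) in enumerate(sites):
        if i < profile.n_snv:
            snv[_random_snv_key(contig, pos, rng)] = float(vafs[i])
        else:
            indel[_random_indel_key(contig, pos, rng)] = float(vafs[i])
    truths = {
        VariantClass.SNV: TruthSet(profile.dataset_id, snv, VariantClass.SNV),
        VariantClass.INDEL: TruthSet(profile.dataset_id, indel, VariantClass.INDEL),
    }
    return truths, regions


def generate_artifact_pool(
    regions: RegionSet,
    rng: np.random.Generator,
    size: int,
    variant_class: VariantClass = VariantClass.SNV,
) -> list[VariantKey]:
    """Shared pool of recurrent artifact sites every caller may draw FPs from."""
    sites = _positions_in_regions(regions, rng, size)
    make = _random_snv_key if variant_class is VariantClass.SNV else _random_indel_key
    return [make(contig, pos, rng) for contig, pos in sites]


def generate_callset(
    truth: TruthSet,
    regions: RegionSet,
    error_model: CallerErrorModel,
    shared_pool: Sequence[VariantKey],
    rng: np.random.Generator,
) -> CallSet:
    """Simulate one caller's call set for one dataset and variant class.

    Each truth variant is detected independently with probability
    sensitivity(VAF).  The FP count is Poisson(fp_rate x region
    megabases); each FP site comes from the shared artifact pool with
    probability ``artifact_pool_affinity`` and is otherwise a fresh
    uniform site inside the regions.
    """
    variants: dict[VariantKey, dict] = {}
    for key in sorted(truth.variants, key=lambda k: (k.contig, k.pos, k.ref, k.alt)):
        vaf = truth.variants[key]
        if rng.random() < error_model.sensitivity(0.0 if vaf is None else vaf):
            variants[key] = {"filter_status": "PASS", "vaf": vaf}
    mb = regions.total_length() / 1e6
    n_fp = int(rng.poisson(error_model.fp_rate_per_mb * mb))
    n_pool = int(rng.binomial(n_fp, error_model.artifact_pool_affinity)) if n_fp else 0
    if n_pool and shared_pool:
        picks = rng.choice(len(shared_pool), size=min(n_pool, len(shared_pool)), replace=False)
        for idx in sorted(int(i) for i in picks):
            key = shared_pool[idx]
            if key not in truth.variants:
                variants.setdefault(key, {"filter_status": "PASS", "vaf": 0.05})
    n_fresh = n_fp - n_pool
    if n_fresh > 0:
        make = (
            _random_snv_key
            if truth.variant_class is not VariantClass.INDEL
            else _random_indel_key
        )
        for contig, pos in _positions_in_regions(regions, rng, n_fresh):
            key = make(contig, pos, rng)
            if key not in truth.variants:
                variants.setdefault(key, {"filter_status": "PASS", "vaf": 0.05})
    return CallSet(
        caller_id=error_model.caller_id,
        dataset_id=truth.dataset_id,
        variants=variants,
        variant_class=truth.variant_class,
    )


# ---------------------------------------------------------------------------
# The designed end-to-end scenario


@dataclass
class Scenario:
    """A full synthetic study: truths, regions, per-caller call sets, resources.

    ``dominant_callers`` records the designed high-performing subset so
    that recovery of the best ensemble can be verified by exhaustive
    search.
    """

    seed: int
    profiles: dict[str, DatasetProfile]
    regions: dict[str, RegionSet]
    truths: dict[str, dict[VariantClass, TruthSet]]
    callsets: dict[str, dict[str, dict[VariantClass, CallSet]]]  # caller -> ds -> class
    caller_models: dict[str, CallerErrorModel]
    caller_meta: dict[str, CallerMeta]
    dominant_callers: frozenset

    def callsets_for_class(self, variant_class: VariantClass) -> dict[str, dict[str, CallSet]]:
        return {
            caller: {ds: by_class[variant_class] for ds, by_class in per_ds.items()}
            for caller, per_ds in self.callsets.items()
        }

    def truths_for_class(self, variant_class: VariantClass) -> dict[str, TruthSet]:
        return {ds: by_class[variant_class] for ds, by_class in self.truths.items()}

    def merged_truths(self) -> dict[str, TruthSet]:
        out = {}
        for ds, by_class in self.truths.items():
            merged: dict[VariantKey, Optional[float]] = {}
            for part in by_class.values():
                merged.update(part.variants)
            out[ds] = TruthSet(ds, merged)
        return out

    def merged_callsets(self) -> dict[str, dict[str, CallSet]]:
        out: dict[str, dict[str, CallSet]] = {}
        for caller, per_ds in self.callsets.items():
            out[caller] = {}
            for ds, by_class in per_ds.items():
                merged: dict[VariantKey, dict] = {}
                for part in by_class.values():
                    merged.update(part.variants)
                out[caller][ds] = CallSet(caller, ds, merged)
        return out

    def write(self, outdir) -> str:
        """Emit VCFs, BEDs, resource TSV and a manifest YAML; returns manifest path."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {"datasets": [], "resources_tsv": "resources.tsv"}
        merged_truths = self.merged_truths()
        merged_calls = self.merged_callsets()
        for ds in sorted(self.profiles):
            contigs = dict(self.profiles[ds].contigs)
            truth_path = outdir / f"{ds}.truth.vcf"
            bed_path = outdir / f"{ds}.regions.bed"
            vcfio.write_truth_vcf(merged_truths[ds], truth_path, contigs)
            self.regions[ds].to_bed(bed_path)
            entry = {
                "id": ds,
                "truth_vcf": truth_path.name,
                "regions_bed": bed_path.name,
                "callers": {},
            }
            for caller in sorted(self.callsets):
                call_path = outdir / f"{ds}.{caller}.vcf"
                vcfio.write_callset_vcf(merged_calls[caller][ds], call_path, contigs)
                entry["callers"][caller] = call_path.name
            manifest["datasets"].append(entry)
        save_resource_table(self.caller_meta, outdir / "resources.tsv")
        manifest_path = outdir / "manifest.yaml"
        with open(manifest_path, "w") as handle:
            yaml.safe_dump(manifest, handle, sort_keys=True)
        return str(manifest_path)


def designed_caller_models() -> tuple[dict[str, CallerErrorModel], frozenset]:
    """Eight synthetic callers with a designed dominant subset.

    alpha/bravo/charlie: high sensitivity, few and weakly correlated FPs.
    delta: nearly as sensitive, cheap, FPs more pool-bound — the designed
    cost-effective substitute.  echo..hotel: low sensitivity and heavy,
    strongly shared artifact load; voting cannot rescue them because
    their FPs co-occur.
    """
    strong = LogisticSensitivity(ceiling=0.97, midpoint=0.012, scale=0.006)
    budget = LogisticSensitivity(ceiling=0.90, midpoint=0.012, scale=0.006)
    weak = LogisticSensitivity(ceiling=0.55, midpoint=0.04, scale=0.02)
    models = {
        "alpha": CallerErrorModel("alpha", strong, 18.0, 0.5, cpu_seconds=4000, peak_memory_mb=6000),
        "bravo": CallerErrorModel("bravo", strong, 18.0, 0.5, cpu_seconds=1200, peak_memory_mb=2500),
        "charlie": CallerErrorModel("charlie", strong, 18.0, 0.5, cpu_seconds=7000, peak_memory_mb=9000),
        "delta": CallerErrorModel("delta", budget, 25.0, 0.8, cpu_seconds=600, peak_memory_mb=1500),
        "echo": CallerErrorModel("echo", weak, 200.0, 0.85, cpu_seconds=2000, peak_memory_mb=4000),
        "foxtrot": CallerErrorModel("foxtrot", weak, 200.0, 0.85, cpu_seconds=3500, peak_memory_mb=7500),
        "golf": CallerErrorModel("golf", weak, 200.0, 0.85, cpu_seconds=900, peak_memory_mb=1000),
        "hotel": CallerErrorModel("hotel", weak, 200.0, 0.85, cpu_seconds=5000, peak_memory_mb=12000),
    }
    return models, frozenset({"alpha", "bravo", "charlie", "delta"})


#: the "similar performance" scale of the designed scenario, used when
#: selecting the cost-effective ensemble on it (combination mean F1s sit
#: around 0.99 there, so 0.015 separates designed near-ties from real gaps)
DESIGNED_F1_TOLERANCE = 0.015

SNV_POOL_SIZE = 60
INDEL_POOL_SIZE = 25


def designed_scenario(seed: int = 0) -> Scenario:
    """Generate the full 4-dataset x 8-caller designed study."""
    rng = np.random.default_rng(seed)
    profiles = bundled_profiles()
    models, dominant = designed_caller_models()
    regions: dict[str, RegionSet] = {}
    truths: dict[str, dict[VariantClass, TruthSet]] = {}
    callsets: dict[str, dict[str, dict[VariantClass, CallSet]]] = {
        caller: {} for caller in models
    }
    for ds in sorted(profiles):
        truth_by_class, region_set = generate_truth(profiles[ds], rng=rng)
        regions[ds] = region_set
        truths[ds] = truth_by_class
        pools = {
            VariantClass.SNV: generate_artifact_pool(
                region_set, rng, SNV_POOL_SIZE, VariantClass.SNV
            ),
            VariantClass.INDEL: generate_artifact_pool(
                region_set, rng, INDEL_POOL_SIZE, VariantClass.INDEL
            ),
        }
        for caller in sorted(models):
            callsets[caller][ds] = {
                vc: generate_callset(
                    truth_by_class[vc], region_set, models[caller], pools[vc], rng
                )
                for vc in (VariantClass.SNV, VariantClass.INDEL)
            }
    caller_meta = {caller: model.meta() for caller, model in models.items()}
    return Scenario(
        seed=seed,
        profiles=profiles,
        regions=regions,
        truths=truths,
        callsets=callsets,
        caller_models=models,
        caller_meta=caller_meta,
        dominant_callers=dominant,
    )
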