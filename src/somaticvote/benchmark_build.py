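"""Multi-sample benchmark construction by VAF-preserving downsampling.

Builds one high-depth virtual tumor/normal pair from many patient pairs
(36 in the reference design) with a two-step procedure:

(i)  outside the regions containing somatic mutations, every sample's
     reads are kept independently with probability 1/n_samples, decided
     at mate-pair granularity, so the merged depth matches one sample's;
(ii) inside a mutation region, reads are taken exclusively and
     completely from the sample in which that somatic mutation was
     observed — keeping all and only the source sample's reads is what
     preserves the variant allele fraction exactly.

Keep/drop decisions in step (i) come from a seeded hash of the mate-pair
identity, so the procedure is reproducible and streaming-friendly.

Truth candidates observed in several samples at the same site are
deduplicated by keeping the highest-VAF sample's allele, which also
prevents multiallelic truth sites.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam

from .variants import RegionSet, TruthSet, VariantKey

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadRecord:
    """One aligned read: 0-based half-open alignment span plus mate-pair group."""

    read_id: str
    sample_id: str
    contig: str
    start: int
    end: int
    pair_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"read {self.read_id}: start must be < end")


@dataclass(frozen=True)
class SourceRegion:
    """A mutation-bearing interval (BED convention) with its source sample."""

    contig: str
    start: int
    end: int
    source_sample: str


@dataclass
class DownsampleSpec:
    n_samples: int
    mutation_regions: Sequence[SourceRegion] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    @property
    def fraction(self) -> float:
        return 1.0 / self.n_samples

    def region_set(self) -> RegionSet:
        if not self.mutation_regions:
            return RegionSet.from_intervals([])
        return RegionSet.from_intervals(
            [(r.contig, r.start, r.end) for r in self.mutation_regions]
        )


def _hash_uniform(seed: int, *tokens: str) -> float:
    """Deterministic uniform in [0, 1) from a seed and identifying tokens."""
    payload = ":".join([str(seed), *tokens]).encode()
    digest = hashlib.blake2b(payload, digest_size=8).digest()
    return int.from_bytes(digest, "big") / 2**64


def _overlapping_sources(
    reads: Sequence[ReadRecord], regions: Sequence[SourceRegion]
) -> set[str]:
    """Source samples of every mutation region any mate of the pair touches."""
    sources = set()
    for region in regions:
        for read in reads:
            if read.contig == region.contig and read.start < region.end and region.start < read.end:
                sources.add(region.source_sample)
                break
    return sources


def downsample_read_set(
    reads_by_sample: Mapping[str, Sequence[ReadRecord]],
    spec: DownsampleSpec,
    seed: int,
    arm: str = "tumor",
) -> list[ReadRecord]:
    """Apply the two-step downsampling to one arm (tumor or normal).

    Mate pairs are kept or dropped together.  A pair overlapping a
    mutation region is kept iff it belongs to that region's source
    sample; a pair overlapping regions with conflicting sources is kept
    if it comes from either source (with a warning).  All other pairs are
    kept with probability 1/n_samples via the seeded hash.
    """
    known_samples = set(reads_by_sample)
    for region in spec.mutation_regions:
        if region.source_sample not in known_samples:
            raise ValueError(
                f"mutation region {region.contig}:{region.start}-{region.end} "
                f"names unknown source sample {region.source_sample!r}"
            )
    merged: list[ReadRecord] = []
    for sample in sorted(reads_by_sample):
        pairs: dict[str, list[ReadRecord]] = defaultdict(list)
        for read in reads_by_sample[sample]:
            if read.sample_id != sample:
                raise ValueError(
                    f"read {read.read_id} carries sample {read.sample_id}, "
                    f"listed under {sample}"
                )
            pairs[read.pair_id].append(read)
        for pair_id in sorted(pairs):
            mates = pairs[pair_id]
            sources = _overlapping_sources(mates, spec.mutation_regions)
            if sources:
                if len(sources) > 1:
                    warnings.warn(
                        f"pair {sample}/{pair_id} spans mutation regions with "
                        f"different sources {sorted(sources)}; kept if from either"
                    )
                if sample in sources:
                    merged.extend(mates)
            elif _hash_uniform(seed, arm, sample, pair_id) < spec.fraction:
                merged.extend(mates)
    merged.sort(key=lambda r: (r.contig, r.start, r.end, r.sample_id, r.read_id))
    return merged


def merge_with_downsampling(
    tumor_by_sample: Mapping[str, Sequence[ReadRecord]],
    normal_by_sample: Mapping[str, Sequence[ReadRecord]],
    spec: DownsampleSpec,
    seed: int,
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Merge per-sample tumor and normal read sets into one downsampled pair."""
    if set(tumor_by_sample) != set(normal_by_sample):
        raise ValueError("tumor and normal read sets must cover the same samples")
    tumor = downsample_read_set(tumor_by_sample, spec, seed, arm="tumor")
    normal = downsample_read_set(normal_by_sample, spec, seed, arm="normal")
    logger.info(
        "merged %d samples: kept %d tumor and %d normal reads",
        len(tumor_by_sample),
        len(tumor),
        len(normal),
    )
    return tumor, normal


# ---------------------------------------------------------------------------
# Truth-set deduplication


@dataclass(frozen=True)
class TruthCandidate:
    contig: str
    pos: int
    ref: str
    alt: str
    sample_id: str
    vaf: float


def dedupe_truth_by_vaf(
    candidates: Iterable[TruthCandidate], dataset_id: str = "merged"
) -> TruthSet:
    """Keep, per (contig, pos, ref) site, only the highest-VAF sample's allele.

    Ties are broken toward the lexicographically smallest sample id, with
    a warning.  The result has at most one alt per site, so the merged
    truth set contains no multiallelic entries.
    """
    by_site: dict[tuple, TruthCandidate] = {}
    for cand in candidates:
        site = (cand.contig, cand.pos, cand.ref)
        best = by_site.get(site)
        if best is None:
            by_site[site] = cand
        elif cand.vaf > best.vaf:
            by_site[site] = cand
        elif cand.vaf == best.vaf and cand.sample_id != best.sample_id:
            warnings.warn(
                f"VAF tie at {cand.contig}:{cand.pos} between samples "
                f"{best.sample_id} and {cand.sample_id}; keeping the "
                "lexicographically smaller sample"
            )
            if cand.sample_id < best.sample_id:
                by_site[site] = cand
    variants = {
        VariantKey(c.contig, c.pos, c.ref, c.alt): c.vaf for c in by_site.values()
    }
    return TruthSet(dataset_id=dataset_id, variants=variants)


def read_truth_candidates(path) -> list[TruthCandidate]:
    """TSV with columns contig, pos, ref, alt, sample, vaf."""
    frame = pd.read_csv(path, sep="\t")
    return [
        TruthCandidate(
            contig=str(row.contig),
            pos=int(row.pos),
            ref=str(row.ref),
            alt=str(row.alt),
            sample_id=str(row.sample),
            vaf=float(row.vaf),
        )
        for row in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# SAM interface


def read_source_regions_bed(path) -> list[SourceRegion]:
    """BED4 where the 4th column names the source sample of each region."""
    regions = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: need 4 BED columns (source sample)")
            regions.append(
                SourceRegion(fields[0], int(fields[1]), int(fields[2]), fields[3])
            )
    return regions


def downsample_sam(
    tumor_paths: Mapping[str, object],
    normal_paths: Mapping[str, object],
    regions_bed,
    n_samples: Optional[int],
    seed: int,
    out_tumor,
    out_normal,
) -> None:
    """SAM-in/SAM-out wrapper around :func:`merge_with_downsampling`.

    Reads per-sample SAM files, applies the two-step procedure and emits
    coordinate-sorted SAM.  Contig headers are taken from the first tumor
    sample; all inputs must share contigs.  Original alignment records
    are passed through untouched for the kept pairs.
    """
    spec = DownsampleSpec(
        n_samples=n_samples if n_samples is not None else len(tumor_paths),
        mutation_regions=read_source_regions_bed(regions_bed),
    )
    for arm, paths, out_path in (
        ("tumor", tumor_paths, out_tumor),
        ("normal", normal_paths, out_normal),
    ):
        alignments: dict[tuple[str, str], list] = defaultdict(list)
        reads_by_sample: dict[str, list[ReadRecord]] = {}
        header = None
        for sample in sorted(paths):
            with pysam.AlignmentFile(str(paths[sample]), "r") as sam:
                if header is None:
                    header = sam.header
                for aln in sam:
                    if aln.is_unmapped or aln.reference_start is None:
                        continue
                    alignments[(sample, aln.query_name)].append(aln.to_dict())
                    reads_by_sample.setdefault(sample, []).append(
                        ReadRecord(
                            read_id=f"{aln.query_name}/{2 if aln.is_read2 else 1}",
                            sample_id=sample,
                            contig=aln.reference_name,
                            start=aln.reference_start,
                            end=aln.reference_end,
                            pair_id=aln.query_name,
                        )
                    )
            reads_by_sample.setdefault(sample, [])
        kept = downsample_read_set(reads_by_sample, spec, seed, arm=arm)
        kept_pairs = {(r.sample_id, r.pair_id) for r in kept}
        out_alns = []
        with pysam.AlignmentFile(str(paths[sorted(paths)[0]]), "r") as template:
            header = template.header
        for sample, qname in sorted(kept_pairs):
            for payload in alignments[(sample, qname)]:
                out_alns.append(pysam.AlignedSegment.from_dict(payload, header))
        out_alns.sort(key=lambda a: (a.reference_id, a.reference_start, a.query_name))
        with pysam.AlignmentFile(str(out_path), "wh", header=header) as out:
            for aln in out_alns:
                out.write(aln)
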