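"""Data model for somatic call sets, truth sets and confidence regions.

Variant identity throughout the package is the normalized 4-tuple
(contig, 1-based position, ref allele, alt allele).  Normalization means
parsimonious (no shared suffix; shared prefix reduced to a single anchor
base for indels, none for SNVs) and, when reference context is available,
left-aligned.  All set comparisons — truth-set evaluation and ensemble
voting alike — operate on these keys, so two callers "agree" on a variant
exactly when their normalized keys are equal.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from typing import Optional

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

_ALLELE_ALPHABET = frozenset("ACGTN")


class VcfFormatError(ValueError):
    """Raised when a VCF source cannot be parsed."""


class VariantClass(enum.Enum):
    """Variant class partition used for all downstream evaluation.

    SNV: single-base substitution; INDEL: alleles of unequal length;
    OTHER: equal-length multi-base substitution (MNV), reported but
    excluded from SNV/indel evaluation.
    """

    SNV = "SNV"
    INDEL = "INDEL"
    OTHER = "OTHER"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def classify(ref: str, alt: str) -> VariantClass:
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SNV
    if len(ref) != len(alt):
        return VariantClass.INDEL
    return VariantClass.OTHER


@dataclass(frozen=True, slots=True)
class VariantKey:
    """Normalized identity of one variant.

    ``pos`` is 1-based (VCF convention).  Equality and hashing use the
    4-tuple only; construct via :func:`normalize_key` unless the spelling
    is already normalized.
    """

    contig: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) is not a variant")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _ALLELE_ALPHABET:
                raise ValueError(f"allele {allele!r} outside alphabet ACGTN")

    @property
    def variant_class(self) -> VariantClass:
        return classify(self.ref, self.alt)


def _ref_base(reference, contig: str, pos1: int) -> str:
    """Fetch the reference base at 1-based ``pos1``.

    ``reference`` may be any mapping from contig name to a sliceable
    sequence (plain str, pyfaidx record, Bio.Seq...).
    """
    seq = reference[contig]
    return str(seq[pos1 - 1]).upper()


def normalize_key(
    contig: str,
    pos: int,
    ref: str,
    alt: str,
    reference: Optional[Mapping[str, object]] = None,
) -> VariantKey:
    """Return the parsimonious, left-aligned key for one (pos, ref, alt).

    Trims any shared suffix, left-shifts indels while upstream reference
    context is available (``reference`` maps contig -> sequence; omit it
    to trim without shifting), then trims the shared prefix down to a
    single anchor base for indels and none for SNVs.  Idempotent.
    """
    if pos <= 0:
        raise ValueError(f"position must be >= 1, got {pos}")
    ref = ref.upper()
    alt = alt.upper()
    if not ref or not alt:
        raise ValueError("ref and alt must be non-empty")
    if ref == alt:
        raise ValueError("ref == alt is not a variant")

    # Suffix trimming with left extension (standard left-alignment loop).
    while ref[-1] == alt[-1]:
        if len(ref) > 1 and len(alt) > 1:
            ref, alt = ref[:-1], alt[:-1]
        elif reference is not None and pos > 1:
            base = _ref_base(reference, contig, pos - 1)
            ref = base + ref[:-1]
            alt = base + alt[:-1]
            pos -= 1
        else:
            break

    # Prefix trimming: keep one anchor base for indels (stops automatically
    # because the shorter allele reaches length 1), none for SNV/MNV cores.
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1

    return VariantKey(contig, pos, ref, alt)


# ---------------------------------------------------------------------------
# Regions


def _contig_aliases(contig: str) -> tuple[str, ...]:
    # "chr1" and "1" style names are treated as the same contig.
    if contig.startswith("chr"):
        return (contig, contig[3:])
    return (contig, "chr" + contig)


@dataclass
class RegionSet:
    """Merged, non-overlapping intervals in BED convention (0-based, half-open)."""

    _trees: dict[str, IntervalTree] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[str, int, int]]) -> "RegionSet":
        trees: dict[str, IntervalTree] = {}
        for contig, start, end in intervals:
            if start >= end:
                raise ValueError(f"empty interval {contig}:{start}-{end}")
            trees.setdefault(contig, IntervalTree()).addi(start, end)
        for tree in trees.values():
            tree.merge_overlaps(strict=False)
        return cls(trees)

    @classmethod
    def from_bed(cls, path) -> "RegionSet":
        intervals = []
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: BED line has <3 columns")
                intervals.append((fields[0], int(fields[1]), int(fields[2])))
        return cls.from_intervals(intervals)

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for contig in sorted(self._trees):
            for iv in sorted(self._trees[contig]):
                out.append((contig, iv.begin, iv.end))
        return out

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())

    def total_length(self) -> int:
        return sum(iv.end - iv.begin for _, t in self._trees.items() for iv in t)

    def contains_position(self, contig: str, pos: int) -> bool:
        """True if the 1-based position lies inside a region (start < pos <= end)."""
        for name in _contig_aliases(contig):
            tree = self._trees.get(name)
            if tree is not None and tree.overlaps_point(pos - 1):
                return True
        return False

    def overlaps_span(self, contig: str, start: int, end: int) -> bool:
        """True if the 0-based half-open span [start, end) intersects a region."""
        for name in _contig_aliases(contig):
            tree = self._trees.get(name)
            if tree is not None and tree.overlap(start, end):
                return True
        return False

    def to_bed(self, path) -> None:
        with open(path, "w") as handle:
            for contig, start, end in self.intervals():
                handle.write(f"{contig}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Call sets and truth sets


@dataclass
class CallSet:
    """One caller's somatic calls for one dataset.

    ``variants`` maps normalized keys to per-variant attributes
    (``filter_status``, optional ``vaf``).  ``stats`` keeps record-count
    bookkeeping from VCF ingestion (read/kept/dropped/decomposed).
    """

    caller_id: str
    dataset_id: str
    variants: dict[VariantKey, dict] = field(default_factory=dict)
    variant_class: Optional[VariantClass] = None
    stats: dict[str, int] = field(default_factory=dict)

    def keys(self) -> set[VariantKey]:
        return set(self.variants)

    def __len__(self) -> int:
        return len(self.variants)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.variants


@dataclass
class TruthSet:
    """Positive set P of true somatic variants with VAFs for one dataset."""

    dataset_id: str
    variants: dict[VariantKey, Optional[float]] = field(default_factory=dict)
    variant_class: Optional[VariantClass] = None

    def keys(self) -> set[VariantKey]:
        return set(self.variants)

    def __len__(self) -> int:
        return len(self.variants)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.variants


def restrict_to_regions(collection, regions: RegionSet):
    """Keep variants whose anchor position lies inside the region set.

    Works on CallSet and TruthSet alike and returns the same type; the
    number of removed variants is logged.  An empty region set yields an
    empty result with a warning.
    """
    if len(regions) == 0:
        warnings.warn("empty region set: restriction removes every variant")
    kept = {
        key: val
        for key, val in collection.variants.items()
        if regions.contains_position(key.contig, key.pos)
    }
    removed = len(collection.variants) - len(kept)
    if removed:
        logger.info(
            "region restriction removed %d/%d variants", removed, len(collection.variants)
        )
    out = dataclasses.replace(collection, variants=kept)
    if isinstance(out, CallSet):
        out.stats = dict(collection.stats, region_removed=removed)
    return out


def partition_by_class(collection):
    """Split a CallSet or TruthSet into exactly three per-class parts.

    The parts are disjoint and their union equals the input.  Class OTHER
    (MNVs) is reported but excluded from downstream evaluation by default.
    """
    parts = {vc: {} for vc in VariantClass}
    for key, val in collection.variants.items():
        parts[key.variant_class][key] = val
    return {
        vc: dataclasses.replace(collection, variants=part, variant_class=vc)
        for vc, part in parts.items()
    }
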