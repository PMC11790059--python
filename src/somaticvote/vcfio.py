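"""VCF ingestion and emission (pysam-backed).

Records are decomposed (one key per alt allele), normalized and
classified on the way in.  Under the default ``pass_only`` filter policy
a record votes only if its FILTER column is PASS or "."; a caller's
filtered records are dropped before any evaluation or voting.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional

import pysam

from .variants import (
    CallSet,
    TruthSet,
    VariantKey,
    VcfFormatError,
    normalize_key,
)

logger = logging.getLogger(__name__)

FILTER_POLICIES = ("pass_only", "all")


def _record_passes(record) -> bool:
    filters = list(record.filter.keys())
    return not filters or filters == ["PASS"]


def _record_vaf(record) -> Optional[float]:
    for tag in ("VAF", "AF"):
        if tag in record.info:
            value = record.info[tag]
            if isinstance(value, (tuple, list)):
                value = value[0]
            try:
                return float(value)
            except (TypeError, ValueError):
                return None
    return None


def _iter_decomposed(
    path,
    filter_policy: str,
    reference: Optional[Mapping[str, object]],
    known_contigs: Optional[set] = None,
    stats: Optional[dict] = None,
):
    """Yield (key, filter_status, vaf) per kept alt, filling ``stats`` in place."""
    if filter_policy not in FILTER_POLICIES:
        raise ValueError(f"filter_policy must be one of {FILTER_POLICIES}")
    if stats is None:
        stats = {}
    stats.update(records_read=0, records_kept=0, records_dropped=0, keys_decomposed=0)
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfFormatError(f"cannot parse VCF {path}: {exc}") from exc
    with vcf:
        record_no = 0
        while True:
            try:
                record = next(vcf, None)
            except (OSError, ValueError) as exc:
                raise VcfFormatError(
                    f"cannot parse VCF {path} at record {record_no + 1}: {exc}"
                ) from exc
            if record is None:
                break
            record_no += 1
            stats["records_read"] += 1
            if filter_policy == "pass_only" and not _record_passes(record):
                stats["records_dropped"] += 1
                continue
            if known_contigs is not None and record.chrom not in known_contigs:
                logger.warning(
                    "%s: contig %s absent from reference index (record kept)",
                    path,
                    record.chrom,
                )
            stats["records_kept"] += 1
            passes = _record_passes(record)
            vaf = _record_vaf(record)
            for alt in record.alts or ():
                if set(alt.upper()) - set("ACGTN"):
                    # symbolic / breakend alleles are outside small-variant scope
                    continue
                key = normalize_key(record.chrom, record.pos, record.ref, alt, reference)
                stats["keys_decomposed"] += 1
                yield key, ("PASS" if passes else ";".join(record.filter.keys())), vaf
    logger.info(
        "%s: read %d records, kept %d, dropped %d, decomposed %d keys",
        path,
        stats["records_read"],
        stats["records_kept"],
        stats["records_dropped"],
        stats["keys_decomposed"],
    )


def read_callset(
    vcf_source,
    caller_id: str,
    dataset_id: str,
    filter_policy: str = "pass_only",
    reference: Optional[Mapping[str, object]] = None,
    known_contigs: Optional[set] = None,
) -> CallSet:
    """Read one caller's VCF into a normalized CallSet."""
    variants: dict[VariantKey, dict] = {}
    stats: dict[str, int] = {}
    for key, filter_status, vaf in _iter_decomposed(
        vcf_source, filter_policy, reference, known_contigs, stats
    ):
        attrs = {"filter_status": filter_status}
        if vaf is not None:
            attrs["vaf"] = vaf
        variants[key] = attrs
    return CallSet(
        caller_id=caller_id, dataset_id=dataset_id, variants=variants, stats=stats
    )


def read_truthset(
    vcf_source,
    dataset_id: str,
    reference: Optional[Mapping[str, object]] = None,
) -> TruthSet:
    """Read a truth-set VCF (all records count; truth sets carry no caller filters)."""
    variants: dict[VariantKey, Optional[float]] = {}
    for key, _status, vaf in _iter_decomposed(vcf_source, "all", reference):
        variants[key] = vaf
    return TruthSet(dataset_id=dataset_id, variants=variants)


def read_contigs(path) -> dict[str, int]:
    """Contig names and lengths declared in a VCF header."""
    with pysam.VariantFile(str(path)) as vcf:
        return {name: rec.length or 0 for name, rec in vcf.header.contigs.items()}


# ---------------------------------------------------------------------------
# Emission


def _make_header(contigs: Mapping[str, int], info_lines: list[tuple]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    for number_type in info_lines:
        header.info.add(*number_type)
    return header


def _sorted_keys(keys, contigs: Mapping[str, int]):
    order = {name: i for i, name in enumerate(contigs)}
    return sorted(keys, key=lambda k: (order.get(k.contig, len(order)), k.pos, k.ref, k.alt))


def write_callset_vcf(callset: CallSet, path, contigs: Mapping[str, int]) -> None:
    """Emit a normalized call set as sorted VCF with a CALLER tag (INFO dropped)."""
    header = _make_header(
        contigs,
        [
            ("CALLER", 1, "String", "Caller that produced this call"),
            ("VAF", 1, "Float", "Variant allele frequency"),
        ],
    )
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for key in _sorted_keys(callset.variants, contigs):
            attrs = callset.variants[key]
            rec = out.new_record(
                contig=key.contig, start=key.pos - 1, alleles=(key.ref, key.alt)
            )
            rec.filter.add("PASS")
            rec.info["CALLER"] = callset.caller_id
            if attrs.get("vaf") is not None:
                rec.info["VAF"] = float(attrs["vaf"])
            out.write(rec)


def write_truth_vcf(truthset: TruthSet, path, contigs: Mapping[str, int]) -> None:
    header = _make_header(
        contigs, [("VAF", 1, "Float", "Variant allele frequency in the tumor")]
    )
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for key in _sorted_keys(truthset.variants, contigs):
            vaf = truthset.variants[key]
            rec = out.new_record(
                contig=key.contig, start=key.pos - 1, alleles=(key.ref, key.alt)
            )
            rec.filter.add("PASS")
            if vaf is not None:
                rec.info["VAF"] = float(vaf)
            out.write(rec)


def write_consensus_vcf(consensus, path, contigs: Mapping[str, int]) -> None:
    """Emit a consensus call set with SUPPORT and CALLERS INFO fields."""
    header = _make_header(
        contigs,
        [
            ("SUPPORT", 1, "Integer", "Number of callers reporting this variant"),
            ("CALLERS", ".", "String", "Callers reporting this variant"),
        ],
    )
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for key in _sorted_keys(consensus.variants, contigs):
            rec = out.new_record(
                contig=key.contig, start=key.pos - 1, alleles=(key.ref, key.alt)
            )
            rec.filter.add("PASS")
            rec.info["SUPPORT"] = consensus.variants[key]
            supporters = consensus.supporters.get(key)
            if supporters:
                rec.info["CALLERS"] = ",".join(sorted(supporters))
            out.write(rec)
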