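"""Two-step VAF-preserving downsampling merge and truth deduplication."""

from __future__ import annotations

import numpy as np
import pytest
import pysam

from somaticvote.benchmark_build import (
    DownsampleSpec,
    ReadRecord,
    SourceRegion,
    TruthCandidate,
    dedupe_truth_by_vaf,
    downsample_read_set,
    downsample_sam,
    merge_with_downsampling,
)
from somaticvote.variants import VariantKey

from .oracles import groupby_max_vaf_oracle


def make_pairs(sample, n_pairs, contig="c", start=0, spacing=300, allele=None, rng=None):
    """n_pairs mate pairs of 100-bp reads, optionally tagged with an allele label."""
    reads = []
    for i in range(n_pairs):
        left = start + i * spacing
        tag = "" if allele is None else f":{allele[i]}"
        for mate, offset in ((1, 0), (2, 150)):
            reads.append(
                ReadRecord(
                    read_id=f"{sample}.p{i}/{mate}{tag}",
                    sample_id=sample,
                    contig=contig,
                    start=left + offset,
                    end=left + offset + 100,
                    pair_id=f"{sample}.p{i}{tag}",
                )
            )
    return reads


class TestDownsampling:
    def test_single_sample_identity(self):
        reads = make_pairs("s1", 50)
        spec = DownsampleSpec(n_samples=1)
        kept = downsample_read_set({"s1": reads}, spec, seed=0)
        assert sorted(kept, key=lambda r: r.read_id) == sorted(
            reads, key=lambda r: r.read_id
        )

    def test_kept_fraction_within_binomial_bounds(self):
        n_samples, n_pairs = 36, 2000
        reads = {f"s{i:02d}": make_pairs(f"s{i:02d}", n_pairs) for i in range(n_samples)}
        spec = DownsampleSpec(n_samples=n_samples)
        kept = downsample_read_set(reads, spec, seed=11)
        f = 1.0 / n_samples
        sigma = np.sqrt(n_pairs * f * (1 - f))
        per_sample = {s: 0 for s in reads}
        for read in kept:
            per_sample[read.sample_id] += 1
        # 4 sigma per sample keeps the family-wise error across the 36
        # simultaneous checks near 0.2%; the total gets the plain 3-sigma bound
        for sample, n_reads in per_sample.items():
            n_kept_pairs = n_reads / 2
            assert abs(n_kept_pairs - n_pairs * f) <= 4 * sigma, sample
        total_pairs = len(kept) / 2
        total_sigma = np.sqrt(n_samples * n_pairs * f * (1 - f))
        assert abs(total_pairs - n_pairs) <= 3 * total_sigma

    def test_mate_pairs_kept_or_dropped_together(self):
        reads = {f"s{i}": make_pairs(f"s{i}", 500) for i in range(4)}
        spec = DownsampleSpec(n_samples=4)
        kept = downsample_read_set(reads, spec, seed=5)
        by_pair = {}
        for read in kept:
            by_pair.setdefault((read.sample_id, read.pair_id), []).append(read)
        assert all(len(mates) == 2 for mates in by_pair.values())

    def test_mutation_region_reads_come_only_from_source(self):
        region = SourceRegion("c", 1000, 2000, "s1")
        reads = {
            "s1": make_pairs("s1", 80, start=900, spacing=10),
            "s2": make_pairs("s2", 80, start=900, spacing=10),
            "s3": make_pairs("s3", 200, start=50_000, spacing=400),
        }
        spec = DownsampleSpec(n_samples=3, mutation_regions=(region,))
        kept = downsample_read_set(reads, spec, seed=1)
        overlapping = [
            r for r in kept if r.contig == "c" and r.start < 2000 and r.end > 1000
        ]
        assert overlapping, "source reads over the region must be present"
        assert {r.sample_id for r in overlapping} == {"s1"}
        # every s1 pair with a mate over the region is kept completely
        s1_overlapping_pairs = {
            r.pair_id for r in reads["s1"] if r.start < 2000 and r.end > 1000
        }
        kept_ids = {r.read_id for r in kept}
        for read in reads["s1"]:
            if read.pair_id in s1_overlapping_pairs:
                assert read.read_id in kept_ids

    def test_vaf_preserved_exactly_over_mutation_region(self):
        # source sample carries the alternate allele on 30% of its pairs
        n_pairs = 40
        alleles = ["alt"] * 12 + ["ref"] * 28
        region = SourceRegion("c", 0, 20_000, "s1")
        reads = {
            "s1": make_pairs("s1", n_pairs, start=0, spacing=400, allele=alleles),
            "s2": make_pairs("s2", n_pairs, start=0, spacing=400, allele=["ref"] * n_pairs),
        }
        spec = DownsampleSpec(n_samples=2, mutation_regions=(region,))
        kept = downsample_read_set(reads, spec, seed=3)
        in_region = [r for r in kept if r.start < 20_000]
        assert len(in_region) == 2 * n_pairs  # all and only s1's pairs
        alt_fraction = sum(":alt" in r.read_id for r in in_region) / len(in_region)
        assert alt_fraction == pytest.approx(12 / 40)

    def test_conflicting_region_sources_warn_but_keep_either(self):
        regions = (
            SourceRegion("c", 100, 400, "s1"),
            SourceRegion("c", 350, 700, "s2"),
        )
        # one long-insert pair from s1 spanning both regions
        straddler = [
            ReadRecord("s1.x/1", "s1", "c", 150, 250, "s1.x"),
            ReadRecord("s1.x/2", "s1", "c", 380, 480, "s1.x"),
        ]
        reads = {"s1": straddler, "s2": [ReadRecord("s2.y/1", "s2", "c", 360, 460, "s2.y")]}
        spec = DownsampleSpec(n_samples=2, mutation_regions=regions)
        with pytest.warns(UserWarning, match="different sources"):
            kept = downsample_read_set(reads, spec, seed=0)
        assert {r.read_id for r in kept} >= {"s1.x/1", "s1.x/2"}

    def test_unknown_source_sample_is_a_configuration_error(self):
        spec = DownsampleSpec(
            n_samples=2, mutation_regions=(SourceRegion("c", 0, 10, "ghost"),)
        )
        with pytest.raises(ValueError, match="ghost"):
            downsample_read_set({"s1": [], "s2": []}, spec, seed=0)

    def test_merge_requires_matching_sample_sets(self):
        spec = DownsampleSpec(n_samples=1)
        with pytest.raises(ValueError, match="same samples"):
            merge_with_downsampling({"s1": []}, {"s2": []}, spec, seed=0)

    def test_tumor_and_normal_arms_are_independent(self):
        reads = {f"s{i}": make_pairs(f"s{i}", 300) for i in range(6)}
        spec = DownsampleSpec(n_samples=6)
        tumor, normal = merge_with_downsampling(reads, reads, spec, seed=9)
        # same input reads, but the seeded hash keys differ per arm
        assert {r.read_id for r in tumor} != {r.read_id for r in normal}

    def test_determinism_given_seed(self):
        reads = {f"s{i}": make_pairs(f"s{i}", 200) for i in range(5)}
        spec = DownsampleSpec(n_samples=5)
        first = downsample_read_set(reads, spec, seed=21)
        second = downsample_read_set(reads, spec, seed=21)
        assert first == second


class TestDedupeTruth:
    def test_single_entry_survives(self):
        truth = dedupe_truth_by_vaf(
            [TruthCandidate("c", 10, "A", "T", "s1", 0.4)]
        )
        assert truth.variants == {VariantKey("c", 10, "A", "T"): 0.4}

    def test_highest_vaf_sample_wins(self):
        truth = dedupe_truth_by_vaf(
            [
                TruthCandidate("c", 10, "A", "T", "s1", 0.30),
                TruthCandidate("c", 10, "A", "G", "s2", 0.45),
            ]
        )
        assert truth.variants == {VariantKey("c", 10, "A", "G"): 0.45}

    def test_vaf_tie_breaks_to_lexicographic_sample_with_warning(self):
        with pytest.warns(UserWarning, match="tie"):
            truth = dedupe_truth_by_vaf(
                [
                    TruthCandidate("c", 10, "A", "T", "s2", 0.30),
                    TruthCandidate("c", 10, "A", "G", "s1", 0.30),
                ]
            )
        assert truth.variants == {VariantKey("c", 10, "A", "G"): 0.30}

    def test_matches_groupby_max_oracle(self, rng):
        alts = {"A": "TGC", "C": "AGT", "G": "ACT", "T": "ACG"}
        entries = []
        sites = [(f"c{rng.integers(1, 3)}", int(p)) for p in rng.integers(1, 500, size=40)]
        for _ in range(100):
            contig, pos = sites[int(rng.integers(0, len(sites)))]
            ref = "ACGT"[int(rng.integers(0, 4))]
            alt = alts[ref][int(rng.integers(0, 3))]
            entries.append(
                (contig, pos, ref, alt, f"s{int(rng.integers(0, 8)):02d}",
                 round(float(rng.random()), 3))
            )
        candidates = [TruthCandidate(*e) for e in entries]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            truth = dedupe_truth_by_vaf(candidates)
            expected = groupby_max_vaf_oracle(entries)
        expected_keys = {}
        for contig, pos, ref, alt, _sample, vaf in expected:
            expected_keys[VariantKey(contig, pos, ref, alt)] = vaf
        assert truth.variants == expected_keys

    def test_no_multiallelic_sites_survive(self, rng):
        candidates = [
            TruthCandidate("c", int(pos), "A", alt, f"s{i}", float(v))
            for i, (pos, alt, v) in enumerate(
                zip(rng.integers(1, 30, size=60), rng.choice(list("CGT"), size=60), rng.random(60))
            )
        ]
        truth = dedupe_truth_by_vaf(candidates)
        sites = [(k.contig, k.pos, k.ref) for k in truth.variants]
        assert len(sites) == len(set(sites))


class TestSamInterface:
    def _write_sam(self, path, sample, pairs):
        header = {"HD": {"VN": "1.6", "SO": "coordinate"},
                  "SQ": [{"SN": "c", "LN": 100_000}]}
        with pysam.AlignmentFile(str(path), "wh", header=header) as out:
            for qname, pos1, pos2 in pairs:
                for i, pos in enumerate((pos1, pos2)):
                    aln = pysam.AlignedSegment(out.header)
                    aln.query_name = qname
                    aln.query_sequence = "A" * 50
                    aln.reference_id = 0
                    aln.reference_start = pos
                    aln.cigarstring = "50M"
                    aln.flag = 99 if i == 0 else 147
                    aln.mapping_quality = 60
                    aln.next_reference_id = 0
                    aln.next_reference_start = pos2 if i == 0 else pos1
                    out.write(aln)

    def test_sam_round_trip_with_exclusive_sourcing(self, tmp_path):
        sams = {}
        for sample, offset in (("s1", 0), ("s2", 40_000)):
            path = tmp_path / f"{sample}.sam"
            pairs = [(f"{sample}.p{i}", offset + i * 200, offset + i * 200 + 100)
                     for i in range(50)]
            # both samples also have reads over the shared mutation region
            pairs += [(f"{sample}.m{i}", 20_000 + i * 30, 20_100 + i * 30) for i in range(10)]
            self._write_sam(path, sample, pairs)
            sams[sample] = path
        bed = tmp_path / "regions.bed"
        bed.write_text("c\t20000\t20500\ts1\n")
        out_t, out_n = tmp_path / "t.sam", tmp_path / "n.sam"
        downsample_sam(sams, sams, bed, None, seed=4, out_tumor=out_t, out_normal=out_n)
        with pysam.AlignmentFile(str(out_t), "r") as result:
            names = [a.query_name for a in result]
        in_region = [n for n in names if n.split(".")[1].startswith("m")]
        assert in_region and all(n.startswith("s1.") for n in in_region)
        assert sorted(n for n in names if n.startswith("s1.m")) == sorted(
            f"s1.m{i}" for i in range(10) for _ in (0, 1)
        )
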