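"""Brute-force oracles kept independent of the implementation under test."""

from __future__ import annotations

import itertools


def apply_variant(seq: str, pos: int, ref: str, alt: str) -> str:
    """Apply one (1-based pos, ref, alt) edit to a reference string."""
    assert seq[pos - 1 : pos - 1 + len(ref)] == ref
    return seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]


def enumerate_equivalent_spellings(seq: str, pos: int, ref: str, alt: str):
    """Every (pos, ref, alt) spelling producing the same edited sequence."""
    edited = apply_variant(seq, pos, ref, alt)
    spellings = []
    for p in range(1, len(seq) + 1):
        for rlen in range(1, len(seq) - p + 2):
            alen = len(edited) - len(seq) + rlen
            if alen < 1:
                continue
            r = seq[p - 1 : p - 1 + rlen]
            a = edited[p - 1 : p - 1 + alen]
            if r == a:
                continue
            if edited == seq[: p - 1] + a + seq[p - 1 + rlen :]:
                spellings.append((p, r, a))
    return spellings


def normalize_oracle(seq: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Most parsimonious, leftmost equivalent spelling (smallest allele sum, then pos)."""
    spellings = enumerate_equivalent_spellings(seq, pos, ref, alt)
    return min(spellings, key=lambda s: (len(s[1]) + len(s[2]), s[0]))


def membership_oracle(pos: int, intervals) -> bool:
    """Per-base scan: 1-based pos inside any 0-based half-open interval."""
    return any(
        any(base == pos - 1 for base in range(start, end)) for start, end in intervals
    )


def rank_oracle(f1_by_caller: dict) -> dict:
    """Descending-F1 ranks with average rank for ties, by explicit sorting."""
    ordered = sorted(f1_by_caller, key=lambda c: -f1_by_caller[c])
    ranks = {}
    i = 0
    while i < len(ordered):
        j = i
        while j < len(ordered) and f1_by_caller[ordered[j]] == f1_by_caller[ordered[i]]:
            j += 1
        avg = (i + 1 + j) / 2  # mean of positions i+1 .. j
        for caller in ordered[i:j]:
            ranks[caller] = avg
        i = j
    return ranks


def pareto_oracle(points):
    """O(n²) dominance scan over (f1, cost) pairs; returns indices of the front."""
    front = []
    for i, (f1_i, cost_i) in enumerate(points):
        dominated = False
        for j, (f1_j, cost_j) in enumerate(points):
            if j == i:
                continue
            if f1_j >= f1_i and cost_j <= cost_i and (f1_j > f1_i or cost_j < cost_i):
                dominated = True
                break
        if not dominated:
            front.append(i)
    return front


def poisson_binomial_tail_oracle(probs, threshold: int) -> float:
    """P(at least `threshold` successes) by explicit subset enumeration."""
    total = 0.0
    for outcome in itertools.product([0, 1], repeat=len(probs)):
        if sum(outcome) >= threshold:
            weight = 1.0
            for hit, p in zip(outcome, probs):
                weight *= p if hit else 1.0 - p
            total += weight
    return total


def support_oracle(callsets_keys: dict) -> dict:
    """Per-key membership scan across caller key sets."""
    support = {}
    all_keys = set().union(*callsets_keys.values()) if callsets_keys else set()
    for key in all_keys:
        support[key] = frozenset(
            caller for caller, keys in callsets_keys.items() if key in keys
        )
    return support


def groupby_max_vaf_oracle(entries):
    """entries: (contig, pos, ref, alt, sample, vaf) -> survivors by site max-VAF."""
    sites = {}
    for entry in entries:
        sites.setdefault((entry[0], entry[1], entry[2]), []).append(entry)
    survivors = []
    for group in sites.values():
        best_vaf = max(e[5] for e in group)
        best = min(e[4] for e in group if e[5] == best_vaf)
        survivors.append(next(e for e in group if e[5] == best_vaf and e[4] == best))
    return survivors
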