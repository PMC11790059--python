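"""Voting-based consensus over multiple call sets.

An ensemble is a set of p callers plus a voting threshold t with
1 <= t <= p: a variant enters the consensus when at least t of the p
callers report it.  t = 1 is the union of the call sets, t = p the
intersection.  Voting uses presence of the normalized key only — no
weights, qualities or per-caller confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .variants import CallSet, VariantKey


@dataclass(frozen=True)
class EnsembleSpec:
    """A combination of callers and the minimum number of agreeing votes."""

    caller_ids: tuple[str, ...]
    threshold: int

    def __post_init__(self) -> None:
        if len(set(self.caller_ids)) != len(self.caller_ids):
            raise ValueError("duplicate caller ids in ensemble spec")
        if not self.caller_ids:
            raise ValueError("ensemble needs at least one caller")
        if not 1 <= self.threshold <= len(self.caller_ids):
            raise ValueError(
                f"threshold {self.threshold} outside [1, {len(self.caller_ids)}]"
            )

    @property
    def size(self) -> int:
        return len(self.caller_ids)


@dataclass
class ConsensusCallSet:
    """Variants passing the vote, with their support counts and supporters."""

    spec: EnsembleSpec
    variants: dict[VariantKey, int] = field(default_factory=dict)
    supporters: dict[VariantKey, frozenset] = field(default_factory=dict)

    def keys(self) -> set[VariantKey]:
        return set(self.variants)

    def __len__(self) -> int:
        return len(self.variants)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.variants


def merge_callsets(callsets: Sequence[CallSet]) -> dict[VariantKey, frozenset]:
    """Merge call sets into a support map key -> set of reporting callers."""
    seen = [cs.caller_id for cs in callsets]
    if len(set(seen)) != len(seen):
        raise ValueError(f"duplicate caller_id among inputs: {sorted(seen)}")
    support: dict[VariantKey, set] = {}
    for cs in callsets:
        for key in cs.variants:
            support.setdefault(key, set()).add(cs.caller_id)
    return {key: frozenset(callers) for key, callers in support.items()}


def vote(support_map: Mapping[VariantKey, frozenset], spec: EnsembleSpec) -> ConsensusCallSet:
    """Apply the voting threshold to a support map built from spec.caller_ids."""
    members = set(spec.caller_ids)
    consensus = ConsensusCallSet(spec=spec)
    for key, callers in support_map.items():
        count = len(callers & members)
        if count >= spec.threshold:
            consensus.variants[key] = count
            consensus.supporters[key] = frozenset(callers & members)
    return consensus


def consensus(callsets: Sequence[CallSet], threshold: int) -> ConsensusCallSet:
    """Convenience wrapper: merge then vote."""
    spec = EnsembleSpec(tuple(cs.caller_id for cs in callsets), threshold)
    return vote(merge_callsets(callsets), spec)


def expected_consensus_recall(sensitivities: Iterable[float], threshold: int) -> float:
    """Closed-form consensus recall for independent callers.

    For callers that detect a true variant independently with
    probabilities s_1..s_p, the number of agreeing votes K follows a
    Poisson-binomial distribution and the consensus recall at threshold t
    is the tail P(K >= t).  Computed by the exact O(p²) convolution.
    """
    probs = list(sensitivities)
    p = len(probs)
    if not 1 <= threshold <= p:
        raise ValueError(f"threshold {threshold} outside [1, {p}]")
    pmf = [1.0]
    for s in probs:
        nxt = [0.0] * (len(pmf) + 1)
        for k, mass in enumerate(pmf):
            nxt[k] += mass * (1.0 - s)
            nxt[k + 1] += mass * s
        pmf = nxt
    return float(sum(pmf[threshold:]))


def majority_threshold(size: int) -> int:
    """Smallest t that is at least half of the ensemble size."""
    if size < 1:
        raise ValueError("ensemble size must be >= 1")
    return (size + 1) // 2


__all__ = [
    "EnsembleSpec",
    "ConsensusCallSet",
    "merge_callsets",
    "vote",
    "consensus",
    "expected_consensus_recall",
    "majority_threshold",
]
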