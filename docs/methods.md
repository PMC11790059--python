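# Methods

## Variant identity and matching

All set operations — truth comparison and voting alike — use the exact
normalized key (contig, 1-based position, ref, alt).  Normalization
trims shared suffixes, left-shifts indels while reference context is
available, and reduces shared prefixes to a single anchor base for
indels (none for SNVs); multiallelic records are decomposed into one key
per alt.  No position-window or fuzzy allele matching is attempted:
exact matching after normalization is the strictest reproducible
convention, and a tolerance-based matcher could be layered on without
changing any interface.  Contig-name dialects (`chr1` vs `1`) are
reconciled by a built-in alias.

Variant classes: SNV (both alleles length 1), indel (unequal lengths),
MNV/other (equal length > 1).  MNVs are reported by the partition but
excluded from both SNV and indel evaluations — the benchmark is defined
over the two main classes only.

Filter policy: by default only records whose FILTER is `PASS` or `.`
count, for individual evaluation and for voting alike; a caller's own
recommended filtering is part of the caller.  `filter_policy="all"` is
available for sensitivity analyses.

Coordinates: VCF positions are 1-based; BED regions 0-based half-open.
A variant is inside a region iff its normalized anchor position is,
i.e. `start < pos <= end`.  Only the anchor is tested, not the full
deleted span — one consistent convention applied to calls and truth
symmetrically, so it cannot bias TP/FP/FN counts.

## Metrics

TP/FP/FN are set cardinalities against the positive set P; recall,
precision and F1 follow the count forms given in the README.  Accuracy
is deliberately absent (meaningless under genome-scale class imbalance).
Zero-denominator metrics are flagged `None` rather than coerced to 0;
the count-form F1 is still well defined whenever the truth set is
non-empty, so an empty call set scores F1 = 0 with precision undefined.

Cross-dataset aggregation is the unweighted arithmetic mean of the
per-dataset F1s.  Datasets with no truth variants for a class (the
SNV-only dataset has no indels) are excluded from that class's mean
rather than contributing an undefined value.  Caller stability is the
population variance (ddof = 0) of per-dataset ranks, computed from
descending-F1 ranks with average ranks on ties; a caller missing from a
dataset is excluded from that dataset's ranking with a warning and its
variance is taken over the datasets where it ran.

## Ensemble voting and the search

Voting counts the presence of the normalized key across the p chosen
call sets; a variant passes at threshold t when at least t callers
report it.  The consensus is anti-monotone in t, equals the union at
t = 1 and the intersection at t = p.  No weights or quality merging:
consensus carries only the support count and supporter list.

The search enumerates all combinations of sizes 2..n and thresholds
1..p per combination — Σ C(n,p) combinations and Σ p·C(n,p) evaluations
(8178 / 53 235 for n = 13; 1013 / 5110 for n = 10).  SNV and indel
searches run independently over their own eligible pools.  The
implementation computes, per combination and dataset, a support
histogram over the union of keys and reads off TP/FP at every threshold
from its suffix sums, so each combination costs O(keys + p) rather than
O(keys · p).  Output order is deterministic (size, lexicographic caller
ids, threshold) and the search itself uses no randomness.

Cost model: the CPU time of a combination is the sum of its callers'
CPU seconds — the worst-case serial execution.  `critical_path` mode
replaces the sum with the maximum, modelling a cluster that runs
callers concurrently, where the ensemble is limited by its slowest
member.  Memory is aggregated as the maximum (callers run as separate
processes).  A joint SNV+indel recommendation scores as the unweighted
mean of the two arm means and unions the two caller sets for costing,
paying for a shared caller once.

Tradeoff selection: the recommended ensemble is the cheapest whose mean
F1 is within `f1_tolerance` of the best (default 0.001, the scale at
which additional tools stop paying for themselves on real benchmarks);
ties break toward fewer callers, then lexicographic ids.  The Pareto
front in (mean F1 max, CPU cost min) is also reported.

## The bundled caller registry

Twenty callers are registered with their supported classes; five (two
commercial, three deep-learning) are excluded from the ensemble search,
leaving 15 eligible — 13 for SNVs, 10 for indels.  The CPU-seconds
column is interpolated from published per-tool and per-ensemble
wall-times; the published aggregates are mutually inconsistent at the
~20-second level, so the bundled table reproduces the individually
quoted times exactly and distributes the remainder so the 20-caller
mean is 5040 s.  Resource numbers are ingested data: the package never
re-measures runtimes.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not sequencing physics — there are no reads, base qualities or mapping
artifacts, only call sets with controlled error behaviour.

* **Truth sets.**  Four bundled profiles mirror the reference truth-set
  sizes and VAF shapes: `clonal3` (474 SNVs / 464 indels, subclones at
  exactly 50/33/20% VAF), `deep_lowvaf` (1160 / 50, Beta-distributed
  VAFs with median 0.10), `clinical` (175 / 38, median 0.20 truncated
  to 2–60%), `snv_only` (257 / 0).  Sites are uniform within the
  regions, distinct by position; indels are 1–3 bp insertions or
  deletions, emitted pre-normalized.  Beta VAFs use
  Beta(m·k, (1−m)·k) with concentration k = 8, whose median tracks m
  closely at that concentration.
* **Regions.**  Two synthetic 5-Mb contigs carry 200 intervals of
  1–10 kb (≈1.1 Mb total) — desk-scale, but large enough that FP sites
  rarely collide by chance.
* **Callers.**  Sensitivity is a logistic function of VAF (low-VAF
  variants are the hard ones; ceiling, midpoint and scale are
  per-caller parameters; a constant curve is available for closed-form
  checks).  False positives are Poisson(rate × region Mb); each FP is
  drawn from the dataset's shared artifact pool with probability
  `artifact_pool_affinity`, else placed fresh.  The pool is the model
  of inter-caller error correlation: shared FPs survive voting,
  independent ones do not.  The real correlation structure of caller
  errors is unknown; the pool is a declared abstraction of it.
* **Germline leakage.**  A caller can be given a high affinity to the
  shared pool to emulate a tool flooding one dataset with shared
  (germline-like) false positives; the designed scenario's weak callers
  behave this way.

The designed scenario (`designed_scenario(seed)`) fixes 8 callers over
the four profiles: three strong callers (`alpha`, `bravo`, `charlie`:
97% sensitivity ceiling, 18 FP/Mb, affinity 0.5), one cheap
near-dominant (`delta`: 90% ceiling, 25 FP/Mb, affinity 0.8, 600 CPU-s
vs charlie's 7000), and four weak, heavily correlated callers (55%
ceiling, 200 FP/Mb, affinity 0.85).  The parameters were chosen from
expected-value calculations so that (a) the best mean-F1 combination is
a majority-vote ensemble inside {alpha, bravo, charlie, delta} and (b) a
strictly cheaper combination lies within 0.015 mean F1 of the best —
0.015 is the scenario's "similar performance" scale, standing an order
of magnitude below the designed gap to any weak-caller combination.
Passing these recovery tests shows the search and selector do what they
claim on data with the assumed structure; it does not certify any
specific real-world caller combination.

Determinism: one `numpy` generator seeds everything, and emitted
VCF/BED/TSV files are byte-identical across runs with the same seed.

## Benchmark construction

`merge_with_downsampling` builds one virtual tumor/normal pair from n
per-sample pairs (reference design: n = 36).  Outside mutation regions,
mate-pair groups are kept with probability 1/n, decided by a
Blake2b hash of (seed, arm, sample, pair id) — reproducible, order
independent and streaming-friendly.  Over each mutation region, reads
are taken exclusively and completely from that region's source sample:
keeping *all and only* the source reads is what makes the merged
alternate-allele fraction equal the source sample's exactly.  A pair
overlaps a region if either mate's alignment span intersects it —
counting half-pairs at region edges would distort allele fractions.  A
pair spanning two regions with different sources is kept if it comes
from either source, with a warning (panel target regions are disjoint
in practice).  Truth candidates sharing a site keep the highest-VAF
sample's allele (ties to the lexicographically smaller sample, with a
warning), which also guarantees a multiallelic-free merged truth set.
I/O is plain SAM via pysam; header reconciliation beyond shared contigs
and base-level processing are out of scope.

## Problem sizes and test design

The test suite and `scripts/acceptance.py` run the full designed
scenario (4 datasets, 8 callers, 1016 search evaluations per class),
a 20 000-variant Monte-Carlo check of consensus recall against the
Poisson-binomial tail (3 MC standard errors ≈ 0.0065 tolerance), and a
36-sample × 1200-pair downsampling check at binomial 3σ tolerance —
sizes at which every stochastic bound has comfortable margin while the
whole suite stays in the tens of seconds.  Statistical tests use fixed
seeds; bounds involving many simultaneous comparisons (per-sample depth
across 36 samples) use family-wise-adjusted 4σ limits.

## Known limitations

* Exact key matching will count a discordantly normalized complex
  representation as FP+FN; real benchmarking against callers with
  haplotype-level output would need a matcher at that level.
* The synthetic generator models caller errors at the call-set level;
  conclusions about specific real callers require real call sets.
* The cost model ignores I/O, memory pressure and per-dataset runtime
  variation; CPU seconds enter as a single per-caller constant.
* The exhaustive search is quadratic-exponential by design (≤ 53 235
  evaluations at n = 13); it is not meant for caller pools much beyond
  that size.
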