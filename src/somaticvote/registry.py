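"""Registry of the 20 benchmarked somatic variant callers.

Twenty callers are tracked per class (18 call SNVs, 15 call indels).
The two commercial callers (Dragen, TNScope) and the three deep-learning
callers (DeepSomatic, NeuSomatic, VarNet) are excluded from the ensemble
search, leaving 15 eligible callers: 13 supporting SNVs and 10 supporting
indels.

The CPU-seconds column reflects single whole-exome tumor/normal runs; the
values anchored by published wall-times are exact and the remainder are
interpolated so the 20-caller mean is 5040 s (1 h 24 min).  Peak memory is
resident set size in MB.  Resource numbers are ingested data, never
re-measured by this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .variants import VariantClass


@dataclass(frozen=True)
class CallerMeta:
    caller_id: str
    supports: frozenset  # subset of {VariantClass.SNV, VariantClass.INDEL}
    eligible_for_ensemble: bool
    cpu_seconds: float
    peak_memory_mb: float

    def supports_class(self, variant_class: VariantClass) -> bool:
        return variant_class in self.supports


_SNV = VariantClass.SNV
_INDEL = VariantClass.INDEL

#: caller_id -> (supported classes, eligible for ensemble, cpu_s, peak_mem_mb)
_DEFAULT_TABLE = [
    ("lofreq",        (_SNV, _INDEL), True,   9000.0,  2500.0),
    ("strelka",       (_SNV, _INDEL), True,   2702.0,  1800.0),
    ("freebayes",     (_SNV, _INDEL), True,   3600.0,  4600.0),
    ("mutect",        (_SNV,),        True,   2400.0,  3900.0),
    ("mutect2",       (_SNV, _INDEL), True,   7000.0,  4200.0),
    ("pindel",        (_INDEL,),      True,   9780.0,  8200.0),
    ("shimmer",       (_SNV,),        True,   1800.0,  1100.0),
    ("vardict",       (_SNV, _INDEL), True,   8000.0,  9600.0),
    ("varscan2",      (_SNV, _INDEL), True,   5118.0,  1400.0),
    ("lancet",        (_SNV, _INDEL), True,  15876.0, 12800.0),
    ("seurat",        (_SNV, _INDEL), True,   4000.0,  5200.0),
    ("somaticsniper", (_SNV,),        True,   1250.0,   274.0),
    ("virmid",        (_SNV,),        True,   2200.0,  2100.0),
    ("muse",          (_SNV,),        True,   1184.0, 33395.0),
    ("scalpel",       (_INDEL,),      True,   6000.0,  7400.0),
    ("deepsomatic",   (_SNV, _INDEL), False,  7200.0, 14500.0),
    ("neusomatic",    (_SNV, _INDEL), False,  5400.0,  9800.0),
    ("varnet",        (_SNV, _INDEL), False,  4800.0, 11200.0),
    ("dragen",        (_SNV, _INDEL), False,  3032.0,  6100.0),
    ("tnscope",       (_SNV, _INDEL), False,   458.0,  5600.0),
]


def default_registry() -> dict[str, CallerMeta]:
    """The bundled 20-caller registry as caller_id -> CallerMeta."""
    return {
        cid: CallerMeta(cid, frozenset(supp), eligible, cpu, mem)
        for cid, supp, eligible, cpu, mem in _DEFAULT_TABLE
    }


def eligible_callers(
    variant_class: VariantClass, registry: dict[str, CallerMeta] | None = None
) -> list[str]:
    """Callers eligible for the ensemble search for one variant class, sorted."""
    registry = registry if registry is not None else default_registry()
    return sorted(
        cid
        for cid, meta in registry.items()
        if meta.eligible_for_ensemble and meta.supports_class(variant_class)
    )


def registry_from_table(frame: pd.DataFrame) -> dict[str, CallerMeta]:
    """Build a registry from a resource table.

    Expected columns: caller_id, supports (comma list of SNV/INDEL),
    eligible_for_ensemble, cpu_seconds, peak_memory_mb.
    """
    registry = {}
    for row in frame.itertuples(index=False):
        supports = frozenset(
            VariantClass(token.strip().upper())
            for token in str(row.supports).split(",")
            if token.strip()
        )
        registry[row.caller_id] = CallerMeta(
            caller_id=row.caller_id,
            supports=supports,
            eligible_for_ensemble=bool(row.eligible_for_ensemble),
            cpu_seconds=float(row.cpu_seconds),
            peak_memory_mb=float(row.peak_memory_mb),
        )
    return registry


def registry_to_table(registry: dict[str, CallerMeta]) -> pd.DataFrame:
    rows = [
        {
            "caller_id": meta.caller_id,
            "supports": ",".join(sorted(vc.value for vc in meta.supports)),
            "eligible_for_ensemble": meta.eligible_for_ensemble,
            "cpu_seconds": meta.cpu_seconds,
            "peak_memory_mb": meta.peak_memory_mb,
        }
        for meta in registry.values()
    ]
    return pd.DataFrame(rows)


def load_resource_table(path) -> dict[str, CallerMeta]:
    return registry_from_table(pd.read_csv(path, sep="\t"))


def save_resource_table(registry: dict[str, CallerMeta], path) -> None:
    registry_to_table(registry).to_csv(path, sep="\t", index=False)
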