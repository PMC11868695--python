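"""Depth normalization and taxon x gene abundance profiles.

Each scaffold has an average depth (mapped reads per base pair) under every
sample's read mapping against its assembly.  Depths are normalized per a
fixed number of mapped reads (1e8 by default) so samples of different
sequencing effort are comparable.  When aggregating over the scaffolds of a
taxon, only the mapping of the sample from which each scaffold was assembled
is summed ("own-sample" rule): reads from one sample can map onto similar
strains assembled in other samples, so the naive all-mappings sum counts
them repeatedly and overestimates taxa present in many samples.  The naive
sum is retained for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

from .errors import ConsistencyError, ValidationError
from .homology_screen import HomologHit
from .taxonomy_resolve import Lineage, lineage_at_rank

__all__ = [
    "DepthRecord",
    "NormConfig",
    "TaxonDepthProfile",
    "UNCLASSIFIED",
    "normalize_depth",
    "aggregate_own_sample",
    "aggregate_naive",
    "profile_by_taxon_gene",
    "sort_sample_labels",
]

#: Label under which scaffolds unclassified at the reporting rank are pooled.
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class DepthRecord:
    """Average depth of one scaffold under one sample's mapping.

    ``mapping_total_reads`` is the total number of reads of the mapping
    sample aligned against the scaffold's assembly, used for normalization.
    """

    scaffold_id: str
    assembly_sample: str
    mapping_sample: str
    avg_depth: float
    mapping_total_reads: float

    def __post_init__(self) -> None:
        if self.avg_depth < 0:
            raise ValidationError(
                f"negative avg_depth for scaffold {self.scaffold_id}"
            )
        if self.mapping_total_reads <= 0:
            raise ValidationError(
                f"non-positive mapping_total_reads for scaffold {self.scaffold_id}"
            )


@dataclass(frozen=True)
class NormConfig:
    """Normalization scale: depth is expressed per ``scale`` mapped reads."""

    scale: float = 1e8

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValidationError("scale must be positive")


@dataclass
class TaxonDepthProfile:
    """Per-sample summed normalized depth of one (taxon, gene family)."""

    taxon: str
    family: str
    values: dict[str, float]

    def is_zero(self) -> bool:
        return all(v == 0 for v in self.values.values())


def normalize_depth(rec: DepthRecord, cfg: NormConfig = NormConfig()) -> float:
    """Depth in reads/bp per ``scale`` mapped reads of the mapping sample."""
    return rec.avg_depth * cfg.scale / rec.mapping_total_reads


def _zero_profile(samples: Sequence[str]) -> dict[str, float]:
    return {s: 0.0 for s in samples}


def aggregate_own_sample(
    records: Iterable[DepthRecord],
    samples: Sequence[str],
    cfg: NormConfig = NormConfig(),
) -> dict[str, float]:
    """Sum normalized depth per sample over own-sample mappings only.

    A record contributes to sample ``s`` iff it was both assembled from and
    mapped by ``s``; samples with no qualifying scaffolds are explicit zeros
    so profiles remain plottable against the full depth series.
    """
    out = _zero_profile(samples)
    for rec in records:
        if rec.assembly_sample == rec.mapping_sample and rec.mapping_sample in out:
            out[rec.mapping_sample] += normalize_depth(rec, cfg)
    return out


def aggregate_naive(
    records: Iterable[DepthRecord],
    samples: Sequence[str],
    cfg: NormConfig = NormConfig(),
) -> dict[str, float]:
    """Sum normalized depth per mapping sample over all mappings.

    This is the double-counting sum the own-sample rule corrects: shared
    strains contribute to every sample that maps onto them.
    """
    out = _zero_profile(samples)
    for rec in records:
        if rec.mapping_sample in out:
            out[rec.mapping_sample] += normalize_depth(rec, cfg)
    return out


def sort_sample_labels(labels: Iterable[str]) -> list[str]:
    """Order sample labels numerically when possible (depth strings)."""
    labels = list(dict.fromkeys(labels))
    try:
        return sorted(labels, key=float)
    except ValueError:
        return sorted(labels)


def profile_by_taxon_gene(
    hits: Iterable[HomologHit],
    resolved_lineages: Mapping[str, Lineage],
    records: Iterable[DepthRecord],
    rank: str = "phylum",
    samples: Optional[Sequence[str]] = None,
    cfg: NormConfig = NormConfig(),
    mode: str = "own",
) -> list[TaxonDepthProfile]:
    """One abundance profile per (taxon at ``rank``, gene family).

    Hits must already be filtered and deduped; each hit-bearing scaffold
    contributes its full average depth once per family regardless of how
    many proteins on it hit.  Scaffolds unclassified at the rank are pooled
    under :data:`UNCLASSIFIED` rather than dropped, so profiles summed over
    all taxa equal the pooled all-scaffold profile.
    """
    if mode not in {"own", "naive"}:
        raise ValidationError(f"unknown aggregation mode {mode!r}")
    records = list(records)
    if samples is None:
        samples = sort_sample_labels(
            [r.mapping_sample for r in records] + [r.assembly_sample for r in records]
        )
    by_scaffold: dict[str, list[DepthRecord]] = {}
    own_seen: set[str] = set()
    for rec in records:
        by_scaffold.setdefault(rec.scaffold_id, []).append(rec)
        if rec.assembly_sample == rec.mapping_sample:
            own_seen.add(rec.scaffold_id)

    family_scaffolds: dict[str, set[str]] = {}
    for hit in hits:
        family_scaffolds.setdefault(hit.family, set()).add(hit.scaffold_id)

    missing = sorted(
        scf
        for scfs in family_scaffolds.values()
        for scf in scfs
        if scf not in own_seen
    )
    if missing:
        raise ConsistencyError(
            "hit scaffolds lack an own-sample depth record: " + ", ".join(missing)
        )

    aggregate = aggregate_own_sample if mode == "own" else aggregate_naive
    profiles: dict[tuple[str, str], list[DepthRecord]] = {}
    for family in sorted(family_scaffolds):
        for scf in sorted(family_scaffolds[family]):
            lineage = resolved_lineages.get(scf, Lineage.unclassified())
            taxon = lineage_at_rank(lineage, rank) or UNCLASSIFIED
            profiles.setdefault((taxon, family), []).extend(by_scaffold[scf])
    return [
        TaxonDepthProfile(taxon, family, aggregate(recs, samples, cfg))
        for (taxon, family), recs in sorted(profiles.items())
    ]
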