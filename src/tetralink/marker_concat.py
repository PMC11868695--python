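"""Genome selection and single-copy-marker supermatrix bookkeeping.

Representative genomes are scored by CheckM-style completeness minus five
times contamination; similar genomes are collapsed by a greedy pass over a
precomputed ANI matrix (one cluster per representative, 99% ANI by
default, genomes under 50% completeness excluded).  Marker genes present in
single copy are extracted per genome, trimmed sequences with more than 60%
gaps are discarded, and the per-family alignments are concatenated per
genome, gap-filling absent families, into a supermatrix with a partition
map.  ANI computation, alignment and trimming are consumed as inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError

__all__ = [
    "MagQuality",
    "DereplicationConfig",
    "Cluster",
    "representative_score",
    "greedy_dereplicate",
    "single_copy_markers",
    "gap_fraction_filter",
    "concatenate_supermatrix",
]

GAP_CHAR = "-"


@dataclass(frozen=True)
class MagQuality:
    """CheckM-style quality estimate of one MAG (percent units)."""

    mag_id: str
    completeness: float
    contamination: float

    def __post_init__(self) -> None:
        if not 0 <= self.completeness <= 100:
            raise ValidationError(
                f"completeness {self.completeness} outside [0, 100] for {self.mag_id}"
            )
        if self.contamination < 0:
            raise ValidationError(
                f"negative contamination for {self.mag_id}"
            )


@dataclass(frozen=True)
class DereplicationConfig:
    """ANI thresholds and completeness floor for genome dereplication.

    ``secondary_ani`` is the clustering threshold; ``primary_ani`` is kept
    as a coarse pre-filter option mirroring two-stage dereplicators but is
    not used by the single greedy pass.
    """

    primary_ani: float = 0.90
    secondary_ani: float = 0.99
    min_completeness: float = 50.0

    def __post_init__(self) -> None:
        if not 0 < self.primary_ani <= self.secondary_ani <= 1:
            raise ValidationError(
                "require 0 < primary_ani <= secondary_ani <= 1"
            )
        if not 0 <= self.min_completeness <= 100:
            raise ValidationError("min_completeness must be in [0, 100]")


@dataclass
class Cluster:
    representative: str
    members: list[str]


def representative_score(q: MagQuality) -> float:
    """Quality score used to pick representatives: completeness - 5 x contamination."""
    return q.completeness - 5.0 * q.contamination


def greedy_dereplicate(
    quality: Sequence[MagQuality],
    ani: pd.DataFrame,
    cfg: DereplicationConfig = DereplicationConfig(),
) -> list[Cluster]:
    """Greedy single-pass dereplication over a supplied ANI matrix.

    MAGs below the completeness floor are removed; the rest are visited in
    decreasing score order (ties: id ascending) and each joins the first
    existing cluster whose representative it matches at >= secondary_ani,
    else founds a new cluster.  Visiting in score order makes every founder
    the highest-scoring member of its cluster.
    """
    if list(ani.index) != list(ani.columns):
        raise ValidationError("ANI matrix index and columns must match")
    vals = ani.to_numpy()
    if ((vals < 0) | (vals > 1)).any():
        raise ValidationError("ANI values must lie in [0, 1]")
    if (abs(vals - vals.T) > 1e-12).any():
        raise ValidationError("ANI matrix must be symmetric")
    if (abs(vals.diagonal() - 1.0) > 1e-12).any():
        raise ValidationError("ANI matrix diagonal must be 1")

    retained = [q for q in quality if q.completeness >= cfg.min_completeness]
    missing = [q.mag_id for q in retained if q.mag_id not in ani.index]
    if missing:
        raise ValidationError(
            "MAGs missing from the ANI matrix: " + ", ".join(sorted(missing))
        )
    order = sorted(retained, key=lambda q: (-representative_score(q), q.mag_id))
    clusters: list[Cluster] = []
    for q in order:
        for cluster in clusters:
            if ani.loc[cluster.representative, q.mag_id] >= cfg.secondary_ani:
                cluster.members.append(q.mag_id)
                break
        else:
            clusters.append(Cluster(representative=q.mag_id, members=[q.mag_id]))
    return clusters


def single_copy_markers(
    family_counts: Mapping[str, int], families: Iterable[str]
) -> set[str]:
    """Marker families present in exactly one copy in the genome."""
    out = set()
    for family in families:
        count = family_counts.get(family, 0)
        if count < 0:
            raise ValidationError(f"negative copy count for family {family!r}")
        if count == 1:
            out.add(family)
    return out


def gap_fraction_filter(aligned_seq: str, gap_max: float = 0.60) -> bool:
    """True (keep) iff the gap fraction does not strictly exceed ``gap_max``.

    A sequence with exactly ``gap_max`` gaps is kept (the cut is strict).
    """
    if not aligned_seq:
        raise ValidationError("cannot gap-filter a zero-length sequence")
    gaps = aligned_seq.count(GAP_CHAR)
    return gaps / len(aligned_seq) <= gap_max


def concatenate_supermatrix(
    alignments: Mapping[str, Mapping[str, str]],
    genomes: Sequence[str],
) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """Concatenate per-family alignments per genome, gap-filling absences.

    ``alignments`` maps family -> genome -> aligned sequence; every sequence
    of one family must share one length.  Returns the genome -> supermatrix
    row mapping plus a partition map of 0-based half-open [start, end)
    spans, in the (sorted) family order used for concatenation.
    """
    if len(set(genomes)) != len(genomes):
        dupes = sorted({g for g in genomes if list(genomes).count(g) > 1})
        raise ValidationError("duplicate genome ids: " + ", ".join(dupes))
    partitions: list[tuple[str, int, int]] = []
    lengths: dict[str, int] = {}
    offset = 0
    for family in sorted(alignments):
        seqs = alignments[family]
        if not seqs:
            raise ValidationError(f"family {family!r} has no sequences")
        lens = {len(s) for s in seqs.values()}
        if len(lens) != 1:
            raise ValidationError(
                f"family {family!r} alignment has inconsistent lengths {sorted(lens)}"
            )
        length = lens.pop()
        lengths[family] = length
        partitions.append((family, offset, offset + length))
        offset += length
    rows: dict[str, str] = {}
    for genome in genomes:
        parts = []
        for family, _, _ in partitions:
            seq = alignments[family].get(genome)
            parts.append(seq if seq is not None else GAP_CHAR * lengths[family])
        rows[genome] = "".join(parts)
    return rows, partitions
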