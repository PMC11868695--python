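"""Taxonomic lineages and the majority-vote classification of bins.

Scaffolds and bins carry rank-prefixed lineages (GTDB style,
``d__...;p__...;...``).  A bin inherits the deepest lineage supported by
more than a fraction ``f`` of its scaffolds' weight, where support is
counted hierarchically: a scaffold classified to a phylum also supports
that phylum's domain.  Hit-bearing scaffolds are classified by their bin's
lineage when binned, and by their own lineage otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ValidationError

__all__ = [
    "RANKS",
    "RANK_PREFIXES",
    "Lineage",
    "MajorityConfig",
    "majority_classify_bin",
    "resolve_hit_taxonomy",
    "lineage_at_rank",
]

RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)
RANK_PREFIXES: tuple[str, ...] = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")


@dataclass(frozen=True)
class Lineage:
    """An ordered domain-to-species classification.

    ``ranks`` always has seven entries; ``None`` marks an unclassified rank.
    No classified rank may appear below an unclassified one.
    """

    ranks: tuple[Optional[str], ...]

    def __post_init__(self) -> None:
        if len(self.ranks) != len(RANKS):
            raise ValidationError(
                f"lineage must have {len(RANKS)} ranks, got {len(self.ranks)}"
            )
        seen_gap = False
        for name in self.ranks:
            if name is None:
                seen_gap = True
            elif seen_gap:
                raise ValidationError(
                    "classified rank below an unclassified rank in "
                    + self.to_string()
                )

    @classmethod
    def unclassified(cls) -> "Lineage":
        return cls((None,) * len(RANKS))

    @classmethod
    def from_names(cls, names: Sequence[Optional[str]]) -> "Lineage":
        """Build from up to seven names ordered domain -> species."""
        padded = tuple(names) + (None,) * (len(RANKS) - len(names))
        return cls(padded)

    @classmethod
    def parse(cls, text: str) -> "Lineage":
        """Parse a classification string.

        GTDB-style rank-prefixed strings are canonical.  Bare semicolon
        separated name lists (NCBI style, superkingdom first) are accepted
        and mapped positionally onto domain -> species.  Rank prefixes out
        of canonical order raise a validation error.
        """
        text = text.strip()
        if not text or text.lower() in {"unclassified", "na", "no support"}:
            return cls.unclassified()
        parts = [p.strip() for p in text.split(";") if p.strip()]
        if not parts:
            return cls.unclassified()
        if any(p[:3] in RANK_PREFIXES for p in parts):
            names: list[Optional[str]] = [None] * len(RANKS)
            last_idx = -1
            for part in parts:
                prefix, _, name = part.partition("__")
                prefix += "__"
                if prefix not in RANK_PREFIXES:
                    raise ValidationError(f"unknown rank prefix in {part!r}")
                idx = RANK_PREFIXES.index(prefix)
                if idx <= last_idx:
                    raise ValidationError(
                        f"rank prefixes out of order in {text!r}"
                    )
                last_idx = idx
                names[idx] = name or None
            # trailing empty prefixes (e.g. "s__") simply stay unclassified
            while None in names and names.index(None) < last_idx:
                # a gap followed by a classified rank: not representable
                gap = names.index(None)
                if all(n is None for n in names[gap:]):
                    break
                raise ValidationError(
                    f"classified rank below an unclassified rank in {text!r}"
                )
            return cls(tuple(names))
        return cls.from_names(parts)

    def at(self, rank: str) -> Optional[str]:
        if rank not in RANKS:
            raise ValidationError(
                f"unknown rank {rank!r}; expected one of {RANKS}"
            )
        return self.ranks[RANKS.index(rank)]

    def classified_depth(self) -> int:
        """Number of leading classified ranks."""
        depth = 0
        for name in self.ranks:
            if name is None:
                break
            depth += 1
        return depth

    def prefix(self, depth: int) -> tuple[Optional[str], ...]:
        return self.ranks[:depth]

    def truncate(self, depth: int) -> "Lineage":
        return Lineage(self.ranks[:depth] + (None,) * (len(RANKS) - depth))

    def to_string(self) -> str:
        parts = []
        for prefix, name in zip(RANK_PREFIXES, self.ranks):
            if name is None:
                break
            parts.append(prefix + name)
        return ";".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string() or "unclassified"


@dataclass(frozen=True)
class MajorityConfig:
    """Support threshold for the bin majority classification.

    ``f`` is the fraction of total weight a lineage must strictly exceed to
    be adopted (0.5 guarantees uniqueness); weights are scaffold lengths by
    default, or scaffold counts.
    """

    f: float = 0.5
    weight_mode: str = "scaffold_length"

    def __post_init__(self) -> None:
        if not 0 < self.f <= 1:
            raise ValidationError("f must be in (0, 1]")
        if self.weight_mode not in {"scaffold_length", "scaffold_count"}:
            raise ValidationError(
                f"unknown weight_mode {self.weight_mode!r}"
            )


def majority_classify_bin(
    scaffold_lineages: Sequence[tuple[Lineage, float]],
    cfg: MajorityConfig = MajorityConfig(),
) -> Lineage:
    """Deepest lineage whose hierarchical support strictly exceeds f x total.

    A scaffold supports every ancestor of its own lineage, so mixed bins
    degrade gracefully to the shallowest rank that still commands a
    majority.  With ``f >= 0.5`` the result is unique at every rank.
    """
    if not scaffold_lineages:
        raise ValidationError("majority classification of an empty bin")
    for _, w in scaffold_lineages:
        if w <= 0:
            raise ValidationError("scaffold weights must be positive")
    total = sum(w for _, w in scaffold_lineages)
    chosen: tuple[str, ...] = ()
    for depth in range(1, len(RANKS) + 1):
        support: dict[tuple[str, ...], float] = {}
        for lin, w in scaffold_lineages:
            if lin.classified_depth() < depth:
                continue
            prefix = lin.prefix(depth)
            if prefix[: depth - 1] != chosen:
                continue
            support[prefix] = support.get(prefix, 0.0) + w
        winners = [p for p, s in support.items() if s > cfg.f * total]
        if not winners:
            break
        # at f >= 0.5 there is exactly one winner; below that, take the
        # best supported, ties broken alphabetically for determinism
        winners.sort(key=lambda p: (-support[p], p))
        chosen = winners[0]
    return Lineage.from_names(chosen)


def resolve_hit_taxonomy(
    scaffold_id: str,
    bins: Mapping[str, str],
    scaffold_lineages: Mapping[str, Lineage],
    bin_lineages: Mapping[str, Lineage],
) -> Lineage:
    """Lineage of one hit-bearing scaffold.

    The bin's classification takes precedence when the scaffold is binned;
    unbinned scaffolds use their own classification; scaffolds absent from
    both tables are reported as fully unclassified, never dropped.
    """
    bin_id = bins.get(scaffold_id)
    if bin_id is not None and bin_id in bin_lineages:
        return bin_lineages[bin_id]
    if scaffold_id in scaffold_lineages:
        return scaffold_lineages[scaffold_id]
    return Lineage.unclassified()


def lineage_at_rank(lineage: Lineage, rank: str) -> Optional[str]:
    """The taxon name at a canonical rank, or None if unclassified there."""
    return lineage.at(rank)
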