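"""Homologue detection over protein-alignment hit tables.

Gene-family homologues are accepted when the alignment e-value is strictly
below 1e-30 and the percent identity is at least 30; surviving hits are
reduced to per-protein, then per-scaffold / per-MAG presence so that tandem
duplicates never inflate abundance.  A simple Smith-Waterman identity
routine is provided as an alignment oracle for validating synthetic hit
tables; it is not a BLAST replacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ConsistencyError, ValidationError

__all__ = [
    "GENE_FAMILIES",
    "GeneFamilyQuery",
    "HomologHit",
    "ScreenConfig",
    "filter_hits",
    "dedupe_hits",
    "presence_by_unit",
    "hit_scaffolds",
    "sw_identity",
]

#: Gene families targeted by the screen: archaeal tetraether synthase (tes),
#: GDGT ring synthase (grsA), GMGT bridge synthase (gms), bacterial
#: membrane-spanning-lipid synthase (mss), glycerol ester reductase (ger),
#: ether-lipid-cluster protein (elbD) and alkylglycerone-phosphate synthase
#: (agps).
GENE_FAMILIES: tuple[str, ...] = ("tes", "grsA", "mss", "ger", "elbD", "agps", "gms")

#: Published query accessions where available (mss and ger queries are
#: lab-specific and supplied by the user per screen).
DEFAULT_QUERY_ACCESSIONS: dict[str, str] = {
    "tes": "ABR56159.1",
    "grsA": "WP_011278400.1",
    "elbD": "ABF88003.1",
    "agps": "ABF89845.1",
    "gms": "AJC70771.1",
}


@dataclass(frozen=True)
class GeneFamilyQuery:
    family: str
    query_accession: str


@dataclass(frozen=True)
class HomologHit:
    """One protein-alignment hit of a family query on a scaffold protein.

    Coordinates are 1-based inclusive as in tabular BLAST output.
    """

    family: str
    scaffold_id: str
    protein_index: int
    pident: float
    evalue: float
    bitscore: float
    qstart: int = 1
    qend: int = 1
    sstart: int = 1
    send: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.pident <= 100:
            raise ValidationError(f"pident {self.pident} outside [0, 100]")
        if self.evalue < 0:
            raise ValidationError(f"negative e-value {self.evalue}")
        if self.qstart > self.qend:
            raise ValidationError("qstart > qend")


@dataclass(frozen=True)
class ScreenConfig:
    """Homologue acceptance thresholds.

    The e-value threshold is exclusive (hit kept iff evalue < evalue_max)
    and the identity threshold inclusive (pident >= pident_min), matching
    the conventional "e-value < 1e-30, identity >= 30%" criterion.
    """

    evalue_max: float = 1e-30
    pident_min: float = 30.0

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValidationError("evalue_max must be positive")
        if not 0 <= self.pident_min <= 100:
            raise ValidationError("pident_min must be in [0, 100]")


def filter_hits(
    hits: Iterable[HomologHit], cfg: ScreenConfig = ScreenConfig()
) -> list[HomologHit]:
    """Keep hits with evalue < evalue_max and pident >= pident_min.

    Order is preserved and the operation is idempotent.
    """
    return [
        h for h in hits if h.evalue < cfg.evalue_max and h.pident >= cfg.pident_min
    ]


def dedupe_hits(hits: Iterable[HomologHit]) -> list[HomologHit]:
    """At most one hit per (family, scaffold, protein).

    Keeps the lowest e-value; ties go to the highest bitscore, then to the
    first occurrence.  Output order follows the first occurrence of each
    protein.
    """
    best: dict[tuple[str, str, int], tuple[int, HomologHit]] = {}
    for pos, hit in enumerate(hits):
        key = (hit.family, hit.scaffold_id, hit.protein_index)
        if key not in best:
            best[key] = (pos, hit)
            continue
        _, incumbent = best[key]
        if hit.evalue < incumbent.evalue or (
            hit.evalue == incumbent.evalue and hit.bitscore > incumbent.bitscore
        ):
            best[key] = (best[key][0], hit)
    return [hit for _, hit in best.values()]


def presence_by_unit(
    hits: Iterable[HomologHit], bins: Mapping[str, str]
) -> dict[tuple[str, str], list[str]]:
    """Reduce deduped hits to per-unit family presence.

    A unit is a bin id for binned scaffolds, or ``"unbinned:" + scaffold``
    for scaffolds outside every bin (so hits on unbinned scaffolds are still
    counted).  Returns a map (family, unit) -> sorted list of hit-bearing
    scaffolds of that unit; a key's presence means the family was detected
    in the unit at least once.
    """
    out: dict[tuple[str, str], set[str]] = {}
    for hit in hits:
        unit = bins.get(hit.scaffold_id)
        if unit is None:
            unit = "unbinned:" + hit.scaffold_id
        out.setdefault((hit.family, unit), set()).add(hit.scaffold_id)
    return {key: sorted(scfs) for key, scfs in out.items()}


def hit_scaffolds(hits: Iterable[HomologHit]) -> dict[str, list[str]]:
    """Map family -> sorted list of scaffolds carrying >= 1 surviving hit."""
    out: dict[str, set[str]] = {}
    for hit in hits:
        out.setdefault(hit.family, set()).add(hit.scaffold_id)
    return {family: sorted(scfs) for family, scfs in out.items()}


def sw_identity(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> float:
    """Percent identity of the best Smith-Waterman local alignment.

    Simple scoring (match/mismatch/linear gap, no substitution matrix);
    identity is matches / alignment columns x 100 along one optimal
    traceback (diagonal preferred over a gap in ``seq_b`` over a gap in
    ``seq_a``).  When the best local score is not positive the empty
    alignment is optimal and identity is reported as 0.0 by convention.
    """
    if not seq_a or not seq_b:
        raise ValidationError("sequences must be non-empty")
    n, m = len(seq_a), len(seq_b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    best_score, best_ij = 0.0, (0, 0)
    for i in range(1, n + 1):
        row, prev = H[i], H[i - 1]
        ai = seq_a[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (match if ai == seq_b[j - 1] else mismatch)
            score = max(0.0, diag, prev[j] + gap, row[j - 1] + gap)
            row[j] = score
            if score > best_score:
                best_score, best_ij = score, (i, j)
    if best_score <= 0:
        return 0.0
    i, j = best_ij
    matches = columns = 0
    while i > 0 and j > 0 and H[i][j] > 0:
        here = H[i][j]
        diag = H[i - 1][j - 1] + (match if seq_a[i - 1] == seq_b[j - 1] else mismatch)
        if here == diag:
            matches += seq_a[i - 1] == seq_b[j - 1]
            i, j = i - 1, j - 1
        elif here == H[i - 1][j] + gap:
            i -= 1
        else:
            j -= 1
        columns += 1
    return 100.0 * matches / columns
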