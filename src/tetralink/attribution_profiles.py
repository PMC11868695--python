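"""Producer attribution: MAG-fraction matrices, co-occurrence, ranking.

Two complementary views link a lipid to candidate producers.  First, the
fraction of MAGs of each taxon in each sample that carry a biosynthetic
gene family — high fractions over many MAGs argue for a real capability of
the taxon rather than a spuriously binned gene.  Second, quantitative
taxon x gene normalized-depth profiles are compared to the lipid's
depth profile by Spearman rank correlation (the field's claims are ordinal
— "maximum at 1000 m" — so rank correlation is the natural choice), and
taxa are ranked as candidate producers.  Within-MAG co-occurrence of two
families (e.g. a chain-coupling and an ether-forming enzyme) indicates
the full pathway in one genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats

from .depth_abundance import UNCLASSIFIED, TaxonDepthProfile
from .errors import InsufficientDataError, ValidationError
from .taxonomy_resolve import Lineage, lineage_at_rank

__all__ = [
    "MagFractionCell",
    "CooccurrenceReport",
    "ProfileComparison",
    "mag_fraction_matrix",
    "gene_cooccurrence",
    "compare_profiles",
    "rank_candidate_producers",
]


@dataclass(frozen=True)
class MagFractionCell:
    """One (taxon, sample) cell of a gene-family prevalence matrix."""

    taxon: str
    sample: str
    family: str
    n_mags: int
    n_with_family: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_with_family <= self.n_mags:
            raise ValidationError(
                f"inconsistent counts {self.n_with_family}/{self.n_mags}"
            )

    @property
    def fraction(self) -> float:
        return self.n_with_family / self.n_mags


@dataclass(frozen=True)
class CooccurrenceReport:
    """Per-taxon counts of MAGs carrying one or both of two gene families."""

    family_pair: tuple[str, str]
    both: dict[str, int]
    first_only: dict[str, int]
    second_only: dict[str, int]

    def taxa(self) -> list[str]:
        return sorted(set(self.both) | set(self.first_only) | set(self.second_only))

    def count_first(self, taxon: str) -> int:
        return self.both.get(taxon, 0) + self.first_only.get(taxon, 0)

    def count_second(self, taxon: str) -> int:
        return self.both.get(taxon, 0) + self.second_only.get(taxon, 0)


@dataclass(frozen=True)
class ProfileComparison:
    """Spearman rank agreement between a lipid and a gene profile."""

    lipid: str
    taxon: str
    family: str
    rho: float
    n: int


def _mag_presence(
    presence: Mapping[tuple[str, str], object]
) -> dict[str, set[str]]:
    """family -> set of binned units (MAG ids); unbinned units excluded."""
    out: dict[str, set[str]] = {}
    for family, unit in presence:
        if unit.startswith("unbinned:"):
            continue
        out.setdefault(family, set()).add(unit)
    return out


def _taxon_of(lineage: Optional[Lineage], rank: str) -> str:
    if lineage is None:
        return UNCLASSIFIED
    return lineage_at_rank(lineage, rank) or UNCLASSIFIED


def mag_fraction_matrix(
    presence: Mapping[tuple[str, str], object],
    mag_lineages: Mapping[str, Lineage],
    mag_samples: Mapping[str, str],
    family: str,
    rank: str = "phylum",
) -> list[MagFractionCell]:
    """Fraction of MAGs of each (taxon, sample) carrying ``family``.

    Every MAG with a binning sample contributes to its cell's denominator;
    MAGs unclassified at the rank form their own row rather than being
    dropped.  Cells are emitted for every (taxon, sample) with at least one
    MAG.
    """
    with_family = _mag_presence(presence).get(family, set())
    totals: dict[tuple[str, str], int] = {}
    hits: dict[tuple[str, str], int] = {}
    for mag, sample in mag_samples.items():
        taxon = _taxon_of(mag_lineages.get(mag), rank)
        key = (taxon, sample)
        totals[key] = totals.get(key, 0) + 1
        if mag in with_family:
            hits[key] = hits.get(key, 0) + 1
    return [
        MagFractionCell(taxon, sample, family, n, hits.get((taxon, sample), 0))
        for (taxon, sample), n in sorted(totals.items())
    ]


def gene_cooccurrence(
    presence: Mapping[tuple[str, str], object],
    mag_lineages: Mapping[str, Lineage],
    pair: tuple[str, str],
    rank: str = "phylum",
) -> CooccurrenceReport:
    """Per-taxon counts of MAGs carrying both, or exactly one, of a pair."""
    fam_a, fam_b = pair
    by_family = _mag_presence(presence)
    mags_a = by_family.get(fam_a, set())
    mags_b = by_family.get(fam_b, set())
    both: dict[str, int] = {}
    first_only: dict[str, int] = {}
    second_only: dict[str, int] = {}
    for mag in mags_a | mags_b:
        taxon = _taxon_of(mag_lineages.get(mag), rank)
        if mag in mags_a and mag in mags_b:
            both[taxon] = both.get(taxon, 0) + 1
        elif mag in mags_a:
            first_only[taxon] = first_only.get(taxon, 0) + 1
        else:
            second_only[taxon] = second_only.get(taxon, 0) + 1
    return CooccurrenceReport(pair, both, first_only, second_only)


def compare_profiles(
    lipid: str,
    lipid_profile: Mapping[str, float],
    gene_profile: TaxonDepthProfile,
) -> ProfileComparison:
    """Spearman rho between a lipid profile and one gene profile.

    Computed on the samples shared by the two profiles, with average ranks
    for ties; fewer than three shared samples is an error.  A profile with
    no variation has undefined rank correlation and yields NaN.
    """
    shared = [s for s in lipid_profile if s in gene_profile.values]
    if len(shared) < 3:
        raise InsufficientDataError(
            f"only {len(shared)} shared samples between lipid {lipid!r} and "
            f"profile ({gene_profile.taxon}, {gene_profile.family})"
        )
    x = [lipid_profile[s] for s in shared]
    y = [gene_profile.values[s] for s in shared]
    rho = stats.spearmanr(x, y).statistic
    return ProfileComparison(
        lipid=lipid,
        taxon=gene_profile.taxon,
        family=gene_profile.family,
        rho=float(rho),
        n=len(shared),
    )


def rank_candidate_producers(
    lipid: str,
    lipid_profile: Mapping[str, float],
    gene_profiles: Iterable[TaxonDepthProfile],
    family: str,
) -> list[tuple[str, float]]:
    """Taxa ranked by Spearman agreement with the lipid profile.

    Only profiles of ``family`` are considered; all-zero gene profiles are
    excluded (a taxon never observed with the gene is not a candidate), as
    are profiles whose correlation is undefined.  Ties are broken
    alphabetically.
    """
    scored: list[tuple[str, float]] = []
    for profile in gene_profiles:
        if profile.family != family or profile.is_zero():
            continue
        comparison = compare_profiles(lipid, lipid_profile, profile)
        if math.isnan(comparison.rho):
            continue
        scored.append((profile.taxon, comparison.rho))
    scored.sort(key=lambda tr: (-tr[1], tr[0]))
    return scored
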