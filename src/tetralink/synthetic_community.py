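"""Synthetic stratified-water-column study generator with ground truth.

Emulates the data model of a depth-resolved metagenomic + lipidomic survey:
a series of samples (labelled by depth in metres) each individually
assembled, reads of every sample mapped back against every assembly that
shares strains with it, scaffolds binned per sample into MAGs with tunable
completeness/contamination and a fraction left unbinned, biosynthetic gene
families planted in chosen phyla, and a lipid peak table with multiple
adducts, an internal standard and per-sample matrix effects.  Everything is
driven by a single seed through one named generator, and the full provenance
(which genome produced which scaffold, bin and lipid signal) is returned as
ground truth so downstream attribution can be scored exactly.

Genome relative abundances are lognormal per sample; per-scaffold read
counts are Poisson around the abundance-proportional expectation and
converted to average depth (reads per base pair).  Strains shared between
adjacent samples produce cross-sample mappings drawn from the same Poisson
model, reproducing the double-counting artefact that own-sample aggregation
corrects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import formats_io
from .depth_abundance import DepthRecord
from .errors import ConfigurationError
from .marker_concat import MagQuality
from .taxonomy_resolve import Lineage, MajorityConfig, majority_classify_bin

__all__ = [
    "DEFAULT_DEPTH_LABELS",
    "CommunityConfig",
    "GroundTruth",
    "BinProvenance",
    "SyntheticBundle",
    "generate_community",
    "generate_lipid_peaks",
    "false_attribution_fraction",
    "write_bundle",
]

#: The 15 water-column depths (m) of the emulated survey, oxic surface to
#: deep euxinic zone.
DEFAULT_DEPTH_LABELS: tuple[str, ...] = (
    "50", "70", "80", "85", "90", "95", "100", "105",
    "110", "130", "170", "250", "500", "1000", "2000",
)

#: Phyla treated as archaeal when building domain-level lineages.
ARCHAEAL_PHYLA: frozenset[str] = frozenset(
    {"Thermoproteota", "Thermoplasmatota", "Nanoarchaeota", "Halobacteriota",
     "Asgardarchaeota", "Aenigmatarchaeota"}
)

DEFAULT_PHYLUM_POOL: tuple[str, ...] = (
    "Desulfobacterota",
    "Planctomycetota",
    "Chloroflexota",
    "Cloacimonadota",
    "Actinobacteriota",
    "Thermoproteota",
)

#: Families planted by default: the bacterial membrane-spanning-lipid
#: synthase and ether-forming reductase in sulfate reducers and
#: planctomycetes, the archaeal tetraether synthase in Thermoproteota, and
#: the GMGT bridge synthase in planctomycetes.
DEFAULT_PLANTED_FAMILIES: dict[str, frozenset[str]] = {
    "mss": frozenset({"Desulfobacterota", "Planctomycetota"}),
    "ger": frozenset({"Desulfobacterota", "Planctomycetota"}),
    "tes": frozenset({"Thermoproteota"}),
    "gms": frozenset({"Planctomycetota"}),
}

_ADDUCT_FRACTIONS = {"M+H": 0.6, "M+NH4": 0.3, "M+Na": 0.1}
_BASE_RESPONSE = 1.0e6
_IS_BASE_AREA = 1.0e5


@dataclass
class CommunityConfig:
    """Everything that defines one synthetic study.

    Defaults emulate a 15-depth water-column survey with a modest community;
    all probabilities and fractions must lie in [0, 1] and all counts must
    be positive.  A fixed seed makes the emitted bundle byte-identical.
    """

    n_samples: int = 15
    sample_labels: Optional[Sequence[str]] = None
    n_genomes: int = 24
    phylum_pool: Sequence[str] = DEFAULT_PHYLUM_POOL
    abundance_logmean: float = 0.0
    abundance_logsd: float = 1.0
    sharing_prob: float = 0.5
    scaffolds_per_genome: int = 10
    scaffold_len_bp: int = 20_000
    reads_per_sample: int = 1_000_000
    planted_families: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_FAMILIES)
    )
    bin_completeness: float = 0.9
    bin_contamination: float = 0.0
    unbinned_frac: float = 0.1
    litres: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_samples": self.n_samples,
            "n_genomes": self.n_genomes,
            "scaffolds_per_genome": self.scaffolds_per_genome,
            "scaffold_len_bp": self.scaffold_len_bp,
            "reads_per_sample": self.reads_per_sample,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ConfigurationError(f"{name} must be a positive integer")
        fractions = {
            "sharing_prob": self.sharing_prob,
            "bin_completeness": self.bin_completeness,
            "bin_contamination": self.bin_contamination,
            "unbinned_frac": self.unbinned_frac,
        }
        for name, value in fractions.items():
            if not 0 <= value <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.abundance_logsd < 0:
            raise ConfigurationError("abundance_logsd must be non-negative")
        if self.litres <= 0:
            raise ConfigurationError("litres must be positive")
        if not self.phylum_pool:
            raise ConfigurationError("phylum_pool must not be empty")
        if self.sample_labels is not None and len(self.sample_labels) != self.n_samples:
            raise ConfigurationError(
                "sample_labels length must equal n_samples"
            )
        pool = set(self.phylum_pool)
        for family, phyla in self.planted_families.items():
            if not set(phyla) <= pool:
                raise ConfigurationError(
                    f"planted_families[{family}] names phyla outside phylum_pool"
                )
        if int(self.seed) != self.seed:
            raise ConfigurationError("seed must be an integer")

    def labels(self) -> list[str]:
        if self.sample_labels is not None:
            return [str(s) for s in self.sample_labels]
        if self.n_samples == len(DEFAULT_DEPTH_LABELS):
            return list(DEFAULT_DEPTH_LABELS)
        if self.n_samples <= len(DEFAULT_DEPTH_LABELS):
            return list(DEFAULT_DEPTH_LABELS[: self.n_samples])
        depths = np.unique(
            np.geomspace(50, 2000, self.n_samples).round().astype(int)
        )
        extra = 2000
        labels = [str(d) for d in depths]
        while len(labels) < self.n_samples:  # pad past 2000 m if oversampled
            extra += 500
            labels.append(str(extra))
        return labels


@dataclass
class BinProvenance:
    """Which genome a bin represents and where its contaminants came from."""

    source_genome: str
    contaminants: dict[str, str]  # contaminant scaffold -> donor genome


@dataclass
class GroundTruth:
    genome_phylum: dict[str, str]
    genome_samples: dict[str, list[str]]
    genome_families: dict[str, set[str]]
    true_abundance: pd.DataFrame  # genomes x samples, relative abundance
    scaffold_genome: dict[str, str]
    bin_provenance: dict[str, BinProvenance]


@dataclass
class SyntheticBundle:
    """All input tables of one synthetic study plus its ground truth."""

    config: CommunityConfig
    samples: list[str]
    hit_rows: list[tuple]
    depth_records: list[DepthRecord]
    bins: dict[str, str]
    bin_samples: dict[str, str]
    scaffold_lineages: dict[str, Lineage]
    bin_lineages: dict[str, Lineage]
    quality: list[MagQuality]
    proteins: dict[str, str]
    queries: dict[str, str]
    truth: GroundTruth


def _genome_lineage(phylum: str) -> Lineage:
    domain = "Archaea" if phylum in ARCHAEAL_PHYLA else "Bacteria"
    return Lineage.from_names([domain, phylum])


_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AMINO_ACIDS, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = []
    for aa in seq:
        if rng.random() < rate:
            out.append(str(rng.choice(_AMINO_ACIDS)))
        else:
            out.append(aa)
    return "".join(out)


def generate_community(config: CommunityConfig) -> SyntheticBundle:
    """Generate a full synthetic study bundle (tables + ground truth).

    See the module docstring for the generative model.  Determinism: the
    same config (including seed) always yields an identical bundle.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = config.labels()
    n = config.n_samples
    genomes = [f"g{i:02d}" for i in range(config.n_genomes)]
    phylum = {
        g: config.phylum_pool[i % len(config.phylum_pool)]
        for i, g in enumerate(genomes)
    }
    planted = {f: frozenset(p) for f, p in config.planted_families.items()}
    genome_families = {
        g: {f for f, phyla in planted.items() if phylum[g] in phyla}
        for g in genomes
    }

    # ----- presence: a contiguous depth range around a random anchor -----
    presence: dict[str, list[str]] = {}
    for g in genomes:
        anchor = int(rng.integers(n))
        lo = anchor
        while lo > 0 and rng.random() < config.sharing_prob:
            lo -= 1
        hi = anchor
        while hi < n - 1 and rng.random() < config.sharing_prob:
            hi += 1
        presence[g] = samples[lo : hi + 1]

    # ----- lognormal relative abundances per sample -----
    raw = {
        (g, s): float(rng.lognormal(config.abundance_logmean, config.abundance_logsd))
        for g in genomes
        for s in presence[g]
    }
    sample_tot = {s: 0.0 for s in samples}
    for (g, s), w in raw.items():
        sample_tot[s] += w
    abundance = pd.DataFrame(0.0, index=genomes, columns=samples)
    for (g, s), w in raw.items():
        abundance.loc[g, s] = w / sample_tot[s]

    # ----- per-assembly scaffolds -----
    scaffolds: dict[str, list[tuple[str, str]]] = {}
    scaffold_genome: dict[str, str] = {}
    for s in samples:
        scaffolds[s] = []
        for g in genomes:
            if s not in presence[g]:
                continue
            for k in range(config.scaffolds_per_genome):
                scf = f"s{s}_{g}_c{k}"
                scaffolds[s].append((scf, g))
                scaffold_genome[scf] = g

    # ----- Poisson read counts -> depth records -----
    per_scf_reads: dict[tuple[str, str], int] = {}  # (scaffold, mapping) -> reads
    for a in samples:
        for scf, g in scaffolds[a]:
            for m in presence[g]:
                lam = (
                    config.reads_per_sample
                    * abundance.loc[g, m]
                    / config.scaffolds_per_genome
                )
                per_scf_reads[(scf, m)] = int(rng.poisson(lam))
    mapping_total: dict[tuple[str, str], int] = {}
    for a in samples:
        for scf, g in scaffolds[a]:
            for m in presence[g]:
                key = (a, m)
                mapping_total[key] = mapping_total.get(key, 0) + per_scf_reads[(scf, m)]
    depth_records: list[DepthRecord] = []
    for a in samples:
        for scf, g in scaffolds[a]:
            for m in presence[g]:
                total = mapping_total[(a, m)]
                if total <= 0:
                    continue  # a mapping with zero reads produces no table
                depth_records.append(
                    DepthRecord(
                        scaffold_id=scf,
                        assembly_sample=a,
                        mapping_sample=m,
                        avg_depth=per_scf_reads[(scf, m)] / config.scaffold_len_bp,
                        mapping_total_reads=float(total),
                    )
                )

    # ----- binning with completeness loss, contamination and unbinned -----
    bins: dict[str, str] = {}
    bin_samples: dict[str, str] = {}
    bin_lineages: dict[str, Lineage] = {}
    quality: list[MagQuality] = []
    bin_provenance: dict[str, BinProvenance] = {}
    for a in samples:
        plan: dict[str, tuple[Optional[list[str]], list[str]]] = {}
        for g in genomes:
            if a not in presence[g]:
                continue
            scfs = [scf for scf, gg in scaffolds[a] if gg == g]
            if rng.random() < config.unbinned_frac:
                plan[g] = (None, scfs)  # whole genome left unbinned here
                continue
            n_keep = max(1, int(round(config.bin_completeness * len(scfs))))
            kept_idx = sorted(rng.choice(len(scfs), size=n_keep, replace=False))
            kept = [scfs[i] for i in kept_idx]
            dropped = [scf for i, scf in enumerate(scfs) if i not in kept_idx]
            plan[g] = (kept, dropped)
        free_pool = [
            (g, scf) for g, (kept, dropped) in plan.items() for scf in dropped
        ]
        taken: set[str] = set()
        for g, (kept, _) in plan.items():
            if kept is None:
                continue
            bin_id = f"s{a}_b{g}"
            members = list(kept)
            contaminants: dict[str, str] = {}
            if config.bin_contamination > 0:
                donors = [
                    (dg, scf)
                    for dg, scf in free_pool
                    if phylum[dg] != phylum[g] and scf not in taken
                ]
                n_cont = int(rng.binomial(len(kept), config.bin_contamination))
                n_cont = min(n_cont, len(donors))
                if n_cont:
                    idx = sorted(rng.choice(len(donors), size=n_cont, replace=False))
                    for i in idx:
                        dg, scf = donors[i]
                        members.append(scf)
                        contaminants[scf] = dg
                        taken.add(scf)
            for scf in members:
                bins[scf] = bin_id
            bin_samples[bin_id] = a
            bin_lineages[bin_id] = majority_classify_bin(
                [(_genome_lineage(phylum[scaffold_genome[scf]]), 1.0) for scf in members],
                MajorityConfig(f=0.5, weight_mode="scaffold_count"),
            )
            quality.append(
                MagQuality(
                    mag_id=bin_id,
                    completeness=100.0 * len(kept) / config.scaffolds_per_genome,
                    contamination=100.0 * len(contaminants) / len(kept),
                )
            )
            bin_provenance[bin_id] = BinProvenance(g, contaminants)

    scaffold_lineages = {
        scf: _genome_lineage(phylum[g]) for scf, g in scaffold_genome.items()
    }

    # ----- gene plants and boundary decoys as tabular alignment rows -----
    families = sorted(planted)
    queries = {f: _random_protein(rng, 60) for f in families}
    proteins: dict[str, str] = {}
    hit_rows: list[tuple] = []

    def _row(family, protein_id, pident, evalue, bits):
        return (
            family, protein_id, round(pident, 2), 60, 10, 0,
            1, 60, 1, 60, evalue, round(bits, 1),
        )

    for a in samples:
        for scf, g in scaffolds[a]:
            for family in sorted(genome_families[g]):
                protein_id = f"{scf}_1"
                if protein_id not in proteins:
                    proteins[protein_id] = _mutate(rng, queries[family], 0.3)
                evalue = float(10.0 ** -rng.uniform(35, 60))
                hit_rows.append(
                    _row(family, protein_id,
                         rng.uniform(40, 90), evalue, rng.uniform(200, 500))
                )
        # boundary decoys pin the threshold operators: an e-value of exactly
        # 1e-30 fails the strict "<", an identity of 29.99 fails ">= 30"
        if not scaffolds[a]:
            continue
        for family in families:
            non_producers = [
                scf for scf, g in scaffolds[a] if family not in genome_families[g]
            ] or [scf for scf, _ in scaffolds[a]]
            scf = non_producers[int(rng.integers(len(non_producers)))]
            pid = f"{scf}_9001"
            proteins.setdefault(pid, _random_protein(rng, 60))
            hit_rows.append(_row(family, pid, 50.0, 1e-30, 120.0))
            scf = non_producers[int(rng.integers(len(non_producers)))]
            pid = f"{scf}_9002"
            proteins.setdefault(pid, _random_protein(rng, 60))
            hit_rows.append(_row(family, pid, 29.99, 1e-40, 120.0))

    truth = GroundTruth(
        genome_phylum=phylum,
        genome_samples=presence,
        genome_families=genome_families,
        true_abundance=abundance,
        scaffold_genome=scaffold_genome,
        bin_provenance=bin_provenance,
    )
    return SyntheticBundle(
        config=config,
        samples=samples,
        hit_rows=hit_rows,
        depth_records=depth_records,
        bins=bins,
        bin_samples=bin_samples,
        scaffold_lineages=scaffold_lineages,
        bin_lineages=bin_lineages,
        quality=quality,
        proteins=proteins,
        queries=queries,
        truth=truth,
    )


def generate_lipid_peaks(
    config: CommunityConfig,
    producer_map: Mapping[str, str],
    truth: GroundTruth,
) -> pd.DataFrame:
    """Lipid peak table implied by the community's planted producers.

    ``producer_map`` maps gene family -> lipid name; a genome contributes to
    a lipid's signal if it carries at least one family mapped to it.  Areas
    split over three adducts, every area (analyte and internal standard) is
    scaled by a per-sample matrix factor that cancels under IS
    normalization, and the IS area is positive in every sample.
    """
    config.validate()
    unknown = [f for f in producer_map if f not in config.planted_families]
    if unknown:
        raise ConfigurationError(
            "producer_map keys must be planted families; unknown: "
            + ", ".join(sorted(unknown))
        )
    rng = np.random.default_rng([config.seed, 101])
    samples = list(truth.true_abundance.columns)
    matrix = {s: float(rng.lognormal(0.0, 0.3)) for s in samples}
    lipids = sorted(set(producer_map.values()))
    rows = []
    for lipid in lipids:
        lipid_families = {f for f, l in producer_map.items() if l == lipid}
        producers = [
            g
            for g, fams in sorted(truth.genome_families.items())
            if fams & lipid_families
        ]
        for s in samples:
            signal = float(truth.true_abundance.loc[producers, s].sum())
            for adduct, frac in _ADDUCT_FRACTIONS.items():
                rows.append(
                    (
                        lipid,
                        s,
                        adduct,
                        signal * _BASE_RESPONSE * frac * matrix[s],
                        _IS_BASE_AREA * matrix[s],
                        config.litres,
                    )
                )
    return pd.DataFrame(rows, columns=formats_io.PEAK_HEADER)


def false_attribution_fraction(
    presence: Mapping[tuple[str, str], object],
    truth: GroundTruth,
    planted_families: Mapping[str, frozenset[str]],
) -> float:
    """Fraction of (family, MAG) presence calls whose MAG's true source
    genome is not of a planted producer phylum (ground-truth scoring of
    contamination-driven mis-attribution).  Returns 0.0 when nothing is
    present."""
    total = wrong = 0
    for family, unit in presence:
        if unit.startswith("unbinned:"):
            continue
        prov = truth.bin_provenance.get(unit)
        if prov is None:
            continue
        total += 1
        source_phylum = truth.genome_phylum[prov.source_genome]
        if source_phylum not in planted_families.get(family, frozenset()):
            wrong += 1
    return wrong / total if total else 0.0


def write_bundle(bundle: SyntheticBundle, outdir) -> dict:
    """Write every bundle table in the pipeline's file dialects.

    Emits a YAML manifest listing each path plus the ground-truth file; the
    write is deterministic so fixed-seed bundles are byte-identical on disk.
    """
    import os

    os.makedirs(outdir, exist_ok=True)

    def p(name):
        return os.path.join(outdir, name)

    formats_io.write_blast6(p("hits.b6"), bundle.hit_rows)
    formats_io.write_depth_table(p("depth.tsv"), bundle.depth_records)
    formats_io.write_bin_table(p("bins.tsv"), dict(sorted(bundle.bins.items())))
    formats_io.write_lineage_table(
        p("scaffold_lineages.tsv"), dict(sorted(bundle.scaffold_lineages.items()))
    )
    formats_io.write_lineage_table(
        p("bin_lineages.tsv"), dict(sorted(bundle.bin_lineages.items()))
    )
    formats_io.write_quality_table(p("quality.tsv"), bundle.quality)
    formats_io.write_fasta(p("proteins.faa"), dict(sorted(bundle.proteins.items())))
    formats_io.write_fasta(p("queries.faa"), dict(sorted(bundle.queries.items())))
    with open(p("bin_samples.tsv"), "w", encoding="utf-8") as fh:
        fh.write("bin\tsample\n")
        for bin_id, sample in sorted(bundle.bin_samples.items()):
            fh.write(f"{bin_id}\t{sample}\n")

    truth = bundle.truth
    truth_doc = {
        "genome_phylum": dict(sorted(truth.genome_phylum.items())),
        "genome_samples": {g: list(s) for g, s in sorted(truth.genome_samples.items())},
        "genome_families": {
            g: sorted(f) for g, f in sorted(truth.genome_families.items())
        },
        "true_abundance": {
            g: {s: float(truth.true_abundance.loc[g, s]) for s in bundle.samples}
            for g in truth.true_abundance.index
        },
        "scaffold_genome": dict(sorted(truth.scaffold_genome.items())),
        "bin_provenance": {
            b: {"source_genome": pr.source_genome, "contaminants": dict(sorted(pr.contaminants.items()))}
            for b, pr in sorted(truth.bin_provenance.items())
        },
    }
    with open(p("ground_truth.yaml"), "w", encoding="utf-8") as fh:
        yaml.safe_dump(truth_doc, fh, sort_keys=True)

    manifest = {
        "samples": bundle.samples,
        "files": {
            "hits": "hits.b6",
            "depth": "depth.tsv",
            "bins": "bins.tsv",
            "scaffold_lineages": "scaffold_lineages.tsv",
            "bin_lineages": "bin_lineages.tsv",
            "bin_samples": "bin_samples.tsv",
            "quality": "quality.tsv",
            "proteins": "proteins.faa",
            "queries": "queries.faa",
            "ground_truth": "ground_truth.yaml",
        },
        "seed": bundle.config.seed,
    }
    with open(p("manifest.yaml"), "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
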