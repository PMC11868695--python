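"""End-to-end orchestration: screen -> resolve -> abundance -> attribution,
with lipid quantification run in parallel, plus a self-contained demo mode
that exercises the whole pipeline on a generated synthetic bundle.

Every run writes a provenance YAML recording thresholds, input checksums and
the package version, sufficient to re-run identically.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import yaml

from . import __version__, formats_io
from .attribution_profiles import (
    gene_cooccurrence,
    mag_fraction_matrix,
    rank_candidate_producers,
)
from .depth_abundance import (
    NormConfig,
    profile_by_taxon_gene,
    sort_sample_labels,
)
from .errors import TetralinkError
from .homology_screen import (
    ScreenConfig,
    dedupe_hits,
    filter_hits,
    presence_by_unit,
)
from .lipid_quant import load_registry, quantify_peaks, verify_registry
from .synthetic_community import (
    CommunityConfig,
    generate_community,
    generate_lipid_peaks,
    write_bundle,
)
from .taxonomy_resolve import (
    MajorityConfig,
    majority_classify_bin,
    resolve_hit_taxonomy,
)

__all__ = ["RunConfig", "StageError", "run_attribution", "run_lipids", "run_demo"]

log = logging.getLogger("tetralink")

DEMO_PRODUCER_MAP = {"mss": "brGDGT-1a", "ger": "brGDGT-1a", "gms": "brGMGT-1a"}


class StageError(TetralinkError):
    """An error wrapped with the name of the pipeline stage that raised it."""


@dataclass
class RunConfig:
    """Paths and parameters of one attribution run."""

    hits: str
    bins: str
    scaffold_lineages: str
    depth: str
    outdir: str
    bin_lineages: Optional[str] = None  # computed by majority vote if absent
    bin_samples: Optional[str] = None
    peaks: Optional[str] = None
    registry: Optional[str] = None
    producer_map: Mapping[str, str] = field(default_factory=dict)
    cooccurrence_pairs: Sequence[tuple[str, str]] = (("mss", "ger"),)
    rank: str = "phylum"
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    majority: MajorityConfig = field(default_factory=MajorityConfig)
    norm: NormConfig = field(default_factory=NormConfig)
    samples: Optional[Sequence[str]] = None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        base = os.path.dirname(os.path.abspath(path))

        def resolve(p):
            if p is None:
                return None
            return p if os.path.isabs(p) else os.path.join(base, p)

        pairs = [tuple(p) for p in doc.get("cooccurrence_pairs", [["mss", "ger"]])]
        return cls(
            hits=resolve(doc["hits"]),
            bins=resolve(doc["bins"]),
            scaffold_lineages=resolve(doc["scaffold_lineages"]),
            depth=resolve(doc["depth"]),
            outdir=resolve(doc["outdir"]),
            bin_lineages=resolve(doc.get("bin_lineages")),
            bin_samples=resolve(doc.get("bin_samples")),
            peaks=resolve(doc.get("peaks")),
            registry=resolve(doc.get("registry")),
            producer_map=doc.get("producer_map", {}),
            cooccurrence_pairs=pairs,
            rank=doc.get("rank", "phylum"),
            screen=ScreenConfig(
                evalue_max=float(doc.get("evalue_max", 1e-30)),
                pident_min=float(doc.get("pident_min", 30.0)),
            ),
            majority=MajorityConfig(f=float(doc.get("majority_f", 0.5))),
            norm=NormConfig(scale=float(doc.get("scale", 1e8))),
            samples=doc.get("samples"),
        )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    """Decorator-ish context: re-raise any pipeline error with its stage."""

    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, TetralinkError):
                raise StageError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def _read_bin_samples(path: str) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("bin\t"):
                continue
            bin_id, sample = line.split("\t")[:2]
            out[bin_id] = sample
    return out


def run_lipids(cfg: RunConfig) -> dict:
    """Quantify the peak table and check registry mass consistency.

    Writes per-lipid response-units-per-litre and relative-abundance tables
    plus an identification report flagging any registry species whose
    computed rounded [M+H]+ m/z conflicts with its declared nominal mass.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    with _stage("lipids"):
        registry = load_registry(cfg.registry)
        conflicts = verify_registry(registry)
        if cfg.peaks is not None:
            peaks = formats_io.read_peak_table(cfg.peaks)
            responses = quantify_peaks(peaks)
        else:
            import pandas as pd

            responses = pd.DataFrame()
        profiles = {
            lipid: {s: float(responses.loc[lipid, s]) for s in responses.columns}
            for lipid in responses.index
        }
        formats_io.write_lipid_profile_table(
            os.path.join(cfg.outdir, "lipid_profiles.tsv"), profiles
        )
        if not responses.empty:
            from .lipid_quant import relative_abundance_profile

            rel = relative_abundance_profile(responses)
            rel_profiles = {
                lipid: {
                    s: float(rel.loc[lipid, s])
                    for s in rel.columns
                    if rel.loc[lipid, s] == rel.loc[lipid, s]  # defined only
                }
                for lipid in rel.index
            }
        else:
            rel_profiles = {}
        formats_io.write_lipid_profile_table(
            os.path.join(cfg.outdir, "lipid_relative_abundance.tsv"), rel_profiles
        )
        report_path = os.path.join(cfg.outdir, "identification_report.tsv")
        with open(report_path, "w", encoding="utf-8") as fh:
            fh.write("lipid\tformula\tcomputed_mz\tnominal_mz\tstatus\n")
            from .lipid_quant import rounded_mz

            for name in sorted(registry):
                sp = registry[name]
                computed = rounded_mz(sp.mz("M+H"))
                status = "ok" if computed == sp.nominal_mz else "conflict"
                fh.write(
                    f"{name}\t{sp.formula}\t{computed}\t{sp.nominal_mz}\t{status}\n"
                )
    return {"profiles": profiles, "conflicts": conflicts}


def run_attribution(cfg: RunConfig) -> dict:
    """Run the full attribution analysis and write the report bundle."""
    inputs = {
        "hits": cfg.hits,
        "bins": cfg.bins,
        "scaffold_lineages": cfg.scaffold_lineages,
        "depth": cfg.depth,
    }
    for opt in ("bin_lineages", "bin_samples", "peaks", "registry"):
        if getattr(cfg, opt) is not None:
            inputs[opt] = getattr(cfg, opt)
    for name, path in inputs.items():
        if not os.path.exists(path):
            raise StageError(f"[inputs] missing {name} table: {path}")

    with _stage("screen"):
        raw_hits = formats_io.read_blast6(cfg.hits)
        kept = filter_hits(raw_hits, cfg.screen)
        hits = dedupe_hits(kept)
        log.info(
            "screen: %d raw hits, %d pass thresholds, %d unique proteins",
            len(raw_hits), len(kept), len(hits),
        )
        bins = formats_io.read_bin_table(cfg.bins)
        presence = presence_by_unit(hits, bins)

    with _stage("resolve"):
        scaffold_lineages = formats_io.read_lineage_table(cfg.scaffold_lineages)
        if cfg.bin_lineages is not None:
            bin_lineages = formats_io.read_lineage_table(cfg.bin_lineages)
        else:
            by_bin: dict[str, list] = {}
            for scf, bin_id in bins.items():
                lin = scaffold_lineages.get(scf)
                if lin is not None:
                    by_bin.setdefault(bin_id, []).append((lin, 1.0))
            bin_lineages = {
                b: majority_classify_bin(pairs, cfg.majority)
                for b, pairs in by_bin.items()
            }
        resolved = {
            scf: resolve_hit_taxonomy(scf, bins, scaffold_lineages, bin_lineages)
            for scf in {h.scaffold_id for h in hits}
        }

    with _stage("abundance"):
        records = formats_io.read_depth_table(cfg.depth)
        samples = (
            list(cfg.samples)
            if cfg.samples is not None
            else sort_sample_labels(
                [r.mapping_sample for r in records]
                + [r.assembly_sample for r in records]
            )
        )
        profiles = profile_by_taxon_gene(
            hits, resolved, records, cfg.rank, samples, cfg.norm, mode="own"
        )
        naive_profiles = profile_by_taxon_gene(
            hits, resolved, records, cfg.rank, samples, cfg.norm, mode="naive"
        )

    with _stage("attribute"):
        if cfg.bin_samples is not None:
            bin_sample_map = _read_bin_samples(cfg.bin_samples)
        else:
            bin_sample_map = {b: "all" for b in set(bins.values())}
        families = sorted({h.family for h in hits})
        fraction_cells = {
            family: mag_fraction_matrix(
                presence, bin_lineages, bin_sample_map, family, cfg.rank
            )
            for family in families
        }
        cooccurrence = [
            gene_cooccurrence(presence, bin_lineages, tuple(pair), cfg.rank)
            for pair in cfg.cooccurrence_pairs
        ]
        rankings: dict[str, list[tuple[str, float]]] = {}
        lipid_profiles: dict[str, dict[str, float]] = {}
        if cfg.peaks is not None:
            lipid_result = run_lipids(cfg)
            lipid_profiles = lipid_result["profiles"]
            for family, lipid in sorted(cfg.producer_map.items()):
                if lipid in lipid_profiles:
                    rankings[f"{lipid}:{family}"] = rank_candidate_producers(
                        lipid, lipid_profiles[lipid], profiles, family
                    )

    os.makedirs(cfg.outdir, exist_ok=True)

    def out(name):
        return os.path.join(cfg.outdir, name)

    formats_io.write_presence_table(out("presence.tsv"), presence)
    formats_io.write_lineage_table(
        out("resolved_lineages.tsv"), dict(sorted(resolved.items()))
    )
    formats_io.write_profile_table(out("profiles_own.tsv"), profiles)
    formats_io.write_profile_table(out("profiles_naive.tsv"), naive_profiles)
    with open(out("mag_fractions.tsv"), "w", encoding="utf-8") as fh:
        fh.write("family\ttaxon\tsample\tn_mags\tn_with_family\tfraction\n")
        for family in families:
            for cell in fraction_cells[family]:
                fh.write(
                    f"{family}\t{cell.taxon}\t{cell.sample}\t{cell.n_mags}\t"
                    f"{cell.n_with_family}\t{cell.fraction:.6g}\n"
                )
    with open(out("cooccurrence.tsv"), "w", encoding="utf-8") as fh:
        fh.write("family_a\tfamily_b\ttaxon\tboth\tonly_a\tonly_b\n")
        for report in cooccurrence:
            fa, fb = report.family_pair
            for taxon in report.taxa():
                fh.write(
                    f"{fa}\t{fb}\t{taxon}\t{report.both.get(taxon, 0)}\t"
                    f"{report.first_only.get(taxon, 0)}\t"
                    f"{report.second_only.get(taxon, 0)}\n"
                )
    with open(out("ranked_candidates.tsv"), "w", encoding="utf-8") as fh:
        fh.write("lipid\tfamily\trank\ttaxon\tspearman_rho\n")
        for key in sorted(rankings):
            lipid, family = key.split(":")
            for i, (taxon, rho) in enumerate(rankings[key], start=1):
                fh.write(f"{lipid}\t{family}\t{i}\t{taxon}\t{rho:.6g}\n")

    provenance = {
        "tetralink_version": __version__,
        "inputs": {name: {"path": os.path.basename(path), "sha256": _sha256(path)}
                   for name, path in sorted(inputs.items())},
        "parameters": {
            "evalue_max": cfg.screen.evalue_max,
            "pident_min": cfg.screen.pident_min,
            "majority_f": cfg.majority.f,
            "weight_mode": cfg.majority.weight_mode,
            "scale": cfg.norm.scale,
            "rank": cfg.rank,
            "samples": samples,
            "producer_map": dict(cfg.producer_map),
            "cooccurrence_pairs": [list(p) for p in cfg.cooccurrence_pairs],
        },
    }
    with open(out("provenance.yaml"), "w", encoding="utf-8") as fh:
        yaml.safe_dump(provenance, fh, sort_keys=True)

    return {
        "presence": presence,
        "profiles": profiles,
        "naive_profiles": naive_profiles,
        "mag_fractions": fraction_cells,
        "cooccurrence": cooccurrence,
        "rankings": rankings,
        "lipid_profiles": lipid_profiles,
    }


def run_demo(seed: int, outdir: str, config: Optional[CommunityConfig] = None) -> dict:
    """Generate a synthetic bundle and run the full pipeline on it."""
    config = config or CommunityConfig(seed=seed)
    if config.seed != seed:
        config.seed = seed
    bundle = generate_community(config)
    data_dir = os.path.join(outdir, "data")
    write_bundle(bundle, data_dir)
    producer_map = {
        f: lipid for f, lipid in DEMO_PRODUCER_MAP.items()
        if f in config.planted_families
    }
    peaks = generate_lipid_peaks(config, producer_map, bundle.truth)
    peaks_path = os.path.join(data_dir, "peaks.tsv")
    formats_io.write_peak_table(peaks_path, peaks)
    cfg = RunConfig(
        hits=os.path.join(data_dir, "hits.b6"),
        bins=os.path.join(data_dir, "bins.tsv"),
        scaffold_lineages=os.path.join(data_dir, "scaffold_lineages.tsv"),
        bin_lineages=os.path.join(data_dir, "bin_lineages.tsv"),
        bin_samples=os.path.join(data_dir, "bin_samples.tsv"),
        depth=os.path.join(data_dir, "depth.tsv"),
        peaks=peaks_path,
        producer_map=producer_map,
        cooccurrence_pairs=[("mss", "ger")],
        samples=bundle.samples,
        outdir=os.path.join(outdir, "report"),
    )
    return run_attribution(cfg)
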