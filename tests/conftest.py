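import pytest
from hypothesis import HealthCheck, settings

from tetralink.formats_io import split_subject_id
from tetralink.homology_screen import HomologHit
from tetralink.synthetic_community import CommunityConfig

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def small_config(seed: int = 0, **overrides) -> CommunityConfig:
    """A scaled-down synthetic study used for fast end-to-end checks."""
    params = dict(
        n_samples=6,
        n_genomes=8,
        phylum_pool=(
            "Desulfobacterota",
            "Planctomycetota",
            "Chloroflexota",
            "Thermoproteota",
        ),
        scaffolds_per_genome=6,
        scaffold_len_bp=5_000,
        reads_per_sample=200_000,
        planted_families={
            "mss": frozenset({"Desulfobacterota"}),
            "ger": frozenset({"Desulfobacterota", "Planctomycetota"}),
            "tes": frozenset({"Thermoproteota"}),
        },
        bin_contamination=0.0,
        seed=seed,
    )
    params.update(overrides)
    return CommunityConfig(**params)


def rows_to_hits(rows) -> list[HomologHit]:
    """Convert raw tabular alignment rows to hit objects without file IO."""
    hits = []
    for r in rows:
        scaffold, protein_index = split_subject_id(str(r[1]))
        hits.append(
            HomologHit(
                family=str(r[0]),
                scaffold_id=scaffold,
                protein_index=protein_index,
                pident=float(r[2]),
                evalue=float(r[10]),
                bitscore=float(r[11]),
                qstart=int(r[6]),
                qend=int(r[7]),
                sstart=int(r[8]),
                send=int(r[9]),
            )
        )
    return hits


@pytest.fixture
def tiny_bundle():
    from tetralink.synthetic_community import generate_community

    return generate_community(small_config(seed=11))
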