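"""The synthetic study generator: determinism, bookkeeping invariants,
planted-gene placement and the lipid peak model."""

import numpy as np
import pytest

from conftest import rows_to_hits, small_config
from tetralink.errors import ConfigurationError
from tetralink.homology_screen import dedupe_hits, filter_hits, presence_by_unit
from tetralink.lipid_quant import quantify_peaks
from tetralink.synthetic_community import (
    CommunityConfig,
    generate_community,
    generate_lipid_peaks,
    write_bundle,
)


class TestConfigValidation:
    def test_default_config_is_valid(self):
        CommunityConfig().validate()

    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_genomes", 0),
            ("sharing_prob", 1.5),
            ("bin_completeness", -0.1),
            ("unbinned_frac", 2.0),
            ("scaffold_len_bp", -5),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ConfigurationError, match=field):
            CommunityConfig(**{field: value}).validate()

    def test_planted_family_outside_pool_rejected(self):
        cfg = small_config(planted_families={"mss": frozenset({"Nosuchphylum"})})
        with pytest.raises(ConfigurationError, match="mss"):
            cfg.validate()

    def test_default_labels_are_depth_series(self):
        labels = CommunityConfig().labels()
        assert labels[0] == "50" and labels[-1] == "2000" and len(labels) == 15


class TestDeterminism:
    def test_same_seed_same_bundle(self):
        a = generate_community(small_config(seed=1))
        b = generate_community(small_config(seed=1))
        assert a.hit_rows == b.hit_rows
        assert a.depth_records == b.depth_records
        assert a.bins == b.bins
        assert a.truth.true_abundance.equals(b.truth.true_abundance)

    def test_written_bundles_byte_identical(self, tmp_path):
        import filecmp

        for name in ("one", "two"):
            write_bundle(generate_community(small_config(seed=4)), tmp_path / name)
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "one", tmp_path / "two",
            [p.name for p in (tmp_path / "one").iterdir()], shallow=False,
        )
        assert not mismatch and not errors

    def test_different_seeds_differ(self):
        a = generate_community(small_config(seed=1))
        b = generate_community(small_config(seed=2))
        assert a.depth_records != b.depth_records


class TestCommunityStructure:
    def test_no_sharing_means_own_sample_mappings_only(self):
        bundle = generate_community(small_config(seed=3, sharing_prob=0.0))
        assert all(
            r.assembly_sample == r.mapping_sample for r in bundle.depth_records
        )

    def test_read_conservation_per_mapping(self, tiny_bundle):
        """Summed depth x length over one mapping's scaffolds equals that
        mapping's total mapped reads."""
        cfg = tiny_bundle.config
        totals: dict[tuple[str, str], float] = {}
        reported: dict[tuple[str, str], float] = {}
        for r in tiny_bundle.depth_records:
            key = (r.assembly_sample, r.mapping_sample)
            totals[key] = totals.get(key, 0.0) + r.avg_depth * cfg.scaffold_len_bp
            reported[key] = r.mapping_total_reads
        for key, total in totals.items():
            assert total == pytest.approx(reported[key], rel=1e-9)

    def test_every_scaffold_traces_to_one_genome(self, tiny_bundle):
        truth = tiny_bundle.truth
        for scf in tiny_bundle.scaffold_lineages:
            assert scf in truth.scaffold_genome
        for r in tiny_bundle.depth_records:
            assert r.scaffold_id in truth.scaffold_genome

    def test_contaminants_come_from_other_phyla(self):
        bundle = generate_community(
            small_config(seed=5, bin_contamination=0.3, n_genomes=12)
        )
        truth = bundle.truth
        n_cont = 0
        for bin_id, prov in truth.bin_provenance.items():
            source_phylum = truth.genome_phylum[prov.source_genome]
            for scf, donor in prov.contaminants.items():
                n_cont += 1
                assert truth.genome_phylum[donor] != source_phylum
                assert bundle.bins[scf] == bin_id
        assert n_cont > 0  # the rate is high enough to exercise the branch

    def test_contamination_free_bins_match_source_lineage(self, tiny_bundle):
        truth = tiny_bundle.truth
        for bin_id, lineage in tiny_bundle.bin_lineages.items():
            source = truth.bin_provenance[bin_id].source_genome
            expected = truth.genome_phylum[source]
            assert lineage.at("phylum") == expected

    def test_true_abundances_sum_to_one_per_sample(self, tiny_bundle):
        sums = tiny_bundle.truth.true_abundance.sum(axis=0)
        assert np.allclose(sums, 1.0)


class TestPlantedGenes:
    def test_nonproducer_mags_carry_no_surviving_hits(self):
        cfg = small_config(
            seed=7,
            planted_families={"mss": frozenset({"Desulfobacterota"})},
            bin_contamination=0.0,
        )
        bundle = generate_community(cfg)
        hits = dedupe_hits(filter_hits(rows_to_hits(bundle.hit_rows)))
        presence = presence_by_unit(hits, bundle.bins)
        truth = bundle.truth
        for family, unit in presence:
            assert family == "mss"
            if unit.startswith("unbinned:"):
                genome = truth.scaffold_genome[unit.removeprefix("unbinned:")]
            else:
                genome = truth.bin_provenance[unit].source_genome
            assert truth.genome_phylum[genome] == "Desulfobacterota"

    def test_boundary_decoys_all_rejected(self, tiny_bundle):
        raw = rows_to_hits(tiny_bundle.hit_rows)
        decoys = [h for h in raw if h.protein_index >= 9001]
        assert decoys, "bundle must contain boundary decoys"
        assert filter_hits(decoys) == []
        # and exactly the planted hits survive
        survivors = filter_hits(raw)
        truth = tiny_bundle.truth
        for hit in survivors:
            genome = truth.scaffold_genome[hit.scaffold_id]
            assert hit.family in truth.genome_families[genome]


class TestLipidPeaks:
    PRODUCERS = {"mss": "brGDGT-1a", "tes": "isoGDGT-0"}

    def test_unknown_family_rejected(self, tiny_bundle):
        with pytest.raises(ConfigurationError):
            generate_lipid_peaks(
                tiny_bundle.config, {"nosuchfamily": "L"}, tiny_bundle.truth
            )

    def test_zero_producer_abundance_means_zero_areas(self, tiny_bundle):
        peaks = generate_lipid_peaks(tiny_bundle.config, self.PRODUCERS,
                                     tiny_bundle.truth)
        truth = tiny_bundle.truth
        producers = [g for g, f in truth.genome_families.items() if "mss" in f]
        for sample in tiny_bundle.samples:
            signal = truth.true_abundance.loc[producers, sample].sum()
            rows = peaks[(peaks.lipid == "brGDGT-1a")
                         & (peaks.sample_depth_m == sample)]
            if signal == 0:
                assert (rows.area == 0).all()
            assert (rows.is_area > 0).all()

    def test_response_linear_in_producer_abundance(self, tiny_bundle):
        """IS-normalized response is exactly proportional to summed producer
        abundance: the per-sample matrix factor cancels."""
        peaks = generate_lipid_peaks(tiny_bundle.config, self.PRODUCERS,
                                     tiny_bundle.truth)
        responses = quantify_peaks(peaks)
        truth = tiny_bundle.truth
        producers = [g for g, f in truth.genome_families.items() if "mss" in f]
        signal = truth.true_abundance.loc[producers].sum(axis=0)
        litres = tiny_bundle.config.litres
        expected = 10.0 * signal / litres  # analyte/IS base-response ratio
        got = responses.loc["brGDGT-1a", signal.index]
        assert np.allclose(got.to_numpy(), expected.to_numpy())

    def test_matrix_effect_cancels(self, tiny_bundle):
        peaks = generate_lipid_peaks(tiny_bundle.config, self.PRODUCERS,
                                     tiny_bundle.truth)
        boosted = peaks.copy()
        sample = tiny_bundle.samples[0]
        mask = boosted.sample_depth_m == sample
        boosted.loc[mask, ["area", "is_area"]] *= 2.0
        a = quantify_peaks(peaks)
        b = quantify_peaks(boosted)
        assert np.allclose(a.to_numpy(), b.to_numpy())
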