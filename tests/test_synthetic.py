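"""Planted-truth generator: determinism, construction fidelity, recovery."""

import numpy as np
import pytest

from mirnet.qpcr import call_differential, group_fold_change
from mirnet.synthetic import (
    ConfigurationError,
    PlantedEffect,
    SynthConfig,
    generate_annotation,
    generate_ct_table,
    generate_prediction_tables,
    injury_screen_config,
)


def small_config(**kw) -> SynthConfig:
    defaults = dict(seed=7, panel_size=20, n_genes=200)
    defaults.update(kw)
    return SynthConfig(**defaults)


class TestGenerateCtTable:
    def test_noise_free_planted_fold_is_exact(self):
        # fold 4 up => mean Ct exactly 2 cycles lower in cisplatin
        cfg = small_config(noise_sd=0.0, planted_effects=(
            PlantedEffect("mmu-miR-S0003", "Cis_vs_Saline", "up", 4.0),))
        ct, _ = generate_ct_table(cfg)
        cis = ct.values.loc["mmu-miR-S0003", ct.samples_of("cisplatin")]
        sal = ct.values.loc["mmu-miR-S0003", ct.samples_of("saline")]
        assert cis.mean() - sal.mean() == pytest.approx(-2.0, abs=1e-12)

    def test_chained_comparisons_realize_each_planted_fold(self):
        # one miRNA planted in both comparisons: each contrast stays exact
        cfg = small_config(noise_sd=0.0, planted_effects=(
            PlantedEffect("mmu-miR-S0001", "Cis_vs_Saline", "down", 8.0),
            PlantedEffect("mmu-miR-S0001", "CisMSC_vs_Cis", "up", 4.0),
        ))
        ct, _ = generate_ct_table(cfg)
        row = ct.values.loc["mmu-miR-S0001"]
        sal = row[ct.samples_of("saline")].mean()
        cis = row[ct.samples_of("cisplatin")].mean()
        msc = row[ct.samples_of("cisplatin_MSC")].mean()
        assert cis - sal == pytest.approx(3.0)   # log2(8), down
        assert msc - cis == pytest.approx(-2.0)  # log2(4), up

    def test_seeded_runs_are_byte_identical(self, tmp_path):
        cfg = small_config(seed=7)
        for tag in ("a", "b"):
            ct, _ = generate_ct_table(cfg)
            ct.write_csv(tmp_path / f"ct_{tag}.csv",
                         tmp_path / f"groups_{tag}.csv")
        assert (tmp_path / "ct_a.csv").read_bytes() == \
            (tmp_path / "ct_b.csv").read_bytes()
        assert (tmp_path / "groups_a.csv").read_bytes() == \
            (tmp_path / "groups_b.csv").read_bytes()

    def test_panel_has_expected_shape(self):
        cfg = small_config()
        ct, _ = generate_ct_table(cfg)
        assert len(ct.values.index) == cfg.panel_size + 1  # + reference
        assert len(ct.samples) == sum(n for _, n in cfg.groups)

    def test_reference_is_constant_by_default(self):
        ct, _ = generate_ct_table(small_config())
        assert (ct.values.loc["SNOR-ref"] == 20.0).all()

    def test_planted_mirna_off_panel_names_the_id(self):
        cfg = small_config(planted_effects=(
            PlantedEffect("miR-ghost", "Cis_vs_Saline", "up", 5.0),))
        with pytest.raises(ConfigurationError, match="miR-ghost"):
            generate_ct_table(cfg)

    def test_named_features_occupy_panel_slots(self):
        cfg = small_config(named_features=("miR-141", "miR-377"),
                           planted_effects=(
            PlantedEffect("miR-141", "Cis_vs_Saline", "down", 6.0),))
        ct, truth = generate_ct_table(cfg)
        assert "miR-141" in ct.features
        assert truth.down("Cis_vs_Saline") == {"miR-141"}

    def test_detection_limit_clamps_to_undetected(self):
        cfg = small_config(baseline_ct_mean=34.5, baseline_ct_sd=1.0,
                           noise_sd=0.5)
        ct, _ = generate_ct_table(cfg)
        assert ct.values.drop("SNOR-ref").isna().any().any()
        assert np.nanmax(ct.values.to_numpy()) <= cfg.detection_limit

    def test_caller_recovers_planted_sets(self):
        # margin log2(5) - log2(3) dwarfs noise at sd 0.1
        cfg = injury_screen_config(seed=11)
        ct, truth = generate_ct_table(cfg)
        fc = group_fold_change(ct, "cisplatin", "saline")
        prof = call_differential(fc, 3.0, comparison_id="Cis_vs_Saline")
        assert set(prof.up) == truth.up("Cis_vs_Saline")
        assert set(prof.down) == truth.down("Cis_vs_Saline")


class TestGeneratePredictionTables:
    def _truth(self, cfg):
        return generate_ct_table(cfg)[1]

    def _intersection(self, tables, mirna):
        sets = [t.genes_of(mirna) for t in tables]
        return set.intersection(*sets)

    def test_full_consensus_recovers_true_targets(self):
        cfg = small_config(consensus_fraction=1.0, planted_effects=(
            PlantedEffect("mmu-miR-S0001", "Cis_vs_Saline", "up", 5.0),))
        truth = self._truth(cfg)
        tables = generate_prediction_tables(cfg, truth)
        assert self._intersection(tables, "mmu-miR-S0001") == \
            truth.targets["mmu-miR-S0001"]

    def test_zero_consensus_gives_empty_intersection(self):
        cfg = small_config(consensus_fraction=0.0, planted_effects=(
            PlantedEffect("mmu-miR-S0001", "Cis_vs_Saline", "up", 5.0),))
        truth = self._truth(cfg)
        tables = generate_prediction_tables(cfg, truth)
        assert self._intersection(tables, "mmu-miR-S0001") == set()

    def test_fractional_consensus_size(self):
        cfg = small_config(consensus_fraction=0.3,
                           per_db_targets_per_mirna=10,
                           planted_effects=(
            PlantedEffect("mmu-miR-S0001", "Cis_vs_Saline", "up", 5.0),))
        truth = self._truth(cfg)
        tables = generate_prediction_tables(cfg, truth)
        assert len(self._intersection(tables, "mmu-miR-S0001")) == 3

    def test_per_db_slot_count(self):
        cfg = small_config(consensus_fraction=0.5,
                           per_db_targets_per_mirna=8, planted_effects=(
            PlantedEffect("mmu-miR-S0002", "Cis_vs_Saline", "down", 5.0),))
        truth = self._truth(cfg)
        for table in generate_prediction_tables(cfg, truth):
            assert len(table.genes_of("mmu-miR-S0002")) == 8

    def test_bad_consensus_fraction_rejected(self):
        with pytest.raises(ConfigurationError, match="consensus_fraction"):
            small_config(consensus_fraction=1.5)


class TestGenerateAnnotation:
    def test_enriched_set_yields_tiny_p(self):
        from mirnet.enrich import hypergeom_enrich
        cfg = small_config(n_genes=100, per_db_targets_per_mirna=5,
                           gene_set_size_range=(5, 10),
                           enriched_set_mirna="mmu-miR-S0001",
                           planted_effects=(
            PlantedEffect("mmu-miR-S0001", "Cis_vs_Saline", "up", 5.0),))
        truth = generate_ct_table(cfg)[1]
        ann = generate_annotation(cfg, truth)
        result = hypergeom_enrich(truth.targets["mmu-miR-S0001"], ann)
        row = result[result["set_name"] == "enriched_mmu-miR-S0001"]
        assert float(row["p"].iloc[0]) < 1e-3

    def test_empty_collection_writes_empty_gmt(self, tmp_path):
        cfg = small_config(n_gene_sets=0)
        truth = generate_ct_table(cfg)[1]
        ann = generate_annotation(cfg, truth)
        path = tmp_path / "empty.gmt"
        ann.write_gmt(path)
        assert len(ann) == 0 and path.read_text() == ""

    def test_gmt_bytes_deterministic(self, tmp_path):
        cfg = small_config(seed=13)
        truth = generate_ct_table(cfg)[1]
        for tag in ("a", "b"):
            generate_annotation(cfg, truth).write_gmt(tmp_path / f"{tag}.gmt")
        assert (tmp_path / "a.gmt").read_bytes() == \
            (tmp_path / "b.gmt").read_bytes()

    def test_set_size_exceeding_universe_rejected(self):
        with pytest.raises(ConfigurationError, match="universe"):
            small_config(n_genes=20, gene_set_size_range=(10, 50))


class TestConfigValidation:
    def test_replicate_minimum(self):
        with pytest.raises(ConfigurationError, match="replicates"):
            small_config(groups=(("saline", 1), ("cisplatin", 3)))

    def test_fold_magnitude_minimum(self):
        with pytest.raises(ConfigurationError, match="fold"):
            PlantedEffect("m", "Cis_vs_Saline", "up", 0.5)

    def test_conflicting_directions_rejected(self):
        cfg = small_config(planted_effects=(
            PlantedEffect("mmu-miR-S0001", "Cis_vs_Saline", "up", 5.0),
            PlantedEffect("mmu-miR-S0001", "Cis_vs_Saline", "down", 5.0)))
        with pytest.raises(ConfigurationError, match="up and down"):
            generate_ct_table(cfg)
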