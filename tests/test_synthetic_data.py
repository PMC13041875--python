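"""Generator correctness: planting, mixtures, crosswalks, pathway fixtures."""

import numpy as np
import pytest
from scipy import stats

from annoconcord import (
    SimConfig,
    fisher_enrich,
    generate_annotation_table,
    generate_id_map,
    generate_pathway_db,
    plant_agreement_class,
    write_wide_table,
)
from annoconcord.agreement_core import TOOL_CATEGORY_LABELS, classify_variant
from annoconcord.id_mapping import map_genes_to_uniprot
from annoconcord.synthetic_data import (
    ConfigurationError,
    gene_ensembl,
    gene_uniprot,
)

from conftest import gene_level_protein_sets

UNIVERSE = [f"g{i}" for i in range(10)]


class TestPlanting:
    @pytest.mark.parametrize("label", TOOL_CATEGORY_LABELS)
    def test_round_trip_every_realizable_label(self, label):
        """classify(plant(label)) == label over the full 23-label taxonomy."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            sets = plant_agreement_class(label, UNIVERSE, rng)
            assert classify_variant(sets).category_label == label

    def test_full_agreement_is_three_identical_nonempty_sets(self):
        rng = np.random.default_rng(0)
        sets = plant_agreement_class("Exact Match", UNIVERSE, rng)
        vals = set(sets.values())
        assert len(vals) == 1 and next(iter(vals))

    def test_two_full_one_partial_is_nested_subset(self):
        rng = np.random.default_rng(0)
        sets = plant_agreement_class(
            "ANNOVAR and SnpEff; VEP subset", UNIVERSE, rng
        )
        assert sets["ANNOVAR"] == sets["SnpEff"]
        assert sets["VEP"] < sets["ANNOVAR"]
        assert sets["VEP"]

    def test_unrealizable_label_lists_realizable(self):
        with pytest.raises(ConfigurationError, match="Exact Match"):
            plant_agreement_class("bogus label", UNIVERSE,
                                  np.random.default_rng(0))

    def test_tiny_universe_rejected(self):
        with pytest.raises(ConfigurationError, match="universe"):
            plant_agreement_class("Exact Match", ["g0"],
                                  np.random.default_rng(0))


class TestAnnotationTable:
    def test_pure_mixture_round_trips(self):
        cfg = SimConfig(n_variants=10, seed=4,
                        class_mixture={"Exact Match": 1.0},
                        vep_intergenic_dropout=0.0)
        per_variant = gene_level_protein_sets(generate_annotation_table(cfg))
        for vid, per_source in per_variant.items():
            for model in cfg.gene_models:
                by_tool = {t: per_source[(t, model)] for t in cfg.tools}
                assert classify_variant(by_tool, vid).category_label == \
                    "Exact Match"

    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = SimConfig(n_variants=50, seed=123)
        for run in ("a", "b"):
            write_wide_table(generate_annotation_table(cfg),
                             tmp_path / f"{run}.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == \
            (tmp_path / "b.tsv").read_bytes()

    def test_mixture_frequencies_within_binomial_ci(self):
        """Observed class frequencies at n=10000 fall inside the exact
        binomial 99% CI of the planted 0.7/0.3 mixture."""
        mixture = {"Exact Match": 0.7, "ANNOVAR and SnpEff": 0.3}
        cfg = SimConfig(n_variants=10000, seed=5, class_mixture=mixture,
                        vep_intergenic_dropout=0.0)
        per_variant = gene_level_protein_sets(generate_annotation_table(cfg))
        counts = {lab: 0 for lab in mixture}
        for vid, per_source in per_variant.items():
            by_tool = {t: per_source[(t, "Ensembl")] for t in cfg.tools}
            counts[classify_variant(by_tool, vid).category_label] += 1
        n = sum(counts.values())
        assert n == 10000
        for lab, p in mixture.items():
            lo = stats.binom.ppf(0.005, n, p)
            hi = stats.binom.ppf(0.995, n, p)
            assert lo <= counts[lab] <= hi, (lab, counts[lab])

    def test_vep_dropout_empties_intergenic_vep_only(self):
        cfg = SimConfig(n_variants=400, seed=9, genic_fraction=0.0,
                        vep_intergenic_dropout=1.0,
                        class_mixture={"Exact Match": 1.0})
        per_variant = gene_level_protein_sets(generate_annotation_table(cfg))
        for per_source in per_variant.values():
            for model in cfg.gene_models:
                assert not per_source[("VEP", model)]
                assert per_source[("ANNOVAR", model)]

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ConfigurationError, match="sum"):
            SimConfig(class_mixture={"Exact Match": 0.5}).validate()
        with pytest.raises(ConfigurationError, match="unrealizable"):
            SimConfig(class_mixture={"nope": 1.0}).validate()


class TestIdMap:
    def test_clean_table_has_one_accession_per_gene(self):
        table = generate_id_map(10)
        assert len(table.rows) == 10
        assert all(r.uniprot_accession for r in table.rows)

    def test_deprecated_rows_absent(self):
        table = generate_id_map(10, frac_deprecated=0.2, seed=1)
        assert len(table.deprecated_genes) == 2
        assert len(table.rows) == 8
        for i in table.deprecated_genes:
            assert table.lookup("ensembl_gene", gene_ensembl(i)) is None

    def test_mapping_loses_exactly_deprecated_plus_noncoding(self):
        """Oracle: direct set difference over the planted universe."""
        n = 50
        table = generate_id_map(n, frac_deprecated=0.1, frac_noncoding=0.2,
                                seed=3)
        gene_ids = [("ensembl_gene", gene_ensembl(i)) for i in range(n)]
        accessions, unmapped = map_genes_to_uniprot(gene_ids, "Ensembl", table)
        lost = set(range(n)) - {
            int(a[1:]) - 1 for a in accessions
        }
        assert lost == set(table.deprecated_genes) | set(table.noncoding_genes)
        # unmapped identifiers are exactly the deprecated ones
        assert {g for _ns, g in unmapped} == {
            gene_ensembl(i) for i in table.deprecated_genes
        }

    def test_fraction_bounds_validated(self):
        with pytest.raises(ConfigurationError):
            generate_id_map(10, frac_deprecated=0.7, frac_noncoding=0.7)


class TestPathwayDb:
    def test_maximal_overlap_gives_minimal_p(self):
        db, query = generate_pathway_db(
            n_pathways=20, pathway_size=10, reference_size=200,
            planted=0, planted_overlap=10, seed=2,
        )
        res = fisher_enrich(query, db)
        assert res.iloc[0]["pathway_id"] == "PW0001"
        assert res.iloc[0]["p_value"] < res["p_value"][1:].min()

    def test_background_level_overlap_not_systematically_first(self):
        """Sign-style check over seeds: with no enrichment planted, the
        nominal pathway wins the ranking only at chance rates."""
        first = 0
        n_seeds = 30
        for seed in range(n_seeds):
            db, query = generate_pathway_db(
                n_pathways=20, pathway_size=10, reference_size=200,
                planted=0, planted_overlap=1, seed=seed, query_size=20,
            )
            res = fisher_enrich(query, db)
            if res.iloc[0]["pathway_id"] == "PW0001" and \
                    res.iloc[0]["p_value"] < res.iloc[1]["p_value"]:
                first += 1
        assert stats.binomtest(first, n_seeds, 0.5, "greater").pvalue > 0.01

    def test_impossible_overlap_rejected(self):
        with pytest.raises(ConfigurationError, match="planted_overlap"):
            generate_pathway_db(5, 10, 100, planted=0, planted_overlap=11)

    def test_gmt_serializable_round_trip(self, tmp_path):
        from annoconcord import read_gmt, write_gmt

        db, _query = generate_pathway_db(5, 8, 100, planted=0,
                                         planted_overlap=4, seed=6)
        path = tmp_path / "toy.gmt"
        write_gmt(db, path)
        db2 = read_gmt(path, background=[gene_uniprot(i) for i in range(100)])
        assert {p: m for p, (_n, m) in db2.pathways.items()} == \
            {p: m for p, (_n, m) in db.pathways.items()}
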