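import numpy as np
import pytest

from oracles import oracle_classify_substitution
from wsforecast.errors import DataValidationError
from wsforecast.gene_models import GeneModel, GeneModelSet
from wsforecast.mutation_catalog import (
    MutationRecord,
    build_spectrum,
    classify_mutation,
    load_mutant_table,
    top_recurrent,
)
from wsforecast.synthetic import gen_cds


@pytest.fixture()
def toy_genes():
    return GeneModelSet(
        [
            GeneModel(
                gene_name="toy",
                cds_seq="ATGAAATGGTAA",
                pathway="Wsp",
                role="negative_regulator",
                upstream_window=100,
            ),
            GeneModel(
                gene_name="polar",
                cds_seq="ATGAAATGGTAA",
                pathway="Aws",
                role="negative_regulator",
                polar_partner="dgc",
            ),
        ]
    )


def rec(gene="toy", coord="cds_nt", pos=1, ref="", alt="", flag=None, iso="i1"):
    return MutationRecord(
        isolate_id=iso, gene_name=gene, coord_system=coord, position=pos,
        ref_allele=ref, alt_allele=alt, structural_flag=flag,
    )


class TestClassifyMutation:
    def test_nonsense_example(self, toy_genes):
        # codon 3 TGG -> TAG via position 8 G>A
        eff = classify_mutation(rec(pos=8, ref="G", alt="A"), toy_genes)
        assert eff.mclass == "nonsense"
        assert eff.protein_change == "W3*"

    def test_codon_boundary_deletion_is_inframe(self, toy_genes):
        eff = classify_mutation(rec(pos=4, ref="AAA", alt=""), toy_genes)
        assert eff.mclass == "inframe_indel"
        assert eff.frame_preserving is True

    def test_single_bp_deletion_is_frameshift(self, toy_genes):
        eff = classify_mutation(rec(pos=4, ref="A", alt=""), toy_genes)
        assert eff.mclass == "frameshift_indel"
        assert eff.frame_preserving is False

    def test_upstream_point_is_promoter(self, toy_genes):
        eff = classify_mutation(
            rec(coord="upstream_nt", pos=-35, ref="C", alt="T"), toy_genes
        )
        assert eff.mclass == "promoter_point"

    def test_structural_flag_is_promoter_capture(self, toy_genes):
        eff = classify_mutation(
            rec(coord="upstream_nt", pos=-120, flag="promoter_capture"), toy_genes
        )
        assert eff.mclass == "promoter_capture"

    def test_outside_window_warns_intergenic(self, toy_genes):
        with pytest.warns(UserWarning, match="intergenic_other"):
            eff = classify_mutation(
                rec(coord="upstream_nt", pos=-500, ref="C", alt="T"), toy_genes
            )
        assert eff.mclass == "intergenic_other"

    def test_ref_mismatch_names_isolate_and_position(self, toy_genes):
        with pytest.raises(DataValidationError, match="i1.*position 2"):
            classify_mutation(rec(pos=2, ref="C", alt="T"), toy_genes)

    def test_synonymous(self, toy_genes):
        # AAA -> AAG both K
        eff = classify_mutation(rec(pos=6, ref="A", alt="G"), toy_genes)
        assert eff.mclass == "synonymous"

    def test_polarity_flag_for_frameshift_in_polar_gene(self, toy_genes):
        eff = classify_mutation(rec(gene="polar", pos=4, ref="A", alt=""), toy_genes)
        assert eff.disrupts_downstream is True
        eff2 = classify_mutation(rec(pos=4, ref="A", alt=""), toy_genes)
        assert eff2.disrupts_downstream is False

    def test_protein_aa_coordinates(self, toy_genes):
        eff = classify_mutation(
            rec(coord="protein_aa", pos=3, ref="W", alt="*"), toy_genes
        )
        assert eff.mclass == "nonsense"

    def test_every_substitution_matches_bruteforce_oracle(self):
        cds = gen_cds(80, 0.5, seed=3)
        genes = GeneModelSet([GeneModel(gene_name="rand", cds_seq=cds)])
        for pos in range(1, len(cds) + 1):
            for alt in "ACGT":
                if alt == cds[pos - 1]:
                    continue
                got = classify_mutation(
                    rec(gene="rand", pos=pos, ref=cds[pos - 1], alt=alt), genes
                ).mclass
                want = oracle_classify_substitution(cds, pos, alt)
                # stop-loss at the terminal codon is folded into missense
                assert got == want, (pos, alt)


class TestBuildSpectrum:
    def test_fixture_pathway_marginals(self, wt_spectrum, genes):
        assert wt_spectrum.pathway_marginals(genes) == {
            "Wsp": 16, "Aws": 14, "Mws": 10, "PFL_3078": 3,
        }

    def test_fixture_gene_counts(self, wt_spectrum):
        coding = wt_spectrum.coding_gene_marginals()
        assert coding["wspF"] == 15
        assert coding["awsX"] == 9
        assert coding["wspE"] == 1
        assert coding["awsR"] == 3
        assert coding["mwsR"] == 10

    def test_empty_input(self, genes):
        spectrum = build_spectrum([], genes)
        assert spectrum.n_total == 0 and spectrum.counts == {}

    def test_permutation_invariance_and_additivity(self, wt_effects, genes):
        import random

        shuffled = wt_effects[:]
        random.Random(1).shuffle(shuffled)
        assert build_spectrum(shuffled, genes).counts == build_spectrum(
            wt_effects, genes
        ).counts
        half = len(wt_effects) // 2
        a = build_spectrum(wt_effects[:half], genes)
        b = build_spectrum(wt_effects[half:], genes)
        combined = build_spectrum(wt_effects, genes)
        for key in combined.counts:
            assert combined.counts[key] == a.counts.get(key, 0) + b.counts.get(key, 0)
        assert combined.n_total == a.n_total + b.n_total

    def test_pathway_marginals_sum_to_total(self, wt_spectrum, genes):
        assert sum(wt_spectrum.pathway_marginals(genes).values()) == wt_spectrum.n_total

    def test_synonymous_excluded_from_ws_spectrum(self, toy_genes):
        eff = classify_mutation(rec(pos=6, ref="A", alt="G"), toy_genes)
        assert build_spectrum([eff], toy_genes).n_total == 0
        assert build_spectrum([eff], toy_genes, include_nonadaptive=True).n_total == 1


class TestTopRecurrent:
    def test_fixture_top_entry(self, wt_effects):
        label, count = top_recurrent(wt_effects)[0]
        assert label == "WspF V271G" and count == 11

    def test_all_distinct(self, toy_genes):
        effs = [
            classify_mutation(rec(pos=p, ref="A", alt="C", iso=f"i{p}"), toy_genes)
            for p in (4, 5, 6)
        ]
        assert all(n == 1 for _, n in top_recurrent(effs))

    def test_repeated_record(self, toy_genes):
        effs = [
            classify_mutation(rec(pos=8, ref="G", alt="A", iso=f"i{k}"), toy_genes)
            for k in range(5)
        ]
        assert top_recurrent(effs) == [("Toy W3*", 5)]


class TestLoadMutantTable:
    def test_fixture_row_counts(self, fixtures):
        assert len(fixtures.wt_mutants) == 43
        assert len(fixtures.triple_deletion_mutants) == 7

    def test_empty_file_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text(
            "isolate_id\texperiment\tgene_name\tcoord_system\tposition\tref\talt"
            "\tstructural_flag\tnotes\n"
        )
        assert load_mutant_table(path) == []

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "isolate_id\texperiment\tgene_name\tcoord_system\tposition\tref\talt"
            "\tstructural_flag\tnotes\n"
            "i1\twt\ttoy\tcds_nt\tnot_a_number\tA\tC\t\t\n"
        )
        with pytest.raises(DataValidationError, match=":2"):
            load_mutant_table(path)

    def test_unknown_gene_rejected(self, tmp_path, genes):
        path = tmp_path / "unknown.tsv"
        path.write_text(
            "isolate_id\texperiment\tgene_name\tcoord_system\tposition\tref\talt"
            "\tstructural_flag\tnotes\n"
            "i1\twt\tnot_a_gene\tcds_nt\t1\tA\tC\t\t\n"
        )
        with pytest.raises(DataValidationError, match="not_a_gene"):
            load_mutant_table(path, genes)

    def test_unknown_column_warns(self, tmp_path):
        path = tmp_path / "extra.tsv"
        path.write_text(
            "isolate_id\texperiment\tgene_name\tcoord_system\tposition\tref\talt"
            "\tstructural_flag\tnotes\tbogus\n"
        )
        with pytest.warns(UserWarning, match="bogus"):
            load_mutant_table(path)
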