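import math

import numpy as np
import pytest

from oracles import oracle_multinomial_p
from wsforecast.errors import DataValidationError
from wsforecast.evaluation import (
    evaluate_predictions,
    exact_multinomial_p,
    g_test,
    rank_agreement,
    region_coverage,
)
from wsforecast.gene_models import GeneModel, GeneModelSet, Region
from wsforecast.mutation_catalog import (
    MutationRecord,
    build_spectrum,
    classify_mutation,
)


class TestGTest:
    def test_perfect_fit_gives_zero(self):
        fit = g_test([27, 15, 8], [0.54, 0.30, 0.16])
        assert fit.value == pytest.approx(0.0, abs=1e-9)
        assert fit.p == pytest.approx(1.0)

    def test_worked_example(self):
        fit = g_test([16, 14, 10], [0.54, 0.30, 0.16])
        assert fit.value == pytest.approx(3.64, abs=0.01)
        assert fit.df == 2
        assert fit.expected == pytest.approx([21.6, 12.0, 6.4])

    def test_doubling_counts_doubles_g(self):
        a = g_test([16, 14, 10], [0.54, 0.30, 0.16])
        b = g_test([32, 28, 20], [0.54, 0.30, 0.16])
        assert b.value == pytest.approx(2 * a.value)

    def test_zero_prob_with_observation_flags_infinite(self):
        fit = g_test([5, 5], [1.0, 0.0])
        assert fit.infinite and math.isinf(fit.value) and fit.p == 0.0

    def test_zero_observed_cell_contributes_zero(self):
        fit = g_test([10, 0], [0.5, 0.5])
        assert math.isfinite(fit.value)

    def test_probs_must_sum_to_one(self):
        with pytest.raises(DataValidationError):
            g_test([1, 2], [0.5, 0.4])


class TestExactMultinomial:
    def test_two_zero_split(self):
        fit = exact_multinomial_p([2, 0], [0.5, 0.5])
        assert fit.p == pytest.approx(0.5)

    def test_modal_outcome_p_one(self):
        fit = exact_multinomial_p([1, 1], [0.5, 0.5])
        assert fit.p == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "observed,probs",
        [
            ((3, 1, 0), (0.5, 0.3, 0.2)),
            ((5, 5, 2), (1 / 3, 1 / 3, 1 / 3)),
            ((0, 0, 12), (0.54, 0.30, 0.16)),
            ((7, 3), (0.6, 0.4)),
        ],
    )
    def test_matches_enumeration_oracle(self, observed, probs):
        fit = exact_multinomial_p(list(observed), list(probs))
        assert fit.p == pytest.approx(oracle_multinomial_p(observed, probs), rel=1e-9)

    def test_monte_carlo_within_3se_of_exact(self):
        observed, probs = [6, 4, 2], [0.5, 0.3, 0.2]
        exact = exact_multinomial_p(observed, probs)
        mc = exact_multinomial_p(
            observed, probs, max_enumeration=1, mc_reps=50_000, seed=9
        )
        assert mc.mc_se is not None
        assert abs(mc.p - exact.p) <= 3 * mc.mc_se

    def test_ordering_agrees_with_g_test(self):
        # monotone relation of evidence on enumerable cases, n <= 12, k <= 3
        probs = [0.5, 0.3, 0.2]
        cases = [(4, 4, 4), (6, 4, 2), (8, 3, 1), (12, 0, 0), (0, 6, 6)]
        g_ps = [g_test(list(c), probs).p for c in cases]
        e_ps = [exact_multinomial_p(list(c), probs).p for c in cases]
        g_order = np.argsort(g_ps)
        e_order = np.argsort(e_ps)
        tau = np.corrcoef(np.argsort(g_order), np.argsort(e_order))[0, 1]
        assert tau > 0.7


class TestRankAgreement:
    def test_paper_pathway_order(self):
        report = rank_agreement(
            {"Wsp": 0.54, "Aws": 0.30, "Mws": 0.16},
            {"Wsp": 16, "Aws": 14, "Mws": 10},
        )
        assert report["exact_order_match"] is True
        assert report["kendall_tau"] == pytest.approx(1.0)

    def test_reversed_order(self):
        report = rank_agreement(
            {"Wsp": 0.54, "Aws": 0.30, "Mws": 0.16},
            {"Wsp": 1, "Aws": 5, "Mws": 9},
        )
        assert report["kendall_tau"] == pytest.approx(-1.0)

    def test_identical_rankings_tau_one(self):
        pred = {c: 10.0 - i for i, c in enumerate("abcdef")}
        obs = {c: 100 - 3 * i for i, c in enumerate("abcdef")}
        assert rank_agreement(pred, obs)["kendall_tau"] == pytest.approx(1.0)

    def test_disjoint_categories_rejected(self):
        with pytest.raises(DataValidationError):
            rank_agreement({"a": 1.0}, {"b": 1})


class TestRegionCoverage:
    @pytest.fixture()
    def simple(self):
        genes = GeneModelSet(
            [GeneModel(gene_name="g", cds_seq="ATG" + "GCA" * 30 + "TAA")]
        )
        regions = [
            Region(gene_name="g", kind="aa_range", start=2, end=5,
                   allowed_classes=frozenset({"missense"}), region_id="r1"),
            Region(gene_name="g", kind="aa_range", start=10, end=12,
                   allowed_classes=frozenset({"missense"}), region_id="r2"),
        ]
        return genes, regions

    def eff(self, genes, codon, iso):
        # GCA -> CCA missense at the first base of the codon
        pos = 3 * (codon - 1) + 1
        return classify_mutation(
            MutationRecord(
                isolate_id=iso, gene_name="g", coord_system="cds_nt",
                position=pos, ref_allele="G", alt_allele="C",
            ),
            genes,
        )

    def test_three_sites_two_covered(self, simple):
        genes, regions = simple
        effects = [
            self.eff(genes, 3, "a"),   # in r1
            self.eff(genes, 11, "b"),  # in r2
            self.eff(genes, 20, "c"),  # uncovered
        ]
        cov = region_coverage(effects, regions)
        assert (cov.covered_count, cov.total_distinct_sites) == (2, 3)
        assert cov.fraction == pytest.approx(2 / 3)

    def test_empty_region_set_zero_coverage(self, simple):
        genes, _ = simple
        with pytest.warns(UserWarning):
            cov = region_coverage([self.eff(genes, 3, "a")], [])
        assert cov.covered_count == 0 and cov.total_distinct_sites == 1

    def test_identical_changes_collapse(self, simple):
        genes, regions = simple
        effects = [self.eff(genes, 20, f"i{k}") for k in range(5)]
        cov = region_coverage(effects, regions)
        assert cov.total_distinct_sites == 1

    def test_same_region_changes_collapse(self, simple):
        genes, regions = simple
        effects = [self.eff(genes, 2, "a"), self.eff(genes, 4, "b")]
        cov = region_coverage(effects, regions)
        assert cov.total_distinct_sites == 1 and cov.covered_count == 1

    def test_monotone_in_regions(self, simple):
        genes, regions = simple
        effects = [self.eff(genes, 3, "a"), self.eff(genes, 20, "b")]
        base = region_coverage(effects, regions[:1])
        more = region_coverage(
            effects,
            regions
            + [Region(gene_name="g", kind="aa_range", start=19, end=21,
                      allowed_classes=frozenset({"missense"}), region_id="r3")],
        )
        assert more.covered_count >= base.covered_count

    def test_fixture_sixteen_of_twentytwo(self, wt_effects, fixtures):
        cov = region_coverage(wt_effects, fixtures.regions)
        assert (cov.covered_count, cov.total_distinct_sites) == (16, 22)


class TestEvaluatePredictions:
    def test_fixture_scoreboard(self, wt_spectrum, wt_effects, fixtures, prediction):
        _, _, predicted = prediction
        scores = evaluate_predictions(
            wt_spectrum, fixtures.gene_models, predicted, wt_effects, fixtures.regions
        )
        by_id = {s.prediction_id: s for s in scores}
        assert by_id[5].status == "supported"
        assert by_id[5].evidence["in_three_pathways"] == 40
        assert by_id[6].status == "supported"
        assert by_id[6].evidence["predicted_genes_without_observations"] == ["wspA"]
        assert by_id[7].status == "supported"
        assert by_id[4].status == "supported"
        for pid in (1, 2, 3, 8):
            assert by_id[pid].status == "not_computable"

    def test_empty_spectrum_not_computable(self, fixtures):
        spectrum = build_spectrum([], fixtures.gene_models)
        scores = evaluate_predictions(spectrum, fixtures.gene_models)
        assert all(s.status == "not_computable" for s in scores)

    def test_deterministic(self, wt_spectrum, wt_effects, fixtures, prediction):
        _, _, predicted = prediction
        args = (wt_spectrum, fixtures.gene_models, predicted, wt_effects, fixtures.regions)
        a = evaluate_predictions(*args)
        b = evaluate_predictions(*args)
        assert [(s.prediction_id, s.status) for s in a] == [
            (s.prediction_id, s.status) for s in b
        ]

    def test_p8_with_fitness_tables(self, wt_spectrum, fixtures, prediction):
        _, _, predicted = prediction
        fitness = {
            "WspF_V271G": 0.0, "WspE_S575F": 0.02,
            "WspA_T293del": -0.05, "PFL_0087_D230G": -0.06,
        }
        scores = evaluate_predictions(
            wt_spectrum, fixtures.gene_models, predicted,
            fitness_by_strain=fitness,
            rare_predicted_strains=["WspA_T293del", "PFL_0087_D230G"],
        )
        by_id = {s.prediction_id: s for s in scores}
        assert by_id[8].status == "supported"

    def test_self_consistency_simulation(self, fixtures, prediction):
        # spectra drawn from the predicted multinomial support P5/P6 most of
        # the time (scaled down from the spec's 500 draws for runtime)
        _, _, predicted = prediction
        genes = fixtures.gene_models
        rng = np.random.default_rng(0)
        gene_names = list(predicted.gene_probs)
        probs = np.array([predicted.gene_probs[g] for g in gene_names])
        wins = 0
        n_draws = 200
        for _ in range(n_draws):
            draw = rng.multinomial(43, probs)
            spectrum = build_spectrum([], genes)
            for g, n in zip(gene_names, draw):
                if n:
                    spectrum.counts[(g, "missense")] = int(n)
                    spectrum.n_total += int(n)
            scores = evaluate_predictions(spectrum, genes, predicted)
            by_id = {s.prediction_id: s for s in scores}
            if by_id[5].status == "supported" and by_id[6].status in (
                "supported", "partially_supported"
            ):
                wins += 1
        assert wins / n_draws >= 0.9
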