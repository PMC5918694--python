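"""Transfer scoring of external profiles and the downstream statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import pathscore as ps
from pathscore.cohort_io import CohortError
from pathscore.transfer import CoverageError


@pytest.fixture()
def transfer_model():
    genes = [f"G{j}" for j in range(10)]
    return ps.ClassifierModel(
        gene_weights={g: w for g, w in zip(genes, [0.8, -0.5, 0.3, 0.2, -0.2,
                                                   0.1, 0.4, -0.3, 0.25, -0.15])},
        covariate_weights={"LUAD": 0.2},
        intercept=-0.5,
        alpha=0.1,
        l1_ratio=0.15,
        feature_means={g: 0.0 for g in genes},
        feature_sds={g: 1.0 for g in genes},
    )


def _profiles(model, n=30, seed=0):
    genes = sorted(model.gene_weights)
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(
        50 + 5 * rng.standard_normal((n, len(genes))),
        index=[f"P{i}" for i in range(n)],
        columns=genes,
    )
    return ps.ExpressionMatrix(data)


class TestScoreExternal:
    def test_identical_profiles_score_sigmoid_of_intercept(self, transfer_model):
        genes = sorted(transfer_model.gene_weights)
        data = pd.DataFrame(
            [[3.0] * len(genes)] * 4, index=list("abcd"), columns=genes
        )
        table = ps.score_external(transfer_model, ps.ExpressionMatrix(data))
        expected = expit(transfer_model.intercept)
        assert np.allclose(table.scores, expected)

    def test_scores_invariant_to_per_gene_affine_transforms(self, transfer_model):
        expr = _profiles(transfer_model)
        rng = np.random.default_rng(1)
        scale = 1.0 + 99.0 * rng.random(expr.data.shape[1])
        offset = 100.0 * rng.standard_normal(expr.data.shape[1])
        shifted = ps.ExpressionMatrix(expr.data * scale + offset)
        a = ps.score_external(transfer_model, expr).scores
        b = ps.score_external(transfer_model, shifted).scores
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=1e-10)

    def test_scores_invariant_to_gene_column_order(self, transfer_model):
        expr = _profiles(transfer_model)
        permuted = ps.ExpressionMatrix(expr.data[expr.data.columns[::-1]])
        a = ps.score_external(transfer_model, expr).scores
        b = ps.score_external(transfer_model, permuted).scores
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())

    def test_low_gene_coverage_refused_with_report(self, transfer_model):
        expr = _profiles(transfer_model)
        sparse = ps.ExpressionMatrix(expr.data.iloc[:, :5])
        with pytest.raises(CoverageError, match="5/10"):
            ps.score_external(transfer_model, sparse)
        table = ps.score_external(transfer_model, sparse, min_coverage=0.5)
        assert table.n_model_genes_found == 5

    def test_mutants_with_planted_signature_score_higher(self, small_cohort, small_result):
        model = small_result.model
        model_genes = model.nonzero_genes
        signal = [g for g in model_genes if g in set(small_cohort.signal_genes)]
        expr, labels = ps.simulate_external_profiles(
            model_genes, n_profiles=40, mutant_fraction=0.5, effect_size=1.0,
            seed=11, signal_genes=signal,
        )
        scores = ps.score_external(model, expr).scores
        mutant = scores[labels == 1]
        wild = scores[labels == 0]
        u, p = __import__("scipy.stats", fromlist=["mannwhitneyu"]).mannwhitneyu(
            mutant, wild, alternative="greater"
        )
        assert p < 0.05

    def test_large_effect_ranks_all_mutants_above_all_wild_types(
        self, small_cohort, small_result
    ):
        model = small_result.model
        signal = [g for g in model.nonzero_genes if g in set(small_cohort.signal_genes)]
        expr, labels = ps.simulate_external_profiles(
            model.nonzero_genes, n_profiles=10, mutant_fraction=0.6,
            effect_size=3.0, seed=2, signal_genes=signal,
        )
        scores = ps.score_external(model, expr).scores
        assert scores[labels == 1].min() > scores[labels == 0].max()


class TestConfusionMetrics:
    def test_printed_cell_line_counts_reproduce_published_percentages(self):
        # 737 profiles: 344 predicted mutant (153 truly mutant),
        # 393 predicted wild-type (357 truly wild-type)
        cm = ps.ConfusionMetrics(tp=153, fp=191, tn=357, fn=36)
        assert cm.n == 737
        assert round(cm.npv_pct, 1) == 90.8
        assert round(cm.precision_pct, 1) == 44.5
        assert round(cm.accuracy_pct, 1) == 69.2

    def test_counts_from_scores_partition_the_samples(self):
        scores = pd.Series([0.9, 0.6, 0.4, 0.1], index=list("abcd"))
        labels = pd.Series([1, 0, 1, 0], index=list("abcd"))
        cm = ps.confusion_metrics(scores, labels)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (1, 1, 1, 1)
        assert cm.tp + cm.fp + cm.tn + cm.fn == len(scores)

    def test_perfect_classifier_scores_hundred_percent(self):
        scores = pd.Series([0.9, 0.8, 0.1, 0.2], index=list("abcd"))
        labels = pd.Series([1, 1, 0, 0], index=list("abcd"))
        cm = ps.confusion_metrics(scores, labels)
        assert cm.precision_pct == cm.npv_pct == cm.accuracy_pct == 100.0

    def test_all_predicted_negative_flags_precision(self):
        scores = pd.Series([0.1, 0.2, 0.3], index=list("abc"))
        labels = pd.Series([0, 1, 0], index=list("abc"))
        cm = ps.confusion_metrics(scores, labels)
        assert "precision" in cm.undefined
        assert np.isnan(cm.precision_pct)
        assert cm.npv_pct == pytest.approx(100 * 2 / 3)


class TestVariantAggregation:
    def _mutations(self):
        rows = [
            ("P0", "KRAS", "Missense_Mutation", "c.35G>T", "p.G12V"),
            ("P1", "KRAS", "Missense_Mutation", "c.35G>A", "p.G12D"),
            ("P2", "KRAS", "Missense_Mutation", "c.34G>T", "p.G12D"),
            ("P3", "NRAS", "Missense_Mutation", None, None),
        ]
        return ps.MutationTable(
            pd.DataFrame(
                rows,
                columns=["sample_id", "gene_id", "variant_classification",
                         "nucleotide_change", "protein_change"],
            )
        )

    def test_mean_of_two_samples(self):
        muts = ps.MutationTable(
            pd.DataFrame(
                [("P0", "KRAS", "Missense_Mutation", "c.35G>T", "p.G12V"),
                 ("P1", "KRAS", "Missense_Mutation", "c.35G>T", "p.G12V")],
                columns=["sample_id", "gene_id", "variant_classification",
                         "nucleotide_change", "protein_change"],
            )
        )
        scores = pd.Series({"P0": 0.4, "P1": 0.6})
        table = ps.aggregate_variant_scores(scores, muts, level="protein")
        assert len(table) == 1
        assert table.loc[0, "mean_score"] == pytest.approx(0.5)
        assert table.loc[0, "n_samples"] == 2

    def test_protein_level_merges_nucleotide_level_splits(self):
        scores = pd.Series({f"P{i}": 0.5 for i in range(4)})
        protein = ps.aggregate_variant_scores(scores, self._mutations(), "protein")
        nucleotide = ps.aggregate_variant_scores(scores, self._mutations(), "nucleotide")
        g12d_protein = protein[protein["change"] == "p.G12D"]
        assert len(g12d_protein) == 1 and g12d_protein.iloc[0]["n_samples"] == 2
        assert len(nucleotide[nucleotide["change"].isin(["c.35G>A", "c.34G>T"])]) == 2

    def test_sample_counts_sum_to_annotated_pairs(self):
        scores = pd.Series({f"P{i}": 0.5 for i in range(4)})
        table = ps.aggregate_variant_scores(scores, self._mutations(), "protein")
        # 3 rows carry a protein change; the un-annotated row is skipped
        assert table["n_samples"].sum() == 3


class TestEnrichmentChi2:
    def test_published_cosmic_table_reproduced_to_one_decimal(self):
        chi2, dof, p = ps.enrichment_chi2((144, 152), (22, 34))
        assert dof == 1
        assert round(chi2, 1) == 26.1
        assert p == pytest.approx(3.2e-7, rel=0.1)

    def test_equal_proportions_give_zero(self):
        chi2, _, p = ps.enrichment_chi2((10, 20), (10, 20))
        assert chi2 == 0.0
        assert p == 1.0

    def test_hand_computed_symmetric_table(self):
        # expected counts all 20; chi2 = 4 * 10^2 / 20 = 20
        chi2, _, _ = ps.enrichment_chi2((30, 40), (10, 40))
        assert chi2 == pytest.approx(20.0)

    def test_zero_margin_is_an_error(self):
        with pytest.raises(CohortError, match="margin"):
            ps.enrichment_chi2((0, 10), (0, 10))


class TestScoreGroupTest:
    def test_identical_groups(self):
        t, _, p = ps.score_group_test([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert t == 0.0 and p == 1.0

    def test_swap_antisymmetry(self):
        a = [0.2, 0.4, 0.3, 0.6]
        b = [0.7, 0.9, 0.8, 0.65]
        t1, _, p1 = ps.score_group_test(a, b)
        t2, _, p2 = ps.score_group_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_power_against_unit_shift(self):
        rng = np.random.default_rng(0)
        rejections = 0
        for _ in range(100):
            a = rng.standard_normal(100)
            b = rng.standard_normal(100) + 1.0
            t, _, p = ps.score_group_test(a, b)
            rejections += p < 0.05
        assert rejections >= 99  # |t| ~ 7 on average; essentially always rejects


class TestDrugRegression:
    def _table(self, scores, activities, drug="drugA"):
        return pd.DataFrame(
            {"profile_id": scores.index, "drug": drug, "activity": activities}
        )

    def test_collinear_activity_gives_unit_correlation(self):
        scores = pd.Series(np.linspace(0.1, 0.9, 10), index=[f"P{i}" for i in range(10)])
        table = self._table(scores, 2.0 * scores.to_numpy())
        groups = pd.Series("wild_type", index=scores.index)
        fits = ps.drug_response_regression(scores, table, groups)
        row = fits.iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] < 1e-12
        assert row["significant"]

    def test_bonferroni_threshold_for_24_drugs_and_2_groups(self):
        rng = np.random.default_rng(5)
        ids = [f"P{i}" for i in range(20)]
        scores = pd.Series(rng.random(20), index=ids)
        groups = pd.Series(["mutant", "wild_type"] * 10, index=ids)
        frames = [
            self._table(scores, rng.random(20), drug=f"d{k:02d}") for k in range(24)
        ]
        fits = ps.drug_response_regression(scores, pd.concat(frames), groups)
        assert fits.attrs["bonferroni_threshold"] == pytest.approx(0.05 / 48)
        assert len(fits) == 48

    def test_small_cells_flagged_not_fit(self):
        scores = pd.Series([0.1, 0.9], index=["P0", "P1"])
        table = self._table(scores, [1.0, 2.0])
        groups = pd.Series(["m", "m"], index=scores.index)
        fits = ps.drug_response_regression(scores, table, groups)
        assert bool(fits.iloc[0]["flagged"])
        assert np.isnan(fits.iloc[0]["slope"])


class TestMultiHit:
    def _inputs(self):
        spec = ps.GeneTargetSpec(
            oncogenes=("KRAS",),
            pathway_genes=("KRAS", "BRAF", "RAF1", "MAP2K1", "SOS1", "PTPN11", "NF1"),
        )
        samples = [f"S{i}" for i in range(5)]
        scores = pd.Series([0.9, 0.7, 0.4, 0.3, 0.6], index=samples)
        rows = [
            ("S0", "KRAS", "Missense_Mutation"),  # core hit, 0 other
            ("S1", "BRAF", "Missense_Mutation"),  # 1 other hit
            ("S2", "BRAF", "Missense_Mutation"),
            ("S2", "RAF1", "Missense_Mutation"),  # 2 other hits
            ("S3", "BRAF", "Missense_Mutation"),
            ("S3", "RAF1", "Missense_Mutation"),
            ("S3", "MAP2K1", "Missense_Mutation"),
            ("S3", "SOS1", "Missense_Mutation"),
            ("S3", "PTPN11", "Missense_Mutation"),  # 5 other hits -> bucket 3+
        ]
        muts = ps.MutationTable(
            pd.DataFrame(rows, columns=["sample_id", "gene_id", "variant_classification"])
        )
        cnv = ps.CopyNumberMatrix(
            pd.DataFrame(0, index=samples, columns=["KRAS", "BRAF", "NF1"])
        )
        return scores, muts, cnv, spec

    def test_five_other_hits_bucketed_three_plus(self):
        scores, muts, cnv, spec = self._inputs()
        table = ps.multi_hit_stratification(scores, muts, cnv, spec)
        mut_rows = table[table["evidence"] == "mutation"]
        row = mut_rows[(mut_rows["core_status"] == 0) & (mut_rows["bucket"] == "3+")]
        assert len(row) == 1 and row.iloc[0]["n"] == 1

    def test_no_other_hits_collapse_to_single_bucket(self):
        spec = ps.GeneTargetSpec(oncogenes=("KRAS",), pathway_genes=("KRAS", "BRAF"))
        samples = ["S0", "S1"]
        scores = pd.Series([0.8, 0.2], index=samples)
        muts = ps.MutationTable(
            pd.DataFrame(
                [("S0", "KRAS", "Missense_Mutation")],
                columns=["sample_id", "gene_id", "variant_classification"],
            )
        )
        cnv = ps.CopyNumberMatrix(pd.DataFrame(0, index=samples, columns=["KRAS"]))
        table = ps.multi_hit_stratification(scores, muts, cnv, spec)
        mut_rows = table[table["evidence"] == "mutation"]
        assert set(mut_rows["bucket"]) == {"0"}

    def test_additive_pathway_hits_raise_scores_in_core_negative_samples(self):
        """Phenocopy-style simulation: extra pathway-gene hits carry the
        signature, so mean scores rise with the hit bucket among samples
        without core events."""
        cfg = ps.SimulationConfig(
            n_samples=500, n_genes=300, n_signal_genes=40, seed=31,
            hypermutator_fraction=0.0,
            phenocopy_genes=("BRAF",), phenocopy_prevalence=0.3,
        )
        cohort = ps.simulate_cohort(cfg)
        result = ps.train_pipeline(
            cohort.expression, cohort.mutations, cohort.copy_number,
            cohort.covariates, cohort.spec,
            ps.TrainingConfig(alpha_grid=(0.1,), l1_ratio_grid=(0.15,), seed=8),
        )
        scores = ps.score_cohort(result.model, cohort.expression, cohort.covariates)
        spec = ps.GeneTargetSpec(
            oncogenes=cohort.spec.oncogenes,
            tumor_suppressors=cohort.spec.tumor_suppressors,
            pathway_genes=cohort.spec.targets + ("BRAF",),
        )
        table = ps.multi_hit_stratification(scores, cohort.mutations,
                                            cohort.copy_number, spec)
        mut_rows = table[(table["evidence"] == "mutation")
                         & (table["core_status"] == 0)].set_index("bucket")
        assert mut_rows.loc["1", "mean_score"] > mut_rows.loc["0", "mean_score"]
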