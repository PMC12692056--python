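import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from stpscore import (
    ValidationError,
    check_reference_comparability,
    compare_pathway_activity,
    correlate,
    mann_whitney,
    ranked_paired_table,
    wilcoxon_signed_rank,
)
from stpscore.datasets import (
    load_paired_example_activity,
    load_paired_example_table,
)
from oracles import mann_whitney_exact_oracle, wilcoxon_exact_oracle


class TestMannWhitney:
    def test_separated_groups_small_n(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_two_sided == pytest.approx(2 / 6)
        assert res.method == "exact"

    def test_identical_multisets_give_p_one(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.p_two_sided == 1.0

    @pytest.mark.parametrize("seed", range(12))
    def test_exact_p_equals_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # mixed continuous and tied data, n up to 8 per group
        n, m = rng.integers(2, 9, size=2)
        x = rng.choice([1.0, 2.0, 2.5, 3.0, 4.0, 5.5], size=n)
        y = rng.choice([1.0, 2.0, 2.5, 3.0, 4.0, 5.5], size=m)
        res = mann_whitney(x, y)
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(
            float(mann_whitney_exact_oracle(x, y)), abs=0
        )

    def test_large_groups_use_corrected_normal_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.8, 1, 30)
        res = mann_whitney(x, y)
        assert res.method == "normal_approx"
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])


class TestWilcoxonSignedRank:
    def test_worked_example_paired_pathway_scores(self):
        """16 tumor/adjacent pairs: tumor shift significant at 0.01."""
        table = load_paired_example_table()
        res = wilcoxon_signed_rank(
            table[["MAPK_adjacent", "MAPK_tumor"]].to_numpy()
        )
        assert res.method == "exact"
        assert res.p_two_sided <= 0.01

    def test_small_example_signed_ranks(self):
        res = wilcoxon_signed_rank([(1, 2), (1, 3), (2, 1)])
        assert res.w_minus == 1.5
        assert res.p_two_sided == pytest.approx(
            float(wilcoxon_exact_oracle([(1, 2), (1, 3), (2, 1)]))
        )

    def test_antisymmetry_under_column_swap(self):
        rng = np.random.default_rng(4)
        pairs = rng.normal(0, 1, (10, 2))
        a = wilcoxon_signed_rank(pairs)
        b = wilcoxon_signed_rank(pairs[:, ::-1])
        assert a.p_two_sided == b.p_two_sided
        assert a.w_plus == b.w_minus and a.w_minus == b.w_plus

    @pytest.mark.parametrize("seed", range(12))
    def test_exact_p_equals_sign_enumeration_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(2, 9))
        pairs = np.column_stack(
            [rng.choice([1.0, 2.0, 3.0, 4.0], n),
             rng.choice([1.0, 2.0, 3.0, 4.0], n)]
        )
        if np.all(pairs[:, 0] == pairs[:, 1]):
            pairs[0, 1] += 1.0
        res = wilcoxon_signed_rank(pairs)
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(
            float(wilcoxon_exact_oracle(pairs)), abs=0
        )

    def test_zero_differences_dropped_and_counted(self):
        res = wilcoxon_signed_rank([(1, 1), (1, 2), (2, 4), (3, 6)])
        assert res.n == (3,)
        assert res.n_zero_dropped == 1

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_signed_rank([(1, 1), (2, 2)])

    def test_large_n_normal_approximation_matches_scipy(self):
        rng = np.random.default_rng(9)
        control = rng.normal(0, 1, 40)
        tumor = control + rng.normal(0.4, 1, 40)
        res = wilcoxon_signed_rank(np.column_stack([control, tumor]))
        assert res.method == "normal_approx"
        ref = sps.wilcoxon(tumor, control, correction=True,
                           mode="approx", alternative="two-sided")
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-6)


class TestTypeIError:
    def test_permutation_null_rate_within_binomial_interval(self, cohort):
        """Label permutations of a fixed cohort hold the 0.01 level."""
        rng = np.random.default_rng(123)
        # any fixed per-sample score vector works; take MKI67 expression
        values = cohort.matrix.values.loc["MKI67"].to_numpy()
        n_tumor = 16
        hits = 0
        n_perm = 1000
        for _ in range(n_perm):
            perm = rng.permutation(values)
            res = mann_whitney(perm[:n_tumor], perm[n_tumor:])
            hits += res.p_two_sided <= 0.01
        lo, hi = sps.binom.interval(0.99, n_perm, 0.01)
        assert lo <= hits <= hi


class TestCorrelate:
    def test_monotone_transform_gives_unit_coefficients(self):
        x = np.arange(10.0)
        assert correlate(x, 2 * x + 1, "spearman")["coefficient"] == \
            pytest.approx(1.0, abs=1e-12)
        assert correlate(x, 2 * x + 1, "pearson")["coefficient"] == \
            pytest.approx(1.0, abs=1e-12)

    def test_reversal_gives_minus_one(self):
        x = np.arange(10.0)
        assert correlate(x, -x, "spearman")["coefficient"] == \
            pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_proliferation_coupling_has_positive_sign(self, cohort):
        """MKI67 tracks the tumor-epithelial MAPK signal by construction."""
        truth = cohort.truth
        ki67 = cohort.matrix.values.loc["MKI67"]
        res = correlate(
            truth["mapk_signal"].to_numpy(), ki67.to_numpy(), "spearman"
        )
        assert res["coefficient"] > 0


class TestComparisonTable:
    def test_paired_cohort_flags_driven_pathway(self, cohort, mapk_model):
        from stpscore import score_matrix
        activity = score_matrix(cohort.matrix, [mapk_model])
        table = compare_pathway_activity(activity, paired=True)
        row = table[table["pathway"] == "MAPK"].iloc[0]
        assert row["significant"] and row["annotate"]
        assert row["method"] == "exact"
        assert row["delta"] > 0

    def test_significant_implies_annotate(self, cohort, mapk_model):
        from stpscore import score_matrix
        activity = score_matrix(cohort.matrix, [mapk_model])
        for paired in (True, False):
            table = compare_pathway_activity(activity, paired=paired)
            assert (table["annotate"] | ~table["significant"]).all()

    def test_single_group_rejected(self, mapk_model):
        from stpscore import ExpressionMatrix, score_matrix
        genes = [t.gene_id for t in mapk_model.targets]
        ann = pd.DataFrame(
            {"group": ["tumor", "tumor"], "pair_id": [None, None],
             "dataset_id": [None, None], "origin": [None, None]},
            index=["s1", "s2"],
        )
        matrix = ExpressionMatrix(
            pd.DataFrame(np.full((len(genes), 2), 7.0), index=genes,
                         columns=["s1", "s2"]),
            ann,
        )
        activity = score_matrix(matrix, [mapk_model])
        with pytest.raises(ValidationError, match="both groups"):
            compare_pathway_activity(activity, paired=False)

    def test_broken_pair_mapping_names_samples(self):
        activity = load_paired_example_activity()
        activity.annotations.loc["T1", "pair_id"] = None
        with pytest.raises(ValidationError, match="T1"):
            compare_pathway_activity(activity, paired=True)


class TestReferenceComparability:
    def test_identical_distributions_comparable(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(20, 40, 20)
        out = check_reference_comparability(
            pd.Series(scores), pd.Series(scores.copy())
        )
        assert out["comparable"]

    def test_large_shift_not_comparable(self):
        rng = np.random.default_rng(1)
        a = pd.Series(rng.uniform(20, 40, 20))
        out = check_reference_comparability(a, a + 20.0)
        assert not out["comparable"]
        assert abs(out["median_delta"]) == pytest.approx(20.0)


class TestRankedPairedTable:
    def test_worked_example_row_order(self):
        activity = load_paired_example_activity()
        table = ranked_paired_table(activity, "MAPK", ["MAPK", "TGFB"])
        assert table.iloc[0]["MAPK_tumor"] == 58.4
        assert table.iloc[-1]["MAPK_tumor"] == 34.0
        row10 = table[table["MAPK_tumor"] == 47.2].iloc[0]
        assert row10["TGFB_tumor"] == 22.7

    def test_ties_break_stably_by_pair_id(self):
        activity = load_paired_example_activity()
        activity.scores["MAPK"] = 50.0  # force a full tie
        table = ranked_paired_table(activity, "MAPK")
        assert list(table["pair_id"]) == sorted(table["pair_id"], key=str)

    def test_unpaired_input_rejected(self):
        activity = load_paired_example_activity()
        activity.annotations["pair_id"] = None
        with pytest.raises(ValidationError):
            ranked_paired_table(activity, "MAPK")
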