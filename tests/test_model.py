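import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stpscore import (
    PI3KInterpretation,
    ParameterError,
    ValidationError,
    calibrate_pathway,
    fuzzify_expression,
    gene_evidence_logodds,
    generate_calibration_set,
    interpret_pi3k,
    load_models,
    normalize_logodds,
    sample_logodds,
    save_models,
    score_matrix,
    score_sample,
)
from stpscore.model import CalibratedPathwayModel, TargetParams

from helpers import random_model
from oracles import enumeration_logodds, rank_auc


def make_target(**kw) -> TargetParams:
    defaults = dict(
        gene_id="G", direction=1, weight=1.0, midpoint=7.0, scale=0.5,
        p_active=0.8, p_inactive=0.2,
    )
    defaults.update(kw)
    return TargetParams(**defaults)


class TestFuzzify:
    def test_midpoint_gives_half(self):
        assert fuzzify_expression(7.0, make_target()) == 0.5

    def test_saturates_at_one(self):
        assert fuzzify_expression(1e6, make_target()) == 1.0

    def test_one_scale_above_midpoint(self):
        # closed form: 1 / (1 + e^-1)
        p = fuzzify_expression(7.5, make_target(scale=0.5))
        assert p == pytest.approx(0.7310585786300049, abs=1e-9)

    def test_negative_direction_reverses(self):
        t = make_target(direction=-1)
        assert fuzzify_expression(9.0, t) < 0.5 < fuzzify_expression(5.0, t)

    def test_non_finite_expression_rejected(self):
        with pytest.raises(ValidationError):
            fuzzify_expression(float("nan"), make_target())


class TestGeneEvidence:
    def test_noninformative_contributes_zero(self):
        t = make_target(p_active=0.5, p_inactive=0.5, informative=False)
        for p in (0.0, 0.3, 1.0):
            assert gene_evidence_logodds(p, t) == 0.0

    def test_hard_evidence_is_log_likelihood_ratio(self):
        t = make_target(p_active=0.8, p_inactive=0.2)
        assert gene_evidence_logodds(1.0, t) == pytest.approx(2.0)

    def test_soft_evidence_marginalizes_gene_node(self):
        # p=0.75, a=0.9, b=0.1: log2(0.7 / 0.3)
        t = make_target(p_active=0.9, p_inactive=0.1)
        expected = math.log2(0.7 / 0.3)
        assert gene_evidence_logodds(0.75, t) == pytest.approx(expected, abs=1e-12)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ParameterError):
            make_target(p_active=1.0)


class TestSampleLogodds:
    def test_contributions_add_on_top_of_prior(self):
        t1 = make_target(gene_id="A")
        t2 = make_target(gene_id="B")
        model = CalibratedPathwayModel("P", [t1, t2], prior_logodds=0.5)
        expr = {"A": 1e6, "B": 1e6}  # both saturate at log2(0.8/0.2) = 2
        assert sample_logodds(expr, model) == pytest.approx(4.5)

    def test_all_targets_missing_errors(self):
        model = CalibratedPathwayModel("P", [make_target()])
        with pytest.raises(ValidationError, match="missing"):
            sample_logodds({"OTHER": 7.0}, model, missing_policy="skip")

    def test_missing_policy_error_raises_on_any_gap(self):
        model = CalibratedPathwayModel(
            "P", [make_target(gene_id="A"), make_target(gene_id="B")]
        )
        with pytest.raises(ValidationError):
            sample_logodds({"A": 7.0}, model, missing_policy="error")

    @pytest.mark.parametrize("seed", range(10))
    def test_factorized_logodds_equals_enumeration(self, seed):
        """Exact inference on the two-layer network equals the weighted sum."""
        rng = np.random.default_rng(seed)
        model = random_model(rng, n_targets=4)
        expr = {t.gene_id: float(rng.normal(7, 1.5)) for t in model.targets}
        assert sample_logodds(expr, model) == pytest.approx(
            enumeration_logodds(model, expr), abs=1e-9
        )


class TestNormalization:
    def test_anchor_values(self, mapk_model):
        assert normalize_logodds(mapk_model.l_max, mapk_model) == 100.0
        assert normalize_logodds(mapk_model.l_min, mapk_model) == 0.0
        mid = (mapk_model.l_min + mapk_model.l_max) / 2
        assert normalize_logodds(mid, mapk_model) == pytest.approx(50.0)

    def test_saturated_evidence_scores_exactly_100(self, mapk_model):
        expr = {
            t.gene_id: t.midpoint + t.direction * 60 * t.scale
            for t in mapk_model.targets
        }
        assert score_sample(expr, mapk_model) == 100.0

    def test_minimal_evidence_scores_exactly_0(self, mapk_model):
        expr = {
            t.gene_id: t.midpoint - t.direction * 60 * t.scale
            for t in mapk_model.targets
        }
        assert score_sample(expr, mapk_model) == 0.0

    def test_no_informative_targets_is_undefined(self):
        t = make_target(p_active=0.5, p_inactive=0.5, informative=False)
        model = CalibratedPathwayModel("P", [t])
        with pytest.raises(ParameterError, match="undefined"):
            normalize_logodds(0.0, model)

    @given(st.floats(-50, 50), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scores_always_within_bounds(self, logodds, seed):
        rng = np.random.default_rng(seed)
        model = random_model(rng, n_targets=3)
        assert 0.0 <= normalize_logodds(logodds, model) <= 100.0

    @given(st.integers(0, 2**31 - 1), st.floats(0.01, 3.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_positive_target_expression(self, seed, step):
        """Raising an induced target's expression never lowers the score."""
        rng = np.random.default_rng(seed)
        model = random_model(rng, n_targets=4)
        target = next(t for t in model.targets if t.direction == 1) \
            if any(t.direction == 1 for t in model.targets) else None
        if target is None:
            return
        expr = {t.gene_id: float(rng.normal(7, 1)) for t in model.targets}
        before = score_sample(expr, model)
        expr[target.gene_id] += step
        assert score_sample(expr, model) >= before - 1e-12

    def test_zero_weight_equals_removal(self):
        rng = np.random.default_rng(3)
        model = random_model(rng, n_targets=4)
        expr = {t.gene_id: float(rng.normal(7, 1)) for t in model.targets}
        zeroed = CalibratedPathwayModel(
            "P",
            [TargetParams(**{**t.__dict__, "weight": 0.0})
             if t.gene_id == "G0" else t for t in model.targets],
            model.prior_logodds,
        )
        removed = CalibratedPathwayModel(
            "P", [t for t in model.targets if t.gene_id != "G0"],
            model.prior_logodds,
        )
        assert score_sample(expr, zeroed) == pytest.approx(
            score_sample(expr, removed), abs=1e-12
        )


class TestCalibration:
    def test_laplace_counts_on_perfect_separation(self, mapk_definition):
        rng = np.random.default_rng(7)
        genes = mapk_definition.gene_ids
        n = 10
        values = np.empty((len(genes), 2 * n))
        for gi, t in enumerate(mapk_definition.targets):
            values[gi, :n] = 7 + t.direction * 2.0 + rng.normal(0, 0.1, n)
            values[gi, n:] = 7 - t.direction * 2.0 + rng.normal(0, 0.1, n)
        from stpscore import ExpressionMatrix
        matrix = ExpressionMatrix(
            pd.DataFrame(values, index=genes,
                         columns=[f"s{i}" for i in range(2 * n)])
        )
        labels = pd.Series(["active"] * n + ["inactive"] * n,
                           index=matrix.sample_ids)
        model = calibrate_pathway(matrix, labels, mapk_definition, pseudocount=1.0)
        for t in model.targets:
            assert t.p_active == pytest.approx(11 / 12)
            assert t.p_inactive == pytest.approx(1 / 12)
            assert t.informative

    def test_uninformative_gene_neutralized(self, mapk_definition):
        matrix, labels = generate_calibration_set(
            mapk_definition, delta=0.0, sigma=0.3, seed=11
        )
        model = calibrate_pathway(matrix, labels, mapk_definition)
        # with no class shift roughly half the genes calibrate to a <= b
        n_neutral = sum(not t.informative for t in model.targets)
        assert n_neutral >= 5
        for t in model.targets:
            if not t.informative:
                assert gene_evidence_logodds(0.9, t) == 0.0

    def test_single_class_labels_rejected(self, mapk_definition):
        matrix, labels = generate_calibration_set(mapk_definition, seed=1)
        with pytest.raises(ValidationError):
            calibrate_pathway(
                matrix, pd.Series("active", index=matrix.sample_ids),
                mapk_definition,
            )

    def test_held_out_auc_high_at_two_sigma_shift(self, mapk_definition):
        train, train_labels = generate_calibration_set(
            mapk_definition, delta=0.6, sigma=0.3, seed=21
        )
        test, test_labels = generate_calibration_set(
            mapk_definition, delta=0.6, sigma=0.3, seed=22
        )
        model = calibrate_pathway(train, train_labels, mapk_definition)
        scores = {
            sid: score_sample(test.values[sid], model)
            for sid in test.sample_ids
        }
        pos = [scores[s] for s in test.sample_ids if test_labels[s] == "active"]
        neg = [scores[s] for s in test.sample_ids if test_labels[s] == "inactive"]
        assert rank_auc(pos, neg) >= 0.95

    def test_null_shift_gives_chance_auc(self, mapk_definition):
        train, train_labels = generate_calibration_set(
            mapk_definition, delta=0.0, sigma=0.3, seed=31
        )
        test, test_labels = generate_calibration_set(
            mapk_definition, delta=0.0, sigma=0.3, seed=32
        )
        model = calibrate_pathway(train, train_labels, mapk_definition)
        scores = {
            sid: score_sample(test.values[sid], model)
            for sid in test.sample_ids
        }
        pos = [scores[s] for s in test.sample_ids if test_labels[s] == "active"]
        neg = [scores[s] for s in test.sample_ids if test_labels[s] == "inactive"]
        assert 0.4 <= rank_auc(pos, neg) <= 0.6


class TestScoreMatrix:
    def test_tumor_scores_exceed_control_for_driven_pathway(
        self, cohort, mapk_model
    ):
        activity = score_matrix(cohort.matrix, [mapk_model])
        groups = activity.annotations["group"]
        tumor = activity.scores.loc[groups == "tumor", "MAPK"]
        control = activity.scores.loc[groups == "control", "MAPK"]
        assert tumor.mean() > control.mean()

    def test_missing_covariate_is_not_fatal(self, mapk_model):
        from stpscore import ExpressionMatrix
        genes = [t.gene_id for t in mapk_model.targets]
        values = pd.DataFrame(
            np.full((len(genes), 2), 7.0), index=genes, columns=["s1", "s2"]
        )
        activity = score_matrix(ExpressionMatrix(values), [mapk_model])
        assert activity.covariates["ki67"].isna().all()

    def test_identical_samples_score_identically(self, mapk_model):
        from stpscore import ExpressionMatrix
        genes = [t.gene_id for t in mapk_model.targets]
        rng = np.random.default_rng(0)
        col = rng.normal(7, 1, len(genes))
        values = pd.DataFrame(
            np.column_stack([col, col]), index=genes, columns=["s1", "s2"]
        )
        activity = score_matrix(ExpressionMatrix(values), [mapk_model])
        assert activity.scores.loc["s1", "MAPK"] == activity.scores.loc["s2", "MAPK"]


class TestPI3KInterpretation:
    @pytest.fixture
    def reference(self):
        return {"foxo_median": 30.0, "sod2_median": 7.0}

    def test_decision_logic(self, reference):
        foxo = pd.Series({"s1": 50.0, "s2": 50.0, "s3": 30.0, "s4": 34.0})
        sod2 = pd.Series({"s1": 9.0, "s2": 7.1, "s3": 9.0, "s4": 7.0})
        out = interpret_pi3k(foxo, sod2, reference)
        assert out["s1"] is PI3KInterpretation.UNINTERPRETABLE_OXIDATIVE_STRESS
        assert out["s2"] is PI3KInterpretation.PI3K_INACTIVE
        assert out["s3"] is PI3KInterpretation.PI3K_ACTIVE  # FOXO low
        assert out["s4"] is PI3KInterpretation.PI3K_ACTIVE  # within tau_foxo
    def test_missing_reference_rejected(self):
        with pytest.raises(ValidationError):
            interpret_pi3k(pd.Series([1.0]), pd.Series([1.0]), {})

    def test_no_controls_rejected(self):
        from stpscore import control_reference
        groups = pd.Series({"s1": "tumor"})
        with pytest.raises(ValidationError, match="control"):
            control_reference(pd.Series({"s1": 1.0}), pd.Series({"s1": 1.0}),
                              groups)


class TestSerialization:
    def test_bit_exact_round_trip(self, mapk_model, tmp_path):
        path = tmp_path / "models.json"
        save_models([mapk_model], path)
        back = load_models(path)[0]
        assert back.pathway_name == mapk_model.pathway_name
        assert back.prior_logodds == mapk_model.prior_logodds
        for t_in, t_out in zip(mapk_model.targets, back.targets):
            assert t_in == t_out
        assert back.l_min == mapk_model.l_min
        assert back.l_max == mapk_model.l_max

    def test_unknown_format_version_rejected(self, tmp_path):
        path = tmp_path / "models.json"
        path.write_text('{"format_version": 99, "models": []}')
        with pytest.raises(ValidationError, match="format_version"):
            load_models(path)
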