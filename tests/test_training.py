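"""Model selection, cross-validation, Platt calibration, final models."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seqfunc.corpus import TermTrainingSet
from seqfunc.features import FeatureMatrix
from seqfunc.partition import DistanceMatrix, PartitionPlan
from seqfunc.training import (ConfusionCounts, GridSpec, KernelSpec, Metrics,
                              PlattCalibration, TermClassifier, TermModel,
                              TrainingConfig, TrainingError,
                              confusion_metrics, cross_validate,
                              finalize_model, greedy_group_elimination,
                              grid_search, holdout_evaluate, platt_fit,
                              reliability_tier)


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        assert m == Metrics(1.0, 1.0, 1.0, 1.0)

    def test_worked_third(self):
        m = confusion_metrics(ConfusionCounts(tp=2, fp=1, tn=2, fn=1))
        assert m.mcc == pytest.approx(1 / 3)

    def test_degenerate_denominator_convention(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fp=0, tn=10, fn=5))
        assert m == Metrics(0.0, 0.0, 1.0, 0.0)

    def test_empty_table_errors(self):
        with pytest.raises(TrainingError):
            confusion_metrics(ConfusionCounts())

    def test_against_sklearn_oracle(self):
        from sklearn.metrics import matthews_corrcoef, recall_score
        rng = np.random.default_rng(0)
        for _ in range(300):
            tp, fp, tn, fn = (int(v) for v in rng.integers(0, 20, 4))
            if tp + fp + tn + fn == 0:
                continue
            y_true = [1] * tp + [0] * fp + [0] * tn + [1] * fn
            y_pred = [1] * tp + [1] * fp + [0] * tn + [0] * fn
            m = confusion_metrics(ConfusionCounts(tp, fp, tn, fn))
            assert m.mcc == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-12)
            assert -1.0 <= m.mcc <= 1.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 50)] * 4))
    def test_mcc_always_in_range(self, counts):
        tp, fp, tn, fn = counts
        if tp + fp + tn + fn == 0:
            return
        m = confusion_metrics(ConfusionCounts(tp, fp, tn, fn))
        assert -1.0 <= m.mcc <= 1.0
        assert 0.0 <= m.sensitivity <= 1.0
        assert 0.0 <= m.precision <= 1.0


def toy_problem(n_pos=40, n_neg=80, n_features=6, separation=2.0, seed=0,
                k=2, holdout_frac=0.25):
    """A small labelled problem with plans, features and distances.

    ``separation > 1`` makes the two classes occupy disjoint ranges on
    the first feature, hence linearly separable by construction.
    """
    rng = np.random.default_rng(seed)
    pos = [f"POS{i:03d}" for i in range(n_pos)]
    neg = [f"NEG{i:03d}" for i in range(n_neg)]
    accs = pos + neg
    x = rng.uniform(0.0, 1.0, size=(len(accs), n_features))
    x[:n_pos, 0] += separation
    layout = [("g1", 0, 2), ("g2", 2, 2), ("g3", 4, 2)]
    matrix = FeatureMatrix(accs, x, layout)

    def plan_of(members):
        n_hold = int(len(members) * holdout_frac)
        holdout = set(members[:n_hold])
        rest = members[n_hold:]
        groups = [set(rest[i::k]) for i in range(k)]
        return PartitionPlan(holdout, groups, k, seed)

    return matrix, plan_of(pos), plan_of(neg)


class TestCrossValidate:
    def test_separable_signal_gives_perfect_mcc(self):
        matrix, pos_plan, neg_plan = toy_problem(separation=2.0)
        cv = cross_validate(matrix, pos_plan, neg_plan,
                            KernelSpec("linear", 1.0))
        assert cv.mcc == 1.0
        assert cv.pooled.total == sum(c.total for c in cv.fold_counts)

    def test_permuted_labels_near_zero(self):
        low = 0
        for seed in range(10):
            matrix, pos_plan, neg_plan = toy_problem(
                n_pos=60, n_neg=140, separation=0.0, seed=seed)
            cv = cross_validate(matrix, pos_plan, neg_plan,
                                KernelSpec("linear", 1.0))
            if abs(cv.mcc) < 0.25:
                low += 1
        assert low >= 8

    def test_j_rule_weight(self):
        seen = []

        def recording_backend(x, y, kernel, pos_weight):
            seen.append(pos_weight)
            from seqfunc.training import svc_backend
            return svc_backend(x, y, kernel, pos_weight)

        matrix, pos_plan, neg_plan = toy_problem(n_pos=40, n_neg=200,
                                                 holdout_frac=0.0, k=2)
        cross_validate(matrix, pos_plan, neg_plan, KernelSpec("linear", 1.0),
                       backend=recording_backend)
        # each fold trains on 20 positives and 100 negatives
        assert seen == [5.0, 5.0]

    def test_mismatched_k_errors(self):
        matrix, pos_plan, neg_plan = toy_problem(k=2)
        bad = PartitionPlan(neg_plan.holdout,
                            [set().union(*neg_plan.groups)], 1,
                            neg_plan.seed)
        with pytest.raises(TrainingError):
            cross_validate(matrix, pos_plan, bad, KernelSpec("linear", 1.0))

    def test_decision_values_cover_every_training_protein(self):
        matrix, pos_plan, neg_plan = toy_problem()
        cv = cross_validate(matrix, pos_plan, neg_plan,
                            KernelSpec("linear", 1.0))
        expected = (set().union(*pos_plan.groups)
                    | set().union(*neg_plan.groups))
        assert set(cv.decision_values) == expected


class TestGridSearch:
    def test_single_configuration(self):
        matrix, pos_plan, neg_plan = toy_problem()
        grid = GridSpec(c_values=(2.0,), gamma_values=(0.1,),
                        kinds=("rbf",))
        spec, cv = grid_search(matrix, pos_plan, neg_plan, grid)
        assert spec == KernelSpec("rbf", 2.0, 0.1)

    def test_degenerate_config_loses(self):
        # an over-localised RBF memorises its training fold and emits
        # near-constant decisions on the test folds; the linear kernel
        # generalises and wins the mcc comparison
        matrix, pos_plan, neg_plan = toy_problem(separation=2.0)
        grid = GridSpec(c_values=(1.0,), gamma_values=(1e6,),
                        kinds=("linear", "rbf"))
        spec, cv = grid_search(matrix, pos_plan, neg_plan, grid)
        assert spec.kind == "linear"
        assert cv.mcc == 1.0

    def test_tie_breaks_deterministically(self):
        # all configs perfect on well-separated data -> first in grid order
        matrix, pos_plan, neg_plan = toy_problem(separation=3.0)
        grid = GridSpec(c_values=(1.0, 4.0), gamma_values=(0.5,),
                        kinds=("linear", "rbf"))
        spec, _ = grid_search(matrix, pos_plan, neg_plan, grid)
        assert spec == KernelSpec("linear", 1.0)

    def test_iteration_order_linear_first_ascending(self):
        grid = GridSpec(c_values=(4.0, 1.0), gamma_values=(0.2, 0.1),
                        kinds=("linear", "rbf"))
        specs = grid.specs()
        assert specs[0] == KernelSpec("linear", 1.0)
        assert specs[1] == KernelSpec("linear", 4.0)
        assert specs[2] == KernelSpec("rbf", 1.0, 0.1)
        assert [s.kind for s in specs] == ["linear"] * 2 + ["rbf"] * 4


class TestGroupElimination:
    def small_grid(self):
        return GridSpec(c_values=(1.0,), kinds=("linear",))

    def test_all_informative_groups_retained(self):
        # signal spread over all three groups: removal hurts
        rng = np.random.default_rng(3)
        pos = [f"POS{i}" for i in range(30)]
        neg = [f"NEG{i}" for i in range(30)]
        x = rng.normal(size=(60, 6), scale=2.0)
        x[:30] += np.array([1.0, 0, 1.0, 0, 1.0, 0])
        matrix = FeatureMatrix(pos + neg, x,
                               [("g1", 0, 2), ("g2", 2, 2), ("g3", 4, 2)])
        plans = (PartitionPlan(set(), [set(pos[:15]), set(pos[15:])], 2, 0),
                 PartitionPlan(set(), [set(neg[:15]), set(neg[15:])], 2, 0))
        retained, spec, cv = greedy_group_elimination(
            matrix, plans[0], plans[1], self.small_grid())
        baseline = grid_search(matrix, plans[0], plans[1],
                               self.small_grid())[1]
        assert cv.mcc >= baseline.mcc

    def test_tie_never_removes_group(self):
        # perfectly separable via g1 alone: removing noise g2 cannot
        # strictly improve an mcc of 1, so g2 stays
        matrix, pos_plan, neg_plan = toy_problem(separation=3.0)
        retained, spec, cv = greedy_group_elimination(
            matrix, pos_plan, neg_plan, self.small_grid())
        assert cv.mcc == 1.0
        assert retained == ["g1", "g2", "g3"]

    def test_single_group_registry(self):
        matrix, pos_plan, neg_plan = toy_problem()
        sub = matrix.select_groups({"g1"})
        retained, _, _ = greedy_group_elimination(
            sub, pos_plan, neg_plan, self.small_grid())
        assert retained == ["g1"]

    def test_empty_registry_errors(self):
        matrix, pos_plan, neg_plan = toy_problem()
        with pytest.raises(TrainingError):
            greedy_group_elimination(matrix, pos_plan, neg_plan,
                                     self.small_grid(), registry_order=[])


class TestReliabilityAndDiscard:
    def test_tier_thresholds(self):
        assert reliability_tier(Metrics(0.31, 0.31, 0.71, 0.31)) == "H"
        assert reliability_tier(Metrics(0.4, 0.5, 0.6, 0.5)) == "L"
        assert reliability_tier(Metrics(0.3, 0.31, 0.71, 0.31)) == "L"

    def test_holdout_separable_is_high_and_kept(self):
        matrix, pos_plan, neg_plan = toy_problem(separation=2.0)
        outcome = holdout_evaluate(matrix, pos_plan, neg_plan,
                                   KernelSpec("linear", 1.0),
                                   ["g1", "g2", "g3"])
        assert outcome.metrics.mcc == 1.0
        assert outcome.reliability == "H"
        assert not outcome.discarded

    def test_noise_is_discarded_when_mcc_low(self):
        matrix, pos_plan, neg_plan = toy_problem(separation=2.0)
        outcome = holdout_evaluate(matrix, pos_plan, neg_plan,
                                   KernelSpec("linear", 1.0),
                                   ["g1", "g2", "g3"], discard_mcc=1.01)
        assert outcome.discarded

    def test_empty_holdout_errors(self):
        matrix, pos_plan, neg_plan = toy_problem(holdout_frac=0.0)
        with pytest.raises(TrainingError):
            holdout_evaluate(matrix, pos_plan, neg_plan,
                             KernelSpec("linear", 1.0), ["g1"])


class TestPlattFit:
    def test_midpoint_posterior(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=400)
        y = np.where(f + 0.3 * rng.normal(size=400) > 0, 1, -1)
        cal = platt_fit(f, y)
        assert cal.posterior(-cal.B / cal.A) == pytest.approx(0.5)

    def test_parameter_recovery_within_5_percent(self):
        rng = np.random.default_rng(42)
        f = rng.normal(scale=2.0, size=10_000)
        p = 1.0 / (1.0 + np.exp(-2.0 * f + 0.0))
        y = np.where(rng.random(10_000) < p, 1, -1)
        cal = platt_fit(f, y)
        assert cal.A == pytest.approx(-2.0, rel=0.05)
        assert abs(cal.B) < 0.1

    def test_sign_of_a_for_separated_classes(self):
        f = np.concatenate([np.full(50, 5.0) + np.arange(50) * 0.01,
                            np.full(50, -5.0) - np.arange(50) * 0.01])
        y = np.concatenate([np.ones(50), -np.ones(50)])
        cal = platt_fit(f, y)
        assert cal.A < 0

    def test_single_class_errors(self):
        with pytest.raises(TrainingError):
            platt_fit([1.0, 2.0], [1, 1])

    def test_matches_reference_implementation(self):
        from sklearn.calibration import _sigmoid_calibration
        rng = np.random.default_rng(5)
        f = rng.normal(size=500)
        p = 1.0 / (1.0 + np.exp(-1.5 * f - 0.2))
        y = np.where(rng.random(500) < p, 1, -1)
        cal = platt_fit(f, y)
        a_ref, b_ref = _sigmoid_calibration(f, (y > 0).astype(float))
        assert cal.A == pytest.approx(float(a_ref), abs=1e-3)
        assert cal.B == pytest.approx(float(b_ref), abs=1e-3)

    def test_posterior_monotone_when_a_negative(self):
        cal = PlattCalibration(A=-1.7, B=0.4)
        grid = np.linspace(-5, 5, 101)
        post = cal.posterior(grid)
        assert np.all(np.diff(post) > 0)
        assert np.all((post > 0) & (post < 1))


class TestFinalizeAndResults:
    def make_inputs(self, seed=0):
        matrix, pos_plan, neg_plan = toy_problem(separation=2.0, seed=seed)
        pos = sorted(set().union(*pos_plan.groups) | pos_plan.holdout)
        neg = sorted(set().union(*neg_plan.groups) | neg_plan.holdout)
        tset = TermTrainingSet("GO:X", set(pos), set(neg), eligible=True)
        accs = matrix.accessions
        n = len(accs)
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) * 1.0
        dist = DistanceMatrix(accs, d)
        return tset, matrix, dist, pos_plan, neg_plan

    def test_final_model_separates_training_data(self):
        tset, matrix, dist, pos_plan, neg_plan = self.make_inputs()
        grid = GridSpec(c_values=(1.0,), kinds=("linear",))
        outcome = holdout_evaluate(matrix, pos_plan, neg_plan,
                                   KernelSpec("linear", 1.0),
                                   ["g1", "g2", "g3"])
        model = finalize_model(tset, matrix, dist, ["g1", "g2", "g3"],
                               "linear", grid, k=2,
                               holdout_outcome=outcome, seed=0)
        for acc in sorted(tset.positives)[:10]:
            assert model.decision_function(matrix.vector(acc)) > 0
        for acc in sorted(tset.negatives)[:10]:
            assert model.decision_function(matrix.vector(acc)) < 0
        # holdout metrics carried over, not re-measured
        assert model.holdout_metrics == outcome.metrics
        assert math.isfinite(model.calibration.A)
        assert math.isfinite(model.calibration.B)
        assert model.calibration.A < 0

    def test_discarded_term_cannot_be_finalised(self):
        tset, matrix, dist, pos_plan, neg_plan = self.make_inputs()
        outcome = holdout_evaluate(matrix, pos_plan, neg_plan,
                                   KernelSpec("linear", 1.0),
                                   ["g1"], discard_mcc=1.01)
        with pytest.raises(TrainingError):
            finalize_model(tset, matrix, dist, ["g1"], "linear",
                           GridSpec(kinds=("linear",)), k=2,
                           holdout_outcome=outcome)

    @pytest.mark.parametrize("kind", ["linear", "rbf"])
    def test_model_json_round_trip(self, kind):
        tset, matrix, dist, pos_plan, neg_plan = self.make_inputs()
        grid = (GridSpec(c_values=(1.0,), kinds=("linear",)) if kind == "linear"
                else GridSpec(c_values=(4.0,), gamma_values=(0.5,),
                              kinds=("rbf",)))
        outcome = holdout_evaluate(matrix, pos_plan, neg_plan,
                                   grid.specs()[0], ["g1", "g2", "g3"])
        model = finalize_model(tset, matrix, dist, ["g1", "g2", "g3"],
                               kind, grid, k=2, holdout_outcome=outcome)
        again = TermModel.from_dict(model.to_dict())
        for acc in matrix.accessions[::17]:
            fv = matrix.vector(acc)
            assert again.decision_function(fv) == \
                pytest.approx(model.decision_function(fv), rel=1e-12)
            assert 0.0 < again.posterior(fv) < 1.0

    def test_results_facade_and_summary(self):
        tset, matrix, dist, _, _ = self.make_inputs()
        cfg = TrainingConfig(min_group_size=10,
                             grid=GridSpec(c_values=(1.0,),
                                           kinds=("linear",)))
        results = TermClassifier(tset, matrix, dist, config=cfg).fit(7)
        assert not results.discarded
        assert results.reliability == "H"
        assert results.model is not None
        text = results.summary()
        assert "holdout MCC" in text and "GO:X" in text

    def test_fit_is_deterministic(self):
        tset, matrix, dist, _, _ = self.make_inputs()
        cfg = TrainingConfig(min_group_size=10,
                             grid=GridSpec(c_values=(1.0,),
                                           kinds=("linear",)))
        r1 = TermClassifier(tset, matrix, dist, config=cfg).fit(3)
        r2 = TermClassifier(tset, matrix, dist, config=cfg).fit(3)
        assert r1.model.to_dict() == r2.model.to_dict()
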