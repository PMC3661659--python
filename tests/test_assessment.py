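"""CAFA precision-recall, relaxed matching, simGIC and COGIC scoring."""

import math

import numpy as np
import pytest

from seqfunc.assessment import (AssessmentError, cafa_pr, cogic,
                                evaluate_cafa, evaluate_cogic,
                                load_predictions, load_reference,
                                propagate_predictions, propagate_reference,
                                relaxed_pr, simgic, summarize_cogic)
from seqfunc.ontology import ICTable, IS_A, information_content

from conftest import build_graph, random_dag


@pytest.fixture
def flat_graph():
    """Root R with independent leaves a, b, c, d (no shared non-root
    ancestors)."""
    return build_graph(["R", "a", "b", "c", "d"],
                       [(x, "R", IS_A) for x in "abcd"])


@pytest.fixture
def two_branch_graph():
    """R <- u <- u1, u2 and R <- v <- v1 (two disjoint branches)."""
    return build_graph(
        ["R", "u", "u1", "u2", "v", "v1"],
        [("u", "R", IS_A), ("u1", "u", IS_A), ("u2", "u", IS_A),
         ("v", "R", IS_A), ("v1", "v", IS_A)])


class TestPropagation:
    def test_ancestors_gain_confidence(self, two_branch_graph):
        pred = {"p": {"u1": 0.9}}
        out = propagate_predictions(pred, two_branch_graph)
        assert out["p"] == {"u1": 0.9, "u": 0.9}   # root excluded

    def test_maximum_over_descendants(self, two_branch_graph):
        pred = {"p": {"u1": 0.3, "u2": 0.8}}
        out = propagate_predictions(pred, two_branch_graph)
        assert out["p"]["u"] == 0.8

    def test_idempotent(self, two_branch_graph):
        pred = {"p": {"u1": 0.3, "u2": 0.8}}
        once = propagate_predictions(pred, two_branch_graph)
        twice = propagate_predictions(once, two_branch_graph)
        assert once == twice


class TestCafaPR:
    def test_worked_fmax_two_thirds(self, flat_graph):
        pred = propagate_predictions({"p": {"a": 0.9, "c": 0.4}}, flat_graph)
        ref = propagate_reference({"p": {"a", "b"}}, flat_graph)
        curve = cafa_pr(pred, ref, flat_graph)
        by_v = {v: (p, r) for v, p, r, _ in curve.points}
        assert by_v[0.9] == (1.0, 0.5)
        assert by_v[0.4] == (0.5, 0.5)
        assert curve.fmax == pytest.approx(2 / 3)

    def test_identical_sets_give_fmax_one(self, two_branch_graph):
        ref = {"p": {"u1", "v1"}, "q": {"u2"}}
        pred = {s: {t: 1.0 for t in terms} for s, terms in ref.items()}
        curve = evaluate_cafa(pred, ref, two_branch_graph)
        assert curve.fmax == 1.0
        for _, precision, recall, n_v in curve.points:
            if n_v:
                assert precision == 1.0 and recall == 1.0

    def test_protein_without_scored_prediction_drops_from_nv(self,
                                                             flat_graph):
        pred = {"p": {"a": 0.9}}          # q has no prediction at all
        ref = {"p": {"a"}, "q": {"b"}}
        curve = cafa_pr(pred, ref, flat_graph, thresholds=[0.5])
        v, precision, recall, n_v = curve.points[0]
        assert n_v == 1
        assert precision == 1.0           # averaged over n_v only
        assert recall == pytest.approx(0.5)  # averaged over |D| = 2

    def test_empty_reference_errors(self, flat_graph):
        with pytest.raises(AssessmentError):
            cafa_pr({}, {}, flat_graph)


def brute_force_pr(pred, ref, graph, relaxed=False):
    """Independent threshold-enumeration oracle for both PR variants."""
    thresholds = sorted({c for s in pred.values() for c in s.values()}
                       | {0.0, 1.0})
    proteins = sorted(s for s, terms in ref.items() if terms)
    points = []
    for v in thresholds:
        precisions, n_v, recall_sum = [], 0, 0.0
        for s in proteins:
            p_sv = {t for t, c in pred.get(s, {}).items() if c >= v}
            a_s = ref[s]
            if not p_sv:
                continue
            n_v += 1
            if relaxed:
                def hits(p, a):
                    return (p == a or p in graph.ancestors(a, {IS_A})
                            or p in graph.descendants(a, {IS_A}))
                tp = sum(1 for p in p_sv if any(hits(p, a) for a in a_s))
                matched = sum(1 for a in a_s
                              if any(hits(p, a) for p in p_sv))
                precisions.append(tp / len(p_sv))
                recall_sum += matched / len(a_s)
            else:
                tp = len(p_sv & a_s)
                precisions.append(tp / len(p_sv))
                recall_sum += tp / len(a_s)
        precision = sum(precisions) / n_v if n_v else 0.0
        recall = recall_sum / len(proteins)
        points.append((v, precision, recall))
    fmax = max((2 * p * r / (p + r) for _, p, r in points if p + r > 0),
               default=0.0)
    return points, fmax


class TestRelaxedPR:
    def test_parent_prediction_counts(self, two_branch_graph):
        pred = {"p": {"u": 0.9}}          # parent of the sole reference
        ref = {"p": {"u1"}}
        curve = relaxed_pr(pred, ref, two_branch_graph, thresholds=[0.9])
        _, precision, recall, _ = curve.points[0]
        assert precision == 1.0 and recall == 1.0

    def test_disjoint_branch_is_false_positive(self, two_branch_graph):
        pred = {"p": {"v1": 0.9}}
        ref = {"p": {"u1"}}
        curve = relaxed_pr(pred, ref, two_branch_graph, thresholds=[0.5])
        _, precision, recall, _ = curve.points[0]
        assert precision == 0.0 and recall == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        graph = random_dag(12, seed, p_part_of=0.0)
        rng = np.random.default_rng(seed + 100)
        ids = sorted(graph.terms)
        pred, ref = {}, {}
        for s in range(4):
            name = f"p{s}"
            pred[name] = {ids[int(i)]: round(float(rng.random()), 2)
                          for i in rng.integers(1, len(ids), 3)}
            ref[name] = {ids[int(i)]
                         for i in rng.integers(1, len(ids), 2)}
        for relaxed in (False, True):
            fn = relaxed_pr if relaxed else cafa_pr
            curve = fn(pred, ref, graph)
            expected_points, expected_fmax = brute_force_pr(
                pred, ref, graph, relaxed=relaxed)
            got = {v: (p, r) for v, p, r, _ in curve.points}
            for v, p, r in expected_points:
                assert got[v] == (pytest.approx(p), pytest.approx(r))
            assert curve.fmax == pytest.approx(expected_fmax)

    def test_relaxed_tp_never_below_exact(self, seed=3):
        graph = random_dag(10, seed, p_part_of=0.0)
        rng = np.random.default_rng(seed)
        ids = sorted(graph.terms)
        pred = {"p": {ids[int(i)]: float(rng.random())
                      for i in rng.integers(1, len(ids), 4)}}
        ref = {"p": {ids[int(i)] for i in rng.integers(1, len(ids), 3)}}
        for v in [0.0, 0.25, 0.5, 0.75, 1.0]:
            exact = cafa_pr(pred, ref, graph, thresholds=[v]).points[0]
            relaxed = relaxed_pr(pred, ref, graph, thresholds=[v]).points[0]
            assert relaxed[1] >= exact[1] - 1e-12   # precision
            assert relaxed[2] >= exact[2] - 1e-12   # recall


class TestSimgic:
    @pytest.fixture
    def ic(self):
        return ICTable(ic={"R": 0.0, "x": 1.0, "y": 2.0, "z": 3.0,
                           "w": math.inf}, corpus_size=10)

    def test_identical_sets(self, ic):
        assert simgic({"R", "x", "y"}, {"R", "x", "y"}, ic) == 1.0

    def test_root_only_overlap(self, ic):
        assert simgic({"R", "x"}, {"R", "y"}, ic) == 0.0

    def test_hand_summed_ratio(self, ic):
        # intersection {x}: mass 1; union {x, y}: mass 3
        assert simgic({"R", "x", "y"}, {"R", "x"}, ic) == \
            pytest.approx(1 / 3)

    def test_symmetry_and_range(self, ic):
        import itertools
        terms = ["R", "x", "y", "z"]
        for a_size, p_size in itertools.product(range(4), repeat=2):
            a, p = set(terms[:a_size]), set(terms[-p_size:] if p_size else [])
            assert simgic(a, p, ic) == simgic(p, a, ic)
            assert 0.0 <= simgic(a, p, ic) <= 1.0

    def test_infinite_ic_excluded(self, ic):
        assert simgic({"x", "w"}, {"x", "w"}, ic) == 1.0

    def test_adding_shared_term_is_monotone(self, ic):
        base = simgic({"x"}, {"x", "y"}, ic)
        richer = simgic({"x", "z"}, {"x", "y", "z"}, ic)
        assert richer > base


class TestCogic:
    @pytest.fixture
    def setup(self, two_branch_graph):
        ic = ICTable(ic={"R": 0.0, "u": 1.0, "u1": 2.0, "u2": 2.0,
                         "v": 1.0, "v1": 2.0}, corpus_size=10)
        return two_branch_graph, ic

    def test_perfect_confident_prediction_scores_one(self, setup):
        graph, ic = setup
        row = cogic({"u1": 0.8, "u2": 0.8}, {"u1", "u2"}, ic, graph)
        assert row["cogic"] == 1.0
        assert all(row[f"S{i}"] == 1.0 for i in range(1, 5))

    def test_root_only_overlap_scores_zero(self, setup):
        graph, ic = setup
        row = cogic({"v1": 0.9}, {"u1"}, ic, graph)
        assert row["cogic"] == 0.0

    def test_weighted_combination_arithmetic(self, setup):
        graph, ic = setup
        pred = {"u1": 0.9, "v1": 0.3}   # v1 wrong, enters S3/S4 only
        ref = {"u1"}
        row = cogic(pred, ref, ic, graph)
        s_hi = simgic({"u1", "u", "R"}, {"u1", "u", "R"}, ic)
        s_lo = simgic({"u1", "u", "R"}, {"u1", "u", "v1", "v", "R"}, ic)
        weights = (8 / 15, 4 / 15, 2 / 15, 1 / 15)
        expected = (weights[0] * s_hi + weights[1] * s_hi
                    + weights[2] * s_lo + weights[3] * s_lo)
        assert row["S1"] == s_hi and row["S3"] == s_lo
        assert row["cogic"] == pytest.approx(expected / sum(weights))

    def test_low_confidence_correct_prediction_scores_below_one(self, setup):
        graph, ic = setup
        row = cogic({"u1": 0.3}, {"u1"}, ic, graph)
        assert row["S1"] == 0.0 and row["S4"] == 1.0
        assert 0.0 < row["cogic"] < 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_boundary_contracts_for_random_weights(self, setup, seed):
        graph, ic = setup
        rng = np.random.default_rng(seed)
        raw = np.sort(rng.random(4))[::-1] + np.array([4.0, 3.0, 2.0, 1.0])
        weights = tuple(raw / raw.sum())
        perfect = cogic({"u1": 0.8}, {"u1"}, ic, graph, weights=weights)
        disjoint = cogic({"v1": 0.8}, {"u1"}, ic, graph, weights=weights)
        assert perfect["cogic"] == pytest.approx(1.0)
        assert disjoint["cogic"] == 0.0

    def test_invalid_weights_rejected(self, setup):
        graph, ic = setup
        with pytest.raises(AssessmentError):
            cogic({}, {"u1"}, ic, graph, weights=(0.25, 0.25, 0.25, 0.25))
        with pytest.raises(AssessmentError):
            cogic({}, {"u1"}, ic, graph, weights=(0.8, 0.4, 0.2, 0.1))


class TestSummarize:
    def test_three_values(self):
        assert summarize_cogic([0.0, 0.5, 1.0])["median"] == 0.5

    def test_single_row(self):
        assert summarize_cogic([0.37])["median"] == 0.37

    def test_lower_interpolation_against_sort_oracle(self):
        rng = np.random.default_rng(1)
        values = rng.random(100).tolist()
        ordered = sorted(values)
        summary = summarize_cogic(values)
        # lower interpolation picks an element at or below the midpoint
        assert summary["median"] in ordered
        assert summary["q1"] in ordered and summary["q3"] in ordered
        assert summary["q1"] <= summary["median"] <= summary["q3"]

    def test_empty_errors(self):
        with pytest.raises(AssessmentError):
            summarize_cogic([])


class TestFileFormats:
    def test_prediction_and_reference_round_trip(self, tmp_path,
                                                 two_branch_graph):
        pred_path = tmp_path / "pred.tsv"
        pred_path.write_text("p\tu1\t0.9\np\tv1\t0.2\nq\tu2\t0.7\n")
        ref_path = tmp_path / "ref.gaf"
        ref_path.write_text("p\tu1\tIDA\np\tv1\tIEA\nq\tu2\tIMP\n")
        pred = load_predictions(pred_path)
        ref = load_reference(ref_path)
        assert pred["p"] == {"u1": 0.9, "v1": 0.2}
        assert ref == {"p": {"u1"}, "q": {"u2"}}   # IEA filtered out

    def test_out_of_range_confidence_rejected(self, tmp_path):
        path = tmp_path / "pred.tsv"
        path.write_text("p\tu1\t1.5\n")
        with pytest.raises(AssessmentError):
            load_predictions(path)

    def test_evaluate_cogic_report(self, two_branch_graph):
        ic = information_content(
            two_branch_graph,
            [("p1", "u1", "IDA"), ("p2", "u2", "IDA"), ("p3", "v1", "IDA")])
        pred = {"p1": {"u1": 0.8}, "p3": {"u1": 0.8}}
        ref = {"p1": {"u1"}, "p3": {"v1"}}
        report = evaluate_cogic(pred, ref, ic, two_branch_graph)
        rows = dict(zip(report.rows["protein"], report.rows["cogic"]))
        assert rows["p1"] == 1.0
        assert rows["p3"] == 0.0
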