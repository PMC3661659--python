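"""Scoring prediction sets against reference annotations.

Four complementary measures of function-prediction accuracy:

* CAFA-style precision-recall and Fmax: predicted and reference term
  sets are propagated to their ``is_a`` ancestors (roots excluded,
  ancestors inherit the maximum confidence of their descendants); at
  each confidence threshold v, per-protein precision is averaged over
  the proteins with at least one prediction scored >= v, per-protein
  recall over the whole evaluation set; Fmax is the best harmonic mean
  over thresholds.
* Relaxed precision-recall: no propagation; a predicted term counts as
  correct when it equals, or is an ancestor or descendant of, a
  reference annotation.  This credits correct-but-generic and
  compatible-but-specific predictions alike.
* simGIC: the information-content-weighted Jaccard similarity of two
  propagated term sets.
* COGIC: a convex combination of simGIC scores computed at four
  confidence strata (>= 0.75, 0.50, 0.25, 0), in [0, 1], rewarding
  confident correct predictions.  It is 1 iff every predicted term is
  validated with confidence >= 0.75 (after propagation), and 0 iff the
  root is the only shared term.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ontology import ASSESSMENT_RELATIONS, ICTable, OntologyGraph

logger = logging.getLogger(__name__)

#: Evidence codes accepted for reference annotations in COGIC scoring
#: (experimental, non-homology-based).
COGIC_EVIDENCE_CODES = frozenset({"IEP", "IPI", "IMP", "IGC", "IGI", "IDA"})

#: Confidence strata defining the four COGIC prediction subsets.
COGIC_STRATA = (0.75, 0.50, 0.25, 0.0)

#: Default stratum weights: positive, strictly decreasing, summing to 1,
#: so that higher-confidence strata earn more credit.  Configurable.
COGIC_WEIGHTS = (8 / 15, 4 / 15, 2 / 15, 1 / 15)

#: protein -> {term: confidence}
PredictionSet = dict[str, dict[str, float]]
#: protein -> {validated terms}
ReferenceSet = dict[str, set[str]]


class AssessmentError(ValueError):
    """Raised for empty evaluation sets and malformed inputs."""


# -- propagation --------------------------------------------------------------

def _term_ancestors(graph: OntologyGraph, term: str,
                    relations: frozenset[str]) -> set[str]:
    if term not in graph:
        mapped = graph.map_obsolete(term)
        if mapped is None:
            return set()
        term = mapped
    return {term} | graph.ancestors(term, relations)


def propagate_predictions(pred: PredictionSet, graph: OntologyGraph,
                          relations: Iterable[str] = ASSESSMENT_RELATIONS,
                          ) -> PredictionSet:
    """Add ancestors with the maximum confidence of their descendants.

    Root terms are excluded; terms missing from the graph are resolved
    through the obsolete-term map or dropped.  Idempotent.
    """
    relations = frozenset(relations)
    out: PredictionSet = {}
    for protein, scored in pred.items():
        bag: dict[str, float] = {}
        for term, conf in scored.items():
            for t in _term_ancestors(graph, term, relations):
                if graph.is_root(t):
                    continue
                bag[t] = max(bag.get(t, 0.0), float(conf))
        out[protein] = bag
    return out


def propagate_reference(ref: ReferenceSet, graph: OntologyGraph,
                        relations: Iterable[str] = ASSESSMENT_RELATIONS,
                        ) -> ReferenceSet:
    relations = frozenset(relations)
    out: ReferenceSet = {}
    for protein, terms in ref.items():
        bag: set[str] = set()
        for term in terms:
            bag |= {t for t in _term_ancestors(graph, term, relations)
                    if not graph.is_root(t)}
        out[protein] = bag
    return out


# -- precision-recall ---------------------------------------------------------

@dataclass
class PRCurve:
    """Precision-recall points over confidence thresholds, plus Fmax."""

    points: list[tuple[float, float, float, int]]  # (v, precision, recall, n_v)
    fmax: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points,
                            columns=["threshold", "precision", "recall",
                                     "n_proteins"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump({"fmax": self.fmax,
                       "points": [list(p) for p in self.points]}, handle)


def _thresholds(pred: PredictionSet,
                thresholds: Sequence[float] | None) -> list[float]:
    if thresholds is not None:
        return sorted(set(float(v) for v in thresholds))
    values = {0.0, 1.0}
    for scored in pred.values():
        values.update(float(c) for c in scored.values())
    return sorted(values)


def _curve_from_counts(point_stats: list[tuple[float, float, float, int]]
                       ) -> PRCurve:
    fmax = 0.0
    for _, precision, recall, _ in point_stats:
        if precision + recall > 0:
            fmax = max(fmax, 2 * precision * recall / (precision + recall))
    return PRCurve(points=point_stats, fmax=fmax)


def cafa_pr(pred: PredictionSet, ref: ReferenceSet, graph: OntologyGraph,
            thresholds: Sequence[float] | None = None) -> PRCurve:
    """CAFA-style precision-recall over already-propagated inputs.

    At threshold v, a protein's true positives are its predictions
    scored >= v that occur among its reference terms.  Overall
    precision averages per-protein precision over the n_v proteins with
    >= 1 prediction scored >= v; overall recall averages per-protein
    recall over the full evaluation set D (proteins with reference
    annotations).  Fmax maximises F over thresholds.
    """
    proteins = [s for s, terms in ref.items() if terms]
    if not proteins:
        raise AssessmentError("empty reference set")
    points = []
    for v in _thresholds(pred, thresholds):
        pr_sum, rc_sum, n_v = 0.0, 0.0, 0
        for s in proteins:
            a_s = ref[s]
            scored = pred.get(s, {})
            p_sv = {t for t, c in scored.items() if c >= v}
            if p_sv:
                n_v += 1
                tp = len(p_sv & a_s)
                pr_sum += tp / len(p_sv)
                rc_sum += tp / len(a_s)
        precision = pr_sum / n_v if n_v else 0.0
        recall = rc_sum / len(proteins)
        points.append((v, precision, recall, n_v))
    return _curve_from_counts(points)


def evaluate_cafa(pred: PredictionSet, ref: ReferenceSet,
                  graph: OntologyGraph,
                  thresholds: Sequence[float] | None = None) -> PRCurve:
    """Propagate both sides (is_a, roots excluded) and run :func:`cafa_pr`."""
    return cafa_pr(propagate_predictions(pred, graph),
                   propagate_reference(ref, graph), graph, thresholds)


def relaxed_pr(pred: PredictionSet, ref: ReferenceSet, graph: OntologyGraph,
               thresholds: Sequence[float] | None = None,
               relations: Iterable[str] = ASSESSMENT_RELATIONS) -> PRCurve:
    """Ancestor/descendant-relaxed precision-recall, without propagation.

    A predicted term scored >= v is a true positive when it equals, or
    is an ancestor or a descendant of, some reference annotation; a
    reference term is a false negative when no prediction scored >= v
    equals it or lies on its ancestor/descendant line.  Aggregation
    matches :func:`cafa_pr`.
    """
    relations = frozenset(relations)
    proteins = [s for s, terms in ref.items() if terms]
    if not proteins:
        raise AssessmentError("empty reference set")

    def related(term: str) -> set[str]:
        if term not in graph:
            return {term}
        return ({term} | graph.ancestors(term, relations)
                | graph.descendants(term, relations))

    related_cache: dict[str, set[str]] = {}

    def rel(term: str) -> set[str]:
        if term not in related_cache:
            related_cache[term] = related(term)
        return related_cache[term]

    points = []
    for v in _thresholds(pred, thresholds):
        pr_sum, rc_sum, n_v = 0.0, 0.0, 0
        for s in proteins:
            a_s = ref[s]
            scored = pred.get(s, {})
            p_sv = {t for t, c in scored.items() if c >= v}
            if p_sv:
                n_v += 1
                tp = sum(1 for p in p_sv if rel(p) & a_s)
                matched_refs = sum(1 for a in a_s
                                   if any(p in rel(a) for p in p_sv))
                pr_sum += tp / len(p_sv)
                rc_sum += matched_refs / len(a_s)
        precision = pr_sum / n_v if n_v else 0.0
        recall = rc_sum / len(proteins)
        points.append((v, precision, recall, n_v))
    return _curve_from_counts(points)


# -- simGIC and COGIC ---------------------------------------------------------

def simgic(a_terms: Iterable[str], p_terms: Iterable[str],
           ic: ICTable) -> float:
    """IC-weighted Jaccard similarity of two propagated term sets.

    Terms with infinite IC (never observed in the corpus) are excluded
    from both sums; terms missing from the table contribute 0 and are
    logged.  Returns 0 when the union carries no IC mass.
    """
    a_set, p_set = set(a_terms), set(p_terms)

    def mass(terms: set[str]) -> float:
        total = 0.0
        for t in terms:
            if t not in ic:
                logger.debug("simgic: term %s missing from IC table", t)
                continue
            value = ic.get(t)
            if math.isfinite(value):
                total += value
        return total

    union_mass = mass(a_set | p_set)
    if union_mass <= 0.0:
        return 0.0
    return mass(a_set & p_set) / union_mass


def _propagate_with_roots(terms: Iterable[str], graph: OntologyGraph,
                          relations: frozenset[str]) -> set[str]:
    bag: set[str] = set()
    for term in terms:
        bag |= _term_ancestors(graph, term, relations)
    return bag


def cogic(pred_s: Mapping[str, float], a_s: Iterable[str],
          ic: ICTable, graph: OntologyGraph,
          strata: Sequence[float] = COGIC_STRATA,
          weights: Sequence[float] = COGIC_WEIGHTS,
          relations: Iterable[str] = ASSESSMENT_RELATIONS,
          ) -> dict[str, float]:
    """COGIC score for one protein.

    P_1..P_4 are the predicted terms with confidence >= the strata
    thresholds; ancestors (roots included, IC 0) are added to each P_i
    and to the reference set A; S_i = simGIC(A, P_i); the score is the
    weighted sum of the S_i.  Weights must be positive, strictly
    decreasing and sum to 1.
    """
    weights = tuple(float(w) for w in weights)
    if len(weights) != len(strata):
        raise AssessmentError("one weight per stratum required")
    if any(w <= 0 for w in weights) or not math.isclose(sum(weights), 1.0):
        raise AssessmentError("weights must be positive and sum to 1")
    if any(weights[i] <= weights[i + 1] for i in range(len(weights) - 1)):
        raise AssessmentError("weights must be strictly decreasing")
    relations = frozenset(relations)
    a_prop = _propagate_with_roots(a_s, graph, relations)
    row: dict[str, float] = {}
    score = 0.0
    for i, (threshold, weight) in enumerate(zip(strata, weights), start=1):
        p_i = [t for t, c in pred_s.items() if c >= threshold]
        p_prop = _propagate_with_roots(p_i, graph, relations)
        s_i = simgic(a_prop, p_prop, ic)
        row[f"S{i}"] = s_i
        score += weight * s_i
    # normalising by the weight sum keeps the boundary identities exact
    # in floating point (all S_i = 1 -> exactly 1; all 0 -> exactly 0)
    row["cogic"] = score / sum(weights)
    return row


@dataclass
class CogicReport:
    """Per-protein COGIC rows plus distribution summary."""

    rows: pd.DataFrame          # protein, S1..S4, cogic

    def summary(self) -> dict[str, float]:
        return summarize_cogic(self.rows["cogic"].tolist())

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def evaluate_cogic(pred: PredictionSet, ref: ReferenceSet,
                   ic: ICTable, graph: OntologyGraph,
                   strata: Sequence[float] = COGIC_STRATA,
                   weights: Sequence[float] = COGIC_WEIGHTS) -> CogicReport:
    """COGIC rows for every reference protein (missing predictions = {})."""
    proteins = sorted(s for s, terms in ref.items() if terms)
    if not proteins:
        raise AssessmentError("empty reference set")
    records = []
    for s in proteins:
        row = cogic(pred.get(s, {}), ref[s], ic, graph, strata, weights)
        records.append({"protein": s, **row})
    return CogicReport(rows=pd.DataFrame(records))


def summarize_cogic(values: Sequence[float]) -> dict[str, float]:
    """Median and quartiles with the lower-interpolation convention."""
    if len(values) == 0:
        raise AssessmentError("no COGIC rows to summarise")
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="lower")
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}


# -- file formats -------------------------------------------------------------

def load_predictions(path) -> PredictionSet:
    """Read a 3-column TSV: protein, term, confidence."""
    frame = pd.read_csv(path, sep="\t",
                        names=["protein", "term", "confidence"],
                        header=None, comment="!")
    if len(frame) and frame.iloc[0]["protein"] == "protein":
        frame = frame.iloc[1:]
    out: PredictionSet = {}
    for _, row in frame.iterrows():
        conf = float(row["confidence"])
        if not 0.0 <= conf <= 1.0:
            raise AssessmentError(
                f"confidence {conf} out of [0,1] for {row['protein']}")
        out.setdefault(str(row["protein"]), {})[str(row["term"])] = conf
    return out


def load_reference(path,
                   evidence_filter: Iterable[str] = COGIC_EVIDENCE_CODES,
                   ) -> ReferenceSet:
    """Read a GAF-style TSV into a reference set, filtered by evidence."""
    from .corpus import _parse_gaf_line
    allowed = set(evidence_filter) if evidence_filter is not None else None
    out: ReferenceSet = {}
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("!"):
                continue
            parsed = _parse_gaf_line(line)
            if parsed is None:
                continue
            accession, term, evidence, qualifier = parsed
            if "NOT" in qualifier.split("|"):
                continue
            if allowed is not None and evidence not in allowed:
                continue
            out.setdefault(accession, set()).add(term)
    return out
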