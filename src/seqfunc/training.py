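"""Per-term SVM model selection, holdout evaluation and calibration.

For each GO term the training procedure selects, simultaneously, a
kernel (linear or RBF), its hyper-parameters, and the list of useful
feature groups, by maximising the Matthews correlation coefficient
(MCC) under homology-aware k-fold cross-validation:

1. an exhaustive grid search over kernel type and parameters with all
   feature groups included;
2. a single backward pass over the groups in registry order, dropping a
   group only when re-running the full grid without it *strictly*
   improves the best cross-validated MCC;
3. training on all k folds pooled and evaluation on the untouched 30%
   holdout — the term is discarded when the holdout MCC falls below
   0.05, and labelled high-reliability (H) when MCC, sensitivity,
   specificity and precision exceed 0.3, 0.3, 0.7 and 0.3;
4. a final refit on every example (holdout included), re-partitioned
   into k groups, with kernel parameters re-optimised at fixed kernel
   type and feature list; the sigmoid of Platt's method is fitted to
   the *cross-validated* decision values of this final run so that the
   posterior estimate is not biased by resubstitution.

Class imbalance is compensated by weighting errors on positives by the
negative/positive ratio of the training fold (SVM-Light's ``j`` rule).

The public entry point follows the Model/Results convention:
:class:`TermClassifier` holds the data and configuration, ``fit()``
returns a :class:`TermClassifierResults` carrying the selected model,
its holdout metrics, reliability tier and a ``summary()`` table.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, NamedTuple, Sequence

import numpy as np
from scipy.special import expit
from sklearn.svm import SVC

from .corpus import TermTrainingSet
from .features import FeatureMatrix, fit_scaling
from .partition import (DEFAULT_HOLDOUT_FRACTION, DEFAULT_MIN_GROUP_SIZE,
                        DistanceMatrix, PartitionPlan, balanced_kmedoids,
                        plan_pair)

logger = logging.getLogger(__name__)

DEFAULT_DISCARD_MCC = 0.05
#: (MCC, sensitivity, specificity, precision) floors for the H tier.
DEFAULT_RELIABILITY_THRESHOLDS = (0.3, 0.3, 0.7, 0.3)


class TrainingError(ValueError):
    """Raised for invalid training inputs."""


# -- confusion counts and metrics ---------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)

    @classmethod
    def from_predictions(cls, y_true: np.ndarray,
                         y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true) > 0
        y_pred = np.asarray(y_pred) > 0
        return cls(tp=int((y_true & y_pred).sum()),
                   fp=int((~y_true & y_pred).sum()),
                   tn=int((~y_true & ~y_pred).sum()),
                   fn=int((y_true & ~y_pred).sum()))


class Metrics(NamedTuple):
    mcc: float
    sensitivity: float
    specificity: float
    precision: float


def confusion_metrics(c: ConfusionCounts) -> Metrics:
    """MCC, sensitivity (recall), specificity and precision.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), defined
    as 0 when any factor of the denominator vanishes; 0/0 ratios are
    reported as 0.
    """
    if c.total == 0:
        raise TrainingError("empty confusion table")
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else 0.0

    denom = ((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    return Metrics(mcc=mcc,
                   sensitivity=ratio(tp, tp + fn),
                   specificity=ratio(tn, tn + fp),
                   precision=ratio(tp, tp + fp))


# -- kernels and grids --------------------------------------------------------

@dataclass(frozen=True)
class KernelSpec:
    kind: str                   # 'linear' | 'rbf'
    C: float
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "rbf"):
            raise TrainingError(f"unknown kernel kind {self.kind!r}")
        if self.C <= 0:
            raise TrainingError("C must be positive")
        if self.kind == "rbf" and (self.gamma is None or self.gamma <= 0):
            raise TrainingError("rbf kernel needs a positive gamma")
        if self.kind == "linear" and self.gamma is not None:
            raise TrainingError("linear kernel takes no gamma")


@dataclass(frozen=True)
class GridSpec:
    """Exhaustive kernel/hyper-parameter grid.

    Iteration order encodes the tie-break rule: linear before RBF, then
    ascending C, then ascending gamma.
    """

    c_values: tuple[float, ...] = tuple(float(2.0 ** e)
                                        for e in range(-5, 8, 2))
    gamma_values: tuple[float, ...] = tuple(float(2.0 ** e)
                                            for e in range(-9, 2, 2))
    kinds: tuple[str, ...] = ("linear", "rbf")

    def specs(self) -> list[KernelSpec]:
        out: list[KernelSpec] = []
        if "linear" in self.kinds:
            out += [KernelSpec("linear", c) for c in sorted(self.c_values)]
        if "rbf" in self.kinds:
            out += [KernelSpec("rbf", c, g)
                    for c in sorted(self.c_values)
                    for g in sorted(self.gamma_values)]
        if not out:
            raise TrainingError("empty grid")
        return out

    def restrict(self, kind: str) -> "GridSpec":
        return replace(self, kinds=(kind,))


# -- classifier backend -------------------------------------------------------

#: Backend contract: fit weighted examples with a kernel, return an
#: object exposing ``decision_function(X) -> ndarray``.  Any binary
#: large-margin implementation with per-class error weighting fits.
ClassifierBackend = Callable[[np.ndarray, np.ndarray, KernelSpec, float],
                             object]


def svc_backend(x: np.ndarray, y: np.ndarray, kernel: KernelSpec,
                pos_weight: float) -> SVC:
    clf = SVC(C=kernel.C,
              kernel=kernel.kind,
              gamma=kernel.gamma if kernel.kind == "rbf" else "scale",
              class_weight={1: pos_weight, -1: 1.0},
              shrinking=True)
    clf.fit(x, y)
    return clf


# -- cross-validation ---------------------------------------------------------

@dataclass
class CVResult:
    fold_counts: list[ConfusionCounts]
    pooled: ConfusionCounts
    mcc: float
    sensitivity: float
    specificity: float
    precision: float
    #: cross-validated decision value per test accession
    decision_values: dict[str, float] = field(default_factory=dict)
    labels: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_folds(cls, fold_counts: list[ConfusionCounts],
                   decision_values: dict[str, float],
                   labels: dict[str, int]) -> "CVResult":
        pooled = sum(fold_counts, ConfusionCounts())
        m = confusion_metrics(pooled)
        return cls(fold_counts=fold_counts, pooled=pooled, mcc=m.mcc,
                   sensitivity=m.sensitivity, specificity=m.specificity,
                   precision=m.precision, decision_values=decision_values,
                   labels=labels)


def _fold_arrays(matrix: FeatureMatrix, pos_accs: Sequence[str],
                 neg_accs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    x = np.vstack([matrix.rows(pos_accs), matrix.rows(neg_accs)])
    y = np.concatenate([np.ones(len(pos_accs)), -np.ones(len(neg_accs))])
    return x, y


def cross_validate(matrix: FeatureMatrix,
                   pos_plan: PartitionPlan,
                   neg_plan: PartitionPlan,
                   kernel: KernelSpec,
                   retained_groups: Iterable[str] | None = None,
                   backend: ClassifierBackend = svc_backend) -> CVResult:
    """k-fold cross-validation over homology-clustered groups.

    Fold *i* trains on every group except *i* (positives and negatives)
    and tests on group *i*.  Feature scaling is fitted on the training
    fold only; errors on positives are weighted by the fold's
    negative/positive ratio.  The reported metrics come from the fold
    confusion counts pooled across folds.
    """
    if pos_plan.k != neg_plan.k:
        raise TrainingError("positive and negative plans must share k")
    if retained_groups is not None:
        matrix = matrix.select_groups(retained_groups)
    k = pos_plan.k
    fold_counts: list[ConfusionCounts] = []
    decisions: dict[str, float] = {}
    labels: dict[str, int] = {}
    for i in range(k):
        train_pos = sorted(a for j in range(k) if j != i
                           for a in pos_plan.groups[j])
        train_neg = sorted(a for j in range(k) if j != i
                           for a in neg_plan.groups[j])
        test_pos = sorted(pos_plan.groups[i])
        test_neg = sorted(neg_plan.groups[i])
        if k == 1:
            # degenerate path: no held-out fold; train == test
            train_pos, train_neg = test_pos, test_neg
        if not test_pos:
            logger.info("fold %d has no test positives; pooled counts "
                        "carry the information", i)
        x_train, y_train = _fold_arrays(matrix, train_pos, train_neg)
        scaler = fit_scaling(x_train)
        pos_weight = len(train_neg) / max(len(train_pos), 1)
        clf = backend(scaler.apply(x_train), y_train, kernel, pos_weight)
        x_test, y_test = _fold_arrays(matrix, test_pos, test_neg)
        f = np.asarray(clf.decision_function(scaler.apply(x_test)),
                       dtype=float)
        fold_counts.append(ConfusionCounts.from_predictions(y_test, f > 0))
        for acc, val, lab in zip(test_pos + test_neg, f, y_test):
            decisions[acc] = float(val)
            labels[acc] = int(lab)
    return CVResult.from_folds(fold_counts, decisions, labels)


def grid_search(matrix: FeatureMatrix,
                pos_plan: PartitionPlan,
                neg_plan: PartitionPlan,
                grid: GridSpec,
                retained_groups: Iterable[str] | None = None,
                backend: ClassifierBackend = svc_backend,
                ) -> tuple[KernelSpec, CVResult]:
    """Evaluate every grid configuration; return the MCC maximiser.

    Ties resolve to the earliest configuration in grid order (linear
    before RBF, then smaller C, then smaller gamma).
    """
    if retained_groups is not None:
        matrix = matrix.select_groups(retained_groups)
    best: tuple[KernelSpec, CVResult] | None = None
    for spec in grid.specs():
        cv = cross_validate(matrix, pos_plan, neg_plan, spec,
                            backend=backend)
        if best is None or cv.mcc > best[1].mcc:
            best = (spec, cv)
    assert best is not None
    return best


def greedy_group_elimination(matrix: FeatureMatrix,
                             pos_plan: PartitionPlan,
                             neg_plan: PartitionPlan,
                             grid: GridSpec,
                             registry_order: Sequence[str] | None = None,
                             backend: ClassifierBackend = svc_backend,
                             ) -> tuple[list[str], KernelSpec, CVResult]:
    """Single backward pass over feature groups in registry order.

    A group stays removed only when the best grid MCC strictly improves
    without it; otherwise it is restored.  The last remaining group is
    never removed.  The returned MCC is therefore never below the
    all-groups baseline.
    """
    if registry_order is None:
        registry_order = matrix.group_names()
    retained = list(registry_order)
    if not retained:
        raise TrainingError("registry must contain at least one group")
    best_spec, best_cv = grid_search(matrix, pos_plan, neg_plan, grid,
                                     retained, backend=backend)
    for group in registry_order:
        if len(retained) == 1:
            break
        candidate = [g for g in retained if g != group]
        spec, cv = grid_search(matrix, pos_plan, neg_plan, grid,
                               candidate, backend=backend)
        if cv.mcc > best_cv.mcc:
            retained = candidate
            best_spec, best_cv = spec, cv
            logger.info("eliminated group %r (cv mcc %.3f)", group, cv.mcc)
    return retained, best_spec, best_cv


# -- holdout evaluation -------------------------------------------------------

def reliability_tier(metrics: Metrics,
                     thresholds: Sequence[float]
                     = DEFAULT_RELIABILITY_THRESHOLDS) -> str:
    """H when MCC, sensitivity, specificity and precision all exceed
    their thresholds (strictly), else L."""
    t_mcc, t_sens, t_spec, t_prec = thresholds
    high = (metrics.mcc > t_mcc and metrics.sensitivity > t_sens
            and metrics.specificity > t_spec and metrics.precision > t_prec)
    return "H" if high else "L"


@dataclass
class HoldoutOutcome:
    metrics: Metrics
    discarded: bool
    reliability: str            # 'H' | 'L'
    counts: ConfusionCounts


def holdout_evaluate(matrix: FeatureMatrix,
                     pos_plan: PartitionPlan,
                     neg_plan: PartitionPlan,
                     kernel: KernelSpec,
                     retained_groups: Iterable[str],
                     discard_mcc: float = DEFAULT_DISCARD_MCC,
                     reliability_thresholds: Sequence[float]
                     = DEFAULT_RELIABILITY_THRESHOLDS,
                     backend: ClassifierBackend = svc_backend,
                     ) -> HoldoutOutcome:
    """Train on the k groups pooled; score on the 30% holdout.

    Discard when holdout MCC < ``discard_mcc``.  Reliability is H when
    MCC, sensitivity, specificity and precision all exceed their
    thresholds, else L.
    """
    if not pos_plan.holdout or not neg_plan.holdout:
        raise TrainingError("empty holdout")
    sub = matrix.select_groups(retained_groups)
    train_pos = pos_plan.training_accessions()
    train_neg = neg_plan.training_accessions()
    x_train, y_train = _fold_arrays(sub, train_pos, train_neg)
    scaler = fit_scaling(x_train)
    pos_weight = len(train_neg) / max(len(train_pos), 1)
    clf = backend(scaler.apply(x_train), y_train, kernel, pos_weight)
    x_test, y_test = _fold_arrays(sub, sorted(pos_plan.holdout),
                                  sorted(neg_plan.holdout))
    f = np.asarray(clf.decision_function(scaler.apply(x_test)), dtype=float)
    counts = ConfusionCounts.from_predictions(y_test, f > 0)
    metrics = confusion_metrics(counts)
    return HoldoutOutcome(metrics=metrics,
                          discarded=metrics.mcc < discard_mcc,
                          reliability=reliability_tier(
                              metrics, reliability_thresholds),
                          counts=counts)


# -- Platt calibration --------------------------------------------------------

@dataclass(frozen=True)
class PlattCalibration:
    """Sigmoid posterior P(y=+1 | f) = 1 / (1 + exp(A f + B)).

    A is negative whenever larger decision values indicate the positive
    class, making the posterior strictly increasing in f.
    """

    A: float
    B: float

    def posterior(self, f: np.ndarray | float) -> np.ndarray | float:
        return expit(-(self.A * np.asarray(f, dtype=float) + self.B))


def platt_fit(decision_values: Sequence[float],
              labels: Sequence[int],
              max_iter: int = 100,
              tol: float = 1e-5,
              sigma: float = 1e-12) -> PlattCalibration:
    """Fit the Platt sigmoid by damped Newton with backtracking.

    Maximises the regularised log-likelihood with the smoothed targets
    t+ = (N+ + 1)/(N+ + 2) and t- = 1/(N- + 2).  The decision values
    must be cross-validated, never resubstitution values, to avoid an
    optimistically steep sigmoid.
    """
    f = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels)
    if f.shape != y.shape or f.ndim != 1 or f.size == 0:
        raise TrainingError("decision values and labels must be equal-length"
                            " 1-d sequences")
    pos = y > 0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise TrainingError("both classes must be present for calibration")
    t = np.where(pos, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def objective(a: float, b: float) -> float:
        z = a * f + b
        return float(np.where(z >= 0,
                              t * z + np.log1p(np.exp(-z)),
                              (t - 1.0) * z + np.log1p(np.exp(z))).sum())

    a, b = 0.0, math.log((n_neg + 1.0) / (n_pos + 1.0))
    fval = objective(a, b)
    for _ in range(max_iter):
        z = a * f + b
        p = expit(-z)                         # P(y=1 | f)
        q = 1.0 - p
        d2 = p * q
        h11 = float((f * f * d2).sum()) + sigma
        h22 = float(d2.sum()) + sigma
        h21 = float((f * d2).sum())
        d1 = t - p
        g1 = float((f * d1).sum())
        g2 = float(d1.sum())
        if abs(g1) < tol and abs(g2) < tol:
            break
        det = h11 * h22 - h21 * h21
        da = -(h22 * g1 - h21 * g2) / det
        db = -(-h21 * g1 + h11 * g2) / det
        gd = g1 * da + g2 * db
        step = 1.0
        while step >= 1e-10:
            new_a, new_b = a + step * da, b + step * db
            new_f = objective(new_a, new_b)
            if new_f < fval + 1e-4 * step * gd:
                a, b, fval = new_a, new_b, new_f
                break
            step /= 2.0
        else:
            logger.warning("platt_fit: line search failed; stopping early")
            break
    return PlattCalibration(A=a, B=b)


# -- the trained per-term artifact --------------------------------------------

@dataclass
class TermModel:
    """A trained, calibrated classifier for one GO term.

    The decision function is stored as plain arrays (support vectors,
    dual coefficients, intercept) so the whole library serialises to
    JSON and predictions need no fitted estimator object.
    The holdout metrics are the ones measured before the final refit:
    the refit uses every example, so its own accuracy can only be
    estimated by that earlier test.
    """

    term: str
    kernel: KernelSpec
    retained_groups: list[str]
    layout: list[tuple[str, int, int]]
    scaler_mins: np.ndarray
    scaler_maxs: np.ndarray
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    calibration: PlattCalibration
    holdout_metrics: Metrics
    reliability: str
    k: int = 1
    seed: int = 0
    name: str = ""
    namespace: str = ""

    def _scale(self, x: np.ndarray) -> np.ndarray:
        span = self.scaler_maxs - self.scaler_mins
        safe = np.where(span > 0, span, 1.0)
        scaled = np.where(span > 0, (x - self.scaler_mins) / safe, 0.0)
        return np.clip(scaled, 0.0, 1.0)

    def _raw_decision(self, x: np.ndarray) -> np.ndarray:
        if self.kernel.kind == "linear":
            w = self.dual_coef @ self.support_vectors
            return x @ w.ravel() + self.intercept
        sq = (np.square(x).sum(axis=1)[:, None]
              + np.square(self.support_vectors).sum(axis=1)[None, :]
              - 2.0 * x @ self.support_vectors.T)
        kmat = np.exp(-self.kernel.gamma * np.maximum(sq, 0.0))
        return kmat @ self.dual_coef.ravel() + self.intercept

    def decision_function(self, vector) -> float:
        """Decision value for a FeatureVector with a full-registry layout."""
        blocks = []
        for group in self.retained_groups:
            try:
                blocks.append(vector.group(group))
            except Exception as exc:
                raise TrainingError(
                    f"model {self.term!r}: feature vector lacks group "
                    f"{group!r}") from exc
        x = np.concatenate(blocks)[None, :]
        if x.shape[1] != self.scaler_mins.shape[0]:
            raise TrainingError(
                f"model {self.term!r}: layout mismatch "
                f"({x.shape[1]} != {self.scaler_mins.shape[0]} features)")
        return float(self._raw_decision(self._scale(x))[0])

    def posterior(self, vector) -> float:
        return float(self.calibration.posterior(self.decision_function(vector)))

    # -- JSON round trip -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "name": self.name,
            "namespace": self.namespace,
            "kernel": {"kind": self.kernel.kind, "C": self.kernel.C,
                       "gamma": self.kernel.gamma},
            "retained_groups": list(self.retained_groups),
            "layout": [list(e) for e in self.layout],
            "scaler_mins": self.scaler_mins.tolist(),
            "scaler_maxs": self.scaler_maxs.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "calibration": {"A": self.calibration.A, "B": self.calibration.B},
            "holdout_metrics": list(self.holdout_metrics),
            "reliability": self.reliability,
            "k": self.k,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "TermModel":
        kernel = KernelSpec(data["kernel"]["kind"], data["kernel"]["C"],
                            data["kernel"]["gamma"])
        return cls(
            term=data["term"],
            name=data.get("name", ""),
            namespace=data.get("namespace", ""),
            kernel=kernel,
            retained_groups=list(data["retained_groups"]),
            layout=[tuple(e) for e in data["layout"]],
            scaler_mins=np.asarray(data["scaler_mins"], dtype=float),
            scaler_maxs=np.asarray(data["scaler_maxs"], dtype=float),
            support_vectors=np.asarray(data["support_vectors"], dtype=float),
            dual_coef=np.asarray(data["dual_coef"], dtype=float),
            intercept=float(data["intercept"]),
            calibration=PlattCalibration(data["calibration"]["A"],
                                         data["calibration"]["B"]),
            holdout_metrics=Metrics(*data["holdout_metrics"]),
            reliability=data["reliability"],
            k=int(data.get("k", 1)),
            seed=int(data.get("seed", 0)),
        )


def finalize_model(tset: TermTrainingSet,
                   matrix: FeatureMatrix,
                   dist: DistanceMatrix,
                   retained_groups: Sequence[str],
                   kernel_kind: str,
                   grid: GridSpec,
                   k: int,
                   holdout_outcome: HoldoutOutcome,
                   seed: int = 0,
                   backend: ClassifierBackend = svc_backend,
                   term_name: str = "",
                   term_namespace: str = "") -> TermModel:
    """Refit on all examples and calibrate, per the final-training recipe.

    All positives and negatives (holdout included) are pooled and
    re-partitioned into k homology groups; kernel parameters are
    re-optimised by a grid search restricted to the selected kernel
    type and feature list; the final classifier is trained on
    everything.  The Platt sigmoid is fitted to the decision values
    from this final k-fold cross-validation.  Holdout metrics carry
    over unchanged from the earlier evaluation.
    """
    if holdout_outcome.discarded:
        raise TrainingError(f"term {tset.term!r} was discarded; no final "
                            "model is trained")
    sub = matrix.select_groups(retained_groups)
    pos = sorted(tset.positives)
    neg = sorted(tset.negatives)
    pos_groups = balanced_kmedoids(dist.submatrix(pos), k, seed)
    neg_groups = balanced_kmedoids(dist.submatrix(neg), k, seed + 1)
    pos_plan = PartitionPlan(set(), pos_groups, k, seed)
    neg_plan = PartitionPlan(set(), neg_groups, k, seed + 1)
    kernel, cv = grid_search(sub, pos_plan, neg_plan,
                             grid.restrict(kernel_kind), backend=backend)
    accs = sorted(cv.decision_values)
    calibration = platt_fit([cv.decision_values[a] for a in accs],
                            [cv.labels[a] for a in accs])

    x_all, y_all = _fold_arrays(sub, pos, neg)
    scaler = fit_scaling(x_all)
    pos_weight = len(neg) / max(len(pos), 1)
    clf = backend(scaler.apply(x_all), y_all, kernel, pos_weight)
    if not hasattr(clf, "support_vectors_"):
        raise TrainingError("backend result does not expose support arrays "
                            "needed for serialisation")
    return TermModel(
        term=tset.term,
        name=term_name,
        namespace=term_namespace,
        kernel=kernel,
        retained_groups=list(retained_groups),
        layout=list(sub.layout),
        scaler_mins=scaler.mins,
        scaler_maxs=scaler.maxs,
        support_vectors=np.asarray(clf.support_vectors_, dtype=float),
        dual_coef=np.asarray(clf.dual_coef_, dtype=float).ravel(),
        intercept=float(np.asarray(clf.intercept_).ravel()[0]),
        calibration=calibration,
        holdout_metrics=holdout_outcome.metrics,
        reliability=holdout_outcome.reliability,
        k=k,
        seed=seed,
    )


# -- Model / Results facade ---------------------------------------------------

def derive_seed(term: str, master_seed: int) -> int:
    """Stable per-term seed below 2^31."""
    return zlib.crc32(f"{term}:{master_seed}".encode()) & 0x7FFFFFFF


@dataclass
class TrainingConfig:
    holdout_fraction: float = DEFAULT_HOLDOUT_FRACTION
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE
    grid: GridSpec = field(default_factory=GridSpec)
    discard_mcc: float = DEFAULT_DISCARD_MCC
    reliability_thresholds: tuple[float, float, float, float] = \
        DEFAULT_RELIABILITY_THRESHOLDS


class TermClassifier:
    """Model object for one GO term's training problem.

    Parameters
    ----------
    training_set
        Positive/negative accessions for the term.
    features
        Full-registry feature matrix covering every accession.
    distances
        Homology distance matrix covering every accession.
    config
        Thresholds, holdout fraction and hyper-parameter grid.
    backend
        Binary large-margin classifier backend (default: SVC).
    """

    def __init__(self, training_set: TermTrainingSet,
                 features: FeatureMatrix,
                 distances: DistanceMatrix,
                 config: TrainingConfig | None = None,
                 backend: ClassifierBackend = svc_backend,
                 term_name: str = "",
                 term_namespace: str = "") -> None:
        self.training_set = training_set
        self.features = features
        self.distances = distances
        self.config = config or TrainingConfig()
        self.backend = backend
        self.term_name = term_name
        self.term_namespace = term_namespace

    def fit(self, master_seed: int = 0) -> "TermClassifierResults":
        cfg = self.config
        tset = self.training_set
        seed = derive_seed(tset.term, master_seed)
        pos_plan, neg_plan = plan_pair(
            sorted(tset.positives), sorted(tset.negatives), self.distances,
            fraction=cfg.holdout_fraction, min_size=cfg.min_group_size,
            seed=seed)
        retained, kernel, cv = greedy_group_elimination(
            self.features, pos_plan, neg_plan, cfg.grid,
            backend=self.backend)
        outcome = holdout_evaluate(
            self.features, pos_plan, neg_plan, kernel, retained,
            discard_mcc=cfg.discard_mcc,
            reliability_thresholds=cfg.reliability_thresholds,
            backend=self.backend)
        model = None
        if not outcome.discarded:
            model = finalize_model(
                tset, self.features, self.distances, retained, kernel.kind,
                cfg.grid, pos_plan.k, outcome, seed=seed,
                backend=self.backend, term_name=self.term_name,
                term_namespace=self.term_namespace)
        return TermClassifierResults(
            term=tset.term, model=model, cv_result=cv,
            selected_kernel=kernel, retained_groups=retained,
            holdout=outcome, k=pos_plan.k, seed=seed)


@dataclass
class TermClassifierResults:
    """Everything the training procedure decided for one term."""

    term: str
    model: TermModel | None
    cv_result: CVResult
    selected_kernel: KernelSpec
    retained_groups: list[str]
    holdout: HoldoutOutcome
    k: int
    seed: int

    @property
    def discarded(self) -> bool:
        return self.holdout.discarded

    @property
    def reliability(self) -> str:
        return self.holdout.reliability

    def summary(self) -> str:
        m = self.holdout.metrics
        kernel = self.selected_kernel
        lines = [
            f"Term classifier results: {self.term}",
            "=" * 48,
            f"kernel            {kernel.kind}  C={kernel.C:g}"
            + (f"  gamma={kernel.gamma:g}" if kernel.gamma else ""),
            f"retained groups   {len(self.retained_groups)}: "
            + ", ".join(self.retained_groups),
            f"cv folds (k)      {self.k}",
            f"cv MCC (pooled)   {self.cv_result.mcc:.3f}",
            f"holdout MCC       {m.mcc:.3f}",
            f"holdout sens      {m.sensitivity:.3f}",
            f"holdout spec      {m.specificity:.3f}",
            f"holdout prec      {m.precision:.3f}",
            f"reliability       {self.reliability}",
            f"discarded         {self.discarded}",
        ]
        if self.model is not None:
            cal = self.model.calibration
            lines.append(f"Platt (A, B)      ({cal.A:.4f}, {cal.B:.4f})")
        return "\n".join(lines)
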