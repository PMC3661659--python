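"""Homology-aware holdout and equal-size k-medoids partitioning.

Cross-validation folds must not share close homologues, or performance
estimates are inflated by trivial sequence similarity.  Each term's
positive and negative sets are therefore split into a 30% holdout plus
k equal-size groups clustered on a pairwise homology distance — the
minimum alignment E-value between the two sequences, capped so that
"no detectable similarity" is a finite, maximal distance.

The grouping is a capacity-constrained K-medoids: points are greedily
assigned to their nearest non-full medoid in descending order of
assignment margin (the cost of being displaced from one's nearest
medoid), then medoid updates, reassignment and improving pair-swaps
alternate until the plan is stable.  Sizes differ by at most one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_HOLDOUT_FRACTION = 0.30
DEFAULT_MIN_GROUP_SIZE = 35
DEFAULT_EVALUE_CAP = 10.0

MAX_KMEDOIDS_PASSES = 100


class PartitionError(ValueError):
    """Raised for invalid split requests or malformed distance input."""


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances over an ordered accession list."""

    accessions: list[str]
    d: np.ndarray
    metric_note: str = ""

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.accessions)
        if self.d.shape != (n, n):
            raise PartitionError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise PartitionError("distance matrix is not symmetric")
        if (self.d < 0).any():
            raise PartitionError("negative distances")
        self._index = {a: i for i, a in enumerate(self.accessions)}

    def submatrix(self, accessions: Sequence[str]) -> "DistanceMatrix":
        idx = [self._index[a] for a in accessions]
        return DistanceMatrix(list(accessions),
                              self.d[np.ix_(idx, idx)], self.metric_note)

    def to_tsv(self, path, square: bool = False) -> None:
        if square:
            frame = pd.DataFrame(self.d, index=self.accessions,
                                 columns=self.accessions)
            frame.to_csv(path, sep="\t")
        else:
            rows = [(self.accessions[i], self.accessions[j], self.d[i, j])
                    for i in range(len(self.accessions))
                    for j in range(i + 1, len(self.accessions))]
            pd.DataFrame(rows, columns=["acc_i", "acc_j", "d"]).to_csv(
                path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, cap: float = DEFAULT_EVALUE_CAP,
                 metric_note: str = "") -> "DistanceMatrix":
        """Read either the 3-column long form or a square table.

        Pairs absent from the long form default to the cap.
        """
        frame = pd.read_csv(path, sep="\t", index_col=None)
        if list(frame.columns[:3]) == ["acc_i", "acc_j", "d"]:
            accs = sorted(set(frame["acc_i"]) | set(frame["acc_j"]))
            index = {a: i for i, a in enumerate(accs)}
            d = np.full((len(accs), len(accs)), np.nan)
            np.fill_diagonal(d, 0.0)
            for _, row in frame.iterrows():
                i, j = index[row["acc_i"]], index[row["acc_j"]]
                value = float(row["d"])
                if not np.isnan(d[i, j]):
                    value = min(value, d[i, j])
                d[i, j] = d[j, i] = value
            d = np.where(np.isnan(d), cap, d)  # absent pairs -> unrelated
            return cls(accs, d, metric_note)
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(a) for a in frame.index],
                   frame.to_numpy(float), metric_note)


@dataclass
class PartitionPlan:
    """A 30% holdout plus k disjoint near-equal groups."""

    holdout: set[str]
    groups: list[set[str]]
    k: int
    seed: int

    def __post_init__(self) -> None:
        if self.k != len(self.groups):
            raise PartitionError("k does not match the group count")
        all_members = [a for g in self.groups for a in g]
        if len(all_members) != len(set(all_members)):
            raise PartitionError("groups are not disjoint")
        if set(all_members) & self.holdout:
            raise PartitionError("holdout overlaps the groups")
        sizes = [len(g) for g in self.groups]
        if sizes and max(sizes) - min(sizes) > 1:
            raise PartitionError("group sizes differ by more than 1")

    def training_accessions(self) -> list[str]:
        return sorted(a for g in self.groups for a in g)

    def to_tsv(self, path) -> None:
        rows = [(a, "holdout") for a in sorted(self.holdout)]
        for i, group in enumerate(self.groups, start=1):
            rows += [(a, f"group_{i}") for a in sorted(group)]
        pd.DataFrame(rows, columns=["accession", "role"]).to_csv(
            path, sep="\t", index=False)


# -- operations ---------------------------------------------------------------

def holdout_split(accessions: Sequence[str],
                  fraction: float = DEFAULT_HOLDOUT_FRACTION,
                  seed: int = 0) -> tuple[list[str], list[str]]:
    """Randomly withhold ``round(fraction * n)`` accessions.

    Deterministic for a given seed; input order does not matter (the
    pool is sorted before shuffling).
    """
    if not 0.0 < fraction < 1.0:
        raise PartitionError("holdout fraction must be in (0, 1)")
    pool = sorted(accessions)
    if len(pool) < 2:
        raise PartitionError("need at least 2 accessions to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    n_holdout = round(fraction * len(pool))
    holdout = sorted(pool[i] for i in order[:n_holdout])
    remainder = sorted(pool[i] for i in order[n_holdout:])
    return holdout, remainder


def max_k(n_pos: int, n_neg: int,
          min_size: int = DEFAULT_MIN_GROUP_SIZE) -> int:
    """Largest shared k with at least ``min_size`` per group on both sides.

    Returns 1 (with a warning) when no k >= 2 is admissible: the term
    remains trainable but cannot be cross-validated.
    """
    upper = min(n_pos, n_neg) // min_size
    for k in range(upper, 1, -1):
        if n_pos // k >= min_size and n_neg // k >= min_size:
            return k
    warnings.warn(
        f"no k >= 2 admits groups of {min_size} (n_pos={n_pos}, "
        f"n_neg={n_neg}); falling back to k=1 without cross-validation",
        stacklevel=2)
    return 1


def _group_sizes(n: int, k: int) -> list[int]:
    base, extra = divmod(n, k)
    return [base + 1] * extra + [base] * (k - extra)


def _assignment_cost(d: np.ndarray, groups: list[list[int]],
                     medoids: list[int]) -> float:
    return float(sum(d[i, m] for g, m in zip(groups, medoids) for i in g))


def balanced_kmedoids(dist: DistanceMatrix, k: int,
                      seed: int = 0) -> list[set[str]]:
    """Partition into k groups of near-equal size around medoids.

    Deterministic for a given seed.  The result is locally stable: no
    single swap of two members between two groups lowers the total
    within-group distance-to-medoid.  Ties break by accession
    lexicographic order.
    """
    n = len(dist.accessions)
    if k < 1 or k > n:
        raise PartitionError(f"k={k} out of range for n={n}")
    order = np.argsort(dist.accessions)  # lexicographic tie-break baseline
    d = dist.d[np.ix_(order, order)]
    accs = [dist.accessions[i] for i in order]
    if k == 1:
        return [set(accs)]
    sizes = _group_sizes(n, k)
    rng = np.random.default_rng(seed)
    # farthest-first seeding: after a seeded first pick, each new medoid
    # maximises its distance to the nearest chosen one, so well-separated
    # planted blocks each receive exactly one initial medoid
    medoids = [int(rng.integers(n))]
    while len(medoids) < k:
        nearest = d[:, medoids].min(axis=1)
        nearest[medoids] = -1.0
        medoids.append(int(np.argmax(nearest)))
    medoids = sorted(medoids)

    groups: list[list[int]] = []
    for _ in range(MAX_KMEDOIDS_PASSES):
        groups = _assign(d, medoids, sizes)
        groups = _swap_improve(d, groups, medoids)
        new_medoids = [_medoid_of(d, g) for g in groups]
        if new_medoids == medoids:
            break
        medoids = new_medoids
    return [set(accs[i] for i in g) for g in groups]


def _assign(d: np.ndarray, medoids: list[int],
            sizes: list[int]) -> list[list[int]]:
    """Greedy capacity-constrained assignment by descending margin."""
    n = d.shape[0]
    dm = d[:, medoids]                      # (n, k)
    if len(medoids) > 1:
        part = np.partition(dm, 1, axis=1)
        margin = part[:, 1] - part[:, 0]
    else:
        margin = np.zeros(n)
    # Points with the most to lose are placed first; ties by index,
    # which is lexicographic in accession order.
    visit = sorted(range(n), key=lambda i: (-margin[i], i))
    remaining = list(sizes)
    groups: list[list[int]] = [[] for _ in medoids]
    for i in visit:
        choices = sorted(range(len(medoids)),
                         key=lambda j: (dm[i, j], j))
        for j in choices:
            if remaining[j] > 0:
                groups[j].append(i)
                remaining[j] -= 1
                break
    return [sorted(g) for g in groups]


def _medoid_of(d: np.ndarray, group: list[int]) -> int:
    costs = d[np.ix_(group, group)].sum(axis=1)
    return group[int(np.argmin(costs))]     # argmin breaks ties by index


def _swap_improve(d: np.ndarray, groups: list[list[int]],
                  medoids: list[int]) -> list[list[int]]:
    """Apply improving pair swaps between groups until none remains."""
    groups = [list(g) for g in groups]
    improved = True
    passes = 0
    while improved and passes < MAX_KMEDOIDS_PASSES:
        improved = False
        passes += 1
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                ma, mb = medoids[a], medoids[b]
                for ia, i in enumerate(groups[a]):
                    for ib, j in enumerate(groups[b]):
                        delta = (d[i, mb] + d[j, ma]
                                 - d[i, ma] - d[j, mb])
                        if delta < -1e-12:
                            groups[a][ia], groups[b][ib] = j, i
                            improved = True
                            i = groups[a][ia]
    return [sorted(g) for g in groups]


def build_plan(accessions: Sequence[str], dist: DistanceMatrix, k: int,
               fraction: float = DEFAULT_HOLDOUT_FRACTION,
               seed: int = 0) -> PartitionPlan:
    """Holdout split then k-medoids grouping of the remainder."""
    holdout, remainder = holdout_split(accessions, fraction, seed)
    groups = balanced_kmedoids(dist.submatrix(remainder), k, seed)
    return PartitionPlan(holdout=set(holdout), groups=groups, k=k, seed=seed)


def plan_pair(positives: Sequence[str], negatives: Sequence[str],
              dist: DistanceMatrix,
              fraction: float = DEFAULT_HOLDOUT_FRACTION,
              min_size: int = DEFAULT_MIN_GROUP_SIZE,
              seed: int = 0) -> tuple[PartitionPlan, PartitionPlan]:
    """Partition a term's positive and negative sets with a shared k.

    The holdout is drawn from each set first; k is the largest value
    giving both remainders groups of at least ``min_size``; each set is
    then clustered separately on its own distance submatrix.
    """
    pos_hold, pos_rem = holdout_split(positives, fraction, seed)
    neg_hold, neg_rem = holdout_split(negatives, fraction, seed + 1)
    k = max_k(len(pos_rem), len(neg_rem), min_size)
    pos_groups = balanced_kmedoids(dist.submatrix(pos_rem), k, seed)
    neg_groups = balanced_kmedoids(dist.submatrix(neg_rem), k, seed + 1)
    return (PartitionPlan(set(pos_hold), pos_groups, k, seed),
            PartitionPlan(set(neg_hold), neg_groups, k, seed + 1))


# -- distances ----------------------------------------------------------------

#: A pairwise scorer returns an E-value-like statistic, a list of them,
#: or None when no alignment is reported, for an ordered sequence pair.
PairwiseScorer = Callable[[str, str], float | Sequence[float] | None]


def pairwise_distance(sequences: Mapping[str, str],
                      aligner: PairwiseScorer,
                      cap: float = DEFAULT_EVALUE_CAP) -> DistanceMatrix:
    """Build the homology distance matrix from a pairwise scorer.

    d(i, j) is the minimum over both orderings and all reported
    alignments, capped at ``cap``; missing alignments and aligner
    failures count as the cap; the diagonal is 0.
    """
    accs = sorted(sequences)
    n = len(accs)
    d = np.zeros((n, n), dtype=float)
    n_failures = 0
    for i in range(n):
        for j in range(i + 1, n):
            best = cap
            for a, b in ((accs[i], accs[j]), (accs[j], accs[i])):
                try:
                    reported = aligner(sequences[a], sequences[b])
                except Exception:
                    n_failures += 1
                    continue
                if reported is None:
                    continue
                values = (reported if isinstance(reported, (list, tuple))
                          else [reported])
                if values:
                    best = min(best, min(float(v) for v in values))
            d[i, j] = d[j, i] = max(min(best, cap), 0.0)
    if n_failures:
        logger.warning("pairwise_distance: %d aligner failures set to cap",
                       n_failures)
    return DistanceMatrix(accs, d, metric_note="min-alignment-E-value")
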