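"""Annotation corpus loading and per-term training-set construction.

Builds positive/negative protein sets for each candidate GO term under
the eligibility rules used to train feature-based function predictors:
positives are proteins annotated with the term or any descendant;
negatives must lie provably outside the term's lineage while still
being well annotated experimentally; a term is only trainable when it
occurs in the curated vocabulary and both sets are large enough.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Callable, Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .ontology import (NAMESPACE_BP, NAMESPACE_MF, OntologyGraph,
                       TRAINING_RELATIONS)

logger = logging.getLogger(__name__)

#: Evidence codes that do NOT count towards the "well annotated"
#: requirement for negative examples (curatorial / electronic).
NEGATIVE_EXCLUDED_EVIDENCE = frozenset({"IC", "NAS", "TAS", "IEA"})

DEFAULT_MAX_LENGTH = 1500
DEFAULT_IDENTITY_THRESHOLD = 0.90
DEFAULT_MIN_POSITIVES = 150
DEFAULT_MIN_NEGATIVES = 500


class CorpusError(ValueError):
    """Raised for unusable corpus inputs."""


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AnnotationRecord:
    accession: str
    term: str
    evidence: str


@dataclass
class AnnotationCorpus:
    """Protein sequences plus their GO annotations."""

    proteins: dict[str, ProteinRecord]
    annotations: list[AnnotationRecord]

    def __post_init__(self) -> None:
        for ann in self.annotations:
            if ann.accession not in self.proteins:
                raise CorpusError(
                    f"annotation references unknown protein {ann.accession!r}")

    def accessions(self) -> list[str]:
        return sorted(self.proteins)

    def annotations_by_protein(self) -> dict[str, list[AnnotationRecord]]:
        out: dict[str, list[AnnotationRecord]] = {a: [] for a in self.proteins}
        for ann in self.annotations:
            out[ann.accession].append(ann)
        return out


@dataclass
class TermTrainingSet:
    """A GO term with its positive/negative accession sets."""

    term: str
    positives: set[str]
    negatives: set[str]
    eligible: bool
    reason: str = ""

    def __post_init__(self) -> None:
        overlap = self.positives & self.negatives
        if overlap:
            raise CorpusError(
                f"positives and negatives overlap for {self.term!r}: "
                f"{sorted(overlap)[:3]}")

    def to_tsv(self, path) -> None:
        rows = [(a, "+") for a in sorted(self.positives)]
        rows += [(a, "-") for a in sorted(self.negatives)]
        pd.DataFrame(rows, columns=["accession", "label"]).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, term: str) -> "TermTrainingSet":
        frame = pd.read_csv(path, sep="\t")
        pos = set(frame.loc[frame["label"] == "+", "accession"])
        neg = set(frame.loc[frame["label"] == "-", "accession"])
        return cls(term=term, positives=pos, negatives=neg, eligible=True)


def _parse_gaf_line(line: str) -> tuple[str, str, str, str] | None:
    """Return (accession, term, evidence, qualifier) or None if unusable.

    Accepts either the minimal 3/4-column dialect
    ``accession<TAB>term<TAB>evidence[<TAB>qualifier]`` or full GAF 2.x
    rows (>= 15 columns: accession in column 2, qualifier in 4, term in
    5, evidence in 7).
    """
    fields = line.rstrip("\n").split("\t")
    if len(fields) >= 15:
        return fields[1], fields[4], fields[6], fields[3]
    if len(fields) >= 3 and all(fields[:3]):
        qualifier = fields[3] if len(fields) > 3 else ""
        return fields[0], fields[1], fields[2], qualifier
    return None


def load_corpus(fasta_source: str | IO[str],
                gaf_source: str | IO[str]) -> AnnotationCorpus:
    """Read sequences (FASTA) and annotations (GAF-style TSV).

    Rows with a ``NOT`` qualifier, malformed rows and annotations for
    accessions absent from the FASTA are dropped and counted in the log.
    Raises :class:`CorpusError` when no usable annotation remains.
    """
    proteins: dict[str, ProteinRecord] = {}
    for record in SeqIO.parse(fasta_source, "fasta"):
        proteins[record.id] = ProteinRecord(record.id, str(record.seq).upper())

    if isinstance(gaf_source, str):
        handle: IO[str] = open(gaf_source)
        close = True
    else:
        handle, close = gaf_source, False
    annotations: list[AnnotationRecord] = []
    n_malformed = n_orphan = n_not = 0
    try:
        for line in handle:
            if not line.strip() or line.startswith("!"):
                continue
            parsed = _parse_gaf_line(line)
            if parsed is None:
                n_malformed += 1
                continue
            accession, term, evidence, qualifier = parsed
            if "NOT" in qualifier.split("|"):
                n_not += 1
                continue
            if accession not in proteins:
                n_orphan += 1
                continue
            annotations.append(AnnotationRecord(accession, term, evidence))
    finally:
        if close:
            handle.close()
    if n_malformed or n_orphan or n_not:
        logger.info("load_corpus: dropped %d malformed, %d orphan, "
                    "%d NOT-qualified rows", n_malformed, n_orphan, n_not)
    if not annotations:
        raise CorpusError("no usable annotation rows")
    return AnnotationCorpus(proteins=proteins, annotations=annotations)


# -- redundancy reduction -----------------------------------------------------

#: A redundancy reducer maps {accession: sequence} plus an identity
#: threshold to the set of cluster-representative accessions.
RedundancyReducer = Callable[[Mapping[str, str], float], set[str]]


def kmer_containment_reducer(sequences: Mapping[str, str],
                             threshold: float, k: int = 5) -> set[str]:
    """Greedy clustering by exact k-mer containment.

    Sequences are visited longest-first; a sequence joins the first
    representative sharing at least ``threshold`` of its k-mers,
    otherwise it founds a new cluster.  Adequate for fixtures and small
    corpora; production users plug an external clusterer through the
    same interface.
    """
    def kmers(seq: str) -> set[str]:
        if len(seq) < k:
            return {seq}
        return {seq[i:i + k] for i in range(len(seq) - k + 1)}

    order = sorted(sequences, key=lambda a: (-len(sequences[a]), a))
    reps: dict[str, set[str]] = {}
    for acc in order:
        mers = kmers(sequences[acc])
        for rep, rep_mers in reps.items():
            shared = len(mers & rep_mers) / max(len(mers), 1)
            if shared >= threshold:
                break
        else:
            reps[acc] = mers
    return set(reps)


def filter_proteins(corpus: AnnotationCorpus,
                    max_length: int = DEFAULT_MAX_LENGTH,
                    reducer: RedundancyReducer = kmer_containment_reducer,
                    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
                    ) -> AnnotationCorpus:
    """Apply the length cap and redundancy reduction.

    Proteins longer than ``max_length`` residues are removed, then the
    reducer keeps one representative per cluster at the given identity
    threshold.  Annotations of removed proteins are dropped.
    """
    kept = {a: p for a, p in corpus.proteins.items()
            if p.length <= max_length}
    n_long = len(corpus.proteins) - len(kept)
    reps = reducer({a: p.sequence for a, p in kept.items()},
                   identity_threshold)
    survivors = {a: p for a, p in kept.items() if a in reps}
    annotations = [a for a in corpus.annotations
                   if a.accession in survivors]
    logger.info("filter_proteins: removed %d over-length, %d redundant; "
                "%d proteins remain", n_long, len(kept) - len(survivors),
                len(survivors))
    return AnnotationCorpus(proteins=survivors, annotations=annotations)


# -- per-term training sets ---------------------------------------------------

def term_eligible(term: str,
                  corpus: AnnotationCorpus,
                  graph: OntologyGraph,
                  swissprot_vocab: Iterable[str],
                  min_positives: int = DEFAULT_MIN_POSITIVES,
                  min_negatives: int = DEFAULT_MIN_NEGATIVES,
                  excluded_evidence: frozenset[str] = NEGATIVE_EXCLUDED_EVIDENCE,
                  ) -> TermTrainingSet:
    """Build the positive/negative sets for a term and test eligibility.

    Positives: proteins annotated with the term or any descendant
    (``is_a`` + ``part_of``).  Negatives: proteins not annotated with
    the term, its descendants or its ancestors, that additionally bear
    at least 2 distinct MF terms and 2 distinct BP terms whose evidence
    code is not curatorial/electronic (IC, NAS, TAS, IEA) — counting
    direct annotations only.  A term is eligible when it occurs in the
    supplied curated vocabulary and the sets reach ``min_positives`` /
    ``min_negatives``.
    """
    if term not in graph:
        raise CorpusError(f"term {term!r} not in ontology")
    vocab = set(swissprot_vocab)
    lineage = ({term}
               | graph.descendants(term, TRAINING_RELATIONS)
               | graph.ancestors(term, TRAINING_RELATIONS))
    positive_terms = {term} | graph.descendants(term, TRAINING_RELATIONS)

    by_protein = corpus.annotations_by_protein()
    positives: set[str] = set()
    negatives: set[str] = set()
    for accession, anns in by_protein.items():
        terms_here = {a.term for a in anns}
        if terms_here & positive_terms:
            positives.add(accession)
            continue
        if terms_here & lineage:
            continue  # annotated inside the lineage: neither side
        informative_mf = {a.term for a in anns
                          if a.evidence not in excluded_evidence
                          and a.term in graph.terms
                          and graph.namespace_of(a.term) == NAMESPACE_MF}
        informative_bp = {a.term for a in anns
                          if a.evidence not in excluded_evidence
                          and a.term in graph.terms
                          and graph.namespace_of(a.term) == NAMESPACE_BP}
        if len(informative_mf) >= 2 and len(informative_bp) >= 2:
            negatives.add(accession)

    reasons = []
    if term not in vocab:
        reasons.append("not_in_vocab")
    if len(positives) < min_positives:
        reasons.append(f"positives<{min_positives}")
    if len(negatives) < min_negatives:
        reasons.append(f"negatives<{min_negatives}")
    return TermTrainingSet(
        term=term,
        positives=positives,
        negatives=negatives,
        eligible=not reasons,
        reason=";".join(reasons),
    )


def build_training_sets(corpus: AnnotationCorpus,
                        graph: OntologyGraph,
                        swissprot_vocab: Iterable[str],
                        candidate_terms: Iterable[str] | None = None,
                        **kwargs) -> dict[str, TermTrainingSet]:
    """Run :func:`term_eligible` over candidate terms (default: all live
    non-root terms that appear in the corpus annotations)."""
    vocab = set(swissprot_vocab)
    if candidate_terms is None:
        seen = {a.term for a in corpus.annotations}
        candidates = sorted(
            t for t in seen
            if t in graph.terms and not graph.terms[t].obsolete
            and not graph.is_root(t))
    else:
        candidates = sorted(candidate_terms)
    return {t: term_eligible(t, corpus, graph, vocab, **kwargs)
            for t in candidates}
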