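"""Synthetic ontologies, proteomes and annotation corpora for testing.

Every input the pipeline consumes can be generated here without any
download: a two-namespace toy GO DAG (with ``part_of`` edges and a
diamond motif), a proteome with block-structured homology, annotation
tables with a configurable evidence-code mix, and feature matrices
with planted per-term signal.  At ``signal_strength = 1`` the planted
signal makes positives and negatives linearly separable by
construction (disjoint value ranges on the signal group's columns); at
0 the features carry no label information at all.

The generator's defaults define the standard study conditions used by
the end-to-end tests: 12 terms per namespace, 700 proteins, 150
positives per modelled term (negatives then exceed 500 under the
eligibility rules), 14 feature groups, 3 homology blocks.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import IO, Mapping, Sequence

import numpy as np

from .corpus import AnnotationCorpus, AnnotationRecord, ProteinRecord
from .features import (FeatureGroupSpec, FeatureMatrix, FeatureProvider,
                       NATIVE_PROVIDER, assemble, default_registry)
from .ontology import (IS_A, NAMESPACE_BP, NAMESPACE_MF, OntologyGraph,
                       PART_OF)
from .partition import DEFAULT_EVALUE_CAP, DistanceMatrix

AA = "ACDEFGHIKLMNPQRSTVWY"

#: Evidence codes drawn for annotations; IEA draws exercise the
#: negative-example evidence filter downstream.
DEFAULT_EVIDENCE_MIX = {"IDA": 0.40, "IMP": 0.25, "IPI": 0.20,
                        "IGI": 0.10, "IEA": 0.05}


@dataclass
class FixtureSpec:
    seed: int = 0
    n_terms: int = 12               # per namespace
    branching: int = 2
    n_proteins: int = 700
    n_signal_terms: int = 3
    n_noise_terms: int = 1
    n_positive: int = 150           # positives planted per modelled term
    signal_strength: float = 1.0
    n_homology_blocks: int = 3
    evidence_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVIDENCE_MIX))
    predictor_dimension: int = 4
    min_seq_length: int = 80
    max_seq_length: int = 200

    def __post_init__(self) -> None:
        if self.branching < 1:
            raise ValueError("branching must be >= 1")
        for name in ("n_terms", "n_proteins", "n_positive",
                     "n_homology_blocks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must be in [0, 1]")
        if self.n_positive > self.n_proteins:
            raise ValueError("n_positive cannot exceed n_proteins")


# -- ontology -----------------------------------------------------------------

def _term_id(namespace: str, index: int) -> str:
    prefix = "1" if namespace == NAMESPACE_MF else "2"
    return f"GO:{prefix}{index:06d}"


def make_ontology(spec: FixtureSpec) -> OntologyGraph:
    """Two rooted DAG namespaces with is_a, part_of and a diamond motif.

    Term *i*'s is_a parent is term ``max(1, i // branching)``, giving a
    chain at branching 1 and a near-balanced tree otherwise.  The last
    term receives a second is_a parent (diamond) and one mid-level term
    gains an additional part_of parent.
    """
    from .ontology import GoTerm

    terms: dict[str, GoTerm] = {}
    edges: list[tuple[str, str, str]] = []
    for namespace in (NAMESPACE_MF, NAMESPACE_BP):
        short = "MF" if namespace == NAMESPACE_MF else "BP"
        ids = [_term_id(namespace, i) for i in range(1, spec.n_terms + 1)]
        for i, tid in enumerate(ids, start=1):
            terms[tid] = GoTerm(id=tid, name=f"{short} term {i}",
                                namespace=namespace)
            if i == 1:
                continue
            parent_index = max(1, min(i - 1, i // spec.branching))
            edges.append((tid, ids[parent_index - 1], IS_A))
        if spec.n_terms >= 4:
            # diamond: the last term gets a second is_a parent
            last = spec.n_terms
            first_parent = max(1, last // spec.branching)
            second_parent = first_parent + 1
            if second_parent < last:
                edges.append((ids[last - 1], ids[second_parent - 1], IS_A))
            # one part_of edge between mid-level terms
            mid = max(3, spec.n_terms // 2)
            edges.append((ids[mid - 1], ids[mid - 2], PART_OF))
    return OntologyGraph(terms, edges)


def model_term_candidates(spec: FixtureSpec) -> list[str]:
    """Leaf-level terms, alternating MF/BP, usable as modelled terms."""
    if spec.n_terms < 11:
        raise ValueError("need >= 11 terms per namespace for the default "
                         "model-term layout")
    picks = [(NAMESPACE_MF, 8), (NAMESPACE_BP, 8), (NAMESPACE_MF, 9),
             (NAMESPACE_BP, 10), (NAMESPACE_MF, 10), (NAMESPACE_BP, 9)]
    return [_term_id(ns, i) for ns, i in picks]


# -- proteome -----------------------------------------------------------------

def _stable_rng(*parts) -> np.random.Generator:
    key = ":".join(str(p) for p in parts)
    return np.random.default_rng(zlib.crc32(key.encode()) & 0x7FFFFFFF)


def _mutate(base: str, rate: float, rng: np.random.Generator) -> str:
    out = list(base)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = AA[rng.integers(len(AA))]
    return "".join(out)


def make_mock_providers(spec: FixtureSpec,
                        registry: Sequence[FeatureGroupSpec],
                        signal_map: Mapping[str, tuple[str, frozenset[str]]]
                        | None = None) -> dict[str, FeatureProvider]:
    """Deterministic hash-seeded providers for the predictor groups.

    ``signal_map`` maps a group name to ``(term, positive accessions)``;
    members of that set get the group's values shifted upward by
    ``signal_strength * (1 + eps)`` so that strength 1 yields disjoint
    value ranges (linear separability by construction).
    """
    signal_map = dict(signal_map or {})
    shift = spec.signal_strength * 1.000001
    providers: dict[str, FeatureProvider] = {}
    for group in registry:
        if group.provider_id == NATIVE_PROVIDER:
            continue

        def provider(accession: str, sequence: str,
                     _name: str = group.name,
                     _dim: int = group.dimension) -> np.ndarray:
            rng = _stable_rng("feat", spec.seed, _name, accession)
            values = rng.uniform(0.0, 1.0, size=_dim)
            planted = signal_map.get(_name)
            if planted is not None and accession in planted[1]:
                values = values + shift
            return values

        providers[group.provider_id] = provider
    return providers


def make_proteome(spec: FixtureSpec, graph: OntologyGraph,
                  ) -> tuple[AnnotationCorpus, FeatureMatrix,
                             DistanceMatrix, dict[str, set[str]]]:
    """Generate the corpus, feature matrix, homology distances and truth.

    Returns ``(corpus, features, distances, truth)`` where ``truth``
    maps each modelled term (signal terms first, then noise terms) to
    its planted positive accessions.  Annotations are
    propagation-consistent (positives are annotated with the modelled
    leaf term itself); every protein receives three distinct background
    annotations per namespace drawn outside all modelled lineages, so
    the eligibility filters are exercised but typically satisfied.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins
    accessions = [f"P{i:06d}" for i in range(1, n + 1)]

    # sequences: block-structured homology
    bases = ["".join(AA[rng.integers(len(AA))] for _ in range(
        int(rng.integers(spec.min_seq_length, spec.max_seq_length + 1))))
        for _ in range(spec.n_homology_blocks)]
    blocks = {acc: i % spec.n_homology_blocks
              for i, acc in enumerate(accessions)}
    proteins = {acc: ProteinRecord(acc, _mutate(bases[blocks[acc]], 0.10, rng))
                for acc in accessions}

    # distances: near zero within a block, the cap across blocks
    d = np.full((n, n), DEFAULT_EVALUE_CAP, dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            if blocks[accessions[i]] == blocks[accessions[j]]:
                d[i, j] = d[j, i] = 1e-6 * (0.5 + rng.random())
    np.fill_diagonal(d, 0.0)
    distances = DistanceMatrix(list(accessions), d,
                               metric_note="synthetic-block-structure")

    # modelled terms; each positive set is sampled independently so that
    # a noise term's labels stay independent of every signal channel
    candidates = model_term_candidates(spec)
    n_model = spec.n_signal_terms + spec.n_noise_terms
    if n_model > len(candidates):
        raise ValueError("not enough leaf candidates for the requested "
                         "number of modelled terms")
    model_terms = candidates[:n_model]
    truth: dict[str, set[str]] = {}
    for term in model_terms:
        chosen = rng.choice(n, size=spec.n_positive, replace=False)
        truth[term] = {accessions[int(i)] for i in chosen}

    # background pool: live non-root terms outside every modelled lineage
    lineages: set[str] = set()
    for term in model_terms:
        lineages |= {term} | graph.ancestors(term) | graph.descendants(term)
    background = {NAMESPACE_MF: [], NAMESPACE_BP: []}
    for t in sorted(graph.terms):
        term = graph.terms[t]
        if term.obsolete or graph.is_root(t) or t in lineages:
            continue
        background[term.namespace].append(t)
    for namespace, pool in background.items():
        if len(pool) < 3:
            raise ValueError(f"background pool too small in {namespace}")

    codes = sorted(spec.evidence_mix)
    probs = np.array([spec.evidence_mix[c] for c in codes])
    probs = probs / probs.sum()

    def draw_code() -> str:
        return codes[rng.choice(len(codes), p=probs)]

    annotations: list[AnnotationRecord] = []
    for acc in accessions:
        for term, members in truth.items():
            if acc in members:
                annotations.append(AnnotationRecord(acc, term, draw_code()))
        for namespace in (NAMESPACE_MF, NAMESPACE_BP):
            pool = background[namespace]
            chosen = rng.choice(len(pool), size=3, replace=False)
            for c in chosen:
                annotations.append(
                    AnnotationRecord(acc, pool[int(c)], draw_code()))
    corpus = AnnotationCorpus(proteins=proteins, annotations=annotations)

    # features: native groups from the sequences; mock predictor groups
    # with one dedicated signal group per signal term
    registry = default_registry(spec.predictor_dimension)
    predictor_groups = [g.name for g in registry
                        if g.provider_id != NATIVE_PROVIDER]
    signal_terms = model_terms[:spec.n_signal_terms]
    signal_map = {predictor_groups[j]: (term, frozenset(truth[term]))
                  for j, term in enumerate(signal_terms)}
    providers = make_mock_providers(spec, registry, signal_map)
    vectors = [assemble(acc, proteins[acc].sequence, providers, registry)
               for acc in accessions]
    features = FeatureMatrix.from_vectors(vectors)
    return corpus, features, distances, truth


def make_ic_corpus(graph: OntologyGraph, n_proteins: int = 20,
                   seed: int = 0) -> list[tuple[str, str, str]]:
    """A small annotation corpus for information-content estimation.

    Each protein receives 1-3 random live terms per namespace with IDA
    evidence, so every branch of the toy DAG accrues finite IC mass.
    """
    rng = np.random.default_rng(seed)
    by_namespace: dict[str, list[str]] = {}
    for t in sorted(graph.terms):
        term = graph.terms[t]
        if term.obsolete or graph.is_root(t):
            continue
        by_namespace.setdefault(term.namespace, []).append(t)
    triples = []
    for i in range(1, n_proteins + 1):
        acc = f"Q{i:05d}"
        for namespace, pool in sorted(by_namespace.items()):
            count = int(rng.integers(1, 4))
            chosen = rng.choice(len(pool), size=min(count, len(pool)),
                                replace=False)
            for c in chosen:
                triples.append((acc, pool[int(c)], "IDA"))
    return triples


# -- writers ------------------------------------------------------------------

def write_obo(graph: OntologyGraph, handle: IO[str]) -> None:
    handle.write("format-version: 1.2\nontology: synthetic\n")
    for tid in sorted(graph.terms):
        term = graph.terms[tid]
        handle.write(f"\n[Term]\nid: {term.id}\nname: {term.name}\n")
        if term.namespace:
            handle.write(f"namespace: {term.namespace}\n")
        for alt in term.alt_ids:
            handle.write(f"alt_id: {alt}\n")
        if term.obsolete:
            handle.write("is_obsolete: true\n")
        for rep in term.replaced_by:
            handle.write(f"replaced_by: {rep}\n")
        for child, parent, relation in sorted(graph.edges()):
            if child != tid:
                continue
            if relation == IS_A:
                handle.write(f"is_a: {parent}\n")
            else:
                handle.write(f"relationship: {relation} {parent}\n")


def write_fasta(corpus: AnnotationCorpus, handle: IO[str]) -> None:
    for acc in sorted(corpus.proteins):
        seq = corpus.proteins[acc].sequence
        handle.write(f">{acc}\n")
        for i in range(0, len(seq), 60):
            handle.write(seq[i:i + 60] + "\n")


def write_gaf(corpus: AnnotationCorpus, handle: IO[str]) -> None:
    for ann in corpus.annotations:
        handle.write(f"{ann.accession}\t{ann.term}\t{ann.evidence}\n")


def write_vocab(graph: OntologyGraph, handle: IO[str]) -> None:
    for tid in sorted(graph.terms):
        if not graph.terms[tid].obsolete:
            handle.write(tid + "\n")
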