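"""Gene Ontology graph handling and information content.

The Gene Ontology (GO) is a pair of rooted directed acyclic graphs of
terms — molecular function (MF) and biological process (BP) — connected
by typed ``is_a`` and ``part_of`` relations.  This module parses OBO
text into a validated, typed DAG, answers transitive ancestor/descendant
queries, resolves obsolete identifiers, and estimates per-term
information content (IC) from an annotation corpus.

IC of a term *y* is defined as ``-log f(y)`` where ``f(y)`` is the
fraction of corpus proteins annotated with *y* or any of its
descendants, among proteins carrying at least one annotation in *y*'s
namespace.  The root of each namespace therefore has IC exactly 0, and
IC never decreases from a parent to a child.  Natural logarithms are
used throughout; IC enters downstream similarity scores (simGIC) only
through ratios of IC sums, so the base cancels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

IS_A = "is_a"
PART_OF = "part_of"
#: Relations followed by default when collecting ancestors/descendants
#: during training-set construction (both typed relations).
TRAINING_RELATIONS = frozenset({IS_A, PART_OF})
#: Relations followed when propagating annotations for assessment and IC.
ASSESSMENT_RELATIONS = frozenset({IS_A})

NAMESPACE_MF = "molecular_function"
NAMESPACE_BP = "biological_process"
NAMESPACES = (NAMESPACE_MF, NAMESPACE_BP)

#: Log base used for information content (natural log).
IC_LOG_BASE = math.e


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies or unknown terms."""


@dataclass(frozen=True)
class GoTerm:
    """A single GO term.

    ``namespace`` is one of :data:`NAMESPACE_MF` / :data:`NAMESPACE_BP`
    for live terms; obsolete stanzas occasionally omit it.
    """

    id: str
    name: str = ""
    namespace: str | None = None
    obsolete: bool = False
    alt_ids: tuple[str, ...] = ()
    replaced_by: tuple[str, ...] = ()


class OntologyGraph:
    """Typed DAG of GO terms restricted to the MF and BP namespaces.

    Edges run child -> parent and carry a relation label (``is_a`` or
    ``part_of``).  One root per namespace is identified as the unique
    live term without an ``is_a`` parent.
    """

    def __init__(self, terms: Mapping[str, GoTerm],
                 edges: Iterable[tuple[str, str, str]]) -> None:
        self.terms: dict[str, GoTerm] = dict(terms)
        g: nx.MultiDiGraph = nx.MultiDiGraph()
        g.add_nodes_from(self.terms)
        for child, parent, relation in edges:
            if child not in self.terms or parent not in self.terms:
                continue
            g.add_edge(child, parent, key=relation)
        self._graph = g
        self._alt_index: dict[str, str] = {}
        for term in self.terms.values():
            for alt in term.alt_ids:
                self._alt_index.setdefault(alt, term.id)
        self._validate()
        self.roots: dict[str, str] = self._find_roots()

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self._graph):
            cycle = nx.find_cycle(self._graph)
            raise OntologyError(
                f"ontology contains a cycle through {cycle[0][0]!r}")
        for term in self.terms.values():
            if not term.obsolete and term.namespace not in NAMESPACES:
                raise OntologyError(
                    f"term {term.id!r} has no MF/BP namespace")

    def _find_roots(self) -> dict[str, str]:
        roots: dict[str, str] = {}
        for term in self.terms.values():
            if term.obsolete:
                continue
            has_parent = self._graph.out_degree(term.id) > 0
            if not has_parent:
                if term.namespace in roots:
                    raise OntologyError(
                        f"namespace {term.namespace!r} has multiple "
                        f"roots: {roots[term.namespace]!r}, {term.id!r}")
                roots[term.namespace] = term.id
        return roots

    # -- basic queries --------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def live_terms(self) -> list[GoTerm]:
        return [t for t in self.terms.values() if not t.obsolete]

    def namespace_of(self, term_id: str) -> str | None:
        return self.terms[term_id].namespace

    def is_root(self, term_id: str) -> bool:
        return term_id in self.roots.values()

    def root_of(self, namespace: str) -> str:
        return self.roots[namespace]

    def edges(self) -> Iterable[tuple[str, str, str]]:
        return self._graph.edges(keys=True)

    # -- traversal ------------------------------------------------------------

    def _closure(self, term_id: str, relations: frozenset[str],
                 reverse: bool) -> set[str]:
        if term_id not in self.terms:
            raise OntologyError(f"unknown term {term_id!r}")
        relations = frozenset(relations)
        seen: set[str] = set()
        stack = [term_id]
        while stack:
            node = stack.pop()
            if reverse:
                step = ((u, rel) for u, _, rel in
                        self._graph.in_edges(node, keys=True))
            else:
                step = ((v, rel) for _, v, rel in
                        self._graph.out_edges(node, keys=True))
            for neighbour, rel in step:
                if rel in relations and neighbour not in seen:
                    seen.add(neighbour)
                    stack.append(neighbour)
        seen.discard(term_id)
        return seen

    def ancestors(self, term_id: str,
                  relations: Iterable[str] = TRAINING_RELATIONS) -> set[str]:
        """Transitive closure over parent edges of the given relation types.

        Excludes the query term itself; includes the namespace root when
        it is reachable through the requested relations.
        """
        return self._closure(term_id, frozenset(relations), reverse=False)

    def descendants(self, term_id: str,
                    relations: Iterable[str] = TRAINING_RELATIONS) -> set[str]:
        """Mirror of :meth:`ancestors` on reversed edges."""
        return self._closure(term_id, frozenset(relations), reverse=True)

    # -- obsolete-term resolution ---------------------------------------------

    def map_obsolete(self, term_id: str) -> str | None:
        """Resolve an identifier to a unique live replacement.

        Live primary identifiers map to themselves.  Alternative
        identifiers map to their live owner.  Obsolete terms map to the
        unique candidate reachable via ``replaced_by`` (falling back to
        a unique reverse ``alt_id`` owner); if no unique candidate
        exists the result is ``None`` and the caller discards the term.
        """
        term = self.terms.get(term_id)
        if term is None:
            owner = self._alt_index.get(term_id)
            if owner is not None and not self.terms[owner].obsolete:
                return owner
            return None
        if not term.obsolete:
            return term_id
        candidates = [t for t in term.replaced_by
                      if t in self.terms and not self.terms[t].obsolete]
        if not candidates:
            owner = self._alt_index.get(term_id)
            if owner is not None and owner != term_id \
                    and not self.terms[owner].obsolete:
                candidates = [owner]
        if len(set(candidates)) == 1:
            return candidates[0]
        return None


def parse_obo(source: str | IO[str]) -> OntologyGraph:
    """Parse OBO 1.2/1.4 text into an :class:`OntologyGraph`.

    Only ``[Term]`` stanzas are consumed; the tags read are ``id``,
    ``name``, ``namespace``, ``is_a``, ``relationship: part_of``,
    ``is_obsolete``, ``replaced_by`` and ``alt_id``.  Cellular-component
    terms are dropped; obsolete MF/BP terms are retained (with their
    ``replaced_by``/``alt_id`` data) so old annotations can be remapped.

    Raises :class:`OntologyError` on cycles or on a live term without a
    namespace.
    """
    raw = obonet.read_obo(source, ignore_obsolete=False)
    terms: dict[str, GoTerm] = {}
    edges: list[tuple[str, str, str]] = []
    for node, data in raw.nodes(data=True):
        if not data:          # referenced but never declared
            continue
        namespace = data.get("namespace")
        obsolete = str(data.get("is_obsolete", "")).lower() == "true"
        if namespace is not None and namespace not in NAMESPACES:
            continue          # cellular_component and friends
        if namespace is None and not obsolete:
            raise OntologyError(f"term {node!r} has no namespace")
        terms[node] = GoTerm(
            id=node,
            name=data.get("name", ""),
            namespace=namespace,
            obsolete=obsolete,
            alt_ids=tuple(data.get("alt_id", ())),
            replaced_by=tuple(data.get("replaced_by", ())),
        )
        for parent in data.get("is_a", ()):
            edges.append((node, parent, IS_A))
        for rel in data.get("relationship", ()):
            parts = rel.split()
            if len(parts) == 2 and parts[0] == PART_OF:
                edges.append((node, parts[1], PART_OF))
    if not terms:
        raise OntologyError("no usable [Term] stanzas found")
    return OntologyGraph(terms, edges)


@dataclass
class ICTable:
    """Per-term information content estimated from an annotation corpus.

    ``ic`` maps term id to a non-negative real; terms never observed in
    the corpus carry ``+inf`` as a sentinel and are excluded from simGIC
    sums by the assessment layer.  ``corpus_size`` records how many
    annotated proteins the frequencies were estimated from.
    """

    ic: dict[str, float]
    corpus_size: int

    def get(self, term_id: str, default: float = 0.0) -> float:
        return self.ic.get(term_id, default)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.ic

    def to_tsv(self, path) -> None:
        frame = pd.DataFrame(
            {"term": list(self.ic), "ic": list(self.ic.values())})
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, corpus_size: int = 0) -> "ICTable":
        frame = pd.read_csv(path, sep="\t")
        return cls(ic=dict(zip(frame["term"], frame["ic"].astype(float))),
                   corpus_size=corpus_size)


def information_content(
        graph: OntologyGraph,
        annotations: Iterable[tuple[str, str, str]],
        evidence_filter: Iterable[str] | None = None,
        relations: Iterable[str] = ASSESSMENT_RELATIONS,
) -> ICTable:
    """Estimate per-term IC from ``(accession, term, evidence)`` triples.

    ``f(y)`` counts proteins annotated with *y* or any descendant
    (equivalently: proteins whose ancestor-propagated annotation set
    contains *y*), divided per namespace by the number of proteins with
    at least one annotation in that namespace.  ``ic = -log f``; the
    namespace roots are forced to exactly 0; unobserved terms get
    ``+inf``.

    ``annotations`` may also be an object with an ``annotations``
    attribute of records carrying ``accession``/``term``/``evidence``
    (an :class:`~seqfunc.corpus.AnnotationCorpus` satisfies this).
    """
    if hasattr(annotations, "annotations"):
        annotations = [(a.accession, a.term, a.evidence)
                       for a in annotations.annotations]
    allowed = set(evidence_filter) if evidence_filter is not None else None
    relations = frozenset(relations)

    # Propagated annotation sets per protein, split by namespace.
    per_protein: dict[str, set[str]] = {}
    dropped_unknown = 0
    for accession, term, evidence in annotations:
        if allowed is not None and evidence not in allowed:
            continue
        mapped = graph.map_obsolete(term)
        if mapped is None:
            dropped_unknown += 1
            continue
        bag = per_protein.setdefault(accession, set())
        bag.add(mapped)
        bag.update(graph.ancestors(mapped, relations))
    if dropped_unknown:
        logger.info("information_content: dropped %d annotations with "
                    "unresolvable terms", dropped_unknown)
    if not per_protein:
        raise OntologyError("no annotations left after evidence filtering")

    ns_totals = {ns: 0 for ns in NAMESPACES}
    term_counts: dict[str, int] = {}
    for bag in per_protein.values():
        seen_ns = set()
        for t in bag:
            term_counts[t] = term_counts.get(t, 0) + 1
            ns = graph.namespace_of(t)
            if ns is not None:
                seen_ns.add(ns)
        for ns in seen_ns:
            ns_totals[ns] += 1

    ic: dict[str, float] = {}
    for term in graph.live_terms():
        total = ns_totals.get(term.namespace, 0)
        count = term_counts.get(term.id, 0)
        if graph.is_root(term.id):
            ic[term.id] = 0.0
        elif total == 0 or count == 0:
            ic[term.id] = math.inf
        else:
            ic[term.id] = -math.log(count / total)
    return ICTable(ic=ic, corpus_size=len(per_protein))
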