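"""Shared fixtures: toy ontologies, random DAGs, small proteomes."""

from __future__ import annotations

import numpy as np
import pytest

from seqfunc.fixtures import FixtureSpec, make_ontology, make_proteome
from seqfunc.ontology import GoTerm, IS_A, NAMESPACE_MF, PART_OF, OntologyGraph

MF = NAMESPACE_MF


def mf_term(tid: str) -> GoTerm:
    return GoTerm(id=tid, name=tid, namespace=MF)


def build_graph(term_ids, edges) -> OntologyGraph:
    return OntologyGraph({t: mf_term(t) for t in term_ids}, edges)


@pytest.fixture
def chain_graph() -> OntologyGraph:
    """R <- A (is_a) <- B (is_a) <- C (part_of)."""
    return build_graph(
        ["R", "A", "B", "C"],
        [("A", "R", IS_A), ("B", "A", IS_A), ("C", "B", PART_OF)])


@pytest.fixture
def diamond_graph() -> OntologyGraph:
    """A root; B, C is_a A; D is_a both B and C."""
    return build_graph(
        ["A", "B", "C", "D"],
        [("B", "A", IS_A), ("C", "A", IS_A),
         ("D", "B", IS_A), ("D", "C", IS_A)])


def random_dag(n_nodes: int, seed: int, p_edge: float = 0.15,
               p_part_of: float = 0.25) -> OntologyGraph:
    """Random single-namespace DAG: edges only point to lower indices,
    node 0 is the root, every other node gets >= 1 parent."""
    rng = np.random.default_rng(seed)
    ids = [f"N{i:03d}" for i in range(n_nodes)]
    edges = []
    for i in range(1, n_nodes):
        parents = [j for j in range(i) if rng.random() < p_edge]
        if not parents:
            parents = [int(rng.integers(0, i))]
        for j in parents:
            rel = PART_OF if rng.random() < p_part_of else IS_A
            edges.append((ids[i], ids[j], rel))
    return build_graph(ids, edges)


def brute_force_reachable(graph: OntologyGraph, start: str,
                          relations, reverse: bool = False) -> set[str]:
    """Exhaustive-path reachability oracle, independent of the BFS code."""
    relations = set(relations)
    edges = [(c, p) for c, p, r in graph.edges() if r in relations]
    if reverse:
        edges = [(p, c) for c, p in edges]
    reached = set()
    frontier = {start}
    while frontier:
        nxt = {b for a, b in edges if a in frontier and b not in reached}
        reached |= nxt
        frontier = nxt
    reached.discard(start)
    return reached


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete proteome bundle shared by several modules."""
    spec = FixtureSpec(seed=11, n_proteins=150, n_positive=40,
                       n_signal_terms=2, n_noise_terms=1)
    graph = make_ontology(spec)
    corpus, features, distances, truth = make_proteome(spec, graph)
    return spec, graph, corpus, features, distances, truth
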