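"""Cohort -> RDF triples -> heterogeneous patient network -> adjacency matrix.

Two conversion rules turn the coded clinical bundles into RDF: (1) every
string-type coded value becomes an entity (a value node shared across patients),
and (2) every value is attached to its patient as the object of a data-type
property named after its record family (``hasGenetic``, ``hasCondition``,
``hasLab``, ``hasMedication``, ``hasFamilyHistory``, ``hasDemographic``).
Merging all patients' triples produces one graph with 7 node types — patients
plus the six value families — in which every edge joins a patient to a value
node, so the network is bipartite, unweighted and deduplicated.

Lab values enter as categorical entities ``code=Normal|Abnormal`` (a Null result
emits no triple: absence carries no edge).  Age is binned into decades to form a
categorical demographic node; sex contributes a second demographic node.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np

from .features import LabCategory, categorize_lab
from .fhir_model import Cohort, PatientBundle

IRI_PREFIX = "urn:graphonc"


class NodeType(str, Enum):
    PATIENT = "PATIENT"
    GENETIC = "GENETIC"
    LAB = "LAB"
    DIAGNOSIS = "DIAGNOSIS"
    MEDICATION = "MEDICATION"
    FAMILY_HISTORY = "FAMILY_HISTORY"
    DEMOGRAPHIC = "DEMOGRAPHIC"


#: record family -> predicate name
PREDICATES: dict[NodeType, str] = {
    NodeType.GENETIC: "hasGenetic",
    NodeType.LAB: "hasLab",
    NodeType.DIAGNOSIS: "hasCondition",
    NodeType.MEDICATION: "hasMedication",
    NodeType.FAMILY_HISTORY: "hasFamilyHistory",
    NodeType.DEMOGRAPHIC: "hasDemographic",
}


@dataclass(frozen=True, order=True)
class NodeId:
    node_type: NodeType
    key: str

    def iri(self) -> str:
        return f"{IRI_PREFIX}:{self.node_type.value}:{urllib.parse.quote(self.key, safe='')}"

    def __str__(self) -> str:
        return f"{self.node_type.value}:{self.key}"


@dataclass(frozen=True, order=True)
class Triple:
    subject: NodeId
    predicate: str
    object: NodeId

    def __post_init__(self) -> None:
        if self.subject.node_type is not NodeType.PATIENT:
            raise ValueError(f"triple subject must be a patient node, got {self.subject}")
        if self.predicate not in PREDICATES.values():
            raise ValueError(f"unknown predicate {self.predicate!r}")


class StructuralError(ValueError):
    """A triple set violates the patient-to-value structure of the model."""


def age_bin(age_years: int) -> str:
    lo = 10 * (age_years // 10)
    return f"{lo}-{lo + 9}"


def bundle_value_nodes(
    bundle: PatientBundle,
    include_normal_labs: bool = True,
    include_demographics: bool = True,
) -> set[NodeId]:
    """Distinct value nodes touched by one patient bundle."""
    nodes: set[NodeId] = set()
    for r in bundle.genetics:
        nodes.add(NodeId(NodeType.GENETIC, r.gene.code))
    for r in bundle.conditions:
        nodes.add(NodeId(NodeType.DIAGNOSIS, r.condition.code))
    for r in bundle.medications:
        nodes.add(NodeId(NodeType.MEDICATION, r.drug.code))
    for r in bundle.family_history:
        nodes.add(NodeId(NodeType.FAMILY_HISTORY, r.condition.code))
    for r in bundle.labs:
        cat = categorize_lab(r.value, r.ref_low, r.ref_high)
        if cat is LabCategory.NULL:
            continue  # absence carries no edge
        if cat is LabCategory.NORMAL and not include_normal_labs:
            continue
        nodes.add(NodeId(NodeType.LAB, f"{r.test.code}={cat.value}"))
    if include_demographics:
        nodes.add(NodeId(NodeType.DEMOGRAPHIC, f"sex={bundle.demographics.sex.value}"))
        nodes.add(
            NodeId(NodeType.DEMOGRAPHIC, f"age={age_bin(bundle.demographics.age_years)}")
        )
    return nodes


def cohort_to_triples(
    cohort: Cohort,
    include_normal_labs: bool = True,
    include_demographics: bool = True,
) -> set[Triple]:
    """One triple per distinct (patient, family, coded value).

    Repeated occurrences of the same value for the same patient collapse to one
    triple (set semantics), so the conversion is order-independent and the triple
    count equals the sum over patients of distinct value nodes touched.
    """
    triples: set[Triple] = set()
    for bundle in cohort.bundles:
        subj = NodeId(NodeType.PATIENT, bundle.patient_id)
        for obj in bundle_value_nodes(bundle, include_normal_labs, include_demographics):
            triples.add(Triple(subj, PREDICATES[obj.node_type], obj))
    return triples


@dataclass(frozen=True)
class PatientGraph:
    """Undirected heterogeneous network; edges join patients to value nodes only."""

    nodes: frozenset[NodeId]
    edges: frozenset[frozenset[NodeId]]
    provenance: frozenset[Triple] = field(default=frozenset(), compare=False)

    def __post_init__(self) -> None:
        for e in self.edges:
            pair = tuple(e)
            if len(pair) != 2:
                raise StructuralError(f"self-loop or malformed edge {pair}")
            types = {n.node_type for n in pair}
            if NodeType.PATIENT not in types or types == {NodeType.PATIENT}:
                raise StructuralError(
                    f"edge {pair[0]} -- {pair[1]} does not join a patient to a value node"
                )
            if not set(pair) <= self.nodes:
                raise StructuralError(f"edge endpoint outside node set: {pair}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_order(self) -> list[NodeId]:
        """Deterministic node ordering (by type then key)."""
        return sorted(self.nodes)

    def adjacency(self) -> dict[NodeId, tuple[NodeId, ...]]:
        """Neighbor lists, each sorted, as a dict keyed by node."""
        adj: dict[NodeId, list[NodeId]] = {n: [] for n in self.nodes}
        for e in self.edges:
            a, b = tuple(e)
            adj[a].append(b)
            adj[b].append(a)
        return {n: tuple(sorted(v)) for n, v in adj.items()}

    def degree(self, node: NodeId) -> int:
        return sum(1 for e in self.edges if node in e)

    def patient_nodes(self) -> list[NodeId]:
        return sorted(n for n in self.nodes if n.node_type is NodeType.PATIENT)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for n in self.node_order():
            g.add_node(str(n), node_type=n.node_type.value, key=n.key)
        for e in sorted(tuple(sorted(e)) for e in self.edges):
            g.add_edge(str(e[0]), str(e[1]))
        return g


def triples_to_graph(triples: Iterable[Triple]) -> PatientGraph:
    """Nodes = all distinct subjects and objects; edges = deduplicated pairs."""
    nodes: set[NodeId] = set()
    edges: set[frozenset[NodeId]] = set()
    tset = set(triples)
    for t in tset:
        if t.subject.node_type is not NodeType.PATIENT:
            raise StructuralError(f"subject {t.subject} is not a patient node")
        nodes.add(t.subject)
        nodes.add(t.object)
        edges.add(frozenset((t.subject, t.object)))
    return PatientGraph(frozenset(nodes), frozenset(edges), frozenset(tset))


def cohort_to_graph(
    cohort: Cohort,
    include_normal_labs: bool = True,
    include_demographics: bool = True,
) -> PatientGraph:
    """Build the patient network, keeping record-less patients as isolated nodes."""
    g = triples_to_graph(
        cohort_to_triples(cohort, include_normal_labs, include_demographics)
    )
    all_patients = {NodeId(NodeType.PATIENT, pid) for pid in cohort.patient_ids}
    if all_patients <= g.nodes:
        return g
    return PatientGraph(g.nodes | all_patients, g.edges, g.provenance)


@dataclass(frozen=True)
class AdjacencyMatrix:
    node_order: tuple[NodeId, ...]
    entries: np.ndarray  # |V| x |V| uint8, symmetric, zero diagonal

    def degree_vector(self) -> np.ndarray:
        return self.entries.sum(axis=1)


def to_adjacency(graph: PatientGraph) -> AdjacencyMatrix:
    """Binary |V|x|V| adjacency matrix over the deterministic node order."""
    order = graph.node_order()
    idx = {n: i for i, n in enumerate(order)}
    m = np.zeros((len(order), len(order)), dtype=np.uint8)
    for e in graph.edges:
        a, b = tuple(e)
        m[idx[a], idx[b]] = 1
        m[idx[b], idx[a]] = 1
    return AdjacencyMatrix(tuple(order), m)


def export_ntriples(triples: Iterable[Triple], path: str | Path) -> None:
    """Write triples in N-Triples syntax, one per line, in sorted lexical order.

    IRIs follow the scheme ``urn:graphonc:<node_type>:<percent-encoded key>``;
    predicates use ``urn:graphonc:pred:<name>``.
    """
    lines = sorted(
        f"<{t.subject.iri()}> <{IRI_PREFIX}:pred:{t.predicate}> <{t.object.iri()}> ."
        for t in set(triples)
    )
    Path(path).write_text("".join(line + "\n" for line in lines))


def export_graphml(graph: PatientGraph, path: str | Path) -> None:
    import networkx as nx

    nx.write_graphml(graph.to_networkx(), str(path))
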