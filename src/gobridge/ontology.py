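"""Gene Ontology handling: DAG parsing, annotation propagation, and
information-accretion weights.

The ontology is read from a go-basic style OBO file into an
:class:`OntologyDAG` restricted to ``is_a`` and ``part_of`` edges, which that
dialect guarantees to be acyclic.  Annotating a protein with a term implies
all of the term's ancestors (the true-path rule), so ground truth and
predictions are both *propagated* up the graph before any evaluation.

Information accretion, ia(f), is the negative log2 conditional probability of
a term given its parents, estimated from a propagated annotation corpus; it
weights rare, specific terms more heavily in WFmax and Smin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Set, TextIO, Tuple

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

PROPAGATION_RELATIONS = ("is_a", "part_of")

#: canonical GO namespace abbreviations plus the toy namespace used in tests
NAMESPACE_ABBREV = {
    "molecular_function": "MFO",
    "biological_process": "BPO",
    "cellular_component": "CCO",
    "toy": "toy",
}


class CycleError(ValueError):
    """Raised when the is_a/part_of graph is not acyclic."""


@dataclass
class OntologyDAG:
    """Acyclic term graph over is_a and part_of relations.

    ``parents`` maps each term to a set of ``(parent, relation)`` pairs, with
    cross-namespace edges already dropped; ``obsolete`` terms carry no edges
    and never participate in propagation.
    """

    terms: Set[str]
    name: Dict[str, str]
    namespace: Dict[str, str]
    parents: Dict[str, Set[Tuple[str, str]]]
    obsolete: Set[str] = field(default_factory=set)
    alt_ids: Dict[str, str] = field(default_factory=dict)
    _ancestors: Dict[str, FrozenSet[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------ graph
    def graph(self) -> nx.DiGraph:
        """Child -> parent digraph over the propagation relations."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, ps in self.parents.items():
            for parent, _rel in ps:
                g.add_edge(child, parent)
        return g

    def validate(self) -> None:
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            member = next(iter(nx.find_cycle(g)))[0]
            raise CycleError(f"ontology graph contains a cycle through {member!r}")
        for term in self.obsolete:
            if self.parents.get(term):
                raise ValueError(f"obsolete term {term!r} carries edges")

    def canonical(self, term: str) -> str:
        return self.alt_ids.get(term, term)

    def ancestors(self, term: str) -> FrozenSet[str]:
        """All ancestors of ``term`` (excluding itself) via is_a/part_of."""
        cached = self._ancestors.get(term)
        if cached is not None:
            return cached
        result: Set[str] = set()
        for parent, _rel in self.parents.get(term, ()):
            result.add(parent)
            result |= self.ancestors(parent)
        frozen = frozenset(result)
        self._ancestors[term] = frozen
        return frozen

    def direct_parents(self, term: str) -> Set[str]:
        return {p for p, _ in self.parents.get(term, ())}

    def roots(self, namespace: Optional[str] = None) -> Set[str]:
        out = set()
        for t in self.terms:
            if t in self.obsolete or self.parents.get(t):
                continue
            if namespace is None or self.namespace.get(t) == namespace:
                out.add(t)
        return out

    def terms_in_namespace(self, namespace: str, include_obsolete: bool = False) -> Set[str]:
        out = {t for t in self.terms if self.namespace.get(t) == namespace}
        if not include_obsolete:
            out -= self.obsolete
        return out

    def children_map(self) -> Dict[str, Set[str]]:
        ch: Dict[str, Set[str]] = {t: set() for t in self.terms}
        for child, ps in self.parents.items():
            for parent, _ in ps:
                ch[parent].add(child)
        return ch


@dataclass
class AnnotationSet:
    """Protein -> term-set mapping for one namespace.

    ``closed`` records whether ancestor propagation has been applied; metric
    code requires closed sets.
    """

    annotations: Dict[str, Set[str]]
    namespace: str
    closed: bool = False

    def proteins(self) -> Iterable[str]:
        return self.annotations.keys()

    def term_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for terms in self.annotations.values():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
        return counts

    def restrict(self, proteins: Iterable[str]) -> "AnnotationSet":
        keep = set(proteins)
        return AnnotationSet(
            {p: set(ts) for p, ts in self.annotations.items() if p in keep},
            self.namespace,
            self.closed,
        )


IAWeights = Dict[str, float]


# ---------------------------------------------------------------------- parse
def parse_obo(stream: TextIO, namespace_map: Optional[Mapping[str, str]] = None) -> OntologyDAG:
    """Parse an OBO 1.2/1.4 flat file into an :class:`OntologyDAG`.

    Only ``is_a`` and ``relationship: part_of`` edges are retained; other
    relationship types are ignored with a warning.  Cross-namespace edges are
    dropped so each sub-ontology stands alone.  ``alt_id`` entries map to
    their canonical term.
    """
    nsmap = dict(NAMESPACE_ABBREV)
    if namespace_map:
        nsmap.update(namespace_map)
    g = obonet.read_obo(stream, ignore_obsolete=False)

    terms: Set[str] = set()
    name: Dict[str, str] = {}
    namespace: Dict[str, str] = {}
    parents: Dict[str, Set[Tuple[str, str]]] = {}
    obsolete: Set[str] = set()
    alt_ids: Dict[str, str] = {}
    ignored_relations: Set[str] = set()

    for term, attrs in g.nodes(data=True):
        terms.add(term)
        name[term] = attrs.get("name", term)
        ns = attrs.get("namespace", "toy")
        namespace[term] = nsmap.get(ns, ns)
        for alt in attrs.get("alt_id", []):
            alt_ids[alt] = term
        if str(attrs.get("is_obsolete", "")).lower() == "true":
            obsolete.add(term)

    for child, parent, rel in g.edges(keys=True):
        if rel not in PROPAGATION_RELATIONS:
            ignored_relations.add(rel)
            continue
        if child in obsolete or parent in obsolete:
            continue
        if namespace.get(child) != namespace.get(parent):
            logger.warning("dropping cross-namespace %s edge %s -> %s", rel, child, parent)
            continue
        parents.setdefault(child, set()).add((parent, rel))

    if ignored_relations:
        logger.warning("ignoring relation types: %s", sorted(ignored_relations))

    return OntologyDAG(terms, name, namespace, parents, obsolete, alt_ids)


def write_obo(dag: OntologyDAG, stream: TextIO) -> None:
    """Serialize a DAG back to a minimal OBO file (round-trip safe)."""
    inverse_ns = {v: k for k, v in NAMESPACE_ABBREV.items()}
    stream.write("format-version: 1.2\nontology: gobridge\n")
    for term in sorted(dag.terms):
        stream.write(f"\n[Term]\nid: {term}\nname: {dag.name.get(term, term)}\n")
        ns = dag.namespace.get(term, "toy")
        stream.write(f"namespace: {inverse_ns.get(ns, ns)}\n")
        for alt, canon in sorted(dag.alt_ids.items()):
            if canon == term:
                stream.write(f"alt_id: {alt}\n")
        for parent, rel in sorted(dag.parents.get(term, ())):
            if rel == "is_a":
                stream.write(f"is_a: {parent}\n")
            else:
                stream.write(f"relationship: {rel} {parent}\n")
        if term in dag.obsolete:
            stream.write("is_obsolete: true\n")


# ------------------------------------------------------------------ propagate
def propagate(annotations: AnnotationSet, dag: OntologyDAG) -> AnnotationSet:
    """Close every protein's term set under ancestor reachability.

    Idempotent; obsolete or unknown terms are a hard error naming the
    offending protein.
    """
    closed: Dict[str, Set[str]] = {}
    for protein, terms in annotations.annotations.items():
        out: Set[str] = set()
        for term in terms:
            term = dag.canonical(term)
            if term not in dag.terms:
                raise KeyError(f"term {term!r} (protein {protein!r}) not in ontology")
            if term in dag.obsolete:
                raise KeyError(f"term {term!r} (protein {protein!r}) is obsolete")
            out.add(term)
            out |= dag.ancestors(term)
        closed[protein] = out
    return AnnotationSet(closed, annotations.namespace, closed=True)


# ---------------------------------------------------------- information accretion
def information_accretion(
    annotations: AnnotationSet,
    dag: OntologyDAG,
    smoothing: bool = True,
) -> IAWeights:
    """Estimate per-term information accretion (bits) from a closed corpus.

    ia(f) = -log2 Pr(f | parents(f)) with counts over proteins whose
    annotation set contains all of f's parents.  With ``smoothing`` the
    ratio is (n_f + 1) / (n_parents + 2), keeping every value finite on
    singleton terms; a term never observed in the corpus gets ia = 0, as
    does a term whose conditioning set is empty.
    """
    if not annotations.closed:
        raise ValueError("information accretion requires a propagated (closed) annotation set")
    if not annotations.annotations:
        raise ValueError("empty corpus")

    protein_terms = list(annotations.annotations.values())
    n_total = len(protein_terms)
    ia: IAWeights = {}
    for term in dag.terms:
        if term in dag.obsolete:
            continue
        parents = dag.direct_parents(term)
        n_cond = 0
        n_joint = 0
        for terms in protein_terms:
            if parents <= terms:
                n_cond += 1
                if term in terms:
                    n_joint += 1
        if n_joint == 0 or n_cond == 0:
            ia[term] = 0.0
        elif smoothing:
            ia[term] = max(0.0, -math.log2((n_joint + 1) / (n_cond + 2)))
        else:
            ia[term] = -math.log2(n_joint / n_cond)
        # parents ⊆ terms is implied for annotated f in a closed corpus, so
        # n_joint equals the plain count of f; n_cond >= n_joint always.
        assert n_cond >= n_joint
    # root of an empty namespace etc. default to 0 via the loop above
    return ia


def write_term_table(dag: OntologyDAG, ia: IAWeights, stream: TextIO) -> None:
    """TSV export: term, name, namespace, ia."""
    stream.write("term\tname\tnamespace\tia\n")
    for term in sorted(dag.terms - dag.obsolete):
        stream.write(
            f"{term}\t{dag.name.get(term, term)}\t{dag.namespace.get(term, '')}\t"
            f"{ia.get(term, 0.0):.6f}\n"
        )
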