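"""Shared fixtures: tiny ontologies, random DAG factories, small corpora."""

from __future__ import annotations

import io
from typing import Dict, Set, Tuple

import numpy as np
import pytest

from gobridge.ontology import AnnotationSet, OntologyDAG, parse_obo


CHAIN_OBO = """\
format-version: 1.2

[Term]
id: TOY:0001
name: alpha process
namespace: toy

[Term]
id: TOY:0002
name: beta process
namespace: toy
is_a: TOY:0001

[Term]
id: TOY:0003
name: gamma process
namespace: toy
is_a: TOY:0002

[Term]
id: TOY:0009
name: dead process
namespace: toy
is_obsolete: true
"""


@pytest.fixture
def chain_dag() -> OntologyDAG:
    """A -> B -> C chain plus one obsolete term."""
    return parse_obo(io.StringIO(CHAIN_OBO))


def random_dag(rng: np.random.Generator, n_terms: int = 20,
               edge_prob: float = 0.15) -> OntologyDAG:
    """Random DAG: edges only from higher to lower index, so acyclic by
    construction; term 0 is the root."""
    terms = [f"TOY:{i:04d}" for i in range(n_terms)]
    parents: Dict[str, Set[Tuple[str, str]]] = {}
    for i in range(1, n_terms):
        choices = [j for j in range(i) if rng.random() < edge_prob]
        if not choices:
            choices = [int(rng.integers(0, i))]
        rel = ("is_a", "part_of")
        parents[terms[i]] = {(terms[j], rel[int(rng.integers(2))]) for j in choices}
    return OntologyDAG(
        terms=set(terms),
        name={t: f"name {t[-4:]}" for t in terms},
        namespace={t: "toy" for t in terms},
        parents=parents,
    )


def brute_force_closure(dag: OntologyDAG, terms: Set[str]) -> Set[str]:
    """Independent reachability oracle: iterate parent expansion to fixpoint."""
    out = set(terms)
    changed = True
    while changed:
        changed = False
        for t in list(out):
            for parent, _rel in dag.parents.get(t, ()):
                if parent not in out:
                    out.add(parent)
                    changed = True
    return out


def random_annotations(rng: np.random.Generator, dag: OntologyDAG,
                       n_proteins: int = 8, p: float = 0.2) -> AnnotationSet:
    usable = sorted(dag.terms - dag.obsolete)
    anns = {}
    for i in range(n_proteins):
        chosen = {t for t in usable if rng.random() < p}
        if chosen:
            anns[f"P{i}"] = chosen
    return AnnotationSet(anns, "toy", closed=False)
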