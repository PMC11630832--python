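"""Prediction containers: per-protein ranked GO terms with scores in [0,1],
closed under the true-path rule (an ancestor's score is at least the best
score of any of its descendants)."""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Mapping, TextIO, Tuple

import networkx as nx

from .ontology import OntologyDAG


@dataclass
class PredictionSet:
    """protein id -> {term id: score}; ``closed`` marks propagation."""

    scores: Dict[str, Dict[str, float]]
    namespace: str
    closed: bool = False

    def top_terms(self, protein: str, k: int = 10) -> List[Tuple[str, float]]:
        items = sorted(self.scores.get(protein, {}).items(), key=lambda x: (-x[1], x[0]))
        return items[:k]


def close_scores(scores: Mapping[str, float], dag: OntologyDAG) -> Dict[str, float]:
    """Propagate one protein's scores: ancestor = max(own, descendants).

    Monotone non-decreasing toward the root and idempotent.  Terms absent
    from the DAG are a hard error.
    """
    for term in scores:
        if term not in dag.terms:
            raise KeyError(f"predicted term {term!r} not in ontology")
    out = dict(scores)
    g = dag.graph()  # child -> parent edges
    for term in nx.topological_sort(g):  # children before parents
        s = out.get(term)
        if s is None:
            continue
        for parent in g.successors(term):
            if out.get(parent, 0.0) < s:
                out[parent] = s
    return out


def close_predictions(predictions: PredictionSet, dag: OntologyDAG) -> PredictionSet:
    return PredictionSet(
        {p: close_scores(s, dag) for p, s in predictions.scores.items()},
        predictions.namespace,
        closed=True,
    )


def write_predictions_jsonl(predictions: PredictionSet, dag: OntologyDAG,
                            stream: TextIO) -> None:
    for pid in sorted(predictions.scores):
        terms = [
            {"term": t, "name": dag.name.get(t, t), "score": round(float(s), 6)}
            for t, s in sorted(predictions.scores[pid].items(), key=lambda x: (-x[1], x[0]))
        ]
        stream.write(json.dumps(
            {"protein_id": pid, "namespace": predictions.namespace, "terms": terms}
        ) + "\n")


def write_predictions_tsv(predictions: PredictionSet, stream: TextIO) -> None:
    stream.write("protein_id\tterm_id\tscore\n")
    for pid in sorted(predictions.scores):
        for t, s in sorted(predictions.scores[pid].items(), key=lambda x: (-x[1], x[0])):
            stream.write(f"{pid}\t{t}\t{s:.6f}\n")


def read_predictions_tsv(stream: TextIO, namespace: str,
                         closed: bool = False) -> PredictionSet:
    scores: Dict[str, Dict[str, float]] = {}
    for i, line in enumerate(stream):
        if i == 0 and line.startswith("protein_id"):
            continue
        if not line.strip():
            continue
        pid, term, s = line.rstrip("\n").split("\t")
        scores.setdefault(pid, {})[term] = float(s)
    return PredictionSet(scores, namespace, closed=closed)
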