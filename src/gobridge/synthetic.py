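"""Desk-scale synthetic corpora with the statistical structure the bridge
model assumes: planted sequence motifs determine GO-like labels on a toy
acyclic ontology, labels can be taxonomy-conditional (the same motif confers
a term only in some taxa, emulating homologs with divergent function), and
homolog pairs can be generated at a controlled pairwise identity to exercise
the leakage-free splitting machinery.

Sequences are background residues drawn uniformly over the 20 amino acids
(configurable) with motifs of length 4-8 inserted at non-overlapping
positions; a protein's noise-free label set is exactly the propagated
ancestor closure of its inserted motifs' terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np

from .corpus import AMINO_ACIDS, ProteinRecord, pairwise_identity, write_annotations_tsv, write_fasta
from .ontology import AnnotationSet, OntologyDAG, write_obo

TOY_NAMESPACE = "toy"

# word bank for synthetic English-like term names, so the text decoder has
# token structure to model
_ADJECTIVES = [
    "alpha", "beta", "gamma", "delta", "acidic", "basic", "polar", "cyclic",
    "terminal", "core", "outer", "inner", "rapid", "slow", "dual", "mono",
]
_NOUNS = [
    "binding", "kinase", "transport", "folding", "cleavage", "assembly",
    "signaling", "repair", "synthesis", "exchange", "adhesion", "transfer",
    "docking", "sensing", "gating", "capping",
]
_SUFFIXES = ["activity", "process", "function", "complex", "pathway", "site"]


@dataclass
class MotifGrammar:
    """Maps planted motifs to toy-ontology terms.

    ``motifs``: unconditional (motif, leaf term) rules.
    ``taxonomy_rules``: (motif, term, allowed taxa) — the term is granted
    only when the protein's taxonomy token is in the allowed set.
    ``label_noise``: probability of dropping a true term from the *emitted*
    annotations (the noise-free truth is always returned separately).
    """

    motifs: List[Tuple[str, str]]
    taxonomy_rules: List[Tuple[str, str, FrozenSet[str]]] = field(default_factory=list)
    background_freqs: Optional[Dict[str, float]] = None
    label_noise: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.label_noise < 1.0:
            raise ValueError("label_noise must be in [0, 1)")
        strings = [m for m, _ in self.motifs] + [m for m, _t, _x in self.taxonomy_rules]
        for i, a in enumerate(strings):
            for j, b in enumerate(strings):
                if i != j and a != b and a in b:
                    raise ValueError(f"motif {a!r} is a substring of {b!r}")

    def validate_against(self, dag: OntologyDAG) -> None:
        for _m, term in self.motifs:
            if term not in dag.terms:
                raise ValueError(f"grammar term {term!r} not in ontology")
        for _m, term, _taxa in self.taxonomy_rules:
            if term not in dag.terms:
                raise ValueError(f"grammar term {term!r} not in ontology")

    def all_motifs(self) -> List[str]:
        seen: List[str] = []
        for m, _ in self.motifs:
            if m not in seen:
                seen.append(m)
        for m, _t, _x in self.taxonomy_rules:
            if m not in seen:
                seen.append(m)
        return seen


def _term_id(i: int) -> str:
    return f"TOY:{i:04d}"


def _term_names(n: int, rng: np.random.Generator) -> List[str]:
    names: List[str] = []
    used: Set[str] = set()
    while len(names) < n:
        name = " ".join(
            [
                _ADJECTIVES[rng.integers(len(_ADJECTIVES))],
                _NOUNS[rng.integers(len(_NOUNS))],
                _SUFFIXES[rng.integers(len(_SUFFIXES))],
            ]
        )
        if name not in used:
            used.add(name)
            names.append(name)
    return names


def generate_toy_ontology(
    n_leaves: int,
    depth: int = 3,
    branching: int = 2,
    seed: int = 0,
    multi_parent_fraction: float = 0.10,
) -> OntologyDAG:
    """Rooted acyclic toy ontology with ``n_leaves`` deepest-level terms.

    Built as a balanced ``branching``-ary tree of the given depth, pruned to
    the requested leaf count; a fraction of non-root terms then receive a
    second parent one level up (never introducing a cycle).
    """
    if n_leaves < 2 or depth < 2:
        raise ValueError("need n_leaves >= 2 and depth >= 2")
    if branching**depth < n_leaves:
        raise ValueError(
            f"branching**depth = {branching**depth} cannot host {n_leaves} leaves"
        )
    rng = np.random.default_rng(seed)
    levels: List[List[str]] = [[_term_id(1)]]
    next_id = 2
    parents: Dict[str, Set[Tuple[str, str]]] = {}
    for level in range(1, depth + 1):
        width = min(branching ** level, n_leaves) if level == depth else branching ** level
        if level == depth:
            width = n_leaves
        row: List[str] = []
        for i in range(width):
            term = _term_id(next_id)
            next_id += 1
            parent = levels[level - 1][i % len(levels[level - 1])]
            parents[term] = {(parent, "is_a")}
            row.append(term)
        levels.append(row)

    # occasional multi-parent nodes: a second is_a parent from the level above
    non_root = [t for row in levels[1:] for t in row]
    term_level = {t: lvl for lvl, row in enumerate(levels) for t in row}
    n_extra = int(math.floor(multi_parent_fraction * len(non_root)))
    candidates = [t for t in non_root if len(levels[term_level[t] - 1]) > 1]
    rng.shuffle(candidates)
    for term in candidates[:n_extra]:
        above = levels[term_level[term] - 1]
        existing = {p for p, _ in parents[term]}
        options = [p for p in above if p not in existing]
        if options:
            parents[term].add((options[rng.integers(len(options))], "is_a"))

    terms = {t for row in levels for t in row}
    names = dict(zip(sorted(terms), _term_names(len(terms), rng)))
    names[_term_id(1)] = "toy root process"
    namespace = {t: TOY_NAMESPACE for t in terms}
    return OntologyDAG(terms, names, namespace, parents)


def leaf_terms(dag: OntologyDAG) -> List[str]:
    have_children = {p for ps in dag.parents.values() for p, _ in ps}
    return sorted(t for t in dag.terms - dag.obsolete if t not in have_children)


def default_grammar(
    dag: OntologyDAG,
    seed: int = 0,
    motif_length: Tuple[int, int] = (5, 7),
    label_noise: float = 0.05,
    taxonomy_leaves: int = 0,
    taxa: Sequence[str] = (),
) -> MotifGrammar:
    """One motif per leaf term; optionally the last ``taxonomy_leaves`` leaves
    become taxonomy-conditional, granted only to the first taxon in ``taxa``."""
    rng = np.random.default_rng(seed)
    leaves = leaf_terms(dag)
    if taxonomy_leaves and not taxa:
        raise ValueError("taxonomy-conditional rules need a taxa list")
    motifs: List[str] = []
    while len(motifs) < len(leaves):
        length = int(rng.integers(motif_length[0], motif_length[1] + 1))
        m = "".join(AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=length))
        if any(m in other or other in m for other in motifs):
            continue
        motifs.append(m)
    plain = leaves[: len(leaves) - taxonomy_leaves]
    conditional = leaves[len(leaves) - taxonomy_leaves:]
    grammar = MotifGrammar(
        motifs=[(m, t) for m, t in zip(motifs, plain)],
        taxonomy_rules=[
            (m, t, frozenset({taxa[0]}))
            for m, t in zip(motifs[len(plain):], conditional)
        ],
        label_noise=label_noise,
    )
    grammar.validate_against(dag)
    return grammar


def _background(rng: np.random.Generator, length: int,
                freqs: Optional[Dict[str, float]]) -> List[str]:
    if freqs is None:
        idx = rng.integers(0, len(AMINO_ACIDS), size=length)
        return [AMINO_ACIDS[i] for i in idx]
    letters = sorted(freqs)
    probs = np.array([freqs[c] for c in letters], dtype=float)
    probs = probs / probs.sum()
    return list(rng.choice(letters, size=length, p=probs))


def _labels_for(motifs: Sequence[str], grammar: MotifGrammar,
                taxon: Optional[str]) -> Set[str]:
    labels: Set[str] = set()
    present = set(motifs)
    for m, term in grammar.motifs:
        if m in present:
            labels.add(term)
    for m, term, allowed in grammar.taxonomy_rules:
        if m in present and taxon is not None and taxon in allowed:
            labels.add(term)
    return labels


def generate_corpus(
    grammar: MotifGrammar,
    dag: OntologyDAG,
    n_proteins: int,
    length_range: Tuple[int, int] = (50, 300),
    motif_rate: float = 2.0,
    taxa: Sequence[str] = (),
    seed: int = 0,
) -> Tuple[List[ProteinRecord], AnnotationSet]:
    """Generate motif-labelled proteins plus their noise-free closed truth.

    Each protein is background sequence with Poisson(``motif_rate``) distinct
    motifs inserted at non-overlapping positions.  Emitted record annotations
    have each true term dropped independently with ``grammar.label_noise``;
    the returned :class:`AnnotationSet` is the noise-free propagated truth.
    """
    grammar.validate_against(dag)
    all_motifs = grammar.all_motifs()
    max_motif = max((len(m) for m in all_motifs), default=0)
    if length_range[0] < 2 * max_motif:
        raise ValueError(
            f"length_range[0]={length_range[0]} too small for motifs up to {max_motif}"
        )
    rng = np.random.default_rng(seed)
    records: List[ProteinRecord] = []
    truth: Dict[str, Set[str]] = {}
    for i in range(n_proteins):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = _background(rng, length, grammar.background_freqs)
        k = min(int(rng.poisson(motif_rate)), len(all_motifs))
        chosen = [all_motifs[j] for j in rng.choice(len(all_motifs), size=k, replace=False)] if k else []
        occupied: List[Tuple[int, int]] = []
        placed: List[str] = []
        for m in chosen:
            for _attempt in range(200):
                start = int(rng.integers(0, length - len(m) + 1))
                span = (start, start + len(m))
                if all(span[1] <= a or span[0] >= b for a, b in occupied):
                    occupied.append(span)
                    seq[span[0]:span[1]] = list(m)
                    placed.append(m)
                    break
        taxon = str(taxa[int(rng.integers(len(taxa)))]) if taxa else None
        pid = f"SYN{i:05d}"
        true_terms = _labels_for(placed, grammar, taxon)
        true_closed: Set[str] = set()
        for t in true_terms:
            true_closed.add(t)
            true_closed |= dag.ancestors(t)
        truth[pid] = true_closed
        emitted = {t for t in true_terms if rng.random() >= grammar.label_noise}
        records.append(
            ProteinRecord(
                pid,
                "".join(seq),
                taxon,
                {TOY_NAMESPACE: {(t, "EXP") for t in emitted}} if emitted else {},
            )
        )
    return records, AnnotationSet(truth, TOY_NAMESPACE, closed=True)


def motif_spans(sequence: str, grammar: MotifGrammar) -> List[Tuple[int, int]]:
    spans: List[Tuple[int, int]] = []
    for m in grammar.all_motifs():
        start = sequence.find(m)
        while start != -1:
            spans.append((start, start + len(m)))
            start = sequence.find(m, start + 1)
    return spans


def generate_homolog_pair(
    record: ProteinRecord,
    target_identity: float,
    seed: int = 0,
    preserve_motifs: bool = True,
    grammar: Optional[MotifGrammar] = None,
    tolerance: float = 0.05,
    max_attempts: int = 100,
) -> ProteinRecord:
    """Point-mutated copy whose measured identity is within ``tolerance`` of
    ``target_identity``.  With ``preserve_motifs`` (requires ``grammar``)
    mutations avoid motif spans; otherwise motifs may be ablated, changing
    the grammar-implied labels."""
    if not 0.0 < target_identity <= 1.0:
        raise ValueError("target_identity must be in (0, 1]")
    if target_identity == 1.0:
        return ProteinRecord(record.id + "_h", record.sequence, record.taxonomy,
                             {ns: set(a) for ns, a in record.annotations.items()})
    rng = np.random.default_rng(seed)
    seq = record.sequence
    protected: Set[int] = set()
    if preserve_motifs and grammar is not None:
        # without a grammar there are no motif spans to protect
        for a, b in motif_spans(seq, grammar):
            protected.update(range(a, b))
    mutable = [i for i in range(len(seq)) if i not in protected]
    n_mut = int(round((1.0 - target_identity) * len(seq)))
    for attempt in range(max_attempts):
        if n_mut > len(mutable):
            raise ValueError("cannot reach target identity with protected motifs")
        chars = list(seq)
        sites = rng.choice(len(mutable), size=n_mut, replace=False) if n_mut else []
        for s in sites:
            i = mutable[s]
            options = [c for c in AMINO_ACIDS if c != seq[i]]
            chars[i] = options[int(rng.integers(len(options)))]
        mutated = "".join(chars)
        measured = pairwise_identity(seq, mutated)
        if abs(measured - target_identity) <= tolerance:
            return ProteinRecord(record.id + "_h", mutated, record.taxonomy,
                                 {ns: set(a) for ns, a in record.annotations.items()})
        n_mut += 1 if measured > target_identity else -1
        n_mut = max(0, n_mut)
    raise RuntimeError(
        f"could not hit identity {target_identity} within {max_attempts} attempts"
    )


def write_corpus(
    directory: Path,
    records: Sequence[ProteinRecord],
    dag: OntologyDAG,
    truth: Optional[AnnotationSet] = None,
) -> None:
    """FASTA + annotation TSV + OBO (+ noise-free truth TSV), so the
    synthetic corpus flows through the real pipeline unchanged."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "sequences.fasta", "w") as fh:
        write_fasta(records, fh)
    with open(directory / "annotations.tsv", "w") as fh:
        write_annotations_tsv(records, fh)
    with open(directory / "ontology.obo", "w") as fh:
        write_obo(dag, fh)
    if truth is not None:
        with open(directory / "truth.tsv", "w") as fh:
            fh.write("protein_id\tterm_id\n")
            for pid in sorted(truth.annotations):
                for t in sorted(truth.annotations[pid]):
                    fh.write(f"{pid}\t{t}\n")
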