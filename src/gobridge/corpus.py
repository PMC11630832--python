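"""Training-corpus construction: filtering, identity clustering, splitting.

Annotated protein corpora are filtered to sequences of 10-1024 residues and
to experimentally supported annotations (evidence codes EXP, IDA, IPI, IMP,
IGI, IEP, TAS, IC, HTP, HDA, HMP, HGI, HEP), then grouped by pairwise
sequence identity so that homologs (>50% identity) never straddle a
train/validation/test boundary; whole groups are allocated 90/5/5.

Pairwise identity uses an affine-gap Smith-Waterman local alignment
(Bio.Align.PairwiseAligner) with identity defined as identical aligned
positions divided by the shorter sequence length — conservative, so
fragments cluster with their parents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, TextIO, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner

from .ontology import AnnotationSet

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"

#: experimental and high-throughput evidence codes used for the curated corpus
EXPERIMENTAL_EVIDENCE_CODES = frozenset(
    {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "TAS", "IC",
     "HTP", "HDA", "HMP", "HGI", "HEP"}
)

KNOWN_EVIDENCE_CODES = EXPERIMENTAL_EVIDENCE_CODES | frozenset(
    {"IEA", "ISS", "ISO", "ISA", "ISM", "IGC", "IBA", "IBD", "IKR", "IRD", "RCA", "NAS", "ND"}
)

SPLITS = ("train", "val", "test")


@dataclass
class ProteinRecord:
    """One protein: id, sequence, optional taxonomy token, annotations.

    ``annotations`` maps namespace -> set of (term id, evidence code).
    """

    id: str
    sequence: str
    taxonomy: Optional[str] = None
    annotations: Dict[str, Set[Tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")

    def terms(self, namespace: str) -> Set[str]:
        return {t for t, _ev in self.annotations.get(namespace, set())}


@dataclass
class ClusterAssignment:
    """Protein -> cluster and cluster -> split mapping."""

    protein_to_cluster: Dict[str, int]
    cluster_to_split: Dict[int, str] = field(default_factory=dict)

    def split_of(self, protein: str) -> Optional[str]:
        cluster = self.protein_to_cluster.get(protein)
        return self.cluster_to_split.get(cluster) if cluster is not None else None

    def proteins_in_split(self, split: str) -> List[str]:
        return [p for p in self.protein_to_cluster if self.split_of(p) == split]


# ------------------------------------------------------------------ filtering
def filter_by_length(records: Iterable[ProteinRecord], min_len: int = 10,
                     max_len: int = 1024) -> List[ProteinRecord]:
    """Keep records with min_len <= length <= max_len; order preserved."""
    kept = [r for r in records if min_len <= len(r.sequence) <= max_len]
    if not kept:
        logger.warning("length filter removed every record")
    return kept


def filter_by_evidence(
    records: Iterable[ProteinRecord],
    allowed: frozenset = EXPERIMENTAL_EVIDENCE_CODES,
) -> List[ProteinRecord]:
    """Keep only annotations whose evidence code is in ``allowed``.

    Records left without annotations in a namespace lose that namespace
    entry; records with no annotations at all are dropped.
    """
    if not allowed:
        raise ValueError("allowed evidence code set is empty")
    unknown = set(allowed) - KNOWN_EVIDENCE_CODES
    if unknown:
        logger.warning("unknown evidence codes in allowed set: %s", sorted(unknown))
    out: List[ProteinRecord] = []
    for r in records:
        filtered = {
            ns: {(t, ev) for t, ev in anns if ev in allowed}
            for ns, anns in r.annotations.items()
        }
        filtered = {ns: anns for ns, anns in filtered.items() if anns}
        if filtered:
            out.append(ProteinRecord(r.id, r.sequence, r.taxonomy, filtered))
    return out


# ----------------------------------------------------------- pairwise identity
def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.5
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical positions in the optimal local alignment,
    normalized by the shorter sequence length.  Symmetric; 1.0 on self."""
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    if seq_a == seq_b:
        return 1.0
    alignments = _ALIGNER.align(seq_a, seq_b)
    if len(alignments) == 0 or alignments.score <= 0:
        return 0.0
    aln = alignments[0]
    ident = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for i in range(a1 - a0):
            if seq_a[a0 + i] == seq_b[b0 + i]:
                ident += 1
    return ident / min(len(seq_a), len(seq_b))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _kmer_sets(seqs: Sequence[str], k: int = 5) -> List[Set[str]]:
    return [{s[i:i + k] for i in range(len(s) - k + 1)} for s in seqs]


def cluster_by_identity(
    records: Sequence[ProteinRecord],
    threshold: float = 0.5,
    prefilter_above: int = 5000,
) -> ClusterAssignment:
    """Single-linkage components of the identity > threshold graph.

    All-vs-all alignment; above ``prefilter_above`` records a shared-5-mer
    prefilter skips pairs that cannot plausibly exceed the threshold.
    Deterministic given input order (cluster ids follow first occurrence).
    """
    if not records:
        raise ValueError("no records to cluster")
    n = len(records)
    seqs = [r.sequence for r in records]
    uf = _UnionFind(n)
    kmers = _kmer_sets(seqs) if n > prefilter_above else None
    for i in range(n):
        for j in range(i + 1, n):
            if uf.find(i) == uf.find(j):
                continue
            if kmers is not None and not (kmers[i] & kmers[j]):
                continue
            if pairwise_identity(seqs[i], seqs[j]) > threshold:
                uf.union(i, j)
    root_to_cluster: Dict[int, int] = {}
    assignment: Dict[str, int] = {}
    for i, r in enumerate(records):
        root = uf.find(i)
        if root not in root_to_cluster:
            root_to_cluster[root] = len(root_to_cluster)
        assignment[r.id] = root_to_cluster[root]
    return ClusterAssignment(assignment)


def split_clusters(
    assignment: ClusterAssignment,
    fractions: Tuple[float, float, float] = (0.90, 0.05, 0.05),
    seed: int = 0,
) -> ClusterAssignment:
    """Shuffle clusters and partition them (not proteins) into train/val/test.

    Fractions apply to cluster counts via largest-remainder apportionment, so
    100 singleton clusters at (0.9, 0.05, 0.05) give exactly 90/5/5.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    clusters = sorted(set(assignment.protein_to_cluster.values()))
    if not clusters:
        raise ValueError("no clusters to split")
    rng = np.random.default_rng(seed)
    order = [clusters[i] for i in rng.permutation(len(clusters))]

    n = len(order)
    quotas = [f * n for f in fractions]
    counts = [int(q) for q in quotas]
    remainders = sorted(range(3), key=lambda i: quotas[i] - counts[i], reverse=True)
    for i in remainders:
        if sum(counts) == n:
            break
        counts[i] += 1

    cluster_to_split: Dict[int, str] = {}
    start = 0
    for label, count in zip(SPLITS, counts):
        for c in order[start:start + count]:
            cluster_to_split[c] = label
        start += count
    for label, count, frac in zip(SPLITS, counts, fractions):
        if frac > 0 and count == 0:
            logger.warning("split %r is empty (%d clusters total)", label, n)
    return ClusterAssignment(dict(assignment.protein_to_cluster), cluster_to_split)


# ------------------------------------------------------------------------- IO
def read_fasta(stream: TextIO) -> List[ProteinRecord]:
    records = []
    for rec in SeqIO.parse(stream, "fasta"):
        taxonomy = None
        for part in rec.description.split()[1:]:
            if part.startswith("taxonomy="):
                taxonomy = part.split("=", 1)[1]
        records.append(ProteinRecord(rec.id, str(rec.seq).upper(), taxonomy))
    return records


def write_fasta(records: Iterable[ProteinRecord], stream: TextIO) -> None:
    for r in records:
        tax = f" taxonomy={r.taxonomy}" if r.taxonomy else ""
        stream.write(f">{r.id}{tax}\n{r.sequence}\n")


def read_annotations_tsv(stream: TextIO, default_namespace: str = "toy") -> Dict[str, Set[Tuple[str, str, str]]]:
    """Read a 3+ column TSV: protein_id, term_id, evidence[, namespace].

    Returns protein -> set of (term, evidence, namespace).
    """
    out: Dict[str, Set[Tuple[str, str, str]]] = {}
    for line_no, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#") or (line_no == 1 and line.startswith("protein")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"annotation TSV line {line_no}: expected >=3 columns")
        pid, term, ev = parts[0], parts[1], parts[2]
        ns = parts[3] if len(parts) > 3 and parts[3] else default_namespace
        out.setdefault(pid, set()).add((term, ev, ns))
    return out


GAF_ASPECT_TO_NAMESPACE = {"F": "MFO", "P": "BPO", "C": "CCO"}


def read_annotations_gaf(stream: TextIO) -> Dict[str, Set[Tuple[str, str, str]]]:
    """Read GAF 2.x: columns 2 (id), 5 (GO id), 7 (evidence), 9 (aspect)."""
    out: Dict[str, Set[Tuple[str, str, str]]] = {}
    for line in stream:
        if line.startswith("!") or not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 9:
            continue
        pid, term, ev, aspect = parts[1], parts[4], parts[6], parts[8]
        ns = GAF_ASPECT_TO_NAMESPACE.get(aspect, aspect)
        out.setdefault(pid, set()).add((term, ev, ns))
    return out


def write_annotations_tsv(records: Iterable[ProteinRecord], stream: TextIO) -> None:
    stream.write("protein_id\tterm_id\tevidence\tnamespace\n")
    for r in records:
        for ns in sorted(r.annotations):
            for term, ev in sorted(r.annotations[ns]):
                stream.write(f"{r.id}\t{term}\t{ev}\t{ns}\n")


def attach_annotations(records: Sequence[ProteinRecord],
                       annotations: Mapping[str, Set[Tuple[str, str, str]]]) -> List[ProteinRecord]:
    out = []
    for r in records:
        anns: Dict[str, Set[Tuple[str, str]]] = {}
        for term, ev, ns in annotations.get(r.id, set()):
            anns.setdefault(ns, set()).add((term, ev))
        out.append(ProteinRecord(r.id, r.sequence, r.taxonomy, anns))
    return out


def write_split_manifest(assignment: ClusterAssignment, stream: TextIO) -> None:
    stream.write("protein_id\tcluster_id\tsplit\n")
    for pid in sorted(assignment.protein_to_cluster):
        cluster = assignment.protein_to_cluster[pid]
        stream.write(f"{pid}\t{cluster}\t{assignment.cluster_to_split.get(cluster, '')}\n")


def read_split_manifest(stream: TextIO) -> ClusterAssignment:
    p2c: Dict[str, int] = {}
    c2s: Dict[int, str] = {}
    for line_no, line in enumerate(stream):
        if line_no == 0 and line.startswith("protein_id"):
            continue
        if not line.strip():
            continue
        pid, cluster, split = line.rstrip("\n").split("\t")
        p2c[pid] = int(cluster)
        if split:
            c2s[int(cluster)] = split
    return ClusterAssignment(p2c, c2s)


def annotation_set(records: Sequence[ProteinRecord], namespace: str) -> AnnotationSet:
    """Unclosed AnnotationSet for one namespace from a record list."""
    return AnnotationSet(
        {r.id: r.terms(namespace) for r in records if r.terms(namespace)},
        namespace,
        closed=False,
    )
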