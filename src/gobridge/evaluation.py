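"""Protein-centric and pair-centric evaluation of GO-term predictions.

Implements the CAFA-style metric family: Fmax (maximum protein-centric F1
over score thresholds), WFmax (the same with information-accretion weights),
Smin (minimum Euclidean combination of ia-weighted remaining uncertainty and
misinformation), micro AUPR over (protein, term) pairs, the naive
frequency baseline S_{p,f} = N_f / N_total, and per-frequency-bin F1.

Conventions: protein-centric precision averages only over proteins with at
least one prediction at the threshold; recall averages over all
truth-bearing proteins; namespace roots are excluded from scoring by
default; threshold ties break toward the larger threshold.  F1 is the
harmonic mean of precision and recall (the standard definition); a
geometric-mean variant is available behind ``f_mean="geometric"`` for
auditability.
"""

from __future__ import annotations

import bisect
import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, TextIO, Tuple

import numpy as np
from sklearn.metrics import average_precision_score

from .ontology import AnnotationSet, IAWeights, OntologyDAG
from .prediction import PredictionSet

Predictions = Mapping[str, Mapping[str, float]]
Truth = Mapping[str, Set[str]]

DEFAULT_TAU_GRID = np.round(np.arange(0.01, 1.001, 0.01), 2)
FREQUENCY_BIN_EDGES = (0, 20, 50, 200, 1000)
FREQUENCY_BIN_LABELS = ("0-20", "20-50", "50-200", "200-1000", "1000+")


@dataclass
class EvaluationReport:
    namespace: str
    fmax: float
    fmax_threshold: float
    wfmax: float
    wfmax_threshold: float
    smin: float
    smin_threshold: float
    aupr: float
    pr_curve: List[Tuple[float, float, float]] = field(default_factory=list)
    bin_f1: Dict[str, float] = field(default_factory=dict)

    def to_json(self, stream: TextIO) -> None:
        json.dump(
            {
                "namespace": self.namespace,
                "fmax": self.fmax,
                "fmax_threshold": self.fmax_threshold,
                "wfmax": self.wfmax,
                "wfmax_threshold": self.wfmax_threshold,
                "smin": self.smin,
                "smin_threshold": self.smin_threshold,
                "aupr": self.aupr,
                "bin_f1": self.bin_f1,
            },
            stream,
            indent=2,
        )


# --------------------------------------------------------------- naive model
@dataclass
class NaiveModel:
    """Every protein receives every term's training frequency as its score."""

    term_scores: Dict[str, float]

    def predict(self, proteins: Iterable[str], namespace: str) -> PredictionSet:
        return PredictionSet(
            {p: dict(self.term_scores) for p in proteins}, namespace, closed=True
        )


def naive_baseline(training: AnnotationSet) -> NaiveModel:
    """Score(f) = N_f / N_total over the closed training corpus."""
    if not training.annotations:
        raise ValueError("empty training corpus")
    if not training.closed:
        raise ValueError("naive baseline requires a closed annotation set")
    n_total = len(training.annotations)
    counts = training.term_counts()
    return NaiveModel({t: c / n_total for t, c in counts.items()})


# ------------------------------------------------------------ threshold sweep
def _resolve_taus(predictions: Predictions, taus) -> np.ndarray:
    if taus is None:
        return DEFAULT_TAU_GRID
    if isinstance(taus, str) and taus == "distinct":
        values = sorted({s for d in predictions.values() for s in d.values() if s > 0})
        return np.array(values if values else [1.0])
    return np.asarray(taus, dtype=float)


def _effective(truth: Truth, exclude: Optional[Set[str]]) -> Dict[str, Set[str]]:
    ex = exclude or set()
    eff = {p: t - ex for p, t in truth.items()}
    eff = {p: t for p, t in eff.items() if t}
    if not eff:
        raise ValueError("no truth-bearing proteins after root exclusion")
    return eff


def _weight(terms: Set[str], ia: Optional[IAWeights]) -> float:
    if ia is None:
        return float(len(terms))
    return float(sum(ia.get(t, 0.0) for t in terms))


def precision_recall_at(
    predictions: Predictions,
    truth: Dict[str, Set[str]],
    tau: float,
    ia: Optional[IAWeights] = None,
    exclude: Optional[Set[str]] = None,
) -> Tuple[float, float, int]:
    """Protein-centric (precision, recall, n_covered) at one threshold."""
    ex = exclude or set()
    prec_sum, n_covered, rec_sum = 0.0, 0, 0.0
    for protein, true_terms in truth.items():
        pred = {t for t, s in predictions.get(protein, {}).items() if s >= tau} - ex
        if pred:
            n_covered += 1
            prec_sum += _weight(pred & true_terms, ia) / _weight(pred, ia)
        rec_sum += _weight(pred & true_terms, ia) / _weight(true_terms, ia)
    precision = prec_sum / n_covered if n_covered else 0.0
    recall = rec_sum / len(truth)
    return precision, recall, n_covered


def _f_measure(precision: float, recall: float, f_mean: str) -> float:
    if f_mean == "harmonic":
        return 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    if f_mean == "geometric":
        return math.sqrt(precision * recall)
    raise ValueError(f"unknown f_mean {f_mean!r}")


def fmax(
    predictions: Predictions,
    truth: Truth,
    taus=None,
    ia: Optional[IAWeights] = None,
    exclude: Optional[Set[str]] = None,
    f_mean: str = "harmonic",
) -> Tuple[float, float]:
    """Maximum protein-centric F over the threshold grid; (Fmax, tau*).

    With ``ia`` set this is WFmax.  Ties break toward the larger threshold.
    """
    if not truth:
        raise ValueError("empty truth")
    eff = _effective(truth, exclude)
    best, best_tau = 0.0, 0.0
    for tau in _resolve_taus(predictions, taus):
        p, r, _ = precision_recall_at(predictions, eff, float(tau), ia, exclude)
        f = _f_measure(p, r, f_mean)
        if f >= best:
            best, best_tau = f, float(tau)
    return best, best_tau


def wfmax(
    predictions: Predictions,
    truth: Truth,
    ia: IAWeights,
    taus=None,
    exclude: Optional[Set[str]] = None,
    f_mean: str = "harmonic",
) -> Tuple[float, float]:
    """Information-accretion-weighted Fmax; reduces to fmax when ia = 1."""
    if any(v < 0 for v in ia.values()):
        raise ValueError("negative information accretion weight")
    return fmax(predictions, truth, taus=taus, ia=ia, exclude=exclude, f_mean=f_mean)


def smin(
    predictions: Predictions,
    truth: Truth,
    ia: IAWeights,
    taus=None,
    exclude: Optional[Set[str]] = None,
) -> Tuple[float, float]:
    """Minimum semantic distance sqrt(ru^2 + mi^2) over thresholds.

    ru = mean ia-mass of missed truth; mi = mean ia-mass of wrong
    predictions; both averaged over all truth-bearing proteins.
    """
    if any(v < 0 for v in ia.values()):
        raise ValueError("negative information accretion weight")
    if not truth:
        raise ValueError("empty truth")
    eff = _effective(truth, exclude)
    ex = exclude or set()
    best, best_tau = math.inf, 0.0
    for tau in _resolve_taus(predictions, taus):
        ru_sum, mi_sum = 0.0, 0.0
        for protein, true_terms in eff.items():
            pred = {t for t, s in predictions.get(protein, {}).items() if s >= float(tau)} - ex
            ru_sum += _weight(true_terms - pred, ia)
            mi_sum += _weight(pred - true_terms, ia)
        n = len(eff)
        s = math.hypot(ru_sum / n, mi_sum / n)
        if s <= best:
            best, best_tau = s, float(tau)
    return best, best_tau


def aupr(
    predictions: Predictions,
    truth: Truth,
    exclude: Optional[Set[str]] = None,
) -> float:
    """Micro (pair-centric) area under the precision-recall curve.

    Label space = all truth terms of the namespace (roots excluded); area by
    the step-wise precision-at-recall-change rule.
    """
    eff = _effective(truth, exclude)
    label_space = sorted(set().union(*eff.values()))
    y, s = [], []
    for protein, true_terms in eff.items():
        pred = predictions.get(protein, {})
        for term in label_space:
            y.append(1 if term in true_terms else 0)
            s.append(float(pred.get(term, 0.0)))
    if not any(y):
        raise ValueError("no positive (protein, term) pairs")
    return float(average_precision_score(np.array(y), np.array(s)))


def pr_curve(
    predictions: Predictions,
    truth: Truth,
    taus=None,
    exclude: Optional[Set[str]] = None,
) -> List[Tuple[float, float, float]]:
    """(tau, precision, recall) rows, thresholds strictly decreasing."""
    eff = _effective(truth, exclude)
    rows = []
    for tau in sorted(_resolve_taus(predictions, taus), reverse=True):
        p, r, _ = precision_recall_at(predictions, eff, float(tau), None, exclude)
        rows.append((float(tau), p, r))
    return rows


def write_pr_curve(rows: Sequence[Tuple[float, float, float]], stream: TextIO) -> None:
    stream.write("threshold\tprecision\trecall\n")
    for tau, p, r in rows:
        stream.write(f"{tau:.4f}\t{p:.6f}\t{r:.6f}\n")


# ------------------------------------------------------------- binned per-term F1
def frequency_bin(count: int) -> str:
    """Left-closed bins over training occurrence counts; 20 -> '20-50'."""
    return FREQUENCY_BIN_LABELS[bisect.bisect_right(FREQUENCY_BIN_EDGES, count) - 1]


def frequency_binned_f1(
    predictions: Predictions,
    truth: Truth,
    train_counts: Mapping[str, int],
    tau: float,
    exclude: Optional[Set[str]] = None,
) -> Dict[str, float]:
    """Mean per-term F1 at ``tau``, grouped by training-set term frequency.

    Terms are the truth label space; a term's F1 counts proteins where it is
    predicted (score >= tau) against proteins where it is true.  Empty bins
    are absent from the result.
    """
    eff = _effective(truth, exclude)
    label_space = sorted(set().union(*eff.values()))
    per_bin: Dict[str, List[float]] = {}
    for term in label_space:
        tp = fp = fn = 0
        for protein, true_terms in eff.items():
            predicted = predictions.get(protein, {}).get(term, 0.0) >= tau
            if predicted and term in true_terms:
                tp += 1
            elif predicted:
                fp += 1
            elif term in true_terms:
                fn += 1
        denom = 2 * tp + fp + fn
        f1 = 2 * tp / denom if denom else 0.0
        per_bin.setdefault(frequency_bin(int(train_counts.get(term, 0))), []).append(f1)
    return {b: float(np.mean(v)) for b, v in per_bin.items()}


# ---------------------------------------------------------------- orchestrator
def evaluate(
    predictions: PredictionSet,
    truth: AnnotationSet,
    train_annotations: AnnotationSet,
    dag: OntologyDAG,
    ia: Optional[IAWeights] = None,
    taus=None,
    exclude_roots: bool = True,
) -> EvaluationReport:
    """Full report: Fmax, WFmax, Smin, AUPR, PR curve, per-bin F1."""
    if not truth.closed or not train_annotations.closed:
        raise ValueError("truth and training annotations must be closed")
    from .ontology import information_accretion

    ns = truth.namespace
    exclude = dag.roots(ns) if exclude_roots else set()
    if ia is None:
        ia = information_accretion(train_annotations, dag)
    preds = predictions.scores
    tr = truth.annotations
    f, f_tau = fmax(preds, tr, taus=taus, exclude=exclude)
    wf, wf_tau = wfmax(preds, tr, ia, taus=taus, exclude=exclude)
    s, s_tau = smin(preds, tr, ia, taus=taus, exclude=exclude)
    a = aupr(preds, tr, exclude=exclude)
    curve = pr_curve(preds, tr, taus=taus, exclude=exclude)
    bins = frequency_binned_f1(preds, tr, train_annotations.term_counts(), f_tau, exclude)
    return EvaluationReport(
        namespace=ns,
        fmax=f, fmax_threshold=f_tau,
        wfmax=wf, wfmax_threshold=wf_tau,
        smin=s, smin_threshold=s_tau,
        aupr=a,
        pr_curve=curve,
        bin_f1=bins,
    )
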