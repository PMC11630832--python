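"""End-to-end pipeline: simulate -> build corpus -> train -> predict ->
evaluate, with every artifact written under one run directory and every
random choice derived from a single root seed (child k uses
``SeedSequence([root_seed, k])``), so re-running a config reproduces the
report bit-identically on one device."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Tuple

from . import corpus as corpus_mod
from . import synthetic
from .bridge import BridgeConfig
from .evaluation import evaluate, naive_baseline, write_pr_curve
from .ontology import AnnotationSet, OntologyDAG, information_accretion, write_term_table
from .prediction import PredictionSet, close_predictions, write_predictions_jsonl, write_predictions_tsv
from .training import SplitCorpus, TrainConfig, _child_seed, _EmbeddingCache, score_vocabulary_batch, train

logger = logging.getLogger(__name__)


@dataclass
class SimulateConfig:
    n_proteins: int = 1000
    n_leaves: int = 12
    depth: int = 3
    branching: int = 3
    label_noise: float = 0.05
    motif_rate: float = 2.0
    length_range: Tuple[int, int] = (50, 300)
    taxa: Tuple[str, ...] = ("Homo", "Phasianus")
    taxonomy_leaves: int = 2


@dataclass
class CorpusConfig:
    min_len: int = 10
    max_len: int = 1024
    identity_threshold: float = 0.5
    fractions: Tuple[float, float, float] = (0.90, 0.05, 0.05)
    cluster: bool = False  # all-vs-all alignment is quadratic; opt in


@dataclass
class RunConfig:
    """Nested configuration for one reproducible run."""

    seed: int = 0
    profile: str = "tiny"
    out_dir: str = "runs/run0"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    corpus: CorpusConfig = field(default_factory=CorpusConfig)
    bridge: BridgeConfig = field(default_factory=BridgeConfig)
    train: TrainConfig = field(default_factory=lambda: TrainConfig(finetune_epochs=0))
    beam_width: int = 5
    max_terms: int = 10
    log_level: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (("simulate", SimulateConfig), ("corpus", CorpusConfig),
                         ("bridge", BridgeConfig), ("train", TrainConfig)):
            if key in d and isinstance(d[key], dict):
                sub_d = dict(d[key])
                for f in dataclasses.fields(sub):
                    if f.name in sub_d and isinstance(sub_d[f.name], list):
                        sub_d[f.name] = tuple(sub_d[f.name])
                d[key] = sub(**sub_d)
        return cls(**d)


def build_split_corpus(
    records: List[corpus_mod.ProteinRecord],
    dag: OntologyDAG,
    truth: AnnotationSet,
    config: CorpusConfig,
    seed: int,
    namespace: str,
) -> SplitCorpus:
    """Filter, (optionally) cluster by identity, and split group-wise."""
    records = corpus_mod.filter_by_length(records, config.min_len, config.max_len)
    records = corpus_mod.filter_by_evidence(records)
    if config.cluster:
        assignment = corpus_mod.cluster_by_identity(records, config.identity_threshold)
    else:
        # synthetic corpora are generated homolog-free; singleton clusters
        assignment = corpus_mod.ClusterAssignment({r.id: i for i, r in enumerate(records)})
    assignment = corpus_mod.split_clusters(assignment, config.fractions, seed)
    return SplitCorpus(records, truth, assignment)


def run_pipeline(config: RunConfig, force: bool = False, resume: bool = False) -> Path:
    """Execute the full pipeline; returns the run directory."""
    out = Path(config.out_dir)
    marker = out / "config.json"
    if marker.exists() and not (force or resume):
        raise FileExistsError(f"{out} holds a previous run; pass force or resume")
    out.mkdir(parents=True, exist_ok=True)
    marker.write_text(config.to_json())

    sim = config.simulate
    dag = synthetic.generate_toy_ontology(
        sim.n_leaves, sim.depth, sim.branching, seed=_child_seed(config.seed, 10)
    )
    grammar = synthetic.default_grammar(
        dag,
        seed=_child_seed(config.seed, 11),
        label_noise=sim.label_noise,
        taxonomy_leaves=sim.taxonomy_leaves,
        taxa=sim.taxa,
    )
    records, truth = synthetic.generate_corpus(
        grammar, dag, sim.n_proteins,
        length_range=sim.length_range, motif_rate=sim.motif_rate,
        taxa=sim.taxa, seed=_child_seed(config.seed, 12),
    )
    synthetic.write_corpus(out / "corpus", records, dag, truth)

    ns = config.train.namespace
    split = build_split_corpus(records, dag, truth, config.corpus,
                               _child_seed(config.seed, 13), ns)
    with open(out / "splits.tsv", "w") as fh:
        corpus_mod.write_split_manifest(split.assignment, fh)

    train_cfg = dataclasses.replace(config.train, seed=_child_seed(config.seed, 14))
    log_path = out / "train_log.jsonl"
    with open(log_path, "w") as log_fh:
        ckpt = train(split, dag, config.bridge, train_cfg,
                     progress=lambda row: log_fh.write(json.dumps(row) + "\n"))
    ckpt.save(out / "checkpoint.npz")

    # dense scoring of the full vocabulary on the test split, then closure
    test_records = [r for r in split.split_records("test")
                    if truth.annotations.get(r.id)]
    model = ckpt.build_model()
    tokenizer = ckpt.tokenizer()
    cache = _EmbeddingCache(ckpt.encoder())
    terms = sorted(dag.terms_in_namespace(ns))
    scores = score_vocabulary_batch(model, tokenizer, cache, test_records, terms,
                                    dag, train_cfg.prompt_template)
    preds = PredictionSet(
        {r.id: dict(zip(terms, row.astype(float))) for r, row in zip(test_records, scores)},
        ns,
    )
    preds = close_predictions(preds, dag)
    with open(out / "predictions.jsonl", "w") as fh:
        write_predictions_jsonl(preds, dag, fh)
    with open(out / "predictions.tsv", "w") as fh:
        write_predictions_tsv(preds, fh)

    train_ids = set(split.assignment.proteins_in_split("train"))
    train_truth = truth.restrict(train_ids)
    test_truth = truth.restrict([r.id for r in test_records])
    ia = information_accretion(train_truth, dag)
    with open(out / "term_table.tsv", "w") as fh:
        write_term_table(dag, ia, fh)

    report = evaluate(preds, test_truth, train_truth, dag, ia=ia)
    naive = naive_baseline(train_truth).predict(test_truth.annotations, ns)
    naive_report = evaluate(naive, test_truth, train_truth, dag, ia=ia)
    with open(out / "report.json", "w") as fh:
        json.dump(
            {
                "model": json.loads(_report_json(report)),
                "naive": json.loads(_report_json(naive_report)),
                "n_test_proteins": len(test_records),
                "selection_epoch": ckpt.selection_epoch,
            },
            fh,
            indent=2,
        )
    with open(out / "pr_curve.tsv", "w") as fh:
        write_pr_curve(report.pr_curve, fh)
    return out


def _report_json(report) -> str:
    import io

    buf = io.StringIO()
    report.to_json(buf)
    return buf.getvalue()
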