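"""Two-stage training and the generation pathway.

Stage 1 aligns queries with function text (contrastive + matching losses);
stage 2 trains text generation (language-modeling loss through the projected
query prefix), with per-epoch model selection on validation Fmax.  An
optional fine-tuning stage repeats LM training at a lower learning rate
(default 1e-5), mirroring a pretrain-then-finetune regime when two corpora
of different annotation quality are available.

Generation is trie-constrained beam search over the tokenized names of all
in-namespace ontology terms: logits for tokens that do not extend a live
trie path are masked out, so every emitted label is an exact term name.  A
completed term's score is exp(mean per-token log-probability) — length
normalized so long names are not penalized.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .bridge import (
    Bridge,
    BridgeConfig,
    ProteinEmbeddings,
    TinyProteinEncoder,
    lm_loss,
    pad_protein_batch,
    ptc_loss,
    ptm_loss,
    similarity_matrix,
)
from .corpus import ClusterAssignment, ProteinRecord
from .nn.autograd import Tensor
from .nn.layers import AdamW
from .ontology import AnnotationSet, OntologyDAG

CHECKPOINT_SCHEMA = "gobridge-checkpoint-1"
DEFAULT_PROMPT_TEMPLATE = "taxonomy: {taxon} ; functions:"


# -------------------------------------------------------------------- tokenizer
class Tokenizer:
    """Word-level tokenizer over the term-name vocabulary."""

    PAD, BOS, EOS, SEP, UNK = 0, 1, 2, 3, 4
    SPECIALS = ["[PAD]", "[BOS]", "[EOS]", "[SEP]", "[UNK]"]
    _WORD = re.compile(r"[a-z0-9\-'{}]+|[^\sa-z0-9]")

    def __init__(self, vocab: Sequence[str]):
        self.itos = list(vocab)
        if self.itos[: len(self.SPECIALS)] != self.SPECIALS:
            raise ValueError("vocabulary must start with the special tokens")
        self.stoi = {w: i for i, w in enumerate(self.itos)}

    @classmethod
    def build(cls, texts: Iterable[str]) -> "Tokenizer":
        words: Set[str] = set()
        for text in texts:
            words.update(cls._words(text))
        return cls(cls.SPECIALS + sorted(words))

    @classmethod
    def _words(cls, text: str) -> List[str]:
        return cls._WORD.findall(text.lower())

    def __len__(self) -> int:
        return len(self.itos)

    def encode(self, text: str) -> List[int]:
        return [self.stoi.get(w, self.UNK) for w in self._words(text)]

    def decode(self, ids: Sequence[int]) -> str:
        return " ".join(self.itos[i] for i in ids if i >= len(self.SPECIALS))


def build_prompt(taxonomy: Optional[str], tokenizer: Tokenizer,
                 template: str = DEFAULT_PROMPT_TEMPLATE) -> List[int]:
    """Tokenize the taxonomy prompt; a null taxonomy yields no tokens."""
    if taxonomy is None:
        return []
    return tokenizer.encode(template.format(taxon=taxonomy))


# ------------------------------------------------------------------------ trie
class TermTrie:
    """Prefix tree over tokenized term names; EOS marks completion."""

    def __init__(self) -> None:
        self.root: dict = {}
        self._terminal: Dict[Tuple[int, ...], str] = {}
        self.n_terms = 0

    @classmethod
    def from_terms(cls, terms: Mapping[str, str], tokenizer: Tokenizer) -> "TermTrie":
        """``terms``: term id -> term name."""
        trie = cls()
        for term_id, name in sorted(terms.items()):
            ids = tuple(tokenizer.encode(name))
            if not ids:
                continue
            node = trie.root
            for tok in ids:
                node = node.setdefault(tok, {})
            trie._terminal[ids] = term_id
            trie.n_terms += 1
        return trie

    def is_empty(self) -> bool:
        return self.n_terms == 0

    def children(self, prefix: Tuple[int, ...]) -> List[int]:
        node = self.root
        for tok in prefix:
            node = node.get(tok)
            if node is None:
                return []
        return list(node.keys())

    def terminal(self, prefix: Tuple[int, ...]) -> Optional[str]:
        return self._terminal.get(prefix)

    def remove(self, term_id: str) -> None:
        for ids, t in list(self._terminal.items()):
            if t == term_id:
                del self._terminal[ids]
                self.n_terms -= 1


# ---------------------------------------------------------------------- config
@dataclass
class TrainConfig:
    stage1_epochs: int = 5
    stage2_epochs: int = 5
    finetune_epochs: int = 5
    pretrain_lr: float = 1e-3
    finetune_lr: float = 1e-5
    batch_size: int = 16
    optimizer: str = "adamw"
    seed: int = 0
    namespace: str = "toy"
    prompt_template: str = DEFAULT_PROMPT_TEMPLATE

    def __post_init__(self) -> None:
        if min(self.stage1_epochs, self.stage2_epochs, self.finetune_epochs) < 0:
            raise ValueError("epoch counts must be >= 0")
        if self.pretrain_lr <= 0 or self.finetune_lr <= 0:
            raise ValueError("learning rates must be positive")


@dataclass
class SplitCorpus:
    """Records plus propagated truth and the cluster/split assignment."""

    records: List[ProteinRecord]
    truth: AnnotationSet  # closed, noise-free when synthetic
    assignment: ClusterAssignment

    def split_records(self, split: str) -> List[ProteinRecord]:
        return [r for r in self.records if self.assignment.split_of(r.id) == split]


@dataclass
class Checkpoint:
    schema: str
    bridge_config: BridgeConfig
    train_config: TrainConfig
    state: Dict[str, np.ndarray]
    vocab: List[str]
    encoder_seed: int
    selection_epoch: int = -1
    history: List[Dict[str, float]] = field(default_factory=list)

    def build_model(self) -> Bridge:
        model = Bridge(self.bridge_config)
        model.load_state_dict(self.state)
        return model

    def tokenizer(self) -> Tokenizer:
        return Tokenizer(self.vocab)

    def encoder(self) -> TinyProteinEncoder:
        return TinyProteinEncoder(
            d_protein=self.bridge_config.d_protein, seed=self.encoder_seed
        )

    def save(self, path: Path) -> None:
        meta = {
            "schema": self.schema,
            "bridge_config": asdict(self.bridge_config),
            "train_config": asdict(self.train_config),
            "vocab": self.vocab,
            "encoder_seed": self.encoder_seed,
            "selection_epoch": self.selection_epoch,
            "history": self.history,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **{f"param/{k}": v for k, v in self.state.items()})

    @classmethod
    def load(cls, path: Path) -> "Checkpoint":
        with np.load(path if str(path).endswith(".npz") else f"{path}.npz") as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta["schema"] != CHECKPOINT_SCHEMA:
                raise ValueError(f"unsupported checkpoint schema {meta['schema']!r}")
            state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
        return cls(
            schema=meta["schema"],
            bridge_config=BridgeConfig(**meta["bridge_config"]),
            train_config=TrainConfig(**meta["train_config"]),
            state=state,
            vocab=meta["vocab"],
            encoder_seed=meta["encoder_seed"],
            selection_epoch=meta["selection_epoch"],
            history=meta["history"],
        )


# ------------------------------------------------------------------- plumbing
def _child_seed(root: int, index: int) -> int:
    """Documented seed scheme: child k = SeedSequence([root, k]) state."""
    return int(np.random.SeedSequence([root, index]).generate_state(1)[0] % (2**31))


def _pad_tokens(rows: Sequence[Sequence[int]], pad_id: int = 0,
                max_len: Optional[int] = None) -> Tuple[np.ndarray, np.ndarray]:
    width = max(len(r) for r in rows)
    if max_len is not None:
        width = min(width, max_len)
    toks = np.full((len(rows), width), pad_id, dtype=int)
    pad = np.ones((len(rows), width), dtype=bool)
    for i, r in enumerate(rows):
        r = list(r)[:width]
        toks[i, : len(r)] = r
        pad[i, : len(r)] = False
    return toks, pad


def _stage1_text(record: ProteinRecord, dag: OntologyDAG, namespace: str,
                 tokenizer: Tokenizer) -> List[int]:
    names = sorted(dag.name[t] for t in record.terms(namespace))
    ids: List[int] = [Tokenizer.BOS]
    for i, name in enumerate(names):
        if i:
            ids.append(Tokenizer.SEP)
        ids.extend(tokenizer.encode(name))
    ids.append(Tokenizer.EOS)
    return ids


def _lm_example(prompt_ids: Sequence[int], name_ids: Sequence[int]) -> Tuple[List[int], List[bool]]:
    """Token row plus per-position target flags (True = position is a
    prediction target, i.e. a term-name token or the closing EOS)."""
    ids = [Tokenizer.BOS, *prompt_ids, *name_ids, Tokenizer.EOS]
    flags = [False] * (1 + len(prompt_ids)) + [True] * (len(name_ids) + 1)
    return ids, flags


class _EmbeddingCache:
    def __init__(self, encoder: TinyProteinEncoder):
        self.encoder = encoder
        self._cache: Dict[str, ProteinEmbeddings] = {}

    def get(self, record: ProteinRecord) -> ProteinEmbeddings:
        if record.id not in self._cache:
            self._cache[record.id] = self.encoder(record.sequence)
        return self._cache[record.id]

    def batch(self, records: Sequence[ProteinRecord]) -> Tuple[np.ndarray, np.ndarray]:
        return pad_protein_batch([self.get(r) for r in records])


# -------------------------------------------------------------------- training
def train(
    corpus: SplitCorpus,
    dag: OntologyDAG,
    bridge_config: BridgeConfig,
    train_config: TrainConfig,
    progress: Optional[callable] = None,
) -> Checkpoint:
    """Run the two-stage schedule (plus optional fine-tuning) and return the
    checkpoint whose stage-2 epoch maximized validation Fmax."""
    from .evaluation import fmax  # local import to avoid a cycle

    ns = train_config.namespace
    train_records = [r for r in corpus.split_records("train") if r.terms(ns)]
    val_records = [r for r in corpus.split_records("val") if r.terms(ns)]
    if not train_records:
        raise ValueError(f"no training records with {ns!r} annotations")

    term_names = {t: dag.name[t] for t in dag.terms_in_namespace(ns)}
    taxa = sorted({r.taxonomy for r in corpus.records if r.taxonomy})
    tokenizer = Tokenizer.build(
        list(term_names.values())
        + [train_config.prompt_template.format(taxon=t) for t in taxa]
    )
    config = bridge_config
    if config.vocab_size != len(tokenizer):
        from dataclasses import replace
        config = replace(config, vocab_size=len(tokenizer))

    model = Bridge(config)
    encoder_seed = _child_seed(train_config.seed, 0)
    cache = _EmbeddingCache(TinyProteinEncoder(d_protein=config.d_protein, seed=encoder_seed))
    rng = np.random.default_rng(_child_seed(train_config.seed, 1))
    history: List[Dict[str, float]] = []

    def make_checkpoint(state: Dict[str, np.ndarray], selection: int) -> Checkpoint:
        return Checkpoint(
            schema=CHECKPOINT_SCHEMA,
            bridge_config=config,
            train_config=train_config,
            state=state,
            vocab=tokenizer.itos,
            encoder_seed=encoder_seed,
            selection_epoch=selection,
            history=history,
        )

    # ---------------------------------------------------------------- stage 1
    opt = AdamW(list(model.parameters()), lr=train_config.pretrain_lr)
    stage1_rows = {r.id: _stage1_text(r, dag, ns, tokenizer) for r in train_records}
    for epoch in range(train_config.stage1_epochs):
        order = rng.permutation(len(train_records))
        epoch_losses = []
        for start in range(0, len(order), train_config.batch_size):
            batch = [train_records[i] for i in order[start:start + train_config.batch_size]]
            if len(batch) < 2:
                continue
            prot, pmask = cache.batch(batch)
            toks, pad = _pad_tokens([stage1_rows[r.id] for r in batch],
                                    max_len=config.max_text_len)
            q_out = model.encode_queries(prot, pmask)
            t_out = model.encode_text(toks, pad)
            t_pooled = t_out[:, 0, :]
            tau = model.log_tau.exp()
            loss_ptc = ptc_loss(q_out, t_pooled, tau, config.ptc_aggregation)
            sim = similarity_matrix(q_out, t_pooled, config.ptc_aggregation)
            loss_ptm = ptm_loss(model, prot, pmask, toks, pad, sim.data, rng)
            loss = loss_ptc * config.w_ptc + loss_ptm * config.w_ptm
            if not np.isfinite(loss.data):
                raise FloatingPointError("non-finite stage-1 loss")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append((float(loss_ptc.data), float(loss_ptm.data)))
        row = {
            "stage": 1.0,
            "epoch": float(epoch),
            "ptc": float(np.mean([x[0] for x in epoch_losses])) if epoch_losses else 0.0,
            "ptm": float(np.mean([x[1] for x in epoch_losses])) if epoch_losses else 0.0,
        }
        history.append(row)
        if progress:
            progress(row)

    # ---------------------------------------------------------------- stage 2
    def lm_examples(records: Sequence[ProteinRecord]) -> List[Tuple[ProteinRecord, List[int], List[bool]]]:
        out = []
        for r in records:
            prompt = build_prompt(r.taxonomy, tokenizer, train_config.prompt_template)
            for term in sorted(r.terms(ns)):
                ids, flags = _lm_example(prompt, tokenizer.encode(dag.name[term]))
                out.append((r, ids, flags))
        return out

    def val_fmax(current: Bridge) -> float:
        if not val_records:
            return 0.0
        scores = score_vocabulary_batch(
            current, tokenizer, cache, val_records, sorted(term_names),
            dag, train_config.prompt_template,
        )
        from .prediction import close_scores
        preds = {
            r.id: close_scores(dict(zip(sorted(term_names), row)), dag)
            for r, row in zip(val_records, scores)
        }
        truth = {r.id: corpus.truth.annotations.get(r.id, set()) for r in val_records}
        truth = {p: t for p, t in truth.items() if t}
        if not truth:
            return 0.0
        value, _tau = fmax(preds, truth, exclude=dag.roots(ns))
        return value

    best_state = model.state_dict()
    best_val = -1.0
    selection_epoch = -1
    examples = lm_examples(train_records)

    def run_lm_epochs(n_epochs: int, lr: float, stage_tag: float) -> None:
        nonlocal best_state, best_val, selection_epoch
        if n_epochs == 0:
            return
        opt2 = AdamW(list(model.parameters()), lr=lr)
        for epoch in range(n_epochs):
            order = rng.permutation(len(examples))
            lm_vals = []
            for start in range(0, len(order), train_config.batch_size):
                batch = [examples[i] for i in order[start:start + train_config.batch_size]]
                prot, pmask = cache.batch([b[0] for b in batch])
                toks, pad = _pad_tokens([b[1] for b in batch], max_len=config.max_text_len)
                tmask = np.zeros_like(pad)
                for i, (_r, ids, flags) in enumerate(batch):
                    flags = flags[: toks.shape[1]]
                    tmask[i, : len(flags)] = flags
                logits = model.generative_logits(prot, pmask, toks, pad)
                loss = lm_loss(logits, toks, tmask)
                if not np.isfinite(loss.data):
                    raise FloatingPointError("non-finite LM loss")
                opt2.zero_grad()
                loss.backward()
                opt2.step()
                lm_vals.append(float(loss.data))
            vf = val_fmax(model)
            row = {
                "stage": stage_tag,
                "epoch": float(epoch),
                "lm": float(np.mean(lm_vals)) if lm_vals else 0.0,
                "val_fmax": vf,
            }
            history.append(row)
            if progress:
                progress(row)
            if vf >= best_val:
                best_val = vf
                best_state = model.state_dict()
                selection_epoch = len(history) - 1

    run_lm_epochs(train_config.stage2_epochs, train_config.pretrain_lr, 2.0)
    run_lm_epochs(train_config.finetune_epochs, train_config.finetune_lr, 3.0)

    if selection_epoch < 0:  # no LM epochs ran; keep the current weights
        best_state = model.state_dict()
    return make_checkpoint(best_state, selection_epoch)


# -------------------------------------------------------------------- scoring
def _mean_token_logprob(model: Bridge, prefix, toks: np.ndarray, pad: np.ndarray,
                        tmask: np.ndarray) -> np.ndarray:
    logits = model.decode_text(prefix, toks, pad)
    ls = logits.data[:, :-1, :]
    ls = ls - ls.max(axis=-1, keepdims=True)
    ls = ls - np.log(np.exp(ls).sum(axis=-1, keepdims=True))
    targets = toks[:, 1:]
    picked = np.take_along_axis(ls, targets[:, :, None], axis=-1)[:, :, 0]
    m = tmask[:, 1:]
    return (picked * m).sum(axis=1) / np.maximum(m.sum(axis=1), 1)


def score_vocabulary_batch(
    model: Bridge,
    tokenizer: Tokenizer,
    cache: _EmbeddingCache,
    records: Sequence[ProteinRecord],
    terms: Sequence[str],
    dag: OntologyDAG,
    prompt_template: str = DEFAULT_PROMPT_TEMPLATE,
    taxonomy_override: Optional[str] = "__record__",
    chunk: int = 512,
) -> np.ndarray:
    """Teacher-forced scores (n_records, n_terms): exp(mean token log-lik of
    each term's name given the protein prefix and taxonomy prompt).

    ``taxonomy_override``: the sentinel ``"__record__"`` uses each record's
    own taxonomy; ``None`` disables the prompt; any other string forces it.
    """
    for t in terms:
        if t not in dag.terms:
            raise KeyError(f"term {t!r} not in ontology")
    # the query prefix depends only on the protein: encode each record once
    prefixes = np.concatenate([
        model.project_queries(
            model.encode_queries(*cache.batch(records[s:s + 64]))
        ).data
        for s in range(0, len(records), 64)
    ])
    rows: List[Tuple[int, List[int], List[bool]]] = []
    for ri, r in enumerate(records):
        taxon = r.taxonomy if taxonomy_override == "__record__" else taxonomy_override
        prompt = build_prompt(taxon, tokenizer, prompt_template)
        for term in terms:
            ids, flags = _lm_example(prompt, tokenizer.encode(dag.name[term]))
            rows.append((ri, ids, flags))
    flat = np.zeros(len(rows))
    for start in range(0, len(rows), chunk):
        part = rows[start:start + chunk]
        prefix = Tensor(prefixes[[ri for ri, _i, _f in part]])
        toks, pad = _pad_tokens([ids for _r, ids, _f in part])
        tmask = np.zeros_like(pad)
        for i, (_r, ids, flags) in enumerate(part):
            tmask[i, : len(flags)] = flags[: toks.shape[1]]
        flat[start:start + len(part)] = _mean_token_logprob(model, prefix, toks, pad, tmask)
    return np.exp(flat).reshape(len(records), len(terms))


def score_vocabulary(
    checkpoint: Checkpoint,
    record: ProteinRecord,
    terms: Sequence[str],
    dag: OntologyDAG,
    taxonomy: Optional[str] = "__record__",
) -> Dict[str, float]:
    """Dense per-term scores for one protein (terms must be in the DAG)."""
    model = checkpoint.build_model()
    tokenizer = checkpoint.tokenizer()
    cache = _EmbeddingCache(checkpoint.encoder())
    scores = score_vocabulary_batch(
        model, tokenizer, cache, [record], list(terms), dag,
        checkpoint.train_config.prompt_template, taxonomy,
    )[0]
    return dict(zip(terms, scores.astype(float)))


# ------------------------------------------------------------------ generation
def generate_terms(
    checkpoint: Checkpoint,
    record: ProteinRecord,
    dag: OntologyDAG,
    beam_width: int = 5,
    max_terms: int = 10,
    taxonomy: Optional[str] = "__record__",
    namespace: Optional[str] = None,
) -> List[Tuple[str, float]]:
    """Trie-constrained beam search; returns ranked (term id, score).

    Beam restarts are diversity-forced: an emitted term is removed from the
    trie before the next restart, so predictions are distinct.  Deterministic
    given a fixed checkpoint and inputs (ties break toward the smaller term
    id).
    """
    if beam_width < 1:
        raise ValueError("beam_width must be >= 1")
    ns = namespace or checkpoint.train_config.namespace
    tokenizer = checkpoint.tokenizer()
    term_names = {t: dag.name[t] for t in dag.terms_in_namespace(ns)}
    trie = TermTrie.from_terms(term_names, tokenizer)
    if trie.is_empty():
        raise ValueError(f"no term names to decode in namespace {ns!r}")
    model = checkpoint.build_model()
    cache = _EmbeddingCache(checkpoint.encoder())
    taxon = record.taxonomy if taxonomy == "__record__" else taxonomy
    prompt = build_prompt(taxon, tokenizer, checkpoint.train_config.prompt_template)
    emb = cache.get(record)
    # the query prefix depends only on the protein: encode once per protein
    prefix = model.project_queries(
        model.encode_queries(emb.matrix[None], emb.mask[None])
    )

    results: List[Tuple[str, float]] = []
    while len(results) < max_terms and not trie.is_empty():
        best = _beam_search_one(model, tokenizer, trie, prefix, prompt, beam_width)
        if best is None:
            break
        term_id, score = best
        results.append((term_id, score))
        trie.remove(term_id)
    results.sort(key=lambda x: (-x[1], x[0]))
    return results


def _beam_search_one(model: Bridge, tokenizer: Tokenizer, trie: TermTrie,
                     prefix, prompt: List[int],
                     beam_width: int) -> Optional[Tuple[str, float]]:
    # beams: (name token tuple, total logp, n tokens scored)
    beams: List[Tuple[Tuple[int, ...], float, int]] = [((), 0.0, 0)]
    completed: List[Tuple[str, float]] = []
    max_steps = 32
    for _step in range(max_steps):
        expansions: List[Tuple[Tuple[int, ...], float, int]] = []
        rows = []
        metas = []
        for name_ids, logp, n in beams:
            allowed = trie.children(name_ids)
            if trie.terminal(name_ids) is not None:
                allowed = allowed + [Tokenizer.EOS]
            if not allowed:
                continue
            rows.append([Tokenizer.BOS, *prompt, *name_ids])
            metas.append((name_ids, logp, n, allowed))
        if not rows:
            break
        toks, pad = _pad_tokens(rows)
        big_prefix = Tensor(np.repeat(prefix.data, len(rows), axis=0))
        logits = model.decode_text(big_prefix, toks, pad).data
        for i, (name_ids, logp, n, allowed) in enumerate(metas):
            last = len(rows[i]) - 1
            row_logits = logits[i, last].astype(np.float64)
            row_logits -= row_logits.max()
            log_probs = row_logits - np.log(np.exp(row_logits).sum())
            for tok in allowed:
                lp = logp + log_probs[tok]
                if tok == Tokenizer.EOS:
                    term_id = trie.terminal(name_ids)
                    completed.append((term_id, float(np.exp(lp / (n + 1)))))
                else:
                    expansions.append((name_ids + (tok,), lp, n + 1))
        expansions.sort(key=lambda b: (-b[1] / max(b[2], 1), b[0]))
        beams = expansions[:beam_width]
        if not beams:
            break
    if not completed:
        return None
    completed.sort(key=lambda x: (-x[1], x[0]))
    return completed[0]
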