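"""The sequence-text bridge: a small transformer with K learnable query
vectors that cross-attend to frozen per-residue protein embeddings and share
self-attention with function text, trained with three joint objectives:

* PTC — protein-text contrastive: symmetric InfoNCE over in-batch pairs,
  protein-side similarity = max over the K query outputs of cosine
  similarity to the pooled text, scaled by a learnable temperature.
* PTM — protein-text matching: binary classification of matched vs
  mismatched pairs, with in-batch hard negatives sampled proportionally to
  contrastive similarity.
* LM — causal language modeling of the function text conditioned on the
  projected query outputs as a decoder prefix.

Attention masking is mode-dependent and exact: in contrastive mode queries
and text run as separate streams over shared weights, so query outputs are
bit-identical under any text; in generative mode text attends causally to
itself and fully to the query prefix, never the reverse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .nn.autograd import Tensor, concat, cross_entropy_with_logits
from .nn.layers import (
    BridgeLayer,
    Embedding,
    LayerNorm,
    Linear,
    Module,
    causal_mask,
    padding_mask,
)

# --------------------------------------------------------------------- encoder


@dataclass
class ProteinEmbeddings:
    """Frozen per-residue embedding matrix (L, D_p) with padding mask."""

    matrix: np.ndarray
    mask: np.ndarray  # (L,) bool, True = padding

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != self.mask.shape[0]:
            raise ValueError("mask length must equal sequence length")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite values in protein embeddings")


class TinyProteinEncoder:
    """Deterministic stand-in protein encoder (frozen after init).

    One windowed mixing layer over learned-free random residue embeddings:
    each output row sees a 5-residue context, so planted motifs produce
    distinctive local features.  Pure numpy, no gradients by construction;
    the full-scale contract (a pretrained protein language model producing
    2560-dim per-residue embeddings) is met by any adapter that returns a
    :class:`ProteinEmbeddings` per sequence.
    """

    WINDOW = 5

    def __init__(self, d_protein: int = 32, d_residue: int = 16,
                 max_len: int = 1024, seed: int = 0,
                 alphabet: str = "ACDEFGHIKLMNPQRSTVWYX"):
        rng = np.random.default_rng(seed)
        self.d_protein = d_protein
        self.max_len = max_len
        self.alphabet = alphabet
        self._index = {c: i for i, c in enumerate(alphabet)}
        self.residue_emb = rng.normal(0, 1.0, (len(alphabet), d_residue)).astype(np.float32)
        self.mix = rng.normal(
            0, 1.0 / np.sqrt(self.WINDOW * d_residue),
            (self.WINDOW * d_residue, d_protein),
        ).astype(np.float32)
        self.bias = rng.normal(0, 0.1, d_protein).astype(np.float32)

    def __call__(self, sequence: str) -> ProteinEmbeddings:
        if not sequence:
            raise ValueError("empty sequence")
        if len(sequence) > self.max_len:
            raise ValueError(
                f"sequence length {len(sequence)} exceeds the maximum of {self.max_len}"
            )
        try:
            idx = np.array([self._index[c] for c in sequence])
        except KeyError as exc:
            raise ValueError(f"illegal residue {exc.args[0]!r} in sequence") from None
        h = self.residue_emb[idx]  # (L, d_residue)
        half = self.WINDOW // 2
        padded = np.pad(h, ((half, half), (0, 0)))
        windows = np.concatenate(
            [padded[i: i + len(sequence)] for i in range(self.WINDOW)], axis=1
        )
        out = np.tanh(windows @ self.mix + self.bias)
        return ProteinEmbeddings(out, np.zeros(len(sequence), dtype=bool))


def pad_protein_batch(items: Sequence[ProteinEmbeddings]) -> Tuple[np.ndarray, np.ndarray]:
    """Stack variable-length embeddings into (B, Lmax, D) + padding mask."""
    lmax = max(p.matrix.shape[0] for p in items)
    d = items[0].matrix.shape[1]
    mat = np.zeros((len(items), lmax, d), dtype=np.float32)
    mask = np.ones((len(items), lmax), dtype=bool)
    for i, p in enumerate(items):
        L = p.matrix.shape[0]
        mat[i, :L] = p.matrix
        mask[i, :L] = False
    return mat, mask


# ---------------------------------------------------------------------- config


@dataclass
class BridgeConfig:
    """Bridge hyperparameters.

    The tiny profile (the default) is sized for CPU training on synthetic
    corpora; the full-scale reference configuration of the architecture is
    K=32 queries of width 768 over 2560-dim protein embeddings.
    """

    d_q: int = 64
    n_layers: int = 4
    n_heads: int = 4
    d_ff: int = 128
    n_queries: int = 8
    d_protein: int = 32
    cross_period: int = 1  # cross-attention every this many blocks
    vocab_size: int = 64
    max_text_len: int = 48
    tau_init: float = 0.07
    ptc_aggregation: str = "max"  # or "mean": query-to-text similarity pooling
    ptm_pooling: str = "mean"  # or "first": query pooling for the match head
    w_ptc: float = 1.0
    w_ptm: float = 1.0
    w_lm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.d_q, self.n_layers, self.n_heads, self.n_queries,
               self.cross_period, self.vocab_size) < 1:
            raise ValueError("all bridge dimensions must be positive")


@dataclass
class BatchLosses:
    ptc: float
    ptm: float
    lm: float
    total: float


# ----------------------------------------------------------------------- model


class Bridge(Module):
    """Query transformer bridging frozen protein embeddings and term text."""

    def __init__(self, config: BridgeConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        self.queries = Tensor(
            rng.normal(0, 0.02, (c.n_queries, c.d_q)).astype(np.float32),
            requires_grad=True,
        )
        self.tok_emb = Embedding(c.vocab_size, c.d_q, rng)
        self.pos_emb = Embedding(c.max_text_len, c.d_q, rng)
        self.layers = [
            BridgeLayer(
                c.d_q, c.n_heads, c.d_ff, c.d_protein,
                has_cross=(i % c.cross_period == 0), rng=rng,
            )
            for i in range(c.n_layers)
        ]
        self.ln_final = LayerNorm(c.d_q)
        # output heads start near zero so the fresh model predicts the
        # uniform distribution (loss ln V / ln 2 before any training)
        self.lm_head = Linear(c.d_q, c.vocab_size, rng, scale=1e-3)
        self.ptm_head = Linear(c.d_q, 2, rng, scale=1e-3)
        # decoder-prefix projection; square and identity-initialized so an
        # untrained model passes queries through unchanged
        self.query_proj = Linear(c.d_q, c.d_q, rng)
        self.query_proj.weight.data = np.eye(c.d_q, dtype=np.float32)
        self.log_tau = Tensor(
            np.array(np.log(c.tau_init), dtype=np.float32), requires_grad=True
        )

    # ------------------------------------------------------------------ helpers
    def _query_batch(self, batch: int) -> Tensor:
        return self.queries.reshape(1, *self.queries.shape) * Tensor(
            np.ones((batch, 1, 1), dtype=np.float32)
        )

    def _embed_text(self, tokens: np.ndarray) -> Tensor:
        if tokens.shape[1] > self.config.max_text_len:
            raise ValueError("text longer than max_text_len")
        pos = np.arange(tokens.shape[1])
        return self.tok_emb(tokens) + self.pos_emb(pos)

    # ------------------------------------------------------------------ streams
    def encode_queries(self, protein: np.ndarray, protein_mask: np.ndarray) -> Tensor:
        """Query stream alone: self-attention over the K queries plus
        periodic cross-attention into the protein features.  (B, K, D)."""
        prot = Tensor(protein.astype(np.float32))
        pmask = padding_mask(protein_mask)
        q = self._query_batch(protein.shape[0])
        for layer in self.layers:
            q = layer.attend_self(q)
            q = layer.attend_cross(q, prot, pmask)
            q = layer.feed_forward(q)
        return self.ln_final(q)

    def encode_text(self, tokens: np.ndarray, pad: np.ndarray) -> Tensor:
        """Unimodal text stream over the shared weights.  (B, T, D)."""
        t = self._embed_text(tokens)
        mask = padding_mask(pad)
        for layer in self.layers:
            t = layer.attend_self(t, mask)
            t = layer.feed_forward(t)
        return self.ln_final(t)

    def forward_matching(self, protein: np.ndarray, protein_mask: np.ndarray,
                         tokens: np.ndarray, pad: np.ndarray) -> Tensor:
        """Joint query-text stream with full bidirectional self-attention;
        returns the 2-way match logits.  (B, 2)."""
        B = protein.shape[0]
        K = self.config.n_queries
        prot = Tensor(protein.astype(np.float32))
        pmask = padding_mask(protein_mask)
        joint_pad = np.concatenate([np.zeros((B, K), dtype=bool), pad], axis=1)
        jmask = padding_mask(joint_pad)
        q = self._query_batch(B)
        t = self._embed_text(tokens)
        for layer in self.layers:
            joint = concat([q, t], axis=1)
            joint = layer.attend_self(joint, jmask)
            q, t = joint[:, :K, :], joint[:, K:, :]
            q = layer.attend_cross(q, prot, pmask)
            q = layer.feed_forward(q)
            t = layer.feed_forward(t)
        q = self.ln_final(q)
        pooled = q.mean(axis=1) if self.config.ptm_pooling == "mean" else q[:, 0, :]
        return self.ptm_head(pooled)

    def project_queries(self, query_outputs: Tensor) -> Tensor:
        """Linear map from query outputs to decoder-prefix states."""
        if query_outputs.shape[-1] != self.config.d_q:
            raise ValueError("query output width does not match the bridge")
        return self.query_proj(query_outputs)

    def decode_text(self, prefix: Tensor, tokens: np.ndarray, pad: np.ndarray) -> Tensor:
        """Generative pathway: causal text stream attending to the projected
        query prefix at every layer.  Returns token logits (B, T, V).

        Text cannot influence the prefix (it is computed first) and logits at
        position t are bit-invariant to tokens after t (causal mask with
        exact-zero attention on masked entries).
        """
        B, T = tokens.shape
        K = prefix.shape[1]
        # (T, K+T) additive mask: prefix always visible, text causal
        cmask = np.concatenate(
            [np.zeros((T, K), dtype=np.float32), causal_mask(T)], axis=1
        )
        kv_pad = np.concatenate([np.zeros((B, K), dtype=bool), pad], axis=1)
        mask = cmask[None, None] + padding_mask(kv_pad)
        t = self._embed_text(tokens)
        for layer in self.layers:
            kv = concat([prefix, layer.ln_self(t)], axis=1)
            t = t + layer.self_attn(layer.ln_self(t), kv, mask)
            t = layer.feed_forward(t)
        return self.lm_head(self.ln_final(t))

    def generative_logits(self, protein: np.ndarray, protein_mask: np.ndarray,
                          tokens: np.ndarray, pad: np.ndarray) -> Tensor:
        q = self.encode_queries(protein, protein_mask)
        return self.decode_text(self.project_queries(q), tokens, pad)

    # -------------------------------------------------------------------- modes
    def forward(self, protein: np.ndarray, protein_mask: np.ndarray,
                tokens: np.ndarray, pad: np.ndarray, mode: str):
        """Spec'd mode dispatch: contrastive | matching | generative."""
        if mode == "contrastive":
            return self.encode_queries(protein, protein_mask), self.encode_text(tokens, pad)
        if mode == "matching":
            return self.forward_matching(protein, protein_mask, tokens, pad)
        if mode == "generative":
            return self.generative_logits(protein, protein_mask, tokens, pad)
        raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------- losses


def _l2_normalize(x: Tensor) -> Tensor:
    norm_sq = (x * x).sum(axis=-1, keepdims=True)
    return x * (norm_sq + 1e-12) ** -0.5


def similarity_matrix(query_outputs: Tensor, text_pooled: Tensor,
                      aggregation: str = "max") -> Tensor:
    """(B, B) protein-to-text cosine similarity, pooled over the K queries."""
    q = _l2_normalize(query_outputs)  # (B, K, D)
    t = _l2_normalize(text_pooled)  # (B, D)
    B, K, D = q.shape
    sims = q.reshape(B * K, D) @ t.swapaxes(0, 1)  # (B*K, B)
    sims = sims.reshape(B, K, B)
    if aggregation == "max":
        return sims.max(axis=1)
    if aggregation == "mean":
        return sims.mean(axis=1)
    raise ValueError(f"unknown aggregation {aggregation!r}")


def ptc_loss(query_outputs: Tensor, text_pooled: Tensor, tau: float,
             aggregation: str = "max") -> Tensor:
    """Symmetric InfoNCE against the batch diagonal.

    ``text_pooled`` is the designated pooled token representation (one vector
    per item).  Uniform similarities give exactly ln N; a dominant diagonal
    drives the loss to 0.
    """
    n = query_outputs.shape[0]
    if n < 2:
        raise ValueError("contrastive loss needs a batch of at least 2 pairs")
    sim = similarity_matrix(query_outputs, text_pooled, aggregation)
    logits = sim * (1.0 / tau) if not isinstance(tau, Tensor) else sim * (tau ** -1.0)
    targets = np.arange(n)
    p2t = cross_entropy_with_logits(logits, targets)
    t2p = cross_entropy_with_logits(logits.swapaxes(0, 1), targets)
    return (p2t + t2p) * 0.5


def sample_hard_negatives(similarity: np.ndarray,
                          rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """In-batch hard negatives: for each protein a negative text index, and
    for each text a negative protein index, sampled with probability
    proportional to the softmax of the (diagonal-masked) similarity row.
    The positive (diagonal) index is never returned."""
    n = similarity.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items for negative sampling")

    def sample_rows(s: np.ndarray) -> np.ndarray:
        masked = s.astype(np.float64).copy()
        np.fill_diagonal(masked, -np.inf)
        masked -= masked.max(axis=1, keepdims=True)
        p = np.exp(masked)
        p /= p.sum(axis=1, keepdims=True)
        return np.array([rng.choice(n, p=p[i]) for i in range(n)])

    neg_text_for_protein = sample_rows(similarity)
    neg_protein_for_text = sample_rows(similarity.T)
    return neg_text_for_protein, neg_protein_for_text


def binary_match_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """2-way cross entropy over match/no-match logits; ln 2 when uniform."""
    return cross_entropy_with_logits(logits, labels.astype(int))


def ptm_loss(model: Bridge, protein: np.ndarray, protein_mask: np.ndarray,
             tokens: np.ndarray, pad: np.ndarray, similarity: np.ndarray,
             rng: np.random.Generator) -> Tensor:
    """Assemble N positives + N hard-negative texts + N hard-negative
    proteins and score them with the matching head."""
    n = protein.shape[0]
    neg_text, neg_prot = sample_hard_negatives(similarity, rng)
    big_prot = np.concatenate([protein, protein, protein[neg_prot]], axis=0)
    big_pmask = np.concatenate([protein_mask, protein_mask, protein_mask[neg_prot]], axis=0)
    big_tok = np.concatenate([tokens, tokens[neg_text], tokens], axis=0)
    big_pad = np.concatenate([pad, pad[neg_text], pad], axis=0)
    labels = np.concatenate([np.ones(n), np.zeros(2 * n)]).astype(int)
    logits = model.forward_matching(big_prot, big_pmask, big_tok, big_pad)
    return binary_match_loss(logits, labels)


def lm_loss(logits: Tensor, tokens: np.ndarray, target_mask: np.ndarray) -> Tensor:
    """Mean next-token cross entropy over unmasked text positions.

    ``logits`` come from the generative pathway (query positions are not in
    the target set by construction); ``target_mask`` selects which shifted
    positions count (padding and prompt positions excluded).
    """
    if not target_mask.any():
        raise ValueError("no unmasked target positions (all-padding text)")
    inputs_logits = logits[:, :-1, :]
    targets = tokens[:, 1:]
    return cross_entropy_with_logits(inputs_logits, targets, target_mask[:, 1:])


def combined_losses(ptc: Tensor, ptm: Tensor, lm: Tensor,
                    config: BridgeConfig) -> Tuple[Tensor, BatchLosses]:
    total = ptc * config.w_ptc + ptm * config.w_ptm + lm * config.w_lm
    report = BatchLosses(
        float(ptc.data), float(ptm.data), float(lm.data), float(total.data)
    )
    return total, report
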