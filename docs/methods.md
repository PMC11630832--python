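# Methods

This note documents the models, procedures, parameter choices and known
limitations of `gobridge`, in the order data flows through the package.

## Ontology handling

The ontology is read from go-basic-dialect OBO into a DAG restricted to
`is_a` and `part_of` edges; that dialect guarantees acyclicity over exactly
these relations, and both participate in annotation propagation (standard
CAFA practice — the true-path rule applies to part-of-style containment as
well as subtype links). Other relationship types (`regulates`, ...) are
ignored with a warning. Cross-namespace `part_of` edges are dropped so each
sub-ontology (MFO/BPO/CCO, or the toy namespace) stands alone; models are
trained and evaluated per namespace. Obsolete terms are tracked but carry
no edges and are rejected in annotation sets. `alt_id`s map to their
canonical term. Cycles are a hard error naming a cycle member.

Information accretion is estimated from a propagated corpus as
ia(f) = −log₂ [ (n_{f ∧ parents} + s₁) / (n_parents + s₂) ], with additive
smoothing (s₁, s₂) = (1, 2) on by default so singleton terms get finite
weights; tests and identity checks use smoothing off, where the estimator
is the plain conditional frequency. Terms never observed, or whose
conditioning set is empty, get ia = 0 by convention — they carry no
measurable information in the corpus and should not dominate weighted
metrics through an arbitrary large value.

## Corpus construction

Length filtering keeps 10–1024-residue sequences inclusive. Evidence
filtering keeps the thirteen experimental/high-throughput codes (EXP, IDA,
IPI, IMP, IGI, IEP, TAS, IC, HTP, HDA, HMP, HGI, HEP); records left with
no annotations are dropped.

Pairwise identity is computed by affine-gap Smith–Waterman local alignment
(Bio.Align.PairwiseAligner; match +2, mismatch −1, gap open −2.5, extend
−0.5) as identical aligned positions divided by the shorter sequence
length. The shorter-sequence denominator is deliberate: it groups fragments
with their parents, the conservative choice for leakage prevention.
Clustering is single-linkage over the identity > threshold graph (default
0.5); above 5000 records a shared-5-mer prefilter skips hopeless pairs.
Splitting shuffles *clusters* with a seed and apportions them 90/5/5 by
largest remainder — fractions apply to cluster counts, not protein counts,
so protein counts per split can be uneven; that is accepted. A corpus that
collapses to one cluster goes entirely to train with a warning.

## Synthetic data

The generator emulates the statistical structure the bridge has to
exploit: function is carried by short sequence motifs. A toy ontology is a
pruned balanced tree (default 12 leaves, depth 3, branching 3) in which 10%
of non-root terms get a second parent from the level above, so multi-parent
propagation paths are exercised. Term names are synthetic English-like
three-word strings from a fixed word bank, giving the text decoder real
token structure.

Each leaf term gets one motif of 5–7 uniformly random residues (mutually
non-substring). Proteins are uniform-background sequences of 50–300
residues with Poisson(2) distinct motifs inserted at non-overlapping
positions; uniform background is the simplest null that keeps motifs
detectable. Taxonomy-conditional rules gate a motif's term on the
protein's taxon (default: 2 of the 12 leaves conditional on "Homo" out of
{Homo, Phasianus}) — the desk-scale analogue of homologous proteins with
taxon-divergent function. Label noise drops each true term from the
*emitted* annotations with probability 0.05; the noise-free propagated
truth is returned separately so oracle tests and evaluation have clean
ground truth. Homolog pairs are produced by point mutation with rejection
until measured identity lands within ±0.05 of the target, optionally
protecting motif spans.

What this does *not* emulate: biophysically plausible backgrounds,
insertion/deletion evolution, motif degeneracy, inter-protein annotation
correlation, or realistic GO term text. Passing tests on this corpus show
the machinery learns planted sequence→label signal end to end; they say
nothing about performance on real proteomes.

## The bridge

All neural components run on a small reverse-mode autograd engine over
numpy arrays (`gobridge.nn`), written for exactly the op set the bridge
needs. Losses are computed at the input precision (float32 parameters;
float64 in tests of closed forms); batch reductions are means. Attention
masks are additive with −1e9 on forbidden entries, which underflows to an
exactly zero softmax weight, so masking contracts hold at the bit level:

* contrastive mode — queries and text run as separate streams over shared
  weights: query outputs are bit-identical under any text;
* matching mode — one joint stream with full bidirectional attention;
* generative mode — the query stream runs first, its outputs are passed
  through the (identity-initialized, learned) projection and used as a
  prefix the text attends to at every layer, while text self-attention is
  causal.

The encoder stand-in is a frozen seeded windowed-mixing layer
(tanh(W·concat(5-residue window)) per position, D_p = 32). It is described
as what it is — a deterministic local-feature encoder satisfying the
per-residue embedding contract; adapters for pretrained protein language
models plug into the same contract.

Objective details the architecture leaves open, resolved here and
config-exposed: PTC aggregates query-to-text similarity by max over the K
queries (mean available); the text representation is the first-token
output of the unimodal text stream; the PTM head pools queries by mean
(first available); τ is learnable, initialized at 0.07; loss weights are
(1, 1, 1).

## Training and generation

The tiny profile is D_q = 64, 4 layers, 4 heads, K = 8 queries, d_ff = 128,
word-level tokenizer over the term-name word bank. Cross-attention is
inserted every block and the pretraining learning rate is 1e-3 (AdamW,
weight decay 0.01, batch 16): at desk scale the 5+5-epoch budget is a few
hundred optimizer steps, and with sparser cross-attention or a smaller
step size the model converges to the unconditional term distribution
before attention has located the motif-bearing residues. The fine-tuning
stage (learning rate 1e-5) exists for the two-corpus regime
(automatic-annotation pretraining, curated fine-tuning); the synthetic
pipeline has a single annotation tier, so its profile sets
`finetune_epochs=0`.

Stage 1 optimizes PTC + PTM on (protein, joined term names) pairs; stage 2
optimizes LM on one example per (protein, annotated term), with the
taxonomy prompt prepended when the record has a taxon. After each LM epoch
the validation split is scored and the best-Fmax state is kept (ties to
the later epoch). The desk-scale decoder is trained from scratch in stage
2 rather than frozen — there is no pretrained tiny decoder — which is the
one deliberate departure from the frozen-decoder contract that applies
when a real pretrained language model is used; it is visible in the config.

Generation scores a term as exp(mean per-token log-probability) of its
name (plus the end token) — length-normalized so long names are not
penalized — under trie-constrained beam search; emitted terms are removed
from the trie before the next restart, forcing distinct outputs. Dense
evaluation uses the same quantity computed by teacher forcing over the
whole vocabulary. Prediction sets are closed by ancestor = max(own,
descendants), which is idempotent and preserves the top-scoring leaf.
Every stochastic component draws its seed from the run seed via
`SeedSequence([root, k])` with fixed component indices; runs are
reproducible byte-for-byte on one device.

## Evaluation

Protein-centric precision at threshold τ averages over proteins with at
least one prediction ≥ τ; recall averages over all truth-bearing proteins.
F1 is the harmonic mean (the standard definition; a geometric-mean variant
is available behind `f_mean="geometric"` for auditability against sources
that describe F1 loosely). Namespace roots are excluded from scoring by
default (they are trivially true). Threshold ties break toward the larger
τ. The default grid is 0.01 steps over (0, 1]; metric tests use the exact
distinct-score threshold set. WFmax replaces counts with ia sums and
reduces exactly to Fmax at ia ≡ 1. Smin is min over τ of √(ru² + mi²) with
ru/mi the mean ia mass of missed/extra terms. AUPR is micro over
(protein, term) pairs on the truth-term label space, step-rule area
(scikit-learn's average precision). Binned F1 assigns terms to
left-closed bins by training-set occurrence (a count of 20 falls in
"20–50") and averages per-term F1 at the Fmax-optimal τ; empty bins are
omitted.

## Problem sizes

The benchmark experiment (tests and `scripts/acceptance.py`) uses 1000
proteins over a 12-leaf ontology with the 5+5 schedule, three seeds,
median-reported — the scale at which one run takes about two minutes on a
single CPU and the full three-seed experiment stays well inside a coffee
break. Unit and property suites use 50–90-protein corpora and ≤ 50-term
random DAGs.

## Known limitations

* The encoder stand-in has a 5-residue receptive field; motifs much longer
  than that, or distributed signals, would need a deeper encoder behind
  the same contract.
* All-vs-all identity clustering is quadratic; the k-mer prefilter makes
  10⁴-record corpora workable but this is not a DIAMOND replacement.
* The naive-autograd transformer is CPU-bound and single-device; the
  architecture is faithful, the scale is not.
* AUPR on the truth-restricted label space slightly favors methods that
  never predict outside it; this matches the pair-centric convention used
  for multilabel annotation but is worth remembering when comparing
  numbers across papers.
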