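"""Generate a motif-labelled synthetic protein corpus.

Builds a small acyclic toy ontology, plants one sequence motif per leaf
term, and samples proteins whose (propagated) labels are determined by the
motifs their sequences carry — the signal a sequence-to-function model has
to learn.
"""

from gobridge import default_grammar, generate_corpus, generate_toy_ontology
from gobridge.synthetic import leaf_terms

dag = generate_toy_ontology(n_leaves=8, depth=3, branching=2, seed=1)
grammar = default_grammar(dag, seed=2, label_noise=0.05,
                          taxonomy_leaves=1, taxa=("Homo", "Phasianus"))
records, truth = generate_corpus(grammar, dag, n_proteins=50,
                                 taxa=("Homo", "Phasianus"), seed=3)

print(f"ontology: {len(dag.terms)} terms, {len(leaf_terms(dag))} leaves, "
      f"root = {sorted(dag.roots('toy'))[0]}")
print(f"grammar: {len(grammar.motifs)} motifs + "
      f"{len(grammar.taxonomy_rules)} taxonomy-conditional rules")
example = next(r for r in records if r.terms("toy"))
print(f"\nexample protein {example.id} (taxon {example.taxonomy}, "
      f"{len(example.sequence)} aa)")
print(f"  emitted labels:    {sorted(example.terms('toy'))}")
print(f"  propagated truth:  {sorted(truth.annotations[example.id])}")
# The truth set contains the emitted leaf terms plus all their ancestors —
# annotating a child always implies its parents (the true-path rule).
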