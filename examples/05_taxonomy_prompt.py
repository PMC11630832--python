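"""The taxonomy prompt: same sequence, different annotation by organism.

The synthetic grammar contains taxonomy-conditional rules — a motif confers
its term only in certain taxa, emulating homologs with divergent function.
A trained model conditioned on a "taxonomy: <taxon>" prompt should score
such a term higher under the matching taxon than a non-matching one.
"""

from gobridge import BridgeConfig, TrainConfig, train
from gobridge.experiment import build_world
from gobridge.pipeline import SimulateConfig
from gobridge.training import score_vocabulary

dag, grammar, split = build_world(seed=31, sim=SimulateConfig(n_proteins=600))
ckpt = train(split, dag, BridgeConfig(),
             TrainConfig(stage1_epochs=3, stage2_epochs=4, finetune_epochs=0,
                         seed=31))

motif, term, allowed = grammar.taxonomy_rules[0]
held = split.split_records("val") + split.split_records("test")
carriers = [r for r in held if motif in r.sequence]
print(f"conditional term {term} ({dag.name[term]!r}) is granted only for "
      f"taxa {sorted(allowed)}")
print(f"{len(carriers)} held-out proteins carry its motif\n")
for record in carriers[:5]:
    s_match = score_vocabulary(ckpt, record, [term], dag, taxonomy="Homo")[term]
    s_other = score_vocabulary(ckpt, record, [term], dag,
                               taxonomy="Phasianus")[term]
    marker = "matching taxon wins" if s_match > s_other else "no effect"
    print(f"  {record.id}: score(term | Homo)={s_match:.3f}  "
          f"score(term | Phasianus)={s_other:.3f}  <- {marker}")
# The prompt is the only difference between the two scores: the model has
# learned that this term co-occurs with the matching taxon token.
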