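"""Train the character bi-RNN-CRF benchmark and score it on held-out data.

Uses a small corpus (1,200 train / 300 held-out sentences) so the run takes
well under a minute; the study-scale run (2,000 train sentences) is what
scripts/acceptance.py performs.
"""

from subtag import BiRnnCrfTagger, GeneratorConfig, Scheme, TaggerConfig, generate_corpus
from subtag.evaluation import corpus_tag_metrics
from subtag.labeling import gold_label_sequence

config = GeneratorConfig(dict_sizes={"DZ": 50, "SX": 20, "BP": 20},
                         attach_prob=0.4, seed=13, sentences_per_doc=1)
docs = generate_corpus(config, 1500)
train, held_out = docs[:1200], docs[1200:]

tagger = BiRnnCrfTagger(TaggerConfig(epochs=30, seed=13)).fit(train)
print(f"trained {len(tagger.loss_history)} epochs, "
      f"loss {tagger.loss_history[0]:.2f} -> {tagger.loss_history[-1]:.2f}")

pairs = [(gold_label_sequence(d, Scheme.IOB_CHAR), tagger.predict(d))
         for d in held_out]
report = corpus_tag_metrics(pairs)
print(f"held-out micro: precision {report.micro.precision:.3f} "
      f"recall {report.micro.recall:.3f} f1 {report.micro.f1:.3f}")
print(f"held-out macro f1: {report.macro.f1:.3f}")
# entities come from closed dictionaries, so a character model that has
# memorized the surface forms and the particle boundaries scores high here
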