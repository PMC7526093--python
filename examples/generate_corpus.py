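"""Generate a synthetic diagnosis-style corpus and inspect its structure.

Builds 200 seeded documents with dictionary-drawn disease (DZ), symptom
(SX) and body-part (BP) entities, some of which carry a postposition glued
without whitespace, then prints the corpus statistics and one annotated
document.
"""

from subtag import GeneratorConfig, generate_corpus
from subtag.synthetic import corpus_stats

config = GeneratorConfig(dict_sizes={"DZ": 50, "SX": 20, "BP": 20},
                         attach_prob=0.4, seed=7)
docs = generate_corpus(config, 200)

stats = corpus_stats(docs)
print("documents:", stats["n_documents"])
for etype, counts in stats["per_type"].items():
    print(f"  {etype}: {counts['annotated']} annotated entities, "
          f"{counts['unique']} unique surface forms")

doc = docs[2]
print("\nexample document:", repr(doc.text))
for sp in doc.spans:
    glued = sp.char_end < len(doc.text) and doc.text[sp.char_end] != " "
    print(f"  ({sp.char_start:3d},{sp.char_end:3d}) {sp.etype}  "
          f"{doc.surface(sp)!r}" + ("  [glued postposition follows]" if glued else ""))
# Entity spans never include the glued particle: the span ends where the
# dictionary form ends, inside the whitespace-delimited word.
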