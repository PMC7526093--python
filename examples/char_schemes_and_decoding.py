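"""Character-level labeling schemes and span decoding with repair.

TRAD makes whitespace a visible placeholder and labels in-entity
whitespace as part of the entity; the char-level IOB variant marks all
whitespace O.  Decoding turns any label sequence back into typed character
spans, repairing invalid starts (I without B) conlleval-style.
"""

from subtag import (
    AnnotatedDocument,
    EntitySpan,
    LabelSequence,
    Scheme,
    decode_entities,
    project_trad_labels,
    trad_to_iob_char,
    trad_units,
)

doc = AnnotatedDocument("demo", "ab cd ef", (EntitySpan(3, 8, "DZ"),))
trad = project_trad_labels(doc)
iob = trad_to_iob_char(trad, doc.text)

print("chars:", " ".join(trad_units(doc.text)))
print("TRAD :", " ".join(f"{l:4s}" for l in trad))
print("IOB  :", " ".join(f"{l:4s}" for l in iob))

for scheme, labels in (("TRAD", trad), ("IOB", iob)):
    decoded = decode_entities(doc.text, labels)
    print(f"decoded from {scheme}: {decoded.spans} (repairs: {decoded.repairs})")

# an invalid predicted sequence: I-DZ with no opening B-DZ
bad = LabelSequence(Scheme.IOB_CHAR, ("O", "I-DZ", "I-DZ"))
decoded = decode_entities("xyz", bad)
print("repaired decode:", decoded.spans, "repairs:", decoded.repairs)
# the dangling I-run is promoted to a fresh entity and the repair is counted,
# so recall stays measurable on malformed predictions
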