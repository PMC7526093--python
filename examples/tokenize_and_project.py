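"""WordPiece tokenization with offsets and postposition-aware labeling.

Shows the central labeling rule: a subword continuation piece (``##`` ...)
inside an entity is X, but a continuation lying wholly outside every
entity — a postposition glued to the entity — is O, so the model can learn
the invisible boundary between an entity and its particle.
"""

from subtag import (
    AnnotatedDocument,
    EntitySpan,
    SubwordVocab,
    bert_to_iob_token,
    bert_to_wp,
    project_bert_labels,
    tokenize_with_offsets,
)

# "abcd" is a body-part entity; "e" is a glued particle outside the span
vocab = SubwordVocab.from_tokens(["ab", "##cd", "##e", "fg"])
doc = AnnotatedDocument("demo", "abcde fg", (EntitySpan(0, 4, "BP"),))

tokens = tokenize_with_offsets(doc.text, vocab)
bert = project_bert_labels(doc, tokens)
wp = bert_to_wp(bert, tokens)
iob = bert_to_iob_token(bert, tokens)

print(f"{'token':8s} {'span':8s} {'BERT':6s} {'WP':6s} {'IOB':6s}")
for tok, b, w, i in zip(tokens, bert, wp, iob):
    print(f"{tok.text:8s} [{tok.char_start},{tok.char_end})   {b:6s} {w:6s} {i:6s}")
# '##cd' continues the entity -> X under BERT (copied under WP, I-BP under
# IOB); '##e' is the glued particle -> O under every scheme, never X.
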