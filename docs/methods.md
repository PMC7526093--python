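# Methods

## Problem setting

Clinical entity recognition over text in an agglutinative language, where
grammatical particles (postpositions, josa) attach to the preceding noun
without whitespace. A gold entity is a typed character span — disease
(DZ), symptom (SX), or body part (BP) — and, because of particle gluing,
a span frequently ends strictly inside a whitespace-delimited word. The
package converts between character-span annotations and the label
sequences that subword or character taggers consume, scores predictions
per tag, and ships a trainable character-level benchmark plus a synthetic
corpus generator so every claim is testable without restricted data.

All offsets are 0-based, half-open, into NFC-normalized text. Entity
spans are flat: sorted, non-overlapping, never starting or ending in
whitespace. These conventions are enforced by validation at every I/O
boundary and assumed everywhere else.

## Tokenization

Basic tokenization splits on Unicode whitespace and emits punctuation
characters as single-character words (ASCII symbol ranges are treated as
punctuation, following the common BERT convention). WordPiece segmentation
is greedy longest-match-first: at each position the longest prefix present
in the vocabulary is taken, with `##` prepended after the first piece; a
word with no match at some step, or longer than `max_word_chars` (default
100), degrades to a single `[UNK]` piece spanning the word. Matching this
reference behavior matters because the label projection depends on exactly
where piece boundaries fall. Case folding and accent stripping are exposed
as vocabulary flags and default off (the cased-multilingual convention).
Special tokens (`[CLS]`, `[SEP]`) are never inserted by the tokenizer, so
token offsets always index the raw text.

## Label schemes and projection

Five schemes, two alignments:

* **BERT** (subword, training-facing). A token is labeled by its *first
  character's* membership: entity-initial token `B-T`; continuation piece
  inside the entity `X`; word-initial piece inside a multi-word entity
  `I-T`; everything else `O`. The postposition override: a continuation
  piece wholly outside every span — the glued particle — is `O`, never
  `X`. First-char-wins also settles straddling tokens (an entity boundary
  strictly inside one piece); these cannot occur when the vocabulary is
  aligned with the annotation (see the generator) but are counted by
  `count_straddles` when they do.
* **WP** (subword, evaluation-facing). Every `X` is replaced by a literal
  copy of the preceding token's label. The replacement rule is read at
  face value; converting copies to `I-T` instead is available as
  `ProjectionConfig(wp_mode="inside")`. Literal copy is the default
  because it preserves the word-boundary information the scheme exists to
  evaluate (whether the tagger starts the entity at the right word).
* **IOB_TOKEN** (subword): standard IOB; in-entity `X` becomes `I-T`.
* **TRAD_CHAR** (character): one label per character; whitespace is shown
  as a placeholder (`^` by default; the display glyph is configurable) and
  in-entity whitespace is labeled `I-T`, so a multi-word entity is one
  contiguous B-I run.
* **IOB_CHAR** (character): as TRAD with all whitespace forced to `O`.
  This is the native scheme of the character benchmark and the common
  currency for comparing subword and character taggers
  (`token_labels_to_char_iob` re-expresses any token scheme here by
  resolving `X`, decoding to spans, and re-projecting).

Decoding (`decode_entities`) inverts projection for any scheme. Invalid
starts — `I-T` with no open entity of type T — are repaired to a fresh
`B-T` (the conlleval convention) rather than dropped, so recall on
malformed predictions remains measurable; repairs are counted and
reported. A dangling `X` (after `O`, or at position 0 in predictions)
carries no type and cannot be repaired to a typed begin; it is treated as
`O` and counted as a repair. Under WP, a same-type label on a
continuation piece extends the open entity (it is a literal copy), while
the same label on a word-initial piece starts a new entity; this is what
keeps two adjacent same-type entities separate. In IOB_CHAR decoding an
open entity survives whitespace `O` positions and resumes on a following
same-type `I-T`, because in-entity whitespace is `O` by construction in
that scheme.

## Evaluation protocol

The primary metric is positionwise multi-class counting per entity tag
(`B-T`, `I-T`): a position contributes tp to its gold tag when predicted
exactly, otherwise fn to the gold tag and fp to the predicted tag. `O` is
never an included tag; positions whose *gold* label is `X` are skipped
entirely. Precision, recall and F1 use the 0-on-zero-division convention
so averages are always defined. Micro averages pool counts over included
tags; macro averages take the unweighted mean over tags with gold support
(absent tags would otherwise dilute macro with structural zeros).
Entity-level exact-match P/R/F1 (type and both offsets) is available as a
secondary report via decoding, since positionwise credit and span credit
answer different questions. `type_micro` pools a single type's B and I
counts, which is what the domain-shift analysis reads.

k-fold splitting is a seeded permutation followed by a contiguous split
into folds whose sizes differ by at most one; cross-validation trains a
fresh tagger per fold and reports each fold plus unweighted means. The
transfer harness trains once and evaluates on held-out source documents
and on shifted-domain documents, reporting both and per-tag deltas.

## The benchmark tagger

A character-level bidirectional recurrent encoder with a linear-chain CRF
output layer, written directly in numpy (forward/backward recursions,
marginals, and backpropagation through time by hand) so that it is
dependency-free, deterministic, and fast enough to train at desk scale.
The recurrent cell is a tanh (Elman) unit; gate machinery was left out
deliberately — on the corpus sizes and sequence lengths this package
targets it met every learnability contract at a fraction of the code, and
the tagger's contract is seeded determinism plus learnability, not a
specific architecture or trajectory.

Scores: a path's score is `start[y1] + Σ emissions[t, yt] +
Σ transitions[yt, yt+1] + end[yL]`. The partition function is computed in
log space by the forward recursion; decoding is Viterbi with ties broken
toward the lower tag index; the training loss is the negative
log-likelihood `log Z − score(gold)`, whose gradients are the CRF
marginals minus gold indicators (verified against finite differences).
Training pads each minibatch and masks both the encoder and the CRF
recursions, so batch composition does not change results for a given seed.

Defaults: embedding 64, hidden 128, Adam at learning rate 1e-3, batch 32,
up to 30 epochs, global gradient-norm clip 5. The character inventory is
built from the training data with one untrained unknown slot; unseen
characters at inference map to it and never raise. Whitespace enters the
encoder as the visible placeholder character. Predicted labels at
whitespace positions are forced to `O`, which the IOB_CHAR scheme defines
rather than the model having to learn it. Checkpoints are `.npz` files
with a versioned JSON header. Hyperparameters of the transformer
fine-tuning route (sequence length 128, batch 32, lr 2e-5, 16 epochs) are
recorded as `BERT_FINETUNE_DEFAULTS` for the export adapter only; the
package deliberately does not implement or fine-tune a transformer — the
adapter is the CoNLL export of BERT-scheme labels.

## Synthetic corpus generator

The generator emulates the *structure* of a clinical question-answering
corpus, not its content: dictionary-drawn entities of three types
(default dictionary sizes 2,191 DZ / 142 SX / 139 BP, the sizes of the
emulated annotation resource; tests use 50/20/20), documents of at most 5
sentences, entities followed by a glued postposition with probability
`attach_prob` (default 0.4 — the real rate is unreported; this is the
package's documented choice), and a question-style shifted domain.

Surface forms are pseudo-syllable strings: ASCII consonant+vowel pairs by
default, real hangul blocks in hangul mode. Shapes encode the type
asymmetry that matters for evaluation: disease names are 1–3 words of 2–4
syllables (the multi-word class), symptoms one word of 2–3 syllables,
body parts one word of 2 syllables. Dictionaries are disjoint across
types and deterministic per seed. The question-domain shift regenerates
only the symptom dictionary with mimetic (reduplicated two-syllable base)
or adjectival (base + a fixed `hada` ending) shapes of 4–5 syllables —
morphology that never occurs in the noun-like answer-domain shapes, so the
two domains' symptom sets are disjoint by construction while disease and
body-part dictionaries are bit-identical across domains.

Sentences are drawn from typed-slot templates. The default template set
is generated from ten sentence shapes (including entity-less ones)
instantiated with every type assignment; at generation time the shape is
sampled uniformly first and the typed variant second, so entity density is
not skewed toward shapes with many typed variants. Three further choices
make the non-entity side of the corpus behave like text rather than like a
closed code book, which is what lets a character model learn that
unfamiliar words are usually `O`: the filler lexicon (40 carrier words) is
supplemented by freshly drawn novel words with probability
`novel_filler_prob` (default 0.3, lengths 1–5 syllables, rejected against
entity forms); postpositions attach to filler nouns at the same rate as to
entities, so a glued particle is not by itself an entity cue; and
sentences of every length may contain no entity at all. Without these,
the trained benchmark develops a "any unfamiliar or particle-bearing word
is an entity" prior that real corpora do not induce, and out-of-vocabulary
symptom forms in the shifted domain are absorbed into the most diverse
class instead of being missed.

`build_vocab` constructs the bundled subword vocabulary from a corpus:
words untouched by entity boundaries become whole-word tokens; a word
containing a boundary (entity + glued particle) is split exactly at the
boundary into a stem token and a `##` continuation; all observed single
characters are fallbacks, so nothing degrades to `[UNK]`. Two properties
make the greedy matcher respect annotation boundaries corpus-wide. First,
phonotactics: stems are strict consonant-vowel syllable sequences while
every postposition begins with a vowel (in hangul mode, with an onset
reserved for particles), so no stem-shaped token can match past an entity
end into a particle. Second, a word string that requires an internal
split anywhere in the corpus is never also added as a whole-word token —
the same glued string can occur once as entity+particle and once as
filler+particle, and a whole-word token would make greedy matching overrun
the split at the first occurrence. Together these guarantee every gold
span starts and ends on a token boundary, which is what makes the
projection round trip exact on generated corpora.

What the generator does not emulate: real phonology and orthographic
variation, morphological inflection beyond the glued particle, annotator
disagreement and span noise, discontinuous or nested entities, Zipfian
word frequencies, and any semantic relation between context and entity
type. Passing tests on generated corpora therefore demonstrate the
*mechanics* — projection exactness, the postposition rule, learnability
and the direction of domain-shift degradation — not clinical-grade
accuracy on real text.

## Study-scale runs and numerical choices

The test suite and `scripts/acceptance.py` use desk-scale sizes chosen
once: 1,000 generated documents for projection/postposition properties;
10,000 random instances for the WordPiece-vs-enumeration oracle; 500
random CRF instances (length ≤ 6, ≤ 4 tags) against explicit path
enumeration at 1e-8 and central-difference gradient checks at 1e-4
relative; 2,000/500 single-sentence train/held-out documents and 20
epochs for benchmark learnability; and three seeds of 2,000 training
sentences for the domain-shift comparison, reported as means over seeds.
Micro/macro identities are asserted to 1e-12 (pure count arithmetic).
Determinism everywhere reduces to numpy `default_rng` seeding; every
stochastic entry point takes an explicit seed, and derived streams use
`default_rng([seed, k])` so that, for instance, disease and body-part
dictionaries are identical across domains while the symptom stream
differs.

## Known limitations

Positionwise evaluation gives partial credit inside entities and is not a
substitute for span-level scoring when boundary exactness is the question
(both are provided). The benchmark's unknown-character embedding is
untrained, so inputs dominated by unseen characters produce arbitrary
(though valid) label sequences. The WP literal-copy convention means WP
label counts at former-`X` positions are not comparable with BERT-scheme
counts except at word-initial positions; comparisons restrict to the
shared positions. The CLI decodes detached token files by reconstructing
offsets under a single-space join, which is only faithful for text that
was single-space separated to begin with.
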