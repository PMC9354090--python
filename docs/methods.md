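# Methods

## Problem and output unit

Free-text clinical records (admission notes, present-illness histories)
describe a patient's condition in a loosely standardized narrative. The unit
of knowledge a medical knowledge graph needs is not a bare entity mention but
an *object-level entity*: an entity label (e.g. Fever) together with its
typed attributes (Body Temperature, Occurrence, Duration), each grounded in a
text span. A bare triple such as "fever–cough" and an attribute such as
"fever–body temperature" live on different levels; conflating them flattens
the medical logic of the record.

This package extracts object-level entities with a four-stage cascade over
one shared character-level encoder:

1. **Punctuation correction.** Clinicians frequently run whole records
   together with commas. Every non-punctuation character is tagged with the
   mark that should *follow* it (a member of the punctuation set, or NONE);
   the raw text's own marks are dropped from the tagged sequence, so
   replacement, insertion and deletion of marks are all expressed by one
   codec. The raw text's own following-mark is fed back in as a
   per-character side-feature embedding: the stage *corrects existing
   punctuation* (a raw period is strong evidence of a boundary; a raw comma
   may be a true comma or a misused period) rather than restoring marks from
   scratch. Head: linear projection + linear-chain CRF.
2. **Sentence classification.** The corrected text is split on sentence-final
   marks (。？！) and each sentence is assigned an entity-type class
   (Symptom, Treatment, Laboratory Test, Imaging) or the reserved ``Other``
   class. Head: softmax over the encoder's summary vector.
3. **Entity-segment tagging.** Inside a classified sentence, contiguous
   segments describing one entity are tagged BIO over the *class-restricted*
   entity label space (a Symptom sentence can only contain Fever or Cough
   segments). Head: bidirectional recurrent layer + linear + CRF.
4. **Attribute tagging.** Inside each segment, attribute sub-spans are tagged
   BIO over the *entity-restricted* attribute space. Same head shape.

Restricting each stage's label space to what its upstream context allows
("minimizing the semantic space") is the point of the cascade: each tagging
problem becomes small and local.

## Joint loss

All four heads share the encoder and are trained simultaneously. Each
sequence-labeling task contributes a summed negative log-likelihood over its
tokens, the classifier a summed NLL over sentences, and the joint loss is the
plain unweighted sum

    L = L_punct + L_entity + L_attr + L_cls

with the sequence-labeling part L_punct + L_entity + L_attr kept as an
explicit subtotal. Sum (not mean) reduction matches the Σ form of the loss;
`ModelConfig(reduction="mean")` provides the mean alternative. The additivity
of the components is asserted on every training batch at 1e-8 relative
tolerance (all arithmetic is float64).

The tagging losses are *sequence-level* CRF likelihoods: the score of a tag
path is the sum of per-position emissions plus tag-pair transitions plus
start/end scores, normalized over all paths by the forward algorithm in
log-space. With `crf="off"` the transition scores are identically zero and
each tagging loss reduces exactly to summed per-token cross-entropy (this
equivalence is tested). BIO well-formedness is enforced structurally with
−∞ transition entries (into I-x from anything but B-x/I-x) when the CRF is
on. Viterbi decoding breaks ties toward the lowest label index.

## Training regime

Teacher forcing: the entity head trains on gold sentences with gold classes,
the attribute head on gold segments with gold entity labels; only at
inference does the cascade feed predictions forward. The attribute head's
segments are boundary-jittered during training (each side independently
shifted by −1/0/+1 characters, never dropping an attribute character): the
upstream segment head can slip a boundary by a character, and the cascade's
error tolerance — attribute decoding unchanged as long as the attribute
characters survive — is a property the training regime must induce, not
assume. A staged mode (`TrainConfig.schedule="staged"`) trains the tasks one
after another in cascade order instead, for ablation. Batches are whole
documents, so every batch exercises all four tasks through the shared
encoder; within a batch, each task's sequences are grouped by length into
padded chunks (a padded-token budget of 4096) purely to bound padding waste —
the summed loss is unchanged by the chunking. Optimization is Adam
(lr 2e-3 with cosine decay to 0.1×, global gradient-norm clip 5.0), 30
epochs, document-shuffled per epoch from a seeded generator; encoder dropout
0.1 (seeded, training only — the loss invariants are asserted on the same
stochastic forward pass, and direct `joint_loss` calls outside the training
loop are deterministic). Parameter initialization and shuffling are
separately seeded; the same seeds reproduce bit-identical parameters.

## Encoder

A small trainable transformer encoder, character-level (one token per Unicode
code point — sub-word merging harms Chinese clinical text): embedding width
64, 2 self-attention layers, 2 heads, feed-forward width 96, pre-norm
residual blocks. Position is encoded as a **clipped relative-distance bias**
added to attention scores (per head, per layer; distances clipped at ±8)
rather than absolute position embeddings. This choice is load-bearing:
punctuation restoration depends on local character patterns that recur at
arbitrary absolute offsets, and with absolute learned positions the model
memorized training-document layouts (near-zero training loss, ~0.80 test F1
on punctuation); the translation-invariant bias closes that gap. A learned
summary slot is prepended at position 0 and serves as the sentence summary
vector for classification. The encoder is deliberately small and trained from
scratch; anything exposing the same interface (per-character context vectors
plus a summary vector) can be swapped in, including a large pretrained
encoder — the method is the head architecture and loss, not specific weights.

The model trains on a single CPU; the automatic differentiation underneath is
a small reverse-mode engine on numpy arrays (`mlee.autodiff`), kept in
float64 so the CRF/enumeration and additivity checks hold at 1e-8.

## Synthetic corpus

The clinical corpus this method was developed for is access-restricted, so a
generator stands in for it. What it emulates:

* documents of 2–5 sentences; each sentence either renders one or two entity
  segments from per-entity templates (slots filled from typed value lexicons:
  temperatures, durations, drug names, test values, imaging findings …) or is
  an ``Other`` distractor (appetite, mental state, general condition);
* class mixture Symptom 0.34 / Treatment 0.18 / Laboratory Test 0.16 /
  Imaging 0.16 / Other 0.16; a Symptom sentence carries both a fever and a
  cough segment (joined by a comma) with probability 0.3;
* templates deliberately vary which attribute subset they fill so the corpus
  averages ≈2.8 attributes per entity, matching the reference corpus's
  printed ratio of 2.82;
* punctuation corruption: each sentence-final period independently becomes a
  comma with probability 0.486 — the punctuation error rate reported for real
  clinical records; an optional deletion mode (off by default) removes marks
  at a configurable rate.

All four gold layers are emitted mutually consistent and schema-validated,
and generation is byte-identical given a seed.

What it does **not** emulate: lexical diversity (small closed lexicons),
misspellings, negation and uncertainty, entity mentions spanning sentence
boundaries, nested or overlapping segments, or clinically plausible
co-occurrence statistics. Passing the end-to-end checks therefore shows the
architecture can recover structure under the stated corruption process, not
that it reaches any particular accuracy on real records. One genuine
ambiguity survives in the synthetic data: a fever segment followed by a cough
segment may be one paired Symptom sentence (comma) or two sentences (period),
so the punctuation stage has a small irreducible error there — which mirrors
the over-segmentation the method tolerates by design (both fragments flow
through classification independently, and segment-boundary slips of ±1
character that preserve the attribute characters leave attribute decoding
unchanged; this tolerance is tested).

## Evaluation

Span scoring is exact-match micro precision/recall/F1 on (label, start, end);
sentence classification reports precision (micro accuracy), punctuation P/R/F1
over non-NONE tags. A `lenient` overlap mode exists for boundary-slip
analysis. To compare systems that see differently punctuated views of a
document, spans are mapped to *core coordinates* (index among non-punctuation
characters), which are invariant under corruption and correction.

The flattened baseline collapses the hierarchy into 23 ``entity-attribute``
labels (47 BIO tags) and tags raw, uncorrected sentence units directly with
the same encoder architecture and budget — no punctuation correction, no
classification, no label-space restriction. Both systems are scored against
identical gold (entity, attribute, core-span) tuples.

On the synthetic corpus both systems operate near ceiling: the small closed
lexicons and fixed templates are trivially memorizable for the flat tagger,
which also never risks a segmentation decision, so it can reach an attribute
F1 of 1.0 while the cascade pays a small residual price for ambiguous
punctuation boundaries. The advantage of the cascade reported on real
clinical data comes from label-space confusability and textual diversity
that the template corpus deliberately does not reproduce; the synthetic
comparison should be read as a ceiling check of both systems, not as a
measurement of that advantage.

## Numerical and design choices

* Offsets are 0-based half-open everywhere; sentence splitting keeps the
  final mark attached to the preceding sentence.
* Ill-formed BIO at decode time is repaired by opening a span at a stray I-x
  (most permissive; maximizes what the attribute stage sees).
* The punctuation-target codec cannot represent two consecutive marks after
  one character and raises an alignment error there; the generator never
  produces them.
* Attribute label space is the set of 19 unique attribute names (shared
  names such as Occurrence/Duration/Body part use one label across entities),
  masked per entity; the entity space is the 7 entity names masked per class.
* One transition matrix per head (not shared across heads).
* Multiple segments of the same entity in one sentence stay separate objects.
* Over-segmentation by the punctuation stage is accepted, not repaired.
* Degenerate inputs: empty documents yield empty results; empty sentences are
  never emitted by the splitter; a vacuous metric (no gold, no predictions)
  reports 1.0 with a zero-support flag.

## Problem sizes used by the shipped study

The end-to-end study (`scripts/acceptance.py`, also exercised by the test
suite) generates 560 documents ≈ 1,900 sentences at corruption 0.486 (corpus
seed fixed at 7 as a study condition), splits 80/20 by document, trains 30
epochs, and evaluates every stage plus the flattened baseline on the held-out
split. Oracle checks run on 100 random CRF instances (T ≤ 5, L ≤ 4), loss
additivity on 50 random two-document batches, codec round-trips on 1,000
random cases each.

## Known limitations

* No nested or overlapping segments; no relation/edge inference between
  extracted objects; no entity normalization or ontology linking.
* The punctuation head restores marks from punctuation-stripped text, so it
  ignores whatever signal the raw (possibly wrong) marks carried.
* The encoder is far smaller than a pretrained language model; on real
  clinical text a pretrained encoder should be plugged in via the encoder
  interface.
* `ModelBundle` serialization stores parameters in an `.npz` archive next to
  a JSON manifest with a config fingerprint; loading verifies the fingerprint
  and reproduces predictions bit-identically.
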