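# Methods

This note documents the models and procedures famhx implements, the
choices made where the design was genuinely open, and what the synthetic
test corpus does and does not establish.

## Task model

A clinical note is processed sentence by sentence.  The system answers
three questions per sentence: who is the subject, which disease
observations are present, and is the subject alive.  Outputs are
document-level sets (the gold format carries no spans): family members as
(relation, side) pairs restricted to 15 valid relations, observation
strings, living-status triples (relation, side, score) and observation
relations (relation, side, observation, negated).

Living status is a product score: `score = alive × healthy`, each
component in {0: no, 1: not applicable, 2: yes}, so scores lie in
{0, 1, 2, 4}.  Detection uses two disjoint phrase sets — deceased terms
("dead", "deceased", "died", "passed away", "stillborn") mapping to
(0, 0), and healthy-and-alive terms ("alive", "alive and well", "doing
well", "generally healthy", "good general health", "good health",
"healthy", "living", "living and well", "otherwise healthy", "well",
"without problems") mapping to (2, 2); the longest matching phrase wins.
The alive-but-unhealthy case (2, 0) is deliberately unmodeled: it is rare
in this task's data and no rule emits it.  Which (alive, healthy) pair
each phrase maps to is this implementation's reading; only the two-set
dichotomy is given.

## Rule-based kinship engine

**Sentence cleaning.** A stop set (~300 common verbs and conjugations,
adjectives/adverbs, articles, number words, plus a first-name list)
is removed and possessives are normalized ("patients'"/"patient's" →
"patients"), which makes kinship chains adjacent: "the patients' uncle
has one son" cleans to "patients uncle son", where "uncle son" composes
to Cousin.  The stop set deliberately excludes kinship modifiers (great,
half, step, maternal, paternal), partner terms, pronouns, conjunctions,
negation cues and living-status phrases, which downstream rules consume.
The exact stop set is unpublished upstream; the bundled one is a curated
default, editable as a data file.

**Workflow per sentence.** (1) Patient-subject test: a patient term heads
the cleaned sentence and no relative is mentioned.  (2) Complex rules:
six-part rules (keyword, ordered before-terms, ordered after-terms,
keep/discard, relative, side) applied in file order, first match wins;
discard rules handle traps like a father's "children" (the patient's
half-siblings).  (3) Exact matching: longest-match lexicon scan with side
words absorbed, and adjacent hits composed through the disambiguation
table.  (4) Sentence linking: a sentence with no subject inherits the
previous sentence's subject; the first sentence defaults to the patient.
Partner-scope detection always runs.

**Precedence.** When a keep rule's keyword lies inside an exact-match
chain that composed a cascade or belongs to a partner branch, the chain
wins (otherwise "the patient's paternal uncle's daughter" would be
annotated Uncle instead of Cousin and partner chains would leak);
otherwise the rule's side-specific mention replaces the chain's.  This
refinement was fixed by the synthetic-corpus experiments.

**Composition.** Disambiguation rules are four-element rows (first
relative, second relative, resolved relative, resolved side) in an
editable table covering first/second-degree combinations; the side is
fixed by the parent line (father∘brother → paternal uncle) or inherited
from the outer mention (maternal aunt∘son → maternal cousin).  Pairs
outside the table fall back to (inner, NA) with a debug log.  Partner
terms (wife/husband/partner/spouse) are lexicon members heading a chain,
so "his wife's maternal aunt's son" resolves to a maternal cousin flagged
partner-branch and is then removed by eligibility filtering, which accepts
exactly the 15 valid relations with no partner flag.

**Partner weighting.** The co-occurrence weights for patient-vs-partner
terms are unpublished; here patient terms carry weight 2 and partner terms
weight 1, so a sentence naming both ("the patient and his wife...") stays
patient-scoped, while a bare partner sentence flips scope and carries it
into subject-less following sentences.  These weights are calibrated on
the bundled fixtures, not claimed to match any other implementation.

**Conflicting side markers** ("maternal/paternal great-aunt") resolve to
side NA rather than guessing.

## Observations and negation

Rule-mode observation extraction is case-insensitive longest-match-first
dictionary matching at word boundaries (so "art" never fires inside
"heart"), followed by a false-positive list.  The bundled ~110-term
dictionary of common conditions exists for tests and demonstrations; real
deployments supply their own vocabulary, and the upstream UMLS-derived
dictionary is out of scope.  Negation is a clause-scoped cue match: a cue
("no", "not", "denies", "without", "no history of", ...) before the
observation, with ";"/"but"/"however"/"although" resetting the scope
("no cancer, but has diabetes" leaves diabetes non-negated).  Negation
inside the rule engine is an extension required by the strict relation
scoring; the upstream engines did not describe one.

## Neural sequence labeler

Architecture: token embeddings (a trainable lookup table; pretrained
embedding matrices can be loaded in its place) → dropout → BiLSTM →
2-head scaled-dot-product self-attention with a residual connection and
layer normalization → linear projection to 5 BIO emissions → linear-chain
CRF (forward algorithm in log space for the loss, Viterbi with
lowest-index tie-breaking for decoding).  Whether attention replaces or
augments the BiLSTM states was unspecified; the residual + layer-norm
choice here is this package's design.  The linear-softmax baseline is
embeddings → linear → softmax with no recurrent encoder.

Auxiliary pieces: the entity-discovery head is a per-token binary
classifier (entity vs not) trained with binary cross-entropy; the total
loss is `α·L_ner + (1−α)·L_ed` with α = 0.5 by default (the combination
coefficients are unpublished).  The external-annotation channel codes
each token 0 (unannotated), 1 (first token of an annotation) or 2
(continuation), normalized by division by 2 — the normalization constant
is a design decision — and appends one feature dimension.  Wordpiece
tokenization uses greedy longest-match segmentation with "##"
continuations over a bundled ~270-piece demonstration vocabulary;
reconstruction promotes any word with a tagged piece to a whole-word
entity (majority class across pieces, ties to the earliest tagged piece),
is idempotent and never shortens an entity.

Training: Adam (lr 0.001), batches of 32 sentences, 100 iterations per
epoch sampled uniformly with replacement from the training partition,
early stopping on validation span-F1 with patience 5, embeddings
trainable for the first 2 epochs then frozen, 5-fold cross-validation.
Defaults follow the published setup (hidden 256, 2 heads, dropout 0.5,
100 epochs); tests and the acceptance script run scaled-down
configurations (embedding 24–32, hidden 32–48, tens of iterations) to fit
a single-CPU time budget — the defaults are not what the tests execute.
All randomness (init, fold splits, batch sampling, dropout) flows from the
config seed; two runs are bitwise identical.

The autodiff layer is a ~300-line reverse-mode engine over float64 numpy
arrays, written because no autodiff framework is available in the target
environment.  Advanced indexing uses scatter-add in the backward pass, so
embedding lookups and CRF path scores differentiate exactly; the CRF
partition function is checked against exhaustive path enumeration to 1e-9.

## Evaluation

Precision/recall/F1 per category, micro-averaged overall (how "overall"
is averaged was unspecified; micro over pooled counts is used).  Matching
is document-scoped.  Family members and living-status triples match
exactly; a wrong family side yields one FP plus one FN.  The partial
observation match is formalized as contiguous token-subsequence
containment in either direction.  Task-2 observation relations are scored
leniently (member+side and observation-or-negation) or strictly
(member+side+observation+negation); both keep member and side required.
Non-exact categories use maximum bipartite matching so counts are
order-independent, verified against a brute-force matching oracle.

## Synthetic corpus

The generator emits template-based family-history narratives: simple
relative sentences with observations or living status, negated
observations ("has no history of X", "was negative for X"), pronoun
continuations exercising sentence linking, cascaded relatives
("the patient's father's brother has X") whose gold resolution comes from
a fixed hard-coded list independent of the kinship tables, partner
branches ("his wife's sister has X") contributing observations but no
family members, ineligible relatives, and patient-only sentences.  Gold
annotations are generation-time ground truth, never extractor output.
Default rates (10% partner, 15% cascade, 10% ineligible, 20% negation,
30% living status, 3–7 sentences per note) are chosen to exercise every
phenomenon while keeping most sentences ordinary; no published corpus
statistics exist to copy at this granularity.

**What a green test establishes.**  The templates use a closed disease
vocabulary, regular syntax and unambiguous kinship chains, so the rule
engine can reach ~perfect scores and the labeler >0.9 observation F1 at
small scale.  That validates the mechanisms (cleaning, composition,
partner exclusion, negation scoping, CRF training dynamics, evaluator
semantics), not clinical-grade accuracy: real notes add misspellings,
section headers, disjoint disease mentions and kinship phrasings outside
the lexicon.  One published qualitative finding — sequence labelers doing
well on observations but poorly on family members — does not reproduce
here, because templated relative surfaces are trivially memorizable;
tests therefore do not assert that ordering.

## Known limitations

- Pronoun possessives across sentences are not composed: in "The
  patient's aunt was seen.  She has a son with asthma.", the son is
  annotated Son, not Cousin — the same context-loss failure mode the
  upstream systems document.
- Dependency-parse-based subject detection and coreference resolution are
  out of scope; sentence linking is the only cross-sentence mechanism.
- The bundled lexicons are demonstration-scale; scores on real corpora
  depend on supplying realistic dictionaries and rule files.
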