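# famhx — family-history extraction from clinical notes

Clinical notes routinely record a patient's family history as free text:
which relatives exist, which side of the family they belong to, what
diseases they had, and whether they are alive.  Structuring that text is
what this package does.  It targets the two subtasks of the family-history
shared-task formulation used in clinical NLP:

1. **Entities** — patient family members, normalized to one of 15 valid
   relations (father, mother, parent, brother, sister, son, daughter,
   child, grandfather, grandmother, grandparent, cousin, sibling, uncle,
   aunt) with a maternal/paternal side, plus disease observations.
   Relatives of the patient's partner and extended relatives (nephew,
   great-grandparents, half-siblings, ...) are recognized but excluded
   from output.
2. **Relations** — living-status scores attached to family members, where
   the score is `alive x healthy` with each component in {0: no, 1: not
   applicable, 2: yes}, and (member, observation, negation) triples.

The package is aimed at clinical-NLP researchers and at anyone who needs a
reproducible, fully self-contained baseline for this task: the real shared
task corpus is access-restricted, so a seeded synthetic-note generator
with exact gold annotations is included and used throughout the tests.

## How it works

- **Rule-based kinship engine** (`rule_engine`, `kinship`): sentences are
  cleaned of common verbs/conjugations, adjectives and names, so kinship
  chains become adjacent (`the patients' uncle has one son` →
  `patients uncle son`), then processed by a patient-subject test, complex
  keyword rules (keyword + ordered before/after context terms,
  keep-or-discard), exact lexicon matching with cascade composition
  (father ∘ brother → paternal uncle; maternal aunt ∘ son → maternal
  cousin, inheriting the side), sentence linking (a subject-less sentence
  inherits the previous subject; the first sentence defaults to the
  patient), and partner-scope detection.
- **Neural sequence labeler** (`ner_model`): an attention-based
  BiLSTM-CRF over BIO tags (`O`, `B-Obs`, `I-Obs`, `B-PFM`, `I-PFM`), with
  a linear-softmax baseline, an optional entity-discovery auxiliary head
  (loss `α·L_ner + (1−α)·L_ed`), an external-annotation feature channel
  (0/1/2 coding, normalized), wordpiece tokenization with whole-word
  reconstruction (`car/##cin/##oma` → one entity), Adam, early stopping,
  and k-fold cross-validation.  Built on a small numpy reverse-mode
  autodiff (`autodiff`) so it has no deep-learning framework dependency.
- **Hybrid pipeline** (`relations`): family members and living status from
  the rule engine; observations from the trained labeler (hybrid mode) or
  a dictionary matcher with false-positive filtering (rule mode); negation
  by clause-scoped cue matching.
- **Evaluators** (`evaluator`): precision/recall/F1 per category.  Family
  members match on exact (relation, side) — a wrong side counts one FP
  *and* one FN.  Observations match leniently (contiguous token-sequence
  containment: `diabetes` matches `diabetes type 2`).  Task-2 observation
  relations are scored **leniently** (member+side plus observation *or*
  negation correct) or **strictly** (everything correct); strict F1 is
  never above lenient F1.

All lexicons (stop set, kinship lexicon, composition table, complex rules,
disease dictionary, living-status and negation cues, wordpiece vocabulary)
ship as editable text files under `src/famhx/data/`.

## Worked example

```python
from famhx import Document, run_hybrid

doc = Document(
    "note-1",
    "The patient's maternal aunt passed away from lung cancer. "
    "The patient's father's brother has no history of asthma. "
    "His wife's sister has diabetes.",
)
(members, observations), relations = run_hybrid(doc)
```

prints, when the pieces are inspected:

```
family members: [('Aunt', 'Maternal'), ('Uncle', 'Paternal')]
observations:   ['lung cancer', 'asthma', 'diabetes']
relation: ('Aunt', 'Maternal') Observation lung cancer NonNegated
relation: ('Aunt', 'Maternal') LivingStatus 0
relation: ('Uncle', 'Paternal') Observation asthma Negated
```

Reading the output: the maternal aunt is dead (score 0 = alive 0 ×
healthy 0) and had lung cancer; "father's brother" was composed to a
paternal uncle whose asthma mention is negated; the wife's sister is a
partner-branch relative, so she is excluded from family members while her
disease mention is still reported as an entity.

There is also a CLI:

```bash
famhx generate --n 100 --seed 1 --out corpus/       # notes + gold
famhx annotate corpus/notes --mode rule --out pred/ # task1.tsv, task2.tsv
famhx train corpus/notes --model-out model.json     # 5-fold CV labeler
famhx evaluate --task 2 --mode strict \
    --pred-task1 pred/task1.tsv --pred-task2 pred/task2.tsv \
    --gold-task1 corpus/gold_task1.tsv --gold-task2 corpus/gold_task2.tsv
```

## Acceptance script

`scripts/acceptance.py` re-runs the whole system from scratch: it
generates a synthetic corpus, annotates it in rule mode, trains a
scaled-down labeler and annotates in hybrid mode, scores both subtasks
under both evaluation schemes, and writes its JSON result to `--out`:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
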