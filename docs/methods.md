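# Methods

This note documents the models and procedures implemented in `phenonote`,
the parameters that matter, the numerical choices, and what the synthetic
test bed does and does not establish.

## Text conventions

All offsets are 0-based, half-open, counted in Unicode code points over
the exact loaded text, so `text[start:end] == surface` is an invariant of
every entity. All string comparison (dictionary matching, cue matching,
qualitative keywords, unit patterns, normalization scoring) happens on
*folded* strings — NFD decomposition, removal of combining marks,
lower-casing — while offsets always refer to the original text; a folded
match is projected back through an explicit character map. This absorbs
the accent and case variation of French clinical orthography
("négatif"/"NEGATIF"/"negatif") without touching spans.

Tokens are maximal letter runs, maximal digit runs, or single non-space
punctuation characters. This deliberately splits `Hb=9g/dL` into
`Hb = 9 g / dL`, which is what the measurement rules and the BILOU
alignment need.

## NER

Two recognizers share one contract (text in, entities out):

* **Dictionary baseline.** Exact matching of folded dictionary synonyms,
  restricted to token boundaries, overlaps resolved longest-match-first
  then leftmost. Complete laboratory tests are not dictionary entries;
  the baseline derives them by extending a recognized test name over an
  inline separator (`:`/`=`/space, never across a line break) followed by
  a titer, a number with an optional unit, or a qualitative keyword.
* **CRF tagger.** Six independent BILOU layers, one per entity category.
  Per-layer tagging is what lets a `lab_name` nest inside a
  `lab_complete` while same-label spans never overlap. Decoding invalid
  tag sequences is total: valid `U` and `B…L` structures parse first, and
  any remaining invalid run is repaired by merging the maximal same-label
  non-O run into one entity. Applying the merge only to invalid runs is
  what keeps `encode∘decode` the identity on valid input (two adjacent
  single-token entities encode as `U,U` and must decode back to two
  entities, not one).

The CRF is a standard linear chain: emission weights over sparse token
features plus a full transition matrix; the partition function comes from
the log-space forward algorithm, gradients from forward–backward
marginals, decoding from Viterbi with ties broken toward the earlier tag
in a fixed alphabet order. Training is full-batch gradient descent on the
L2-regularized negative log-likelihood with a fixed step — chosen over
faster optimizers because it is exactly reproducible: weights start at
zero, the gradient is averaged over sequences, and the same corpus and
hyperparameters give bitwise-identical weights. Defaults: step 0.2,
σ = 1.0, 50 epochs. The default token encoder (`sparse-v1`) is purely
lexical — folded form, character 3-grams, digit/punctuation shape, ±2
context tokens — so no pretrained weights are required; a contextual
encoder can be registered under its own id and substituted without
touching model or training code. The default train/test split fraction is
0.806/0.194 at the document level (103 documents split 83/20).

## Qualification

Only drug-name mentions are qualified. Defaults are
action=`unknown`, temporality=`present`, certainty=`certain`,
negation=`false` — deliberately the "keep" state of the downstream
filter, so a bare mention counts as an asserted fact and only explicit
cues can demote it. A cue lexicon entry carries a surface form, the axis
and value it sets, a direction (`before`/`after`/`both`) and a maximum
token distance. For each axis the nearest in-scope cue within the same
sentence wins; ties break by lexicon order, then position, making the
operation deterministic and independent of entity order. Sentences are
line-oriented: a newline always terminates one, as does a period followed
by whitespace and an upper-case letter (so decimal points do not split).
The shipped French lexicon ("pas de" → negated, "arrêt" → stop,
"antécédent" → past, "si besoin" → conditional, …) is a starter set and
fully config-replaceable; its contents are package choices, not facts
about any particular hospital's corpus.

## Measurement extraction

Given a complete laboratory test span and its nested name span(s), the
name characters are blanked (separators kept), and the residual is parsed
with precedence **titer > numeric > qualitative**, leftmost match within
each class. The precedence is forced by `1/160`: its digits must not
parse as a bare numeric value. Decimal commas are normalized to dots;
a unit is a letter/µ/% token attached to the number or separated by at
most one space. Standardization:

* qualitative tokens are graded through a folded lexicon — positive
  family → 1.0, negative family → 0.0, normal family → 0.5 (multi-word
  negative forms like "non détecté" are matched before their positive
  substring);
* titers `1/N` are stored as value N with unit `titer`, so "stronger
  positivity" is numeric order and a ≥ 1/80 rule is `value >= 80`;
* numeric units are converted through a table of (pattern, canonical,
  factor) rows; the table must be closed (every canonical unit maps to
  itself with factor 1), which makes conversion idempotent. Unknown units
  pass through verbatim with a warning flag rather than dropping the
  measurement.

Intervals ("entre 5 et 7") and inequalities ("< 0,5") are out of scope
beyond raw capture.

## Normalization

A detected term is folded and scored against every synonym of the
dictionary (brute-force scan; desk-scale dictionaries make an index
unnecessary, and the total tie-break — higher score, then smaller code,
then shorter synonym — makes scan order irrelevant). The code of the
argmax synonym is returned when the score reaches τ. Defaults: τ = 0.85
for the string scorers, τ = 0.60 for embedding cosine; τ = 0 restores
pure argmax behavior. Method assignment per entity kind follows the
package default of Jaro–Winkler for drugs and embedding cosine for
laboratory tests. The default embedder is an L2-normalized character
3-gram count vector over the folded term — deterministic, no weights to
download — and the embedder slot accepts any fixed-dimension term
encoder.

## Phenotyping

Text evidence is first filtered to mentions qualified as certain and not
negated; action and temporality are deliberately ignored by the filter (a
stopped or past treatment still documents exposure). Per patient and
concept group:

* structured lab hit — any record with a group code whose interpretation
  flag is true, or, absent a flag, whose value exceeds the upper
  reference bound;
* text lab hit — any retained mention with a group code whose
  measurement is positive: qualitative 1.0; titer ≥ the group threshold;
  numeric value above the patient's structured reference range for the
  same concept when one exists. A numeric text value with no reference
  available anywhere is conservatively non-positive and logged — the
  alternative (guessing a range) would manufacture false positives;
* drug hits — existence of an administration record / a retained mention
  with a group code.

The cohort table counts, per group, patients with
`structured_only`+`both` (structured), plus `unstructured_only`
(combined), and reports `n_benefit = n_combined − n_structured` with
percentages over the cohort size (two decimals).

## Evaluation

Matching is strict and one-to-one (greedy in document order for
duplicate spans): exact boundaries + label; end-to-end additionally
requires the predicted code to be in the gold entity's list of acceptable
codes (gold may carry several); measurement scoring requires equal
canonical value (tolerance 1e-9) and unit. P/R/F1 are percent-scale with
the zero-denominator → 0 convention, rounded to one decimal for reports
only. CIs resample whole documents with replacement (B = 1000, seeded)
and recompute the pooled-count micro metric per replicate; the percentile
interval is the default and the basic (reflected) variant is available,
since "empirical bootstrap" does not pin down one of the two.

## Synthetic cohort

The generator draws, per patient and group, whether the fact is
mentioned in text (default 0.5) and whether it is covered by the
structured system (0.6 given a text mention; 0.15 structured-only),
writes template sentences ("Introduction de hydroxychloroquine 200 mg",
"AAN : 1/160.", "anti-ADN : positifs.", "Pas de traitement par …"), and
records the flag it just realized in a truth table. Numeric labs always
get a structured record carrying the reference range (as a routine assay
would), so text numeric positivity is decidable; titer and qualitative
labs are structured only when the structured source actually covers
them. Typos are single random edits applied to names at a configurable
rate. Distractor content (non-group drugs, a confusable name
`hydroxycarbamide`, negated mentions, filler labs) exercises the filters.

Defaults (200 patients, 2 notes/patient, typo rate 0, cue rate 0.3) are
the conditions of the recovery suite. What passing shows: every stage
contract composes — at zero noise, the pipeline output equals the truth
table exactly, and under 10% typos fuzzy normalization strictly beats
exact matching. What it does not show: performance on real clinical
language, whose spelling variation, ellipsis, section structure and
class frequencies the rigid templates do not model. Real-corpus scores
require real annotated notes.

The bootstrap-coverage suite simulates 500 corpora of 103 documents each
(the scale of a realistically annotatable discharge-summary set) with a
known Bernoulli/Binomial error process and checks that the 95% F1 CI
covers the population micro-F1 in 92–98% of trials. The percentile
bootstrap is known to undercover at much smaller document counts; that
is a property of the method, not a defect of the implementation.

## Known limitations

* The dictionary NER baseline recognizes names only; strength, dose and
  form require the CRF.
* The qualification engine is a rule stand-in with sentence-local scope;
  long-range or discourse-level assertion is out of reach.
* Unit conversion is multiplicative only (no molarity conversions).
* Each concept group is scored independently; patients are not
  deduplicated across overlapping disease cohorts.
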