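# Methods

This note documents the models, rules and numerical choices behind
`raretext`, and what the shipped tests do and do not demonstrate.

## Problem setting

Given a corpus of clinical notes D and an ontology defining rare diseases R
with phenotypes P, the pipeline approximates a function f: D → R×P that maps
each note to the rare-disease concepts it genuinely asserts for the patient.
It factorises into a high-recall candidate generator (dictionary matching
against an ontology-derived vocabulary) and a precision-restoring assertion
classifier y = f(m, c) ∈ {0, 1} applied to each candidate mention m with
surrounding context c.

## Vocabulary construction

* **Normalization.** All matching happens on a canonical form: NFKC
  compatibility normalization, lowercasing, non-alphanumeric characters
  replaced by spaces, whitespace collapsed. The function is idempotent and
  deterministic; it deliberately erases punctuation distinctions
  ("Huntington's disease" ≡ "huntington s disease").
* **Linking.** A source concept links to a CUI when its normalized label or
  any synonym equals any normalized atom string of that CUI *and* the CUI
  carries at least one whitelisted semantic type. Matching is
  normalized-exact only — no fuzzy or approximate matching — because exact
  matching is deterministic, auditable, and sufficient once UMLS-scale
  synonymy is folded in. Concepts may link to several CUIs; label matches
  outrank synonym matches for provenance.
* **Semantic-type whitelist.** Default {T019, T047, T048, T049, T050, T190,
  T191}: congenital abnormalities, diseases/syndromes, mental and
  physiological dysfunctions, anatomical abnormalities, neoplastic
  processes. This filter is the package's refinement step standing in for
  hierarchy-based disambiguation; a full hierarchical-relationship walk is
  not implemented (no algorithm for it is well defined by the sources the
  vocabulary consumes), and the whitelist is configurable where a different
  trade-off is wanted.
* **Acronyms.** Any original-case term that is all-uppercase and at most 4
  characters (configurable) is stored separately in original case. The
  length-4 default covers the clinically notorious short forms (HD, PID,
  PNA, SAR) while excluding longer all-caps strings that are rarely
  ambiguous.
* **Collisions.** One normalized term claimed by two CUIs is resolved by a
  configurable policy — `drop_colliding` (default: remove everywhere, log),
  `prefer_first`, or `error`. Dropping is the conservative default: an
  ambiguous surface form harms precision more than its absence harms recall.
* **Crosswalk.** CUIs found in the ICD mapping table resolve directly; the
  rest are flagged `unresolved` (the expert-review step that would resolve
  them is out of scope). Resolved + unresolved always equals the number of
  distinct links. ICD codes are compared dot-free and uppercased
  ("Q33.0" ≡ "Q330") to join MIMIC-style tables that omit dots.

## Extraction

Tokens are maximal alphanumeric runs with 0-based half-open character
offsets; sentence boundaries fall at terminal punctuation and newline runs
(rule-based — clinical notes are too irregular for a trained segmenter to
add value deterministically). The matcher is a trie over normalized token
sequences; a scan advances one token at a time and walks at most the longest
pattern depth, with overlaps resolved leftmost-longest and ties broken by
lower (CUI, concept id). Matching is token-sequence based, so terms never
fire inside words ("HD" cannot match inside "CHD"). Acronym-flagged
patterns additionally require the raw slice to equal a stored original-case
form exactly. No assertion reasoning happens at this stage; negated and
hypothetical mentions are extracted on purpose and left to the filter.

Context windows come in three granularities: ±k tokens, ±k sentences, or
the whole document, truncated silently at document edges. "Words" are
tokens as defined above.

## Filtering

Prompts are assembled from four plain-text template files (instruction /
definition / example / query blocks) shipped as package data, so alternate
wordings can be swapped without code changes; prompt text is byte-identical
for identical inputs. Few-shot examples are sampled without replacement
with a seeded generator from a user-supplied annotated bank, never from
documents under evaluation. Knowledge-augmented prompts inject the
concept's resolved terminology definition; a missing definition degrades
gracefully to the zero-shot layout with a logged warning.

Backends implement one operation — prompt in, response text out — and must
generate greedily (the temperature-0 analogue), which makes runs
reproducible. Responses are parsed by their first token
({yes,y,true,1} / {no,n,false,0}); anything else is `unparseable` and maps
to *keep* by default: the filter exists to raise precision, and silently
discarding candidates on a parse failure would corrupt recall invisibly.
The policy is configurable and every such event is logged.

The deterministic rule backend is a NegEx-style classifier scoped to the
mention's sentence: pre-negation cues within 6 tokens before the mention
(no scope breaker such as "but" between), post-negation cues within 4
tokens after, hypothetical cues anywhere earlier in the sentence,
family-history cues anywhere in the sentence, and an
ambiguous-abbreviation table that vetoes acronym matches unless an
expansion phrase appears in the window. The 6/4 windows and cue lists
follow the NegEx convention and are configuration, not code. This backend
is the package's own fully-offline classifier; remote language-model
services plug in through the HTTP adapter by configuration only.

## Evaluation

* Gold standards are standoff rows verified against the corpus
  (span text must equal the recorded surface). Dual annotation is
  adjudicated: agreed positions keep the common label, disagreements take
  the third annotator's label; Cohen's kappa = (po − pe)/(1 − pe) with an
  explicit error on degenerate marginals (pe = 1).
* Matching of kept mentions to gold is greedy by position with each gold
  annotation consumed once; span agreement is any-character overlap by
  default (annotator spans rarely align character-for-character with
  dictionary spans), with exact mode available; CUIs must agree when both
  sides carry one.
* The recall denominator includes gold positives the dictionary never
  proposed. This is the only reading under which a dictionary baseline can
  show recall below 1, and it measures the system, not just the filter.
  Metrics are mention-level; table values are rounded half-up to 4 decimals.
* Sweeps vary shot count k (fixed seed per run) or context size (0 is the
  whole-document sentinel) and emit one metrics row per setting.

## Synthetic generator

The generator emulates the failure modes the filter exists for, at desk
scale. Disease names are pronounceable pseudo-word bigrams (plus a synonym
and, for some entries, a unique uppercase acronym), so they cannot occur in
filler prose; filler sentences are drawn from a fixed clinical-boilerplate
pool containing no vocabulary terms, which makes candidate recall exactly
measurable. Each document belongs to a patient owning 1–3 documents
(enabling patient-level aggregation), has a log-normal token budget
(median 300, σ = 0.6 — skewed like real discharge summaries but light
enough to exercise window truncation cheaply), and carries a Poisson
number of planted mentions (mean 2). Each mention draws a category —
affirmative (residual mass, default 0.55), negated (0.15), hypothetical
(0.10), family-history (0.10), ambiguous-abbreviation (0.10) — and
instantiates a template; the category alone determines the gold label
(affirmative = 1, everything else = 0). A structured-diagnosis table
covers each true (patient, disease) pair with probability 0.6 (the
`icd_coverage` knob), emulating under-coding; the realized coverage is
recorded in the manifest.

In default mode the templates use exactly the rule backend's cue phrases,
so extract → filter solves the corpus with precision = recall = 1 — a
closure property that validates the plumbing end to end. `hard_mode`
substitutes cue-evading paraphrases ("unremarkable for X",
"X was entertained") for half of the negated/hypothetical draws,
guaranteeing an imperfect run. Passing closure therefore demonstrates
compositional correctness, **not** clinical accuracy: real notes contain
paraphrase, misspelling and discourse structure the generator does not
model, and the rule backend's cue lists would not reach these numbers on
real text.

Everything the generator emits is a deterministic function of
(seed, parameters); 20% of documents are reserved as the few-shot bank
split so example selection can never overlap evaluation documents.

## Pipeline and reproducibility

The orchestrator executes vocabulary → extraction → filtering →
evaluation/cohort from a validated YAML config, writing each stage's
artifact plus a manifest of versions, parameters and SHA-256 digests of
inputs and outputs. The manifest records no wall-clock state, so two runs
under the same config produce byte-identical artifacts with any
deterministic backend. A stage failure halts the run, retains prior
artifacts and writes a FAILED marker naming the stage. Execution is
single-process and streaming per document; corpus-scale throughput
engineering is out of scope.

When the rule backend is selected, its ambiguous-abbreviation table
defaults to the built-in clinical set unioned with the loaded vocabulary's
acronym terms, so synthetic bundles filter correctly out of the box; an
explicit `ambiguous_abbrevs` list in the backend config overrides this.

## Problem sizes

The shipped tests and the acceptance script use 400-document synthetic
studies (~800 mentions), 200 random corpora for matcher/brute-force
equivalence, and cohort fixtures of up to 100 patients — sizes chosen so
the whole suite completes in well under a minute while keeping every
statistical check (exact binomial 99% bands on category rates) adequately
powered.

## Known limitations

* Normalized-exact matching misses misspellings and inflectional variants.
* The rule backend is a cue-list classifier; it does not handle scope
  ambiguity, coordination, or paraphrased negation (by design — that gap is
  what a language-model backend is for).
* Hierarchy-based concept refinement is reduced to the semantic-type
  whitelist; ORDO OWL parsing and expert-in-the-loop ICD mapping review are
  out of scope.
* Published full-corpus counts from credentialed clinical datasets are not
  reproducible here; the synthetic study stands in for them structurally,
  not numerically.
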