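# raretext

Hybrid rare-disease text phenotyping for clinical notes.

Rare diseases are chronically under-coded in structured EHR data: a patient's
discharge summary may describe a condition for which no ICD code was ever
entered. Dictionary-based clinical NLP finds those mentions with high recall,
but it also surfaces negated statements ("no evidence of Huntington's
disease"), hypothetical and family-history mentions, and ambiguous
abbreviations ("PID" — primary immunodeficiency or pelvic inflammatory
disease?). `raretext` implements the two-stage hybrid architecture that
addresses this:

1. **Vocabulary construction** — ontology disease concepts (ORPHA-style id,
   label, synonyms) are linked to UMLS-style CUIs by normalized exact string
   matching, refined with a semantic-type whitelist (T019, T047, T048, T049,
   T050, T190, T191 by default), expanded with every synonym the CUI carries,
   and joined to ICD-9/10 codes through a crosswalk table.
2. **Candidate extraction** — a token-sequence trie matcher scans notes for
   vocabulary terms with leftmost-longest overlap resolution; all-uppercase
   short forms ("HD") are verified case-sensitively against the raw text.
3. **Contextual filtering** — every candidate mention *m* with its context
   window *c* gets a binary assertion decision *y = f(m, c)*: 1 if the text
   asserts the patient has the condition, 0 otherwise. The classifier is a
   pluggable backend behind zero-shot / few-shot / knowledge-augmented prompt
   templates; shipped backends include a deterministic NegEx-style rule
   classifier, an oracle, a scripted responder, a keep-everything no-op, and a
   configuration-only HTTP adapter for remote language-model services
   (greedy, temperature-0 generation is part of the backend contract).
4. **Evaluation** — Cohen's kappa and third-annotator adjudication for gold
   standards, mention-level precision / recall / F1 (P = tp/(tp+fp),
   R = tp/(tp+fn), F1 = 2PR/(P+R), with dictionary misses counted in the
   recall denominator), and few-shot / context-length sweeps.
5. **Cohort comparison** — kept mentions aggregate to per-disease patient
   sets and are compared with ICD-coded cohorts per disease: how many
   patients only the free text finds.

A deterministic synthetic discharge-summary generator produces corpora with
planted mentions of known assertion status, so the entire pipeline is
testable offline with exact expected answers.

## Worked example

```python
import raretext as rt

bundle = rt.generate_bundle(rt.SynthParams(n_docs=100, seed=0))
mentions = rt.extract_corpus_mentions(
    bundle.documents, rt.build_matcher(bundle.vocabulary))
decisions = rt.run_filter(
    mentions, bundle.documents, bundle.vocabulary,
    rt.PromptStrategy(), rt.RuleBasedBackend(bundle.rule_config()))
counts = rt.match_and_count(rt.kept_mentions(decisions), bundle.gold_set())
row = rt.precision_recall_f1(counts)
print(f"P={row.precision:.4f} R={row.recall:.4f} F1={row.f1:.4f}")
```

prints

```
P=1.0000 R=1.0000 F1=1.0000
```

In the generator's default mode the mention templates use exactly the cue
phrases the rule classifier knows, so the pipeline solves the corpus
perfectly — a closed-system check that extraction, filtering and scoring
compose correctly. With `hard_mode=True` the generator mixes in paraphrases
that evade the cues ("unremarkable for X") and the same run prints
`P=0.8254 R=1.0000 F1=0.9043`: the false positives a contextual
language-model backend is meant to remove.

The `examples/` directory holds one short narrative script per capability
(vocabulary building, extraction + filtering, the synthetic study, prompt
strategies and sweeps, cohort comparison). A thin CLI mirrors the stages:

```bash
raretext synth --n-docs 100 --seed 0 --out bundle/
raretext extract --vocab bundle/vocabulary.json --corpus bundle/corpus.jsonl --out mentions.jsonl
raretext run --config pipeline.yaml
```

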