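"""Candidate extraction and contextual filtering on a small note.

Shows the division of labour: the dictionary matcher proposes every
surface occurrence (high recall, including negated and abbreviated
ones), then the rule-based assertion filter decides y = f(m, c) for
each candidate and discards the false positives.
"""

from raretext import (
    Document,
    PromptStrategy,
    RuleBasedBackend,
    RuleConfig,
    Vocabulary,
    VocabularyEntry,
    build_matcher,
    extract_mentions,
    kept_mentions,
    run_filter,
)

vocab = Vocabulary(
    entries=[
        VocabularyEntry(
            cui="C0020179", concept_id="ORPHA:399",
            preferred_label="Huntington disease",
            surface_terms={"huntington disease", "huntington s disease", "hd"},
            acronym_terms={"HD"},
        ),
        VocabularyEntry(
            cui="C0016167", concept_id="ORPHA:324",
            preferred_label="Fabry disease",
            surface_terms={"fabry disease"},
        ),
        VocabularyEntry(
            cui="C0021051", concept_id="ORPHA:101997",
            preferred_label="Primary immunodeficiency",
            surface_terms={"primary immunodeficiency", "pid"},
            acronym_terms={"PID"},
        ),
    ]
)

note = Document(
    "note-1",
    "Patient has a history of Fabry disease. "
    "No evidence of Huntington's disease on exam. "
    "Mother had HD. "
    "Continued PID prophylaxis per protocol.",
    patient_id="P1",
)

mentions = extract_mentions(note, build_matcher(vocab))
print(f"{len(mentions)} candidates proposed by the dictionary stage:")
for m in mentions:
    print(f"  [{m.start}:{m.end}] {m.surface!r} -> {m.cui} "
          f"(acronym={m.is_acronym_match})")

decisions = run_filter(
    mentions, [note], vocab, PromptStrategy(),
    RuleBasedBackend(RuleConfig()),
    context_unit="sentences", context_size=1,
)
print("\nfilter decisions (1 = patient has the condition):")
for d in decisions:
    print(f"  {d.mention.surface!r}: label={d.label} ({d.raw_response})")

kept = kept_mentions(decisions)
print(f"\nkept after filtering: {[m.surface for m in kept]}")
# Only the affirmative Fabry mention survives: the Huntington mention is
# negated, the HD acronym sits in a family-history sentence, and PID is in
# the ambiguous-abbreviation table with no expansion nearby.
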