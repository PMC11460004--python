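"""Prompt construction, response parsing, rule classifier, run_filter."""

import pytest

from raretext import (
    Document,
    FewShotExample,
    Mention,
    NoOpBackend,
    OracleBackend,
    PromptStrategy,
    RuleBasedBackend,
    RuleConfig,
    ScriptedBackend,
    build_matcher,
    build_prompt,
    classify_mention,
    extract_context,
    extract_corpus_mentions,
    extract_mentions,
    kept_mentions,
    lookup_definition,
    parse_response,
    rule_backend,
    run_filter,
    select_few_shot,
)
from raretext.filtering import FilteringError, make_backend
from .test_extraction import make_vocab


def mention_in(text, term="fabry disease", doc_id="d1"):
    vocab = make_vocab({"C0000001": [term]})
    doc = Document(doc_id, text)
    mentions = extract_mentions(doc, build_matcher(vocab))
    assert mentions, f"term {term!r} not found in {text!r}"
    return doc, mentions[0]


def context_for(text, term="fabry disease", unit="sentences", size=1):
    doc, m = mention_in(text, term)
    return m, extract_context(doc, m, unit, size)


class TestParseResponse:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Yes", "yes"),
            ("  YES.", "yes"),
            ("no, the mention is negated.", "no"),
            ("N", "no"),
            ("1", "yes"),
            ("false", "no"),
            ("The patient might have it", "unparseable"),
            ("", "unparseable"),
        ],
    )
    def test_first_token_rule(self, raw, expected):
        assert parse_response(raw) == expected


class TestBuildPrompt:
    def test_zero_shot_layout(self):
        m, ctx = context_for("He has Fabry disease today.")
        prompt = build_prompt(m, ctx, PromptStrategy())
        assert prompt.text.count("Condition:") == 1
        assert "Definition" not in prompt.text
        assert m.surface in prompt.text and ctx.text in prompt.text

    def test_few_shot_blocks_precede_query(self):
        m, ctx = context_for("He has Fabry disease today.")
        examples = [
            FewShotExample("X disease", "Has X disease.", 1, "b1"),
            FewShotExample("Y disease", "No Y disease.", 0, "b2"),
        ]
        prompt = build_prompt(
            m, ctx, PromptStrategy(mode="few_shot", k=2), examples
        )
        assert prompt.text.count("Condition:") == 3
        assert prompt.text.count("Answer: Yes") == 1
        assert prompt.text.count("Answer: No") == 1
        assert prompt.text.rstrip().endswith("Answer:")

    def test_few_shot_count_mismatch(self):
        m, ctx = context_for("He has Fabry disease today.")
        with pytest.raises(FilteringError):
            build_prompt(m, ctx, PromptStrategy(mode="few_shot", k=2), ())

    def test_kag_definition_block_and_fallback(self):
        m, ctx = context_for("He has Fabry disease today.")
        with_def = build_prompt(
            m, ctx, PromptStrategy(mode="kag"), definition="A lysosomal disorder."
        )
        assert with_def.definition_used
        assert "Definition of Fabry disease: A lysosomal disorder." in with_def.text
        without = build_prompt(m, ctx, PromptStrategy(mode="kag"), definition=None)
        assert not without.definition_used and "Definition" not in without.text

    def test_byte_identical_across_calls(self):
        m, ctx = context_for("He has Fabry disease today.")
        a = build_prompt(m, ctx, PromptStrategy())
        b = build_prompt(m, ctx, PromptStrategy())
        assert a.text == b.text

    def test_strategy_validation(self):
        with pytest.raises(FilteringError):
            PromptStrategy(mode="few_shot", k=0)
        with pytest.raises(FilteringError):
            PromptStrategy(mode="few_shot", k=11)
        with pytest.raises(FilteringError):
            PromptStrategy(mode="zero_shot", k=2)


class TestSelectFewShot:
    BANK = [FewShotExample(f"t{i}", f"ctx {i}", i % 2, f"doc{i}") for i in range(10)]

    def test_seeded_determinism(self):
        a = select_few_shot(self.BANK, 3, seed=42)
        b = select_few_shot(self.BANK, 3, seed=42)
        assert a == b and len(a) == 3 and len(set(id(x) for x in a)) == 3

    def test_insufficient_bank(self):
        with pytest.raises(FilteringError):
            select_few_shot(self.BANK, 11, seed=0)

    def test_test_set_exclusion(self):
        excluded = {"doc3"}
        for seed in range(30):
            sampled = select_few_shot(self.BANK, 5, seed, excluded_doc_ids=excluded)
            assert all(ex.source_doc_id != "doc3" for ex in sampled)


class TestRuleBackend:
    @pytest.mark.parametrize(
        "text,label",
        [
            ("No evidence of Fabry disease.", 0),
            ("Patient has a history of Fabry disease.", 1),
            ("Rule out Fabry disease.", 0),
            ("Mother had Fabry disease.", 0),
            ("Patient denies Fabry disease.", 0),
            ("Fabry disease was ruled out.", 0),
            ("Negative for Fabry disease.", 0),
            ("Possible Fabry disease.", 0),
            ("Family history of Fabry disease.", 0),
            ("Fabry disease was confirmed by enzyme assay.", 1),
            ("Not Fabry disease but something else.", 0),
        ],
    )
    def test_cue_examples(self, text, label):
        m, ctx = context_for(text)
        assert rule_backend(m, ctx) == label

    def test_negation_scope_breaker(self):
        # negation followed by "but" before the mention: out of scope
        m, ctx = context_for("No fever but Fabry disease was confirmed.")
        assert rule_backend(m, ctx) == 1

    def test_negation_window_limit(self):
        far = "No evidence of one two three four five six seven Fabry disease."
        m, ctx = context_for(far)
        assert rule_backend(m, ctx) == 1  # cue more than 6 tokens away

    def test_cue_in_other_sentence_ignored(self):
        m, ctx = context_for("No acute issues. Patient has Fabry disease.")
        assert rule_backend(m, ctx) == 1

    def test_ambiguous_acronym(self):
        vocab = make_vocab({"C0000001": []}, {"C0000001": ["PID"]})
        doc = Document("d1", "Continued PID for two days.")
        (m,) = extract_mentions(doc, build_matcher(vocab))
        ctx = extract_context(doc, m, "sentences", 1)
        assert rule_backend(m, ctx) == 0
        rescued = RuleConfig(
            expansions={"PID": ("primary immunodeficiency",)}
        )
        doc2 = Document(
            "d2", "Primary immunodeficiency (PID) was managed. Continued PID today."
        )
        mentions = extract_mentions(
            doc2, build_matcher(make_vocab({"C0000001": []}, {"C0000001": ["PID"]}))
        )
        ctx2 = extract_context(doc2, mentions[0], "document", 1)
        assert rule_backend(mentions[0], ctx2, rescued) == 1


class TestClassifyAndRun:
    def test_scripted_yes_and_gibberish_policy(self):
        m, ctx = context_for("He has Fabry disease today.")
        prompt = build_prompt(m, ctx, PromptStrategy())
        d = classify_mention(prompt, ScriptedBackend(["Yes"]), m, ctx)
        assert (d.label, d.parsed) == (1, "yes")
        d2 = classify_mention(prompt, ScriptedBackend(["zzz?"]), m, ctx)
        assert (d2.label, d2.parsed) == (1, "unparseable")
        discard = build_prompt(
            m, ctx, PromptStrategy(unparseable_policy="discard")
        )
        d3 = classify_mention(discard, ScriptedBackend(["zzz?"]), m, ctx)
        assert d3.label == 0

    def test_rule_backend_wrapped_ignores_prompt(self):
        m, ctx = context_for("No evidence of Fabry disease.")
        prompt = build_prompt(m, ctx, PromptStrategy())
        d = classify_mention(prompt, RuleBasedBackend(), m, ctx)
        assert d.label == 0 and d.backend_id == "rule"

    def test_run_filter_empty(self):
        assert run_filter([], [], None, PromptStrategy(), NoOpBackend()) == []

    def test_oracle_keeps_exactly_gold_positives(self, small_bundle):
        matcher = build_matcher(small_bundle.vocabulary)
        mentions = extract_corpus_mentions(small_bundle.documents, matcher)
        backend = OracleBackend(small_bundle.oracle_labels())
        decisions = run_filter(
            mentions, small_bundle.documents, small_bundle.vocabulary,
            PromptStrategy(), backend,
        )
        kept = {(m.doc_id, m.start, m.end) for m in kept_mentions(decisions)}
        gold_pos = {
            k for k, label in small_bundle.oracle_labels().items() if label == 1
        }
        cand = {(m.doc_id, m.start, m.end) for m in mentions}
        assert kept == gold_pos & cand

    def test_kept_is_subset_of_candidates(self, small_bundle):
        mentions = extract_corpus_mentions(
            small_bundle.documents, build_matcher(small_bundle.vocabulary)
        )
        for backend in (
            RuleBasedBackend(small_bundle.rule_config()),
            OracleBackend(small_bundle.oracle_labels()),
            NoOpBackend(),
            ScriptedBackend(["Yes", "No", "maybe"]),
        ):
            decisions = run_filter(
                mentions, small_bundle.documents, small_bundle.vocabulary,
                PromptStrategy(), backend,
            )
            assert len(decisions) == len(mentions)
            assert set(kept_mentions(decisions)) <= set(mentions)

    def test_unknown_document_rejected(self):
        m = Mention("ghost", 0, 3, "foo", "foo", "C0000001", "ORPHA:0", False)
        with pytest.raises(FilteringError, match="ghost"):
            run_filter([m], [], None, PromptStrategy(), NoOpBackend())

    def test_rule_filter_bitwise_reproducible(self, small_bundle):
        mentions = extract_corpus_mentions(
            small_bundle.documents, build_matcher(small_bundle.vocabulary)
        )
        runs = [
            run_filter(
                mentions, small_bundle.documents, small_bundle.vocabulary,
                PromptStrategy(), RuleBasedBackend(small_bundle.rule_config()),
            )
            for _ in range(2)
        ]
        assert [d.to_dict() for d in runs[0]] == [d.to_dict() for d in runs[1]]


class TestDefinitionsAndBackendFactory:
    def test_lookup_definition(self):
        defs = {"C0000001": "A disorder."}
        assert lookup_definition("C0000001", defs) == "A disorder."
        assert lookup_definition("C0000009", defs) is None

    def test_make_backend_validation(self):
        assert make_backend("noop").backend_id == "noop"
        with pytest.raises(FilteringError):
            make_backend("oracle")
        with pytest.raises(FilteringError):
            make_backend("http", http_options={"endpoint": "x"})
        with pytest.raises(FilteringError):
            make_backend("nonsense")
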