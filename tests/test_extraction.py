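"""Dictionary matching: tokenization, leftmost-longest extraction with a
brute-force oracle, acronym case rules, context windows."""

import random

import pytest

from raretext import (
    Document,
    Vocabulary,
    build_matcher,
    extract_context,
    extract_mentions,
    normalize_term,
    sentence_spans,
    tokenize,
)
from raretext.extraction import ExtractionError
from raretext.vocabulary import VocabularyEntry


def make_vocab(terms_by_cui, acronyms_by_cui=None):
    """Vocabulary from {cui: [original-case terms]}; acronyms are the
    all-uppercase short terms, flagged for case verification."""
    acronyms_by_cui = acronyms_by_cui or {}
    entries = []
    for i, (cui, terms) in enumerate(sorted(terms_by_cui.items())):
        surface = {normalize_term(t) for t in terms}
        acros = set(acronyms_by_cui.get(cui, ()))
        surface |= {normalize_term(a) for a in acros}
        entries.append(
            VocabularyEntry(
                cui=cui,
                concept_id=f"ORPHA:{i}",
                preferred_label=terms[0] if terms else sorted(acros)[0],
                surface_terms={s for s in surface if s},
                acronym_terms=acros,
            )
        )
    return Vocabulary(entries=entries)


# ---------------------------------------------------------------------------
# Brute-force oracle: try every term at every token position
# ---------------------------------------------------------------------------

def brute_force_extract(doc, vocab):
    tokens = tokenize(doc.text)
    patterns = []
    for entry in vocab.entries:
        acro_norms = {normalize_term(a): a for a in entry.acronym_terms}
        for term in entry.surface_terms:
            patterns.append(
                (
                    tuple(term.split()),
                    term,
                    entry.cui,
                    entry.concept_id,
                    frozenset(
                        a for a in entry.acronym_terms if normalize_term(a) == term
                    ),
                )
            )

    def valid_matches_at(i):
        out = []
        for toks, term, cui, concept_id, acro_forms in patterns:
            j = i + len(toks)
            if j > len(tokens):
                continue
            if tuple(t.normalized for t in tokens[i:j]) != toks:
                continue
            if acro_forms:
                raw = doc.text[tokens[i].start:tokens[j - 1].end]
                if raw not in acro_forms:
                    continue
            out.append((len(toks), term, cui, concept_id, bool(acro_forms)))
        return out

    result = []
    i = 0
    while i < len(tokens):
        cands = valid_matches_at(i)
        if not cands:
            i += 1
            continue
        best = min(cands, key=lambda c: (-c[0], c[2], c[3]))
        length, term, cui, concept_id, is_acro = best
        start, end = tokens[i].start, tokens[i + length - 1].end
        result.append((doc.doc_id, start, end, term, cui, concept_id, is_acro))
        i += length
    return result


def as_tuples(mentions):
    return [
        (m.doc_id, m.start, m.end, m.matched_term, m.cui, m.concept_id,
         m.is_acronym_match)
        for m in mentions
    ]


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

class TestTokenize:
    def test_offsets_and_surfaces(self):
        tokens = tokenize("No evidence of HD.")
        assert [t.surface for t in tokens] == ["No", "evidence", "of", "HD"]
        assert (tokens[3].start, tokens[3].end) == (15, 17)

    def test_empty(self):
        assert tokenize("") == []

    def test_hyphen_splits(self):
        assert [t.surface for t in tokenize("x-linked")] == ["x", "linked"]

    def test_span_fidelity(self):
        text = "A b3.c, d-e!\nf"
        for t in tokenize(text):
            assert text[t.start:t.end] == t.surface

    def test_sentence_spans_cover_punctuation_and_newlines(self):
        text = "First sentence. Second one!\n\nThird line"
        spans = sentence_spans(text)
        assert [text[s:e] for s, e in spans] == [
            "First sentence.", "Second one!", "Third line"
        ]


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

class TestExtractMentions:
    def test_single_match_offsets(self):
        vocab = make_vocab({"C0000001": ["fabry disease"]})
        doc = Document("d1", "He has Fabry disease.")
        (m,) = extract_mentions(doc, build_matcher(vocab))
        assert (m.start, m.end, m.surface) == (7, 20, "Fabry disease")
        assert m.cui == "C0000001" and not m.is_acronym_match

    def test_leftmost_longest(self):
        vocab = make_vocab(
            {"C0000001": ["marfan syndrome"], "C0000002": ["syndrome"]}
        )
        doc = Document("d1", "classic Marfan syndrome features")
        mentions = extract_mentions(doc, build_matcher(vocab))
        assert [m.surface for m in mentions] == ["Marfan syndrome"]

    def test_acronym_case_rule(self):
        vocab = make_vocab({"C0000001": []}, {"C0000001": ["PID"]})
        matcher = build_matcher(vocab)
        assert extract_mentions(Document("d1", "treated for pid today"), matcher) == []
        (m,) = extract_mentions(Document("d2", "treated for PID today"), matcher)
        assert m.is_acronym_match and m.surface == "PID"

    def test_no_substring_match_inside_words(self):
        vocab = make_vocab({"C0000001": []}, {"C0000001": ["HD"]})
        assert extract_mentions(
            Document("d1", "CHD was noted"), build_matcher(vocab)
        ) == []

    def test_empty_vocabulary_rejected(self):
        with pytest.raises(ExtractionError):
            build_matcher(Vocabulary(entries=[]))

    def test_rebuild_determinism(self):
        vocab = make_vocab(
            {"C0000001": ["fabry disease"], "C0000002": ["gaucher disease"]}
        )
        doc = Document("d1", "fabry disease and Gaucher Disease")
        m1 = extract_mentions(doc, build_matcher(vocab))
        m2 = extract_mentions(doc, build_matcher(vocab))
        assert as_tuples(m1) == as_tuples(m2)

    def test_span_fidelity_property(self, small_bundle):
        matcher = build_matcher(small_bundle.vocabulary)
        for doc in small_bundle.documents:
            for m in extract_mentions(doc, matcher):
                assert doc.text[m.start:m.end] == m.surface


class TestOracleEquivalence:
    """The trie matcher must agree exactly with the brute-force scanner."""

    WORDS = ["alpha", "beta", "gamma", "delta", "kappa", "zeta", "omega",
             "pax", "rex", "tor", "vel", "zed"]

    def random_case(self, rng, word):
        return word.upper() if rng.random() < 0.2 else (
            word.capitalize() if rng.random() < 0.3 else word
        )

    def random_vocab(self, rng):
        n_terms = rng.randint(3, 12)
        terms_by_cui, acronyms_by_cui = {}, {}
        used = set()
        for i in range(n_terms):
            cui = f"C{i:07d}"
            if rng.random() < 0.25:
                acro = rng.choice(["HD", "PID", "PNA", "SAR", "REX"])
                key = normalize_term(acro)
                if key in used:
                    continue
                used.add(key)
                terms_by_cui[cui] = []
                acronyms_by_cui[cui] = [acro]
            else:
                term = " ".join(
                    rng.choice(self.WORDS)
                    for _ in range(rng.randint(1, 3))
                )
                if normalize_term(term) in used:
                    continue
                used.add(normalize_term(term))
                terms_by_cui[cui] = [term]
        return make_vocab(terms_by_cui, acronyms_by_cui)

    def random_doc(self, rng, doc_id):
        pieces = []
        for _ in range(rng.randint(5, 60)):
            w = self.random_case(rng, rng.choice(self.WORDS + ["hd", "pid", "the"]))
            pieces.append(w)
            pieces.append(rng.choice([" ", " ", " ", ". ", ", ", "\n", "-"]))
        return Document(doc_id, "".join(pieces))

    @pytest.mark.parametrize("seed", range(25))
    def test_matcher_equals_bruteforce(self, seed):
        rng = random.Random(seed)
        vocab = self.random_vocab(rng)
        if len(vocab) == 0:
            return
        matcher = build_matcher(vocab)
        for d in range(rng.randint(1, 6)):
            doc = self.random_doc(rng, f"doc{d}")
            assert as_tuples(extract_mentions(doc, matcher)) == brute_force_extract(
                doc, vocab
            )


# ---------------------------------------------------------------------------
# Context windows
# ---------------------------------------------------------------------------

class TestExtractContext:
    @pytest.fixture
    def doc_and_mention(self):
        vocab = make_vocab({"C0000001": ["mentionterm"]})
        doc = Document("d1", "a b c mentionterm d e f")
        (m,) = extract_mentions(doc, build_matcher(vocab))
        return doc, m

    def test_word_window(self, doc_and_mention):
        doc, m = doc_and_mention
        win = extract_context(doc, m, "words", 2)
        assert win.text == "b c mentionterm d e"
        assert win.mention_surface == "mentionterm"

    def test_word_window_at_document_start(self):
        vocab = make_vocab({"C0000001": ["mentionterm"]})
        doc = Document("d1", "mentionterm d e f")
        (m,) = extract_mentions(doc, build_matcher(vocab))
        win = extract_context(doc, m, "words", 2)
        assert win.text == "mentionterm d e"
        assert win.mention_relative_start == 0

    def test_document_unit(self, doc_and_mention):
        doc, m = doc_and_mention
        win = extract_context(doc, m, "document", 1)
        assert win.text == doc.text

    def test_sentence_unit(self):
        vocab = make_vocab({"C0000001": ["mentionterm"]})
        doc = Document("d1", "One before. Has mentionterm here. One after. Two after.")
        (m,) = extract_mentions(doc, build_matcher(vocab))
        win = extract_context(doc, m, "sentences", 1)
        assert win.text == "One before. Has mentionterm here. One after."
        assert win.mention_surface == "mentionterm"

    def test_oversized_windows_saturate(self, doc_and_mention):
        doc, m = doc_and_mention
        a = extract_context(doc, m, "words", 100)
        b = extract_context(doc, m, "words", 5000)
        assert a.text == b.text == doc.text

    def test_foreign_mention_rejected(self, doc_and_mention):
        doc, m = doc_and_mention
        other = Document("d2", "something else entirely")
        with pytest.raises(ExtractionError):
            extract_context(other, m, "words", 2)
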