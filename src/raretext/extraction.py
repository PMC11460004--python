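"""Dictionary-based candidate mention extraction.

The matcher indexes every vocabulary surface term as a sequence of
normalized tokens in a trie and scans documents left to right, keeping
the leftmost-longest match at each position (ties broken by lower CUI,
then concept id).  Matching is token-sequence based, so an abbreviation
like "HD" can never fire inside "CHD"; acronym-flagged patterns are
additionally verified case-sensitively against the raw text, which is
what lets "PID" match while "pid" does not.

No assertion-status reasoning happens here: negated, hypothetical and
family-history mentions are deliberately extracted as candidates and left
to the contextual filter, mirroring the division of labour between a
dictionary NER stage and a downstream classifier.

Offsets are 0-based, half-open, in characters on the raw document text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .vocabulary import Vocabulary, normalize_term


class ExtractionError(ValueError):
    pass


@dataclass(frozen=True)
class Document:
    """One clinical note; ``patient_id`` links notes to a patient."""

    doc_id: str
    text: str
    patient_id: str | None = None


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int
    normalized: str


@dataclass(frozen=True)
class Mention:
    """A candidate rare-disease mention normalized to a vocabulary concept."""

    doc_id: str
    start: int
    end: int
    surface: str
    matched_term: str
    cui: str
    concept_id: str
    is_acronym_match: bool = False

    def to_dict(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "start": self.start,
            "end": self.end,
            "surface": self.surface,
            "matched_term": self.matched_term,
            "cui": self.cui,
            "concept_id": self.concept_id,
            "is_acronym_match": self.is_acronym_match,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Mention":
        return cls(**{k: d[k] for k in (
            "doc_id", "start", "end", "surface", "matched_term",
            "cui", "concept_id", "is_acronym_match",
        )})


@dataclass(frozen=True)
class ContextWindow:
    """Text surrounding a mention at word/sentence/document granularity."""

    doc_id: str
    mention_start: int
    mention_end: int
    text: str
    unit: str  # "words" | "sentences" | "document"
    size: int
    mention_relative_start: int

    @property
    def mention_surface(self) -> str:
        length = self.mention_end - self.mention_start
        return self.text[self.mention_relative_start:self.mention_relative_start + length]


# ---------------------------------------------------------------------------
# Tokenization and sentence segmentation
# ---------------------------------------------------------------------------

def tokenize(text: str) -> list[Token]:
    """Split text into maximal alphanumeric runs with offsets."""
    tokens: list[Token] = []
    i, n = 0, len(text)
    while i < n:
        if text[i].isalnum():
            j = i + 1
            while j < n and text[j].isalnum():
                j += 1
            surface = text[i:j]
            tokens.append(Token(surface, i, j, normalize_term(surface)))
            i = j
        else:
            i += 1
    return tokens


def sentence_spans(text: str) -> list[tuple[int, int]]:
    """Character spans of sentences.

    Boundaries fall after terminal punctuation ('.', '!', '?') and at
    newline runs; spans are trimmed of surrounding whitespace and jointly
    cover every non-whitespace character.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch in ".!?":
            spans.append((start, i + 1))
            start = i + 1
            i += 1
        elif ch == "\n":
            if i > start:
                spans.append((start, i))
            while i < n and text[i] == "\n":
                i += 1
            start = i
        else:
            i += 1
    if start < n:
        spans.append((start, n))
    trimmed = []
    for s, e in spans:
        while s < e and text[s].isspace():
            s += 1
        while e > s and text[e - 1].isspace():
            e -= 1
        if s < e:
            trimmed.append((s, e))
    return trimmed


# ---------------------------------------------------------------------------
# Matcher
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Pattern:
    term: str                     # normalized surface term
    cui: str
    concept_id: str
    acronym_forms: frozenset[str]  # non-empty => case-sensitive verification

    @property
    def is_acronym(self) -> bool:
        return bool(self.acronym_forms)


class Matcher:
    """Multi-pattern token-sequence index over a vocabulary.

    Patterns live in a trie keyed by normalized tokens; a scan touches
    each token position once and walks at most the depth of the longest
    pattern, giving linear-time behaviour in practice.
    """

    def __init__(self, vocab: Vocabulary):
        if len(vocab) == 0:
            raise ExtractionError("cannot build a matcher from an empty vocabulary")
        self._root: dict = {}
        self._n_patterns = 0
        acronym_norms: dict[tuple[str, str, str], set[str]] = {}
        for entry in vocab.entries:
            for acro in entry.acronym_terms:
                key = (normalize_term(acro), entry.cui, entry.concept_id)
                acronym_norms.setdefault(key, set()).add(acro)
        for entry in vocab.entries:
            for term in entry.surface_terms:
                toks = tuple(term.split())
                if not toks:
                    continue
                forms = acronym_norms.get((term, entry.cui, entry.concept_id), set())
                self._insert(
                    toks,
                    _Pattern(term, entry.cui, entry.concept_id, frozenset(forms)),
                )

    def _insert(self, toks: tuple[str, ...], pattern: _Pattern) -> None:
        node = self._root
        for tok in toks:
            node = node.setdefault(tok, {})
        node.setdefault(None, []).append(pattern)
        self._n_patterns += 1

    @property
    def n_patterns(self) -> int:
        return self._n_patterns

    def matches_at(self, tokens: Sequence[Token], i: int) -> Iterator[tuple[int, _Pattern]]:
        """Yield (n_tokens, pattern) for every pattern starting at token i."""
        node = self._root
        j = i
        while j < len(tokens):
            node = node.get(tokens[j].normalized)
            if node is None:
                return
            j += 1
            for pattern in node.get(None, ()):
                yield j - i, pattern


def build_matcher(vocab: Vocabulary) -> Matcher:
    return Matcher(vocab)


def extract_mentions(doc: Document, matcher: Matcher) -> list[Mention]:
    """All leftmost-longest vocabulary matches in one document."""
    tokens = tokenize(doc.text)
    mentions: list[Mention] = []
    i = 0
    while i < len(tokens):
        best: tuple[int, _Pattern] | None = None
        for length, pattern in matcher.matches_at(tokens, i):
            if pattern.is_acronym:
                raw = doc.text[tokens[i].start:tokens[i + length - 1].end]
                if raw not in pattern.acronym_forms:
                    continue
            if best is None or (length, ) > (best[0], ) or (
                length == best[0]
                and (pattern.cui, pattern.concept_id)
                < (best[1].cui, best[1].concept_id)
            ):
                best = (length, pattern)
        if best is None:
            i += 1
            continue
        length, pattern = best
        start, end = tokens[i].start, tokens[i + length - 1].end
        mentions.append(
            Mention(
                doc_id=doc.doc_id,
                start=start,
                end=end,
                surface=doc.text[start:end],
                matched_term=pattern.term,
                cui=pattern.cui,
                concept_id=pattern.concept_id,
                is_acronym_match=pattern.is_acronym,
            )
        )
        i += length
    return mentions


def extract_corpus_mentions(
    docs: Iterable[Document], matcher: Matcher
) -> list[Mention]:
    out: list[Mention] = []
    for doc in sorted(docs, key=lambda d: d.doc_id):
        out.extend(extract_mentions(doc, matcher))
    return out


# ---------------------------------------------------------------------------
# Context windows
# ---------------------------------------------------------------------------

def extract_context(
    doc: Document, mention: Mention, unit: str = "words", size: int = 100
) -> ContextWindow:
    """Context around a mention: ±size tokens, ±size sentences, or the
    whole document.  Truncation at document edges is silent."""
    if mention.doc_id != doc.doc_id or doc.text[mention.start:mention.end] != mention.surface:
        raise ExtractionError(
            f"mention {mention.doc_id}[{mention.start}:{mention.end}] "
            f"does not belong to document {doc.doc_id}"
        )
    if unit == "document":
        window_start, window_end = 0, len(doc.text)
    elif unit == "words":
        if size < 1:
            raise ExtractionError("size must be >= 1 for unit='words'")
        tokens = tokenize(doc.text)
        first = next(
            (k for k, t in enumerate(tokens) if t.end > mention.start), 0
        )
        last = max(
            (k for k, t in enumerate(tokens) if t.start < mention.end),
            default=first,
        )
        lo = max(0, first - size)
        hi = min(len(tokens) - 1, last + size)
        window_start = min(tokens[lo].start, mention.start)
        window_end = max(tokens[hi].end, mention.end)
    elif unit == "sentences":
        if size < 0:
            raise ExtractionError("size must be >= 0 for unit='sentences'")
        spans = sentence_spans(doc.text)
        idx = next(
            (k for k, (s, e) in enumerate(spans) if s <= mention.start < e),
            None,
        )
        if idx is None:
            window_start, window_end = mention.start, mention.end
        else:
            lo = max(0, idx - size)
            hi = min(len(spans) - 1, idx + size)
            window_start = min(spans[lo][0], mention.start)
            window_end = max(spans[hi][1], mention.end)
    else:
        raise ExtractionError(f"unknown context unit {unit!r}")
    return ContextWindow(
        doc_id=doc.doc_id,
        mention_start=mention.start,
        mention_end=mention.end,
        text=doc.text[window_start:window_end],
        unit=unit,
        size=0 if unit == "document" else size,
        mention_relative_start=mention.start - window_start,
    )


# ---------------------------------------------------------------------------
# Corpus and mention I/O
# ---------------------------------------------------------------------------

def load_corpus(path: str | Path) -> list[Document]:
    """Load a corpus from a JSONL file (doc_id, patient_id, text) or a
    directory of plain-text files (filename stem = doc_id)."""
    path = Path(path)
    docs: list[Document] = []
    if path.is_dir():
        for f in sorted(path.glob("*.txt")):
            docs.append(Document(doc_id=f.stem, text=f.read_text(encoding="utf-8")))
    else:
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                rec = json.loads(line)
                if "doc_id" not in rec or "text" not in rec:
                    raise ExtractionError(
                        f"{path}:{lineno}: corpus record needs doc_id and text"
                    )
                docs.append(
                    Document(
                        doc_id=rec["doc_id"],
                        text=rec["text"],
                        patient_id=rec.get("patient_id"),
                    )
                )
    seen: set[str] = set()
    for d in docs:
        if d.doc_id in seen:
            raise ExtractionError(f"duplicate doc_id {d.doc_id!r} in corpus")
        seen.add(d.doc_id)
    return docs


def write_corpus(docs: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(
                json.dumps(
                    {"doc_id": d.doc_id, "patient_id": d.patient_id, "text": d.text},
                    sort_keys=True,
                )
                + "\n"
            )


def write_mentions(mentions: Iterable[Mention], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in mentions:
            fh.write(json.dumps(m.to_dict(), sort_keys=True) + "\n")


def read_mentions(path: str | Path) -> list[Mention]:
    out: list[Mention] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(Mention.from_dict(json.loads(line)))
    return out
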