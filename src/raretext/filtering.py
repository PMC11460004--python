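"""Contextual assertion filtering of candidate mentions.

Each candidate mention m with its context window c is classified with a
binary decision y = f(m, c): 1 keeps the mention as a true assertion
that the patient has the condition, 0 discards it as negated,
hypothetical, family-history or an ambiguous abbreviation.  The
classifier is a pluggable backend behind a prompt: remote
language-model services can be plugged in by configuration (greedy,
temperature-0 generation is part of the contract), while the shipped
deterministic backends — a NegEx-style rule classifier, an oracle, a
scripted responder and a keep-everything no-op — make the whole
pipeline testable offline.

Prompt construction supports zero-shot, few-shot (k examples sampled
without replacement from an annotated bank, never from evaluation
documents) and knowledge-augmented prompts that inject the concept's
terminology definition.  Templates are plain-text data files with named
placeholders so alternates can be swapped without code changes.
"""

from __future__ import annotations

import json
import logging
import random
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Protocol, Sequence

from .extraction import ContextWindow, Document, Mention, extract_context, tokenize
from .vocabulary import Vocabulary, normalize_term

logger = logging.getLogger(__name__)


class FilteringError(ValueError):
    pass


class BackendError(RuntimeError):
    """Transport-level backend failure (retried, then fatal)."""


# ---------------------------------------------------------------------------
# Strategies, prompts, decisions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PromptStrategy:
    mode: str = "zero_shot"  # "zero_shot" | "few_shot" | "kag"
    k: int = 0
    seed: int = 0
    unparseable_policy: str = "keep"  # "keep" | "discard"

    def __post_init__(self) -> None:
        if self.mode not in ("zero_shot", "few_shot", "kag"):
            raise FilteringError(f"unknown prompt mode {self.mode!r}")
        if self.mode == "few_shot":
            if not 1 <= self.k <= 10:
                raise FilteringError("few_shot requires 1 <= k <= 10")
        elif self.k != 0:
            raise FilteringError(f"mode {self.mode} requires k = 0")
        if self.unparseable_policy not in ("keep", "discard"):
            raise FilteringError(
                f"unknown unparseable policy {self.unparseable_policy!r}"
            )

    def descriptor(self) -> dict:
        return {
            "mode": self.mode,
            "k": self.k,
            "seed": self.seed,
            "unparseable_policy": self.unparseable_policy,
        }


@dataclass(frozen=True)
class FewShotExample:
    term: str
    context: str
    gold_label: int
    source_doc_id: str

    def __post_init__(self) -> None:
        if self.gold_label not in (0, 1):
            raise FilteringError("gold_label must be 0 or 1")


@dataclass(frozen=True)
class Prompt:
    text: str
    strategy: PromptStrategy
    mention: Mention
    definition_used: bool = False


@dataclass(frozen=True)
class FilterDecision:
    mention: Mention
    label: int
    backend_id: str
    raw_response: str
    parsed: str  # "yes" | "no" | "unparseable"

    def to_dict(self) -> dict:
        d = self.mention.to_dict()
        d.update(
            label=self.label,
            backend_id=self.backend_id,
            raw_response=self.raw_response,
            parsed=self.parsed,
        )
        return d


def _load_template(name: str) -> str:
    return (
        resources.files("raretext")
        .joinpath("data", "templates", f"{name}.txt")
        .read_text(encoding="utf-8")
    )


def build_prompt(
    mention: Mention,
    context: ContextWindow,
    strategy: PromptStrategy,
    examples: Sequence[FewShotExample] = (),
    definition: str | None = None,
) -> Prompt:
    """Instantiate the canonical prompt for one mention.

    Layout: instruction block, optional definition block (kag), k example
    blocks (few_shot), then the query block holding the mention term and
    its context verbatim.  Byte-identical for identical inputs.
    """
    if strategy.mode == "few_shot" and len(examples) != strategy.k:
        raise FilteringError(
            f"few_shot k={strategy.k} but {len(examples)} examples supplied"
        )
    if strategy.mode != "few_shot" and examples:
        raise FilteringError(f"examples supplied for mode {strategy.mode}")

    blocks = [_load_template("instruction")]
    definition_used = False
    if strategy.mode == "kag":
        if definition:
            blocks.append(
                _load_template("definition").format(
                    term=mention.surface, definition=definition
                )
            )
            definition_used = True
        else:
            logger.warning(
                "kag prompt for %s (%s): no definition available, block omitted",
                mention.surface, mention.cui,
            )
    example_tpl = _load_template("example")
    for ex in examples:
        blocks.append(
            example_tpl.format(
                term=ex.term,
                context=ex.context,
                answer="Yes" if ex.gold_label == 1 else "No",
            )
        )
    blocks.append(
        _load_template("query").format(term=mention.surface, context=context.text)
    )
    return Prompt(
        text="\n\n".join(blocks),
        strategy=strategy,
        mention=mention,
        definition_used=definition_used,
    )


def select_few_shot(
    bank: Sequence[FewShotExample],
    k: int,
    seed: int,
    excluded_doc_ids: Iterable[str] = (),
) -> list[FewShotExample]:
    """Sample k distinct examples, never from excluded (test) documents."""
    excluded = set(excluded_doc_ids)
    eligible = [ex for ex in bank if ex.source_doc_id not in excluded]
    if len(eligible) < k:
        raise FilteringError(
            f"few-shot bank has only {len(eligible)} eligible examples, need {k}"
        )
    return random.Random(seed).sample(eligible, k)


_YES_TOKENS = {"yes", "y", "true", "1"}
_NO_TOKENS = {"no", "n", "false", "0"}


def parse_response(raw: str) -> str:
    """Map a free-text response to yes/no/unparseable by its first token."""
    stripped = re.sub(r"^[\s\W_]+", "", raw)
    first = re.split(r"[\s\W_]+", stripped, maxsplit=1)[0].lower() if stripped else ""
    if first in _YES_TOKENS:
        return "yes"
    if first in _NO_TOKENS:
        return "no"
    return "unparseable"


def lookup_definition(cui: str, definitions: Mapping[str, str]) -> str | None:
    return definitions.get(cui)


# ---------------------------------------------------------------------------
# Rule backend: NegEx-style cue matching
# ---------------------------------------------------------------------------

def _cue_tokens(phrases: Iterable[str]) -> tuple[tuple[str, ...], ...]:
    return tuple(tuple(normalize_term(p).split()) for p in phrases)


DEFAULT_PRE_NEGATION = (
    "no", "not", "without", "denies", "denied", "negative for",
    "no evidence of", "no signs of", "free of", "ruled out", "rules out",
)
DEFAULT_POST_NEGATION = ("was ruled out", "is ruled out", "ruled out", "unlikely")
DEFAULT_HYPOTHETICAL = (
    "if", "consider", "possible", "suspected", "concern for", "rule out",
)
DEFAULT_FAMILY = ("mother", "father", "brother", "sister", "family history")
DEFAULT_AMBIGUOUS_ABBREVS = frozenset({"PID", "PNA", "SAR", "HD", "ALS"})


@dataclass(frozen=True)
class RuleConfig:
    """Cue lists and scope windows for the deterministic rule classifier."""

    pre_negation: tuple[str, ...] = DEFAULT_PRE_NEGATION
    post_negation: tuple[str, ...] = DEFAULT_POST_NEGATION
    hypothetical: tuple[str, ...] = DEFAULT_HYPOTHETICAL
    family: tuple[str, ...] = DEFAULT_FAMILY
    pre_window: int = 6
    post_window: int = 4
    scope_breakers: tuple[str, ...] = ("but",)
    ambiguous_abbrevs: frozenset[str] = DEFAULT_AMBIGUOUS_ABBREVS
    #: abbrev -> normalized expansion phrases whose presence in the window
    #: rescues the acronym as a genuine disease mention
    expansions: Mapping[str, tuple[str, ...]] = field(default_factory=dict)


def _find_cue_ends(
    norm_tokens: Sequence[str], cues: Sequence[tuple[str, ...]]
) -> list[tuple[int, int]]:
    """(start, end) token index pairs (half-open) of every cue occurrence."""
    hits = []
    for cue in cues:
        L = len(cue)
        if L == 0:
            continue
        for i in range(len(norm_tokens) - L + 1):
            if tuple(norm_tokens[i:i + L]) == cue:
                hits.append((i, i + L))
    return hits


def rule_backend(
    mention: Mention, context: ContextWindow, config: RuleConfig = RuleConfig()
) -> int:
    """Deterministic assertion classifier over the mention's sentence.

    Label 0 when, inside the sentence containing the mention, a
    pre-negation cue ends within ``pre_window`` tokens before the mention
    with no scope breaker between, a post-negation cue starts within
    ``post_window`` tokens after it, a hypothetical cue precedes it, or a
    family-history cue occurs anywhere; acronym matches listed in the
    ambiguous-abbreviation table are dropped unless an expansion phrase
    appears in the window.  Otherwise label 1.
    """
    from .extraction import sentence_spans  # local: avoids cycle at import time

    text = context.text
    m_start = context.mention_relative_start
    m_end = m_start + (context.mention_end - context.mention_start)

    sent = next(
        ((s, e) for s, e in sentence_spans(text) if s <= m_start < e),
        (0, len(text)),
    )
    tokens = [t for t in tokenize(text[sent[0]:sent[1]])]
    offset = sent[0]
    norm = [t.normalized for t in tokens]
    mention_tok = [
        i for i, t in enumerate(tokens)
        if t.start + offset < m_end and t.end + offset > m_start
    ]
    if not mention_tok:
        return 1
    first, last = mention_tok[0], mention_tok[-1]

    breakers = {normalize_term(b) for b in config.scope_breakers}

    # (a) pre-negation within pre_window tokens, no scope breaker between
    for _, cue_end in _find_cue_ends(norm, _cue_tokens(config.pre_negation)):
        if cue_end <= first and first - cue_end <= config.pre_window:
            if not any(norm[j] in breakers for j in range(cue_end, first)):
                return 0
    # (b) post-negation within post_window tokens after the mention
    for cue_start, _ in _find_cue_ends(norm, _cue_tokens(config.post_negation)):
        if cue_start > last and cue_start - last <= config.post_window:
            return 0
    # (c) hypothetical cue anywhere before the mention in-sentence
    for _, cue_end in _find_cue_ends(norm, _cue_tokens(config.hypothetical)):
        if cue_end <= first:
            return 0
    # (d) family-history cue anywhere in-sentence
    hits = _find_cue_ends(norm, _cue_tokens(config.family))
    if any(s > last or e <= first for s, e in hits):
        return 0
    # (e) ambiguous abbreviation with no expansion phrase in the window
    if mention.is_acronym_match and mention.surface in config.ambiguous_abbrevs:
        window_norm = normalize_term(text)
        expansions = config.expansions.get(mention.surface, ())
        if not any(normalize_term(x) in window_norm for x in expansions):
            return 0
    return 1


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------

class Backend(Protocol):
    """Contract: one call taking the prompt (plus the mention/context it
    was built from) and returning raw response text; deterministic, greedy
    generation — the temperature-0 analogue."""

    backend_id: str
    deterministic: bool

    def respond(
        self, prompt: Prompt, mention: Mention, context: ContextWindow
    ) -> str: ...


class RuleBasedBackend:
    """Prompt-ignoring wrapper around :func:`rule_backend`."""

    backend_id = "rule"
    deterministic = True

    def __init__(self, config: RuleConfig = RuleConfig()):
        self.config = config

    def respond(self, prompt: Prompt, mention: Mention, context: ContextWindow) -> str:
        return "Yes" if rule_backend(mention, context, self.config) == 1 else "No"


class OracleBackend:
    """Answers from gold labels keyed by (doc_id, start, end); mentions
    absent from the gold table are answered "No"."""

    backend_id = "oracle"
    deterministic = True

    def __init__(self, labels: Mapping[tuple[str, int, int], int]):
        self._labels = dict(labels)

    def respond(self, prompt: Prompt, mention: Mention, context: ContextWindow) -> str:
        label = self._labels.get((mention.doc_id, mention.start, mention.end), 0)
        return "Yes" if label == 1 else "No"


class ScriptedBackend:
    """Replays a fixed response sequence (cycled); for tests and replay."""

    deterministic = True

    def __init__(self, responses: Sequence[str], backend_id: str = "scripted"):
        if not responses:
            raise FilteringError("scripted backend needs at least one response")
        self._responses = list(responses)
        self._i = 0
        self.backend_id = backend_id

    def respond(self, prompt: Prompt, mention: Mention, context: ContextWindow) -> str:
        r = self._responses[self._i % len(self._responses)]
        self._i += 1
        return r


class NoOpBackend:
    """Keeps every candidate — reproduces the unfiltered baseline."""

    backend_id = "noop"
    deterministic = True

    def respond(self, prompt: Prompt, mention: Mention, context: ContextWindow) -> str:
        return "Yes"


class HttpBackend:
    """Adapter for a remote chat/completions service (configuration only).

    Generation settings are pinned to greedy decoding (temperature 0).
    Network access is intentionally exercised nowhere in the test suite.
    """

    deterministic = True

    def __init__(
        self,
        endpoint: str,
        model: str,
        backend_id: str | None = None,
        timeout: float = 60.0,
        extra: Mapping | None = None,
    ):
        self.endpoint = endpoint
        self.model = model
        self.timeout = timeout
        self.extra = dict(extra or {})
        self.backend_id = backend_id or f"http:{model}"

    def respond(self, prompt: Prompt, mention: Mention, context: ContextWindow) -> str:
        import urllib.request

        payload = json.dumps(
            {"model": self.model, "prompt": prompt.text, "temperature": 0, **self.extra}
        ).encode()
        req = urllib.request.Request(
            self.endpoint, data=payload, headers={"Content-Type": "application/json"}
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                body = json.loads(resp.read().decode())
        except Exception as exc:  # transport failure -> retryable
            raise BackendError(str(exc)) from exc
        try:
            return body["choices"][0]["text"]
        except (KeyError, IndexError, TypeError) as exc:
            raise BackendError(f"malformed response body: {body!r}") from exc


def make_backend(
    name: str,
    *,
    rule_config: RuleConfig | None = None,
    oracle_labels: Mapping[tuple[str, int, int], int] | None = None,
    responses: Sequence[str] | None = None,
    http_options: Mapping | None = None,
) -> Backend:
    """Construct a backend by short name ("rule", "oracle", "scripted",
    "noop", "http")."""
    if name == "rule":
        return RuleBasedBackend(rule_config or RuleConfig())
    if name == "oracle":
        if oracle_labels is None:
            raise FilteringError("oracle backend needs gold labels")
        return OracleBackend(oracle_labels)
    if name == "scripted":
        return ScriptedBackend(responses or ())
    if name == "noop":
        return NoOpBackend()
    if name == "http":
        if not http_options or "endpoint" not in http_options or "model" not in http_options:
            raise FilteringError("http backend needs endpoint and model")
        return HttpBackend(**dict(http_options))
    raise FilteringError(f"unknown backend {name!r}")


# ---------------------------------------------------------------------------
# Classification driver
# ---------------------------------------------------------------------------

def classify_mention(
    prompt: Prompt,
    backend: Backend,
    mention: Mention,
    context: ContextWindow,
    retries: int = 0,
) -> FilterDecision:
    """Invoke the backend once (with transport retries), parse, decide."""
    attempt = 0
    while True:
        try:
            raw = backend.respond(prompt, mention, context)
            break
        except BackendError as exc:
            attempt += 1
            if attempt > retries:
                raise BackendError(
                    f"backend {backend.backend_id} failed for mention "
                    f"{mention.doc_id}[{mention.start}:{mention.end}] "
                    f"({mention.surface!r}): {exc}"
                ) from exc
    parsed = parse_response(raw)
    if parsed == "yes":
        label = 1
    elif parsed == "no":
        label = 0
    else:
        label = 1 if prompt.strategy.unparseable_policy == "keep" else 0
        logger.warning(
            "unparseable response %r for %s[%d:%d]; policy=%s -> label=%d",
            raw, mention.doc_id, mention.start, mention.end,
            prompt.strategy.unparseable_policy, label,
        )
    return FilterDecision(
        mention=mention,
        label=label,
        backend_id=backend.backend_id,
        raw_response=raw,
        parsed=parsed,
    )


def run_filter(
    mentions: Sequence[Mention],
    docs: Iterable[Document],
    vocab: Vocabulary | None,
    strategy: PromptStrategy,
    backend: Backend,
    context_unit: str = "words",
    context_size: int = 100,
    fewshot_bank: Sequence[FewShotExample] = (),
    definitions: Mapping[str, str] | None = None,
    retries: int = 0,
) -> list[FilterDecision]:
    """Classify every candidate mention; the kept set is {label == 1}.

    Few-shot examples are drawn once per run with the strategy seed,
    excluding every document that contributes a mention (the evaluation
    set); definitions default to those stored in the vocabulary.
    """
    doc_index = {d.doc_id: d for d in docs}
    missing = sorted({m.doc_id for m in mentions} - set(doc_index))
    if missing:
        raise FilteringError(f"mentions reference unknown documents: {missing}")
    if definitions is None:
        definitions = vocab.definitions() if vocab is not None else {}

    examples: list[FewShotExample] = []
    if strategy.mode == "few_shot":
        examples = select_few_shot(
            fewshot_bank, strategy.k, strategy.seed,
            excluded_doc_ids={m.doc_id for m in mentions},
        )

    decisions: list[FilterDecision] = []
    for mention in sorted(mentions, key=lambda m: (m.doc_id, m.start, m.end)):
        context = extract_context(
            doc_index[mention.doc_id], mention, context_unit, context_size
        )
        definition = (
            lookup_definition(mention.cui, definitions)
            if strategy.mode == "kag" else None
        )
        prompt = build_prompt(mention, context, strategy, examples, definition)
        decisions.append(
            classify_mention(prompt, backend, mention, context, retries=retries)
        )
    return decisions


def kept_mentions(decisions: Iterable[FilterDecision]) -> list[Mention]:
    return [d.mention for d in decisions if d.label == 1]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_decisions(
    decisions: Iterable[FilterDecision], path: str | Path,
    strategy: PromptStrategy | None = None,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in decisions:
            rec = d.to_dict()
            if strategy is not None:
                rec["strategy"] = strategy.descriptor()
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_decisions(path: str | Path) -> list[FilterDecision]:
    out: list[FilterDecision] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            out.append(
                FilterDecision(
                    mention=Mention.from_dict(rec),
                    label=rec["label"],
                    backend_id=rec["backend_id"],
                    raw_response=rec["raw_response"],
                    parsed=rec["parsed"],
                )
            )
    return out


def read_fewshot_bank(path: str | Path) -> list[FewShotExample]:
    out: list[FewShotExample] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            out.append(
                FewShotExample(
                    term=rec["term"],
                    context=rec["context"],
                    gold_label=rec["gold_label"],
                    source_doc_id=rec["source_doc_id"],
                )
            )
    return out


def write_fewshot_bank(bank: Iterable[FewShotExample], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ex in bank:
            fh.write(
                json.dumps(
                    {
                        "term": ex.term,
                        "context": ex.context,
                        "gold_label": ex.gold_label,
                        "source_doc_id": ex.source_doc_id,
                    },
                    sort_keys=True,
                )
                + "\n"
            )
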