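"""Synthetic discharge-summary generator with known gold labels.

Produces a self-contained study bundle — vocabulary, crosswalk,
definitions, documents, standoff gold annotations, few-shot bank and an
ICD diagnosis table — whose statistical structure is fully controlled,
so every pipeline stage can be exercised and measured without any
external data.

Disease names are pronounceable pseudo-words, so they can never occur in
filler prose; each mention is planted by a template whose category
(affirmative, negated, hypothetical, family-history, ambiguous
abbreviation) determines its gold label.  In default mode the templates
use exactly the cue phrases the rule classifier knows, which makes the
end-to-end extract→filter run a closed system with precision and recall
1.0 by construction; ``hard_mode`` mixes in paraphrases that evade the
cue lists, exercising the imperfect-filter code paths.

Everything is a deterministic function of (seed, parameters).
"""

from __future__ import annotations

import dataclasses
import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .cohort import IcdDiagnosis, write_diagnoses
from .evaluation import GoldAnnotation, GoldSet
from .extraction import Document, write_corpus
from .filtering import (
    DEFAULT_AMBIGUOUS_ABBREVS,
    FewShotExample,
    RuleConfig,
    write_fewshot_bank,
)
from .vocabulary import CrosswalkEntry, Vocabulary, VocabularyEntry, normalize_term


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthParams:
    """Generator knobs; category probabilities must sum to <= 1 and the
    residual mass is affirmative."""

    n_docs: int = 100
    mentions_per_doc_mean: float = 2.0
    p_negated: float = 0.15
    p_hypothetical: float = 0.10
    p_family: float = 0.10
    p_ambiguous_abbrev: float = 0.10
    icd_coverage: float = 0.6
    hard_mode: bool = False
    seed: int = 0
    n_terms: int = 30
    n_acronyms: int = 6
    median_doc_tokens: int = 300
    doc_length_sigma: float = 0.6

    def __post_init__(self) -> None:
        probs = (
            self.p_negated, self.p_hypothetical,
            self.p_family, self.p_ambiguous_abbrev, self.icd_coverage,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise SyntheticError("probabilities must lie in [0, 1]")
        if sum(probs[:4]) > 1.0 + 1e-12:
            raise SyntheticError("category probabilities must sum to <= 1")
        if self.n_docs < 1 or self.n_terms < 1:
            raise SyntheticError("n_docs and n_terms must be >= 1")
        if self.mentions_per_doc_mean < 0:
            raise SyntheticError("mentions_per_doc_mean must be >= 0")

    @property
    def p_affirmative(self) -> float:
        return 1.0 - (
            self.p_negated + self.p_hypothetical
            + self.p_family + self.p_ambiguous_abbrev
        )

    def category_probs(self) -> dict[str, float]:
        return {
            "affirmative": self.p_affirmative,
            "negated": self.p_negated,
            "hypothetical": self.p_hypothetical,
            "family": self.p_family,
            "ambiguous_abbrev": self.p_ambiguous_abbrev,
        }


# ---------------------------------------------------------------------------
# Vocabulary generation
# ---------------------------------------------------------------------------

_ONSETS = ["b", "d", "f", "g", "k", "l", "m", "n", "p", "r", "s", "t", "v", "z",
           "br", "dr", "gr", "kl", "pr", "st", "tr", "vl"]
_VOWELS = ["a", "e", "i", "o", "u"]
_CODAS = ["", "n", "r", "s", "x", "th", "l"]
_SUFFIXES = ["syndrome", "disease", "deficiency", "disorder"]

# words used by filler/template prose; pseudo-words colliding with these
# (or with cue words) are re-drawn
_RESERVED = {
    "patient", "history", "diagnosis", "evidence", "signs", "mother", "father",
    "brother", "sister", "family", "rule", "ruled", "out", "possible",
    "suspected", "consider", "negative", "denies", "unremarkable", "exam",
    "entertained", "hospital", "stable", "normal", "discharge", "admission",
    "continued", "tolerated", "without", "unlikely", "if", "no", "not",
} | set(_SUFFIXES)


@dataclass(frozen=True)
class SyntheticVocabulary:
    vocabulary: Vocabulary
    crosswalk: list[CrosswalkEntry]
    definitions: dict[str, str]


def _pseudo_word(rng: random.Random, n_syllables: int = 3) -> str:
    return "".join(
        rng.choice(_ONSETS) + rng.choice(_VOWELS) + rng.choice(_CODAS)
        for _ in range(n_syllables)
    )


def generate_vocab(
    n_terms: int, n_acronyms: int = 0, seed: int = 0
) -> SyntheticVocabulary:
    """Synthetic diseases: unique pseudo-word names with a synonym each,
    optional uppercase acronyms for the first ``n_acronyms`` entries,
    synthetic CUIs / ORPHA-style ids, definitions, and an ICD-10-like
    crosswalk code per disease."""
    if n_terms < 1:
        raise SyntheticError("n_terms must be >= 1")
    if n_acronyms > n_terms:
        raise SyntheticError("n_acronyms cannot exceed n_terms")
    rng = random.Random(seed)
    entries: list[VocabularyEntry] = []
    crosswalk: list[CrosswalkEntry] = []
    definitions: dict[str, str] = {}
    used_words: set[str] = set()
    used_acronyms: set[str] = set()
    for i in range(n_terms):
        while True:
            word = _pseudo_word(rng)
            if word not in used_words and word not in _RESERVED and len(word) >= 5:
                used_words.add(word)
                break
        suffix = _SUFFIXES[i % len(_SUFFIXES)]
        label = f"{word.capitalize()} {suffix}"
        synonym = f"{word.capitalize()} {_SUFFIXES[(i + 1) % len(_SUFFIXES)]}"
        cui = f"C9{i:06d}"
        concept_id = f"ORPHA:9{i:05d}"
        surface_terms = {normalize_term(label), normalize_term(synonym)}
        acronym_terms: set[str] = set()
        if i < n_acronyms:
            while True:
                acro = "".join(
                    rng.choice("BCDFGHJKLMNPQRSTVWXZ")
                    for _ in range(rng.randint(2, 4))
                )
                if (
                    acro not in used_acronyms
                    and acro.lower() not in _RESERVED
                    and acro not in DEFAULT_AMBIGUOUS_ABBREVS
                ):
                    used_acronyms.add(acro)
                    break
            acronym_terms.add(acro)
            surface_terms.add(normalize_term(acro))
        entries.append(
            VocabularyEntry(
                cui=cui,
                concept_id=concept_id,
                preferred_label=label,
                surface_terms=surface_terms,
                acronym_terms=acronym_terms,
                category="disease",
            )
        )
        crosswalk.append(
            CrosswalkEntry(
                concept_id=concept_id,
                cui=cui,
                icd10_codes=frozenset({f"Q{i % 100:02d}{i // 100}"}),
            )
        )
        definitions[cui] = (
            f"{label} is a synthetic rare disorder characterized by "
            f"progressive {word}-type involvement."
        )
    vocab = Vocabulary(
        entries=entries,
        metadata={
            "entry_count": len(entries),
            "acronym_max_len": 4,
            "collision_policy": "drop_colliding",
            "n_surface_terms": sum(len(e.surface_terms) for e in entries),
            "source_versions": {"generator": "raretext-synthetic/1", "seed": seed},
            "definitions": definitions,
        },
    )
    return SyntheticVocabulary(vocab, crosswalk, definitions)


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

TEMPLATES: dict[str, tuple[str, ...]] = {
    "affirmative": (
        "Patient has a history of {X}.",
        "The patient has {X}.",
        "Diagnosis of {X} was confirmed this admission.",
        "She was treated for {X} during the stay.",
    ),
    "negated": (
        "No evidence of {X}.",
        "No signs of {X} on exam.",
        "Patient denies {X}.",
        "{X} was ruled out.",
        "Negative for {X}.",
    ),
    "hypothetical": (
        "Rule out {X}.",
        "Possible {X}.",
        "Consider {X} given the presentation.",
        "Suspected {X}.",
    ),
    "family": (
        "Mother had {X}.",
        "Family history of {X}.",
        "Her brother was diagnosed with {X}.",
    ),
    "ambiguous_abbrev": (
        "{X} was tolerated well.",
        "Continued {X} per protocol.",
    ),
}

#: hard-mode paraphrases that deliberately evade the rule cue lists
HARD_TEMPLATES: dict[str, tuple[str, ...]] = {
    "negated": ("Exam was unremarkable for {X}.",),
    "hypothetical": ("{X} was entertained as an etiology.",),
}

_FILLERS = (
    "Vital signs remained stable throughout the stay.",
    "The patient was admitted from the emergency department.",
    "Laboratory values were within normal limits.",
    "He was discharged home in good condition.",
    "Follow up with the primary care clinic in two weeks.",
    "Physical exam was otherwise normal.",
    "Medications were reconciled at discharge.",
    "The hospital course was uncomplicated.",
    "Imaging of the chest showed clear lung fields.",
    "Diet was advanced as tolerated overnight.",
    "Blood cultures showed no growth after five days.",
    "The care team discussed the plan with the patient.",
)

_CATEGORIES = ("affirmative", "negated", "hypothetical", "family", "ambiguous_abbrev")


@dataclass
class SynthCorpus:
    """A generated study bundle with its provenance manifest."""

    documents: list[Document]
    gold: list[GoldAnnotation]
    vocabulary: Vocabulary
    crosswalk: list[CrosswalkEntry]
    definitions: dict[str, str]
    icd_diagnoses: list[IcdDiagnosis]
    manifest: dict

    def gold_set(self) -> GoldSet:
        return GoldSet(
            annotations=sorted(self.gold, key=lambda a: a.key),
            per_annotator={"synth": {a.key: a.label for a in self.gold}},
        )

    def oracle_labels(self) -> dict[tuple[str, int, int], int]:
        return {(a.doc_id, a.start, a.end): a.label for a in self.gold}

    def rule_config(self) -> RuleConfig:
        """Rule-classifier config whose ambiguous-abbreviation table
        covers this bundle's acronyms (the generator and the cue lists
        are mutually constructed)."""
        acronyms = set()
        for entry in self.vocabulary.entries:
            acronyms |= entry.acronym_terms
        return RuleConfig(
            ambiguous_abbrevs=frozenset(DEFAULT_AMBIGUOUS_ABBREVS | acronyms)
        )

    @property
    def bank_doc_ids(self) -> set[str]:
        return set(self.manifest["bank_doc_ids"])

    @property
    def eval_doc_ids(self) -> set[str]:
        return set(self.manifest["eval_doc_ids"])

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_corpus(self.documents, out_dir / "corpus.jsonl")
        lines = ["doc_id\tstart\tend\tsurface\tcui\tlabel\tannotator"]
        for a in sorted(self.gold, key=lambda a: a.key):
            lines.append(
                f"{a.doc_id}\t{a.start}\t{a.end}\t{a.surface}\t"
                f"{a.cui or ''}\t{a.label}\t{a.annotator}"
            )
        (out_dir / "gold.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
        self.vocabulary.write(out_dir / "vocabulary.json")
        from .vocabulary import write_crosswalk

        write_crosswalk(self.crosswalk, out_dir / "crosswalk.tsv")
        write_diagnoses(self.icd_diagnoses, out_dir / "diagnoses.csv")
        (out_dir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )


def _poisson(rng: random.Random, lam: float) -> int:
    """Knuth's method; lam is small here (a few mentions per document)."""
    if lam <= 0:
        return 0
    L = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= L:
            return k
        k += 1


def generate_corpus(
    synth_vocab: SyntheticVocabulary, params: SynthParams
) -> SynthCorpus:
    """Generate documents, gold annotations and the ICD table."""
    vocab = synth_vocab.vocabulary
    rng = random.Random(params.seed)
    entries = list(vocab.entries)
    acronym_entries = [e for e in entries if e.acronym_terms]
    if params.p_ambiguous_abbrev > 0 and not acronym_entries:
        raise SyntheticError(
            "p_ambiguous_abbrev > 0 requires a vocabulary with acronyms"
        )

    probs = [params.category_probs()[c] for c in _CATEGORIES]
    cumulative = []
    acc = 0.0
    for p in probs:
        acc += p
        cumulative.append(acc)

    documents: list[Document] = []
    gold: list[GoldAnnotation] = []
    category_counts = {c: 0 for c in _CATEGORIES}
    affirmative_pairs: set[tuple[str, str]] = set()  # (patient, concept)

    doc_index = 0
    patient_index = 0
    while doc_index < params.n_docs:
        patient_index += 1
        patient_id = f"P{patient_index:05d}"
        for _ in range(rng.randint(1, 3)):
            if doc_index >= params.n_docs:
                break
            doc_id = f"doc-{doc_index:05d}"
            n_mentions = _poisson(rng, params.mentions_per_doc_mean)
            target_tokens = int(
                math.exp(
                    math.log(params.median_doc_tokens)
                    + rng.gauss(0.0, params.doc_length_sigma)
                )
            )
            n_fillers = max(3, target_tokens // 8)
            slots: list[tuple[str, str | None]] = [
                ("filler", None) for _ in range(n_fillers)
            ]
            for _ in range(n_mentions):
                u = rng.random()
                category = next(
                    c for c, edge in zip(_CATEGORIES, cumulative) if u < edge
                )
                slots.insert(rng.randint(0, len(slots)), ("mention", category))

            text_parts: list[str] = []
            pos = 0
            for slot_i, (kind, category) in enumerate(slots):
                if kind == "filler":
                    sentence = rng.choice(_FILLERS)
                    span = None
                else:
                    category_counts[category] += 1
                    if category == "ambiguous_abbrev":
                        entry = rng.choice(acronym_entries)
                        surface = sorted(entry.acronym_terms)[0]
                    else:
                        entry = rng.choice(entries)
                        surface = entry.preferred_label
                    pool = list(TEMPLATES[category])
                    if params.hard_mode and category in HARD_TEMPLATES:
                        if rng.random() < 0.5:
                            pool = list(HARD_TEMPLATES[category])
                    template = rng.choice(pool)
                    prefix = template.split("{X}")[0]
                    sentence = template.replace("{X}", surface)
                    label = 1 if category == "affirmative" else 0
                    span = (pos + len(prefix), pos + len(prefix) + len(surface),
                            surface, entry, label, category)
                text_parts.append(sentence)
                pos += len(sentence)
                separator = "\n" if (slot_i + 1) % 6 == 0 else " "
                if slot_i < len(slots) - 1:
                    text_parts.append(separator)
                    pos += len(separator)
                if span is not None:
                    start, end, surface, entry, label, category = span
                    gold.append(
                        GoldAnnotation(
                            doc_id=doc_id, start=start, end=end, surface=surface,
                            cui=entry.cui, label=label, annotator="synth",
                        )
                    )
                    if label == 1:
                        affirmative_pairs.add((patient_id, entry.concept_id))
            documents.append(
                Document(doc_id=doc_id, text="".join(text_parts), patient_id=patient_id)
            )
            doc_index += 1

    # structured diagnoses: each affirmative (patient, disease) pair is
    # coded with probability icd_coverage
    code_of = {
        e.concept_id: sorted(e.icd10_codes)[0]
        for e in synth_vocab.crosswalk
        if e.icd10_codes
    }
    diagnoses: list[IcdDiagnosis] = []
    covered = 0
    for patient_id, concept_id in sorted(affirmative_pairs):
        if rng.random() < params.icd_coverage:
            covered += 1
            diagnoses.append(
                IcdDiagnosis(
                    patient_id=patient_id,
                    icd_version=10,
                    icd_code=code_of[concept_id],
                )
            )

    doc_ids = [d.doc_id for d in documents]
    bank_doc_ids = sorted(doc_ids[i] for i in range(4, len(doc_ids), 5))
    eval_doc_ids = sorted(set(doc_ids) - set(bank_doc_ids))
    n_mentions_total = sum(category_counts.values())
    manifest = {
        "params": dataclasses.asdict(params),
        "n_documents": len(documents),
        "n_patients": len({d.patient_id for d in documents}),
        "n_mentions": n_mentions_total,
        "category_counts": category_counts,
        "n_affirmative_pairs": len(affirmative_pairs),
        "realized_icd_coverage": (
            covered / len(affirmative_pairs) if affirmative_pairs else 0.0
        ),
        "bank_doc_ids": bank_doc_ids,
        "eval_doc_ids": eval_doc_ids,
        "ambiguous_abbrevs": sorted(
            a for e in vocab.entries for a in e.acronym_terms
        ),
    }
    return SynthCorpus(
        documents=documents,
        gold=gold,
        vocabulary=vocab,
        crosswalk=list(synth_vocab.crosswalk),
        definitions=dict(synth_vocab.definitions),
        icd_diagnoses=diagnoses,
        manifest=manifest,
    )


def generate_bundle(params: SynthParams) -> SynthCorpus:
    """Vocabulary + corpus in one call, both derived from params.seed."""
    synth_vocab = generate_vocab(
        params.n_terms, params.n_acronyms, seed=params.seed
    )
    return generate_corpus(synth_vocab, params)


# ---------------------------------------------------------------------------
# Few-shot bank
# ---------------------------------------------------------------------------

def generate_fewshot_bank(
    corpus: SynthCorpus, k_max: int, seed: int = 0
) -> list[FewShotExample]:
    """Draw a labelled example bank from the bank (non-test) documents,
    balanced across labels when possible."""
    from .extraction import sentence_spans

    doc_text = {d.doc_id: d.text for d in corpus.documents}
    bank_ids = corpus.bank_doc_ids
    candidates: list[FewShotExample] = []
    for ann in sorted(corpus.gold, key=lambda a: a.key):
        if ann.doc_id not in bank_ids:
            continue
        text = doc_text[ann.doc_id]
        sent = next(
            ((s, e) for s, e in sentence_spans(text) if s <= ann.start < e),
            (ann.start, ann.end),
        )
        candidates.append(
            FewShotExample(
                term=ann.surface,
                context=text[sent[0]:sent[1]],
                gold_label=ann.label,
                source_doc_id=ann.doc_id,
            )
        )
    if len(candidates) < k_max:
        raise SyntheticError(
            f"only {len(candidates)} labelled mentions outside the test split, "
            f"need {k_max}"
        )
    rng = random.Random(seed)
    positives = [c for c in candidates if c.gold_label == 1]
    negatives = [c for c in candidates if c.gold_label == 0]
    rng.shuffle(positives)
    rng.shuffle(negatives)
    bank: list[FewShotExample] = []
    while len(bank) < k_max:
        pools = [p for p in (positives, negatives) if p]
        if not pools:
            break
        for pool in (positives, negatives):
            if pool and len(bank) < k_max:
                bank.append(pool.pop())
    return bank


def write_bundle(
    corpus: SynthCorpus, out_dir: str | Path, k_max_bank: int = 10, seed: int = 0
) -> None:
    """Write the full bundle including a few-shot bank."""
    out_dir = Path(out_dir)
    corpus.write(out_dir)
    try:
        bank = generate_fewshot_bank(corpus, k_max_bank, seed=seed)
    except SyntheticError:
        bank = []
    write_fewshot_bank(bank, out_dir / "fewshot_bank.jsonl")
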