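"""Rare-disease vocabulary construction.

Builds a searchable terminology by linking source ontology concepts
(ORDO-style: identifier, preferred label, synonyms) to metathesaurus
concepts (CUIs) by normalized exact string matching, refining the links
with a semantic-type whitelist, expanding each linked concept with the
full set of atom strings carried by its CUI, and attaching an ICD-9/10
crosswalk so that text-derived cohorts can be compared with structured
diagnosis tables.

The readers consume the standard pipe-delimited metathesaurus table
dialects (MRCONSO / MRSTY / MRDEF) and a small TSV concept table; the
finished vocabulary round-trips through a versioned JSON file.
"""

from __future__ import annotations

import json
import logging
import re
import unicodedata
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Default semantic-type whitelist: congenital abnormalities, diseases,
#: mental/behavioral dysfunctions, cell/molecular dysfunctions, signs and
#: symptoms, anatomical abnormalities, and neoplastic processes.
DEFAULT_SEMANTIC_WHITELIST = frozenset(
    {"T019", "T047", "T048", "T049", "T050", "T190", "T191"}
)

DEFAULT_ACRONYM_MAX_LEN = 4

_CUI_RE = re.compile(r"^C\d{7}$")
_TUI_RE = re.compile(r"^T\d{3}$")
_NON_ALNUM_RE = re.compile(r"[^0-9a-z]+")


class VocabularyError(ValueError):
    """Raised for malformed terminology inputs or unresolvable builds."""


def normalize_term(raw: str) -> str:
    """Normalize a surface term for exact matching.

    Applies compatibility Unicode normalization (NFKC), lowercases,
    replaces every non-alphanumeric character with a space, collapses
    whitespace runs and trims.  Idempotent; may return "" for
    symbol-only input.
    """
    text = unicodedata.normalize("NFKC", raw).lower()
    text = _NON_ALNUM_RE.sub(" ", text)
    return " ".join(text.split())


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SourceConcept:
    """One ontology concept: identifier, preferred label and synonyms."""

    concept_id: str
    preferred_label: str
    synonyms: frozenset[str] = frozenset()
    category: str = "disease"  # "disease" | "phenotype"

    def __post_init__(self) -> None:
        if not self.preferred_label:
            raise VocabularyError(f"{self.concept_id}: empty preferred label")
        if self.category not in ("disease", "phenotype"):
            raise VocabularyError(
                f"{self.concept_id}: unknown category {self.category!r}"
            )
        norm_label = normalize_term(self.preferred_label)
        cleaned = frozenset(
            s for s in self.synonyms if s and normalize_term(s) != norm_label
        )
        object.__setattr__(self, "synonyms", cleaned)

    @property
    def all_terms(self) -> frozenset[str]:
        return self.synonyms | {self.preferred_label}


@dataclass(frozen=True)
class AtomRecord:
    """A metathesaurus atom: one string attached to one CUI."""

    cui: str
    term_string: str
    source_vocab: str = ""
    term_type: str = ""
    language: str = "ENG"
    suppressed: bool = False

    def __post_init__(self) -> None:
        if not _CUI_RE.match(self.cui):
            raise VocabularyError(f"bad CUI {self.cui!r}")
        if not self.term_string:
            raise VocabularyError(f"{self.cui}: empty atom string")


@dataclass(frozen=True)
class SemanticTypeAssignment:
    cui: str
    type_id: str
    type_name: str = ""

    def __post_init__(self) -> None:
        if not _TUI_RE.match(self.type_id):
            raise VocabularyError(f"bad semantic type id {self.type_id!r}")


@dataclass(frozen=True)
class ConceptDefinition:
    cui: str
    definition_text: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.definition_text:
            raise VocabularyError(f"{self.cui}: empty definition")


@dataclass(frozen=True)
class ConceptLink:
    """A (concept, CUI) pairing produced by normalized-exact matching."""

    concept_id: str
    cui: str
    match_kind: str  # "label_exact" | "synonym_exact"
    semantic_types: frozenset[str] = frozenset()


@dataclass
class VocabularyEntry:
    """One disease concept with its searchable surface terms.

    ``surface_terms`` hold normalized forms; ``acronym_terms`` keep the
    original all-uppercase short forms (length-capped) so the matcher can
    demand exact-case occurrences of abbreviations like "HD" or "PID".
    """

    cui: str
    concept_id: str
    preferred_label: str
    surface_terms: set[str] = field(default_factory=set)
    acronym_terms: set[str] = field(default_factory=set)
    category: str = "disease"

    def to_dict(self) -> dict:
        return {
            "cui": self.cui,
            "concept_id": self.concept_id,
            "preferred_label": self.preferred_label,
            "surface_terms": sorted(self.surface_terms),
            "acronym_terms": sorted(self.acronym_terms),
            "category": self.category,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VocabularyEntry":
        return cls(
            cui=d["cui"],
            concept_id=d["concept_id"],
            preferred_label=d["preferred_label"],
            surface_terms=set(d["surface_terms"]),
            acronym_terms=set(d["acronym_terms"]),
            category=d.get("category", "disease"),
        )


@dataclass
class Vocabulary:
    """The finished searchable terminology plus build metadata."""

    entries: list[VocabularyEntry] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.metadata.setdefault("entry_count", len(self.entries))
        if self.metadata["entry_count"] != len(self.entries):
            raise VocabularyError(
                "metadata entry_count does not match number of entries"
            )

    def __len__(self) -> int:
        return len(self.entries)

    def definitions(self) -> dict[str, str]:
        return dict(self.metadata.get("definitions", {}))

    # -- persistence -------------------------------------------------------

    def write(self, path: str | Path) -> None:
        payload = {
            "format": "raretext-vocabulary/1",
            "metadata": self.metadata,
            "entries": [e.to_dict() for e in self.entries],
        }
        Path(path).write_text(
            json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8"
        )

    @classmethod
    def read(cls, path: str | Path) -> "Vocabulary":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format") != "raretext-vocabulary/1":
            raise VocabularyError(f"{path}: not a raretext vocabulary file")
        return cls(
            entries=[VocabularyEntry.from_dict(d) for d in payload["entries"]],
            metadata=payload["metadata"],
        )


@dataclass(frozen=True)
class CrosswalkEntry:
    """ICD codes attached to one (concept, CUI) link, or unresolved."""

    concept_id: str
    cui: str
    icd9_codes: frozenset[str] = frozenset()
    icd10_codes: frozenset[str] = frozenset()

    @property
    def resolution(self) -> str:
        return "direct" if (self.icd9_codes or self.icd10_codes) else "unresolved"


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line:
                yield lineno, line


def read_concepts(path: str | Path) -> list[SourceConcept]:
    """Read the 4-column concept TSV (header row required).

    Columns: concept_id, preferred_label, pipe-separated synonyms, category.
    """
    concepts: list[SourceConcept] = []
    seen: set[str] = set()
    for lineno, line in _read_lines(path):
        if lineno == 1:  # header
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise VocabularyError(
                f"{path}:{lineno}: expected 4 tab-separated fields, got {len(fields)}"
            )
        concept_id, label, syn_field, category = fields
        if concept_id in seen:
            raise VocabularyError(f"{path}:{lineno}: duplicate concept_id {concept_id}")
        seen.add(concept_id)
        synonyms = frozenset(s for s in syn_field.split("|") if s)
        try:
            concepts.append(
                SourceConcept(concept_id, label, synonyms, category or "disease")
            )
        except VocabularyError as exc:
            raise VocabularyError(f"{path}:{lineno}: {exc}") from exc
    return concepts


def _split_rrf(path, lineno: int, line: str, n_fields: int) -> list[str]:
    fields = line.split("|")
    # n_fields data fields plus the empty string after the trailing pipe
    if len(fields) != n_fields + 1 or fields[-1] != "":
        raise VocabularyError(
            f"{path}:{lineno}: expected {n_fields} pipe-delimited fields "
            f"with trailing pipe, got {len(fields) - 1}"
        )
    return fields[:-1]


def read_atoms(
    path: str | Path,
    languages: set[str] = frozenset({"ENG"}),
    include_suppressed: bool = False,
) -> list[AtomRecord]:
    """Read an MRCONSO-dialect atom table (18 fields, trailing pipe)."""
    atoms: list[AtomRecord] = []
    for lineno, line in _read_lines(path):
        f = _split_rrf(path, lineno, line, 18)
        suppressed = f[16] in ("O", "E", "Y")
        if f[1] not in languages:
            continue
        if suppressed and not include_suppressed:
            continue
        try:
            atoms.append(
                AtomRecord(
                    cui=f[0], term_string=f[14], source_vocab=f[11],
                    term_type=f[12], language=f[1], suppressed=suppressed,
                )
            )
        except VocabularyError as exc:
            raise VocabularyError(f"{path}:{lineno}: {exc}") from exc
    return atoms


def read_semantic_types(path: str | Path) -> list[SemanticTypeAssignment]:
    """Read an MRSTY-dialect table (6 fields, trailing pipe)."""
    out: list[SemanticTypeAssignment] = []
    for lineno, line in _read_lines(path):
        f = _split_rrf(path, lineno, line, 6)
        try:
            out.append(SemanticTypeAssignment(cui=f[0], type_id=f[1], type_name=f[3]))
        except VocabularyError as exc:
            raise VocabularyError(f"{path}:{lineno}: {exc}") from exc
    return out


def read_definitions(
    path: str | Path, source_priority: Sequence[str] = ()
) -> dict[str, ConceptDefinition]:
    """Read an MRDEF-dialect table and resolve one definition per CUI.

    A source earlier in ``source_priority`` wins; sources not listed rank
    after all listed ones; remaining ties go to first occurrence in file
    order.
    """
    rank = {sab: i for i, sab in enumerate(source_priority)}
    best: dict[str, tuple[int, int, ConceptDefinition]] = {}
    for lineno, line in _read_lines(path):
        f = _split_rrf(path, lineno, line, 8)
        cui, sab, definition = f[0], f[4], f[5]
        if not definition:
            continue
        key = (rank.get(sab, len(rank)), lineno)
        if cui not in best or key < best[cui][:2]:
            best[cui] = (*key, ConceptDefinition(cui, definition, sab))
    return {cui: entry[2] for cui, entry in best.items()}


def read_icd_map(path: str | Path) -> dict[str, dict[int, frozenset[str]]]:
    """Read the CUI→ICD crosswalk TSV (cui, icd_version, icd_code; header).

    Codes are canonicalized: dots removed, uppercased.
    """
    table: dict[str, dict[int, set[str]]] = defaultdict(lambda: {9: set(), 10: set()})
    for lineno, line in _read_lines(path):
        if lineno == 1:
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise VocabularyError(
                f"{path}:{lineno}: expected 3 tab-separated fields, got {len(fields)}"
            )
        cui, version, code = fields
        if version not in ("9", "10"):
            raise VocabularyError(f"{path}:{lineno}: icd_version must be 9 or 10")
        table[cui][int(version)].add(normalize_icd_code(code))
    return {
        cui: {9: frozenset(v[9]), 10: frozenset(v[10])} for cui, v in table.items()
    }


def normalize_icd_code(code: str) -> str:
    """Canonical ICD code form: uppercase, dots stripped ("Q33.0" → "Q330")."""
    return code.replace(".", "").strip().upper()


# ---------------------------------------------------------------------------
# Linking and building
# ---------------------------------------------------------------------------

def link_concepts(
    concepts: Iterable[SourceConcept],
    atoms: Iterable[AtomRecord],
    semantic_types: Iterable[SemanticTypeAssignment],
    whitelist: Iterable[str] = DEFAULT_SEMANTIC_WHITELIST,
) -> tuple[list[ConceptLink], list[str]]:
    """Link concepts to CUIs by normalized-exact string match.

    A link is made when the normalized preferred label or any normalized
    synonym equals a normalized atom string *and* the atom's CUI carries at
    least one whitelisted semantic type.  Label matches take precedence
    over synonym matches for the same (concept, CUI); a concept may link
    to several CUIs.  Returns (links, unresolved concept ids), both in
    deterministic sorted order regardless of input ordering.
    """
    whitelist = set(whitelist)
    if not whitelist:
        raise VocabularyError("semantic-type whitelist must be non-empty")

    types_by_cui: dict[str, set[str]] = defaultdict(set)
    for st in semantic_types:
        types_by_cui[st.cui].add(st.type_id)

    cuis_by_norm: dict[str, set[str]] = defaultdict(set)
    for atom in atoms:
        if types_by_cui[atom.cui] & whitelist:
            norm = normalize_term(atom.term_string)
            if norm:
                cuis_by_norm[norm].add(atom.cui)

    links: dict[tuple[str, str], ConceptLink] = {}
    unresolved: list[str] = []
    for concept in sorted(concepts, key=lambda c: c.concept_id):
        found = False
        candidates = [("label_exact", concept.preferred_label)] + [
            ("synonym_exact", s) for s in sorted(concept.synonyms)
        ]
        for kind, term in candidates:
            for cui in sorted(cuis_by_norm.get(normalize_term(term), ())):
                found = True
                key = (concept.concept_id, cui)
                if key in links and links[key].match_kind == "label_exact":
                    continue
                links[key] = ConceptLink(
                    concept_id=concept.concept_id,
                    cui=cui,
                    match_kind=kind,
                    semantic_types=frozenset(types_by_cui[cui] & whitelist),
                )
        if not found:
            unresolved.append(concept.concept_id)
    ordered = [links[k] for k in sorted(links)]
    return ordered, unresolved


def build_vocabulary(
    links: Iterable[ConceptLink],
    atoms: Iterable[AtomRecord],
    concepts: Iterable[SourceConcept],
    acronym_max_len: int = DEFAULT_ACRONYM_MAX_LEN,
    collision_policy: str = "drop_colliding",
    definitions: Mapping[str, ConceptDefinition] | None = None,
    source_versions: Mapping[str, str] | None = None,
) -> Vocabulary:
    """Assemble the searchable vocabulary from concept-CUI links.

    Per (concept, CUI) entry: every atom string of the CUI plus the
    concept's own label and synonyms contribute their normalized forms to
    ``surface_terms``; original-case terms that are all-uppercase and at
    most ``acronym_max_len`` characters additionally populate
    ``acronym_terms``.  A normalized term claimed by two different CUIs is
    resolved per ``collision_policy``: "drop_colliding" removes it
    everywhere (logged), "prefer_first" keeps the first entry in
    (concept_id, cui) order, "error" raises listing the colliding terms.
    """
    if collision_policy not in ("drop_colliding", "prefer_first", "error"):
        raise VocabularyError(f"unknown collision policy {collision_policy!r}")

    atoms_by_cui: dict[str, list[str]] = defaultdict(list)
    for atom in atoms:
        atoms_by_cui[atom.cui].append(atom.term_string)
    concept_by_id = {c.concept_id: c for c in concepts}

    entries: list[VocabularyEntry] = []
    for link in sorted(links, key=lambda l: (l.concept_id, l.cui)):
        concept = concept_by_id[link.concept_id]
        originals = set(atoms_by_cui.get(link.cui, ())) | concept.all_terms
        entry = VocabularyEntry(
            cui=link.cui,
            concept_id=link.concept_id,
            preferred_label=concept.preferred_label,
            category=concept.category,
        )
        for original in originals:
            norm = normalize_term(original)
            if not norm:
                continue
            entry.surface_terms.add(norm)
            if (
                original.isupper()
                and any(ch.isalpha() for ch in original)
                and len(original) <= acronym_max_len
            ):
                entry.acronym_terms.add(original)
        if entry.surface_terms:
            entries.append(entry)

    _resolve_collisions(entries, collision_policy)

    metadata = {
        "entry_count": len(entries),
        "acronym_max_len": acronym_max_len,
        "collision_policy": collision_policy,
        "n_surface_terms": sum(len(e.surface_terms) for e in entries),
        "source_versions": dict(source_versions or {}),
    }
    if definitions:
        link_cuis = {e.cui for e in entries}
        metadata["definitions"] = {
            cui: d.definition_text
            for cui, d in sorted(definitions.items())
            if cui in link_cuis
        }
    return Vocabulary(entries=entries, metadata=metadata)


def _resolve_collisions(entries: list[VocabularyEntry], policy: str) -> None:
    claims: dict[str, list[VocabularyEntry]] = defaultdict(list)
    for entry in entries:
        for term in entry.surface_terms:
            claims[term].append(entry)
    colliding = {
        term: owners
        for term, owners in claims.items()
        if len({e.cui for e in owners}) > 1
    }
    if not colliding:
        return
    if policy == "error":
        raise VocabularyError(
            "surface terms map to multiple CUIs: " + ", ".join(sorted(colliding))
        )
    for term, owners in sorted(colliding.items()):
        keep = owners[0] if policy == "prefer_first" else None
        for entry in owners:
            if entry is keep:
                continue
            entry.surface_terms.discard(term)
            entry.acronym_terms = {
                a for a in entry.acronym_terms if normalize_term(a) != term
            }
        logger.warning(
            "surface term %r claimed by CUIs %s: policy=%s",
            term, sorted({e.cui for e in owners}), policy,
        )
    entries[:] = [e for e in entries if e.surface_terms]


def build_crosswalk(
    links: Iterable[ConceptLink],
    cui_to_icd: Mapping[str, Mapping[int, frozenset[str]]],
) -> list[CrosswalkEntry]:
    """Attach ICD-9/10 codes to each distinct (concept, CUI) link.

    Links whose CUI is absent from the mapping become unresolved entries
    (the expert-review step that would resolve them is out of scope), so
    resolved + unresolved always equals the number of distinct links.
    """
    out: list[CrosswalkEntry] = []
    for link in sorted(
        {(l.concept_id, l.cui) for l in links}
    ):
        concept_id, cui = link
        codes = cui_to_icd.get(cui, {})
        out.append(
            CrosswalkEntry(
                concept_id=concept_id,
                cui=cui,
                icd9_codes=frozenset(codes.get(9, ())),
                icd10_codes=frozenset(codes.get(10, ())),
            )
        )
    return out


def write_crosswalk(entries: Iterable[CrosswalkEntry], path: str | Path) -> None:
    lines = ["concept_id\tcui\ticd9_codes\ticd10_codes\tresolution"]
    for e in entries:
        lines.append(
            "\t".join(
                [
                    e.concept_id,
                    e.cui,
                    "|".join(sorted(e.icd9_codes)),
                    "|".join(sorted(e.icd10_codes)),
                    e.resolution,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_crosswalk(path: str | Path) -> list[CrosswalkEntry]:
    entries: list[CrosswalkEntry] = []
    for lineno, line in _read_lines(path):
        if lineno == 1:
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise VocabularyError(
                f"{path}:{lineno}: expected 5 fields, got {len(fields)}"
            )
        concept_id, cui, icd9, icd10, _resolution = fields
        entries.append(
            CrosswalkEntry(
                concept_id=concept_id,
                cui=cui,
                icd9_codes=frozenset(c for c in icd9.split("|") if c),
                icd10_codes=frozenset(c for c in icd10.split("|") if c),
            )
        )
    return entries
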