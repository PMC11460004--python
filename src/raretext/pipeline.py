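"""End-to-end orchestration: vocabulary → extraction → filtering →
evaluation / cohort, driven by a YAML config, with a reproducibility
manifest.

Runs are single-process and streaming per document; with a
deterministic backend a re-run under the identical config produces
byte-identical artifacts (the manifest records no wall-clock state,
only parameters, versions and content digests).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .cohort import (
    aggregate_patients,
    compare,
    icd_patients,
    load_diagnoses,
    write_comparison,
)
from .evaluation import (
    load_gold,
    match_and_count,
    precision_recall_f1,
    write_metrics,
)
from .extraction import (
    build_matcher,
    extract_corpus_mentions,
    load_corpus,
    write_mentions,
)
from .filtering import (
    DEFAULT_AMBIGUOUS_ABBREVS,
    PromptStrategy,
    RuleConfig,
    kept_mentions,
    make_backend,
    read_fewshot_bank,
    run_filter,
    write_decisions,
)
from .vocabulary import (
    DEFAULT_SEMANTIC_WHITELIST,
    Vocabulary,
    build_crosswalk,
    build_vocabulary,
    link_concepts,
    read_atoms,
    read_concepts,
    read_crosswalk,
    read_definitions,
    read_icd_map,
    read_semantic_types,
    write_crosswalk,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration (exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (exit code 3)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


_VALID_UNITS = ("words", "sentences", "document")


@dataclass
class PipelineConfig:
    corpus: str
    out_dir: str
    vocabulary: str | None = None           # prebuilt vocabulary.json
    vocab_sources: dict | None = None       # or raw terminology tables
    crosswalk: str | None = None
    gold: str | None = None
    diagnoses: str | None = None
    fewshot_bank: str | None = None
    backend: dict = field(default_factory=lambda: {"name": "rule"})
    strategy: dict = field(default_factory=dict)
    context: dict = field(default_factory=lambda: {"unit": "words", "size": 100})
    span_mode: str = "overlap"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc

    def validate(self) -> None:
        for name in ("corpus", "gold", "diagnoses", "fewshot_bank",
                     "vocabulary", "crosswalk"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ConfigError(f"{name} path does not exist: {value}")
        if self.vocabulary is None and self.vocab_sources is None:
            raise ConfigError("one of 'vocabulary' or 'vocab_sources' is required")
        if self.vocab_sources is not None:
            for key in ("concepts", "atoms", "semtypes"):
                if key not in self.vocab_sources:
                    raise ConfigError(f"vocab_sources requires {key!r}")
                if not Path(self.vocab_sources[key]).exists():
                    raise ConfigError(
                        f"vocab_sources.{key} path does not exist: "
                        f"{self.vocab_sources[key]}"
                    )
        if self.context.get("unit", "words") not in _VALID_UNITS:
            raise ConfigError(f"context.unit must be one of {_VALID_UNITS}")
        unit = self.context.get("unit", "words")
        if unit != "document" and int(self.context.get("size", 100)) < 1:
            raise ConfigError("context.size must be >= 1")
        if self.span_mode not in ("exact", "overlap"):
            raise ConfigError("span_mode must be 'exact' or 'overlap'")
        try:
            self.prompt_strategy()
        except Exception as exc:
            raise ConfigError(f"invalid strategy: {exc}") from exc
        name = self.backend.get("name")
        if name not in ("rule", "oracle", "scripted", "noop", "http"):
            raise ConfigError(f"unknown backend {name!r}")
        if name == "oracle" and not self.gold:
            raise ConfigError("oracle backend requires a gold file")
        if self.prompt_strategy().mode == "few_shot" and not self.fewshot_bank:
            raise ConfigError("few_shot strategy requires a fewshot_bank file")

    def prompt_strategy(self) -> PromptStrategy:
        mode_alias = {"zero": "zero_shot", "few": "few_shot",
                      "zero_shot": "zero_shot", "few_shot": "few_shot",
                      "kag": "kag"}
        mode = mode_alias.get(self.strategy.get("mode", "zero_shot"))
        if mode is None:
            raise ConfigError(f"unknown strategy mode {self.strategy.get('mode')!r}")
        return PromptStrategy(
            mode=mode,
            k=int(self.strategy.get("k", 0)),
            seed=int(self.strategy.get("seed", 0)),
            unparseable_policy=self.strategy.get("unparseable_policy", "keep"),
        )

    def to_dict(self) -> dict:
        return {
            name: getattr(self, name) for name in self.__dataclass_fields__
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def build_vocabulary_from_sources(sources: Mapping[str, Any]) -> tuple[Vocabulary, list]:
    """Run the full terminology build from raw tables; returns the
    vocabulary and the ICD crosswalk (empty when no icd_map given)."""
    concepts = read_concepts(sources["concepts"])
    atoms = read_atoms(
        sources["atoms"],
        languages=set(sources.get("languages", ["ENG"])),
        include_suppressed=bool(sources.get("include_suppressed", False)),
    )
    semtypes = read_semantic_types(sources["semtypes"])
    whitelist = set(sources.get("whitelist", DEFAULT_SEMANTIC_WHITELIST))
    definitions = (
        read_definitions(sources["defs"], sources.get("def_priority", ()))
        if sources.get("defs") else {}
    )
    links, unresolved = link_concepts(concepts, atoms, semtypes, whitelist)
    if unresolved:
        logger.info("%d concepts had no CUI link", len(unresolved))
    vocab = build_vocabulary(
        links, atoms, concepts,
        acronym_max_len=int(sources.get("acronym_max_len", 4)),
        collision_policy=sources.get("collision_policy", "drop_colliding"),
        definitions=definitions,
    )
    crosswalk = (
        build_crosswalk(links, read_icd_map(sources["icd_map"]))
        if sources.get("icd_map") else []
    )
    return vocab, crosswalk


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns the run manifest.

    Artifacts land in ``out_dir``: vocabulary.json, mentions.jsonl,
    decisions.jsonl, metrics.csv (with gold), cohort files (with
    diagnoses), manifest.json.  A stage failure leaves prior artifacts in
    place plus a FAILED marker naming the stage.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "raretext_version": __version__,
        "config": config.to_dict(),
        "inputs": {},
        "outputs": {},
        "stages": {},
    }
    for name in ("corpus", "gold", "diagnoses", "fewshot_bank",
                 "vocabulary", "crosswalk"):
        value = getattr(config, name)
        if value and Path(value).is_file():
            manifest["inputs"][name] = _sha256(Path(value))

    current_stage = "vocabulary"
    try:
        if config.vocabulary:
            vocab = Vocabulary.read(config.vocabulary)
        else:
            vocab, built_crosswalk = build_vocabulary_from_sources(
                config.vocab_sources
            )
            vocab.write(out_dir / "vocabulary.json")
            manifest["outputs"]["vocabulary"] = _sha256(out_dir / "vocabulary.json")
            if built_crosswalk and not config.crosswalk:
                write_crosswalk(built_crosswalk, out_dir / "crosswalk.tsv")
                config.crosswalk = str(out_dir / "crosswalk.tsv")
        manifest["stages"]["vocabulary"] = {"n_entries": len(vocab)}

        current_stage = "extraction"
        docs = load_corpus(config.corpus)
        matcher = build_matcher(vocab)
        mentions = extract_corpus_mentions(docs, matcher)
        write_mentions(mentions, out_dir / "mentions.jsonl")
        manifest["outputs"]["mentions"] = _sha256(out_dir / "mentions.jsonl")
        manifest["stages"]["extraction"] = {
            "n_documents": len(docs),
            "n_patterns": matcher.n_patterns,
            "n_candidates": len(mentions),
        }

        current_stage = "filtering"
        gold = load_gold(config.gold, docs) if config.gold else None
        strategy = config.prompt_strategy()
        backend_opts = dict(config.backend)
        backend_name = backend_opts.pop("name")
        vocab_acronyms = frozenset(
            a for e in vocab.entries for a in e.acronym_terms
        )
        rule_config = RuleConfig(
            ambiguous_abbrevs=frozenset(
                set(backend_opts.pop("ambiguous_abbrevs", []))
                or (DEFAULT_AMBIGUOUS_ABBREVS | vocab_acronyms)
            )
        )
        backend = make_backend(
            backend_name,
            rule_config=rule_config,
            oracle_labels=gold.labels_by_position() if gold else None,
            responses=backend_opts.pop("responses", None),
            http_options=backend_opts.pop("http", None),
        )
        bank = (
            read_fewshot_bank(config.fewshot_bank) if config.fewshot_bank else []
        )
        decisions = run_filter(
            mentions, docs, vocab, strategy, backend,
            context_unit=config.context.get("unit", "words"),
            context_size=int(config.context.get("size", 100)),
            fewshot_bank=bank,
        )
        write_decisions(decisions, out_dir / "decisions.jsonl", strategy)
        kept = kept_mentions(decisions)
        manifest["outputs"]["decisions"] = _sha256(out_dir / "decisions.jsonl")
        manifest["stages"]["filtering"] = {
            "backend_id": backend.backend_id,
            "strategy": strategy.descriptor(),
            "n_candidates": len(mentions),
            "n_kept": len(kept),
        }

        if gold is not None:
            current_stage = "evaluation"
            counts = match_and_count(kept, gold, config.span_mode)
            row = precision_recall_f1(
                counts,
                {"backend_id": backend.backend_id, "mode": strategy.mode,
                 "k": strategy.k,
                 "context_unit": config.context.get("unit", "words"),
                 "context_size": int(config.context.get("size", 100))},
            )
            write_metrics([row], out_dir / "metrics.csv")
            manifest["outputs"]["metrics"] = _sha256(out_dir / "metrics.csv")
            manifest["stages"]["evaluation"] = {
                "tp": counts.tp, "fp": counts.fp, "fn": counts.fn,
                "precision": row.precision, "recall": row.recall, "f1": row.f1,
                "n_gold": gold.n_mentions,
            }

        if config.diagnoses and config.crosswalk:
            current_stage = "cohort"
            diagnoses = load_diagnoses(config.diagnoses)
            crosswalk = read_crosswalk(config.crosswalk)
            nlp_map = aggregate_patients(kept, docs)
            icd_map = icd_patients(diagnoses, crosswalk)
            rows, summary = compare(nlp_map, icd_map)
            write_comparison(rows, summary, out_dir)
            manifest["outputs"]["cohort_comparison"] = _sha256(
                out_dir / "cohort_comparison.csv"
            )
            manifest["stages"]["cohort"] = summary.to_dict()
    except Exception as exc:
        (out_dir / "FAILED").write_text(
            f"stage: {current_stage}\nerror: {exc}\n", encoding="utf-8"
        )
        raise StageError(current_stage, exc) from exc

    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
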