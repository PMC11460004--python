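"""Gold-standard handling and mention-level evaluation.

Covers standoff-annotation ingestion with span verification, Cohen's
kappa for dual annotation, third-annotator adjudication, mention-level
precision/recall/F1 against an adjudicated gold set, and the few-shot /
context-length sweeps.

The recall denominator includes gold positives that were never proposed
as candidates by the dictionary stage (dictionary misses): a pipeline
cannot be credited with recall on mentions it never saw, which is also
the only reading under which a dictionary baseline shows recall < 1.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .extraction import Document, Mention
from .filtering import (
    Backend,
    FewShotExample,
    FilterDecision,
    PromptStrategy,
    kept_mentions,
    run_filter,
)


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Gold standard
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GoldAnnotation:
    doc_id: str
    start: int
    end: int
    surface: str
    cui: str | None
    label: int
    annotator: str

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise EvaluationError("gold label must be 0 or 1")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.doc_id, self.start, self.end, self.cui or "")


@dataclass
class GoldSet:
    """Adjudicated annotations plus the raw per-annotator label tables."""

    annotations: list[GoldAnnotation]
    per_annotator: dict[str, dict[tuple, int]] = field(default_factory=dict)

    @property
    def n_mentions(self) -> int:
        return len(self.annotations)

    def labels_by_position(self) -> Mapping[tuple[str, int, int], int]:
        return {
            (a.doc_id, a.start, a.end): a.label for a in self.annotations
        }


def load_gold(
    path: str | Path,
    docs: Iterable[Document] | None = None,
    adjudicator: str = "adjudicator",
) -> GoldSet:
    """Load standoff gold TSV (doc_id, start, end, surface, cui, label,
    annotator; header row) and adjudicate.

    Every span is verified against the corpus when documents are given.
    With one annotator the labels are final; with two, agreed positions
    take the common label and disagreements are resolved by the
    ``adjudicator`` annotator's rows (error when missing).
    """
    doc_index = {d.doc_id: d for d in docs} if docs is not None else None
    rows: list[GoldAnnotation] = []
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"doc_id", "start", "end", "surface", "cui", "label", "annotator"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise EvaluationError(f"{path}: gold file must have columns {sorted(required)}")
        for lineno, rec in enumerate(reader, start=2):
            ann = GoldAnnotation(
                doc_id=rec["doc_id"],
                start=int(rec["start"]),
                end=int(rec["end"]),
                surface=rec["surface"],
                cui=rec["cui"] or None,
                label=int(rec["label"]),
                annotator=rec["annotator"],
            )
            if doc_index is not None:
                if ann.doc_id not in doc_index:
                    raise EvaluationError(f"{path}:{lineno}: unknown doc_id {ann.doc_id}")
                slice_ = doc_index[ann.doc_id].text[ann.start:ann.end]
                if slice_ != ann.surface:
                    raise EvaluationError(
                        f"{path}:{lineno}: span text {slice_!r} != surface {ann.surface!r}"
                    )
            rows.append(ann)

    per_annotator: dict[str, dict[tuple, int]] = {}
    exemplar: dict[tuple, GoldAnnotation] = {}
    for ann in rows:
        per_annotator.setdefault(ann.annotator, {})[ann.key] = ann.label
        exemplar.setdefault(ann.key, ann)

    primary = sorted(a for a in per_annotator if a != adjudicator)
    if not primary:
        raise EvaluationError(f"{path}: no primary annotators found")
    if len(primary) == 1:
        final = dict(per_annotator[primary[0]])
    elif len(primary) == 2:
        ta, tb = (per_annotator[a] for a in primary)
        if set(ta) != set(tb):
            raise EvaluationError(
                f"{path}: annotators {primary} cover different mention sets"
            )
        third = per_annotator.get(adjudicator, {})
        keys = sorted(ta)
        final = dict(
            zip(
                keys,
                adjudicate(
                    [ta[k] for k in keys],
                    [tb[k] for k in keys],
                    [third.get(k) for k in keys],
                ),
            )
        )
    else:
        raise EvaluationError(
            f"{path}: expected at most two primary annotators, got {primary}"
        )

    adjudicated = [
        GoldAnnotation(
            doc_id=exemplar[k].doc_id,
            start=exemplar[k].start,
            end=exemplar[k].end,
            surface=exemplar[k].surface,
            cui=exemplar[k].cui,
            label=label,
            annotator="final",
        )
        for k, label in sorted(final.items())
    ]
    return GoldSet(annotations=adjudicated, per_annotator=per_annotator)


# ---------------------------------------------------------------------------
# Agreement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementResult:
    kappa: float
    observed_agreement: float
    expected_agreement: float
    n: int


def cohens_kappa(labels_a: Sequence[int], labels_b: Sequence[int]) -> AgreementResult:
    """Chance-corrected agreement: kappa = (po - pe) / (1 - pe)."""
    if len(labels_a) != len(labels_b):
        raise EvaluationError("label sequences differ in length")
    n = len(labels_a)
    if n == 0:
        raise EvaluationError("need at least one label pair")
    po = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    classes = set(labels_a) | set(labels_b)
    pe = sum(
        (sum(a == c for a in labels_a) / n) * (sum(b == c for b in labels_b) / n)
        for c in classes
    )
    if pe >= 1.0:
        raise EvaluationError(
            "degenerate marginals (expected agreement = 1); kappa undefined"
        )
    return AgreementResult(
        kappa=(po - pe) / (1 - pe),
        observed_agreement=po,
        expected_agreement=pe,
        n=n,
    )


def adjudicate(
    labels_a: Sequence[int],
    labels_b: Sequence[int],
    labels_c: Sequence[int | None],
) -> list[int]:
    """Agreed positions keep the common label; disagreements take the
    third annotator's label (which must then be present)."""
    if not (len(labels_a) == len(labels_b) == len(labels_c)):
        raise EvaluationError("label sequences differ in length")
    final: list[int] = []
    for i, (a, b, c) in enumerate(zip(labels_a, labels_b, labels_c)):
        if a == b:
            final.append(a)
        elif c is None:
            raise EvaluationError(f"position {i}: disagreement but no third label")
        else:
            final.append(c)
    return final


# ---------------------------------------------------------------------------
# Confusion counting and metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int | None = None

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")


@dataclass(frozen=True)
class MetricsRow:
    precision: float
    recall: float
    f1: float
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"precision": self.precision, "recall": self.recall,
                "f1": self.f1, **self.config}


def _spans_overlap(s1: int, e1: int, s2: int, e2: int) -> bool:
    return s1 < e2 and s2 < e1


def match_and_count(
    kept: Sequence[Mention],
    gold: GoldSet,
    span_mode: str = "overlap",
) -> ConfusionCounts:
    """Greedy positional matching of kept mentions to gold annotations.

    A kept mention matches a gold annotation in the same document whose
    span agrees per ``span_mode`` ("exact" or any-character "overlap")
    and whose CUI agrees when both sides carry one; each gold annotation
    is consumed at most once.  tp counts matches to gold label 1, fp
    matches to gold label 0 plus unmatched kept mentions, fn gold
    positives left unmatched — including those the dictionary never
    proposed.
    """
    if span_mode not in ("exact", "overlap"):
        raise EvaluationError(f"unknown span_mode {span_mode!r}")
    by_doc: dict[str, list[GoldAnnotation]] = {}
    for ann in sorted(gold.annotations, key=lambda a: (a.doc_id, a.start, a.end)):
        by_doc.setdefault(ann.doc_id, []).append(ann)
    consumed: set[tuple] = set()
    tp = fp = 0
    for m in sorted(kept, key=lambda m: (m.doc_id, m.start, m.end)):
        match = None
        for ann in by_doc.get(m.doc_id, ()):
            if ann.key in consumed:
                continue
            if span_mode == "exact":
                if (ann.start, ann.end) != (m.start, m.end):
                    continue
            elif not _spans_overlap(m.start, m.end, ann.start, ann.end):
                continue
            if ann.cui and m.cui and ann.cui != m.cui:
                continue
            match = ann
            break
        if match is None:
            fp += 1
        else:
            consumed.add(match.key)
            if match.label == 1:
                tp += 1
            else:
                fp += 1
    fn = sum(
        1 for ann in gold.annotations
        if ann.label == 1 and ann.key not in consumed
    )
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)


def precision_recall_f1(
    counts: ConfusionCounts, config: Mapping | None = None
) -> MetricsRow:
    """P = tp/(tp+fp), R = tp/(tp+fn), F1 their harmonic mean; zero
    denominators yield zero."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return MetricsRow(precision=p, recall=r, f1=f1, config=dict(config or {}))


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def round_half_up(x: float, places: int = 4) -> float:
    """Round-half-up to ``places`` decimals (table-reporting convention)."""
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

def _evaluate_run(
    decisions: Sequence[FilterDecision],
    gold: GoldSet,
    span_mode: str,
    config: Mapping,
) -> MetricsRow:
    counts = match_and_count(kept_mentions(decisions), gold, span_mode)
    return precision_recall_f1(counts, config)


def sweep_few_shot(
    mentions: Sequence[Mention],
    docs: Sequence[Document],
    gold: GoldSet,
    backend: Backend,
    fewshot_bank: Sequence[FewShotExample],
    k_values: Sequence[int],
    seed: int = 0,
    context_unit: str = "words",
    context_size: int = 100,
    span_mode: str = "overlap",
    definitions: Mapping[str, str] | None = None,
) -> list[MetricsRow]:
    """One metrics row per shot count k, fixed seed, deterministic with a
    deterministic backend."""
    rows: list[MetricsRow] = []
    for k in k_values:
        strategy = PromptStrategy(mode="few_shot", k=k, seed=seed)
        decisions = run_filter(
            mentions, docs, None, strategy, backend,
            context_unit, context_size, fewshot_bank, definitions or {},
        )
        rows.append(
            _evaluate_run(
                decisions, gold, span_mode,
                {"mode": "few_shot", "k": k, "seed": seed,
                 "context_unit": context_unit, "context_size": context_size,
                 "backend_id": backend.backend_id},
            )
        )
    return rows


DOCUMENT_SIZE_SENTINEL = 0  # size 0 in a context sweep = whole document


def sweep_context(
    mentions: Sequence[Mention],
    docs: Sequence[Document],
    gold: GoldSet,
    backend: Backend,
    sizes: Sequence[int],
    strategy: PromptStrategy = PromptStrategy(),
    fewshot_bank: Sequence[FewShotExample] = (),
    span_mode: str = "overlap",
    definitions: Mapping[str, str] | None = None,
) -> list[MetricsRow]:
    """One metrics row per context size (word windows); the sentinel size
    0 requests a whole-document window."""
    rows: list[MetricsRow] = []
    for size in sizes:
        unit = "document" if size == DOCUMENT_SIZE_SENTINEL else "words"
        decisions = run_filter(
            mentions, docs, None, strategy, backend,
            unit, max(size, 1), fewshot_bank, definitions or {},
        )
        rows.append(
            _evaluate_run(
                decisions, gold, span_mode,
                {"mode": strategy.mode, "k": strategy.k,
                 "context_unit": unit, "context_size": size,
                 "backend_id": backend.backend_id},
            )
        )
    return rows


def metrics_table(rows: Iterable[MetricsRow]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in rows])


def write_metrics(rows: Iterable[MetricsRow], path: str | Path) -> None:
    metrics_table(rows).to_csv(path, index=False, float_format="%.6f")
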