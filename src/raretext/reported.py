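"""Published benchmark table for rare-disease identification systems.

Ships the mention-level precision/recall/F1 figures reported for a
dictionary baseline and several prompted language-model filters on a
dual-annotated discharge-summary gold standard, as a small data table.
Used to cross-check the package's metric arithmetic (recomputing F1
from the printed precision and recall) and as a reference point in
examples.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .evaluation import f1_from_precision_recall, round_half_up


def load_reported_metrics() -> pd.DataFrame:
    """The published metrics table: system, mode, f1, precision, recall."""
    with resources.as_file(
        resources.files("raretext").joinpath("data", "reported_metrics.csv")
    ) as path:
        return pd.read_csv(path)


def recompute_f1_table(places: int = 4) -> pd.DataFrame:
    """Recompute F1 from the printed precision/recall of every row.

    Adds ``f1_recomputed`` (rounded half-up to ``places``) and
    ``f1_discrepancy`` = f1_recomputed − printed f1; under correct metric
    arithmetic the discrepancy is bounded by the printed rounding.
    """
    table = load_reported_metrics().copy()
    table["f1_recomputed"] = [
        round_half_up(f1_from_precision_recall(p, r), places)
        for p, r in zip(table["precision"], table["recall"])
    ]
    table["f1_discrepancy"] = table["f1_recomputed"] - table["f1"]
    return table
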