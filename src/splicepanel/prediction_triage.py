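"""Splice-prediction score triage and predictor-vs-RNA concordance.

Two predictor styles are handled as *inputs* (the tools themselves are never
run here):

* a percentage-scale predictor with a textual mechanism label, where the
  label "NTR" (nothing to report) means a negative call regardless of its
  small residual percentage;
* a four-delta predictor (acceptor gain/loss, donor gain/loss, each in
  [0, 1]) summarised by its maximum delta.

Variant-selection buckets follow the percentage thresholds used to triage
panel variants for RNA study: high > 50, moderate 20-50, negative < 20 (the
boundaries 20 and 50 fall in the moderate bucket).

The concordance cross-tab mirrors the published comparison layout: rows
positive-high / positive-low / negative / not-available, columns total /
partial / no splice effect.  A "complex" RNA outcome counts as a transcript
modification in the outcome marginals but is not credited to a predictor as a
validated splice effect in the high-confidence positive predictive value
(see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import pandas as pd

from .synthetic_data import VariantEvidence

__all__ = [
    "PredictionRecord",
    "spliceai_max",
    "bucket",
    "spip_row",
    "spliceai_row",
    "concordance",
    "high_confidence_ppv",
]

NTR_LABEL = "NTR"
ROWS = ("positive_high", "positive_low", "negative", "not_available")
COLUMNS = ("total_effect", "partial_effect", "no_effect")

_OUTCOME_COLUMN = {
    "total_event": "total_effect",
    "complex": "total_effect",  # a modified transcript, mechanism unresolved
    "partial_event": "partial_effect",
    "normal": "no_effect",
    "unknown": "no_effect",  # no demonstrated effect
}


@dataclass(frozen=True)
class PredictionRecord:
    """Predictor scores for one variant (either or both tools may be absent)."""

    spip_percent: Optional[float] = None
    spip_phrase: str = ""
    spliceai_deltas: Optional[tuple[float, float, float, float]] = None

    def __post_init__(self) -> None:
        if self.spip_percent is not None and not 0 <= self.spip_percent <= 100:
            raise ValueError("spip_percent must lie in [0, 100]")
        if self.spliceai_deltas is not None and not all(
            0 <= d <= 1 for d in self.spliceai_deltas
        ):
            raise ValueError("SpliceAI deltas must lie in [0, 1]")


def spliceai_max(record: PredictionRecord) -> Optional[float]:
    """Maximum of the four deltas; None when the deltas are unavailable."""
    if record.spliceai_deltas is None:
        return None
    return max(record.spliceai_deltas)


def bucket(score: Optional[float]) -> str:
    """Triage bucket for a 0-100 scale score (map deltas with x100 first)."""
    if score is None:
        return "not_available"
    if score > 50:
        return "high"
    if score >= 20:
        return "moderate"
    return "negative"


def _as_prediction(v) -> PredictionRecord:
    if isinstance(v, PredictionRecord):
        return v
    return PredictionRecord(
        spip_percent=v.spip_percent,
        spip_phrase=v.spip_phrase,
        spliceai_deltas=v.spliceai,
    )


def spip_row(v) -> str:
    """Concordance row for the percentage-scale predictor.

    The "NTR" label is a negative call regardless of its percentage; scored
    non-NTR predictions split at 50%.
    """
    r = _as_prediction(v)
    if r.spip_phrase.strip().upper() == NTR_LABEL:
        return "negative"
    if r.spip_percent is None:
        return "not_available"
    return "positive_high" if r.spip_percent > 50 else "positive_low"


def spliceai_row(v) -> str:
    """Concordance row for the delta predictor: >0.5 / 0.2-0.5 / <0.2 / NA."""
    m = spliceai_max(_as_prediction(v))
    if m is None:
        return "not_available"
    if m > 0.5:
        return "positive_high"
    if m >= 0.2:
        return "positive_low"
    return "negative"


def concordance(
    fixture: Iterable[VariantEvidence], tool: str = "spip"
) -> pd.DataFrame:
    """Cross-tabulate prediction rows against RNA outcome classes.

    Returns a 4x3 integer DataFrame (rows ``positive_high``, ``positive_low``,
    ``negative``, ``not_available``; columns ``total_effect``,
    ``partial_effect``, ``no_effect``).  Order-invariant in the input.
    """
    if tool not in ("spip", "spliceai"):
        raise ValueError("tool must be 'spip' or 'spliceai'")
    row_of = spip_row if tool == "spip" else spliceai_row
    table = pd.DataFrame(0, index=list(ROWS), columns=list(COLUMNS), dtype=int)
    for v in fixture:
        table.loc[row_of(v), _OUTCOME_COLUMN[v.rna_outcome]] += 1
    return table


def high_confidence_ppv(fixture: Sequence[VariantEvidence], tool: str = "spip") -> int:
    """Positive predictive value (percent, half-up integer) of high predictions.

    Numerator: high-bucket variants whose RNA outcome is a demonstrated total
    or partial splice event. Raises when the tool has no high-bucket variant.
    """
    row_of = spip_row if tool == "spip" else spliceai_row
    high = [v for v in fixture if row_of(v) == "positive_high"]
    if not high:
        raise ValueError(f"no high-confidence predictions for tool {tool!r}")
    hits = sum(1 for v in high if v.rna_outcome in ("total_event", "partial_event"))
    pct = Decimal(100 * hits) / Decimal(len(high))
    return int(pct.quantize(Decimal(1), rounding=ROUND_HALF_UP))
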