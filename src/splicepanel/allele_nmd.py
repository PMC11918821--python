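"""Allele-level effect estimates and nonsense-mediated-decay exclusion logic.

A junction fraction measures aberrant transcripts among *all* molecules; what
classification needs is the fraction of the *variant-carrying allele's*
molecules that are aberrant.  With balanced biallelic expression (the default
assumption, allele_balance = 0.5) a total heterozygous event shows up as a
junction fraction of 0.5, and a junction fraction f converts to
100 * f / allele_balance percent of the variant allele.

NMD can silently remove frameshift products, so "no aberrant transcript seen"
is only reassuring when a heterozygous exonic marker shows both alleles are
present in the RNA at a balanced ratio.  ``nmd_status`` encodes that logic;
``allelic_ratio`` measures the marker.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .synthetic_data import AlignmentRecord

__all__ = [
    "AlleleSummary",
    "AlleleEffect",
    "allelic_ratio",
    "percent_variant_allele",
    "grade_effect",
    "nmd_status",
]

DEFAULT_HET_MIN_READS = 10
DEFAULT_HET_MIN_FRACTION = 0.05
BALANCED_WINDOW = (0.3, 0.7)
TOTAL_EFFECT_THRESHOLD = 90.0  # percent of the variant allele


@dataclass(frozen=True)
class AlleleSummary:
    """Read support for the two alleles at a heterozygous exonic marker."""

    marker_present: bool
    ref_reads: int
    var_reads: int
    allelic_ratio: Optional[float]  # var / (ref + var)

    def balanced(self, window: tuple[float, float] = BALANCED_WINDOW) -> bool:
        return (
            self.allelic_ratio is not None
            and window[0] <= self.allelic_ratio <= window[1]
        )


@dataclass(frozen=True)
class AlleleEffect:
    """Variant-allele-level splicing effect."""

    percent_of_variant_allele: float
    effect_grade: str  # total / partial / none
    nmd_flag: str  # excluded / not_excluded / not_applicable


def allelic_ratio(
    reads: Iterable[AlignmentRecord],
    marker_position: int,
    het_min_reads: int = DEFAULT_HET_MIN_READS,
    het_min_fraction: float = DEFAULT_HET_MIN_FRACTION,
) -> AlleleSummary:
    """Count marker-informative reads and decide whether both alleles are seen.

    A read is informative when one of its aligned blocks covers the marker and
    the simulator (or upstream genotyper) recorded the base class it carries.
    The marker is called heterozygous-present when both classes reach
    ``het_min_reads`` reads and the minor fraction reaches
    ``het_min_fraction``.
    """
    ref = var = 0
    for read in reads:
        obs = read.marker_base_observed
        if obs is None:
            continue
        if not any(s <= marker_position <= e for s, e in read.blocks()):
            continue
        if obs == "ref":
            ref += 1
        elif obs == "var":
            var += 1
    total = ref + var
    ratio = var / total if total else None
    present = (
        ref >= het_min_reads
        and var >= het_min_reads
        and ratio is not None
        and min(ratio, 1 - ratio) >= het_min_fraction
    )
    return AlleleSummary(marker_present=present, ref_reads=ref, var_reads=var, allelic_ratio=ratio)


def percent_variant_allele(
    event_fraction: float,
    allele_balance: float = 0.5,
    aberrant_from_variant_only: bool = True,
) -> float:
    """Convert a junction fraction to percent of the variant-carrying allele.

    100 * event_fraction / allele_balance, capped at 100 (sampling noise can
    push the raw ratio past 1 when the event is total and
    ``aberrant_from_variant_only`` holds).
    """
    if not 0.0 <= event_fraction <= 1.0:
        raise ValueError("event_fraction must lie in [0, 1]")
    if allele_balance <= 0.0:
        raise ValueError("allele_balance must be positive to express a per-allele effect")
    pct = 100.0 * event_fraction / allele_balance
    if aberrant_from_variant_only:
        pct = min(pct, 100.0)
    return pct


def grade_effect(
    percent: float,
    has_event: bool,
    total_threshold: float = TOTAL_EFFECT_THRESHOLD,
) -> str:
    """``total`` at or above the threshold, ``partial`` below, ``none`` without a call."""
    if not has_event:
        return "none"
    return "total" if percent >= total_threshold else "partial"


def nmd_status(
    effect_grade: str,
    frame: str,
    marker: Optional[AlleleSummary],
    balanced_window: tuple[float, float] = BALANCED_WINDOW,
) -> str:
    """Can allele dropout through nonsense-mediated decay be excluded?

    * a total observed effect needs no exclusion (``not_applicable``);
    * a balanced heterozygous marker proves both alleles are represented in
      the RNA (``excluded``);
    * a skewed marker, or no marker with a normal result or a partial
      frameshift product, leaves silent decay possible (``not_excluded``);
    * a partial in-frame product is not an NMD substrate (``not_applicable``).
    """
    if effect_grade not in ("total", "partial", "none"):
        raise ValueError(f"unknown effect grade {effect_grade!r}")
    if frame not in ("in_frame", "frameshift", "unknown"):
        raise ValueError(f"unknown frame {frame!r}")
    if effect_grade == "total":
        return "not_applicable"
    if marker is not None and marker.marker_present:
        return "excluded" if marker.balanced(balanced_window) else "not_excluded"
    if effect_grade == "none":
        return "not_excluded"
    # partial event, no usable marker
    if frame == "in_frame":
        return "not_applicable"
    return "not_excluded"
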