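"""ACMG-AMP evidence combination with strength modifiers, and summary counts.

Evidence codes are the familiar ACMG-AMP identifiers (PVS1, PS3, PM2, PP3,
BP4, BP7, ...) optionally carrying a strength-modifier suffix as used in
splicing-focused applications of the framework: ``_S`` strong, ``_M``
moderate, ``_P`` supporting, ``_VS`` very strong, ``_NA`` not applicable
(the code is recorded but contributes nothing to the combination).

``combine`` implements the standard combining rules over the active codes:

Pathogenic (class 5)
    >=2 VS; or 1 VS with (>=1 S, or >=2 M, or 1 M + 1 P, or >=2 P);
    or >=2 S; or 1 S with (>=3 M, or 2 M + >=2 P, or 1 M + >=4 P).
Likely pathogenic (class 4)
    1 VS + 1 M; or 1 S + 1-2 M; or 1 S + >=2 P; or >=3 M; or 2 M + >=2 P;
    or 1 M + >=4 P.
Benign (class 1)
    stand-alone benign, or >=2 strong benign.
Likely benign (class 2)
    >=1 strong benign, or >=2 supporting benign.

Strong benign evidence overrides isolated moderate/supporting pathogenic
context codes (a rare-population code plus an in-silico code do not hold a
variant at VUS against a demonstrated-normal transcript).  If the remaining
pathogenic codes would reach class 4/5 on their own the evidence genuinely
conflicts and the variant stays a VUS; benign evidence coexisting with
strong-or-better pathogenic evidence raises an error (it never occurs in
practice here).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .allele_nmd import AlleleEffect
from .synthetic_data import DuplicationRecord, VariantEvidence

__all__ = [
    "EvidenceCode",
    "Classification",
    "ConflictError",
    "parse_code",
    "parse_criteria",
    "derive_rna_codes",
    "combine",
    "classify",
    "classify_duplication",
    "summarize",
]

STRENGTHS = ("stand_alone", "very_strong", "strong", "moderate", "supporting", "not_applicable")

_BASE_STRENGTH = {
    "PVS": ("pathogenic", "very_strong"),
    "PS": ("pathogenic", "strong"),
    "PM": ("pathogenic", "moderate"),
    "PP": ("pathogenic", "supporting"),
    "BA": ("benign", "stand_alone"),
    "BS": ("benign", "strong"),
    "BP": ("benign", "supporting"),
}

_SUFFIX = {
    "VS": "very_strong",
    "S": "strong",
    "M": "moderate",
    "P": "supporting",
    "NA": "not_applicable",
}


class ConflictError(ValueError):
    """Strong benign and strong-or-better pathogenic evidence on one variant."""


@dataclass(frozen=True)
class EvidenceCode:
    """One ACMG evidence code with its effective strength."""

    base: str  # e.g. "PVS1", "BP7"
    strength: str
    direction: str  # pathogenic / benign

    def __post_init__(self) -> None:
        if self.strength not in STRENGTHS:
            raise ValueError(f"unknown strength {self.strength!r}")
        if self.direction not in ("pathogenic", "benign"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def __str__(self) -> str:
        default = _BASE_STRENGTH[_family(self.base)][1]
        if self.strength == default:
            return self.base
        suffix = {v: k for k, v in _SUFFIX.items()}[self.strength]
        return f"{self.base}_{suffix}"


def _family(base: str) -> str:
    m = re.match(r"^(PVS|PS|PM|PP|BA|BS|BP)", base)
    if not m:
        raise ValueError(f"unrecognized evidence code family in {base!r}")
    return m.group(1)


def parse_code(text: str) -> EvidenceCode:
    """Parse e.g. ``PVS1``, ``PVS1_M``, ``BP7_S``, ``PM2``."""
    text = text.strip()
    m = re.match(r"^(?P<base>(?:PVS|PS|PM|PP|BA|BS|BP)\d*)(?:_(?P<suffix>VS|S|M|P|NA))?$", text)
    if not m:
        raise ValueError(f"unparseable ACMG code {text!r}")
    base = m.group("base")
    direction, default = _BASE_STRENGTH[_family(base)]
    strength = _SUFFIX[m.group("suffix")] if m.group("suffix") else default
    return EvidenceCode(base=base, strength=strength, direction=direction)


def parse_criteria(codes: Iterable[str]) -> list[EvidenceCode]:
    return [parse_code(c) for c in codes]


@dataclass(frozen=True)
class Classification:
    """A combined class with the audit trail of fired rules."""

    acmg_class: int
    codes: tuple[EvidenceCode, ...]
    rationale: tuple[str, ...]
    variant: Optional[VariantEvidence] = None


# --- RNA evidence -> codes --------------------------------------------------


def derive_rna_codes(
    effect: Optional[AlleleEffect],
    frame: str = "unknown",
    context: str | set[str] = "standard",
) -> list[EvidenceCode]:
    """Map an observed RNA result to PVS1/BP7 codes with strength modifiers.

    Decision table (``context`` may include ``monoallelic_assay_total`` when a
    minigene-style monoallelic assay showed the effect is total on the variant
    allele, and ``deep_intronic`` for variants found by transcript screening):

    ==========================  ==========================================
    normal, decay excluded      BP7 strong
    normal, decay not excluded  BP7 not-applicable (recorded, inert)
    total + frameshift          PVS1 very strong
    total + in-frame            PVS1 moderate
    total + unknown frame       PVS1 not-applicable
    partial                     PVS1 not-applicable, unless a monoallelic
                                assay shows a total effect -> PVS1 strong
    complex / no effect object  no RNA code
    ==========================  ==========================================
    """
    if effect is None:
        return []
    ctx = {context} if isinstance(context, str) else set(context)
    grade = effect.effect_grade
    if grade == "none":
        if effect.nmd_flag == "excluded":
            return [EvidenceCode("BP7", "strong", "benign")]
        return [EvidenceCode("BP7", "not_applicable", "benign")]
    if grade == "total":
        if frame == "frameshift":
            return [EvidenceCode("PVS1", "very_strong", "pathogenic")]
        if frame == "in_frame":
            return [EvidenceCode("PVS1", "moderate", "pathogenic")]
        return [EvidenceCode("PVS1", "not_applicable", "pathogenic")]
    if grade == "partial":
        if "monoallelic_assay_total" in ctx:
            return [EvidenceCode("PVS1", "strong", "pathogenic")]
        return [EvidenceCode("PVS1", "not_applicable", "pathogenic")]
    raise ValueError(f"unknown effect grade {grade!r}")


# --- combining --------------------------------------------------------------


def _counts(codes: Sequence[EvidenceCode]) -> dict[str, int]:
    c = {k: 0 for k in ("vs", "s", "m", "p", "ba", "bs", "bp")}
    for code in codes:
        if code.strength == "not_applicable":
            continue
        if code.direction == "pathogenic":
            key = {"very_strong": "vs", "strong": "s", "moderate": "m", "supporting": "p"}[
                code.strength
            ]
        else:
            # benign strengths collapse to stand-alone / strong / supporting
            # tiers; an (unusual) moderate benign counts as supporting
            key = {
                "stand_alone": "ba",
                "very_strong": "bs",
                "strong": "bs",
                "moderate": "bp",
                "supporting": "bp",
            }[code.strength]
        c[key] += 1
    return c


def _pathogenic_tier(c: dict[str, int]) -> tuple[int, Optional[str]]:
    vs, s, m, p = c["vs"], c["s"], c["m"], c["p"]
    if vs >= 2:
        return 5, ">=2 very strong"
    if vs >= 1 and (s >= 1 or m >= 2 or (m >= 1 and p >= 1) or p >= 2):
        return 5, "very strong + corroboration"
    if s >= 2:
        return 5, ">=2 strong"
    if s == 1 and (m >= 3 or (m == 2 and p >= 2) or (m == 1 and p >= 4)):
        return 5, "strong + moderates/supportings"
    if vs >= 1 and m >= 1:
        return 4, "very strong + 1 moderate"
    if s == 1 and (1 <= m <= 2 or p >= 2):
        return 4, "strong + moderates or supportings"
    if m >= 3 or (m == 2 and p >= 2) or (m == 1 and p >= 4):
        return 4, "moderates + supportings"
    return 3, None


def _benign_tier(c: dict[str, int]) -> tuple[int, Optional[str]]:
    if c["ba"] >= 1 or c["bs"] >= 2:
        return 1, "stand-alone or >=2 strong benign"
    if c["bs"] >= 1 or c["bp"] >= 2:
        return 2, "strong benign or >=2 supporting benign"
    return 3, None


def combine(codes: Sequence[EvidenceCode | str]) -> int:
    """Combine evidence codes into the 1-5 class (see module docstring)."""
    return classify(codes).acmg_class


def classify(
    codes: Sequence[EvidenceCode | str], variant: Optional[VariantEvidence] = None
) -> Classification:
    """Like :func:`combine` but returns the audit trail as well."""
    parsed = tuple(parse_code(c) if isinstance(c, str) else c for c in codes)
    c = _counts(parsed)
    rationale: list[str] = []
    b_class, b_rule = _benign_tier(c)
    p_class, p_rule = _pathogenic_tier(c)
    if b_class < 3:
        if c["vs"] or c["s"]:
            raise ConflictError(
                "benign evidence coexists with strong-or-better pathogenic evidence"
            )
        if p_class > 3:
            rationale.append(
                f"conflicting evidence: benign ({b_rule}) vs pathogenic ({p_rule}) -> VUS"
            )
            return Classification(3, parsed, tuple(rationale), variant)
        rationale.append(f"benign: {b_rule}")
        if c["m"] or c["p"]:
            rationale.append("benign evidence overrides isolated moderate/supporting codes")
        return Classification(b_class, parsed, tuple(rationale), variant)
    if p_class > 3:
        rationale.append(f"pathogenic: {p_rule}")
        return Classification(p_class, parsed, tuple(rationale), variant)
    rationale.append("insufficient evidence -> VUS")
    return Classification(3, parsed, tuple(rationale), variant)


# --- duplications and summaries ---------------------------------------------


def classify_duplication(record: DuplicationRecord, frame_disrupting: bool) -> int:
    """Class for a large duplication given transcript-level chimeric evidence.

    Chimeric back-junction reads prove the extra copy sits in tandem within
    the transcript; if the duplicated segment disrupts the reading frame the
    variant is pathogenic (5).  Without chimeric reads the arrangement is
    unproven and the variant stays a VUS (3) — as does a proven tandem
    duplication whose length change preserves the frame.
    """
    if not record.chimeric_reads:
        return 3
    return 5 if frame_disrupting else 3


def summarize(fixture: Sequence[VariantEvidence]) -> dict:
    """Recompute classes from each record's criteria and tally the cohort.

    Returns counts of transcript-modifying results (total, partial or complex
    outcomes), the per-class histogram of recomputed classes, the likely
    benign and pathogenic/likely pathogenic counts, and how many recomputed
    classes agree with the recorded ones.
    """
    classes = [combine(v.acmg_criteria) for v in fixture]
    hist = {k: 0 for k in (1, 2, 3, 4, 5)}
    for cl in classes:
        hist[cl] += 1
    effects = sum(
        1 for v in fixture if v.rna_outcome in ("total_event", "partial_event", "complex")
    )
    concordant = sum(1 for v, cl in zip(fixture, classes) if cl == v.assigned_class)
    return {
        "n": len(fixture),
        "rna_effect_count": effects,
        "no_effect_count": sum(1 for v in fixture if v.rna_outcome in ("normal", "unknown")),
        "class_histogram": hist,
        "class2_count": hist[2],
        "class45_count": hist[4] + hist[5],
        "concordant_with_recorded": concordant,
    }
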