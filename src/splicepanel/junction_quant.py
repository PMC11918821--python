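"""Junction counting, relative expression and aberrant-event typing.

The quantifier turns gapped alignments into a per-junction read-count matrix,
expresses every junction relative to the gene's natural (reference) junctions,
and calls typed aberrant events:

* ``exon_skip``        — both junction ends sit on natural exon boundaries
                         with at least one exon omitted between them;
* ``cryptic_donor`` /
  ``cryptic_acceptor`` — exactly one end is a novel coordinate;
* ``intron_retention`` — evidenced not by a junction but by gapless reads
                         crossing an exon-intron boundary;
* ``back_junction``    — acceptor at or 5' of the donor: the chimeric junction
                         diagnostic of a tandem exon duplication;
* ``complex``          — both ends novel.

Relative expression of a junction j is c(j) / (c(j) + r(j)), where r(j) is the
mean count of the natural junctions sharing j's donor or acceptor site (both,
averaged, for an exon-skipping junction; all natural junctions when neither
end is shared; the gene's other natural junctions when j itself is natural).
Under balanced sampling this makes a heterozygous total event read out at 0.5:
the value the equal-depth full-length / exon-skipped comparison rests on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import numpy as np

from .panel_model import RnaChange, TranscriptModel
from .synthetic_data import AlignmentRecord

__all__ = [
    "Junction",
    "JunctionCountMatrix",
    "SpliceEventCall",
    "count_junctions",
    "relative_expression",
    "detect_events",
    "event_to_rna_change",
    "matrix_to_frame",
    "calls_to_frame",
]

DEFAULT_MIN_READS = 10
DEFAULT_MIN_FRACTION = 0.05
DEFAULT_ANCHOR_MIN = 8


@dataclass(frozen=True, order=True)
class Junction:
    """A splice junction on the unspliced gene axis.

    ``donor`` is the last matched base before the gap, ``acceptor`` the first
    matched base after it.  ``acceptor <= donor`` marks a chimeric
    back-junction.
    """

    gene: str
    donor: int
    acceptor: int

    def __post_init__(self) -> None:
        if self.donor == self.acceptor:
            raise ValueError("junction donor and acceptor must differ")


@dataclass
class JunctionCountMatrix:
    """Per-junction gap counts plus unspliced boundary coverage for one sample."""

    sample_id: str
    gene: str
    counts: dict[Junction, int] = field(default_factory=dict)
    boundary_donor: dict[Junction, int] = field(default_factory=dict)
    boundary_acceptor: dict[Junction, int] = field(default_factory=dict)
    n_gap_observations: int = 0
    n_skipped_reads: int = 0

    def boundary_unspliced(self, j: Junction) -> float:
        """Mean gapless coverage of the two exon-intron boundaries of j's intron."""
        return 0.5 * (self.boundary_donor.get(j, 0) + self.boundary_acceptor.get(j, 0))


@dataclass(frozen=True)
class SpliceEventCall:
    """One typed aberrant splicing event with its quantification."""

    gene: str
    event_type: str
    junction: Junction
    relative_expression: float
    supporting_reads: int
    affected_exons: Optional[tuple[int, int]]
    rna_change: Optional[RnaChange]


def _natural_junctions(model: TranscriptModel) -> list[Junction]:
    return [
        Junction(model.gene.symbol, d, a) for d, a in model.natural_junctions()
    ]


def count_junctions(
    reads: Iterable[AlignmentRecord],
    model: TranscriptModel,
    sample_id: str = "sample",
    anchor_min: int = DEFAULT_ANCHOR_MIN,
) -> JunctionCountMatrix:
    """Build the junction read-count matrix for one gene.

    Every gap in every read contributes exactly one count to its
    (donor, acceptor) junction.  Gapless stretches that cross a natural
    exon-intron boundary with at least ``anchor_min`` matched bases on both
    sides increment that boundary's unspliced counter (the intron-retention
    signal).  Reads outside the gene axis are skipped and tallied.
    """
    gene = model.gene.symbol
    naturals = _natural_junctions(model)
    mat = JunctionCountMatrix(sample_id=sample_id, gene=gene)
    axis_end = model.axis_length
    for read in reads:
        blocks = read.blocks()
        if blocks[0][0] < 1 or max(e for _, e in blocks) > axis_end:
            mat.n_skipped_reads += 1
            continue
        for donor, acceptor in read.junctions():
            j = Junction(gene, donor, acceptor)
            mat.counts[j] = mat.counts.get(j, 0) + 1
            mat.n_gap_observations += 1
        for bs, be in blocks:
            for nj in naturals:
                # donor boundary: between nj.donor and nj.donor+1
                if bs <= nj.donor - anchor_min + 1 and be >= nj.donor + anchor_min:
                    mat.boundary_donor[nj] = mat.boundary_donor.get(nj, 0) + 1
                # acceptor boundary: between nj.acceptor-1 and nj.acceptor
                if bs <= nj.acceptor - anchor_min and be >= nj.acceptor + anchor_min - 1:
                    mat.boundary_acceptor[nj] = mat.boundary_acceptor.get(nj, 0) + 1
    return mat


def relative_expression(
    matrix: JunctionCountMatrix, model: TranscriptModel, j: Junction
) -> Optional[float]:
    """c(j) / (c(j) + r(j)); ``None`` when there is no coverage at all."""
    naturals = _natural_junctions(model)
    natural_set = set(naturals)
    c = matrix.counts.get(j, 0)
    if j in natural_set:
        others = [matrix.counts.get(n, 0) for n in naturals if n != j]
        r = float(np.mean(others)) if others else 0.0
    else:
        partners = [n for n in naturals if n.donor == j.donor or n.acceptor == j.acceptor]
        if not partners:
            partners = naturals
        r = float(np.mean([matrix.counts.get(n, 0) for n in partners])) if partners else 0.0
    if c == 0 and r == 0:
        return None
    return c / (c + r)


def _type_junction(
    model: TranscriptModel, j: Junction
) -> tuple[str, Optional[tuple[int, int]]]:
    end_of_exon = {model.exon_end(i): i for i in range(1, model.n_exons + 1)}
    start_of_exon = {model.exon_start(i): i for i in range(1, model.n_exons + 1)}
    if j.acceptor <= j.donor:
        d_ex = end_of_exon.get(j.donor, model.exon_containing(j.donor))
        a_ex = start_of_exon.get(j.acceptor, model.exon_containing(j.acceptor))
        affected = (a_ex, d_ex) if (a_ex and d_ex) else None
        return "back_junction", affected
    d_nat = j.donor in end_of_exon
    a_nat = j.acceptor in start_of_exon
    if d_nat and a_nat:
        a, b = end_of_exon[j.donor], start_of_exon[j.acceptor]
        if b > a + 1:
            return "exon_skip", (a + 1, b - 1)
        return "complex", None  # natural pairing would not reach here
    if d_nat:
        e = model.exon_containing(j.acceptor)
        return "cryptic_acceptor", (e, e) if e else None
    if a_nat:
        e = model.exon_containing(j.donor)
        return "cryptic_donor", (e, e) if e else None
    return "complex", None


def event_to_rna_change(
    model: TranscriptModel, junction_or_call: Union[Junction, "SpliceEventCall"]
) -> Optional[RnaChange]:
    """Transcript-space deletion implied by an aberrant forward junction.

    For a junction whose donor and acceptor both fall in exonic sequence, the
    omitted bases are exactly the exonic bases strictly between them; the
    result is reported as an r. deletion in c.-style numbering.  Junctions
    with an intronic end (retained intronic sequence), back-junctions and
    complex events have no pure-deletion description and return ``None``
    (rendered downstream as "r.?").
    """
    j = junction_or_call.junction if isinstance(junction_or_call, SpliceEventCall) else junction_or_call
    if j.acceptor <= j.donor:
        return None
    if model.exon_containing(j.donor) is None or model.exon_containing(j.acceptor) is None:
        return None
    t_donor = model.axis_to_transcript(j.donor)
    t_acceptor = model.axis_to_transcript(j.acceptor)
    if t_acceptor - t_donor <= 1:
        return None  # nothing omitted: the natural junction itself
    c_start = model.transcript_to_c(t_donor + 1)
    c_end = model.transcript_to_c(t_acceptor - 1)
    desc = f"r.{c_start}_{c_end}del"
    return RnaChange(kind="deletion", start=c_start, end=c_end, description=desc)


def detect_events(
    matrix: JunctionCountMatrix,
    model: TranscriptModel,
    min_reads: int = DEFAULT_MIN_READS,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> list[SpliceEventCall]:
    """Call abnormally expressed junctions and intron retention.

    A non-natural junction is called when it has at least ``min_reads``
    supporting gaps and relative expression at least ``min_fraction``.
    Intron retention is called from unspliced boundary coverage B of a natural
    junction: B >= min_reads and B / (B + c_natural) >= min_fraction.
    """
    if min_reads <= 0 or min_fraction <= 0:
        raise ValueError("thresholds must be positive")
    natural_set = set(_natural_junctions(model))
    calls: list[SpliceEventCall] = []
    for j in sorted(matrix.counts):
        if j in natural_set:
            continue
        c = matrix.counts[j]
        if c < min_reads:
            continue
        rel = relative_expression(matrix, model, j)
        if rel is None or rel < min_fraction:
            continue
        ev_type, affected = _type_junction(model, j)
        calls.append(
            SpliceEventCall(
                gene=matrix.gene,
                event_type=ev_type,
                junction=j,
                relative_expression=rel,
                supporting_reads=c,
                affected_exons=affected,
                rna_change=event_to_rna_change(model, j),
            )
        )
    for i, nj in enumerate(_natural_junctions(model), start=1):
        b = matrix.boundary_unspliced(nj)
        if b < min_reads:
            continue
        c_nat = matrix.counts.get(nj, 0)
        rel = b / (b + c_nat)
        if rel < min_fraction:
            continue
        calls.append(
            SpliceEventCall(
                gene=matrix.gene,
                event_type="intron_retention",
                junction=nj,
                relative_expression=rel,
                supporting_reads=int(round(b)),
                affected_exons=(i, i + 1),
                rna_change=None,
            )
        )
    calls.sort(key=lambda c: (c.junction.donor, c.junction.acceptor, c.event_type))
    return calls


# --- tabular export ---------------------------------------------------------


def matrix_to_frame(matrix: JunctionCountMatrix, model: TranscriptModel):
    """Junction matrix as a DataFrame (gene, donor, acceptor, count, natural, rel)."""
    import pandas as pd

    natural_set = set(_natural_junctions(model))
    rows = []
    for j in sorted(matrix.counts):
        rows.append(
            {
                "sample_id": matrix.sample_id,
                "gene": j.gene,
                "donor": j.donor,
                "acceptor": j.acceptor,
                "count": matrix.counts[j],
                "natural": j in natural_set,
                "relative_expression": relative_expression(matrix, model, j),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "gene", "donor", "acceptor", "count", "natural", "relative_expression",
        ],
    )


def calls_to_frame(calls: list[SpliceEventCall]):
    """Event calls as a DataFrame; RnaChange rendered as its r. description."""
    import pandas as pd

    rows = []
    for c in calls:
        rows.append(
            {
                "gene": c.gene,
                "event_type": c.event_type,
                "donor": c.junction.donor,
                "acceptor": c.junction.acceptor,
                "relative_expression": c.relative_expression,
                "supporting_reads": c.supporting_reads,
                "affected_exons": "-".join(map(str, c.affected_exons)) if c.affected_exons else "",
                "rna_change": c.rna_change.description if c.rna_change else "r.?",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "event_type", "donor", "acceptor", "relative_expression",
            "supporting_reads", "affected_exons", "rna_change",
        ],
    )
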