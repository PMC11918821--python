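"""SAM round-trip for simulated panel reads (via pysam).

Forward splices are written as ``M``/``N`` CIGAR operations against a
single-reference header (one gene per file, ``SN`` = gene symbol, ``LN`` =
unspliced axis length).  A chimeric back-junction read — the signature of a
tandem exon duplication — cannot be expressed with ``N`` (reference gaps only
run forward), so it is emitted the way a spliced aligner reports chimeras: a
primary line for the 5' piece and a supplementary line (flag 0x800) for the
piece that re-enters upstream sequence, sharing the query name.  The reader
re-pairs such lines into one :class:`~splicepanel.synthetic_data.AlignmentRecord`.

Simulation truth tags travel as optional fields: ``XA:Z`` allele of origin,
``XM:Z`` marker base class observed on the read.
"""

from __future__ import annotations

from typing import Iterable, Optional

import pysam

from .panel_model import TranscriptModel
from .synthetic_data import AlignmentRecord

__all__ = ["write_sam", "read_sam"]


def _split_parts(record: AlignmentRecord) -> list[tuple[int, list[tuple[int, int]]]]:
    """Split segments at negative gaps -> [(axis_start, forward_segments), ...]."""
    parts: list[tuple[int, list[tuple[int, int]]]] = []
    cur: list[tuple[int, int]] = []
    cur_start = record.start
    pos = record.start
    for match, gap in record.segments:
        donor = pos + match - 1
        if gap < 0:
            cur.append((match, 0))
            parts.append((cur_start, cur))
            cur = []
            cur_start = donor + gap + 1
        else:
            cur.append((match, gap))
        pos = pos + match + gap
    if cur:
        parts.append((cur_start, cur))
    return parts


def write_sam(reads: Iterable[AlignmentRecord], model: TranscriptModel, path: str) -> None:
    """Write reads for one gene as headered SAM text."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": model.gene.symbol, "LN": model.axis_length}],
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for record in reads:
            parts = _split_parts(record)
            for idx, (axis_start, segments) in enumerate(parts):
                a = pysam.AlignedSegment(out.header)
                a.query_name = record.read_id
                a.flag = 0 if idx == 0 else 0x800
                a.reference_id = 0
                a.reference_start = axis_start - 1
                a.mapping_quality = 60
                cigar = []
                for match, gap in segments:
                    cigar.append((0, match))  # M
                    if gap > 0:
                        cigar.append((3, gap))  # N
                a.cigartuples = cigar
                a.query_sequence = None
                tags = [("XA", record.allele)]
                if record.marker_base_observed is not None:
                    tags.append(("XM", record.marker_base_observed))
                a.set_tags(tags)
                out.write(a)


def _alignment_segments(a: pysam.AlignedSegment) -> tuple[int, list[tuple[int, int]]]:
    """(axis_start, [(match, gap), ...]) from an M/N/S CIGAR (S skipped)."""
    start = a.reference_start + 1
    segments: list[tuple[int, int]] = []
    match_run = 0
    for op, length in a.cigartuples or []:
        if op == 0:  # M
            match_run += length
        elif op == 3:  # N
            segments.append((match_run, length))
            match_run = 0
        elif op == 4:  # S — soft clip, consumes neither model axis nor matrix
            continue
        else:
            raise ValueError(
                f"unsupported CIGAR op {op} in read {a.query_name!r}; only M/N/S handled"
            )
    segments.append((match_run, 0))
    return start, segments


def read_sam(path: str) -> list[AlignmentRecord]:
    """Read a SAM file back into alignment records, re-pairing chimeric lines."""
    primaries: dict[str, tuple[int, list[tuple[int, int]], dict]] = {}
    supplementary: dict[str, tuple[int, list[tuple[int, int]]]] = {}
    order: list[str] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            start, segments = _alignment_segments(a)
            if a.is_supplementary:
                supplementary[a.query_name] = (start, segments)
            else:
                tags = dict(a.get_tags())
                primaries[a.query_name] = (start, segments, tags)
                order.append(a.query_name)
    records = []
    for name in order:
        start, segments, tags = primaries[name]
        if name in supplementary:
            sup_start, sup_segments = supplementary[name]
            pos = start
            for match, gap in segments:
                pos = pos + match + gap
            primary_end = pos - 1  # last gap is 0
            joined = segments[:-1] + [(segments[-1][0], sup_start - primary_end - 1)] + sup_segments
            segments = joined
        records.append(
            AlignmentRecord(
                read_id=name,
                start=start,
                segments=tuple(segments),
                allele=tags.get("XA", "unknown"),
                marker_base_observed=tags.get("XM"),
            )
        )
    return records
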