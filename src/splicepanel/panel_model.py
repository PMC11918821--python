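"""Transcript models for the 48-gene hereditary-cancer panel and HGVS arithmetic.

Everything here lives in transcript space: a gene is an ordered run of exons
and introns laid out 5'->3' on a single "unspliced axis" (1-based, inclusive).
Genomic coordinates and strand are deliberately not modelled; every quantity
the downstream pipeline needs (junction positions, r./c. coordinates, reading
frame, RT-PCR product sizes) is expressible on this axis.

Coordinate conventions
----------------------
* unspliced axis: base 1 is the first base of exon 1; introns occupy the gaps
  between exons.
* transcript (spliced) coordinates: 1-based over the concatenated exons.
* c./r. coordinates: HGVS-style coding numbering. c.1 is the first base of the
  CDS; 5'UTR bases are negative (no position 0). Intronic positions are
  expressed as an exonic anchor plus a signed offset (c.791-20 is 20 bases
  upstream of the acceptor of the exon that starts at c.791).

HGVS support is deliberately minimal: substitutions, del, dup, delins, ins,
intron offsets, negative 5'UTR bases, and the uncertainty notations "r.?"
and "r.=".  Anything else raises :class:`HgvsParseError` rather than guessing.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

__all__ = [
    "HgvsParseError",
    "UnsupportedChangeError",
    "GeneRecord",
    "TranscriptModel",
    "CodingPosition",
    "CdnaVariant",
    "RnaChange",
    "parse_hgvs_c",
    "parse_hgvs_r",
    "format_hgvs_c",
    "deleted_length",
    "frame_effect",
    "codons_overlapped",
    "predict_rtpcr_size",
    "read_panel_tsv",
    "read_transcript_models_tsv",
    "read_transcript_models_gtf",
    "load_panel_fixture",
    "load_transcript_models",
]


class HgvsParseError(ValueError):
    """Raised when an HGVS description cannot be parsed; names the bad token."""


class UnsupportedChangeError(ValueError):
    """Raised when an operation is asked about a change kind it cannot handle."""


@dataclass(frozen=True)
class GeneRecord:
    """One panel gene: symbol plus the versioned reference transcript."""

    symbol: str
    transcript_id: str

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("gene symbol must be nonempty")
        if not self.transcript_id:
            raise ValueError("transcript_id must be nonempty")


@dataclass(frozen=True)
class CodingPosition:
    """A c.-coordinate: exonic anchor base plus a signed intron offset.

    ``base`` may be negative for 5'UTR positions (e.g. c.-113); there is no
    position 0. ``intron_offset`` is 0 for exonic positions, +n for positions
    n bases downstream of a donor, -n for positions n bases upstream of an
    acceptor.
    """

    base: int
    intron_offset: int = 0

    def __post_init__(self) -> None:
        if self.base == 0:
            raise ValueError("c. coordinates have no position 0")

    def __str__(self) -> str:
        if self.intron_offset == 0:
            return str(self.base)
        return f"{self.base}{self.intron_offset:+d}"


@dataclass(frozen=True)
class CdnaVariant:
    """A parsed HGVS c. description.

    ``end`` is None for point descriptions.  The edit suffix (``del``, ``dup``,
    ``ins``, ``delins`` with optional inserted bases, or ``REF>ALT``) is
    captured verbatim but not interpreted here.
    """

    start: CodingPosition
    end: Optional[CodingPosition]
    edit: str

    @property
    def positions(self) -> Union[CodingPosition, tuple[CodingPosition, CodingPosition]]:
        if self.end is None:
            return self.start
        return (self.start, self.end)


_RNA_KINDS = ("deletion", "duplication", "substitution", "unknown")


@dataclass(frozen=True)
class RnaChange:
    """An observed RNA-level change in r. coordinates (c.-style numbering)."""

    kind: str
    start: int = 0
    end: int = 0
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _RNA_KINDS:
            raise ValueError(f"unknown RnaChange kind {self.kind!r}")
        if self.kind != "unknown" and self.start > self.end:
            raise ValueError("RnaChange start must be <= end")


# --- HGVS parsing -----------------------------------------------------------

_POS_RE = re.compile(r"(?P<base>-?\d+)(?P<off>[+-]\d+)?")
_EDIT_RE = re.compile(
    r"(?P<edit>delins[ACGTUN]*|del[ACGTUN]*|dup[ACGTUN]*|ins[ACGTUN\[\]?\d]+|[ACGTUN]>[ACGTUN])$"
)


def _parse_position(text: str) -> tuple[CodingPosition, str]:
    m = _POS_RE.match(text)
    if not m:
        raise HgvsParseError(f"expected a position at {text!r}")
    base = int(m.group("base"))
    off = int(m.group("off")) if m.group("off") else 0
    if base == 0:
        raise HgvsParseError(f"position 0 is not a valid c. coordinate in {text!r}")
    return CodingPosition(base, off), text[m.end():]


def parse_hgvs_c(text: str) -> CdnaVariant:
    """Parse a (minimal) HGVS c. description.

    >>> v = parse_hgvs_c("c.206+6T>G")
    >>> (v.start.base, v.start.intron_offset, v.edit)
    (206, 6, 'T>G')
    >>> v = parse_hgvs_c("c.791-489_791-20del")
    >>> (str(v.start), str(v.end))
    ('791-489', '791-20')
    """
    if not isinstance(text, str) or not text.startswith("c."):
        raise HgvsParseError(f"HGVS c. description must start with 'c.': {text!r}")
    body = text[2:]
    start, rest = _parse_position(body)
    end: Optional[CodingPosition] = None
    if rest.startswith("_"):
        end, rest = _parse_position(rest[1:])
    if rest:
        m = _EDIT_RE.match(rest)
        if not m:
            raise HgvsParseError(f"unrecognized edit suffix {rest!r} in {text!r}")
        edit = m.group("edit")
    else:
        edit = ""
    return CdnaVariant(start=start, end=end, edit=edit)


def format_hgvs_c(variant: CdnaVariant) -> str:
    """Canonical string for a parsed c. description (round-trips via parse)."""
    s = f"c.{variant.start}"
    if variant.end is not None:
        s += f"_{variant.end}"
    return s + variant.edit


_R_POINT_RE = re.compile(
    r"^r\.(?P<pos>-?\d+)(?P<sub>[ACGTUacgtu]>[ACGTUacgtu])?$"
)
_R_RANGE_RE = re.compile(
    r"^r\.(?P<start>-?\d+)_(?P<end>-?\d+)(?P<kind>del|dup)(?:ins[ACGTUacgtu]+)?$"
)


def parse_hgvs_r(text: str) -> RnaChange:
    """Parse an HGVS r. description into an :class:`RnaChange`.

    ``r.=`` (no change) and ``r.?`` (undetermined) map to kind ``unknown``.
    """
    if not isinstance(text, str) or not text.startswith("r."):
        raise HgvsParseError(f"HGVS r. description must start with 'r.': {text!r}")
    body = text.strip()
    if body in ("r.=", "r.?"):
        return RnaChange(kind="unknown", description=body)
    m = _R_RANGE_RE.match(body)
    if m:
        start, end = int(m.group("start")), int(m.group("end"))
        kind = "deletion" if m.group("kind") == "del" else "duplication"
        if start > end:
            raise HgvsParseError(f"range start > end in {text!r}")
        return RnaChange(kind=kind, start=start, end=end, description=body)
    m = _R_POINT_RE.match(body)
    if m:
        pos = int(m.group("pos"))
        if m.group("sub"):
            return RnaChange(kind="substitution", start=pos, end=pos, description=body)
        raise HgvsParseError(f"bare position without an edit in {text!r}")
    # single-position del/dup, e.g. r.100del
    m = re.match(r"^r\.(?P<pos>-?\d+)(?P<kind>del|dup)$", body)
    if m:
        pos = int(m.group("pos"))
        kind = "deletion" if m.group("kind") == "del" else "duplication"
        return RnaChange(kind=kind, start=pos, end=pos, description=body)
    raise HgvsParseError(f"unsupported r. description {text!r}")


# --- interval arithmetic ----------------------------------------------------


def deleted_length(change: RnaChange) -> int:
    """Number of nucleotides removed (deletion) or added (duplication).

    c./r. numbering has no position 0, so intervals that cross the CDS start
    (negative start, positive end) span one fewer base than plain end-start+1.
    """
    if change.kind not in ("deletion", "duplication"):
        raise UnsupportedChangeError(
            f"length is undefined for kind {change.kind!r} ({change.description!r})"
        )
    n = change.end - change.start + 1
    if change.start < 0 < change.end:
        n -= 1
    return n


def frame_effect(change: RnaChange) -> str:
    """``in_frame`` iff the removed/added length is a multiple of 3."""
    return "in_frame" if deleted_length(change) % 3 == 0 else "frameshift"


def codons_overlapped(c_start: int, c_end: int, cds_length: Optional[int] = None) -> int:
    """Number of codons touched by coding bases ``c_start..c_end`` inclusive.

    Codon k covers coding bases 3k-2..3k, so the count is
    ceil(end/3) - ceil(start/3) + 1.  UTR (non-positive) positions are
    rejected; positions beyond ``cds_length`` (when given) are rejected.
    """
    if c_start < 1 or c_end < c_start:
        raise ValueError("positions must satisfy 1 <= c_start <= c_end")
    if cds_length is not None and c_end > cds_length:
        raise ValueError(f"c.{c_end} lies beyond the CDS (length {cds_length})")
    return math.ceil(c_end / 3) - math.ceil(c_start / 3) + 1


def predict_rtpcr_size(reference_amplicon: int, change: RnaChange) -> int:
    """Expected RT-PCR product size after a deletion or duplication.

    The change must lie fully inside the amplified interval, so a deletion may
    not remove the whole amplicon.
    """
    n = deleted_length(change)
    if change.kind == "deletion":
        if n >= reference_amplicon:
            raise ValueError(
                f"deletion of {n} nt does not fit inside a {reference_amplicon} bp amplicon"
            )
        return reference_amplicon - n
    return reference_amplicon + n


# --- transcript structure ---------------------------------------------------


@dataclass
class TranscriptModel:
    """Exon/intron structure of one panel gene in transcript orientation.

    ``cds_start_offset`` is the 0-based offset of the first coding base within
    the concatenated exonic sequence; ``cds_length`` is a multiple of 3.
    """

    gene: GeneRecord
    exon_lengths: list[int]
    intron_lengths: list[int]
    cds_start_offset: int = 0
    cds_length: int = 0
    _exon_starts: list[int] = field(init=False, repr=False)
    _tx_starts: list[int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.exon_lengths:
            raise ValueError("at least one exon is required")
        if any(l <= 0 for l in self.exon_lengths):
            raise ValueError("exon lengths must be positive")
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need exactly one fewer intron than exons")
        if any(l <= 0 for l in self.intron_lengths):
            raise ValueError("intron lengths must be positive")
        if self.cds_length % 3 != 0:
            raise ValueError("cds_length must be a multiple of 3")
        if self.cds_start_offset + self.cds_length > sum(self.exon_lengths):
            raise ValueError("CDS extends beyond the spliced transcript")
        starts, pos = [], 1
        for i, el in enumerate(self.exon_lengths):
            starts.append(pos)
            pos += el
            if i < len(self.intron_lengths):
                pos += self.intron_lengths[i]
        self._exon_starts = starts
        tx_starts, t = [], 1
        for el in self.exon_lengths:
            tx_starts.append(t)
            t += el
        self._tx_starts = tx_starts

    # axis geometry ----------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exon_lengths)

    @property
    def axis_length(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)

    @property
    def spliced_length(self) -> int:
        return sum(self.exon_lengths)

    def exon_start(self, i: int) -> int:
        """Unspliced-axis start of exon ``i`` (1-based exon index)."""
        return self._exon_starts[i - 1]

    def exon_end(self, i: int) -> int:
        return self._exon_starts[i - 1] + self.exon_lengths[i - 1] - 1

    def natural_junctions(self) -> list[tuple[int, int]]:
        """(donor, acceptor) axis coordinates of the reference junctions."""
        return [
            (self.exon_end(i), self.exon_start(i + 1)) for i in range(1, self.n_exons)
        ]

    def exon_containing(self, axis_pos: int) -> Optional[int]:
        """1-based index of the exon containing ``axis_pos``; None if intronic."""
        for i in range(1, self.n_exons + 1):
            if self.exon_start(i) <= axis_pos <= self.exon_end(i):
                return i
        return None

    # coordinate conversions -------------------------------------------

    def axis_to_transcript(self, axis_pos: int) -> int:
        """Spliced (1-based) coordinate of an exonic axis position."""
        e = self.exon_containing(axis_pos)
        if e is None:
            raise ValueError(f"axis position {axis_pos} is intronic")
        return self._tx_starts[e - 1] + (axis_pos - self.exon_start(e))

    def transcript_to_axis(self, t: int) -> int:
        if not 1 <= t <= self.spliced_length:
            raise ValueError(f"transcript position {t} out of range")
        for i in range(self.n_exons - 1, -1, -1):
            if t >= self._tx_starts[i]:
                return self._exon_starts[i] + (t - self._tx_starts[i])
        raise AssertionError("unreachable")

    def transcript_to_c(self, t: int) -> int:
        """c.-style coordinate (no zero; 5'UTR negative) of spliced position t."""
        c = t - self.cds_start_offset
        return c if c >= 1 else c - 1

    def c_to_transcript(self, c: int) -> int:
        if c == 0:
            raise ValueError("c. coordinates have no position 0")
        t = c + self.cds_start_offset if c > 0 else c + self.cds_start_offset + 1
        if not 1 <= t <= self.spliced_length:
            raise ValueError(f"c.{c} falls outside the transcript")
        return t

    def exon_c_bounds(self, i: int) -> tuple[int, int]:
        """(first, last) c.-style coordinates of exon ``i``."""
        t0 = self._tx_starts[i - 1]
        return (self.transcript_to_c(t0), self.transcript_to_c(t0 + self.exon_lengths[i - 1] - 1))


# --- readers ----------------------------------------------------------------


def read_panel_tsv(path) -> list[GeneRecord]:
    """Read a panel table (columns ``symbol``, ``transcript_id``)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    records = [GeneRecord(r.symbol, r.transcript_id) for r in df.itertuples()]
    symbols = [g.symbol for g in records]
    if len(set(symbols)) != len(symbols):
        raise ValueError("panel gene symbols must be unique")
    return records


def read_transcript_models_tsv(path) -> dict[str, TranscriptModel]:
    """Read transcript models from a TSV.

    Expected columns: gene, transcript_id, exon_index, exon_length,
    intron_length_after (empty for the last exon), cds_start_offset,
    cds_length.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    models: dict[str, TranscriptModel] = {}
    for gene, grp in df.groupby("gene", sort=False):
        grp = grp.sort_values("exon_index")
        exons = [int(x) for x in grp["exon_length"]]
        introns = [int(x) for x in grp["intron_length_after"].iloc[:-1]]
        models[gene] = TranscriptModel(
            gene=GeneRecord(str(gene), str(grp["transcript_id"].iloc[0])),
            exon_lengths=exons,
            intron_lengths=introns,
            cds_start_offset=int(grp["cds_start_offset"].iloc[0]),
            cds_length=int(grp["cds_length"].iloc[0]),
        )
    return models


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_transcript_models_gtf(path_or_lines) -> dict[str, TranscriptModel]:
    """Read transcript models from a GTF-like file with ``exon`` features.

    The seqname column is the gene's unspliced axis; start/end are exon
    coordinates on that axis. Attributes must carry ``gene_id`` and
    ``transcript_id``; ``cds_start_offset`` and ``cds_length`` may appear on
    any exon line of the gene (last value wins).
    """
    if isinstance(path_or_lines, (str, Path)):
        with open(path_or_lines) as fh:
            lines = fh.read().splitlines()
    else:
        lines = list(path_or_lines)
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict[str, str]] = {}
    for line in lines:
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 9:
            raise ValueError(f"malformed GTF line: {line!r}")
        if fields[2] != "exon":
            continue
        attrs = dict(_GTF_ATTR_RE.findall(fields[8]))
        gene = attrs.get("gene_id") or fields[0]
        exons.setdefault(gene, []).append((int(fields[3]), int(fields[4])))
        meta.setdefault(gene, {}).update(attrs)
    models: dict[str, TranscriptModel] = {}
    for gene, blocks in exons.items():
        blocks.sort()
        exon_lengths = [e - s + 1 for s, e in blocks]
        intron_lengths = [blocks[i + 1][0] - blocks[i][1] - 1 for i in range(len(blocks) - 1)]
        attrs = meta[gene]
        models[gene] = TranscriptModel(
            gene=GeneRecord(gene, attrs.get("transcript_id", gene)),
            exon_lengths=exon_lengths,
            intron_lengths=intron_lengths,
            cds_start_offset=int(attrs.get("cds_start_offset", 0)),
            cds_length=int(attrs.get("cds_length", 0)),
        )
    return models


def _data_path(name: str):
    return resources.files("splicepanel.data").joinpath(name)


def load_panel_fixture() -> list[GeneRecord]:
    """The packaged 48-gene hereditary-cancer panel."""
    with resources.as_file(_data_path("panel_genes.tsv")) as p:
        return read_panel_tsv(p)


def load_transcript_models() -> dict[str, TranscriptModel]:
    """Packaged synthetic transcript models for the worked examples.

    Exon boundaries that carry published c. coordinates are exact; the
    remaining exon lengths and all intron lengths are invented stand-ins, and
    the BRCA2 entry models only the 5-exon capture window around its exon 3.
    """
    with resources.as_file(_data_path("transcript_models.tsv")) as p:
        return read_transcript_models_tsv(p)
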