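"""Simulated spliced alignments with known ground truth, plus packaged fixtures.

The generator emulates what a targeted blood-RNA panel sees around one gene:

* balanced biallelic transcription (``allele_balance`` is the fraction of
  transcript molecules from the variant-carrying allele, default 0.5);
* a per-molecule probability that a variant-allele transcript is aberrantly
  spliced (``per_allele_event_fraction``);
* one aberrant isoform per scenario — whole/partial exon skipping, cryptic
  donor/acceptor use, intron retention, or a tandem exon duplication whose
  transcripts carry a chimeric back-junction;
* optional nonsense-mediated decay, modelled as a uniform survival probability
  applied only to frameshift aberrant products;
* an optional heterozygous exonic marker variant: reads overlapping its
  position report which allele they came from, all other reads are
  uninformative, as in real data;
* gene-level depth differences (a poorly expressed gene is simply simulated at
  lower depth).

Reads are sampled per molecule: first the molecule's category (allele,
aberrant or not, NMD survival), then a uniform start on that isoform.  The
category weights carry a factor of (isoform length - read length + 1) so that
per-base coverage is proportional to molecule abundance, as fragmentation-based
library preparation produces; junction-fraction and marker-ratio estimators
are then unbiased.

Gapped alignments are encoded as ``(matched_length, gap_after)`` segments on
the gene's unspliced axis.  Gaps are intron-sized and nonnegative for forward
splices; a *negative* gap encodes the chimeric back-junction of a tandem
duplication (the read continues at an upstream coordinate), which the SAM
layer renders as a primary + supplementary split-read pair.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from io import BytesIO
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .panel_model import TranscriptModel

__all__ = [
    "ConfigurationError",
    "FixtureIntegrityError",
    "ScenarioConfig",
    "AlignmentRecord",
    "VariantEvidence",
    "DuplicationRecord",
    "EVENT_TYPES",
    "isoform_blocks",
    "isoform_junctions",
    "frame_delta",
    "simulate_reads",
    "simulate_tandem_duplication",
    "load_table2_fixture",
    "load_table4_fixture",
]


class ConfigurationError(ValueError):
    """Scenario parameters inconsistent with the transcript structure."""


class FixtureIntegrityError(RuntimeError):
    """A packaged fixture does not match its recorded checksum."""


EVENT_TYPES = (
    "none",
    "exon_skip",
    "partial_exon_skip",
    "cryptic_donor",
    "cryptic_acceptor",
    "intron_retention",
    "tandem_duplication",
)


@dataclass(frozen=True)
class AlignmentRecord:
    """One (possibly gapped) read on a gene's unspliced axis.

    ``segments`` is an ordered list of ``(matched_length, gap_after)``; the
    final gap is 0.  ``allele`` is the simulation truth tag; downstream
    estimators only use ``marker_base_observed`` ("ref"/"var"/None), which is
    set only when the read overlaps the configured marker position.
    """

    read_id: str
    start: int
    segments: tuple[tuple[int, int], ...]
    allele: str = "unknown"
    marker_base_observed: Optional[str] = None

    def blocks(self) -> list[tuple[int, int]]:
        """Aligned blocks as (start, end) axis intervals, 1-based inclusive."""
        out, pos = [], self.start
        for match, gap in self.segments:
            out.append((pos, pos + match - 1))
            pos = pos + match + gap
        return out

    def junctions(self) -> list[tuple[int, int]]:
        """(donor, acceptor) pairs implied by the gaps, in read order."""
        out, pos = [], self.start
        for match, gap in self.segments[:-1]:
            donor = pos + match - 1
            acceptor = pos + match + gap
            out.append((donor, acceptor))
            pos = acceptor
        return out

    @property
    def matched_length(self) -> int:
        return sum(m for m, _ in self.segments)


@dataclass
class ScenarioConfig:
    """Ground-truth description of one simulated sample.

    ``event_params`` is event-specific:

    ==================  ====================================================
    exon_skip           ``{"exons": (a, b)}`` or ``{"exons": a}``
    partial_exon_skip   ``{"exons": (a, b), "extra_acceptor_bases": m}`` —
                        skip exons a..b plus the first m bases of exon b+1
    cryptic_donor       ``{"exon": e, "shift": s}`` (s<0 truncates the exon
                        3' end by |s| nt; s>0 includes s intronic nt)
    cryptic_acceptor    ``{"exon": e, "shift": s}`` (s>0 truncates the exon
                        5' start by s nt; s<0 includes |s| intronic nt)
    intron_retention    ``{"intron": i}``
    tandem_duplication  ``{"exons": (j, k)}``
    ==================  ====================================================
    """

    transcript: TranscriptModel
    depth: int
    seed: int
    allele_balance: float = 0.5
    event: str = "none"
    event_params: Optional[dict] = None
    per_allele_event_fraction: float = 0.0
    nmd_survival: float = 1.0
    marker: Optional[int] = None
    read_length: int = 100

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ConfigurationError("depth must be positive")
        if self.read_length <= 0:
            raise ConfigurationError("read_length must be positive")
        for name in ("allele_balance", "per_allele_event_fraction", "nmd_survival"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.event not in EVENT_TYPES:
            raise ConfigurationError(f"unknown event {self.event!r}")
        if self.marker is not None and self.transcript.exon_containing(self.marker) is None:
            raise ConfigurationError(f"marker position {self.marker} is not exonic")
        # validate event parameters eagerly
        if self.event != "none":
            isoform_blocks(self.transcript, self.event, self.event_params or {})


# --- isoform geometry -------------------------------------------------------


def _exon_range(params: dict, key: str = "exons") -> tuple[int, int]:
    v = params.get(key)
    if v is None:
        raise ConfigurationError(f"event_params missing {key!r}")
    if isinstance(v, int):
        return (v, v)
    a, b = int(v[0]), int(v[1])
    if a > b:
        raise ConfigurationError(f"exon range {v!r} is reversed")
    return (a, b)


def isoform_blocks(
    model: TranscriptModel, event: str, params: Optional[dict] = None
) -> list[tuple[int, int]]:
    """Aligned blocks (axis intervals) of the isoform produced by ``event``.

    ``event == "none"`` returns the reference isoform (all exons).
    """
    params = params or {}
    exons = [(model.exon_start(i), model.exon_end(i)) for i in range(1, model.n_exons + 1)]
    if event == "none":
        return exons
    if event == "exon_skip":
        a, b = _exon_range(params)
        if not (1 <= a <= b <= model.n_exons) or (a == 1 and b == model.n_exons):
            raise ConfigurationError(f"cannot skip exons {a}..{b}")
        return exons[: a - 1] + exons[b:]
    if event == "partial_exon_skip":
        a, b = _exon_range(params)
        m = int(params.get("extra_acceptor_bases", 0))
        if not (1 <= a <= b < model.n_exons) or a == 1:
            raise ConfigurationError(f"cannot partially skip exons {a}..{b}")
        if not 0 < m < model.exon_lengths[b]:
            raise ConfigurationError("extra_acceptor_bases must be inside the next exon")
        nxt_s, nxt_e = exons[b]
        return exons[: a - 1] + [(nxt_s + m, nxt_e)] + exons[b + 1:]
    if event == "cryptic_donor":
        e = int(params.get("exon", 0))
        s = int(params.get("shift", 0))
        if not 1 <= e < model.n_exons or s == 0:
            raise ConfigurationError("cryptic_donor needs an internal exon and nonzero shift")
        es, ee = exons[e - 1]
        new_end = ee + s
        if not es <= new_end < model.exon_start(e + 1):
            raise ConfigurationError(f"donor shift {s} leaves exon/intron bounds")
        return exons[: e - 1] + [(es, new_end)] + exons[e:]
    if event == "cryptic_acceptor":
        e = int(params.get("exon", 0))
        s = int(params.get("shift", 0))
        if not 1 < e <= model.n_exons or s == 0:
            raise ConfigurationError("cryptic_acceptor needs a non-first exon and nonzero shift")
        es, ee = exons[e - 1]
        new_start = es + s
        if not model.exon_end(e - 1) < new_start <= ee:
            raise ConfigurationError(f"acceptor shift {s} leaves exon/intron bounds")
        return exons[: e - 1] + [(new_start, ee)] + exons[e:]
    if event == "intron_retention":
        i = int(params.get("intron", 0))
        if not 1 <= i < model.n_exons:
            raise ConfigurationError(f"no intron {i}")
        merged = (model.exon_start(i), model.exon_end(i + 1))
        return exons[: i - 1] + [merged] + exons[i + 1:]
    if event == "tandem_duplication":
        j, k = _exon_range(params)
        if not 1 <= j <= k <= model.n_exons:
            raise ConfigurationError(f"bad duplication range {j}..{k}")
        return exons[:k] + exons[j - 1:]
    raise ConfigurationError(f"unknown event {event!r}")


def isoform_junctions(blocks: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """(donor, acceptor) pairs between consecutive isoform blocks."""
    return [
        (blocks[i][1], blocks[i + 1][0]) for i in range(len(blocks) - 1)
    ]


def frame_delta(model: TranscriptModel, event: str, params: Optional[dict] = None) -> int:
    """Signed change in spliced length relative to the reference isoform."""
    blocks = isoform_blocks(model, event, params)
    return sum(e - s + 1 for s, e in blocks) - model.spliced_length


def _read_segments(
    blocks: Sequence[tuple[int, int]], iso_start: int, read_length: int
) -> tuple[int, tuple[tuple[int, int], ...]]:
    """Map a read starting at isoform coordinate ``iso_start`` to axis segments."""
    lens = [e - s + 1 for s, e in blocks]
    offsets = np.cumsum([0] + lens)
    remaining = read_length
    pos = iso_start - 1  # 0-based within isoform
    idx = int(np.searchsorted(offsets, pos, side="right")) - 1
    segments: list[tuple[int, int]] = []
    axis_start = None
    while remaining > 0:
        bs, be = blocks[idx]
        within = pos - offsets[idx]
        seg_start = bs + within
        take = min(remaining, lens[idx] - within)
        if axis_start is None:
            axis_start = seg_start
        if idx + 1 < len(blocks) and remaining > take:
            gap = blocks[idx + 1][0] - (seg_start + take - 1) - 1
        else:
            gap = 0
        segments.append((take, gap))
        remaining -= take
        pos += take
        idx += 1
    assert axis_start is not None
    return axis_start, tuple(segments)


# --- the simulator ----------------------------------------------------------


def simulate_reads(config: ScenarioConfig) -> list[AlignmentRecord]:
    """Draw spliced reads for one scenario.

    Identical configs (including ``seed``) produce identical read lists.
    Frameshift aberrant molecules are dropped with probability
    ``1 - nmd_survival``, so the returned list may be shorter than ``depth``.
    """
    model = config.transcript
    rng = np.random.default_rng(config.seed)
    R = config.read_length

    normal_blocks = isoform_blocks(model, "none")
    categories: list[tuple[str, list[tuple[int, int]], bool]] = []  # (allele, blocks, aberrant)
    weights: list[float] = []
    b = config.allele_balance
    p = config.per_allele_event_fraction if config.event != "none" else 0.0

    def _positions(blocks) -> int:
        n = sum(e - s + 1 for s, e in blocks) - R + 1
        if n < 1:
            raise ConfigurationError("read_length exceeds the isoform length")
        return n

    n_norm = _positions(normal_blocks)
    categories.append(("ref", normal_blocks, False))
    weights.append((1.0 - b) * n_norm)
    categories.append(("var", normal_blocks, False))
    weights.append(b * (1.0 - p) * n_norm)
    aberrant_frameshift = False
    if p > 0.0:
        ab_blocks = isoform_blocks(model, config.event, config.event_params or {})
        aberrant_frameshift = frame_delta(model, config.event, config.event_params or {}) % 3 != 0
        categories.append(("var", ab_blocks, True))
        weights.append(b * p * _positions(ab_blocks))

    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ConfigurationError("no transcript molecules to sample from")
    w = w / w.sum()

    cats = rng.choice(len(categories), size=config.depth, p=w)
    survival_draws = rng.random(config.depth)
    start_draws = rng.random(config.depth)

    reads: list[AlignmentRecord] = []
    for i in range(config.depth):
        allele, blocks, aberrant = categories[cats[i]]
        if (
            aberrant
            and aberrant_frameshift
            and config.nmd_survival < 1.0
            and survival_draws[i] >= config.nmd_survival
        ):
            continue  # degraded by NMD
        n_pos = _positions(blocks)
        iso_start = 1 + int(start_draws[i] * n_pos)
        axis_start, segments = _read_segments(blocks, iso_start, R)
        marker_obs = None
        if config.marker is not None:
            covered = any(s <= config.marker <= e for s, e in _segment_blocks(axis_start, segments))
            if covered:
                marker_obs = "var" if allele == "var" else "ref"
        reads.append(
            AlignmentRecord(
                read_id=f"read{i:06d}",
                start=axis_start,
                segments=segments,
                allele=allele,
                marker_base_observed=marker_obs,
            )
        )
    return reads


def _segment_blocks(start: int, segments) -> list[tuple[int, int]]:
    out, pos = [], start
    for match, gap in segments:
        out.append((pos, pos + match - 1))
        pos = pos + match + gap
    return out


def simulate_tandem_duplication(config: ScenarioConfig) -> list[AlignmentRecord]:
    """Simulate a tandem exon duplication scenario (back-junction reads)."""
    if config.event != "tandem_duplication":
        raise ConfigurationError("config.event must be 'tandem_duplication'")
    return simulate_reads(config)


# --- packaged evidence fixtures --------------------------------------------

RNA_OUTCOMES = ("normal", "total_event", "partial_event", "complex", "unknown")
NMD_EXCLUSION_STATES = ("het_marker_present", "no_het_marker", "not_applicable")


@dataclass(frozen=True)
class VariantEvidence:
    """One row of the packaged 53-variant evidence table."""

    gene: str
    hgvs_c: str
    hgvs_p: str
    spip_text: str
    spip_phrase: str
    spip_percent: Optional[float]
    spliceai: Optional[tuple[float, float, float, float]]  # AG, AL, DG, DL
    rna_outcome: str
    rna_detail: str
    other_evidence: str
    hgvs_r: str
    nmd_exclusion: str
    acmg_criteria: tuple[str, ...]
    assigned_class: int

    def __post_init__(self) -> None:
        if self.rna_outcome not in RNA_OUTCOMES:
            raise ValueError(f"bad rna_outcome {self.rna_outcome!r}")
        if self.nmd_exclusion not in NMD_EXCLUSION_STATES:
            raise ValueError(f"bad nmd_exclusion {self.nmd_exclusion!r}")
        if not 1 <= self.assigned_class <= 5:
            raise ValueError("assigned_class must be 1..5")
        if self.spliceai is not None and not all(0.0 <= d <= 1.0 for d in self.spliceai):
            raise ValueError("SpliceAI deltas must lie in [0, 1]")
        if self.spip_percent is not None and not 0.0 <= self.spip_percent <= 100.0:
            raise ValueError("SpIP percent must lie in [0, 100]")


@dataclass(frozen=True)
class DuplicationRecord:
    """One row of the packaged large-duplication table."""

    gene: str
    hgvs_c: str
    exons: tuple[int, int]
    chimeric_reads: bool
    assigned_class: int


_TABLE2_SHA256 = "1827f741d5c65bd27366afebf73915d660ee81f903bacaa4ae3f76b750f5d106"
_TABLE4_SHA256 = "747f3eea0b12807a33bad19f97b42c8f8362f69a70bd45ea108e1a55b57538f2"


def _verified_bytes(path, expected_sha256: Optional[str]) -> bytes:
    data = Path(path).read_bytes() if not hasattr(path, "read_bytes") else path.read_bytes()
    if expected_sha256 is not None:
        digest = hashlib.sha256(data).hexdigest()
        if digest != expected_sha256:
            raise FixtureIntegrityError(
                f"fixture checksum mismatch for {path}: {digest} != {expected_sha256}"
            )
    return data


def load_table2_fixture(path=None, *, verify: bool = True) -> list[VariantEvidence]:
    """Load the packaged 53-variant evidence table (checksum-verified)."""
    import pandas as pd

    if path is None:
        path = resources.files("splicepanel.data").joinpath("variant_table.tsv")
    data = _verified_bytes(path, _TABLE2_SHA256 if verify else None)
    df = pd.read_csv(BytesIO(data), sep="\t", dtype=str, keep_default_na=False)
    records = []
    for r in df.itertuples(index=False):
        spip_percent = float(r.spip_percent) if r.spip_percent not in ("", "NA") else None
        if r.spliceai_ag in ("", "NA"):
            spliceai = None
        else:
            spliceai = (
                float(r.spliceai_ag),
                float(r.spliceai_al),
                float(r.spliceai_dg),
                float(r.spliceai_dl),
            )
        records.append(
            VariantEvidence(
                gene=r.gene,
                hgvs_c=r.hgvs_c,
                hgvs_p=r.hgvs_p,
                spip_text=r.spip_text,
                spip_phrase=r.spip_phrase,
                spip_percent=spip_percent,
                spliceai=spliceai,
                rna_outcome=r.rna_outcome,
                rna_detail=r.rna_detail,
                other_evidence=r.other_evidence,
                hgvs_r=r.hgvs_r,
                nmd_exclusion=r.nmd_exclusion,
                acmg_criteria=tuple(c.strip() for c in r.acmg_criteria.split(",") if c.strip()),
                assigned_class=int(r.assigned_class),
            )
        )
    if len(records) != 53:
        raise FixtureIntegrityError(f"expected 53 variant records, found {len(records)}")
    return records


def load_table4_fixture(path=None, *, verify: bool = True) -> list[DuplicationRecord]:
    """Load the packaged large-duplication table (checksum-verified)."""
    import pandas as pd

    if path is None:
        path = resources.files("splicepanel.data").joinpath("duplication_table.tsv")
    data = _verified_bytes(path, _TABLE4_SHA256 if verify else None)
    df = pd.read_csv(BytesIO(data), sep="\t", dtype=str)
    records = []
    for r in df.itertuples(index=False):
        a, b = (int(x) for x in r.exons.split("-"))
        records.append(
            DuplicationRecord(
                gene=r.gene,
                hgvs_c=r.hgvs_c,
                exons=(a, b),
                chimeric_reads=r.chimeric_reads.strip().lower() == "yes",
                assigned_class=int(r.assigned_class),
            )
        )
    if len(records) != 4:
        raise FixtureIntegrityError(f"expected 4 duplication records, found {len(records)}")
    return records
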