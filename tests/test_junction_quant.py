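"""Junction counting, relative expression and event typing."""

import math

import pytest

from splicepanel.junction_quant import (
    Junction,
    JunctionCountMatrix,
    calls_to_frame,
    count_junctions,
    detect_events,
    event_to_rna_change,
    matrix_to_frame,
    relative_expression,
)
from splicepanel.panel_model import GeneRecord, TranscriptModel
from splicepanel.sam import read_sam, write_sam
from splicepanel.synthetic_data import (
    AlignmentRecord,
    ScenarioConfig,
    simulate_reads,
)


def _read(start, segments, read_id="r", allele="unknown"):
    return AlignmentRecord(read_id=read_id, start=start, segments=tuple(segments), allele=allele)


class TestCounting:
    def test_each_gap_counts_once(self, toy3_model):
        m = toy3_model
        d1, a1 = m.natural_junctions()[0]
        reads = [
            _read(d1 - 19, [(20, a1 - d1 - 1), (80, 0)], read_id=f"r{i}") for i in range(100)
        ]
        mat = count_junctions(reads, m)
        assert mat.counts[Junction("TOY3", d1, a1)] == 100
        assert mat.n_gap_observations == 100

    def test_two_gap_read_increments_both_junctions(self, toy3_model):
        m = toy3_model
        (d1, a1), (d2, a2) = m.natural_junctions()
        # read touching the last 10 bases of exon 1, all of exon 2, 10 of exon 3
        seg = [(10, a1 - d1 - 1), (m.exon_lengths[1], a2 - d2 - 1), (10, 0)]
        mat = count_junctions([_read(d1 - 9, seg)], m)
        assert mat.counts[Junction("TOY3", d1, a1)] == 1
        assert mat.counts[Junction("TOY3", d2, a2)] == 1
        assert mat.n_gap_observations == 2

    def test_count_conservation_on_simulated_data(self, pten_model):
        cfg = ScenarioConfig(
            transcript=pten_model, depth=4000, seed=23, event="exon_skip",
            event_params={"exons": (3, 4)}, per_allele_event_fraction=0.4,
        )
        reads = simulate_reads(cfg)
        total_gaps = sum(len(r.segments) - 1 for r in reads)
        mat = count_junctions(reads, pten_model)
        assert sum(mat.counts.values()) == mat.n_gap_observations == total_gaps

    def test_out_of_bounds_reads_skipped(self, toy3_model):
        mat = count_junctions([_read(10**6, [(100, 0)])], toy3_model)
        assert mat.n_skipped_reads == 1
        assert not mat.counts


class TestRelativeExpression:
    def _matrix_with(self, model, skip_count, natural_count):
        gene = model.gene.symbol
        mat = JunctionCountMatrix(sample_id="s", gene=gene)
        (d1, a1), (d2, a2) = model.natural_junctions()[:2]
        skip = Junction(gene, d1, model.exon_start(3))
        mat.counts[skip] = skip_count
        mat.counts[Junction(gene, d1, a1)] = natural_count
        mat.counts[Junction(gene, d2, a2)] = natural_count
        return mat, skip

    def test_equal_depths_read_out_at_half(self, toy3_model):
        mat, skip = self._matrix_with(toy3_model, 500, 500)
        assert relative_expression(mat, toy3_model, skip) == pytest.approx(0.5)

    def test_minor_isoform_fraction(self, toy3_model):
        mat, skip = self._matrix_with(toy3_model, 210, 790)
        assert relative_expression(mat, toy3_model, skip) == pytest.approx(0.21)

    def test_zero_count_is_zero(self, toy3_model):
        mat, skip = self._matrix_with(toy3_model, 0, 100)
        assert relative_expression(mat, toy3_model, skip) == 0.0

    def test_no_coverage_is_undefined(self, toy3_model):
        mat, skip = self._matrix_with(toy3_model, 0, 0)
        assert relative_expression(mat, toy3_model, skip) is None

    def test_shared_site_counts_are_averaged(self, toy4_model):
        # skip junction sharing donor with J1 (count 300) and acceptor with
        # J2 (count 100): reference is their mean, 200
        m = toy4_model
        gene = m.gene.symbol
        (d1, a1), (d2, a2), _ = m.natural_junctions()
        mat = JunctionCountMatrix(sample_id="s", gene=gene)
        mat.counts[Junction(gene, d1, a1)] = 300
        mat.counts[Junction(gene, d2, a2)] = 100
        skip = Junction(gene, d1, a2)
        mat.counts[skip] = 100
        assert relative_expression(mat, m, skip) == pytest.approx(100 / 300)


class TestEventDetectionAndTyping:
    def test_event_free_simulation_yields_no_calls(self, pten_model):
        for seed in (1, 2, 3):
            cfg = ScenarioConfig(transcript=pten_model, depth=10000, seed=seed)
            mat = count_junctions(simulate_reads(cfg), pten_model)
            assert detect_events(mat, pten_model) == []

    @pytest.mark.parametrize("fraction", [0.1, 0.25, 0.5])
    def test_skip_fraction_recovered(self, brca2_window_model, fraction):
        m = brca2_window_model
        cfg = ScenarioConfig(
            transcript=m, depth=10000, seed=31, event="exon_skip",
            event_params={"exons": 2}, allele_balance=1.0,
            per_allele_event_fraction=fraction,
        )
        mat = count_junctions(simulate_reads(cfg), m)
        calls = detect_events(mat, m)
        assert len(calls) == 1
        call = calls[0]
        n = call.supporting_reads / call.relative_expression
        se = math.sqrt(fraction * (1 - fraction) / n)
        assert abs(call.relative_expression - fraction) <= 3 * se

    def test_total_exon3_skip_call(self, pten_model):
        cfg = ScenarioConfig(
            transcript=pten_model, depth=10000, seed=5, event="exon_skip",
            event_params={"exons": 3}, per_allele_event_fraction=1.0,
        )
        mat = count_junctions(simulate_reads(cfg), pten_model)
        calls = detect_events(mat, pten_model)
        assert len(calls) == 1
        call = calls[0]
        assert call.event_type == "exon_skip"
        assert call.affected_exons == (3, 3)
        assert call.rna_change.description == "r.165_209del"

    def test_cryptic_donor_call(self, mlh1_model):
        # donor shifted 5 nt into exon 3: loses the last 5 exonic bases
        cfg = ScenarioConfig(
            transcript=mlh1_model, depth=10000, seed=9, event="cryptic_donor",
            event_params={"exon": 3, "shift": -5}, per_allele_event_fraction=1.0,
        )
        mat = count_junctions(simulate_reads(cfg), mlh1_model)
        calls = detect_events(mat, mlh1_model)
        assert [c.event_type for c in calls] == ["cryptic_donor"]
        assert calls[0].rna_change.description == "r.302_306del"

    def test_cryptic_acceptor_call(self, mlh1_model):
        cfg = ScenarioConfig(
            transcript=mlh1_model, depth=10000, seed=9, event="cryptic_acceptor",
            event_params={"exon": 5, "shift": 12}, per_allele_event_fraction=1.0,
        )
        mat = count_junctions(simulate_reads(cfg), mlh1_model)
        calls = detect_events(mat, mlh1_model)
        assert [c.event_type for c in calls] == ["cryptic_acceptor"]
        first_c, _ = mlh1_model.exon_c_bounds(5)
        assert calls[0].rna_change.description == f"r.{first_c}_{first_c + 11}del"

    def test_partial_exon_skip_types_as_cryptic_acceptor(self, brca2_window_model):
        # skip of exon 2 plus the first 4 bases of exon 3 (r.68_320del)
        m = brca2_window_model
        cfg = ScenarioConfig(
            transcript=m, depth=10000, seed=29, event="partial_exon_skip",
            event_params={"exons": (2, 2), "extra_acceptor_bases": 4},
            per_allele_event_fraction=1.0,
        )
        mat = count_junctions(simulate_reads(cfg), m)
        calls = detect_events(mat, m)
        assert [c.event_type for c in calls] == ["cryptic_acceptor"]
        assert calls[0].rna_change.description == "r.68_320del"

    def test_intron_retention_called_from_boundary_coverage(self, pten_model):
        cfg = ScenarioConfig(
            transcript=pten_model, depth=10000, seed=3, event="intron_retention",
            event_params={"intron": 2}, per_allele_event_fraction=1.0,
        )
        mat = count_junctions(simulate_reads(cfg), pten_model)
        calls = detect_events(mat, pten_model)
        retention = [c for c in calls if c.event_type == "intron_retention"]
        assert len(retention) == 1
        assert retention[0].affected_exons == (2, 3)
        assert retention[0].rna_change is None
        # roughly half the molecules retain the intron
        assert 0.3 <= retention[0].relative_expression <= 0.7

    def test_back_junction_called_for_tandem_duplication(self, msh2_model):
        cfg = ScenarioConfig(
            transcript=msh2_model, depth=8000, seed=19, event="tandem_duplication",
            event_params={"exons": (7, 7)}, per_allele_event_fraction=1.0,
        )
        mat = count_junctions(simulate_reads(cfg), msh2_model)
        calls = detect_events(mat, msh2_model)
        back = [c for c in calls if c.event_type == "back_junction"]
        assert len(back) == 1
        assert back[0].junction.donor == msh2_model.exon_end(7)
        assert back[0].junction.acceptor == msh2_model.exon_start(7)
        assert back[0].affected_exons == (7, 7)
        assert back[0].rna_change is None  # rendered as r.?

    def test_exon12_skip_rna_change_in_large_model(self):
        # model with exon 12 spanning c.6842-6937 (96 nt, in frame)
        exons = [67, 249, 109] + [802] * 8 + [96, 299]
        model = TranscriptModel(
            GeneRecord("BRCA2FULL", "BRCA2FULL.1"),
            exon_lengths=exons,
            intron_lengths=[200] * 12,
            cds_start_offset=0,
            cds_length=sum(exons),
        )
        assert model.exon_c_bounds(12) == (6842, 6937)
        j = Junction("BRCA2FULL", model.exon_end(11), model.exon_start(13))
        change = event_to_rna_change(model, j)
        assert change.description == "r.6842_6937del"

    def test_exon10_skip_rna_change(self, mlh1_model):
        j = Junction("MLH1", mlh1_model.exon_end(9), mlh1_model.exon_start(11))
        assert event_to_rna_change(mlh1_model, j).description == "r.791_884del"

    def test_intronic_end_has_no_deletion_description(self, mlh1_model):
        j = Junction("MLH1", mlh1_model.exon_end(3) + 30, mlh1_model.exon_start(4))
        assert event_to_rna_change(mlh1_model, j) is None


def _brute_force_calls(matrix, model, min_reads, min_fraction):
    """Independent enumerator: classify every observed junction by exhaustive
    comparison with the natural junction list."""
    naturals = model.natural_junctions()
    nat_set = set(naturals)
    donor_sites = {d for d, _ in naturals} | {model.exon_end(model.n_exons)}
    acceptor_sites = {a for _, a in naturals} | {model.exon_start(1)}
    end_exon = {model.exon_end(i): i for i in range(1, model.n_exons + 1)}
    start_exon = {model.exon_start(i): i for i in range(1, model.n_exons + 1)}
    out = []
    for j, c in matrix.counts.items():
        d, a = j.donor, j.acceptor
        if (d, a) in nat_set or c < min_reads:
            continue
        partners = [n for n in naturals if n[0] == d or n[1] == a] or naturals
        ref = sum(matrix.counts.get(Junction(model.gene.symbol, *n), 0) for n in partners) / len(partners)
        if c + ref == 0 or c / (c + ref) < min_fraction:
            continue
        if a <= d:
            kind = "back_junction"
        elif d in donor_sites and a in acceptor_sites and start_exon[a] - end_exon[d] > 1:
            kind = "exon_skip"
        elif d in donor_sites and a not in acceptor_sites:
            kind = "cryptic_acceptor"
        elif d not in donor_sites and a in acceptor_sites:
            kind = "cryptic_donor"
        else:
            kind = "complex"
        out.append(((d, a), kind))
    return sorted(out)


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("seed", [1, 7, 13, 29])
    @pytest.mark.parametrize(
        "event,params",
        [
            ("exon_skip", {"exons": 2}),
            ("exon_skip", {"exons": (2, 3)}),
            ("cryptic_donor", {"exon": 2, "shift": -6}),
            ("cryptic_acceptor", {"exon": 3, "shift": 9}),
            ("tandem_duplication", {"exons": (2, 3)}),
        ],
    )
    def test_detection_matches_enumerator_on_small_models(self, toy4_model, seed, event, params):
        cfg = ScenarioConfig(
            transcript=toy4_model, depth=200, seed=seed, event=event,
            event_params=params, per_allele_event_fraction=0.8, read_length=60,
        )
        mat = count_junctions(simulate_reads(cfg), toy4_model)
        min_reads, min_fraction = 5, 0.05
        calls = detect_events(mat, toy4_model, min_reads=min_reads, min_fraction=min_fraction)
        got = sorted(
            ((c.junction.donor, c.junction.acceptor), c.event_type)
            for c in calls
            if c.event_type != "intron_retention"
        )
        assert got == _brute_force_calls(mat, toy4_model, min_reads, min_fraction)


class TestSamRoundTrip:
    def test_roundtrip_preserves_records_and_counts(self, msh2_model, tmp_path):
        cfg = ScenarioConfig(
            transcript=msh2_model, depth=600, seed=37, event="tandem_duplication",
            event_params={"exons": (4, 5)}, per_allele_event_fraction=0.7,
            marker=msh2_model.exon_start(2) + 11,
        )
        reads = simulate_reads(cfg)
        path = str(tmp_path / "reads.sam")
        write_sam(reads, msh2_model, path)
        back = read_sam(path)
        assert len(back) == len(reads)
        for a, b in zip(reads, back):
            assert (a.read_id, a.start, a.segments) == (b.read_id, b.start, b.segments)
            assert (a.allele, a.marker_base_observed) == (b.allele, b.marker_base_observed)
        mat_a = count_junctions(reads, msh2_model)
        mat_b = count_junctions(back, msh2_model)
        assert mat_a.counts == mat_b.counts


class TestExports:
    def test_matrix_and_call_frames(self, pten_model):
        cfg = ScenarioConfig(
            transcript=pten_model, depth=3000, seed=41, event="exon_skip",
            event_params={"exons": 3}, per_allele_event_fraction=1.0,
        )
        mat = count_junctions(simulate_reads(cfg), pten_model)
        calls = detect_events(mat, pten_model)
        mdf = matrix_to_frame(mat, pten_model)
        assert mdf["count"].sum() == mat.n_gap_observations
        assert mdf["natural"].sum() == len(pten_model.natural_junctions())
        cdf = calls_to_frame(calls)
        assert list(cdf["rna_change"]) == ["r.165_209del"]
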