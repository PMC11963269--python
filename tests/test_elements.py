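"""Element reconstruction: flank windows, LTR pair search, TSD, builder."""

import numpy as np
import pytest

from prare.elements import (
    BuilderParams,
    build_elements,
    check_insertion_repeat,
    extract_flanks,
    find_ltr_pair,
)
from prare.io import GenomeRecord
from prare.rtsearch import RtHit, find_rt_hits
from prare.seqtools import random_dna, revcomp, stratified_positions, substitute_dna
from prare.synthetic import ElementSpec, plant_element


def _hit(genome_id, start, end, strand="+"):
    return RtHit(genome_id, start, end, strand, 0, "q", (end - start) // 3, 500.0, "")


class TestExtractFlanks:
    def test_window_arithmetic(self, rng):
        genome = GenomeRecord("c", random_dna(rng, 200_000))
        fw = extract_flanks(genome, _hit("c", 50_000, 50_477), 10_000)
        assert len(fw.seq) == 20_477
        assert not fw.left_truncated and not fw.right_truncated
        assert fw.rt_span == (10_000, 10_477)

    def test_truncated_left_flank(self, rng):
        genome = GenomeRecord("c", random_dna(rng, 50_000))
        fw = extract_flanks(genome, _hit("c", 2_000, 2_477), 10_000)
        assert fw.left_truncated and not fw.right_truncated
        assert fw.offset == 0 and fw.rt_span == (2_000, 2_477)

    def test_coordinate_roundtrip(self, rng):
        genome = GenomeRecord("c", random_dna(rng, 60_000))
        fw = extract_flanks(genome, _hit("c", 30_000, 30_480))
        for pos in (0, 123, 20_479):
            assert fw.to_window(fw.to_genome(pos)) == pos
        assert genome.seq[fw.to_genome(0) : fw.to_genome(len(fw.seq))] == fw.seq


class TestFindLtrPair:
    def _window_with_ltrs(self, rng, ltr_len=600, sub_positions=()):
        """Window [flank | LTR | spacer | RT | spacer | LTR' | flank] with
        junction bases chosen so the pair cannot extend beyond the LTRs."""
        ltr = random_dna(rng, ltr_len)
        ltr3 = substitute_dna(rng, ltr, sub_positions)
        # distinct junction characters break any extension of the exact repeat
        window = random_dna(rng, 1_999) + "A" + ltr + "C" + random_dna(rng, 2_999)
        rt = (len(window), len(window) + 480)
        window += (
            random_dna(rng, 480) + random_dna(rng, 1_999) + "G" + ltr3 + "T"
            + random_dna(rng, 1_499)
        )
        return window, rt, (2_000, 2_000 + ltr_len)

    def test_identical_pair_recovered_exactly(self, rng):
        window, rt, ltr5 = self._window_with_ltrs(rng)
        pair = find_ltr_pair(window, rt)
        assert pair is not None
        p5, p3 = pair
        assert p5 == ltr5
        assert window[p5[0] : p5[1]] == window[p3[0] : p3[1]]

    def test_diverged_pair_rejected_at_reference_min_ltr(self, rng):
        # 2 interior substitutions ~200 bp apart leave no exact repeat >= 315
        window, rt, _ = self._window_with_ltrs(rng, ltr_len=600, sub_positions=(200, 400))
        assert find_ltr_pair(window, rt, min_ltr=315) is None

    def test_no_repeat_returns_none(self, rng):
        window = random_dna(rng, 8_000)
        assert find_ltr_pair(window, (4_000, 4_480), min_ltr=100) is None

    def test_bad_bounds_raise(self, rng):
        with pytest.raises(ValueError):
            find_ltr_pair("ACGT" * 100, (100, 120), min_ltr=500, max_ltr=300)


class TestCheckInsertionRepeat:
    def test_planted_tsd_returned(self, rng, queries):
        genome = GenomeRecord("g", random_dna(rng, 30_000))
        spec = ElementSpec(ltr_length=400, internal_length=9_000,
                           rt_protein=queries[0].sequence)
        planted, truth = plant_element(genome, spec, 12_000, 3)
        tsd, edge = check_insertion_repeat(planted, truth.element_span)
        assert tsd == truth.tsd_sequence and not edge

    def test_mismatched_flanks_none(self):
        genome = GenomeRecord("g", "ACGTA" + "T" * 50 + "ACGTT")
        assert check_insertion_repeat(genome, (5, 55)) == (None, False)

    def test_contig_edge_flagged(self):
        genome = GenomeRecord("g", "A" * 100)
        tsd, edge = check_insertion_repeat(genome, (0, 50))
        assert tsd is None and edge


class TestBuildElements:
    @pytest.fixture(scope="class")
    def scenario_elements(self, small_scenario, queries):
        _, genomes, truths = small_scenario
        elements, rejections = [], []
        for g in genomes:
            hits = find_rt_hits(g, queries)
            els, rejs = build_elements(g, hits, BuilderParams())
            elements.extend(els)
            rejections.extend(rejs)
        return elements, rejections, truths

    def test_intact_elements_recovered_with_exact_boundaries(self, scenario_elements):
        elements, _, truths = scenario_elements
        truth_map = {
            (t.genome_id, tuple(t.element_span)): t
            for t in truths
            if t.kind in ("intact", "non_retand_rt")
        }
        spans = {(e.genome_id, tuple(e.element_span)) for e in elements}
        assert spans == set(truth_map)
        for e in elements:
            t = truth_map[(e.genome_id, tuple(e.element_span))]
            assert tuple(e.ltr5_span) == tuple(t.ltr5_span)
            assert tuple(e.ltr3_span) == tuple(t.ltr3_span)
            assert e.tsd_sequence == t.tsd_sequence

    def test_decoys_rejected(self, scenario_elements):
        _, rejections, truths = scenario_elements
        # diverged-LTR and truncated plantings must all fail the criteria
        bad = [t for t in truths if t.kind in ("diverged_ltr", "truncated")]
        assert len(rejections) == len(bad)
        assert {r.reason for r in rejections} <= {"no-ltr-pair", "no-tsd"}

    def test_invariants_hold_literally(self, scenario_elements, small_scenario):
        elements, _, _ = scenario_elements
        _, genomes, _ = small_scenario
        by_id = {g.id: g for g in genomes}
        for e in elements:
            g = by_id[e.genome_id].seq
            assert g[e.ltr5_span[0] : e.ltr5_span[1]] == g[e.ltr3_span[0] : e.ltr3_span[1]]
            assert g[e.element_span[0] - 5 : e.element_span[0]] == e.tsd_sequence
            assert g[e.element_span[1] : e.element_span[1] + 5] == e.tsd_sequence
            assert e.internal_span[0] <= e.rt_hit.start < e.rt_hit.end <= e.internal_span[1]
            assert e.ltr5_span[1] <= e.internal_span[0] and e.internal_span[1] <= e.ltr3_span[0]

    def test_order_independence(self, small_scenario, queries):
        _, genomes, _ = small_scenario
        g = genomes[0]
        hits = find_rt_hits(g, queries)
        a, _ = build_elements(g, hits)
        b, _ = build_elements(g, list(reversed(hits)))
        assert [e.element_id for e in a] == [e.element_id for e in b]

    def test_reverse_strand_twin_ltr(self, scenario_elements, small_scenario):
        elements, _, truths = scenario_elements
        _, genomes, _ = small_scenario
        strands = {
            (t.genome_id, tuple(t.element_span)): t.strand for t in truths
        }
        minus = [e for e in elements if strands[(e.genome_id, tuple(e.element_span))] == "-"]
        assert minus, "scenario should plant at least one reverse-strand element"
        for e in minus:
            assert e.rt_hit.strand == "-"
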