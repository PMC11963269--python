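"""ORF finding, domain scanning, POL-3'LTR delimitation, tandem arrays."""

import numpy as np
import pytest

from prare.annotation import (
    OrfAnnotation,
    annotate_element,
    classify_autonomy,
    delimit_pol_3ltr,
    find_orfs,
    find_tandem_arrays,
)
from prare.profiles import DomainHit, calibrate_profile_threshold, scan_domains
from prare.rtsearch import find_rt_hits
from prare.elements import BuilderParams, build_elements
from prare.seqtools import encode_protein, random_dna, random_protein, revcomp

from oracles import orf_scan_oracle, tandem_oracle


def _orf_dna(rng, protein):
    return "ATG" + encode_protein(rng, protein, stop=False) + "TAA"


class TestFindOrfs:
    def test_sense_orf_exact_span(self, rng):
        orf = _orf_dna(rng, random_protein(rng, 399))
        seq = random_dna(rng, 150) + "TAA" + orf + random_dna(rng, 150)
        found = find_orfs(seq, 600)
        assert [(o.start, o.end, o.strand) for o in found] == [(153, 153 + 1203, "+")]
        assert found[0].orientation == "sense" and not found[0].short

    def test_antisense_orf_reported_with_flipped_orientation(self, rng):
        orf = _orf_dna(rng, random_protein(rng, 399))
        seq = random_dna(rng, 150) + revcomp("TAA" + orf) + random_dna(rng, 150)
        found = find_orfs(seq, 600)
        assert len(found) == 1
        assert found[0].strand == "-" and found[0].orientation == "antisense"

    def test_no_atg_no_orfs(self):
        assert find_orfs("C" * 900, 600) == []

    def test_short_orf_rescued_only_with_trp28(self, rng, profiles):
        trp = profiles["TRP28"].consensus
        with_dom = _orf_dna(rng, random_protein(rng, 50) + trp + random_protein(rng, 50))
        without = _orf_dna(rng, random_protein(rng, 163))
        seq = (
            random_dna(rng, 90) + "TAA" + with_dom + random_dna(rng, 90)
            + "TAA" + without + random_dna(rng, 90)
        )
        plain = find_orfs(seq, 600)
        assert plain == []  # both ORFs are < 600 bp
        rescued = find_orfs(seq, 600, profiles)
        assert len(rescued) == 1
        assert rescued[0].short and "TRP28" in rescued[0].domain_names()

    def test_matches_bruteforce_oracle(self, rng):
        """Dual-route check against a literal codon-walking scan."""
        for _ in range(10):
            seq = random_dna(rng, 3_000)
            mine = {(o.start, o.end, o.strand) for o in find_orfs(seq, 90)}
            assert mine == orf_scan_oracle(seq, 90)


class TestScanDomains:
    def test_consensus_scores_maximally_at_offset(self, rng, profiles):
        p = profiles["GAG"]
        prot = random_protein(rng, 40) + p.consensus + random_protein(rng, 40)
        hits = p.scan(prot)
        assert len(hits) == 1 and hits[0].offset == 40
        assert hits[0].score == p.window_scores(prot).max()

    def test_shuffled_protein_below_threshold(self, profiles):
        rng = np.random.default_rng(99)
        prot = random_protein(rng, 600)
        assert scan_domains(prot, profiles.values()) == []

    def test_two_copies_two_hits(self, rng, profiles):
        p = profiles["TRP28"]
        prot = (
            random_protein(rng, 20) + p.consensus + random_protein(rng, 30)
            + p.consensus + random_protein(rng, 20)
        )
        hits = p.scan(prot)
        assert [h.offset for h in hits] == [20, 20 + len(p) + 30]

    def test_profile_wider_than_protein_no_hit(self, profiles):
        assert profiles["RT"].scan("MKV") == []

    def test_calibration_reproducible(self, profiles):
        t1 = calibrate_profile_threshold("ACDEFGHIKLMNPQRSTVWY" * 3, rng_seed=5)
        t2 = calibrate_profile_threshold("ACDEFGHIKLMNPQRSTVWY" * 3, rng_seed=5)
        assert t1 == t2


class TestDelimitPol3Ltr:
    def _orf(self, start, end, orientation="sense", domains=()):
        o = OrfAnnotation(start, end, "+", orientation, "M" * ((end - start) // 3 - 1))
        o.domain_hits = [DomainHit(d, 0, 10, 100.0) for d in domains]
        return o

    def test_distance_to_3ltr(self):
        orfs = [self._orf(100, 2_000, domains=("RT", "INT"))]
        assert delimit_pol_3ltr(orfs, 6_000) == (2_000, 6_000)

    def test_abutting_pol_orf_gives_zero(self):
        orfs = [self._orf(100, 6_000, domains=("RT",))]
        span = delimit_pol_3ltr(orfs, 6_000)
        assert span == (6_000, 6_000) and span[1] - span[0] == 0

    def test_two_orf_layout_measured_from_pol_only(self):
        orfs = [
            self._orf(100, 800, domains=("GAG",)),
            self._orf(900, 3_000, domains=("RT", "RH", "INT")),
            self._orf(3_200, 4_000, orientation="antisense", domains=("TRP28",)),
        ]
        assert delimit_pol_3ltr(orfs, 8_000) == (3_000, 8_000)

    def test_no_pol_domains_undefined(self):
        orfs = [self._orf(100, 800, domains=("GAG",))]
        assert delimit_pol_3ltr(orfs, 8_000) is None


class TestFindTandemArrays:
    def test_planted_array_exact(self, rng):
        s = random_dna(rng, 97) + "T" + "ACGTACGG" * 5 + "C" + random_dna(rng, 100)
        arrays = [a for a in find_tandem_arrays(s) if a.period == 8]
        assert [(a.start, a.end, a.copies) for a in arrays] == [(98, 138, 5)]

    def test_homopolymer_reported_once_as_period_one(self):
        s = "G" + "A" * 30 + "G"
        arrays = find_tandem_arrays(s, min_identity=1.0)
        best = max(arrays, key=lambda a: a.copies * a.period)
        assert (best.period, best.copies) == (1, 30)

    def test_min_copies_respected(self, rng):
        s = random_dna(rng, 50) + "ACGTTGCA" * 2 + random_dna(rng, 50)
        assert [a for a in find_tandem_arrays(s, min_identity=1.0) if a.period == 8] == []

    def test_bad_period_bounds(self):
        with pytest.raises(ValueError):
            find_tandem_arrays("ACGT", min_period=5, max_period=2)

    def test_matches_exhaustive_oracle(self, rng):
        """Dual-route check at 100% copy identity, periods <= 20."""
        for _ in range(10):
            s = random_dna(rng, 300)
            mine = [
                (a.start, a.end, a.period, a.copies)
                for a in find_tandem_arrays(s, max_period=20, min_identity=1.0)
            ]
            assert sorted(mine) == tandem_oracle(s, max_period=20)


class TestClassifyAutonomy:
    def _orfs(self, domains):
        o = OrfAnnotation(0, 900, "+", "sense", "M" * 299)
        o.domain_hits = [DomainHit(d, 0, 10, 100.0) for d in domains]
        return [o]

    def test_all_domains_complete(self):
        assert classify_autonomy(self._orfs(("GAG", "AP", "RT", "RH", "INT"))) == (
            "complete", frozenset()
        )

    def test_missing_gag(self):
        status, missing = classify_autonomy(self._orfs(("AP", "RT", "RH", "INT")))
        assert (status, missing) == ("defective", frozenset({"GAG"}))

    def test_missing_gag_and_ap(self):
        status, missing = classify_autonomy(self._orfs(("RT", "RH", "INT")))
        assert (status, missing) == ("defective", frozenset({"GAG", "AP"}))

    def test_antisense_domains_do_not_count(self):
        o = OrfAnnotation(0, 900, "-", "antisense", "M" * 299)
        o.domain_hits = [DomainHit(d, 0, 10, 100.0) for d in ("GAG", "AP", "RT", "RH", "INT")]
        assert classify_autonomy([o])[0] == "defective"


class TestAnnotateElement:
    @pytest.fixture(scope="class")
    def annotated(self, small_scenario, queries, profiles):
        _, genomes, truths = small_scenario
        g = genomes[0]
        hits = find_rt_hits(g, queries)
        elements, _ = build_elements(g, hits, BuilderParams())
        truth_by_span = {tuple(t.element_span): t for t in truths if t.genome_id == g.id}
        return [
            (e, annotate_element(g, e, profiles), truth_by_span[tuple(e.element_span)])
            for e in elements
            if truth_by_span[tuple(e.element_span)].kind == "intact"
        ]

    def test_planted_orfs_recovered_with_exact_spans(self, annotated):
        assert annotated
        for element, ann, truth in annotated:
            planted = {
                (f["start"], f["end"])
                for f in truth.features
                if f["type"] == "orf" and f["end"] - f["start"] >= 600
            }
            s, e = element.element_span
            found = {ann.to_genome_span((o.start, o.end)) for o in ann.orfs}
            assert planted <= found

    def test_planted_arrays_recovered(self, annotated):
        for element, ann, truth in annotated:
            planted = {
                (f["start"], f["end"], f["extra"]["period"], f["extra"]["copies"])
                for f in truth.features
                if f["type"] == "tandem_array"
            }
            found = {
                (*ann.to_genome_span((t.start, t.end)), t.period, t.copies)
                for t in ann.tandem_arrays
            }
            assert planted <= found

    def test_autonomy_and_layout(self, annotated):
        for element, ann, truth in annotated:
            assert ann.autonomy == "complete"
            assert ann.gag_pol_layout in ("one-ORF", "two-ORF")

    def test_pol_3ltr_matches_planted_geometry(self, annotated):
        for element, ann, truth in annotated:
            pol_orf_ends = [
                f["end"] if truth.strand == "+" else f["start"]
                for f in truth.features
                if f["type"] == "orf" and f["name"] in ("gag-pol", "pol")
            ]
            assert ann.pol_3ltr_span is not None
            # length equals distance from the pol ORF stop to the 3'LTR
            s, e = truth.element_span
            if truth.strand == "+":
                expected = truth.ltr3_span[0] - max(pol_orf_ends)
            else:
                expected = min(pol_orf_ends) - truth.ltr5_span[1]
            assert ann.pol_3ltr_length == expected
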