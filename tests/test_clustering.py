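"""Clustering, consensus sizes, the PRARE 2% filter and representatives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prare.clustering import (
    Cluster,
    cluster_ltrs,
    consensus_sizes,
    dna_identity,
    pick_representative,
    prare_filter,
)
from prare.seqtools import random_dna, substitute_dna


class _FakeElement:
    def __init__(self, ltr_size, internal_size):
        self.ltr_size = ltr_size
        self.internal_size = internal_size


class _FakeAnnotation:
    def __init__(self, orientations=("sense", "antisense"), domains=("RT",), arrays=0):
        from types import SimpleNamespace

        self.min_orf = 600
        self.orfs = [
            SimpleNamespace(
                orientation=o, start=0, end=900,
                domain_hits=[SimpleNamespace(name=d) for d in domains],
                domain_names=lambda d=domains: set(d),
            )
            for o in orientations
        ]
        self.tandem_arrays = [None] * arrays


def _cluster(members, rep=None):
    return Cluster("c1", rep or members[0], list(members))


class TestClusterLtrs:
    def test_identity_thresholds(self, rng):
        base = random_dna(rng, 100)
        near = substitute_dna(rng, base, range(5, 100, 20))  # 5 subs: 95% identity
        far = substitute_dna(rng, base, range(3, 93, 6))  # 15 subs: 85% identity
        assert dna_identity(base, near) == pytest.approx(0.95)
        assert len(cluster_ltrs({"a": base, "b": near}, 0.90)) == 1
        assert len(cluster_ltrs({"a": base, "b": far}, 0.90)) == 2

    def test_three_distinct_families_three_clusters(self, rng):
        fams = {f"f{i}": random_dna(rng, 400) for i in range(3)}
        seqs = {}
        for name, ltr in fams.items():
            for k in range(3):
                seqs[f"{name}_m{k}"] = substitute_dna(rng, ltr, range(k))
        clusters = cluster_ltrs(seqs, 0.90)
        assert len(clusters) == 3
        for cl in clusters:
            assert len({m.split("_")[0] for m in cl.member_ids}) == 1

    def test_exact_cutoff_groups_only_identical(self, rng):
        a = random_dna(rng, 200)
        b = substitute_dna(rng, a, [50])
        clusters = cluster_ltrs({"x": a, "y": a, "z": b}, 1.0)
        assert sorted(sorted(c.member_ids) for c in clusters) == [["x", "y"], ["z"]]

    def test_monotone_in_cutoff(self, rng):
        base = random_dna(rng, 300)
        seqs = {
            f"s{i}": substitute_dna(rng, base, range(0, 6 * i, 2)) for i in range(8)
        }
        counts = [
            len(cluster_ltrs(seqs, cutoff)) for cutoff in (0.80, 0.90, 0.95, 1.0)
        ]
        assert counts == sorted(counts)

    def test_input_order_irrelevant(self, rng):
        seqs = {f"s{i}": random_dna(rng, 150) for i in range(5)}
        a = cluster_ltrs(dict(sorted(seqs.items())), 0.9)
        b = cluster_ltrs(dict(sorted(seqs.items(), reverse=True)), 0.9)
        assert [sorted(c.member_ids) for c in a] == [sorted(c.member_ids) for c in b]

    def test_bad_cutoff(self):
        with pytest.raises(ValueError):
            cluster_ltrs({"a": "ACGT"}, 0.0)


class TestConsensusSizes:
    @pytest.mark.parametrize(
        "ltr_sizes,expected",
        [((500, 500, 500), 500), ((498, 500, 900), 500), ((500, 502), 500)],
    )
    def test_median_rules(self, ltr_sizes, expected):
        elements = {
            f"e{i}": _FakeElement(s, 10_000) for i, s in enumerate(ltr_sizes)
        }
        cl = _cluster(list(elements))
        assert consensus_sizes(cl, elements)[0] == expected

    def test_empty_cluster_raises(self):
        with pytest.raises(ValueError):
            consensus_sizes(Cluster("c", "x", []), {})


class TestPrareFilter:
    def test_threshold_boundaries(self):
        elements = {
            "consensus_a": _FakeElement(500, 10_000),
            "consensus_b": _FakeElement(500, 10_000),
            "consensus_c": _FakeElement(500, 10_000),
            "ok_509": _FakeElement(509, 10_000),      # deviation 0.018: retained
            "out_511": _FakeElement(511, 10_000),     # deviation 0.022: excluded
        }
        cl = _cluster(list(elements))
        ps = prare_filter(cl, elements)
        assert "ok_509" in ps.retained
        excluded = {m: dl for m, dl, _ in ps.excluded}
        assert excluded == pytest.approx({"out_511": 0.022})

    def test_both_criteria_required(self):
        elements = {
            "a": _FakeElement(500, 10_000),
            "b": _FakeElement(500, 10_000),
            "c": _FakeElement(500, 10_000),
            "ltr_ok_internal_bad": _FakeElement(505, 10_500),  # 0.01 / 0.05
        }
        cl = _cluster(list(elements))
        ps = prare_filter(cl, elements)
        assert ("ltr_ok_internal_bad", 0.01, 0.05) in [
            (m, round(dl, 6), round(di, 6)) for m, dl, di in ps.excluded
        ]

    @given(delta=st.integers(min_value=0, max_value=50))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_retained_deviations_never_exceed_tolerance(self, delta):
        elements = {
            "a": _FakeElement(500, 10_000),
            "b": _FakeElement(500, 10_000),
            "c": _FakeElement(500 + delta, 10_000),
        }
        cl = _cluster(list(elements))
        ps = prare_filter(cl, elements)
        for m in ps.retained:
            e = elements[m]
            assert abs(e.ltr_size - cl.consensus_ltr_size) / cl.consensus_ltr_size <= 0.02
            assert (
                abs(e.internal_size - cl.consensus_internal_size)
                / cl.consensus_internal_size
                <= 0.02
            )
        assert set(ps.retained) | {m for m, _, _ in ps.excluded} == set(cl.member_ids)

    def test_zero_consensus_raises(self):
        elements = {"a": _FakeElement(0, 0)}
        cl = _cluster(["a"])
        with pytest.raises(ValueError):
            prare_filter(cl, elements)


class TestPickRepresentative:
    def test_modal_structure_wins(self):
        elements = {f"e{i}": _FakeElement(500, 10_000) for i in range(10)}
        annotations = {f"e{i}": _FakeAnnotation() for i in range(8)}
        annotations["e8"] = _FakeAnnotation(orientations=("sense",))
        annotations["e9"] = _FakeAnnotation(orientations=("sense",))
        cl = _cluster(list(elements))
        rep = pick_representative(cl, annotations, elements)
        assert rep in {f"e{i}" for i in range(8)}
        assert rep == "e0"  # deterministic tie-break: smallest deviation then id

    def test_single_member(self):
        elements = {"only": _FakeElement(400, 9_000)}
        cl = _cluster(["only"])
        assert pick_representative(cl, {"only": _FakeAnnotation()}, elements) == "only"

    def test_member_order_invariance(self):
        elements = {f"e{i}": _FakeElement(500, 10_000) for i in range(6)}
        annotations = {k: _FakeAnnotation() for k in elements}
        a = pick_representative(_cluster(sorted(elements)), annotations, elements)
        b = pick_representative(
            _cluster(sorted(elements, reverse=True), rep="e0"), annotations, elements
        )
        assert a == b
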