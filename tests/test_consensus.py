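"""Retention rule, repeat similarity/clustering and candidate matching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crispr_cohort import (
    ValidationParams,
    cluster_repeats,
    match_candidates,
    plant_array,
    repeat_similarity,
    validate,
)
from crispr_cohort._seq import random_dna, revcomp
from crispr_cohort.consensus import (
    ConfigurationError,
    cas_loci_from_gff,
    candidate_classes,
)
from crispr_cohort.models import CandidateArray, CasLocus, GffFeature

# 33-mers at exact edit distance 6 and 7 from BASE (verified NW edit
# distance; reverse-complement orientation is strictly worse for both)
BASE = "GTGGTGATTGTAAATTTGACACTGCACGCCACT"
DIST6 = "GAGGAGATAGTCACTTTTACACTGCACGCCACT"
DIST7 = "GTGGTTAAAGTAACTTTGCCAGTGCACGCCACA"

dna = st.text(alphabet="ACGT", min_size=5, max_size=40)


class TestRepeatSimilarity:
    def test_identical_is_one_forward(self):
        sim, orient = repeat_similarity(BASE, BASE)
        assert sim == 1.0 and orient == "forward"

    def test_six_substitutions_just_above_threshold(self):
        sim, orient = repeat_similarity(BASE, DIST6)
        assert sim == pytest.approx(1 - 6 / 33)
        assert sim >= 0.8 and orient == "forward"

    def test_seven_substitutions_below_threshold(self):
        sim, _ = repeat_similarity(BASE, DIST7)
        assert sim == pytest.approx(1 - 7 / 33)
        assert sim < 0.8

    def test_revcomp_is_one(self):
        sim, orient = repeat_similarity(BASE, revcomp(BASE))
        assert sim == 1.0 and orient == "revcomp"

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            repeat_similarity("ACGT", "ACXT")

    @settings(deadline=None, max_examples=60)
    @given(dna, dna)
    def test_symmetric(self, a, b):
        assert repeat_similarity(a, b)[0] == pytest.approx(repeat_similarity(b, a)[0])


class TestClusterRepeats:
    def _items(self, seqs, samples=None):
        samples = samples or [f"s{i}" for i in range(len(seqs))]
        return [(seq, s, f"arr{i}") for i, (seq, s) in enumerate(zip(seqs, samples))]

    def test_three_identical_one_cluster(self):
        clusters = cluster_repeats(self._items([BASE, BASE, BASE]))
        assert len(clusters) == 1
        assert clusters[0].n_members == 3
        assert clusters[0].member_samples() == {"s0", "s1", "s2"}

    def test_dissimilar_pair_two_singletons(self):
        clusters = cluster_repeats(self._items([BASE, DIST7]), threshold=0.8)
        assert len(clusters) == 2
        assert all(c.n_members == 1 for c in clusters)

    def test_similar_pair_merged(self):
        clusters = cluster_repeats(self._items([BASE, DIST6]), threshold=0.8)
        assert len(clusters) == 1

    def test_revcomp_joins_cluster(self):
        clusters = cluster_repeats(self._items([BASE, revcomp(BASE)]))
        assert len(clusters) == 1

    def test_empty_input(self):
        assert cluster_repeats([]) == []

    def test_partition_exhaustive_disjoint_deterministic(self):
        rng = np.random.default_rng(3)
        seqs = [random_dna(rng, int(rng.integers(25, 40))) for _ in range(30)]
        items = self._items(seqs)
        c1 = cluster_repeats(items, 0.8)
        c2 = cluster_repeats(list(reversed(items)), 0.8)
        seen = [m for c in c1 for m in c.members]
        assert sorted(seen) == sorted(items)  # exhaustive and disjoint
        # input order must not matter
        assert sorted(frozenset(c.members) for c in c1) == sorted(
            frozenset(c.members) for c in c2
        )
        for c in c1:
            for seq, _, _ in c.members:
                assert repeat_similarity(c.seed_repeat, seq)[0] >= 0.8


def _cand(contig_id, start, end, detector="kmer", n_copies=4, repeat="G" * 30):
    copies = [repeat] * n_copies
    spacers = [random_dna(np.random.default_rng(start + i), 35) for i in range(n_copies - 1)]
    return CandidateArray(contig_id, start, end, repeat, copies, spacers, detector)


class TestMatchCandidates:
    def test_identical_intervals(self):
        a, b = _cand("c", 0, 100), _cand("c", 0, 100, "maxrep")
        assert match_candidates(a, b, 1.0)

    def test_disjoint_intervals(self):
        assert not match_candidates(_cand("c", 0, 100), _cand("c", 200, 300, "maxrep"))

    def test_partial_overlap_below_threshold(self):
        # [0,100) vs [60,160): overlap 40 < 0.5 * 100 on both sides
        a, b = _cand("c", 0, 100), _cand("c", 60, 160, "maxrep")
        assert not match_candidates(a, b, 0.5)
        assert match_candidates(a, b, 0.4)

    def test_different_contigs_never_match(self):
        assert not match_candidates(_cand("c1", 0, 100), _cand("c2", 0, 100, "maxrep"))

    def test_symmetric(self):
        a, b = _cand("c", 10, 300), _cand("c", 150, 400, "maxrep")
        for thr in (0.3, 0.5, 0.9):
            assert match_candidates(a, b, thr) == match_candidates(b, a, thr)


def _planted_candidates(seed=1):
    """A clean planted array detected as two coincident candidates."""
    rng = np.random.default_rng(seed)
    contig = random_dna(rng, 3000)
    repeat = random_dna(rng, 33)
    spacers = [random_dna(rng, 35) for _ in range(4)]
    contig, truth = plant_array(contig, repeat, spacers, 1200, 0.0, rng)
    s, e = truth["array_start"], truth["array_end"]
    a = CandidateArray("c1", s, e, repeat, truth["repeat_copies"], spacers, "kmer")
    b = CandidateArray("c1", s, e, repeat, truth["repeat_copies"], spacers, "maxrep")
    return contig, a, b


class TestValidate:
    LENGTHS = {"c1": 3500}

    def test_all_detectors_support(self):
        _, a, b = _planted_candidates()
        out = validate({"kmer": [a], "maxrep": [b]}, [], "s1", self.LENGTHS)
        assert len(out) == 1
        assert "all_detectors" in out[0].support
        assert out[0].supporting_detectors == {"kmer", "maxrep"}

    def test_unsupported_singleton_discarded(self):
        _, a, _ = _planted_candidates()
        out = validate({"kmer": [a], "maxrep": []}, [], "s1", self.LENGTHS)
        assert out == []

    def test_cas_within_window_retained(self):
        _, a, _ = _planted_candidates()
        cas = [CasLocus("c1", a.end + 300, a.end + 1200, ["cas1"])]
        out = validate({"kmer": [a], "maxrep": []}, cas, "s1", self.LENGTHS)
        assert len(out) == 1
        assert out[0].support == {"cas_adjacent"}

    def test_cas_outside_window_discarded(self):
        _, a, _ = _planted_candidates()
        cas = [CasLocus("c1", a.end + 1100, a.end + 2000, ["cas1"])]
        out = validate({"kmer": [a], "maxrep": []}, cas, "s1", self.LENGTHS)
        assert out == []

    def test_cluster_support_retained(self):
        from crispr_cohort.consensus import class_id_for
        from crispr_cohort.models import RepeatCluster

        _, a, _ = _planted_candidates()
        cid = class_id_for("s1", a)
        cluster = RepeatCluster(
            "DRC0001", a.repeat_consensus,
            [(a.repeat_consensus, "s1", cid), (a.repeat_consensus, "s2", "other")],
            0.8,
        )
        out = validate({"kmer": [a], "maxrep": []}, [], "s1", self.LENGTHS,
                       cluster_membership={cid: cluster})
        assert len(out) == 1
        assert out[0].support == {"repeat_cluster"}
        assert out[0].cluster_id == "DRC0001"

    def test_singleton_cluster_confers_no_support(self):
        from crispr_cohort.consensus import class_id_for
        from crispr_cohort.models import RepeatCluster

        _, a, _ = _planted_candidates()
        cid = class_id_for("s1", a)
        cluster = RepeatCluster("DRC0001", a.repeat_consensus,
                                [(a.repeat_consensus, "s1", cid)], 0.8)
        out = validate({"kmer": [a], "maxrep": []}, [], "s1", self.LENGTHS,
                       cluster_membership={cid: cluster})
        assert out == []

    def test_flank_fields_and_complete_flag(self):
        _, a, b = _planted_candidates()
        out = validate({"kmer": [a], "maxrep": [b]}, [], "s1", self.LENGTHS)
        v = out[0]
        assert v.left_flank == v.start
        assert v.right_flank == self.LENGTHS["c1"] - v.end
        assert v.complete == (v.left_flank >= 200 and v.right_flank >= 200)
        assert v.support  # non-empty by construction

    def test_monotone_in_cas_evidence(self):
        """Adding a cas locus never removes a validated array."""
        _, a, b = _planted_candidates()
        base = validate({"kmer": [a], "maxrep": [b]}, [], "s1", self.LENGTHS)
        more = validate({"kmer": [a], "maxrep": [b]},
                        [CasLocus("c1", a.end + 10, a.end + 900, ["cas2"])],
                        "s1", self.LENGTHS)
        kept = {(v.contig_id, v.start, v.end) for v in base}
        assert kept <= {(v.contig_id, v.start, v.end) for v in more}

    def test_no_detectors_is_error(self):
        with pytest.raises(ConfigurationError):
            validate({}, [], "s1", self.LENGTHS)


class TestCasLexicon:
    def test_gene_name_and_product_matched(self):
        feats = [
            GffFeature("c1", "x", "gene", 0, 900, "+", {"Name": "cas9"}),
            GffFeature("c1", "x", "CDS", 1000, 1900, "+",
                       {"product": "CRISPR-associated endonuclease"}),
            GffFeature("c1", "x", "gene", 2000, 2900, "+", {"Name": "gyrA"}),
            GffFeature("c1", "x", "region", 0, 5000, "+", {"Name": "cas1"}),
        ]
        loci = cas_loci_from_gff(feats)
        assert [(l.start, l.end) for l in loci] == [(0, 900), (1000, 1900)]


def test_candidate_classes_merge_across_detectors():
    _, a, b = _planted_candidates()
    classes = candidate_classes({"kmer": [a], "maxrep": [b]}, "s1")
    assert len(classes) == 1
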