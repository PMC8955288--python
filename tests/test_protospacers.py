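"""Protospacer search vs the exhaustive oracle; exclusion; fractions; lists."""

import numpy as np
import pandas as pd
import pytest

from crispr_cohort import (
    TargetIndex,
    apply_repeat_exclusion,
    compare_phage_lists,
    find_protospacers,
    plant_protospacer,
    protospacer_fraction,
)
from crispr_cohort._seq import random_dna, revcomp
from crispr_cohort.models import ProtospacerHit
from crispr_cohort.protospacers import records_containing

from conftest import bf_hamming_hits


def _hit_set(hits):
    return {(h.target_id, h.position, h.strand, h.mismatches) for h in hits}


class TestFindProtospacers:
    def test_verbatim_plant_found_plus_strand(self):
        rng = np.random.default_rng(0)
        spacer = random_dna(rng, 35)
        target = random_dna(rng, 8000)
        target, pos = plant_protospacer(target, spacer, 0, "+", rng)
        hits = find_protospacers(spacer, {"t": target}, 4)
        assert _hit_set(hits) == {("t", pos, "+", 0)}

    def test_distance_five_never_reported_at_four(self):
        rng = np.random.default_rng(1)
        spacer = random_dna(rng, 35)
        target = random_dna(rng, 8000)
        target, pos = plant_protospacer(target, spacer, 5, "+", rng)
        assert find_protospacers(spacer, {"t": target}, 4) == []
        # the same plant is found once the budget allows five
        assert _hit_set(find_protospacers(spacer, {"t": target}, 5)) == {
            ("t", pos, "+", 5)
        }

    def test_revcomp_plant_found_minus_strand(self):
        rng = np.random.default_rng(2)
        spacer = random_dna(rng, 34)
        target = random_dna(rng, 6000)
        target, pos = plant_protospacer(target, spacer, 2, "-", rng)
        hits = find_protospacers(spacer, {"t": target}, 4)
        assert _hit_set(hits) == {("t", pos, "-", 2)}

    def test_matches_exhaustive_oracle(self):
        """50 spacers vs 20 small records: identical hit sets to the
        all-window Hamming scan."""
        rng = np.random.default_rng(3)
        records = {f"r{i:02d}": random_dna(rng, 600) for i in range(20)}
        # plant a few guaranteed hits at assorted distances
        spacers = [random_dna(rng, int(rng.integers(32, 39))) for _ in range(50)]
        for i in (0, 5, 10, 15):
            rid = f"r{i % 20:02d}"
            records[rid], _ = plant_protospacer(
                records[rid], spacers[i], int(rng.integers(0, 5)),
                "+" if i % 2 else "-", rng,
            )
        index = TargetIndex(records)
        for spacer in spacers:
            mine = _hit_set(find_protospacers(spacer, index, 4))
            oracle = bf_hamming_hits(spacer, records, 4)
            assert mine == oracle

    def test_hits_sorted_by_record_and_position(self):
        rng = np.random.default_rng(4)
        spacer = random_dna(rng, 33)
        records = {}
        for rid in ("a", "b"):
            t = random_dna(rng, 5000)
            t, _ = plant_protospacer(t, spacer, 1, "+", rng, position=3000)
            t, _ = plant_protospacer(t, spacer, 1, "+", rng, position=500)
            records[rid] = t
        hits = find_protospacers(spacer, records, 4)
        keys = [(h.target_id, h.position) for h in hits]
        assert keys == sorted(keys)


class TestRepeatExclusion:
    def _setup(self):
        rng = np.random.default_rng(10)
        repeat = random_dna(rng, 33)
        spacer = random_dna(rng, 35)
        a = random_dna(rng, 6000)
        b = random_dna(rng, 6000)
        a, _ = plant_protospacer(a, spacer, 1, "+", rng)
        b, _ = plant_protospacer(b, spacer, 2, "+", rng)
        a, _ = plant_protospacer(a, repeat, 0, "+", rng, region=(4000, 6000))
        return {"A": a, "B": b}, repeat, spacer

    def test_record_with_repeat_excluded_others_kept(self):
        records, repeat, spacer = self._setup()
        hits = find_protospacers(spacer, records, 4)
        assert {h.target_id for h in hits} == {"A", "B"}
        apply_repeat_exclusion(hits, repeat, records, 4)
        by_record = {h.target_id: h.excluded for h in hits}
        assert by_record == {"A": True, "B": False}
        excluded = [h for h in hits if h.excluded]
        assert all(h.exclusion_reason == "repeat_in_target" for h in excluded)

    def test_no_repeat_in_target_keeps_hit(self):
        rng = np.random.default_rng(11)
        spacer, repeat = random_dna(rng, 35), random_dna(rng, 33)
        t = random_dna(rng, 5000)
        t, _ = plant_protospacer(t, spacer, 0, "+", rng)
        hits = find_protospacers(spacer, {"t": t}, 4)
        apply_repeat_exclusion(hits, repeat, {"t": t}, 4)
        assert not hits[0].excluded

    def test_flags_only_nothing_deleted(self):
        records, repeat, spacer = self._setup()
        hits = find_protospacers(spacer, records, 4)
        n = len(hits)
        out = apply_repeat_exclusion(hits, repeat, records, 4)
        assert len(out) == n

    def test_decoy_array_triggers_exclusion(self, small_bundle):
        """Every planted decoy's source repeat must mark its record as
        contaminated under the same <=4-mismatch criterion."""
        decoys = small_bundle.truth[small_bundle.truth.feature == "decoy_array"]
        assert len(decoys) >= 1
        index = TargetIndex(small_bundle.targets)
        for row in decoys.itertuples(index=False):
            assert row.seq_id in records_containing(row.repeat_seq, index, 4)


class TestFraction:
    def _hits(self, refs, excluded=()):
        return [
            ProtospacerHit(r, "t", "+", 0, 0, 35, excluded=r in excluded)
            for r in refs
        ]

    def test_three_of_ten(self):
        refs = [f"s:{i}" for i in range(10)]
        hits = self._hits(refs[:3])
        assert protospacer_fraction(refs, hits) == pytest.approx(30.0)

    def test_all_excluded_is_zero(self):
        refs = [f"s:{i}" for i in range(10)]
        hits = self._hits(refs[:3], excluded=set(refs[:3]))
        assert protospacer_fraction(refs, hits) == 0.0

    def test_multiple_hits_count_once(self):
        refs = ["s:0", "s:1"]
        hits = self._hits(["s:0"] * 10)
        assert protospacer_fraction(refs, hits) == pytest.approx(50.0)

    def test_zero_spacers_error(self):
        with pytest.raises(ValueError):
            protospacer_fraction([], [])

    def test_exclusion_is_antitone(self):
        """Excluding more records can never increase a fraction."""
        refs = [f"s:{i}" for i in range(8)]
        hits = self._hits(refs[:5])
        f0 = protospacer_fraction(refs, hits)
        for h in hits[:2]:
            h.excluded = True
        assert protospacer_fraction(refs, hits) <= f0


class TestComparePhageLists:
    META = pd.DataFrame(
        [
            {"record_id": r, "assembly_id": r, "taxon": r,
             "family": fam, "kind": "phage"}
            for r, fam in [("P1", "Siphoviridae"), ("P2", "Siphoviridae"),
                           ("P3", "Myoviridae"), ("P4", "Podoviridae")]
        ]
        + [{"record_id": "B1", "assembly_id": "B1", "taxon": "B1",
            "family": "", "kind": "bacterium"}]
    )

    def _hit(self, rid, n=1):
        return [ProtospacerHit(f"s:{i}", rid, "+", i, 0, 35) for i in range(n)]

    def test_intersection_set_arithmetic(self):
        by_group = {
            "case": self._hit("P1") + self._hit("P2") + self._hit("P3"),
            "control": self._hit("P2") + self._hit("P3") + self._hit("P4"),
        }
        plc = compare_phage_lists(by_group, self.META)
        assert plc.list_case == {"P1", "P2", "P3"}
        assert plc.intersection == {"P2", "P3"}

    def test_single_family_hundred_percent(self):
        by_group = {"case": self._hit("P1", 3), "control": self._hit("P2", 2)}
        plc = compare_phage_lists(by_group, self.META)
        assert plc.family_abundance_pct("case") == {"Siphoviridae": 100.0}
        assert plc.family_abundance_pct("control") == {"Siphoviridae": 100.0}

    def test_bacterial_hits_ignored(self):
        by_group = {"case": self._hit("B1", 5), "control": []}
        plc = compare_phage_lists(by_group, self.META)
        assert plc.list_case == set()

    def test_excluded_hits_ignored(self):
        hits = self._hit("P1", 3)
        for h in hits:
            h.excluded = True
        plc = compare_phage_lists({"case": hits, "control": []}, self.META)
        assert plc.list_case == set()

    def test_multi_protospacer_records_flagged(self):
        by_group = {"case": self._hit("P1", 5) + self._hit("P2", 4),
                    "control": self._hit("P1", 2)}
        plc = compare_phage_lists(by_group, self.META)
        assert plc.multi_protospacer_records == {"P1"}

    def test_family_counts_sum_to_unexcluded_hits(self):
        by_group = {"case": self._hit("P1", 3) + self._hit("P3", 2),
                    "control": self._hit("P4", 1)}
        plc = compare_phage_lists(by_group, self.META)
        assert sum(plc.family_counts["case"].values()) == 5
        assert sum(plc.family_counts["control"].values()) == 1


class TestPigeonholeSeeding:
    def test_seeding_never_loses_hits(self):
        """Randomized instances: the seeded search equals brute force."""
        rng = np.random.default_rng(77)
        for trial in range(60):
            L = int(rng.integers(30, 40))
            spacer = random_dna(rng, L)
            records = {"t": random_dna(rng, 800)}
            mm = int(rng.integers(0, 6))
            records["t"], _ = plant_protospacer(records["t"], spacer, mm,
                                                "+" if trial % 2 else "-", rng)
            for budget in (0, 2, 4):
                mine = _hit_set(find_protospacers(spacer, records, budget))
                assert mine == bf_hamming_hits(spacer, records, budget)
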