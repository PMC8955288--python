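"""Generator contracts: planted counts, truth completeness, determinism."""

import numpy as np
import pandas as pd
import pytest

from crispr_cohort import CohortConfig, generate_cohort, plant_array, plant_protospacer
from crispr_cohort._seq import hamming, random_dna, revcomp
from crispr_cohort.simulate import (
    ConfigurationError,
    GenerationError,
    _n_arrays,
    simulate_summary_frame,
)


class TestConfig:
    def test_inconsistent_range_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(spacer_length_range=(40, 30))

    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(truncated_fraction=1.5)

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(array_density_case=0.0)

    def test_mismatch_weights_validated(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(protospacer_mismatch_distribution=(1.0, 0.0))

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown"):
            CohortConfig.from_dict({"n_case": 3, "n_control": 3, "bogus": 1})


class TestPlantedCounts:
    def test_density_times_size_is_exact(self):
        # 500 arrays/Gb at 0.2 Gb -> exactly 100 planted arrays
        assert _n_arrays(500.0, 200_000_000) == 100

    def test_realized_cohort_count_matches_formula(self):
        cfg = CohortConfig(
            n_case=1, n_control=1, series_labels=("I",),
            assembly_size_per_sample=2_000_000, assembly_size_cv=0.0,
            array_density_case=5_000.0, array_density_control=6_000.0,
            repeat_mutation_rate=0.0, protospacer_planting_rate=0.0,
            decoy_array_in_target_rate=0.0, seed=5,
        )
        b = generate_cohort(cfg)
        per_sample = pd.Series([a.sample_id for a in b.arrays]).value_counts()
        assert per_sample["A01"] == round(5_000 * 2e6 / 1e9) == 10
        assert per_sample["C01"] == round(6_000 * 2e6 / 1e9) == 12

    def test_group_density_ratio_is_exact(self):
        # equal sizes, case 450/Gb vs control 500/Gb -> count ratio 0.9
        df = simulate_summary_frame(
            CohortConfig(
                n_case=10, n_control=10, series_labels=("I",),
                assembly_size_per_sample=100_000_000, assembly_size_cv=0.0,
                array_density_case=450.0, array_density_control=500.0,
                seed=1,
            )
        )
        case = df.loc[df.group == "case", "n_arrays"].sum()
        control = df.loc[df.group == "control", "n_arrays"].sum()
        assert case / control == pytest.approx(0.9)

    def test_total_contig_length_within_one_percent(self):
        cfg = CohortConfig(
            n_case=2, n_control=2, series_labels=("I",),
            assembly_size_per_sample=1_000_000, assembly_size_cv=0.0,
            array_density_case=5_000.0, array_density_control=5_000.0,
            protospacer_planting_rate=0.0, seed=9,
        )
        b = generate_cohort(cfg)
        for row in b.metadata.itertuples(index=False):
            assert abs(row.assembly_size_nt - 1_000_000) <= 0.01 * 1_000_000
        # and no contig below the assembly filter
        for contigs in b.contigs.values():
            assert min(len(s) for s in contigs.values()) >= 200


class TestDeterminism:
    def test_same_seed_same_bundle_bytes(self, tmp_path):
        cfg = dict(
            n_case=2, n_control=2, series_labels=("I",),
            assembly_size_per_sample=500_000, assembly_size_cv=0.1,
            array_density_case=8_000.0, array_density_control=8_000.0,
            n_phage_records=3, n_bacterial_records=2,
            phage_record_length=10_000, bacterial_record_length=40_000,
            prophage_island_length=15_000, protospacer_planting_rate=0.3,
            seed=77,
        )
        p1, p2 = tmp_path / "r1", tmp_path / "r2"
        generate_cohort(CohortConfig(**cfg), out_dir=p1)
        generate_cohort(CohortConfig(**cfg), out_dir=p2)
        files1 = sorted(f.relative_to(p1) for f in p1.rglob("*") if f.is_file())
        files2 = sorted(f.relative_to(p2) for f in p2.rglob("*") if f.is_file())
        assert files1 == files2
        for rel in files1:
            assert (p1 / rel).read_bytes() == (p2 / rel).read_bytes(), rel

    def test_different_seed_differs(self):
        base = dict(
            n_case=1, n_control=1, series_labels=("I",),
            assembly_size_per_sample=300_000, array_density_case=8_000.0,
            array_density_control=8_000.0, protospacer_planting_rate=0.0,
        )
        b1 = generate_cohort(CohortConfig(**base, seed=1))
        b2 = generate_cohort(CohortConfig(**base, seed=2))
        assert b1.contigs != b2.contigs


class TestPlantArray:
    def test_inserted_length_arithmetic(self):
        rng = np.random.default_rng(0)
        repeat = random_dna(rng, 33)
        spacers = [random_dna(rng, 35) for _ in range(5)]
        contig = random_dna(rng, 1000)
        new, truth = plant_array(contig, repeat, spacers, 400, 0.0, rng)
        assert truth["array_end"] - truth["array_start"] == 6 * 33 + 5 * 35 == 373
        assert len(new) == 1000 + 373

    def test_rate_zero_copies_identical(self):
        rng = np.random.default_rng(1)
        repeat = random_dna(rng, 30)
        spacers = [random_dna(rng, 34) for _ in range(3)]
        _, truth = plant_array(random_dna(rng, 500), repeat, spacers, 100, 0.0, rng)
        assert all(c == repeat for c in truth["repeat_copies"])

    def test_rate_one_every_base_differs(self):
        rng = np.random.default_rng(2)
        repeat = random_dna(rng, 25)
        spacers = [random_dna(rng, 30) for _ in range(2)]
        _, truth = plant_array(random_dna(rng, 500), repeat, spacers, 50, 1.0, rng)
        for copy in truth["repeat_copies"]:
            assert all(a != b for a, b in zip(copy, repeat))

    def test_duplicate_spacers_rejected(self):
        rng = np.random.default_rng(3)
        sp = random_dna(rng, 35)
        with pytest.raises(GenerationError, match="distinct"):
            plant_array(random_dna(rng, 500), random_dna(rng, 30), [sp, sp], 100, 0.0, rng)

    def test_planted_text_reconstructs(self):
        rng = np.random.default_rng(4)
        repeat = random_dna(rng, 36)
        spacers = [random_dna(rng, 33) for _ in range(4)]
        contig = random_dna(rng, 2000)
        new, truth = plant_array(contig, repeat, spacers, 900, 0.02, rng)
        text = "".join(
            c + (spacers[i] if i < len(spacers) else "")
            for i, c in enumerate(truth["repeat_copies"])
        )
        assert new[truth["array_start"] : truth["array_end"]] == text
        assert truth["left_flank"] == 900
        assert truth["right_flank"] == len(new) - truth["array_end"]


class TestPlantProtospacer:
    @pytest.mark.parametrize("n_mm", [0, 2, 5])
    def test_hamming_distance_is_exact(self, n_mm):
        rng = np.random.default_rng(10 + n_mm)
        spacer = random_dna(rng, 35)
        target = random_dna(rng, 5000)
        new, pos = plant_protospacer(target, spacer, n_mm, "+", rng)
        assert hamming(new[pos : pos + 35], spacer) == n_mm
        assert len(new) == len(target)  # replacement, not insertion

    def test_minus_strand_reads_as_spacer(self):
        rng = np.random.default_rng(20)
        spacer = random_dna(rng, 34)
        target = random_dna(rng, 3000)
        new, pos = plant_protospacer(target, spacer, 3, "-", rng)
        assert hamming(revcomp(new[pos : pos + 34]), spacer) == 3

    def test_too_many_mismatches_rejected(self):
        rng = np.random.default_rng(21)
        with pytest.raises(GenerationError):
            plant_protospacer(random_dna(rng, 100), "ACGTACGT", 9, "+", rng)


class TestTruthCompleteness:
    """Every truth row must correspond to real planted sequence, verified
    by direct string comparison at the recorded coordinates."""

    def test_arrays_reconstruct_at_coordinates(self, small_bundle):
        truth = small_bundle.truth
        arrays = truth[truth.feature == "array"]
        assert len(arrays) == len(small_bundle.arrays) > 50
        for a in small_bundle.arrays:
            seq = small_bundle.contigs[a.sample_id][a.contig_id]
            text = "".join(
                c + (a.spacer_seqs[i] if i < len(a.spacer_seqs) else "")
                for i, c in enumerate(a.repeat_copies)
            )
            assert seq[a.start : a.end] == text
            assert a.left_flank == a.start
            assert a.right_flank == len(seq) - a.end
            assert len(set(a.spacer_seqs)) == len(a.spacer_seqs)

    def test_protospacers_match_stated_distance(self, small_bundle):
        truth = small_bundle.truth
        spacer_by_ref = {}
        for a in small_bundle.arrays:
            for i, sp in enumerate(a.spacer_seqs):
                spacer_by_ref[f"{a.array_id}:{i}"] = sp
        protos = truth[truth.feature == "protospacer"]
        assert len(protos) > 20
        for row in protos.itertuples(index=False):
            spacer = spacer_by_ref[row.spacer_ref]
            window = small_bundle.targets[row.seq_id][int(row.start) : int(row.end)]
            read = window if row.strand == "+" else revcomp(window)
            assert hamming(read, spacer) == int(row.mismatches)

    def test_decoy_repeats_present_in_targets(self, small_bundle):
        decoys = small_bundle.truth[small_bundle.truth.feature == "decoy_array"]
        assert len(decoys) >= 1
        for row in decoys.itertuples(index=False):
            segment = small_bundle.targets[row.seq_id][int(row.start) : int(row.end)]
            assert segment.count(row.repeat_seq) == 4  # all decoy copies exact

    def test_islands_inside_records(self, small_bundle):
        for r in small_bundle.islands:
            assert 0 <= r.start < r.end <= len(small_bundle.targets[r.record_id])

    def test_cas_annotation_near_flagged_arrays(self, small_bundle):
        cas_by_contig = {}
        for f in small_bundle.cas_features:
            cas_by_contig.setdefault(f.seqid, []).append(f)
        flagged = [a for a in small_bundle.arrays if a.cas_adjacent]
        assert flagged
        for a in flagged:
            feats = cas_by_contig.get(a.contig_id, [])
            assert any(
                max(f.start - a.end, a.start - f.end, 0) <= 1000 for f in feats
            )


class TestSummaryFrame:
    def test_summary_matches_full_generator_counts(self):
        cfg = CohortConfig(
            n_case=2, n_control=2, series_labels=("I",),
            assembly_size_per_sample=1_000_000, assembly_size_cv=0.0,
            array_density_case=10_000.0, array_density_control=10_000.0,
            protospacer_planting_rate=0.0, seed=31,
        )
        df = simulate_summary_frame(cfg)
        assert (df.n_arrays == 10).all()
        assert (df.n_complete_arrays <= df.n_arrays).all()
        assert np.allclose(df.arrays_per_gb, df.n_arrays / df.assembly_size_gb)

    def test_spacer_count_floor_and_mean(self):
        cfg = CohortConfig(
            n_case=30, n_control=2, series_labels=("I",),
            assembly_size_per_sample=10_000_000, assembly_size_cv=0.0,
            array_density_case=5_000.0, array_density_control=5_000.0,
            spacers_per_array_case=9.0, spacers_per_array_control=9.0,
            truncated_fraction=0.0, seed=8,
        )
        df = simulate_summary_frame(cfg)
        per_array_mean = df.n_spacers.sum() / df.n_arrays.sum()
        assert per_array_mean == pytest.approx(9.0, rel=0.05)
        assert (df.spacers_per_complete_array >= 2).all()
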