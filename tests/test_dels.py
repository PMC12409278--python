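"""Mappability masking and fixed-deletion calling from depth tracks."""

import numpy as np
import pytest

from arctic_sweep import sim
from arctic_sweep.dels import (
    build_mappability,
    call_deletions,
    deletion_gene_overlap,
    mask_from_intervals,
    sum_depth,
)
from arctic_sweep.io import DepthTrackSet, IntervalSet, intersect


def random_sequence(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


def oracle_mappability_sites(reference, k=50, threshold=25):
    """Exhaustive per-site unmappability via a brute-force k-mer dictionary."""
    from collections import Counter

    counts = Counter()
    comp = str.maketrans("ACGT", "TGCA")
    for seq in reference.values():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            counts[kmer] += 1
            rc = kmer.translate(comp)[::-1]
            if rc != kmer:
                counts[rc] += 1
    out = {}
    for chrom, seq in reference.items():
        length = len(seq)
        unmappable = np.ones(length, dtype=bool)
        if length >= k:
            for pos in range(length):
                depth = 0
                for w in range(max(0, pos - k + 1), min(pos + 1, length - k + 1)):
                    if counts[seq[w : w + k]] == 1:
                        depth += 1
                unmappable[pos] = depth < threshold
        out[chrom] = unmappable
    return out


class TestMappability:
    def test_unique_sequence_masks_only_contig_edges(self):
        rng = np.random.default_rng(0)
        seq = random_sequence(rng, 3_000)
        mask = build_mappability({"chr1": seq}, merge_gap=0)
        got = mask.site_mask("chr1", 3_000)
        # interior sites are covered by 50 unique k-mers; only the edges,
        # where fewer windows overlap, fall below the depth threshold
        assert not got[100:-100].any()
        assert got[:24].all() and got[-24:].all()

    def test_tandem_duplication_is_unmappable(self):
        rng = np.random.default_rng(1)
        unique = random_sequence(rng, 2_000)
        repeat = random_sequence(rng, 1_000)
        seq = unique + repeat + repeat + random_sequence(rng, 2_000)
        mask = build_mappability({"chr1": seq}, merge_gap=0)
        got = mask.site_mask("chr1", len(seq))
        # interior of both repeat copies is unmappable (all 50-mers occur
        # twice); the copy1->copy2 junction k-mers equal the tract's own
        # start context and stay unique, so ~25 bp around 3000 stay mappable
        assert got[2_100:2_950].all()
        assert got[3_050:3_900].all()
        assert not got[500:1_500].any()

    def test_short_contig_wholly_unmappable(self):
        mask = build_mappability({"tiny": "ACGT" * 5})
        assert mask.site_mask("tiny", 20).all()

    def test_matches_exhaustive_kmer_oracle(self):
        rng = np.random.default_rng(2)
        core = random_sequence(rng, 4_000)
        repeat = random_sequence(rng, 300)
        # plant the repeat three times, plus a reverse-complement copy
        comp = str.maketrans("ACGT", "TGCA")
        rc = repeat.translate(comp)[::-1]
        seq = core[:1_000] + repeat + core[1_000:2_000] + repeat + core[2_000:3_000] + rc + core[3_000:]
        reference = {"chr1": seq, "chr2": random_sequence(rng, 1_500)}
        mask = build_mappability(reference, merge_gap=0)
        expected = oracle_mappability_sites(reference)
        for chrom, exp in expected.items():
            got = mask.site_mask(chrom, len(reference[chrom]))
            np.testing.assert_array_equal(got, exp)

    def test_mask_monotone_under_planted_repeat(self):
        """Replacing distant unique sequence with a copy of an existing tract
        can only grow the mask (outside the rewritten neighbourhood)."""
        rng = np.random.default_rng(3)
        core = random_sequence(rng, 3_000)
        tract = core[500:700]
        seq2 = core[:2_400] + tract + core[2_600:]  # same length, planted copy
        m1 = build_mappability({"chr1": core}, merge_gap=0)
        m2 = build_mappability({"chr1": seq2}, merge_gap=0)
        s1 = m1.site_mask("chr1", 3_000)
        s2 = m2.site_mask("chr1", 3_000)
        untouched = np.ones(3_000, dtype=bool)
        untouched[2_400 - 49 : 2_600 + 49] = False  # rewritten region ± k
        assert (s2[untouched] >= s1[untouched]).all()
        assert s2[530:670].all()  # the original tract's interior lost uniqueness


class TestSumDepth:
    def _tracks(self):
        depths = {
            "chr1": np.array([[2, 3, 0, 1], [3, 4, 0, 0], [5, 5, 0, 2]], dtype=np.int32)
        }
        return DepthTrackSet(
            depths=depths,
            genomes=["f0", "f1", "c0"],
            cohorts={"f0": "focal", "f1": "focal", "c0": "comparison"},
            mean_depths={"f0": 2.0, "f1": 2.0, "c0": 4.0},
        )

    def test_sums_are_per_cohort(self):
        sums = sum_depth(self._tracks())
        np.testing.assert_array_equal(sums["chr1"]["focal"], [5, 7, 0, 1])
        np.testing.assert_array_equal(sums["chr1"]["comparison"], [5, 5, 0, 2])

    def test_masked_sites_flagged(self):
        mask = mask_from_intervals(
            IntervalSet.from_records([("chr1", 1, 3, "")], kind="unmappable")
        )
        sums = sum_depth(self._tracks(), mask)
        np.testing.assert_array_equal(sums["chr1"]["masked"], [False, True, True, False])


class TestCallDeletions:
    def _cohort(self, length=200_000, deletions=(), seed=0, n_focal=12, n_comparison=6):
        spec = sim.CohortSpec(chrom_lengths={"chr1": length}, seed=seed)
        tracks, truth = sim.simulate_depth_tracks(
            spec,
            deletions=[("chr1", s, e) for s, e in deletions],
            mean_depth_per_genome={"focal": 15.0, "comparison": 12.0},
            n_focal=n_focal,
            n_comparison=n_comparison,
        )
        return tracks, truth

    def test_planted_deletions_recovered_with_window_resolution(self):
        planted = [(10_000, 10_800), (50_000, 52_500), (120_000, 125_000)]
        decoys = [(80_000, 80_300), (150_000, 150_400)]  # below the length cutoff
        tracks, _ = self._cohort(deletions=planted + decoys)
        sums = sum_depth(tracks)
        calls = call_deletions(
            sums,
            expected_focal=tracks.expected_cohort_depth("focal"),
            expected_comparison=tracks.expected_cohort_depth("comparison"),
        )
        assert len(calls) == len(planted)
        for (s, e), call in zip(planted, sorted(calls, key=lambda c: c.start)):
            assert abs(call.start - s) <= 100
            assert abs(call.end - e) <= 100
            assert call.focal_mean == 0.0
            assert call.comparison_mean > 0.5 * tracks.expected_cohort_depth("comparison")

    def test_no_deletions_no_calls(self):
        tracks, _ = self._cohort()
        sums = sum_depth(tracks)
        calls = call_deletions(
            sums,
            expected_focal=tracks.expected_cohort_depth("focal"),
            expected_comparison=tracks.expected_cohort_depth("comparison"),
        )
        assert calls == []

    def test_low_coverage_gap_merges_split_deletion(self):
        """Stray reads inside a deletion split it; the 250 bp / <5% rule rejoins it."""
        tracks, _ = self._cohort(deletions=[(20_000, 23_000)])
        # mis-mapped stray reads in a 150 bp stretch inside the deletion
        focal_rows = tracks.cohort_rows("focal")
        tracks.depths["chr1"][focal_rows[0], 21_000:21_150] = 1
        sums = sum_depth(tracks)
        expected_focal = tracks.expected_cohort_depth("focal")
        calls = call_deletions(
            sums,
            expected_focal=expected_focal,
            expected_comparison=tracks.expected_cohort_depth("comparison"),
        )
        assert len(calls) == 1
        call = calls[0]
        assert call.start <= 20_000 and call.end >= 22_900
        assert len(call.merged_from) >= 2  # provenance records the join

    def test_wide_noisy_gap_does_not_merge(self):
        tracks, _ = self._cohort(deletions=[(20_000, 20_800), (21_400, 22_200)])
        # the 600 bp gap between the two deletions has normal focal coverage
        sums = sum_depth(tracks)
        calls = call_deletions(
            sums,
            expected_focal=tracks.expected_cohort_depth("focal"),
            expected_comparison=tracks.expected_cohort_depth("comparison"),
        )
        assert len(calls) == 2

    def test_deletion_broken_by_mask_is_bridged(self):
        tracks, _ = self._cohort(deletions=[(30_000, 32_000)])
        mask = mask_from_intervals(
            IntervalSet.from_records([("chr1", 30_800, 31_200, "")], kind="unmappable")
        )
        sums = sum_depth(tracks, mask)
        calls = call_deletions(
            sums,
            expected_focal=tracks.expected_cohort_depth("focal"),
            expected_comparison=tracks.expected_cohort_depth("comparison"),
        )
        assert len(calls) == 1
        assert calls[0].start <= 30_000 and calls[0].end >= 31_900

    def test_short_call_discarded(self):
        tracks, _ = self._cohort(deletions=[(40_000, 40_400)])
        sums = sum_depth(tracks)
        calls = call_deletions(
            sums,
            expected_focal=tracks.expected_cohort_depth("focal"),
            expected_comparison=tracks.expected_cohort_depth("comparison"),
        )
        assert calls == []

    def test_autosome_restriction(self):
        tracks, _ = self._cohort(deletions=[(10_000, 11_000)])
        sums = sum_depth(tracks)
        calls = call_deletions(
            sums,
            expected_focal=tracks.expected_cohort_depth("focal"),
            expected_comparison=tracks.expected_cohort_depth("comparison"),
            autosomes=[],
        )
        assert calls == []

    def test_bad_expected_coverage_rejected(self):
        tracks, _ = self._cohort()
        with pytest.raises(ValueError):
            call_deletions(sum_depth(tracks), expected_focal=0.0, expected_comparison=10.0)


class TestGeneOverlap:
    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(4)
        from conftest import random_intervals
        from arctic_sweep.dels import DeletionCall

        dels = random_intervals(rng, 50, chroms=("chr1",), max_pos=100_000, max_len=3_000)
        calls = [
            DeletionCall(r.chrom, r.start, r.end, 0.0, 20.0)
            for r in dels.df.itertuples(index=False)
        ]
        genes = random_intervals(rng, 40, chroms=("chr1",), max_pos=100_000, max_len=4_000)
        hits = deletion_gene_overlap(calls, genes)
        call_set = IntervalSet.from_records(
            [(c.chrom, c.start, c.end, f"del_{i}") for i, c in enumerate(calls)]
        )
        expected = {
            (call_set.df["name"].iat[i], genes.df["name"].iat[j])
            for i, j in intersect(call_set, genes)
        }
        assert set(zip(hits["deletion"], hits["gene"])) == expected
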