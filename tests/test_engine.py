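import numpy as np
import pytest

from loraln import (
    EngineParams,
    ErrorProfile,
    ReadRecord,
    align_read,
    alignment_stage,
    assignment_stage,
    build_index,
    candidate_from_pair,
    finalize,
    make_reference,
    primitive_seeds,
)
from loraln.engine import CandidatePosition, _cluster_radius
from loraln.fragmentation import Seed
from loraln.io_formats import revcomp
from loraln.seed_index import SeedHit, map_seed
from loraln.simulator import NOISELESS, simulate_reads

PROF = ErrorProfile(0.01, 0.10, 0.3)


def _seed(offset, length=40, read_id="r"):
    return Seed(read_id, offset, length, "A" * length, "primitive")


class TestCandidateFromPair:
    PARAMS = EngineParams(profile=PROF)

    def test_zero_drift_consistent(self):
        cand = candidate_from_pair(
            (_seed(0), SeedHit(5000, "+", 0)),
            (_seed(40), SeedHit(5040, "+", 0)),
            800,
            self.PARAMS,
        )
        assert cand is not None and cand.implied_start == 5000
        assert cand.strand == "+" and cand.support == 2

    def test_large_drift_inconsistent(self):
        cand = candidate_from_pair(
            (_seed(0), SeedHit(5000, "+", 0)),
            (_seed(40), SeedHit(5240, "+", 0)),
            800,
            self.PARAMS,
        )
        assert cand is None  # 200 bp drift over a 40 bp gap

    def test_opposite_strands_inconsistent(self):
        cand = candidate_from_pair(
            (_seed(0), SeedHit(5000, "+", 0)),
            (_seed(40), SeedHit(5040, "-", 0)),
            800,
            self.PARAMS,
        )
        assert cand is None

    def test_reverse_strand_projection(self):
        # read of length 800 on '-': seed at read offset o occupies oriented
        # offset 800 - o - 40; brute-force projection of read base 0
        read_len = 800
        a_off, b_off = 720, 680
        hit_a = SeedHit(5000 + (read_len - a_off - 40), "-", 0)
        hit_b = SeedHit(5000 + (read_len - b_off - 40), "-", 0)
        cand = candidate_from_pair(
            (_seed(a_off), hit_a), (_seed(b_off), hit_b), read_len, self.PARAMS
        )
        assert cand is not None and cand.implied_start == 5000


@pytest.fixture(scope="module")
def noisy_world():
    ref = make_reference(400_000, 20260929)
    return ref, build_index(ref)


class TestAlignmentStage:
    def test_first_consistent_pair_wins_on_clean_read(self, noisy_world):
        ref, idx = noisy_world
        params = EngineParams(profile=NOISELESS)
        reads, truth = simulate_reads(ref, 1, 800, NOISELESS, 5)
        read, t = reads[0], truth[0]
        seeds = primitive_seeds(read, params.L)
        cands = list(alignment_stage(read, seeds, idx, params))
        assert cands, "clean read must yield a candidate"
        assert cands[0].support == 2
        assert abs(cands[0].implied_start - t.true_start) <= params.L

    def test_all_repeat_seeds_fail_within_th(self):
        # a read from a perfect two-copy repeat: every seed has two hits
        ref = make_reference(120_000, 31, repeat=(10_000, 20_000, 80_000))
        idx = build_index(ref)
        params = EngineParams(profile=NOISELESS)
        read = ReadRecord("rep", ref.seq[12_000:12_800], "I" * 800)
        seeds = primitive_seeds(read, params.L)
        mapped = {}
        cands = list(alignment_stage(read, seeds, idx, params, mapped))
        assert cands == []
        assert len(mapped) <= params.Th
        assert all(m.status == "repeat" for m in mapped.values())


class TestAssignmentStage:
    def test_best_cluster_matches_brute_force(self, noisy_world):
        """Top cluster equals an O(n^2) enumeration over all projections."""
        ref, idx = noisy_world
        params = EngineParams(profile=PROF)
        reads, truth = simulate_reads(ref, 5, 1200, PROF, 77)
        for read, t in zip(reads, truth):
            cands = assignment_stage(read, idx, ref, params)
            assert cands, "noisy read should still form a cluster"
            # brute force: project every hit of every overlapping seed
            from loraln.fragmentation import overlapping_seeds

            projections = []
            for seed in overlapping_seeds(read, params.L):
                m = map_seed(idx, seed.seq, params.seed_edit_cap)
                for h in m.hits:
                    if h.strand == "+":
                        off = seed.offset
                    else:
                        off = len(read) - seed.offset - seed.length
                    projections.append((h.strand, h.offset - off, seed.offset))
            radius = _cluster_radius(params, len(read))
            best = (0, None)
            for strand, center, _ in projections:
                support = len(
                    {
                        s
                        for st_, p, s in projections
                        if st_ == strand and abs(p - center) <= radius
                    }
                )
                if support > best[0]:
                    best = (support, strand)
            assert cands[0].support == best[0]
            assert cands[0].strand == best[1] == t.strand
            assert abs(cands[0].implied_start - t.true_start) <= radius

    def test_equal_support_tie_prefers_smaller_start(self):
        ref = make_reference(120_000, 31, repeat=(10_000, 20_000, 80_000))
        idx = build_index(ref)
        params = EngineParams(profile=NOISELESS)
        read = ReadRecord("rep", ref.seq[12_000:12_800], "I" * 800)
        cands = assignment_stage(read, idx, ref, params)
        assert len(cands) >= 2
        assert cands[0].support == cands[1].support
        assert cands[0].implied_start < cands[1].implied_start

    def test_unmappable_read_yields_nothing(self, noisy_world):
        ref, idx = noisy_world
        rng = np.random.default_rng(123)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 800))
        read = ReadRecord("rand", seq, "I" * 800)
        params = EngineParams(profile=NOISELESS)
        assert assignment_stage(read, idx, ref, params) == []


class TestFinalize:
    def test_verified_candidate_positions_match(self, noisy_world):
        ref, idx = noisy_world
        params = EngineParams(profile=NOISELESS)
        start = 33_333
        read = ReadRecord("x", ref.seq[start : start + 800], "I" * 800)
        cand = CandidatePosition(start, "+", 2, 40)
        res = finalize(read, cand, ref, params)
        assert res is not None and res.mapped
        assert res.pos - 1 == start and res.mapq == 60
        assert res.cigar == "800M" and res.edit_distance == 0

    def test_decoy_candidate_rejected(self, noisy_world):
        ref, idx = noisy_world
        params = EngineParams(profile=NOISELESS)
        read = ReadRecord("x", ref.seq[1000:1800], "I" * 800)
        decoy = CandidatePosition(300_000, "+", 2, 40)
        assert finalize(read, decoy, ref, params) is None


class TestAlignRead:
    def test_error_free_read_maps_exactly(self, noisy_world):
        ref, idx = noisy_world
        params = EngineParams(profile=NOISELESS)
        reads, truth = simulate_reads(ref, 20, 800, NOISELESS, 40)
        for read, t in zip(reads, truth):
            res = align_read(read, idx, ref, params)
            assert res.mapped and res.mapq == 60
            assert res.pos - 1 == t.true_start
            assert res.strand == t.strand
            assert res.edit_distance == 0

    def test_two_copy_repeat_read_is_filtered(self):
        ref = make_reference(120_000, 31, repeat=(10_000, 20_000, 80_000))
        idx = build_index(ref)
        params = EngineParams(profile=NOISELESS)
        read = ReadRecord("rep", ref.seq[15_000:15_800], "I" * 800)
        res = align_read(read, idx, ref, params)
        assert (not res.mapped) or res.mapq < 10

    def test_determinism_per_read(self, noisy_world):
        ref, idx = noisy_world
        params = EngineParams(profile=PROF, rng_seed=7)
        reads, _ = simulate_reads(ref, 5, 1000, PROF, 50)
        a = [align_read(r, idx, ref, params) for r in reads]
        b = [align_read(r, idx, ref, params) for r in reads]
        assert a == b
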