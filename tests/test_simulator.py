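import numpy as np
import pytest
from scipy import stats

from loraln import (
    AlignmentResult,
    ErrorProfile,
    EvalParams,
    Reference,
    evaluate,
    make_reference,
    simulate_reads,
    write_sam,
)
from loraln.io_formats import revcomp
from loraln.simulator import NOISELESS, TruthRecord


class TestMakeReference:
    def test_deterministic(self):
        assert make_reference(16, 5).seq == make_reference(16, 5).seq

    def test_base_frequencies_uniform(self):
        ref = make_reference(1_000_000, 11)
        counts = {b: ref.seq.count(b) for b in "ACGT"}
        # each base ~ Binomial(1e6, 1/4); 5 sigma band
        sigma = (1e6 * 0.25 * 0.75) ** 0.5
        for b, c in counts.items():
            assert abs(c - 250_000) <= 5 * sigma, (b, c)

    def test_planted_repeat_copies_segment(self):
        ref = make_reference(10_000, 3, repeat=(1000, 500, 7000))
        assert ref.seq[7000:7500] == ref.seq[1000:1500]

    def test_bad_length(self):
        with pytest.raises(ValueError):
            make_reference(0, 1)


class TestSimulateReads:
    def test_noiseless_forward_reads_are_substrings(self):
        ref = make_reference(50_000, 2)
        reads, truth = simulate_reads(ref, 30, 500, NOISELESS, 9)
        for read, t in zip(reads, truth):
            assert t.span == 500
            expected = ref.seq[t.true_start : t.true_start + 500]
            if t.strand == "+":
                assert read.seq == expected
            else:
                assert revcomp(read.seq) == expected

    def test_deterministic_given_seed(self):
        ref = make_reference(10_000, 2)
        prof = ErrorProfile(0.01, 0.16, 0.3)
        a = simulate_reads(ref, 10, 700, prof, 123)
        b = simulate_reads(ref, 10, 700, prof, 123)
        assert a == b

    def test_mean_substitution_count(self):
        # substitution-only profile: mismatches against the true substring
        # are exactly the substitution events
        ref = make_reference(200_000, 4)
        p_sub = 0.01
        reads, truth = simulate_reads(
            ref, 500, 7000, ErrorProfile(p_sub, 0.0, 0.0), 17
        )
        total = 0
        for read, t in zip(reads, truth):
            seq = read.seq if t.strand == "+" else revcomp(read.seq)
            template = ref.seq[t.true_start : t.true_start + t.span]
            total += sum(a != b for a, b in zip(seq, template))
        n = 500 * 7000
        sigma = (n * p_sub * (1 - p_sub)) ** 0.5
        assert abs(total - n * p_sub) <= 5 * sigma

    def test_substitution_counts_match_binomial(self):
        """Chi-square goodness of fit of per-read substitution counts."""
        ref = make_reference(200_000, 4)
        p_sub = 0.02
        read_len, n_reads = 1000, 600  # >= 10^4 expected events
        reads, truth = simulate_reads(
            ref, n_reads, read_len, ErrorProfile(p_sub, 0.0, 0.0), 21
        )
        counts = []
        for read, t in zip(reads, truth):
            seq = read.seq if t.strand == "+" else revcomp(read.seq)
            template = ref.seq[t.true_start : t.true_start + t.span]
            counts.append(sum(a != b for a, b in zip(seq, template)))
        counts = np.asarray(counts)
        dist = stats.binom(read_len, p_sub)
        edges = [0, 12, 16, 19, 22, 25, 29, read_len + 1]
        observed = np.histogram(counts, bins=edges)[0]
        expected = np.diff([dist.cdf(e - 1) for e in edges]) * n_reads
        expected[0] = dist.cdf(edges[1] - 1) * n_reads
        chi2 = ((observed - expected) ** 2 / expected).sum()
        crit = stats.chi2.ppf(1 - 0.001, df=len(observed) - 1)
        assert chi2 <= crit, (observed, expected.round(1))

    def test_indel_bases_near_expected_rate(self):
        ref = make_reference(400_000, 6)
        import edlib

        prof = ErrorProfile(0.0, 0.05, 0.3)
        reads, truth = simulate_reads(ref, 200, 2000, prof, 30)
        total = 0
        for read, t in zip(reads, truth):
            seq = read.seq if t.strand == "+" else revcomp(read.seq)
            template = ref.seq[t.true_start : t.true_start + t.span]
            total += edlib.align(seq, template, mode="NW")["editDistance"]
        mean = 200 * 2000 * prof.indel_base_rate
        # parsimony can only undercount; allow a loose two-sided band
        assert 0.85 * mean <= total <= 1.1 * mean

    def test_read_len_exceeding_reference(self):
        ref = make_reference(100, 1)
        with pytest.raises(ValueError):
            simulate_reads(ref, 1, 101, NOISELESS, 1)


def _sam_for(truth, placements, ref, path):
    """Build a SAM where read i is placed at (pos0, strand, mapq)."""
    results = []
    for t, (pos0, strand, mapq) in zip(truth, placements):
        results.append(
            AlignmentResult(
                read_id=t.read_id,
                ref_name=ref.name,
                pos=pos0 + 1,
                strand=strand,
                cigar="10M",
                edit_distance=0,
                mapq=mapq,
                mapped=mapq is not None,
                seq="A" * 10,
                qual="I" * 10,
            )
        )
    write_sam(results, ref, path)


class TestEvaluate:
    @pytest.fixture()
    def ref(self):
        return Reference(name="ref", seq="A" * 5000)

    def test_tolerance_boundary(self, tmp_path, ref):
        truth = [TruthRecord("r1", 1000, "+", 10), TruthRecord("r2", 1000, "+", 10)]
        sam = tmp_path / "e.sam"
        _sam_for(truth, [(1100, "+", 60), (1101, "+", 60)], ref, sam)
        rep = evaluate(sam, truth, EvalParams(tolerance=100))
        assert rep.n_mapped == 2 and rep.n_correct == 1  # X=1100 in, 1101 out

    def test_mapq_filter(self, tmp_path, ref):
        truth = [TruthRecord("r1", 1000, "+", 10)]
        sam = tmp_path / "e.sam"
        _sam_for(truth, [(1000, "+", 9)], ref, sam)
        rep = evaluate(sam, truth, EvalParams(tolerance=100, mapq_min=10))
        assert rep.n_mapped == 0 and rep.n_correct == 0

    def test_strand_must_match(self, tmp_path, ref):
        truth = [TruthRecord("r1", 1000, "-", 10)]
        sam = tmp_path / "e.sam"
        _sam_for(truth, [(1000, "+", 60)], ref, sam)
        rep = evaluate(sam, truth, EvalParams(tolerance=0))
        assert rep.n_mapped == 1 and rep.n_correct == 0

    def test_unknown_read_id_is_error(self, tmp_path, ref):
        truth = [TruthRecord("r1", 0, "+", 10)]
        sam = tmp_path / "e.sam"
        _sam_for([TruthRecord("rX", 0, "+", 10)], [(0, "+", 60)], ref, sam)
        with pytest.raises(ValueError):
            evaluate(sam, truth, EvalParams())

    def test_perfect_sam_from_truth_scores_100(self, tmp_path):
        ref = make_reference(30_000, 8)
        reads, truth = simulate_reads(ref, 50, 400, NOISELESS, 3)
        sam = tmp_path / "p.sam"
        _sam_for(truth, [(t.true_start, t.strand, 60) for t in truth], ref, sam)
        rep = evaluate(sam, truth, EvalParams(tolerance=0))
        assert rep.map_rate == 100.0 and rep.accuracy == 100.0
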