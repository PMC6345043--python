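# Methods

This note records the models, defaults and design choices behind `loraln`,
and what the synthetic benchmarks do and do not demonstrate.

## Error model and simulator

Reads are fixed-length walks over a reference: per emitted base a
substitution occurs with probability `p_sub` (uniform over the three other
bases); per consumed reference base an indel event fires with probability
`p_indel`, equally likely insertion or deletion, with length
1 + Geometric(`indel_ext`) (mean 1/(1−`indel_ext`); default `indel_ext` =
0.3, the customary wgsim extension probability). Insertions emit uniform
random bases; substitutions are applied to the finished template so a read
carries exactly Binomial(ℓ, `p_sub`) substituted positions. Start positions
and strands are uniform; reverse-strand reads are emitted as reverse
complements; qualities are constant Q40 (the error model is positional, not
quality-driven).

Two boundary rules make the ground truth well-posed:

* the first emitted base always consumes `ref[true_start]` — an indel drawn
  before the first base would silently redefine the start (a read with a
  leading deletion *is* a read that starts k bases later), leaving no
  correct answer for an aligner to find;
* `true_start` is the leftmost reference offset of the consumed span for
  both strands, matching the SAM leftmost-coordinate convention.

What the simulator does **not** model: quality-dependent error rates,
length distributions drawn from real instruments (all reads in one dataset
share one length), chimeras, and reference polymorphism. Passing the
benchmarks therefore demonstrates correctness of the alignment machinery
under the stated aggregate error rates on a repeat-poor reference — not
performance on a real genome, whose segmental duplications and low-entropy
tracts are harsher than anything a uniform-random 1 Mb sequence contains.

## Seed mapping

The index stores every k-mer of the forward reference (k = 13 default;
dict of sorted offset arrays). Reverse-strand hits come from querying the
seed's reverse complement, which yields exactly the hit set of an index
over both strands in one coordinate system. A seed of length L (40 default)
is mapped by exact k-mer anchoring followed by bounded edit-distance
verification (edlib, infix mode) at each implied locus, with hits within
`max_edits` bp collapsed to their best representative. `max_edits` defaults
to ⌈0.1·L⌉ = 4. The pigeonhole guarantee (an exact k-mer anchor must
survive) holds for fewer than ⌊L/k⌋ = 3 edits; 3–4-edit seeds are found
only when an anchor happens to survive, which is the usual seed-and-extend
compromise. "Unique" means exactly one surviving hit cluster; more than
`max_hits` = 64 hits are truncated to the lowest-edit 64.

## Smith–Waterman and the feedback loop

The local aligner is an affine-gap Gotoh DP over a diagonal band
(numba-compiled), optimizing lexicographically: maximal score, then minimal
edit distance among maximal-score alignments. The second key makes the
reported edit distance a well-defined function of the operands, which the
verification threshold consumes; it also fixes tie-breaks deterministically.
Opening a gap costs `gap_open + gap_extend`, extending `gap_extend`. N
matches nothing, including N.

Default scoring is (match 3, mismatch −5, gap open −2, gap extend −1),
chosen for indel-dominant data by three constraints: a one-base gap (−3)
must be cheaper than a mismatch (−5), otherwise near-start indels are
re-interpreted as mismatch runs and the declared start drifts by ±1–3 bp;
an insertion+deletion pair (−6) must not be cheaper than a mismatch, or
substitutions decode as gap pairs and the edit distance inflates; and
skipping reference via gaps between chance matches must be strictly
score-negative (3 < 2 + 1·k for k ≥ 2), or local alignments creep into
flanking sequence.

A candidate placement is verified iff its edit distance is at most
`max(⌈μ·slack⌉, μ + 5√μ + 5)` with μ = (p_sub + p_indel/(1−indel_ext))·ℓ
the expected edit load, `slack` = 1.5, and the aligned interval covers at
least `min_cov` = 0.8 of the read. The additive term is a Poisson-tail
floor: for a 300 bp read at 1% total error the expected count is ~3 and a
multiplicative band alone rejects ordinary fluctuations. A random placement
has edit distance near 0.52·ℓ on a uniform reference, an order of magnitude
above the ceiling, so the test separates cleanly. The refinement window is
the candidate ± ⌈0.25·ℓ⌉, covering the ~15% seed-drift bound with margin;
the band half-width is max(128, ⌈0.08·ℓ⌉) and is widened 3× once if
verification fails, in case the optimal path clipped the band.

### Declared position

The SAM position is the alignment's start projected back over any clipped
read prefix (`window_start + ref_start − read_start`), then re-decoded by a
semi-global pair-HMM Viterbi over the first 250 read bases (window: ±60 bp
around the projected start). The decoder's costs are the log-likelihoods of
the stated error process — log(1−p_sub) / log(p_sub/3) for match/mismatch,
log(p_indel/2) + log(1−indel_ext) to open an event, log(indel_ext) to
extend, inserted bases paying their log(1/4) emission. Parsimony (the SW
traceback) and likelihood disagree systematically at 10–16% indel rates:
a deletion plus a chance match is often "cheaper" than the true history.
The ML decode is what lifts exact-start (T = 0) accuracy to the high 80s on
the 16%-indel profiles. Residual T = 0 error is dominated by genuinely
ambiguous events (an inserted base equal to its reference neighbour).

## Engine

`Th` = 10 bounds alignment-stage seed mappings per read. Pair consistency
allows |Δref − Δread| up to ⌈2·indel_base_rate·|Δread|⌉ + L. Assignment
clusters use radius ⌈indel_base_rate·ℓ⌉ + L, support counts distinct seeds,
ties prefer the smaller implied start, and at most 3 clusters are tried
through verification. MAPQ: 60 for a verified unique-pair placement; 20 for
a verified cluster with support ≥ 3; 13 for support 2 (still a whole-read
verification, hence above the MAPQ ≥ 10 filter); 3 when a rival cluster has
comparable support (≥ max(2, ⌈support/2⌉)), which is what demotes reads
from two-copy repeats below the filter. Unmapped and repeat seeds are
treated identically by the traversal (both uninformative).

Per-read RNG streams are seeded from (global seed, CRC32 of the read id),
so results are independent of thread scheduling and partition boundaries;
the runner's output is byte-identical for any thread count and partition
size, and the index is built once per run and stays resident.

## Load balancing

`partition_reads` scans once, sorts each consecutive group of N reads by
length, sends the group's longest read to bin g mod N (each bin receives a
group maximum exactly once every N groups) and the rest longest-first to
the currently lightest bins — O(R log N) comparisons, asserted by an
instrumented counter. The adaptive placement of the non-longest ranks was
chosen over a fixed rotation because it also corrects within-rank sampling
noise; on random length profiles of 200–1000 reads its per-bin mean-length
spread beats contiguous chunking in >99% of trials, versus ~87% for the
fixed rotation. `split_for_threads` is greedy longest-first onto the
lightest queue; idle threads steal from the tail of the fullest queue
(owner pops the head), giving exactly-once consumption without a global
queue lock.

## Benchmark sizing

The packaged benchmarks run 500 reads per error profile on a random 1 Mb
reference — sized so the whole suite and the reproduction script each
finish in minutes on one CPU while keeping binomial noise on a 500-read
percentage near ±1–2 points. Profiles span 300–12000 bp reads, 0–9%
substitutions and 0.1–16% indel events, matching the synthetic dataset
grid the pipeline targets.

## Known limitations

Single-contig references only; no split/chimeric or secondary alignments;
no base-quality awareness; the k-mer dict index is memory-hungry at
gigabase scale (engineering, not algorithmic, work); reads shorter than
about 1.5 seed lengths cannot gather two seeds and go unmapped; and the
declared-position decoder assumes the dataset's stated error rates are
roughly right — badly misstated rates degrade T = 0 accuracy (though not
mapping itself, which only uses the rates through the generous
verification ceiling).
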