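"""Per-read orchestration: alignment stage, assignment stage, feedback loop.

A read is placed in two attempts:

1. **Alignment stage** — primitive seeds are visited in the randomized
   traversal order; as soon as two uniquely mapped seeds on the same strand
   are mutually consistent, the pair implies a candidate read start.  The
   stage gives up after ``Th`` seed-mapping attempts.
2. **Assignment stage** — every *overlapping* seed is mapped (primitive
   seeds are not re-mapped; their alignment-stage mappings are reused for
   free), every hit of every seed is projected to an implied read start, and
   implied starts are clustered per strand.  Clusters are ranked by seed
   support.

Every candidate must pass the local-alignment feedback test
(:func:`loraln.local_align.verify_edit_distance`) before it is reported;
a failed verification resumes the stage that produced the candidate
(further traversal within ``Th``, or the next-best cluster, at most
``max_clusters`` of them).  The verified placement's position is refined
from the Smith-Waterman traceback, correcting seed-implied drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

from .fragmentation import DEFAULT_SEED_LEN, Seed, overlapping_seeds, primitive_seeds
from .io_formats import AlignmentResult, ReadRecord, Reference, revcomp
from .local_align import (
    DEFAULT_MIN_COV,
    DEFAULT_SCORING,
    DEFAULT_SLACK,
    ScoringScheme,
    decode_start,
    refine_position,
    smith_waterman,
    verify_edit_distance,
)
from .seed_index import SeedHit, SeedIndex, SeedMapping, default_max_edits, map_seed
from .simulator import NOISELESS, ErrorProfile
from .traversal import TraversalState, next_seed

__all__ = [
    "EngineParams",
    "CandidatePosition",
    "align_read",
    "alignment_stage",
    "assignment_stage",
    "candidate_from_pair",
    "finalize",
]


@dataclass(frozen=True)
class EngineParams:
    """Tunables of the per-read pipeline (defaults documented in docs/methods.md)."""

    L: int = DEFAULT_SEED_LEN  # seed length (bp)
    Th: int = 10  # max alignment-stage seed-mapping attempts
    k: int = 13  # index anchor k-mer size
    max_edits_seed: int | None = None  # per-seed edit cap; None -> ceil(0.1 L)
    slack: float = DEFAULT_SLACK
    min_cov: float = DEFAULT_MIN_COV
    max_hits: int = 64
    rng_seed: int = 42
    profile: ErrorProfile = NOISELESS  # expected error rates of the input data
    scoring: ScoringScheme = DEFAULT_SCORING
    band_frac: float = 0.08  # SW band half-width as fraction of read length
    window_margin: float = 0.25  # refinement window margin fraction
    max_clusters: int = 3  # assignment-stage clusters tried through feedback
    polish_len: int = 250  # read-prefix length for the ML start decode
    polish_margin: int = 60  # window slop around the SW start for the decode

    def __post_init__(self) -> None:
        if self.Th < 2:
            raise ValueError("Th must be >= 2")
        if self.L < self.k:
            raise ValueError("seed length L must be >= anchor size k")

    @property
    def seed_edit_cap(self) -> int:
        return (
            self.max_edits_seed
            if self.max_edits_seed is not None
            else default_max_edits(self.L)
        )


@dataclass(frozen=True)
class CandidatePosition:
    """A seed-implied read start on the forward reference."""

    implied_start: int  # 0-based offset of read base 0 (may be < 0 pre-clamp)
    strand: str
    support: int
    total_indel_slack: int
    origin: str = "alignment"  # "alignment" | "assignment"
    rival_support: int = 0  # support of the best other-locus cluster


def _adjusted_offset(seed: Seed, read_len: int, strand: str) -> int:
    """Seed offset within the alignment-oriented read."""
    if strand == "+":
        return seed.offset
    return read_len - seed.offset - seed.length


def _pair_slack(profile: ErrorProfile, distance: int, L: int) -> int:
    return math.ceil(profile.indel_base_rate * distance * 2) + L


def candidate_from_pair(
    a: tuple[Seed, SeedHit],
    b: tuple[Seed, SeedHit],
    read_len: int,
    params: EngineParams,
) -> CandidatePosition | None:
    """Candidate position from two uniquely mapped seeds, or None if inconsistent.

    The pair is consistent when the reference-offset difference of the two
    hits matches the (strand-adjusted) read-offset difference up to the indel
    slack expected over that stretch of read.
    """
    seed_a, hit_a = a
    seed_b, hit_b = b
    if hit_a.strand != hit_b.strand:
        return None
    strand = hit_a.strand
    off_a = _adjusted_offset(seed_a, read_len, strand)
    off_b = _adjusted_offset(seed_b, read_len, strand)
    d_read = off_b - off_a
    d_ref = hit_b.offset - hit_a.offset
    slack = _pair_slack(params.profile, abs(d_read), params.L)
    if abs(d_ref - d_read) > slack:
        return None
    return CandidatePosition(
        implied_start=hit_a.offset - off_a,
        strand=strand,
        support=2,
        total_indel_slack=slack,
        origin="alignment",
    )


def alignment_stage(
    read: ReadRecord,
    seeds: list[Seed],
    index: SeedIndex,
    params: EngineParams,
    mapped_out: dict[int, SeedMapping] | None = None,
) -> Iterator[CandidatePosition]:
    """Yield candidate positions from unique seed pairs, in traversal order.

    The generator embodies the resume-on-failed-verification semantics: the
    caller pulls the next candidate to continue the stage after a rejection.
    ``mapped_out`` collects every seed mapping made, so the assignment stage
    can reuse primitive-seed evidence without re-mapping.
    """
    if not seeds:
        return
    state = TraversalState.for_read(len(seeds), params.rng_seed, read.id)
    uniques: list[tuple[Seed, SeedHit]] = []
    yielded: list[CandidatePosition] = []
    reject_radius = _cluster_radius(params, len(read))
    for _ in range(params.Th):
        idx = next_seed(state)
        if idx is None:
            return
        seed = seeds[idx]
        mapping = map_seed(index, seed.seq, params.seed_edit_cap)
        if mapped_out is not None:
            mapped_out[idx] = mapping
        state.record(idx, mapping.status)
        if mapping.status != "unique":
            continue
        new = (seed, mapping.hits[0])
        for prev in uniques:
            cand = candidate_from_pair(prev, new, len(read), params)
            if cand is None:
                continue
            if any(
                c.strand == cand.strand
                and abs(c.implied_start - cand.implied_start) <= reject_radius
                for c in yielded
            ):
                continue  # same locus already tried and rejected
            yielded.append(cand)
            yield cand
        uniques.append(new)


def _cluster_radius(params: EngineParams, read_len: int) -> int:
    return math.ceil(params.profile.indel_base_rate * read_len) + params.L


def assignment_stage(
    read: ReadRecord,
    index: SeedIndex,
    ref: Reference,
    params: EngineParams,
    primitive_maps: dict[int, SeedMapping] | None = None,
    primitive: list[Seed] | None = None,
) -> list[CandidatePosition]:
    """Rank candidate positions by projecting every hit of every overlapping seed.

    Only the newly added (overlapping) seeds are mapped here; primitive-seed
    mappings already computed by the alignment stage contribute to the vote at
    zero extra cost.  Returns clusters ranked by (support desc, implied start
    asc); empty list when no cluster reaches support 2.
    """
    read_len = len(read)
    evidence: list[tuple[Seed, SeedMapping]] = []
    for seed in overlapping_seeds(read, params.L):
        evidence.append((seed, map_seed(index, seed.seq, params.seed_edit_cap)))
    if primitive_maps and primitive:
        for idx, mapping in primitive_maps.items():
            evidence.append((primitive[idx], mapping))

    projections: dict[str, list[tuple[int, int]]] = {"+": [], "-": []}
    for seed, mapping in evidence:
        for hit in mapping.hits[: params.max_hits]:
            off = _adjusted_offset(seed, read_len, hit.strand)
            projections[hit.strand].append((hit.offset - off, seed.offset))

    radius = _cluster_radius(params, read_len)
    clusters: list[tuple[int, int, str]] = []  # (support, implied_start, strand)
    for strand, items in projections.items():
        items.sort()
        group: list[tuple[int, int]] = []
        for item in items:
            if group and item[0] - group[-1][0] > radius:
                clusters.append(_summarize(group, strand))
                group = []
            group.append(item)
        if group:
            clusters.append(_summarize(group, strand))

    clusters = [c for c in clusters if c[0] >= 2]
    clusters.sort(key=lambda c: (-c[0], c[1], c[2]))
    out: list[CandidatePosition] = []
    for i, (support, implied, strand) in enumerate(clusters):
        rival = max((c[0] for j, c in enumerate(clusters) if j != i), default=0)
        out.append(
            CandidatePosition(
                implied_start=implied,
                strand=strand,
                support=support,
                total_indel_slack=radius,
                origin="assignment",
                rival_support=rival,
            )
        )
    return out


def _summarize(group: list[tuple[int, int]], strand: str) -> tuple[int, int, str]:
    support = len({seed_off for _, seed_off in group})
    positions = sorted(p for p, _ in group)
    median = positions[(len(positions) - 1) // 2]
    return (support, median, strand)


def _mapq(cand: CandidatePosition) -> int:
    """MAPQ reflecting the evidence class behind a verified placement.

    Two consistent unique seeds plus full-read verification is near-certain
    (60).  Assignment-stage clusters are down-weighted by support, and a
    rival cluster of comparable support marks the placement ambiguous (3,
    below the standard MAPQ >= 10 filter).
    """
    if cand.origin == "alignment":
        return 60
    if cand.rival_support >= max(2, math.ceil(cand.support / 2)):
        return 3
    if cand.support >= 3:
        return 20
    if cand.support == 2:
        return 13
    return 0


def finalize(
    read: ReadRecord,
    cand: CandidatePosition,
    ref: Reference,
    params: EngineParams,
) -> AlignmentResult | None:
    """Run the feedback loop on one candidate: SW, verify, refine; None on reject."""
    read_len = len(read)
    oriented = read.seq if cand.strand == "+" else revcomp(read.seq)
    qual = read.qual if cand.strand == "+" else read.qual[::-1]
    margin = math.ceil(params.window_margin * read_len)
    est = cand.implied_start
    hw = max(128, math.ceil(params.band_frac * read_len))
    for attempt in range(2):
        wstart = max(0, est - margin)
        wend = min(ref.length, est + read_len + margin)
        if wend - wstart < params.k:
            return None
        aln = smith_waterman(
            oriented,
            ref.seq[wstart:wend],
            params.scoring,
            band_center=est - wstart,
            band_halfwidth=hw,
        )
        if verify_edit_distance(
            aln, read_len, params.profile, params.slack, params.min_cov
        ):
            break
        hw *= 3  # band may have clipped the optimal path; widen once
    else:
        return None
    pos0 = refine_position(wstart, aln)
    if params.polish_len > 0:
        # maximum-likelihood start decode under the stated error rates:
        # parsimony (SW) and likelihood disagree on indel-dense read starts
        B = min(params.polish_len, read_len)
        p0 = max(0, pos0 - params.polish_margin)
        p1 = min(ref.length, pos0 + B + params.polish_margin)
        if p1 - p0 >= 1:
            pos0 = p0 + decode_start(oriented[:B], ref.seq[p0:p1], params.profile)
    # keep the declared position consistent with the reference span
    pos0 = max(0, min(pos0, ref.length - (aln.ref_end - aln.ref_start)))
    lead = aln.read_start
    tail = read_len - aln.read_end
    cigar = (
        (f"{lead}S" if lead else "")
        + aln.cigar
        + (f"{tail}S" if tail else "")
    )
    return AlignmentResult(
        read_id=read.id,
        ref_name=ref.name,
        pos=pos0 + 1,
        strand=cand.strand,
        cigar=cigar,
        edit_distance=aln.edit_distance,
        mapq=_mapq(cand),
        mapped=True,
        seq=oriented,
        qual=qual,
    )


def _unmapped(read: ReadRecord, ref: Reference) -> AlignmentResult:
    return AlignmentResult(
        read_id=read.id,
        ref_name=ref.name,
        pos=0,
        strand="+",
        cigar="",
        edit_distance=0,
        mapq=0,
        mapped=False,
        seq=read.seq,
        qual=read.qual,
    )


def align_read(
    read: ReadRecord,
    index: SeedIndex,
    ref: Reference,
    params: EngineParams,
    stats: dict | None = None,
) -> AlignmentResult:
    """Place one read: alignment stage, then assignment stage, else unmapped."""
    seeds = primitive_seeds(read, params.L)
    primitive_maps: dict[int, SeedMapping] = {}
    for cand in alignment_stage(read, seeds, index, params, primitive_maps):
        result = finalize(read, cand, ref, params)
        if result is not None:
            if stats is not None:
                stats["alignment_stage"] = stats.get("alignment_stage", 0) + 1
            return result
    for cand in assignment_stage(read, index, ref, params, primitive_maps, seeds)[
        : params.max_clusters
    ]:
        result = finalize(read, cand, ref, params)
        if result is not None:
            if stats is not None:
                stats["assignment_stage"] = stats.get("assignment_stage", 0) + 1
            return result
    if stats is not None:
        stats["unmapped"] = stats.get("unmapped", 0) + 1
    return _unmapped(read, ref)
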