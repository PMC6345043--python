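"""Short-seed mapper with unique / repeat / unmapped classification.

The mapper anchors a seed at a reference locus whenever any of the seed's
k-mers occurs there exactly (pigeonhole: with e < floor(L/k) edits at least
one of the seed's non-overlapping k-mers survives untouched), then verifies
every candidate locus by bounded edit distance (substitutions + indels,
via edlib's infix mode) and clusters surviving hits that fall within
``max_edits`` bp of each other.  A seed is

* ``unique``   — exactly one surviving hit cluster,
* ``repeat``   — several clusters (truncated to the ``max_hits`` lowest-edit
  hits),
* ``unmapped`` — none.

Reverse-strand hits are found by querying the seed's reverse complement
against the forward-strand table; offsets are always reported on the forward
reference, so the hit set equals that of an index built over the reference
plus its reverse complement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
import numpy as np

from .io_formats import Reference, revcomp

__all__ = [
    "SeedIndex",
    "SeedHit",
    "SeedMapping",
    "build_index",
    "map_seed",
    "default_max_edits",
    "BUILD_COUNT",
]

DEFAULT_K = 13
DEFAULT_MAX_HITS = 64
_MAX_CANDIDATES = 512  # cap anchor-implied loci per strand (poly-repeats)

# instrumentation: how many times an index was built in this process
BUILD_COUNT = 0


def default_max_edits(seed_len: int) -> int:
    """Per-seed edit cap: 10% of the seed length, rounded up."""
    return math.ceil(0.1 * seed_len)


@dataclass(frozen=True)
class SeedHit:
    offset: int  # forward-reference offset of the seed's window start
    strand: str  # "+" | "-"
    edits: int


@dataclass(frozen=True)
class SeedMapping:
    status: str  # "unique" | "repeat" | "unmapped"
    hits: tuple[SeedHit, ...]


@dataclass
class SeedIndex:
    k: int
    ref: Reference
    max_hits: int
    # k-mer (2-bit packed int) -> sorted array of forward offsets
    table: dict[int, np.ndarray] = field(repr=False, default_factory=dict)

    def lookup(self, kmer: str) -> np.ndarray:
        """Forward-strand offsets of an exact k-mer (empty if absent)."""
        if len(kmer) != self.k or any(c not in "ACGT" for c in kmer):
            return np.empty(0, dtype=np.int64)
        return self.table.get(_pack(kmer), np.empty(0, dtype=np.int64))


_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _pack(kmer: str) -> int:
    v = 0
    for c in kmer:
        v = (v << 2) | int(_CODE[ord(c)])
    return v


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def build_index(ref: Reference, k: int = DEFAULT_K) -> SeedIndex:
    """Index every k-mer of the forward reference (deterministic).

    k-mers containing non-ACGT characters are skipped.
    """
    global BUILD_COUNT
    if k > ref.length:
        raise ValueError(f"k={k} exceeds reference length {ref.length}")
    if k < 4:
        raise ValueError("k must be >= 4")
    codes = _encode(ref.seq)
    n_kmers = ref.length - k + 1
    keys = np.zeros(n_kmers, dtype=np.int64)
    valid = np.ones(n_kmers, dtype=bool)
    for i in range(k):
        col = codes[i : i + n_kmers]
        keys = (keys << 2) | np.where(col >= 0, col, 0)
        valid &= col >= 0
    offsets = np.nonzero(valid)[0]
    keys = keys[valid]
    order = np.argsort(keys, kind="stable")
    keys_sorted = keys[order]
    offs_sorted = offsets[order]
    uniq, starts = np.unique(keys_sorted, return_index=True)
    bounds = np.append(starts, len(keys_sorted))
    table = {
        int(uniq[i]): np.sort(offs_sorted[bounds[i] : bounds[i + 1]])
        for i in range(len(uniq))
    }
    BUILD_COUNT += 1
    return SeedIndex(k=k, ref=ref, max_hits=DEFAULT_MAX_HITS, table=table)


def _candidate_starts(index: SeedIndex, query: str) -> np.ndarray:
    """Window starts implied by exact k-mer anchors of ``query``."""
    k = index.k
    n_kmers = len(query) - k + 1
    if n_kmers <= 0:
        return np.empty(0, dtype=np.int64)
    cands: list[np.ndarray] = []
    for j in range(n_kmers):
        hits = index.lookup(query[j : j + k])
        if hits.size:
            cands.append(hits - j)
    if not cands:
        return np.empty(0, dtype=np.int64)
    out = np.unique(np.concatenate(cands))
    if out.size > _MAX_CANDIDATES:
        out = out[:_MAX_CANDIDATES]
    return out


def _verify(
    index: SeedIndex, query: str, starts: np.ndarray, max_edits: int, strand: str
) -> list[SeedHit]:
    """Bounded edit-distance verification of candidate windows via edlib."""
    ref_seq = index.ref.seq
    n = index.ref.length
    L = len(query)
    found: dict[int, int] = {}
    # merge candidate starts closer than max_edits to avoid duplicate windows
    merged: list[int] = []
    for s in starts.tolist():
        if not merged or s - merged[-1] > max_edits:
            merged.append(s)
    for s in merged:
        lo = max(0, s - max_edits)
        hi = min(n, s + L + max_edits)
        res = edlib.align(query, ref_seq[lo:hi], mode="HW", task="locations", k=max_edits)
        if res["editDistance"] < 0:
            continue
        edits = res["editDistance"]
        for loc in res["locations"]:
            off = lo + (loc[0] if loc[0] is not None else 0)
            if off not in found or edits < found[off]:
                found[off] = edits
    return [SeedHit(offset=o, strand=strand, edits=e) for o, e in found.items()]


def _cluster(hits: list[SeedHit], max_edits: int) -> list[SeedHit]:
    """Collapse hits within max_edits bp (per strand) to their best member."""
    out: list[SeedHit] = []
    for strand in ("+", "-"):
        group = sorted(
            (h for h in hits if h.strand == strand), key=lambda h: h.offset
        )
        cluster: list[SeedHit] = []
        for h in group:
            if cluster and h.offset - cluster[-1].offset > max_edits:
                out.append(min(cluster, key=lambda x: (x.edits, x.offset)))
                cluster = []
            cluster.append(h)
        if cluster:
            out.append(min(cluster, key=lambda x: (x.edits, x.offset)))
    return out


def map_seed(index: SeedIndex, seed_seq: str, max_edits: int | None = None) -> SeedMapping:
    """Map one seed against the reference, both strands.

    Returns a :class:`SeedMapping` whose status reflects the number of
    surviving hit clusters; hits are (forward offset, strand, edits).
    """
    if max_edits is None:
        max_edits = default_max_edits(len(seed_seq))
    if len(seed_seq) < index.k:
        return SeedMapping(status="unmapped", hits=())
    hits: list[SeedHit] = []
    for strand, query in (("+", seed_seq), ("-", revcomp(seed_seq))):
        starts = _candidate_starts(index, query)
        if starts.size:
            hits.extend(_verify(index, query, starts, max_edits, strand))
    hits = _cluster(hits, max_edits)
    if not hits:
        return SeedMapping(status="unmapped", hits=())
    if len(hits) == 1:
        return SeedMapping(status="unique", hits=(hits[0],))
    hits.sort(key=lambda h: (h.edits, h.offset, h.strand))
    return SeedMapping(status="repeat", hits=tuple(hits[: index.max_hits]))
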