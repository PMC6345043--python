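"""Synthetic references, wgsim-style noisy long reads, and SAM evaluation.

The generator emulates fixed-length reads with an independent per-base
substitution rate and a per-base indel event rate whose event lengths are
1 + Geometric(indel_ext) — the aggregate error profiles quoted for
PacBio-like long reads (e.g. 7000 bp reads at 1% mismatch / 16% indel).
Substitutions are applied per *output* base, so a read of length ``read_len``
carries Binomial(read_len, p_sub) substituted bases; indel events are drawn
per consumed reference base while building the read template.

Evaluation follows the tolerance protocol: an alignment with MAPQ below
``mapq_min`` (default 10) counts as unmapped; a mapped read is correct iff
its strand matches the truth and the declared 0-based leftmost position X
satisfies P - T <= X <= P + T against the true start P.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_formats import ReadRecord, Reference, read_sam, revcomp

__all__ = [
    "ErrorProfile",
    "TruthRecord",
    "EvalParams",
    "EvalReport",
    "make_reference",
    "simulate_reads",
    "evaluate",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ErrorProfile:
    """Per-base error rates of a simulated dataset.

    p_sub:     substitution probability per read base (fraction, e.g. 0.01)
    p_indel:   indel *event* probability per consumed reference base
    indel_ext: geometric extension probability; event length = 1 + Geom(indel_ext),
               mean length 1 / (1 - indel_ext)
    """

    p_sub: float
    p_indel: float
    indel_ext: float = 0.3

    def __post_init__(self) -> None:
        for name in ("p_sub", "p_indel", "indel_ext"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")

    @property
    def indel_base_rate(self) -> float:
        """Expected indel *bases* per consumed reference base."""
        return self.p_indel / (1.0 - self.indel_ext)

    @property
    def expected_edit_rate(self) -> float:
        """Expected edit operations per read base (substitutions + indel bases)."""
        return self.p_sub + self.indel_base_rate


NOISELESS = ErrorProfile(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated read.

    true_start is the 0-based leftmost reference offset of the read's origin
    (for both strands); span is the number of reference bases consumed.
    """

    read_id: str
    true_start: int
    strand: str
    span: int


@dataclass(frozen=True)
class EvalParams:
    tolerance: int = 0
    mapq_min: int = 10

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


@dataclass(frozen=True)
class EvalReport:
    n_reads: int
    n_mapped: int
    n_correct: int

    @property
    def map_rate(self) -> float:
        """Percentage of reads reported mapped (correct or not)."""
        return 100.0 * self.n_mapped / self.n_reads if self.n_reads else 0.0

    @property
    def accuracy(self) -> float:
        """Percentage of *all* reads whose declared position is correct."""
        return 100.0 * self.n_correct / self.n_reads if self.n_reads else 0.0

    def as_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "n_mapped": self.n_mapped,
            "n_correct": self.n_correct,
            "map_rate": self.map_rate,
            "accuracy": self.accuracy,
        }


def make_reference(
    length: int,
    rng_seed: int,
    name: str = "synthetic_ref",
    repeat: tuple[int, int, int] | None = None,
) -> Reference:
    """Generate an i.i.d. uniform-random reference of ``length`` bp.

    ``repeat=(src_start, rep_len, dest_start)`` additionally copies the
    segment [src_start, src_start+rep_len) over [dest_start, dest_start+rep_len)
    to plant an exact two-copy repeat (for repeat-region tests).
    """
    if length < 1:
        raise ValueError(f"reference length must be >= 1, got {length}")
    rng = np.random.default_rng(rng_seed)
    codes = rng.integers(0, 4, size=length)
    arr = _BASES[codes]
    if repeat is not None:
        src, rep_len, dest = repeat
        if not (0 <= src <= length - rep_len and 0 <= dest <= length - rep_len):
            raise ValueError("planted repeat out of reference bounds")
        arr = arr.copy()
        arr[dest : dest + rep_len] = arr[src : src + rep_len]
    return Reference(name=name, seq=arr.tobytes().decode("ascii"))


def _mutate_walk(
    ref_codes: np.ndarray,
    start: int,
    read_len: int,
    profile: ErrorProfile,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int] | None:
    """Walk the reference from ``start`` emitting a read-length template.

    Per consumed reference base, an indel event fires with probability
    p_indel: equally likely an insertion (emit 1+Geom random bases, consume
    nothing) or a deletion (skip 1+Geom reference bases).  The first emitted
    base always consumes ``ref_codes[start]``: an indel in front of the first
    base would silently redefine the read's true start (a leading deletion is
    indistinguishable from starting k bases later), leaving the ground truth
    ill-posed.  Returns (template codes, reference span) or None if the walk
    ran off the end.
    """
    n = len(ref_codes)
    out = np.empty(read_len, dtype=np.int64)
    filled = 0
    pos = start
    p_indel, ext = profile.p_indel, profile.indel_ext
    while filled < read_len:
        if pos >= n:
            return None
        if filled > 0 and p_indel > 0.0 and rng.random() < p_indel:
            k = 1 + rng.geometric(1.0 - ext) - 1 if ext > 0.0 else 1
            if rng.random() < 0.5:  # insertion of k random bases
                take = min(k, read_len - filled)
                out[filled : filled + take] = rng.integers(0, 4, size=take)
                filled += take
            else:  # deletion of k reference bases
                pos += k
        else:
            out[filled] = ref_codes[pos]
            filled += 1
            pos += 1
    return out, pos - start


def simulate_reads(
    ref: Reference,
    n: int,
    read_len: int,
    profile: ErrorProfile,
    rng_seed: int,
    id_prefix: str = "sim",
) -> tuple[list[ReadRecord], list[TruthRecord]]:
    """Simulate ``n`` fixed-length noisy reads with ground truth.

    Start positions and strands are uniform; reverse-strand reads are emitted
    as the reverse complement of the mutated forward-strand template.  All
    qualities are the constant Sanger 'I' (Q40): the error model here is
    positional, not quality-driven.
    """
    if read_len > ref.length:
        raise ValueError(
            f"read_len {read_len} exceeds reference length {ref.length}"
        )
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(rng_seed)
    ref_codes = np.frombuffer(ref.seq.encode("ascii"), dtype=np.uint8)
    # map ASCII to 0..3; N (rare, only from external FASTA) becomes A
    lut = np.zeros(256, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    ref_codes = lut[ref_codes]

    # leave head-room for deletions consuming extra reference
    max_start = max(ref.length - read_len, 0)
    qual = "I" * read_len
    reads: list[ReadRecord] = []
    truth: list[TruthRecord] = []
    for i in range(n):
        while True:
            start = int(rng.integers(0, max_start + 1))
            walk = _mutate_walk(ref_codes, start, read_len, profile, rng)
            if walk is not None:
                break
        template, span = walk
        if profile.p_sub > 0.0:
            hit = rng.random(read_len) < profile.p_sub
            shift = rng.integers(1, 4, size=int(hit.sum()))
            template[hit] = (template[hit] + shift) % 4
        seq = _BASES[template].tobytes().decode("ascii")
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = revcomp(seq)
        read_id = f"{id_prefix}_{i:05d}"
        reads.append(ReadRecord(id=read_id, seq=seq, qual=qual))
        truth.append(
            TruthRecord(read_id=read_id, true_start=start, strand=strand, span=span)
        )
    return reads, truth


def evaluate(
    sam_path: str | Path,
    truth: list[TruthRecord] | dict[str, TruthRecord],
    params: EvalParams = EvalParams(),
) -> EvalReport:
    """Score a SAM file against simulator ground truth.

    Records that are unmapped, secondary/supplementary, or below the MAPQ
    filter count as unmapped.  A mapped read is correct iff its strand matches
    the truth and its declared 0-based leftmost position is within
    ``params.tolerance`` of the true start.
    """
    if not isinstance(truth, dict):
        truth = {t.read_id: t for t in truth}
    n_mapped = 0
    n_correct = 0
    seen: set[str] = set()
    for seg in read_sam(sam_path):
        if seg.is_secondary or seg.is_supplementary:
            continue
        name = seg.query_name
        if name not in truth:
            raise ValueError(f"SAM read id {name!r} absent from truth table")
        if name in seen:
            raise ValueError(f"duplicate primary SAM record for {name!r}")
        seen.add(name)
        if seg.is_unmapped or seg.mapping_quality < params.mapq_min:
            continue
        n_mapped += 1
        rec = truth[name]
        strand = "-" if seg.is_reverse else "+"
        x = seg.reference_start  # 0-based
        if strand == rec.strand and abs(x - rec.true_start) <= params.tolerance:
            n_correct += 1
    return EvalReport(n_reads=len(truth), n_mapped=n_mapped, n_correct=n_correct)
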