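"""Readers and writers for FASTA, FastQ, SAM and the simulator truth table.

Coordinate convention: everything internal is 0-based, half-open.  The single
conversion to SAM's 1-based inclusive leftmost coordinate happens in
:func:`write_sam`; :func:`~loraln.simulator.evaluate` converts back when it
parses SAM records through pysam (which itself exposes 0-based coordinates).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "FormatError",
    "ReadRecord",
    "Reference",
    "AlignmentResult",
    "read_fasta",
    "read_fastq",
    "write_fastq",
    "write_sam",
    "read_sam",
    "write_truth",
    "read_truth",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# anything outside the DNA alphabet is collapsed to N on input
_TO_N = {c: "N" for c in map(chr, range(256)) if c not in "ACGTN"}
_NORMALIZE = str.maketrans(_TO_N)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised for malformed FASTA/FastQ/SAM/truth inputs."""


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: identifier, bases and per-base Sanger qualities."""

    id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("read with empty id")
        if len(self.seq) != len(self.qual) or not self.seq:
            raise FormatError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)} (both must be > 0)"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Reference:
    """A reference contig: name, uppercase sequence and its length in bp."""

    name: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class AlignmentResult:
    """Final verified placement of one read.

    ``pos`` is the 1-based leftmost reference coordinate of the *declared*
    read start (see :func:`loraln.local_align.refine_position`); ``cigar``
    consumes exactly ``len(seq)`` read bases (S/M/I read-consuming ops).
    ``seq``/``qual`` are stored in alignment orientation (reverse-complemented
    for ``-`` strand placements, as SAM requires).
    """

    read_id: str
    ref_name: str
    pos: int
    strand: str
    cigar: str
    edit_distance: int
    mapq: int
    mapped: bool
    seq: str = ""
    qual: str = ""
    tags: dict = field(default_factory=dict)


def read_fasta(path: str | Path) -> Reference:
    """Read the first record of a FASTA file as a :class:`Reference`.

    The sequence is uppercased and non-ACGTN characters are mapped to N.
    Additional records trigger a warning and are ignored (single-contig
    references suffice for this package).
    """
    try:
        records = SeqIO.parse(str(path), "fasta")
        first = next(records, None)
        if first is None:
            raise FormatError(f"{path}: no FASTA records found")
        if next(records, None) is not None:
            warnings.warn(f"{path}: multiple FASTA records; using only the first")
    except ValueError as exc:  # e.g. sequence data before any '>' header
        raise FormatError(f"{path}: {exc}") from exc
    seq = str(first.seq).upper().translate(_NORMALIZE)
    if not seq:
        raise FormatError(f"{path}: first FASTA record is empty")
    return Reference(name=first.id, seq=seq)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Lazily yield :class:`ReadRecord` from a 4-line-per-record FastQ file."""
    with open(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                read_id = title.split()[0]
                if len(seq) != len(qual):
                    raise FormatError(
                        f"read {read_id!r}: sequence/quality length mismatch"
                    )
                yield ReadRecord(id=read_id, seq=seq.upper(), qual=qual)
        except ValueError as exc:  # biopython's own structural complaints
            if isinstance(exc, FormatError):
                raise
            raise FormatError(str(exc)) from exc


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        for read in reads:
            handle.write(f"@{read.id}\n{read.seq}\n+\n{read.qual}\n")


def _ref_consumed(cigar: str) -> int:
    n, total = 0, 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + int(ch)
        else:
            if ch in "MDN=X":
                total += n
            n = 0
    return total


def write_sam(
    results: Sequence[AlignmentResult], ref: Reference, path: str | Path
) -> None:
    """Write alignment results as a minimal valid SAM file.

    Emits @HD/@SQ headers, FLAG 16 for ``-`` strand, FLAG 4 for unmapped
    reads, the MAPQ column from :attr:`AlignmentResult.mapq` and the edit
    distance as an ``NM`` tag.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": ref.name, "LN": ref.length}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for res in results:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = res.read_id
            if res.mapped:
                if res.pos < 1:
                    raise FormatError(
                        f"read {res.read_id!r}: mapped at non-positive pos {res.pos}"
                    )
                if res.pos - 1 + _ref_consumed(res.cigar) > ref.length:
                    raise FormatError(
                        f"read {res.read_id!r}: alignment overruns reference "
                        f"{ref.name} (len {ref.length})"
                    )
                seg.flag = 16 if res.strand == "-" else 0
                seg.reference_id = 0
                seg.reference_start = res.pos - 1
                seg.mapping_quality = res.mapq
                seg.cigarstring = res.cigar
            else:
                seg.flag = 4
                seg.reference_id = -1
                seg.reference_start = -1
                seg.mapping_quality = 0
            if res.seq:
                seg.query_sequence = res.seq
                seg.query_qualities = pysam.qualitystring_to_array(res.qual)
            tags = [("NM", res.edit_distance)] if res.mapped else []
            tags.extend(sorted(res.tags.items()))
            seg.set_tags(tags)
            out.write(seg)


def read_sam(path: str | Path) -> Iterator[pysam.AlignedSegment]:
    """Iterate SAM records (pysam segments, 0-based coordinates)."""
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as handle:
        yield from handle


def write_truth(truth_records, path: str | Path) -> None:
    """Write simulator ground truth as TSV: read_id, true_start, strand, true_length."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["read_id", "true_start", "strand", "true_length"])
        for rec in truth_records:
            writer.writerow([rec.read_id, rec.true_start, rec.strand, rec.span])


def read_truth(path: str | Path):
    """Read a truth TSV back into a list of TruthRecord."""
    from .simulator import TruthRecord  # local import to avoid a cycle

    out = []
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is None or header[:2] != ["read_id", "true_start"]:
            raise FormatError(f"{path}: not a truth table (bad header {header})")
        for row in reader:
            out.append(
                TruthRecord(
                    read_id=row[0],
                    true_start=int(row[1]),
                    strand=row[2],
                    span=int(row[3]),
                )
            )
    return out
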