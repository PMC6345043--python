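"""Fragmentation of a long read into seeds.

Two seedings are used: *primitive* seeds tile the read end to end at offsets
0, L, 2L, ... (first fragmentation, alignment stage); *overlapping* seeds sit
half a seed later at offsets L//2, L//2 + L, ... so each interior one
straddles two primitive seeds (second fragmentation, assignment stage).
Trailing remainders shorter than L are discarded — short seeds have an
inflated chance of being repetitive.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import ReadRecord

__all__ = ["Seed", "primitive_seeds", "overlapping_seeds", "DEFAULT_SEED_LEN"]

DEFAULT_SEED_LEN = 40


@dataclass(frozen=True)
class Seed:
    read_id: str
    offset: int  # 0-based offset in the read
    length: int
    seq: str
    kind: str  # "primitive" | "overlapping"


def primitive_seeds(read: ReadRecord, L: int = DEFAULT_SEED_LEN) -> list[Seed]:
    """Non-overlapping seeds of length L at offsets 0, L, 2L, ...

    A read shorter than L degenerates to a single full-length seed.
    """
    if len(read) < L:
        return [
            Seed(read.id, 0, len(read), read.seq, "primitive")
        ]
    count = len(read) // L
    return [
        Seed(read.id, i * L, L, read.seq[i * L : (i + 1) * L], "primitive")
        for i in range(count)
    ]


def overlapping_seeds(read: ReadRecord, L: int = DEFAULT_SEED_LEN) -> list[Seed]:
    """Seeds of length L at offsets L//2, L//2 + L, ... (may be empty)."""
    half = L // 2
    if len(read) < half + L:
        return []
    count = (len(read) - half) // L
    return [
        Seed(
            read.id,
            half + i * L,
            L,
            read.seq[half + i * L : half + i * L + L],
            "overlapping",
        )
        for i in range(count)
    ]
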