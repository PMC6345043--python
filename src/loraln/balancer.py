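"""Length-aware load balancing of FastQ reads.

Two balancing problems are solved here.  Across *nodes*, a static one-pass
partitioner scans the reads, sorts every consecutive group of N by length
(descending) and deals the group round-robin with a rotating start, so each
bin receives the group's longest read once every N groups — O(R log N)
comparisons for R reads.  Within a node, reads are split across *threads* by
greedy longest-first assignment to the currently lightest queue, and idle
threads steal from the tail of the fullest queue (owner pops the head, thief
pops the tail, so each read is consumed exactly once).
"""

from __future__ import annotations

from collections import deque
from typing import Sequence, TypeVar

from .io_formats import ReadRecord

__all__ = ["partition_reads", "split_for_threads", "steal"]

T = TypeVar("T")


class _CountedLen:
    """Sort key that counts comparisons, for complexity instrumentation."""

    __slots__ = ("value", "counter")

    def __init__(self, value: int, counter: list[int]):
        self.value = value
        self.counter = counter

    def __lt__(self, other: "_CountedLen") -> bool:
        self.counter[0] += 1
        return self.value < other.value


def partition_reads(
    reads: Sequence[ReadRecord],
    N: int,
    comparison_counter: list[int] | None = None,
) -> list[list[ReadRecord]]:
    """Distribute reads into N bins: group-sort-round-robin with rotation.

    Group ``g`` (reads ``gN .. gN+N-1``) is sorted by length descending; its
    longest read goes to bin ``g % N`` — so the bin receiving a group's
    longest read rotates, every bin getting the maximum once in every N
    groups — and the remaining sorted reads go longest-first to the bins
    with the smallest running total length.  A final partial group is
    distributed the same way.  One pass with two N-element sorts per group:
    O(R log N) comparisons overall.  ``comparison_counter`` (a one-element
    list) accumulates sort comparisons for the complexity assertion.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    bins: list[list[ReadRecord]] = [[] for _ in range(N)]
    totals = [0] * N

    def sort_desc(group: list[ReadRecord]) -> list[ReadRecord]:
        if comparison_counter is not None:
            return sorted(
                group,
                key=lambda r: _CountedLen(-len(r), comparison_counter),
            )
        return sorted(group, key=len, reverse=True)

    def place(b: int, r: ReadRecord) -> None:
        bins[b].append(r)
        totals[b] += len(r)

    group: list[ReadRecord] = []
    g = 0
    for read in reads:
        group.append(read)
        if len(group) == N:
            ordered = sort_desc(group)
            place(g % N, ordered[0])
            rest = sorted(
                (b for b in range(N) if b != g % N), key=lambda b: (totals[b], b)
            )
            for r, b in zip(ordered[1:], rest):
                place(b, r)
            group = []
            g += 1
    for r in sort_desc(group):  # partial final group
        place(min(range(N), key=lambda b: (totals[b], b)), r)
    return bins


def split_for_threads(reads: Sequence[ReadRecord], t: int) -> list[deque]:
    """Greedy longest-first split into t work queues with near-equal total length.

    Queue items are ``(original_index, read)`` so consumers can restore input
    order; each queue is a deque supporting owner/thief ends.
    """
    if t < 1:
        raise ValueError("thread count must be >= 1")
    order = sorted(range(len(reads)), key=lambda i: (-len(reads[i]), i))
    queues: list[list[tuple[int, ReadRecord]]] = [[] for _ in range(t)]
    totals = [0] * t
    for i in order:
        q = min(range(t), key=lambda j: (totals[j], j))
        queues[q].append((i, reads[i]))
        totals[q] += len(reads[i])
    return [deque(q) for q in queues]


def steal(queues: Sequence[deque], finished_thread: int) -> tuple[int, T] | None:
    """One work-stealing step for a thread whose own queue is empty.

    Takes one item from the *tail* of the queue with the most remaining reads
    (owners pop from the head).  Returns ``(victim_index, item)`` or None when
    every queue is empty.  Callers serialise access with a lock; the
    head/tail discipline guarantees exactly-once consumption.
    """
    if queues[finished_thread]:
        raise ValueError("steal() requires the finished thread's queue to be empty")
    order = sorted(range(len(queues)), key=lambda i: (-len(queues[i]), i))
    for victim in order:
        try:
            return victim, queues[victim].pop()
        except IndexError:  # empty, or emptied by its owner concurrently
            continue
    return None
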