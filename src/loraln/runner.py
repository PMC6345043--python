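"""Partitioned processing with a resident aligner and a bounded thread pool.

The reference index is built once and stays in memory for the whole run
(resident aligner); the input FastQ is consumed in fixed-size partitions;
at most one partition is in flight at a time (semaphore admission); inside a
partition, reads are split across threads by total length and idle threads
work-steal.  The output is invariant under thread count, partition size and
partition submission order: each read's placement depends only on the read,
the reference and the engine parameters (per-read RNG streams are derived
from the read id, never from scheduling).
"""

from __future__ import annotations

import itertools
import threading
from dataclasses import dataclass, field
from pathlib import Path

from . import seed_index
from .balancer import split_for_threads, steal
from .engine import EngineParams, align_read
from .io_formats import (
    AlignmentResult,
    ReadRecord,
    Reference,
    read_fasta,
    read_fastq,
    read_truth,
    write_sam,
)
from .simulator import EvalParams, EvalReport, evaluate

__all__ = ["Partition", "ResidentAligner", "RunConfig", "process_partition", "run"]

DEFAULT_PARTITION_SIZE = 4750  # reads per partition (~64 MB at 7 kb mean length)


@dataclass
class Partition:
    id: int
    reads: list[ReadRecord]


class ResidentAligner:
    """Index built exactly once, reused across partitions, one partition at a time."""

    def __init__(self, ref: Reference, params: EngineParams):
        self.ref = ref
        self.params = params
        self._index = None
        self._admission = threading.Semaphore(1)
        self.stats: dict[str, int] = {}
        self._stats_lock = threading.Lock()

    def initialize(self) -> None:
        if self._index is None:
            self._index = seed_index.build_index(self.ref, self.params.k)

    @property
    def index(self):
        if self._index is None:
            raise RuntimeError("ResidentAligner not initialized (call initialize())")
        return self._index

    def align(self, read: ReadRecord) -> AlignmentResult:
        local: dict[str, int] = {}
        result = align_read(read, self.index, self.ref, self.params, stats=local)
        with self._stats_lock:
            for k, v in local.items():
                self.stats[k] = self.stats.get(k, 0) + v
        return result


def process_partition(
    p: Partition,
    engine: ResidentAligner,
    params: EngineParams | None = None,
    t: int = 1,
) -> list[AlignmentResult]:
    """Align every read of one partition with ``t`` worker threads.

    Results come back in the partition's input order.  Admission through the
    engine's semaphore serialises concurrently submitted partitions.
    """
    if engine._index is None:
        raise RuntimeError("engine not initialized before process_partition")
    if params is not None and params is not engine.params:
        engine.params = params
    with engine._admission:
        results: list[AlignmentResult | None] = [None] * len(p.reads)
        if not p.reads:
            return []
        queues = split_for_threads(p.reads, t)
        steal_lock = threading.Lock()

        def worker(me: int) -> None:
            while True:
                try:
                    # owner end; deque pops are atomic under CPython
                    item = queues[me].popleft()
                except IndexError:
                    with steal_lock:
                        stolen = steal(queues, me)
                    if stolen is None:
                        return
                    _, item = stolen
                idx, read = item
                results[idx] = engine.align(read)

        if t == 1:
            worker(0)
        else:
            threads = [
                threading.Thread(target=worker, args=(i,)) for i in range(t)
            ]
            for th in threads:
                th.start()
            for th in threads:
                th.join()
        return results  # type: ignore[return-value]


@dataclass
class RunConfig:
    ref_path: str | Path
    reads_path: str | Path
    out_sam: str | Path
    params: EngineParams = field(default_factory=EngineParams)
    partition_size: int = DEFAULT_PARTITION_SIZE
    threads: int = 1
    truth_path: str | Path | None = None
    eval_params: EvalParams = field(default_factory=EvalParams)


def _partitions(reads, size: int):
    it = iter(reads)
    for pid in itertools.count():
        chunk = list(itertools.islice(it, size))
        if not chunk:
            return
        yield Partition(id=pid, reads=chunk)


def run(config: RunConfig) -> EvalReport | None:
    """End-to-end driver: index once, align partition by partition, write SAM.

    Returns an :class:`EvalReport` when a truth table is supplied, else None.
    """
    ref = read_fasta(config.ref_path)
    engine = ResidentAligner(ref, config.params)
    engine.initialize()
    results: list[AlignmentResult] = []
    for part in _partitions(read_fastq(config.reads_path), config.partition_size):
        results.extend(process_partition(part, engine, t=config.threads))
    write_sam(results, ref, config.out_sam)
    if config.truth_path is not None:
        truth = read_truth(config.truth_path)
        return evaluate(config.out_sam, truth, config.eval_params)
    return None
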