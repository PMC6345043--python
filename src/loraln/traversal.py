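"""Randomized seed-traversal order for the alignment stage.

Two adjacent seeds of a read have a high chance of lying in the same kind of
reference region, so the traversal exploits the outcome of the previous seed:

* after a seed that mapped **uniquely** (a "random region"), the next seed is
  a uniform pick among the unvisited immediate neighbours of the last index,
  falling back to a uniform pick over all unvisited seeds when both
  neighbours are gone;
* after a **repeat** (or unmapped — equally uninformative) seed, and for the
  very first draw, the next seed is uniform over all unvisited seeds.

Compared with a first-to-last sequential sweep this reaches the uniquely
mappable part of a read much sooner when a prefix of the read lies in a
repeat region.  Every index is returned exactly once; the stream is fully
deterministic given the RNG seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

__all__ = ["TraversalState", "next_seed", "read_rng_seed"]


def read_rng_seed(global_seed: int, read_id: str) -> list[int]:
    """Stable per-read RNG seed material, independent of thread schedule."""
    return [global_seed & 0x7FFFFFFF, zlib.crc32(read_id.encode())]


@dataclass
class TraversalState:
    n_seeds: int
    rng: np.random.Generator
    visited: set[int] = field(default_factory=set)
    last_index: int | None = None
    last_status: str | None = None  # "unique" | "repeat" | "unmapped"

    @classmethod
    def for_read(cls, n_seeds: int, global_seed: int, read_id: str) -> "TraversalState":
        return cls(
            n_seeds=n_seeds,
            rng=np.random.default_rng(read_rng_seed(global_seed, read_id)),
        )

    def record(self, index: int, status: str) -> None:
        """Feed back the mapping status of the seed just processed."""
        self.last_index = index
        self.last_status = status


def next_seed(state: TraversalState) -> int | None:
    """Draw the next seed index, or None when every seed has been visited."""
    remaining = state.n_seeds - len(state.visited)
    if remaining <= 0:
        return None
    if state.last_status == "unique" and state.last_index is not None:
        neighbors = [
            j
            for j in (state.last_index - 1, state.last_index + 1)
            if 0 <= j < state.n_seeds and j not in state.visited
        ]
        if neighbors:
            idx = neighbors[int(state.rng.integers(len(neighbors)))]
            state.visited.add(idx)
            return idx
    # first draw, uninformative last seed, or neighbourhood exhausted
    pool = [j for j in range(state.n_seeds) if j not in state.visited]
    idx = pool[int(state.rng.integers(len(pool)))]
    state.visited.add(idx)
    return idx
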