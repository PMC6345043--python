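"""Reproducible simulate-align-evaluate experiments.

One call generates a noisy dataset from a stated error profile, aligns it
with the full pipeline against the same reference, and scores the SAM by
map rate and tolerance accuracy — the protocol used throughout the test
suite and the results-reproduction script.  The Table-style profiles of
PacBio-like synthetic datasets (fixed read length, per-base mismatch and
indel percentages) are provided as :data:`WGSIM_PROFILES`.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass

from .engine import EngineParams, align_read
from .io_formats import Reference, write_sam
from .seed_index import build_index
from .simulator import ErrorProfile, EvalParams, EvalReport, simulate_reads

__all__ = ["WGSIM_PROFILES", "ProfileSpec", "run_profile_experiment"]


@dataclass(frozen=True)
class ProfileSpec:
    read_len: int
    p_sub: float
    p_indel: float

    @property
    def profile(self) -> ErrorProfile:
        return ErrorProfile(p_sub=self.p_sub, p_indel=self.p_indel)


# fixed-length wgsim-style dataset profiles: (read length, mismatch, indel)
WGSIM_PROFILES: dict[str, ProfileSpec] = {
    "wgsim_S0": ProfileSpec(300, 0.009, 0.001),
    "wgsim_S1": ProfileSpec(1000, 0.009, 0.001),
    "wgsim_S2": ProfileSpec(1000, 0.0, 0.10),  # indel rich
    "wgsim_S3": ProfileSpec(1000, 0.09, 0.01),  # mismatch rich
    "wgsim_L0": ProfileSpec(7000, 0.01, 0.16),  # indel rich
    "wgsim_L1": ProfileSpec(7000, 0.009, 0.001),
    "wgsim_L2": ProfileSpec(12000, 0.01, 0.16),  # indel rich
}


def run_profile_experiment(
    ref: Reference,
    spec: ProfileSpec | ErrorProfile,
    n: int,
    seed: int,
    read_len: int | None = None,
    tolerances: tuple[int, ...] = (0, 10, 100),
    mapq_min: int = 10,
    index=None,
    params: EngineParams | None = None,
) -> dict[int, EvalReport]:
    """Simulate ``n`` reads, align them, and evaluate at each tolerance.

    Returns ``{tolerance: EvalReport}``.  ``index`` may be passed to reuse a
    prebuilt seed index of ``ref``.
    """
    from .simulator import evaluate  # local import keeps module load cheap

    if isinstance(spec, ProfileSpec):
        profile = spec.profile
        read_len = spec.read_len if read_len is None else read_len
    else:
        profile = spec
        if read_len is None:
            raise ValueError("read_len required when passing a bare ErrorProfile")
    if params is None:
        params = EngineParams(profile=profile, rng_seed=seed)
    if index is None:
        index = build_index(ref, params.k)
    reads, truth = simulate_reads(ref, n, read_len, profile, seed)
    results = [align_read(read, index, ref, params) for read in reads]
    fd, sam_path = tempfile.mkstemp(suffix=".sam")
    os.close(fd)
    try:
        write_sam(results, ref, sam_path)
        return {
            t: evaluate(sam_path, truth, EvalParams(tolerance=t, mapq_min=mapq_min))
            for t in tolerances
        }
    finally:
        os.unlink(sam_path)
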