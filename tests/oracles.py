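"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results through different algorithms and code
paths than the package: a full-matrix numpy local-alignment DP, an
exhaustive per-offset semi-global scan for seed mapping, and the plain
first-to-last sequential seed traversal.
"""

from __future__ import annotations

import numpy as np

# (score, edits) lexicographic semiring packed into one integer:
# key = score * _SCALE - edits.  _SCALE exceeds any reachable edit count for
# operands <= a few hundred bases, so maximizing the key maximizes score and
# then minimizes edits.
_SCALE = 1 << 12

_L = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _L[_b] = _i


def _codes(s: str) -> np.ndarray:
    return _L[np.frombuffer(s.encode(), dtype=np.uint8)]


def sw_score_edits(a: str, b: str, scoring) -> tuple[int, int]:
    """Full-matrix affine local alignment: (max score, min edits at max score)."""
    q, t = _codes(a), _codes(b)
    m, n = len(q), len(t)
    NEG = np.int64(-(1 << 40))
    go = (scoring.gap_open + scoring.gap_extend) * _SCALE - 1
    ge = scoring.gap_extend * _SCALE - 1
    H = np.zeros(n + 1, dtype=np.int64)
    E = np.full(n + 1, NEG, dtype=np.int64)
    F = np.full(n + 1, NEG, dtype=np.int64)
    best = np.int64(0)
    match_key = scoring.match * _SCALE
    mis_key = scoring.mismatch * _SCALE - 1
    for i in range(1, m + 1):
        sub = np.where((t == q[i - 1]) & (q[i - 1] < 4), match_key, mis_key)
        diag = H[:-1] + sub  # H[i-1, j-1] + s
        F = np.maximum(H + go, F + ge)  # from row i-1, same j
        newH = np.empty(n + 1, dtype=np.int64)
        newH[0] = 0
        e = NEG
        for j in range(1, n + 1):  # E needs the running row -> scalar loop
            e = max(newH[j - 1] + go, e + ge)
            newH[j] = max(np.int64(0), diag[j - 1], e, F[j])
            E[j] = e
        H = newH
        best = max(best, H.max())
    if best <= 0:
        return 0, 0
    score, rem = divmod(int(best), _SCALE)
    # key = score*S - edits with edits >= 0: negative remainder wraps
    if rem:
        score += 1
        edits = _SCALE - rem
    else:
        edits = 0
    return score, edits


def scan_seed(ref_seq: str, query: str, max_edits: int):
    """Exhaustive per-offset semi-global scan of one strand.

    Returns clusters [(representative_offset, min_edits)] of offsets whose
    full-query alignment starting there costs <= max_edits; neighbouring
    offsets within max_edits bp collapse into one cluster represented by the
    best (then smallest) offset.
    """
    q = _codes(query)
    m = len(q)
    width = m + max_edits
    n_off = len(ref_seq) - m + max_edits + 1
    if n_off <= 0:
        return []
    padded = np.concatenate(
        [_codes(ref_seq), np.full(width, 5, dtype=np.int8)]
    )
    idx = np.arange(n_off)[:, None] + np.arange(width)[None, :]
    win = padded[idx]  # all windows, one row per offset
    prev = np.tile(np.arange(width + 1, dtype=np.int32), (n_off, 1))
    for i in range(1, m + 1):
        cur = np.empty_like(prev)
        cur[:, 0] = i
        sub = np.where((win == q[i - 1]) & (q[i - 1] < 4), 0, 1).astype(np.int32)
        diag = prev[:, :-1] + sub
        up = prev[:, 1:] + 1
        cur[:, 1:] = np.minimum(diag, up)
        for j in range(1, width + 1):
            np.minimum(cur[:, j], cur[:, j - 1] + 1, out=cur[:, j])
        prev = cur
    dist = prev.min(axis=1)
    hits = [(int(o), int(d)) for o, d in enumerate(dist) if d <= max_edits]
    clusters = []
    group: list[tuple[int, int]] = []
    for o, d in hits:
        if group and o - group[-1][0] > max_edits:
            clusters.append(group)
            group = []
        group.append((o, d))
    if group:
        clusters.append(group)
    return [
        (min(g, key=lambda x: (x[1], x[0]))[0], min(d for _, d in g))
        for g in clusters
    ]


def sequential_draws_until(statuses: list[str], want: str) -> int:
    """Draws a first-to-last sequential traversal needs to reach a seed
    whose mapping status equals ``want``."""
    for i, s in enumerate(statuses):
        if s == want:
            return i + 1
    return len(statuses)
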