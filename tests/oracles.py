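"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive computation (dynamic
programming, all-offset scans) and stay independent of the library code paths
they check.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from kredit.editing_aware_align import AlignmentParams
from kredit.mito_reference import revcomp


def dp_minimal_t_indels(pre: str, edited: str) -> tuple[int, int]:
    """Minimal (insertions, deletions) aligning two sequences with T-only indels.

    Full O(n*m) dynamic program: non-T characters may only match, Ts may
    match, be deleted from `pre`, or be inserted from `edited`. Returns the
    per-kind counts of the minimal-cost alignment (cost = total indels).
    """
    n, m = len(pre), len(edited)
    INF = 10**9
    dp = np.full((n + 1, m + 1), INF, dtype=np.int64)
    dp[0, 0] = 0
    for i in range(n + 1):
        for j in range(m + 1):
            v = dp[i, j]
            if v == INF:
                continue
            if i < n and j < m and pre[i] == edited[j] and dp[i + 1, j + 1] > v:
                dp[i + 1, j + 1] = v
            if i < n and pre[i] == "T" and dp[i + 1, j] > v + 1:
                dp[i + 1, j] = v + 1  # deletion of a preedited T
            if j < m and edited[j] == "T" and dp[i, j + 1] > v + 1:
                dp[i, j + 1] = v + 1  # insertion of an edited T
    total = int(dp[n, m])
    if total >= INF:
        raise ValueError("not alignable with T-only indels")
    # insertions - deletions is fixed by the length difference
    diff = m - n
    insertions = (total + diff) // 2
    deletions = (total - diff) // 2
    return insertions, deletions


def exhaustive_hits(
    tag: str, sequences: dict[str, str], params: AlignmentParams
) -> set[tuple[str, int, str, int]]:
    """All qualifying ungapped loci by scanning every offset on both strands.

    Returns {(ref_id, start, strand, mismatches)} for loci with
    mismatches <= max_mismatches and score >= min_score_fraction * length.
    """
    L = len(tag)
    out: set[tuple[str, int, str, int]] = set()
    if L < params.seed_length:
        return out
    min_score = params.min_score_fraction * L * params.match_score - 1e-9
    for ref_id, ref in sequences.items():
        if len(ref) < L:
            continue
        windows = sliding_window_view(np.frombuffer(ref.encode(), np.uint8), L)
        for strand, oriented in (("+", tag), ("-", revcomp(tag))):
            t = np.frombuffer(oriented.encode(), np.uint8)
            mm = (windows != t).sum(axis=1)
            score = (L - mm) * params.match_score - mm * params.mismatch_penalty
            ok = (mm <= params.max_mismatches) & (score >= min_score)
            for pos in np.nonzero(ok)[0]:
                out.add((ref_id, int(pos), strand, int(mm[pos])))
    return out


def random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(np.frombuffer(b"ACGT", np.uint8), size=length).tobytes().decode()


def mutate(seq: str, n: int, rng: np.random.Generator) -> str:
    """Apply exactly n substitutions at distinct positions."""
    arr = bytearray(seq, "ascii")
    for p in rng.choice(len(arr), size=n, replace=False):
        arr[p] = rng.choice([b for b in b"ACGT" if b != arr[p]])
    return arr.decode()
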