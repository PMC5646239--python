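"""Affine-gap dynamic-programming kernels (Smith–Waterman and Needleman–Wunsch).

Gap model: a gap of length L costs ``gap_open + (L-1) * gap_extend`` — the
first gapped residue pays the opening penalty.  Kernels are numba-compiled;
exhaustive DP is the point here (no heuristic seeding), so the screen finds
arbitrarily divergent loci at desk scale.

Tie-breaking in tracebacks is deterministic: diagonal, then subject gap,
then query gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

NEG = -(10**9)


@dataclass(frozen=True)
class LocalHit:
    """One local alignment fragment in query/subject coordinates (0-based, half-open)."""

    score: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


@dataclass(frozen=True)
class GlobalAlignment:
    score: int
    aligned_a: str
    aligned_b: str
    matches: int
    columns: int  # columns after trimming terminal-gap overhangs
    identity: float


@njit(cache=True)
def _sw_best_score(profile, s, gap_open, gap_extend):  # pragma: no cover - numba
    n = profile.shape[0]
    m = s.shape[0]
    h_prev = np.zeros(m + 1, np.int32)
    f_prev = np.full(m + 1, NEG, np.int32)
    h_cur = np.zeros(m + 1, np.int32)
    f_cur = np.full(m + 1, NEG, np.int32)
    best = 0
    for i in range(1, n + 1):
        e = NEG
        h_cur[0] = 0
        for j in range(1, m + 1):
            e = max(h_cur[j - 1] - gap_open, e - gap_extend)
            f = max(h_prev[j] - gap_open, f_prev[j] - gap_extend)
            h = h_prev[j - 1] + profile[i - 1, s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            h_cur[j] = h
            f_cur[j] = f
            if h > best:
                best = h
        h_prev, h_cur = h_cur, h_prev
        f_prev, f_cur = f_cur, f_prev
    return best


@njit(cache=True)
def _sw_fill(profile, s, gap_open, gap_extend, banned):  # pragma: no cover - numba
    n = profile.shape[0]
    m = s.shape[0]
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), NEG, np.int32)
    F = np.full((n + 1, m + 1), NEG, np.int32)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if banned[j - 1]:
                continue
            e = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            f = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            E[i, j] = e
            F[i, j] = f
            h = H[i - 1, j - 1] + profile[i - 1, s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
    return H, E, F


@njit(cache=True)
def _nw_fill(profile, s, gap_open, gap_extend):  # pragma: no cover - numba
    n = profile.shape[0]
    m = s.shape[0]
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), NEG, np.int32)
    F = np.full((n + 1, m + 1), NEG, np.int32)
    for j in range(1, m + 1):
        E[0, j] = -(gap_open + (j - 1) * gap_extend)
        H[0, j] = E[0, j]
    for i in range(1, n + 1):
        F[i, 0] = -(gap_open + (i - 1) * gap_extend)
        H[i, 0] = F[i, 0]
        for j in range(1, m + 1):
            e = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            f = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            E[i, j] = e
            F[i, j] = f
            h = H[i - 1, j - 1] + profile[i - 1, s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, j] = h
    return H, E, F


def _traceback_local(H, E, F, q, s, profile, gap_open, gap_extend, i, j):
    qi1, sj1 = i, j
    matches = 0
    columns = 0
    state = 0  # 0=H, 1=E (gap in query, consume subject), 2=F (gap in subject)
    while True:
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            if i > 0 and j > 0 and h == H[i - 1, j - 1] + profile[i - 1, s[j - 1]]:
                columns += 1
                if q[i - 1] == s[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = 1
            elif h == F[i, j]:
                state = 2
            else:  # pragma: no cover - DP consistency
                raise AssertionError("inconsistent traceback state")
        elif state == 1:
            columns += 1
            if E[i, j] == H[i, j - 1] - gap_open:
                j -= 1
                state = 0
            else:
                j -= 1
        else:
            columns += 1
            if F[i, j] == H[i - 1, j] - gap_open:
                i -= 1
                state = 0
            else:
                i -= 1
    return i, qi1, j, sj1, matches, columns


def sw_best(q_enc, s_enc, matrix, gap_open, gap_extend) -> int:
    """Best local alignment score only (O(m) memory)."""
    if len(q_enc) == 0 or len(s_enc) == 0:
        return 0
    profile = np.ascontiguousarray(matrix[q_enc.astype(np.intp)])
    return int(_sw_best_score(profile, s_enc.astype(np.uint8), gap_open, gap_extend))


def sw_all_hits(
    q_enc,
    s_enc,
    matrix,
    gap_open,
    gap_extend,
    min_score,
    max_hits: int = 64,
) -> list[LocalHit]:
    """All non-overlapping (in the subject) local alignments scoring >= min_score.

    Greedy: the optimal alignment is extracted, its subject span masked, and
    the DP re-run until the best remaining score drops below ``min_score``.
    """
    if len(q_enc) == 0 or len(s_enc) == 0:
        return []
    profile = np.ascontiguousarray(matrix[q_enc.astype(np.intp)])
    s_arr = s_enc.astype(np.uint8)
    banned = np.zeros(len(s_enc), dtype=np.bool_)
    hits: list[LocalHit] = []
    for _ in range(max_hits):
        H, E, F = _sw_fill(profile, s_arr, gap_open, gap_extend, banned)
        flat = int(H.argmax())
        i, j = divmod(flat, H.shape[1])
        score = int(H[i, j])
        if score < min_score:
            break
        q0, q1, s0, s1, matches, columns = _traceback_local(
            H, E, F, q_enc, s_arr, profile, gap_open, gap_extend, i, j
        )
        if s1 <= s0:  # pragma: no cover - defensive
            break
        hits.append(LocalHit(score, q0, q1, s0, s1, matches, columns))
        banned[s0:s1] = True
    return hits


def sw_single_best(q_enc, s_enc, matrix, gap_open, gap_extend) -> LocalHit | None:
    """The optimal local alignment, or None when the best score is 0."""
    hits = sw_all_hits(q_enc, s_enc, matrix, gap_open, gap_extend, min_score=1, max_hits=1)
    return hits[0] if hits else None


def nw_align(a: str, b: str, a_enc, b_enc, matrix, gap_open, gap_extend) -> GlobalAlignment:
    """Optimal affine-gap global alignment with aligned strings and identity.

    Identity is matches / aligned columns after trimming terminal-gap
    overhangs (runs of columns at either end where one row is all gap).
    """
    profile = np.ascontiguousarray(matrix[a_enc.astype(np.intp)])
    s_arr = b_enc.astype(np.uint8)
    H, E, F = _nw_fill(profile, s_arr, gap_open, gap_extend)
    i, j = len(a), len(b)
    ops: list[str] = []
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + profile[i - 1, s_arr[j - 1]]:
                ops.append("M")
                i -= 1
                j -= 1
            elif j > 0 and H[i, j] == E[i, j]:
                state = 1
            elif i > 0 and H[i, j] == F[i, j]:
                state = 2
            else:  # pragma: no cover - DP consistency
                raise AssertionError("inconsistent traceback state")
        elif state == 1:
            ops.append("I")  # gap in a, consume b
            if E[i, j] == H[i, j - 1] - gap_open:
                j -= 1
                state = 0
            else:
                j -= 1
        else:
            ops.append("D")  # gap in b, consume a
            if F[i, j] == H[i - 1, j] - gap_open:
                i -= 1
                state = 0
            else:
                i -= 1
    ops.reverse()
    ra, rb = [], []
    ia = ib = 0
    for op in ops:
        if op == "M":
            ra.append(a[ia])
            rb.append(b[ib])
            ia += 1
            ib += 1
        elif op == "I":
            ra.append("-")
            rb.append(b[ib])
            ib += 1
        else:
            ra.append(a[ia])
            rb.append("-")
            ia += 1
    aligned_a = "".join(ra)
    aligned_b = "".join(rb)
    lo = 0
    hi = len(aligned_a)
    while lo < hi and (aligned_a[lo] == "-" or aligned_b[lo] == "-"):
        lo += 1
    while hi > lo and (aligned_a[hi - 1] == "-" or aligned_b[hi - 1] == "-"):
        hi -= 1
    columns = hi - lo
    matches = sum(
        1 for x, y in zip(aligned_a[lo:hi], aligned_b[lo:hi]) if x == y and x != "-"
    )
    identity = matches / columns if columns else 0.0
    return GlobalAlignment(
        int(H[len(a), len(b)]), aligned_a, aligned_b, matches, columns, identity
    )
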