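"""Semi-global (free end-gap) pairwise alignment kernel.

Scoring is unit match/mismatch/gap (+1/-1/-1); leading and trailing gap runs
are free and their columns are excluded from the identity denominator, so

    identity = matches / (matches + mismatches + internal gap columns)

over the maximum-score path.  Ties are resolved deterministically: at each
cell the diagonal move is preferred over the vertical, which is preferred
over the horizontal; among end points the higher score wins, then the longer
alignment, in a fixed scan order.  When every non-empty alignment scores
below zero the empty alignment wins and the identity is 0.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _CODE[_b] = _i
_N_CODE = 4  # N never matches anything, including another N


def encode(sequence: str) -> np.ndarray:
    """Encode A,C,G,T,N as uint8 codes 0..4."""
    arr = _CODE[np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted(set(sequence) - set("ACGTNacgtn"))
        raise ValueError(f"unexpected characters in sequence: {bad}")
    return arr


@njit(cache=True, nogil=True)
def _semi_global(a, b):  # pragma: no cover - exercised via pairwise_identity
    n = a.shape[0]
    m = b.shape[0]
    # previous/current row triplets: best score, matches and columns on the
    # tie-broken best path into each cell
    ps = np.zeros(m + 1, dtype=np.int32)
    pm = np.zeros(m + 1, dtype=np.int32)
    pc = np.zeros(m + 1, dtype=np.int32)
    cs = np.zeros(m + 1, dtype=np.int32)
    cm = np.zeros(m + 1, dtype=np.int32)
    cc = np.zeros(m + 1, dtype=np.int32)

    best_s = np.int32(0)  # empty alignment via the free corner path
    best_m = np.int32(0)
    best_c = np.int32(0)

    for i in range(1, n + 1):
        ai = a[i - 1]
        cs[0] = 0
        cm[0] = 0
        cc[0] = 0
        for j in range(1, m + 1):
            if ai == b[j - 1] and ai != 4:
                s = ps[j - 1] + 1
                mt = pm[j - 1] + 1
            else:
                s = ps[j - 1] - 1
                mt = pm[j - 1]
            ct = pc[j - 1] + 1
            su = ps[j] - 1  # gap in b
            if su > s:
                s = su
                mt = pm[j]
                ct = pc[j] + 1
            sl = cs[j - 1] - 1  # gap in a
            if sl > s:
                s = sl
                mt = cm[j - 1]
                ct = cc[j - 1] + 1
            cs[j] = s
            cm[j] = mt
            cc[j] = ct
        # end point on the last column: trailing gaps in a are free
        if cs[m] > best_s or (cs[m] == best_s and cc[m] > best_c):
            best_s = cs[m]
            best_m = cm[m]
            best_c = cc[m]
        ps, cs = cs, ps
        pm, cm = cm, pm
        pc, cc = cc, pc
    # end points on the last row: trailing gaps in b are free
    for j in range(m + 1):
        if ps[j] > best_s or (ps[j] == best_s and pc[j] > best_c):
            best_s = ps[j]
            best_m = pm[j]
            best_c = pc[j]
    return best_m, best_c


@njit(cache=True, nogil=True)
def _semi_global_banded(a, b, lo, hi):  # pragma: no cover
    """Banded variant restricted to diagonals j - i in [-lo, +hi].

    Exact whenever the optimal path stays inside the band; callers size the
    band from the length difference plus the gap budget a threshold-passing
    alignment could spend, so any genuine above-threshold hit is scored
    exactly.  ``a`` must be the longer sequence.
    """
    n = a.shape[0]
    m = b.shape[0]
    NEG = np.int32(-(1 << 28))
    ps = np.full(m + 1, NEG, dtype=np.int32)
    pm = np.zeros(m + 1, dtype=np.int32)
    pc = np.zeros(m + 1, dtype=np.int32)
    cs = np.full(m + 1, NEG, dtype=np.int32)
    cm = np.zeros(m + 1, dtype=np.int32)
    cc = np.zeros(m + 1, dtype=np.int32)
    for j in range(0, min(m, hi) + 1):
        ps[j] = 0  # free leading gaps in a
    best_s = np.int32(0)
    best_m = np.int32(0)
    best_c = np.int32(0)
    for i in range(1, n + 1):
        ai = a[i - 1]
        jlo = i - lo
        jhi = i + hi
        if jlo < 0:
            jlo = 0
        if jhi > m:
            jhi = m
        if jlo > m:
            break
        if jlo == 0:
            cs[0] = 0  # free leading gaps in b
            cm[0] = 0
            cc[0] = 0
            jstart = 1
        else:
            cs[jlo - 1] = NEG  # guard: left neighbour outside the band
            jstart = jlo
        for j in range(jstart, jhi + 1):
            if ai == b[j - 1] and ai != 4:
                s = ps[j - 1] + 1
                mt = pm[j - 1] + 1
            else:
                s = ps[j - 1] - 1
                mt = pm[j - 1]
            ct = pc[j - 1] + 1
            su = ps[j] - 1
            if su > s:
                s = su
                mt = pm[j]
                ct = pc[j] + 1
            sl = cs[j - 1] - 1
            if sl > s:
                s = sl
                mt = cm[j - 1]
                ct = cc[j - 1] + 1
            cs[j] = s
            cm[j] = mt
            cc[j] = ct
        if jhi + 1 <= m:
            cs[jhi + 1] = NEG  # stale cell guard for the next row's diagonal move
        if jhi == m and (cs[m] > best_s or (cs[m] == best_s and cc[m] > best_c)):
            best_s = cs[m]
            best_m = cm[m]
            best_c = cc[m]
        ps, cs = cs, ps
        pm, cm = cm, pm
        pc, cc = cc, pc
    jlo = n - lo
    if jlo < 0:
        jlo = 0
    jhi = n + hi
    if jhi > m:
        jhi = m
    for j in range(jlo, jhi + 1):
        if ps[j] > best_s or (ps[j] == best_s and pc[j] > best_c):
            best_s = ps[j]
            best_m = pm[j]
            best_c = pc[j]
    return best_m, best_c


def banded_identity(a: np.ndarray, b: np.ndarray, threshold: float,
                    margin: int = 8) -> float:
    """Identity via the banded kernel, sized for the given join threshold.

    ``a`` must be the canonically larger sequence (longer, or equal length
    and lexicographically later encoding).
    """
    gap_budget = int(np.ceil((1.0 - threshold) * a.shape[0])) + margin
    lo = (a.shape[0] - b.shape[0]) + gap_budget
    matches, columns = _semi_global_banded(a, b, lo, gap_budget)
    if columns == 0:
        return 0.0
    return matches / columns


def semi_global_identity(a: np.ndarray, b: np.ndarray) -> float:
    """Identity of the best semi-global alignment of two encoded sequences.

    Called with a canonical argument order by the public wrapper so that
    identity(a, b) == identity(b, a) exactly even on tie-broken paths.
    """
    matches, columns = _semi_global(a, b)
    if columns == 0:
        return 0.0
    return matches / columns
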