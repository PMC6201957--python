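"""Independent brute-force oracles used only by the test suite.

Everything here is written from the definitions, deliberately avoiding the
package's optimised code paths: full-matrix dynamic programming instead of
rolling rows, dictionary bookkeeping instead of the clustering classes,
explicit enumeration instead of scipy, so agreement between the two routes
is meaningful.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def dp_identity(a: str, b: str) -> float:
    """Full-matrix semi-global identity with the package's tie conventions:
    diagonal > up > left inside cells; endpoints scanned down the last
    column then along the last row, keeping strictly better (score, then
    columns).  Arguments are canonically ordered like the package does."""
    if (len(a), a) < (len(b), b):
        a, b = b, a
    n, m = len(a), len(b)
    NEG = -(10 ** 9)
    score = [[0] * (m + 1) for _ in range(n + 1)]
    match = [[0] * (m + 1) for _ in range(n + 1)]
    cols = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            hit = a[i - 1] == b[j - 1] and a[i - 1] != "N"
            s = score[i - 1][j - 1] + (1 if hit else -1)
            mt = match[i - 1][j - 1] + (1 if hit else 0)
            ct = cols[i - 1][j - 1] + 1
            if score[i - 1][j] - 1 > s:
                s = score[i - 1][j] - 1
                mt = match[i - 1][j]
                ct = cols[i - 1][j] + 1
            if score[i][j - 1] - 1 > s:
                s = score[i][j - 1] - 1
                mt = match[i][j - 1]
                ct = cols[i][j - 1] + 1
            score[i][j] = s
            match[i][j] = mt
            cols[i][j] = ct
    best = (0, 0, 0)  # (score, cols, matches): empty alignment allowed
    for i in range(1, n + 1):
        cand = (score[i][m], cols[i][m], match[i][m])
        if cand[0] > best[0] or (cand[0] == best[0] and cand[1] > best[1]):
            best = cand
    for j in range(0, m + 1):
        cand = (score[n][j], cols[n][j], match[n][j])
        if cand[0] > best[0] or (cand[0] == best[0] and cand[1] > best[1]):
            best = cand
    return best[2] / best[1] if best[1] else 0.0


def greedy_reference(ordered, threshold, identity_fn):
    """First-hit greedy clustering from the definition.

    ``ordered`` is a list of (id, sequence) already in processing order;
    returns a list of (representative_id, [member ids]).
    """
    otus: list[tuple[str, str, list[str]]] = []  # (rep id, rep seq, members)
    for rid, seq in ordered:
        for rep_id, rep_seq, members in otus:
            if identity_fn(rep_seq, seq) >= threshold:
                members.append(rid)
                break
        else:
            otus.append((rid, seq, [rid]))
    return [(rep_id, members) for rep_id, _, members in otus]


def commonality_reference(otus1, otus2, n_reads=None) -> float:
    """A = (sum over OTUs of db1 of m) / N from the published definition.

    ``otus1``/``otus2`` are lists of (representative, set of members); m is
    the overlap between a db1 OTU and the db2 OTU containing its
    representative.
    """
    if n_reads is None:
        n_reads = sum(len(mem) for _, mem in otus1)
    total = 0
    for rep, members in otus1:
        for _, members2 in otus2:
            if rep in members2:
                total += len(set(members) & set(members2))
                break
    return total / n_reads


def mannwhitney_exact(x, y) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of group splits."""
    pooled = list(x) + list(y)
    nx = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) \
            + 0.5 * sum(1 for a in xs for b in ys if a == b)

    observed = u_stat(x, y)
    n_obs = min(observed, len(x) * len(y) - observed)
    count = 0
    total = 0
    idx = range(len(pooled))
    for comb in itertools.combinations(idx, nx):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in idx if i not in comb]
        u = u_stat(xs, ys)
        u = min(u, len(xs) * len(ys) - u)
        total += 1
        if u <= n_obs + 1e-12:
            count += 1
    return count / total


def fisher_exact_two_sided(k1, n1, k2, n2) -> float:
    """Two-sided Fisher p by enumerating tables with fixed margins."""
    row1 = k1 + k2
    total = n1 + n2

    def table_p(a):
        return Fraction(math.comb(n1, a) * math.comb(n2, row1 - a),
                        math.comb(total, row1))

    p_obs = table_p(k1)
    p = Fraction(0)
    for a in range(max(0, row1 - n2), min(n1, row1) + 1):
        pa = table_p(a)
        if pa <= p_obs:
            p += pa
    return float(p)


def chao1_reference(counts):
    f1 = sum(1 for c in counts if c == 1)
    f2 = sum(1 for c in counts if c == 2)
    return len(counts) + f1 * (f1 - 1) / (2 * (f2 + 1))


def shannon_reference(counts):
    tot = sum(counts)
    return -sum((c / tot) * math.log(c / tot) for c in counts)


def random_partition(rng, ids):
    """A uniform-ish random partition: random number of blocks, random
    assignment, representatives = first member."""
    ids = list(ids)
    rng.shuffle(ids)
    k = int(rng.integers(1, len(ids) + 1))
    blocks = [[] for _ in range(k)]
    for i, x in enumerate(ids):
        if i < k:
            blocks[i].append(x)  # every block non-empty
        else:
            blocks[int(rng.integers(0, k))].append(x)
    return [(b[0], set(b)) for b in blocks if b]
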