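"""Independent brute-force oracles used to validate the package's
implementations.  These deliberately use naive algorithms (exhaustive scans,
plain DP recursions, full permutation enumeration) and share no code with
the package's own implementation paths."""

from __future__ import annotations

import itertools
from functools import lru_cache

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"}, "U": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
         "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
         "B": "V", "V": "B", "D": "H", "H": "D"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def window_mismatches(window: str, primer: str) -> int:
    """Per-position set-membership mismatch count; template N matches nothing."""
    n = 0
    for t, p in zip(window, primer):
        tset = IUPAC_SETS.get(t, set()) if t != "N" else set()
        if not (tset & IUPAC_SETS[p]):
            n += 1
    return n


def primer_sites_bruteforce(template: str, primer: str,
                            max_mismatch: int, clamp: int):
    """All (start, end, strand, mismatches) by sliding every offset."""
    L = len(primer)
    out = []
    for start in range(len(template) - L + 1):
        window = template[start:start + L]
        mm = window_mismatches(window, primer)
        clamp_mm = window_mismatches(window[L - clamp:], primer[L - clamp:])
        if mm <= max_mismatch and clamp_mm == 0:
            out.append((start, start + L, "+", mm))
        rcp = rc(primer)
        mm = window_mismatches(window, rcp)
        clamp_mm = window_mismatches(window[:clamp], rcp[:clamp])
        if mm <= max_mismatch and clamp_mm == 0:
            out.append((start, start + L, "-", mm))
    return sorted(out)


def identity_oracle(a: str, b: str) -> float:
    """Global-alignment identity minimizing (edit distance, insertions)
    lexicographically; plain recursive DP."""

    @lru_cache(maxsize=None)
    def f(i: int, j: int) -> tuple[int, int]:
        if i == 0:
            return (j, j)
        if j == 0:
            return (i, 0)
        ds, ins = f(i - 1, j - 1)
        cands = [(ds + (a[i - 1] != b[j - 1]), ins)]
        ds, ins = f(i - 1, j)
        cands.append((ds + 1, ins))
        ds, ins = f(i, j - 1)
        cands.append((ds + 1, ins + 1))
        return min(cands)

    d, ins = f(len(a), len(b))
    cols = len(a) + ins
    return (cols - d) / cols


def smith_waterman_score(a: str, b: str, match: int = 2, mismatch: int = -3,
                         gap_open: int = 5, gap_extend: int = 2) -> float:
    """Best local-alignment raw score; a gap of length L costs
    gap_open + gap_extend * L.  Quadratic-space Gotoh DP."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (skip a char)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (skip b char)
    best = 0.0
    first_gap = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - first_gap, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - first_gap, F[i][j - 1] - gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def greedy_cluster_bruteforce(uniques, threshold: float):
    """Replay of abundance-greedy clustering using the identity oracle.

    ``uniques``: list of (sequence, abundance).  Returns a list of clusters,
    each a list of member sequences, first member = representative.
    """
    order = sorted(uniques, key=lambda t: (-t[1], t[0]))
    clusters: list[list[str]] = []
    for seq, _ab in order:
        for members in clusters:
            if identity_oracle(seq, members[0]) >= threshold:
                members.append(seq)
                break
        else:
            clusters.append([seq])
    return clusters


def rank_sum_exact_oracle(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating every group relabelling."""
    pooled = list(x) + list(y)
    nx = len(x)
    # average ranks with ties
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and pooled[order[j]] == pooled[order[i]]:
            j += 1
        avg = (i + 1 + j) / 2.0
        for k in range(i, j):
            ranks[order[k]] = avg
        i = j
    mu = nx * (len(pooled) - nx) / 2.0

    def ustat(idx):
        return sum(ranks[i] for i in idx) - nx * (nx + 1) / 2.0

    obs = abs(ustat(range(nx)) - mu)
    total = 0
    extreme = 0
    for combo in itertools.combinations(range(len(pooled)), nx):
        total += 1
        if abs(ustat(combo) - mu) >= obs - 1e-9:
            extreme += 1
    return extreme / total


def stepwise_quality_trim_oracle(quals, tail_window=25, tail_minq=30.0,
                                 end_window=4, end_minq=20.0):
    """One-base-at-a-time windowed trimmer; returns (start, stop) kept slice."""
    q = list(quals)
    start = 0
    # stage 1: 3' tail, long window
    while q[start:]:
        tail = q[start:][-min(tail_window, len(q) - start):]
        if sum(tail) / len(tail) >= tail_minq:
            break
        q.pop()
    # stage 2: both ends, short window, 5' first each round
    changed = True
    while changed and q[start:]:
        changed = False
        cur = q[start:]
        head = cur[:min(end_window, len(cur))]
        if sum(head) / len(head) < end_minq:
            start += 1
            changed = True
            continue
        cur = q[start:]
        tail = cur[-min(end_window, len(cur)):]
        if cur and sum(tail) / len(tail) < end_minq:
            q.pop()
            changed = True
    return start, len(q)
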