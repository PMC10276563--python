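"""Greedy de-novo OTU clustering, chimera flagging, OTU-table construction.

Pairwise identity is defined on a global alignment as matching columns
divided by alignment columns, gap columns counting as non-matching.  The
alignment used is the one minimizing, lexicographically, (edit distance,
number of alignment columns) -- i.e. among all minimum-edit-distance
alignments the most compact one, which makes the identity value well defined
and independent of aligner tie-breaking.

Clustering is abundance-greedy at a fixed identity threshold (default 0.990):
unique sequences are visited in decreasing dereplicated abundance (ties by
lexicographic sequence order) and each joins the first existing centroid it
matches at or above the threshold, else founds a new OTU.

Chimera flagging is a deliberately simplified two-parent breakpoint test
(a stand-in for reference pipelines' de-novo chimera removal): an OTU is
flagged when its representative splits at one breakpoint into a prefix and a
suffix that each match a distinct more-abundant representative at >= 0.99
identity while the full sequence matches neither.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd


@dataclass
class OTU:
    otu_id: str
    representative: str
    member_ids: list[str] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# pairwise identity

def _lex_alignment_stats(a: str, b: str) -> tuple[int, int]:
    """(edit distance, insertions-into-a) of the lexicographically minimal
    (distance, columns) global alignment, by anti-diagonal DP."""
    n, m = len(a), len(b)
    big = n + m + 1  # combined cost = distance * big + insertions
    ea = np.frombuffer(a.encode(), dtype=np.uint8)
    eb = np.frombuffer(b.encode(), dtype=np.uint8)
    D = np.empty((n + 1, m + 1), dtype=np.int64)
    D[0, :] = np.arange(m + 1) * (big + 1)
    D[:, 0] = np.arange(n + 1) * big
    for k in range(2, n + m + 1):
        i0, i1 = max(1, k - m), min(n, k - 1)
        if i0 > i1:
            continue
        i = np.arange(i0, i1 + 1)
        j = k - i
        sub = D[i - 1, j - 1] + big * (ea[i - 1] != eb[j - 1])
        dele = D[i - 1, j] + big
        ins = D[i, j - 1] + big + 1
        D[i, j] = np.minimum(sub, np.minimum(dele, ins))
    cost = int(D[n, m])
    return cost // big, cost % big


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matching columns / alignment columns."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a, b = a.upper(), b.upper()
    if a == b:
        return 1.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    if len(a) == len(b):
        h = int(np.count_nonzero(
            np.frombuffer(a.encode(), np.uint8)
            != np.frombuffer(b.encode(), np.uint8)))
        if d == h:  # a gap-free alignment is already optimal
            return 1.0 - d / len(a)
    dist, insertions = _lex_alignment_stats(a, b)
    cols = len(a) + insertions
    return (cols - dist) / cols


def identity_at_least(a: str, b: str, threshold: float) -> bool:
    """Fast banded test for pairwise_identity(a, b) >= threshold."""
    a, b = a.upper(), b.upper()
    if a == b:
        return True
    # identity = 1 - d/cols with cols <= len(a)+len(b), so a large distance
    # alone rules the pair out
    k = int((1.0 - threshold) * (len(a) + len(b)))
    d = edlib.align(a, b, task="distance", k=k)["editDistance"]
    if d < 0:
        return False
    return pairwise_identity(a, b) >= threshold


# ---------------------------------------------------------------------------
# greedy clustering

def dereplicate(reads) -> list[tuple[str, int, dict[str, int], list[str]]]:
    """Pool identical sequences.

    ``reads`` yields (sequence, sample_id, read_id).  Returns a list of
    (sequence, total, per-sample counts, member read ids) sorted by
    decreasing abundance, ties by lexicographic sequence order.
    """
    pools: dict[str, tuple[dict[str, int], list[str]]] = {}
    for seq, sample, rid in reads:
        seq = seq.upper()
        if seq not in pools:
            pools[seq] = (defaultdict(int), [])
        per_sample, members = pools[seq]
        per_sample[sample] += 1
        members.append(rid)
    out = [(seq, sum(ps.values()), dict(ps), mem)
           for seq, (ps, mem) in pools.items()]
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def cluster_greedy(reads, identity_threshold: float = 0.990) -> list[OTU]:
    """Abundance-greedy centroid clustering of (seq, sample, read_id) reads."""
    uniques = dereplicate(reads)
    otus: list[OTU] = []
    for seq, total, per_sample, members in uniques:
        placed = None
        for otu in otus:
            if identity_at_least(seq, otu.representative, identity_threshold):
                placed = otu
                break
        if placed is None:
            placed = OTU(otu_id=f"OTU{len(otus) + 1:05d}", representative=seq)
            otus.append(placed)
        placed.member_ids.extend(members)
        for s, c in per_sample.items():
            placed.counts[s] = placed.counts.get(s, 0) + c
    return otus


# ---------------------------------------------------------------------------
# chimera flagging

def _prefix_identity(query: str, target: str) -> float:
    """Identity of `query` against its best-matching prefix of `target`."""
    if not query or not target:
        return 0.0
    d = edlib.align(query, target, mode="SHW", task="distance")["editDistance"]
    return 1.0 - d / len(query)


def _is_two_parent_chimera(rep: str, candidates: list[OTU],
                           min_identity: float, stride: int,
                           min_segment: int) -> bool:
    full_ok = [identity_at_least(rep, c.representative, min_identity)
               for c in candidates]
    if any(full_ok):
        return False
    L = len(rep)
    if L < 2 * min_segment:
        return False
    breakpoints = range(min_segment, L - min_segment + 1, stride)
    pre_best: dict[int, tuple[float, int]] = {}
    suf_best: dict[int, tuple[float, int]] = {}
    for ci, cand in enumerate(candidates):
        t = cand.representative
        tr = t[::-1]
        for b in breakpoints:
            p = _prefix_identity(rep[:b], t)
            if b not in pre_best or p > pre_best[b][0]:
                pre_best[b] = (p, ci)
            s = _prefix_identity(rep[b:][::-1], tr)
            if b not in suf_best or s > suf_best[b][0]:
                suf_best[b] = (s, ci)
    for b in breakpoints:
        p, pi = pre_best[b]
        s, si = suf_best[b]
        if p >= min_identity and s >= min_identity and pi != si:
            return True
    return False


def flag_chimeras(otus: list[OTU], min_identity: float = 0.99,
                  stride: int = 5, min_segment: int = 30
                  ) -> tuple[list[OTU], list[OTU]]:
    """Split OTUs into (kept, flagged-as-chimeric).

    Candidates for parenthood of an OTU are the strictly more abundant OTUs.
    Breakpoints are scanned on a small stride; segments shorter than
    ``min_segment`` are not considered evidence for a parent.
    """
    order = sorted(otus, key=lambda o: (-o.total, o.otu_id))
    kept: list[OTU] = []
    flagged: list[OTU] = []
    for otu in order:
        candidates = [k for k in kept if k.total > otu.total]
        if len(candidates) >= 2 and _is_two_parent_chimera(
                otu.representative, candidates, min_identity,
                stride, min_segment):
            flagged.append(otu)
        else:
            kept.append(otu)
    kept.sort(key=lambda o: o.otu_id)
    flagged.sort(key=lambda o: o.otu_id)
    return kept, flagged


# ---------------------------------------------------------------------------
# OTU table

def build_otu_table(otus: list[OTU], sample_ids: list[str] | None = None,
                    min_total: int = 2) -> pd.DataFrame:
    """Counts table (rows: OTUs, columns: samples), singletons removed.

    Rows whose total count is below ``min_total`` are dropped; all other
    counts are conserved.
    """
    if sample_ids is None:
        seen: set[str] = set()
        for o in otus:
            seen.update(o.counts)
        sample_ids = sorted(seen)
    rows = {o.otu_id: [o.counts.get(s, 0) for s in sample_ids]
            for o in otus if o.total >= min_total}
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=list(sample_ids), dtype=int)
    table.index.name = "otu_id"
    return table.sort_index()
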