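"""Paired-end read processing: clipping, trimming, truncation, merging.

The cascade reimplements a Trimmomatic/Usearch-style recipe in a fixed order:

1. palindrome (read-through) clipping: if the mates' reverse-complement
   overlap implies sequencing past the fragment end by more than 30 bases,
   the read-through bases are clipped from the 3' ends of both mates;
2. terminal homopolymer trimming: a 5' or 3' run of one base longer than
   9 nt is removed;
3. quality trimming: 3' bases are removed one at a time while the trailing
   25-base window has mean Phred < 30, then either end is stepped back while
   its terminal short window (4 nt) has mean Phred < 20;
4. truncation to 300 nt and removal of reads shorter than 250 nt;
5. overlap merging of the mate pair, taking the higher-quality base at
   disagreeing overlap positions.

All window rules evaluate the full read when it is shorter than the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .seqs import revcomp


@dataclass
class FastqRead:
    read_id: str
    bases: str
    quals: np.ndarray  # per-base Phred scores

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int32)
        if len(self.bases) != self.quals.size:
            raise ValueError(f"{self.read_id}: bases/quals length mismatch")
        if self.quals.size and (self.quals.min() < 0 or self.quals.max() > 60):
            raise ValueError(f"{self.read_id}: Phred scores outside [0, 60]")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class QCParams:
    palindrome_min_clip: int = 30
    homopolymer_max: int = 9
    tail_window_len: int = 25
    tail_window_minq: float = 30.0
    end_window_len: int = 4
    end_window_minq: float = 20.0
    truncate_len: int = 300
    min_len: int = 250
    merge_min_overlap: int = 16
    merge_max_mismatch_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.min_len > self.truncate_len:
            raise ValueError("min_len must not exceed truncate_len")


@dataclass
class MergedRead:
    read_id: str
    bases: str
    quals: np.ndarray
    overlap_len: int

    def __len__(self) -> int:
        return len(self.bases)


# ---------------------------------------------------------------------------
# overlap search shared by palindrome clipping and merging

def _overlap_at(b1: np.ndarray, b2: np.ndarray, o: int) -> tuple[int, int]:
    """(overlap_len, mismatches) of read2c placed at offset o on read1."""
    if o >= 0:
        L = min(b1.size - o, b2.size)
        if L <= 0:
            return 0, 0
        mism = int(np.count_nonzero(b1[o:o + L] != b2[:L]))
    else:
        L = min(b1.size, b2.size + o)
        if L <= 0:
            return 0, 0
        mism = int(np.count_nonzero(b1[:L] != b2[-o:-o + L]))
    return L, mism


def _find_overlap(r1_bases: str, r2c_bases: str, min_overlap: int,
                  max_mismatch_frac: float, seed_len: int = 16
                  ) -> tuple[int, int, int] | None:
    """Best placement of r2c on r1.

    Returns ``(offset, overlap_len, mismatches)`` maximizing matching bases
    subject to overlap >= min_overlap and mismatch fraction <= the cap, or
    None.  Exact seed hits are tried first; a full offset scan is the
    fallback, so errors inside the seed do not lose the pair.
    """
    b1 = np.frombuffer(r1_bases.encode(), dtype=np.uint8)
    b2 = np.frombuffer(r2c_bases.encode(), dtype=np.uint8)
    n1, n2 = b1.size, b2.size
    if min(n1, n2) < min_overlap:
        return None

    def evaluate(offsets):
        best = None
        for o in offsets:
            L, mism = _overlap_at(b1, b2, o)
            if L < min_overlap or mism > max_mismatch_frac * L:
                continue
            key = (L - mism, L, -abs(o), -o)
            if best is None or key > best[0]:
                best = (key, o, L, mism)
        return best

    seeds: list[int] = []
    k = min(seed_len, n1, n2)
    probe = r2c_bases[:k]
    start = r1_bases.find(probe)
    while start != -1:
        seeds.append(start)
        start = r1_bases.find(probe, start + 1)
    probe = r1_bases[:k]
    start = r2c_bases.find(probe)
    while start != -1:
        if -start not in seeds:
            seeds.append(-start)
        start = r2c_bases.find(probe, start + 1)
    best = evaluate(seeds)
    if best is None:
        best = evaluate(range(-(n2 - min_overlap), n1 - min_overlap + 1))
    if best is None:
        return None
    _, o, L, mism = best
    return o, L, mism


# ---------------------------------------------------------------------------
# cascade steps

def clip_palindrome(pair: tuple[FastqRead, FastqRead],
                    params: QCParams) -> tuple[FastqRead, FastqRead]:
    """Clip 3' read-through longer than ``palindrome_min_clip`` bases.

    A negative best offset of mate2's reverse complement on mate1 means the
    fragment was shorter than the reads; both mates are cut back to the
    inferred fragment length.  Read-through of exactly the threshold is kept.
    """
    r1, r2 = pair
    hit = _find_overlap(r1.bases, revcomp(r2.bases),
                        params.merge_min_overlap,
                        params.merge_max_mismatch_frac)
    if hit is None:
        return pair
    o, _, _ = hit
    if o >= 0:
        return pair
    frag_len = len(r2) + o
    read_through = max(len(r1), len(r2)) - frag_len
    if read_through <= params.palindrome_min_clip:
        return pair
    c1 = FastqRead(r1.read_id, r1.bases[:frag_len], r1.quals[:frag_len])
    c2 = FastqRead(r2.read_id, r2.bases[:frag_len], r2.quals[:frag_len])
    return c1, c2


def _terminal_run(bases: str, from_end: bool) -> int:
    if not bases:
        return 0
    s = bases[::-1] if from_end else bases
    c = s[0]
    i = 1
    while i < len(s) and s[i] == c:
        i += 1
    return i


def trim_homopolymer(read: FastqRead, params: QCParams) -> FastqRead:
    """Remove a terminal single-base run longer than ``homopolymer_max``."""
    bases, quals = read.bases, read.quals
    lead = _terminal_run(bases, from_end=False)
    if lead > params.homopolymer_max:
        bases, quals = bases[lead:], quals[lead:]
    tail = _terminal_run(bases, from_end=True)
    if tail > params.homopolymer_max:
        bases, quals = bases[:-tail], quals[:-tail]
    return FastqRead(read.read_id, bases, quals)


def _longest_passing_prefix(quals: np.ndarray, window: int,
                            minq: float) -> int:
    """Largest L so that the trailing `window` mean at L passes, else 0.

    Equivalent to trimming one 3' base at a time while the trailing-window
    mean quality is below ``minq``.
    """
    n = quals.size
    if n == 0:
        return 0
    cs = np.concatenate(([0], np.cumsum(quals, dtype=np.float64)))
    ends = np.arange(1, n + 1)
    w = np.minimum(ends, window)
    means = (cs[ends] - cs[ends - w]) / w
    passing = np.flatnonzero(means >= minq)
    return int(passing[-1] + 1) if passing.size else 0


def trim_quality(read: FastqRead, params: QCParams) -> FastqRead:
    """Two-stage windowed quality trimming (Q30/25 nt tail, then Q20 ends)."""
    # stage 1: 3' tail, 25-base window, mean >= 30
    L = _longest_passing_prefix(read.quals, params.tail_window_len,
                                params.tail_window_minq)
    bases, quals = read.bases[:L], read.quals[:L]
    # stage 2: both ends, short window, mean >= 20; one base per iteration
    w, minq = params.end_window_len, params.end_window_minq
    changed = True
    while changed and quals.size:
        changed = False
        k = min(w, quals.size)
        if quals[:k].mean() < minq:
            bases, quals = bases[1:], quals[1:]
            changed = True
            continue
        k = min(w, quals.size)
        if quals.size and quals[-k:].mean() < minq:
            bases, quals = bases[:-1], quals[:-1]
            changed = True
    return FastqRead(read.read_id, bases, quals)


def truncate_and_filter(read: FastqRead, params: QCParams) -> FastqRead | None:
    """Truncate to ``truncate_len``; drop reads shorter than ``min_len``."""
    bases, quals = read.bases, read.quals
    if len(bases) > params.truncate_len:
        bases = bases[:params.truncate_len]
        quals = quals[:params.truncate_len]
    if len(bases) < params.min_len:
        return None
    return FastqRead(read.read_id, bases, quals)


def merge_pair(pair: tuple[FastqRead, FastqRead],
               params: QCParams) -> MergedRead | None:
    """Overlap-merge a mate pair (mate 2 reverse-complemented first).

    Disagreeing overlap positions take the base with the higher Phred score
    (mate 1 wins ties); agreeing positions keep the higher of the two scores.
    """
    r1, r2 = pair
    r2c_bases = revcomp(r2.bases)
    r2c_quals = r2.quals[::-1]
    hit = _find_overlap(r1.bases, r2c_bases, params.merge_min_overlap,
                        params.merge_max_mismatch_frac)
    if hit is None:
        return None
    o, L, _ = hit
    b1 = np.frombuffer(r1.bases.encode(), dtype=np.uint8)
    b2 = np.frombuffer(r2c_bases.encode(), dtype=np.uint8)
    if o >= 0:
        n = max(b1.size, o + b2.size)
        bases = np.zeros(n, dtype=np.uint8)
        quals = np.full(n, -1, dtype=np.int32)
        bases[:b1.size] = b1
        quals[:b1.size] = r1.quals
        sl = slice(o, o + b2.size)
        take2 = (r2c_quals > quals[sl]) | (bases[sl] == 0)
        agree = (bases[sl] == b2) & (quals[sl] >= 0)
        bases[sl] = np.where(take2, b2, bases[sl])
        quals[sl] = np.where(agree, np.maximum(quals[sl], r2c_quals),
                             np.where(take2, r2c_quals, quals[sl]))
    else:
        # fragment shorter than the reads; keep only the fragment span
        F = b2.size + o
        n = min(max(b1.size, F), F)
        bases = b2[-o:-o + n].copy()
        quals = r2c_quals[-o:-o + n].copy()
        m = min(b1.size, n)
        take1 = r1.quals[:m] >= quals[:m]
        agree = b1[:m] == bases[:m]
        bases[:m] = np.where(take1, b1[:m], bases[:m])
        quals[:m] = np.where(agree, np.maximum(quals[:m], r1.quals[:m]),
                             np.where(take1, r1.quals[:m], quals[:m]))
    return MergedRead(r1.read_id, bases.tobytes().decode(), quals, L)


@dataclass
class StageCounts:
    input_pairs: int = 0
    clipped_pairs: int = 0
    dropped_reads: int = 0
    merged: int = 0
    unmerged: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def process_pair(pair: tuple[FastqRead, FastqRead], params: QCParams,
                 counts: StageCounts | None = None) -> MergedRead | None:
    """Run the full cascade on one mate pair."""
    r1, r2 = pair
    c1, c2 = clip_palindrome((r1, r2), params)
    if counts is not None and len(c1) != len(r1):
        counts.clipped_pairs += 1
    out = []
    for r in (c1, c2):
        r = trim_homopolymer(r, params)
        r = trim_quality(r, params)
        r = truncate_and_filter(r, params)
        out.append(r)
    if out[0] is None or out[1] is None:
        if counts is not None:
            counts.dropped_reads += (out[0] is None) + (out[1] is None)
        return None
    merged = merge_pair((out[0], out[1]), params)
    if counts is not None:
        if merged is None:
            counts.unmerged += 1
        else:
            counts.merged += 1
    return merged


def run_qc(pairs, params: QCParams | None = None
           ) -> tuple[list[MergedRead], StageCounts]:
    """Process an iterable of mate pairs; returns merged reads and a ledger."""
    params = params or QCParams()
    counts = StageCounts()
    merged = []
    for pair in pairs:
        counts.input_pairs += 1
        m = process_pair(pair, params, counts)
        if m is not None:
            merged.append(m)
    return merged, counts
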