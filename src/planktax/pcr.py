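"""In-silico PCR with degenerate primers.

Primer sites are accepted when the number of template/primer incompatibilities
does not exceed ``max_mismatch``, with zero mismatches tolerated in the 3'
terminal ``clamp`` bases (polymerase extension requires a matched 3' end).
A template base matches a primer base iff their IUPAC expansions intersect;
a template ``N`` matches nothing, so runs of N cannot create spurious sites.

Amplicons are every compatible forward/reverse site pairing whose inner
length (bases strictly between the primer footprints) lies in
``(0, max_amplicon)``.  Products whose amplified region (primer footprints
included) contains a poly-N run longer than 4 bases are discarded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .seqs import encode_masks, revcomp

#: Published primer pairs shipped as built-in configurations.
#: 18S: V7-9 hypervariable region; 28S: D2 region.
BUILTIN_PRIMERS: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    "18S": (("18S-V7F", "TGGAGYGATHTGTCTGGTTDATTCCG"),
            ("18S-V9R", "TCACCTACGGAWACCTTGTTACG")),
    "28S": (("Zoop_28S_D2F", "GAGAGTTCAAVAGTACGTGAA"),
            ("R635", "GGTCCGTGTTTCAAGACGG")),
    "28S-D1-2": (("F63", "GCATATCAATAAGCGGAGGAAAAG"),
                 ("R635", "GGTCCGTGTTTCAAGACGG")),
}


@dataclass(frozen=True)
class Primer:
    """A 5'->3' oligonucleotide, possibly degenerate."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 4:
            raise ValueError(f"primer {self.name!r} shorter than 4 nt")
        from .seqs import IUPAC_MASK

        bad = set(self.sequence.upper()) - set(IUPAC_MASK)
        if bad:
            raise ValueError(f"primer {self.name!r} has non-IUPAC bases {bad}")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    forward: Primer
    reverse: Primer
    max_mismatch: int = 3
    clamp: int = 3
    max_amplicon: int = 500

    def __post_init__(self) -> None:
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if self.clamp > min(len(self.forward), len(self.reverse)):
            raise ValueError("clamp longer than a primer")


def builtin_pair(marker: str, **kwargs) -> PrimerPair:
    """The published primer pair for a marker ('18S', '28S', '28S-D1-2')."""
    (fn, fs), (rn, rs) = BUILTIN_PRIMERS[marker]
    return PrimerPair(Primer(fn, fs), Primer(rn, rs), **kwargs)


@dataclass(frozen=True)
class PrimerSite:
    """One primer annealing window, on forward-strand coordinates."""

    start: int
    end: int  # half-open
    strand: str  # '+': primer 3' end at `end`; '-': primer 3' end at `start`
    mismatches: int


@dataclass(frozen=True)
class AmpliconHit:
    template_id: str
    fwd_start: int
    fwd_end: int
    rev_start: int
    rev_end: int
    strand: str
    mismatches_fwd: int
    mismatches_rev: int
    inner_sequence: str  # in amplicon (primer) orientation


def degenerate_mismatches(primer_window: str, primer: Primer) -> int:
    """Mismatch count between a template window and a primer, 5'->3'.

    A position matches iff the template base's IUPAC expansion intersects the
    primer base's expansion; template N counts as a mismatch everywhere.
    """
    if len(primer_window) != len(primer):
        raise ValueError(
            f"window length {len(primer_window)} != primer length {len(primer)}"
        )
    tmask = encode_masks(primer_window, template_n_matches_nothing=True)
    pmask = encode_masks(primer.sequence)
    return int(np.count_nonzero((tmask & pmask) == 0))


def _scan_oriented(template_mask: np.ndarray, pattern: str,
                   max_mismatch: int, clamp: int,
                   clamp_at_right: bool) -> list[tuple[int, int]]:
    """All (start, mismatches) of `pattern` along the forward strand."""
    k = len(pattern)
    n = template_mask.size
    if n < k:
        return []
    pmask = encode_masks(pattern)
    windows = np.lib.stride_tricks.sliding_window_view(template_mask, k)
    miss = (windows & pmask) == 0
    total = miss.sum(axis=1)
    ok = total <= max_mismatch
    if clamp > 0:
        clamp_block = miss[:, -clamp:] if clamp_at_right else miss[:, :clamp]
        ok &= ~clamp_block.any(axis=1)
    starts = np.flatnonzero(ok)
    return [(int(s), int(total[s])) for s in starts]


def find_primer_sites(template: str, primer: Primer,
                      max_mismatch: int = 3, clamp: int = 3) -> list[PrimerSite]:
    """All annealing windows of a primer on both strands of a template.

    '+' sites are windows where the primer reads along the forward strand
    (3' end to the right); '-' sites are windows where the primer anneals to
    the forward strand, i.e. its reverse complement reads along the forward
    strand (3' end to the left).
    """
    tmask = encode_masks(template.upper(), template_n_matches_nothing=True)
    sites = [
        PrimerSite(s, s + len(primer), "+", mm)
        for s, mm in _scan_oriented(tmask, primer.sequence, max_mismatch,
                                    clamp, clamp_at_right=True)
    ]
    rc = revcomp(primer.sequence)
    sites += [
        PrimerSite(s, s + len(primer), "-", mm)
        for s, mm in _scan_oriented(tmask, rc, max_mismatch,
                                    clamp, clamp_at_right=False)
    ]
    return sorted(sites, key=lambda x: (x.start, x.strand))


_POLYN = re.compile("N{5,}")


def extract_amplicons(template_id: str, template: str, pair: PrimerPair,
                      polyn_on_inner_only: bool = False) -> list[AmpliconHit]:
    """Every amplicon a primer pair would produce from a template.

    Both orientations are searched: a '+' hit has the forward primer on the
    forward strand and the reverse primer annealing downstream; a '-' hit is
    the mirror image.  The poly-N exclusion (run of N longer than 4) is tested
    on the amplified region including the primer footprints by default.
    """
    template = template.upper()
    fwd_sites = find_primer_sites(template, pair.forward,
                                  pair.max_mismatch, pair.clamp)
    rev_sites = find_primer_sites(template, pair.reverse,
                                  pair.max_mismatch, pair.clamp)
    hits: list[AmpliconHit] = []
    # '+' amplicons: forward primer '+', reverse primer '-' downstream
    for f in (s for s in fwd_sites if s.strand == "+"):
        for r in (s for s in rev_sites if s.strand == "-"):
            if f.end > r.start:
                continue
            inner = template[f.end:r.start]
            if not 0 < len(inner) < pair.max_amplicon:
                continue
            region = inner if polyn_on_inner_only else template[f.start:r.end]
            if _POLYN.search(region):
                continue
            hits.append(AmpliconHit(template_id, f.start, f.end,
                                    r.start, r.end, "+",
                                    f.mismatches, r.mismatches, inner))
    # '-' amplicons: mirror image (forward primer on the reverse strand)
    for f in (s for s in fwd_sites if s.strand == "-"):
        for r in (s for s in rev_sites if s.strand == "+"):
            if r.end > f.start:
                continue
            inner = template[r.end:f.start]
            if not 0 < len(inner) < pair.max_amplicon:
                continue
            region = inner if polyn_on_inner_only else template[r.start:f.end]
            if _POLYN.search(region):
                continue
            hits.append(AmpliconHit(template_id, f.start, f.end,
                                    r.start, r.end, "-",
                                    f.mismatches, r.mismatches, revcomp(inner)))
    return hits


def amplicon_region(template: str, hit: AmpliconHit) -> str:
    """Full amplified product (primer footprints included), 5'->3'."""
    if hit.strand == "+":
        return template[hit.fwd_start:hit.rev_end].upper()
    return revcomp(template[hit.rev_start:hit.fwd_end].upper())
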