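"""Top-hit taxonomic assignment of OTU representatives.

Each representative is locally aligned against every reference record under a
megablast-like scoring scheme (match +2, mismatch -3, gap open 5, gap extend
2); the bitscore is the Karlin-Altschul transform of the raw score.  The hits
attaining the maximal bitscore form the top-hit set; among them, names are
grouped by identical similarity (identities / alignment columns) and the
highest-similarity group is reported as the enumerated top-hit name list.

An OTU is resolved at species level only when the top-hit similarity exceeds
0.98 and the name list is either a single full binomial or one binomial
accompanied only by "Genus sp." records of the same genus (the multi-top-hit
rule).  OTUs sharing an identical top-hit name set are treated as artificial
duplicates of one biological OTU and merged into the member with the greatest
similarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import Align

from .cluster import OTU
from .refdb import RefRecord, ReferenceDatabase

_PLACEHOLDER_EPITHETS = {"sp.", "sp", "cf.", "aff."}


@dataclass(frozen=True)
class ScoringScheme:
    """BLASTN-like default scoring and Karlin-Altschul parameters."""

    match_reward: int = 2
    mismatch_penalty: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    lam: float = 0.625
    k: float = 0.41

    def __post_init__(self) -> None:
        if self.match_reward <= 0 or self.mismatch_penalty >= 0:
            raise ValueError("match reward must be positive, penalty negative")
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")

    def bitscore(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.k)) / math.log(2)

    def aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = self.match_reward
        aligner.mismatch_score = self.mismatch_penalty
        # a gap of length L costs gap_open + gap_extend * L
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


@dataclass(frozen=True)
class AlignmentHit:
    ref_id: str
    ref_name: str
    bitscore: float
    similarity: float  # identities / alignment columns, unrounded
    align_len: int
    raw_score: float


@dataclass
class TopHitAssignment:
    otu_id: str
    tophit_names: tuple[str, ...]
    similarity: float
    resolution: str  # 'species' | 'genus' | 'higher' | 'unassigned'
    species_name: str | None = None
    bitscore: float = float("nan")

    @property
    def similarity_3dp(self) -> float:
        return round(self.similarity, 3)


def local_align(query: str, ref: str,
                scheme: ScoringScheme | None = None,
                ref_id: str = "", ref_name: str = "") -> AlignmentHit:
    """Best local alignment of query vs ref under the scoring scheme."""
    if not query or not ref:
        raise ValueError("query and reference must be non-empty")
    scheme = scheme or ScoringScheme()
    aligner = scheme.aligner()
    alignments = aligner.align(query.upper(), ref.upper())
    best = alignments[0]
    counts = best.counts()
    columns = best.length
    identities = counts.identities
    similarity = identities / columns if columns else 0.0
    return AlignmentHit(ref_id=ref_id, ref_name=ref_name,
                        bitscore=scheme.bitscore(best.score),
                        similarity=similarity, align_len=columns,
                        raw_score=best.score)


def top_hits(query: str, db: ReferenceDatabase | list[RefRecord],
             scheme: ScoringScheme | None = None) -> list[AlignmentHit]:
    """All hits attaining the maximal bitscore over the database.

    Raw scores are computed for every record first (cheap); full alignments
    with identities are only reconstructed for the top-scoring records.
    """
    records = db.records if isinstance(db, ReferenceDatabase) else list(db)
    if not records:
        raise ValueError("reference database is empty")
    scheme = scheme or ScoringScheme()
    aligner = scheme.aligner()
    q = query.upper()
    scores = [float(aligner.score(q, r.sequence)) for r in records]
    best = max(scores)
    hits = [
        local_align(q, r.sequence, scheme, ref_id=r.record_id,
                    ref_name=r.taxonomy_name)
        for r, s in zip(records, scores) if s == best
    ]
    hits.sort(key=lambda h: (-h.similarity, h.ref_name, h.ref_id))
    return hits


def _is_full_binomial(name: str) -> bool:
    parts = name.split()
    return len(parts) >= 2 and parts[1].lower() not in _PLACEHOLDER_EPITHETS


def _genus(name: str) -> str:
    return name.split()[0]


def _resolve_names(names: tuple[str, ...], above_threshold: bool
                   ) -> tuple[str, str | None]:
    """(resolution, species_name) from an enumerated top-hit name list."""
    binomials = sorted({n for n in names if _is_full_binomial(n)})
    genus_sp = [n for n in names if not _is_full_binomial(n) and len(n.split()) >= 2]
    other = [n for n in names if len(n.split()) < 2]
    if above_threshold and len(binomials) == 1 and not other:
        target_genus = _genus(binomials[0])
        if all(_genus(n) == target_genus for n in genus_sp):
            return "species", binomials[0]
    genera = {_genus(n) for n in names if len(n.split()) >= 2}
    if len(genera) == 1 and not other:
        return "genus", None
    return "higher", None


def assign(otu: OTU | str, db: ReferenceDatabase | list[RefRecord],
           threshold: float = 0.98,
           scheme: ScoringScheme | None = None) -> TopHitAssignment:
    """Assign one OTU (or raw sequence) by the top-hit rules.

    Species level requires top-hit similarity strictly above the threshold
    and a name list that pins down a single species (single binomial, or one
    binomial plus same-genus "sp." records).
    """
    if isinstance(otu, OTU):
        otu_id, seq = otu.otu_id, otu.representative
    else:
        otu_id, seq = "query", otu
    hits = top_hits(seq, db, scheme)
    top_sim = hits[0].similarity
    group = [h for h in hits if h.similarity == top_sim]
    names = tuple(sorted({h.ref_name for h in group}))
    if hits[0].raw_score <= 0:
        return TopHitAssignment(otu_id, names, 0.0, "unassigned",
                                bitscore=hits[0].bitscore)
    resolution, species = _resolve_names(names, top_sim > threshold)
    return TopHitAssignment(otu_id, names, top_sim, resolution,
                            species_name=species, bitscore=hits[0].bitscore)


def classify_otus(otus: list[OTU], db: ReferenceDatabase | list[RefRecord],
                  threshold: float = 0.98,
                  scheme: ScoringScheme | None = None
                  ) -> list[TopHitAssignment]:
    return [assign(o, db, threshold, scheme) for o in otus]


def merge_artificial_otus(assignments: list[TopHitAssignment],
                          table: pd.DataFrame
                          ) -> tuple[list[TopHitAssignment], pd.DataFrame,
                                     dict[str, str]]:
    """Merge OTUs sharing an identical top-hit name set.

    The survivor of each group is the OTU with the greatest similarity
    (ties: lexicographically smallest otu_id); per-sample counts are summed
    into the survivor's row.  Unassigned OTUs are never merged.  Returns the
    surviving assignments, the merged table and a provenance map
    merged_id -> survivor_id.
    """
    by_id = {a.otu_id: a for a in assignments}
    missing = [a.otu_id for a in assignments if a.otu_id not in table.index]
    if missing:
        raise ValueError(f"assignments without table rows: {missing}")
    groups: dict[tuple[str, ...], list[TopHitAssignment]] = {}
    for a in assignments:
        if a.resolution == "unassigned" or not a.tophit_names:
            groups[(a.otu_id, "<unassigned>")] = [a]
        else:
            groups.setdefault(a.tophit_names, []).append(a)
    provenance: dict[str, str] = {}
    survivors: list[TopHitAssignment] = []
    merged_table = table.copy()
    for members in groups.values():
        members = sorted(members, key=lambda a: (-a.similarity, a.otu_id))
        keeper = members[0]
        survivors.append(keeper)
        for loser in members[1:]:
            merged_table.loc[keeper.otu_id] += merged_table.loc[loser.otu_id]
            merged_table = merged_table.drop(index=loser.otu_id)
            provenance[loser.otu_id] = keeper.otu_id
    survivors.sort(key=lambda a: a.otu_id)
    merged_table = merged_table.sort_index()
    return survivors, merged_table, provenance


def assignments_frame(assignments: list[TopHitAssignment]) -> pd.DataFrame:
    """Tabular view (similarity reported to 3 decimals)."""
    return pd.DataFrame({
        "otu_id": [a.otu_id for a in assignments],
        "tophit_names": [";".join(a.tophit_names) for a in assignments],
        "similarity": [a.similarity_3dp for a in assignments],
        "bitscore": [round(a.bitscore, 1) for a in assignments],
        "resolution": [a.resolution for a in assignments],
        "species_name": [a.species_name or "" for a in assignments],
    }).set_index("otu_id")
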