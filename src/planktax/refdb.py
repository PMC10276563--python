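"""Reference-database curation: keyword filtering, deduplication, augmentation.

Mirrors the curation rules used when subsetting a public nucleotide database
for rRNA metabarcoding classification: keep records whose description mentions
the ribosomal locus ("ribosomal", "rrna", "rdna"), drop records flagged as
protein/metagenome/uncultured/environmental, drop duplicate accessions, and
build the augmented ("new") database as the old database plus taxonomically
verified sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqs import IUPAC_MASK

DEFAULT_INCLUDE = ("ribosomal", "rrna", "rdna")
DEFAULT_EXCLUDE = ("protein", "metagenome", "uncultured", "environmental")

_MARKER_TOKENS = {"18S": "18S", "28S": "28S"}


@dataclass
class RefRecord:
    """One public-style reference sequence with its reported taxonomy name."""

    record_id: str
    description: str
    marker: str  # '18S' | '28S' | 'unknown'
    sequence: str
    taxonomy_name: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.record_id!r} has empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set(IUPAC_MASK)
        if bad:
            raise ValueError(
                f"record {self.record_id!r} has non-IUPAC characters {bad}"
            )


@dataclass
class KeywordFilter:
    """Substring include/exclude filter over record descriptions.

    A record is kept iff its description contains at least one include term
    and no exclude term.  Matching is case-insensitive by default, mirroring
    Entrez-style free-text behavior.
    """

    include_terms: tuple[str, ...] = DEFAULT_INCLUDE
    exclude_terms: tuple[str, ...] = DEFAULT_EXCLUDE
    case_sensitive: bool = False

    def __post_init__(self) -> None:
        self.include_terms = tuple(self.include_terms)
        self.exclude_terms = tuple(self.exclude_terms)
        if not self.include_terms:
            raise ValueError("include_terms must be non-empty")

    def keeps(self, description: str) -> bool:
        text = description if self.case_sensitive else description.lower()
        inc = self.include_terms if self.case_sensitive else tuple(
            t.lower() for t in self.include_terms)
        exc = self.exclude_terms if self.case_sensitive else tuple(
            t.lower() for t in self.exclude_terms)
        return any(t in text for t in inc) and not any(t in text for t in exc)


@dataclass
class ReferenceDatabase:
    records: list[RefRecord]
    label: str  # 'old' | 'new'

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> set[str]:
        return {r.record_id for r in self.records}

    def for_marker(self, marker: str) -> list[RefRecord]:
        return [r for r in self.records if r.marker == marker]


def filter_records(records: Iterable[RefRecord],
                   kw: KeywordFilter | None = None) -> list[RefRecord]:
    """Keep records passing the keyword filter, preserving input order."""
    kw = kw or KeywordFilter()
    return [r for r in records if kw.keeps(r.description)]


def dedup_records(records: Iterable[RefRecord]) -> list[RefRecord]:
    """Drop later records sharing a record_id with an earlier one (stable)."""
    seen: set[str] = set()
    out: list[RefRecord] = []
    for r in records:
        if r.record_id not in seen:
            seen.add(r.record_id)
            out.append(r)
    return out


def augment(old: ReferenceDatabase,
            verified: Iterable[RefRecord]) -> ReferenceDatabase:
    """Old database plus verified sequences; record_ids must not collide."""
    verified = list(verified)
    old_ids = old.ids()
    for r in verified:
        if r.record_id in old_ids:
            raise ValueError(
                f"verified record id {r.record_id!r} collides with old database"
            )
    vids = [r.record_id for r in verified]
    if len(vids) != len(set(vids)):
        dup = sorted({i for i in vids if vids.count(i) > 1})
        raise ValueError(f"duplicate verified record ids {dup}")
    return ReferenceDatabase(records=list(old.records) + verified, label="new")


def _parse_description(description: str) -> tuple[str, str]:
    """(taxonomy_name, marker) from 'acc Name ... 18S ribosomal RNA gene'."""
    tokens = description.split()
    for i, tok in enumerate(tokens):
        if tok in _MARKER_TOKENS:
            return " ".join(tokens[1:i]), _MARKER_TOKENS[tok]
    return " ".join(tokens[1:]) or tokens[0], "unknown"


def read_fasta(path: str | Path) -> list[RefRecord]:
    """Read reference records from FASTA; the description line carries the
    taxonomy name and the marker token ('18S'/'28S')."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name, marker = _parse_description(rec.description)
        out.append(RefRecord(record_id=rec.id, description=rec.description,
                             marker=marker, sequence=str(rec.seq),
                             taxonomy_name=name))
    return out


def write_fasta(records: Iterable[RefRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.record_id,
                  description=r.description[len(r.record_id):].strip()
                  if r.description.startswith(r.record_id) else r.description)
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")
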