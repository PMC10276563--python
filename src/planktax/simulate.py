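"""Synthetic zooplankton metabarcoding communities.

Everything downstream of wet-lab work is exercised on mock data emulating a
multi-year weekly coastal time series: a pool of copepod-like taxa carrying
18S/28S marker sequences with conserved primer-binding sites, an "old"
public-style reference database with controlled registration gaps plus decoy
records, the taxonomically verified sequences that augment it, seasonal
sea-surface temperature, and paired-end amplicon reads with substitution
errors and two-parent chimeras.

Marker sequences are built as random flank + forward primer site + variable
core + reverse primer site + random flank, with the primer sites inserted as
one concrete realization of each degenerate base, so in-silico PCR recovers
exactly one amplicon per template.  Species within a genus share a genus
ancestor core and differ from it at a bounded number of positions.

Warm-affinity taxa are present only in autumn samples with SST above a
threshold, emulating seasonal transport of warm-water species by a coastal
warm current; paired with a registration mix in which warm taxa are
preferentially unregistered, this produces the autumn excess of
new-database-only detections the pipeline is designed to quantify.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pcr import PrimerPair, builtin_pair, extract_amplicons, amplicon_region
from .qc import FastqRead
from .refdb import RefRecord
from .seqs import realize_degenerate, revcomp

MARKERS = ("18S", "28S")
REGISTRATIONS = ("species_in_old", "genus_only_in_old", "new_only", "absent")

#: default variable-core length per marker (amplicon incl. primers < 500 nt)
CORE_LEN = {"18S": 400, "28S": 370}
FLANK_LEN = 60

#: synthetic sequencing adapters seen on 3' read-through
ADAPTER_R1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCACGTAGCTAGCTAGCTAGCTAGCTAGCT"
ADAPTER_R2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTAGATCTCGGTGGTCGCCGTATCATTAA"

_GENUS_NAMES = [
    "Calanovia", "Oithonella", "Oncaeopsis", "Pseudocalania", "Acartiella",
    "Metridiona", "Centropagia", "Microsetellina", "Corycaella", "Eucalania",
    "Clausopella", "Neocalanella", "Paracalanops", "Scolecella", "Temorina",
    "Tortanella",
]
_EPITHETS = [
    "borealis", "okhotensis", "pacificus", "similis", "venustus", "gracilis",
    "longicornis", "parvus", "abyssalis", "littoralis", "plumosus", "tenuis",
    "robustus", "elegans", "minutus", "septentrionalis", "meridianus",
    "vernalis", "aestivus", "autumnalis", "hiemalis", "orientalis",
    "nipponicus", "insularis", "maritimus", "profundus", "crassus",
    "angustus", "latus", "obscurus", "nitidus", "variabilis",
]

_SST_MEAN = 8.7
_SST_AMPLITUDE = 10.3
_SST_PEAK_DOY = 230  # mid-August peak
_SST_FLOOR = -1.8  # freezing point of seawater


@dataclass(frozen=True)
class SimParams:
    """Knobs for the synthetic study; defaults are the study conditions."""

    seed: int = 0
    read_length: int = 300
    depth_per_sample: int = 500
    substitution_error_rate: float = 0.001
    quality_profile: tuple[float, ...] | None = None  # mean Phred per cycle
    chimera_rate: float = 0.02
    divergence_rate_within_genus: float = 0.02
    divergence_rate_between_genera: float = 0.10
    min_within_genus_diffs: int = 3
    max_within_genus_diffs: int = 40
    quality_jitter_sd: float = 2.0
    sst_noise_sd: float = 3.0
    warm_sst_threshold: float = 10.0
    warm_months: tuple[int, ...] = (9, 10, 11)

    def __post_init__(self) -> None:
        for name in ("substitution_error_rate", "chimera_rate",
                     "divergence_rate_within_genus",
                     "divergence_rate_between_genera"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.read_length < 250:
            raise ValueError("read_length must be >= 250")

    def profile(self) -> np.ndarray:
        """Mean Phred by cycle: plateau at 38, decaying to 22 over the last
        60 cycles (exercises the windowed quality-trimming rules)."""
        if self.quality_profile is not None:
            prof = np.asarray(self.quality_profile, dtype=float)
            if prof.size != self.read_length:
                raise ValueError("quality_profile length != read_length")
            return prof
        n = self.read_length
        ramp = min(60, n)
        prof = np.full(n, 38.0)
        prof[n - ramp:] = np.linspace(38.0, 22.0, ramp)
        return prof


@dataclass
class MockTaxon:
    taxon_id: str
    lineage: dict[str, str]
    binomial_or_sp: str
    marker_seqs: dict[str, str]
    thermal_affinity: str  # 'cold' | 'warm'
    registration: str

    @property
    def genus(self) -> str:
        return self.lineage["genus"]


@dataclass
class SampleSpec:
    sample_id: str
    date: dt.date
    sst_celsius: float
    abundance: np.ndarray  # per-taxon, aligned with scenario.taxa


@dataclass
class CommunityScenario:
    samples: list[SampleSpec]
    taxa: list[MockTaxon]
    seed: int

    def dates(self) -> dict[str, dt.date]:
        return {s.sample_id: s.date for s in self.samples}


# ---------------------------------------------------------------------------
# taxon pool

def _random_core(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    arr = np.array(list(seq))
    pos = rng.choice(len(arr), size=n_subs, replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _registration_counts(n: int, fracs: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n taxa over registration classes."""
    raw = {k: n * fracs.get(k, 0.0) for k in REGISTRATIONS}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    rest = n - sum(counts.values())
    order = sorted(REGISTRATIONS, key=lambda k: raw[k] - counts[k],
                   reverse=True)
    for k in order[:rest]:
        counts[k] += 1
    return counts


#: default registration mix: most dominant species unregistered at species
#: level (70% new_only or genus-only)
DEFAULT_REGISTRATION_FRACS = {
    "species_in_old": 0.3,
    "genus_only_in_old": 0.2,
    "new_only": 0.5,
    "absent": 0.0,
}


def generate_taxon_pool(n_species: int, n_genera: int,
                        frac_warm: float = 0.25,
                        params: SimParams | None = None,
                        registration_counts: dict[str, int] | None = None,
                        registration_fracs: dict[str, float] | None = None,
                        markers: tuple[str, ...] = MARKERS
                        ) -> list[MockTaxon]:
    """Deterministically generate a pool of mock taxa.

    Species are spread round-robin over genera; each genus has an ancestral
    amplicon core per marker from which its species diverge at between
    ``min_within_genus_diffs`` and ``max_within_genus_diffs`` substitutions.
    Warm-affinity taxa are drawn preferentially from the unregistered
    (new_only, then absent) classes.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if not 1 <= n_genera <= n_species:
        raise ValueError("need 1 <= n_genera <= n_species")
    params = params or SimParams()
    rng = np.random.default_rng([params.seed, 11])

    if registration_counts is None:
        fracs = registration_fracs or DEFAULT_REGISTRATION_FRACS
        registration_counts = _registration_counts(n_species, fracs)
    if sum(registration_counts.values()) != n_species:
        raise ValueError("registration counts must sum to n_species")
    labels = [k for k in REGISTRATIONS
              for _ in range(registration_counts.get(k, 0))]
    labels = [labels[i] for i in rng.permutation(n_species)]

    n_warm = int(round(frac_warm * n_species))
    warm_priority = {"new_only": 0, "absent": 1,
                     "genus_only_in_old": 2, "species_in_old": 3}
    by_priority = sorted(range(n_species),
                         key=lambda i: (warm_priority[labels[i]], i))
    warm_idx = set(by_priority[:n_warm])

    genus_names = list(_GENUS_NAMES)
    while len(genus_names) < n_genera:
        genus_names.append(f"Genus{len(genus_names) + 1:02d}")
    pairs = {m: builtin_pair(m) for m in markers}
    fwd_site = {m: realize_degenerate(pairs[m].forward.sequence)
                for m in markers}
    rev_site_rc = {m: revcomp(realize_degenerate(pairs[m].reverse.sequence))
                   for m in markers}
    # rRNA amplicons are broadly conserved across taxa: all genera diverge
    # from one backbone core per marker, so cross-genus alignments span the
    # whole amplicon rather than isolated conserved primer footprints
    backbone = {m: _random_core(rng, CORE_LEN[m]) for m in markers}
    ancestor = {
        (g, m): _mutate(rng, backbone[m],
                        int(rng.binomial(CORE_LEN[m],
                                         params.divergence_rate_between_genera)))
        for g in range(n_genera) for m in markers
    }

    taxa: list[MockTaxon] = []
    used_cores: dict[tuple[int, str], set[str]] = {}
    for i in range(n_species):
        g = i % n_genera
        genus = genus_names[g]
        epithet = _EPITHETS[(i // n_genera) % len(_EPITHETS)]
        binomial = f"{genus} {epithet}"
        marker_seqs: dict[str, str] = {}
        for m in markers:
            for _attempt in range(20):
                n_subs = int(rng.binomial(CORE_LEN[m],
                                          params.divergence_rate_within_genus))
                n_subs = min(max(n_subs, params.min_within_genus_diffs),
                             params.max_within_genus_diffs)
                core = _mutate(rng, ancestor[(g, m)], n_subs)
                if core in used_cores.setdefault((g, m), set()):
                    continue
                seq = (_random_core(rng, FLANK_LEN) + fwd_site[m] + core
                       + rev_site_rc[m] + _random_core(rng, FLANK_LEN))
                if len(extract_amplicons(f"check", seq, pairs[m])) == 1:
                    used_cores[(g, m)].add(core)
                    marker_seqs[m] = seq
                    break
            else:
                raise RuntimeError("could not build a unique marker sequence")
        order = ("Calanoida", "Cyclopoida", "Harpacticoida")[g % 3]
        taxa.append(MockTaxon(
            taxon_id=f"T{i + 1:03d}",
            lineage={"kingdom": "Animalia", "phylum": "Arthropoda",
                     "class": "Copepoda", "order": order,
                     "family": f"{genus}idae", "genus": genus,
                     "species": binomial},
            binomial_or_sp=binomial,
            marker_seqs=marker_seqs,
            thermal_affinity="warm" if i in warm_idx else "cold",
            registration=labels[i],
        ))
    return taxa


# ---------------------------------------------------------------------------
# reference databases

def _ref_description(acc: str, name: str, marker: str) -> str:
    return f"{acc} {name} {marker} ribosomal RNA gene"


def generate_reference_databases(pool: list[MockTaxon], decoy_count: int = 0,
                                 params: SimParams | None = None,
                                 markers: tuple[str, ...] = MARKERS
                                 ) -> tuple[list[RefRecord], list[RefRecord]]:
    """(old public-style records, taxonomically verified records).

    The old database holds species-level records for ``species_in_old`` taxa,
    "Genus sp." records for ``genus_only_in_old`` taxa, nothing for
    ``new_only``/``absent`` taxa, plus ``decoy_count`` records whose
    descriptions carry excluded keywords (uncultured/environmental/...).
    The verified set holds species-level records for every taxon except the
    ``absent`` class.
    """
    if not pool:
        raise ValueError("taxon pool must be non-empty")
    params = params or SimParams()
    rng = np.random.default_rng([params.seed, 23])
    old: list[RefRecord] = []
    verified: list[RefRecord] = []
    serial = 0
    for taxon in pool:
        for m in markers:
            if m not in taxon.marker_seqs:
                continue
            serial += 1
            if taxon.registration == "species_in_old":
                acc = f"PUB{serial:05d}"
                old.append(RefRecord(
                    record_id=acc,
                    description=_ref_description(acc, taxon.binomial_or_sp, m),
                    marker=m, sequence=taxon.marker_seqs[m],
                    taxonomy_name=taxon.binomial_or_sp))
            elif taxon.registration == "genus_only_in_old":
                acc = f"PUB{serial:05d}"
                name = f"{taxon.genus} sp."
                old.append(RefRecord(
                    record_id=acc,
                    description=_ref_description(acc, name, m),
                    marker=m, sequence=taxon.marker_seqs[m],
                    taxonomy_name=name))
            if taxon.registration in ("species_in_old", "genus_only_in_old",
                                      "new_only"):
                acc = f"VER{serial:05d}"
                verified.append(RefRecord(
                    record_id=acc,
                    description=_ref_description(acc, taxon.binomial_or_sp, m),
                    marker=m, sequence=taxon.marker_seqs[m],
                    taxonomy_name=taxon.binomial_or_sp))
    decoy_styles = (
        "uncultured eukaryote {m} ribosomal RNA gene clone",
        "uncultured marine environmental sample {m} rRNA",
        "hypothetical protein gene, partial cds, {m} rRNA region",
        "marine metagenome {m} ribosomal RNA fragment",
    )
    for d in range(decoy_count):
        acc = f"DEC{d + 1:05d}"
        m = markers[d % len(markers)]
        style = decoy_styles[d % len(decoy_styles)]
        old.append(RefRecord(
            record_id=acc,
            description=f"{acc} " + style.format(m=m),
            marker=m, sequence=_random_core(rng, 500),
            taxonomy_name="uncultured organism"))
    return old, verified


# ---------------------------------------------------------------------------
# sea-surface temperature

def sst_model(date: dt.date, params: SimParams | None = None) -> float:
    """Seasonal SST (deg C): sinusoid peaking in mid-August plus seeded noise.

    Calibrated so long-run seasonal means land near 3.6 (spring), 16.5
    (summer), 13.8 (autumn) and 1.0 (winter); day-to-day noise (default SD
    3 deg C) reproduces a realistic observed range; values are floored at the
    freezing point of seawater.
    """
    params = params or SimParams()
    doy = date.timetuple().tm_yday
    base = _SST_MEAN + _SST_AMPLITUDE * math.cos(
        2 * math.pi * (doy - _SST_PEAK_DOY) / 365.25)
    if params.sst_noise_sd > 0:
        rng = np.random.default_rng([params.seed, 57, date.toordinal()])
        base += float(rng.normal(0.0, params.sst_noise_sd))
    return max(base, _SST_FLOOR)


# ---------------------------------------------------------------------------
# community scenario

def generate_scenario(taxa: list[MockTaxon], years: int = 4,
                      start: dt.date = dt.date(2012, 4, 3),
                      params: SimParams | None = None) -> CommunityScenario:
    """Weekly samples over ``years`` years with seasonal composition shifts.

    Cold-affinity taxa are always present with lognormal baseline abundances
    and per-sample lognormal variation; warm-affinity taxa appear only in
    autumn samples with SST above the warm threshold.
    """
    if not taxa:
        raise ValueError("taxa must be non-empty")
    params = params or SimParams()
    rng = np.random.default_rng([params.seed, 101])
    n = len(taxa)
    baseline = rng.lognormal(mean=3.0, sigma=1.0, size=n)
    warm = np.array([t.thermal_affinity == "warm" for t in taxa])
    n_samples = years * 52
    samples: list[SampleSpec] = []
    for w in range(n_samples):
        date = start + dt.timedelta(weeks=w)
        sst = sst_model(date, params)
        noise = rng.lognormal(mean=0.0, sigma=0.5, size=n)
        abundance = baseline * noise
        in_warm_window = (date.month in params.warm_months
                          and sst > params.warm_sst_threshold)
        if not in_warm_window:
            abundance[warm] = 0.0
        if abundance.sum() == 0:
            abundance[0] = 1.0  # every sample has at least one taxon
        samples.append(SampleSpec(sample_id=f"S{w + 1:04d}", date=date,
                                  sst_celsius=sst, abundance=abundance))
    return CommunityScenario(samples=samples, taxa=taxa, seed=params.seed)


# ---------------------------------------------------------------------------
# read simulation

def taxon_amplicons(taxa: list[MockTaxon], marker: str,
                    pair: PrimerPair | None = None) -> dict[str, str]:
    """Full amplified product (primer footprints included) per taxon."""
    pair = pair or builtin_pair(marker)
    out: dict[str, str] = {}
    for t in taxa:
        if marker not in t.marker_seqs:
            raise ValueError(f"taxon {t.taxon_id} lacks marker {marker}")
        hits = extract_amplicons(t.taxon_id, t.marker_seqs[marker], pair)
        if len(hits) != 1:
            raise RuntimeError(
                f"taxon {t.taxon_id} yields {len(hits)} amplicons, expected 1")
        out[t.taxon_id] = amplicon_region(t.marker_seqs[marker], hits[0])
    return out


def _make_pair(rng: np.random.Generator, read_id: str, amplicon: str,
               params: SimParams, profile: np.ndarray,
               mean_profile_err: float) -> tuple[FastqRead, FastqRead]:
    R = params.read_length
    templates = (amplicon + ADAPTER_R1 * 5,
                 revcomp(amplicon) + ADAPTER_R2 * 5)
    reads = []
    for template in templates:
        bases = np.array(list(template[:R]))
        quals = np.clip(np.rint(
            profile + rng.normal(0.0, params.quality_jitter_sd, R)),
            2, 40).astype(np.int32)
        if params.substitution_error_rate > 0:
            per_base = (params.substitution_error_rate
                        * np.power(10.0, -quals / 10.0) / mean_profile_err)
            hit = np.flatnonzero(rng.random(R) < per_base)
            for p in hit:
                choices = [b for b in "ACGT" if b != bases[p]]
                bases[p] = choices[rng.integers(0, 3)]
        reads.append(FastqRead(read_id, "".join(bases), quals))
    return reads[0], reads[1]


def simulate_reads(scenario: CommunityScenario, marker: str,
                   params: SimParams | None = None
                   ) -> tuple[dict[str, tuple[list[FastqRead], list[FastqRead]]],
                              pd.DataFrame]:
    """Paired reads per sample plus the ground-truth ledger.

    Read pairs are drawn from taxon amplicons proportionally to abundance;
    a ``chimera_rate`` fraction of pairs come from two-parent breakpoint
    chimeras.  Read identifiers are "sample:taxon:serial".  The truth table
    has one row per (taxon, sample) with the emitted read-pair count.
    """
    params = params or SimParams()
    if not scenario.samples:
        raise ValueError("scenario has no samples")
    amplicons = taxon_amplicons(scenario.taxa, marker)
    profile = params.profile()
    mean_profile_err = float(np.mean(np.power(10.0, -profile / 10.0)))
    taxon_ids = [t.taxon_id for t in scenario.taxa]
    meta = {t.taxon_id: t for t in scenario.taxa}
    breakpoint_fracs = (0.35, 0.5, 0.65)

    reads_by_sample: dict[str, tuple[list[FastqRead], list[FastqRead]]] = {}
    truth_rows = []
    for si, sample in enumerate(scenario.samples):
        rng = np.random.default_rng([params.seed, 977, si])
        ab = np.asarray(sample.abundance, dtype=float)
        p = ab / ab.sum()
        depth = params.depth_per_sample
        n_chim = rng.binomial(depth, params.chimera_rate) if depth else 0
        if np.count_nonzero(p) < 2:
            n_chim = 0  # chimeras need two distinct parents
        counts = rng.multinomial(depth - n_chim, p)
        r1s: list[FastqRead] = []
        r2s: list[FastqRead] = []
        serial = 0
        for ti, c in enumerate(counts):
            tid = taxon_ids[ti]
            for _ in range(int(c)):
                serial += 1
                rid = f"{sample.sample_id}:{tid}:{serial}"
                r1, r2 = _make_pair(rng, rid, amplicons[tid], params,
                                    profile, mean_profile_err)
                r1s.append(r1)
                r2s.append(r2)
            if c > 0:
                truth_rows.append((tid, sample.sample_id, int(c),
                                   meta[tid].registration,
                                   meta[tid].thermal_affinity))
        chim_counts: dict[str, int] = {}
        for _ in range(int(n_chim)):
            serial += 1
            a, b = rng.choice(len(taxon_ids), size=2, replace=False, p=p)
            frac = breakpoint_fracs[rng.integers(0, len(breakpoint_fracs))]
            amp_a, amp_b = amplicons[taxon_ids[a]], amplicons[taxon_ids[b]]
            chimera = (amp_a[:int(frac * len(amp_a))]
                       + amp_b[int(frac * len(amp_b)):])
            ctid = f"chimera~{taxon_ids[a]}~{taxon_ids[b]}"
            rid = f"{sample.sample_id}:{ctid}:{serial}"
            r1, r2 = _make_pair(rng, rid, chimera, params,
                                profile, mean_profile_err)
            r1s.append(r1)
            r2s.append(r2)
            chim_counts[ctid] = chim_counts.get(ctid, 0) + 1
        for ctid, c in sorted(chim_counts.items()):
            truth_rows.append((ctid, sample.sample_id, c, "chimera", "na"))
        reads_by_sample[sample.sample_id] = (r1s, r2s)
    truth = pd.DataFrame(truth_rows, columns=[
        "taxon_id", "sample_id", "abundance", "registration",
        "thermal_affinity"])
    return reads_by_sample, truth


# ---------------------------------------------------------------------------
# writers (plain-text outputs)

def write_fastq(reads: list[FastqRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            quals = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{quals}\n")


def write_metadata(scenario: CommunityScenario, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tdate\tsst\n")
        for s in scenario.samples:
            fh.write(f"{s.sample_id}\t{s.date.isoformat()}\t"
                     f"{s.sst_celsius:.2f}\n")


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
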