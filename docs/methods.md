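# Methods

## The question the package operationalizes

Metabarcoding assigns amplicon clusters (OTUs) to species by finding each
cluster representative's best hit in a reference database and accepting the
assignment only when the hit is close enough.  When a species' marker
sequence is absent from the database, its OTUs stall at genus level or
below.  `planktax` measures the gain from database augmentation directly:
one fixed set of OTUs is classified twice — against a conventional database
and against the same database plus taxonomically verified sequences — and
the per-sample difference in species-level detections (delta OTUs) is the
quantity of interest.

## Synthetic community model

**Marker sequences.**  Each mock taxon carries one sequence per marker (18S
V7–9, 28S D2) built as

```
flank(60) + forward-primer site + core + revcomp(reverse-primer site) + flank(60)
```

The primer sites are one concrete realization of each degenerate base
(alphabetically first expansion), so every template amplifies exactly once
by construction; this is asserted at generation time and templates are
redrawn on the rare violation.  Core lengths are 400 nt (18S) and 370 nt
(28S), giving amplicons of 449/410 nt including primer footprints — under
the 500 bp in-silico PCR ceiling.

**Sequence divergence.**  Real rRNA amplicons are broadly alignable across
taxa: conserved stretches are interleaved with variable ones, and a BLAST
hit between two copepods spans essentially the whole amplicon.  The
generator reproduces this with a three-level substitution hierarchy: one
random backbone core per marker; genus ancestors diverged from it at
`divergence_rate_between_genera` (default 0.10 per site); species diverged
from their genus ancestor at `divergence_rate_within_genus` (default 0.02,
floored at 3 and capped at 40 substitutions, species cores unique within a
genus).  The defaults place within-genus amplicon identity near 0.96 —
below the 0.98 species-assignment threshold, so a congener's record cannot
species-resolve an unregistered taxon — and cross-genus identity near 0.82,
well clear of everything.  An earlier design with fully independent random
cores per genus was rejected: with no shared backbone, the best *local*
alignment against an unrelated reference collapsed onto the conserved
primer footprint — a short perfect segment with similarity 1.000 — which is
an artifact no real amplicon database exhibits.

**Registration classes.**  Each taxon is labelled `species_in_old`
(species-level record in the old database), `genus_only_in_old` (an
old-database record carrying the same sequence but named "Genus sp."),
`new_only` (record only in the verified set) or `absent` (in neither).  The
default mix is 30/20/50/0 % — most dominant taxa unregistered at species
level, matching the situation that motivates database augmentation.  Decoy
records ("uncultured …", "… metagenome", etc.) are added to the raw old
database and must be removed by the keyword filter.

**Seasonality.**  SST follows
`8.7 + 10.3·cos(2π(doy − 230)/365.25)` °C plus N(0, 3²) noise seeded per
date, floored at −1.8 °C (freezing seawater).  Over four years of weekly
sampling the seasonal means land near 3.8 (spring), 16.4 (summer), 13.8
(autumn) and 1.0 (winter) °C and the noisy series spans roughly −1.8 to
23 °C.  Warm-affinity taxa (default 25 % of the pool, drawn preferentially
from the unregistered classes, emulating seasonal transport of warm-water
species by a coastal warm current) have zero abundance except in
September–November samples with SST > 10 °C.  Cold taxa are always present
with per-taxon lognormal(3, 1) baselines and per-sample lognormal(0, 0.5)
variation.

**Reads.**  Pairs are drawn multinomially over taxon amplicons proportional
to abundance; read length 300 nt; mean Phred 38 with a linear decay to 22
over the last 60 cycles plus N(0, 2²) per-base jitter (clipped to [2, 40]).
Substitution errors are Bernoulli per base with probability
`substitution_error_rate · 10^(−q/10) / mean(10^(−profile/10))` — i.e. the
stated mean rate (default 0.001), concentrated where quality is low.  A
`chimera_rate` fraction of pairs (default 0.02) are two-parent chimeras:
parents drawn abundance-weighted without replacement, breakpoint at 35/50/65
% of the amplicon.  Fragments shorter than the read are padded with fixed
synthetic adapter sequence so read-through clipping is exercised.  Read ids
are `sample:taxon:serial`; a truth table records reads per (taxon, sample)
with registration and thermal affinity.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: indel sequencing errors and quality binning, PCR
amplification bias, primer-template mismatch dropout, intragenomic rRNA
copy variation, mesh-size selectivity, and the taxonomic breadth of a real
nucleotide archive (thousands of off-target records).  Synthetic decoys
test the keyword filter, not database-scale retrieval.

## Analysis parameters

| stage | parameter | default | note |
|---|---|---|---|
| PCR | max mismatches / primer | 3 | none allowed in 3′ clamp |
| PCR | 3′ clamp | 3 bases | applied to both primers |
| PCR | max amplicon | 500 nt | inner sequence bound |
| PCR | poly-N exclusion | run > 4 N | tested on the full amplified region (configurable to inner-only) |
| QC | palindrome clip | > 30 nt read-through | strict inequality |
| QC | homopolymer trim | terminal run > 9 nt | internal runs untouched |
| QC | tail quality | mean Q < 30 over last 25 nt | one base per iteration |
| QC | end quality | mean Q < 20 over terminal 4 nt | window length is our choice; the rule's source names none |
| QC | truncate / min length | 300 / 250 nt | |
| QC | merge | overlap ≥ 16, mismatch ≤ 10 % | merger defaults, configurable |
| cluster | identity | 0.990 (inclusive) | abundance-greedy, ties by sequence order |
| cluster | singleton filter | total < 2 removed | |
| chimera | segment identity | ≥ 0.99 to two distinct more-abundant parents | full sequence < 0.99 to both |
| classify | scoring | +2/−3, gap 5 + 2·L | megablast-like defaults |
| classify | bitscore | λ = 0.625, K = 0.41 | |
| classify | species threshold | similarity > 0.98 (strict) | |
| compare | seasons | MAM/JJA/SON/DJF | |
| compare | rank-sum | exact if pooled n ≤ 20, else tie-corrected normal | two-sided |

## Numerical choices

**Pairwise identity** (clustering) is matching columns over alignment
columns in a global alignment, gap columns counting against identity.  To
make the value well defined across co-optimal alignments, the alignment
minimizes (edit distance, insertion count) lexicographically — the most
compact minimum-distance alignment; identity is then
`(columns − distance)/columns`.  The implementation uses a banded edit
distance (edlib) to reject distant pairs early, a gap-free fast path when a
substitution-only alignment is already optimal, and an anti-diagonal
vectorized DP otherwise; random-pair tests pin it to an independent plain
recursive DP.

**Local alignment** (classification) is Biopython's `PairwiseAligner` in
local mode with `open_gap_score = −(open + extend)` so that a gap of length
L costs `open + extend·L`, matching the BLAST gap convention; raw scores are
pinned to an independent Gotoh DP in tests.  Similarity is identities over
alignment columns of the first optimal alignment; comparisons use unrounded
values and reports round to 3 decimals.  Raw scores are computed for every
record first and full alignments only for the top-scoring set.

**Top-hit ties.**  All records attaining the maximal bitscore form the top
set; within it, names are grouped by identical similarity and the
highest-similarity group is the enumerated top-hit name list.  A "full
species name" is a binomial whose epithet is not `sp.`/`cf.`/`aff.`.
Sub-threshold assignments report the deepest rank shared by the top-hit
names (genus if all names share one genus, else higher); this layer is
reporting-only.

**Artificial-OTU merging** groups OTUs by identical top-hit name set; the
survivor has the greatest similarity, ties broken by smallest OTU id;
unassigned OTUs never merge.  Counts are conserved and the operation is
idempotent.

**Rank-sum test.**  Exact p-values enumerate all C(n₁+n₂, n₁) group
relabellings of the tie-averaged ranks (feasible for pooled n ≤ 20, the
regime of the small-sample tests); larger samples use the tie-corrected
normal approximation with continuity correction.  The old-vs-new per-sample
comparison uses the unpaired test deliberately, although the data are
paired, for fidelity to the procedure being emulated; a paired signed-rank
variant is available behind `paired=True`.  Seasonal pairwise p-values are
reported raw, without multiple-testing correction.

**Quality trimming granularity** removes one base per iteration,
re-evaluating windows, with the stage order 3′-tail-Q30 first, then the
short Q20 windows at the 5′ then 3′ end until stable; reads shorter than a
window are judged on their full length.

**Chimera flagging** scans breakpoints on a stride of 5 nt with a minimum
segment of 30 nt, using prefix/suffix edit distances against candidate
parents.  It is a deliberately simplified stand-in for production chimera
detectors and is documented as such; on simulated chimera-bearing samples
it recovers ≥ 80 % of truth-labelled chimeric OTUs with no false flags on
parent taxa.

## Open design points settled here

- Keyword matching is case-insensitive substring matching over the
  description line only (not a structured organism field).
- Deduplication keeps the first occurrence of a record id.
- Greedy clustering processes unique sequences in decreasing dereplicated
  abundance (ties: lexicographic sequence order), after dereplication.
- The 3′ clamp applies to both primers of a pair.
- A template `N` matches no primer base (preventing N-runs from creating
  spurious sites); non-N template degeneracy matches when expansions
  intersect.
- "Amplified region" for the poly-N exclusion includes the primer
  footprints (configurable).
- Merge consensus takes the higher-Phred base at disagreements (mate 1 wins
  ties) and the max Phred at agreements.
- Warm-affinity taxa are assigned to unregistered registration classes
  first; this coupling (warm ⇒ likely unregistered) is what produces the
  autumn delta-OTU excess and is the intended study condition, not an
  accident.

## Problem sizes used by the shipped tests and acceptance script

Oracle-equivalence tests run 100–120 random instances per primitive at
sequence lengths ≤ 60 nt and sample sizes ≤ 8, where brute force is exact
and fast.  The parameter-recovery study uses 24 taxa over two years of
weekly samples at 500 pairs/sample; the seasonal-contrast runs use four
years at 80 pairs/sample over five seeds; the acceptance script's synthetic
study uses four years at 150 pairs/sample.  These sizes are the package's
defaults for a desk-scale, fully reproducible study; all scale linearly in
depth and sample count.

## Known limitations

- The aligner-level agreement with BLAST is at the level of scoring rules,
  not implementation: no word seeding, X-drop or E-values; at desk scale an
  exact aligner over all references is used instead.
- Exact rank-sum enumeration is limited to pooled n ≤ 20; beyond that the
  normal approximation is used even where an exact network algorithm would
  apply.
- The chimera stand-in tests a single breakpoint only; multi-parent or
  multi-break chimeras would evade it.
- Genus-level and higher assignments depend on parsing name strings, not on
  a taxonomy service; lineage-aware filtering (e.g. restricting to target
  phyla) is available only insofar as the synthetic lineages carry it.
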