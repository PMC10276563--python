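# planktax

Species-level identification of marine zooplankton by rRNA metabarcoding is
only as good as the reference database behind it: when a dominant copepod's
18S or 28S sequence is missing from the public database, its reads are
assigned at genus level at best.  `planktax` is a testbed for quantifying how
much **augmenting a reference database with taxonomically verified
sequences** improves species-level detection in an amplicon metabarcoding
time series — without requiring any real sequence archive.  It simulates a
multi-year weekly coastal zooplankton community with controlled
reference-registration gaps, runs a complete metabarcoding analysis over it,
and compares species-level detections under the conventional ("old") and the
augmented ("new") database.

## What it implements

- **Synthetic communities** (`planktax.simulate`): mock copepod-like taxa
  whose 18S/28S marker sequences carry conserved degenerate-primer binding
  sites around variable cores evolved from a shared backbone; an old
  public-style database with species-level gaps, "Genus sp." records and
  decoy entries; seasonal sea-surface temperature; paired-end reads with
  substitution errors and two-parent chimeras; and a ground-truth ledger.
- **Reference curation** (`planktax.refdb`): keyword include/exclude
  filtering of description lines ("ribosomal"/"rrna"/"rdna" in;
  "protein"/"metagenome"/"uncultured"/"environmental" out), duplicate-id
  removal, and augmentation `new = old ∪ verified`.
- **In-silico PCR** (`planktax.pcr`): degenerate IUPAC primer matching with
  ≤ 3 mismatches per primer, a strict 3′ clamp of 3 bases, amplicons
  < 500 bp, and poly-N (> 4 nt) exclusion.  The published 18S V7–9 and 28S
  D2 primer pairs ship as built-ins.
- **Read QC** (`planktax.qc`): palindrome (read-through) clipping > 30 bp,
  terminal homopolymer trimming > 9 bp, windowed quality trimming
  (mean Q < 30 over the trailing 25 bp, then mean Q < 20 at either end),
  truncation to 300 bp, removal of reads < 250 bp, and overlap merging of
  mate pairs with a higher-Phred consensus.
- **OTU picking** (`planktax.cluster`): abundance-greedy de-novo clustering
  at 0.990 global-alignment identity, a two-parent breakpoint chimera test,
  and an OTU table with singleton (total < 2) removal.
- **Classification** (`planktax.classify`): BLASTN-style local alignment
  (match +2, mismatch −3, gap open 5, gap extend 2; bitscore
  `(λ·S − ln K)/ln 2` with λ = 0.625, K = 0.41), top-hit enumeration over
  equal bitscore and similarity, the strict `similarity > 0.98` species
  rule, the multi-top-hit "one binomial + same-genus sp." rule, and merging
  of artificial OTUs that share an identical top-hit name set.
- **Comparison** (`planktax.compare`): shared/unique OTU counts, per-sample
  delta OTUs (new − old), percent increases, exact/asymptotic two-sided
  Wilcoxon rank-sum tests, and per-season delta summaries
  (spring = Mar–May, …, winter = Dec–Feb).

## Worked example

Two years of weekly samples over 24 taxa (8 registered at species level in
the old database, 10 carried only by the verified set, 6 in neither), 500
read pairs per sample:

```python
from planktax import PipelineConfig, run_pipeline
from planktax.simulate import SimParams

config = PipelineConfig(
    seed=1, years=2, n_species=24, n_genera=8,
    sim=SimParams(depth_per_sample=500),
    registration_counts={"species_in_old": 8, "new_only": 10, "absent": 6},
    merge_artificial=False)
result = run_pipeline(config)
r = result.report
```

printing the report fields gives:

```
OTUs detected at species level:  old 8, new 18
shared 8, unique to new 10, unique to old 0
difference 10 (+125% in total)
per sample: old 7.9 +/- 0.4, new 12.7 +/- 2.3 (+62% per sample)
mean delta OTUs 4.9 +/- 2.3
rank-sum p (old vs new per-sample counts): 7.88e-40
seasonal mean delta: {'spring': 3.9, 'summer': 3.8, 'autumn': 7.9, 'winter': 3.8}
spring vs autumn rank-sum p: 1.64e-06
```

Reading it: the 8 species with old-database records are recovered under both
databases; the 10 taxa present only in the verified set become species-level
detections only after augmentation (`unique to new 10`, every per-sample
delta ≥ 0); and because the warm-affinity unregistered taxa enter the
community only in warm autumn weeks, the delta-OTU excess concentrates in
autumn, which the spring-vs-autumn rank-sum test flags decisively.

The same stages are exposed on the command line
(`planktax simulate | build-db | pcr | qc | cluster | classify | compare |
run`), all reading and writing plain FASTA/FASTQ/TSV/JSON.

## Further reading

`docs/methods.md` describes the simulation model, every threshold and
default, the numerical choices inside the aligners and tests, and the known
limitations of the synthetic approach.
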