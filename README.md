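# probeatlas

Transcriptomics resources for non-model organisms are usually built by
assembling sequencing reads into a transcriptome and designing a
gene-expression microarray against it — which means every probe inherits the
assembler's mistakes and nothing ever confirms that a probe works in an
actual hybridization.  `probeatlas` implements the alternative workflow in
which probes are designed **directly on the sequencing reads**, screened by
two physical hybridization experiments, and only then reduced to a compact
validated library against the assembly:

1. **Design** fixed-length oligos (60-mers by default) on every read longer
   than 60 bp with no unknown bases, constrained by GC content (≤ 50 %),
   homopolymer runs (≤ 7), tandem dinucleotide repeats (≤ 5 copies), and a
   cross-hybridization screen on shared exact words.
2. **Genomic screen (aCGH)** — a two-channel comparative genomic
   hybridization of target-species vs reference-species gDNA.  With log2
   signals *t* and *r*, each probe gets M = t − r and A = t + r and is
   placed in a category by three thresholds (parameter I = 10,
   II = 8, III = 1):
   * **A**: t > I and M > III — strong, species-specific;
   * **B**: II < t ≤ I and M > III — intermediate, specific;
   * **C**: t > I and M ≤ III — strong but non-specific;
   * otherwise rejected.  Probes from contaminant or erroneous reads have
     no genomic target and land in *rejected*.
3. **Expression screen (aGE)** — the same mRNA pool amplified twice: a
   regular oligo-dT linear amplification (3′-biased) and a ddNTP-truncated
   amplification (tightly 3′-restricted).  The restricted channel certifies
   3′ proximity, so probes are ranked by it (`res` descending, ties by
   `reg`, then id).
4. **Match** probes to the assembled transcriptome with Smith–Waterman
   local alignment; a *good match* has bit score
   (λ·S − ln K)/ln 2 > 80 (λ = 1.28, K = 0.46; a perfect 60-mer scores
   ≈ 112 bits).  A probe is usable only if it is **unique to one isogroup**
   (isoforms of one gene may share it) or to exactly one singleton.
5. **Select** greedily in rank order: a probe is taken iff it covers an
   isotig of its isogroup not yet covered, until every isotig of every
   isogroup is covered or candidates run out; then the same pass over the
   singleton set.  Coverage reports follow.

A fully ground-truthed synthetic-data generator (gene/isoform structure
with shared exons, pyrosequencing-like reads with homopolymer-indel errors
and a contaminant fraction, GC-dependent hybridization background, the
two-protocol 3′ decay model) makes the whole pipeline testable offline,
with truth tables for parameter-recovery checks.

## Worked example

A self-contained demo simulates an organism, designs probes on its reads,
runs both screens, matches and selects:

```bash
probeatlas run --seed 42 --out demo_run
```

prints (and writes to `demo_run/manifest.json`):

```json
{
  "n_probes_selected": 52,
  "n_isotigs": 44,
  "n_isotigs_covered": 44,
  "isotig_coverage_pct": 100.0,
  "n_isogroups": 37,
  "n_isogroups_covered": 37,
  "isogroup_coverage_pct": 100.0,
  "n_singletons": 14,
  "n_singletons_covered": 12,
  "singleton_coverage_pct": 85.7,
  "uncovered_reasons": {
    "no_candidate": 1,
    "non_unique_only": 0,
    "filtered_only": 1
  }
}
```

Read: from 748 candidate probes (598 read-designed plus 150 controls) the
pipeline kept 52, enough to target every one of the 44 isotigs (each
isogroup's isoforms all covered) and 12 of 14 singletons.  The two
uncovered singletons are diagnosed: one had no probe reaching it at all
(`no_candidate`), one — a planted contaminant fragment — was reachable only
by probes the genomic screen rejected (`filtered_only`), which is exactly
the clean-up the aCGH stage exists for.  The per-origin screen rates in
`demo_run/acgh_rates.tsv` show 1.0 % of negative-control probes selected,
100 % of positive controls, and 95.0 % of probes from genuine transcript
reads.

Every stage is also available as its own subcommand (`simulate`, `design`,
`acgh`, `age`, `match`, `select`, `report`) over shared TSV contracts, so
real intensity data can replace any simulated table.

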