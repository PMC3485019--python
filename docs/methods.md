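# Methods

## The selection model

`probeatlas` treats probe selection as four independent per-probe
predicates followed by one greedy pass.  The predicates — genomic-screen
category, existence of a good match at the current level, isogroup (or
singleton) uniqueness, and sequence complexity — commute, so their order is
immaterial and is asserted as such in the tests.  The greedy pass walks
survivors in expression-rank order and takes a probe iff it covers at least
one not-yet-covered isotig of its isogroup.  This is deliberately *not*
minimal set cover: the rank encodes measured hybridization quality in the
3′-restricted channel, and a well-measured probe is preferred over a
smaller library.  The worked example in the tests (three probes, two
isotigs) pins the difference: greedy-by-rank selects two probes where the
optimum is one.

### Boundary and tie conventions

* Category boundaries: t = parameter I belongs to B (B's upper edge is
  inclusive), M = parameter III belongs to C (A requires strictly
  M > III).  The published definitions say only "above"/"between"/"below";
  any consistent partition works, this one is fixed and verified by a grid
  audit adjacent to all three thresholds.
* Good-match threshold is strict: bits must exceed 80, so a hit at exactly
  80.0 is excluded.
* Ranking is a total order: restricted channel descending, regular channel
  descending, probe id ascending.  The restricted channel leads because the
  ddNTP-truncated protocol is the one that certifies 3′ proximity; the key
  is configurable (`res` | `reg` | `sum`).
* The isotig set is processed before the singleton set and a selected probe
  is never reused; a probe with any isotig match can never be
  singleton-unique (singleton uniqueness requires exactly one singleton hit
  and zero isotig hits), which prevents double-targeting across sets.
* Category C (strong but non-specific genomic signal) is allowed by
  default; restricting to {A, B} is a config switch.
* All coordinates are 0-based half-open on the forward strand of the
  stored sequence; isotig sequences are assumed stored 5′→3′.

## Alignment and bit scores

Local alignment is Smith–Waterman with affine gaps (match +1, mismatch −2,
gap open −5, extend −2; a gap of length L costs open + (L−1)·extend),
computed by Biopython's `PairwiseAligner`; both subject strands are
searched and the best hit reported.  Raw scores convert to bits by the
Karlin–Altschul relation bits = (λ·S − ln K)/ln 2 with λ = 1.28, K = 0.46,
constants approximating the ungapped +1/−2 nucleotide regime.  Only the
single best local alignment per probe–target pair is scored; there are no
E-values.  The equivalence of the alignment path with an exhaustive
enumeration of alignments is asserted on short strings in the tests.

A word-seeding prefilter may skip probe–target pairs sharing no exact
w-mer.  The safe w is *computed from the scoring scheme*, not assumed: an
alignment whose exact-match runs are all ≤ w−1 long is score-bounded
(mismatch separators consume a query base each; gap separators do not but
cost more), and w is the largest word size for which that bound stays below
the minimum raw score for 80 bits (w = 9 for 60-mers under the defaults).
The bound is tight — an alignment clearing 80 bits with no shared 10-mer
exists — and both safety and tightness are asserted in the tests.  Larger,
faster seed words would silently lose true hits.

## The synthetic data generator

The generator is the package's study-condition definition, not a tuning
surface.  It emulates:

* **Gene structure** — genes with 1–6 exons; isoform counts drawn with
  probabilities 0.86/0.10/0.04 for 1/2/3 isoforms (the skew observed in
  pyrosequencing transcriptome assemblies); isoform k > 1 skips one exon,
  so isoforms share sequence and form isogroups.  Transcripts are
  400–3,000 bp at GC ≈ 0.40 ± 0.07.  30 % of genes are left "unassembled":
  a read-sized 3′ fragment of each becomes a singleton.  The target genome
  concatenates each gene's exons with intergenic spacers (introns are not
  modeled, so only exon-*skip* junctions can break a probe's genomic
  target); the reference genome is independent random sequence except for
  10 % of loci copied in with 2 % divergence.
* **Reads** — 300 reads of truncated-normal length (mean 330, sd 80,
  bounds 60–600; empirical N50 ≈ 347), substitution errors at 10⁻³/base,
  homopolymer indels at 0.01·(run−2) per run of ≥ 3 (the dominant
  pyrosequencing error mode), and 5 % contaminant reads from an unrelated
  random 20 kb genome.  Contaminants are random sequence rather than a real
  foreign genome so the generator needs no downloads; a user FASTA can
  substitute.
* **Genomic hybridization** — a probe present in a genome (decided by
  alignment of the probe against its source locus; > 80 bits) reads out at
  12 log2 units in that channel; absent probes read the background
  6 + 10·max(0, GC − 0.45), i.e. background climbs one log2 unit per 10 %
  GC above 45 %, reaching +2 at GC 0.65.  Noise is Gaussian, sd 0.3 log2
  units.  Contaminant-origin probes are recorded absent without a
  genome-wide scan: an unrelated random 60-mer cannot reach the 43-point
  raw score the threshold requires against either genome.
* **Expression readout** — per-transcript log2 expression ~ N(8, 1.5²).  A
  probe at distance d from the 3′ end reads expr − d/(decay·ln 2), floored
  at a background of 3, with decay 1,500 bp for the regular protocol and
  300 bp for the ddNTP-restricted one — so the restricted channel loses a
  log2 unit every ~208 bp while the regular one loses it every ~1,040 bp,
  which is what makes the restricted signal a usable 3′-proximity ranking.
* **Controls** — 100 negative controls (random oligos, GC spread 0.20–0.70
  to exercise the GC-background diagnostic, present in no genome) and 50
  positive controls drawn from target-genome loci so their genomic presence
  is guaranteed.  Positive controls are defined by construction on the
  *target* genome — the cleanest way to give the selection-rate check a
  population whose expected outcome is known.

All draws flow from one seed through fixed per-stage substreams, so any
stage can be regenerated alone.  Problem sizes (50 genes, 300 reads, 2
probes per read) are chosen so a full run with alignment of every probe
against every transcript completes in about two minutes on one CPU while
still containing multi-isoform isogroups, singletons, conserved loci and
contaminants in countable numbers.

### What passing tests do and do not show

The generator plants exactly the structure the pipeline is built to
recover, with Gaussian noise and a clean two-state (present/absent) signal
model.  Passing the recovery checks therefore shows the *algorithms* do
what they claim — contaminant probes fall at the genomic screen, the
restricted channel ranks 3′ proximity, greedy selection covers everything
reachable — not that real arrays behave this cleanly.  Real two-channel
data has dye bias, spatial artifacts, saturation, partial hybridization of
diverged targets and population overlap far worse than the simulation's;
the published control rates (2.7 % negative, 86.6 % positive) are
noisier than the synthetic analogues (≈ 1 %, ≈ 100 %) for exactly those
reasons.  No between- or within-array normalization is applied — the
workflow consumes extracted median log2 signals directly — but a
pass-through hook exists for user-supplied normalization.

## Known limitations

* No thermodynamic (Tm/ΔG) or secondary-structure modeling in design; the
  cross-hybridization screen is a shared-exact-word proxy (24-mers by
  default) rather than a hybridization-energy model.
* The aligner scores only the best local hit per pair; probes matching one
  target twice are not distinguished.
* Singleton 3′ orientation is taken on faith from the stored sequence; if
  orientation is unknown the relative-position analysis should be read
  per-orientation.
* The expression decay model is an abstraction of amplification chemistry;
  it makes no attempt at sequence-dependent termination rates.
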