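# Methods

This package re-implements, as a tested pipeline, the downstream computational
stages of a FoxH1 ChIP-seq + two-genotype expression study in early zebrafish
embryos: peak quality filtering, canonical/non-canonical (CAN/NC) peak
classification by the FoxH1 consensus, peak-to-gene association through
basal+extended regulatory domains, Smad2-binding-region (SBR) co-localization
profiling, SMAD–FoxH1 motif pairing, and the integration of peak classes with
log2 fold changes from two mutant-vs-wild-type contrasts. A synthetic-data
generator with planted ground truth stands in for the original sequencing and
microarray products, so every stage runs and is validated offline.

## Coordinate model

All internal coordinates are 0-based half-open (BED convention). GFF3/GTF
1-based inclusive coordinates are converted at the I/O boundary only, which
keeps all overlap and windowing arithmetic free of off-by-one adjustments.
Each gene is reduced to one model per gene (default: the transcript whose TSS
is most distal in the direction of transcription; a per-transcript mode
exists). Exons are stored as fragments flagged `UTR` / `non-UTR`, where
`non-UTR` means the CDS-overlapping portion of the exon — exonic bases minus
annotated UTR bases. This is the set the exon-overlap filter uses.

## Peak QC

Three pure per-peak predicates, applied p-value → exon → repeat:

* **p-value** — retain peaks with −log10 p strictly above the cutoff
  (default 4, i.e. p < 1e−4), mirroring MACS cutoff semantics. Configurable
  to ≥.
* **Coding-exon overlap** — remove a peak iff its overlap with the *merged*
  union of non-UTR exonic bases exceeds 50% of the peak length, strictly:
  exactly half is retained. Merging prevents double-counting where exons of
  different genes/transcripts overlap. UTR bases never count. Peaks on
  chromosomes absent from the annotation are retained with a warning.
* **Simple repeats** — remove a peak iff its extracted forward-strand
  sequence contains any of the repeat literals as an exact substring. The
  default set is the three patterns used for the original peak set, with the
  bracketed position `AGAGAGAGA[GA]AGAGAGAGAGA` read as a one-base G/A
  character class, yielding two 21-mers. The 8-bp pattern `GAGAGAAA` is
  deliberately permissive and is applied verbatim; whether it was intended as
  a longer pattern is unknowable from the source material, so it is kept
  as printed and documented here. The CT- and AG-run patterns are each
  other's reverse-complement family, so a forward-strand scan effectively
  covers both strands; an explicit both-strand mode is available.

Because each filter is a pure predicate, the retained set is invariant to
filter order (tested); only the attribution of removal reasons depends on it.
With `exhaustive_flags` every filter is evaluated for every peak.

## Motif scanning and CAN/NC classification

The FoxH1 consensus AATMCACA (M = A/C) is scanned as an exact IUPAC match on
both strands; sequence `N` matches nothing; overlapping matches are all
reported. Reverse-strand hits are matches of the reverse-complemented pattern
on the forward sequence, reported at the forward-coordinate window start. A
peak is CAN iff it contains ≥ 1 hit inside its interval, otherwise NC. A
PWM-with-threshold mode was considered and deliberately left out of the
default path: the classification that defines CAN/NC in this analysis family
is the exact consensus, and an exact matcher is oracle-testable (the suite
compares it against an expand-and-test brute force, and the background hit
rate against the analytic expectation 2·(L−m+1)·k/4^m).

**SMAD pairing.** Nodal-responsive CAN sites typically carry a SMAD-binding
element a short distance 5′ of the FoxH1 word. A peak is `smad_paired` iff
some SMAD hit's 3′-most base lies within `max_gap` (default 100) bases 5′ of
some FoxH1 hit's 5′ end, where 5′/3′ are defined by the *FoxH1 hit's strand*
— motif orientation, not the reference strand, defines cis-regulatory
direction. Negative gaps (overlap) are excluded by default (`min_gap=0`,
configurable). The SMAD scan window extends `max_gap` plus the motif length
beyond the peak so near-edge FoxH1 hits see their flanks. The proprietary
Genomatix SMAD weight matrices are not distributable; the default SMAD motif
is the published palindromic Smad-binding element GTCTAGAC, and users can
supply any IUPAC consensus list.

## Regulatory domains and association

Every gene receives an unconditional **basal domain**: 5 kb upstream and 1 kb
downstream of the TSS, gene-oriented, with the TSS base counted in the
downstream part on both strands ('+': `[TSS−5000, TSS+1000)`; '−':
`[TSS−999, TSS+5001)`). Basal domains of different genes may overlap. The
**extended domain** stretches each side to the nearest of: the edge of
another gene's basal domain that does **not** overlap this gene's own basal
(domains may abut, never overlap such a neighbor), the directional cap
(50 kb upstream / 20 kb downstream of the TSS), or the chromosome edge.
Neighbors whose basal overlaps the gene's own basal cannot constrain the
extension (they are skipped and the next constraint applies). Ties between
coinciding neighbor edges need no tie-break — both give the same boundary.
The implementation is compared, exactly, against an independent quadratic
brute force on random gene layouts.

Peak→gene membership is by peak **midpoint** (`floor((start+end)/2)`),
GREAT-style, because interval membership is ambiguous for straddling peaks;
an `any_overlap` mode exists. A peak may associate with several genes.
Signed distances are gene-oriented (negative = upstream). A second, simpler
screen — a fixed 50 kb/20 kb TSS window with no neighbor limiting — is
exposed separately (`genes_with_peaks_in_window`); every midpoint association
is provably inside the corresponding window (tested).

## SBR co-localization

For every same-chromosome (center, query) pair, the signed
midpoint-to-midpoint distance is binned into half-open 250 bp bins inside a
±window (default ±10 kb — the profile window is not fixed by the source
analysis; ±10 kb covers the proximal enhancer range and is configurable);
distance 0 falls in the bin `[0, 250)`. The baseline profile repeats the
computation around an equal-sized set of uniformly re-placed peaks
(per-chromosome and per-length matched by default; seeded and reproducible).
The comparison reports per-bin ratios of pair-normalized counts with a +1
pseudo-count on the baseline bin counts (stability at empty bins), a central
(|d| < 1 kb) enrichment score, and a one-sided binomial test of the real
central proportion against the baseline central proportion. Degenerate
inputs (zero pairs) are flagged rather than tested. Both raw counts and
densities are emitted since either normalization may be wanted downstream.

## Expression integration

Regulation calls are UP iff log2FC ≥ 1 and DOWN iff ≤ −1 — the twofold
boundary is **inclusive** ("at least twofold"); a strict mode exists because
the category definition is stated both ways in the source material. Genes
are classed CAN / NC / CAN+NC by the classes of their associated peaks, or
`none` (reported, not dropped) when no peak associates. The summary counts
genes per (peak class × regulation) cell, counts SMAD-cobound regulated
genes, and measures **concordance**: the fraction of primary-contrast
regulated genes regulated in the same direction, at the same threshold, in
the secondary contrast. The heatmap matrix sorts genes by primary log2FC
descending with lexicographic gene-id tie-break. Probe-level tables can be
collapsed to gene level by maximum |log2FC| (helper provided; the default
input is assumed gene-level).

## Synthetic data generator

The generator emulates the study's downstream products at a desk-scale size
chosen for fast, exhaustive testing: 4 chromosomes × 1.5 Mb, 500 genes,
2,000 peaks of which 14% carry one planted consensus word, 1,000 SBRs of
which 60% are placed at a Normal(0, 500 bp) displacement from a canonical
peak midpoint, and a two-contrast expression table with 150 regulated genes
whose planted |log2FC| is 1 + Exponential(0.75) and whose direction agrees
between contrasts with probability 0.76. Decoy peaks exercise each filter:
5% sub-threshold p-values, 5% placed to overlap a coding exon by > 50%, 5%
carrying a planted repeat literal.

Key design choices:

* **Background** is i.i.d. uniform {A,C,G,T}; an order-1 Markov option with
  configurable GC adds repeat-like runs for filter realism. With
  `motif_free_background` (default) the background is rejection-sampled
  until it contains no consensus word on either strand, so the CAN calls on
  generated data equal the planted CAN set exactly.
* **Unambiguous plants.** Planted features never overlap; peaks are placed
  with a safety margin so scan windows never touch; after planting, the
  non-planted bases of each peak window are re-drawn until no unplanted
  consensus hit, no unplanted repeat literal, and no spurious SMAD pairing
  remains. Non-decoy peaks are also rejected from placements that would
  trip the exon filter. Each peak therefore triggers exactly its planted
  removal reasons and classification.
* **Expression noise** defaults to 0 so observed fold changes equal planted
  effects and the measured concordance is exactly the planted Bernoulli
  rate; `noise_sd` adds Normal noise to both contrasts for robustness
  studies (measured concordance then falls below the planted rate, since
  near-threshold secondary effects drop below twofold).
* **Ground-truth gene categories** are recorded at generation time by
  running the package's own domain-association logic on the planted
  post-filter peak set. That logic is validated independently against a
  quadratic brute-force oracle, so the end-to-end recovery test checks
  pipeline wiring without circularity at the algorithmic level.
* **Randomness** flows from one seed through named substreams (genome,
  genes, peaks, SBRs, expression, sequence-fixup), so changing one artifact
  count does not perturb the others, and the expression substream can be
  re-drawn standalone (used for the 50-seed concordance calibration).
* `audit()` re-reads every emitted file and verifies each planted feature
  (motif words at recorded positions, repeat literals, exon-overlap
  fractions, SBR displacements, expression values); any failure is reported
  per feature.

What the generator does **not** emulate: genome-like base composition and
repeat landscapes, read-level noise, peak-width/summit structure from
fragment pileups, probe-level microarray variation, or inter-gene
correlation in expression. Passing tests therefore demonstrate algorithmic
correctness of the pipeline's rules on data with known truth — not
robustness to every artifact of real ChIP-seq or microarray data.

## Numerical and degenerate-input conventions

* Strictness: p-value filter and exon-overlap filter are strict (`>`);
  regulation thresholds are inclusive (`≥`); all interval membership is
  half-open.
* Peaks without p-values are admitted with −log10 p = 0 plus a warning, so
  only an explicit threshold removes them.
* Empty inputs yield empty outputs and zeroed reports; an empty regulated
  set yields a missing (null) concordance; zero-pair profiles are flagged
  degenerate.
* Problem sizes in the test suite (200 random layouts for the domain
  oracles, 1,000 sequences for the scanner oracle, a 2,000-peak / 500-gene
  end-to-end run, 50 expression seeds, 100 flatness seeds) were chosen so
  the whole suite completes in well under a minute while keeping every
  statistical check's power high.

## Known limitations

* Genome-build liftover of SBRs is out of scope; SBRs must already be on
  the working build.
* The scanner is exact-IUPAC only in the default path; users with weight
  matrices must reduce them to consensus strings (a deliberate scope
  decision, not an oversight).
* The extension rule treats every gene symmetrically; tissue-specific or
  expression-aware domain assignment (as in newer GREAT variants) is not
  modeled.
* `run_all` executes stages in-process and sequentially; there is no
  workflow-engine integration.
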