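# regdomain-integrator

Tools for the downstream half of a transcription-factor ChIP-seq study:
given called peaks, a genome, a gene annotation, and expression fold
changes, decide which peaks are *canonical* (they contain the factor's
binding consensus) versus *non-canonical* (bound without it), assign peaks
to the genes they plausibly regulate, and cross those assignments with
differential expression.

The concrete analysis it reproduces is the FoxH1 story in early zebrafish
embryos. FoxH1 is the forkhead transcription factor that targets Nodal/TGF-β
signaling to its response genes; it binds the consensus **AATMCACA**
(M = A/C), usually with a SMAD-binding element just 5′ of it, yet most of
its ChIP peaks lack the consensus entirely. The pipeline classifies peaks
CAN/NC, profiles Smad2-binding-region (SBR) co-localization around CAN
peaks against a matched random baseline, pairs SMAD motifs with FoxH1
motifs (SMAD word ≤ 100 bp 5′ of the FoxH1 word, 5′ defined by the FoxH1
hit's strand), and integrates everything with log2 fold changes from two
mutant contrasts (*MZsur*, the foxH1 mutant, and *MZoep*, the
Nodal-co-receptor mutant).

## Method summary

* **Peak QC** — keep peaks with −log10 p > 4 (p < 1e−4); drop peaks
  overlapping the merged union of non-UTR (coding) exonic bases by more
  than 50% of their length (exactly half is kept); drop peaks containing
  any of the simple repeats `CTCTCTCTCTCTCTCTCTCTCTCTCTCT`,
  `AGAGAGAGA[GA]AGAGAGAGAGA` (bracket = one G/A base, two 21-mer literals),
  `GAGAGAAA`.
* **Classification** — a peak is CAN iff it contains ≥ 1 exact IUPAC match
  of AATMCACA on either strand, else NC.
* **Regulatory domains** (GREAT-style basal+extension) — every gene gets a
  basal domain `TSS − 5 kb … TSS + 1 kb` (gene-oriented); each side is then
  extended to the nearest non-overlapping neighbor basal edge, capped at
  50 kb upstream / 20 kb downstream of the TSS. Peaks associate with a gene
  when their midpoint falls in its domain; a peak may hit several genes.
* **Co-localization** — signed midpoint distances of SBRs around CAN peaks
  in 250 bp bins (±10 kb window), compared with the same count around an
  equal number of uniformly re-placed random peaks.
* **Integration** — genes with |log2FC| ≥ 1 ("at least twofold", inclusive)
  are UP/DOWN; each regulated gene is classed CAN / NC / CAN+NC / none by
  its associated peaks; concordance is the fraction of primary-contrast
  regulated genes regulated the same way in the secondary contrast.

A synthetic-data module generates genomes, gene models, peaks, SBRs, and
expression tables with planted ground truth (and a self-`audit`), so the
whole pipeline runs and is validated without any download. See
`docs/methods.md` for the full model description and design decisions.

## Worked example

Generate a synthetic dataset at study scale (2,000 peaks, 500 genes, 14%
planted CAN fraction, 76% planted concordance) and run the full pipeline:

```bash
regdomain-integrator simulate --out-dir demo/data --seed 1
cat > demo/run.yaml <<EOF
peaks: demo/data/peaks.narrowPeak
annotation: demo/data/genes.gff3
genome: demo/data/genome.fa
chrom_sizes: demo/data/chrom.sizes
sbrs: demo/data/sbrs.bed
expression: demo/data/expression.tsv
out_dir: demo/results
seed: 1
EOF
regdomain-integrator run-all --config demo/run.yaml
```

The run logs each stage's record counts:

```
qc: 2000 -> 1700 peaks (pvalue 100, exon 100, repeat 100)
classify: 280 CAN / 1420 NC (70 SMAD-paired)
annotate: 2546 associations
coloc: central enrichment 4.68 (p=7.6e-267)
integrate: 150 regulated, 149 peak-associated, concordance 0.7733333333333333
```

Reading these numbers: the three QC filters removed exactly the 300 planted
decoys (100 per filter); the 280 CAN calls are the planted 14% of 2,000
(the motif-free background guarantees no accidental consensus); SBRs pile
up ~4.7-fold over the random baseline within ±1 kb of CAN peak midpoints
because 60% of them were planted at Normal(0, 500 bp) displacements; and
77% of the 150 regulated genes change the same way in the second contrast,
matching the planted 76% rate up to binomial sampling. `demo/results/`
contains the filtered peaks, per-peak classes and motif hits, per-gene
associations and domains, the binned co-localization profile, the gene
category table, the heatmap matrix, and a `manifest.json` with a content
hash per output (reruns with the same config are hash-identical).

Every stage is also a library call (`regdomain_integrator.run_qc`,
`classify_peaks`, `extend_domains`, `associate`, `profile`, `summarize`,
…) and a standalone subcommand (`qc`, `classify`, `annotate`, `coloc`,
`integrate`).

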