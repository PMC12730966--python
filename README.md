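# msapkit

Scoring and simulation toolkit for MSAP (methylation-sensitive amplified
polymorphism) experiments: from genomic DNA with annotated CCGG methylation
states, through in silico EcoRI + HpaII/MspI double digestion and virtual
band calling, to band-type classification, methylation-ratio statistics,
control-vs-treated transition-class rates, and the 2^-ddCt relative-expression
calculation used for qPCR readouts.

## What it does

- **`msapkit.core`** — the isoschizomer sensitivity model over the four
  per-cytosine 5mC flags of a CCGG duplex, the band-type classification
  (H/M presence pairs (1,1)/(1,0)/(0,1)/(0,0) → types I–IV), band-matrix
  counting and methylation-ratio statistics (total / fully / hemi /
  non-methylated percentages).
- **`msapkit.transitions`** — the 14 labeled control→treated transition
  classes (A1–A3 no change, B1–B5 demethylation, C1–C6 methylation), the
  two unclassifiable patterns, and the three summary rates over classified
  loci.
- **`msapkit.digest`** — in silico EcoRI + HpaII or MspI double digestion of
  FASTA genomes against a BED-like CCGG methylome track, gel-window band
  selection, and scoring of virtual bands into matrices.
- **`msapkit.simulate`** — synthetic genomes (random or clean amplicon
  layout), i.i.d. methylomes from a categorical state prior, a treatment
  transition kernel parameterized by demethylation/methylation masses
  (d, m), and method-of-moments recovery of those parameters from scored
  output.
- **`msapkit.quant`** — 2^-ddCt relative expression with replicate
  aggregation (technical replicates averaged, per-biological-replicate
  folds, mean ± SD per condition).

## CLI

```sh
# band-type counts and methylation ratios for a sample group
msapkit score --matrix bands.tsv --samples CK --out ratios.json

# control -> treated transition classes and rates
msapkit transitions --control ck.tsv --treated az.tsv --out summary.json

# virtual digestion of a genome against a methylome track
msapkit simulate-digest --fasta g.fa --track t.bed --lane hpaii --out frags.tsv

# end-to-end simulated experiment (genome, tracks, matrices, truth.json)
msapkit simulate --config sim.yaml --seed 42 --outdir run1/

# relative expression from a Ct table
msapkit ddct --table ct.csv --ref 18S --control day0
```

File formats are plain text: band matrices are TSV with a `locus` column
and paired `<sample>_H` / `<sample>_M` columns of 0/1/NA; methylome tracks
are 4-column BED-like TSV (`seq_id  start  start+4  STATE`, 0-based
half-open); Ct tables are CSV with columns
`sample,condition,gene,replicate,ct`.

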