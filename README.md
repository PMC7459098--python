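# passenger-tracer

Cross-species "passenger transcript" accounting for efferocytosis
single-cell RNA-seq.

## The problem

When macrophages engulf apoptotic cells (efferocytosis), mRNA from the
engulfed corpse rides along inside the phagocyte. In droplet single-cell
RNA-seq of such co-cultures these *passenger transcripts* masquerade as
phagocyte gene expression and can distort any downstream transcriptional
analysis. A barnyard design solves the attribution problem: murine
phagocytes are co-cultivated with **human** apoptotic cells carrying a GFP
transgene, so every read's species of origin identifies its cell of origin,
and GFP — absent from both genomes — is an unambiguous reporter of
apoptotic-cell cargo.

`passenger-tracer` implements the complete accounting pipeline for this
design, for anyone running or simulating cross-species engulfment assays:

1. **Species classification** — every read pair (R1 = 16 bp cell barcode +
   10 bp UMI, R2 = 98 bp cDNA) is labeled `mouse`, `human`, `ambiguous` or
   `unaligned` by canonical k-mer voting against the two species
   transcriptomes (k = 21; a read is aligned when ≥ `min_hits` = 10 windows
   match, and species-assigned when one species has ≥ `margin` = 2× the
   other's hits; k-mers shared between species count for neither).
2. **Unaligned-read rescue** — the unaligned bin is deduplicated
   (first-seen exact sequence), matched against a reporter mini-genome
   containing only *GFP* and *APOL1*, deduplicated again, and the hit
   barcodes intersected with the filtered-cell whitelist to count
   passenger-positive cells.
3. **Cell matrix + QC** — mouse reads build a UMI-collapsed barcode × gene
   matrix; cells are excluded if they express fewer than `min_genes` genes,
   have a novelty score log₁₀(genes)/log₁₀(UMIs) below `novelty_min`, or
   exceed `max_mito` mitochondrial UMI fraction. QC-passing cells with zero
   GFP/APOL1 hits and zero human reads are flagged **passenger-free**
   (engulfed mRNA degraded).
4. **Kinetics** — per-condition passenger read fractions are fitted with the
   decay law **p(t) = p₀ · 2^(−t/h)**, yielding the passenger half-life
   *h* in hours.
5. **Synthetic data** — a truth-annotated generator emulates the whole
   experiment (three conditions: −AC control, +AC 2 h, +AC 6 h; ambient
   contamination, sequencing error, unalignable junk reads), so every stage
   is testable without any sequencing download.

## Worked example

```bash
passenger-tracer run --outdir runs/demo --seed 1
```

runs simulate → classify → QC → rescue → report at the default study
conditions (200 cells/condition, ~200 reads/cell, p₀ = 0.30, h = 1.5 h)
and prints the kinetics table:

```
condition  t_hours  total_reads  fraction_human_aligned  fraction_unaligned  passenger_read_fraction  n_reporter_hits_dedup  n_passenger_cells  n_cells_passed_qc  fraction_passenger_free
  control      NaN        40153                0.000000            0.048589                 0.000000                      0                  0                200                    1.000
    AC_2h      2.0        39823                0.066645            0.056073                 0.073274                    264                110                200                    0.255
    AC_6h      6.0        40229                0.009968            0.051455                 0.011285                     53                 41                200                    0.345
fitted half-life: 1.482 h (p0_hat=0.1867)
```

Reading it: the control library contains no human or reporter material;
2 h after apoptotic-cell exposure 6.7 % of reads align to the human
transcriptome and 264 deduplicated GFP/APOL1 reads mark 110 of 200 cells
as passenger-positive; by 6 h both signals have collapsed (1.0 % human,
41 cells) and the passenger-free fraction has risen — engulfed RNA is
being degraded. The fitted half-life of 1.48 h recovers the simulated
truth of 1.5 h; the fitted p₀ of 0.19 is the population-level initial
fraction (cell-level p₀ = 0.30 times the fraction of cells that engulfed).

Every stage is also exposed individually (`simulate`, `classify`, `qc`,
`rescue`, `report` subcommands) and as plain library functions
(`passenger_tracer.classify_fastq`, `run_rescue`, `qc_filter`,
`fit_decay`, ...).

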