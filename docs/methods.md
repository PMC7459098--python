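# Methods

## Overview

`passenger-tracer` quantifies apoptotic-cell-derived ("passenger") RNA
inside phagocytes in a cross-species engulfment assay: murine phagocytes
co-cultivated with human apoptotic cells carrying a GFP transgene, profiled
by droplet scRNA-seq with a 26-cycle barcode+UMI read and a 98-cycle cDNA
read. The pipeline classifies each read by species, rescues unaligned reads
against a GFP/APOL1 reporter mini-genome, applies cell QC, counts
passenger-positive cells per co-culture timepoint, and fits the passenger
decay half-life. A truth-annotated simulator replaces sequencing data.

## Species classification by canonical k-mer voting

A full dual-genome aligner is unnecessary for the decision this pipeline
needs — per read: mouse, human, or neither. Each k-window of the cDNA
(k = 21, odd and in [11, 31]) is reduced to canonical form (lexicographic
minimum of the window and its reverse complement, making calls
strand-insensitive) and looked up in an index built from both
transcriptome FASTAs. K-mers present in both species are flagged *shared*
and vote for neither.

Decision rule, with defaults `min_hits = 10`, `margin = 2.0`:

* `unaligned` if max(mouse hits, human hits) < `min_hits`;
* `mouse` (resp. `human`) if that species' hits ≥ `margin` × the other's;
* `ambiguous` otherwise — an explicit fourth bin; downstream treats it as
  evidence for neither species.

`min_hits = 10` demands ~13% of a 98-mer's 78 windows match, tolerant of
several substitution errors yet far above chance for random sequence;
`margin = 2` resolves chimeric or contaminated reads toward the clearly
dominant species. Increasing `min_hits` can only move reads toward
`unaligned` (monotonicity is a tested invariant). `best_gene` is the modal
gene among the winning species' hit k-mers, ties broken toward the
lexicographically smallest id.

Barcodes are matched to the whitelist exactly — no 1-mismatch correction —
keeping every downstream count reproducible by a set-based oracle.

## Unaligned-read rescue

The unaligned bin may contain reporter transcripts (GFP is absent from both
genomes by design) and degraded human material. The chain: extract
unaligned reads → remove exact duplicate sequences (first occurrence kept;
the dedup keys on the cDNA sequence alone, reproducing an
`awk '!seen[$0]++'` pass over read records; a UMI-aware key is available
via `dedup_key="barcode_umi_seq"`) → count canonical k-mer matches per
reporter, a hit needing `reporter_min_hits = 10` windows (same rationale as
the classifier; ties broken toward the higher count, then lexicographic
name) → dedup hits by sequence → intersect hit barcodes with the
**post-QC filtered** whitelist to count passenger-positive cells. Hits on
non-whitelist barcodes are retained in the hit counts but contribute no
cell. Only the cDNA mate is matched; stage counts are monotone by
construction and the whole chain is deterministic.

## Count matrix and cell QC

Only mouse-classified reads with whitelisted barcodes enter the matrix;
counting collapses identical (barcode, UMI, gene) triples to one molecule
(exact-match UMI collapse, no error correction, so a brute-force
distinct-triple tally reproduces the matrix exactly). Three exclusion
rules, evaluated per barcode:

* **genes**: fewer than `min_genes` detected genes (boundary: 499 fails a
  threshold of 500);
* **complexity**: novelty score log₁₀(n_genes)/log₁₀(n_UMIs) below
  `novelty_min`. A nominal "UMIs per gene below 0.8" rule is vacuous taken
  literally — every detected gene carries ≥ 1 UMI so the ratio is always
  ≥ 1 — so the novelty score, the standard library-complexity metric on
  the same two quantities, is the default; the literal reading stays
  available behind `literal_umi_ratio=True`, and a test documents that it
  excludes nothing. Cells with < 2 UMIs have an undefined score and fail.
* **mito**: mitochondrial UMI fraction strictly above `max_mito` (boundary:
  10.1% fails a threshold of 0.10; exactly 10% passes). Mitochondrial
  genes are identified by the `mt-` id prefix.

Defaults (`min_genes = 500`, `novelty_min = 0.8`, `max_mito = 0.10`) are
the standard absolute cuts for genome-wide droplet libraries. The toy
references span only ~50 genes/species, so the pipeline's default *config*
passes scaled thresholds (`min_genes = 20`, `novelty_min = 0.6`,
`max_mito = 0.15`) chosen from the toy regime's typical profile (~50
detected genes, ~190 UMIs, ~6% expected mito fraction); the rule semantics
are identical at either scale.

A QC-passing cell with zero reporter hits **and** zero human-classified
reads is `passenger_free`: operationally, a phagocyte whose engulfed
apoptotic mRNA has been degraded.

## Decay kinetics

Per condition, the passenger read fraction is the human-aligned fraction
plus raw reporter hits over total reads. The decay law

    p(t) = p0 · 2^(−t/h)

is least-squares fitted to the post-exposure timepoints (the control has
no co-culture time and is excluded, shown as baseline). The fit is
deterministic: a log-spaced grid over h ∈ [0.05, 200] h with the
closed-form optimal p₀ per candidate (a weighted linear regression, p₀
clipped to [0, 1]) seeds a bounded trust-region refinement (tolerances
1e-15). Two exact points are reproduced to machine precision; all-zero
fractions return a degenerate fit (p₀ = 0, h undefined) rather than an
error. The fit uses read fractions, not cell fractions, because read
fractions are what the assay quantifies directly; the cell-level
passenger-free fraction is reported alongside, unfitted. With engulfment
probability < 1 the fitted p₀ is the population-level initial fraction
(cell-level p₀ × engulfment rate); the half-life is unaffected. The fitted
half-life is a construct of this pipeline, not a literature estimate.

## Synthetic experiment generator

**References.** Random transcripts (default 50/species, 300–500 bp) with a
verification pass that regenerates any sequence sharing a canonical 21-mer
with a previously accepted one, so mouse/human/reporter k-mer sets are
pairwise disjoint — classification on clean reads is then exact and every
oracle is a set computation. The first ~6% of mouse genes are `mt-`-marked
mitochondrial stand-ins. "GFP" (720 bp) and "APOL1" (1200 bp) are synthetic
random stand-ins for the reporter sequences; only their absence from both
species references matters.

**Reads.** Three conditions — control (no exposure), +AC 2 h, +AC 6 h —
with 200 cells each and Poisson(200) reads/cell. Cells belong to an
LPM-like (60%) or SPM-like (40%) subset differing only in engulfment
probability (0.7 vs 0.4, the large-peritoneal-macrophage-like subset being
the more efficient engulfer); engulfment is Bernoulli per cell. Each read
is junk with probability 0.05 (uniform random sequence, re-drawn on the
rare reference k-mer collision, hence unalignable by construction),
passenger with probability p₀·2^(−t/h) for engulfing cells (p₀ = 0.30,
h = 1.5 h; within passenger reads 10% come from the reporters), otherwise
a mouse transcript; the three-way split is taken on one uniform draw so
the expected passenger share among an engulfing cell's reads equals the
decay law exactly. Sequences are uniform windows of the source transcript
with per-base substitution errors (0.005); with probability 0.02 a read is
recorded under another cell's barcode (ambient contamination, within
condition only). Quality strings are constant 'I'; the pipeline never
reads qualities. The per-sample index read is not simulated —
demultiplexing is represented by separate files per condition. Reference
and read generation use separate child seed streams of the one user seed,
so the read stream can never replay the bytes that built the references;
identical seed and parameters give byte-identical outputs (gzip written
with zeroed mtime).

p₀ and h are free parameters of the simulator, not measured values; the
defaults are the conditions under which the test suite demonstrates the
qualitative behaviour of the real assay (passenger signal high at 2 h,
largely dissipated at 6 h).

**What the simulator does not model** — and hence what passing tests do
not show about real data: intron/UTR structure and splicing, empty
droplets and doublets, barcode sequencing errors (whitelist matching is
exact), PCR duplicates beyond exact duplicates, index hopping, cell-type
expression structure beyond the two engulfment subsets, and realistic
transcript abundance skew (expression is uniform over toy genes).

## Problem sizes

Defaults were chosen so a full pipeline run (~120k reads over 600 cells)
completes in well under a minute on one core; the test suite uses smaller
cohorts (15–200 cells, 40–250 reads/cell) per check, with replicate counts
of 10 (temporal ordering) and 20 (half-life recovery) for the stochastic
properties.

## Known limitations

* K-mer voting has no concept of unique genomic placement; homologous
  regions between real mouse/hg38 transcriptomes would land in the shared
  bin and lower sensitivity rather than cause misassignment.
* The whole-transcriptome index is held in memory as a Python dict —
  appropriate at toy scale and for targeted panels, not for a full
  genome-scale index.
* With only two post-exposure timepoints the decay fit is exactly
  determined; goodness-of-fit (SSE) becomes informative only with ≥ 3
  timepoints.
* Reporter hits are counted per read, not UMI-collapsed, mirroring a
  raw-read counting procedure; deduplication is by exact sequence only.
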