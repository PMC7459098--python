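"""Truth-annotated synthetic data for the cross-species efferocytosis assay.

The experiment this module emulates: murine peritoneal phagocytes are
co-cultivated with human apoptotic cells that carry a GFP transgene, then
profiled by droplet single-cell RNA-seq (10x 5' chemistry: read 1 carries a
16-base cell barcode plus a 10-base UMI, read 2 carries 98 bases of cDNA).
Transcripts from engulfed apoptotic cells ("passenger" transcripts — human
mRNAs plus the GFP reporter) are detectable inside the phagocyte shortly
after engulfment and decay with co-culture time. The simulator generates
toy mouse/human/reporter references, paired FASTQ per co-culture condition,
a barcode whitelist, and per-read/per-cell truth tables, so every pipeline
stage can be tested against known ground truth without any sequencing data.

Passenger abundance follows exponential decay: an engulfing cell sampled at
co-culture time ``t`` emits human/reporter reads at expected fraction
``p0 * 2**(-t / h)`` where ``p0`` is the passenger fraction at engulfment
and ``h`` the passenger half-life in hours. The control condition has no
apoptotic-cell exposure and therefore no passenger reads.

The reporter sequences named GFP and APOL1 are synthetic random stand-ins
generated alongside the toy species references, not the biological
sequences; only their role (absent from both species references) matters.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._io import write_fasta, write_gzip_text
from .kmers import K_DEFAULT, canonical_kmer_set

_BASES = "ACGT"

#: species labels used in the truth table
TRUTH_SPECIES = ("mouse", "human", "reporter-GFP", "reporter-APOL1", "junk")


class BarcodeCollisionError(RuntimeError):
    """Two simulated cells drew the same barcode; regenerate with a new seed."""


@dataclass(frozen=True)
class ToyReferenceSet:
    """Toy stand-ins for the mouse and human transcriptomes and the
    GFP/APOL1 reporter mini-genome.

    Construction guarantees that no canonical k-mer (k=21) is shared between
    any two transcripts, so the species k-mer sets are disjoint and no
    transcript is a substring of another.
    """

    mouse_transcripts: tuple[tuple[str, str], ...]
    human_transcripts: tuple[tuple[str, str], ...]
    reporter_transcripts: tuple[tuple[str, str], ...]
    mito_gene_ids: frozenset[str]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the three FASTA files; returns their paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "mouse": outdir / "refs_mouse.fasta",
            "human": outdir / "refs_human.fasta",
            "reporter": outdir / "refs_reporter.fasta",
        }
        write_fasta(paths["mouse"], list(self.mouse_transcripts))
        write_fasta(paths["human"], list(self.human_transcripts))
        write_fasta(paths["reporter"], list(self.reporter_transcripts))
        return paths

    def all_transcripts(self) -> list[tuple[str, str]]:
        return (
            list(self.mouse_transcripts)
            + list(self.human_transcripts)
            + list(self.reporter_transcripts)
        )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def make_references(
    seed: int,
    n_genes_per_species: int = 50,
    transcript_length_range: tuple[int, int] = (300, 500),
    *,
    k: int = K_DEFAULT,
    mito_fraction: float = 0.06,
    reporter_lengths: Mapping[str, int] = {"GFP": 720, "APOL1": 1200},
) -> ToyReferenceSet:
    """Generate toy mouse/human references plus the reporter mini-genome.

    Sequences are drawn uniformly at random; a verification pass rebuilds
    any sequence whose canonical k-mer set intersects a previously accepted
    transcript, so cross-species (and cross-transcript) k-mer sets are
    disjoint by construction. Mitochondrial stand-ins are the first
    ``round(mito_fraction * n)`` mouse genes, marked with the ``mt-`` prefix.

    Deterministic for a fixed seed.
    """
    lo, hi = transcript_length_range
    if n_genes_per_species < 2:
        raise ValueError("n_genes_per_species must be >= 2")
    if lo < 2 * k:
        raise ValueError(
            f"transcript lengths must be >= 2*k = {2 * k}; got minimum {lo}"
        )
    rng = np.random.default_rng([seed, 101])  # child stream: references
    used_kmers: set[str] = set()

    def fresh_seq(length: int) -> str:
        for _ in range(200):
            seq = _random_seq(rng, length)
            kset = canonical_kmer_set(seq, k)
            if used_kmers.isdisjoint(kset):
                used_kmers.update(kset)
                return seq
        raise RuntimeError("could not generate a k-mer-disjoint sequence")

    n_mito = max(1, round(mito_fraction * n_genes_per_species))
    mouse, human = [], []
    for i in range(n_genes_per_species):
        gid = f"mm_g{i:03d}" if i >= n_mito else f"mt-mm_g{i:03d}"
        mouse.append((gid, fresh_seq(int(rng.integers(lo, hi + 1)))))
    for i in range(n_genes_per_species):
        human.append((f"hs_g{i:03d}", fresh_seq(int(rng.integers(lo, hi + 1)))))
    reporters = [
        (name, fresh_seq(length)) for name, length in sorted(reporter_lengths.items())
    ]
    return ToyReferenceSet(
        mouse_transcripts=tuple(mouse),
        human_transcripts=tuple(human),
        reporter_transcripts=tuple(reporters),
        mito_gene_ids=frozenset(g for g, _ in mouse if g.startswith("mt-")),
    )


@dataclass
class SimulationParams:
    """Study conditions for the simulated co-culture experiment.

    Defaults mirror the assay design: a no-exposure control plus 2 h and 6 h
    apoptotic-cell co-culture timepoints; two phagocyte subsets where the
    large-peritoneal-macrophage-like subset engulfs more efficiently than
    the small one; passenger reads decaying with half-life ``decay_half_life_hours``
    from initial fraction ``passenger_initial_fraction``.
    """

    n_cells_per_condition: int = 200
    conditions: tuple[tuple[str, float | None], ...] = (
        ("control", None),
        ("AC_2h", 2.0),
        ("AC_6h", 6.0),
    )
    barcode_length: int = 16
    umi_length: int = 10
    cdna_length: int = 98
    reads_per_cell: float = 200.0
    subset_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"LPM": 0.6, "SPM": 0.4}
    )
    engulfment_prob_by_subset: Mapping[str, float] = field(
        default_factory=lambda: {"LPM": 0.7, "SPM": 0.4}
    )
    passenger_initial_fraction: float = 0.30
    decay_half_life_hours: float = 1.5
    reporter_share: float = 0.10  # share of passenger reads drawn from GFP/APOL1
    ambient_rate: float = 0.02
    error_rate: float = 0.005
    junk_read_fraction: float = 0.05
    rng_seed: int = 0

    def validate(self) -> None:
        probs = {
            "passenger_initial_fraction": self.passenger_initial_fraction,
            "reporter_share": self.reporter_share,
            "ambient_rate": self.ambient_rate,
            "error_rate": self.error_rate,
            "junk_read_fraction": self.junk_read_fraction,
            **{f"engulfment_prob[{s}]": p for s, p in self.engulfment_prob_by_subset.items()},
            **{f"subset_fraction[{s}]": p for s, p in self.subset_fractions.items()},
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]; got {p}")
        if self.barcode_length + self.umi_length != 26:
            raise ValueError("barcode_length + umi_length must equal 26 (R1 is 26 cycles)")
        if self.cdna_length != 98:
            raise ValueError("cdna_length must be 98 (R2 is 98 cycles)")
        if self.decay_half_life_hours <= 0:
            raise ValueError("decay_half_life_hours must be > 0")
        if self.n_cells_per_condition < 1 or self.reads_per_cell <= 0:
            raise ValueError("need at least one cell and a positive read depth")
        if abs(sum(self.subset_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("subset_fractions must sum to 1")
        if set(self.subset_fractions) != set(self.engulfment_prob_by_subset):
            raise ValueError("subset_fractions and engulfment_prob_by_subset keys differ")


def expected_passenger_fraction(params: SimulationParams, t_hours: float | None, engulfed: bool) -> float:
    """Expected share of a cell's reads that are passenger (human+reporter)."""
    if not engulfed or t_hours is None:
        return 0.0
    return params.passenger_initial_fraction * 2.0 ** (-t_hours / params.decay_half_life_hours)


@dataclass(frozen=True)
class SimulatedExperiment:
    """Paths and truth tables produced by :func:`simulate_experiment`."""

    fastq_paths: dict[str, tuple[Path, Path]]  # condition -> (R1, R2)
    whitelist_path: Path
    whitelist: tuple[str, ...]
    truth_reads: pd.DataFrame
    truth_cells: pd.DataFrame
    reference_paths: dict[str, Path]


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for p in pos:
        alternatives = _BASES.replace(chars[p], "")
        chars[p] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def simulate_experiment(
    refs: ToyReferenceSet,
    params: SimulationParams,
    outdir: str | Path,
) -> SimulatedExperiment:
    """Simulate the co-culture experiment and write all inputs to ``outdir``.

    Per condition, each cell draws a Poisson read count; each read is junk
    (uniform random sequence, unalignable by construction) with probability
    ``junk_read_fraction``, passenger (human or reporter transcript) with
    probability ``p0 * 2**(-t/h)`` for engulfing cells, and a mouse
    transcript otherwise, so the expected passenger share of an engulfing
    cell's reads equals the decay law exactly. Substitution errors are
    applied per base; with probability ``ambient_rate`` a read is recorded
    under a random other cell barcode of the same condition (ambient
    contamination). Quality strings are constant 'I' — the pipeline never
    consumes qualities.

    Outputs: ``{condition}_R1.fastq.gz`` / ``_R2.fastq.gz``, the reference
    FASTAs, ``whitelist.txt`` (one barcode per line), ``truth_reads.tsv``
    and ``truth_cells.tsv``. Byte-identical for identical params and seed.
    """
    params.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # child stream distinct from the reference generator's, so read draws can
    # never replay the byte stream that produced the reference sequences
    rng = np.random.default_rng([params.rng_seed, 202])

    ref_paths = refs.write(outdir)
    mouse = list(refs.mouse_transcripts)
    human = list(refs.human_transcripts)
    reporters = list(refs.reporter_transcripts)
    # junk reads must not collide with any reference k-mer
    ref_kmers: set[str] = set()
    for _, seq in refs.all_transcripts():
        ref_kmers |= canonical_kmer_set(seq, K_DEFAULT)

    subsets = sorted(params.subset_fractions)
    subset_p = np.array([params.subset_fractions[s] for s in subsets])

    # --- cells ---
    cell_rows = []
    seen_barcodes: set[str] = set()
    for cond, t in params.conditions:
        for _ in range(params.n_cells_per_condition):
            bc = _random_seq(rng, params.barcode_length)
            if bc in seen_barcodes:
                raise BarcodeCollisionError(f"barcode collision: {bc}")
            seen_barcodes.add(bc)
            subset = subsets[rng.choice(len(subsets), p=subset_p)]
            engulfed = bool(
                t is not None
                and rng.random() < params.engulfment_prob_by_subset[subset]
            )
            cell_rows.append(
                {
                    "barcode": bc,
                    "condition": cond,
                    "t_hours": t,
                    "subset": subset,
                    "engulfed": engulfed,
                    "expected_passenger_fraction": expected_passenger_fraction(
                        params, t, engulfed
                    ),
                }
            )
    truth_cells = pd.DataFrame(cell_rows)

    # --- reads ---
    fastq_paths: dict[str, tuple[Path, Path]] = {}
    read_rows = []
    qual26 = "I" * (params.barcode_length + params.umi_length)
    qual_cdna = "I" * params.cdna_length
    for cond, t in params.conditions:
        cells = truth_cells[truth_cells["condition"] == cond]
        barcodes = cells["barcode"].to_list()
        r1_buf, r2_buf = io.StringIO(), io.StringIO()
        serial = 0
        for _, cell in cells.iterrows():
            pf = cell["expected_passenger_fraction"]
            n_reads = int(rng.poisson(params.reads_per_cell))
            for _ in range(n_reads):
                u = rng.random()
                if u < params.junk_read_fraction:
                    species, gene = "junk", ""
                    cdna = _random_seq(rng, params.cdna_length)
                    tries = 0
                    while not ref_kmers.isdisjoint(
                        canonical_kmer_set(cdna, K_DEFAULT)
                    ):
                        cdna = _random_seq(rng, params.cdna_length)
                        tries += 1
                        if tries > 50:
                            raise RuntimeError("cannot draw unalignable junk read")
                elif u < params.junk_read_fraction + pf:
                    if rng.random() < params.reporter_share:
                        gene, src = reporters[rng.integers(0, len(reporters))]
                        species = f"reporter-{gene}"
                    else:
                        gene, src = human[rng.integers(0, len(human))]
                        species = "human"
                    start = rng.integers(0, len(src) - params.cdna_length + 1)
                    cdna = _mutate(
                        rng, src[start : start + params.cdna_length], params.error_rate
                    )
                else:
                    gene, src = mouse[rng.integers(0, len(mouse))]
                    species = "mouse"
                    start = rng.integers(0, len(src) - params.cdna_length + 1)
                    cdna = _mutate(
                        rng, src[start : start + params.cdna_length], params.error_rate
                    )
                observed_bc = cell["barcode"]
                if len(barcodes) > 1 and rng.random() < params.ambient_rate:
                    other = barcodes[rng.integers(0, len(barcodes))]
                    while other == cell["barcode"]:
                        other = barcodes[rng.integers(0, len(barcodes))]
                    observed_bc = other
                umi = _random_seq(rng, params.umi_length)
                read_id = f"{cond}:{serial:07d}"
                serial += 1
                r1 = observed_bc + umi
                r1_buf.write(f"@{read_id}\n{r1}\n+\n{qual26}\n")
                r2_buf.write(f"@{read_id}\n{cdna}\n+\n{qual_cdna}\n")
                read_rows.append(
                    {
                        "read_id": read_id,
                        "condition": cond,
                        "true_barcode": cell["barcode"],
                        "observed_barcode": observed_bc,
                        "true_species": species,
                        "true_gene": gene,
                    }
                )
        r1_path = outdir / f"{cond}_R1.fastq.gz"
        r2_path = outdir / f"{cond}_R2.fastq.gz"
        write_gzip_text(r1_path, r1_buf.getvalue())
        write_gzip_text(r2_path, r2_buf.getvalue())
        fastq_paths[cond] = (r1_path, r2_path)

    truth_reads = pd.DataFrame(read_rows)
    whitelist = tuple(truth_cells["barcode"])
    whitelist_path = outdir / "whitelist.txt"
    whitelist_path.write_text("\n".join(whitelist) + "\n", encoding="ascii")
    truth_reads.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
    truth_cells.to_csv(outdir / "truth_cells.tsv", sep="\t", index=False)
    return SimulatedExperiment(
        fastq_paths=fastq_paths,
        whitelist_path=whitelist_path,
        whitelist=whitelist,
        truth_reads=truth_reads,
        truth_cells=truth_cells,
        reference_paths=ref_paths,
    )
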