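"""Barcode-gene count matrix, cell QC filters, and the passenger-free flag.

Only mouse-classified reads with whitelisted barcodes contribute to the
matrix (the phagocytes are murine; human and reporter material is tracked
separately as passenger signal). Counting collapses identical
(barcode, UMI, gene) triples to a single molecule — exact-match UMI
collapse, no error correction.

Cell exclusion follows three rules: fewer than ``min_genes`` detected
genes; library complexity (novelty score, log10 genes / log10 UMIs) below
``novelty_min``; mitochondrial UMI fraction above ``max_mito``. The
novelty score stands in for a nominal "UMIs per gene below 0.8" rule,
which taken literally can exclude nothing (every detected gene carries at
least one UMI, so UMIs/gene >= 1 always); the literal reading remains
available via ``literal_umi_ratio=True``.

Cells passing QC form the filtered whitelist consumed by the rescue stage.
A QC-passing cell with zero reporter hits and zero human-classified reads
is flagged ``passenger_free``: it is taken to have reached a stage of
efferocytosis at which engulfed apoptotic-cell mRNA has been degraded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .unaligned_rescue import ReporterHit

MITO_PREFIX = "mt-"


@dataclass(frozen=True)
class CountMatrix:
    """Cells x genes matrix of UMI counts, with ordered labels."""

    barcodes: tuple[str, ...]
    gene_ids: tuple[str, ...]
    counts: sp.csr_matrix

    def write(self, outdir: str | Path) -> None:
        """CellRanger-style triplet layout: matrix.mtx + barcodes.tsv + genes.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(outdir / "matrix.mtx", self.counts.tocoo(), field="integer")
        (outdir / "barcodes.tsv").write_text("\n".join(self.barcodes) + "\n")
        (outdir / "genes.tsv").write_text("\n".join(self.gene_ids) + "\n")


@dataclass
class QCThresholds:
    """Cell-exclusion thresholds; defaults are the standard absolute cuts
    for real droplet libraries (toy-scale runs pass scaled-down values)."""

    min_genes: int = 500
    novelty_min: float = 0.8
    max_mito: float = 0.10
    literal_umi_ratio: bool = False


def build_matrix(calls: pd.DataFrame, whitelist: Iterable[str]) -> CountMatrix:
    """UMI-collapsed barcode-gene matrix from mouse-classified reads.

    Identical (barcode, UMI, gene) triples count once. Barcodes with zero
    mouse reads are simply absent from the matrix.
    """
    wl = set(whitelist)
    sel = calls[
        (calls["label"] == "mouse")
        & calls["barcode"].isin(wl)
        & (calls["best_gene"] != "")
        & calls["best_gene"].notna()
    ]
    triples = sel[["barcode", "umi", "best_gene"]].drop_duplicates()
    barcodes = tuple(sorted(triples["barcode"].unique()))
    genes = tuple(sorted(triples["best_gene"].unique()))
    b_idx = {b: i for i, b in enumerate(barcodes)}
    g_idx = {g: i for i, g in enumerate(genes)}
    grouped = triples.groupby(["barcode", "best_gene"], sort=False).size()
    rows = [b_idx[b] for b, _ in grouped.index]
    cols = [g_idx[g] for _, g in grouped.index]
    counts = sp.coo_matrix(
        (grouped.to_numpy(), (rows, cols)),
        shape=(len(barcodes), len(genes)),
        dtype=np.int64,
    ).tocsr()
    return CountMatrix(barcodes=barcodes, gene_ids=genes, counts=counts)


def qc_filter(
    matrix: CountMatrix,
    mito_gene_ids: Iterable[str],
    thresholds: QCThresholds | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Evaluate the three exclusion rules per barcode.

    Boundary semantics: "fewer than ``min_genes``" excludes
    n_genes <= min_genes - 1; mitochondrial fraction strictly above
    ``max_mito`` excludes (no rounding). Cells with fewer than 2 UMIs have
    an undefined novelty score and fail QC.

    Returns (profiles table, filtered whitelist). The profiles table keeps
    one row per barcode with the QC metrics, pass flag, and per-rule
    failure flags.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    mito = set(mito_gene_ids)
    n_umis = np.asarray(matrix.counts.sum(axis=1)).ravel()
    n_genes = matrix.counts.getnnz(axis=1)
    mito_cols = [i for i, g in enumerate(matrix.gene_ids) if g in mito]
    if mito_cols:
        mito_umis = np.asarray(matrix.counts[:, mito_cols].sum(axis=1)).ravel()
    else:
        mito_umis = np.zeros_like(n_umis)
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_fraction = np.where(n_umis > 0, mito_umis / np.maximum(n_umis, 1), 0.0)
        umi_per_gene = np.where(n_genes > 0, n_umis / np.maximum(n_genes, 1), np.nan)
        novelty = np.where(
            (n_umis >= 2) & (n_genes >= 1),
            np.log10(np.maximum(n_genes, 1)) / np.log10(np.maximum(n_umis, 2)),
            np.nan,
        )
    fail_genes = n_genes <= thresholds.min_genes - 1
    if thresholds.literal_umi_ratio:
        fail_complexity = ~(umi_per_gene >= thresholds.novelty_min)
    else:
        fail_complexity = ~(novelty >= thresholds.novelty_min)  # NaN fails
    fail_mito = mito_fraction > thresholds.max_mito
    passed = ~(fail_genes | fail_complexity | fail_mito)
    profiles = pd.DataFrame(
        {
            "barcode": matrix.barcodes,
            "n_genes": n_genes,
            "n_umis": n_umis.astype(np.int64),
            "mito_fraction": mito_fraction,
            "umi_per_gene": umi_per_gene,
            "novelty": novelty,
            "fail_min_genes": fail_genes,
            "fail_complexity": fail_complexity,
            "fail_mito": fail_mito,
            "passed_qc": passed,
        }
    )
    filtered = [b for b, ok in zip(matrix.barcodes, passed) if ok]
    return profiles, filtered


def flag_passenger_free(
    profiles: pd.DataFrame,
    rescue_hits: Sequence[ReporterHit],
    calls: pd.DataFrame,
) -> pd.DataFrame:
    """Attach passenger read counts and the passenger-free flag.

    ``passenger_reads`` per barcode = reporter hits (GFP/APOL1) plus
    human-classified reads; ``passenger_free`` is true iff that count is
    zero — the operational definition of a phagocyte whose engulfed
    apoptotic-cell mRNA has been degraded.
    """
    human_counts = (
        calls.loc[calls["label"] == "human", "barcode"].value_counts().to_dict()
    )
    reporter_counts: dict[str, int] = {}
    for hit in rescue_hits:
        reporter_counts[hit.barcode] = reporter_counts.get(hit.barcode, 0) + 1
    out = profiles.copy()
    out["passenger_reads"] = [
        human_counts.get(b, 0) + reporter_counts.get(b, 0) for b in out["barcode"]
    ]
    out["passenger_free"] = out["passenger_reads"] == 0
    return out


def write_profiles(profiles: pd.DataFrame, path: str | Path) -> None:
    profiles.to_csv(path, sep="\t", index=False)


def write_whitelist(barcodes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(barcodes) + ("\n" if barcodes else ""))
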