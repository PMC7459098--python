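"""Rescue of unaligned reads against the reporter mini-genome.

Reads that align to neither species are not necessarily noise: in the
co-culture assay they may derive from the GFP transgene (absent from both
genomes) or from human transcripts such as APOL1 too degraded or too
diverged to classify. The rescue chain mirrors the standard recipe:

1. extract the unaligned reads,
2. drop exact duplicate sequences (first occurrence wins),
3. match survivors against the reporter mini-genome (GFP + APOL1) by
   canonical k-mer counting,
4. drop exact duplicate hits,
5. intersect hit barcodes with the filtered-cell whitelist to count
   passenger-positive cells.

Duplicate removal keys on the cDNA sequence alone, reproducing an
``awk '!seen[$0]++'`` pass over read records; barcode and UMI ride along
with the first occurrence. A UMI-aware variant is available via
``dedup_key="barcode_umi_seq"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

from ._io import iter_fastq, read_fasta
from .kmers import K_DEFAULT, canonical_kmer_set, iter_canonical

REPORTER_MIN_HITS_DEFAULT = 10


class PipelineInputError(RuntimeError):
    """Raised when stage inputs are missing or out of sync with each other."""


class UnalignedRead(NamedTuple):
    read_id: str
    barcode: str
    umi: str
    sequence: str


@dataclass
class ReporterHit:
    read_id: str
    barcode: str
    umi: str
    reporter_name: str
    matching_kmer_count: int


@dataclass
class RescueSummary:
    condition: str
    n_unaligned_in: int
    n_after_dedup: int
    n_reporter_raw_hits: int
    n_reporter_hits_dedup: int
    n_passenger_cells: int
    passenger_cell_barcodes: set[str] = field(default_factory=set)


def extract_unaligned(
    calls: pd.DataFrame, r2_path: str | Path
) -> list[UnalignedRead]:
    """Pull the unaligned-labeled reads, with their original sequences.

    Order follows the calls table. A read id present in the calls but
    absent from the FASTQ means the two inputs are out of sync and raises
    :class:`PipelineInputError`.
    """
    wanted = calls.loc[calls["label"] == "unaligned", ["read_id", "barcode", "umi"]]
    ids = set(wanted["read_id"])
    seqs: dict[str, str] = {}
    if ids:
        for read_id, seq in iter_fastq(r2_path):
            if read_id in ids:
                seqs[read_id] = seq
    missing = ids - seqs.keys()
    if missing:
        raise PipelineInputError(
            f"{len(missing)} unaligned read ids not found in {r2_path} "
            f"(e.g. {sorted(missing)[0]})"
        )
    return [
        UnalignedRead(r.read_id, r.barcode, r.umi, seqs[r.read_id])
        for r in wanted.itertuples(index=False)
    ]


def dedup_exact(
    records: Sequence[UnalignedRead], key: str = "seq"
) -> list[UnalignedRead]:
    """Keep the first occurrence of each distinct record; stable, idempotent.

    ``key="seq"`` deduplicates on the cDNA sequence alone (the default,
    matching a plain ``!seen[$0]++`` over sequence records);
    ``key="barcode_umi_seq"`` keys on (barcode, UMI, sequence).
    """
    if key not in ("seq", "barcode_umi_seq"):
        raise ValueError(f"unknown dedup key: {key}")
    seen: set = set()
    out: list[UnalignedRead] = []
    for rec in records:
        k = rec.sequence if key == "seq" else (rec.barcode, rec.umi, rec.sequence)
        if k not in seen:
            seen.add(k)
            out.append(rec)
    return out


def _load_reporter_sets(
    reporter_fasta: str | Path, k: int
) -> dict[str, set[str]]:
    records = read_fasta(reporter_fasta)
    if not records:
        raise PipelineInputError(f"empty reporter FASTA: {reporter_fasta}")
    return {name: canonical_kmer_set(seq, k) for name, seq in records}


def _scan_reporters(
    records: Iterable[UnalignedRead],
    reporter_sets: dict[str, set[str]],
    k: int,
    reporter_min_hits: int,
) -> list[tuple[ReporterHit, str]]:
    """Raw reporter hits (with sequences kept for later dedup)."""
    names = sorted(reporter_sets)
    hits: list[tuple[ReporterHit, str]] = []
    for rec in records:
        counts = {name: 0 for name in names}
        if len(rec.sequence) >= k:
            for kmer in iter_canonical(rec.sequence, k):
                for name in names:
                    if kmer in reporter_sets[name]:
                        counts[name] += 1
        # ties toward the higher count, then lexicographic name
        best = min(names, key=lambda n: (-counts[n], n))
        if counts[best] >= reporter_min_hits:
            hits.append(
                (
                    ReporterHit(rec.read_id, rec.barcode, rec.umi, best, counts[best]),
                    rec.sequence,
                )
            )
    return hits


def map_to_reporter(
    records: Sequence[UnalignedRead],
    reporter_fasta: str | Path,
    k: int = K_DEFAULT,
    reporter_min_hits: int = REPORTER_MIN_HITS_DEFAULT,
) -> list[ReporterHit]:
    """Match records against the reporter mini-genome.

    A record is a hit if at least ``reporter_min_hits`` of its canonical
    k-windows occur in one reporter sequence. Non-hits are dropped and the
    surviving hits are deduplicated by exact sequence (first kept),
    mirroring the second duplicate-removal pass of the rescue recipe.
    """
    reporter_sets = _load_reporter_sets(reporter_fasta, k)
    raw = _scan_reporters(records, reporter_sets, k, reporter_min_hits)
    seen: set[str] = set()
    out: list[ReporterHit] = []
    for hit, seq in raw:
        if seq not in seen:
            seen.add(seq)
            out.append(hit)
    return out


def count_passenger_cells(
    hits: Sequence[ReporterHit], whitelist: Iterable[str]
) -> tuple[set[str], int]:
    """Intersect hit barcodes with the filtered-cell whitelist.

    Hits carrying non-whitelist barcodes contribute no cell. Returns the
    passenger-positive barcode set and its cardinality.
    """
    wl = set(whitelist)
    if not wl:
        raise ValueError("whitelist is empty")
    barcodes = {h.barcode for h in hits} & wl
    return barcodes, len(barcodes)


def run_rescue(
    calls: pd.DataFrame,
    r2_path: str | Path,
    reporter_fasta: str | Path,
    whitelist: Iterable[str],
    *,
    k: int = K_DEFAULT,
    reporter_min_hits: int = REPORTER_MIN_HITS_DEFAULT,
    condition: str = "",
    dedup_key: str = "seq",
) -> tuple[list[ReporterHit], RescueSummary]:
    """Run the full rescue chain for one condition."""
    unaligned = extract_unaligned(calls, r2_path)
    deduped = dedup_exact(unaligned, key=dedup_key)
    reporter_sets = _load_reporter_sets(reporter_fasta, k)
    raw = _scan_reporters(deduped, reporter_sets, k, reporter_min_hits)
    seen: set[str] = set()
    hits: list[ReporterHit] = []
    for hit, seq in raw:
        if seq not in seen:
            seen.add(seq)
            hits.append(hit)
    barcodes, n_cells = count_passenger_cells(hits, whitelist)
    summary = RescueSummary(
        condition=condition,
        n_unaligned_in=len(unaligned),
        n_after_dedup=len(deduped),
        n_reporter_raw_hits=len(raw),
        n_reporter_hits_dedup=len(hits),
        n_passenger_cells=n_cells,
        passenger_cell_barcodes=barcodes,
    )
    return hits, summary


def write_hits(hits: Sequence[ReporterHit], path: str | Path) -> None:
    pd.DataFrame(
        [(h.read_id, h.barcode, h.umi, h.reporter_name, h.matching_kmer_count) for h in hits],
        columns=["read_id", "barcode", "umi", "reporter_name", "matching_kmer_count"],
    ).to_csv(path, sep="\t", index=False)


def write_rescue_summary(summaries: Sequence[RescueSummary], path: str | Path) -> pd.DataFrame:
    table = pd.DataFrame(
        [
            {
                "condition": s.condition,
                "n_unaligned_in": s.n_unaligned_in,
                "n_after_dedup": s.n_after_dedup,
                "n_reporter_raw_hits": s.n_reporter_raw_hits,
                "n_reporter_hits_dedup": s.n_reporter_hits_dedup,
                "n_passenger_cells": s.n_passenger_cells,
            }
            for s in summaries
        ]
    )
    table.to_csv(path, sep="\t", index=False)
    return table
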