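"""Per-read species-of-origin calls by canonical k-mer voting.

In a barnyard design (mouse phagocytes engulfing human apoptotic cells)
each read's species of origin identifies its cell of origin. Rather than
aligning to both genomes, each cDNA read is scanned for canonical k-mers
and votes are counted per species; k-mers present in both references are
flagged "shared" and count for neither. A read is

* ``unaligned``  if neither species reaches ``min_hits`` matching windows,
* ``mouse`` / ``human`` if that species' hits are at least ``margin`` times
  the other species',
* ``ambiguous`` otherwise.

The unaligned bin feeds the reporter rescue stage; ambiguous reads count
as evidence for neither species downstream.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import zip_longest
from pathlib import Path

import pandas as pd

from ._io import open_text, read_fasta
from .kmers import K_DEFAULT, iter_canonical

LABELS = ("mouse", "human", "ambiguous", "unaligned")

#: default minimum number of matching k-mer windows for an aligned call
MIN_HITS_DEFAULT = 10
#: default dominance factor one species needs over the other
MARGIN_DEFAULT = 2.0


@dataclass(frozen=True)
class KmerIndex:
    """Canonical k-mer lookup: k-mer -> (origin, gene ids).

    ``origin`` is ``"mouse"``, ``"human"`` or ``"shared"``; shared k-mers
    are never counted as evidence for either species.
    """

    k: int
    entries: dict[str, tuple[str, tuple[str, ...]]]

    @property
    def n_shared(self) -> int:
        return sum(1 for origin, _ in self.entries.values() if origin == "shared")


@dataclass
class SpeciesCall:
    read_id: str
    barcode: str
    umi: str
    label: str
    mouse_hits: int
    human_hits: int
    best_gene: str | None


def build_index(
    mouse_fasta: str | Path, human_fasta: str | Path, k: int = K_DEFAULT
) -> KmerIndex:
    """Index every distinct canonical k-mer of both species' transcripts.

    Raises ``ValueError`` on an empty FASTA (missing reference) or a k
    outside the odd 11..31 range (even k breaks canonical-form uniqueness
    for palindromes; very small k loses specificity).
    """
    if k % 2 == 0 or not 11 <= k <= 31:
        raise ValueError(f"k must be odd and within [11, 31]; got {k}")
    entries: dict[str, tuple[str, tuple[str, ...]]] = {}
    for species, path in (("mouse", mouse_fasta), ("human", human_fasta)):
        records = read_fasta(path)
        if not records:
            raise ValueError(f"empty reference FASTA: {path}")
        for gene_id, seq in records:
            for kmer in set(iter_canonical(seq, k)):
                if kmer not in entries:
                    entries[kmer] = (species, (gene_id,))
                else:
                    origin, genes = entries[kmer]
                    if origin == species:
                        if gene_id not in genes:
                            entries[kmer] = (origin, genes + (gene_id,))
                    else:
                        entries[kmer] = ("shared", ())
    return KmerIndex(k=k, entries=entries)


def classify_read(
    cdna_sequence: str,
    index: KmerIndex,
    min_hits: int = MIN_HITS_DEFAULT,
    margin: float = MARGIN_DEFAULT,
) -> SpeciesCall:
    """Classify one cDNA sequence; identifier fields are left empty.

    Every k-window contributes one vote to the species owning its canonical
    form (shared k-mers vote for neither). A read shorter than k is
    ``unaligned`` with zero hits rather than an error.
    """
    mouse_hits = human_hits = 0
    gene_votes: dict[str, Counter] = {"mouse": Counter(), "human": Counter()}
    if len(cdna_sequence) >= index.k:
        for kmer in iter_canonical(cdna_sequence, index.k):
            entry = index.entries.get(kmer)
            if entry is None:
                continue
            origin, genes = entry
            if origin == "mouse":
                mouse_hits += 1
                gene_votes["mouse"].update(genes)
            elif origin == "human":
                human_hits += 1
                gene_votes["human"].update(genes)
    if max(mouse_hits, human_hits) < min_hits:
        label = "unaligned"
    elif mouse_hits >= margin * human_hits:
        label = "mouse"
    elif human_hits >= margin * mouse_hits:
        label = "human"
    else:
        label = "ambiguous"
    best_gene = None
    if label in ("mouse", "human") and gene_votes[label]:
        # modal gene; ties broken toward the lexicographically smallest id
        best = max(gene_votes[label].items(), key=lambda kv: (kv[1], _neg_lex(kv[0])))
        best_gene = best[0]
    return SpeciesCall(
        read_id="",
        barcode="",
        umi="",
        label=label,
        mouse_hits=mouse_hits,
        human_hits=human_hits,
        best_gene=best_gene,
    )


class _neg_lex(str):
    """Order-reversing wrapper so max() prefers the lexicographically smallest."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)


def classify_fastq(
    r1_path: str | Path,
    r2_path: str | Path,
    index: KmerIndex,
    *,
    min_hits: int = MIN_HITS_DEFAULT,
    margin: float = MARGIN_DEFAULT,
    condition: str = "",
    barcode_length: int = 16,
    umi_length: int = 10,
) -> tuple[pd.DataFrame, dict]:
    """Classify every read pair of one library.

    R1 supplies barcode (first 16 bases) and UMI (next 10); R2 supplies the
    cDNA. Returns the per-read calls table and one species-fraction row
    {condition, total_reads, fraction_mouse/human/ambiguous/unaligned}.
    Aborts on mismatched R1/R2 record counts (corrupt pairing).
    """
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    rows = []
    counts = Counter()
    with open_text(r1_path) as h1, open_text(r2_path) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        for rec1, rec2 in zip_longest(it1, it2):
            if rec1 is None or rec2 is None:
                raise ValueError(
                    f"R1/R2 record counts differ between {r1_path} and {r2_path}"
                )
            title1, seq1, _ = rec1
            title2, seq2, _ = rec2
            if len(seq1) < barcode_length + umi_length:
                raise ValueError(f"R1 record shorter than {barcode_length + umi_length} bases")
            call = classify_read(seq2, index, min_hits=min_hits, margin=margin)
            call.read_id = title2.split()[0]
            call.barcode = seq1[:barcode_length]
            call.umi = seq1[barcode_length : barcode_length + umi_length]
            counts[call.label] += 1
            rows.append(
                (
                    call.read_id,
                    call.barcode,
                    call.umi,
                    call.label,
                    call.mouse_hits,
                    call.human_hits,
                    call.best_gene if call.best_gene is not None else "",
                )
            )
    calls = pd.DataFrame(
        rows,
        columns=["read_id", "barcode", "umi", "label", "mouse_hits", "human_hits", "best_gene"],
    )
    total = len(calls)
    fractions = {
        "condition": condition,
        "total_reads": total,
        **{
            f"fraction_{lab}": (counts[lab] / total if total else 0.0)
            for lab in LABELS
        },
    }
    return calls, fractions


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"read_id": str, "barcode": str, "umi": str}, keep_default_na=False
    )


def write_fraction_table(rows: list[dict], path: str | Path) -> pd.DataFrame:
    table = pd.DataFrame(rows)
    table.to_csv(path, sep="\t", index=False)
    return table
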