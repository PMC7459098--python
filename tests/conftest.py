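"""Shared fixtures: toy references, a small simulated experiment, indexes.

Oracle helpers deliberately re-derive canonical k-mers through Biopython's
reverse complement rather than the package's own helpers, so oracle and
implementation stay independent.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import pytest
from Bio.Seq import Seq

from passenger_tracer import (
    SimulationParams,
    build_index,
    make_references,
    simulate_experiment,
)

K = 21


# --- independent oracle primitives -----------------------------------------

def oracle_canonical(kmer: str) -> str:
    rc = str(Seq(kmer).reverse_complement())
    return min(kmer, rc)


def oracle_kmer_set(seq: str, k: int = K) -> set[str]:
    return {oracle_canonical(seq[i : i + k]) for i in range(len(seq) - k + 1)}


def oracle_classify(
    seq: str,
    mouse_kmers: set[str],
    human_kmers: set[str],
    min_hits: int = 10,
    margin: float = 2.0,
) -> tuple[str, int, int]:
    """Brute-force sliding-window species call over plain k-mer sets."""
    shared = mouse_kmers & human_kmers
    m = h = 0
    for i in range(len(seq) - K + 1):
        kmer = oracle_canonical(seq[i : i + K])
        if kmer in shared:
            continue
        if kmer in mouse_kmers:
            m += 1
        elif kmer in human_kmers:
            h += 1
    if max(m, h) < min_hits:
        return "unaligned", m, h
    if m >= margin * h:
        return "mouse", m, h
    if h >= margin * m:
        return "human", m, h
    return "ambiguous", m, h


_KSET_CACHE: dict[int, tuple[set[str], set[str]]] = {}


def species_kmer_sets(refs) -> tuple[set[str], set[str]]:
    key = id(refs)
    if key not in _KSET_CACHE:
        mouse = set().union(*(oracle_kmer_set(s) for _, s in refs.mouse_transcripts))
        human = set().union(*(oracle_kmer_set(s) for _, s in refs.human_transcripts))
        _KSET_CACHE[key] = (mouse, human)
    return _KSET_CACHE[key]


def read_fastq_records(path: Path) -> list[tuple[str, str, str]]:
    """(id, seq, qual) triples, plain parsing for validity checks."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        lines = [line.rstrip("\n") for line in fh]
    assert len(lines) % 4 == 0, "FASTQ record not 4 lines"
    out = []
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        assert header.startswith("@") and plus.startswith("+")
        out.append((header[1:].split()[0], seq, qual))
    return out


# --- fixtures ---------------------------------------------------------------

@pytest.fixture(scope="session")
def toy_refs():
    return make_references(seed=1, n_genes_per_species=20, transcript_length_range=(150, 220))


@pytest.fixture(scope="session")
def ref_dir(toy_refs, tmp_path_factory) -> Path:
    outdir = tmp_path_factory.mktemp("refs")
    toy_refs.write(outdir)
    return outdir


@pytest.fixture(scope="session")
def toy_index(ref_dir):
    return build_index(ref_dir / "refs_mouse.fasta", ref_dir / "refs_human.fasta", k=K)


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    return SimulationParams(
        n_cells_per_condition=40,
        reads_per_cell=60.0,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_sim(toy_refs, small_params, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("sim")
    return simulate_experiment(toy_refs, small_params, outdir)
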