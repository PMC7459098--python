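"""Canonical k-mer primitives shared by the classifier, rescue and simulator.

A canonical k-mer is the lexicographic minimum of a k-mer and its reverse
complement; using canonical form makes every downstream comparison
strand-insensitive, since droplet cDNA read orientation is not modeled.
"""

from __future__ import annotations

from typing import Iterator

K_DEFAULT = 21

_RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T} alphabet."""
    return seq.translate(_RC)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic min of a k-mer and its reverse complement."""
    rc = kmer.translate(_RC)[::-1]
    return kmer if kmer <= rc else rc


def iter_canonical(seq: str, k: int) -> Iterator[str]:
    """Yield the canonical form of every k-window of ``seq``, in order."""
    for i in range(len(seq) - k + 1):
        yield canonical(seq[i : i + k])


def canonical_kmer_set(seq: str, k: int) -> set[str]:
    """Distinct canonical k-mers of ``seq``."""
    return set(iter_canonical(seq, k))
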