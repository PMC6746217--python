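"""Low-level sequence helpers shared across the pipeline.

Everything here operates on plain uppercase DNA strings over {A,C,G,T,N}
plus IUPAC ambiguity codes where noted.
"""

from __future__ import annotations

from typing import Iterator

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)

# unordered base set -> IUPAC code
IUPAC_CODES = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
    frozenset("ACG"): "V",
    frozenset("ACT"): "H",
    frozenset("AGT"): "D",
    frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic min of a k-mer and its reverse complement."""
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


def kmers(seq: str, k: int, skip_n: bool = True) -> Iterator[tuple[int, str]]:
    """Yield (position, k-mer) pairs; windows containing N are skipped."""
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if skip_n and "N" in km:
            continue
        yield i, km


def iupac_code(bases: set[str] | frozenset[str]) -> str:
    """IUPAC code for a set of unambiguous bases (ties in consensus calls)."""
    return IUPAC_CODES[frozenset(bases)]


def gc_percent(seq: str, ndigits: int = 1) -> float:
    """GC% over unambiguous A/C/G/T positions only (ambiguities excluded)."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return round(100.0 * (seq.count("G") + seq.count("C")) / acgt, ndigits)


def normalize(seq: str) -> str:
    """Canonical alphabet used everywhere downstream: uppercase, U->T."""
    return seq.upper().replace("U", "T")


def hamming_identity(a: str, b: str) -> float:
    """Fraction of equal positions between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming_identity requires equal lengths")
    if not a:
        return 1.0
    return sum(x == y for x, y in zip(a, b)) / len(a)
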