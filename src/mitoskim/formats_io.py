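"""Readers and writers for the standard formats the pipeline touches.

All sequence I/O is funnelled through this module so that the rest of the
package only ever sees :class:`ReadPair` and :class:`SeqRecord` objects with
a single canonical alphabet (uppercase, U->T, Phred+33 qualities decoded to
integers).  FASTQ parsing follows the CASAVA 1.8 header convention
``instrument:run:flowcell:lane:tile:x:y`` so that per-tile quality filtering
downstream can recover the flowcell tile of every read.
"""

from __future__ import annotations

import gzip
import io
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._seq import normalize

logger = logging.getLogger(__name__)

PHRED_OFFSET = 33


@dataclass
class SeqRecord:
    """A named nucleotide sequence (bait references, contigs, consensus)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        self.seq = normalize(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadPair:
    """A mate pair with per-base qualities and flowcell tile coordinates."""

    read_id: str
    mate1_seq: str
    mate2_seq: str
    mate1_quals: Sequence[int]
    mate2_quals: Sequence[int]
    lane: int = 1
    tile: int = 1

    def __post_init__(self) -> None:
        self.mate1_seq = normalize(self.mate1_seq)
        self.mate2_seq = normalize(self.mate2_seq)
        if not self.mate1_seq or not self.mate2_seq:
            raise ValueError(f"{self.read_id}: empty mate sequence")
        if len(self.mate1_seq) != len(self.mate1_quals) or len(
            self.mate2_seq
        ) != len(self.mate2_quals):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")
        if self.tile < 1:
            raise ValueError(f"{self.read_id}: tile must be >= 1")

    @property
    def mates(self) -> tuple[tuple[str, Sequence[int]], tuple[str, Sequence[int]]]:
        return (self.mate1_seq, self.mate1_quals), (self.mate2_seq, self.mate2_quals)


def _open_text(path: str | os.PathLike, mode: str = "rt"):
    """Open plain or gzip-compressed text transparently by extension."""
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_casava_header(header: str) -> tuple[str, int, int]:
    """Return (read id sans mate suffix, lane, tile) from a FASTQ title line.

    Headers lacking the 7-field colon convention fall back to lane=1/tile=1
    with a logged warning, so non-Illumina input still streams through.
    """
    name = header.split()[0]
    if name.endswith("/1") or name.endswith("/2"):
        name = name[:-2]
    parts = name.split(":")
    if len(parts) >= 7:
        try:
            return name, int(parts[3]), int(parts[4])
        except ValueError:
            pass
    logger.warning("header %r lacks lane:tile fields; assuming lane=1 tile=1", header)
    return name, 1, 1


def _decode_quals(qual: str, offset: int = PHRED_OFFSET) -> list[int]:
    return [ord(c) - offset for c in qual]


def _encode_quals(quals: Sequence[int], offset: int = PHRED_OFFSET) -> str:
    return "".join(chr(q + offset) for q in quals)


def read_fastq_pairs(
    path1: str | os.PathLike,
    path2: str | os.PathLike,
    phred_offset: int = PHRED_OFFSET,
) -> Iterator[ReadPair]:
    """Stream mate pairs from two parallel FASTQ files (optionally gzipped).

    Raises if the two files hold different record counts or if mate ids
    disagree after stripping the /1 //2 suffix.
    """
    with _open_text(path1) as h1, _open_text(path2) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                short = path1 if rec1 is None else path2
                raise ValueError(f"mismatched pair counts: {short} is shorter")
            (t1, s1, q1), (t2, s2, q2) = rec1, rec2
            id1, lane, tile = _parse_casava_header(t1)
            id2, _, _ = _parse_casava_header(t2)
            if id1 != id2:
                raise ValueError(f"mate id mismatch: {id1!r} vs {id2!r}")
            yield ReadPair(
                read_id=id1,
                mate1_seq=s1,
                mate2_seq=s2,
                mate1_quals=_decode_quals(q1, phred_offset),
                mate2_quals=_decode_quals(q2, phred_offset),
                lane=lane,
                tile=tile,
            )


def write_fastq_pairs(
    pairs: Iterable[ReadPair],
    path1: str | os.PathLike,
    path2: str | os.PathLike,
) -> int:
    """Write pairs to two parallel FASTQ files; returns the pair count."""
    n = 0
    with _open_text(path1, "wt") as h1, _open_text(path2, "wt") as h2:
        for p in pairs:
            h1.write(f"@{p.read_id} 1:N:0:1\n{p.mate1_seq}\n+\n{_encode_quals(p.mate1_quals)}\n")
            h2.write(f"@{p.read_id} 2:N:0:1\n{p.mate2_seq}\n+\n{_encode_quals(p.mate2_quals)}\n")
            n += 1
    return n


def read_fasta(path: str | os.PathLike) -> list[SeqRecord]:
    """Read FASTA records; sequences are normalized to uppercase, U->T."""
    records: list[SeqRecord] = []
    with _open_text(path) as handle:
        rec_id = None
        desc = ""
        chunks: list[str] = []
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if rec_id is not None:
                    records.append(SeqRecord(rec_id, "".join(chunks), desc))
                fields = line[1:].split(None, 1)
                rec_id = fields[0] if fields else ""
                desc = fields[1] if len(fields) > 1 else ""
                chunks = []
            elif line:
                chunks.append(line)
        if rec_id is not None:
            records.append(SeqRecord(rec_id, "".join(chunks), desc))
    return records


def write_fasta(
    records: Iterable[SeqRecord],
    path: str | os.PathLike,
    width: int = 70,
) -> None:
    """Write FASTA with fixed line width; read(write(x)) == x for id and seq."""
    if width < 1:
        raise ValueError("width must be >= 1")
    with _open_text(path, "wt") as handle:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            handle.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                handle.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Feature output: GFF3 (1-based closed intervals) and NCBI 5-column table.
# Both writers are deterministic ("bit-stable") given identical input.
# ---------------------------------------------------------------------------

_GFF_TYPE = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "D_loop", "NCR": "region"}


def write_gff3(features, seqid: str, length: int, path: str | os.PathLike) -> None:
    """Write features (annotate.FeatureAnnotation-like) as GFF3.

    Features carry 0-based half-open coordinates internally; GFF3 is 1-based
    closed, so start+1..end.
    """
    with _open_text(path, "wt") as handle:
        handle.write("##gff-version 3\n")
        handle.write(f"##sequence-region {seqid} 1 {length}\n")
        for i, f in enumerate(sorted(features, key=lambda f: (f.start, f.end))):
            ftype = _GFF_TYPE.get(f.kind, "region")
            attrs = [f"ID={f.name or f.kind}.{i}", f"Name={f.name or f.kind}"]
            if getattr(f, "flags", None):
                attrs.append("note=" + ",".join(sorted(f.flags)))
            handle.write(
                "\t".join(
                    [
                        seqid,
                        "mitoskim",
                        ftype,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        "0" if f.kind == "CDS" else ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def parse_gff3(path: str | os.PathLike):
    """Read a mitoskim GFF3 back into FeatureAnnotation objects."""
    from .annotate import FeatureAnnotation  # local import avoids a cycle

    inverse = {v: k for k, v in _GFF_TYPE.items()}
    feats = []
    with _open_text(path) as handle:
        for line in handle:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            kind = inverse.get(cols[2], "NCR")
            if kind == "CR" and attrs.get("Name") == "NCR":
                kind = "NCR"
            flags = set(attrs["note"].split(",")) if "note" in attrs else set()
            feats.append(
                FeatureAnnotation(
                    name=attrs.get("Name", cols[2]),
                    kind=kind,
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6],
                    evidence=set(),
                    flags=flags,
                )
            )
    return feats


def write_feature_table(features, seqid: str, path: str | os.PathLike) -> None:
    """NCBI 5-column feature table (tbl2asn flavour), 1-based inclusive."""
    kind_to_key = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "D-loop", "NCR": "misc_feature"}
    with _open_text(path, "wt") as handle:
        handle.write(f">Feature {seqid}\n")
        for f in sorted(features, key=lambda f: (f.start, f.end)):
            start, end = f.start + 1, f.end
            if f.strand == "-":
                start, end = end, start
            handle.write(f"{start}\t{end}\t{kind_to_key.get(f.kind, 'misc_feature')}\n")
            qualifier = "product" if f.kind in ("tRNA", "rRNA") else "gene"
            if f.name:
                handle.write(f"\t\t\t{qualifier}\t{f.name}\n")
            for flag in sorted(getattr(f, "flags", ()) or ()):
                handle.write(f"\t\t\tnote\t{flag}\n")
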