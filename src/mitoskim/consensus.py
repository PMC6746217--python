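"""Conservative consensus calling from a read pileup.

Raw reads are mapped back onto the putative mitogenome and a consensus is
called per column with a deliberately conservative rule: a base is accepted
only when it matches at least ``agree`` (default 99%) of the covering reads
and the column depth is at least ``min_cov`` (default 3).  Columns below the
depth floor become N; columns without a 99% winner receive the IUPAC code of
every base carried by at least (1 - agree) of the reads, so singleton
sequencing errors cannot inflate the ambiguity code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from ._seq import iupac_code, revcomp
from .assemble import _BASES, _SeedMap, _align_and_tally, Contig
from .formats_io import ReadPair, SeqRecord


@dataclass
class ConsensusParams:
    agree: float = 0.99
    min_cov: int = 3

    def __post_init__(self) -> None:
        if not (0.5 < self.agree <= 1.0):
            raise ValueError("agree must be in (0.5, 1]")
        if self.min_cov < 1:
            raise ValueError("min_cov must be >= 1")


@dataclass
class PileupColumn:
    pos: int
    counts: list[int]  # A, C, G, T tallies
    qual_mean: float
    gaps: int = 0
    flagged_gap: bool = False

    @property
    def depth(self) -> int:
        return sum(self.counts)


def build_pileup(
    contig: Contig | SeqRecord | str,
    pairs: Iterable[ReadPair],
    min_map_identity: float = 0.90,
) -> list[PileupColumn]:
    """Map reads back to the contig and tally bases per position.

    Circular contigs are handled by mapping against the contig extended by
    its own prefix and folding columns modulo the contig length, so reads
    spanning the origin contribute to both ends.
    """
    if isinstance(contig, str):
        seq, circular = contig, False
    else:
        seq = contig.seq
        circular = getattr(contig, "circular", False)
    L = len(seq)
    pairs = list(pairs)
    wrap = 0
    if circular and pairs:
        wrap = min(L, max(max(len(p.mate1_seq), len(p.mate2_seq)) for p in pairs))
    ext = seq + seq[:wrap]
    seeds = _SeedMap(ext)
    counts = [[0, 0, 0, 0] for _ in range(len(ext))]
    qual_sums = [0.0] * len(ext)
    gap_counts = [0] * len(ext)
    dump: dict[int, list[int]] = {}

    for pair in pairs:
        for mate_seq, mate_quals in pair.mates:
            for oriented, oq in (
                (mate_seq, list(mate_quals)),
                (revcomp(mate_seq), list(mate_quals)[::-1]),
            ):
                diag, votes = seeds.best_diagonal(oriented)
                if votes < 1:
                    continue
                if _align_and_tally(
                    oriented, oq, ext, diag, min_map_identity,
                    counts, qual_sums, dump, dump, gap_counts,
                ):
                    break  # mapped in this orientation

    # fold the wrapped extension back onto the origin
    for i in range(L, len(ext)):
        col = i - L
        for b in range(4):
            counts[col][b] += counts[i][b]
        qual_sums[col] += qual_sums[i]
        gap_counts[col] += gap_counts[i]

    columns = []
    for i in range(L):
        depth = sum(counts[i])
        flagged = gap_counts[i] >= max(1, depth) * 0.5 and gap_counts[i] > 0
        columns.append(
            PileupColumn(
                pos=i,
                counts=counts[i],
                qual_mean=qual_sums[i] / depth if depth else 0.0,
                gaps=gap_counts[i],
                flagged_gap=flagged,
            )
        )
    return columns


def call_consensus(
    pileup: Sequence[PileupColumn],
    params: ConsensusParams | None = None,
    record_id: str = "consensus",
) -> SeqRecord:
    """Apply the >=99% agreement / >=3x coverage rule column by column."""
    params = params or ConsensusParams()
    bases = []
    n_ambiguous = 0
    n_low_cov = 0
    for col in pileup:
        depth = col.depth
        if depth < params.min_cov:
            bases.append("N")
            n_low_cov += 1
            continue
        eps = 1e-9  # guard float artifacts at exact-threshold fractions
        fractions = [c / depth for c in col.counts]
        best = max(fractions)
        if best >= params.agree - eps:
            bases.append(_BASES[fractions.index(best)])
            continue
        carried = {
            b for b, f in zip(_BASES, fractions) if f >= (1.0 - params.agree) - eps
        }
        bases.append(iupac_code(carried) if carried else "N")
        n_ambiguous += 1
    rec = SeqRecord(
        id=record_id,
        seq="".join(bases),
        description=f"ambiguities={n_ambiguous} low_coverage={n_low_cov}",
    )
    return rec


def count_ambiguities(seq: str) -> int:
    """Number of non-ACGT characters (IUPAC codes and N)."""
    return sum(1 for c in seq if c not in "ACGT")


def write_depth_report(pileup: Sequence[PileupColumn], path) -> None:
    with open(path, "w") as handle:
        handle.write("pos\tA\tC\tG\tT\tdepth\tmean_q\tgaps\n")
        for col in pileup:
            a, c, g, t = col.counts
            handle.write(
                f"{col.pos}\t{a}\t{c}\t{g}\t{t}\t{col.depth}\t{col.qual_mean:.1f}\t{col.gaps}\n"
            )
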