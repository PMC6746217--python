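"""Read quality control: per-tile filtering and sliding-window 3' trimming.

Illumina flowcells occasionally produce whole tiles of degraded base calls
(bubbles, focus loss).  Dropping every read from a bad tile before assembly
is cheaper and safer than trying to rescue individual reads.  The per-read
step then applies Trimmomatic-style SLIDINGWINDOW semantics from the 3' end
and discards any pair in which either trimmed mate becomes too short - the
assembler downstream consumes full pairs only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .formats_io import ReadPair


@dataclass
class QCParams:
    """Quality-control thresholds.

    tile_min_q     minimum tile mean Phred for the tile to survive
    window         sliding-window length (bases)
    window_min_q   minimum window mean Phred; the read is cut at the first
                   window falling below this
    min_len        minimum surviving read length; shorter => pair dropped
    trim_3prime_only  only the 3' end is ever trimmed (reads stay prefixes)
    """

    tile_min_q: float = 25.0
    window: int = 4
    window_min_q: float = 20.0
    min_len: int = 36
    trim_3prime_only: bool = True

    def __post_init__(self) -> None:
        if self.window < 1 or self.min_len < 1:
            raise ValueError("window and min_len must be >= 1")


@dataclass
class TileStats:
    lane: int
    tile: int
    n_reads: int
    mean_q: float
    passed: bool


def compute_tile_stats(
    pairs: Iterable[ReadPair], tile_min_q: float = 25.0
) -> list[TileStats]:
    """Mean Phred per (lane, tile) over all bases of all reads in the tile."""
    sums: dict[tuple[int, int], list[float]] = {}
    for p in pairs:
        key = (p.lane, p.tile)
        acc = sums.setdefault(key, [0.0, 0, 0])  # qual sum, base count, reads
        for _, quals in p.mates:
            acc[0] += sum(quals)
            acc[1] += len(quals)
            acc[2] += 1
    if not sums:
        raise ValueError("no reads")
    stats = []
    for (lane, tile) in sorted(sums):
        qsum, nbases, nreads = sums[(lane, tile)]
        mean_q = qsum / nbases
        stats.append(TileStats(lane, tile, nreads, mean_q, mean_q >= tile_min_q))
    return stats


def filter_tiles(
    pairs: Iterable[ReadPair], tile_stats: list[TileStats]
) -> Iterator[ReadPair]:
    """Keep exactly the pairs whose (lane, tile) passed tile selection."""
    verdict = {(t.lane, t.tile): t.passed for t in tile_stats}
    for p in pairs:
        key = (p.lane, p.tile)
        if key not in verdict:
            raise ValueError(f"pair {p.read_id} in unknown tile {key}")
        if verdict[key]:
            yield p


def _trim_length(quals, window: int, window_min_q: float) -> int:
    """Surviving prefix length under SLIDINGWINDOW trimming.

    The read is cut at the start of the first full window whose mean Phred
    drops below window_min_q; windows that would run past the read end are
    not evaluated (short tails keep their bases).
    """
    n = len(quals)
    threshold = window_min_q * window
    for i in range(n - window + 1):
        if sum(quals[i : i + window]) < threshold:
            # keep leading bases of the failing window that individually
            # meet the threshold (SLIDINGWINDOW semantics)
            j = i
            while j < n and quals[j] >= window_min_q:
                j += 1
            return j
    return n


def trim_and_filter(pair: ReadPair, params: QCParams) -> ReadPair | None:
    """Trim both mates from the 3' end; drop the whole pair if either mate
    falls below min_len (no singletons survive)."""
    n1 = _trim_length(pair.mate1_quals, params.window, params.window_min_q)
    n2 = _trim_length(pair.mate2_quals, params.window, params.window_min_q)
    if n1 < params.min_len or n2 < params.min_len:
        return None
    if n1 == len(pair.mate1_seq) and n2 == len(pair.mate2_seq):
        return pair
    return ReadPair(
        read_id=pair.read_id,
        mate1_seq=pair.mate1_seq[:n1],
        mate2_seq=pair.mate2_seq[:n2],
        mate1_quals=list(pair.mate1_quals[:n1]),
        mate2_quals=list(pair.mate2_quals[:n2]),
        lane=pair.lane,
        tile=pair.tile,
    )


def run_qc(
    pairs: Iterable[ReadPair], params: QCParams | None = None
) -> tuple[list[ReadPair], list[TileStats]]:
    """Full QC pass: tile selection, then per-pair trimming/filtering."""
    params = params or QCParams()
    pairs = list(pairs)
    stats = compute_tile_stats(pairs, params.tile_min_q)
    surviving = []
    for p in filter_tiles(pairs, stats):
        trimmed = trim_and_filter(p, params)
        if trimmed is not None:
            surviving.append(trimmed)
    return surviving, stats


def write_tile_report(stats: list[TileStats], path) -> None:
    with open(path, "w") as handle:
        handle.write("lane\ttile\tn_reads\tmean_q\tpass\n")
        for t in stats:
            handle.write(
                f"{t.lane}\t{t.tile}\t{t.n_reads}\t{t.mean_q:.2f}\t{int(t.passed)}\n"
            )
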