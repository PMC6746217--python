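"""Junction-window circularization testing.

A putative circular mitogenome contig, if truly circular, is supported by
reads that span the artificial junction between its two ends.  The test
concatenates the terminal flanks of the contig (default 50 nt each) into a
2F-long junction window, recruits reads by exact seed sharing at several
seed lengths, aligns them locally into the window, and summarizes the
support as four statistics:

* avg_coverage    mean aligned read depth over the 2F columns
* avg_contiguity  the same mean depth counting only reads whose alignment
                  covers both seam-adjacent columns with no gap opened
                  across the seam (the circularity signal)
* avg_quality     mean Phred of read bases aligned into the window
* aln_score       mean over aligned reads of (local score - maximum possible
                  score for the aligned span); 0 is perfect, more negative
                  means noisier support

The seed length maximizing contiguity is selected and a combined-criterion
verdict (circular / linear / ambiguous) is emitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import Align

from ._seq import revcomp
from .assemble import Contig
from .formats_io import ReadPair

DEFAULT_SEED_LENS = (15, 19, 23, 31)


@dataclass
class JunctionWindow:
    """Concatenation of the last F and first F nt of the contig."""

    seq: str
    flank_len: int

    @property
    def seam(self) -> int:
        """Column index of the first base after the seam (== F)."""
        return self.flank_len


@dataclass
class CircStats:
    seed_len: int
    avg_coverage: float
    avg_contiguity: float
    avg_quality: float
    aln_score: float
    n_reads: int
    verdict: str = "linear"


def make_junction(contig: Contig | str, flank_len: int = 50) -> JunctionWindow:
    """Build the junction window from a contig's terminal flanks."""
    seq = contig.seq if isinstance(contig, Contig) else contig
    if flank_len < 10:
        raise ValueError("flank_len must be >= 10")
    if len(seq) < 2 * flank_len:
        raise ValueError(
            f"contig ({len(seq)} nt) shorter than 2 x flank_len ({2 * flank_len})"
        )
    return JunctionWindow(seq=seq[-flank_len:] + seq[:flank_len], flank_len=flank_len)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


def _window_seeds(window: str, k: int) -> set[str]:
    return {window[i : i + k] for i in range(len(window) - k + 1)}


def _shares_seed(read: str, seeds: set[str], k: int) -> bool:
    return any(read[i : i + k] in seeds for i in range(len(read) - k + 1))


def junction_stats(
    window: JunctionWindow,
    pairs: Iterable[ReadPair],
    seed_lens: Sequence[int] = DEFAULT_SEED_LENS,
    min_contiguity: float = 10.0,
    min_ratio: float = 0.5,
) -> list[CircStats]:
    """Compute the circularization statistics at each seed length."""
    if not seed_lens:
        raise ValueError("seed_lens must be non-empty")
    pairs = list(pairs)
    aligner = _make_aligner()
    wseq = window.seq
    two_f = len(wseq)
    seam = window.seam
    out = []
    for k in sorted(seed_lens):
        seeds = _window_seeds(wseq, k)
        cov_cols = 0  # total aligned columns across reads
        contig_cols = 0  # same, seam-spanning gap-free reads only
        qual_sum = 0.0
        qual_n = 0
        score_sum = 0.0
        n_reads = 0
        for pair in pairs:
            for mate_seq, mate_quals in pair.mates:
                for oriented, oq in (
                    (mate_seq, list(mate_quals)),
                    (revcomp(mate_seq), list(mate_quals)[::-1]),
                ):
                    if len(oriented) < k or not _shares_seed(oriented, seeds, k):
                        continue
                    aln = aligner.align(wseq, oriented)
                    best = aln[0]
                    blocks = best.aligned  # (target blocks, query blocks)
                    t_blocks, q_blocks = blocks[0], blocks[1]
                    aligned_cols = sum(int(e - s) for s, e in t_blocks)
                    if aligned_cols == 0:
                        continue
                    n_reads += 1
                    cov_cols += aligned_cols
                    # seam-spanning without a gap across the seam: one
                    # ungapped block must contain columns seam-1 and seam
                    spans = any(s <= seam - 1 and e >= seam + 1 for s, e in t_blocks)
                    if spans:
                        contig_cols += aligned_cols
                    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
                        qual_sum += sum(oq[int(qs) : int(qe)])
                        qual_n += int(qe - qs)
                    score_sum += best.score - aligned_cols
                    break  # one orientation per mate
        stats = CircStats(
            seed_len=k,
            avg_coverage=cov_cols / two_f,
            avg_contiguity=contig_cols / two_f,
            avg_quality=qual_sum / qual_n if qual_n else 0.0,
            aln_score=score_sum / n_reads if n_reads else 0.0,
            n_reads=n_reads,
        )
        stats.verdict = _verdict(stats, min_contiguity, min_ratio)
        out.append(stats)
    return out


def _verdict(stats: CircStats, min_contiguity: float, min_ratio: float) -> str:
    if (
        stats.avg_contiguity >= min_contiguity
        and stats.avg_coverage > 0
        and stats.avg_contiguity / stats.avg_coverage >= min_ratio
    ):
        return "circular"
    if stats.avg_contiguity < min_contiguity / 2:
        return "linear"
    return "ambiguous"


def select_and_verdict(
    stats: list[CircStats],
    min_contiguity: float = 10.0,
    min_ratio: float = 0.5,
) -> CircStats:
    """Pick the best seed length by the combined criterion and re-verdict.

    Selection maximizes avg_contiguity; ties broken by higher avg_quality,
    then less-negative aln_score.
    """
    if not stats:
        raise ValueError("stats must be non-empty")
    best = max(
        stats, key=lambda s: (s.avg_contiguity, s.avg_quality, s.aln_score)
    )
    best.verdict = _verdict(best, min_contiguity, min_ratio)
    return best


def circularity_check(
    contig: Contig | str,
    pairs: Iterable[ReadPair],
    flank_len: int = 50,
    seed_lens: Sequence[int] = DEFAULT_SEED_LENS,
    min_contiguity: float = 10.0,
    min_ratio: float = 0.5,
) -> tuple[CircStats, list[CircStats]]:
    """Convenience wrapper: window -> per-seed stats -> selected verdict."""
    window = make_junction(contig, flank_len)
    stats = junction_stats(window, pairs, seed_lens, min_contiguity, min_ratio)
    return select_and_verdict(stats, min_contiguity, min_ratio), stats
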