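"""Baiting-and-iterative-mapping mitogenome assembly.

The assembler recruits reads that share canonical k-mers with a cross-species
bait mitogenome, maps them onto the bait backbone, and then repeatedly
re-baits with the growing contig, extending its ends with the consensus of
overhanging reads until the contig reaches a fixpoint.  When the two contig
ends come to share a long high-identity overlap the molecule is declared
circular and the duplicated overlap is trimmed once.

Read placement is seed-and-verify: exact 15-mer seeds vote for a placement
diagonal, the winning placement is verified by banded edit-distance
alignment (edlib) and only alignments at or above ``min_map_identity``
contribute to base tallies.  All tie-breaks are deterministic, so a fixed
``rng_seed`` gives bit-identical output.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib

from ._seq import canonical, iupac_code, kmers, revcomp
from .formats_io import ReadPair, SeqRecord

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}

SEED_K = 15  # exact-seed length for read placement (distinct from bait k)
MIN_OVERLAP = 20  # shortest read/contig overlap worth tallying


@dataclass
class AssemblyParams:
    """Knobs of the baiting / mapping / extension loop."""

    k_bait: int = 31
    min_shared_kmers: int = 2
    min_map_identity: float = 0.90
    min_extend_cov: int = 3
    max_extension_per_iter: int = 500
    max_iter: int = 50
    overlap_for_circularity: int = 50
    overlap_identity: float = 0.99
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.min_map_identity <= 1):
            raise ValueError("min_map_identity must be in (0, 1]")
        for name in ("min_shared_kmers", "min_extend_cov", "max_iter"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class Contig:
    """Assembled sequence plus per-position evidence.

    tallies[i] is the [A, C, G, T] count at column i; coverage[i] is their
    sum.  ``qual_sums[i]`` accumulates Phred scores for mean-quality reports.
    """

    seq: str
    tallies: list[list[int]] = field(default_factory=list)
    qual_sums: list[float] = field(default_factory=list)
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.tallies:
            self.tallies = [[0, 0, 0, 0] for _ in self.seq]
        if not self.qual_sums:
            self.qual_sums = [0.0] * len(self.seq)
        if len(self.tallies) != len(self.seq):
            raise ValueError("tallies/seq length mismatch")

    @property
    def coverage(self) -> list[int]:
        return [sum(t) for t in self.tallies]

    def __len__(self) -> int:
        return len(self.seq)

    def coverage_stats(self) -> dict:
        """Mean coverage with quartiles, as assembly reports print them."""
        cov = sorted(self.coverage)
        if not cov:
            return {"mean": 0.0, "q1": 0.0, "q3": 0.0}

        def _quantile(q: float) -> float:
            idx = q * (len(cov) - 1)
            lo, hi = int(math.floor(idx)), int(math.ceil(idx))
            return cov[lo] + (cov[hi] - cov[lo]) * (idx - lo)

        return {
            "mean": sum(cov) / len(cov),
            "q1": _quantile(0.25),
            "q3": _quantile(0.75),
        }


@dataclass
class AssemblyState:
    iteration: int
    contig: Contig
    n_baited: int
    n_mapped: int
    converged: bool
    circularized: bool


class KmerIndex:
    """Canonical k-mer -> set of (pair index, mate number) postings."""

    def __init__(self, k: int):
        self.k = k
        self.index: dict[str, list[tuple[int, int]]] = {}

    def add_read(self, pair_idx: int, mate: int, seq: str) -> None:
        seen: set[str] = set()
        for _, km in kmers(seq, self.k):
            can = canonical(km)
            if can not in seen:  # count distinct k-mers once per read
                seen.add(can)
                self.index.setdefault(can, []).append((pair_idx, mate))


def build_kmer_index(pairs: Sequence[ReadPair], k: int = 31) -> KmerIndex:
    """Index every N-free canonical k-mer of every mate."""
    if not (11 <= k <= 63) or k % 2 == 0:
        raise ValueError("k must be odd and in [11, 63]")
    max_len = max((max(len(p.mate1_seq), len(p.mate2_seq)) for p in pairs), default=0)
    if k > max_len:
        raise ValueError(f"k={k} exceeds longest read ({max_len})")
    idx = KmerIndex(k)
    for i, p in enumerate(pairs):
        idx.add_read(i, 1, p.mate1_seq)
        idx.add_read(i, 2, p.mate2_seq)
    return idx


def bait_reads(
    index: KmerIndex, query: str, min_shared_kmers: int = 2
) -> set[int]:
    """Pair indices recruited by the query: either mate sharing enough
    distinct canonical k-mers recruits the whole pair (pair-aware baiting)."""
    if len(query) < index.k:
        raise ValueError("query shorter than k")
    shared: Counter[tuple[int, int]] = Counter()
    seen: set[str] = set()
    for _, km in kmers(query, index.k):
        can = canonical(km)
        if can in seen:
            continue
        seen.add(can)
        for posting in index.index.get(can, ()):
            shared[posting] += 1
    return {pair for (pair, _), n in shared.items() if n >= min_shared_kmers}


# ---------------------------------------------------------------------------
# Read placement
# ---------------------------------------------------------------------------


class _SeedMap:
    """Exact-seed position lookup on a contig for diagonal voting."""

    def __init__(self, seq: str, k: int = SEED_K):
        self.k = k
        self.seq = seq
        self.positions: dict[str, list[int]] = {}
        for i, km in kmers(seq, k, skip_n=False):
            self.positions.setdefault(km, []).append(i)

    def best_diagonal(self, read: str, step: int = 4) -> tuple[int, int]:
        """(diagonal, votes); diagonal = contig_pos - read_pos."""
        votes: Counter[int] = Counter()
        n = len(read)
        if n < self.k:
            return 0, 0
        offsets = list(range(0, n - self.k + 1, step))
        if offsets[-1] != n - self.k:
            offsets.append(n - self.k)
        for i in offsets:
            for pos in self.positions.get(read[i : i + self.k], ()):
                votes[pos - i] += 1
        if not votes:
            return 0, 0
        # deterministic: most votes, smallest diagonal on ties
        diag, n_votes = min(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        return diag, n_votes


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _align_and_tally(
    read: str,
    quals: Sequence[int] | None,
    contig_seq: str,
    diag: int,
    min_identity: float,
    tallies: list[list[int]],
    qual_sums: list[float],
    left_over: dict[int, list[int]],
    right_over: dict[int, list[int]],
    gap_counts: list[int] | None = None,
) -> bool:
    """Verify a diagonal placement and add the read's bases to the tallies.

    Returns True when the read mapped at or above min_identity.  Bases that
    fall outside the contig (overhangs) are tallied into left_over /
    right_over keyed by their (possibly negative) virtual column.
    """
    L = len(contig_seq)
    qstart = max(0, -diag)
    qend = min(len(read), L - diag)
    if qend - qstart < MIN_OVERLAP:
        return False
    q_seg = read[qstart:qend]
    c_start, c_end = diag + qstart, diag + qend
    c_seg = contig_seq[c_start:c_end]
    res = edlib.align(q_seg, c_seg, mode="NW", task="path")
    dist = res["editDistance"]
    identity = 1.0 - dist / len(q_seg)
    if identity < min_identity:
        return False
    hamming = sum(a != b for a, b in zip(q_seg, c_seg))
    if dist == hamming:
        # substitutions alone explain the differences; tally positionally so
        # adjacent mismatches are never re-expressed as an indel pair
        for j in range(len(q_seg)):
            b = _BASE_IDX.get(q_seg[j])
            if b is not None:
                tallies[c_start + j][b] += 1
                if quals is not None:
                    qual_sums[c_start + j] += quals[qstart + j]
    else:
        qpos, cpos = qstart, c_start
        for n, op in _cigar_ops(res["cigar"]):
            if op in "=XM":
                for j in range(n):
                    b = _BASE_IDX.get(read[qpos + j])
                    if b is not None:
                        tallies[cpos + j][b] += 1
                        if quals is not None:
                            qual_sums[cpos + j] += quals[qpos + j]
                qpos += n
                cpos += n
            elif op == "I":  # extra bases in the read
                qpos += n
            elif op == "D":  # contig bases absent from the read
                if gap_counts is not None:
                    for j in range(n):
                        gap_counts[cpos + j] += 1
                cpos += n
    # overhangs (placed by diagonal; no alignment beyond contig ends)
    for qpos in range(0, qstart):
        col = diag + qpos
        if col < 0:
            b = _BASE_IDX.get(read[qpos])
            if b is not None:
                left_over.setdefault(col, [0, 0, 0, 0])[b] += 1
    for qpos in range(qend, len(read)):
        col = diag + qpos
        if col >= L:
            b = _BASE_IDX.get(read[qpos])
            if b is not None:
                right_over.setdefault(col, [0, 0, 0, 0])[b] += 1
    return True


def _consensus_base(tally: Sequence[int]) -> str:
    """Strict-majority base; ties become the IUPAC code of the tied bases."""
    top = max(tally)
    winners = {b for b, n in zip(_BASES, tally) if n == top and n > 0}
    if not winners:
        return "N"
    return iupac_code(winners) if len(winners) > 1 else winners.pop()


def map_and_extend(
    contig: Contig,
    reads: Iterable[ReadPair],
    params: AssemblyParams,
    extend: bool = True,
    recall_interior: bool = True,
) -> tuple[Contig, int]:
    """One mapping round: place reads, re-call the interior consensus, and
    grow each contig end from overhang consensus columns with coverage at or
    above ``min_extend_cov`` (up to ``max_extension_per_iter`` per end).

    Returns (new contig, number of mapped mates).
    """
    seq = contig.seq
    L = len(seq)
    seeds = _SeedMap(seq)
    tallies = [[0, 0, 0, 0] for _ in range(L)]
    qual_sums = [0.0] * L
    left_over: dict[int, list[int]] = {}
    right_over: dict[int, list[int]] = {}
    n_mapped = 0
    for pair in reads:
        for mate_seq, mate_quals in pair.mates:
            placed = False
            for oriented, oq in (
                (mate_seq, list(mate_quals)),
                (revcomp(mate_seq), list(mate_quals)[::-1]),
            ):
                diag, votes = seeds.best_diagonal(oriented)
                if votes < 1:
                    continue
                if _align_and_tally(
                    oriented, oq, seq, diag, params.min_map_identity,
                    tallies, qual_sums, left_over, right_over,
                ):
                    placed = True
                    break
            if placed:
                n_mapped += 1
    if n_mapped == 0:
        return Contig(seq=seq, circular=contig.circular), 0

    if recall_interior:
        # below min_extend_cov the evidence is too thin to overrule the
        # current base (bait-backbone bases persist only where no reads map)
        body = [
            _consensus_base(t) if sum(t) >= params.min_extend_cov else seq[i]
            for i, t in enumerate(tallies)
        ]
    else:
        body = list(seq)

    left_ext: list[str] = []
    left_tal: list[list[int]] = []
    right_ext: list[str] = []
    right_tal: list[list[int]] = []
    if extend:
        col = -1
        while (
            col in left_over
            and sum(left_over[col]) >= params.min_extend_cov
            and len(left_ext) < params.max_extension_per_iter
        ):
            left_ext.append(_consensus_base(left_over[col]))
            left_tal.append(left_over[col])
            col -= 1
        left_ext.reverse()
        left_tal.reverse()
        col = L
        while (
            col in right_over
            and sum(right_over[col]) >= params.min_extend_cov
            and len(right_ext) < params.max_extension_per_iter
        ):
            right_ext.append(_consensus_base(right_over[col]))
            right_tal.append(right_over[col])
            col += 1

    new = Contig(
        seq="".join(left_ext) + "".join(body) + "".join(right_ext),
        tallies=left_tal + tallies + right_tal,
        qual_sums=[0.0] * len(left_tal) + qual_sums + [0.0] * len(right_tal),
        circular=contig.circular,
    )
    return new, n_mapped


def find_terminal_overlap(
    seq: str,
    min_olen: int,
    min_identity: float,
    coverage: Sequence[int] | None = None,
    min_cov: int = 3,
) -> int:
    """Length of a shared end overlap (suffix == prefix) or 0.

    Probes short exact anchors from the contig prefix against the second
    half of the contig, then verifies candidate overlaps column by column.
    When per-column coverage is supplied, columns where either copy falls
    below ``min_cov`` are uninformative and excluded from the identity
    calculation: the duplicated tails of a nearly-closed circle are
    coverage-starved (reads prefer their full-length placement in the other
    copy), so stray low-confidence bases must not veto circularization.
    Returns the longest verified overlap >= min_olen.
    """
    L = len(seq)
    best = 0
    for off in (0, 16, 32):
        probe = seq[off : off + 16]
        if len(probe) < 16:
            break
        start = max(L // 2, off + 16)
        j = seq.find(probe, start)
        while j != -1:
            p = j - off  # candidate: seq[p:] == seq[:L-p]
            olen = L - p
            if min_olen <= olen <= L // 2:
                matches = 0
                informative = 0
                for i in range(olen):
                    if coverage is not None and (
                        coverage[i] < min_cov or coverage[p + i] < min_cov
                    ):
                        continue
                    informative += 1
                    if seq[i] == seq[p + i]:
                        matches += 1
                if informative >= min_olen // 2 and (
                    matches / informative >= min_identity
                ):
                    best = max(best, olen)
            j = seq.find(probe, j + 1)
    return best


def _polish_circular(
    contig: Contig, reads: Sequence[ReadPair], params: AssemblyParams
) -> tuple[Contig, int]:
    """One wrap-aware mapping round on a closed circle.

    Reads are mapped against the contig extended by its own prefix, tallies
    are folded modulo the contig length, and the consensus is re-called at
    columns with adequate depth.  This repairs bases frozen from the bait
    at the coverage-starved linear ends of the pre-circularization contig.
    """
    seq = contig.seq
    L = len(seq)
    wrap = min(L, max((max(len(p.mate1_seq), len(p.mate2_seq)) for p in reads), default=0))
    ext = seq + seq[:wrap]
    seeds = _SeedMap(ext)
    tallies = [[0, 0, 0, 0] for _ in range(len(ext))]
    qual_sums = [0.0] * len(ext)
    dump: dict[int, list[int]] = {}
    n_mapped = 0
    for pair in reads:
        for mate_seq, mate_quals in pair.mates:
            for oriented, oq in (
                (mate_seq, list(mate_quals)),
                (revcomp(mate_seq), list(mate_quals)[::-1]),
            ):
                diag, votes = seeds.best_diagonal(oriented)
                if votes < 1:
                    continue
                if _align_and_tally(
                    oriented, oq, ext, diag, params.min_map_identity,
                    tallies, qual_sums, dump, dump,
                ):
                    n_mapped += 1
                    break
    for i in range(L, len(ext)):
        for b in range(4):
            tallies[i - L][b] += tallies[i][b]
        qual_sums[i - L] += qual_sums[i]
    tallies = tallies[:L]
    body = [
        _consensus_base(t) if sum(t) >= params.min_extend_cov else seq[i]
        for i, t in enumerate(tallies)
    ]
    return (
        Contig(seq="".join(body), tallies=tallies, qual_sums=qual_sums[:L], circular=True),
        n_mapped,
    )


def iterative_assemble(
    pairs: Sequence[ReadPair],
    bait: SeqRecord,
    params: AssemblyParams | None = None,
) -> AssemblyState:
    """Assemble a single organelle contig by baited iterative mapping.

    Iteration 0 recruits reads with the (possibly cross-species) bait and
    calls an initial consensus over the bait backbone; later iterations
    re-bait with the current contig, map, and extend.  Convergence is an
    exact contig fixpoint; circularization (terminal overlap at high
    identity) trims the duplicated overlap and stops the loop.
    """
    params = params or AssemblyParams()
    pairs = list(pairs)
    index = build_kmer_index(pairs, params.k_bait)
    recruited = bait_reads(index, bait.seq, params.min_shared_kmers)
    if not recruited:
        raise ValueError("bait too divergent or wrong input: no reads recruited")

    contig = Contig(seq=bait.seq)
    reads = [pairs[i] for i in sorted(recruited)]
    contig, n_mapped = map_and_extend(contig, reads, params)

    iteration = 0
    converged = False
    circularized = False
    while iteration < params.max_iter:
        olen = find_terminal_overlap(
            contig.seq,
            params.overlap_for_circularity,
            params.overlap_identity,
            coverage=contig.coverage,
            min_cov=params.min_extend_cov,
        )
        if olen:
            cut = len(contig) - olen
            contig = Contig(
                seq=contig.seq[:cut],
                tallies=contig.tallies[:cut],
                qual_sums=contig.qual_sums[:cut],
                circular=True,
            )
            circularized = True
            # wrap-aware polish rounds until the closed circle is stable
            for _ in range(3):
                polished, n_mapped = _polish_circular(contig, reads, params)
                if polished.seq == contig.seq:
                    contig = polished
                    break
                contig = polished
            converged = True
            break
        iteration += 1
        recruited |= bait_reads(index, contig.seq, params.min_shared_kmers)
        reads = [pairs[i] for i in sorted(recruited)]
        new_contig, n_mapped = map_and_extend(contig, reads, params)
        if new_contig.seq == contig.seq:
            contig = new_contig
            converged = True
            break
        contig = new_contig

    return AssemblyState(
        iteration=iteration,
        contig=contig,
        n_baited=len(recruited),
        n_mapped=n_mapped,
        converged=converged,
        circularized=circularized,
    )


def estimate_required_read_pairs(
    mito_len: int, mito_fraction: float, read_len: int, target_cov: float
) -> int:
    """Read pairs needed for a target mitogenome coverage, given the
    mitochondrial fraction of the library.

    pairs = ceil(target_cov * mito_len / (2 * read_len * mito_fraction))
    """
    if not (0 < mito_fraction <= 1):
        raise ValueError("mito_fraction must be in (0, 1]")
    return math.ceil(target_cov * mito_len / (2 * read_len * mito_fraction))
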