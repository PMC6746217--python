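"""Multi-evidence mitogenome annotation under alternative genetic codes.

Metazoan mitochondria use non-standard genetic codes: the invertebrate
mitochondrial code (NCBI table 5) and the echinoderm/flatworm code (table 9)
reassign TGA to Trp, AGA/AGG to Ser and - in table 9 - AAA to Asn.  Correct
gene calls therefore depend on running every evidence track under the code
of the study taxon.

Four independent evidence tracks are computed and reconciled:

* ``orf``          maximal reading frames bounded by stops, six frames
* ``protein_sim``  translated similarity to a reference peptide set
                   (word-seeded diagonal voting, BLAST-like)
* ``trna_scan``    cloverleaf secondary-structure heuristic with anticodon
                   identity assignment
* ``rrna_sim``     nucleotide similarity to reference rRNAs

Reconciliation is deterministic: CDS boundaries are snapped to in-frame
start/stop codons, missing stops are truncated at the downstream feature
with an ``incomplete_stop`` flag (mirroring post-transcriptional
polyadenylation of partial T / TA stops), and residual overlaps are flagged
as conflicts for curator review rather than silently resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from ._seq import revcomp
from .formats_io import SeqRecord

START_PREFERRED = ("ATT", "ATG")
START_ALTERNATE = ("ATA", "GTG", "TCG")
ALL_STARTS = START_PREFERRED + START_ALTERNATE

AA3 = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly",
    "H": "His", "I": "Ile", "K": "Lys", "L": "Leu", "M": "Met", "N": "Asn",
    "P": "Pro", "Q": "Gln", "R": "Arg", "S": "Ser", "T": "Thr", "V": "Val",
    "W": "Trp", "Y": "Tyr",
}


_IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "M": "AC", "R": "AG", "W": "AT", "S": "CG", "Y": "CT", "K": "GT",
    "V": "ACG", "H": "ACT", "D": "AGT", "B": "CGT", "N": "ACGT",
}


@dataclass
class GeneticCode:
    """A translation table: codon map plus start/stop codon sets."""

    table_id: int
    forward: dict[str, str]
    start_codons: frozenset[str]
    stop_codons: frozenset[str]

    def translate_codon(self, codon: str) -> str:
        """Codon -> amino acid; IUPAC-ambiguous codons resolve when every
        expansion agrees (e.g. GGN -> G), otherwise X."""
        if codon in self.stop_codons:
            return "*"
        aa = self.forward.get(codon)
        if aa is not None:
            return aa
        if all(b in _IUPAC_EXPAND for b in codon) and len(codon) == 3:
            aas = set()
            for b1 in _IUPAC_EXPAND[codon[0]]:
                for b2 in _IUPAC_EXPAND[codon[1]]:
                    for b3 in _IUPAC_EXPAND[codon[2]]:
                        c = b1 + b2 + b3
                        aas.add("*" if c in self.stop_codons else self.forward[c])
                        if len(aas) > 1:
                            return "X"
            if len(aas) == 1:
                return aas.pop()
        return "X"


def get_code(table_id: int) -> GeneticCode:
    """Build a GeneticCode from the NCBI translation table registry."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return GeneticCode(
        table_id=table_id,
        forward=dict(table.forward_table),
        start_codons=frozenset(table.start_codons),
        stop_codons=frozenset(table.stop_codons),
    )


def translate(seq: str, code: GeneticCode, allow_partial: bool = False) -> str:
    """Translate a CDS; ambiguous/unknown codons become X, stops '*'.

    A trailing 1-2 nt remainder is tolerated only with allow_partial (the
    incomplete-stop case); otherwise length must be divisible by 3.
    """
    rem = len(seq) % 3
    if rem and not allow_partial:
        raise ValueError(f"CDS length {len(seq)} not divisible by 3")
    return "".join(
        code.translate_codon(seq[i : i + 3]) for i in range(0, len(seq) - rem, 3)
    )


@dataclass
class FeatureAnnotation:
    """A located feature on the forward strand (0-based, half-open)."""

    name: str
    kind: str  # CDS | tRNA | rRNA | CR | NCR
    start: int
    end: int
    strand: str
    evidence: set[str] = field(default_factory=set)
    flags: set[str] = field(default_factory=set)
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.name}: bad interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "FeatureAnnotation") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class EvidenceTrack:
    source: str
    candidates: list[FeatureAnnotation]


# ---------------------------------------------------------------------------
# ORF scan
# ---------------------------------------------------------------------------


def scan_orfs(genome: SeqRecord, code: GeneticCode, min_aa: int = 50) -> EvidenceTrack:
    """All maximal reading frames bounded by stop codons, both strands.

    Candidate start = first preferred/alternate start codon in frame; score
    = length in amino acids.
    """
    L = len(genome.seq)
    candidates = []
    for strand, seq in (("+", genome.seq), ("-", revcomp(genome.seq))):
        for off in range(3):
            seg_start = off  # first in-frame position after the last stop
            for i in range(off, len(seq) - 2, 3):
                if seq[i : i + 3] in code.stop_codons:
                    cand = _orf_candidate(
                        seq, seg_start, i + 3, True, strand, L, min_aa
                    )
                    if cand is not None:
                        candidates.append(cand)
                    seg_start = i + 3
    return EvidenceTrack(source="orf", candidates=candidates)


def _orf_candidate(seq, seg_start, seg_end, has_stop, strand, L, min_aa):
    # scan for the first start codon within the stop-bounded segment
    stop_len = 3 if has_stop else 0
    for j in range(seg_start, seg_end - stop_len, 3):
        if seq[j : j + 3] in ALL_STARTS:
            aa_len = (seg_end - stop_len - j) // 3
            if aa_len < min_aa:
                return None
            s, e = j, seg_end
            if strand == "-":
                s, e = L - seg_end, L - j
            return FeatureAnnotation(
                name="", kind="CDS", start=s, end=e, strand=strand,
                evidence={"orf"}, score=float(aa_len),
            )
    return None


# ---------------------------------------------------------------------------
# Similarity tracks (word-seeded diagonal voting)
# ---------------------------------------------------------------------------


def _word_hits(query: str, subject_words: dict[str, list[int]], w: int):
    """Counter of diagonal -> votes plus matched (diag, qpos) records."""
    votes: Counter[int] = Counter()
    matches: list[tuple[int, int]] = []
    for i in range(len(query) - w + 1):
        for pos in subject_words.get(query[i : i + w], ()):
            votes[pos - i] += 1
            matches.append((pos - i, i))
    return votes, matches


def _best_interval(votes, matches, w, band: int = 2):
    """Best diagonal cluster -> (subject interval, vote count) or None."""
    if not votes:
        return None
    diag, _ = min(votes.items(), key=lambda kv: (-kv[1], kv[0]))
    cluster = [
        (d + q, q) for d, q in matches if abs(d - diag) <= band
    ]  # (subject pos, query pos)
    n = len(cluster)
    lo = min(p for p, _ in cluster)
    hi = max(p for p, _ in cluster) + w
    return (lo, hi), n


def protein_similarity(
    genome: SeqRecord,
    ref_peptides: Sequence[SeqRecord],
    code: GeneticCode,
    word: int = 4,
    min_words: int = 5,
) -> EvidenceTrack:
    """Translated similarity search of reference peptides against all six
    frames; each reference contributes its single best diagonal cluster."""
    if not ref_peptides:
        return EvidenceTrack(source="protein_sim", candidates=[])
    L = len(genome.seq)
    frames = []  # (strand, offset, peptide, word index)
    for strand, seq in (("+", genome.seq), ("-", revcomp(genome.seq))):
        for off in range(3):
            n_codons = (len(seq) - off) // 3
            pep = "".join(
                code.translate_codon(seq[off + 3 * i : off + 3 * i + 3])
                for i in range(n_codons)
            )
            words: dict[str, list[int]] = {}
            for i in range(len(pep) - word + 1):
                words.setdefault(pep[i : i + word], []).append(i)
            frames.append((strand, off, pep, words))

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1

    candidates = []
    for ref in ref_peptides:
        best = None  # (votes, strand, off, aa interval)
        for strand, off, pep, words in frames:
            votes, matches = _word_hits(ref.seq.upper(), words, word)
            hit = _best_interval(votes, matches, word)
            if hit is None:
                continue
            (lo, hi), n = hit
            if best is None or n > best[0]:
                best = (n, strand, off, lo, hi, pep)
        if best is None or best[0] < min_words:
            continue
        n, strand, off, lo, hi, pep = best
        # refine the cluster's boundaries by local protein alignment
        pad = 60
        region_lo = max(0, lo - pad)
        region = pep[region_lo : min(len(pep), hi + pad)]
        try:
            aln = aligner.align(region, ref.seq.upper())[0]
            t_blocks = aln.aligned[0]
            lo = region_lo + int(t_blocks[0][0])
            hi = region_lo + int(t_blocks[-1][1])
            score = float(aln.score)
        except (IndexError, ValueError):
            score = float(n)
        if strand == "+":
            s, e = off + 3 * lo, min(L, off + 3 * hi)
        else:
            s, e = max(0, L - (off + 3 * hi)), L - (off + 3 * lo)
        candidates.append(
            FeatureAnnotation(
                name=ref.id, kind="CDS", start=s, end=e, strand=strand,
                evidence={"protein_sim"}, score=score,
            )
        )
    return EvidenceTrack(source="protein_sim", candidates=candidates)


def rrna_similarity(
    genome: SeqRecord,
    ref_rrnas: Sequence[SeqRecord],
    word: int = 11,
    min_words: int = 5,
) -> EvidenceTrack:
    """Nucleotide similarity track for the two mitochondrial rRNAs."""
    candidates = []
    L = len(genome.seq)
    for strand, seq in (("+", genome.seq), ("-", revcomp(genome.seq))):
        words: dict[str, list[int]] = {}
        for i in range(len(seq) - word + 1):
            words.setdefault(seq[i : i + word], []).append(i)
        for ref in ref_rrnas:
            votes, matches = _word_hits(ref.seq, words, word)
            hit = _best_interval(votes, matches, word, band=5)
            if hit is None:
                continue
            (lo, hi), n = hit
            if n < min_words:
                continue
            s, e = (lo, hi) if strand == "+" else (L - hi, L - lo)
            candidates.append(
                FeatureAnnotation(
                    name=ref.id, kind="rRNA", start=max(0, s), end=min(L, e),
                    strand=strand, evidence={"rrna_sim"}, score=float(n),
                )
            )
    # keep the best placement per reference
    best: dict[str, FeatureAnnotation] = {}
    for c in candidates:
        if c.name not in best or c.score > best[c.name].score:
            best[c.name] = c
    return EvidenceTrack(source="rrna_sim", candidates=list(best.values()))


# ---------------------------------------------------------------------------
# tRNA cloverleaf heuristic
# ---------------------------------------------------------------------------

# fixed cloverleaf layout (window positions); v = variable-arm length 0..8
_ACC = (0, 7)          # acceptor stem 5' arm, 7 bp
_D_STEM = (9, 13)      # D stem 5' arm, 4 bp (8-nt loop)
_AC_STEM = (26, 31)    # anticodon stem 5' arm, 5 bp (7-nt loop)
_AC_LOOP = (31, 38)
ANTICODON_SLICE = (33, 36)
_T_REL = 43            # T arm begins here + v
TRNA_MIN_LEN = 67
TRNA_MAX_LEN = 75

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def _pair_ok(a: str, b: str) -> bool:
    """Watson-Crick or G.U pairing, IUPAC-aware (any expansion pairs)."""
    if (a, b) in _PAIRS:
        return True
    ea, eb = _IUPAC_EXPAND.get(a), _IUPAC_EXPAND.get(b)
    if ea is None or eb is None or (len(ea) == 1 and len(eb) == 1):
        return False
    return any((x, y) in _PAIRS for x in ea for y in eb)


def _stem_mismatches(five: str, three: str) -> int:
    """Mismatches in a stem; G.U wobble counts as paired."""
    return sum(1 for a, b in zip(five, reversed(three)) if not _pair_ok(a, b))


def _cloverleaf_score(w: str, v: int) -> int | None:
    """Paired-base score of a candidate window, or None if not tRNA-like."""
    t0 = _T_REL + v
    acc_mm = _stem_mismatches(w[0:7], w[t0 + 17 : t0 + 24])
    if acc_mm > 1:
        return None
    d_mm = _stem_mismatches(w[9:13], w[21:25])
    ac_mm = _stem_mismatches(w[26:31], w[38:43])
    t_mm = _stem_mismatches(w[t0 : t0 + 5], w[t0 + 12 : t0 + 17])
    # one wobble-free mismatch across all four stems keeps random hits on a
    # 15 kb AT-rich genome below ~0.05 expected false windows
    if ac_mm > 1 or d_mm > 1 or t_mm > 1 or acc_mm + d_mm + ac_mm + t_mm > 1:
        return None
    return 21 - (acc_mm + d_mm + ac_mm + t_mm)


def scan_trnas(genome: SeqRecord, code: GeneticCode | None = None) -> EvidenceTrack:
    """Scan both strands for cloverleaf-folding windows.

    The heuristic demands an acceptor stem (7 bp, <=1 mismatch, G.U allowed),
    a 4-bp D stem, a 5-bp anticodon stem with 7-nt loop and a 5-bp T stem in
    a fixed layout with a 0-8 nt variable arm; identity is read off the
    anticodon.  This is a pattern matcher, not a covariance model.
    """
    code = code or get_code(5)
    L = len(genome.seq)
    raw: list[FeatureAnnotation] = []
    for strand, seq in (("+", genome.seq), ("-", revcomp(genome.seq))):
        n = len(seq)
        for i in range(n - TRNA_MIN_LEN + 1):
            best = None
            for v in range(0, TRNA_MAX_LEN - TRNA_MIN_LEN + 1):
                wlen = TRNA_MIN_LEN + v
                if i + wlen > n:
                    break
                w = seq[i : i + wlen]
                score = _cloverleaf_score(w, v)
                if score is not None and (best is None or score > best[0]):
                    best = (score, wlen, w)
            if best is None:
                continue
            score, wlen, w = best
            anticodon = w[ANTICODON_SLICE[0] : ANTICODON_SLICE[1]]
            aa = code.translate_codon(revcomp(anticodon))
            if aa in ("*", "X"):
                continue
            s, e = (i, i + wlen) if strand == "+" else (L - i - wlen, L - i)
            raw.append(
                FeatureAnnotation(
                    name=f"tRNA-{AA3[aa]}({anticodon})",
                    kind="tRNA", start=s, end=e, strand=strand,
                    evidence={"trna_scan"}, score=float(score),
                )
            )
    # greedy non-overlapping selection, best score first (deterministic)
    raw.sort(key=lambda f: (-f.score, f.start, f.strand))
    accepted: list[FeatureAnnotation] = []
    for cand in raw:
        if all(cand.overlap(a) <= 10 for a in accepted):
            accepted.append(cand)
    accepted.sort(key=lambda f: f.start)
    return EvidenceTrack(source="trna_scan", candidates=accepted)


# ---------------------------------------------------------------------------
# Reconciliation
# ---------------------------------------------------------------------------


def _snap_cds(
    cand: FeatureAnnotation,
    genome_seq: str,
    code: GeneticCode,
    occupied: list[tuple[int, int]],
) -> FeatureAnnotation:
    """Snap a similarity hit to in-frame start/stop codons.

    ``occupied`` lists accepted tRNA/rRNA intervals in forward coordinates;
    a CDS without an in-frame stop is truncated at the first downstream
    feature (partial T/TA stop) and flagged incomplete_stop.
    """
    L = len(genome_seq)
    seq = genome_seq if cand.strand == "+" else revcomp(genome_seq)
    if cand.strand == "+":
        s, e = cand.start, cand.end
    else:
        s, e = L - cand.end, L - cand.start

    # upstream in-frame stop bounds the start search
    upstream = s % 3
    i = s - 3
    while i >= 0:
        if seq[i : i + 3] in code.stop_codons:
            upstream = i + 3
            break
        i -= 3

    # start codon nearest to the hit start (preferring ATT/ATG on ties)
    starts = []
    for j in range(upstream, min(s + 45, len(seq) - 2), 3):
        codon = seq[j : j + 3]
        if codon in ALL_STARTS:
            rank = 0 if codon in START_PREFERRED else 1
            starts.append((abs(j - s), rank, j))
    flags: set[str] = set()
    if starts:
        start = min(starts)[2]
    else:
        start = s
        flags.add("noncanonical_start")

    # next downstream feature (strand coordinates) bounds the stop search
    def to_strand(iv: tuple[int, int]) -> tuple[int, int]:
        if cand.strand == "+":
            return iv
        return (L - iv[1], L - iv[0])

    downstream = [to_strand(iv)[0] for iv in occupied if to_strand(iv)[0] >= e - 3]
    limit = min(downstream) if downstream else len(seq)

    end = None
    j = start
    while j + 3 <= min(limit + 3, len(seq)):
        if seq[j : j + 3] in code.stop_codons:
            end = j + 3
            break
        j += 3
    if end is None:
        aligned = start + 3 * ((limit - start) // 3)
        leftover = limit - aligned
        if leftover == 1 and seq[aligned] == "T":
            end = limit
            flags.add("incomplete_stop")
        elif leftover == 2 and seq[aligned : aligned + 2] == "TA":
            end = limit
            flags.add("incomplete_stop")
        else:
            end = aligned
            flags.add("incomplete_stop")
    if end <= start:
        end = start + 3  # degenerate hit; keep a stub flagged as conflict
        flags.add("conflict")

    fs, fe = (start, end) if cand.strand == "+" else (L - end, L - start)
    if end - start < 150:
        flags.add("short")
    return FeatureAnnotation(
        name=cand.name, kind="CDS", start=fs, end=fe, strand=cand.strand,
        evidence=set(cand.evidence), flags=flags, score=cand.score,
    )


def reconcile(
    tracks: Iterable[EvidenceTrack],
    genome: SeqRecord,
    code: GeneticCode,
    max_overlap: int = 40,
) -> list[FeatureAnnotation]:
    """Merge evidence tracks into the final feature set.

    CDS require protein_sim support (boundaries snapped to starts/stops,
    corroborated by the orf track when an ORF agrees); tRNA/rRNA are
    accepted from their tracks.  Residual overlaps beyond ``max_overlap``
    flag the lower-scoring feature as a conflict.
    """
    by_source = {t.source: t for t in tracks}
    accepted: list[FeatureAnnotation] = []

    for f in by_source.get("trna_scan", EvidenceTrack("trna_scan", [])).candidates:
        accepted.append(f)
    for f in by_source.get("rrna_sim", EvidenceTrack("rrna_sim", [])).candidates:
        accepted.append(f)

    occupied = [(f.start, f.end) for f in accepted]
    orf_track = by_source.get("orf", EvidenceTrack("orf", []))

    best_cds: dict[str, FeatureAnnotation] = {}
    for cand in by_source.get("protein_sim", EvidenceTrack("protein_sim", [])).candidates:
        if cand.name in best_cds and cand.score <= best_cds[cand.name].score:
            continue
        best_cds[cand.name] = cand
    seen_names: set[str] = set()
    for name in sorted(best_cds):
        if name in seen_names:
            raise ValueError(f"duplicate gene {name}")
        seen_names.add(name)
        snapped = _snap_cds(best_cds[name], genome.seq, code, occupied)
        for orf in orf_track.candidates:
            if orf.strand == snapped.strand:
                ov = orf.overlap(snapped)
                if ov >= 0.5 * snapped.length and ov >= 0.5 * orf.length:
                    snapped.evidence.add("orf")
                    break
        accepted.append(snapped)

    accepted.sort(key=lambda f: (f.start, f.end))
    for i, a in enumerate(accepted):
        for b in accepted[i + 1 :]:
            if b.start >= a.end:
                break
            if a.overlap(b) > max_overlap:
                loser = min(a, b, key=lambda f: f.score)
                loser.flags.add("conflict")
    return accepted


def assign_noncoding(
    features: list[FeatureAnnotation],
    genome: SeqRecord,
    min_ncr: int = 50,
    circular: bool = True,
) -> list[FeatureAnnotation]:
    """Label unannotated gaps >= min_ncr as NCRs; the longest becomes the CR."""
    L = len(genome.seq)
    core = sorted(
        (f for f in features if f.kind in ("CDS", "tRNA", "rRNA")),
        key=lambda f: f.start,
    )
    # each gap is a list of linear segments (two for a wrap-around gap)
    gaps: list[list[tuple[int, int]]] = []
    if not core:
        if L >= min_ncr:
            gaps.append([(0, L)])
    else:
        cursor = core[0].end
        for f in core[1:]:
            if f.start - cursor >= min_ncr:
                gaps.append([(cursor, f.start)])
            cursor = max(cursor, f.end)
        tail = L - cursor
        head = core[0].start
        if circular:
            # the gap spanning the origin counts once, as its linear pieces
            if tail + head >= min_ncr:
                segments = [(s, e) for s, e in ((cursor, L), (0, head)) if e > s]
                if segments:
                    gaps.append(segments)
        else:
            if tail >= min_ncr:
                gaps.append([(cursor, L)])
            if head >= min_ncr:
                gaps.append([(0, head)])
    if not gaps:
        return list(features)

    def total(gap):
        return sum(e - s for s, e in gap)

    longest = max(gaps, key=total)
    out = list(features)
    for gap in gaps:
        kind = "CR" if gap is longest else "NCR"
        for s, e in gap:
            out.append(
                FeatureAnnotation(
                    name=kind, kind=kind, start=s, end=e, strand="+",
                    evidence={"gap"},
                )
            )
    out.sort(key=lambda f: (f.start, f.end))
    return out


def annotate_genome(
    genome: SeqRecord,
    ref_peptides: Sequence[SeqRecord],
    ref_rrnas: Sequence[SeqRecord],
    code: GeneticCode,
    min_ncr: int = 50,
    circular: bool = True,
) -> list[FeatureAnnotation]:
    """Full annotation: evidence tracks -> reconcile -> non-coding regions."""
    tracks = [
        scan_orfs(genome, code),
        protein_similarity(genome, ref_peptides, code),
        scan_trnas(genome, code),
        rrna_similarity(genome, ref_rrnas),
    ]
    features = reconcile(tracks, genome, code)
    return assign_noncoding(features, genome, min_ncr=min_ncr, circular=circular)
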