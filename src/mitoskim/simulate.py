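"""Synthetic annotated mitogenomes and paired-end reads with ground truth.

The simulator emulates the two study systems of the protocol: an AT-rich
insect (fly-like) mitogenome with 13 protein-coding genes on both strands,
and a cestode-style mitogenome with 12 PCGs (no ATP8), all genes on one
strand, arranged in a Category-IV-like tRNA order.  Genes are placed
contiguously; CDS carry valid start/stop codons under the configured
mitochondrial genetic code, tRNAs are structure-true for the cloverleaf
detector, and a single control-region gap is planted.

Reads are drawn as uniformly placed fragments (wrapping the origin for
circular genomes) with Normal insert sizes, per-base substitution errors,
and CASAVA-style tile assignment so that tile-level QC can be exercised:
designated bad tiles get a flat Phred shift.  Every emitted read's true
origin is recorded, so downstream stages can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import revcomp
from .annotate import AA3, FeatureAnnotation, GeneticCode, get_code, translate
from .formats_io import ReadPair, SeqRecord
from .geneorder import GeneOrder, extract_gene_order

# one standard anticodon per tRNA (DNA alphabet); Leu/Ser paralogs carry
# anticodons of the two codon families so order analysis can tell them apart
TRNA_ANTICODONS = {
    "tRNA-Ala": "TGC", "tRNA-Arg": "TCG", "tRNA-Asn": "GTT", "tRNA-Asp": "GTC",
    "tRNA-Cys": "GCA", "tRNA-Gln": "TTG", "tRNA-Glu": "TTC", "tRNA-Gly": "TCC",
    "tRNA-His": "GTG", "tRNA-Ile": "GAT", "tRNA-Lys": "CTT", "tRNA-Met": "CAT",
    "tRNA-Phe": "GAA", "tRNA-Pro": "TGG", "tRNA-Ser(AGN)": "GCT",
    "tRNA-Ser(UCN)": "TGA", "tRNA-Thr": "TGT", "tRNA-Trp": "TCA",
    "tRNA-Tyr": "GTA", "tRNA-Val": "TAC", "tRNA-Leu(CUN)": "TAG",
    "tRNA-Leu(UUR)": "TAA",
}

# nominal CDS lengths (nt, incl. stop) loosely matching metazoan mitogenomes
CDS_LENGTHS = {
    "MT-CO1": 1536, "MT-CO2": 684, "MT-CO3": 786, "MT-CYB": 1137,
    "MT-ND1": 939, "MT-ND2": 1023, "MT-ND3": 351, "MT-ND4": 1338,
    "MT-ND4L": 294, "MT-ND5": 1719, "MT-ND6": 522, "MT-ATP6": 678,
    "MT-ATP8": 159,
}
RRNA_LENGTHS = {"RNR1": 750, "RNR2": 1000}

# fly-like arrangement: 14 tRNAs + 9 PCGs on the majority strand, the two
# rRNAs, four PCGs and eight tRNAs on the minority strand
INSECT_ORDER = [
    ("tRNA-Ile", "+"), ("tRNA-Gln", "-"), ("tRNA-Met", "+"), ("MT-ND2", "+"),
    ("tRNA-Trp", "+"), ("tRNA-Cys", "-"), ("tRNA-Tyr", "-"), ("MT-CO1", "+"),
    ("tRNA-Leu(UUR)", "+"), ("MT-CO2", "+"), ("tRNA-Lys", "+"),
    ("tRNA-Asp", "+"), ("MT-ATP8", "+"), ("MT-ATP6", "+"), ("MT-CO3", "+"),
    ("tRNA-Gly", "+"), ("MT-ND3", "+"), ("tRNA-Ala", "+"), ("tRNA-Arg", "+"),
    ("tRNA-Asn", "+"), ("tRNA-Ser(AGN)", "+"), ("tRNA-Glu", "+"),
    ("tRNA-Phe", "-"), ("MT-ND5", "-"), ("tRNA-His", "-"), ("MT-ND4", "-"),
    ("MT-ND4L", "-"), ("tRNA-Thr", "+"), ("tRNA-Pro", "-"), ("MT-ND6", "+"),
    ("MT-CYB", "+"), ("tRNA-Ser(UCN)", "+"), ("MT-ND1", "-"),
    ("tRNA-Leu(CUN)", "-"), ("RNR2", "-"), ("tRNA-Val", "-"), ("RNR1", "-"),
]

# cestode-style arrangement: single strand, no ATP8, Category-IV motif
# trnS(UCN)-trnL(CUN) 3' of the cox2-trnE-nad6-trnY block
CESTODE_ORDER = [
    ("MT-CO1", "+"), ("tRNA-Thr", "+"), ("RNR2", "+"), ("tRNA-Cys", "+"),
    ("RNR1", "+"), ("MT-CO2", "+"), ("tRNA-Glu", "+"), ("MT-ND6", "+"),
    ("tRNA-Tyr", "+"), ("tRNA-Ser(UCN)", "+"), ("tRNA-Leu(CUN)", "+"),
    ("tRNA-Leu(UUR)", "+"), ("MT-ND5", "+"), ("tRNA-Gly", "+"),
    ("MT-CO3", "+"), ("tRNA-His", "+"), ("MT-CYB", "+"), ("MT-ND4L", "+"),
    ("MT-ND4", "+"), ("tRNA-Gln", "+"), ("tRNA-Phe", "+"), ("tRNA-Met", "+"),
    ("MT-ATP6", "+"), ("MT-ND2", "+"), ("tRNA-Val", "+"), ("tRNA-Ala", "+"),
    ("tRNA-Asp", "+"), ("MT-ND1", "+"), ("tRNA-Asn", "+"), ("tRNA-Pro", "+"),
    ("tRNA-Ile", "+"), ("tRNA-Lys", "+"), ("MT-ND3", "+"),
    ("tRNA-Ser(AGN)", "+"), ("tRNA-Trp", "+"), ("tRNA-Arg", "+"),
]

_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass
class SimConfig:
    """Study conditions for one simulated sample.

    Defaults mirror the protocol's conditions: a 15 kb circular AT-rich
    genome (GC 0.25), 60x coverage of PE-150 reads at 1% substitution
    error, a cross-species bait at 5% divergence, and an 800 nt control
    region.
    """

    rng_seed: int
    mode: str = "insect"  # insect | cestode
    genome_len: int = 15000
    gc: float = 0.25
    cr_len: int = 800
    circular: bool = True
    table: int | None = None  # default: 5 (insect), 9 (cestode)
    read_len: int = 150
    insert_mean: int = 400
    insert_sd: int = 40
    coverage: float = 60.0
    error_rate: float = 0.01
    indel_rate: float = 0.0
    n_tiles: int = 4
    n_bad_tiles: int = 0
    bad_tile_q_shift: int = -20
    bait_divergence: float = 0.05

    def __post_init__(self) -> None:
        if self.mode not in ("insect", "cestode"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for frac in (self.gc, self.error_rate, self.indel_rate, self.bait_divergence):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must be in [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")

    @property
    def table_id(self) -> int:
        if self.table is not None:
            return self.table
        return 5 if self.mode == "insect" else 9


@dataclass
class GroundTruth:
    genome: SeqRecord
    features: list[FeatureAnnotation]
    gene_order: GeneOrder
    circular: bool
    code: GeneticCode
    read_origins: dict[str, tuple[int, int, int]] = field(default_factory=dict)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _random_codon(rng: np.random.Generator, gc: float, code: GeneticCode) -> str:
    while True:
        codon = _random_bases(rng, 3, gc)
        if codon not in code.stop_codons:
            return codon


def _make_cds(
    rng: np.random.Generator, name: str, length: int, gc: float,
    code: GeneticCode, mode: str,
) -> str:
    """A CDS of ``length`` nt with valid start/stop and no internal stop."""
    n_codons = length // 3
    if name == "MT-CO1" and mode == "insect":
        start = "TCG"  # the classic non-canonical Diptera cox1 start
    else:
        start = "ATT" if rng.random() < 0.5 else "ATG"
    stop = "TAG" if name == "MT-CYB" else "TAA"
    middle = [_random_codon(rng, gc, code) for _ in range(n_codons - 2)]
    return start + "".join(middle) + stop


def _make_trna(rng: np.random.Generator, name: str, gc: float) -> str:
    """A structure-true cloverleaf with the symbol's anticodon.

    Layout matches the annotation heuristic: 7 bp acceptor stem, 4 bp
    D stem (8 nt loop), 5 bp anticodon stem (7 nt loop, anticodon at loop
    positions 2-4), 0-8 nt variable arm, 5 bp T stem (7 nt loop).
    """
    anticodon = TRNA_ANTICODONS[name]
    v = int(rng.integers(0, 9))

    def stem(n: int) -> tuple[str, str]:
        five = _random_bases(rng, n, gc)
        return five, "".join(_WC[b] for b in reversed(five))

    acc5, acc3 = stem(7)
    d5, d3 = stem(4)
    ac5, ac3 = stem(5)
    t5, t3 = stem(5)
    parts = [
        acc5,
        _random_bases(rng, 2, gc),            # spacer
        d5, _random_bases(rng, 8, gc), d3,    # D arm
        _random_bases(rng, 1, gc),            # spacer
        ac5,
        _random_bases(rng, 2, gc) + anticodon + _random_bases(rng, 2, gc),
        ac3,
        _random_bases(rng, v, gc),            # variable arm
        t5, _random_bases(rng, 7, gc), t3,    # T arm
        acc3,
    ]
    return "".join(parts)


def simulate_mitogenome(cfg: SimConfig) -> GroundTruth:
    """Generate an annotated genome; same seed -> identical output."""
    rng = np.random.default_rng(cfg.rng_seed)
    code = get_code(cfg.table_id)
    order = INSECT_ORDER if cfg.mode == "insect" else CESTODE_ORDER

    trna_seqs = {
        name: _make_trna(rng, name, cfg.gc) for name, _ in order
        if name.startswith("tRNA")
    }
    trna_total = sum(len(s) for s in trna_seqs.values())
    rrna_names = [n for n, _ in order if n.startswith("RNR")]
    cds_names = [n for n, _ in order if n.startswith("MT-")]
    # scale CDS/rRNA/CR together so small test genomes stay packable;
    # floors (153 nt CDS, 100 nt rRNA) need a fixpoint allocation
    nominal_rest = (
        sum(CDS_LENGTHS[n] for n in cds_names)
        + sum(RRNA_LENGTHS[n] for n in rrna_names)
        + cfg.cr_len
    )
    f0 = min(1.0, (cfg.genome_len - trna_total) / nominal_rest)
    budget = cfg.genome_len - trna_total - max(50, round(cfg.cr_len * f0))
    items = [(n, CDS_LENGTHS[n], 153, 3) for n in cds_names]
    items += [(n, RRNA_LENGTHS[n], 100, 1) for n in rrna_names]
    sizes = {n: nominal for n, nominal, _, _ in items}
    for _ in range(10):
        floored = {n for n, nominal, floor, _ in items if sizes[n] <= floor}
        free_nominal = sum(nom for n, nom, _, _ in items if n not in floored)
        fixed = sum(sizes[n] for n in floored)
        if free_nominal <= 0:
            break
        f = min(1.0, (budget - fixed) / free_nominal)
        new_sizes = dict(sizes)
        for n, nominal, floor, gran in items:
            if n not in floored:
                new_sizes[n] = max(floor, gran * round(nominal * f / gran))
        if new_sizes == sizes:
            break
        sizes = new_sizes
    planned = trna_total + sum(sizes.values())
    if cfg.genome_len - planned < 50:
        raise ValueError(
            f"infeasible packing: genome_len={cfg.genome_len} cannot hold "
            f"{len(cds_names)} CDS plus RNAs and the control region"
        )
    cds_lens = {n: sizes[n] for n in cds_names}
    rrna_lens = {n: sizes[n] for n in rrna_names}

    pieces: list[str] = []
    features: list[FeatureAnnotation] = []
    pos = 0
    for name, strand in order:
        feature_name = name
        if name.startswith("tRNA"):
            seq, kind = trna_seqs[name], "tRNA"
            base = name.split("(")[0]
            feature_name = f"{base}({TRNA_ANTICODONS[name]})"
        elif name.startswith("RNR"):
            seq, kind = _random_bases(rng, rrna_lens[name], cfg.gc), "rRNA"
        else:
            seq, kind = _make_cds(rng, name, cds_lens[name], cfg.gc, code, cfg.mode), "CDS"
        placed = seq if strand == "+" else revcomp(seq)
        pieces.append(placed)
        features.append(
            FeatureAnnotation(
                name=feature_name, kind=kind, start=pos, end=pos + len(placed),
                strand=strand, evidence={"planted"},
            )
        )
        pos += len(placed)
    cr_len = cfg.genome_len - pos
    features.append(
        FeatureAnnotation(
            name="CR", kind="CR", start=pos, end=pos + cr_len, strand="+",
            evidence={"planted"},
        )
    )
    pieces.append(_random_bases(rng, cr_len, cfg.gc))
    genome = SeqRecord(
        id=f"sim_{cfg.mode}_{cfg.rng_seed}",
        seq="".join(pieces),
        description=f"simulated {cfg.mode} mitogenome",
    )
    assert len(genome.seq) == cfg.genome_len
    gene_order = extract_gene_order(features, anchor="MT-CO1", circular=cfg.circular)
    return GroundTruth(
        genome=genome, features=features, gene_order=gene_order,
        circular=cfg.circular, code=code,
    )


def _apply_errors(
    rng: np.random.Generator, seq: str, error_rate: float, indel_rate: float
) -> str:
    if error_rate == 0 and indel_rate == 0:
        return seq
    out = []
    others = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}
    for b in seq:
        if indel_rate and rng.random() < indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append("ACGT"[rng.integers(4)])  # insertion before the base
        if error_rate and rng.random() < error_rate:
            out.append(others.get(b, ["N"] * 3)[rng.integers(3)])
        else:
            out.append(b)
    return "".join(out)


def _read_quals(
    rng: np.random.Generator, n: int, shift: int = 0
) -> list[int]:
    q = rng.normal(38.0, 3.0, size=n) + shift
    return [int(x) for x in np.clip(np.rint(q), 2, 41)]


def simulate_reads(
    truth: GroundTruth, cfg: SimConfig
) -> list[ReadPair]:
    """Simulate PE reads; origins are recorded in truth.read_origins.

    Pair count = coverage * genome_len / (2 * read_len); fragments wrap the
    origin for circular genomes; tiles 1101.. are assigned uniformly and
    the first ``n_bad_tiles`` tiles get the configured quality shift.
    """
    rng = np.random.default_rng(cfg.rng_seed + 1_000_003)
    genome = truth.genome.seq
    L = len(genome)
    doubled = genome + genome
    n_pairs = int(round(cfg.coverage * L / (2 * cfg.read_len)))
    tiles = [1101 + i for i in range(cfg.n_tiles)]
    bad = set(tiles[: cfg.n_bad_tiles])
    pairs = []
    truth.read_origins.clear()
    for i in range(n_pairs):
        for _ in range(20):  # bounded resampling of degenerate inserts
            frag = int(round(rng.normal(cfg.insert_mean, cfg.insert_sd)))
            if cfg.read_len <= frag <= (L if not cfg.circular else 2 * L):
                break
        else:
            frag = max(cfg.read_len, cfg.insert_mean)
        frag = min(frag, L)
        if cfg.circular:
            start = int(rng.integers(0, L))
        else:
            start = int(rng.integers(0, max(1, L - frag + 1)))
        fragment = doubled[start : start + frag]
        m1 = fragment[: cfg.read_len]
        m2 = revcomp(fragment[-cfg.read_len :])
        m1 = _apply_errors(rng, m1, cfg.error_rate, cfg.indel_rate)
        m2 = _apply_errors(rng, m2, cfg.error_rate, cfg.indel_rate)
        tile = tiles[int(rng.integers(len(tiles)))]
        shift = cfg.bad_tile_q_shift if tile in bad else 0
        read_id = f"SIM:{cfg.rng_seed}:FC1:1:{tile}:{i}:{int(rng.integers(10000))}"
        pairs.append(
            ReadPair(
                read_id=read_id,
                mate1_seq=m1, mate2_seq=m2,
                mate1_quals=_read_quals(rng, len(m1), shift),
                mate2_quals=_read_quals(rng, len(m2), shift),
                lane=1, tile=tile,
            )
        )
        truth.read_origins[read_id] = (start, frag, tile)
    return pairs


def make_bait(truth: GroundTruth, cfg: SimConfig) -> SeqRecord:
    """Cross-species stand-in: the planted genome mutated at
    ``bait_divergence`` (substitutions only)."""
    rng = np.random.default_rng(cfg.rng_seed + 7_777_777)
    seq = list(truth.genome.seq)
    n_mut = int(round(cfg.bait_divergence * len(seq)))
    sites = rng.choice(len(seq), size=n_mut, replace=False)
    for s in sites:
        choices = [c for c in "ACGT" if c != seq[s]]
        seq[s] = choices[int(rng.integers(3))]
    return SeqRecord(
        id="bait", seq="".join(seq),
        description=f"bait at {cfg.bait_divergence:.0%} divergence",
    )


def make_reference_peptides(
    truth: GroundTruth, divergence: float = 0.0, seed: int = 0
) -> list[SeqRecord]:
    """Reference peptides for annotation, optionally diverged at the amino
    acid level (random substitutions) to emulate cross-taxon references."""
    rng = np.random.default_rng(seed + 13)
    aas = sorted(AA3)
    refs = []
    for f in truth.features:
        if f.kind != "CDS":
            continue
        nt = truth.genome.seq[f.start : f.end]
        if f.strand == "-":
            nt = revcomp(nt)
        pep = translate(nt, truth.code).rstrip("*")
        if divergence:
            pep = "".join(
                aas[int(rng.integers(len(aas)))] if rng.random() < divergence else a
                for a in pep
            )
        refs.append(SeqRecord(id=f.name, seq="", description="reference peptide"))
        refs[-1].seq = pep  # bypass DNA normalization for peptides
    return refs


def make_reference_rrnas(
    truth: GroundTruth, divergence: float = 0.0, seed: int = 0
) -> list[SeqRecord]:
    rng = np.random.default_rng(seed + 17)
    refs = []
    for f in truth.features:
        if f.kind != "rRNA":
            continue
        nt = truth.genome.seq[f.start : f.end]
        if f.strand == "-":
            nt = revcomp(nt)
        if divergence:
            nt = "".join(
                "ACGT"[int(rng.integers(4))] if rng.random() < divergence else b
                for b in nt
            )
        refs.append(SeqRecord(id=f.name, seq=nt, description="reference rRNA"))
    return refs


def rotate_genome(truth: GroundTruth, shift: int) -> GroundTruth:
    """Rotate a circular genome by ``shift`` nt, remapping features."""
    if not truth.circular:
        raise ValueError("cannot rotate a linear genome")
    L = len(truth.genome.seq)
    shift %= L
    seq = truth.genome.seq[shift:] + truth.genome.seq[:shift]
    feats = []
    for f in truth.features:
        s, e = f.start - shift, f.end - shift
        if s < 0 and e <= 0:
            s, e = s + L, e + L
        elif s < 0:  # feature now crosses the origin; split
            feats.append(replace(f, start=s + L, end=L, flags=set(f.flags)))
            feats.append(replace(f, start=0, end=e, flags=set(f.flags)))
            continue
        feats.append(replace(f, start=s, end=e, flags=set(f.flags)))
    return GroundTruth(
        genome=SeqRecord(id=truth.genome.id + f"_rot{shift}", seq=seq),
        features=sorted(feats, key=lambda f: f.start),
        gene_order=truth.gene_order,
        circular=True,
        code=truth.code,
    )
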