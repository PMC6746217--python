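# Methods

## Model and scope

`mitoskim` reconstructs a single circular (or linear) organelle genome
from paired-end shotgun reads in which the mitochondrial fraction is a
small but high-copy component. The method assumes (i) one dominant target
molecule per library — no multi-contig output, no NUMT disambiguation;
(ii) a bait mitogenome from a related taxon, close enough to share exact
31-mers with target reads; (iii) Illumina-style substitution-dominated
errors (an indel rate is available but defaults to zero).

## Quality control

Tile selection uses the tile mean Phred against a fixed threshold
(default 25): whole-tile failures (bubbles, focus loss) are cheaper to
drop than to rescue per-read. Trimming follows SLIDINGWINDOW semantics:
scanning 5′→3′ with a 4-base window, the read is cut at the first window
whose mean falls below 20, then leading bases of that window that
individually meet the threshold are kept. Pairs in which either trimmed
mate drops below 36 nt are discarded whole — downstream assembly consumes
full pairs only. Adapter removal is assumed upstream.

## Assembly: baiting and iterative mapping

Recruitment is exact canonical *k*-mer sharing (*k* = 31; a pair is
recruited when either mate shares ≥ 2 distinct canonical 31-mers with the
query, and a baited mate always recruits its partner). This replaces
mapping-heuristic recruitment with a rule that a brute-force oracle can
check exactly.

Read placement is seed-and-verify: exact 15-mer seeds vote for a
placement diagonal (most votes, smallest diagonal on ties); the placement
is verified by edit-distance alignment (edlib) of the overlapping
segments and discarded below 90 % identity. When the edit distance equals
the Hamming distance of the placed segments the read is tallied
positionally — this makes the substitution interpretation canonical and
prevents two adjacent mismatches from being re-expressed as an
insertion/deletion pair, which would silently starve one column and
corrupt its neighbour. True indels (edit distance < Hamming) are tallied
through the CIGAR.

Each round re-calls the interior consensus by strict majority at columns
with depth ≥ 3 (ties become the IUPAC code of the tied bases, which is
deterministic); below that depth the existing base — initially the bait
backbone — is kept, because one or two reads are too thin to overrule it.
Contig ends grow from overhang consensus columns with depth ≥ 3, up to
500 nt per end per iteration. Convergence is an exact sequence fixpoint.

Circularization: the contig is scanned for a suffix≡prefix overlap
≥ 50 nt at ≥ 99 % identity. The identity is evaluated column-wise and
only over columns where *both* copies have depth ≥ 3: once the ends of a
nearly closed circle overlap, reads prefer their full-length placement in
one copy, so the other copy's tail is coverage-starved and a stray
low-confidence base there must not veto closure. The 3′ copy of the
overlap is trimmed (the 5′ copy is kept), after which up to three
wrap-aware polish rounds re-map all recruited reads against the closed
circle and repair bases frozen at the formerly linear ends. No rotation
normalization is applied; comparisons against references allow rotation.

The read-budget estimator returns
`ceil(target_cov × mito_len / (2 × read_len × mito_fraction))` pairs.

## Circularization statistics

The junction window is the concatenation of the last and first *F* = 50
contig nt. For each seed length in {15, 19, 23, 31}, reads sharing ≥ 1
exact seed with the window are aligned locally (match +1, mismatch −1,
gap open −2, extend −1). Statistics over the 2*F* columns:

* `avg_coverage` — mean aligned-column depth;
* `avg_contiguity` — the same mean counting only reads whose alignment
  covers both seam-adjacent columns inside one ungapped block. This
  operationalization of the contiguity index (seam-spanning, gap-free
  depth) is this package's own definition;
* `avg_quality` — mean Phred of aligned read bases;
* `aln_score` — mean of (score − match·aligned-columns) per read, a ≤ 0
  scale on which 0 means every aligned read is perfect. It is analogous
  to, but not numerically comparable with, aligner-native scores.

The seed length maximizing contiguity is selected (ties: higher quality,
then less-negative score). Verdict: `circular` when contiguity ≥ 10 and
contiguity/coverage ≥ 0.5; `linear` when contiguity < 5; otherwise
`ambiguous`. On simulated data these defaults separate circular from
linear perfectly at ≥ 20× coverage and ≤ 2 % error.

## Conservative consensus

Reads are mapped back to the contig (wrapping the origin for circular
molecules) and each column is called: depth < 3 → N; winning base
fraction ≥ 0.99 → that base; otherwise the IUPAC code of every base
carried by ≥ 1 % of reads — so singleton errors at high depth never
inflate the code, but at moderate depth (where one read exceeds 1 %) the
column honestly becomes ambiguous. The rule only fully resolves at depths
of several hundred; at 60× roughly 40 % of columns carry an ambiguity
code that still contains the true base. Accuracy statements about the
consensus therefore use IUPAC-compatible identity (the true base lies
within the called code). Threshold comparisons carry a 1e-9 epsilon so
exact fractions like 2/200 sit on the intended side of `1 − agree`.
Read deletions do not reduce column depth; a column where ≥ 50 % of reads
show a gap is flagged, not removed.

## Annotation

Four tracks are computed independently and reconciled:

* **ORF scan** — maximal stop-bounded frames on both strands; candidate
  start is the first of ATT/ATG (preferred) or ATA/GTG/TCG in frame;
  score = length in amino acids.
* **Protein similarity** — each reference peptide is word-matched (4-mer
  amino-acid words, diagonal voting) against all six frame translations,
  then the best diagonal cluster is refined by local alignment (BLOSUM62,
  gap open −11/extend −1) to residue-precise boundaries.
* **tRNA scan** — a fixed cloverleaf layout: 7 bp acceptor stem, 4 bp
  D stem (8 nt loop), 5 bp anticodon stem (7 nt loop, anticodon at loop
  positions 2–4), 0–8 nt variable arm, 5 bp T stem (7 nt loop); G·U
  counts as paired, at most one unpaired position across all four stems.
  Requiring all four stems keeps the expected number of spurious windows
  on a 15 kb AT-rich genome near zero while planted (fully paired) tRNAs
  score maximally. This is a pattern matcher, not a covariance model:
  real tRNAs with non-canonical arm lengths (notably the D-armless tRNAs
  of some flatworms) will be missed, which is the main caveat when moving
  from simulated to real data.
* **rRNA similarity** — 11-mer nucleotide word voting per reference.

Reconciliation is deterministic, replacing manual curation with rules
plus flags: tRNA/rRNA candidates are accepted from their tracks; a CDS
requires protein-similarity support, its boundaries snapped to the start
codon nearest the refined hit (preferring ATT/ATG on ties, searching back
to the upstream in-frame stop) and to the first in-frame stop. When no
stop occurs before the next downstream feature, the CDS is truncated
there — at a codon-aligned partial T or TA when present — and flagged
`incomplete_stop`, mirroring stops completed by polyadenylation. An ORF
candidate agreeing reciprocally (≥ 50 % overlap, same strand) adds
corroborating evidence. Features overlapping by > 40 nt flag the
lower-scoring one `conflict` for curator review; nothing is silently
deleted. Unannotated gaps ≥ 50 nt become NCRs, the longest (summing the
two pieces of a gap spanning the origin) is the control region.

Translation tables come from the NCBI registry via Biopython; ambiguous
codons resolve when every IUPAC expansion agrees (GGN → Gly), and stem
pairing in the tRNA scan is likewise IUPAC-aware, so moderately ambiguous
consensus sequences remain annotatable. Insect mode defaults to table 5
(invertebrate mitochondrial); table 4 can be forced with `--table 4` for
compatibility with workflows that used it, but table 5's TGA→Trp matches
the observed in-frame TGA codons in fly mitogenomes. Flatworm mode uses
table 9. The pipeline annotates the assembly contig (majority-rule
sequence) rather than the conservative consensus, whose ambiguity density
at moderate coverage would starve the similarity tracks; the consensus
remains the deposited sequence.

## Gene order

Orders are linearized from an anchor (default MT-CO1, oriented forward;
a minus-strand anchor reverse-complements the whole order). Leu/Ser tRNA
paralogs are distinguished by anticodon codon family (CUN/UUR, UCN/AGN).
Cestode categories are keyed on the published diagnostic motifs, checked
in priority III → IV → II → I: the TDRL block
trnL(CUN)–trnL(UUR)–trnY–trnS(UCN) (III); the trnS(UCN)–trnL(CUN)
adjacency (IV); the ancestral trnL(CUN)–trnS(UCN) adjacency 3′ of the
cox2–trnE–nad6–trnY block (II) or elsewhere (I). The full gene
complements of the categories are not encoded — only the diagnostic
adjacencies — so orders lacking the relevant tRNAs return `unclassified`.
Breakpoint distance counts strand-aware unordered adjacencies of one
order absent from the other; for circular orders the adjacency set is
rotation-invariant, and the count is symmetric for equal symbol sets.

## Simulator

The simulator is the ground-truth side of every test. It emulates the two
study systems: an insect-style genome (13 CDS including ATP8, 22 tRNAs,
2 rRNAs, one control region; 14 tRNAs + 9 PCGs on the majority strand in
a fly-like arrangement) and a cestode-style genome (12 CDS, no ATP8, all
genes on one strand, a Category-IV-like tRNA arrangement). Defaults are
the study conditions: 15 kb circular genome at GC 0.25, 60× coverage of
PE-150 reads, 1 % substitution error, insert 400 ± 40 nt, bait at 5 %
divergence, 800 nt control region. Nominal gene lengths follow metazoan
mitogenomes and are scaled (with floors of 153 nt per CDS and 100 nt per
rRNA) to fit the configured genome length; infeasible packings raise.
CDS are random codon sequences with valid starts (TCG for insect MT-CO1,
ATT/ATG otherwise) and stops (TAG for MT-CYB, TAA otherwise) and no
internal stop under the configured code; tRNAs are fully paired
cloverleafs in the detector's layout; rRNAs, spacers and the CR are
random bases at the configured GC.

Reads are uniform fragments (wrapping the origin when circular) with
Normal insert lengths, per-base substitutions at the configured rate,
qualities ~N(38, 3) clipped to [2, 41], uniform tile assignment, and a
flat Phred shift on designated bad tiles. Error placement is independent
of the emitted quality scores. What the simulator does **not** model —
platform-specific error profiles, PCR duplicates, coverage bias with GC,
nuclear background/NUMTs, heteroplasmy, D-armless tRNAs — bounds what
passing tests show about real libraries: they validate the algorithms'
correctness on their stated assumptions, not robustness to every
real-data artifact.

## Problem sizes and determinism

The test suite and the acceptance script run the full 15 kb / 60×
conditions for recovery; circularity discrimination uses 4 kb / 40×
fixtures (50 + 50 seeds in the suite, 30 + 30 in the script) and
annotation recovery uses 50 (suite) or 20 (script) full-size genomes with
30 %-diverged references — sizes chosen so a complete run stays in the
minutes range on one core. All randomness flows from explicit seeds
(NumPy `default_rng`); every tie-break in consensus, selection and
classification is deterministic, so fixed seeds give bit-identical
outputs, which the suite asserts.

## Known limitations

* Single-molecule assumption: heavy nuclear contamination sharing
  31-mers with the bait, or two co-amplified organelles, will confuse
  recruitment.
* The tRNA detector's fixed cloverleaf layout misses structurally
  divergent tRNAs common in some taxa.
* Boundary snapping trusts reading frames; frameshift sequencing errors
  in a real contig shift the snapped boundary to the nearest in-frame
  codon.
* The conservative consensus needs depth in the hundreds to produce an
  ambiguity-free sequence; at skimming depths its output is deliberately
  ambiguity-rich.
* The deposited-assembly check compares length/GC (and gene counts when
  an annotation is supplied); fetching the records requires network
  access.
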