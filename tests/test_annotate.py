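"""Genetic codes, evidence tracks, and annotation reconciliation."""

import numpy as np
import pytest

from mitoskim._seq import revcomp
from mitoskim.annotate import (
    EvidenceTrack,
    annotate_genome,
    assign_noncoding,
    get_code,
    protein_similarity,
    reconcile,
    rrna_similarity,
    scan_orfs,
    scan_trnas,
    translate,
    FeatureAnnotation,
)
from mitoskim.formats_io import SeqRecord
from mitoskim.simulate import (
    SimConfig,
    make_reference_peptides,
    make_reference_rrnas,
    simulate_mitogenome,
)


class TestGeneticCodes:
    @pytest.mark.parametrize(
        "codon,table,expected",
        [
            ("TGA", 9, "W"),  # flatworm: opal read-through as Trp
            ("AGA", 9, "S"),
            ("AGG", 9, "S"),
            ("AAA", 9, "N"),  # flatworm-specific Lys->Asn reassignment
            ("TGA", 5, "W"),
            ("AGA", 5, "S"),
            ("AGG", 5, "S"),
            ("AAA", 5, "K"),
            ("ATA", 5, "M"),
        ],
    )
    def test_codon_reassignments(self, codon, table, expected):
        assert get_code(table).translate_codon(codon) == expected

    def test_translate_cds_under_table5(self):
        assert translate("ATGAAATAA", get_code(5)) == "MK*"

    def test_non_triplet_length_rejected_without_flag(self):
        with pytest.raises(ValueError):
            translate("ATGAA", get_code(5))
        assert translate("ATGAA", get_code(5), allow_partial=True) == "M"

    def test_ambiguous_codons_resolve_when_synonymous(self):
        code = get_code(5)
        assert code.translate_codon("GGN") == "G"  # all GGx are Gly
        assert code.translate_codon("ANT") == "X"


class TestScanOrfs:
    def test_planted_cds_recovered_with_exact_stops(self, small_truth):
        code = small_truth.code
        track = scan_orfs(small_truth.genome, code, min_aa=45)
        found_ends = {(c.end if c.strand == "+" else c.start, c.strand)
                      for c in track.candidates}
        for f in small_truth.features:
            if f.kind != "CDS":
                continue
            key = (f.end, "+") if f.strand == "+" else (f.start, "-")
            assert key in found_ends, f.name

    def test_matches_brute_force_on_random_sequence(self):
        rng = np.random.default_rng(42)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        code = get_code(5)
        min_aa = 20
        track = scan_orfs(SeqRecord("r", seq), code, min_aa=min_aa)
        got = {(c.start, c.end, c.strand) for c in track.candidates}

        starts = {"ATT", "ATG", "ATA", "GTG", "TCG"}
        expected = set()
        L = len(seq)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for off in range(3):
                boundary = off
                for i in range(off, len(s) - 2, 3):
                    codon = s[i : i + 3]
                    if codon in code.stop_codons:
                        for j in range(boundary, i, 3):
                            if s[j : j + 3] in starts:
                                if (i - j) // 3 >= min_aa:
                                    a, b = j, i + 3
                                    if strand == "-":
                                        a, b = L - (i + 3), L - j
                                    expected.add((a, b, strand))
                                break
                        boundary = i + 3
        assert got == expected

    def test_reverse_complement_mirror_symmetry(self, small_truth):
        code = small_truth.code
        L = len(small_truth.genome.seq)
        fwd = scan_orfs(small_truth.genome, code, min_aa=45)
        rc = scan_orfs(SeqRecord("rc", revcomp(small_truth.genome.seq)), code, min_aa=45)
        fwd_set = {(c.start, c.end, c.strand) for c in fwd.candidates}
        mir_set = {
            (L - c.end, L - c.start, "+" if c.strand == "-" else "-")
            for c in rc.candidates
        }
        assert fwd_set == mir_set


class TestProteinSimilarity:
    def test_identity_references_hit_planted_intervals(self, small_truth):
        refs = make_reference_peptides(small_truth)
        track = protein_similarity(small_truth.genome, refs, small_truth.code)
        planted = {
            f.name: f for f in small_truth.features if f.kind == "CDS"
        }
        assert len(track.candidates) == len(planted)
        for cand in track.candidates:
            p = planted[cand.name]
            assert cand.strand == p.strand
            # the reference peptide excludes the stop codon, which sits at
            # the 3' end of the gene (start side in forward coords for '-')
            if p.strand == "+":
                assert (cand.start, cand.end) == (p.start, p.end - 3)
            else:
                assert (cand.start, cand.end) == (p.start + 3, p.end)

    def test_thirty_percent_divergence_recovers_nearly_all(self, small_truth):
        refs = make_reference_peptides(small_truth, divergence=0.30, seed=99)
        track = protein_similarity(small_truth.genome, refs, small_truth.code)
        planted = {f.name: f for f in small_truth.features if f.kind == "CDS"}
        good = 0
        for cand in track.candidates:
            p = planted[cand.name]
            if (
                cand.strand == p.strand
                and abs(cand.start - p.start) <= 30
                and abs(cand.end - (p.end - 3)) <= 30
            ):
                good += 1
        assert good >= len(planted) - 1

    def test_absent_gene_reported_missing(self):
        # a cestode-style genome lacks ATP8: insect references must not
        # produce an ATP8 hit
        cfg = SimConfig(rng_seed=41, mode="cestode", genome_len=8000)
        truth = simulate_mitogenome(cfg)
        insect_truth = simulate_mitogenome(SimConfig(rng_seed=42, genome_len=8000))
        refs = make_reference_peptides(insect_truth)
        track = protein_similarity(truth.genome, refs, truth.code)
        names = {c.name for c in track.candidates}
        assert "MT-ATP8" not in names

    def test_empty_reference_set_gives_empty_track(self, small_truth):
        track = protein_similarity(small_truth.genome, [], small_truth.code)
        assert track.candidates == []


class TestScanTrnas:
    def test_planted_trnas_detected_with_correct_anticodon(self, small_truth):
        track = scan_trnas(small_truth.genome, small_truth.code)
        planted = {
            (f.name, f.start, f.end, f.strand)
            for f in small_truth.features
            if f.kind == "tRNA"
        }
        got = {(c.name, c.start, c.end, c.strand) for c in track.candidates}
        assert planted <= got

    def test_poly_a_has_no_candidates(self):
        track = scan_trnas(SeqRecord("a", "A" * 200), get_code(5))
        assert track.candidates == []

    def test_minus_strand_trna_detected(self, small_truth):
        track = scan_trnas(small_truth.genome, small_truth.code)
        minus_planted = [
            f for f in small_truth.features if f.kind == "tRNA" and f.strand == "-"
        ]
        assert minus_planted  # insect layout has minus-strand tRNAs
        got_minus = {(c.start, c.end) for c in track.candidates if c.strand == "-"}
        for f in minus_planted:
            assert (f.start, f.end) in got_minus


class TestReconcile:
    def test_planted_genome_annotated_exactly(self, small_truth):
        feats = annotate_genome(
            small_truth.genome,
            make_reference_peptides(small_truth),
            make_reference_rrnas(small_truth),
            small_truth.code,
        )
        planted = {
            (f.name, f.kind, f.start, f.end, f.strand)
            for f in small_truth.features
            if f.kind in ("CDS", "tRNA", "rRNA")
        }
        got = {
            (f.name, f.kind, f.start, f.end, f.strand)
            for f in feats
            if f.kind in ("CDS", "tRNA", "rRNA")
        }
        assert got == planted

    def test_mutated_stop_yields_incomplete_stop_flag(self, small_truth):
        g = small_truth.genome.seq
        # pick a plus-strand CDS directly followed by another feature
        target = next(
            f for f in small_truth.features if f.kind == "CDS" and f.strand == "+"
        )
        stop = g[target.end - 3 : target.end]
        assert stop in ("TAA", "TAG")
        mutated = g[: target.end - 3] + "C" + g[target.end - 2 :]
        genome = SeqRecord("mut", mutated)
        feats = annotate_genome(
            genome,
            make_reference_peptides(small_truth),
            make_reference_rrnas(small_truth),
            small_truth.code,
        )
        cds = next(f for f in feats if f.name == target.name)
        assert "incomplete_stop" in cds.flags

    def test_empty_tracks_give_empty_annotation(self, small_truth):
        feats = reconcile(
            [EvidenceTrack("protein_sim", []), EvidenceTrack("trna_scan", [])],
            small_truth.genome,
            small_truth.code,
        )
        assert feats == []


class TestAssignNoncoding:
    def _feature(self, start, end, name="g", kind="CDS"):
        return FeatureAnnotation(name=name, kind=kind, start=start, end=end, strand="+")

    def test_single_gap_becomes_cr(self):
        genome = SeqRecord("g", "A" * 2000)
        feats = [self._feature(0, 600), self._feature(1400, 2000)]
        out = assign_noncoding(feats, genome, circular=True)
        crs = [f for f in out if f.kind == "CR"]
        assert [(f.start, f.end) for f in crs] == [(600, 1400)]

    def test_fully_tiled_genome_has_no_ncr(self):
        genome = SeqRecord("g", "A" * 1000)
        feats = [self._feature(0, 500), self._feature(500, 1000)]
        out = assign_noncoding(feats, genome)
        assert all(f.kind not in ("CR", "NCR") for f in out)

    def test_two_gaps_longest_is_cr(self):
        genome = SeqRecord("g", "A" * 3000)
        feats = [
            self._feature(0, 500),
            self._feature(1400, 2000, name="h"),
            self._feature(2060, 3000, name="i"),
        ]
        out = assign_noncoding(feats, genome)
        kinds = {(f.start, f.end): f.kind for f in out if f.kind in ("CR", "NCR")}
        assert kinds[(500, 1400)] == "CR"
        assert kinds[(2000, 2060)] == "NCR"

    def test_short_gap_below_threshold_ignored(self):
        genome = SeqRecord("g", "A" * 1000)
        feats = [self._feature(0, 480), self._feature(510, 1000)]
        out = assign_noncoding(feats, genome, min_ncr=50)
        assert all(f.kind not in ("CR", "NCR") for f in out)


def test_annotation_mirror_under_reverse_complement(small_truth):
    code = small_truth.code
    L = len(small_truth.genome.seq)
    refs = make_reference_peptides(small_truth)
    rrnas = make_reference_rrnas(small_truth)
    fwd = annotate_genome(small_truth.genome, refs, rrnas, code)
    rc_genome = SeqRecord("rc", revcomp(small_truth.genome.seq))
    rev = annotate_genome(rc_genome, refs, rrnas, code)
    fwd_set = {
        (f.name, f.start, f.end, f.strand)
        for f in fwd
        if f.kind in ("CDS", "tRNA", "rRNA")
    }
    mir_set = {
        (f.name, L - f.end, L - f.start, "+" if f.strand == "-" else "-")
        for f in rev
        if f.kind in ("CDS", "tRNA", "rRNA")
    }
    assert fwd_set == mir_set


def test_no_internal_stops_in_accepted_unflagged_cds(small_truth):
    feats = annotate_genome(
        small_truth.genome,
        make_reference_peptides(small_truth),
        make_reference_rrnas(small_truth),
        small_truth.code,
    )
    g = small_truth.genome.seq
    for f in feats:
        if f.kind != "CDS" or f.flags:
            continue
        nt = g[f.start : f.end]
        if f.strand == "-":
            nt = revcomp(nt)
        pep = translate(nt, small_truth.code, allow_partial=True)
        assert "*" not in pep[:-1], f.name
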