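"""Splice-site scanning, candidate enumeration, transcripts and peptides."""

import numpy as np
import pytest
from Bio.Seq import Seq, reverse_complement

from tenest.exonization import (ExonizationCandidate, SpliceSite,
                                compare_peptides, enumerate_candidates,
                                find_first_orf, make_transcript,
                                scan_splice_sites, splice_in)


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def acceptor(pos):
    return SpliceSite(kind="acceptor_3ss", position=pos, dinucleotide="AG")


def donor(pos):
    return SpliceSite(kind="donor_5ss", position=pos, dinucleotide="GT")


class TestScanSpliceSites:
    def test_plus_strand_motifs(self):
        sites = scan_splice_sites("TTAGCCGTAA", (0, 10), "+")
        kinds = {(s.kind, s.position) for s in sites}
        assert kinds == {("acceptor_3ss", 2), ("donor_5ss", 6)}

    def test_no_motifs_empty(self):
        assert scan_splice_sites("TTTTCCCC", (0, 8), "+") == []

    def test_minus_strand_scans_sense_motifs(self):
        # sense AG of a - strand gene reads CT on the genome
        region = "AACTAA" + "AACAA"  # CT at 2 (acceptor), AC at 7 (donor)
        sites = scan_splice_sites(region, (0, len(region)), "-")
        got = {(s.kind, s.position) for s in sites}
        assert ("acceptor_3ss", 2) in got
        assert ("donor_5ss", 7) in got
        assert all(s.dinucleotide in ("AG", "GT") for s in sites)

    def test_counts_match_sliding_window_oracle(self, rng):
        seq = _random_seq(rng, 10_000)
        sites = scan_splice_sites(seq, (0, len(seq)), "+")
        n_ag = sum(1 for i in range(len(seq) - 1) if seq[i:i + 2] == "AG")
        n_gt = sum(1 for i in range(len(seq) - 1) if seq[i:i + 2] == "GT")
        assert sum(s.kind == "acceptor_3ss" for s in sites) == n_ag
        assert sum(s.kind == "donor_5ss" for s in sites) == n_gt

    def test_strand_flip_symmetry(self, rng):
        """A sense-strand site of a − gene mirrors a + site on the rc genome."""
        region = _random_seq(rng, 500)
        plus = scan_splice_sites(region, (0, 500), "+")
        minus = scan_splice_sites(reverse_complement(region), (0, 500), "-")
        mapped = {(s.kind, 500 - s.position - 2) for s in minus}
        assert {(s.kind, s.position) for s in plus} == mapped


class TestEnumerateCandidates:
    def test_two_acceptors_one_donor_gives_two_candidates(self):
        cands = enumerate_candidates([acceptor(100), acceptor(160)],
                                     [donor(300)], intron=(0, 1000))
        assert len(cands) == 2
        assert {c.length for c in cands} == {198, 138}
        assert len({(c.exon_start, c.exon_end) for c in cands}) == 2

    def test_donor_upstream_of_acceptors_empty(self):
        assert enumerate_candidates([acceptor(500)], [donor(100)],
                                    intron=(0, 1000)) == []

    def test_length_bounds_enforced(self):
        cands = enumerate_candidates([acceptor(100)], [donor(110)],
                                     intron=(0, 1000), min_len=25)
        assert cands == []

    def test_minus_strand_ordering(self):
        # transcript direction right-to-left: acceptor genomic pos > donor
        cands = enumerate_candidates([acceptor(500)], [donor(100)],
                                     intron=(0, 1000), strand="-")
        assert len(cands) == 1
        assert (cands[0].exon_start, cands[0].exon_end) == (102, 500)

    def test_count_matches_exhaustive_pairing(self, rng):
        accs = [acceptor(int(p)) for p in rng.integers(0, 2000, 25)]
        dons = [donor(int(p)) for p in rng.integers(0, 2000, 25)]
        cands = enumerate_candidates(accs, dons, intron=(0, 2000),
                                     min_len=25, max_len=500)
        expected = sum(
            1 for a in accs for d in dons
            if 25 <= d.position - a.position - 2 <= 500)
        assert len(cands) == expected


class TestTranscripts:
    def make_locus(self, rng):
        seq = _random_seq(rng, 5000)
        exons = [(i * 1000, i * 1000 + 200) for i in range(5)]
        return seq, exons

    def test_candidate_in_intron_4_yields_six_exons(self, rng):
        seq, exons = self.make_locus(rng)
        cand = ExonizationCandidate(
            acceptor=acceptor(3398), donor=donor(3600),
            exon_start=3400, exon_end=3600, strand="+")
        tm = splice_in(seq, exons, cand)
        assert len(tm.exons) == 6
        assert tm.exons[4] == (3400, 3600)

    def test_splice_in_then_removal_restores_reference(self, rng):
        seq, exons = self.make_locus(rng)
        ref = make_transcript(seq, exons, "+")
        cand = ExonizationCandidate(
            acceptor=acceptor(3398), donor=donor(3600),
            exon_start=3400, exon_end=3600, strand="+")
        tm = splice_in(seq, exons, cand)
        back = make_transcript(seq, [e for e in tm.exons if e != tm.inserted],
                               "+")
        assert back.mrna == ref.mrna

    def test_length_bookkeeping(self, rng):
        seq, exons = self.make_locus(rng)
        ref = make_transcript(seq, exons, "+")
        cand = ExonizationCandidate(
            acceptor=acceptor(2298), donor=donor(2500),
            exon_start=2300, exon_end=2500, strand="+")
        tm = splice_in(seq, exons, cand)
        assert len(tm.mrna) == len(ref.mrna) + cand.length

    def test_candidate_outside_introns_rejected(self, rng):
        seq, exons = self.make_locus(rng)
        cand = ExonizationCandidate(
            acceptor=acceptor(98), donor=donor(190),
            exon_start=100, exon_end=190, strand="+")  # inside exon 1
        with pytest.raises(ValueError, match="not inside"):
            splice_in(seq, exons, cand)

    def test_minus_strand_mrna_is_reverse_complement(self, rng):
        seq, exons = self.make_locus(rng)
        plus = make_transcript(seq, exons, "+")
        minus = make_transcript(seq, exons, "-")
        assert minus.mrna == reverse_complement(plus.mrna)


class TestFindFirstOrf:
    def test_hand_translatable(self):
        report = find_first_orf("ATGAAATAA")
        assert report.peptide == "MK"
        assert (report.orf_start, report.orf_end) == (0, 9)

    def test_429_nt_orf_gives_142_aa(self, v1v2_locus):
        report = find_first_orf(v1v2_locus.reference_mrna)
        assert report.orf_end - report.orf_start == 429
        assert report.length_aa == 142

    def test_no_orf_reports_absent(self):
        report = find_first_orf("CCCCCCCCCC")
        assert not report.found

    def test_first_start_rule_vs_exhaustive_scan(self, rng):
        """First-start selection equals a brute-force all-ATG scan."""
        stops = {"TAA", "TAG", "TGA"}
        for _ in range(500):
            seq = _random_seq(rng, 300)
            best = None
            for i in range(len(seq) - 2):
                if seq[i:i + 3] != "ATG":
                    continue
                for j in range(i, len(seq) - 2, 3):
                    if seq[j:j + 3] in stops:
                        best = (i, j + 3)
                        break
                if best:
                    break
            report = find_first_orf(seq)
            if best is None:
                assert not report.found
            else:
                assert (report.orf_start, report.orf_end) == best
                assert report.peptide == str(
                    Seq(seq[best[0]:best[1] - 3]).translate())

    def test_orf_length_arithmetic(self, rng):
        for _ in range(50):
            seq = _random_seq(rng, 400)
            report = find_first_orf(seq)
            if report.found:
                assert 3 * (report.length_aa + 1) == \
                    report.orf_end - report.orf_start


class TestComparePeptides:
    def test_identical_is_no_divergence(self):
        cmp_ = compare_peptides("MKLV", "MKLV")
        assert cmp_.divergence_point is None
        assert not cmp_.premature_stop

    def test_divergence_after_137_shared(self):
        ref = "A" * 142
        var = "A" * 137 + "WYFQR" + "LL"
        cmp_ = compare_peptides(ref, var)
        assert cmp_.divergence_point == 138
        assert cmp_.shared_prefix_len == 137
        assert cmp_.premature_stop

    def test_truncation_flags_premature_stop(self):
        cmp_ = compare_peptides("MKLVW", "MKL")
        assert cmp_.premature_stop
        assert cmp_.divergence_point == 4

    def test_matches_brute_force_first_mismatch(self, rng):
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(200):
            ref = "".join(aas[i] for i in rng.integers(0, 20, 30))
            var = "".join(aas[i] for i in rng.integers(0, 20, 30))
            cmp_ = compare_peptides(ref, var)
            mismatches = [i for i, (a, b) in enumerate(zip(ref, var))
                          if a != b]
            if mismatches:
                assert cmp_.divergence_point == mismatches[0] + 1
            elif len(ref) == len(var):
                assert cmp_.divergence_point is None


class TestBoundaryContext:
    def test_candidate_exons_flanked_by_ag_and_gt(self, v1v2_locus):
        """Re-extracting each candidate reproduces its boundary context."""
        loc = v1v2_locus
        seq = loc.chrom.seq
        sites = scan_splice_sites(seq, loc.te_region, "+")
        cands = enumerate_candidates(
            [s for s in sites if s.kind == "acceptor_3ss"],
            [s for s in sites if s.kind == "donor_5ss"],
            intron=(loc.gene.exon_ends[3], loc.gene.exon_starts[4]))
        assert cands
        for c in cands:
            assert seq[c.exon_start - 2:c.exon_start] == "AG"
            assert seq[c.exon_end:c.exon_end + 2] == "GT"
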