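"""IUPAC scanning, CAN/NC classification, SMAD-FoxH1 pairing geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regdomain_integrator.genome_model import GenomeAnnotation
from regdomain_integrator.motif import (
    ConsensusMotif,
    classify_peaks,
    expand_iupac,
    find_smad_pairs,
    scan_consensus,
)
from regdomain_integrator.peak_qc import revcomp

from conftest import make_peak, plant, scaffold

FOX = ConsensusMotif("FoxH1", "AATMCACA")
SMAD = ConsensusMotif("SMAD", "GTCTAGAC")


def brute_force_scan(seq: str, motif: ConsensusMotif) -> list[tuple[int, str]]:
    """Expand-and-test every window on both strands (independent oracle)."""
    words = expand_iupac(motif)
    rc_words = {revcomp(w) for w in words}
    m = len(motif)
    out = []
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        if window in words:
            out.append((i, "+"))
        if window in rc_words:
            out.append((i, "-"))
    return sorted(out)


class TestExpandIupac:
    def test_foxh1_consensus_two_words(self):
        assert expand_iupac(FOX) == {"AATACACA", "AATCCACA"}

    def test_literal_motif(self):
        assert expand_iupac(ConsensusMotif("m", "ACGT")) == {"ACGT"}

    def test_full_degeneracy_count(self):
        assert len(expand_iupac(ConsensusMotif("m", "NNNN"))) == 256

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError):
            ConsensusMotif("m", "ACGX")


class TestScanConsensus:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GGAATACACAGG", [(2, "+")]),  # M matches A
            ("GGAATCCACAGG", [(2, "+")]),  # M matches C
            ("CCTGTGGATTCC", [(2, "-")]),  # reverse complement of AATCCACA
            ("GGAATGCACAGG", []),  # M never matches G
        ],
    )
    def test_known_hits(self, seq, expected):
        hits = scan_consensus(seq, FOX)
        assert [(h.start, h.strand) for h in hits] == expected

    def test_minus_hit_word_reported_on_minus_strand(self):
        (hit,) = scan_consensus("CCTGTGGATTCC", FOX)
        assert hit.matched_word == "AATCCACA"

    def test_motif_longer_than_sequence(self):
        assert scan_consensus("ACGT", FOX) == []

    def test_sequence_n_matches_nothing(self):
        assert scan_consensus("AATNCACA", FOX) == []

    def test_overlapping_hits_found(self):
        # AATACACA starting at 0 and again at 6 share the "CA" junction
        seq = "AATACACAATACACA"
        hits = scan_consensus(seq, FOX, both_strands=False)
        assert [h.start for h in hits] == [0, 7]

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=300))
    def test_matches_brute_force(self, seq):
        hits = [(h.start, h.strand) for h in scan_consensus(seq, FOX)]
        assert hits == brute_force_scan(seq, FOX)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.text(alphabet="ACGT", min_size=8, max_size=300))
    def test_strand_symmetry(self, seq):
        fwd = scan_consensus(seq, FOX)
        rev = scan_consensus(revcomp(seq), FOX)
        m = len(FOX)
        mirrored = sorted(
            (len(seq) - h.start - m, {"+": "-", "-": "+"}[h.strand]) for h in rev
        )
        assert mirrored == sorted((h.start, h.strand) for h in fwd)

    def test_planted_recovery_and_background_rate(self, rng):
        # plant one word per sequence; count extra background hits
        n_seqs, L, m, k = 400, 1_000, len(FOX), 2
        planted_found = 0
        background_hits = 0
        for _ in range(n_seqs):
            seq = "".join(rng.choice(list("ACGT"), L))
            pos = int(rng.integers(0, L - m))
            word = "AATACACA" if rng.random() < 0.5 else "AATCCACA"
            planted = plant(seq, pos, word)
            hits = scan_consensus(planted, FOX)
            assert any(h.start == pos and h.strand == "+" for h in hits)
            planted_found += 1
            background_hits += len(scan_consensus(seq, FOX))
        assert planted_found == n_seqs
        expected = n_seqs * 2 * (L - m + 1) * k / 4**m
        assert abs(background_hits - expected) <= 3 * np.sqrt(expected)


class TestClassifyPeaks:
    def test_planted_motif_gives_can(self):
        seq = plant(scaffold(300), 140, "AATACACA")
        genome = {"chr1": seq}
        (c,) = classify_peaks([make_peak("chr1", 100, 300, "p")], genome)
        assert c.peak_class == "CAN"
        assert c.foxh1_hits[0].start == 140

    def test_motif_free_peak_is_nc(self):
        genome = {"chr1": scaffold(300)}
        (c,) = classify_peaks([make_peak("chr1", 0, 300, "p")], genome)
        assert c.peak_class == "NC"

    def test_planted_fraction_recovered(self, rng):
        """1000 motif-free peaks, motifs planted in 140 -> exactly 140 CAN."""
        n, planted_n, plen = 1_000, 140, 120
        seq = scaffold(n * plen)
        can_idx = set(rng.choice(n, planted_n, replace=False).tolist())
        for i in can_idx:
            seq = plant(seq, i * plen + 40, "AATCCACA")
        genome = {"chr1": seq}
        peaks = [make_peak("chr1", i * plen, (i + 1) * plen, f"p{i}") for i in range(n)]
        classes = classify_peaks(peaks, genome)
        got_can = {i for i, c in enumerate(classes) if c.peak_class == "CAN"}
        assert got_can == can_idx


class TestSmadPairing:
    def _classified(self, seq):
        genome = {"chr1": seq}
        classes = classify_peaks([make_peak("chr1", 0, len(seq), "p")], genome)
        return classes, genome

    def test_plus_strand_gap30_paired(self):
        seq = scaffold(400)
        fox_start = 200
        smad_start = fox_start - 30 - 8  # SMAD word ends 30 bp 5' of the hit
        seq = plant(plant(seq, fox_start, "AATACACA"), smad_start, "GTCTAGAC")
        classes, genome = self._classified(seq)
        find_smad_pairs(classes, genome, [SMAD])
        assert classes[0].smad_paired

    def test_plus_strand_gap150_not_paired(self):
        seq = scaffold(400)
        fox_start = 250
        smad_start = fox_start - 150 - 8
        seq = plant(plant(seq, fox_start, "AATACACA"), smad_start, "GTCTAGAC")
        classes, genome = self._classified(seq)
        find_smad_pairs(classes, genome, [SMAD])
        assert not classes[0].smad_paired

    def test_minus_strand_five_prime_is_higher_coordinates(self):
        # '-' FoxH1 hit: its 5' flank lies at higher genomic coordinates
        seq = scaffold(400)
        fox_start = 100
        seq = plant(seq, fox_start, revcomp("AATACACA"))
        smad_start = fox_start + 8 + 80  # gap 80 on the 5' side
        seq = plant(seq, smad_start, "GTCTAGAC")
        classes, genome = self._classified(seq)
        assert classes[0].foxh1_hits[0].strand == "-"
        find_smad_pairs(classes, genome, [SMAD])
        assert classes[0].smad_paired

    def test_minus_strand_wrong_side_not_paired(self):
        seq = scaffold(400)
        fox_start = 200
        seq = plant(seq, fox_start, revcomp("AATACACA"))
        smad_start = fox_start - 30 - 8  # 3' side for a '-' hit
        seq = plant(seq, smad_start, "GTCTAGAC")
        classes, genome = self._classified(seq)
        find_smad_pairs(classes, genome, [SMAD])
        assert not classes[0].smad_paired

    def test_smad_outside_peak_boundary_still_found(self):
        # FoxH1 hit near the peak edge; SMAD word upstream of the peak start
        chrom = scaffold(1_000)
        peak_start, peak_end = 500, 700
        fox_start = peak_start + 5
        smad_start = fox_start - 40 - 8  # 452 < peak_start
        chrom = plant(plant(chrom, fox_start, "AATCCACA"), smad_start, "GTCTAGAC")
        genome = {"chr1": chrom}
        classes = classify_peaks([make_peak("chr1", peak_start, peak_end, "p")], genome)
        find_smad_pairs(classes, genome, [SMAD])
        assert classes[0].smad_paired

    def test_empty_smad_motifs_warns_and_clears(self, caplog):
        seq = plant(scaffold(300), 100, "AATACACA")
        classes, genome = self._classified(seq)
        with caplog.at_level("WARNING"):
            find_smad_pairs(classes, genome, [])
        assert not classes[0].smad_paired

    def test_nc_peak_never_paired(self):
        seq = plant(scaffold(300), 100, "GTCTAGAC")
        classes, genome = self._classified(seq)
        find_smad_pairs(classes, genome, [SMAD])
        assert classes[0].peak_class == "NC"
        assert not classes[0].smad_paired
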