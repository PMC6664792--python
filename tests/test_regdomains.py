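"""Basal/extended regulatory domains and peak-gene association."""

import numpy as np
import pytest

from regdomain_integrator.genome_model import GenomeAnnotation, Interval
from regdomain_integrator.regdomains import (
    DomainParams,
    associate,
    associate_bruteforce,
    build_basal,
    extend_domains,
    extend_domains_bruteforce,
    genes_with_peaks_in_window,
)

from conftest import make_gene, make_peak, random_annotation

PARAMS = DomainParams()


def domains_by_id(domains):
    return {d.gene_id: d for d in domains}


class TestBuildBasal:
    def test_plus_strand(self):
        g = make_gene("g", "chr1", "+", 100_000, 101_000)
        iv, flags = build_basal(g, PARAMS, 1_000_000)
        assert iv == Interval("chr1", 95_000, 101_000)
        assert not flags

    def test_minus_strand_mirror(self):
        g = make_gene("g", "chr1", "-", 99_000, 100_001)  # tss = 100_000
        iv, _ = build_basal(g, PARAMS, 1_000_000)
        assert iv == Interval("chr1", 99_001, 105_001)

    def test_chromosome_edge_clip(self):
        g = make_gene("g", "chr1", "+", 2_000, 3_000)
        iv, flags = build_basal(g, PARAMS, 1_000_000)
        assert iv == Interval("chr1", 0, 3_000)
        assert "clipped_at_chrom_edge" in flags


class TestExtendDomains:
    def test_isolated_gene_reaches_caps(self):
        ann = GenomeAnnotation(
            {"chr1": 1_000_000},
            [make_gene("g", "chr1", "+", 100_000, 101_000)],
        )
        (d,) = extend_domains(ann, PARAMS)
        assert d.extended == Interval("chr1", 50_000, 120_000)
        assert {"capped_up", "capped_down"} <= d.flags

    def test_two_gene_neighbor_limiting(self):
        # A: tss 100k, B: tss 140k, both '+'
        ann = GenomeAnnotation(
            {"chr1": 1_000_000},
            [
                make_gene("gA", "chr1", "+", 100_000, 101_500),
                make_gene("gB", "chr1", "+", 140_000, 141_500),
            ],
        )
        d = domains_by_id(extend_domains(ann, PARAMS))
        # A's downstream cap (120k) is closer than B's basal start (135k)
        assert d["gA"].extended == Interval("chr1", 50_000, 120_000)
        # B's upstream extension stops at A's basal end (101k), not its 90k cap
        assert d["gB"].extended == Interval("chr1", 101_000, 160_000)
        assert "limited_by_neighbor_up" in d["gB"].flags

    def test_overlapping_neighbor_basal_is_skipped(self):
        # B's basal overlaps A's basal; it must not constrain A's extension,
        # so A reaches the next constraint (C's basal edge)
        ann = GenomeAnnotation(
            {"chr1": 1_000_000},
            [
                make_gene("gA", "chr1", "+", 100_000, 101_500),
                make_gene("gB", "chr1", "+", 103_000, 104_500),  # basal [98k,104k)
                make_gene("gC", "chr1", "+", 140_000, 141_500),  # basal [135k,141k)
            ],
        )
        d = domains_by_id(extend_domains(ann, PARAMS))
        # downstream of A: B overlaps A's basal [95k,101k) -> skipped;
        # C's basal start 135k is beyond A's cap 120k -> cap applies
        assert d["gA"].extended.end == 120_000
        # upstream of C: B's basal end 104k limits (cap would be 90k)
        assert d["gC"].extended.start == 104_000

    def test_matches_bruteforce_oracle(self, rng):
        for rep in range(25):
            ann = random_annotation(rng, n_genes=int(rng.integers(2, 50)))
            fast = {
                (d.gene_id): (d.basal, d.extended) for d in extend_domains(ann, PARAMS)
            }
            slow = {
                (d.gene_id): (d.basal, d.extended)
                for d in extend_domains_bruteforce(ann, PARAMS)
            }
            assert fast == slow

    def test_gene_order_permutation_invariance(self, rng):
        ann = random_annotation(rng, n_genes=30)
        ref = {
            d.gene_id: d.extended for d in extend_domains(ann, PARAMS)
        }
        perm = list(ann.genes)
        rng.shuffle(perm)
        ann2 = GenomeAnnotation(dict(ann.chrom_sizes), perm)
        assert {d.gene_id: d.extended for d in extend_domains(ann2, PARAMS)} == ref

    def test_containment_and_neighbor_exclusion(self, rng):
        ann = random_annotation(rng, n_genes=40)
        domains = extend_domains(ann, PARAMS)
        basal = {d.gene_id: d.basal for d in domains}
        for d in domains:
            assert d.extended.start <= d.basal.start <= d.basal.end <= d.extended.end
            for other in domains:
                if other.gene_id == d.gene_id or other.chrom != d.chrom:
                    continue
                if other.basal.overlap(basal[d.gene_id]) > 0:
                    continue  # exempt per the non-overlap rule
                assert d.extended.overlap(other.basal) == 0


class TestAssociate:
    def test_midpoint_in_single_domain(self):
        ann = GenomeAnnotation(
            {"chr1": 1_000_000}, [make_gene("g", "chr1", "+", 100_000, 101_000)]
        )
        domains = extend_domains(ann, PARAMS)
        peak = make_peak("chr1", 60_000, 60_400, "p")
        (a,) = associate([peak], domains)
        assert (a.gene_id, a.part, a.distance) == ("g", "extended", -39_800)

    def test_midpoint_in_two_overlapping_basals(self):
        ann = GenomeAnnotation(
            {"chr1": 1_000_000},
            [
                make_gene("gA", "chr1", "+", 100_000, 101_500),
                make_gene("gB", "chr1", "+", 103_000, 104_500),  # basal [98k, 104k)
            ],
        )
        domains = extend_domains(ann, PARAMS)
        peak = make_peak("chr1", 99_000, 99_200, "p")  # midpoint 99,100
        got = associate([peak], domains)
        assert [(a.gene_id, a.part) for a in got] == [("gA", "basal"), ("gB", "basal")]

    def test_peak_outside_all_domains(self):
        ann = GenomeAnnotation(
            {"chr1": 1_000_000}, [make_gene("g", "chr1", "+", 100_000, 101_000)]
        )
        domains = extend_domains(ann, PARAMS)
        assert associate([make_peak("chr1", 500_000, 500_200, "p")], domains) == []

    def test_matches_allpairs_bruteforce(self, rng):
        for rep in range(10):
            ann = random_annotation(rng, n_genes=int(rng.integers(2, 50)))
            domains = extend_domains(ann, PARAMS)
            peaks = []
            for i in range(200):
                s = int(rng.integers(0, 299_000))
                peaks.append(
                    make_peak(
                        f"chr{int(rng.integers(1, 3))}", s, s + int(rng.integers(50, 900)), f"p{i:03d}"
                    )
                )
            assert associate(peaks, domains) == associate_bruteforce(peaks, domains)

    def test_distance_sign_minus_strand(self):
        ann = GenomeAnnotation(
            {"chr1": 1_000_000}, [make_gene("g", "chr1", "-", 99_000, 100_001)]
        )
        domains = extend_domains(ann, PARAMS)
        # 10 kb upstream of a '-' gene means higher coordinates
        peak = make_peak("chr1", 109_900, 110_100, "p")  # midpoint 110,000
        (a,) = associate([peak], domains)
        assert a.distance == -10_000


class TestWindowScreen:
    def _ann(self):
        return GenomeAnnotation(
            {"chr1": 1_000_000}, [make_gene("g", "chr1", "+", 100_000, 101_000)]
        )

    @pytest.mark.parametrize(
        "mid,expected",
        [
            (70_000, True),  # 30 kb upstream
            (130_000, False),  # 30 kb downstream, beyond the 20 kb cap
            (119_999, True),  # 19,999 bp downstream: inside half-open window
            (120_000, False),
        ],
    )
    def test_window_boundaries(self, mid, expected):
        peaks = [make_peak("chr1", mid - 100, mid + 100, "p")]
        got = genes_with_peaks_in_window(peaks, self._ann())
        assert ("g" in got) == expected

    def test_every_domain_association_is_in_window(self, rng):
        ann = random_annotation(rng, n_genes=40)
        domains = extend_domains(ann, PARAMS)
        peaks = []
        for i in range(300):
            s = int(rng.integers(0, 299_000))
            peaks.append(make_peak(f"chr{int(rng.integers(1, 3))}", s, s + 200, f"p{i}"))
        assoc = associate(peaks, domains)
        window = genes_with_peaks_in_window(peaks, ann, PARAMS.max_up, PARAMS.max_down)
        for a in assoc:
            assert a.peak_name in window.get(a.gene_id, [])
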