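"""Peak filtering: p-value cutoff semantics, coding-exon overlap, repeats."""

import itertools

import numpy as np
import pytest

from regdomain_integrator.genome_model import GenomeAnnotation, Interval, Peak
from regdomain_integrator.peak_qc import (
    QcConfig,
    RepeatPattern,
    default_repeat_patterns,
    filter_by_exon_overlap,
    filter_by_pvalue,
    filter_by_repeat_content,
    run_qc,
)

from conftest import make_gene, make_peak, plant, scaffold


class TestPvalueFilter:
    def test_strict_at_threshold(self):
        peaks = [make_peak("chr1", 0, 100, f"p{i}", p) for i, p in enumerate([3.9, 4.0, 4.1])]
        kept, n_removed = filter_by_pvalue(peaks, 4.0)
        assert [p.neg_log10_p for p in kept] == [4.1]
        assert n_removed == 2

    def test_threshold_zero_removes_only_scoreless(self):
        peaks = [make_peak("chr1", 0, 100, f"p{i}", p) for i, p in enumerate([0.0, 0.5, 7])]
        kept, _ = filter_by_pvalue(peaks, 0.0)
        assert [p.name for p in kept] == ["p1", "p2"]

    def test_counts_by_hand(self):
        peaks = [make_peak("chr1", 0, 100, f"p{i}", p) for i, p in enumerate([5.5, 6.2, 4.9])]
        kept, _ = filter_by_pvalue(peaks, 5.0)
        assert len(kept) == 2

    def test_monotone_in_threshold(self, rng):
        peaks = [
            make_peak("chr1", 0, 100, f"p{i}", float(p))
            for i, p in enumerate(rng.uniform(0, 10, 200))
        ]
        counts = [len(filter_by_pvalue(peaks, t)[0]) for t in np.linspace(0, 10, 25)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_empty_input(self):
        assert filter_by_pvalue([], 4.0) == ([], 0)


@pytest.fixture
def exon_annotation():
    # one gene with a non-UTR exon [1000, 2000) and a UTR fragment [500, 700)
    gene = make_gene(
        "g1", "chr1", "+", 500, 2000,
        exons=[(500, 700, "UTR"), (1000, 2000, "non-UTR")],
    )
    return GenomeAnnotation(chrom_sizes={"chr1": 100_000}, genes=[gene])


class TestExonOverlapFilter:
    def test_exactly_half_retained(self, exon_annotation):
        peak = make_peak("chr1", 900, 1100, "p")  # 100 of 200 bp in the exon
        kept, _ = filter_by_exon_overlap([peak], exon_annotation)
        assert kept == [peak]

    def test_more_than_half_removed(self, exon_annotation):
        peak = make_peak("chr1", 901, 1101, "p")  # 101 of 200 bp
        kept, _ = filter_by_exon_overlap([peak], exon_annotation)
        assert kept == []

    def test_utr_overlap_does_not_count(self, exon_annotation):
        peak = make_peak("chr1", 510, 710, "p")  # 190 bp on the UTR fragment
        kept, _ = filter_by_exon_overlap([peak], exon_annotation)
        assert kept == [peak]

    def test_unknown_chromosome_retained_with_warning(self, exon_annotation, caplog):
        peak = make_peak("chrUn", 0, 200, "p")
        with caplog.at_level("WARNING"):
            kept, _ = filter_by_exon_overlap([peak], exon_annotation)
        assert kept == [peak]
        assert any("absent" in r.message for r in caplog.records)

    def test_merged_exons_not_double_counted(self):
        # two genes with nested/overlapping exons over [1000, 2000)
        g1 = make_gene("g1", "chr1", "+", 1000, 2000, exons=[(1000, 2000, "non-UTR")])
        g2 = make_gene("g2", "chr1", "+", 1200, 1800, exons=[(1200, 1800, "non-UTR")])
        ann = GenomeAnnotation(chrom_sizes={"chr1": 100_000}, genes=[g1, g2])
        peak = make_peak("chr1", 900, 1100, "p")  # 100/200 = exactly half
        kept, _ = filter_by_exon_overlap([peak], ann)
        assert kept == [peak]

    def test_agrees_with_base_by_base_oracle(self, rng):
        chrom_len = 50_000
        genes = []
        for i in range(30):
            start = int(rng.integers(0, chrom_len - 3000))
            e1 = (start, start + int(rng.integers(100, 1000)), "non-UTR")
            e2s = e1[1] + int(rng.integers(50, 500))
            e2 = (e2s, e2s + int(rng.integers(100, 800)), rng.choice(["UTR", "non-UTR"]))
            genes.append(make_gene(f"g{i}", "chr1", "+", start, e2[1], exons=[e1, e2]))
        ann = GenomeAnnotation(chrom_sizes={"chr1": chrom_len}, genes=genes)
        coding = np.zeros(chrom_len, dtype=bool)
        for g in genes:
            for iv, flag in g.exons:
                if flag == "non-UTR":
                    coding[iv.start : iv.end] = True
        peaks = []
        for i in range(300):
            s = int(rng.integers(0, chrom_len - 400))
            peaks.append(make_peak("chr1", s, s + int(rng.integers(50, 400)), f"p{i}"))
        kept, _ = filter_by_exon_overlap(peaks, ann)
        expected = [
            p for p in peaks if coding[p.start : p.end].sum() / len(p.interval) <= 0.5
        ]
        assert kept == expected


class TestRepeatFilter:
    @pytest.mark.parametrize(
        "literal",
        [
            "CTCTCTCTCTCTCTCTCTCTCTCTCTCT",
            "AGAGAGAGAGAGAGAGAGAGA",  # bracket -> G
            "AGAGAGAGAAAGAGAGAGAGA",  # bracket -> A
            "GAGAGAAA",
        ],
    )
    def test_each_pattern_triggers_removal(self, literal):
        seq = plant(scaffold(400), 150, literal)
        genome = {"chr1": seq}
        peak = make_peak("chr1", 0, 400, "p")
        kept, _ = filter_by_repeat_content([peak], genome)
        assert kept == []

    def test_clean_sequence_retained(self):
        genome = {"chr1": scaffold(400)}
        kept, _ = filter_by_repeat_content([make_peak("chr1", 0, 400, "p")], genome)
        assert len(kept) == 1

    def test_n_matches_nothing(self):
        genome = {"chr1": "N" * 400}
        kept, _ = filter_by_repeat_content([make_peak("chr1", 0, 400, "p")], genome)
        assert len(kept) == 1

    def test_bracket_expansion(self):
        pat = RepeatPattern.from_string("AGAGAGAGA[GA]AGAGAGAGAGA")
        assert set(pat.literal_variants) == {
            "AGAGAGAGAGAGAGAGAGAGA",
            "AGAGAGAGAAAGAGAGAGAGA",
        }
        assert all(len(v) == 21 for v in pat.literal_variants)


def _planted_fixture():
    """10 peaks: 2 low-p, 2 exonic, 1 repeat decoy, 5 clean."""
    gene = make_gene("g1", "chr1", "+", 5_000, 6_000, exons=[(5_000, 6_000, "non-UTR")])
    ann = GenomeAnnotation(chrom_sizes={"chr1": 50_000}, genes=[gene])
    seq = scaffold(50_000)
    seq = plant(seq, 10_100, "GAGAGAAA")
    genome = {"chr1": seq}
    peaks = [
        make_peak("chr1", 100, 300, "lowp_1", 2.0),
        make_peak("chr1", 500, 700, "lowp_2", 3.9),
        make_peak("chr1", 5_050, 5_250, "exonic_1"),
        make_peak("chr1", 5_500, 5_700, "exonic_2"),
        make_peak("chr1", 10_000, 10_200, "repeat_1"),
    ] + [make_peak("chr1", 20_000 + 1_000 * i, 20_200 + 1_000 * i, f"clean_{i}") for i in range(5)]
    return peaks, ann, genome


class TestRunQc:
    def test_planted_fixture_reasons(self):
        peaks, ann, genome = _planted_fixture()
        kept, report = run_qc(peaks, ann, genome)
        assert report.n_retained == 5
        assert {p.name for p in kept} == {f"clean_{i}" for i in range(5)}
        assert report.reasons == {
            "lowp_1": {"pvalue"},
            "lowp_2": {"pvalue"},
            "exonic_1": {"exon_overlap"},
            "exonic_2": {"exon_overlap"},
            "repeat_1": {"repeat"},
        }
        assert (report.n_removed_pvalue, report.n_removed_exon, report.n_removed_repeat) == (2, 2, 1)

    def test_all_pass(self):
        peaks, ann, genome = _planted_fixture()
        clean = [p for p in peaks if p.name.startswith("clean")]
        kept, report = run_qc(clean, ann, genome)
        assert report.n_retained == report.n_input == len(clean)
        assert report.reasons == {}

    def test_empty_input(self):
        _, ann, genome = _planted_fixture()
        kept, report = run_qc([], ann, genome)
        assert kept == []
        assert report.n_input == report.n_retained == 0

    def test_retained_set_is_filter_order_invariant(self):
        peaks, ann, genome = _planted_fixture()
        filters = {
            "pvalue": lambda ps: filter_by_pvalue(ps, 4.0)[0],
            "exon": lambda ps: filter_by_exon_overlap(ps, ann)[0],
            "repeat": lambda ps: filter_by_repeat_content(ps, genome)[0],
        }
        results = set()
        for order in itertools.permutations(filters.values()):
            current = peaks
            for f in order:
                current = f(current)
            results.add(frozenset(p.name for p in current))
        assert len(results) == 1

    def test_exhaustive_flags_scans_all_filters(self):
        peaks, ann, genome = _planted_fixture()
        # make one low-p peak also exonic: it should carry both reasons
        extra = make_peak("chr1", 5_300, 5_400, "lowp_exonic", 1.0)
        cfg = QcConfig(exhaustive_flags=True)
        _, report = run_qc(peaks + [extra], ann, genome, cfg)
        assert report.reasons["lowp_exonic"] == {"pvalue", "exon_overlap"}
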