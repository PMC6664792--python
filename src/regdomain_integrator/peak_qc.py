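"""Post-peak-calling filters: p-value cutoff, coding-exon overlap, simple repeats.

The filters reduce a raw MACS-style peak list to the analysis set. Each filter
is a pure predicate over one peak, so the retained set is independent of
filter order; only the attribution of removal reasons depends on it (a peak
removed early is not scanned by later filters unless ``exhaustive_flags``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np

from .genome_model import GenomeAnnotation, Peak, merged_non_utr_exons

logger = logging.getLogger(__name__)

#: Simple-repeat patterns removed from the peak set. The bracketed position in
#: the second pattern is a one-base G/A character class, expanded to two 21-mer
#: literals. The third, 8 bp, pattern is deliberately permissive; see docs.
DEFAULT_REPEAT_STRINGS = (
    "CTCTCTCTCTCTCTCTCTCTCTCTCTCT",
    "AGAGAGAGA[GA]AGAGAGAGAGA",
    "GAGAGAAA",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RepeatPattern:
    """A repeat with bracketed single-base alternatives expanded to literals."""

    pattern_id: str
    literal_variants: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.literal_variants:
            raise ValueError(f"{self.pattern_id}: no literal variants")
        for v in self.literal_variants:
            if set(v) - set("ACGT"):
                raise ValueError(f"{self.pattern_id}: non-ACGT variant {v!r}")

    @classmethod
    def from_string(cls, raw: str, pattern_id: str | None = None) -> "RepeatPattern":
        """Parse e.g. ``AGAGAGAGA[GA]AGAGAGAGAGA`` -> two literals."""
        text = raw.replace(" ", "").upper()
        segments: list[tuple[str, ...]] = []
        i = 0
        while i < len(text):
            if text[i] == "[":
                j = text.index("]", i)
                segments.append(tuple(text[i + 1 : j]))
                i = j + 1
            else:
                segments.append((text[i],))
                i += 1
        variants = tuple("".join(combo) for combo in product(*segments))
        return cls(pattern_id=pattern_id or raw, literal_variants=variants)


def default_repeat_patterns() -> list[RepeatPattern]:
    return [RepeatPattern.from_string(s) for s in DEFAULT_REPEAT_STRINGS]


@dataclass
class FilterReport:
    """Tally of the peak-filtering funnel plus per-peak removal reasons."""

    n_input: int = 0
    n_removed_pvalue: int = 0
    n_removed_exon: int = 0
    n_removed_repeat: int = 0
    n_retained: int = 0
    reasons: dict[str, set[str]] = field(default_factory=dict)

    def flag(self, peak_name: str, reason: str) -> None:
        self.reasons.setdefault(peak_name, set()).add(reason)

    def validate(self) -> None:
        removed = len(self.reasons)
        if self.n_retained != self.n_input - removed:
            raise AssertionError(
                f"inconsistent report: {self.n_input} in, {removed} flagged, "
                f"{self.n_retained} retained"
            )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_pvalue": self.n_removed_pvalue,
            "n_removed_exon": self.n_removed_exon,
            "n_removed_repeat": self.n_removed_repeat,
            "n_retained": self.n_retained,
            "reasons": {k: sorted(v) for k, v in sorted(self.reasons.items())},
        }


class SequenceSource(Protocol):
    """Anything indexable as ``source[chrom][start:end]`` yielding sequence."""

    def __getitem__(self, chrom: str): ...


def fetch_sequence(genome: SequenceSource, chrom: str, start: int, end: int) -> str:
    """Extract an uppercase forward-strand sequence from a FASTA-like source."""
    record = genome[chrom]
    seq = record[start:end]
    return str(seq).upper()


# ---------------------------------------------------------------------------
# Individual filters (pure predicates)
# ---------------------------------------------------------------------------


def filter_by_pvalue(
    peaks: Sequence[Peak], threshold_neg_log10_p: float, strict: bool = True
) -> tuple[list[Peak], int]:
    """Keep peaks with -log10 p above the cutoff (strict > by default).

    The strict inequality mirrors MACS "cutoff" semantics: a peak exactly at
    the threshold is removed.
    """
    if threshold_neg_log10_p < 0:
        raise ValueError("threshold must be >= 0")
    if strict:
        kept = [p for p in peaks if p.neg_log10_p > threshold_neg_log10_p]
    else:
        kept = [p for p in peaks if p.neg_log10_p >= threshold_neg_log10_p]
    return kept, len(peaks) - len(kept)


class _ExonCoverage:
    """Per-chromosome merged non-UTR exon intervals with O(log n) overlap."""

    def __init__(self, annotation: GenomeAnnotation):
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, merged in merged_non_utr_exons(annotation).items():
            starts = np.array([s for s, _ in merged], dtype=np.int64)
            ends = np.array([e for _, e in merged], dtype=np.int64)
            cum = np.concatenate([[0], np.cumsum(ends - starts)])
            self._index[chrom] = (starts, ends, cum)

    def coverage_before(self, chrom: str, pos: int) -> int:
        """Total merged exonic bases in [0, pos)."""
        starts, ends, cum = self._index[chrom]
        i = int(np.searchsorted(starts, pos, side="right"))
        total = int(cum[i])
        if i > 0 and ends[i - 1] > pos:  # pos falls inside interval i-1
            total -= int(ends[i - 1] - pos)
        return total

    def overlap(self, chrom: str, start: int, end: int) -> int:
        if chrom not in self._index:
            return 0
        return self.coverage_before(chrom, end) - self.coverage_before(chrom, start)

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._index


def filter_by_exon_overlap(
    peaks: Sequence[Peak],
    annotation: GenomeAnnotation,
    max_fraction: float = 0.5,
) -> tuple[list[Peak], int]:
    """Remove peaks overlapping the merged non-UTR exon union by more than
    ``max_fraction`` of their own length (strictly more; exactly half is kept).

    UTR-flagged exonic bases never count. Peaks on chromosomes absent from the
    annotation are retained with a warning.
    """
    if not (0 <= max_fraction <= 1):
        raise ValueError("max_fraction must be in [0, 1]")
    cov = _ExonCoverage(annotation)
    kept: list[Peak] = []
    warned: set[str] = set()
    for p in peaks:
        if p.chrom not in annotation.chrom_sizes and p.chrom not in warned:
            logger.warning("peak %s: chromosome %s absent from annotation", p.name, p.chrom)
            warned.add(p.chrom)
        ov = cov.overlap(p.chrom, p.start, p.end)
        if ov / len(p.interval) > max_fraction:
            continue
        kept.append(p)
    return kept, len(peaks) - len(kept)


def filter_by_repeat_content(
    peaks: Sequence[Peak],
    genome: SequenceSource,
    patterns: Iterable[RepeatPattern] | None = None,
    both_strands: bool = False,
) -> tuple[list[Peak], int]:
    """Remove peaks whose forward-strand sequence contains any repeat literal.

    The default patterns are CT/AG runs whose reverse complements are covered
    by the listed set on the opposite strand; ``both_strands`` additionally
    scans the reverse complement explicitly.
    """
    pats = list(patterns) if patterns is not None else default_repeat_patterns()
    variants = [v for pat in pats for v in pat.literal_variants]
    kept: list[Peak] = []
    for p in peaks:
        seq = fetch_sequence(genome, p.chrom, p.start, p.end)
        hit = any(v in seq for v in variants)
        if not hit and both_strands:
            rc = revcomp(seq)
            hit = any(v in rc for v in variants)
        if not hit:
            kept.append(p)
    return kept, len(peaks) - len(kept)


# ---------------------------------------------------------------------------
# Combined QC
# ---------------------------------------------------------------------------


@dataclass
class QcConfig:
    threshold_neg_log10_p: float = 4.0  # p < 1e-4
    max_exon_fraction: float = 0.5
    repeat_patterns: tuple[RepeatPattern, ...] = tuple(
        RepeatPattern.from_string(s) for s in DEFAULT_REPEAT_STRINGS
    )
    strict_pvalue: bool = True
    repeat_both_strands: bool = False
    exhaustive_flags: bool = False


def run_qc(
    peaks: Sequence[Peak],
    annotation: GenomeAnnotation,
    genome: SequenceSource,
    config: QcConfig | None = None,
) -> tuple[list[Peak], FilterReport]:
    """Apply the p-value, exon-overlap, and repeat filters in that order.

    With ``exhaustive_flags`` every filter is evaluated for every input peak so
    the removal-reason map is complete; otherwise a peak removed by an earlier
    filter is not scanned by later ones.
    """
    cfg = config or QcConfig()
    report = FilterReport(n_input=len(peaks))

    def apply(
        current: Sequence[Peak], predicate, reason: str
    ) -> tuple[list[Peak], int]:
        scan = peaks if cfg.exhaustive_flags else current
        passed = {p.name for p in predicate(scan)}
        removed_now = 0
        out: list[Peak] = []
        for p in current:
            if p.name in passed:
                out.append(p)
            else:
                removed_now += 1
        for p in scan:
            if p.name not in passed:
                report.flag(p.name, reason)
        return out, removed_now

    current, n = apply(
        peaks,
        lambda ps: filter_by_pvalue(ps, cfg.threshold_neg_log10_p, cfg.strict_pvalue)[0],
        "pvalue",
    )
    report.n_removed_pvalue = n
    current, n = apply(
        current,
        lambda ps: filter_by_exon_overlap(ps, annotation, cfg.max_exon_fraction)[0],
        "exon_overlap",
    )
    report.n_removed_exon = n
    current, n = apply(
        current,
        lambda ps: filter_by_repeat_content(
            ps, genome, cfg.repeat_patterns, cfg.repeat_both_strands
        )[0],
        "repeat",
    )
    report.n_removed_repeat = n
    report.n_retained = len(current)
    report.validate()
    return current, report
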