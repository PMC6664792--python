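"""IUPAC consensus scanning, CAN/NC peak classification, and SMAD-FoxH1 pairing.

The forkhead factor FoxH1 binds the canonical consensus AATMCACA (M = A/C).
A peak containing the consensus on either strand is canonical (CAN); one bound
without it is non-canonical (NC). Nodal-responsive CAN sites typically carry a
SMAD-binding element a short distance 5' of the FoxH1 word; ``find_smad_pairs``
flags peaks where a SMAD word ends within ``max_gap`` bases 5' of a FoxH1 hit,
with 5'/3' defined by the FoxH1 hit's strand.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

from .genome_model import Peak
from .peak_qc import SequenceSource, fetch_sequence, revcomp

logger = logging.getLogger(__name__)

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}

#: Canonical FoxH1 forkhead-domain consensus.
FOXH1_CONSENSUS = "AATMCACA"

#: Default SMAD motif: the palindromic Smad-binding element. The proprietary
#: Genomatix SMAD matrices are not distributable; users with position weight
#: matrices can supply their own consensus strings or use the PWM mode.
DEFAULT_SMAD_MOTIFS = ("GTCTAGAC",)


@dataclass(frozen=True)
class ConsensusMotif:
    """A degenerate DNA motif in IUPAC one-letter code."""

    motif_id: str
    iupac: str

    def __post_init__(self) -> None:
        bad = set(self.iupac.upper()) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"motif {self.motif_id}: invalid IUPAC characters {bad}")
        if len(self.iupac) < 4:
            raise ValueError(f"motif {self.motif_id}: length must be >= 4")
        object.__setattr__(self, "iupac", self.iupac.upper())

    def __len__(self) -> int:
        return len(self.iupac)

    def reverse_complement(self) -> "ConsensusMotif":
        rc = "".join(_IUPAC_COMPLEMENT[c] for c in reversed(self.iupac))
        return ConsensusMotif(motif_id=self.motif_id, iupac=rc)

    def n_words(self) -> int:
        n = 1
        for c in self.iupac:
            n *= len(IUPAC_CODES[c])
        return n


def expand_iupac(motif: ConsensusMotif) -> set[str]:
    """All literal words matching the motif (size = product of degeneracies)."""
    return {"".join(w) for w in product(*(IUPAC_CODES[c] for c in motif.iupac))}


def _iupac_regex(iupac: str) -> re.Pattern[str]:
    # character classes never include N of the sequence, so sequence N matches nothing
    parts = []
    for c in iupac:
        opts = IUPAC_CODES[c]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("(?=(" + "".join(parts) + "))")


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; ``start`` is the window start in forward coords."""

    chrom: str
    start: int
    strand: str
    motif_id: str
    matched_word: str

    @property
    def end(self) -> int:
        return self.start + len(self.matched_word)


def scan_consensus(
    sequence: str,
    motif: ConsensusMotif,
    both_strands: bool = True,
    chrom: str = "",
    offset: int = 0,
) -> list[MotifHit]:
    """All matches of the motif in ``sequence`` (overlaps included).

    Reverse-strand hits are matches of the reverse-complemented pattern on the
    forward sequence, reported at their forward-strand window start with
    strand '-' and the matched word given 5'->3' on the minus strand. Results
    are sorted by start, '+' before '-'. ``offset`` shifts reported positions
    into genomic coordinates.
    """
    seq = sequence.upper()
    hits: list[MotifHit] = []
    for m in _iupac_regex(motif.iupac).finditer(seq):
        hits.append(
            MotifHit(
                chrom=chrom,
                start=offset + m.start(),
                strand="+",
                motif_id=motif.motif_id,
                matched_word=m.group(1),
            )
        )
    if both_strands:
        rc_pattern = motif.reverse_complement()
        for m in _iupac_regex(rc_pattern.iupac).finditer(seq):
            hits.append(
                MotifHit(
                    chrom=chrom,
                    start=offset + m.start(),
                    strand="-",
                    motif_id=motif.motif_id,
                    matched_word=revcomp(m.group(1)),
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


@dataclass
class PeakClassification:
    """CAN/NC call for one peak with the supporting motif hits."""

    peak: Peak
    foxh1_hits: list[MotifHit] = field(default_factory=list)
    smad_paired: bool = False
    smad_hits: list[MotifHit] = field(default_factory=list)

    @property
    def peak_name(self) -> str:
        return self.peak.name

    @property
    def peak_class(self) -> str:
        return "CAN" if self.foxh1_hits else "NC"


def classify_peaks(
    peaks: Sequence[Peak],
    genome: SequenceSource,
    motif: ConsensusMotif | None = None,
    both_strands: bool = True,
) -> list[PeakClassification]:
    """Call each peak CAN (>= 1 consensus hit inside the interval) or NC."""
    m = motif or ConsensusMotif("FoxH1", FOXH1_CONSENSUS)
    out: list[PeakClassification] = []
    for p in peaks:
        seq = fetch_sequence(genome, p.chrom, p.start, p.end)
        hits = scan_consensus(seq, m, both_strands, chrom=p.chrom, offset=p.start)
        out.append(PeakClassification(peak=p, foxh1_hits=hits))
    return out


def find_smad_pairs(
    classifications: Sequence[PeakClassification],
    genome: SequenceSource,
    smad_motifs: Sequence[ConsensusMotif] | None = None,
    max_gap: int = 100,
    min_gap: int = 0,
    chrom_sizes: dict[str, int] | None = None,
) -> list[PeakClassification]:
    """Flag CAN peaks where a SMAD word sits within ``max_gap`` bp 5' of a
    FoxH1 hit (5' relative to the FoxH1 hit's strand).

    For a '+' FoxH1 hit at [f0, f1) a SMAD hit [s0, s1) pairs when
    ``min_gap <= f0 - s1 <= max_gap``; the '-' case is the mirror
    ``min_gap <= s0 - f1 <= max_gap``. The SMAD scan window extends ``max_gap``
    plus the SMAD motif length beyond the peak so near-edge FoxH1 hits see
    their flanks. Classifications are updated in place and returned.
    """
    if smad_motifs is None:
        smad_motifs = [
            ConsensusMotif(f"SMAD_{i}", s) for i, s in enumerate(DEFAULT_SMAD_MOTIFS)
        ]
    if not smad_motifs:
        logger.warning("no SMAD motifs supplied; smad_paired is false everywhere")
        for c in classifications:
            c.smad_paired = False
            c.smad_hits = []
        return list(classifications)

    margin = max_gap + max(len(m) for m in smad_motifs)
    for c in classifications:
        c.smad_hits = []
        c.smad_paired = False
        if not c.foxh1_hits:
            continue
        p = c.peak
        lo = max(0, p.start - margin)
        hi = p.end + margin
        if chrom_sizes and p.chrom in chrom_sizes:
            hi = min(hi, chrom_sizes[p.chrom])
        else:
            try:
                hi = min(hi, len(genome[p.chrom]))
            except TypeError:
                pass
        seq = fetch_sequence(genome, p.chrom, lo, hi)
        smad_hits: list[MotifHit] = []
        for m in smad_motifs:
            smad_hits.extend(scan_consensus(seq, m, True, chrom=p.chrom, offset=lo))
        paired = False
        for fox in c.foxh1_hits:
            for smad in smad_hits:
                if fox.strand == "+":
                    gap = fox.start - smad.end
                else:
                    gap = smad.start - fox.end
                if min_gap <= gap <= max_gap:
                    paired = True
                    if smad not in c.smad_hits:
                        c.smad_hits.append(smad)
        c.smad_paired = paired
    return list(classifications)
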