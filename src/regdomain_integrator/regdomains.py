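"""GREAT-style basal + extension regulatory domains and peak-gene association.

Every gene gets an unconditional basal domain (default 5 kb upstream, 1 kb
downstream of the TSS, TSS base included downstream); basal domains of
neighboring genes may overlap. The basal domain is then extended in both
directions up to the nearest edge of a *non-overlapping* neighbor basal
domain, a directional cap (default 50 kb upstream / 20 kb downstream of the
TSS), or the chromosome edge — whichever is closest. Peaks falling inside a
gene's domain associate with that gene; a peak can associate with several
genes where domains overlap.

"Upstream"/"downstream" are gene-oriented: for a '-' strand gene upstream
means higher genomic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

from .genome_model import GeneModel, GenomeAnnotation, Interval, Peak


@dataclass(frozen=True)
class DomainParams:
    basal_up: int = 5_000
    basal_down: int = 1_000
    max_up: int = 50_000
    max_down: int = 20_000

    def __post_init__(self) -> None:
        if min(self.basal_up, self.basal_down, self.max_up, self.max_down) < 0:
            raise ValueError("domain distances must be >= 0")
        if self.basal_up > self.max_up or self.basal_down > self.max_down:
            raise ValueError("basal extent must not exceed the directional caps")


@dataclass(frozen=True)
class RegulatoryDomain:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    basal: Interval
    extended: Interval
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (
            self.extended.start <= self.basal.start
            and self.basal.end <= self.extended.end
        ):
            raise ValueError(f"{self.gene_id}: basal not contained in extended")


@dataclass(frozen=True)
class PeakGeneAssociation:
    peak_name: str
    gene_id: str
    part: Literal["basal", "extended"]
    distance: int  # signed bp from TSS, negative = upstream in gene orientation


def build_basal(
    gene: GeneModel, params: DomainParams, chrom_len: int
) -> tuple[Interval, frozenset[str]]:
    """Strand-oriented basal window around the TSS, clipped to the chromosome.

    '+' strand: [TSS - basal_up, TSS + basal_down); '-' strand mirror:
    [TSS - basal_down + 1, TSS + basal_up + 1). The TSS base itself falls in
    the downstream portion on both strands.
    """
    if gene.strand == "+":
        lo = gene.tss - params.basal_up
        hi = gene.tss + params.basal_down
    else:
        lo = gene.tss - params.basal_down + 1
        hi = gene.tss + params.basal_up + 1
    flags: set[str] = set()
    if lo < 0 or hi > chrom_len:
        flags.add("clipped_at_chrom_edge")
    return Interval(gene.chrom, max(0, lo), min(chrom_len, hi)), frozenset(flags)


def _caps(gene: GeneModel, params: DomainParams, chrom_len: int) -> tuple[int, int]:
    """Genomic [left, right) bounds implied by the directional caps."""
    if gene.strand == "+":
        lo = gene.tss - params.max_up
        hi = gene.tss + params.max_down
    else:
        lo = gene.tss - params.max_down + 1
        hi = gene.tss + params.max_up + 1
    return max(0, lo), min(chrom_len, hi)


def extend_domains(
    annotation: GenomeAnnotation, params: DomainParams | None = None
) -> list[RegulatoryDomain]:
    """Build basal + extended domains for every gene.

    In each direction the extension stops at the nearest of: the edge of
    another gene's basal domain that does not overlap this gene's own basal
    (domains may abut but never overlap such a neighbor), the directional cap,
    or the chromosome edge. Neighbor basals that overlap the gene's own basal
    are skipped per the non-overlap requirement. Output order follows input
    gene order; the result is independent of it.
    """
    params = params or DomainParams()
    basal: dict[str, tuple[Interval, frozenset[str]]] = {}
    for gene in annotation.genes:
        basal[gene.gene_id] = build_basal(
            gene, params, annotation.chrom_sizes[gene.chrom]
        )

    # per-chromosome sorted basal edge lists for nearest-neighbor queries
    by_chrom: dict[str, list[tuple[str, Interval]]] = {}
    for gene in annotation.genes:
        by_chrom.setdefault(gene.chrom, []).append((gene.gene_id, basal[gene.gene_id][0]))

    out: list[RegulatoryDomain] = []
    for gene in annotation.genes:
        chrom_len = annotation.chrom_sizes[gene.chrom]
        b, clip_flags = basal[gene.gene_id]
        cap_lo, cap_hi = _caps(gene, params, chrom_len)
        left, right = cap_lo, cap_hi
        flags: set[str] = set(clip_flags)
        left_reason = "cap"
        right_reason = "cap"
        if cap_lo == 0 and gene.tss - (params.max_up if gene.strand == "+" else params.max_down - 1) < 0:
            left_reason = "chrom_edge"
        if cap_hi == chrom_len and gene.tss + (params.max_down if gene.strand == "+" else params.max_up + 1) > chrom_len:
            right_reason = "chrom_edge"

        for other_id, ob in by_chrom[gene.chrom]:
            if other_id == gene.gene_id:
                continue
            if ob.overlap(b) > 0:  # overlapping neighbor basal: skipped
                continue
            if ob.end <= b.start and ob.end > left:
                left = ob.end
                left_reason = "neighbor"
            if ob.start >= b.end and ob.start < right:
                right = ob.start
                right_reason = "neighbor"

        # guarantee basal containment (caps cannot violate it by construction)
        left = min(left, b.start)
        right = max(right, b.end)

        up_is_left = gene.strand == "+"
        if left_reason == "neighbor":
            flags.add("limited_by_neighbor_up" if up_is_left else "limited_by_neighbor_down")
        elif left_reason == "cap":
            flags.add("capped_up" if up_is_left else "capped_down")
        else:
            flags.add("clipped_at_chrom_edge")
        if right_reason == "neighbor":
            flags.add("limited_by_neighbor_down" if up_is_left else "limited_by_neighbor_up")
        elif right_reason == "cap":
            flags.add("capped_down" if up_is_left else "capped_up")
        else:
            flags.add("clipped_at_chrom_edge")

        out.append(
            RegulatoryDomain(
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                strand=gene.strand,
                tss=gene.tss,
                basal=b,
                extended=Interval(gene.chrom, left, right),
                flags=frozenset(flags),
            )
        )
    return out


def extend_domains_bruteforce(
    annotation: GenomeAnnotation, params: DomainParams | None = None
) -> list[RegulatoryDomain]:
    """Quadratic reference: per gene and direction, scan every other basal.

    Kept deliberately independent of :func:`extend_domains` as a test oracle.
    """
    params = params or DomainParams()
    all_basal = [
        (g, build_basal(g, params, annotation.chrom_sizes[g.chrom])[0])
        for g in annotation.genes
    ]
    out: list[RegulatoryDomain] = []
    for gene, b in all_basal:
        chrom_len = annotation.chrom_sizes[gene.chrom]
        cap_lo, cap_hi = _caps(gene, params, chrom_len)
        left_candidates = [cap_lo]
        right_candidates = [cap_hi]
        for other, ob in all_basal:
            if other.gene_id == gene.gene_id or other.chrom != gene.chrom:
                continue
            if ob.overlap(b) > 0:
                continue
            if ob.end <= b.start:
                left_candidates.append(ob.end)
            if ob.start >= b.end:
                right_candidates.append(ob.start)
        left = min(max(left_candidates), b.start)
        right = max(min(right_candidates), b.end)
        out.append(
            RegulatoryDomain(
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                strand=gene.strand,
                tss=gene.tss,
                basal=b,
                extended=Interval(gene.chrom, left, right),
            )
        )
    return out


def associate(
    peaks: Sequence[Peak],
    domains: Sequence[RegulatoryDomain],
    mode: Literal["midpoint", "any_overlap"] = "midpoint",
) -> list[PeakGeneAssociation]:
    """Associate peaks with genes whose regulatory domain they fall in.

    ``midpoint`` (default, GREAT-style): the peak midpoint
    floor((start+end)/2) must lie inside the domain. ``any_overlap``: any
    overlap with the extended domain counts. A peak may associate with
    several genes. Output sorted by peak name then gene id.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for d in domains:
        trees.setdefault(d.chrom, IntervalTree()).addi(
            d.extended.start, d.extended.end, d
        )
    out: list[PeakGeneAssociation] = []
    for p in peaks:
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        if mode == "midpoint":
            mid = p.midpoint
            matches = tree[mid]
        elif mode == "any_overlap":
            matches = tree[p.start : p.end]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        for m in matches:
            d: RegulatoryDomain = m.data
            ref = p.midpoint
            distance = ref - d.tss if d.strand == "+" else d.tss - ref
            part: Literal["basal", "extended"] = (
                "basal" if d.basal.contains(p.midpoint) else "extended"
            )
            out.append(
                PeakGeneAssociation(
                    peak_name=p.name, gene_id=d.gene_id, part=part, distance=distance
                )
            )
    out.sort(key=lambda a: (a.peak_name, a.gene_id))
    return out


def associate_bruteforce(
    peaks: Sequence[Peak], domains: Sequence[RegulatoryDomain]
) -> list[PeakGeneAssociation]:
    """All-pairs midpoint association, as an oracle for :func:`associate`."""
    out: list[PeakGeneAssociation] = []
    for p in peaks:
        for d in domains:
            if d.chrom != p.chrom or not d.extended.contains(p.midpoint):
                continue
            distance = (
                p.midpoint - d.tss if d.strand == "+" else d.tss - p.midpoint
            )
            part: Literal["basal", "extended"] = (
                "basal" if d.basal.contains(p.midpoint) else "extended"
            )
            out.append(
                PeakGeneAssociation(
                    peak_name=p.name, gene_id=d.gene_id, part=part, distance=distance
                )
            )
    out.sort(key=lambda a: (a.peak_name, a.gene_id))
    return out


def genes_with_peaks_in_window(
    peaks: Sequence[Peak],
    annotation: GenomeAnnotation,
    up: int = 50_000,
    down: int = 20_000,
) -> dict[str, list[str]]:
    """Fixed gene-oriented TSS window screen (no neighbor limiting).

    A peak counts for a gene when its midpoint lies within ``up`` bp upstream
    to ``down`` bp downstream of the TSS. This is the simple genome screen;
    the basal+extension rule is :func:`extend_domains` + :func:`associate`.
    """
    out: dict[str, list[str]] = {}
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for gene in annotation.genes:
        chrom_len = annotation.chrom_sizes[gene.chrom]
        if gene.strand == "+":
            lo, hi = gene.tss - up, gene.tss + down
        else:
            lo, hi = gene.tss - down + 1, gene.tss + up + 1
        lo, hi = max(0, lo), min(chrom_len, hi)
        hits = [p.name for p in by_chrom.get(gene.chrom, []) if lo <= p.midpoint < hi]
        if hits:
            out[gene.gene_id] = sorted(hits)
    return out
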