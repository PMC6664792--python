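"""Genomic coordinate model and readers/writers for standard interval formats.

All internal coordinates are 0-based half-open (BED convention); 1-based
inclusive formats (GFF3/GTF) are converted at the I/O boundary only. A gene is
represented by a single :class:`GeneModel` whose exons are split into UTR and
non-UTR (CDS-overlapping) fragments, because downstream peak filtering
distinguishes coding-exon overlap from UTR overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

logger = logging.getLogger(__name__)

Strand = Literal["+", "-"]
UtrFlag = Literal["UTR", "non-UTR"]


class AnnotationError(ValueError):
    """Raised for malformed or internally inconsistent annotation input."""


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak call with a -log10 p-value score.

    ``summit_offset`` is the distance of the point-source summit from the peak
    start (narrowPeak column 10), if known.
    """

    interval: Interval
    name: str
    neg_log10_p: float = 0.0
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.neg_log10_p) or self.neg_log10_p < 0:
            raise AnnotationError(
                f"peak {self.name}: neg_log10_p must be finite and >= 0"
            )
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise AnnotationError(
                f"peak {self.name}: summit offset {self.summit_offset} outside peak"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def midpoint(self) -> int:
        return self.interval.midpoint


@dataclass(frozen=True)
class GeneModel:
    """One gene with TSS, span, and UTR-flagged exon fragments.

    ``exons`` holds non-overlapping (interval, flag) fragments; an annotated
    exon that is part UTR, part CDS appears as two fragments.
    """

    gene_id: str
    chrom: str
    strand: Strand
    tss: int
    span: Interval
    exons: tuple[tuple[Interval, UtrFlag], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        expected_tss = self.span.start if self.strand == "+" else self.span.end - 1
        if self.tss != expected_tss:
            raise AnnotationError(
                f"gene {self.gene_id}: tss {self.tss} inconsistent with span "
                f"{self.span.start}-{self.span.end} on {self.strand}"
            )
        prev_end = -1
        for iv, _flag in sorted(self.exons, key=lambda e: e[0].start):
            if iv.chrom != self.chrom:
                raise AnnotationError(f"gene {self.gene_id}: exon on wrong chromosome")
            if iv.start < self.span.start or iv.end > self.span.end:
                raise AnnotationError(
                    f"gene {self.gene_id}: exon {iv.start}-{iv.end} outside span"
                )
            if iv.start < prev_end:
                raise AnnotationError(f"gene {self.gene_id}: overlapping exons")
            prev_end = iv.end

    def exon_fragments(self, flag: UtrFlag | None = None) -> list[Interval]:
        return [iv for iv, f in self.exons if flag is None or f == flag]


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus gene models, validated against each other."""

    chrom_sizes: dict[str, int]
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        for gene in self.genes:
            size = self.chrom_sizes.get(gene.chrom)
            if size is None:
                raise AnnotationError(
                    f"gene {gene.gene_id}: chromosome {gene.chrom} not in chrom_sizes"
                )
            if gene.span.end > size:
                raise AnnotationError(
                    f"gene {gene.gene_id}: span exceeds chromosome length {size}"
                )

    def genes_by_chrom(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for gene in self.genes:
            out.setdefault(gene.chrom, []).append(gene)
        return out


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Parse a two-column ``<chrom>\\t<length>`` file.

    Raises on duplicate chromosome names and non-positive or non-integer
    lengths.
    """
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise AnnotationError(f"{path} line {lineno}: expected two columns")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise AnnotationError(
                    f"{path} line {lineno}: non-integer length {fields[1]!r}"
                ) from None
            if length <= 0:
                raise AnnotationError(f"{path} line {lineno}: non-positive length")
            if name in sizes:
                raise AnnotationError(f"{path} line {lineno}: duplicate chromosome {name}")
            sizes[name] = length
    return sizes


def _split_exons_by_utr(
    exons: list[Interval], utrs: list[Interval]
) -> tuple[tuple[Interval, UtrFlag], ...]:
    """Split exon intervals into UTR and non-UTR fragments.

    The non-UTR fragments are exonic bases minus annotated UTR bases, i.e. the
    CDS-overlapping portion of each exon.
    """
    out: list[tuple[Interval, UtrFlag]] = []
    for exon in sorted(exons, key=lambda iv: iv.start):
        cut_points = {exon.start, exon.end}
        for u in utrs:
            if u.overlap(exon):
                cut_points.add(max(u.start, exon.start))
                cut_points.add(min(u.end, exon.end))
        edges = sorted(cut_points)
        for a, b in zip(edges, edges[1:]):
            frag = Interval(exon.chrom, a, b)
            flag: UtrFlag = (
                "UTR" if any(u.overlap(frag) == len(frag) for u in utrs) else "non-UTR"
            )
            out.append((frag, flag))
    # merge adjacent fragments with identical flags for compactness
    merged: list[tuple[Interval, UtrFlag]] = []
    for frag, flag in out:
        if merged and merged[-1][1] == flag and merged[-1][0].end == frag.start:
            prev = merged.pop()
            frag = Interval(frag.chrom, prev[0].start, frag.end)
        merged.append((frag, flag))
    return tuple(merged)


_UTR_FEATURES = {
    "five_prime_UTR",
    "three_prime_UTR",
    "five_prime_utr",
    "three_prime_utr",
    "UTR",
}


def read_gene_annotation(
    path: str | Path,
    dialect: Literal["gff3", "gtf", "bed12"],
    chrom_sizes: Mapping[str, int] | None = None,
    transcript_mode: Literal["most_distal", "per_transcript"] = "most_distal",
) -> GenomeAnnotation:
    """Read gene models from GFF3/GTF (via gffutils) or BED12.

    GFF/GTF 1-based inclusive coordinates are converted to 0-based half-open.
    With ``most_distal`` (default) genes with several transcripts collapse to
    the transcript whose TSS is most distal in the direction of transcription;
    ``per_transcript`` emits one model per transcript (ids ``gene:transcript``).
    """
    if dialect == "bed12":
        genes = _read_bed12(path)
    elif dialect in ("gff3", "gtf"):
        genes = _read_gff_like(path, dialect, transcript_mode)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if chrom_sizes is None:
        chrom_sizes = {}
        for g in genes:
            chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.span.end)
    return GenomeAnnotation(chrom_sizes=dict(chrom_sizes), genes=genes)


def _read_gff_like(
    path: str | Path,
    dialect: Literal["gff3", "gtf"],
    transcript_mode: Literal["most_distal", "per_transcript"],
) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.id
        if gene.strand not in ("+", "-"):
            raise AnnotationError(f"gene {gene_id}: unknown strand {gene.strand!r}")
        span = Interval(gene.seqid, gene.start - 1, gene.end)
        transcripts = list(db.children(gene, featuretype=("mRNA", "transcript"), level=1))
        candidates: list[tuple[str, list[Interval], list[Interval], Interval]] = []
        if transcripts:
            for tx in transcripts:
                exons = [
                    Interval(f.seqid, f.start - 1, f.end)
                    for f in db.children(tx, featuretype="exon")
                ]
                utrs = [
                    Interval(f.seqid, f.start - 1, f.end)
                    for f in db.children(tx)
                    if f.featuretype in _UTR_FEATURES
                ]
                tx_span = Interval(tx.seqid, tx.start - 1, tx.end)
                candidates.append((tx.id, exons, utrs, tx_span))
        else:
            # gene with direct exon/UTR children (no transcript level)
            exons = [
                Interval(f.seqid, f.start - 1, f.end)
                for f in db.children(gene, featuretype="exon")
            ]
            utrs = [
                Interval(f.seqid, f.start - 1, f.end)
                for f in db.children(gene)
                if f.featuretype in _UTR_FEATURES
            ]
            candidates.append((gene_id, exons, utrs, span))

        def build(model_id: str, exons, utrs, model_span) -> GeneModel:
            for exon in exons:
                if exon.start < model_span.start or exon.end > model_span.end:
                    raise AnnotationError(
                        f"gene {gene_id}: exon {exon.start}-{exon.end} outside span"
                    )
            tss = model_span.start if gene.strand == "+" else model_span.end - 1
            return GeneModel(
                gene_id=model_id,
                chrom=gene.seqid,
                strand=gene.strand,  # type: ignore[arg-type]
                tss=tss,
                span=model_span,
                exons=_split_exons_by_utr(exons, utrs),
            )

        if transcript_mode == "per_transcript" and len(candidates) > 1:
            for tx_id, exons, utrs, tx_span in candidates:
                genes.append(build(f"{gene_id}:{tx_id}", exons, utrs, tx_span))
        else:
            # most distal TSS in the direction of transcription
            if gene.strand == "+":
                chosen = min(candidates, key=lambda c: c[3].start)
            else:
                chosen = max(candidates, key=lambda c: c[3].end)
            _tx_id, exons, utrs, tx_span = chosen
            genes.append(build(gene_id, exons, utrs, tx_span))
    return genes


def _read_bed12(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise AnnotationError(f"{path} line {lineno}: BED12 needs 12 columns")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            if strand not in ("+", "-"):
                raise AnnotationError(f"gene {name}: unknown strand {strand!r}")
            thick_start, thick_end = int(f[6]), int(f[7])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise AnnotationError(f"gene {name}: block count mismatch")
            span = Interval(chrom, start, end)
            exons = [
                Interval(chrom, start + off, start + off + size)
                for off, size in zip(starts, sizes)
            ]
            # UTR = exonic bases outside [thickStart, thickEnd)
            utrs: list[Interval] = []
            if thick_start < thick_end:
                if start < thick_start:
                    utrs.append(Interval(chrom, start, thick_start))
                if thick_end < end:
                    utrs.append(Interval(chrom, thick_end, end))
            else:  # non-coding: everything is UTR
                utrs.append(Interval(chrom, start, end))
            tss = start if strand == "+" else end - 1
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,  # type: ignore[arg-type]
                    tss=tss,
                    span=span,
                    exons=_split_exons_by_utr(exons, utrs),
                )
            )
    return genes


def read_peaks(
    path: str | Path,
    dialect: Literal["bed", "narrowPeak"] = "narrowPeak",
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[Peak]:
    """Read peak calls from BED or ENCODE narrowPeak.

    narrowPeak column 8 is taken as -log10 p; BED6 uses the score column.
    BED3 lines are admitted with neg_log10_p = 0 and a logged warning so that
    a p-value filter removes them only when asked to.
    """
    peaks: list[Peak] = []
    warned_scoreless = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if start >= end:
                raise AnnotationError(
                    f"{path} line {lineno}: start {start} >= end {end}"
                )
            name = f[3] if len(f) > 3 and f[3] not in (".", "") else f"peak_{lineno}"
            summit: int | None = None
            if dialect == "narrowPeak":
                if len(f) < 8:
                    raise AnnotationError(
                        f"{path} line {lineno}: narrowPeak needs >= 8 columns"
                    )
                neg_log10_p = float(f[7])
                if len(f) >= 10 and f[9] not in (".", "", "-1"):
                    s = int(f[9])
                    summit = s if s >= 0 else None
            else:
                if len(f) >= 5:
                    neg_log10_p = float(f[4])
                else:
                    neg_log10_p = 0.0
                    if not warned_scoreless:
                        logger.warning(
                            "%s: BED lines without score column; neg_log10_p set to 0",
                            path,
                        )
                        warned_scoreless = True
            if chrom_sizes is not None:
                size = chrom_sizes.get(chrom)
                if size is not None and end > size:
                    raise AnnotationError(
                        f"{path} line {lineno}: interval end {end} exceeds "
                        f"{chrom} length {size}"
                    )
            peaks.append(
                Peak(
                    interval=Interval(chrom, start, end),
                    name=name,
                    neg_log10_p=neg_log10_p,
                    summit_offset=summit,
                )
            )
    return peaks


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_intervals(
    items: Sequence[Peak | Interval],
    path: str | Path,
    dialect: Literal["bed", "narrowPeak", "tsv"] = "bed",
) -> None:
    """Write records as tab-separated BED6, narrowPeak, or a plain TSV.

    ``read_peaks(write_intervals(x))`` round-trips for bed/narrowPeak.
    """
    with open(path, "w", newline="\n") as fh:
        if dialect == "tsv":
            fh.write("chrom\tstart\tend\tname\tneg_log10_p\n")
        for i, item in enumerate(items):
            if isinstance(item, Peak):
                iv, name, p, summit = item.interval, item.name, item.neg_log10_p, item.summit_offset
            else:
                iv, name, p, summit = item, f"iv_{i}", 0.0, None
            p_str = repr(float(p))  # shortest exact round-trip representation
            if dialect == "bed":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{p_str}\t.\n")
            elif dialect == "narrowPeak":
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t.\t0\t{p_str}\t-1\t"
                    f"{summit if summit is not None else -1}\n"
                )
            elif dialect == "tsv":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{p_str}\n")
            else:
                raise ValueError(f"unknown dialect {dialect!r}")


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/UTR features).

    Internal 0-based half-open fragments are converted back to 1-based
    inclusive; UTR-flagged fragments are emitted both as exon parts and as
    five_prime_UTR / three_prime_UTR features so the reader round-trips.
    """
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for name, size in annotation.chrom_sizes.items():
            fh.write(f"##sequence-region {name} 1 {size}\n")
        for g in annotation.genes:
            base = (g.chrom, "rdi", g.strand)

            def line(ftype: str, iv: Interval, attrs: str) -> str:
                return (
                    f"{base[0]}\t{base[1]}\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{base[2]}\t.\t{attrs}\n"
                )

            fh.write(line("gene", g.span, f"ID={g.gene_id}"))
            tx_id = f"{g.gene_id}.t1"
            fh.write(line("mRNA", g.span, f"ID={tx_id};Parent={g.gene_id}"))
            # merge contiguous fragments back into whole exons for the exon rows
            frags = sorted(g.exons, key=lambda e: e[0].start)
            exon_ivs: list[Interval] = []
            for iv, _flag in frags:
                if exon_ivs and exon_ivs[-1].end == iv.start:
                    exon_ivs[-1] = Interval(iv.chrom, exon_ivs[-1].start, iv.end)
                else:
                    exon_ivs.append(iv)
            for k, iv in enumerate(exon_ivs, 1):
                fh.write(line("exon", iv, f"ID={tx_id}.exon{k};Parent={tx_id}"))
            for k, (iv, flag) in enumerate(frags, 1):
                if flag != "UTR":
                    continue
                # orientation decides five' vs three'
                if g.strand == "+":
                    ftype = "five_prime_UTR" if iv.start - g.span.start < g.span.end - iv.end else "three_prime_UTR"
                else:
                    ftype = "five_prime_UTR" if g.span.end - iv.end < iv.start - g.span.start else "three_prime_UTR"
                fh.write(line(ftype, iv, f"ID={tx_id}.utr{k};Parent={tx_id}"))


def merged_non_utr_exons(annotation: GenomeAnnotation) -> dict[str, list[tuple[int, int]]]:
    """Union of non-UTR exonic bases per chromosome, as sorted merged tuples."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for gene in annotation.genes:
        for iv in gene.exon_fragments("non-UTR"):
            per_chrom.setdefault(gene.chrom, []).append((iv.start, iv.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in per_chrom.items():
        ivs.sort()
        out: list[tuple[int, int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[chrom] = out
    return merged
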