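"""Synthetic genomes, gene models, peaks, SBRs, and expression tables with
planted ground truth.

The generator emulates the downstream products of a FoxH1 ChIP-seq +
microarray study — a peak set of which a configurable fraction carries the
AATMCACA consensus, Smad2-binding regions enriched near canonical peaks, and
a two-contrast fold-change table with a configurable directional concordance
— so the whole pipeline can run and be validated offline.

Design notes:

* Background sequence is i.i.d. uniform over {A,C,G,T} (an order-1 Markov
  background with configurable GC is available for repeat-filter realism).
  With ``motif_free_background`` the background is rejection-sampled until it
  contains no consensus word on either strand, so classification recovers the
  planted CAN set exactly.
* Planted features never overlap each other within a peak, peaks are placed
  with a safety margin so their scan windows do not touch, and non-decoy
  peaks are re-drawn until they trigger no filter and no spurious SMAD
  pairing: the planted per-peak truth is therefore unambiguous.
* All randomness flows from one seed through named substreams (one per
  artifact type), so e.g. adding peaks does not perturb gene placement.
* The per-gene association truth is recorded at generation time by running
  the package's regulatory-domain logic on the planted post-filter peak set;
  that logic is itself validated against an independent quadratic oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from .genome_model import (
    GeneModel,
    GenomeAnnotation,
    Interval,
    Peak,
    write_gff3,
    write_intervals,
)
from .motif import ConsensusMotif, DEFAULT_SMAD_MOTIFS, FOXH1_CONSENSUS, expand_iupac, scan_consensus
from .peak_qc import (
    DEFAULT_REPEAT_STRINGS,
    RepeatPattern,
    _ExonCoverage,
    revcomp,
)

_SUBSTREAMS = {
    "genome": 0,
    "genes": 1,
    "peaks": 2,
    "sbrs": 3,
    "expression": 4,
    "plant": 5,
}

PRIMARY_CONTRAST = "mzsur"
SECONDARY_CONTRAST = "mzoep"


class SimulationConfig(BaseModel, extra="forbid"):
    """All knobs of the generator; defaults mirror the study's downstream
    products at a desk-scale problem size."""

    seed: int = 1
    n_chroms: int = Field(4, ge=1)
    chrom_length: int = Field(1_500_000, ge=10_000)
    n_genes: int = Field(500, ge=0)
    spacing_law: Literal["uniform", "exponential"] = "uniform"
    spacing_params: tuple[float, float] = (1_000, 9_000)
    gene_exon_length: tuple[int, int] = (200, 800)
    gene_intron_length: tuple[int, int] = (100, 1_500)
    n_peaks: int = Field(2_000, ge=0)
    peak_length_range: tuple[int, int] = (200, 600)
    fraction_can: float = Field(0.14, ge=0, le=1)
    fraction_smad_paired: float = Field(0.25, ge=0, le=1)
    fraction_exonic_decoys: float = Field(0.05, ge=0, le=1)
    fraction_repeat_decoys: float = Field(0.05, ge=0, le=1)
    fraction_low_pvalue: float = Field(0.05, ge=0, le=1)
    pvalue_threshold: float = 4.0
    n_sbrs: int = Field(1_000, ge=0)
    sbr_coupled_fraction: float = Field(0.6, ge=0, le=1)
    sbr_displacement_sd: float = Field(500.0, ge=0)
    sbr_length_range: tuple[int, int] = (150, 400)
    n_regulated: int = Field(150, ge=0)
    effect_scale: float = Field(0.75, gt=0)
    log2_threshold: float = 1.0
    concordance_rho: float = Field(0.76, ge=0, le=1)
    noise_sd: float = Field(0.0, ge=0)
    background_model: Literal["iid", "markov1"] = "iid"
    gc_content: float = Field(0.5, gt=0, lt=1)
    motif_free_background: bool = True
    foxh1_motif: str = FOXH1_CONSENSUS
    smad_motif: str = DEFAULT_SMAD_MOTIFS[0]
    max_gap: int = Field(100, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if (
            self.fraction_exonic_decoys
            + self.fraction_repeat_decoys
            + self.fraction_low_pvalue
            + self.fraction_can
        ) > 1:
            raise ValueError("class fractions sum to more than 1")
        if self.n_regulated > self.n_genes:
            raise ValueError("n_regulated exceeds n_genes")
        if self.peak_length_range[0] < len(self.foxh1_motif) + len(self.smad_motif) + self.max_gap + 10:
            raise ValueError("peaks too short to host a planted SMAD/FoxH1 pair")
        return self


@dataclass
class SimulationResult:
    out_dir: Path
    config: SimulationConfig
    annotation: GenomeAnnotation
    peaks: list[Peak]
    truth: dict

    @property
    def files(self) -> dict[str, Path]:
        d = self.out_dir
        return {
            "fasta": d / "genome.fa",
            "gff3": d / "genes.gff3",
            "chrom_sizes": d / "chrom.sizes",
            "peaks": d / "peaks.narrowPeak",
            "sbrs": d / "sbrs.bed",
            "expression": d / "expression.tsv",
            "ground_truth": d / "ground_truth.json",
            "config": d / "config.yaml",
        }


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_SUBSTREAMS[stream],))
    )


# ---------------------------------------------------------------------------
# Genes
# ---------------------------------------------------------------------------


def _draw_spacing(config: SimulationConfig, rng: np.random.Generator) -> int:
    a, b = config.spacing_params
    if config.spacing_law == "uniform":
        return int(rng.integers(int(a), int(b) + 1))
    return int(a + rng.exponential(b))


def _make_genes(config: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    genes: list[GeneModel] = []
    idx = 0
    for chrom, count in zip(chroms, per_chrom):
        pos = _draw_spacing(config, rng)
        for _ in range(count):
            idx += 1
            gene_id = f"g{idx:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 5))
            exon_lens = rng.integers(
                config.gene_exon_length[0], config.gene_exon_length[1] + 1, n_exons
            )
            intron_lens = rng.integers(
                config.gene_intron_length[0],
                config.gene_intron_length[1] + 1,
                n_exons - 1,
            )
            span_len = int(exon_lens.sum() + intron_lens.sum())
            start = pos
            end = start + span_len
            if end > config.chrom_length:
                raise ValueError(
                    f"gene overflow on {chrom}: need {end} bp, have "
                    f"{config.chrom_length} (reduce n_genes or spacing)"
                )
            exons: list[Interval] = []
            cursor = start
            for k in range(n_exons):
                exons.append(Interval(chrom, cursor, cursor + int(exon_lens[k])))
                cursor += int(exon_lens[k])
                if k < n_exons - 1:
                    cursor += int(intron_lens[k])
            # UTRs at the transcript termini, capped to leave coding bases
            first, last = exons[0], exons[-1]
            u5 = min(150, len(first) - 50)
            u3 = min(250, len(last) - 50)
            if strand == "+":
                utrs = [
                    Interval(chrom, first.start, first.start + u5),
                    Interval(chrom, last.end - u3, last.end),
                ]
            else:
                utrs = [
                    Interval(chrom, last.end - u5, last.end),
                    Interval(chrom, first.start, first.start + u3),
                ]
            from .genome_model import _split_exons_by_utr

            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    tss=start if strand == "+" else end - 1,
                    span=Interval(chrom, start, end),
                    exons=_split_exons_by_utr(exons, utrs),
                )
            )
            pos = end + _draw_spacing(config, rng)
    return genes


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------

#: safety margin between placed peaks so SMAD scan windows never overlap
_PEAK_MARGIN = 150


@dataclass
class _PlantedPeak:
    peak: Peak
    peak_class: str  # CAN or NC
    removal_reasons: tuple[str, ...] = ()
    fox: dict | None = None  # {"start", "strand", "word"} genomic
    smad: dict | None = None
    repeat: dict | None = None
    exon_overlap_fraction: float | None = None


def _make_peaks(
    config: SimulationConfig,
    annotation: GenomeAnnotation,
    rng: np.random.Generator,
) -> list[_PlantedPeak]:
    n = config.n_peaks
    n_can = round(config.fraction_can * n)
    n_smad = round(config.fraction_smad_paired * n_can)
    n_exonic = round(config.fraction_exonic_decoys * n)
    n_repeat = round(config.fraction_repeat_decoys * n)
    n_lowp = round(config.fraction_low_pvalue * n)
    if n_can + n_exonic + n_repeat + n_lowp > n:
        raise ValueError("class counts exceed n_peaks")

    roles: list[tuple[str, tuple[str, ...]]] = []
    for i in range(n_can):
        roles.append(("CAN_smad" if i < n_smad else "CAN", ()))
    roles += [("exonic", ("exon_overlap",))] * n_exonic
    roles += [("repeat", ("repeat",))] * n_repeat
    roles += [("lowp", ("pvalue",))] * n_lowp
    roles += [("NC", ())] * (n - len(roles))

    chroms = list(annotation.chrom_sizes)
    exon_cov = _ExonCoverage(annotation)
    fragments = [
        iv
        for g in annotation.genes
        for iv in g.exon_fragments("non-UTR")
        if len(iv) >= 150
    ]
    if n_exonic > 0 and not fragments:
        raise ValueError("no non-UTR exon fragments long enough for exonic decoys")

    from intervaltree import IntervalTree

    occupied: dict[str, IntervalTree] = {c: IntervalTree() for c in chroms}

    def blocked(chrom: str, start: int, end: int) -> bool:
        return bool(occupied[chrom][start - _PEAK_MARGIN : end + _PEAK_MARGIN])

    planted: list[_PlantedPeak] = []
    for i, (role, reasons) in enumerate(roles):
        name = f"peak_{i + 1:05d}"
        length = int(
            rng.integers(config.peak_length_range[0], config.peak_length_range[1] + 1)
        )
        placed = None
        for _try in range(10_000):
            if role == "exonic":
                frag = fragments[int(rng.integers(0, len(fragments)))]
                plen = min(length, 2 * len(frag) - 20)
                plen = max(plen, 50)
                chrom, start = frag.chrom, frag.start
                end = start + plen
                if end > annotation.chrom_sizes[chrom] or blocked(chrom, start, end):
                    continue
                frac = exon_cov.overlap(chrom, start, end) / plen
                if frac <= 0.5:
                    continue
                placed = (chrom, start, end, frac)
                break
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(0, annotation.chrom_sizes[chrom] - length + 1))
            end = start + length
            if blocked(chrom, start, end):
                continue
            frac = exon_cov.overlap(chrom, start, end) / length
            if frac > 0.5:
                continue
            placed = (chrom, start, end, frac)
            break
        if placed is None:
            raise RuntimeError(f"could not place {name} (role {role})")
        chrom, start, end, frac = placed
        occupied[chrom].addi(start, end)

        if role == "lowp":
            neg_log10_p = float(rng.uniform(0.5, config.pvalue_threshold - 0.1))
        else:
            neg_log10_p = float(config.pvalue_threshold + 0.05 + rng.exponential(2.0))
        peak = Peak(Interval(chrom, start, end), name=name, neg_log10_p=neg_log10_p)

        fox = smad = repeat = None
        flen = len(config.foxh1_motif)
        slen = len(config.smad_motif)
        if role in ("CAN", "CAN_smad"):
            fox_strand = "+" if rng.random() < 0.5 else "-"
            words = sorted(expand_iupac(ConsensusMotif("FoxH1", config.foxh1_motif)))
            word = words[int(rng.integers(0, len(words)))]
            if role == "CAN_smad":
                gap = int(rng.integers(0, config.max_gap + 1))
                if fox_strand == "+":
                    offset = int(rng.integers(gap + slen, (end - start) - flen + 1))
                    smad_start = start + offset - gap - slen
                else:
                    offset = int(rng.integers(0, (end - start) - flen - gap - slen + 1))
                    smad_start = start + offset + flen + gap
                smad = {"start": smad_start, "word": config.smad_motif, "gap": gap}
            else:
                offset = int(rng.integers(0, (end - start) - flen + 1))
            fox = {"start": start + offset, "strand": fox_strand, "word": word}
            peak_class = "CAN"
        else:
            peak_class = "NC"
        if role == "repeat":
            variants = sorted(
                v
                for s in DEFAULT_REPEAT_STRINGS
                for v in RepeatPattern.from_string(s).literal_variants
            )
            lit = variants[int(rng.integers(0, len(variants)))]
            off = int(rng.integers(0, (end - start) - len(lit) + 1))
            repeat = {"start": start + off, "literal": lit}

        planted.append(
            _PlantedPeak(
                peak=peak,
                peak_class=peak_class,
                removal_reasons=reasons,
                fox=fox,
                smad=smad,
                repeat=repeat,
                exon_overlap_fraction=float(frac),
            )
        )
    return planted


# ---------------------------------------------------------------------------
# Genome sequence
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _draw_bases(config: SimulationConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    if config.background_model == "iid":
        gc = config.gc_content
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        return _BASES[rng.choice(4, size=n, p=p)]
    # order-1 Markov chain with a same-base stickiness around the target GC,
    # enough to produce occasional simple-repeat-like runs
    gc = config.gc_content
    stay = 0.55
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    trans = np.array([base_p * (1 - stay) for _ in range(4)])
    for i in range(4):
        trans[i, i] += stay
        trans[i] /= trans[i].sum()
    states = np.empty(n, dtype=np.int64)
    states[0] = rng.choice(4, p=base_p)
    u = rng.random(n)
    cum = np.cumsum(trans, axis=1)
    for i in range(1, n):
        states[i] = np.searchsorted(cum[states[i - 1]], u[i])
    return _BASES[states]


def _consensus_hit_positions(seq: str, motif: ConsensusMotif) -> list[tuple[int, str]]:
    return [(h.start, h.strand) for h in scan_consensus(seq, motif, both_strands=True)]


def _make_genome(
    config: SimulationConfig,
    chrom_sizes: dict[str, int],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    motif = ConsensusMotif("FoxH1", config.foxh1_motif)
    genome: dict[str, np.ndarray] = {}
    for chrom, size in chrom_sizes.items():
        arr = _draw_bases(config, rng, size)
        if config.motif_free_background:
            for _round in range(200):
                seq = arr.tobytes().decode()
                hits = _consensus_hit_positions(seq, motif)
                if not hits:
                    break
                for pos, _strand in hits:
                    arr[pos : pos + len(motif)] = _draw_bases(
                        config, rng, len(motif)
                    )
            else:
                raise RuntimeError(f"{chrom}: could not purge consensus words")
        genome[chrom] = arr
    return genome


def _plant_and_fix(
    config: SimulationConfig,
    genome: dict[str, np.ndarray],
    planted: list[_PlantedPeak],
    rng: np.random.Generator,
) -> None:
    """Write planted words into the genome, then re-draw non-planted bases of
    each peak window until no unplanted consensus hit, no unplanted repeat,
    and no spurious SMAD pairing remains."""
    fox_motif = ConsensusMotif("FoxH1", config.foxh1_motif)
    smad_motif = ConsensusMotif("SMAD", config.smad_motif)
    repeat_variants = [
        v
        for s in DEFAULT_REPEAT_STRINGS
        for v in RepeatPattern.from_string(s).literal_variants
    ]
    flen = len(fox_motif)
    slen = len(smad_motif)

    def write(chrom: str, pos: int, word: str) -> None:
        genome[chrom][pos : pos + len(word)] = np.frombuffer(
            word.encode(), dtype=np.uint8
        )

    for pp in planted:
        if pp.fox is not None:
            word = pp.fox["word"]
            write(
                pp.peak.chrom,
                pp.fox["start"],
                word if pp.fox["strand"] == "+" else revcomp(word),
            )
        if pp.smad is not None:
            write(pp.peak.chrom, pp.smad["start"], pp.smad["word"])
        if pp.repeat is not None:
            write(pp.peak.chrom, pp.repeat["start"], pp.repeat["literal"])

    margin = config.max_gap + slen + flen
    for pp in planted:
        p = pp.peak
        chrom_arr = genome[p.chrom]
        lo = max(0, p.start - margin)
        hi = min(len(chrom_arr), p.end + margin)
        protected: set[int] = set()
        if pp.fox is not None:
            protected.update(range(pp.fox["start"], pp.fox["start"] + flen))
        if pp.smad is not None:
            protected.update(range(pp.smad["start"], pp.smad["start"] + slen))
        if pp.repeat is not None:
            protected.update(
                range(pp.repeat["start"], pp.repeat["start"] + len(pp.repeat["literal"]))
            )

        for _round in range(200):
            window = chrom_arr[lo:hi].tobytes().decode()
            bad: set[int] = set()

            if config.motif_free_background:
                for pos, _strand in _consensus_hit_positions(window, fox_motif):
                    gpos = lo + pos
                    span = set(range(gpos, gpos + flen))
                    if pp.fox is not None and pp.fox["start"] == gpos:
                        continue
                    # redraw the non-planted portion; a hit cannot sit fully
                    # inside a planted word with the default patterns
                    bad |= span - protected

            peak_seq = chrom_arr[p.start : p.end].tobytes().decode()
            if pp.repeat is None:
                for lit in repeat_variants:
                    idx = peak_seq.find(lit)
                    while idx != -1:
                        span = set(range(p.start + idx, p.start + idx + len(lit)))
                        bad |= span - protected
                        idx = peak_seq.find(lit, idx + 1)

            if pp.fox is not None:
                # spurious SMAD words that would flip the planted pairing flag
                smad_hits = scan_consensus(
                    window, smad_motif, both_strands=True, offset=lo
                )
                want = pp.smad is not None
                for sh in smad_hits:
                    if want and sh.start == pp.smad["start"]:
                        continue
                    if pp.fox["strand"] == "+":
                        gap = pp.fox["start"] - (sh.start + slen)
                    else:
                        gap = sh.start - (pp.fox["start"] + flen)
                    if 0 <= gap <= config.max_gap:
                        span = set(range(sh.start, sh.start + slen))
                        bad |= span - protected

            bad &= set(range(lo, hi))
            if not bad:
                break
            for gpos in sorted(bad):
                chrom_arr[gpos] = _draw_bases(config, rng, 1)[0]
        else:
            raise RuntimeError(f"could not sanitize sequence around {p.name}")


# ---------------------------------------------------------------------------
# SBRs and expression
# ---------------------------------------------------------------------------


def _make_sbrs(
    config: SimulationConfig,
    chrom_sizes: dict[str, int],
    can_peaks: Sequence[Peak],
    rng: np.random.Generator,
) -> list[tuple[Interval, str, str | None, int | None]]:
    """Returns (interval, name, coupled_peak_name_or_None, displacement)."""
    n_coupled = round(config.sbr_coupled_fraction * config.n_sbrs)
    if not can_peaks:
        n_coupled = 0
    chroms = list(chrom_sizes)
    out: list[tuple[Interval, str, str | None, int | None]] = []
    for i in range(config.n_sbrs):
        name = f"sbr_{i + 1:05d}"
        length = int(
            rng.integers(config.sbr_length_range[0], config.sbr_length_range[1] + 1)
        )
        if i < n_coupled:
            center = can_peaks[int(rng.integers(0, len(can_peaks)))]
            disp = int(round(rng.normal(0, config.sbr_displacement_sd)))
            mid = center.midpoint + disp
            start = mid - length // 2
            start = max(0, min(start, chrom_sizes[center.chrom] - length))
            actual_disp = (start + (start + length)) // 2 - center.midpoint
            out.append(
                (Interval(center.chrom, start, start + length), name, center.name, actual_disp)
            )
        else:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(0, chrom_sizes[chrom] - length + 1))
            out.append((Interval(chrom, start, start + length), name, None, None))
    return out


def _make_expression(
    config: SimulationConfig,
    gene_ids: Sequence[str],
    rng: np.random.Generator,
) -> tuple["pd.DataFrame", dict]:
    import pandas as pd

    chosen = rng.permutation(len(gene_ids))[: config.n_regulated]
    regulated = {gene_ids[int(i)] for i in chosen}
    rows = []
    truth: dict[str, dict] = {}
    for g in gene_ids:
        if g in regulated:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            mag1 = config.log2_threshold + rng.exponential(config.effect_scale)
            mag2 = config.log2_threshold + rng.exponential(config.effect_scale)
            same = rng.random() < config.concordance_rho
            planted1 = sign * mag1
            planted2 = (sign if same else -sign) * mag2
        else:
            planted1 = planted2 = 0.0
        obs1 = planted1 + (rng.normal(0, config.noise_sd) if config.noise_sd else 0.0)
        obs2 = planted2 + (rng.normal(0, config.noise_sd) if config.noise_sd else 0.0)
        rows.append((g, obs1, obs2))
        reg1 = "UP" if planted1 >= config.log2_threshold else (
            "DOWN" if planted1 <= -config.log2_threshold else "NONE"
        )
        reg2 = "UP" if planted2 >= config.log2_threshold else (
            "DOWN" if planted2 <= -config.log2_threshold else "NONE"
        )
        truth[g] = {
            "planted_log2fc": {PRIMARY_CONTRAST: planted1, SECONDARY_CONTRAST: planted2},
            "observed_log2fc": {PRIMARY_CONTRAST: obs1, SECONDARY_CONTRAST: obs2},
            "regulation": {PRIMARY_CONTRAST: reg1, SECONDARY_CONTRAST: reg2},
        }
    df = pd.DataFrame(rows, columns=["gene_id", PRIMARY_CONTRAST, SECONDARY_CONTRAST])
    return df, truth


def simulate_expression_truth(config: SimulationConfig) -> tuple["pd.DataFrame", dict]:
    """The expression substream alone (same draws as within :func:`simulate`)."""
    gene_ids = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    return _make_expression(config, gene_ids, _rng(config, "expression"))


# ---------------------------------------------------------------------------
# Top-level simulate / audit
# ---------------------------------------------------------------------------


def simulate(config: SimulationConfig, out_dir: str | Path) -> SimulationResult:
    """Generate all input files plus ground_truth.json into ``out_dir``.

    Outputs are byte-identical for a fixed config (including seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chrom_sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}

    genes = _make_genes(config, _rng(config, "genes"))
    annotation = GenomeAnnotation(chrom_sizes=dict(chrom_sizes), genes=genes)

    planted = _make_peaks(config, annotation, _rng(config, "peaks"))

    genome = _make_genome(config, chrom_sizes, _rng(config, "genome"))
    _plant_and_fix(config, genome, planted, _rng(config, "plant"))

    retained = [pp.peak for pp in planted if not pp.removal_reasons]
    can_peaks = [
        pp.peak for pp in planted if not pp.removal_reasons and pp.peak_class == "CAN"
    ]
    sbrs = _make_sbrs(config, chrom_sizes, can_peaks, _rng(config, "sbrs"))

    gene_ids = [g.gene_id for g in genes]
    expr_df, expr_truth = _make_expression(
        config, gene_ids, _rng(config, "expression")
    )

    # association truth on the planted post-filter peak set
    from .regdomains import DomainParams, associate, extend_domains

    domains = extend_domains(annotation, DomainParams())
    associations = associate(retained, domains, mode="midpoint")
    class_by_peak = {pp.peak.name: pp.peak_class for pp in planted}
    assoc_by_gene: dict[str, list[str]] = {}
    for a in associations:
        assoc_by_gene.setdefault(a.gene_id, []).append(a.peak_name)
    smad_by_peak = {
        pp.peak.name: pp.smad is not None for pp in planted if not pp.removal_reasons
    }

    gene_truth: dict[str, dict] = {}
    cat_counts: dict[str, int] = {}
    n_reg = n_assoc_reg = n_smad_reg = n_same = 0
    for g in gene_ids:
        peaks_here = sorted(assoc_by_gene.get(g, []))
        classes = {class_by_peak[p] for p in peaks_here}
        if not classes:
            pclass = "none"
        elif classes == {"CAN"}:
            pclass = "CAN"
        elif classes == {"NC"}:
            pclass = "NC"
        else:
            pclass = "CAN+NC"
        et = expr_truth[g]
        gene_truth[g] = {
            **et,
            "associated_peaks": peaks_here,
            "peak_class": pclass,
        }
        reg1 = et["regulation"][PRIMARY_CONTRAST]
        if reg1 != "NONE":
            n_reg += 1
            if pclass != "none":
                n_assoc_reg += 1
                cat_counts[f"{pclass}|{reg1}"] = cat_counts.get(f"{pclass}|{reg1}", 0) + 1
            if any(smad_by_peak.get(p, False) for p in peaks_here):
                n_smad_reg += 1
            if et["regulation"][SECONDARY_CONTRAST] == reg1:
                n_same += 1

    peak_truth = {
        pp.peak.name: {
            "class": pp.peak_class,
            "removal_reasons": list(pp.removal_reasons),
            "foxh1": pp.fox,
            "smad": pp.smad,
            "repeat": pp.repeat,
            "exon_overlap_fraction": pp.exon_overlap_fraction,
        }
        for pp in planted
    }
    sbr_truth = {
        name: {"coupled_to": coupled, "displacement": disp}
        for _iv, name, coupled, disp in sbrs
    }
    truth = {
        "summary": {
            "n_peaks": len(planted),
            "n_retained": len(retained),
            "n_can_planted": sum(1 for pp in planted if pp.peak_class == "CAN"),
            "n_can_retained": len(can_peaks),
            "n_removed_pvalue": sum(
                1 for pp in planted if "pvalue" in pp.removal_reasons
            ),
            "n_removed_exon": sum(
                1 for pp in planted if "exon_overlap" in pp.removal_reasons
            ),
            "n_removed_repeat": sum(
                1 for pp in planted if "repeat" in pp.removal_reasons
            ),
            "category_counts": dict(sorted(cat_counts.items())),
            "n_regulated": n_reg,
            "n_peak_associated_regulated": n_assoc_reg,
            "n_smad_cobound_regulated": n_smad_reg,
            "concordance": (n_same / n_reg) if n_reg else None,
        },
        "peaks": peak_truth,
        "genes": gene_truth,
        "sbrs": sbr_truth,
    }

    # ---------------- write files ----------------
    files = SimulationResult(out, config, annotation, retained, truth).files
    with open(files["fasta"], "w", newline="\n") as fh:
        for chrom, arr in genome.items():
            fh.write(f">{chrom}\n")
            seq = arr.tobytes().decode()
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    write_gff3(annotation, files["gff3"])
    with open(files["chrom_sizes"], "w", newline="\n") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    all_peaks = sorted(
        (pp.peak for pp in planted), key=lambda p: (p.chrom, p.start, p.name)
    )
    write_intervals(all_peaks, files["peaks"], dialect="narrowPeak")
    with open(files["sbrs"], "w", newline="\n") as fh:
        for iv, name, _c, _d in sorted(sbrs, key=lambda t: (t[0].chrom, t[0].start)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t.\n")
    expr_df_out = expr_df.copy()
    expr_df_out[PRIMARY_CONTRAST] = expr_df_out[PRIMARY_CONTRAST].map(lambda v: f"{v:.6f}")
    expr_df_out[SECONDARY_CONTRAST] = expr_df_out[SECONDARY_CONTRAST].map(
        lambda v: f"{v:.6f}"
    )
    expr_df_out.to_csv(files["expression"], sep="\t", index=False)
    with open(files["ground_truth"], "w", newline="\n") as fh:
        json.dump(truth, fh, sort_keys=True, indent=1)
        fh.write("\n")
    with open(files["config"], "w", newline="\n") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True)

    return SimulationResult(out, config, annotation, retained, truth)


def audit(out_dir: str | Path) -> list[str]:
    """Re-read every emitted file and verify each planted feature is present.

    Returns a list of human-readable failures (empty on success).
    """
    from pyfaidx import Fasta

    out = Path(out_dir)
    failures: list[str] = []
    truth_path = out / "ground_truth.json"
    for required in (
        "genome.fa",
        "genes.gff3",
        "chrom.sizes",
        "peaks.narrowPeak",
        "sbrs.bed",
        "expression.tsv",
        "ground_truth.json",
    ):
        if not (out / required).exists():
            raise FileNotFoundError(out / required)
    truth = json.loads(truth_path.read_text())

    genome = Fasta(str(out / "genome.fa"))
    from .genome_model import read_gene_annotation, read_peaks, read_chrom_sizes

    chrom_sizes = read_chrom_sizes(out / "chrom.sizes")
    annotation = read_gene_annotation(out / "genes.gff3", "gff3", chrom_sizes)
    peaks = {p.name: p for p in read_peaks(out / "peaks.narrowPeak", "narrowPeak")}
    cov = _ExonCoverage(annotation)

    for name, pt in truth["peaks"].items():
        if name not in peaks:
            failures.append(f"{name}: missing from peak file")
            continue
        p = peaks[name]
        if pt["foxh1"] is not None:
            f = pt["foxh1"]
            want = f["word"] if f["strand"] == "+" else revcomp(f["word"])
            got = str(genome[p.chrom][f["start"] : f["start"] + len(want)]).upper()
            if got != want:
                failures.append(
                    f"{name}: FoxH1 word at {p.chrom}:{f['start']} is {got}, expected {want}"
                )
        if pt["smad"] is not None:
            s = pt["smad"]
            got = str(genome[p.chrom][s["start"] : s["start"] + len(s["word"])]).upper()
            if got != s["word"]:
                failures.append(f"{name}: SMAD word at {p.chrom}:{s['start']} is {got}")
        if pt["repeat"] is not None:
            r = pt["repeat"]
            got = str(
                genome[p.chrom][r["start"] : r["start"] + len(r["literal"])]
            ).upper()
            if got != r["literal"]:
                failures.append(f"{name}: repeat literal at {p.chrom}:{r['start']} absent")
        if "exon_overlap" in pt["removal_reasons"]:
            frac = cov.overlap(p.chrom, p.start, p.end) / len(p.interval)
            if frac <= 0.5:
                failures.append(f"{name}: exon overlap {frac:.3f} not > 0.5")

    import pandas as pd

    expr = pd.read_csv(out / "expression.tsv", sep="\t").set_index("gene_id")
    for g, gt in truth["genes"].items():
        for contrast, want in gt["observed_log2fc"].items():
            got = float(expr.loc[g, contrast])
            if abs(got - want) > 5e-7:
                failures.append(
                    f"{g}: {contrast} log2fc {got} differs from recorded {want}"
                )

    sbr_df = pd.read_csv(
        out / "sbrs.bed",
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    ).set_index("name")
    for name, st in truth["sbrs"].items():
        if name not in sbr_df.index:
            failures.append(f"{name}: missing from SBR file")
            continue
        if st["coupled_to"] is not None:
            if st["coupled_to"] not in peaks:
                failures.append(f"{name}: coupled center {st['coupled_to']} missing")
                continue
            row = sbr_df.loc[name]
            mid = (int(row["start"]) + int(row["end"])) // 2
            disp = mid - peaks[st["coupled_to"]].midpoint
            if disp != st["displacement"]:
                failures.append(
                    f"{name}: displacement {disp} != recorded {st['displacement']}"
                )
    return failures
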