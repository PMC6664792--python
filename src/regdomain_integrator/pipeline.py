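"""End-to-end pipeline: qc -> classify -> annotate -> coloc -> integrate.

Every stage reads and writes the standard text formats, logs its record
counts (the filter-funnel numbers), and the whole run emits a manifest with a
content hash per output so reruns with identical config and inputs are
verifiable byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field

from . import coloc as coloc_mod
from . import integrate as integrate_mod
from .genome_model import (
    GenomeAnnotation,
    read_chrom_sizes,
    read_gene_annotation,
    read_peaks,
    write_intervals,
)
from .motif import (
    ConsensusMotif,
    DEFAULT_SMAD_MOTIFS,
    FOXH1_CONSENSUS,
    classify_peaks,
    find_smad_pairs,
)
from .peak_qc import QcConfig, RepeatPattern, DEFAULT_REPEAT_STRINGS, run_qc
from .regdomains import DomainParams, associate, extend_domains

logger = logging.getLogger(__name__)


class PipelineConfig(BaseModel, extra="forbid"):
    """Paths plus every stage parameter, defaulting to the study settings."""

    # inputs
    peaks: str
    annotation: str
    annotation_dialect: str = "gff3"
    genome: str
    chrom_sizes: str
    sbrs: Optional[str] = None
    expression: Optional[str] = None
    out_dir: str = "results"
    # qc
    pvalue_cutoff_neg_log10: float = Field(4.0, ge=0)  # p < 1e-4
    max_exon_fraction: float = Field(0.5, ge=0, le=1)
    repeat_patterns: list[str] = list(DEFAULT_REPEAT_STRINGS)
    # motif
    foxh1_motif: str = FOXH1_CONSENSUS
    smad_motifs: list[str] = list(DEFAULT_SMAD_MOTIFS)
    max_gap: int = Field(100, ge=0)
    # regulatory domains
    basal_up: int = 5_000
    basal_down: int = 1_000
    max_up: int = 50_000
    max_down: int = 20_000
    association_mode: str = "midpoint"
    # coloc
    bin_width: int = 250
    window: int = 10_000
    # integration
    primary_contrast: str = "mzsur"
    secondary_contrast: Optional[str] = "mzoep"
    log2_threshold: float = 1.0
    # misc
    seed: int = 0
    log_level: str = "INFO"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    for label, path in (
        ("peaks", config.peaks),
        ("annotation", config.annotation),
        ("genome", config.genome),
        ("chrom_sizes", config.chrom_sizes),
    ):
        if not Path(path).exists():
            raise FileNotFoundError(f"{label} file not found: {path}")

    from pyfaidx import Fasta

    chrom_sizes = read_chrom_sizes(config.chrom_sizes)
    annotation = read_gene_annotation(
        config.annotation, config.annotation_dialect, chrom_sizes  # type: ignore[arg-type]
    )
    genome = Fasta(config.genome)
    peaks = read_peaks(config.peaks, "narrowPeak", chrom_sizes)
    logger.info("loaded %d peaks, %d genes", len(peaks), len(annotation.genes))

    outputs: dict[str, Path] = {}

    # --- qc ---
    qc_cfg = QcConfig(
        threshold_neg_log10_p=config.pvalue_cutoff_neg_log10,
        max_exon_fraction=config.max_exon_fraction,
        repeat_patterns=tuple(
            RepeatPattern.from_string(s) for s in config.repeat_patterns
        ),
    )
    retained, report = run_qc(peaks, annotation, genome, qc_cfg)
    logger.info(
        "qc: %d -> %d peaks (pvalue %d, exon %d, repeat %d)",
        report.n_input,
        report.n_retained,
        report.n_removed_pvalue,
        report.n_removed_exon,
        report.n_removed_repeat,
    )
    outputs["qc_peaks"] = out / "peaks.filtered.narrowPeak"
    write_intervals(retained, outputs["qc_peaks"], "narrowPeak")
    outputs["qc_report"] = out / "qc_report.json"
    outputs["qc_report"].write_text(json.dumps(report.to_dict(), indent=1) + "\n")

    # --- classify ---
    fox = ConsensusMotif("FoxH1", config.foxh1_motif)
    smads = [ConsensusMotif(f"SMAD_{i}", s) for i, s in enumerate(config.smad_motifs)]
    classifications = classify_peaks(retained, genome, fox)
    find_smad_pairs(classifications, genome, smads, config.max_gap, chrom_sizes=chrom_sizes)
    n_can = sum(1 for c in classifications if c.peak_class == "CAN")
    logger.info(
        "classify: %d CAN / %d NC (%d SMAD-paired)",
        n_can,
        len(classifications) - n_can,
        sum(1 for c in classifications if c.smad_paired),
    )
    outputs["classes"] = out / "peak_classes.tsv"
    with open(outputs["classes"], "w", newline="\n") as fh:
        fh.write("peak\tclass\tn_hits\tsmad_paired\n")
        for c in classifications:
            fh.write(
                f"{c.peak_name}\t{c.peak_class}\t{len(c.foxh1_hits)}\t"
                f"{int(c.smad_paired)}\n"
            )
    outputs["motif_hits"] = out / "motif_hits.bed"
    with open(outputs["motif_hits"], "w", newline="\n") as fh:
        for c in classifications:
            for h in c.foxh1_hits + c.smad_hits:
                fh.write(
                    f"{h.chrom}\t{h.start}\t{h.end}\t{h.motif_id}:{c.peak_name}\t0\t{h.strand}\n"
                )

    # --- annotate ---
    params = DomainParams(
        basal_up=config.basal_up,
        basal_down=config.basal_down,
        max_up=config.max_up,
        max_down=config.max_down,
    )
    domains = extend_domains(annotation, params)
    associations = associate(retained, domains, mode=config.association_mode)  # type: ignore[arg-type]
    logger.info("annotate: %d associations", len(associations))
    outputs["associations"] = out / "associations.tsv"
    with open(outputs["associations"], "w", newline="\n") as fh:
        fh.write("peak\tgene\tpart\tdistance\n")
        for a in associations:
            fh.write(f"{a.peak_name}\t{a.gene_id}\t{a.part}\t{a.distance}\n")
    outputs["domains"] = out / "regulatory_domains.bed"
    with open(outputs["domains"], "w", newline="\n") as fh:
        for d in domains:
            fh.write(
                f"{d.chrom}\t{d.extended.start}\t{d.extended.end}\t{d.gene_id}\t0\t{d.strand}\n"
            )

    # --- coloc (needs SBRs) ---
    if config.sbrs:
        sbr_peaks = read_peaks(config.sbrs, "bed")
        can_peaks = [c.peak for c in classifications if c.peak_class == "CAN"]
        real = coloc_mod.profile(
            can_peaks,
            [p.interval for p in sbr_peaks],
            config.bin_width,
            config.window,
            label="CAN",
        )
        rand_set = coloc_mod.random_peaks(can_peaks, chrom_sizes, seed=config.seed)
        rand = coloc_mod.profile(
            rand_set.peaks,
            [p.interval for p in sbr_peaks],
            config.bin_width,
            config.window,
            label="random",
        )
        table, summary = coloc_mod.compare_profiles(real, rand)
        logger.info(
            "coloc: central enrichment %.2f (p=%.2g)",
            summary["central_enrichment"],
            summary["p_value"],
        )
        outputs["coloc_profile"] = out / "coloc_profile.tsv"
        table.to_csv(outputs["coloc_profile"], sep="\t", index=False)
        outputs["coloc_summary"] = out / "coloc_summary.json"
        outputs["coloc_summary"].write_text(json.dumps(summary, indent=1) + "\n")

    # --- integrate (needs expression) ---
    if config.expression:
        table_expr = integrate_mod.ExpressionTable.read_tsv(config.expression)
        summary_obj = integrate_mod.summarize(
            table_expr,
            associations,
            classifications,
            config.primary_contrast,
            config.secondary_contrast,
            config.log2_threshold,
        )
        logger.info(
            "integrate: %d regulated, %d peak-associated, concordance %s",
            summary_obj.n_regulated,
            summary_obj.n_peak_associated_regulated,
            summary_obj.concordance_fraction,
        )
        outputs["gene_table"] = out / "gene_categories.tsv"
        summary_obj.gene_table.to_csv(outputs["gene_table"], sep="\t", index=False)
        outputs["integration_summary"] = out / "integration_summary.json"
        outputs["integration_summary"].write_text(
            json.dumps(summary_obj.to_dict(), indent=1) + "\n"
        )
        matrix = integrate_mod.heatmap_matrix(table_expr, config.primary_contrast)
        outputs["heatmap_matrix"] = out / "heatmap_matrix.tsv"
        matrix.to_csv(outputs["heatmap_matrix"], sep="\t")

    # --- manifest ---
    manifest = {
        "config": config.model_dump(),
        "outputs": {
            k: {"path": str(p), "sha256": _sha256(p)} for k, p in sorted(outputs.items())
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
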