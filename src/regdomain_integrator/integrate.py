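"""Join peak-gene associations with two-genotype expression fold changes.

Produces the gene categories (CAN / NC / CAN+NC peak class crossed with UP /
DOWN regulation), the count of SMAD-cobound regulated genes, and the
directional concordance between the primary and secondary contrasts
(fraction of primary-regulated genes regulated the same way, at the same
threshold, in the secondary contrast).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd

from .motif import PeakClassification
from .regdomains import PeakGeneAssociation

Regulation = Literal["UP", "DOWN", "NONE"]
PeakClass = Literal["CAN", "NC", "CAN+NC", "none"]


@dataclass
class ExpressionTable:
    """Per-gene log2 fold changes across >= 2 contrasts.

    ``data`` is indexed by gene_id with one float column per contrast;
    ``detected`` marks genes with usable measurements.
    """

    data: pd.DataFrame
    detected: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.detected is None:
            self.detected = pd.Series(True, index=self.data.index)

    @property
    def contrasts(self) -> list[str]:
        return list(self.data.columns)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t")
        gene_col = df.columns[0]
        df = df.set_index(gene_col)
        detected = None
        if "detected" in df.columns:
            detected = df.pop("detected").astype(bool)
        return cls(data=df.astype(float), detected=detected)

    def write_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "gene_id", out.index)
        out["detected"] = self.detected
        out.to_csv(path, sep="\t", index=False)


def collapse_probes(df: pd.DataFrame, gene_col: str = "gene_id") -> pd.DataFrame:
    """Collapse probe-level rows to one row per gene, keeping per contrast the
    value with the largest |log2fc| (helper for probe-level microarray input)."""
    value_cols = [c for c in df.columns if c != gene_col]

    def pick(series: pd.Series) -> float:
        return series.loc[series.abs().idxmax()]

    return df.groupby(gene_col)[value_cols].agg(pick)


def call_regulation(
    table: ExpressionTable, contrast: str, log2_threshold: float = 1.0,
    inclusive: bool = True,
) -> dict[str, Regulation]:
    """UP / DOWN / NONE call per gene for one contrast.

    "At least twofold" is inclusive by default: UP iff log2fc >= threshold,
    DOWN iff <= -threshold. Undetected genes are NONE.
    """
    if contrast not in table.data.columns:
        raise KeyError(f"unknown contrast {contrast!r}")
    out: dict[str, Regulation] = {}
    for gene_id, value in table.data[contrast].items():
        if not bool(table.detected.loc[gene_id]) or pd.isna(value):
            out[gene_id] = "NONE"
        elif (value >= log2_threshold) if inclusive else (value > log2_threshold):
            out[gene_id] = "UP"
        elif (value <= -log2_threshold) if inclusive else (value < -log2_threshold):
            out[gene_id] = "DOWN"
        else:
            out[gene_id] = "NONE"
    return out


def assign_peak_class(
    associations: Sequence[PeakGeneAssociation],
    classifications: Sequence[PeakClassification],
) -> dict[str, PeakClass]:
    """Per gene: CAN if only CAN peaks associate, NC if only NC, CAN+NC if
    both. Genes without associated peaks are simply absent (class none)."""
    class_by_peak = {c.peak_name: c.peak_class for c in classifications}
    seen: dict[str, set[str]] = {}
    for a in associations:
        if a.peak_name not in class_by_peak:
            raise KeyError(f"association references unclassified peak {a.peak_name!r}")
        seen.setdefault(a.gene_id, set()).add(class_by_peak[a.peak_name])
    out: dict[str, PeakClass] = {}
    for gene_id, classes in seen.items():
        if classes == {"CAN"}:
            out[gene_id] = "CAN"
        elif classes == {"NC"}:
            out[gene_id] = "NC"
        else:
            out[gene_id] = "CAN+NC"
    return out


@dataclass
class IntegrationSummary:
    counts: dict[tuple[str, str], int]
    n_regulated: int
    n_peak_associated_regulated: int
    n_smad_cobound_regulated: int
    concordance_fraction: float | None
    gene_table: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "counts": {f"{pc}|{reg}": n for (pc, reg), n in sorted(self.counts.items())},
            "n_regulated": self.n_regulated,
            "n_peak_associated_regulated": self.n_peak_associated_regulated,
            "n_smad_cobound_regulated": self.n_smad_cobound_regulated,
            "concordance_fraction": self.concordance_fraction,
        }


def summarize(
    table: ExpressionTable,
    associations: Sequence[PeakGeneAssociation],
    classifications: Sequence[PeakClassification],
    primary_contrast: str,
    secondary_contrast: str | None = None,
    log2_threshold: float = 1.0,
) -> IntegrationSummary:
    """Count genes per (peak class x regulation) cell and measure directional
    concordance between the two contrasts.

    Concordance is |{genes regulated in primary and regulated in the same
    direction, at the same threshold, in secondary}| / |{genes regulated in
    primary}|; None when no gene is regulated or no secondary contrast given.
    """
    regulation = call_regulation(table, primary_contrast, log2_threshold)
    peak_class = assign_peak_class(associations, classifications)
    smad_by_peak = {c.peak_name: c.smad_paired for c in classifications}
    smad_genes = {
        a.gene_id for a in associations if smad_by_peak.get(a.peak_name, False)
    }

    regulated = [g for g, r in regulation.items() if r != "NONE"]
    counts: dict[tuple[str, str], int] = {}
    for pc in ("CAN", "NC", "CAN+NC", "none"):
        for reg in ("UP", "DOWN"):
            counts[(pc, reg)] = 0
    for g in regulated:
        counts[(peak_class.get(g, "none"), regulation[g])] += 1

    n_peak_associated_regulated = sum(
        n for (pc, _), n in counts.items() if pc != "none"
    )
    n_smad = len([g for g in regulated if g in smad_genes])

    concordance: float | None = None
    secondary_reg: dict[str, Regulation] = {}
    if secondary_contrast is not None and regulated:
        secondary_reg = call_regulation(table, secondary_contrast, log2_threshold)
        same = sum(1 for g in regulated if secondary_reg.get(g) == regulation[g])
        concordance = same / len(regulated)

    gene_rows = []
    for g in sorted(regulation):
        gene_rows.append(
            {
                "gene_id": g,
                "regulation": regulation[g],
                "secondary_regulation": secondary_reg.get(g, "NONE")
                if secondary_reg
                else "NONE",
                "peak_class": peak_class.get(g, "none"),
                "smad_cobound": g in smad_genes,
            }
        )
    return IntegrationSummary(
        counts=counts,
        n_regulated=len(regulated),
        n_peak_associated_regulated=n_peak_associated_regulated,
        n_smad_cobound_regulated=n_smad,
        concordance_fraction=concordance,
        gene_table=pd.DataFrame(gene_rows),
    )


def heatmap_matrix(
    table: ExpressionTable,
    primary_contrast: str,
    contrasts: Sequence[str] | None = None,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Genes x contrasts log2fc matrix, rows sorted by primary-contrast
    log2fc descending, ties broken by gene id (lexicographic)."""
    cols = list(contrasts) if contrasts is not None else table.contrasts
    if primary_contrast not in cols:
        raise KeyError(f"primary contrast {primary_contrast!r} not among contrasts")
    df = table.data[cols]
    if genes is not None:
        df = df.loc[[g for g in genes if g in df.index]]
    order = df.assign(_gene=df.index).sort_values(
        [primary_contrast, "_gene"], ascending=[False, True]
    )
    return order.drop(columns="_gene")
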