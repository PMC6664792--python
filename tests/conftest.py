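"""Shared fixtures: tiny annotations, in-memory genomes, random-model helpers.

A plain ``dict[str, str]`` doubles as a FASTA-like sequence source throughout
(string slicing matches the pyfaidx access pattern the package uses).
"""

from __future__ import annotations

import numpy as np
import pytest

from regdomain_integrator.genome_model import (
    GeneModel,
    GenomeAnnotation,
    Interval,
    Peak,
)


def make_gene(
    gene_id: str,
    chrom: str,
    strand: str,
    start: int,
    end: int,
    exons: list[tuple[int, int, str]] | None = None,
) -> GeneModel:
    """Exons are (start, end, flag) triples; flag in {UTR, non-UTR}."""
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        tss=start if strand == "+" else end - 1,
        span=Interval(chrom, start, end),
        exons=tuple((Interval(chrom, s, e), f) for s, e, f in (exons or [])),
    )


def make_peak(chrom: str, start: int, end: int, name: str, p: float = 10.0) -> Peak:
    return Peak(Interval(chrom, start, end), name=name, neg_log10_p=p)


def random_annotation(
    rng: np.random.Generator,
    n_genes: int = 50,
    n_chroms: int = 2,
    chrom_len: int = 300_000,
) -> GenomeAnnotation:
    """Random gene models (possibly overlapping) for oracle comparisons."""
    sizes = {f"chr{i + 1}": chrom_len for i in range(n_chroms)}
    genes = []
    for i in range(n_genes):
        chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
        length = int(rng.integers(500, 5_000))
        start = int(rng.integers(0, chrom_len - length))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(make_gene(f"g{i:03d}", chrom, strand, start, start + length))
    return GenomeAnnotation(chrom_sizes=sizes, genes=genes)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


# A motif-free scaffold sequence (no AATMCACA on either strand, no repeat
# literals) used wherever tests plant features at known offsets.
_SCAFFOLD_UNIT = "GCTTGACCTGAATCGGTCCA"


def scaffold(n: int) -> str:
    s = (_SCAFFOLD_UNIT * (n // len(_SCAFFOLD_UNIT) + 1))[:n]
    return s


def plant(seq: str, pos: int, word: str) -> str:
    assert pos + len(word) <= len(seq)
    return seq[:pos] + word + seq[pos + len(word) :]


@pytest.fixture
def small_sim(tmp_path_factory):
    """One small full simulation, shared read-only across tests."""
    from regdomain_integrator.synthetic_data import SimulationConfig, simulate

    cfg = SimulationConfig(
        seed=11,
        n_chroms=2,
        chrom_length=400_000,
        n_genes=40,
        n_peaks=150,
        n_sbrs=120,
        n_regulated=20,
    )
    out = tmp_path_factory.mktemp("small_sim")
    return simulate(cfg, out)
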