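"""Gene-level scoring of SNP GWAS results and the gene x QT finding matrix.

A brain-wide GWAS produces one SNP-level p-value per (SNP, quantitative trait)
pair. These are collapsed to gene level by the minimum p-value over all SNPs
falling within a symmetric window around the gene body (default +/-20 kb), one
score per (gene, QT). The resulting rectangular matrix is the universe
``G_d x B_d`` of ``N = N_G * N_B`` gene-QT associations from which the
significant finding list is drawn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GeneAnnotation, SnpAssociation, ValidationError, normalize_chrom

logger = logging.getLogger(__name__)

__all__ = [
    "GeneQtMatrix",
    "SignificantPairSet",
    "map_snps_to_genes",
    "significant_pairs",
    "read_gene_qt_matrix",
    "write_gene_qt_matrix",
]


@dataclass
class GeneQtMatrix:
    """Gene x QT p-value matrix: the GWAS finding universe.

    ``p_values[i, j]`` is the gene-level p-value of gene ``gene_ids[i]`` for
    trait ``qt_ids[j]``; every entry lies in (0, 1].
    """

    gene_ids: list[str]
    qt_ids: list[str]
    p_values: np.ndarray
    _gene_index: dict[str, int] = field(init=False, repr=False)
    _qt_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.qt_ids = [str(q) for q in self.qt_ids]
        self.p_values = np.asarray(self.p_values, dtype=float)
        if self.p_values.shape != (len(self.gene_ids), len(self.qt_ids)):
            raise ValidationError(
                f"p-value matrix shape {self.p_values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.qt_ids)} QTs"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids in GeneQtMatrix")
        if len(set(self.qt_ids)) != len(self.qt_ids):
            raise ValidationError("duplicate QT ids in GeneQtMatrix")
        if self.p_values.size and not (
            (self.p_values > 0).all() and (self.p_values <= 1).all()
        ):
            raise ValidationError("all gene-QT p-values must be in (0, 1]")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._qt_index = {q: j for j, q in enumerate(self.qt_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_qts(self) -> int:
        return len(self.qt_ids)

    @property
    def universe_size(self) -> int:
        """N = N_G * N_B, the number of gene-QT pairs in the universe."""
        return self.n_genes * self.n_qts

    @property
    def gene_index(self) -> dict[str, int]:
        return self._gene_index

    @property
    def qt_index(self) -> dict[str, int]:
        return self._qt_index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p_values, index=self.gene_ids, columns=self.qt_ids)


@dataclass
class SignificantPairSet:
    """The set ``A`` of gene-QT pairs whose p-value passed the threshold."""

    threshold: float
    pairs: set[tuple[str, str]]

    @property
    def count(self) -> int:
        """n = |A|."""
        return len(self.pairs)


def map_snps_to_genes(
    snps: Sequence[SnpAssociation],
    genes: Sequence[GeneAnnotation],
    window_bp: int = 20_000,
) -> GeneQtMatrix:
    """Collapse SNP-level p-values to gene level by the window-minimum rule.

    For each gene and QT the gene-level p-value is the smallest p-value over
    all SNPs on the same chromosome whose position falls in the closed window
    ``[max(1, start - window_bp), end + window_bp]``. A gene covered for some
    QTs but not others receives 1.0 for the uncovered QTs (keeping the
    universe rectangular); a gene with no in-window SNP for any QT is dropped.
    QTs are those present in the SNP records, in order of first appearance.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    if not snps or not genes:
        raise ValueError("need at least one SNP record and one gene annotation")

    qt_ids: list[str] = []
    qt_index: dict[str, int] = {}
    for s in snps:
        if s.qt_id not in qt_index:
            qt_index[s.qt_id] = len(qt_ids)
            qt_ids.append(s.qt_id)

    # Per-chromosome position-sorted arrays for binary-search window lookups.
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    chrom_records: dict[str, list[SnpAssociation]] = {}
    for s in snps:
        chrom_records.setdefault(normalize_chrom(s.chrom), []).append(s)
    for chrom, recs in chrom_records.items():
        pos = np.array([r.pos for r in recs], dtype=np.int64)
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        pvals = np.array([recs[i].p_value for i in order], dtype=float)
        qts = np.array([qt_index[recs[i].qt_id] for i in order], dtype=np.int64)
        by_chrom[chrom] = (pos, pvals, qts)

    rows: list[np.ndarray] = []
    kept_genes: list[str] = []
    n_dropped = 0
    for gene in genes:
        chrom = normalize_chrom(gene.chrom)
        if chrom not in by_chrom:
            n_dropped += 1
            continue
        pos, pvals, qts = by_chrom[chrom]
        lo = max(1, gene.start - window_bp)
        hi = gene.end + window_bp
        i0, i1 = np.searchsorted(pos, [lo, hi + 1])
        if i0 == i1:
            n_dropped += 1
            continue
        row = np.ones(len(qt_ids), dtype=float)
        np.minimum.at(row, qts[i0:i1], pvals[i0:i1])
        rows.append(row)
        kept_genes.append(gene.gene_id)

    if n_dropped:
        logger.info("dropped %d genes with no SNP in the +/-%d bp window", n_dropped, window_bp)
    if not kept_genes:
        raise ValueError("no gene received any SNP: empty gene-QT universe")
    return GeneQtMatrix(gene_ids=kept_genes, qt_ids=qt_ids, p_values=np.vstack(rows))


def significant_pairs(matrix: GeneQtMatrix, threshold: float = 1.0e-5) -> SignificantPairSet:
    """Collect the gene-QT pairs with p strictly below ``threshold`` (the set A)."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    gi, qj = np.nonzero(matrix.p_values < threshold)
    pairs = {(matrix.gene_ids[i], matrix.qt_ids[j]) for i, j in zip(gi.tolist(), qj.tolist())}
    return SignificantPairSet(threshold=threshold, pairs=pairs)


def write_gene_qt_matrix(matrix: GeneQtMatrix, path: str | Path) -> None:
    """Checkpoint the gene x QT matrix as a labelled TSV."""
    matrix.to_frame().to_csv(path, sep="\t", float_format="%.17g")


def read_gene_qt_matrix(path: str | Path) -> GeneQtMatrix:
    """Read a gene x QT matrix written by :func:`write_gene_qt_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GeneQtMatrix(
        gene_ids=[str(g) for g in df.index],
        qt_ids=[str(q) for q in df.columns],
        p_values=df.to_numpy(dtype=float),
    )
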