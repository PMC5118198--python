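"""Seeded synthetic fixtures with planted, recoverable ground truth.

Real inputs for this kind of analysis (a brain-wide GWAS and an atlas-scale
expression matrix) are large and access-restricted, so every stage of the
pipeline is exercised on synthetic data with known structure instead:

* an expression matrix with planted gene x ROI co-expression blocks, built
  from a two-sided latent-factor design. For a block with gene set ``G_k``,
  ROI set ``R_k`` and correlation target ``rho``, with ``s = sqrt(rho /
  (1 - rho))``::

      x[g, r] = s * f_r * [g in G_k]  +  s * u_g * [r in R_k]  +  eps[g, r]

  where ``f`` (one value per ROI) and ``u`` (one value per gene) are the
  block's latent factors and ``eps`` is unit Gaussian noise. Inside the block
  the expected gene-gene correlation across the block's ROIs is exactly
  ``rho`` (and symmetrically for ROI pairs across the block's genes), while
  the factors extend over the whole matrix at diluted strength so that the
  global UPGMA clustering of full expression profiles can actually find the
  planted gene set and circuit -- mirroring how a genuinely co-expressed
  module in atlas data is co-expressed brain-wide, not just inside itself.

* a gene x QT p-value matrix that is Uniform(0, 1) under the null, with
  planted enriched blocks drawn Beta(a, 1) with ``a < 1`` (stochastically
  small; at threshold t a block entry is significant with probability
  ``t ** a``).

* SNP-level records laid out on one synthetic chromosome whose window-minimum
  gene scores reproduce a known gene x QT target matrix exactly.

Synthetic QTs correspond one-to-one with ROIs and share their labels: each
QT plays the role of an imaging measurement of one ROI.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .gene_scoring import GeneQtMatrix
from .io import GeneAnnotation, SnpAssociation
from .modules import ExpressionMatrix

__all__ = [
    "CoexpressionBlock",
    "EnrichmentBlock",
    "SyntheticSpec",
    "GroundTruth",
    "simulate_expression",
    "simulate_gene_qt_pvalues",
    "simulate_snp_level",
    "single_block_spec",
    "multi_block_spec",
]


@dataclass(frozen=True)
class CoexpressionBlock:
    """A planted gene x ROI co-expression block with target correlation rho."""

    gene_indices: tuple[int, ...]
    roi_indices: tuple[int, ...]
    rho: float

    def __post_init__(self) -> None:
        if not (0.0 < self.rho < 1.0):
            raise ValueError(f"rho must be in (0, 1), got {self.rho}")
        if len(set(self.gene_indices)) != len(self.gene_indices):
            raise ValueError("duplicate gene indices in block")
        if len(set(self.roi_indices)) != len(self.roi_indices):
            raise ValueError("duplicate ROI indices in block")


@dataclass(frozen=True)
class EnrichmentBlock:
    """A planted gene x QT block of stochastically small p-values, Beta(a, 1)."""

    gene_indices: tuple[int, ...]
    qt_indices: tuple[int, ...]
    beta_a: float

    def __post_init__(self) -> None:
        if not (0.0 < self.beta_a <= 1.0):
            raise ValueError(f"beta_a must be in (0, 1], got {self.beta_a}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Dimensions, planted structure and seed of one synthetic data set."""

    n_genes: int
    n_rois: int
    n_qts: int
    coexpression_blocks: tuple[CoexpressionBlock, ...] = ()
    enrichment_blocks: tuple[EnrichmentBlock, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_rois, self.n_qts) < 2:
            raise ValueError("all dimensions must be at least 2")
        for b in self.coexpression_blocks:
            if max(b.gene_indices, default=0) >= self.n_genes:
                raise ValueError("co-expression block gene index out of bounds")
            if max(b.roi_indices, default=0) >= self.n_rois:
                raise ValueError("co-expression block ROI index out of bounds")
        for b in self.enrichment_blocks:
            if max(b.gene_indices, default=0) >= self.n_genes:
                raise ValueError("enrichment block gene index out of bounds")
            if max(b.qt_indices, default=0) >= self.n_qts:
                raise ValueError("enrichment block QT index out of bounds")
        for a, b in itertools.combinations(self.coexpression_blocks, 2):
            if set(a.gene_indices) & set(b.gene_indices):
                raise ValueError("planted co-expression blocks overlap in genes")
            if set(a.roi_indices) & set(b.roi_indices):
                raise ValueError("planted co-expression blocks overlap in ROIs")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]

    @property
    def roi_ids(self) -> list[str]:
        return [f"R{j + 1:03d}" for j in range(self.n_rois)]

    @property
    def qt_ids(self) -> list[str]:
        # QTs are identified one-to-one with ROIs when the counts match.
        if self.n_qts == self.n_rois:
            return self.roi_ids
        return [f"Q{j + 1:03d}" for j in range(self.n_qts)]


@dataclass
class GroundTruth:
    """Planted memberships, resolved to label space."""

    coexpression_modules: list[dict] = field(default_factory=list)
    enriched_blocks: list[dict] = field(default_factory=list)


def _resolve_truth(spec: SyntheticSpec) -> GroundTruth:
    genes, rois, qts = spec.gene_ids, spec.roi_ids, spec.qt_ids
    truth = GroundTruth()
    for b in spec.coexpression_blocks:
        truth.coexpression_modules.append(
            {
                "gene_ids": [genes[i] for i in b.gene_indices],
                "roi_ids": [rois[j] for j in b.roi_indices],
                "rho": b.rho,
            }
        )
    for b in spec.enrichment_blocks:
        truth.enriched_blocks.append(
            {
                "gene_ids": [genes[i] for i in b.gene_indices],
                "qt_ids": [qts[j] for j in b.qt_indices],
                "beta_a": b.beta_a,
            }
        )
    return truth


def simulate_expression(spec: SyntheticSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw the expression matrix with planted co-expression blocks.

    Background entries are i.i.d. standard normal; each block adds its
    two-sided latent factors as described in the module docstring. Columns
    are standardized (mean 0, population sd 1) before return.
    """
    rng = np.random.default_rng(spec.seed)
    x = rng.standard_normal((spec.n_genes, spec.n_rois))
    for block in spec.coexpression_blocks:
        s = np.sqrt(block.rho / (1.0 - block.rho))
        f = rng.standard_normal(spec.n_rois)  # gene-side factor, one value per ROI
        u = rng.standard_normal(spec.n_genes)  # ROI-side factor, one value per gene
        x[list(block.gene_indices), :] += s * f[None, :]
        x[:, list(block.roi_indices)] += s * u[:, None]
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    expr = ExpressionMatrix(gene_ids=spec.gene_ids, roi_ids=spec.roi_ids, values=x)
    return expr, _resolve_truth(spec)


def simulate_gene_qt_pvalues(spec: SyntheticSpec, truth: GroundTruth | None = None) -> GeneQtMatrix:
    """Draw the gene x QT p-value matrix with planted enriched blocks.

    Background entries are Uniform(0, 1]; entries in planted blocks are
    Beta(a, 1) samples obtained as ``U ** (1/a)``, which are stochastically
    smaller than uniform for ``a < 1``.
    """
    rng = np.random.default_rng((spec.seed, 1))
    p = 1.0 - rng.random((spec.n_genes, spec.n_qts))  # in (0, 1]
    for block in spec.enrichment_blocks:
        gi = np.asarray(block.gene_indices)
        qj = np.asarray(block.qt_indices)
        u = 1.0 - rng.random((gi.size, qj.size))
        # floor guards against underflow to 0 at extreme shape parameters
        p[np.ix_(gi, qj)] = np.maximum(u ** (1.0 / block.beta_a), 1e-300)
    return GeneQtMatrix(gene_ids=spec.gene_ids, qt_ids=spec.qt_ids, p_values=p)


def simulate_snp_level(
    spec: SyntheticSpec,
    window_bp: int = 20_000,
    gene_length: int = 10_000,
    spacing: int = 100_000,
) -> tuple[list[SnpAssociation], list[GeneAnnotation], GeneQtMatrix]:
    """Lay genes on one synthetic chromosome and emit SNP records.

    Each gene gets 1-10 SNPs inside its +/-window and one decoy SNP exactly
    one base pair outside it carrying a deliberately tiny p-value; the
    window-minimum mapping must exclude the decoy. Per QT, one in-window
    "lead" SNP carries the gene's target p-value and the remaining SNPs draw
    from Uniform(target, 1], so the min-p gene score equals the target
    exactly. Returns (snps, annotations, target gene x QT matrix).
    """
    if spacing <= 2 * window_bp + gene_length + 2:
        raise ValueError("spacing too small: gene windows would overlap")
    target = simulate_gene_qt_pvalues(spec)
    rng = np.random.default_rng((spec.seed, 2))
    snps: list[SnpAssociation] = []
    annots: list[GeneAnnotation] = []
    counter = itertools.count(1)
    for i, gene_id in enumerate(spec.gene_ids):
        start = 1 + window_bp + 1 + i * spacing
        end = start + gene_length - 1
        annots.append(GeneAnnotation(gene_id=gene_id, chrom="1", start=start, end=end))
        lo, hi = start - window_bp, end + window_bp
        n_snps = int(rng.integers(1, 11))
        positions = sorted(rng.choice(np.arange(lo, hi + 1), size=n_snps, replace=False))
        snp_ids = [f"rs{next(counter)}" for _ in positions]
        lead = int(rng.integers(0, n_snps))
        for j, qt_id in enumerate(spec.qt_ids):
            tp = float(target.p_values[i, j])
            for s_idx, (sid, pos) in enumerate(zip(snp_ids, positions)):
                if s_idx == lead:
                    p = tp
                else:
                    p = tp + (1.0 - tp) * (1.0 - float(rng.random()))  # in (tp, 1]
                snps.append(
                    SnpAssociation(snp_id=sid, chrom="1", pos=int(pos), qt_id=qt_id, p_value=p)
                )
        # decoy just outside the window, far more significant than anything inside
        decoy_id = f"rs{next(counter)}"
        decoy_p = min(float(target.p_values[i].min()) / 10.0, 1e-30)
        for qt_id in spec.qt_ids:
            snps.append(
                SnpAssociation(
                    snp_id=decoy_id, chrom="1", pos=hi + 1, qt_id=qt_id, p_value=max(decoy_p, 1e-300)
                )
            )
    return snps, annots, target


def single_block_spec(
    n_genes: int = 200,
    n_rois: int = 30,
    n_qts: int = 30,
    block_genes: int = 20,
    block_rois: int = 6,
    rho: float = 0.9,
    beta_a: float = 0.05,
    seed: int = 0,
) -> SyntheticSpec:
    """One planted co-expression block whose gene x QT sub-block is enriched.

    The default sizes (200 genes x 30 ROIs x 30 QTs with a 20 x 6 block at
    rho = 0.9 and Beta(0.05, 1) p-values) define the standard planted-recovery
    scenario used throughout the test suite.
    """
    genes = tuple(range(block_genes))
    rois = tuple(range(block_rois))
    return SyntheticSpec(
        n_genes=n_genes,
        n_rois=n_rois,
        n_qts=n_qts,
        coexpression_blocks=(CoexpressionBlock(genes, rois, rho),),
        enrichment_blocks=(EnrichmentBlock(genes, rois, beta_a),),
        seed=seed,
    )


def multi_block_spec(seed: int = 0, enriched: bool = True) -> SyntheticSpec:
    """Four co-expression blocks of graded strength; the strongest is enriched.

    1000 genes x 40 ROIs/QTs with blocks of 25, 20, 30 and 15 genes over 8, 6,
    7 and 5 ROIs at rho 0.9, 0.55, 0.5 and 0.45. The enriched block is well
    separated in rho from the decoys because the co-expression ranking
    estimates correlations over only a handful of ROIs per circuit, which is
    noisy. When ``enriched`` is set, the rho = 0.9 block's gene x QT
    sub-block draws Beta(0.4, 1) p-values (about 6 % of its pairs pass
    p < 1e-3): a moderate, gene-diffuse signal that is overwhelming in
    aggregate but collapses once gene labels are permuted, which is exactly
    the contrast the permutation evaluation needs. This is the fixture for
    permutation-based tests: several decoy modules exist and only one
    carries genuine GWAS signal.
    """
    sizes_g = (25, 20, 30, 15)
    sizes_r = (8, 6, 7, 5)
    rhos = (0.9, 0.55, 0.5, 0.45)
    blocks = []
    g0 = r0 = 0
    for ng, nr, rho in zip(sizes_g, sizes_r, rhos):
        blocks.append(
            CoexpressionBlock(tuple(range(g0, g0 + ng)), tuple(range(r0, r0 + nr)), rho)
        )
        g0 += ng
        r0 += nr
    enrich = (
        (EnrichmentBlock(blocks[0].gene_indices, blocks[0].roi_indices, beta_a=0.4),)
        if enriched
        else ()
    )
    return SyntheticSpec(
        n_genes=1000,
        n_rois=40,
        n_qts=40,
        coexpression_blocks=tuple(blocks),
        enrichment_blocks=enrich,
        seed=seed,
    )
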