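"""Construction of gene-set x brain-circuit (GS-BC) modules from co-expression.

The expression matrix E (genes x ROIs, each ROI column standardized) is
clustered twice: rows by the correlation dissimilarity
``d_gene(i1, i2) = (1 - corr(e^i1, e^i2)) / 2`` and columns by the analogous
``d_roi``. Each dendrogram (UPGMA / average linkage) is cut at half of its
root height; gene clusters are size-filtered (default 10-200, the usual bound
on pathway sizes in enrichment analysis) to give gene sets, and ROI clusters
of at least two regions give brain circuits. Every gene-set x circuit pair is
a candidate module, scored by the average Fisher z-transformed pairwise
correlation of its expression submatrix along each axis (z_gene over gene
pairs, z_roi over ROI pairs); the top fraction (default 20 %) by either score
-- or the intersection of both -- enters the enrichment analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import RawExpressionTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "Dendrogram",
    "GeneSet",
    "BrainCircuit",
    "GsBcModule",
    "preprocess_expression",
    "gene_dissimilarity",
    "roi_dissimilarity",
    "dissimilarity_matrix",
    "upgma_cluster",
    "cut_half_height",
    "filter_gene_clusters",
    "make_brain_circuits",
    "combine_modules",
    "fisher_z",
    "module_z_gene",
    "module_z_roi",
    "select_top_fraction",
    "build_modules",
]

STRATEGIES = ("gene_based", "roi_based", "gene_and_roi")

#: Margin by which correlations are pulled off +/-1 before the z-transform,
#: keeping scores finite while preserving their order.
CORR_CLAMP = 1.0e-12


@dataclass
class ExpressionMatrix:
    """Gene x ROI expression with per-ROI standardized columns.

    Each column has mean 0 and population standard deviation 1 unless it was
    constant in the input, in which case it is all zeros and listed in
    ``constant_rois``.
    """

    gene_ids: list[str]
    roi_ids: list[str]
    values: np.ndarray
    constant_rois: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.roi_ids = [str(r) for r in self.roi_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.roi_ids)):
            raise ValidationError(
                f"expression shape {self.values.shape} does not match labels"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids in ExpressionMatrix")
        if len(set(self.roi_ids)) != len(self.roi_ids):
            raise ValidationError("duplicate ROI ids in ExpressionMatrix")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)


@dataclass
class Dendrogram:
    """An agglomerative clustering tree over labelled leaves.

    ``linkage_matrix`` follows the standard scipy encoding: row ``t`` merges
    nodes ``Z[t, 0]`` and ``Z[t, 1]`` at height ``Z[t, 2]`` into a cluster of
    ``Z[t, 3]`` leaves, the new node receiving index ``n_leaves + t``.
    """

    leaf_ids: list[str]
    linkage_matrix: np.ndarray

    def __post_init__(self) -> None:
        heights = self.linkage_matrix[:, 2]
        if heights.size and np.any(np.diff(heights) < -1e-12):
            raise ValidationError("dendrogram merge heights are not monotone")

    @property
    def root_height(self) -> float:
        if self.linkage_matrix.shape[0] == 0:
            return 0.0
        return float(self.linkage_matrix[-1, 2])

    @property
    def merges(self) -> list[tuple[int, int, float, int]]:
        return [
            (int(a), int(b), float(h), int(s))
            for a, b, h, s in self.linkage_matrix
        ]


@dataclass(frozen=True)
class GeneSet:
    """A cluster of co-expressed genes (a GS)."""

    gs_id: str
    gene_ids: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class BrainCircuit:
    """A cluster of co-expressed brain regions (a BC)."""

    bc_id: str
    roi_ids: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.roi_ids)


@dataclass
class GsBcModule:
    """A candidate gene-set x brain-circuit module with its co-expression scores."""

    module_id: str
    gene_set: GeneSet
    circuit: BrainCircuit
    submatrix: np.ndarray  # restriction of E to the module's genes and ROIs
    z_gene: float = float("nan")
    z_roi: float = float("nan")
    selected_by: set[str] = field(default_factory=set)

    @property
    def n_genes(self) -> int:
        return self.gene_set.size

    @property
    def n_rois(self) -> int:
        return self.circuit.size


def preprocess_expression(
    samples: RawExpressionTable,
    sample_to_roi: dict[str, str] | None = None,
    probe_to_gene: dict[str, str] | None = None,
) -> ExpressionMatrix:
    """Merge samples into ROIs and probes into genes, then standardize per ROI.

    Sample columns mapping to the same ROI are averaged, then probe rows
    mapping to the same gene are averaged, then each ROI column is z-scored
    (mean 0, population standard deviation 1). Samples or probes absent from
    the supplied maps are dropped with a log entry; a constant column is set
    to zero and flagged rather than producing NaNs.
    """
    frame = samples.frame.copy()

    if samples.col_kind == "sample":
        if sample_to_roi is None:
            raise ValueError("sample columns require a sample_to_roi map")
        keep = [c for c in frame.columns if str(c) in sample_to_roi]
        dropped = len(frame.columns) - len(keep)
        if dropped:
            logger.info("dropped %d sample columns with no ROI mapping", dropped)
        if not keep:
            raise ValidationError("no sample column maps to any ROI")
        frame = frame[keep]
        frame = frame.T.groupby([sample_to_roi[str(c)] for c in keep], sort=False).mean().T

    if samples.row_kind == "probe":
        if probe_to_gene is None:
            raise ValueError("probe rows require a probe_to_gene map")
        keep_rows = [r for r in frame.index if str(r) in probe_to_gene]
        dropped = len(frame.index) - len(keep_rows)
        if dropped:
            logger.info("dropped %d probe rows with no gene mapping", dropped)
        if not keep_rows:
            raise ValidationError("no probe row maps to any gene")
        frame = frame.loc[keep_rows]
        frame = frame.groupby([probe_to_gene[str(r)] for r in keep_rows], sort=False).mean()

    values = frame.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0)  # population sd (ddof=0)
    constant = sd < 1e-15
    centered = values - mean
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(constant, 0.0, centered / np.where(constant, 1.0, sd))
    constant_rois = [str(c) for c, flag in zip(frame.columns, constant) if flag]
    if constant_rois:
        logger.warning("constant ROI columns zeroed: %s", constant_rois)
    return ExpressionMatrix(
        gene_ids=[str(r) for r in frame.index],
        roi_ids=[str(c) for c in frame.columns],
        values=normalized,
        constant_rois=constant_rois,
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation with zero-variance vectors mapped to 0 (warned)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    sa = a.std()
    sb = b.std()
    if sa < 1e-15 or sb < 1e-15:
        logger.warning("zero-variance vector in correlation; defining corr = 0")
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def gene_dissimilarity(a: np.ndarray, b: np.ndarray) -> float:
    """Correlation dissimilarity between two gene expression rows, in [0, 1]."""
    return 0.5 * (1.0 - _pearson(a, b))


def roi_dissimilarity(a: np.ndarray, b: np.ndarray) -> float:
    """Correlation dissimilarity between two ROI expression columns, in [0, 1]."""
    return 0.5 * (1.0 - _pearson(a, b))


def dissimilarity_matrix(values: np.ndarray, axis: str = "gene") -> np.ndarray:
    """Full pairwise correlation dissimilarity matrix along rows or columns.

    ``axis="gene"`` compares rows, ``axis="roi"`` compares columns. Vectors
    with zero variance get correlation 0 (dissimilarity 0.5) against all
    others, matching the scalar functions.
    """
    m = np.asarray(values, dtype=float)
    if axis == "roi":
        m = m.T
    elif axis != "gene":
        raise ValueError("axis must be 'gene' or 'roi'")
    sd = m.std(axis=1)
    degenerate = sd < 1e-15
    if degenerate.any():
        logger.warning("%d zero-variance vectors in dissimilarity_matrix", int(degenerate.sum()))
    safe = m.copy()
    # give degenerate vectors unit variance noise-free placeholders; fix below
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(safe)
    corr = np.asarray(corr, dtype=float)
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    d = 0.5 * (1.0 - corr)
    d = 0.5 * (d + d.T)  # enforce exact symmetry
    np.fill_diagonal(d, 0.0)
    return d


def upgma_cluster(dist: np.ndarray, leaf_ids: Sequence[str]) -> Dendrogram:
    """UPGMA (average-linkage) hierarchical clustering of a distance matrix.

    The inter-cluster distance is the unweighted mean over all cross-cluster
    leaf pairs; each merge happens at that distance, so merge heights are
    monotone non-decreasing.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if dist.shape[0] != len(leaf_ids):
        raise ValueError("leaf_ids length does not match the distance matrix")
    if np.isnan(dist).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(dist, dist.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.abs(np.diag(dist)).max(initial=0.0) > 1e-10:
        raise ValueError("distance matrix must have a zero diagonal")
    if dist.min(initial=0.0) < -1e-12:
        raise ValueError("distances must be non-negative")
    if len(leaf_ids) == 1:
        return Dendrogram(leaf_ids=list(leaf_ids), linkage_matrix=np.empty((0, 4)))
    condensed = squareform(0.5 * (dist + dist.T), checks=False)
    z = linkage(condensed, method="average")
    return Dendrogram(leaf_ids=[str(l) for l in leaf_ids], linkage_matrix=z)


def cut_half_height(dend: Dendrogram) -> list[list[str]]:
    """Cut a dendrogram at half of its root height.

    Leaves whose cophenetic distance is at most ``0.5 * root_height`` end up
    in the same cluster (the cut is inclusive). Clusters are returned in order
    of their first leaf, as lists of leaf ids.
    """
    if not dend.leaf_ids:
        raise ValueError("empty dendrogram")
    if dend.linkage_matrix.shape[0] == 0:
        return [[dend.leaf_ids[0]]]
    cutoff = 0.5 * dend.root_height
    labels = fcluster(dend.linkage_matrix, t=cutoff, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for leaf, lab in zip(dend.leaf_ids, labels):
        clusters.setdefault(int(lab), []).append(leaf)
    ordered = sorted(clusters.values(), key=lambda c: dend.leaf_ids.index(c[0]))
    return ordered


def filter_gene_clusters(
    clusters: Iterable[Sequence[str]], min_size: int = 10, max_size: int = 200
) -> list[GeneSet]:
    """Keep gene clusters whose size lies in [min_size, max_size] (inclusive).

    Surviving clusters receive stable ids GS01, GS02, ... in input order.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    kept = [c for c in clusters if min_size <= len(c) <= max_size]
    width = max(2, len(str(len(kept))))
    return [
        GeneSet(gs_id=f"GS{i:0{width}d}", gene_ids=tuple(str(g) for g in c))
        for i, c in enumerate(kept, start=1)
    ]


def make_brain_circuits(
    clusters: Iterable[Sequence[str]], min_size: int = 2
) -> list[BrainCircuit]:
    """Turn ROI clusters into circuits, requiring at least ``min_size`` regions.

    The ROI-pair score z_roi needs at least one pair, so singletons are
    always excluded.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2 (a circuit needs an ROI pair)")
    kept = [c for c in clusters if len(c) >= min_size]
    width = max(2, len(str(len(kept))))
    return [
        BrainCircuit(bc_id=f"BC{i:0{width}d}", roi_ids=tuple(str(r) for r in c))
        for i, c in enumerate(kept, start=1)
    ]


def fisher_z(c):
    """Fisher z-transform ``z(c) = 0.5 * log((1 + c) / (1 - c)) = arctanh(c)``.

    Correlations are clamped to ``[-1 + 1e-12, 1 - 1e-12]`` first so that
    perfectly correlated pairs give a large finite score instead of infinity.
    Accepts scalars or arrays.
    """
    arr = np.asarray(c, dtype=float)
    if np.any(np.abs(arr) > 1.0):
        raise ValueError("correlation magnitude exceeds 1")
    clamped = np.clip(arr, -1.0 + CORR_CLAMP, 1.0 - CORR_CLAMP)
    out = np.arctanh(clamped)
    return float(out) if np.isscalar(c) or arr.ndim == 0 else out


def _mean_pairwise_z(rows: np.ndarray) -> float:
    """Mean Fisher z over all unordered row pairs of ``rows``."""
    n = rows.shape[0]
    if n < 2:
        raise ValueError("need at least two vectors for a pairwise score")
    sd = rows.std(axis=1)
    degenerate = sd < 1e-15
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(rows)
    corr = np.asarray(corr, dtype=float)
    if degenerate.any():
        logger.warning("zero-variance vectors in module score; corr set to 0")
        corr[degenerate, :] = 0.0
        corr[:, degenerate] = 0.0
    iu = np.triu_indices(n, k=1)
    vals = np.clip(corr[iu], -1.0, 1.0)
    return float(np.mean(fisher_z(vals)))


def module_z_gene(module: GsBcModule) -> float:
    """Gene-side score: mean Fisher z over all gene-row pairs of the submatrix."""
    return _mean_pairwise_z(module.submatrix)


def module_z_roi(module: GsBcModule) -> float:
    """ROI-side score: mean Fisher z over all ROI-column pairs of the submatrix."""
    return _mean_pairwise_z(module.submatrix.T)


def combine_modules(
    gene_sets: Sequence[GeneSet],
    circuits: Sequence[BrainCircuit],
    expression: ExpressionMatrix,
) -> list[GsBcModule]:
    """Form the Cartesian product of gene sets and circuits as scored modules."""
    if not gene_sets or not circuits:
        raise ValueError("need at least one gene set and one circuit")
    gidx = {g: i for i, g in enumerate(expression.gene_ids)}
    ridx = {r: j for j, r in enumerate(expression.roi_ids)}
    modules: list[GsBcModule] = []
    for gs in gene_sets:
        rows = [gidx[g] for g in gs.gene_ids]
        sub_rows = expression.values[rows, :]
        for bc in circuits:
            cols = [ridx[r] for r in bc.roi_ids]
            sub = sub_rows[:, cols]
            mod = GsBcModule(
                module_id=f"{gs.gs_id}-{bc.bc_id}",
                gene_set=gs,
                circuit=bc,
                submatrix=sub,
            )
            mod.z_gene = module_z_gene(mod)
            mod.z_roi = module_z_roi(mod)
            modules.append(mod)
    return modules


def select_top_fraction(
    modules: Sequence[GsBcModule],
    fraction: float = 0.2,
    strategy: str = "gene_based",
) -> list[GsBcModule]:
    """Select the top ``ceil(fraction * M)`` modules by co-expression score.

    ``gene_based`` ranks by z_gene, ``roi_based`` by z_roi, and
    ``gene_and_roi`` intersects the two single-score selections. Boundary ties
    are broken by ascending module id so the selection is deterministic.
    Selected modules have the strategy added to their ``selected_by`` set.
    """
    if not modules:
        raise ValueError("empty module list")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if strategy == "gene_and_roi":
        by_gene = {m.module_id for m in select_top_fraction(modules, fraction, "gene_based")}
        by_roi = {m.module_id for m in select_top_fraction(modules, fraction, "roi_based")}
        chosen = [m for m in modules if m.module_id in (by_gene & by_roi)]
        chosen.sort(key=lambda m: m.module_id)
        for m in chosen:
            m.selected_by.add("gene_and_roi")
        return chosen
    if strategy == "gene_based":
        key = lambda m: (-m.z_gene, m.module_id)
    elif strategy == "roi_based":
        key = lambda m: (-m.z_roi, m.module_id)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    k = math.ceil(fraction * len(modules))
    chosen = sorted(modules, key=key)[:k]
    for m in chosen:
        m.selected_by.add(strategy)
    return chosen


def build_modules(
    expression: ExpressionMatrix,
    min_gs: int = 10,
    max_gs: int = 200,
    min_bc: int = 2,
    top_fraction: float = 0.2,
) -> dict:
    """Run the full module-construction stage on a standardized expression matrix.

    Returns a dict with the dendrograms, raw cluster lists, gene sets,
    circuits, all candidate modules and the per-strategy selections, plus the
    counts reported by the pipeline.
    """
    d_gene = dissimilarity_matrix(expression.values, axis="gene")
    d_roi = dissimilarity_matrix(expression.values, axis="roi")
    dend_gene = upgma_cluster(d_gene, expression.gene_ids)
    dend_roi = upgma_cluster(d_roi, expression.roi_ids)
    gene_clusters = cut_half_height(dend_gene)
    roi_clusters = cut_half_height(dend_roi)
    gene_sets = filter_gene_clusters(gene_clusters, min_size=min_gs, max_size=max_gs)
    circuits = make_brain_circuits(roi_clusters, min_size=min_bc)
    if not gene_sets:
        raise ValueError("no gene cluster within the size bounds; no modules to build")
    if not circuits:
        raise ValueError("no ROI cluster of size >= 2; no modules to build")
    modules = combine_modules(gene_sets, circuits, expression)
    selections = {
        s: select_top_fraction(modules, fraction=top_fraction, strategy=s)
        for s in STRATEGIES
    }
    return {
        "dendrogram_gene": dend_gene,
        "dendrogram_roi": dend_roi,
        "gene_clusters": gene_clusters,
        "roi_clusters": roi_clusters,
        "gene_sets": gene_sets,
        "circuits": circuits,
        "modules": modules,
        "selections": selections,
        "counts": {
            "n_gene_clusters": len(gene_clusters),
            "n_gene_sets": len(gene_sets),
            "n_roi_clusters": len(roi_clusters),
            "n_circuits": len(circuits),
            "n_modules": len(modules),
            **{f"n_selected_{s}": len(selections[s]) for s in STRATEGIES},
        },
    }
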