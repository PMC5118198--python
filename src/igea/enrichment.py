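"""Hypergeometric over-representation test of GS-BC modules in GWAS findings.

Out of the ``N = N_G * N_B`` gene-QT pairs of the GWAS universe, ``n`` are
significant (the set A). A module with gene set ``G_k`` and QT set ``B_k``
covers the pairs ``T = {(g, b) : g in G_d ∩ G_k, b in B_d ∩ B_k}`` with
``m = |T|``, of which ``k`` are significant. The enrichment p-value is the
hypergeometric upper tail

    p = P(|A ∩ T| >= k) = sum_{i >= k} C(m, i) C(N - m, n - i) / C(N, n),

i.e. the one-sided Fisher exact test of independence, Bonferroni-corrected
over the testable modules of the current strategy set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import hypergeom

from .gene_scoring import GeneQtMatrix, SignificantPairSet
from .modules import GsBcModule

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleOverlap",
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "compute_overlap",
    "enrich_all",
]


@dataclass
class ModuleOverlap:
    """The intersection of a module with the GWAS universe and finding list."""

    module_id: str
    m: int  # |T| = |G_d ∩ G_k| * |B_d ∩ B_k|
    k: int  # significant pairs inside T
    testable: bool  # False when the module misses the universe entirely


@dataclass
class EnrichmentResult:
    """Per-module hypergeometric test record."""

    module_id: str
    N: int
    n: int
    m: int
    k: int
    p_raw: float
    p_corrected: float
    n_tests: int
    significant: bool
    testable: bool = True


def hypergeom_upper_tail(N: int, n: int, m: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts module pairs among ``n`` draws without replacement from ``N``
    pairs of which ``m`` belong to the module. Computed via the survival
    function, which is numerically stable for the tiny tail probabilities
    that strongly enriched modules produce.
    """
    for name, val in (("N", N), ("n", n), ("m", m), ("k", k)):
        if int(val) != val or val < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {val!r}")
    if m > N or n > N:
        raise ValueError("m and n must not exceed N")
    if k > min(m, n):
        raise ValueError("k must not exceed min(m, n)")
    # sf(k-1) = P(X >= k); hypergeom takes (M=N, n=m, N=n) in scipy's naming
    p = float(hypergeom.sf(k - 1, N, m, n))
    return min(max(p, 0.0), 1.0)


def compute_overlap(
    module: GsBcModule, matrix: GeneQtMatrix, sig: SignificantPairSet
) -> ModuleOverlap:
    """Intersect a module with the gene-QT universe and count significant pairs.

    The module's circuit is identified with a QT set: its ROI labels are
    matched against the matrix's QT labels (in the brain-wide GWAS each QT is
    a measurement of one ROI). Modules missing the universe on either axis
    are flagged untestable.
    """
    genes = [g for g in module.gene_set.gene_ids if g in matrix.gene_index]
    qts = [r for r in module.circuit.roi_ids if r in matrix.qt_index]
    m = len(genes) * len(qts)
    if m == 0:
        logger.info("module %s does not intersect the GWAS universe", module.module_id)
        return ModuleOverlap(module_id=module.module_id, m=0, k=0, testable=False)
    pairs = sig.pairs
    k = sum(1 for g in genes for q in qts if (g, q) in pairs)
    return ModuleOverlap(module_id=module.module_id, m=m, k=k, testable=True)


def enrich_all(
    modules: Sequence[GsBcModule],
    matrix: GeneQtMatrix,
    sig: SignificantPairSet,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> list[EnrichmentResult]:
    """Test every module and Bonferroni-correct over the testable ones.

    ``n_tests`` counts only testable modules in the supplied set (normally
    one strategy's selection); untestable modules are reported with
    ``p_raw = 1`` and never significant.
    """
    if not modules:
        raise ValueError("empty module list")
    if correction != "bonferroni":
        raise ValueError(f"unknown correction {correction!r}")
    N = matrix.universe_size
    n = sig.count
    overlaps = [compute_overlap(mod, matrix, sig) for mod in modules]
    n_tests = sum(1 for ov in overlaps if ov.testable)
    results: list[EnrichmentResult] = []
    for ov in overlaps:
        if ov.testable:
            p_raw = hypergeom_upper_tail(N, n, ov.m, ov.k)
            p_corr = min(1.0, p_raw * n_tests)
            significant = p_corr < alpha
        else:
            p_raw, p_corr, significant = 1.0, 1.0, False
        results.append(
            EnrichmentResult(
                module_id=ov.module_id,
                N=N,
                n=n,
                m=ov.m,
                k=ov.k,
                p_raw=p_raw,
                p_corrected=p_corr,
                n_tests=n_tests,
                significant=significant,
                testable=ov.testable,
            )
        )
    return results
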