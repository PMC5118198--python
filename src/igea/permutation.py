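"""Permutation evaluation of the number of significant modules.

The observed GWAS result should light up more modules than chance. The null
is built by shuffling the gene row labels of the gene x QT p-value matrix
(each gene keeps its own co-occurrence pattern across QTs, but the
gene-to-module correspondence is broken) and re-running the enrichment on
``n`` permuted copies. With Prop(R) the proportion of testable modules that
are significant under result R, the observed proportion is compared to the
permuted ones through a one-sided Student-t tail:

    p = P( T_{n-1} >= (Prop(R_orig) - mu_perm) / (sqrt(1 + 1/n) * sigma_perm) )

where mu_perm and sigma_perm are the sample mean and sample standard
deviation (divisor n - 1) of the permuted proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import t as student_t

from .enrichment import EnrichmentResult, enrich_all
from .gene_scoring import GeneQtMatrix, significant_pairs
from .modules import GsBcModule

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateNullError",
    "PermutationEvaluation",
    "permute_gwas",
    "proportion_significant",
    "permutation_pvalue",
    "evaluate_permutations",
]

#: Seed used when none is supplied, so unconfigured runs are still reproducible.
DEFAULT_SEED = 17


class DegenerateNullError(ValueError):
    """All permuted proportions are identical; the t-statistic is undefined.

    When raised from :func:`evaluate_permutations`, ``prop_orig`` and
    ``props_perm`` carry the computed proportions so callers can still see
    how the observed result compares to the (constant) permuted ones.
    """

    def __init__(self, message: str, prop_orig: float | None = None,
                 props_perm: list[float] | None = None) -> None:
        super().__init__(message)
        self.prop_orig = prop_orig
        self.props_perm = props_perm


@dataclass
class PermutationEvaluation:
    """Summary of the permutation test for one strategy's module set."""

    n_perm: int
    props_perm: list[float]
    prop_orig: float
    mu_perm: float
    sigma_perm: float
    t_stat: float
    p_value: float


def permute_gwas(
    matrix: GeneQtMatrix,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    mode: str = "rows",
) -> GeneQtMatrix:
    """Return a label-permuted copy of the gene x QT matrix.

    ``mode="rows"`` (default) permutes the gene rows as whole blocks: every
    gene keeps its own p-value profile across QTs but is reassigned a random
    gene label, which preserves within-gene structure while breaking the
    correspondence between genes and modules. ``mode="columns"`` permutes
    each QT column independently, a fully unstructured alternative null.
    """
    if matrix.p_values.size == 0:
        raise ValueError("cannot permute an empty matrix")
    if rng is None:
        if seed is None:
            logger.info("permute_gwas: no seed supplied, using default %d", DEFAULT_SEED)
            seed = DEFAULT_SEED
        rng = np.random.default_rng(seed)
    if mode == "rows":
        perm = rng.permutation(matrix.n_genes)
        values = matrix.p_values[perm, :]
    elif mode == "columns":
        values = matrix.p_values.copy()
        for j in range(matrix.n_qts):
            values[:, j] = values[rng.permutation(matrix.n_genes), j]
    else:
        raise ValueError(f"unknown permutation mode {mode!r}")
    return GeneQtMatrix(
        gene_ids=list(matrix.gene_ids), qt_ids=list(matrix.qt_ids), p_values=values
    )


def proportion_significant(results: Sequence[EnrichmentResult]) -> float:
    """Prop(R): significant testable modules over all testable modules."""
    testable = [r for r in results if r.testable]
    if not testable:
        raise ValueError("no testable modules; proportion undefined")
    return sum(1 for r in testable if r.significant) / len(testable)


def permutation_pvalue(
    prop_orig: float, props_perm: Sequence[float]
) -> tuple[float, float]:
    """One-sided t-tail p-value for the observed proportion against permutations.

    Returns ``(t_stat, p_value)``. Raises :class:`DegenerateNullError` when
    the permuted proportions have zero sample standard deviation.
    """
    props = np.asarray(props_perm, dtype=float)
    n = props.size
    if n < 2:
        raise ValueError("need at least two permuted proportions")
    mu = float(props.mean())
    sigma = float(props.std(ddof=1))
    if np.all(props == props[0]):  # sigma is then 0 up to rounding noise
        raise DegenerateNullError(
            "degenerate permutation distribution: all permuted proportions equal"
        )
    t_stat = (prop_orig - mu) / (np.sqrt(1.0 + 1.0 / n) * sigma)
    p_value = float(student_t.sf(t_stat, df=n - 1))
    return float(t_stat), p_value


def evaluate_permutations(
    modules: Sequence[GsBcModule],
    matrix: GeneQtMatrix,
    threshold: float,
    alpha: float = 0.05,
    n_perm: int = 50,
    seed: int | None = None,
    mode: str = "rows",
) -> PermutationEvaluation:
    """Run the full permutation evaluation for one module set.

    The observed proportion comes from ``matrix`` itself; ``n_perm`` permuted
    copies (seeded) provide the null sample.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    if seed is None:
        logger.info("evaluate_permutations: no seed supplied, using default %d", DEFAULT_SEED)
        seed = DEFAULT_SEED
    rng = np.random.default_rng(seed)

    sig = significant_pairs(matrix, threshold)
    prop_orig = proportion_significant(enrich_all(modules, matrix, sig, alpha=alpha))

    props_perm: list[float] = []
    for _ in range(n_perm):
        permuted = permute_gwas(matrix, rng=rng, mode=mode)
        sig_p = significant_pairs(permuted, threshold)
        props_perm.append(
            proportion_significant(enrich_all(modules, permuted, sig_p, alpha=alpha))
        )

    try:
        t_stat, p_value = permutation_pvalue(prop_orig, props_perm)
    except DegenerateNullError as exc:
        raise DegenerateNullError(str(exc), prop_orig=prop_orig, props_perm=props_perm) from None
    props = np.asarray(props_perm)
    return PermutationEvaluation(
        n_perm=n_perm,
        props_perm=props_perm,
        prop_orig=prop_orig,
        mu_perm=float(props.mean()),
        sigma_perm=float(props.std(ddof=1)),
        t_stat=t_stat,
        p_value=p_value,
    )
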