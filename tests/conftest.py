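"""Shared fixtures: tiny handcrafted inputs and the standard synthetic scenarios."""

import numpy as np
import pytest

from igea.gene_scoring import GeneQtMatrix
from igea.modules import BrainCircuit, ExpressionMatrix, GeneSet
from igea.pipeline import PipelineParams
from igea.simulate import multi_block_spec, simulate_expression, simulate_gene_qt_pvalues

# Study conditions for all synthetic planted-signal runs: gene-level
# significance at 1e-3 (appropriate for a few-thousand-pair universe) and
# circuits of at least 4 ROIs, the smallest size at which pairwise
# correlations are estimable rather than degenerate (two-point correlations
# are always +/-1).
SYNTH_PARAMS = dict(threshold=1e-3, min_bc=4)


@pytest.fixture
def synth_params() -> PipelineParams:
    return PipelineParams(run_permutation=False, **SYNTH_PARAMS)


@pytest.fixture(scope="session")
def multi_block_run():
    """One multi-block synthetic data set with its constructed modules."""
    from igea.pipeline import run_pipeline

    spec = multi_block_spec(seed=0)
    expr, truth = simulate_expression(spec)
    gqt = simulate_gene_qt_pvalues(spec, truth)
    result = run_pipeline(
        expr, gqt, PipelineParams(run_permutation=False, **SYNTH_PARAMS)
    )
    return {"spec": spec, "truth": truth, "expression": expr, "gene_qt": gqt, **result}


@pytest.fixture(scope="session")
def paper_scale_modules():
    """171 gene sets x 9 circuits over a small random expression matrix.

    Gene sets of 10 genes and circuits of 4 ROIs keep the combination cheap
    while exercising the real scoring path for every module.
    """
    from igea.modules import combine_modules

    rng = np.random.default_rng(42)
    n_gs, gs_size, n_bc, bc_size = 171, 10, 9, 4
    gene_ids = [f"g{i}" for i in range(n_gs * gs_size)]
    roi_ids = [f"r{j}" for j in range(n_bc * bc_size)]
    expr = ExpressionMatrix(
        gene_ids=gene_ids,
        roi_ids=roi_ids,
        values=rng.standard_normal((len(gene_ids), len(roi_ids))),
    )
    gene_sets = [
        GeneSet(gs_id=f"GS{i:03d}", gene_ids=tuple(gene_ids[i * gs_size : (i + 1) * gs_size]))
        for i in range(n_gs)
    ]
    circuits = [
        BrainCircuit(bc_id=f"BC{j:02d}", roi_ids=tuple(roi_ids[j * bc_size : (j + 1) * bc_size]))
        for j in range(n_bc)
    ]
    return combine_modules(gene_sets, circuits, expr)


@pytest.fixture
def tiny_gene_qt() -> GeneQtMatrix:
    return GeneQtMatrix(
        gene_ids=["g1", "g2"],
        qt_ids=["b1", "b2"],
        p_values=np.array([[1e-6, 0.02], [0.5, 1e-7]]),
    )
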