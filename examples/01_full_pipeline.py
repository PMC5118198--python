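"""Full analysis on synthetic data with one genuinely enriched module.

Simulates a 1000-gene x 40-ROI expression matrix containing four planted
co-expression blocks and a gene x QT p-value matrix in which only the
strongest block carries GWAS signal, then runs module construction,
enrichment and the permutation evaluation.
"""

from igea import multi_block_spec, simulate_expression, simulate_gene_qt_pvalues
from igea.pipeline import PipelineParams, run_pipeline

spec = multi_block_spec(seed=0)
expression, truth = simulate_expression(spec)
gene_qt = simulate_gene_qt_pvalues(spec, truth)

params = PipelineParams(threshold=1e-3, min_bc=4, n_perm=50, seed=100)
result = run_pipeline(expression, gene_qt, params)
report = result["report"]

print(f"universe: {report['N_G']} genes x {report['N_B']} QTs = {report['N']} pairs")
print(f"significant gene-QT pairs at p < {report['threshold']}: {report['n_significant_pairs']}")
print(f"gene sets: {report['n_gene_sets']}   circuits: {report['n_circuits']}   "
      f"candidate modules: {report['n_modules']}")
print(f"selected (top 20 %, gene-based): {report['n_selected_gene_based']}")
print(f"Bonferroni-significant modules: {report['n_significant_modules']}")
for r in result["enrichment"]["gene_based"]:
    if r.significant:
        print(f"  {r.module_id}: {r.k} of its {r.m} pairs significant "
              f"(corrected p = {r.p_corrected:.3g})")
perm = report["permutation"]["gene_based"]
if perm is None:
    print("permutation evaluation: degenerate null (no permuted run produced "
          "a significant module) -- the observed count exceeds every permuted one")
else:
    print(f"permutation evaluation (gene-based): observed proportion "
          f"{perm['prop_orig']:.3f} vs permuted {perm['mu_perm']:.4f} "
          f"+/- {perm['sigma_perm']:.4f}; t = {perm['t_stat']:.2f}, p = {perm['p_value']:.2g}")
print()
print("The planted module (the rho = 0.9 block) should be the one flagged "
      "significant; the permutation p-value says how unusual the observed "
      "number of significant modules is under shuffled gene labels.")
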