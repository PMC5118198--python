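"""Two-way clustering and co-expression scoring of GS-BC modules.

Simulates an expression matrix with one planted 20-gene x 6-ROI block of
correlation 0.9, clusters genes and ROIs by UPGMA with a half-height cut,
and shows that the planted module gets the top Fisher-z co-expression
scores on both axes.
"""

from igea import simulate_expression, single_block_spec
from igea.modules import build_modules

spec = single_block_spec(seed=0)
expression, truth = simulate_expression(spec)
built = build_modules(expression, min_bc=4)

print(f"gene clusters after half-height cut: {built['counts']['n_gene_clusters']} "
      f"({built['counts']['n_gene_sets']} within the 10-200 size bounds)")
print(f"ROI clusters: {built['counts']['n_roi_clusters']} "
      f"({built['counts']['n_circuits']} circuits of >= 4 regions)")
print(f"candidate modules: {built['counts']['n_modules']}\n")

print("module scores (z = average Fisher-z of pairwise correlations):")
for m in sorted(built["modules"], key=lambda m: -m.z_gene):
    mark = ""
    planted = set(truth.coexpression_modules[0]["gene_ids"])
    if planted <= set(m.gene_set.gene_ids):
        mark = "   <- contains the planted gene set"
    print(f"  {m.module_id}: {m.n_genes} genes x {m.n_rois} ROIs, "
          f"z_gene = {m.z_gene:+.3f}, z_roi = {m.z_roi:+.3f}{mark}")
print("\nA z_gene of ~1.5 corresponds to an average pairwise correlation of "
      "~0.9 (arctanh scale); background modules sit near 0.")
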