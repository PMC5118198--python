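# Methods

This note documents the statistical model implemented by `igea`, the
parameter defaults and why they were chosen, the design of the synthetic
data generator, and the numerical conventions that make runs bit-for-bit
reproducible.

## The model

The analysis connects two data sets through the gene × QT grid:

* a **brain-wide GWAS**: SNP-level association p-values for each of many
  imaging quantitative traits (QTs), one GWAS per QT. Each QT is a scalar
  imaging measurement of one brain ROI, so QTs and ROIs are in one-to-one
  correspondence and share labels throughout the package.
* an **expression atlas**: a gene × ROI expression matrix from brain-wide
  transcriptome sampling.

The hypothesis is that sets of co-expressed genes acting on sets of
co-expressed brain regions form functional units, and that genuine imaging
genetic signal concentrates in such gene-set × brain-circuit (GS–BC) blocks
rather than in isolated gene–QT cells.

### Gene scoring

Gene-level p-values are the minimum SNP p-value within ±`window_bp` of the
gene body (default 20,000 bp, the conventional window for assigning
regulatory variants to genes). The window is closed on both ends and
symmetric; strand is ignored. This min-p score is deliberately simple — it
is biased for genes with many SNPs, and set-based alternatives (VEGAS-style
sums, GATES) exist — but it is the score the rest of the analysis is defined
on. Genes with no in-window SNP for *any* QT are dropped from the universe;
a gene covered for some QTs but not others receives the non-informative
score 1.0 for the uncovered QTs so that the universe stays a full
rectangle, which the enrichment test's N = N_G × N_B assumes. Missing
(`NA`) SNP p-values are skipped on input, never imputed, with a logged
count. The finding list uses a strict inequality p < threshold.

### Module construction

Expression preprocessing averages sample columns per ROI, then probe rows
per gene, then z-scores each ROI column (mean 0, population standard
deviation). Population rather than sample SD is an arbitrary but fixed
choice; it affects nothing downstream because Pearson correlations are
scale-invariant. A constant column cannot be standardized; it is set to
zero and flagged.

Both axes are clustered by UPGMA (average linkage) on the correlation
dissimilarity d = (1 − r)/2 ∈ [0, 1]. Zero-variance vectors have undefined
correlation; they are assigned r = 0 (d = 0.5) with a warning, which keeps
them maximally uninformative instead of propagating NaNs. Each dendrogram
is cut at **half of its root height**, with cluster membership defined by
cophenetic distance ≤ the cutoff (an inclusive cut). "Height" here means
the root merge height, not a branch-length sum; both the inclusive
comparison and this reading are conventions fixed so that results are
exactly reproducible, not claims about the only possible reading.

Gene clusters are filtered to 10–200 members (inclusive), the size range
conventionally imposed on pathways in enrichment analysis: smaller sets are
statistically unstable, larger ones uninterpretable. ROI clusters need at
least `min_bc` members; the library default is the mathematical minimum of
2 (the ROI-pair score needs one pair). All synthetic study conditions in
the tests and the acceptance script use `min_bc = 4` instead, for a reason
worth stating explicitly: the correlation of two vectors observed at only
two points is always ±1, so for 2-ROI circuits every gene-pair correlation
inside the module is ±1 and z̄_gene collapses to the clamp value. Any
strongly co-expressed gene set then produces an inflated, essentially
degenerate score with any 2-ROI circuit, and the score ranking stops
measuring co-expression. Four regions is the smallest circuit at which the
pairwise correlations are estimates rather than artifacts, and matches the
size range of anatomically meaningful circuits (a handful to a few dozen
regions).

Module scores average arctanh-transformed pairwise correlations (Fisher's
variance-stabilizing z). Correlations are clamped to |r| ≤ 1 − 1e-12 before
the transform so that duplicate rows give a large finite score (≈ 14.16)
instead of infinity; the clamp preserves score order. Selection keeps the
top ⌈fraction · M⌉ modules (ceiling, so 20 % of 1539 modules is 308) by
z̄_gene or z̄_roi, with boundary ties broken by module id to make the
selection a deterministic function of the scores. The gene-and-ROI strategy
is the intersection of the two single-score selections and can be empty;
the pipeline reports an empty selection rather than failing.

### Enrichment and correction

The over-representation test is the hypergeometric upper tail (one-sided
Fisher exact test), computed through the survival function so that tail
probabilities of 1e-40 and below are representable. The tail includes k
itself: P(X ≥ k). Modules that do not intersect the GWAS universe on both
axes carry no information; they are flagged untestable, reported with
p = 1, and excluded from the Bonferroni denominator. Correction is applied
within each strategy's selection by default (the three sets are tested
separately); `correction_scope="union"` pools the selections into one
denominator for the stricter reading.

### Permutation evaluation

The null is built by permuting the **gene row labels** of the gene × QT
matrix: each gene keeps its own p-value profile across QTs (within-gene
dependence is preserved) while the correspondence between genes and modules
is broken. A `columns` mode that permutes each QT column independently is
available as a fully unstructured alternative. Row permutation preserves
column margins, so signal that is concentrated in a few QT columns remains
in those columns under the null; the test therefore measures specifically
the gene-side alignment between findings and modules, which is the
component the modules claim to capture.

With Prop(R) the proportion of tested modules significant under result R,
the observed proportion is compared to n = 50 permuted proportions through
a one-sided Student-t tail with n − 1 degrees of freedom, using the sample
standard deviation (divisor n − 1) and the √(1 + 1/n) prediction-interval
inflation. When every permuted proportion is identical (in small synthetic
studies usually all zero) the t-statistic is undefined; the package raises
a dedicated error carrying the observed and permuted proportions rather
than reporting a fabricated p-value. Callers that need a number in this
case can fall back on the empirical permutation p-value (r + 1)/(n + 1), as
the acceptance script does. The proportions are discrete (multiples of one
over the number of tested modules), so with few modules the t-approximation
is coarse; the self-consistency test below quantifies how coarse.

## Synthetic data

The generator emulates the two inputs with planted, recoverable structure.

**Expression.** Background entries are i.i.d. standard normal. A planted
block (gene set G_k, ROI set R_k, target correlation ρ) adds two latent
factors with weight s = √(ρ/(1−ρ)):

    x[g, r] = s·f_r·[g ∈ G_k] + s·u_g·[r ∈ R_k] + ε[g, r]

with f one value per ROI (shared by the block's genes) and u one value per
gene (shared by the block's ROIs). Inside the block the expected gene–gene
correlation across the block's ROIs is exactly ρ, and symmetrically for
ROI pairs. The factors deliberately extend over the whole matrix at diluted
strength: a genuinely co-expressed module in atlas data is co-expressed
brain-wide, not only inside its own block, and the global UPGMA clustering
(which sees full profiles) can only recover structure that is visible
globally. A purely block-local signal would be invisible to this pipeline
by construction — detecting local co-expression patterns requires
co-clustering methods that are out of scope here. Columns are z-scored
after generation, which perturbs the factor algebra only at O(1/√n_genes).

**GWAS p-values.** Background entries are Uniform(0, 1]; entries of a
planted enriched block are Beta(a, 1) with a < 1, drawn as U^(1/a) (floored
at 1e-300 against underflow). At threshold t a block entry is significant
with probability t^a — a closed form the tests check directly.

**SNP level.** Genes are laid on one synthetic chromosome with 100 kb
spacing so that ±20 kb windows never overlap. Each gene gets 1–10 in-window
SNPs; per QT one of them carries the gene's target p-value and the rest
draw from Uniform(target, 1], so the window-minimum mapping reproduces the
target matrix exactly. Each gene also gets a decoy SNP exactly one base
pair outside the window with a p-value orders of magnitude below anything
inside — any window arithmetic error would surface as a mismatch.

**Standard scenarios.** `single_block_spec` (200 genes × 30 ROIs × 30 QTs;
one 20 × 6 block at ρ = 0.9 whose gene × QT sub-block draws Beta(0.05, 1))
is the planted-recovery scenario: the signal is strong and the question is
whether the pipeline finds it. `multi_block_spec` (1000 genes × 40
ROIs/QTs; four blocks of graded ρ = 0.9, 0.55, 0.5, 0.45, with only the
strongest enriched at Beta(0.4, 1)) is the permutation-evaluation scenario:
decoy modules exist, the per-pair signal is moderate (about 6 % of block
pairs pass p < 1e-3 — overwhelming in aggregate over 200 pairs, but thin
once gene labels are shuffled), and the decoys' ρ values are well separated
from the enriched block's because the co-expression ranking estimates
correlations over only a handful of ROIs per circuit and is noisy. Planted
analyses use a significance threshold of 1e-3, appropriate for universes
of 10^4–10^5 pairs (the conventional 1e-5 would leave a few-thousand-pair
universe with no background findings at all).

What passing these tests shows — and does not. Recovery and calibration on
this generator demonstrate that the pipeline's stages compose correctly and
that the statistics behave as designed under a model where co-expression is
factor-driven and noise is Gaussian and independent. Real atlas expression
has spatial autocorrelation, donor effects and heavy-tailed noise; real
GWAS p-values carry linkage disequilibrium between neighbouring genes and
correlated traits. None of these are modelled, so the tests validate the
implementation, not the method's power or error control on real data.

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; every simulation, permutation and pipeline run is a deterministic
  function of (inputs, parameters, seed). Unseeded permutation calls fall
  back to a logged constant seed rather than nondeterminism.
* Distance matrices are symmetrized (0.5·(D + Dᵀ)) and their diagonals
  zeroed before linkage to keep tiny floating-point asymmetries from
  reordering merges; UPGMA merge heights are asserted monotone on every
  run.
* Expression TSVs are written with 17 significant digits and parsed with
  correctly-rounded `float()` conversion, so write/read round trips are
  exact.
* BED input (0-based, half-open) is converted on read to the internal
  1-based inclusive convention; chromosome labels are compared after
  stripping a leading `chr` and case-folding.
* Degenerate inputs have defined behaviour throughout: zero-variance
  vectors score r = 0 with a warning, constant columns are zeroed and
  flagged, untestable modules are excluded from correction, and an all-equal
  permutation null raises instead of dividing by zero.

## Known limitations

* The min-p gene score favours long, SNP-dense genes; no per-gene
  SNP-count correction is applied.
* The module construction considers global co-expression only; modules
  that are co-expressed on a small subset of ROIs or genes are invisible.
* The hypergeometric test uses only the count of significant pairs, not
  the strength of the underlying associations; rank-based two-dimensional
  enrichment is not implemented.
* The permutation null preserves QT-column margins; it does not test
  against spatially structured imaging noise.
* With few tested modules the permutation proportions are coarse and the
  Student-t tail is an approximation; the degenerate all-equal case is
  surfaced explicitly rather than papered over.
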