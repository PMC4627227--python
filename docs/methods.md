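# Methods

## The analysis problem

Four sequencing libraries — self-renewing (SR) and replicatively senescent
(SEN) human adipose-derived mesenchymal stem cells, each with and without a
24-hour IL-2 priming — with **no replicates**. Nothing downstream can
estimate within-condition variance, so the pipeline combines: a
housekeeping-gene (beta-actin) normalization that tolerates genuine global
expression shifts, a posterior fold-change score whose uncertainty comes
entirely from Poisson counting noise, set algebra over the two
within-state contrasts, and over-representation statistics that need only
gene lists.

## Normalization model

For library *j*, the anchor scaling factor and normalized expression are

    s_j = (1/n) Σ_k c_ACTB,k / c_ACTB,j
    e_ij = c_ij × s_j / l_i

with *l*<sub>*i*</sub> the total exon length (bp) of gene *i*. Two exact
algebraic consequences are enforced by tests: *c*<sub>ACTB,*j*</sub> ×
*s*<sub>*j*</sub> equals the cross-library mean anchor count for every *j*
(so the anchor row of the normalized matrix is constant), and rescaling one
library's counts by a constant changes the whole normalized matrix only by
a single global factor (the rescaling enters through the cross-library
anchor mean), leaving all between-library expression ratios untouched.
Note the second property is *equivariance up to a global constant*, not
strict invariance of the rescaled library.

The CPM filter precedes normalization and works on raw counts: CPM =
*c*<sub>*ij*</sub> / total<sub>*j*</sub> × 10⁶, with library totals taken
over endogenous genes only (spike-in content tracks the dilution of the
mix, not biology, and spike-ins are exempt from filtering). Removal is
strict (`CPM < 1` in the relevant scope); a gene at exactly the threshold
survives. The default scope keeps a gene expressed above threshold in *any*
library, because state-specific expression is precisely the object of
interest; an all-libraries scope is available in the configuration.

## Replicate-free differential expression

Expression in one library is modeled as Poisson; with a flat prior the rate
given count *c* has a Gamma(*c*+1, 1) posterior. For a contrast (baseline
*a*, treated *b*) with effective sizes *s*<sub>a</sub>, *s*<sub>b</sub>,
the posterior of L = log2((λ_b/s_b)/(λ_a/s_a)) is summarized by its
(q, 1−q) quantiles, q = 0.01 by default. The generalized-fold-change score
is the conservative signed quantile: the lower quantile when the whole
interval is positive, the upper when negative, and 0 when the interval
covers no change. Calls use the ±0.01 score cutoff — effectively a
significance device, since any interval clearing zero by even 0.01 log2
units produces a call.

Computation is exact: λ_b/(λ_a+λ_b) ~ Beta(c_b+1, c_a+1), and the rate
ratio is a monotone transform of that Beta variate, so every quantile is a
transformed Beta quantile (`scipy.stats.beta.ppf`), vectorized over genes.
A seeded Monte-Carlo sampling path (independent Gamma draws) exists purely
as a cross-check; the two agree within 0.01 log2 units at 10⁵ draws except
in the extreme tails of zero-count genes, where the posterior tail is
exponential-like and the Monte-Carlo quantile itself carries ~0.05 log2
units of sampling error.

**Effective library size.** The default size is the library's anchor count
(ACTB sizing), consistent with the normalization philosophy. Total-count
sizing is available but interacts badly with designs in which treatment
shifts overall transcriptional output: the shift inflates the totals and
makes unchanged genes appear down-regulated — the global-normalization
artifact the anchor approach exists to avoid. The gene's exon length
cancels in within-gene between-library ratios and plays no role in
scoring.

**Known limitation.** Anchoring on a single gene injects that gene's own
Poisson noise as a coherent log2 shift (≈ √2/√c_ACTB / ln 2, about ±0.01
for a 40,000-count anchor) into every gene's fold change. Because the score
cutoff is also 0.01, this noise floor measurably inflates one tail of null
calls in any one contrast, and at very high depth it — not gene-level
counting noise — becomes the limiting factor on false calls. This is a
property of the method, not of the implementation.

## Classification, distances, clustering

Up/down calls from the SR and SEN contrasts are partitioned by set algebra
into up/down × {both, SR-only, SEN-only}. The three up sets are pairwise
disjoint and union to all genes called up anywhere; likewise down. A gene
up in one state and down in the other lands in one up-only and one
down-only set and is reported in a separate `discordant` set rather than
dropped.

Condition distance is 1 − Spearman correlation of log2(e + ε) profiles
(ε = 10⁻⁶ admits zeros); rank correlation is robust to the heavy-tailed
normalized values and invariant to per-library monotone transformations.
Pearson and Euclidean variants and complete/single linkage are available in
the configuration. Clustering is agglomerative with average linkage;
libraries enter the linkage in lexicographic id order so tie-breaking and
leaf order are deterministic. The dendrogram is exported as Newick, and an
`outlier_leaf` helper reports the condition that stands alone at the root.

## Enrichment and pathway network

Over-representation uses the one-sided hypergeometric upper tail: universe
N (genes surviving the CPM filter — only they could have been called), K
pathway members in the universe, n DE genes, overlap k, p = P(X ≥ k). Sets
with fewer than two testable members are skipped (a pathway must contain
multiple genes). q-values are Benjamini–Hochberg within one (direction,
state-scope) block, without π₀ estimation. The network admits pathways
with q ≤ 0.25 (a conventional screening level for gene-set analysis,
configurable); node weight is the pathway's DE-gene count, and an edge
joins pathways sharing at least one DE gene (configurable), weighted by the
shared count with the shared ids attached. Over-representation on discrete
up/down lists is used deliberately in place of a ranked gene-set
statistic: the inputs are hard-thresholded call sets, for which set-overlap
logic is the appropriate test.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
known truth:

- **Baseline expression** per unit length is log-normal across genes
  (σ = 1.5 natural-log scale), giving a realistic ~3-orders-of-magnitude
  dynamic range; abundance is baseline × exon length (lengths uniform on
  500–10,000 bp).
- **Mean model**: expected count = library depth × baseline relative
  abundance × 2^log2FC, the fold applied only in the IL-2+ library of the
  state(s) where the gene carries an effect. Relative abundances are fixed
  by the baseline (not renormalized per library), so doubling depth doubles
  every expected count exactly, and programmed up-regulation genuinely
  raises a library's total output — the signal the anchor normalization is
  designed to preserve.
- **Anchor**: ACTB receives a fixed 2% of depth in every library
  (housekeeping-level abundance) and never carries an effect.
- **Spike-ins**: 92 species, 250–2000 nt, expected concentrations on an
  exact log-uniform ladder spanning six orders of magnitude, jointly
  receiving 2% of depth.
- **Counts**: Poisson, or Gamma–Poisson with variance m + φm² when the
  dispersion φ > 0 (φ = 0 reduces exactly to Poisson, so the caller can be
  exercised both in-model and out-of-model).
- **Default design**: 2,000 genes, depth 2×10⁶ per library; 200/100/100
  genes up in both/SR-only/SEN-only and 100/50/50 down. SR effects are
  |log2FC| = 2 and SEN effects |log2FC| = 4: the senescent response is made
  stronger so that the SEN IL-2+ condition is the clear outlier of the
  condition dendrogram, the qualitative structure the pipeline is meant to
  expose. With equal effect sizes the two primed libraries are nearly
  equidistant from everything and the outlier structure is not resolved.

What the generator does **not** model: donor pooling and donor-to-donor
heterogeneity, sequencing-run batch effects, length-dependent capture
bias, and correlated (co-regulated) gene programs. Tests passing on this
generator therefore certify the statistical machinery under its stated
assumptions, not robustness to those real-data complications.

## Numerical and degenerate-input choices

- Spike-in QC needs ≥ 3 species with observed counts; a library with all
  observed counts equal is rejected as a degenerate fit. The observed side
  uses a +1 pseudocount; expected concentrations are positive by
  invariant. The flagging floor is Pearson r < 0.9.
- Constant expression profiles make correlation distances undefined and
  raise an error rather than returning NaN.
- Quantile probabilities are restricted to (0, 0.5); library sizes must be
  positive; the anchor must be present with positive counts in every
  library (errors name the offending library).
- All randomness flows from explicit seeds; the exact scoring path is
  fully deterministic, and sampling substreams are keyed by contrast label
  and sorted gene rank so input order never changes results.
- Heatmap tables order genes by category, then decreasing mean normalized
  expression, ties broken by gene id.

## Problem sizes used by the test suite

The suite simulates at 2,000 genes and depths of 10⁶–2×10⁶ (one deep
5×10⁷ run for the category-recovery property, where the conservative
quantile is tight enough for clean recovery), uses 10⁶-draw Monte-Carlo
oracles for the score checks, and enumerates hypergeometric tails exactly
for all universes up to 25 genes. These sizes were chosen so the whole
suite completes in well under a minute while leaving each check's sampling
error an order of magnitude below its assertion tolerance.
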