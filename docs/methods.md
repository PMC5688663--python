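# Methods

This note documents the models, parameters and numerical choices behind
`xcellkit`, and what the synthetic validation does and does not show.

## Model and assumptions

The pipeline treats a bulk expression profile as an additive mixture of
pure cell-type profiles, `m = M f` with non-negative fractions summing
to 1, and estimates *enrichment* of each cell type rather than deconvolving
the full composition. Three assumptions carry the method:

* **Rank sufficiency.** A cell type's presence shifts its marker genes up
  the sample's expression ranking. The ssGSEA statistic uses only
  within-sample ranks, so linear-scale normalization differences (TPM vs
  FPKM vs array intensity) and monotone batch distortions do not affect
  scores.
* **Signature transferability.** Genes overexpressed in a cell type in one
  reference source remain overexpressed in other sources/platforms. The
  selection step enforces this by scoring candidates only in sources they
  were not learned from.
* **Smooth score–fraction response.** The raw score is a monotone,
  saturating function of the cell-type fraction, well approximated over the
  0.8–25.6% range by a power law; a per-cell-type exponent linearizes it.

Independence is a design feature: until spillover compensation, each cell
type's score depends only on its own signatures, so a corrupted signature
cannot contaminate other cell types.

## Pipeline stages and tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| τ (ssGSEA weight exponent) | 0.25 | weight of rank value in the in-set ECDF; the customary single-sample GSEA weighting |
| minimum shared genes | 5000 | hard floor on the intersection of input genes with the signature universe; thin intersections give untrustworthy ranks (internal synthetic runs lower it explicitly, since the planted universe is ~1200 genes) |
| signature size bounds | 8–200 genes | candidates outside these bounds are discarded during learning |
| quantile pairs | (10, 90), (25, 75), (33.3, 66.6), (50, 50) | low quantile of the target type vs high quantile of the others |
| opposing ranks | 1–3 | the r-th largest opposing high quantile; ranks 2–3 deliberately ignore the most confusable cell type so that shared-program markers can still enter a signature |
| thresholds | 0, 0.1, log2(1.5), 1, 3, 4, 5 | log2-scale quantile differences; the full grid is 84 configurations per cell type per source |
| cancer overexpression cutoff | 5% (strict) | genes overexpressed (>2× the KDE peak of the cross-line distribution, in log2(x+3) space) in ≥5% of carcinoma lines are excluded — except for cell types that can be a solid tumor's cell of origin (epithelial cells, sebocytes, keratinocytes, hepatocytes, melanocytes, astrocytes, neurons), whose markers are legitimately cancer-expressed |
| titration grid | 0.8%–25.6%, doubling | designed mixtures against a control; the range targets low abundances, where detection matters most |
| score divisor | 5000 | fixed scale constant in the transform |
| α (spillover scaling) | 0.5 | multiplies off-diagonal K before NNLS; full compensation (α = 1) can destroy genuine associations |
| spillover cap | 0.5 | off-diagonal K entries are clipped; stronger compensation removed real signal |
| null mixtures per cell type | 1000 | random excluded-type mixtures used to fit each beta null |
| non-significance threshold | p > 0.2 | conventional reporting cutoff |

## Learned parameters

* **P (power coefficient).** Per cell type and platform family, fitted on
  noiseless median-profile titrations. The titration scores are shifted to
  0 at the 0.8% level and divided by 5000; the fit uses the positive points
  in 0.8–25.6%. Because the transform's purpose is linearization, the
  default estimator picks (P, a) minimizing ‖score^P − a·f‖ directly
  (seeded by the log-log slope); score-domain nonlinear and log-log OLS
  fits are available as options. The rank statistic's saturation makes the
  curve deviate from an exact power law, and the two classical estimators
  weight the low end too heavily to linearize the top of the range well.
  P is averaged across the family's sources containing the cell type.
* **V1 (slope).** Intercept-free least-squares slope of the power-adjusted
  titration scores on fraction, averaged across sources. Intercept-free
  because only the slope is used for calibration.
* **K and V2 (spillover).** Every non-control cell type is mixed at 25%
  with 75% control (median profiles); the panel is scored and transformed
  with V2 provisionally 1, averaged across the family's sources, and each
  row divided by its diagonal (the pre-normalization diagonal is V2). The
  control cell types themselves appear at 75% in every panel mixture and
  are never absent, so their scores have no baseline anchor there; they
  receive identity K rows/columns and V2 = 1 — controls exist for
  calibration, not for compensation. Cell types absent from one platform
  family are completed verbatim from the other family's matrix.
* **Hierarchy cleanup.** Parents are compensated only against other
  parents; children only against siblings and non-ancestral parents; all
  parent–descendant entries are zeroed in both directions, remaining
  off-diagonal entries clipped to [0, 0.5]. The cleanup is idempotent.
* **Beta nulls.** Adjusted scores of the excluded cell type in its null
  mixtures are capped at 1 and clipped to (1e-6, 1−1e-6) before a
  maximum-likelihood beta fit (method-of-moments fallback); all-zero score
  vectors become the constant null 0.001. Capping is a pragmatic choice —
  the transform does not guarantee scores ≤ 1.

Note on scale: dividing by V2 normalizes each cell type's 25%-abundance
score to 1, so transformed and adjusted scores sit on a scale where the
slope against true fraction is ≈ 1/0.25, not 1. They are reported as
arbitrary units resembling proportions; no option to rescale them into
percentages is offered, because they are not proportions.

## The synthetic atlas: what it emulates, what it does not

The generator plants, for each cell type, a block of marker genes boosted
by 6 log2 units over a log-normal baseline, across several sources that
differ by per-gene multiplicative platform factors (σ = 0.3 log2 units)
and within-type replicate noise (σ = 0.2 log2 units). Two control cell
types per platform family mirror the progenitor/endothelial and
erythrocyte/monocyte controls used with real atlases. Relatedness between a
pair of cell types is planted as a shared marker subset (full strength in
both) plus symmetric graded cross-expression of the remaining markers at a
fraction of full strength — emulating the partially shared transcriptional
programs of closely related cell types, which is what makes perfectly
discriminative signatures impossible and spillover real. A carcinoma
cell-line panel overexpresses a chosen fraction of markers in 10% of lines
to exercise the cancer-gene filter.

Mixtures follow `M f` in three modes: noiseless median profiles
(calibration), randomly drawn replicates (training/evaluation), and a
single replicate with per-gene uniform noise up to ±20% (testing). Fraction
vectors default to a symmetric Dirichlet; the evaluation scenario instead
draws independent uniform per-type fractions with a control filler
absorbing the remainder, because a simplex draw imposes a negative
compositional correlation (≈ −1/(k−1)) between every pair of fractions that
masks spillover in off-diagonal score–fraction correlations.

What passing tests on this generator do **not** show: performance on real
tissues. The generator has no correlated biological programs beyond the
planted relatedness, no covariance between marker genes, no partial marker
expression in unrelated lineages, no library-size or GC artifacts, and far
fewer genes (1200 vs ~10⁴). Real signatures are weaker and noisier; the
synthetic results validate the machinery (the estimators recover what was
planted), not clinical accuracy.

## Numerical choices

* ssGSEA rank ties break by gene identifier (stable, platform-independent);
  set genes missing from a sample are dropped for that sample; an empty
  set–profile intersection is an error, not a zero.
* The matrix scorer sorts genes lexicographically once and uses stable
  argsort per sample, making results independent of input row order.
* NNLS uses the Lawson–Hanson active-set solver (`scipy.optimize.nnls`):
  deterministic and exact for these small, diagonally dominant systems. An
  independent FISTA projected-gradient solver is used in tests only.
* The transform's min(Aᵢ) is taken within the user's input matrix, not from
  stored training minima; consequently a single-sample input scores 0
  everywhere, and inputs should contain heterogeneous samples. The
  significance power analysis therefore scores target-present and
  target-absent mixtures in a single matrix.
* KDE peak estimation for the cancer filter: Gaussian kernel, Silverman
  bandwidth, 512-point grid in log2(x+3) space; constant genes short-circuit
  to their value (rate 0 by the strict comparison).
* Top-3 signature selection breaks ties by higher t, then more genes, then
  name; duplicate gene sets are deduplicated before scoring and within the
  top-3 of a (cell type, source).
* All stage seeds fork from one root seed (`numpy` Generator); reruns are
  bit-identical, which the test suite asserts on the full pipeline digest.

## Problem sizes used in validation

The shipped scenarios use 8 cell types + 2 controls × 3 sources
(2 sequencing, 1 array), 25 markers per type, 1200 genes, 4 replicates per
type, a 100-line carcinoma panel, 500 evaluation mixtures, 1000 null
mixtures per cell type and 40 + 40 power/false-signal mixtures per target —
sizes at which every statistical property of interest is measurable with
comfortable margins while the complete pipeline runs in about a minute.

## Known limitations

* Enrichment scores are not proportions and cannot be summed meaningfully
  across cell types except as the (deliberately coarse) microenvironment
  score.
* Spillover compensation reintroduces limited coupling between cell-type
  estimates; with α = 0.5 and the 0.5 cap the coupling is mild, but a
  grossly wrong signature can now perturb its relatives.
* The learned spillover magnitude between related types varies with
  replicate noise realizations (signature selection may land on more or
  less discriminative candidate sets); directional claims (reduction of
  off-diagonal correlation, related > unrelated entries) are stable, exact
  magnitudes are not.
* Beta nulls are fitted per platform family on the reference atlas; a
  target data set with very different noise structure shifts the null and
  mis-calibrates p-values.
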