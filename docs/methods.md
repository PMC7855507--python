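# Methods

## The statistical model

Counts for gene *g* in sample *j* are modelled as negative binomial (NB) with
mean μ_g·s_j and dispersion φ_g (Var = μ + φμ²). The two-group comparison is
an exact conditional test on the within-group sums of depth-equalized
pseudo-counts ŷ_gj = round(y_gj / s_j): a sum of n i.i.d. NB(μ, φ) variables
is NB(nμ, φ/n), so under the null the group sums A ~ NB(n₁μ, φ/n₁·…) with
size n₁/φ and B with size n₂/φ are independent, and

    P(A = a | A + B = T) = f₁(a)·f₂(T − a) / Σ_{a'=0}^{T} f₁(a')·f₂(T − a')

is evaluated exactly (log-PMFs via gammaln, normalized with logsumexp). The
two-sided p-value doubles the smaller of P(A ≤ a_obs) and P(A ≥ a_obs) —
the observed value is included in both tails — and is capped at 1. When
φ = 0 the NB degenerates to Poisson and the conditional law is exactly
Binomial(T, n₁/(n₁+n₂)); the implementation switches to the Poisson log-PMF
there, and the dispersion-zero path is oracle-tested against the closed-form
binomial tail to 12 significant digits.

Rounding pseudo-counts keeps the conditional support integral; at the count
scales used (means ~e⁴–e⁵) the rounding perturbation is negligible, which
the null-calibration test verifies directly (KS statistic of raw p-values
vs U(0,1) below 0.05 at 5,000 genes).

## Normalization: why three scorers

The consensus design needs scorers that can genuinely disagree. The three
variants differ in their size-factor estimator, the axis along which the
published DE packages they emulate actually differ:

* **UQ** — 75th percentile (linear interpolation between order statistics;
  conventions differ, so this one is stated) of each sample's counts over
  genes detected in ≥1 sample, rescaled to unit geometric mean.
* **MOR** — median over all-positive genes of the ratio of a sample's count
  to the per-gene geometric mean.
* **FPKM** — FPKM rescaled back to a common depth. Algebraically,
  FPKM_gj · L_g · D̄ / 10⁹ = y_gj · (D̄ / D_j) with D_j the sample depth and
  D̄ the geometric-mean depth, i.e. total-count size factors; the scorer is
  implemented that way, and gene length cancels from every two-group ratio.

Each scorer estimates its own dispersions and is BH-adjusted independently,
so their significant sets differ in exactly the way consensus voting is
designed to exploit.

## Dispersion estimation

Per-gene method of moments on normalized counts, pooled across groups with
(n_k − 1) weights: φ̂_k = max(0, v_k − m_k)/m_k². With 3–4 replicates the raw
estimate is very noisy, so it is shrunk 50/50 toward the mean raw dispersion
of the gene's expression decile. The weight and binning are configurable;
50/50 over deciles is simple, documented, and sufficient for calibrated
p-values at the replicate numbers this design targets (verified by the
null-calibration test). No independent filtering of low-count genes is
applied.

## Thresholds and voting

Defaults: Padj ≤ 0.05 and |log2FC| ≥ 1, inclusive; a strict (<, >) mode is a
flag, since published wordings of the rule differ between "≤/≥" and
"less/greater than". log2FC adds one pseudo-count (on the normalized-count
scale) to each group mean to stay finite at zeros. A gene needs ≥2 of 3
scorers with concordant sign; discordant genes are excluded and surfaced as
warnings rather than averaged (concordance was an empirical observation in
the motivating study, so it is enforced and monitored here). The consensus
fold change averages the *significant* scorers only — a non-significant
third scorer's estimate does not dilute it.

## Overrepresentation

Two one-sided binomial tails per category, the smaller reported with its
direction; no two-sided doubling, because over- and underrepresentation are
reported (and plotted) separately. Bonferroni m defaults to the number of
categories actually tested in the run and is recorded on the result. Genes
in no category form a synthetic "unclassified" category so the conventional
drop-from-plots rule has a concrete referent; the boundary p_bonf = α is
retained (inclusive).

## Cell-type association

The 0.1-FPKM background rule is applied to the **maximum** across the seven
cell types and read strictly ("did not rise above" ⇒ max > 0.1 retained);
whether the original analysis filtered per cell type or on the maximum is
not documented, so the choice is stated here. A source ID mapping to several
reference rows resolves to the row with the largest total expression (the
most reliably detected measurement) and the event is logged. Percentage
profiles are scale-free by construction, hence correlation distance
(1 − Pearson) with average linkage for clustering; a constant (uniform)
profile has undefined correlation, so the distance is defined as 0 between
two constant profiles and 1 against any varying one. Dendrogram output is
made deterministic twice over: ties in merge distance break on the
lexicographically smallest member IDs, and at each merge the subtree
containing the smallest ID goes left. Top-unique rankings break fold-change
ties lexicographically.

## The synthetic-data generator

The generator emulates the study design the pipeline targets, not any real
tissue: NB counts with 4 replicates per group; log-normal gene means
(natural-log location 4.0, scale 1 — a realistic bulk dynamic range, chosen
because no expression distribution is documented); log-normal per-sample
depth multipliers with CV 0.2 emulating pooling/depth variation; 5% planted
DE genes at a fixed |log2FC| of 2 with signs split evenly (a fixed magnitude
is the simplest structure that exercises the |log2FC| ≥ 1 threshold); one
annotation category enriched 5-fold for DE genes, built by direct placement
of round(size·fold·rate) DE members so the planted fold is exact, with
categories sampled independently so non-enriched categories are not
depleted; a 7-cell-type reference in which markers carry 95% of their
expression in one cell type, 5% of genes sit below the 0.1-FPKM background
everywhere, and 5% of source IDs are withheld from the ID map. All
randomness flows from one `default_rng(seed)` per generator call, so outputs
are bit-identical under a fixed config.

What it does **not** emulate: read-level artifacts, batch effects, pooling
as an explicit process (dispersion is exposed directly instead), correlated
gene modules, or age-dependent biology. Passing tests therefore demonstrate
that the machinery is correct and calibrated under its stated model — not
that the model captures every property of real cords.

## Problem sizes and numerics

The verification suite and the acceptance script use 5,000-gene simulations,
10 seeds for the power/FDR and enrichment recovery averages, and 4
replicates per group — the design point of the study this emulates and
comfortably sized for the statistics measured. The exact test's per-gene
cost is O(T) in the conditional support; at these count scales a full
three-scorer run on 5,000 genes takes a few seconds. Oracle comparisons
(BH step-up, binomial tails, dispersion-zero exact test, clustering
agglomeration) are asserted to 12 significant digits or better; percentage
profiles must sum to 100 within 1e-9. Degenerate inputs are defined, not
special-cased ad hoc: constant rows min–max-scale to 0.5, single-profile
clustering blocks pass through, empty blocks are skipped with a log entry,
and all-zero samples or empty study sets raise errors naming the offender.

## Known limitations

* The exact conditional test assumes a common dispersion across groups per
  gene and known (estimated) φ; with 3–4 replicates the estimate is shrunk,
  which trades a little power for calibration.
* The FPKM scorer reduces to total-count normalization by construction, so
  its disagreement with UQ/MOR is smaller than between fully independent
  published tools; the consensus voting still sees three distinct
  normalization regimes.
* Only two-group contrasts are supported — no covariates, GLM designs, or
  transcript-level inference.
* Cell-type association is descriptive (percentage profiles), not a
  statistical deconvolution of bulk mixtures.
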