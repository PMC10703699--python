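# Methods

This note records the statistical model behind `sortscreen`, the
assumptions it makes, the defaults and why, and the design choices taken
where the design was genuinely open.

## The sorted-bin screen model

A pooled library of gRNAs is delivered to cells at low MOI; after
expansion, cells are stained for a marker and the lower and upper
`f`-tails (default 10%) of its expression are sorted. Guides that shift
the marker change their representation between the LOW and HIGH bins.

The generative model the analysis assumes (and the simulator implements):
each cell carries one guide; its marker value is `Normal(δ_g, 1)`, where
`δ_g` is the guide's true shift in s.d. units (0 for non-targeting guides
and unperturbed genes). Sort thresholds are the `f` and `1 − f` quantiles
of the *null* marker distribution — perturbed cells are assumed to be a
small minority of the pool, so the thresholds are set by the unperturbed
majority. A guide's capture probabilities are then

    p_low(δ)  = Φ(Φ⁻¹(f) − δ)
    p_high(δ) = 1 − Φ(Φ⁻¹(1 − f) − δ)

and its expected log₂ fold change between bins is
`log₂(p_high/p_low)`, antisymmetric in δ. At δ = Φ⁻¹(0.9) ≈ 1.2816 and
f = 0.1 this gives p_high = 0.5, p_low ≈ 0.00519, log₂FC ≈ 6.59 — the
analytic anchor used in the tests and the acceptance script. Fixing the
marker s.d. at 1 is an identifiability convention: δ is measured in s.d.
units.

Sequencing counts per donor and bin are negative binomial around
depth-scaled expected abundances `a_gd · p_bin(δ_g)`, with per-donor
log-normal guide abundances (log s.d. 0.3 by default — a realistic
plasmid-pool width) and dispersion φ in the `var = μ + φμ²`
parameterisation (φ = 0 degenerates to Poisson). Defaults mirror the
screens the pipeline targets: 200 genes × 8 guides, 120 NT controls,
3 donors, f = 0.10, 300× depth per sample, φ = 0.05.

What the simulator does **not** emulate: PCR jackpotting and chimeric
reads, guide-level variation in editing efficiency, multi-guide cells in
the bulk screen, and any transcriptome beyond a single marker value.
Passing tests therefore demonstrate the statistics are correct *under the
stated model*, not that real screens meet its assumptions.

## Per-guide enrichment (`enrich`)

- **Normalisation.** Median-of-ratios size factors: per sample, the
  median over all-positive guide rows of `K_gj / geomean_g(K_g·)`. Rows
  containing any zero are excluded from the median; if no all-positive
  row exists the fit stops with an error suggesting a pseudo-reference.
  Note the geometric-mean reference makes size factors equivariant only
  up to a common constant: scaling one of *n* columns by *c* multiplies
  its factor by `c^((n−1)/n)` and every other factor by `c^(−1/n)`; the
  *relative* factors behave exactly.
- **Dispersion.** Per guide, the dispersion is profiled on a refined
  log₁₀ grid holding fitted means fixed, maximising the **Cox–Reid
  adjusted** likelihood `ℓ(α) − ½ log det(XᵀWX)`. The adjustment matters
  here: with 6 samples and 4 coefficients there are 2 residual degrees of
  freedom, and the unadjusted MLE is ~3-fold biased low, which inflates
  Wald statistics badly. A mean–dispersion trend `α_tr(μ) = a₀ + a₁/μ` is
  then fitted by **gamma-deviance minimisation** (mean-targeting; the
  sampling distribution of per-guide estimates is right-skewed, so a
  median-targeting robust fit would systematically undershoot), with one
  round of extreme-outlier exclusion (|log residual| ≥ 3). Final
  dispersions maximise the profile likelihood penalised by a normal prior
  on log α centred at the trend with fixed variance 0.25 (configurable;
  fixed rather than estimated for simplicity), clipped to lie between the
  raw and trend values in log space.
- **Numerical floors.** α is floored at 1e−8. Final values below ten
  times the floor snap to the floor — that band is numerically
  indistinguishable from Poisson. When the *median* raw estimate is at
  the floor, the data are treated as numerically Poisson and the trend
  collapses to the floor: the minority of nonzero estimates in that
  regime are pure selection noise and must not define a trend.
- **Test.** Per guide, an NB log-link regression with donor indicators
  and a HIGH-bin coefficient, fitted by IRLS vectorised across guides
  (shared design matrix, per-guide weights; a 1e−8 ridge and a linear
  predictor cap keep separated fits finite). The bin coefficient is the
  unshrunk log₂FC; SE comes from the observed information, two-sided p
  from the standard normal reference, one-sided p from the signed Wald
  statistic (`p_high + p_low = 1`). No fold-change shrinkage anywhere —
  the gene stage requires unshrunk estimates. No independent filtering or
  outlier replacement: screens have no within-guide replicates to
  justify them. Under complete separation (a bin with all-zero counts)
  the estimate stays finite via the cap but the Wald p suffers the
  Hauck–Donner effect; such guides are rare at the screens' coverage.
  On fully null simulated screens the two-sided p < 0.05 fraction is
  0.044–0.052 (nominal 0.05).
- **BH.** Step-up adjustment with missing values propagated and excluded
  from the family size.

The per-guide stage was cross-checked against the Bioconductor reference
implementation of this class of model on a small simulated screen:
log₂FC agrees to r > 0.999 (max |Δ| < 0.01) and −log₁₀ p to r ≈ 0.97
(the residual difference traces to its differently fitted dispersion
trend). Exact numerical agreement is not a contract; definitional
oracles and simulations are.

## Gene-level inference (`geneagg`)

- **Calibration.** The sorted two-sided NT p-values map to midpoint
  plotting positions `(i − 0.5)/n`, anchored at (0,0) and (1,1), with
  ties collapsed to their mean position; evaluation is piecewise-linear,
  clamped to [0,1]. Built separately for two-sided, HIGH and LOW
  one-sided p-values. At least 10 NT values are required (configurable
  floor). If NT guides are distributed like null targeting guides, the
  transformed null p-values are uniform by construction, whatever the
  parametric test's miscalibration — the property is verified on held-out
  draws from Beta(a,b) nulls with a,b ∈ {0.5, 1, 2}.
- **Aggregation.** `ρ = min_j BetaCDF(p(j); j, k−j+1)` over the sorted
  transformed p-values — the canonical order-statistic form of robust
  rank aggregation. The original method's "modification" is not specified
  anywhere we could find; since significance comes entirely from the
  simulated null rather than an analytic Beta bound, the exact ρ variant
  is second-order: any monotone variant yields the same empirical p up to
  Monte-Carlo error.
- **Simulated null.** For each realized gene size k, `N_sim` draws of k
  uniform p-values are aggregated to ρ. The uniforms live on the *raw*
  p-value scale (the null hypothesis the calibration enforces), so the
  pipeline pushes them through the same calibration map before computing
  ρ. This is not cosmetic: the map is shared by all genes, and when the
  smallest NT p-value happens to be large the map compresses the entire
  screen's tail at once; a null table that ignores the map then
  anti-calibrates exactly when it matters (in our null experiments, 4/25
  screens produced spurious BH hits without the shared-map null; 25/25
  were clean with it). Empirical p uses the +1 correction,
  `p = (1 + #{ρ_null ≤ ρ})/(N_sim + 1)`, never zero. `N_sim` defaults to
  10⁷ (chunked to bound memory); the tests and the acceptance script use
  10⁵, ample for FDR-level resolution.
- **NTC pseudo-genes.** NT guides are shuffled (seeded) and grouped by
  sizes drawn with replacement from the screen's guides-per-gene
  distribution until all NT guides are used; the final group takes the
  remainder. NTCs run through the identical pipeline.
- **FDR family.** BH runs jointly over genes and NTCs (they are analyzed
  the same way, so they belong to the same family); hit calls then
  exclude NTCs. Both choices are switchable.
- **Effect sizes.** `E_d = Σ w_i β_i / Σ w_i` with `w = 1 − p̃_d` from
  the direction-specific calibration. Weighting by the transformed
  p-value itself would up-weight the *least* significant guides, so the
  significance-increasing form is the default; the literal form is
  available behind `weight_mode="literal_p"`. The direction with larger
  |E| is chosen, ties toward HIGH (documented, arbitrary). A direction
  with zero total weight is undefined (NaN); both zero raises.

## Guide library design (`library`)

Spacer length is fixed at 21 nt by convention for this nuclease
(configurable); coordinates are 0-based half-open internally, spacer only
(PAM excluded), exported 1-based inclusive with a header note. The
off-target filter is ungapped Hamming distance evaluated only at
PAM-adjacent windows of a user-supplied background — a conservative,
self-contained reading of alignment-based library filters; it is not a
genome-scale index. A candidate is removed when any background window
other than one perfect self-match lies within the exclusion distance
(default: fewer than four mismatches). NT spacers are drawn from the
pooled mononucleotide composition of the targeting spacers
(position-independent — the matching requirement says composition, not
position), rejected on any near-match in the background or any duplicate
of an existing spacer, with a bounded draw budget. Genes whose windows
yield no surviving guide are reported as untargeted, never silently
dropped. Duplicate spacers across genes keep the first occurrence with a
warning.

## Quantification (`quantify`)

Reads are assigned by exact spacer lookup at a fixed offset, or at the
first occurrence of a constant scaffold anchor (`AUTO`), optionally
tolerating one substitution via the single-substitution neighbourhood.
Exact counting replaces read alignment deliberately: it is deterministic
and dependency-free, and with ≤1 mismatch it covers the dominant error
mode of short amplicon reads. Reads shorter than offset + spacer length,
anchor-less reads in AUTO mode, and unmatched spacers count as
unassigned; assigned + unassigned equals reads processed, always.
Coverage is column sum / library size (and sorted cells / library size
when cell counts are given), flagged below a configurable 300× floor.

## Single-cell assignment (`sc_assign`)

Cells failing transcriptome QC are discarded first (defaults: fewer than
200 detected genes, more than 20% mitochondrial, less than 5% ribosomal;
the discard rules are strict inequalities, so boundary cells are kept).
Guides are assigned where UMI > 4 (strict). Multiplet cells are excluded
from per-guide groups by default. The marker response test is a two-sided
rank-sum test of a guide's cells against the NT-only pool with Bonferroni
correction — a deliberate divergence from hurdle-model single-cell DE
(out of scope here); the test function is a pluggable seam. TP rate is
the fraction of tested screen-hit guides significant in the
screen-concordant direction (a non-directional variant is also reported,
since the original display's exact definition is not spelled out); TN
rate is the fraction of tested NT guides that stay quiet, each NT guide
tested against the NT-only cells not carrying it.

## Problem sizes

The test suite and acceptance script run the full pipeline at
200 genes × 8 guides + 120 NT × 6 samples (1,720 guides), 50 null screens
for the FDR check, 10⁵-draw null tables, and 10⁶-draw Monte-Carlo oracles
for the order-statistic checks — sizes at which every stochastic band in
the tests has comfortable Monte-Carlo margin while the whole suite runs
in about a minute.

## Known limitations

- Wald p-values under complete separation are conservative
  (Hauck–Donner); a conditional or likelihood-ratio test would do better
  but is out of scope.
- The dispersion prior variance is fixed, not estimated from the
  dispersion spread.
- The sort-threshold approximation (null-quantile bins) biases expected
  fold changes slightly when perturbed cells are a large fraction of the
  pool.
- The off-target filter sees only the background it is given; it is not
  a substitute for genome-scale specificity screening.
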