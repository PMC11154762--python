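# Methods

## Model and assumptions

The package implements summary-data two-sample Mendelian randomization.
A SNP is a valid instrument for an exposure X on an outcome Y if it is
(i) associated with X, (ii) independent of X–Y confounders, and (iii)
affects Y only through X. Under these assumptions each instrument's Wald
ratio r_j = β̂_Yj/β̂_Xj estimates the causal effect β, and the estimators
differ in how they pool ratios and in which violations they tolerate.

The two samples (exposure GWAS, outcome GWAS) are assumed independent
and drawn from comparable populations; effect sizes are per-allele
associations on standardized traits (or log-odds for binary outcomes).
Measurement error in β̂_X is ignored by the first-order ratio SE
(the "NOME" approximation), which is accurate for strong instruments —
hence the F > 10 screen.

## Instrument selection

Candidates are SNPs with exposure p strictly below the threshold
(5×10⁻⁸ primary; 5×10⁻⁶ secondary when the stricter cut leaves too few
instruments — both presets are exposed as Analysis "A"/"B"). Six filters
follow, in order, each appending `kept`/`removed` rows to a `FilterLog`
(the threshold itself is logged as step 0):

1. **LD clumping** — greedy by ascending p (ties broken by snp_id);
   an index SNP removes same-chromosome SNPs within 10,000 kb with
   r² ≥ 0.01 against it. LD comes from a user-supplied sparse table;
   absent pairs count as r² = 0 and are tallied as a warning counter,
   since silent sparsity would weaken the filter.
2. **Cross-exposure exclusivity** — a SNP instrumenting ≥2 exposures in
   the screened panel is removed from all of them.
3. **Confounder associations** — SNPs annotated to confounder traits
   (age, BMI, sex, weight, …) in a local annotation table are removed;
   the table replaces live PhenoScanner queries for reproducibility.
4. **Harmonization / palindromes** — outcome effects are re-oriented to
   the exposure's effect allele, resolving strand flips (reverse
   complements) automatically; palindromic A/T and C/G SNPs are removed
   outright rather than rescued by allele frequency. Instruments absent
   from the outcome GWAS are dropped (no proxy lookup).
5. **Outcome association** — harmonized instruments with outcome
   p < 5×10⁻⁵ are removed as potentially acting on the outcome directly.
6. **MR-PRESSO outliers** — run when ≥4 instruments survive; flagged
   outliers are removed in a single pass (not iterated).

All p-value comparisons are strict (<), so boundary values survive.
`min_instruments` defaults to 3 — the smallest count at which all three
estimators are defined; the threshold is configurable because "adequate
number of instruments" has no universal definition.

## Estimators

With ratios r_j and weights w_j = (σ_Yj/|β̂_Xj|)⁻²:

- **IVW**: β̂ = Σw_j r_j/Σw_j, fixed-effect SE (Σw_j)^(−1/2). The default
  multiplicative random-effects mode scales the SE by √φ,
  φ = max(1, Q/(J−1)); under-dispersion never tightens the interval
  (conservative by construction). p-values are two-sided normal; the 95%
  multiplier is fixed at 1.96. The ratio form is algebraically identical
  to zero-intercept WLS of β̂_Y on β̂_X with weights 1/σ_Y², and the test
  suite asserts both routes agree to 1e-12.
- **MR-Egger**: instruments are oriented so β̂_X ≥ 0 (negating both
  betas, which leaves ratios unchanged), then WLS with intercept,
  weights 1/σ_Y². The residual variance factor is max(1, RSS_w/(J−2));
  slope and intercept inference uses t(J−2), and the CI uses the t
  quantile rather than 1.96. The intercept test is the directional-
  pleiotropy diagnostic.
- **Weighted median**: ratios sorted; with normalized weights w′ the
  cumulative midpoints p_j = Σ_{k≤j}w′_k − w′_j/2 define a piecewise-
  linear quantile function evaluated at 0.5. The SE is the SD of the
  estimate over n_boot = 1000 parametric-bootstrap replicates (β̂_X and
  β̂_Y redrawn from normals at their observed values/SEs) with a
  user-visible seed; p from a normal approximation. The penalized-weight
  variant is deliberately omitted.

Binary outcomes additionally get exp(β̂) with an exponentiated CI
(odds-ratio scale); the caller decides which scale to present.

## Sensitivity diagnostics

- **Instrument strength**: per-SNP
  R² = 2β²pq / (2β²pq + 2σ²Npq) (p = EAF, q = 1−p; the 2pq factor
  cancels, making R² symmetric in p↔q, and the transcription is kept
  literal) and F = R²(N−2)/(1−R²). F > 10 is reported as a screen, not
  enforced as a filter.
- **Heterogeneity**: Cochran's Q = Σw_j(r_j − β̂_IVW-FE)², df = J−1,
  chi-square upper tail.
- **Power**: the cited interactive calculator's formula is not printed
  anywhere, so the standard two-sided asymptotic approximation is used:
  non-centrality ν = |β|√(N·R²) (times √(k(1−k)) for binary outcomes
  with case fraction k), power = 1 − Φ(z_{1−α/2} − ν) + Φ(−z_{1−α/2} − ν).
  Total instrument R² is the sum of per-SNP R² (independence after
  clumping). A Monte-Carlo z-test oracle validates the approximation in
  the test suite.
- **Influence**: leave-one-out IVW re-estimates (flagging sign changes
  and significance crossings) and per-SNP forest/funnel tables
  (ratio ± 1.96·SE; precision = 1/SE).

## MR-PRESSO

Observed statistic: RSS = Σ_j (β̂_Yj − β̂_{−j}β̂_Xj)², where β̂_{−j} is the
IVW slope excluding SNP j. The parametric null redraws
β*_Xj ~ N(β̂_Xj, σ_Xj) and β*_Yj ~ N(β̂_{−j}β̂_Xj, σ_Yj) k_sim = 1000
times, recomputing leave-one-out slopes within each replicate. Empirical
p-values use add-one smoothing (never zero): global on total RSS;
per-SNP on RSS_j, Bonferroni-adjusted by J, flagged below α = 0.05.
The distortion test compares the relative IVW shift after outlier
removal against the same contrast for 1000 random subsets of the outlier
count; it is reported but never used for filtering. Identical inputs and
seed give identical results.

## Orchestration

`run_bidirectional` runs every exposure×outcome pair forward, then
swaps roles (the reverse direction reuses the same selection config,
including the exposure threshold, applied to the outcome-trait GWAS).
The primary inference is multiplicative random-effects IVW at nominal
α = 0.05 with **no multiple-testing correction across the grid** — a
deliberate, documented caveat matching common MR screening practice; a
Benjamini–Hochberg matrix is emitted for reference only. Verdicts:
"unidirectional" (forward significant, reverse not), "bidirectional"
(both), "reverse_only", "none", or "undetermined" (too few forward
instruments). Per-pair seeds are derived deterministically from the run
seed and the pair's names, so full runs are byte-reproducible.

## Synthetic data: what it emulates, and what it does not

`simulate_dataset_pair` draws, per SNP: MAF ~ U(0.1, 0.4); true exposure
effect γ with magnitude ~ U(0.1, 0.3) and random sign; SEs from the
large-sample law σ = [2p(1−p)N]^(−1/2) for unit-variance traits;
observed β̂_X ~ N(γ, σ_X²) and β̂_Y ~ N(βγ + α, σ_Y²). Invalid SNPs
(configured fraction) receive a direct outcome effect
α = sign(γ)·N(mean, sd) — the sign convention defines pleiotropy
direction in the exposure-increasing orientation, so a non-zero mean
shifts every invalid ratio the same way regardless of which allele is
labelled "effect". Defaults: exposure N = 8293 (the pooled cytokine-GWAS
cohort size), outcome N = 254,894 (grip-strength meta-GWAS scale); the
γ and MAF ranges are chosen so that default instruments are plausibly
genome-wide significant at N ≈ 8000 with F in the tens-to-hundreds,
matching the instrument-strength regime the diagnostics target.

Deliberate simplifications: no individual-level genotypes; LD is emitted
as block-constant r² entries (enough to exercise the clumping contract,
not a realistic LD landscape); EAF is reported noise-free by default to
keep R²/F checks sharp; no case-control ascertainment beyond a case
fraction; exposure and outcome noise are independent (two-sample
design). A green simulation-based test therefore establishes correctness
of the statistical machinery under the stated generative model — not
robustness to real-data pathologies such as sample overlap, population
stratification, or winner's-curse-selected instruments.

## Numerical choices and degenerate inputs

- Strict inequalities at every p-value threshold; ties in clumping break
  lexicographically, making output order-independent.
- β̂_X = 0 raises a degenerate-instrument error for ratio computation;
  bootstrap draws that hit zero are nudged to the smallest positive
  float.
- Under-dispersion clamps: φ ≥ 1 (IVW) and σ² ≥ 1 (Egger) — intervals
  never shrink below their fixed-effect/homoscedastic baselines.
- Empirical resampling p-values use (1 + #{≥})/(k + 1).
- Harmonized output is sorted by snp_id; all estimators are permutation-
  invariant.

## Known limitations

No proxy-SNP lookup for instruments missing in the outcome GWAS; no
Steiger filtering, MR-RAPS, mode-based or multivariable estimators; no
I²/Rucker framework; LD must be supplied (no reference-panel
computation); plots are exported as data tables, not rendered figures.
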