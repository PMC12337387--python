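# Methods notes

This note records the modeling assumptions, parameter choices, numerical
decisions, and known limitations behind `eggarch`, in the order the
pipeline runs.

## Laying-curve models and the stage split

Weekly mean laying rates y_t ∈ [0,1] are fitted on model time
t = week_of_age − 20, so the recorded cycle (weeks 21–43 of age) maps to
t = 1…23. The offset matters: the Yang-Ning parameter d ("model-time of
first egg") is only interpretable, and the published stationary point only
reproducible, under this convention. Fitting is bounded nonlinear least
squares (`scipy.optimize.least_squares`, trf) from a fixed multi-start
grid (a ∈ {0.5, 0.8, 1.0}, b ∈ {0.005, 0.02, 0.05}, c ∈ {0.5, 1, 2},
d ∈ {1, 3, 5}); the best start by RSS wins. BIC uses the Gaussian
concentrated form n·ln(RSS/n) + k·ln(n). Parameters landing within 1e-6
of a bound raise the `at_bound` flag rather than an error — constant input
degenerates the Wood model this way.

The Yang-Ning stationary point is closed-form,
t* = d + ln((c−b)/b)/c for 0 < b < c, else the curve is monotone and no
stage split is defined. `segment_stages` floors t*+20 to end the up-stage:
up = 21…⌊week⌋, sustained = ⌊week⌋+1…43.

## Derived traits

Week w of age covers day columns 7(w−21)+1…7(w−21)+7; 23 weeks → 161
days. Per stage and individual:

- EV / WEV / BWEV — sample variance (ddof = 1) of weekly egg counts,
  weekly rates (counts/7), and bi-weekly rates (counts/14; trailing odd
  week dropped). EV and WEV differ only by the 1/49 scale; both are kept
  because both appear in the trait panel this package mirrors.
- WMLR / BWMLR — max weekly (bi-weekly) count / 7 (14).
- Clutch structure — clutches are maximal runs of 1s; intervals are
  maximal runs of 0s strictly between the stage's first and last egg
  (pre-onset and post-cessation zeros reflect maturity, not gaps).
  CPN and TCS count all clutches; ECI = TCS₍c≥2₎/CPN₍c≥2₎ and
  II = (#intervals)/CPN₍c≥2₎ are restricted to effective clutches
  (length ≥ 2) and are missing when none exists.
- LIT — days from first to last egg inclusive; TILI/MILI/AILI — sum, max,
  mean of interval lengths (0 when there are no intervals).

These concrete definitions are this package's normative interpretations
of the trait panel; where the upstream trait glossary is ambiguous (EV vs
WEV, LIT) the interpretation is stated here rather than hidden.
The 3σ filter is a single pass per trait column (mean ± 3·SD, ddof = 1);
it is intentionally not iterated. A `mean_fill` utility exists for
convenience but makes no fidelity claim (the upstream workflow used a
random-forest imputation that is out of scope here).

The per-trait desirable-direction registry (`traits.TRAIT_DIRECTION`)
drives BHA/UHA polarity: intensity/production traits are
higher-is-better; variance and interval traits lower-is-better. ECI is
higher-is-better, TILI lower-is-better.

## Synthetic cohorts

The generator's job is statistical structure, not demographic realism:

- **Haplotypes** are copied from a founder pool (default 8 founders,
  per-site founder frequency ~ U(0.05, 0.95)) with per-SNP template
  switching at `recombination_prob` (default 0.01). This produces
  block-scale LD tunable by one parameter and is exactly reproducible
  from the seed. It is not a coalescent: its site-frequency spectrum and
  window-level D/π distributions are not neutral-theory quantities (the
  neutral-coalescent checks in the test suite use msprime for exactly
  that reason).
- **Singletons** are injected as brand-new private sites at
  `mutation_density` per haplotype per Mb (Poisson counts per haplotype
  per chromosome), never reusing a position, so singleton-based statistics
  have exact ground truth (`meta['singletons']`). `inject_singletons`
  accepts per-haplotype rates, which is how selective sweeps are emulated:
  haplotypes with high trait-increasing allele content get proportionally
  sparser singletons.
- **Laying records**: weekly probability
  p_iw = clamp(YangNing(w−20) + g_i + e_i, 0, 1), daily Bernoulli draws.
  The genetic value g is the planted-QTL dosage score, centered and scaled
  so var(g)/(var(g)+var(e)) = `h2_target` with total latent SD
  `individual_sd` (default 0.15 on the rate scale — roughly the
  between-hen spread a real cohort shows). Genetic effects therefore act
  additively on the probability scale, matching the additive association
  models downstream; the clamp keeps probabilities valid and is the main
  nonlinearity the GWAS models do not see. Day-level Bernoulli noise
  dilutes the latent h² slightly when traits are computed from finite
  records.
- **Population panels** perturb per-site allele frequencies by one bounded
  uniform step of magnitude `drift` (E|shift| = drift/2 away from the
  boundaries) and sample haplotypes site-independently. Panel 5-mer
  frequencies are therefore near products of marginals — sufficient for
  enriched-score machinery, not a model of inter-population LD.

Defaults (600 individuals, 5 × 1,000 SNPs, 10 Mb chromosomes) are the
package's standing study conditions; tests state smaller sizes explicitly
where they use them.

## Mixed-model machinery

All single-component REML goes through one code path
(`lmm.fit_null_lmm`): eigendecompose the relationship matrix once, profile
the restricted likelihood over δ = σ²ₑ/σ²_g on the rotated data, optimize
log δ by a 49-point grid plus bounded Brent refinement. Scans whiten with
the fitted V^(−1/2) and run per-column OLS t-tests with the residual scale
re-estimated per column; with an identity GRM this reduces *exactly* to
OLS, which is the calibration anchor the unit tests assert to 1e-10.

The haplotype scan is deliberately two-step (null mixed model once,
conditional residuals ê = y − Qα̂ − ĝ regressed on each block's
combination factor) — the per-block exact test is reserved for the test
suite's cross-check, which demands Spearman ρ ≥ 0.9 between the two.
Combination levels with fewer than 5 carriers merge into one "rare" level
to avoid saturated one-way designs. Allele effects are estimated jointly
across significant blocks by default (per-block mode via `joint=False`),
dropping the most frequent allele per block as reference and pruning
collinear dosage columns by pivoted QR.

## EM-REML for two GRMs

The two-component model uses the classical EM update
σ²ᵢ ← [σ⁴ᵢ y′PKᵢPy + tr(σ²ᵢI − σ⁴ᵢPKᵢ)]/n, which keeps the restricted
likelihood non-decreasing (asserted in tests). Components are floored at
1e-8·var(y); a pinned component triggers one jittered restart. Stopping:
relative component change < 1e-6 (default), a likelihood plateau at
1e-3·tol relative, or 500 iterations. EM is slow near the boundary —
that is accepted in exchange for monotonicity and easy verification
against the exact single-component fit (agreement to 1e-6 when one GRM is
zero). Per iteration the only O(n³) operation is one Cholesky inversion;
traces use elementwise products.

## CCA scan

With a single dosage on one side, the first canonical correlation
satisfies ρ² = R² of regressing dosage on the traits, computed via the
pseudo-inverse of the trait covariance (derived traits can be exactly
collinear — EV and WEV — and pinv handles that). Significance uses
Bartlett's χ² = −(n − 1 − (q+2)/2)·ln(1−ρ²) on q df, with n the
post-listwise-deletion count. Trait-side coefficients are reported on
standardized traits, scaled to a unit-variance canonical variate, sign
fixed so the first (nonzero) coefficient is non-negative — that makes
cross-stage coefficient comparisons reproducible. Constant genotypes get
the p = 1 sentinel. The genotype-by-stage interaction model is a plain
two-way fixed-effect OLS with an F-test for the interaction block and
Bonferroni-adjusted per-genotype-within-stage contrasts against the
stage's mean of genotype means (a balanced-design estimated-marginal-mean
contrast).

## Singleton-density scores

The raw score is a gap-ratio surrogate for the full tip-branch-length
likelihood formulation of the singleton density score: per haplotype, the
distance from the test SNP to the nearest carried singleton upstream plus
downstream (a missing side doubles the available side; haplotypes with no
singletons are excluded), then
rSDS = ln(mean gap | alt) − ln(mean gap | ref). Its absolute scale is not
comparable to the likelihood-based score — only sign and rank behavior are
claimed, which is what the bin-standardization, windowing, polarization,
and trend statistics consume. Reference/alternative (not
ancestral/derived) polarity is used throughout. Standardization bins are
0.005 wide on alternative-allele frequency in [0.05, 0.95]; bins under 10
SNPs merge into their nearest neighbor. Window assignment for mSDS and
D/π uses pos // window_size with BED-style output.

Tajima's D uses the textbook a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ constants
with S segregating sites per window; π sums k(n−k)/C(n,2) per site and is
reported per bp.

## Prediction protocol

Per repeat, a fixed validation set (default 100) is drawn and excluded
from all training; the remainder is split into 10 folds; each fold's
training portion re-runs block discovery (HGWAS with FDR ≤ 0.05, falling
back to nominal p < 0.05, then the 5 smallest p so the predictor is never
undefined) and effect estimation; predictions are correlated with observed
phenotypes on the validation set and averaged over folds, then repeats.
A hard leakage guard raises if any validation individual reaches a
training design. Re-discovery inside each split is the default because
reusing whole-data discovery leaks; the leaky variant is available
explicitly (`reuse_discovery=`) for comparison.

## Problem sizes in the test suite

The statistical acceptance tests run at desk scale, chosen as the sizes
at which each property is comfortably identifiable: scan calibration on
three 500 × 2,000 cohorts pooled; planted-QTL power at n = 600;
variance-fraction recovery (2:3:5) at n = 600 over 10 seeds; tSDS trend
signs at n = 120 with 1,500 backbone SNPs over 10 seeds per direction;
prediction protocol at n = 220 with scaled-down CV (50-validation /
5-fold / 3-repeat). The demo pipeline defaults to 300 × 1,500 markers and
reduced CV (5-fold × 3) so a full end-to-end run stays interactive.

## Known limitations

- The founder-pool generator has no demographic interpretation; absolute
  selection/diversity statistics on it are internally consistent but not
  neutral-theory calibrated.
- The gap-ratio SDS is a surrogate (see above); no Ne-based gamma-shape
  estimation is performed.
- Haplotype blocks are fixed five-SNP windows; no LD-adaptive boundaries.
- EM-REML reports no standard errors, and supports exactly two genomic
  components.
- The interaction model's post-hoc contrasts assume the cell-means
  parameterization; heavily unbalanced designs will have conservative
  Bonferroni adjustment.
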