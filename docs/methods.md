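# Methods

## Model

Two-sample summary-statistic MR. For variant *j*, the exposure GWAS
reports β̂_Xj ≈ N(γ_j, σ²_Xj) per SD of the exposure; the outcome GWAS,
in a disjoint sample, reports β̂_Yj ≈ N(θγ_j + α_j, σ²_Yj) on the log-odds
scale for binary outcomes. θ is the causal effect of one SD of exposure;
α_j is a direct (horizontally pleiotropic) effect, zero for valid
instruments. All estimators operate on the harmonised pairs
(β̂_Xj, β̂_Yj) with first-order weights w_j = 1/σ²_Yj (ratio-scale weights
β̂²_Xj/σ²_Yj where ratios are combined); second-order weights and exposure
measurement-error corrections (e.g. I²_GX-adjusted Egger) are out of scope.

Estimators:

- Wald ratio θ̂ = β̂_Y/β̂_X with SE σ_Y/|β̂_X| (first-order delta method;
  accurate when the instrument F = (β̂_X/σ_X)² is well above 10 — at F = 625
  the parametric-bootstrap SE differs by ~2%, at F = 100 with a large ratio
  it can differ by ~10%).
- IVW: origin-constrained WLS, θ̂ = Σw_jβ̂_Xjβ̂_Yj / Σw_jβ̂²_Xj. The
  headline model is multiplicative random effects, variance inflated by
  φ = max(1, Q/(k−1)); the fixed-effect variant is always reported
  alongside. φ ≥ 1 makes the default mildly conservative under exact
  homogeneity (type-I error ~4% at nominal 5% with k = 30).
- MR-Egger: WLS of β̂_Y on β̂_X with free intercept after orienting every
  pair to β̂_X ≥ 0 (a joint sign flip is model-invariant; orientation makes
  the intercept interpretable as mean directional pleiotropy). Both SEs are
  scaled by max(1, √(RSS/(k−2))). Normal (not t) reference throughout, for
  consistency with IVW; t-based implementations will give slightly wider
  intervals at small k.
- Weighted median: order ratio estimates, weight w_j = β̂²_Xj/σ²_Yj
  normalised, interpolate the cumulative-weight midpoints at 0.5. SE by
  parametric bootstrap (default 1000 replicates, mandatory explicit seed;
  resamples both β̂_X and β̂_Y from their sampling distributions).
- Cochran's Q with first-order weights around the IVW estimate,
  chi-square(k−1) reference; leave-one-out IVW with the maximum absolute
  deviation reported.
- 95% intervals use z = 1.959963984540054 throughout.

Instrument selection: variants below 5×10⁻⁸ are greedily clumped (index =
smallest p; remove same-chromosome variants within 10,000 kb at r² ≥ 0.01);
if none qualify the threshold relaxes to 5×10⁻⁷ and the set is flagged;
still none ⇒ the exposure is uninstrumentable (a flag, not an error). Ties
in p break by chromosome, position, then id, making clumping invariant to
input order. Proxies for variants absent from an outcome GWAS require
r² ≥ 0.8 (ties: smaller distance, then id). Per-SNP strength uses
F = (β̂/σ)² and r² = 2β̂²·eaf·(1−eaf) (fallback F/(F+n−2) without eaf);
the cumulative F is the joint-regression form
(R²/(1−R²))·((n−k−1)/k) with R² = Σ per-SNP r² capped at 0.99, valid after
clumping when instruments are approximately independent. Cis filtering
keeps variants within a flank (default 100 kb, configurable) of the
encoding gene, 1-based inclusive bounds.

Harmonization policy: non-palindromic variants resolve from allele letters
(match ⇒ keep; swap ⇒ negate beta, complement eaf; strand complement
applied first when needed). Palindromic variants carry no strand
information in their letters; orientation is inferred from effect-allele
frequencies only when both sides fall outside the ambiguity window
(default 0.42–0.58): same side of 0.5 ⇒ same allele, opposite sides ⇒
flip. Any frequency inside the window, or missing, drops the variant as
ambiguous (palindromic variants are always dropped when a frequency is
missing). An optional letters-only mode keeps palindromic variants under a
same-strand assumption. Duplicate ids within a file keep the smallest-p
row; missing p-values are recomputed as two-sided normal from beta/SE.

Power (binary outcome): with case fraction p, the IVW/Wald statistic has
approximate non-centrality √(N·R²·p(1−p))·|ln OR|, so power at two-sided
level α is Φ(ncp − z₁₋α/₂) + Φ(−ncp − z₁₋α/₂). At the study configuration
(N = 79,145; 24,087 cases; OR 1.1/SD; α = 0.05) this gives 57.0% at
R² = 3% and 85.6% at R² = 6%, bracketing the 60–80% range quoted for that
design. The formula is monotone in N, R² and |ln OR| and symmetric in
OR ↔ 1/OR.

## Synthetic data

The generator emulates the data layout of the cytokine-Alzheimer's design;
its defaults are the study's conditions: exposure GWAS n = 8,293 (the
largest cytokine cohort), binary outcome GWAS n = 79,145 with case
fraction 24,087/79,145, MAF ~ U(0.05, 0.5), γ_j ~ N(0, 0.15) (per-SNP F
mostly 20–300, matching the reported instrument-strength range), θ = 0.1
(OR ≈ 1.1/SD, the effect size the power analysis targets), 30 instruments.
Standard errors use the GWAS approximation σ = 1/√(2N·maf(1−maf)), inflated
by 1/√(p(1−p)) for the binary outcome; SEs are not themselves resampled.
Pleiotropy regimes: balanced (zero-mean α), directional (non-zero mean α
independent of γ — InSIDE holds, so Egger stays consistent while IVW is
biased), and InSIDE-violating (α correlated with γ, biasing Egger too).
The two samples are always disjoint (no overlap modelling), instruments
are generated mutually independent (post-clumping assumption), and
covariate adjustment of the source GWAS (sex, age, BMI) is represented
only by its absence — collider effects of the BMI adjustment are not
simulated. Passing tests therefore demonstrate estimator correctness under
the stated sampling model, not robustness to sample overlap, LD
misspecification or selection effects in real data.

An individual-level path (binomial genotypes, shared confounder, unit-
variance exposure, linear or logistic-score outcome GWAS with the logistic
intercept solved to hit the target case fraction) backs the summary-level
shortcut; the two agree distributionally and are cross-checked by a KS
test. A deliberate guard (≤10⁸ genotype draws) keeps it at desk scale.
`scramble_alleles` corrupts allele coding (seeded swaps, strand flips,
palindromic redesignation) and returns the clean reference alongside, so
harmonization can be verified variant by variant; `make_ld_blocks` builds
block-diagonal LD for clumping tests.

## Validation experiments and problem sizes

The test suite and `scripts/acceptance.py` run, at sizes chosen to keep the
whole suite around ten seconds: 1000 replicates for effect recovery
(mean IVW within 0.005 of θ = 0.1; 95% CI coverage 93–97%) and type-I error
(null θ, band 3.2–6.8%); 500 replicates per directional-pleiotropy arm
(40% invalid weight: weighted median less biased than IVW in ≥90% of
replicates, mean Egger intercept within Monte-Carlo error of the simulated
mean pleiotropy; 60%: the median escapes the valid-ratio range in most
replicates); 200-variant harmonization round-trips; 500 random ≤12-variant
clumping instances against a brute-force restatement of the greedy rule;
2000 10-instrument homogeneous datasets for the chi-square(9) calibration
of Q. The Q calibration uses a null causal effect because, with first-order
weights, Q is then exactly chi-square(k−1) conditional on the exposure
betas — the oracle is exact rather than asymptotic. The directional-
pleiotropy arm uses γ ~ N(0.25, 0.07) (all instruments oriented
exposure-increasing — the orientation that makes directional pleiotropy
bias IVW) and α ~ N(0.1, 0.01); a narrower γ spread leaves Egger weakly
identified and its intercept attenuated by regression dilution, which is a
property of the estimator, not a bug, and is avoided in the consistency
check by design.

IVW and Egger are verified against statsmodels WLS (independent route) to
1e-10; the estimators themselves are implemented from the closed-form
normal equations and do not call statsmodels.

## Numerical choices and degenerate inputs

- Exact float round-trip on all tables (%.17g out, round-trip parsing in).
- p-values clamped into (0, 1] (underflow protection).
- β̂_X = 0 for a single instrument, or all zero, is an estimation error;
  k < 3 raises a typed "not estimable" signal for Egger/median/LOO, which
  the pipeline converts to flags rather than failures.
- Cumulative F undefined for n ≤ k+1; r² fallback undefined without eaf
  and n (flagged None).
- Clump/proxy treat variants missing from the LD matrix as unlinked, with
  a warning.
- Grid runs are deterministic given inputs and the base seed; per-pair
  bootstrap seeds derive from a CRC of (exposure, outcome, seed), so
  adding a pair never changes another pair's results.

## Known limitations

No multivariable MR, MR-PRESSO, mode-based estimators, Steiger filtering
or winner's-curse correction; no LD-aware effect simulation; no VCF input,
liftover, or INDEL alleles; proxy substitution uses the local LD matrix
only (no external lookups). Score ("OR-labelled" linear) outcomes are
exponentiated like binary ones but explicitly labelled, since the effect
is per SD of a score rather than a log odds.
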