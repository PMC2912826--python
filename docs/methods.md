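# Methods

`socsurv` estimates direct and associative (social, indirect) genetic effects
on survival time in group-housed animals — the motivating case is mortality
from cannibalism in laying hens kept four to a cage — and compares two
estimation routes by cage-wise cross-validation. This note records the models,
the numerical choices, and what the synthetic data do and do not establish.

## The problem

Survival time of a hen depends on her own genes (direct effects, breeding
value `a_D`) and on the genes of her cage mates (associative effects, `a_S`):
a pecking cage mate shortens everyone else's life. Two features make the trait
hard: half to three quarters of the records are right-censored (the hen is
still alive when the study ends), and standard survival software has no slot
for the cage mates' genetic effects. The package therefore implements a
two-step route ("2STEP") alongside the direct linear route ("LAM"):

1. **Step 1 — Cox frailty animal model.** Hazard
   `λ_i(t) = λ_0(t)·exp(x_i'β + a_i)` with `a ~ N(0, σ²_a A)`, `A` the
   additive relationship matrix from the pedigree. Fixed effects are one
   class per house × row × level combination plus the mean survival days of
   the back (neighbouring) cage. The fit yields per-animal effects `â_i`
   on the log-hazard scale and cumulative risks
   `ω_i = Λ̂_0(t_i)·exp(x_i'β̂ + â_i)`.
2. **Linearization — pseudo-records.** Each animal contributes one weighted
   linear record `ỹ_i = â_i + (δ_i − ω_i)/ω_i` with weight `ω_i` (δ the
   0/1 censoring code). At the Breslow optimum the score equation is
   `δ − ω = A⁻¹â/σ²_a`, which is exactly the mixed-model equation for `â`
   on `(ỹ, ω)`: a univariate weighted BLUP on the pseudo-records reproduces
   the survival EBVs to machine precision. `verify_equivalence` computes this
   correlation after every two-step fit; it is the method's built-in validity
   check.
3. **Step 2 — associative-effects mixed model.**
   `ỹ = 1μ + Z_D a_D + Z_S a_S + e` with genetic covariance
   `Var([a_D; a_S]) = G0 ⊗ A`, `G0 = [[σ²_AD, σ_ADS], [σ_ADS, σ²_AS]]`;
   `Z_S` links each record to its n−1 cage mates. Residuals of cage mates are
   correlated: `Var(e_i) = σ²_e/ω_i`, `Cov(e_i, e_j) = ρσ²_e/√(ω_i ω_j)`
   within a cage (ρ is a correlation of standardized residuals; the
   heterogeneous-weight cross term is not fully determined by a CORU-style
   structure, and this choice keeps each cage block a correlation matrix
   after standardization). For the 2STEP path σ²_e is fixed to one and the
   fixed part is an intercept (fixed effects were absorbed in step 1); the
   LAM path fits observed survival days directly with unit weights, the full
   fixed-effect design and all five components free.

Derived quantities (group size n, unrelated cage mates):

- total breeding value `TBV_i = a_D,i + (n−1)·a_S,i`;
- total heritable variance `σ²_TBV = σ²_AD + 2(n−1)σ_ADS + (n−1)²σ²_AS`;
- phenotypic variance `σ²_P = σ²_AD + (n−1)σ²_AS + σ²_e` (ρ and cage-mate
  genetic covariances do not enter an individual's own variance);
- `T² = σ²_TBV/σ²_P`, the social generalization of heritability (may exceed
  h² and even 1); `r_A = σ_ADS/√(σ²_AD σ²_AS)`.

Standard errors of derived quantities are first-order delta method on the
inverse average-information matrix.

## Estimation choices

**Breslow ties.** Daily observation produces many tied death times; all
partial-likelihood quantities use the Breslow convention, which also keeps the
pseudo-record algebra exact.

**Mode finding.** At fixed σ²_a, (β, a) is maximized by Newton steps with
step halving on the penalized partial log-likelihood; the Hessian is the exact
Breslow curvature (diagonal minus a sum of risk-set rank-one terms) plus
`A⁻¹/σ²_a`, assembled densely and factorized by Cholesky.

**Estimating σ²_a.** The default is an iterated-linearization REML: at the
current σ², compute the mode and the working records (ỹ, ω), then estimate σ²
by exact REML in the univariate working model `ỹ = 1μ + a + e`,
`Var(e) = diag(1/ω)` (one eigendecomposition of the whitened kernel makes the
restricted likelihood O(n) per candidate, searched by golden section on
log σ²), and repeat to a fixed point. A Laplace-approximate marginal
likelihood (profile the mode, subtract half the log-determinant of the
penalized curvature) is available as `sigma2_method="laplace"`, but with one
record per frailty term it is materially biased upward — on data simulated
with no genetic variance its profile peaks near σ² ≈ 1.4 while the
working-model REML stays near zero — so it is not the default. The
two routes agree on which animals rank where; only the variance scale
differs.

**ω convention.** The weight uses the full linear predictor including `â_i`.
The BLUP-equivalence property holds exactly for this working weight; a
`weights="fixed_only"` switch preserves the narrower reading (fixed effects
only) for comparison.

**AI-REML.** Step 2 maximizes the restricted likelihood of
`V(θ) = σ²_AD K_DD + σ_ADS(K_DS + K_DS') + σ²_AS K_SS + σ²_e(D + ρC)` by
average-information steps with step halving, parameterized so every iterate
is valid: `G0 = LL'` with log-Cholesky `L` (positive semidefinite by
construction), ρ through a logistic map onto `(−1/(n−1), 1)` (the positive-
definiteness range of the cage residual block), σ²_e through log. When the
optimum sits on the singular-`G0` boundary (|r_A| → 1, common in small
samples) AI steps creep, and an L-BFGS-B polish with the analytic gradient on
the same transformed surface finishes the job; such fits carry a `boundary`
flag. Convergence: |Δ restricted loglik| < 1e-8 (config-overridable).
Standard errors come from the inverse AI matrix at the optimum. BLUPs are
computed as `û = G Z'P y`, which solves Henderson's mixed-model equations
(verified against a dense MME assembly in the tests).

**Fixed-effect designs.** The first house×row×level class in sort order is
the reference. Columns that are linearly dependent given an (implicit)
intercept are dropped — in small training folds the back-cage covariate can
be exactly collinear with the class dummies (one cage pair per class).

## Cross-validation

Cages are dealt round-robin into k = 5 folds within each fixed-effect class
(seeded shuffle plus a random starting fold per class, so classes with fewer
cages than folds still spread over all folds). Each fold is held out once;
both routes are refit on the training 80% and held-out animals are predicted
from training EBVs: CBV (classical direct-only model: the survival `â` on the
2STEP path, a direct animal model on the LAM path), DBV (own `â_D`), SBV (sum
of cage mates' `â_S`), DSBV (DBV + SBV). Two-step predictions are hazards and
are multiplied by −1 before ranking. Reported per method × mode: pooled
best/worst 25% groups (mean observed days ± SE, Kaplan-Meier curves,
best−worst difference), the best-group overlap between methods, the
censoring-aware rank correlation (mean ± SD/√k over folds) and an approximate
accuracy.

**Censoring-aware rank correlation.** Uncensored animals are ranked by their
fixed-effect-adjusted observed days; every censored animal receives the
average of the remaining ranks n+1..N. Because each hypothetical ordering of
the censored animals is a permutation of those ranks, the denominator keeps
the *untied* rank variance; with that convention the statistic equals the
expectation of Spearman's correlation over uniformly random censored
orderings exactly (enumerated small cases agree to 1e-10). Observed
phenotypes are adjusted with the linear-route fixed-effect solutions (a
choice that, if anything, favours the linear route); censoring status itself
is never altered by the adjustment.

**Approximate accuracy.** `r_IH = r̂ / ρ_max` with
`ρ_max = √((σ²_AD + (n−1)σ²_AS)/σ²_P)` — the ceiling a rank correlation can
reach when breeding values are known without error. Components on the
observed-day scale (the linear-route estimates) are used for both methods.

## Synthetic data

The generator mirrors the study design: founder sires each mated to 8 dams,
Poisson(12.3) female offspring per dam, random 4-bird cages, house × row ×
level classes (2 × 8 × 3 by default), symmetric back-to-back cage pairing
(the back-cage covariate is the realized mean survival of the paired cage,
computed after simulation), and a common study end at day 406 (~58 weeks)
giving 50–75% censoring depending on the baseline. Breeding values follow
`A ⊗ G0` exactly (parent average plus Mendelian sampling with
inbreeding-adjusted variance). Survival is generated either on the hazard
scale (Weibull baseline, shape 2, scale 570 days; social effects additive on
the log hazard — the same scale on which step 2 estimates them) or on the
linear scale (cage-correlated Gaussian residuals; the generative model the
direct linear route assumes). Default `G0` is typical of layer lines on the
log-hazard scale (σ²_AD = 0.31, σ²_AS = 0.041, r_A = 0.13). An optional
scenario re-censors a fraction of the censored records at an earlier day
(e.g. half of them at day 200) to create variable censoring times; a small
uniform-time "removal" fraction is available and defaults to zero.

What the generator does not emulate: age-batch confounding beyond class
labels, behavioural dynamics of cannibalism (social effects are constant on
the log hazard), multi-generation selection, or line differences (one line
per dataset; the analysis is per line throughout).

**What passing tests show.** On linear-scale data the LAM route recovers all
five generating components (20 replicates of ~500 cages: every component's
2-SE interval covered truth in all replicates when measured here). On
hazard-scale data the two-step route detects the social variance as positive
and recovers the direct variance within its uncertainty, but transfers social
variance in attenuated form — step 1 ignores social effects, and censored
animals enter the linearization as the constant `â_i − 1` — so hazard-scale
closure is checked directionally, not as unbiased recovery. Real data add
structure (selection history, non-proportional hazards, behavioural feedback)
that no closure test here speaks to.

**Problem sizes.** Test populations are scaled to a few hundred cages so the
full suite runs in minutes on one CPU; small populations use a
proportionally reduced fixed-effect grid (e.g. 2 × 2 × 2) to keep ~8 or more
cages per class, since with only one cage pair per class the Cox fixed
effects separate (classes without deaths). The qualitative cross-validation
comparisons (combined direct+social predictions beat direct-only; the
survival route beats the linear route when censoring times vary) use
generators with strong social/genetic signal so that a ~400-bird experiment
is informative; they are asserted as majorities over 20 fixed seeds.

## Known limitations

- σ²_a from the iterated linearization inherits the usual working-model
  (PQL-style) approximation; its scale should be read together with the
  step-2 estimates rather than as a gold-standard frailty variance.
- Attenuation of hazard-scale social variance through the linearization is
  structural (see above); between-scale comparisons of variance components
  are not meaningful, which is precisely why cross-validation on observed
  days is the comparison device.
- Boundary solutions (|r_A| = 1) occur regularly in small samples; they are
  flagged, and their AI-based standard errors are optimistic.
- The cross-validated accuracy formula is approximate by construction (ranks
  instead of phenotypes; hazards instead of days on the two-step side).
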