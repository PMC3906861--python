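# Methods

## The model

Group-housed fish interact: an individual's genes affect not only its own
phenotype (the direct genetic effect) but also the phenotypes of its tank
mates (the social, or indirect, genetic effect). The package implements the
two univariate animal models used to quantify this in a tank experiment with
Atlantic cod juveniles.

Conventional animal model:

    y = Xb + Z_D a_D + W_c c + W_t t + e

Social animal model:

    y = Xb + Z_D a_D + Z_S a_S + W_c c + W_t t + e

with

* `y` — trait vector (one recording of one trait per analysis);
* `b` — fixed effects: intercept, age at recording (centred covariate), and a
  scorer factor for fin-length traits (three persons measured the digital
  images; first-level-reference contrasts);
* `a_D`, `a_S` — direct and social additive genetic effects over *all*
  pedigree individuals, with Var([a_D; a_S]) = G ⊗ A, where
  G = [[σ²_AD, σ_ADS], [σ_ADS, σ²_AS]] and A is the numerator relationship
  matrix;
* `c` — common rearing-environment effect (full-sib families were reared in
  separate tanks before the experiment), Var = σ²_c I;
* `t` — experimental-tank effect, Var = σ²_t I (fitting the tank is
  equivalent to fitting a shared non-genetic social environment);
* `e` — residual, Var = σ²_e I.

Row i of `Z_S` carries a 1 for every tank mate of fish i and 0 for i itself,
so `(Z_D + Z_S)` rows sum to the group size n. A fish whose own phenotype is
missing (mortality) loses its row in `y` but keeps its genetic column: its
genes still acted on its tank mates.

### Derived parameters

For group size n (nominal 21 fish per tank):

    σ²_TBV = σ²_AD + 2(n−1)σ_ADS + (n−1)²σ²_AS          total heritable variance
    σ²_P   = σ²_AD + (n−1)σ²_AS + σ²_c + σ²_t + σ²_e    phenotypic variance
                                                         (unrelated group mates)
    T²     = σ²_TBV / σ²_P
    h²     = σ²_AD / σ²_P
    r_AS,AD = σ_ADS / √(σ²_AD σ²_AS)

T² can exceed 1 because an individual's total heritable impact is spread
over its whole group; values above 1 are reported as-is (with large standard
errors at this experiment's size). `n` defaults to the nominal 21 and is
configurable; the nominal value reproduces the published percentage
partition of σ²_TBV for first-dorsal fin length (21.5 / 33.1 / 45.4%).
Standard errors of derived parameters use the first-order delta method on
the REML sampling covariance; for near-boundary components these are known
to be optimistic, and a parametric bootstrap (refitting simulated
replicates) is the recommended alternative when it matters.

## REML implementation

The restricted log-likelihood is evaluated through the sparse mixed-model
equations, never through a dense V:

    logL = −½ [(N−p) log 2π + N log σ²_e + log|D| + log|C| + yᵀPy]

with C = MᵀM/σ²_e + diag(0, D⁻¹), M = [X Z], D the random-effect covariance
block-diagonal (G ⊗ A for the genetic pair, built from the sparse A⁻¹ by
Henderson's rules with Meuwissen–Luo inbreeding). log|A| comes free from the
pedigree factorization (log|A| = Σ log d_i over Mendelian variances).

Numerical choices that matter:

* **Elimination order.** Generic fill-reducing orderings (COLAMD/MMD) fail
  badly on the social model: each tank couples 21 direct + 21 social columns
  into a clique, and the fill explodes (~10⁷ factor nonzeros at 2100 fish).
  The package orders unknowns tank by tank (each tank's offspring genetic
  columns, then ancestors, then environmental and fixed columns), which
  keeps elimination local (~3×10⁵ nonzeros, ~70× faster). SuperLU is run in
  symmetric mode with diagonal pivoting on this fixed order.
* **Parameterization.** Variances are optimized on the log scale and G
  through its Cholesky factor, so positivity and PSD constraints hold by
  construction. The residual-relative floor for pinning a variance to the
  boundary is 1e−8 × var(y); pinned components are reported as exact zeros
  with a boundary flag.
* **Optimizer.** Bounded L-BFGS-B with finite-difference gradients
  (step 1e−6 on transformed scale), from two starts for the social model
  (an equal-split start and a near-null start with σ²_AS ≈ 0 — the latter
  guarantees the social optimum is never below the nested conventional
  optimum), followed by a short Nelder–Mead polish (≤ 60·dim evaluations)
  that triggers a re-run only if it finds a materially better point
  (> 5e−3 log-units). On ≤ 60-observation instances the optimum agrees with
  a dense brute-force maximization within 0.01 log-units (tested).
* **Curvature.** Sampling covariance of the estimates is the inverse of a
  central-difference Hessian of −logL on the natural scale, computed only
  over non-boundary components (steps clipped to keep G PSD); pseudo-inverse
  fallback for near-singular curvature.
* **Starting values.** Equal split of the phenotypic variance over the
  model's variance contributions; the social share is assigned to
  (n−1)σ²_AS (the scale on which σ²_AS enters σ²_P), σ_ADS starts at 0.

### Likelihood-ratio test

Adding the social terms adds two parameters (σ²_AS, σ_ADS), so the naive
reference distribution is χ²₂ on 2ΔlogL, for which p = exp(−ΔlogL). Because
σ²_AS is tested on its boundary, this is conservative under the null; the
empirical type-I error in the scaled-down null calibration is well below
0.05 (tested at 200 replicates). A ½χ²₁ + ½χ²₂ mixture correction is
available (`lrt(..., mixture=True)`) but off by default to match the naive
convention.

## Trait definitions

* Condition factor CF = weight/length³ (g, cm), ~0.009–0.010 for these
  juveniles; CCF = CF₃ − CF₁ across the six-week experiment.
* Specific growth rate SGR = (ln w₃ − ln w₁)/(t₃ − t₁) × 100 %/day; elapsed
  time comes from per-fish recording ages when present, else the global
  42-day duration.
* Fin lengths (first/second/third dorsal, caudal) are the socially affected
  traits of interest; fin erosion is scored once, at the final recording.

## The simulator

`simulate_dataset` emulates the experiment as stated: 73 sires × 100 dams
(27 sires serve two dams, giving half-sib links) → 100 full-sib families of
21 tagged offspring; each family split into 3 groups of 7; 300 groups dealt
into 100 tanks of 21 with no family appearing twice in a tank (rejection
sampling over assignments). Breeding values are generated by
Mendelian-sampling recursion (founders ~ N(0, G); offspring = parent mean +
deviation with variance d_i·G, d_i = ½ − ¼(F_s + F_d)), which yields
Cov = G ⊗ A exactly; family, tank and residual effects are iid normal.

Defaults define the stated world and are not tuning knobs:

* true components σ²_AD = 6.13, σ²_AS = 0.03, σ_ADS = 0.23, σ²_c = 0.51,
  σ²_t = 0.15 (a strongly social fin-length scenario on the mm scale), with
  σ²_e = 4.02 chosen so σ²_P = 11.41 at n = 21;
* fixed effects: mean 15.8, age slope 0.05/day, scorer offsets
  (0, +0.4, −0.3) assigned in proportions 40/49/11% — plausible fin-length
  values chosen once, since only the variance structure matters for the
  recovery experiments;
* age covariate: family-level hatch-date jitter of ±10 days around a base
  age of 222 days, so the age effect is estimable;
* optional missingness: `n_missing` fish (default 0; the experiment lost
  28 of 2100) get a masked phenotype while remaining social partners.

What the simulator does **not** emulate: non-Gaussian traits (fin erosion is
a bounded percentage in reality; the analysis model treats all traits as
Gaussian, and so does the generator), behavioural dynamics behind the social
effects, non-random mortality, and measurement-repeatability structure
beyond the scorer factor. A green recovery test therefore establishes that
the estimator recovers the parameters of its own generating model at the
experimental design's size — not that the Gaussian social model is correct
for real fin damage.

## Scaled-down experiments

Two stochastic checks run routinely:

* **Recovery at experiment scale** (2100 fish, 100 tanks, 30 seeded
  replicates): mean REML estimates recover σ²_AD, σ²_AS, σ_ADS within two
  Monte-Carlo standard errors; the LRT rejects at α = 0.001 in every
  replicate under the strongly social truth. σ²_AD is the weakly identified
  component here — it shares a flat likelihood ridge with σ²_c and σ²_e
  (full-sib families are confounded with their rearing environment, and only
  the 27 reused sires link families genetically), so its per-replicate
  spread is large (SD ≈ 2) and small replicate sets can miss the truth by
  a couple of standard errors without any implementation defect.
* **Null calibration** (20 tanks × 6 fish, no social effects, 200
  replicates): empirical type-I error of the naive LRT stays at or below
  the nominal 0.05 up to binomial noise.

## Known limitations

* Univariate analyses only; the direct–social cross-trait correlations of
  the original study's bivariate models are out of scope.
* No genetic groups for unknown parents (single base population), no
  genomic relationships, no dominance.
* Group sizes may vary in the math (Z_S rows count actual tank mates), but
  the default simulator only produces the balanced design; dilution of
  social effects with group size is not modelled.
* Delta-method SEs for ratios (T², r_AS,AD) are first-order and can be
  unreliable near boundaries — mirrored by the very wide SEs the original
  experiment reported for T².
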