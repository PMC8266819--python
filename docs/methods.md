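# Methods

## Observation model

Each usable 15-mm hair section contributes a (δ¹³C, δ¹⁵N) pair. Given a
bear's diet composition **p** over the K = 7 source categories, each isotope
is modelled independently as

δ_j | p ~ Normal( m_j(p), s²_j(p) + σ²_j ),

m_j(p) = Σ_k p_k q_kj μ′_kj / Σ_k p_k q_kj,
s²_j(p) = Σ_k (p_k q_kj)² sd′²_kj / (Σ_k p_k q_kj)²,

where μ′_kj = μ_kj + Δ_kj is the TEF-corrected source mean,
sd′²_kj = sd²_kj + Δsd²_kj the TEF-corrected source variance, and q_kj the
source's digestible concentration of the element (percent dry weight; any
common rescaling of the q's cancels). The "process + residual" error form is
additive: propagated source and TEF uncertainty plus a residual SD σ_j per
isotope. A multiplicative alternative exists in the SIMM literature; the
additive form is the package's documented choice and the residual SDs are
reported with every fit (they can also be fixed via
`MCMCSettings.sigma_res_fixed`, which the oracle tests use).

Assumptions worth stating plainly: sections are conditionally independent
given the bear's diet; diets are constant within a bear-season; sources and
TEFs are season-invariant; isotopes are conditionally independent (no
residual correlation).

## Compositions and covariates

Diets are mapped to ℝ^(K−1) by the isometric log-ratio transform with a
fixed Helmert basis, sources ordered alphabetically (recorded in every
result). The linear predictor is

z_b = μ + β_sex[sex(b)] + β_status[status(b)] + u_b,

with reference levels F (sex) and non-management (status) absorbed into μ,
management status a 3-level factor (management / non-management / unknown),
and u_b ~ N(0, σ_u² I) an individual random effect. Bears of unknown sex are
dropped from Sex models (counted in `PosteriorResult.n_dropped`), retained
everywhere else. Exactly seven structures are supported: Null, Sex, Status,
BearID, Sex+Status, Sex+BearID, Status+BearID.

## Priors

- Baseline composition ilr⁻¹(μ): Dirichlet(α) with α_k = max(0.01,
  EDEC_k / Σ EDEC × K), so a uniform EDEC vector is exactly the flat
  Dirichlet(1) prior and any informative vector carries the same total
  weight K. The density is evaluated in ILR coordinates including the
  change-of-variables Jacobian, so the prior on p is exactly Dirichlet.
- The per-season EDEC vectors for the real study population (scat-derived
  digestible-energy shares) are not published; `DEFAULT_EDEC` is a
  clearly-labelled placeholder encoding generic bear food phenology (herbs
  in spring, ants in early summer, fleshy fruits in late summer, hard mast
  in autumn) and should be replaced with real values where available. It is
  deliberately weak (largest α ≈ 2.8).
- Covariate coefficients: Normal(0, variance 10) per ILR coordinate — on
  the log-ratio scale this is already very diffuse; ±3 ILR units span
  essentially the whole simplex.
- σ_u: half-normal(0, 2); σ_j: half-normal(0, 5 ‰), both sampled on the
  log scale with the Jacobian included.

## Sampler

Adaptive random-walk Metropolis-within-Gibbs:

- one block per coefficient vector (μ, each β level) with proposal
  covariance learned from the running empirical covariance during burn-in
  (Cholesky-shaped proposals, diagonal regularisation 10⁻⁶·tr(Σ)/d);
- one vectorised block proposing all u_b simultaneously and
  accepting/rejecting per bear (valid because bears' likelihood
  contributions are conditionally independent);
- scalar log-scale blocks for σ_u and (jointly) the residual SDs;
- two kinds of likelihood-preserving or funnel-crossing moves:
  *recentering* (μ → μ + δ, u → u − δ, and the analogous per-coefficient
  move on the bears carrying that coefficient), and an *interweaving
  rescale* (σ_u → σ_u·e^ε, u → u·e^ε) whose u-prior ratio cancels against
  the transform Jacobian. Without these, the (β, u) anti-correlation and
  the (σ_u, u) funnel dominate the autocorrelation time; with them all
  R-hats on the study-design scenario drop below 1.05.

Proposal scales adapt in windows of 100 iterations toward 20–40 %
acceptance during burn-in only; after burn-in the kernel is fixed, so the
chain is a valid Markov chain for the posterior. Defaults follow the
published settings (3 chains × 300 000 iterations, burn-in 200 000,
thinning 100 → 3 000 kept draws); all analyses in the test suite and the
acceptance script use shortened chains (below). One master seed spawns one
stream per chain; identical seeds give bit-identical results. The
per-bear likelihood kernel is numba-compiled when numba is importable, with
a pure-numpy reference branch that agrees to ~10⁻¹³ and is exercised when
numba is absent.

Pointwise log-likelihoods (per section, summed over isotopes) are stored
for every kept draw, so LOO needs no refitting.

## Convergence

Gelman–Rubin R̂ uses the classic formula √(((n−1)/n·W + B/n)/W) on the kept
draws of every scalar parameter across chains; degenerate chains (W = 0)
report 1 with a warning. The Geweke diagnostic compares the first 10 % to
the last 50 % of each chain with segment variances from the spectral
density at zero (Bartlett-windowed autocovariances, lag cutoff n^⅓ — the
cube root calibrates the z-scores to near-unit variance on iid and AR(1)
chains). Pass thresholds default to R̂ < 1.05 and |z| < 2 and are
configurable; with dozens of monitored parameters the per-parameter |z| < 2
rule flags ~5 % of healthy parameters by construction, so R̂ is the primary
criterion and the report exposes both.

## Mixing polygons

Mixing-space adequacy is checked before fitting: each of (default) 1 500
iterations redraws every corrected source mean from Normal(mean, corrected
SD) — population spread, not standard error; an SE mode exists — builds the
convex hull in (δ¹³C, δ¹⁵N) space, and tests consumers with closed
boundaries (tolerance 10⁻⁹, via shapely). Consumers inside in fewer than
5 % of iterations are excluded from models but kept in the report. C4
plants never enter the mixing space; their extreme δ¹³C is exactly why the
corn signal is screened rather than modelled.

## Model selection

PSIS-LOO per model: importance ratios 1/p(y_i|θ_s) are Pareto-smoothed
(the generalized-Pareto fit to the upper tail is delegated to
`arviz.stats.psislw`; observations with non-finite smoothed weights fall
back to truncated importance sampling with a warning, and Pareto k > 0.7 is
counted). LOOic = −2 Σ elpd_i with SE = 2√(n·var(elpd_i)); ΔLOOic is taken
against the minimum (ties broken by label order) with paired SEs from the
pointwise elpd differences — which is why SE(Δ) can be far below either
model's SE(LOOic) for near-tied models. Akaike weights are
exp(−Δ/2)/Σexp(−Δ/2) with max-subtraction; the selected set is every model
with weight > 0.2.

## Synthetic studies

The generator reproduces the published design: 27 bears (16 F / 11 M, with
3 management and 2 unknown-status individuals by default), per-season
section counts matching the published seasonal table exactly (e.g. spring
females: 45 sections), and a key-food table whose species-level means, SDs
and sample sizes (n = 191 samples in 8 categories) match the printed values
exactly — samples are drawn and then affinely adjusted to the printed
moments, with a positivity-constrained retry for elemental concentrations.
Hair lengths and collection dates are constructed by a deterministic greedy
plan (pre-moult hairs extend backwards from November, post-moult hairs from
August) so that the chronology module itself reproduces the target season
counts; infeasible targets raise rather than approximate. Section isotope
values are drawn from the same observation model the SIMM fits, at true
diets ilr⁻¹(ilr(group diet) + covariate shifts + bear effect). Defaults:
σ_res = 0.5 ‰ per isotope (well above the ±0.05 ‰ instrument error, to
stand in for unmodelled within-individual variation), σ_u = 0.2 ILR units,
no fixed-effect shifts. True group diets echo the qualitative seasonal
pattern (herbs 0.40 in spring, ants 0.35 in early summer, wild fleshy
fruits 0.45 in late summer, hard mast 0.55 in autumn) without claiming any
published estimate. Everything latent is written to `truth.json`.

What the generator does *not* emulate: year-to-year food variation,
within-season diet drift along a hair, diet-dependent hair growth rate,
spatial structure, genotyping error, or isotopic routing differences among
macronutrients. Passing recovery tests therefore show the inferential
machinery is correct under its own assumptions — not that those assumptions
hold for real hair data.

## Problem sizes used by the test suite and acceptance script

Simulation-based checks run the full published design (27 bears, 191
source samples, 196 sections per replicate) but with shortened chains,
chosen as the package's reduced analysis scale: 3 chains × 8 000 iterations,
burn-in 4 000, thinning 4 (3 000 kept draws) for recovery fits; 3 replicates
for coverage (84 source-season cells) and 5 for covariate detection; the
grid-oracle check uses 3 × 25 000 iterations on the 2-source/1-isotope
model. At these sizes coverage of true diets is 97–100 % and the strong
simulated sex effect is detected by LOO in 5/5 replicates across the seeds
tried.

## Known limitations

- With two tracers and seven sources the likelihood alone cannot separate
  the mast/fruit cluster; posterior means there are prior-sensitive by
  construction (wide CIs make this visible). This is a property of the
  problem, not the sampler.
- Per-parameter Geweke flags are conservative (see above); treat the
  convergence report as a whole.
- The default EDEC prior is a phenology placeholder, not measured
  digestible-energy data.
- Hairs longer than one activity period are flagged out-of-activity and
  excluded rather than wrapped into the previous year, since per-individual
  moult dates are unknown.
- The remainder < 15 mm at the hair tip is discarded (oldest, most
  uncertain material); the alternative of merging it into the last section
  is not offered.
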