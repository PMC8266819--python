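# hairsimm

Seasonal diet reconstruction for brown bears from stable isotopes of
sectioned guard hairs.

Guard-hair keratin archives a bear's assimilated diet sequentially: hair
grows at roughly 15 mm per month during the activity period and the annual
moult resets the record, so cutting a hair into 15-mm sections and dating
each section back from its growth anchor yields a month-by-month isotopic
chronology for an individually identified animal. `hairsimm` turns such
section-level δ¹³C/δ¹⁵N measurements, together with an isotopic key-food
table, into seasonal diet estimates. It is written for trophic ecologists
and wildlife managers who want the full inferential chain — not just a
mixing-model fit — as reproducible, tested code:

1. **Source aggregation** — key-food samples pooled a priori into seven diet
   categories (herbs, hard mast, wild/cultivated fleshy fruits, cultivated
   vegetables, ungulates, ants) with exact weighted means and within+between
   pooled SDs; C4 plants (corn) are screened but never enter the models.
2. **Hair chronology** — moult-model month assignment (pre-moult hairs
   anchor at the previous November, post-moult hairs at the month before
   collection) and pooling into four dietary seasons.
3. **Mixing-space validation** — simulated mixing polygons: source
   signatures are redrawn each iteration, the convex hull rebuilt, and
   consumers outside the 95 % mixing region excluded.
4. **Bayesian mixing models** — concentration-dependent SIMMs with
   covariate structures (sex, management status, individual random
   effects), informative Dirichlet priors from prior dietary knowledge,
   and full convergence diagnostics (Gelman–Rubin R̂, Geweke z).
5. **Model selection** — PSIS-LOO, paired standard errors of ΔLOOic, and
   Akaike weights with the "lowest LOOic and weight > 0.2" selection rule.
6. **Synthetic studies** — a generator that reproduces the published study
   design (27 bears, the published per-season section counts, a key-food
   table whose species-level moments match the printed values exactly), so
   every stage is testable end-to-end without access to the unpublished
   section-level data.

## The model

For a hair section from bear *b* with diet proportions
**p**<sub>b</sub> = (p₁ … p<sub>K</sub>) on the simplex, the observed δ
value of isotope *j* (δ¹³C or δ¹⁵N) is modelled as

    δ_j ~ Normal( Σ_k p_k q_kj (δ_kj + Δ_kj) / Σ_k p_k q_kj ,  s²_j(p) + σ²_j )

where q<sub>kj</sub> is source *k*'s digestible elemental concentration of
the isotope's element, Δ<sub>kj</sub> the trophic enrichment factor for the
source's trophic class (vegetable: Δ¹³C = 3.4 ± 0.5 ‰, Δ¹⁵N = 2.4 ± 0.2 ‰;
animal: Δ¹³C = 2.1 ± 0.2 ‰, Δ¹⁵N = 3.9 ± 0.3 ‰), s²ⱼ(p) the propagated
source+TEF ("process") variance under the same concentration weights, and
σⱼ a residual SD. Compositions are modelled in isometric log-ratio (ILR)
coordinates,

    z_b = ilr(p_b) = μ + β_sex[sex(b)] + β_status[status(b)] + u_b ,
    u_b ~ Normal(0, σ_u² I) ,

with seven covariate structures (Null, Sex, Status, BearID, Sex+Status,
Sex+BearID, Status+BearID) compared per season by PSIS-LOO. Prior dietary
knowledge enters as a Dirichlet prior on the baseline composition
ilr⁻¹(μ), with concentrations α ∝ EDEC % scaled to total weight K.
Sampling is adaptive Metropolis-within-Gibbs with covariance-shaped
proposals, a vectorised per-bear block, and recentering/interweaving moves
that cross the (μ, u) and (σ_u, u) ridges.

## Worked example

```python
import numpy as np
from hairsimm import (
    ScenarioConfig, generate_scenario, aggregate_all, build_mixing_space,
    build_chronology, fit_mcmc, ModelSpec, MCMCSettings, prior_from_edec,
    summarize_posterior,
)
from hairsimm.simm import DEFAULT_EDEC
from hairsimm.synth import _samples_from_frame

ds = generate_scenario(ScenarioConfig(seed=42))          # full synthetic study
categories = aggregate_all(_samples_from_frame(ds.sources))
space = build_mixing_space(categories)                    # TEF + concentration
sections = build_chronology(ds.hairs, ds.sections).merge(ds.bears, on="bear_id")
spring = sections[(sections.exclusion_reason == "") & (sections.season == "spring")]

result = fit_mcmc(
    spring, space, ModelSpec.from_label("BearID", season="spring"),
    prior_from_edec(DEFAULT_EDEC["spring"]),
    MCMCSettings(chains=3, iterations=30000, burn_in=20000, thin=10),
    seed=0,
)
print(summarize_posterior(result).round(3).to_string(index=False))
print("truth:", np.round(ds.truth["true_group_diets"]["spring"], 3))
print("max R-hat: %.3f" % max(result.convergence.rhat.values()))
```

prints

```
     level                   source  mean    sd  q2.5  q97.5
population Cultivated fleshy fruits 0.043 0.063 0.000  0.232
population    Cultivated vegetables 0.026 0.032 0.000  0.111
population               Formicidae 0.102 0.059 0.006  0.212
population               Hard masts 0.234 0.107 0.042  0.439
population                    Herbs 0.408 0.065 0.283  0.532
population                Ungulates 0.073 0.058 0.002  0.197
population       Wild fleshy fruits 0.114 0.099 0.004  0.361
truth: [0.04 0.03 0.1  0.25 0.4  0.08 0.1 ]
max R-hat: 1.009
```

Each row is one diet source's posterior mean proportion of the assimilated
spring diet, with SD and 95 % credible interval; the generating truth (herbs
dominant at 0.40) is recovered inside every interval. The isotopically
confusable mast/fruit sources carry honest, wide intervals.

The same pipeline runs from the shell:

```sh
hairsimm simulate --out data/ --seed 42
hairsimm run-all --config run.yaml
```

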