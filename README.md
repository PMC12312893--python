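# footsel

Hierarchical Bayesian resource-selection analysis of mammal space use
against a fine-scale human-footprint index in protected areas.

## The problem

GPS-collared mammals in parks face two distinct kinds of human disturbance:
permanent recreation infrastructure (roads, trails, car parks, buildings,
campgrounds — collectively the *human footprint*) and the transient
presence of visitors.  The 2020 closures of protected areas separated the
two for the first time: infrastructure stayed, people vanished.  `footsel`
implements the full analysis pipeline for asking how animals select or
avoid the footprint within their home ranges (third-order selection),
whether that changed between an open year (2019) and the closure year
(2020), and whether an individual's *exposure* — the mean footprint in its
home range — mediates its response (a functional response in habitat
selection: habituation if animals in developed areas avoid the footprint
less, sensitisation if more).

Because raw animal locations from such studies are withheld for the
animals' safety, the package ships a synthetic landscape + telemetry
generator with known ground truth; every stage of the pipeline is tested
against it.

## The model

For each population, each animal-year *j* contributes used points (GPS
fixes) and available points (uniform in its 95% kernel home range, 1:50):

    used_i ~ Bernoulli(p_i)
    logit(p_i) = β₀[j] + β_fp[j]·footprint_i + β_elev[j]·elevation_i
               + β_slope[j]·slope_i + Σ_c I_c[j]·β_c[j]·cover_{c,i}

Individual coefficients are drawn from population hyperdistributions,
β[j] ~ Normal(μ, τ) (a joint multivariate normal with Wishart-prior
precision for the five land-cover terms), sampled with a purpose-built
Metropolis-within-Gibbs sampler and judged by split-chain Gelman–Rubin
R̂ ≤ 1.1.  A second stage regresses the individual footprint coefficients
(as observations with known measurement precision 1/sd²) on exposure, with
year-specific slopes, at global, guild and species structure:

    β_fp[j] = β_int[k,t] + β_slope[t]·exposure_j + measurement error.

See `docs/methods.md` for priors, the footprint-index construction, the
sampler, and the design choices.

## Worked example

```python
import numpy as np
from footsel import (MCMCConfig, SimulationDesign, classify_selection,
                     derive_population_summaries, run_pipeline, simulate_study)
from footsel.trackprep import InclusionThresholds

design = SimulationDesign(n_individuals=12, n_used_per_individual=120)
study = simulate_study(design=design, seed=42)   # truth: -1.88 (2019), -1.75 (2020)
result = run_pipeline(study, ratio=20, availability="truth",
                      mcmc=MCMCConfig(seed=42),
                      thresholds=InclusionThresholds(min_fixes=20), seed=43)

post = result.posterior
summ = derive_population_summaries(post)
print(f"individual-years fitted: {len(post.groups)} (excluded: {len(result.exclusions)})")
print(f"max split R-hat: {post.max_rhat:.3f}")
for yr in (2019, 2020):
    s = summ[yr]
    label = classify_selection(s["mean"], s["ci_low"], s["ci_high"])
    print(f"population mean footprint coefficient {yr}: {s['mean']:.2f} "
          f"(95% CI {s['ci_low']:.2f} to {s['ci_high']:.2f}) -> {label}")
mu = post.flat("mu.footprint")
lo, hi = np.percentile(mu, [2.5, 97.5])
print(f"hyper-mean mu_footprint: {mu.mean():.2f} (95% CI {lo:.2f} to {hi:.2f}); "
      "truth -1.88 / -1.75")
d = summ["difference"]
print(f"interannual difference (2020-2019): {d['mean']:.2f} "
      f"(95% CI {d['ci_low']:.2f} to {d['ci_high']:.2f})")
```

prints (in a few minutes on one CPU)

```
individual-years fitted: 24 (excluded: 0)
max split R-hat: 1.148
population mean footprint coefficient 2019: -1.40 (95% CI -1.96 to -0.90) -> avoid
population mean footprint coefficient 2020: -1.39 (95% CI -1.94 to -0.89) -> avoid
hyper-mean mu_footprint: -1.39 (95% CI -1.95 to -0.89); truth -1.88 / -1.75
interannual difference (2020-2019): 0.02 (95% CI -0.21 to 0.25)
```

Both years' credible intervals sit below zero — the simulated population
avoids the footprint, and the interannual difference is indistinguishable
from zero, as the generating truth (−1.88 vs −1.75) implies at this sample
size.  The hyper-mean's 95% interval covers the truth.  Fitting the
functional response to coefficient observations generated with slopes −1
(open year) and +4 (closure year) recovers both:

```
functional-response slope 2019: -1.15 (95% CI -1.77 to -0.47)  [truth -1]
functional-response slope 2020: 4.24 (95% CI 3.60 to 4.90)  [truth +4]
```

A negative slope means animals with more footprint in their home range
avoid it more (sensitisation); the positive closure-year slope means
highly exposed animals shifted toward selecting the footprint once people
were gone.

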