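# epochdiv

Bayesian inference of **episodic diversification rates** from time-calibrated
phylogenies, with **empirical (clade-informed) taxon sampling** and
**environment-linked rate models**.

## The problem

Species-rich clades such as grasses and daisies are sampled very unevenly in
molecular phylogenies: tens of thousands of extant species are known to
taxonomy, but only a few thousand appear in the tree, and the missing species
are concentrated in particular named clades. Standard birth–death inference
assumes every extant species was sampled with the same probability ρ, which
badly distorts rates through time when sampling is clade-biased. At the same
time, a central comparative question — did diversification track an
environmental driver such as atmospheric CO₂? — requires a model in which
rates both vary freely through time *and* respond to an environmental curve,
so that correlation is not manufactured by forcing all rate variation through
the environment.

`epochdiv` implements, for users of time-calibrated trees:

* the exact probability density of a reconstructed tree under the **episodic
  birth–death process** (piecewise-constant speciation λᵢ and extinction μᵢ
  on an epoch grid, uniform sampling fraction ρ at the present);
* an **empirical taxon-sampling** density: each named clade with MRCA age
  cᵢ and kᵢ known missing species contributes the integrated probability of
  a surviving speciation event between cᵢ and the present,

  ```
  f(Ψ, 𝕂) = f(Ψ; ρ=1) · (m−1)!/(n−1)! · Π᷍ᵢ Mᵢ^{kᵢ}/kᵢ! ,
  Mᵢ = 1 − P(N(T)>0 | N(cᵢ)=1) · e^{r(cᵢ,T)} ,
  ```

  with r(t,T) = ∫(μ−λ);
* prior models on log rates: **UCLN** (i.i.d. lognormal), **GMRF**
  (first-difference Gaussian Markov random field, a discretised Brownian
  motion) and **HSMRF** (horseshoe MRF with per-epoch local scales γᵢ);
* four **environment-linked** models in which a correlation factor β maps
  changes of an environmental series into log-rate changes,
  `ln λᵢ = ln λᵢ₋₁ + β·ΔEᵢ (+ noise)` — the *fixed*, UCLN-env, GMRF-env and
  HSMRF-env variants, all collapsing exactly to their environment-free
  counterparts at β = 0;
* adaptive **MCMC**, **stepping-stone** marginal likelihoods, and
  posterior-odds **Bayes factors** for the sign of β, using the add-one
  smoothed rule BF(β<0) = (N₋+1)/(N₊+1) under the symmetric zero-centred
  β prior;
* a **forward simulator** (episodic and environment-linked), uniform
  pruning, and the add-missing-species/redraw-times/prune protocol that
  mimics empirical taxon sampling, used for power and false-positive
  studies.

## Worked example

```python
import numpy as np
import epochdiv as ed

# a synthetic Cenozoic-like CO2 curve (ppm) and a tree grown under
# environment-linked rates (beta = -0.005 per ppm, sigma = 0.02)
ages = np.arange(0.0, 45.25, 0.25)
env = ed.EnvSeries(ages, ed.cenozoic_co2_curve(ages))
grid, truth = ed.env_linked_grid(env, 45.0, 10, lam0=0.28, mu0=0.10,
                                 beta_lam=-0.005, beta_mu=-0.005,
                                 sigma_lam=0.02, sigma_mu=0.02, seed=101)
tree, _ = ed.simulate_tree(ed.SimConfig(grid=grid, seed=201, root_age=45.0))

model = ed.build_model(tree, n_epochs=10, model="GMRF-env", env=env)
trace = ed.run_mcmc(model, iterations=8000, burnin=2000, seed=1)
print("tips:", tree.n_tips)
print("P(beta_lambda < 0):", ed.posterior_sign_probability(trace, "beta_lambda"))
print("BF(beta<0):", ed.bayes_factor_beta(trace))
print("beta median:", trace.df["beta_lambda"].median())
```

Output (seed-for-seed reproducible):

```
tips: 388
P(beta_lambda < 0): 0.8993333333333333
BF(beta<0): 8.920661157024794
beta median: -0.0028766667979318794
```

Nine-tenths of the posterior mass lands on a negative correlation between
the speciation rate and CO₂ — the sign the tree was simulated under — with a
posterior-odds Bayes factor of ≈9 in favour; the rate-through-time medians
(via `ed.summarize_rates(trace, grid)`) recover the simulated rise in
speciation rates after the CO₂ drop. A single ~400-tip tree carries only
moderate information about β, so decisive support (BF > 20) typically needs
larger trees; the methods note discusses this information ceiling.

A command-line interface mirrors the library:

```bash
epochdiv simulate  --mode fixtures --out fixtures/ --seed 7
epochdiv estimate  --tree fixtures/tree200.nwk --epochs 10 --model GMRF \
                   --iters 5000 --seed 1 --out runs/rates
epochdiv correlate --tree fixtures/tree200.nwk --env fixtures/co2_synthetic.csv \
                   --model GMRF-env --epochs 10 --iters 5000 --seed 1 --out runs/co2
epochdiv evidence  --tree fixtures/tree200.nwk --model GMRF --epochs 10 \
                   --stones 128 --seed 1 --out runs/ev
```

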