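# Methods

## Model

`epochdiv` works with the reconstructed evolutionary process: a birth–death
process with piecewise-constant speciation rates λᵢ and extinction rates μᵢ
on an ordered epoch grid, observed only through the tree of sampled extant
species. Rates are homogeneous across contemporaneous lineages and shift
instantaneously at epoch boundaries; lineage-specific rate shifts are out of
scope. Ages are measured in Myr before present (0 = present); epoch
intervals are half-open `(older, younger]` so that an observation exactly on
a boundary belongs to the younger epoch, and rate vectors are indexed from
the present backwards.

### Likelihood

Let E(a) be the probability that a lineage alive at age a leaves no sampled
descendant (E(0) = 1 − ρ), s = 1 − E, and r(a) = ∫₀ᵃ (μ − λ). Within one
epoch s propagates in closed form,

    s(a₀+d) = s(a₀) e^{rd} / (1 + λ s(a₀) g),   g = (e^{rd} − 1)/r ,

where g → d smoothly as λ → μ; the implementation evaluates g by a
second-order series when |rd| < 10⁻⁸ and switches between e^{+rd}/e^{−rd}
forms by the sign of rd, so no parameter combination in λ, μ ∈ [10⁻⁶, 10],
ρ ∈ (0, 1] produces NaN. The per-lineage "exactly one sampled descendant"
flow is p1(a) = s(a)² e^{r(a)}/ρ, and the density of a reconstructed tree
with n tips, conditioned on the two root lineages at age t₁ both being
ancestral to sampled tips, is

    f(Ψ) = 2^{n−1}/n! · [p1(t₁)/s(t₁)]² · Π_{non-root nodes} λ(xᵢ) p1(xᵢ) .

The product runs over the n−2 non-root branching events: the root split
itself is part of the conditioning, so it contributes no λ factor. This
form is proved in the tests against (i) an independently coded constant-rate
(Nee et al.) closed form at 1, 10 and 100 equal-rate epochs, (ii) the
pure-birth closed form, (iii) the telescoping identity
∫ λ p1 = (ρ − s(t₁)e^{r(t₁)})/ρ by quadrature, and (iv) a three-tip total-
probability identity using the geometric offspring distribution.

The speciation-time CDF used for missing species,

    F(t | N(t₀)=1) = 1 − [1 − s(t)e^{r(t)}] / [1 − s(t₀)e^{r(t₀)}]   (forward time),

is validated against 10⁵ forward simulations. Under incomplete sampling
(ρ < 1) F is *defective* — its total mass at the present is below one, the
remainder being the probability that the would-be event belongs to an
unsampled lineage — so Monte-Carlo comparisons normalise by F(T).

### Empirical taxon sampling

A clade-sampling table assigns kᵢ missing extant species to named clades,
each identified by two sampled tips whose MRCA defines it. The joint
density multiplies the complete-sampling (ρ = 1) tree density by

    (m−1)!/(n−1)! · Πᵢ Mᵢ^{kᵢ}/kᵢ! ,   Mᵢ = 1 − s(cᵢ) e^{r(cᵢ)} ,

where Mᵢ equals ∫ λ p1 over the window from the clade age cᵢ to the
present — the probability mass of a surviving speciation event inside the
clade's window (checked by quadrature to 10⁻⁶). The window starts at the
clade's **crown age by default**; stem-age conditioning is available via
`clade_age="stem"`. We prefer the crown age because the conditioning
N(cᵢ) = 1 describes one surviving lineage of the *observed* clade, whose
oldest certain age is the crown node; the stem variant simply widens the
window. Combining a global ρ < 1 with clade terms would double-count
missing species, so the empirical density requires ρ = 1 and enforces it.
All factorials are computed as log-gamma differences.

### Rate priors

Log rates receive one of three priors: UCLN (i.i.d. Normal(m₀, σ)), GMRF
(increments Normal(0, σ)) or HSMRF (increments Normal(0, σγᵢ) with local
scales γᵢ ~ half-Cauchy(0, 1)). Speciation and extinction get independent,
identically structured priors with their own hyperparameters. Choices the
literature leaves open, fixed here:

* **Anchor**: the present-day (first-epoch) rate of GMRF/HSMRF fields takes
  a Uniform(0, 100 events/Myr) prior on the natural scale, mirroring the λ₀
  prior of the environment-linked models.
* **Global scale**: σ ~ half-Cauchy(0, ζ) with ζ calibrated numerically so
  the prior expected number of increments exceeding log 2 in magnitude
  ("effective shifts") is ≈ log 2 over the grid; the horseshoe variant uses
  the same criterion with the horseshoe marginal and therefore a smaller ζ.
* **UCLN hypers**: m₀ ~ Uniform(−10, 5) on the log scale (≈4.5×10⁻⁵ to 148
  events/Myr); σ ~ half-Cauchy(0, 1).
* Epoch counts 4–200 are the profiled range; other values only warn.

### Environment-linked models

Per-epoch environmental means Eᵢ (present epoch first) come from arithmetic
binning of the raw series on the *same* grid as the rates; ΔEᵢ = Eᵢ − Eᵢ₋₁,
with ΔE₁ = 0. Only the exponential dependency is implemented — log rates
are linear in E, so rates stay positive; a linear dependency can go
negative and is deliberately excluded. The four models (fixed, UCLN-env,
GMRF-env, HSMRF-env) collapse to constant rates / UCLN / GMRF / HSMRF
exactly at β = 0 (asserted to 10⁻¹²). Epochs with no environmental
observation are filled by linear interpolation of neighbouring epoch means
(with a warning); series reaching beyond the root age are truncated. The β
prior is Normal(0, σ_β), zero-centred and symmetric — required by the
posterior-odds Bayes factor — with σ_β = 3/range(E) by default so one prior
standard deviation of β spans three log-rate units across the observed
environmental range.

### Inference

The sampler is adaptive Metropolis-within-Gibbs: positive parameters move
multiplicatively (log-scale random walk with the Jacobian in the acceptance
ratio), rate fields are updated site by site plus three joint moves — a
whole-field shift per field, a *both-fields* shift (the λ–μ ridge along
which the likelihood changes slowly), and for environment-linked fields a
*trend move* that perturbs β and tilts the whole field by β′s cumulative ΔE
so the MRF increments stay fixed. Proposal scales adapt toward 44%
acceptance during burn-in (default 10% of iterations) and are frozen
afterwards. Initial states are drawn from the prior (up to 100 redraws on a
non-finite posterior), with the rate draw narrowed to a window around a
crude net-diversification guess log(n/2)/t₁ — an initialisation device
only; the prior density itself is unchanged. Effective sample sizes are
computed by the standard autocorrelation-time estimate and reported, not
enforced.

Marginal likelihoods use stepping-stone sampling with power-posterior
exponents at quantiles of Beta(0.3, 1), default 128 stones × 2000
iterations, each stone warm-started from the previous one; a stone whose
weights span more than 50 log units is warned about and its interval
subdivided once. Engine and estimator are validated against a conjugate
normal-mean model with analytic posterior and evidence, and the posterior
machinery by simulation-based calibration of β under the fixed-linkage
model. Bayes factors for the sign of β are posterior odds with add-one
smoothing, (N₋+1)/(N₊+1), so an all-negative trace of 37,500 samples yields
the finite, sample-size-bound value 37,501; the raw ratio is available by
flag. One iteration here is a full sweep over all parameters, so iteration
counts are not comparable to single-move-per-iteration software.

## Simulator and study conditions

Forward simulation is Gillespie with exact epoch-boundary handling,
starting from two lineages at the root age (or, for constant rates, running
until a taxon-count target is first reached, with the present placed
uniformly inside the following waiting interval). Conditioning on survival
— at least two sampled tips, or optionally both root lineages surviving,
which matches the likelihood's conditioning exactly — is by rejection.

The synthetic environmental curve is a smooth Cenozoic-like CO₂ history in
ppm: ~280 ppm at the present rising to ~900 ppm in the Palaeogene through a
steep logistic step centred at 33.5 Mya, plus a gentle ramp and low-
amplitude wiggles. The simulation studies use root age 45 Myr, 10 epochs,
present-day rates λ₀ = 0.28, μ₀ = 0.10 events/Myr, rate-variation σ = 0.02
and correlation factor β = −0.005 per ppm (with β = 0, σ = 0 for the
constant-rate null), tree sizes conditioned to ~200 tips, and for the
sampling-bias study 100-tip base trees with 400 missing species in eight
clades (sampling fraction ρ = 0.2, missing counts biased toward young
clades — the daisy-like regime scaled down), with redraw rates chosen
consistent with the total richness over the root age
(λ − μ = log(m/2)/t₁), since inconsistent redraw rates make the
branching-time shape contradict the tip count and contaminate the
comparison. What these synthetic data do
not emulate: dating error and topological uncertainty in the input tree,
measurement error in the environmental proxy, lineage-specific rate
variation, and the sheer size of real supertrees — so passing tests show
the machinery is correct at desk scale, not that a 200-tip empirical tree
would yield decisive correlations.

## Known limitations

* **Information ceiling at small n.** On ~200-tip trees the profile
  log-likelihood ratio between the true environment-linked model
  (β = −0.005) and the best constant-rate model is only ~0–4 nats, so
  posterior P(β < 0) plateaus around 0.85–0.95 and decisive support
  (BF > 20) is rare; decisive results of the kind reported for multi-
  thousand-tip trees require correspondingly larger trees. The power
  experiment in the acceptance suite states this expectation honestly
  rather than relaxing its threshold.
* The GMRF/HSMRF drift terms can absorb part of a genuine environmental
  trend (and vice versa); the fixed model is the sharp-null comparison.
* Taxon-count-stopped simulations are a convenience for fixtures, not a
  statistically exact tree-prior conditioning on n.
* The empirical-sampling protocol attaches missing species uniformly over
  clade branches and redraws node times rank-preservingly from the
  speciation-time CDF; this matches the uniform-attachment construction
  for constant rates and is an approximation for strongly time-varying
  rates.
* The empirical-sampling density treats the kᵢ missing speciation times as
  independent draws from the clade window; the exact marginal of the
  complete process also involves the number of clade lineages available at
  each attachment time. The approximation is accurate at moderate kᵢ but
  can distort present-day rate estimates when kᵢ exceeds the observed tip
  count many-fold.
* ρ is a fixed input, never a free parameter; fossilised birth–death and
  multivariate or lagged environmental dependencies are out of scope.
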