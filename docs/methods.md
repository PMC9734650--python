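# Methods

## Model class

`txnoise` implements steady-state models of a single gene whose
transcription rate K(t) is itself a continuous stochastic process, coupled
to discrete RNA dynamics

    0 --K(t)--> N --beta--> M --gamma--> 0,

where N counts nascent (unspliced) and M mature (spliced) transcripts.
Two biophysically motivated drivers are treated:

* **gamma Ornstein–Uhlenbeck (Γ-OU)** — mean reversion at rate κ plus
  compound-Poisson jumps (frequency a, exponentially distributed sizes
  with mean θ).  Mechanistically this is a coarse model of DNA
  supercoiling: transcription mechanically frustrates the template at
  rate κ, topoisomerase arrivals relieve it in jumps.
* **Cox–Ingersoll–Ross (CIR)** — the square-root diffusion
  dK = (aθ − κK)dt + √(2κθK) dW, the chemical-Langevin description of an
  abundant regulator produced at rate a and degraded at rate κ, with gain
  θ coupling regulator copy number to initiation.

Both drivers share the stationary law K ~ Gamma(a/κ, θ), hence the same
mean rate ⟨K⟩ = aθ/κ, and — remarkably — identical count means,
variances, covariances and autocorrelation functions.  They differ only
through the *dynamics* of the fluctuations, which shape the full joint
distribution P(x_N, x_M).

Distribution shape is organised by two dimensionless coordinates: the
reversion ratio κ/(κ+β+γ) and the gain ratio θ/(θ+a).  The corners of
this unit square are classical limits: constitutive (Poisson product) at
fast reversion/low gain, the gamma-mixture (bivariate negative-binomial
type) at slow reversion, geometric bursting for Γ-OU at fast
reversion/high gain — where CIR instead produces a distinct, heavier-
tailed family (its κ→∞ limit, labelled `CIR_LIMIT` here).

## Exact distributions

The log of the shifted probability-generating function
φ(u_N, u_M) = log E[(1+u_N)^{X_N} (1+u_M)^{X_M}] is a quadrature over the
solution of characteristic ODEs flowing backward through the splicing
cascade (U2 → U1 → U0).  For Γ-OU, U0 is a closed-form sum of three
exponentials and φ = ⟨K⟩∫ U0/(1 − (θ/κ)U0) ds; for CIR, U0 solves a
Riccati equation integrated numerically and φ = ⟨K⟩∫ U0 ds.  The PMF is
recovered by evaluating exp φ on a product grid of unit-circle roots and
taking an inverse FFT.

Numerical choices (each validated in the test suite against adaptive
scipy oracles):

* **s-quadrature.** A graded geometric grid (panel growth 1.5, first panel
  1e-3 of the fastest time scale) truncated at 28 slowest-rate e-folds
  (truncation tail ~7e-13).  Closed-form integrands (Γ-OU, bursty,
  CIR-limit) use 4-point Gauss–Legendre panels; the CIR Riccati system is
  integrated for all FFT nodes simultaneously with fixed-step RK4 on a
  10%-growth graded grid, step-capped at 1.8/λ (λ a bound on the local
  Jacobian) so the scheme stays inside the RK4 stability region for stiff
  (large-κ) drivers.  Accuracy is ~1e-6 relative for CIR and ~1e-8 for
  the closed forms.
* **Grid sizing.** Count-grid extents default to mean + 10 sd per species
  (14 sd for the heavy-tailed CIR variants), computed from the closed-form
  moments; if probability mass above 1e-8 reaches the grid boundary the
  extents grow geometrically.  For likelihood work a looser boundary
  tolerance (1e-6) and a hard per-axis cap (320) apply; a capped,
  truncation-aliased PMF is accepted when the folded mass is below 1e-3,
  since the corresponding log-likelihood error (≤ n_cells × 1e-3) is
  negligible against the model-comparison scales involved.
* **Degenerate rates.** The closed forms divide by pairwise rate gaps
  (removable singularities).  Rates closer than a relative 1e-6 are split
  deterministically by that amount; the autocorrelation bracket, which
  divides by *products* of gaps, uses a coarser 1e-4 split so round-off
  amplification stays below ~1e-8.  The mature autocorrelation needs no
  additive constant at lag zero: the three-exponential bracket vanishes
  identically at τ = 0 by the partial-fractions identity.
* **iFFT hygiene.** Imaginary parts above 1e-8 or negatives below −1e-10
  raise; smaller negatives are clipped to zero.  Conjugate symmetry is
  exploited to evaluate only half the grid rows.

## Stochastic simulation

Simulation is hybrid: the driver path is generated exactly, then the
discrete reactions are produced by inverting the integrated total
propensity against Exp(1) targets (a time-varying direct method).

* Γ-OU paths are piecewise exponential decays between exponential jumps;
  on each decay segment the transcription flux inversion
  cτ + (K₀/κ)(1 − e^{−κτ}) = E is solved exactly with the principal
  Lambert-W branch (evaluated in log space when the argument would
  overflow) plus one Newton polish.
* CIR paths use the exact transition law (scaled noncentral chi-squared,
  sampled as a Poisson-mixed gamma) on a grid of step
  dt = 0.01/max(κ, ⟨K⟩, β, γ); the flux integral is accumulated
  trapezoidally (K piecewise linear), giving a quadratic within-cell
  inversion.
* Splicing and degradation have count-proportional, K-independent
  propensities and need no special treatment; the firing channel is drawn
  from the instantaneous propensities at the firing time.

K(0) is drawn from the exact stationary law, so the driver is stationary
from t = 0 and only the counts must equilibrate; the default
equilibration horizon is therefore 15/min(β, γ) (a warning fires below
10 turnover times), independent of κ — this is what makes the
slow-reversion corner simulable.  Autocorrelation estimates record counts
on a lag grid over a further 5/min(β, γ) horizon and pool all start-time
pairs across replicates.  All kernels are seeded and bit-reproducible.

The validation protocol simulates 10⁴ cells per parameter set for six
sets (four near the regime-square corners at coordinates
(0.9, 0.1), (0.1, 0.1), (0.9, 0.9), (0.1, 0.9) and two intermediate,
(0.5, 0.5) and (0.3, 0.7)), with β = 1.2, γ = 0.7 and ⟨K⟩ = 10.

## Inference and model selection

Likelihoods are sums of log PMF lookups (floor 1e-12 against grid
truncation).  Maximum-likelihood fits run L-BFGS-B in log10-parameter
space over box constraints, multi-started from Latin-hypercube draws and,
in the pipeline, warm-started from the reduced-model optima.  During a
fit the PMF grid is held fixed at 1.5× the observed count range (rounded
to 32) so the objective is smooth in the parameters; candidates whose
10-sigma count range exceeds three grid lengths receive a graded penalty
instead of an evaluation, and the optimum is re-scored afterwards on a
properly sized grid.

Bayes factors use box-uniform priors in log10 space (±2 decades around
natural scales: κ, a ~ β+γ and θ ~ √(⟨K⟩(β+γ))); with ⟨K⟩ fixed, a is
eliminated via a = ⟨K⟩κ/θ, leaving two free dimensions.  Marginal
likelihoods are computed by deterministic midpoint quadrature on a tensor
grid (default 10–12 nodes per dimension), with an error estimate from
coarsening the grid twofold; |log₁₀BF| ≥ 2 is reported as decisive.
Because the quadrature nodes are data-independent, PMFs are cached per
(model, parameters) and reused across datasets and lattice points — this
is what makes the lattice distinguishability and repeated-recovery
experiments tractable.  Quadrature nodes whose 10-sigma count range
exceeds 400 are assigned zero likelihood: with the mean pinned by the
prior, such extreme-variance parameter sets place vanishing probability
on any moderate-count dataset.

Posterior sampling uses emcee's affine-invariant ensemble sampler (a
non-gradient MCMC) under the same priors, with a split-R̂ convergence
diagnostic; the deterministic grid posterior (normalized likelihood on
the quadrature grid) backs the credible-region coverage experiments.

Synthetic datasets for these experiments are drawn directly from the
exact steady-state PMF rather than via the stochastic simulator; the two
routes are exchangeable because simulator–solver agreement is established
independently, and exact sampling is orders of magnitude faster.

## Gene-screening pipeline

Steady-state joint PMFs identify rates only up to a global time scaling,
so all pipeline fits pin γ = 1; reduced (limiting) models additionally
pin κ = 1, since the limits depend only on a/κ and θ/κ.  Regime
coordinates and all model comparisons are invariant to this convention.

Stages: (i) Matrix-Market ingestion with axis validation; (ii) cell
filter (total molecules < threshold, strict, default 10⁴); (iii) gene
filter — removed if, in either species, mean ≤ 0.01, max ≤ 3, or
max ≥ 400 (boundaries inclusive; the OR-over-species reading treats a
gene as uninformative if either species is); (iv) coarse regime
assignment: the three 3-parameter reduced models (bursty, heavy-tailed
CIR limit, mixture) are fit per gene per dataset and compared by Akaike
weights (AIC = 2k − 2ℓ); a gene is assigned a regime only if the argmax
weight agrees in every dataset with minimum weight ≥ 0.5, else
"unassigned"; (v) ranking by the worst (maximum) across-dataset rank of a
Pearson χ² statistic of the best reduced model, with probability-ordered
pooling of expected counts below 5 into bins; (vi) full four-parameter
Γ-OU and CIR fits on the shortlist, compared by log₁₀ likelihood ratios,
with |log₁₀LR| > 150 flagged as a failed optimization and excluded from
summaries.

The CIR-like reduced model evaluates the κ→∞ limit of the Riccati
characteristics quasi-statically: U0 relaxes instantly to the continuous
root of U0 = U1 + bU0², giving a closed-form integrand with b = θ/κ the
burst-size analogue.  The test suite confirms the full CIR model
converges to this limit (TV < 1e-3 at κ = 100 max(β, γ)) while remaining
bounded away from the geometric-burst model.

## Synthetic fixtures

The generator emulates replicated single-animal datasets: each gene has
fixed kinetic parameters (β = 1.2, γ = 0.7, ⟨K⟩ log-uniform in [3, 8]),
regime-planted in corner boxes of the regime square (reversion 0.75–0.9
and gain 0.8–0.92 for the bursty/heavy-tail corners; reversion 0.01–0.03
for the mixture corner), with counts simulated independently per
replicate.  Replicates differ *only* by RNG stream — the strictest
reading of biological replication, which makes cross-replicate
consistency checks well-posed.  Three constructed genes violate exactly
one expression-filter rule each.  Cells carry animal and subtype labels;
regime assignment conventionally uses one animal's subtype datasets
(mirroring a screen that calibrates on a single animal) and the full
selection uses all animals.

The fixtures do **not** emulate technical noise (dropout, ambient
molecules, barcode errors), cell-size variation, or cross-gene coupling.
Tests passing on fixtures therefore demonstrate the statistical
machinery under the models' own assumptions, not robustness to
measurement artifacts in real single-cell data.

## Problem sizes

Default experiment sizes are chosen so the full validation suite runs on
a single CPU in well under half an hour: 10⁴ cells per simulator
validation run, 1000-cell datasets for recovery and distinguishability
(about the size at which joint-distribution model selection becomes
decisive over most of the regime square), a 3×3 regime lattice with 2–3
datasets per point, 15×15 posterior grids, and fixture screens of 6–12
planted genes over four replicates.  All of these scale up linearly
through function arguments.

## Known limitations

* The likelihood grid cap (320 per axis) limits fits to genes with
  maximum counts of a few hundred — consistent with the pipeline's own
  max ≥ 400 exclusion rule.
* Evidence quadrature at 10–12 nodes per dimension resolves Bayes factors
  to roughly ±0.3 on the log10 scale near zero; decisions at the ±2
  decisive threshold are insensitive to this, but near-zero Bayes factors
  should be read qualitatively.
* The CIR heavy-tail regime slows the Riccati integration (stability-
  capped steps scale with κ); fits restrict κ to ≤ 31.6 γ, which is
  already deep in the bursty limit for count purposes.
* Time-dependent (non-stationary) distributions, feedback, multi-gene
  coupling and technical-noise layers are out of scope.
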