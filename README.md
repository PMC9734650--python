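# txnoise

Stochastic-transcription-rate models of single-cell RNA counts: exact
joint nascent/mature distributions, hybrid simulation, and Bayesian model
selection.

## The problem

Single-cell RNA counts are overdispersed, and the standard fix — fitting
negative-binomial-like distributions — says nothing about *why*.  This
package implements a class of mechanistic alternatives in which the
transcription rate K(t) of a gene is itself a stochastic process driving
the reaction chain

    0 --K(t)--> nascent --beta--> mature --gamma--> 0

Two biophysically motivated drivers are implemented, both with stationary
law K ~ Gamma(a/κ, θ) and mean ⟨K⟩ = aθ/κ:

* **Γ-OU** (gamma Ornstein–Uhlenbeck): exponential decay at rate κ plus
  compound-Poisson jumps (frequency a, mean size θ) — a coarse model of
  DNA supercoiling relieved by topoisomerase arrivals;
* **CIR** (Cox–Ingersoll–Ross): dK = (aθ − κK)dt + √(2κθK)dW — regulation
  by an abundant, fluctuating regulator.

The two models have *identical* means, variances, covariances and
autocorrelations — summary statistics cannot tell them apart — but their
full joint distributions P(x_N, x_M) differ, and the package provides the
machinery to exploit that: exact PMFs via generating functions and
inverse FFT, seeded hybrid Gillespie simulators, likelihood and
Bayes-factor model selection, and a gene-screening pipeline with a
synthetic-data generator.  Limiting models (constitutive, gamma-mixture,
geometric-burst, and the CIR heavy-tail family) are first-class.

Intended users: quantitative biologists and methods developers working
with paired spliced/unspliced count matrices who want
mechanism-discriminating fits rather than descriptive ones.

## Worked example

```python
import numpy as np
from txnoise import (
    ModelKind, PMFCache, PriorSpec, SimProtocol, log10_bayes_factor,
    params_from_regime, regime_coordinates, sample_dataset, simulate_cells,
    steady_state_moments,
)

# a moderately overdispersed gene: regime coordinates (0.5, 0.8),
# mean rate 10, splicing 1.0, degradation 1.7
p = params_from_regime(0.5, 0.8, 10.0, 1.0, 1.7)
m = steady_state_moments(p)
print(f"mu_N={m.mu_N:.2f} var_N={m.var_N:.2f} cov={m.cov_NM:.2f}")

# simulate 2000 cells under the gamma-OU driver and compare moments
cells = simulate_cells(ModelKind.GOU, p, SimProtocol(n_reps=2000, seed=1))
print(f"simulated mean_N={cells.nascent.mean():.2f}")

# can 1000 cells of CIR-generated data reject the gamma-OU model?
cache = PMFCache()
data = sample_dataset(ModelKind.CIR, p, 1000, np.random.default_rng(0), cache)
prior = PriorSpec.default(beta=1.0, gamma_=1.7, mean_rate=10.0)
sel = log10_bayes_factor(data, ModelKind.CIR, ModelKind.GOU, prior,
                         n_quad=10, cache=cache)
print(f"log10 Bayes factor (CIR vs GOU) = {sel.log10_bf:.2f}")
```

Output:

```
mu_N=10.00 var_N=38.09 cov=12.77
simulated mean_N=9.91
log10 Bayes factor (CIR vs GOU) = 6.42
```

The closed-form moments show the gene is strongly overdispersed
(variance ≈ 4× mean); the simulator reproduces the mean within Monte
Carlo error; and the log₁₀ Bayes factor of ≈ 6.4 — far above the
decisive threshold of 2 — shows that with 1000 cells the joint
nascent/mature distribution cleanly identifies the CIR driver even
though every summary statistic of the two models is identical.

A command-line interface mirrors the library
(`txnoise solve|moments|simulate|fit|pipeline|fixtures`), e.g.

```bash
txnoise fixtures --genes-per-regime 3 --cells 500 --animals 2 --out fx/
txnoise moments --params params.json
```

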