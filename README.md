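# crkinetics

Kinetic analysis of microbial hexavalent-chromium cometabolism in batch
reactors. Hexavalent chromium, Cr(VI), is a soluble, carcinogenic
pollutant that some bacteria (e.g. *Serratia* sp.) reduce to the far less
toxic Cr(III) — faster when fed cometabolic substrates such as glucose
and zero-valent-iron-rich high-carbon iron filings (HCIF). This package
implements the kinetic machinery such a study needs, end to end:

* **Pseudo-order decay kinetics** of the pollutant,
  `C(t) = C₀·e^(−kt)` (first order) and `C(t) = C₀/(1 + k·C₀·t)`
  (second order), fitted in closed form by linearisation.
* **Specific growth rate** `µ = d ln X/dt`, estimated from biomass time
  courses by a reproducible exponential-phase window search (max-R² over
  all contiguous log-linear windows).
* **Haldane–Andrews substrate inhibition**,
  `µ(S) = µmax·S / (S + S²/K_I + K_S)`, with bounded, seeded multi-start
  nonlinear least squares for (µmax, K_S, K_I).
* **A three-substrate Monod cometabolism model**: growth on glucose (C),
  Cr(VI) (P) and HCIF (h), each Monod term inhibited by the other two
  substrates singly (K₂ᵢ, K₃ᵢ) and jointly (K₄ᵢ) — nine cross-inhibition
  constants estimated with the per-substrate base parameters held fixed.
* **A batch-reactor simulator** (yield-coupled Monod mass balances with a
  saturating Cr(VI) reduction term) that generates triplicate, noisy time
  courses with known ground truth, so every fitter is testable by
  parameter recovery.
* **A pipeline + CLI** that reads (or synthesises) condition time series,
  estimates µ, fits everything, and writes a JSON report plus flat CSV
  tables of rate constants and K·S interaction products.

Intended users: environmental-bioprocess and bioremediation researchers
who want reproducible, scriptable versions of the growth/decay fits
usually done ad hoc in GraphPad or Excel.

## Worked example

```python
import numpy as np
from crkinetics import (
    HaldaneParams, fit_haldane, fit_rate_constant,
    generate_mu_dataset, preset_config, preset_conditions, simulate_batch,
)

# 1. recover a Haldane-Andrews parameter set from noise-free data
truth = HaldaneParams(mu_max=0.1129, K_S=0.5, K_I=1.01)  # glucose-like
S = np.geomspace(truth.S_star / 30, truth.S_star * 30, 10)
data = generate_mu_dataset(truth, list(S), noise_cv=0.0, seed=1)
fit = fit_haldane(data, n_starts=20, seed=1)
print(f"mu_max={fit.params.mu_max:.4f}  K_I={fit.params.K_I:.3f}  R2={fit.r_squared:.4f}")

# 2. simulate a tertiary batch and fit its Cr(VI) decay
cfg = preset_config("set2_tertiary", seed=1, noise_cv=0.0)
sim = simulate_batch(preset_conditions("set2_tertiary")[-1], cfg)  # 100 mg/L
rate = fit_rate_constant(sim.noise_free["crvi"], "first")
print(f"k1={rate.k:.4f} /h  R2={rate.r_squared:.3f}  n={rate.n_points}")
```

prints

```
mu_max=0.1129  K_I=1.010  R2=1.0000
k1=0.0113 /h  R2=0.632  n=9
```

The first line shows exact recovery of the generating growth parameters
(maximum specific growth rate 0.1129 h⁻¹, self-inhibition constant
1.01 mg/L, perfect fit). The second line is the apparent first-order
reduction constant of the simulated 100 mg/L tertiary batch; its modest
R² reflects that the simulated reduction is biomass-coupled and sigmoidal,
not truly exponential — exactly the situation in which the pseudo-order
fit is a rough empirical summary.

The same analysis from a shell:

```sh
crkinetics run-all --input set2_tertiary --seed 1 --noise-cv 0.0 --out report/
crkinetics simulate --preset set1_binary --seed 1 --out batch.csv
```

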