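# swimhmm

Hidden Markov models linking zebrafish larva swim-bout sequences and
ARTR (Anterior Rhombencephalic Turning Region) neural state dynamics.

Zebrafish larvae explore by discrete swim bouts, each reorienting the
animal by an angle δθ.  A trimodal angle distribution motivates three
bout types — forward (F), left turn (L), right turn (R) — whose
temporal organization carries behavioral memory.  `swimhmm` provides a
tested implementation of the full state-space analysis:

- **Threshold Markov chain baseline** (`swimhmm.markov`): label bouts
  at ±δθ₀ (default 10°), estimate the 3×3 transition matrix
  P(s→s′) = #(s→s′)/Σ#(s→·), stationary distribution.
- **Symmetric behavioral HMM** (`swimhmm.behavior`): emissions
  E(δθ|F) = 𝒩(δθ; 0, σ), E(δθ|L) = Γ(+δθ; α, θ),
  E(δθ|R) = Γ(−δθ; α, θ) with α > 1, and left–right (non-handed)
  symmetry ties on the transition matrix.  Baum–Welch training (exact
  forward–backward E-step, weighted Gamma maximum-likelihood M-step),
  Viterbi decoding, and the static Normal+Gamma mixture validation.
- **Persistence statistics** (`swimhmm.persistence`): streak-length
  histograms and exponential fits ℓ₁, closed forms
  ℓ₁(s) = −1/ln P(s→s) and ℓ₀(s) = −1/ln P(s), and the stubbornness
  factor f_q = N₌/N₊ with its binomial uncertainty — the Markovianity
  probe that equals 1 for q ≥ 1 under any non-handed 3-state chain.
- **Neural HMM** (`swimhmm.neural`): K-state HMM over binarized
  rasters with independent Bernoulli emissions
  P(σ|s) = Π_i e^{h_i^s σ_i}/(1+e^{h_i^s}), closed-form field M-step,
  state labeling by lateralized excitability Δh_s, and held-out
  cross-validation over K.
- **Temporal bridge** (`swimhmm.bridge`): sojourn-time distributions,
  the scaling factor f_N/B = argmin_f RMSE(Q(Δt_b), f·Q(Δt_n)), and
  matrix-power rescaling P* = P^round(ν·f) for transition comparison.
- **Trajectory synthesis** (`swimhmm.trajectory`): neural-state-driven
  2D trajectories (x_k = Σ d_n cos θ_n) and the Mean Square
  Reorientation MSR(q) = ⟨(θ_{n+q} − θ_n)²⟩ with bias correction and
  diffusive/correlation decomposition.
- **Phenotyping** (`swimhmm.phenotyping`): chunked per-fish training,
  relative-likelihood confusion matrices, identification curves.
- **Synthetic data** (`swimhmm.synthetic`): generators for both
  modalities with known ground truth, linked by a known scaling
  factor — every pipeline stage is testable without downloads.

## Worked example

```python
import numpy as np
from swimhmm.synthetic import GroundTruth, gen_behavior_sessions
from swimhmm.behavior import fit_behavior_hmm
from swimhmm.config import FitConfig
from swimhmm.markov import stationary_distribution
from swimhmm.persistence import stubbornness_theoretical, theoretical_lengths

truth = GroundTruth(seed=13)          # sigma=15 deg, alpha=2, theta=10 deg
sessions = gen_behavior_sessions(truth, n_traj=500, length_law=60, seed=13)
model, trace = fit_behavior_hmm([b.dtheta for b, _ in sessions],
                                FitConfig(restarts=3, seed=13))
print(np.round(model.transition, 3))
print(round(model.sigma_f, 2), round(model.alpha, 2), round(model.theta, 2))
pi = stationary_distribution(model.transition)
print(round(theoretical_lengths(model.transition, pi)["L"]["ell1"], 2))
print(round(stubbornness_theoretical(model.transition, pi, 1), 4))
```

prints

```
[[0.705 0.148 0.148]
 [0.452 0.487 0.061]
 [0.452 0.061 0.487]]
15.14 2.02 9.82
1.39
1.0
```

The fitted transition matrix reproduces the generating one (forward
self-transition 0.70, turn self-transition 0.49, direct L↔R switches
rare), the emission parameters (σ = 15°, α = 2, θ = 10°) are recovered
to ~2%, the characteristic turning-streak length ℓ₁ ≈ 1.4 bouts, and
the stubbornness factor of the symmetric fit is exactly 1 — the
left-right symmetric chain carries no orientation memory across
forward bouts.

A command-line surface mirrors the pipeline
(`swimhmm simulate | label-mc | fit-behavior | fit-neural | decode |
persistence | bridge | generate | identify | crossval`); e.g.
`swimhmm bridge --seed 1 --out bridge.json` generates a linked
behavioral/neural dataset with scaling factor 0.44 and recovers
`f = 0.434` with a rescaled transition RMSE near 0.

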