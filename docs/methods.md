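# Methods

## Models

### Behavioral HMM

Bout sequences are modeled by a three-state hidden Markov model over
{F, L, R}.  Emissions are the reorientation angle in degrees, with
δθ > 0 a left turn:

- forward: δθ | F ~ Normal(0, σ);
- left turn: δθ | L ~ Gamma(α, θ) on δθ > 0;
- right turn: −δθ | R ~ Gamma(α, θ) on δθ < 0,

with θ > 0 and the shape constrained to α > 1 so the turn density
vanishes at zero (a mode strictly away from straight swimming).
Non-handedness (no population-level left/right preference) is imposed
by tying P(F→L)=P(F→R), P(L→L)=P(R→R), P(L→R)=P(R→L), P(L→F)=P(R→F)
and sharing (α, θ) between the turn states.  A direct consequence,
asserted in the tests, is an exactly left-right symmetric stationary
distribution, P(L)=P(R).

Assumptions worth keeping in mind: angles are conditionally
independent given states; intervals and distances are independent of
the bout type; there is no covariate structure (temperature or
individual enter only through separate fits).

### Neural HMM

Binarized rasters (neurons × frames) are modeled by a K-state HMM
(default K = 3) with independent Bernoulli emissions: neuron i fires
in state s with probability logistic(h_i^s).  The 3·N local fields
h_i^s are the only emission parameters; no left-right symmetry is
enforced on the neural model.  States of a fitted K = 3 model are
assigned F/L/R labels by the lateralized excitability
Δh_s = ⟨logistic(h_i^s)⟩_{i∈left} − ⟨logistic(h_i^s)⟩_{i∈right},
ordering Δh_L > Δh_F > Δh_R.  Within-state independence means
ipsilateral pairwise correlations are underestimated whenever the
data-generating process correlates neurons inside a state; the
synthetic generator (independent emissions) does not exhibit this
mismatch, so tests verify two-point reproduction only for what the
model family can express.

## Training

Both families are trained by Baum–Welch: exact forward–backward
E-step (scaled, numba-compiled), M-steps in closed form except the
Gamma shape.  Defaults follow the training protocol of at most 500 EM
iterations, stopping when the total log-likelihood gain drops below
10⁻⁶, with 5 random restarts keeping the best final log-likelihood.
The log-likelihood trace is non-decreasing on every run (hard test
assertion).  With strongly overlapping emissions (σ = 15°, Gamma mode
≈ 10°) EM can need more than 500 iterations to meet the 10⁻⁶ gain
threshold; recovery experiments that require full convergence raise
`max_iter` explicitly.

Numerical choices:

- Out-of-support turn emissions use a finite log-density floor of
  −10⁶ instead of −∞, keeping the dynamic programming NaN-free; the
  forward state's full support guarantees finite per-frame likelihood.
- Gamma M-step: weighted MLE on |δθ| with turn-posterior weights,
  solving log α − ψ(α) = log(wmean) − wmean(log) by Newton iteration
  from the Minka closed-form start; if the optimum has α ≤ 1, α is
  clamped to 1+10⁻⁶ and θ maximized given α.
- Neural field M-step: posterior-weighted mean activities are clipped
  to [10⁻⁶, 1−10⁻⁶] before the logit so fields stay finite when a
  neuron is silent or saturated within a state.
- Symmetry is enforced by averaging tied expected-count entries
  before row normalization (the exact constrained M-step).
- Transition initialization: symmetrized Dirichlet draws (behavioral)
  or diagonal-favoring Dirichlet draws (neural, where states persist
  across frames); emissions initialize from 10°-threshold moment
  matching (behavioral) or perturbed global firing logits (neural).
- Viterbi ties break toward the fixed state order F < L < R.
- Restarts that starve a state of posterior mass are discarded and
  redrawn (up to 4× the requested restart count).

## Persistence and stubbornness

Streak statistics treat maximal runs of F as forward streaks and
maximal runs of a single turn direction as turning streaks (a
direction change breaks the run); runs truncated by trajectory ends
are included by default, with an exclusion flag for sensitivity.  The
exponential streak fit regresses log counts on run length over bins
with at least 5 observations and needs at least 3 such bins.

The stubbornness factor at q intermediary forward bouts is the ratio
N₌/N₊ of same- to opposite-direction turn pairs T₁→F^q→T₂, counting
overlapping patterns.  Its uncertainty uses the binomial delta-method
form Δf_q = f_q·sqrt[(1/(N₌+N₊))(N₌/N₊ + N₊/N₌)], cross-checked
against a bootstrap in the tests.  For the matrix form at q ≥ 1 the
P(F→F)^q factor cancels, and any non-handed chain gives f_q = 1
exactly — the package's central analytic identity.

## Temporal bridge

Sojourn times are durations t_k − t_1 of maximal runs (length-1 runs
contribute 0; a flag drops zero-duration sojourns for sensitivity).
The scaling factor minimizes RMSE between matched quantile vectors of
the pooled behavioral and neural sojourn samples over f ∈ [0, 1].
The quantile grid uses 101 plotting positions (i − ½)/101: evenly
spaced but interior, because the pooled sojourn distributions are
heavy-tailed and quantile vectors that include the sample extremes
make the functional dominated by a single order statistic (measured:
including p = 1 inflates the estimator's standard deviation about
sixfold).  The RMSE-vs-f curve is quadratic in f, so the reported
argmin is the exact quadratic minimizer clamped to [0, 1]; the curve
is also returned on a 0.001-step grid.  Transition matrices are
compared after matrix-power rescaling P* = P^round(ν·f) (nearest
integer, halves away from zero), which preserves the stationary
distribution exactly.

## Trajectory synthesis and MSR

Bout times on the neural clock draw behavioral inter-bout intervals
and divide them by the scaling factor (neural dynamics are slower by
1/f; equivalently, multiplying neural time by f maps it onto
behavioral time).  Each bout inherits the neural state of the nearest
frame at or before its time; angles come from the behavioral emission
of that state and distances i.i.d. from the empirical pool, both
unconditioned on bout type.  Headings accumulate as θ_n = Σ δθ (bout
n's reorientation applies before its displacement), and positions as
x_k = Σ d_n cos θ_n with degree→radian conversion only inside the
trigonometric step.

The Mean Square Reorientation MSR(q) = ⟨(θ_{n+q} − θ_n)²⟩ subtracts
the dataset-mean angle first (bias correction: a constant angular
drift would otherwise grow as q²), averages over valid windows within
each trajectory and then over trajectories, never across boundaries.
The decomposition splits each window's squared sum into the sum of
squares (diffusive part, q × the window-averaged angle variance) and
twice the lagged cross-products (correlation part); the two add up to
MSR(q) identically, which the tests assert to 10⁻⁸.

## Synthetic data: what it emulates, and what not

The generator reproduces the statistical structure the analysis
relies on: trimodal angle distributions (central Normal + two signed
Gammas), Markov hidden-state dynamics with persistent forward and
turn states and rare direct L↔R switches, Bernoulli rasters with
lateralized fields, and a known neural-to-behavioral time scaling.
Defaults are the study conditions: σ = 15°, α = 2, θ = 10°; forward
self-transition 0.70, turn self-transition 0.49 (streak length
ℓ₁ ≈ 1.4 bouts), direct switch probability 0.06; rasters at
ν = 5.9 Hz with ~23-minute recordings and ~60–300 neurons; behavioral
sessions of 1148 trajectories × 60 bouts; scaling factor 0.44.
Inter-bout intervals default to Gamma (mean 1 s, shape 4) and
distances to LogNormal (median 1 mm, σ_log 0.5) — positive,
right-skewed stand-ins, since the empirical families are not part of
the model.  One root seed spawns independent substreams per
trajectory, so earlier draws are invariant to the trajectory count.

It does **not** emulate: within-state neuron-neuron correlations,
calcium dynamics or deconvolution artifacts, arena walls or
region-of-interest exits (hence no trajectory-length/stubbornness
coupling), temperature covariates, or inter-individual variability
beyond what the phenotyping tests construct explicitly.  Passing
tests therefore demonstrate correctness of the estimators under the
model's own assumptions, not robustness to these real-data features.

### The linked dataset

For linked behavioral/neural experiments the neural per-frame
transition matrix is the matrix root P_n = P_b^(1/k), k = round(ν·f)
(clipped and renormalized if the fractional power carries tiny
negative entries), so that matrix-power rescaling inverts the
construction exactly.  A behavioral run of m bouts spans m−1 random
intervals while a neural run of m frames spans (m−1)/ν seconds: the
two sojourn families cannot match in distribution exactly, so the
interval mean is calibrated so that the quantile-matching functional
that defines the scaling factor has expectation f under the study
conditions.  The calibration simulates finite chains of the actual
sequence lengths (run truncation at boundaries shifts the quantiles
noticeably) with a fixed internal stream, and exploits that
behavioral sojourn quantiles scale linearly in the interval mean, so
it is a one-shot ratio rather than a search.  Six neural recordings
are pooled for sojourn statistics, mirroring multi-recording
datasets.

A practical limitation, measured and documented: Viterbi decoding of
*behavioral* sequences under heavily overlapping emissions produces
MAP paths smoother than the true ones (observed ~3.5× longer apparent
sojourns at the default parameters), so quantitative scaling-factor
recovery uses the generator's true state sequences; the
transition-matrix comparison, which is robust to this, runs fully
end-to-end on fitted models.  Neural decoding at the default field
strengths is essentially exact, so this asymmetry does not affect the
neural side.

## Phenotyping

Sessions are split into contiguous equal-duration chunks (default
10), each trajectory assigned whole to the chunk containing its start
time.  Identification compares total test log-likelihoods (not
per-bout averages) relative to the self-model, marking ties
explicitly; the identification curve refits per-fish models on a
fresh random 50/50 trajectory split every trial and subsamples the
requested fraction of test trajectories.  Chunk and per-fish models
inherit the left-right symmetry constraint.

## Known limitations

- The behavioral state space is fixed at three states; model-order
  selection is implemented only on the neural side (held-out
  log-likelihood per unit time and two-point-moment correlation).
- The stubbornness uncertainty treats q-plets as independent
  Bernoulli trials and its closed form sits below the exact binomial
  delta-method sd by the factor sqrt(p² + (1−p)²) (≈ 0.71 near
  f_q = 1); together with plet overlap this makes the quoted error
  mildly anti-conservative (standardized deviations have spread
  slightly above 1 in simulation).
- The scaling-factor estimator remains tail-sensitive even on the
  interior quantile grid; its recovery tolerance (±0.05) reflects
  that.
- `split_chunks` without explicit start times assumes back-to-back
  trajectories, which compresses real inter-trajectory gaps.
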