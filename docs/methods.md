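# Methods

This note documents the models implemented in `cbgt`, the reasoning behind
the tunable defaults, the numerical choices, and what the simulations do and
do not establish.

## The spiking CBGT circuit

### Neurons

Every neuron follows the integrate-and-fire-or-burst equation

```
C dV/dt = −gL (V − VL) − gT h H(V − Vh) (V − VT) − I_syn + I_ext
dh/dt   = −h/τh−            when V ≥ Vh
        = (1 − h)/τh+       when V < Vh
```

with a hard spike threshold, reset, and absolute refractory period. With
`gT = 0` this is exactly a leaky integrate-and-fire unit; GPe and STN use
`gT = 60 nS`, giving a low-threshold Ca²⁺ current whose slow gate `h`
de-inactivates during hyperpolarization and produces post-inhibitory
rebound bursts. `I_ext` is depolarizing-positive (the sign convention of the
external current is absorbed into its parameter). Defaults: `C = 0.5 nF`,
`gL = 25 nS` (τm = 20 ms), `VL = −70 mV`, threshold −50 mV, reset −70 mV,
refractory 2 ms, `Vh = −60 mV`, `VT = 120 mV`, `τh− = 20 ms`,
`τh+ = 100 ms`. These are standard conductance-LIF values; none are taken
from a published parameter table for this circuit (see "Parameter
provenance" below).

### Synapses

Each neuron carries one gating variable per receptor class:

```
ds_AMPA/dt = Σ_j w_j δ(t − t_j) − s_AMPA/τ_AMPA        τ_AMPA = 2 ms
ds_GABA/dt = Σ_j w_j δ(t − t_j) − s_GABA/τ_GABA        τ_GABA = 5 ms
ds_NMDA/dt = α (1 − s_NMDA) Σ_j w_j δ(t − t_j) − s_NMDA/τ_NMDA
                                                        τ_NMDA = 100 ms, α = 0.63/ms
```

so AMPA/GABA integrate incoming spikes linearly (weight `w_j` per synapse)
while NMDA saturates below 1; saturation is applied per presynaptic impulse
so synchronous volleys cannot overshoot. The synaptic current is

```
I_syn = g_AMPA s_AMPA (V − V_E)
      + g_NMDA s_NMDA (V − V_E) / (1 + e^(−0.062 V)/3.57)
      + g_GABA s_GABA (V − V_I)
```

with `V_E = 0`, `V_I = −80 mV`; the NMDA factor is the standard
magnesium-block curve.

### Architecture

Sixteen population instances: Cx, dSPN, iSPN, GPe, STN, GPi and Th split
into left/right action channels; CxI and FSI shared. Projections follow the
canonical direct (Cx→dSPN→GPi→Th), indirect (Cx→iSPN→GPe→STN/GPi) and
hyperdirect (Cx→STN) pathways, with recurrent cortex, feedback Th→Cx and
thalamostriatal branches; STN→GPi is diffuse (both channels). Adjacency is
realized by independent Bernoulli draws at the configured probabilities;
the same seed always yields the same network. Two stabilizing
implementation choices:

* **In-degree normalization** (`normalize_in_degree`, on by default): each
  target neuron's summed static in-weight per projection is rescaled to its
  expectation. The Bernoulli adjacency (and its count statistics) is
  untouched; what this removes is the frozen left/right gain asymmetry that
  finite-size binomial sampling would otherwise build into every instance,
  which at these population sizes (tens of neurons) can dominate the
  learned weight differences that should drive choice. Plastic synapses are
  not rescaled.
* **Demeaned drive heterogeneity** (`hetero_sd`): each neuron receives a
  frozen current offset drawn per instance and demeaned within the
  instance. This desynchronizes otherwise-identical neurons (preventing
  population-wide oscillatory volleys) without biasing one channel.

### Background drive and stimulus

Each nucleus receives a mean-reverting (Ornstein–Uhlenbeck) background
current, `x ← x + θ(μ − x)·1ms + σ·N(0,1)·√1ms`, **shared by both channels
of the nucleus**. This placement matters: common drive fluctuations modulate
how fast either channel can reach threshold (broadening the RT
distribution) without deciding *which* channel wins, so the choice stays
sensitive to the learned corticostriatal weights. Independent per-channel
walks were tried and made choice essentially random with respect to the
weights. Independent per-neuron current noise (refreshed every 1 ms) adds
within-trial variability. The stimulus is a current step to both cortical
channels (54 pA default) with a 60 ms linear onset ramp; an instantaneous
step synchronizes cortex and produces artifactual threshold crossings
within tens of milliseconds.

### Decision readout

A choice is registered when either thalamic subpopulation's firing rate —
estimated in a 20 ms sliding boxcar stepped at 1 ms — reaches 30 Hz after
stimulus onset. RT is the crossing time; trials without a crossing within
1000 ms are dropped (and logged). If both channels cross in the same step
the higher rate wins, with a fair coin on exact ties (tie counts are
reported in run metadata). Trial features for decoding are the mean firing
rates of all sixteen population instances over [onset, decision] (a fixed
pre-decision window is available behind `readout.feature_window` for
sensitivity analyses).

### Integration

Fixed-step exponential-Euler at `dt = 0.1 ms`: the total conductance is
frozen within a step and the membrane relaxed exactly toward its
instantaneous equilibrium. For constant current and `gT = 0` this solves
the membrane equation exactly (the test suite asserts machine-precision
agreement with the closed form); with time-varying synaptic conductances
the per-step freeze stays within 0.05 mV of a 10×-finer reference on
transients. Spikes propagate with a one-step delay. The production path is
a fused numba kernel; the pure-numpy reference steps define the semantics
and the kernel is cross-checked against them spike-for-spike with noise
disabled.

## Dopamine-modulated corticostriatal plasticity

Each plastic synapse (Cx→dSPN and Cx→iSPN, within channel; one learned
weight drives both the AMPA and NMDA gate) carries a signed eligibility

```
τ_PRE dA_PRE/dt  = Δ_PRE X_PRE − A_PRE
τ_POST dA_POST/dt = Δ_POST X_POST − A_POST
τ_E dE/dt        = X_POST A_PRE − X_PRE A_POST − E
```

(spikes add `Δ/τ`, the impulse response of the printed dynamics). With
`Δ_PRE = 10 > Δ_POST = 6` the expected drift of E under co-activation is
positive and proportional to the product of pre- and postsynaptic rates, so
the channel that fired during the decision carries the credit. Defaults:
`τ_PRE = τ_POST = 20 ms`, `τ_E = 150 ms` (long enough to bridge the
decision-to-reward delay).

Phasic dopamine follows `τ_DOP dK/dt = C_scale (DA_inc − K) δ(t) − K` with
`DA_inc = r − Q_chosen` from a Q-update (`α_q = 0.15`, Q₀ = 0.5),
`τ_DOP = 20 ms`, `C_scale = 20` (so an event jumps K by ≈ the prediction
error). Negative errors give dopamine dips (K < 0). Reward is delivered at
the start of the 600 ms inter-trial interval; plasticity integrates
continuously through it.

Weights update as

```
dw/dt = [α_w E f_X(K)(W_max − w)]₊ + [α_w E f_X(K)(w − W_min)]₋
f_dSPN(K) = K        f_iSPN(K) = K / (c + |K|),   c = 0.5
```

with `α_w = +5 /ms` (dSPN), `−5 /ms` (iSPN), `W_max = 0.6`,
`W_min = 0.001`, initial weight 0.3. The soft bounds guarantee
`w ∈ [W_min, W_max]` for any input (property-fuzzed in the tests). The two
pathways play distinct roles at equilibrium: the dSPN weight relaxes back
toward the midpoint once Q-values converge (it carries the fast transient
after a reversal), while the saturating iSPN transfer makes the chosen
channel's indirect pathway depress persistently under a 75%-reward arm —
the stable component of the learned preference. Both pathway gains
(dSPN→GPi, iSPN→GPe→GPi) are therefore set high enough that a weight
asymmetry of ±0.06 shifts choice probability by ≈25 points.

In the fused kernel, traces/eligibility/dopamine/weights advance on a 1 ms
stride (their time constants are ≥ 20 ms), with the weight loop gated on
|K| > 10⁻⁴; the pure functions in `cbgt.plasticity` are the reference and
are verified against closed-form impulse responses and event-based oracles.

## Task protocols

* **Network protocol**: binary rewards at (75%, 25%), deterministic switch
  every 10 trials, 600 ms inter-trial interval. "Conflict" means the
  suboptimal side still pays 25% of the time.
* **Human protocol**: integer point rewards `round(N(3,1))` (half-even,
  floored at 0) on rewarded choices, −1 point otherwise; sessions start at
  60 points; responses outside (0.1 s, 0.75 s) cost 5 points; switches are
  probabilistic with geometric block lengths (memoryless hazard 1/k,
  minimum length 1) for k ∈ {10, 20, 30}, crossed with
  p ∈ {0.65, 0.75, 0.85} over nine 300-trial conditions.

## Reduced-Bayesian ideal observer

Per trial, with hazard `H` (default the generative 1/k):

```
Ω   = H·L_new / (H·L_new + (1−H)·L_cur)
ERL ← (1−Ω)(ERL + 1) + Ω
B_chosen ← B_chosen + (r − B_chosen)/(ERL + 2)
B_unchosen ← B_unchosen + Ω (prior − B_unchosen)
ΔB  = B_optimal − B_suboptimal            (optimal = generative identity)
```

`L_cur` is the outcome likelihood under the current belief (Bernoulli for
binary rewards, Gaussian for points), `L_new` the new-regime prior
predictive (0.5, or a wide Gaussian). The learning rate is Ω-modulated
through the expected run length: a suspected change collapses ERL and makes
the next updates fast, while stable runs anneal the rate toward a running
mean. We deliberately route the Ω-modulation through ERL rather than mixing
Ω into every single update: with asymmetric Bernoulli likelihoods the
per-outcome mixture systematically biases beliefs toward 0.5, whereas the
ERL form converges to the arm's true expected reward (asserted in the
tests) and tracks the exact Bayesian run-length filter (mean |ΔΩ| < 0.03,
rank correlation > 0.6 on 600-trial sequences; the exact filter ships as a
test oracle only).

## Drift-diffusion model

The Wiener first-passage density (diffusion coefficient 1, boundaries 0 and
`a`, relative start `z`, nondecision time `t0`) is evaluated with the
small-time/large-time series expansions and the per-evaluation switching
rule that picks whichever needs fewer terms for a requested truncation
error (default 10⁻¹⁰; 10⁻⁷ inside optimization loops). The density
integrates to 1 over both boundaries to < 10⁻³ and matches the closed-form
absorption probability and a bridge-corrected first-passage simulator
(tests). Responses are accuracy-coded: upper boundary = objectively optimal
choice; `z` is fixed at 0.5 by default.

Trial-wise links `v_t = v0 + β·ΔB_t` and `a_t = a0 + β·Ω_t` (model family:
null, each single link, both, and the swapped pairings) are fit by
maximum likelihood with multi-start L-BFGS-B (bounds: `a ∈ [0.2, 5]`,
`t0 ∈ [0, min RT)`, slopes in ±8; `a_t` floored at 0.05 inside the
likelihood). Uncertainty comes from trial-resampling bootstrap refits
(percentile intervals); model comparison uses AIC/BIC relative to the
intercept-only fit with the conventional interpretation bands (≤2
equivocal; 3–7 considerably less support; ≥10 essentially none). This is a
per-subject likelihood pipeline, not a hierarchical sampler: information
criteria are labeled AIC/BIC, never DIC, and no across-subject pooling is
done. Parameter recovery at n = 1500 synthetic trials keeps the mean bias
of (v0, a, t0, β) below 10%.

## LASSO-PCR decoding and classifier uncertainty

Per training fold: center X, take the SVD `X = U S Vᵀ`, regress the choice
`y ∈ {−1, +1}` on the component scores `Z = U S` with the penalized
objective `pen(β) + C Σ log(1 + exp(−y_i z_iᵀβ))`; the intercept is part of
β and is penalized with it. Both penalties are implemented — `lasso`
(`‖β‖₁`, the default: it is the method's namesake) and `quadratic`
(`½βᵀβ`) — and the choice is recorded in every model object. `C = 1.0` by
default and is not tuned. All components with nonzero singular value are
retained. The solver is scikit-learn's liblinear path; the tests verify it
against a direct numerical minimizer of the written objective.

Coefficients back-project to a feature-space weight map `w = Vβ` (exact
identity `x·w = z·β` on the training span), predictions are
`ŷ = (1 − e^(−x·w))/(1 + e^(−x·w)) ∈ (−1, 1)` with `p̂ = (1 + ŷ)/2`, and
interpretation uses the forward-model encoding pattern
`A = cov(X)w / var(Xw)`. Classifier uncertainty is `U = |p̂ − opt_choice|`
with the optimal side coded 1 (left) / 0 (right) on the probability scale,
so a decoded left-probability of 0.8 under a left-optimal contingency gives
U = 0.2 exactly. Cross-validation is leave-one-run-out; centering, SVD and
coefficients never see the held-out run (a canary-feature test enforces
this).

## Change-point analyses

`align_to_changepoints` re-indexes any per-trial series by lag around the
block boundaries (mean ± 95% normal CI per lag; under-observed lags
dropped). `associate` bootstrap-resamples trials to estimate the slope of
trial-wise drift rate on classifier uncertainty, alongside Spearman rank
correlation; `associate_by_subject` adds a pooled estimate with per-subject
mean levels removed. The trial-wise drift series is the fitted linear
predictor `v0 + β·ΔB_t` of the regression model. Bootstrap is trial-level.

## Synthetic-data generators

* `gen_features`: `X = y·patternᵀ·effect + N(0, σ)` with a signed,
  half-positive/half-negative informative pattern emulating contralateral
  tuning; block-structured optimal sides; defaults mirror the 45-run ×
  60-trial human scale.
* `gen_ddm_behavior`: Euler–Maruyama at 1 ms with Brownian-bridge
  within-step crossing corrections (without the bridge, coarse steps bias
  passage times enough to fail distributional tests at large n).
* `gen_bold_and_betas`: one boxcar-convolved column per trial (double-gamma
  HRF: gamma(6,1) − gamma(16,1)/6, peak ≈ 5 s), polynomial drift
  regressors, white noise, ordinary-least-squares single-trial estimates —
  a deliberately toy-scale stand-in: no robust weighting, no physiological
  or motion structure, no NIfTI handling.

These generators emulate the statistical shape of the real pipelines
(lateralized encoding plus noise; diffusion behavior with known links), not
their physiology: passing tests demonstrate the correctness of the analysis
machinery, not claims about real hemodynamic data.

## Parameter provenance and calibration

No neuron, connectivity, or plasticity constant in this package comes from
a published table for this specific circuit; every default in
`data/default_network.yaml` is an implementation choice. The calibration
targets were the circuit's published *observables*: plausible baseline
firing rates (cortex ≈ 2–6 Hz, striatal projection neurons ≈ 1–4 Hz, FSI
≈ 15 Hz, GPe ≈ 50–60 Hz, STN ≈ 18 Hz, GPi ≈ 60–120 Hz, thalamus low), the
decision RT percentiles (median ≈ 196 ms, 75th ≈ 314 ms), reversal
learning within 10-trial blocks, and partial co-activation of the two
action channels during decisions. Background drives were fitted to the rate
targets with an iterative controller; the stimulus amplitude was then set
so that the pooled RT percentiles of four seeded instances land near the
reference values. At rest the tuned circuit sits in a regime where GPi
output is high and the thalamus nearly silent; decisions are transient
disinhibition events. The thalamocortical drive is split within/across
channels (0.18/0.12) so that the losing channel's thalamus co-activates
during decisions rather than staying silent — without this the two action
representations are perfectly separable and the notion of classifier
uncertainty degenerates.

## Default study sizes

The in-suite acceptance study uses four network instances × 240 closed-loop
trials (six pseudo-runs of 40), bootstrap sizes of 60 (DDM) and 500
(association), and a 400 ms settling period before each session; the
examples use single subjects at 80–200 trials. These sizes were chosen so
the full suite runs in minutes on one CPU while keeping the sign/reliability
patterns stable across instances.

## Known limitations

* Decoding the network's own firing-rate features recovers choice at
  ≈ 0.85–0.92 accuracy (AUC ≈ 0.9+), above the ≈ 0.75 regime reported for
  comparable simulations: with the feature window ending at the thalamic
  threshold crossing, the winner's features carry a strong deterministic
  signature, and this circuit's representations remain more separable than
  its reference despite the cross-channel co-activation. Increasing
  cross-talk further would push accuracy down but measurably destroys the
  learning-dependent effects (the drift-rate regression and the
  uncertainty–drift coupling), so the defaults favor the latter.
* Reversal learning at desk scale is modest (late-block accuracy ≈ 0.55–0.65
  pooled); single instances can be poor learners, which is why all
  statistical claims are made at the 3-of-4-instances level.
* Population sizes (≈ 750 neurons total) are small; instance-to-instance
  variability is correspondingly large and treated as "individual
  differences".
* The human protocol exists as a behavioral simulator and generator only;
  nothing here touches real imaging data.
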