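# cbgt — competing action representations in a spiking basal-ganglia decision circuit

`cbgt` is a research library for studying how cortico-basal-ganglia-thalamic
(CBGT) circuits adapt decision policies when reward contingencies change. It
implements, end to end, the generative modeling chain used to argue that
**competition between action representations sets the rate of evidence
accumulation**:

1. a **spiking CBGT network** — nine populations (Cx, CxI, dSPN, iSPN, FSI,
   GPe, STN, GPi, Th) of integrate-and-fire-or-burst neurons with
   conductance-based AMPA/NMDA/GABA synapses, organized into left/right
   action channels; a choice is read out when either thalamic subpopulation
   reaches 30 Hz (max 1000 ms, otherwise the trial is dropped);
2. **dopamine-modulated corticostriatal plasticity** — spike-timing
   eligibility traces `τ_E dE/dt = X_post A_pre − X_pre A_post − E` gated by
   phasic dopamine `K_DA` driven by Q-learning reward prediction errors,
   with soft-bounded weights
   `dw/dt = [α_w E f_X(K_DA)(W_max − w)]₊ + [α_w E f_X(K_DA)(w − W_min)]₋`
   that potentiate direct-pathway (dSPN) and depress indirect-pathway
   (iSPN) synapses when dopamine rises;
3. a **change-point two-armed bandit** (75/25 reward conflict, reversals
   every 10 trials for the network; probabilistic switches and point
   rewards for the human protocol);
4. a **reduced-Bayesian ideal observer** producing trial-wise change-point
   probability Ω and the belief advantage of the optimal target
   ΔB = B_opt − B_subopt;
5. a **drift-diffusion model** (Wiener first-passage likelihood, small/large
   time series expansions) with trial-wise regressions `v_t = v0 + β·ΔB_t`,
   `a_t = a0 + β·Ω_t`, maximum-likelihood fitting, bootstrap intervals and
   information-criterion model comparison;
6. a **LASSO-PCR decoder** (SVD of the trial × feature matrix, penalized
   logistic regression on component scores, back-projected weight maps and
   Haufe-style encoding patterns) with leave-one-run-out cross-validation,
   and the **classifier uncertainty** `U = |p̂ − opt_choice|` that measures
   co-activation of competing action representations;
7. **change-point-aligned analyses** and the bootstrap association between
   classifier uncertainty and trial-wise drift rate.

Synthetic-data generators (lateralized feature matrices, diffusion behavior
with known links, a toy boxcar×HRF single-trial GLM) make every analysis
stage testable without the simulator or any imaging data.

## Worked example

```bash
python examples/run_network_session.py
```

simulates one seeded network subject through 200 reversal-bandit trials and
prints (output from this exact command):

```
valid trials        : 187 / 200
median RT           : 208 ms (75th pct 380 ms)
overall accuracy    : 0.49
accuracy by position: 0.40 0.58 0.42 0.47 0.71 0.35 0.53 0.39 0.45 0.62
mean plastic weights at session end:
  w_dSPN_left: 0.187
  w_iSPN_left: 0.155
  w_dSPN_right: 0.181
  w_iSPN_right: 0.394
```

The accuracy-by-position row is aligned to the reward switches: accuracy
tends to be lowest right after a contingency change (position 0,
perseveration on the old target) and higher late in the 10-trial block as
dopaminergic plasticity shifts the corticostriatal weight balance toward
the new optimal channel; at a single subject and 20 blocks the profile is
noisy (the test suite pools four subjects for the statistical checks). Note
the learned asymmetry in the indirect pathway (`w_iSPN_right` high:
right-channel suppression while the left target was optimal in the final
block). Other examples cover decoding with classifier uncertainty
(`examples/decode_choices.py`), drift-diffusion link recovery
(`examples/fit_ddm_links.py`), and the ideal observer
(`examples/ideal_observer_demo.py`).

A thin CLI mirrors the main operations:

```bash
cbgt simulate --trials 120 --seed 3 --out runs/s3/
cbgt synth --kind features --out synth/
cbgt decode --features synth/features.csv --trials synth/trials.csv --out preds.csv
cbgt fit-ddm --trials ddm_trials.csv --model v~dB --out fit.json
```

All network constants live in one unit-annotated YAML
(`src/cbgt/data/default_network.yaml`); see `docs/methods.md` for the model
description, parameter provenance, and known limitations.

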