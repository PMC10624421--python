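"""Recover drift-diffusion regression links from simulated behavior.

Samples choices and reaction times from a diffusion whose drift is
modulated trial-by-trial by a belief covariate (v_t = v0 + 0.9 dB_t), fits
the regression family by maximum likelihood, and compares models by AIC
against the intercept-only fit. The fitted slope should recover 0.9 and the
linked model should beat the null decisively.
"""

import numpy as np

from cbgt.ddm import DDMParams, compare_models, fit_model
from cbgt.synth import gen_ddm_behavior

rng = np.random.default_rng(0)
delta_b = rng.uniform(-0.5, 0.8, 1500)
trials = gen_ddm_behavior(
    DDMParams(v=0.6, a=1.4, t0=0.25, z=0.5),
    n_trials=1500, seed=1, delta_b=delta_b, beta_v=0.9,
)

fits = {
    "null": fit_model(trials, model="null", seed=2),
    "v~dB": fit_model(trials, model="v~dB", n_boot=100, seed=3),
}
fit = fits["v~dB"]
lo, hi = fit.ci("beta_v~dB")
print(f"true drift link 0.9 -> estimated {fit.params['beta_v~dB']:.3f} "
      f"(95% bootstrap CI [{lo:.3f}, {hi:.3f}])")
print(f"v0={fit.params['v0']:.3f}  a={fit.params['a0']:.3f}  t0={fit.params['t0']:.3f}")

table = compare_models(fits)
print("\nmodel comparison (AIC):")
print(table.to_string(index=False))
print("\ndelta_null > 10 means the belief-linked drift model has essentially "
      "all the support relative to the intercept-only model.")
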