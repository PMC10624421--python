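"""Synthetic data generators for every downstream stage.

These make the decoding, drift-diffusion, and analysis machinery testable
without running the spiking circuit or downloading any imaging data:

* :func:`gen_features` — trial x feature matrices with a known lateralized
  encoding pattern plus Gaussian noise, emulating either firing-rate
  features of the circuit or single-trial hemodynamic response estimates
  (the human design scale is 45 runs x 60 trials).
* :func:`gen_ddm_behavior` — choices and reaction times sampled from the
  diffusion process by Euler-Maruyama with Brownian-bridge boundary-crossing
  correction, optionally with trial-wise drift/boundary modulated by
  supplied observer series (known ground-truth link coefficients for
  parameter-recovery tests).
* :func:`gen_bold_and_betas` — a toy single-trial hemodynamic regression:
  boxcar regressors convolved with a double-gamma hemodynamic response
  function, one design column per trial, drift regressors, and ordinary
  least-squares trial-wise estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist


@dataclass
class SynthFeatureConfig:
    """Lateralized-feature generator settings (defaults mirror the human
    design scale: 45 runs of 60 trials)."""

    n_runs: int = 45
    trials_per_run: int = 60
    n_features: int = 200
    n_informative: int = 40
    effect: float = 1.0
    noise_sd: float = 1.0
    p_optimal_choice: float = 0.75
    seed: int | None = None


def gen_features(config: SynthFeatureConfig):
    """Generate (X, y, runs, opt_choice, pattern).

    Half the informative features carry positive (left-preferring) weights
    and half negative, emulating contralateral tuning; X = y pattern^T *
    effect + N(0, noise_sd). ``y`` is the choice in {-1, +1} (+1 = left);
    ``opt_choice`` codes the optimal side on the probability scale (1 =
    left); choices agree with the optimal side with probability
    ``p_optimal_choice``.
    """
    if config.n_features < 1:
        raise ValueError("need at least one feature")
    rng = np.random.default_rng(config.seed)
    n = config.n_runs * config.trials_per_run
    pattern = np.zeros(config.n_features)
    k = min(config.n_informative, config.n_features)
    signs = np.ones(k)
    signs[k // 2:] = -1.0
    pattern[:k] = signs * rng.uniform(0.5, 1.5, k)
    opt = np.zeros(n, dtype=int)
    # optimal side alternates in blocks of 10 within each run
    for r in range(config.n_runs):
        start = r % 2
        for i in range(config.trials_per_run):
            opt[r * config.trials_per_run + i] = (start + (i // 10)) % 2
    y = np.where(rng.random(n) < config.p_optimal_choice, 1, -1)
    y = np.where(opt == 1, y, -y)  # align choice with the optimal side
    X = np.outer(y * config.effect, pattern) + rng.normal(0.0, config.noise_sd, (n, config.n_features))
    runs = np.repeat(np.arange(config.n_runs), config.trials_per_run)
    return X, y, runs, opt, pattern


def gen_ddm_behavior(
    params,
    n_trials: int = 1000,
    seed: int | None = None,
    delta_b: np.ndarray | None = None,
    beta_v: float = 0.0,
    omega: np.ndarray | None = None,
    beta_a: float = 0.0,
    dt: float = 1e-3,
    t_max: float = 10.0,
) -> pd.DataFrame:
    """Sample (rt, response) trials from the diffusion process.

    Euler-Maruyama paths between absorbing bounds 0 and a, with a
    Brownian-bridge correction for within-step boundary crossings (without it
    coarse steps systematically overestimate passage times). Trial-wise
    drift/boundary follow ``v_t = v + beta_v * delta_b_t`` and
    ``a_t = a + beta_a * omega_t``. Columns: rt (s), response (1 = upper),
    plus the covariates used.
    """
    if dt > 2e-3:
        raise ValueError("dt too coarse for accurate first-passage sampling")
    rng = np.random.default_rng(seed)
    v_t = np.full(n_trials, params.v)
    a_t = np.full(n_trials, params.a)
    if delta_b is not None:
        v_t = v_t + beta_v * np.asarray(delta_b, dtype=float)
    if omega is not None:
        a_t = a_t + beta_a * np.asarray(omega, dtype=float)
    if np.any(a_t <= 0):
        raise ValueError("boundary collapsed to zero")
    x = params.z * a_t
    rt = np.full(n_trials, np.nan)
    resp = np.zeros(n_trials, dtype=int)
    alive = np.ones(n_trials, dtype=bool)
    sqdt = np.sqrt(dt)
    n_steps = int(t_max / dt)
    for step in range(1, n_steps + 1):
        idx = np.where(alive)[0]
        if idx.size == 0:
            break
        x_new = x[idx] + v_t[idx] * dt + sqdt * rng.standard_normal(idx.size)
        hit_up = x_new >= a_t[idx]
        hit_lo = x_new <= 0.0
        # Brownian bridge: crossing probability within the step for paths
        # whose endpoints stayed inside the bounds
        inside = ~(hit_up | hit_lo)
        if np.any(inside):
            xi0, xi1 = x[idx][inside], x_new[inside]
            ai = a_t[idx][inside]
            p_up = np.exp(-2.0 * (ai - xi0) * (ai - xi1) / dt)
            p_lo = np.exp(-2.0 * xi0 * xi1 / dt)
            u = rng.random(inside.sum())
            bridge_up = u < p_up
            bridge_lo = (~bridge_up) & (u < p_up + p_lo)
            hit_up[inside] |= bridge_up
            hit_lo[inside] |= bridge_lo
        done = hit_up | hit_lo
        done_idx = idx[done]
        rt[done_idx] = step * dt + params.t0
        resp[done_idx] = hit_up[done].astype(int)
        alive[done_idx] = False
        x[idx[~done]] = x_new[~done]
    out = pd.DataFrame(dict(rt=rt, response=resp))
    if delta_b is not None:
        out["delta_B"] = np.asarray(delta_b, dtype=float)
    if omega is not None:
        out["omega"] = np.asarray(omega, dtype=float)
    return out.dropna().reset_index(drop=True)


# ---------------------------------------------------------------------------
# toy hemodynamic regression
# ---------------------------------------------------------------------------

@dataclass
class SynthBoldConfig:
    """Toy single-trial hemodynamic design (one design column per trial)."""

    tr: float = 0.75
    n_trials: int = 20
    trial_duration: float = 1.5
    mean_iti: float = 6.0
    n_voxels: int = 10
    noise_sd: float = 1.0
    drift_order: int = 3
    seed: int | None = None
    onsets: np.ndarray | None = field(default=None, repr=False)


def double_gamma_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma hemodynamic response (peak ~5 s, undershoot
    ~15 s, undershoot ratio 1/6), evaluated at times ``t`` in seconds."""
    t = np.asarray(t, dtype=float)
    peak = gamma_dist.pdf(t, 6.0, scale=1.0)
    under = gamma_dist.pdf(t, 16.0, scale=1.0)
    h = peak - under / 6.0
    return h


def build_design(config: SynthBoldConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boxcar-convolved single-trial design matrix.

    Returns (design [scans x trials], drift regressors incl. intercept,
    onsets). Each trial is a boxcar of ``trial_duration`` convolved with the
    double-gamma HRF and sampled at the TR.
    """
    rng = np.random.default_rng(config.seed)
    if config.onsets is None:
        itis = rng.exponential(config.mean_iti - 4.0, config.n_trials) + 4.0
        onsets = np.cumsum(itis) + 2.0
    else:
        onsets = np.asarray(config.onsets, dtype=float)
    total = onsets[-1] + 25.0
    n_scan = int(np.ceil(total / config.tr))
    dt_hi = 0.1  # high-resolution grid for the convolution
    t_hi = np.arange(0, n_scan * config.tr, dt_hi)
    hrf = double_gamma_hrf(np.arange(0, 30, dt_hi))
    design = np.zeros((n_scan, len(onsets)))
    scan_t = np.arange(n_scan) * config.tr
    for j, on in enumerate(onsets):
        box = ((t_hi >= on) & (t_hi < on + config.trial_duration)).astype(float)
        conv = np.convolve(box, hrf)[: len(t_hi)] * dt_hi
        design[:, j] = np.interp(scan_t, t_hi, conv)
    # polynomial drift regressors (Legendre-like, includes intercept)
    tt = np.linspace(-1, 1, n_scan)
    drift = np.vstack([tt**p for p in range(config.drift_order + 1)]).T
    return design, drift, onsets


def gen_bold_and_betas(
    config: SynthBoldConfig, true_betas: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate voxel time series and recover trial-wise responses by OLS.

    BOLD = design @ true_betas + slow drift + white noise; the estimator
    regresses each voxel's series on [design | drift] and returns the trial
    coefficients (a toy-scale stand-in for a robust single-trial GLM).
    Returns (bold [scans x voxels], design, beta_hat [trials x voxels]).
    """
    true_betas = np.atleast_2d(np.asarray(true_betas, dtype=float))
    if true_betas.shape[0] != config.n_trials:
        raise ValueError("true_betas must have one row per trial")
    design, drift, _ = build_design(config)
    rng = np.random.default_rng(None if config.seed is None else config.seed + 1)
    n_scan = design.shape[0]
    n_vox = true_betas.shape[1]
    drift_coef = rng.normal(0.0, 1.0, (drift.shape[1], n_vox))
    bold = design @ true_betas + drift @ drift_coef
    bold = bold + rng.normal(0.0, config.noise_sd, (n_scan, n_vox))
    full = np.hstack([design, drift])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError("rank-deficient design")
    coef, *_ = np.linalg.lstsq(full, bold, rcond=None)
    beta_hat = coef[: design.shape[1]]
    return bold, design, beta_hat
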