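"""Drift-diffusion model: first-passage likelihood, trial-wise regression, and
model comparison.

The decision process is a one-dimensional diffusion with drift ``v`` between
absorbing boundaries at 0 and ``a`` (diffusion coefficient fixed at 1),
starting at relative position ``z`` in (0, 1), with nondecision time ``t0``
added to every first-passage time. Responses are accuracy-coded: the upper
boundary is the objectively optimal choice.

The first-passage density is evaluated with the small-time/large-time series
expansions and the automatic switching rule of Navarro & Fuss (2009); the
number of series terms is chosen per evaluation for a requested truncation
error.

Trial-wise covariates from the ideal observer enter through linear links,
``v_t = v0 + beta_v * dB_t`` and ``a_t = a0 + beta_a * Omega_t``. Models are
fit by maximum likelihood (multi-start L-BFGS-B) with trial-resampling
bootstrap intervals, and compared by information criteria relative to an
intercept-only model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

_SQRT_2PI = np.sqrt(2.0 * np.pi)
_TINY = 1e-29


@dataclass
class DDMParams:
    """Core diffusion parameters (evidence units; time in seconds)."""

    v: float = 1.0    # drift rate
    a: float = 1.5    # boundary separation
    t0: float = 0.25  # nondecision time
    z: float = 0.5    # relative starting point in (0, 1)

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("boundary separation a must be positive")
        if self.t0 < 0:
            raise ValueError("nondecision time must be nonnegative")
        if not (0.0 < self.z < 1.0):
            raise ValueError("starting point z must lie in (0, 1)")


def _fpt_series(tau: np.ndarray, w: np.ndarray, err: float) -> np.ndarray:
    """Density of the normalized (v=0, a=1) diffusion hitting the lower bound.

    ``tau`` is first-passage time rescaled by a^2. Chooses between the
    small-time and large-time expansions so that the truncation error of the
    kept terms is below ``err`` (Navarro & Fuss 2009).
    """
    tau = np.maximum(tau, 1e-9)
    # required number of terms for each expansion
    with np.errstate(divide="ignore", invalid="ignore"):
        ks = 2.0 + np.sqrt(-2.0 * tau * np.log(2.0 * err * np.sqrt(2.0 * np.pi * tau)))
        ks = np.where(2.0 * err * np.sqrt(2.0 * np.pi * tau) < 1.0, ks, 2.0)
        ks = np.maximum(ks, np.sqrt(tau) + 1.0)
        kl = np.sqrt(-2.0 * np.log(np.pi * tau * err) / (np.pi**2 * tau))
        kl = np.where(np.pi * tau * err < 1.0, kl, 1.0 / (np.pi * np.sqrt(tau)))
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(tau)))
    out = np.empty_like(tau)
    use_small = ks < kl
    if np.any(use_small):
        t_s, w_s = tau[use_small], w[use_small]
        K = int(np.ceil(np.max(ks[use_small])))
        k = np.arange(-((K - 1) // 2), K // 2 + 1)
        arg = w_s[:, None] + 2.0 * k[None, :]
        dens = np.sum(arg * np.exp(-(arg**2) / (2.0 * t_s[:, None])), axis=1)
        out[use_small] = dens / np.sqrt(2.0 * np.pi * t_s**3)
    if np.any(~use_small):
        t_l, w_l = tau[~use_small], w[~use_small]
        K = int(np.ceil(np.max(kl[~use_small])))
        k = np.arange(1, K + 1)
        dens = np.sum(
            k[None, :]
            * np.exp(-(k[None, :] ** 2) * np.pi**2 * t_l[:, None] / 2.0)
            * np.sin(k[None, :] * np.pi * w_l[:, None]),
            axis=1,
        )
        out[~use_small] = np.pi * dens
    return np.maximum(out, 0.0)


def wfpt_density(
    rt: np.ndarray | float,
    response: np.ndarray | int,
    params: DDMParams | None = None,
    *,
    v: float | np.ndarray | None = None,
    a: float | np.ndarray | None = None,
    t0: float | None = None,
    z: float | None = None,
    err: float = 1e-10,
) -> np.ndarray:
    """Wiener first-passage density of observing (``rt``, ``response``).

    ``response`` codes the boundary: 1 = upper (optimal), 0 = lower.
    Parameters may be supplied as a :class:`DDMParams` or as (possibly
    trial-wise) keyword overrides. RTs at or below ``t0`` get zero density.
    """
    if params is not None:
        v = params.v if v is None else v
        a = params.a if a is None else a
        t0 = params.t0 if t0 is None else t0
        z = params.z if z is None else z
    rt = np.atleast_1d(np.asarray(rt, dtype=float))
    response = np.broadcast_to(np.atleast_1d(response), rt.shape)
    v = np.broadcast_to(np.asarray(v, dtype=float), rt.shape).copy()
    a = np.broadcast_to(np.asarray(a, dtype=float), rt.shape)
    z_arr = np.broadcast_to(np.asarray(z, dtype=float), rt.shape)
    t = rt - t0
    ok = t > 0
    # reflect so every observation is a lower-boundary passage
    upper = response >= 0.5
    v_eff = np.where(upper, -v, v)
    w_eff = np.where(upper, 1.0 - z_arr, z_arr)
    tau = np.where(ok, t, 1.0) / a**2
    base = _fpt_series(tau, w_eff, err)
    dens = base / a**2 * np.exp(-v_eff * a * w_eff - v_eff**2 * np.where(ok, t, 1.0) / 2.0)
    return np.where(ok, dens, 0.0)


def prob_upper(v: float, a: float, z: float = 0.5) -> float:
    """Probability of absorption at the upper boundary (closed form, sigma=1)."""
    if abs(v) < 1e-12:
        return z
    num = 1.0 - np.exp(-2.0 * v * a * z)
    den = 1.0 - np.exp(-2.0 * v * a)
    return float(num / den)


# ---------------------------------------------------------------------------
# trial-wise regression models
# ---------------------------------------------------------------------------

#: model family considered for selection: which observer estimate modulates
#: which decision parameter
MODEL_FAMILY = (
    "null",
    "v~dB",
    "a~Omega",
    "v~dB,a~Omega",
    "v~Omega",
    "a~dB",
    "v~Omega,a~dB",
)


def _parse_links(spec: str) -> list[tuple[str, str]]:
    if spec == "null":
        return []
    links = []
    for part in spec.split(","):
        lhs, rhs = part.strip().split("~")
        if lhs not in ("v", "a") or rhs not in ("dB", "Omega"):
            raise ValueError(f"unknown link {part!r}")
        links.append((lhs, rhs))
    return links


@dataclass
class FitResult:
    """Maximum-likelihood fit of one regression model."""

    model: str
    params: dict
    loglik: float
    aic: float
    bic: float
    n_trials: int
    v_trial: np.ndarray = field(repr=False, default=None)
    a_trial: np.ndarray = field(repr=False, default=None)
    bootstrap: pd.DataFrame | None = field(repr=False, default=None)

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        if self.bootstrap is None:
            raise ValueError("fit without bootstrap samples")
        q = (1.0 - level) / 2.0
        col = self.bootstrap[name]
        return float(col.quantile(q)), float(col.quantile(1.0 - q))


def _covariate(trials: pd.DataFrame, name: str) -> np.ndarray:
    col = {"dB": "delta_B", "Omega": "omega"}[name]
    return trials[col].to_numpy(dtype=float)


def _neg_loglik(theta, links, rt, resp, covs, z):
    v0, a0, t0 = theta[0], theta[1], theta[2]
    betas = theta[3:]
    v_t = np.full_like(rt, v0)
    a_t = np.full_like(rt, a0)
    for (lhs, rhs), b in zip(links, betas):
        if lhs == "v":
            v_t = v_t + b * covs[rhs]
        else:
            a_t = a_t + b * covs[rhs]
    a_t = np.maximum(a_t, 0.05)
    dens = wfpt_density(rt, resp, v=v_t, a=a_t, t0=t0, z=z, err=1e-7)
    return -np.sum(np.log(np.maximum(dens, _TINY)))


def fit_model(
    trials: pd.DataFrame,
    observer_series: pd.DataFrame | None = None,
    model: str = "v~dB,a~Omega",
    *,
    z: float = 0.5,
    n_boot: int = 0,
    n_starts: int = 3,
    seed: int | None = None,
) -> FitResult:
    """Fit a trial-wise DDM regression by maximum likelihood.

    ``trials`` must contain ``rt`` (seconds) and ``response`` (1 = optimal /
    upper boundary, 0 = suboptimal). Observer covariates ``delta_B`` and
    ``omega`` are taken from ``observer_series`` (aligned row-for-row) or
    from ``trials`` itself. ``n_boot`` trial-resampling replicates provide
    percentile intervals for every free parameter.
    """
    links = _parse_links(model)
    data = trials.reset_index(drop=True)
    if observer_series is not None:
        if len(observer_series) != len(data):
            raise ValueError("observer series not aligned to trials")
        data = pd.concat(
            [data, observer_series.reset_index(drop=True)[["delta_B", "omega"]]], axis=1
        )
    rt = data["rt"].to_numpy(dtype=float)
    resp = data["response"].to_numpy(dtype=float)
    covs = {rhs: _covariate(data, rhs) for _, rhs in links} if links else {}

    rng = np.random.default_rng(seed)
    est, nll = _fit_once(rt, resp, covs, links, z, n_starts, rng)

    names = ["v0", "a0", "t0"] + [f"beta_{l}~{r}" for l, r in links]
    params = dict(zip(names, est))
    k = len(est)
    n = len(rt)
    loglik = -nll
    result = FitResult(
        model=model,
        params=params,
        loglik=loglik,
        aic=2 * k - 2 * loglik,
        bic=k * np.log(n) - 2 * loglik,
        n_trials=n,
    )
    result.v_trial, result.a_trial = _trial_series(est, links, rt, covs)
    if n_boot > 0:
        rows = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            covs_b = {key: val[idx] for key, val in covs.items()}
            est_b, _ = _fit_once(rt[idx], resp[idx], covs_b, links, z, 1, rng, x0=est)
            rows.append(dict(zip(names, est_b)))
        result.bootstrap = pd.DataFrame(rows)
    return result


def _trial_series(theta, links, rt, covs):
    v_t = np.full_like(rt, theta[0])
    a_t = np.full_like(rt, theta[1])
    for (lhs, rhs), b in zip(links, theta[3:]):
        if lhs == "v":
            v_t = v_t + b * covs[rhs]
        else:
            a_t = a_t + b * covs[rhs]
    return v_t, np.maximum(a_t, 0.05)


def _fit_once(rt, resp, covs, links, z, n_starts, rng, x0=None):
    rt_min = float(np.min(rt))
    bounds = [(-8.0, 8.0), (0.2, 5.0), (0.0, max(rt_min - 1e-3, 1e-3))]
    bounds += [(-8.0, 8.0)] * len(links)
    if x0 is None:
        x0 = np.array([0.5, 1.5, 0.5 * rt_min] + [0.0] * len(links))
    best, best_nll = None, np.inf
    for i in range(n_starts):
        start = np.asarray(x0, dtype=float)
        if i > 0:
            start = start + rng.normal(0.0, [0.5, 0.3, 0.05 * rt_min] + [0.3] * len(links))
            start = np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(
            _neg_loglik,
            start,
            args=(links, rt, resp, covs, z),
            method="L-BFGS-B",
            bounds=bounds,
        )
        if res.fun < best_nll:
            best, best_nll = res.x, res.fun
    return best, best_nll


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def _band(delta: float) -> str:
    if delta <= 2.0:
        return "cannot rule out"
    if delta < 10.0:
        return "considerably less support"
    return "essentially no support"


def compare_models(fits: dict[str, FitResult], criterion: str = "aic") -> pd.DataFrame:
    """Rank fitted models by an information criterion relative to the null.

    Returns one row per model with ``delta_null = IC_null - IC_model``
    (positive = better than intercept-only) and ``delta_best`` against the
    best model, annotated with the conventional interpretation bands
    (<=2 equivocal, 3-7 considerably less support, >=10 essentially none).
    """
    if "null" not in fits:
        raise ValueError("comparison requires the intercept-only ('null') fit")
    n_ref = fits["null"].n_trials
    for name, f in fits.items():
        if f.n_trials != n_ref:
            raise ValueError(f"model {name!r} fit on a different trial set")
    ic = {name: getattr(f, criterion) for name, f in fits.items()}
    best = min(ic.values())
    rows = [
        dict(
            model=name,
            ic=ic[name],
            delta_null=ic["null"] - ic[name],
            delta_best=ic[name] - best,
            band=_band(ic[name] - best),
        )
        for name in fits
    ]
    return pd.DataFrame(rows).sort_values("ic").reset_index(drop=True)
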