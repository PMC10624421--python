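"""Change-point-aligned trial dynamics and the uncertainty/drift-rate association.

Two entry points:

* :func:`align_to_changepoints` re-indexes any per-trial series by lag
  relative to the contingency switches of the session, yielding the
  peri-switch profile (e.g. the drop-and-recovery of drift rate, or the
  transient rise of classifier uncertainty).
* :func:`associate` quantifies the headline relation between classifier
  uncertainty U and trial-wise drift rate v-hat: a trial-resampling bootstrap
  of the linear slope of v on U plus Spearman rank correlation, per subject
  and pooled (with subject mean offsets removed before pooling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AssociationResult:
    slope: float
    slope_ci: tuple[float, float]
    t: float
    p: float
    spearman_rho: float
    spearman_p: float
    n: int
    boot_slopes: np.ndarray


def align_to_changepoints(
    values: np.ndarray,
    boundaries: np.ndarray,
    window: tuple[int, int] = (-5, 6),
    min_n: int = 2,
) -> pd.DataFrame:
    """Mean +- 95% CI of a per-trial series by lag around each change point.

    ``boundaries`` are trial indices of block starts (lag 0 = first trial of
    the new block; negative lags precede the switch). Lags observed fewer
    than ``min_n`` times are dropped.
    """
    values = np.asarray(values, dtype=float)
    boundaries = np.asarray(boundaries, dtype=int)
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty window")
    rows = []
    for lag in range(lo, hi):
        idx = boundaries + lag
        idx = idx[(idx >= 0) & (idx < len(values))]
        vals = values[idx]
        vals = vals[np.isfinite(vals)]
        if len(vals) < min_n:
            continue
        m = vals.mean()
        sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        rows.append(dict(lag=lag, mean=m, ci_lo=m - 1.96 * sem, ci_hi=m + 1.96 * sem, n=len(vals)))
    return pd.DataFrame(rows)


def associate(
    u_series: np.ndarray,
    v_series: np.ndarray,
    n_boot: int = 2000,
    seed: int | None = None,
) -> AssociationResult:
    """Bootstrap association between classifier uncertainty and drift rate.

    Resamples trials with replacement and refits the slope of v on U; also
    reports the plain OLS t test and the Spearman rank correlation over all
    trials.
    """
    u = np.asarray(u_series, dtype=float)
    v = np.asarray(v_series, dtype=float)
    if u.shape != v.shape:
        raise ValueError("series length mismatch")
    ok = np.isfinite(u) & np.isfinite(v)
    u, v = u[ok], v[ok]
    n = len(u)
    lr = stats.linregress(u, v)
    rho, rho_p = stats.spearmanr(u, v)
    rng = np.random.default_rng(seed)
    slopes = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        ub = u[idx]
        if ub.std() == 0:
            slopes[b] = np.nan
            continue
        slopes[b] = stats.linregress(ub, v[idx]).slope
    slopes = slopes[np.isfinite(slopes)]
    ci = (float(np.percentile(slopes, 2.5)), float(np.percentile(slopes, 97.5)))
    return AssociationResult(
        slope=float(lr.slope),
        slope_ci=ci,
        t=float(lr.slope / lr.stderr) if lr.stderr > 0 else np.nan,
        p=float(lr.pvalue),
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        n=n,
        boot_slopes=slopes,
    )


def associate_by_subject(
    frame: pd.DataFrame,
    u_col: str = "uncertainty",
    v_col: str = "v_hat",
    subject_col: str = "subject",
    n_boot: int = 2000,
    seed: int | None = None,
) -> dict[str, AssociationResult]:
    """Per-subject associations plus a pooled ("aggregate") estimate.

    The aggregate removes each subject's mean U and v before pooling, so it
    reflects within-subject covariation rather than subject-level offsets.
    """
    out: dict[str, AssociationResult] = {}
    rng = np.random.default_rng(seed)
    u_all, v_all = [], []
    for subj, grp in frame.groupby(subject_col):
        out[str(subj)] = associate(
            grp[u_col].to_numpy(), grp[v_col].to_numpy(),
            n_boot=n_boot, seed=int(rng.integers(2**31)),
        )
        u_all.append(grp[u_col].to_numpy() - grp[u_col].mean())
        v_all.append(grp[v_col].to_numpy() - grp[v_col].mean())
    out["aggregate"] = associate(
        np.concatenate(u_all), np.concatenate(v_all),
        n_boot=n_boot, seed=int(rng.integers(2**31)),
    )
    return out


def plot_aligned(profiles: dict[str, pd.DataFrame], path: str | None = None):
    """Plot change-point-aligned mean +- CI profiles (one line per series).

    ``profiles`` maps labels to :func:`align_to_changepoints` outputs.
    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    for label, prof in profiles.items():
        ax.plot(prof.lag, prof["mean"], marker="o", label=label)
        ax.fill_between(prof.lag, prof.ci_lo, prof.ci_hi, alpha=0.2)
    ax.axvline(0, color="k", ls="--", lw=0.8)
    ax.set_xlabel("trials from change point")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
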