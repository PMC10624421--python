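"""Shared fixtures.

The expensive fixture is ``study``: a four-subject in-silico experiment
(four seeded network instances, 160 closed-loop bandit trials each) with the
full analysis chain — LASSO-PCR decoding with leave-one-run-out folds,
classifier uncertainty, ideal-observer estimates, and drift-diffusion
regression. It is computed once per test session and shared by the
acceptance tests and the slower behavioral property tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from cbgt import ddm
from cbgt.analysis import associate
from cbgt.config import default_config
from cbgt.decoding import cross_validate, uncertainty
from cbgt.observer import ObserverConfig, run_observer
from cbgt.sim import SimulatedSubject
from cbgt.task import BanditConfig, BanditEnv

N_SUBJECTS = 4
TRIALS_PER_SUBJECT = 240  # six pseudo-runs of 40 trials per instance
BLOCK = 10


@pytest.fixture(scope="session")
def study():
    """Four simulated participants through the network bandit protocol,
    plus every downstream estimate the analyses need."""
    warnings.filterwarnings("ignore", module="sklearn")
    rng = np.random.default_rng(20240901)
    subjects = []
    for seed in range(1, N_SUBJECTS + 1):
        subj = SimulatedSubject(default_config(), seed=seed, warmup_ms=400)
        env = BanditEnv(
            BanditConfig(n_trials=TRIALS_PER_SUBJECT, k=BLOCK, p_optimal=0.75, seed=40 + seed)
        )
        res = subj.run_session(env)
        tr = res.trials
        ok = ~tr.dropped.values
        X = res.features[ok]
        y = np.where(tr.choice.values[ok] == "left", 1, -1)
        runs = tr.trial.values[ok] // 40
        cv = cross_validate(X, y, runs, C=1.0, penalty="lasso")
        opt = (tr.optimal_side.values[ok] == "left").astype(int)
        unc = uncertainty(cv.phat, opt)
        obs = run_observer(tr[ok].reset_index(drop=True), ObserverConfig(hazard=1.0 / BLOCK))
        dat = tr[ok].reset_index(drop=True).copy()
        dat["rt"] = dat.rt / 1000.0
        dat["response"] = (dat.choice == dat.optimal_side).astype(int)
        fits = {
            m: ddm.fit_model(
                dat, obs, m,
                n_boot=60 if m == "v~dB,a~Omega" else 0,
                seed=int(rng.integers(2**31)),
            )
            for m in ("null", "v~dB,a~Omega")
        }
        assoc = associate(unc, fits["v~dB,a~Omega"].v_trial,
                          n_boot=500, seed=int(rng.integers(2**31)))
        subjects.append(
            dict(
                seed=seed,
                subject=subj,
                trials=tr,
                valid=ok,
                features=X,
                y=y,
                runs=runs,
                cv=cv,
                uncertainty=unc,
                observer=obs,
                data=dat,
                fits=fits,
                assoc=assoc,
                boundaries=res.boundaries,
                weights=res.weights,
            )
        )
    return subjects
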