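import numpy as np
import pandas as pd
import pytest

from devddm.behavior import DiffusionParams, MomentSummary, ez_estimate


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_trials(rts, correct=None, participant="P0", task="attention",
                condition="no:neutral"):
    """Minimal trial table from explicit RTs (all correct unless given)."""
    rts = np.asarray(rts, dtype=float)
    if correct is None:
        correct = np.ones(rts.size, dtype=bool)
    return pd.DataFrame(
        {
            "participant_id": participant,
            "task": task,
            "condition": condition,
            "correct": np.asarray(correct, dtype=bool),
            "rt": rts,
        }
    )


@pytest.fixture
def trials_factory():
    return make_trials


def wiener_recovery_errors(trials, truth: DiffusionParams, n_boot=200, seed=7):
    """(deviation / bootstrap MC SE) for v, a, Ter from simulated trials.

    The MC standard errors are estimated by resampling the simulated trials
    and re-running the closed-form estimator, which is independent of the
    simulator under test.
    """
    corr = trials["correct"].to_numpy()
    rt = trials["rt"].to_numpy()

    def estimate(c, r):
        rc = r[c]
        return ez_estimate(
            MomentSummary(pc=c.mean(), mrt=rc.mean(), vrt=rc.var(ddof=1),
                          n=c.size)
        )

    est = estimate(corr, rt)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, 3))
    for b in range(n_boot):
        idx = rng.integers(0, rt.size, rt.size)
        e = estimate(corr[idx], rt[idx])
        boots[b] = (e.v, e.a, e.ter)
    se = boots.std(axis=0, ddof=1)
    dev = np.array([est.v - truth.v, est.a - truth.a, est.ter - truth.ter])
    return dev / se


@pytest.fixture
def wiener_recovery():
    return wiener_recovery_errors
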