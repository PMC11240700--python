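import numpy as np
import pandas as pd
import pytest

from radsurv.simulate import (
    CensoringConfig,
    CohortSimConfig,
    WeibullBaseline,
    generate_cohort,
    generate_survival_times,
)


@pytest.fixture(scope="session")
def survival_fixture_30():
    """30 subjects with censoring and a single continuous covariate."""
    rng = np.random.default_rng(42)
    x = rng.standard_normal(30)
    t, e = generate_survival_times(
        0.8 * x, WeibullBaseline(), CensoringConfig(target_event_fraction=0.8), seed=7
    )
    return x, t, e


@pytest.fixture(scope="session")
def small_cohort():
    """Null 60-patient cohort (no true effects), reused across tests."""
    cfg = CohortSimConfig(n_patients=60, n_features=12, seed=123)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def signal_cohort():
    """140-patient cohort with a prognostic lesion feature and protective
    heterogeneity, matching the generator's study conditions."""
    cfg = CohortSimConfig(
        n_patients=140, beta_feature=0.4, beta_ipith=-0.3, seed=11
    )
    return generate_cohort(cfg)


def efron_loglik(beta: float, x: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Independent Efron partial log-likelihood for a single covariate.

    Written directly from the definition (loop over distinct event times)
    for use as a grid-search oracle.
    """
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    eta = beta * x
    ll = 0.0
    for ut in np.unique(time[event]):
        D = event & (time == ut)
        R = time >= ut
        d = int(D.sum())
        sum_d = np.exp(eta[D]).sum()
        sum_r = np.exp(eta[R]).sum()
        ll += eta[D].sum()
        for l in range(d):
            ll -= np.log(sum_r - l / d * sum_d)
    return ll


def brute_force_cindex(risk, time, event):
    """Pair-enumeration Harrell c-index (same comparability convention:
    shorter-time-event pairs, plus tied-time both-event pairs at 0.5)."""
    risk = np.asarray(risk, float)
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if time[i] < time[j] and event[i]:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    for i in range(n):
        for j in range(i + 1, n):
            if time[i] == time[j] and event[i] and event[j]:
                den += 1
                num += 0.5
    return num / den
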