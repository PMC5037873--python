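import logging

import numpy as np
import pytest

from retikin.fitting import fit_carotene_arm, fit_retinol_arm
from retikin.model import (
    COHORT_MEANS,
    COHORT_SDS,
    CaroteneArmParams,
    RetinolArmParams,
    SubjectParams,
    TracerCurve,
    mean_params,
    simulate_fd,
)
from retikin.synthetic import STUDY_SCHEDULE

logging.getLogger("retikin").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def cohort_mean_params() -> SubjectParams:
    return mean_params()


@pytest.fixture(scope="session")
def schedule() -> np.ndarray:
    return np.asarray(STUDY_SCHEDULE)


@pytest.fixture(scope="session")
def clean_curves(cohort_mean_params, schedule):
    """Noise-free curve pair at the study schedule, cohort-mean parameters."""
    return (simulate_fd(cohort_mean_params, "C10", schedule),
            simulate_fd(cohort_mean_params, "C5", schedule))


def lognormal_subject_draw(rng) -> SubjectParams:
    """One subject drawn from the moment-matched published population."""
    vals = {}
    for k, m in COHORT_MEANS.items():
        s = COHORT_SDS[k]
        sigma2 = np.log1p((s / m) ** 2)
        vals[k] = rng.lognormal(np.log(m) - sigma2 / 2.0, np.sqrt(sigma2))
    vals["DT3"] = min(vals["DT3"], 1.0)
    vals["DT13"] = min(vals["DT13"], 1.0)
    return SubjectParams(
        RetinolArmParams(vals["L21"], vals["L52"], vals["DT3"], vals["L54"],
                         vals["L65"], vals["L56"], vals["L106"]),
        CaroteneArmParams(vals["P11"], vals["L1512"], vals["DT13"],
                          vals["L1514"]),
    )


def multiplicative_noise(rng, size, cv):
    """Mean-1 lognormal noise factors with the given CV."""
    sigma2 = np.log1p(cv**2)
    return np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size))


@pytest.fixture(scope="session")
def noise_fit_study(cohort_mean_params, schedule, clean_curves):
    """50 replicate two-arm fits of 5%-noise data at cohort-mean truth.

    Shared between the fitting unit tests and the acceptance suite so the
    replicate study runs once per session.
    """
    rng = np.random.default_rng(20160810)
    c10, c5 = clean_curves
    results = {"fit10": [], "fit5": []}
    for _ in range(50):
        n10 = multiplicative_noise(rng, schedule.size, 0.05)
        n5 = multiplicative_noise(rng, schedule.size, 0.05)
        obs10 = TracerCurve("C10", schedule, c10.fd * n10)
        obs5 = TracerCurve("C5", schedule, c5.fd * n5)
        f10 = fit_retinol_arm(obs10)
        f5 = fit_carotene_arm(obs5, f10.params)
        results["fit10"].append(f10)
        results["fit5"].append(f5)
    return results
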