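"""Shared fixtures: reference parameters, simulated cohorts, toy designs.

Expensive simulation experiments (cohort recovery, null-covariate
calibration) are session-scoped so several tests can assert on one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from dexpopk import (
    CohortConfig,
    DispositionParams,
    PopulationModel,
    SubjectData,
    fit_population,
    naive_two_stage_init,
    simulate_cohort,
)
from dexpopk.estimation import DesignBase
from dexpopk.pk import InfusionSchedule


@pytest.fixture(scope="session")
def ref_params() -> DispositionParams:
    """Published typical disposition values (CL, Q in L/h; volumes in L)."""
    return DispositionParams(cl=38.5, q=46.4, v_c=27.0, v_t=87.6)


@pytest.fixture(scope="session")
def study_cohort():
    """One study-sized synthetic cohort (27 subjects, both protocols)."""
    return simulate_cohort(CohortConfig(seed=20240915))


@pytest.fixture(scope="session")
def study_fit(study_cohort):
    """Population fit of the study-sized cohort from the two-stage init."""
    init = naive_two_stage_init(study_cohort.subjects)
    return fit_population(study_cohort.subjects, init)


# ---------------------------------------------------------------------------
# linear-Gaussian toy: f = a + B·log(P) is linear in η when θ = 1, so with
# additive error the marginal likelihood has a closed form and FOCE-I,
# Laplace and quadrature must all reproduce it exactly
# ---------------------------------------------------------------------------


class LogLinearDesign(DesignBase):
    """Toy structural model f = a + B·log(P), one random effect."""

    def __init__(self, subjects, coeffs):
        super().__init__(subjects)
        self.param_names = ("p1",)
        self.a = np.concatenate([coeffs[int(s.id)][0] for s in subjects])
        self.B = np.concatenate([coeffs[int(s.id)][1] for s in subjects])

    def predict(self, params):
        return self.a + self.B * np.log(params)[self.sidx, 0]


@pytest.fixture(scope="session")
def linear_toy():
    """Subjects, design factory, model and the exact marginal −2LL."""
    rng = np.random.default_rng(3)
    omega2, sigma2 = 0.49, 0.09
    subjects, coeffs = [], {}
    for i in range(3):
        n = 2 + i
        a = rng.uniform(1, 3, n)
        b = rng.uniform(0.5, 2, n)
        y = a + b * rng.normal() * np.sqrt(omega2) + rng.normal(size=n) * np.sqrt(sigma2)
        subjects.append(
            SubjectData(
                id=i,
                schedule=InfusionSchedule([(0, 1, 1)]),
                obs_times=np.linspace(1, 2, n),
                dv=np.abs(y) + 0.1,
                covariates={},
            )
        )
        coeffs[i] = (a, b)

    def factory(subs):
        return LogLinearDesign(subs, coeffs)

    model = PopulationModel(
        theta={"p1": 1.0}, omega2={"p1": omega2}, sigma2=sigma2, error_model="additive"
    )

    def exact_ofv(subs=subjects):
        total = 0.0
        for s in subs:
            a, b = coeffs[int(s.id)]
            V = np.outer(b, b) * omega2 + np.eye(len(a)) * sigma2
            r = s.dv - a
            total += (
                len(a) * np.log(2 * np.pi)
                + np.linalg.slogdet(V)[1]
                + r @ np.linalg.solve(V, r)
            )
        return total

    return {
        "subjects": subjects,
        "factory": factory,
        "model": model,
        "exact_ofv": exact_ofv,
        "coeffs": coeffs,
        "omega2": omega2,
        "sigma2": sigma2,
    }


# ---------------------------------------------------------------------------
# expensive session-level experiments (shared by acceptance + invariant tests)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def recovery_results():
    """Simulate-and-refit experiment: cohorts of 100 subjects at truth.

    The suite runs 10 replicate cohorts — enough for stable medians of the
    recovered parameters; the reproduction script runs the full 20."""
    from dexpopk.validation import parameter_recovery

    return parameter_recovery(n_cohorts=10, n_subjects=100, seed=20240901)


@pytest.fixture(scope="session")
def null_deltas():
    """ΔOFV of a null weight-on-CL candidate over 200 simulated cohorts."""
    from dexpopk.validation import null_covariate_deltas

    return null_covariate_deltas(n_replicates=200, seed=123)
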