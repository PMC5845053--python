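"""Hierarchical population-PK model definition.

The population model follows the standard nonlinear mixed-effects
formulation: individual disposition parameters are lognormally distributed
around covariate-adjusted typical values,

    P_i = TV_P(x_i) · exp(η_P,i),      η_P,i ~ N(0, ω_P²)

and observed concentrations carry proportional residual error,

    C_obs,ij = C_P(t_ij; P_i) · (1 + ε_ij),   ε_ij ~ N(0, σ²).

Between-subject variability is reported on the percent-CV scale.  Two
conventions circulate in the population-PK literature; this package uses the
exact lognormal CV, ``100·sqrt(exp(ω²)−1)``, as its primary convention and
also exposes the first-order approximation ``100·sqrt(ω²)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pk import DispositionParams, InfusionSchedule, InvalidParameterError

__all__ = [
    "PK_PARAMS_2CPT",
    "PK_PARAMS_1CPT",
    "CovariateSpec",
    "PopulationModel",
    "SubjectData",
    "individual_params",
    "residual_variance",
    "omega2_to_cv",
    "cv_to_omega2",
    "sigma2_to_cv",
    "cv_to_sigma2",
    "reference_model",
]

#: canonical parameter order of the two-compartment disposition model
PK_PARAMS_2CPT = ("cl", "v_c", "v_t", "q")
#: one-compartment reduction used for model-comparison exercises
PK_PARAMS_1CPT = ("cl", "v_c")

_CATEGORICAL_COVARIATES = frozenset({"sex", "inotropes"})


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate effect on one disposition parameter.

    Forms (``x`` the subject's covariate value, ``x_ref`` the reference):

    - ``linear``:    TV = θ · (1 + β·(x − x_ref))
    - ``power``:     TV = θ · (x / x_ref)^β
    - ``indicator``: TV = θ · (1 + β·x)   with x ∈ {0, 1}

    The reference value keeps θ interpretable as the typical value for a
    reference patient (study medians: weight 75 kg, age 59.5 y, infusion
    duration 42.8 h).
    """

    parameter: str
    covariate: str
    form: str
    beta: float = 0.0
    reference: float | None = None

    def __post_init__(self) -> None:
        if self.form not in ("linear", "power", "indicator"):
            raise ValueError(f"unknown covariate form {self.form!r}")
        if self.form == "indicator":
            if self.covariate not in _CATEGORICAL_COVARIATES:
                raise ValueError(
                    f"indicator form requires a categorical covariate, got {self.covariate!r}"
                )
        else:
            if self.reference is None:
                raise ValueError(f"{self.form} form requires a reference value")
            if self.form == "power" and not self.reference > 0:
                raise ValueError("power form requires a positive reference value")

    def multiplier(self, x: np.ndarray, beta: float | None = None) -> np.ndarray:
        """Multiplicative adjustment to the typical value for covariate values ``x``."""
        b = self.beta if beta is None else beta
        x = np.asarray(x, dtype=float)
        if self.form == "power":
            return (x / self.reference) ** b
        if self.form == "linear":
            return 1.0 + b * (x - self.reference)
        return 1.0 + b * x

    @property
    def label(self) -> str:
        return f"{self.covariate}~{self.parameter}[{self.form}]"


@dataclass(frozen=True)
class PopulationModel:
    """Typical values, IIV variances and residual variance of the population model.

    Parameters
    ----------
    theta : mapping
        Typical disposition values keyed by parameter name (``cl`` L/h,
        ``v_c`` L, ``v_t`` L, ``q`` L/h); a two-entry mapping defines the
        one-compartment reduction.
    omega2 : mapping
        Diagonal IIV variances on the log scale (unitless); a parameter may
        be absent or zero, which pins its random effect at zero.
    sigma2 : float
        Residual error variance (proportional by default, so unitless).
    covariate_terms : sequence of CovariateSpec
        At most one term per (parameter, covariate) pair.
    error_model : str
        ``"proportional"`` (the study model) or ``"additive"`` (kept for
        toy/comparison fits; additive σ² is then in (ng/mL)²).
    """

    theta: Mapping[str, float]
    omega2: Mapping[str, float]
    sigma2: float
    covariate_terms: tuple[CovariateSpec, ...] = ()
    error_model: str = "proportional"

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", dict(self.theta))
        object.__setattr__(self, "omega2", dict(self.omega2))
        object.__setattr__(self, "covariate_terms", tuple(self.covariate_terms))
        for name, value in self.theta.items():
            if not (np.isfinite(value) and value > 0):
                raise InvalidParameterError(f"theta[{name}] must be positive, got {value!r}")
        for name, value in self.omega2.items():
            if not (np.isfinite(value) and value >= 0):
                raise InvalidParameterError(f"omega2[{name}] must be >= 0, got {value!r}")
            if name not in self.theta:
                raise InvalidParameterError(f"omega2 names unknown parameter {name!r}")
        if not (np.isfinite(self.sigma2) and self.sigma2 > 0):
            raise InvalidParameterError(f"sigma2 must be positive, got {self.sigma2!r}")
        if self.error_model not in ("proportional", "additive"):
            raise InvalidParameterError(f"unknown error model {self.error_model!r}")
        pairs = [(t.parameter, t.covariate) for t in self.covariate_terms]
        if len(pairs) != len(set(pairs)):
            raise InvalidParameterError("duplicate (parameter, covariate) covariate term")
        for term in self.covariate_terms:
            if term.parameter not in self.theta:
                raise InvalidParameterError(
                    f"covariate term targets unknown parameter {term.parameter!r}"
                )

    @property
    def param_names(self) -> tuple[str, ...]:
        order = PK_PARAMS_2CPT if len(self.theta) == 4 else PK_PARAMS_1CPT
        if set(order) == set(self.theta):
            return order
        return tuple(self.theta.keys())  # non-PK structural models (toys)

    def theta_vector(self) -> np.ndarray:
        return np.array([self.theta[p] for p in self.param_names])

    def omega2_vector(self) -> np.ndarray:
        return np.array([self.omega2.get(p, 0.0) for p in self.param_names])

    def typical_values(self, covariates: pd.DataFrame) -> np.ndarray:
        """Covariate-adjusted typical values, shape ``(n_subjects, n_params)``.

        Raises if any adjustment drives a typical value non-positive (a
        linear or indicator term with an extreme slope can do so; such
        candidates are rejected during covariate search).
        """
        names = self.param_names
        tv = np.tile(self.theta_vector(), (len(covariates), 1))
        for term in self.covariate_terms:
            j = names.index(term.parameter)
            x = covariates[term.covariate].to_numpy(dtype=float)
            tv[:, j] *= term.multiplier(x)
        if np.any(tv <= 0):
            raise InvalidParameterError("covariate adjustment produced non-positive typical value")
        return tv

    def with_term(self, term: CovariateSpec) -> "PopulationModel":
        return replace(self, covariate_terms=self.covariate_terms + (term,))

    def without_term(self, term: CovariateSpec) -> "PopulationModel":
        kept = tuple(
            t
            for t in self.covariate_terms
            if (t.parameter, t.covariate) != (term.parameter, term.covariate)
        )
        return replace(self, covariate_terms=kept)


@dataclass
class SubjectData:
    """Dosing history, observations and baseline covariates for one subject.

    Times are hours relative to the subject's first dose.  ``dv`` holds the
    observed plasma concentrations in ng/mL; the study reported no
    measurements below the quantification limit, so all observations must be
    finite and positive.
    """

    id: str | int
    schedule: InfusionSchedule
    obs_times: np.ndarray
    dv: np.ndarray
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.obs_times = np.asarray(self.obs_times, dtype=float)
        self.dv = np.asarray(self.dv, dtype=float)
        if self.obs_times.shape != self.dv.shape:
            raise ValueError(f"subject {self.id}: obs_times and dv differ in length")
        if self.obs_times.size and np.any(np.diff(self.obs_times) < 0):
            raise ValueError(f"subject {self.id}: observation times must be sorted")
        if not np.all(np.isfinite(self.dv) & (self.dv > 0)):
            raise ValueError(f"subject {self.id}: dv must be finite and positive")
        if self.obs_times.size and self.obs_times[0] < self.schedule.start:
            raise ValueError(
                f"subject {self.id}: observation precedes the dosing history"
            )

    @property
    def n_obs(self) -> int:
        return int(self.obs_times.size)


def individual_params(
    theta: Mapping[str, float], eta: Mapping[str, float]
) -> DispositionParams:
    """Individual disposition parameters ``P_i = θ_P · exp(η_P,i)``.

    The lognormal map is total: any real η yields strictly positive
    parameters.  Missing η entries default to zero (no deviation).
    """
    values = {p: theta[p] * float(np.exp(eta.get(p, 0.0))) for p in theta}
    return DispositionParams(**values)


def residual_variance(pred: np.ndarray, sigma2: float) -> np.ndarray:
    """Proportional residual variance ``Var(C_obs | pred) = pred²·σ²``."""
    pred = np.asarray(pred, dtype=float)
    return pred**2 * sigma2


def omega2_to_cv(omega2, convention: str = "lognormal"):
    """Percent CV implied by a log-scale variance ω².

    ``lognormal`` (primary): 100·sqrt(exp(ω²)−1), the exact CV of a
    lognormal variate.  ``naive``: 100·sqrt(ω²), the small-variance
    approximation common in run records.
    """
    omega2 = np.asarray(omega2, dtype=float)
    if convention == "lognormal":
        out = 100.0 * np.sqrt(np.expm1(omega2))
    elif convention == "naive":
        out = 100.0 * np.sqrt(omega2)
    else:
        raise ValueError(f"unknown CV convention {convention!r}")
    return float(out) if out.ndim == 0 else out


def cv_to_omega2(cv_percent, convention: str = "lognormal"):
    """Inverse of :func:`omega2_to_cv`."""
    cv = np.asarray(cv_percent, dtype=float) / 100.0
    if convention == "lognormal":
        out = np.log1p(cv**2)
    elif convention == "naive":
        out = cv**2
    else:
        raise ValueError(f"unknown CV convention {convention!r}")
    return float(out) if out.ndim == 0 else out


def sigma2_to_cv(sigma2: float) -> float:
    """Proportional-error magnitude as percent CV: 100·σ."""
    return 100.0 * float(np.sqrt(sigma2))


def cv_to_sigma2(cv_percent: float) -> float:
    return (float(cv_percent) / 100.0) ** 2


def clearance_ml_min_kg(cl_l_per_h: float, weight_kg: float) -> float:
    """Convert a clearance in L/h to the weight-normalized mL/min/kg scale
    (38.5 L/h for a 70 kg patient → 9.2 mL/min/kg)."""
    return cl_l_per_h * 1000.0 / 60.0 / weight_kg


def reference_model() -> PopulationModel:
    """The final published dexmedetomidine ICU model used as default truth.

    Typical values: CL 38.5 L/h, V_C 27.0 L, V_T 87.6 L, Q 46.4 L/h; IIV
    63.2 / 124 / 89.0 / 80.9 %CV (lognormal convention); proportional
    residual error 24 %CV.
    """
    cvs = {"cl": 63.2, "v_c": 124.0, "v_t": 89.0, "q": 80.9}
    return PopulationModel(
        theta={"cl": 38.5, "v_c": 27.0, "v_t": 87.6, "q": 46.4},
        omega2={p: cv_to_omega2(cv) for p, cv in cvs.items()},
        sigma2=cv_to_sigma2(24.0),
    )
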