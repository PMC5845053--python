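"""Synthetic ICU dexmedetomidine cohorts with the study's design.

The generator emulates the observational analgosedation study this package
models: 27 mechanically ventilated adults, dexmedetomidine infused
continuously without a loading dose, started at 0.8–1 μg/kg/h and maintained
at 0.4–1.5 μg/kg/h with recorded rate adjustments, infusion durations of
23.7–102 h (median 42.8), and two arterial sampling protocols (22 subjects on
the short rich schedule, 5 on the extended one).  Concentrations are drawn
from the two-compartment population model with lognormal between-subject
variability and proportional residual error, and the latent truth (η draws
and noise-free concentrations) is always returned alongside the observable
table so recovery experiments can score themselves.

Weight, age and infusion duration are sampled from truncated (log)normal
distributions whose location is calibrated numerically so the *truncated*
median hits the study median exactly; only medians and ranges are known, so
the distribution shape is a declared assumption carried in the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .model import CovariateSpec, PopulationModel, SubjectData, reference_model
from .pk import DispositionParams, InfusionSchedule, predict_concentrations

__all__ = [
    "CohortConfig",
    "SimulatedCohort",
    "sample_covariates",
    "build_schedule",
    "sampling_times",
    "simulate_cohort",
    "PROTOCOL_A_INFUSION_HOURS",
    "PROTOCOL_A_POSTSTOP_HOURS",
    "PROTOCOL_B_INFUSION_HOURS",
    "PROTOCOL_B_POSTSTOP_HOURS",
]

# nominal sampling times, hours; 0 in the during-infusion list is the
# pre-dose draw and 0 in the post-stop list is the just-before-cessation draw
PROTOCOL_A_INFUSION_HOURS = (0.0, 1.0, 4.0, 8.0, 12.0, 16.0, 20.0)
PROTOCOL_A_POSTSTOP_HOURS = (0.0, 5 / 60, 10 / 60, 20 / 60, 1.0, 2.0, 4.0, 6.0)
PROTOCOL_B_INFUSION_HOURS = (0.0, 2.0, 8.0, 24.0, 32.0, 48.0, 56.0, 72.0, 80.0)
PROTOCOL_B_POSTSTOP_HOURS = (0.0, 5 / 60, 10 / 60, 15 / 60, 30 / 60, 1.0, 2.0, 4.0, 6.0, 12.0)


@dataclass
class CohortConfig:
    """Design parameters of a synthetic cohort (defaults = study design)."""

    n_subjects: int = 27
    n_protocol_b: int | None = None  # default: 5/27 of the cohort, rounded
    truth: PopulationModel = field(default_factory=reference_model)
    weight_range: tuple[float, float] = (45.0, 100.0)
    weight_median: float = 75.0
    weight_sd: float = 12.0
    age_range: tuple[float, float] = (19.0, 84.0)
    age_median: float = 59.5
    age_sd: float = 16.0
    duration_range: tuple[float, float] = (23.7, 102.0)
    duration_median: float = 42.8
    duration_log_sd: float = 0.35
    initial_rate_range: tuple[float, float] = (0.8, 1.0)  # μg/kg/h
    maintenance_rate_range: tuple[float, float] = (0.4, 1.5)  # μg/kg/h
    max_rate_adjustments: int = 3
    p_male: float = 17 / 27
    p_inotropes: float = 21 / 27
    sofa_range: tuple[int, int] = (5, 16)
    sofa_center: float = 12.0
    sofa_sd: float = 2.5
    time_jitter_sd: float = 0.0  # h, optional deviation from nominal times
    covariate_effects: tuple[CovariateSpec, ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        for lo, hi in (
            self.weight_range, self.age_range, self.duration_range,
            self.initial_rate_range, self.maintenance_rate_range,
        ):
            if not hi > lo:
                raise ValueError("ranges must be non-degenerate (hi > lo)")
        nb = self.protocol_split[1]
        if not 0 <= nb <= self.n_subjects:
            raise ValueError("protocol split must sum to n_subjects")

    @property
    def protocol_split(self) -> tuple[int, int]:
        nb = (
            self.n_protocol_b
            if self.n_protocol_b is not None
            else round(self.n_subjects * 5 / 27)
        )
        return self.n_subjects - nb, nb


@dataclass
class SimulatedCohort:
    """Observable data plus the latent truth of one simulated cohort."""

    subjects: list[SubjectData]
    eta: pd.DataFrame  # per-subject random-effect draws
    conc_true: list[np.ndarray]  # noise-free concentrations per subject
    protocols: list[str]
    config: CohortConfig


def _calibrated_truncnorm(lo, hi, median, sd):
    """Truncated normal whose *post-truncation* median equals ``median``."""

    def med(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return truncnorm.ppf(0.5, a, b, loc=loc, scale=sd) - median

    loc = brentq(med, lo, hi)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return truncnorm(a, b, loc=loc, scale=sd)


def _calibrated_trunclognorm(lo, hi, median, log_sd):
    """Truncated lognormal (on the log scale) with calibrated median."""
    dist = _calibrated_truncnorm(np.log(lo), np.log(hi), np.log(median), log_sd)
    return dist


def sample_covariates(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Baseline covariate table: weight, age, sex, SOFA, inotropes, duration.

    Continuous covariates come from range-truncated distributions whose
    medians match the study's Table of demographics; sex and inotrope use
    are Bernoulli at the study prevalences; SOFA is an integer score in
    5–16 centered near 12.
    """
    n = config.n_subjects
    wdist = _calibrated_truncnorm(*config.weight_range, config.weight_median, config.weight_sd)
    adist = _calibrated_truncnorm(*config.age_range, config.age_median, config.age_sd)
    ddist = _calibrated_trunclognorm(
        *config.duration_range, config.duration_median, config.duration_log_sd
    )
    weight = wdist.ppf(rng.uniform(size=n))
    age = adist.ppf(rng.uniform(size=n))
    duration = np.exp(ddist.ppf(rng.uniform(size=n)))
    sex = (rng.uniform(size=n) < config.p_male).astype(int)  # 1 = male
    inotropes = (rng.uniform(size=n) < config.p_inotropes).astype(int)
    lo, hi = config.sofa_range
    sofa = np.clip(
        np.rint(rng.normal(config.sofa_center, config.sofa_sd, size=n)), lo, hi
    ).astype(int)
    return pd.DataFrame(
        {
            "weight": weight,
            "age": age,
            "sex": sex,
            "sofa": sofa,
            "inotropes": inotropes,
            "duration": duration,
        }
    )


def build_schedule(
    covariates: pd.Series, config: CohortConfig, rng: np.random.Generator
) -> InfusionSchedule:
    """Weight-scaled piecewise-constant infusion history for one subject.

    The first segment runs at the starting rate (0.8–1 μg/kg/h by default);
    subsequent segments, delimited by 0–3 recorded dose adjustments at random
    times, run at maintenance rates (0.4–1.5 μg/kg/h).  No loading dose.
    """
    wt = float(covariates["weight"])
    duration = float(covariates["duration"])
    n_adj = int(rng.integers(0, config.max_rate_adjustments + 1))
    # adjustments happen away from start/stop so segments stay non-trivial
    t_adj = np.sort(rng.uniform(1.0, max(duration - 1.0, 1.5), size=n_adj))
    edges = np.concatenate([[0.0], t_adj, [duration]])
    rates = np.empty(n_adj + 1)
    rates[0] = rng.uniform(*config.initial_rate_range) * wt
    rates[1:] = rng.uniform(*config.maintenance_rate_range, size=n_adj) * wt
    return InfusionSchedule(
        [(a, b, r) for a, b, r in zip(edges[:-1], edges[1:], rates)]
    )


def sampling_times(
    protocol: str,
    schedule: InfusionSchedule,
    jitter_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Nominal arterial sampling times for one subject, hours from first dose.

    Protocol ``"A"`` (22/27 subjects): pre-dose and 1, 4, 8, 12, 16, 20 h
    after start, then pre-stop and 5, 10, 20, 60 min and 2, 4, 6 h after
    cessation.  Protocol ``"B"``: pre-dose and 2, 8, 24, 32, 48, 56, 72,
    80 h, then pre-stop and 5, 10, 15, 30, 60 min and 2, 4, 6, 12 h after
    cessation.  During-infusion times beyond the actual stop are dropped,
    as happened in the study when infusions ended early.
    """
    if protocol == "A":
        during, post = PROTOCOL_A_INFUSION_HOURS, PROTOCOL_A_POSTSTOP_HOURS
    elif protocol == "B":
        during, post = PROTOCOL_B_INFUSION_HOURS, PROTOCOL_B_POSTSTOP_HOURS
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    stop = schedule.end
    times = [t for t in during if t < stop] + [stop + t for t in post]
    times = np.asarray(times)
    if jitter_sd > 0:
        if rng is None:
            raise ValueError("jitter requires an rng")
        jitter = rng.normal(0.0, jitter_sd, size=times.size)
        jitter[times == 0.0] = 0.0  # the pre-dose draw stays pre-dose
        times = np.maximum(times + jitter, 1e-3)
        times.sort()
    return times


def _individual_profile(params: dict, schedule: InfusionSchedule, times: np.ndarray) -> np.ndarray:
    """Noise-free central concentrations for either compartment count."""
    if "v_t" in params:
        return predict_concentrations(
            DispositionParams(**params), schedule, times
        ).conc_central
    cl, v_c = params["cl"], params["v_c"]
    k10 = cl / v_c
    c = np.zeros_like(times, dtype=float)
    for ts, te, r in schedule.segments:
        c += (r / cl) * (
            np.exp(-k10 * np.maximum(times - te, 0.0))
            - np.exp(-k10 * np.maximum(times - ts, 0.0))
        )
    return np.maximum(c, 0.0)


def simulate_cohort(config: CohortConfig | None = None) -> SimulatedCohort:
    """Draw one full synthetic cohort from the population model.

    Per subject: covariates → infusion schedule → sampling times → η draw →
    individual parameters ``TV·exp(η)`` → noise-free profile → proportional
    error (truncated at ε > −0.999 so concentrations stay positive; the
    study reported no below-quantification measurements).  The pre-dose
    sample is part of the design but carries zero drug, so it produces no
    concentration record.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    cov = sample_covariates(config, rng)
    truth = replace(config.truth, covariate_terms=config.covariate_effects)
    n_a, _ = config.protocol_split
    protocols = ["A"] * n_a + ["B"] * (config.n_subjects - n_a)

    names = truth.param_names
    omega = np.sqrt(truth.omega2_vector())
    sigma = np.sqrt(truth.sigma2)
    tv = truth.typical_values(cov)

    subjects, conc_true, etas = [], [], []
    for i in range(config.n_subjects):
        schedule = build_schedule(cov.iloc[i], config, rng)
        times = sampling_times(
            protocols[i], schedule, config.time_jitter_sd,
            rng if config.time_jitter_sd > 0 else None,
        )
        times = times[times > 0.0]
        eta = rng.normal(0.0, 1.0, size=len(names)) * omega
        params_i = dict(zip(names, tv[i] * np.exp(eta)))
        c = _individual_profile(params_i, schedule, times)
        eps = rng.normal(0.0, sigma, size=c.size)
        for _ in range(100):
            bad = eps <= -0.999
            if not bad.any():
                break
            eps[bad] = rng.normal(0.0, sigma, size=int(bad.sum()))
        dv = c * (1.0 + eps)
        subjects.append(
            SubjectData(
                id=i + 1,
                schedule=schedule,
                obs_times=times,
                dv=dv,
                covariates=cov.iloc[i].to_dict(),
            )
        )
        conc_true.append(c)
        etas.append(eta)
    eta_df = pd.DataFrame(etas, columns=list(names), index=[s.id for s in subjects])
    return SimulatedCohort(
        subjects=subjects,
        eta=eta_df,
        conc_true=conc_true,
        protocols=protocols,
        config=config,
    )
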