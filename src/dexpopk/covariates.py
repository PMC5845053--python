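"""Shrinkage-gated stepwise covariate search on the PK parameters.

Screening restricts the search to parameters whose η-shrinkage is below a
threshold (default 25%): when empirical Bayes estimates are shrunk toward
zero they carry little information about covariate relationships, so testing
them mostly produces false leads.  Candidate effects are then evaluated by
likelihood-ratio steps: forward selection includes the candidate with the
largest OFV drop whenever that drop exceeds the χ²₁(0.95) point (3.84,
p < 0.05), and backward elimination removes terms whose deletion costs less
than the χ²₁(0.99) point (6.63, p < 0.01).

For continuous covariates both a linear and a power relationship are tried
and the better ΔOFV represents the candidate; categorical covariates enter
through indicator variables.  Continuous covariates are referenced at the
study medians (weight 75 kg, age 59.5 y, infusion duration 42.8 h) so
typical values keep their reference-patient interpretation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .estimation import FitSettings, PopulationFit, fit_population
from .model import CovariateSpec, PopulationModel, SubjectData

__all__ = [
    "FORWARD_THRESHOLD",
    "BACKWARD_THRESHOLD",
    "PARAMETER_ORDER",
    "COVARIATE_ORDER",
    "DEFAULT_REFERENCES",
    "SearchStep",
    "SearchTrace",
    "screen_parameters",
    "apply_covariate",
    "candidate_grid",
    "forward_selection",
    "backward_elimination",
    "run_covariate_search",
]

#: χ²(1) critical value at p = 0.05 — forward inclusion requires a larger OFV drop
FORWARD_THRESHOLD = float(chi2.ppf(0.95, df=1))  # 3.8415
#: χ²(1) critical value at p = 0.01 — backward retention requires a larger OFV rise
BACKWARD_THRESHOLD = float(chi2.ppf(0.99, df=1))  # 6.6349

# tie-break enumeration order (exact ΔOFV ties go to the earlier candidate)
PARAMETER_ORDER = ("cl", "v_c", "v_t", "q")
COVARIATE_ORDER = ("age", "weight", "sex", "duration", "inotropes", "sofa")
_CATEGORICAL = {"sex", "inotropes"}

#: study-median reference values for continuous covariates
DEFAULT_REFERENCES = {"weight": 75.0, "age": 59.5, "duration": 42.8, "sofa": 12.0}


@dataclass
class SearchStep:
    """One candidate evaluation in the stepwise trace."""

    step: int
    phase: str  # "forward" | "backward"
    candidate: str
    ofv: float
    delta_ofv: float
    decision: str  # "included" | "removed" | "rejected" | "retained" | "failed"


@dataclass
class SearchTrace:
    """Ordered record of a stepwise search plus its final model."""

    steps: list[SearchStep] = field(default_factory=list)
    final_model: PopulationModel | None = None
    final_fit: PopulationFit | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": s.step,
                    "phase": s.phase,
                    "candidate": s.candidate,
                    "ofv": s.ofv,
                    "delta_ofv": s.delta_ofv,
                    "decision": s.decision,
                }
                for s in self.steps
            ]
        )

    @property
    def selected(self) -> tuple[CovariateSpec, ...]:
        return self.final_model.covariate_terms if self.final_model else ()


def screen_parameters(
    fit: PopulationFit, shrinkage_threshold: float = 25.0
) -> tuple[str, ...]:
    """Parameters eligible for covariate testing: η-shrinkage strictly below
    the threshold (a parameter at exactly the threshold is excluded).

    Parameters with missing shrinkage (zero IIV) are excluded with a warning.
    """
    eligible = []
    for p in fit.model.param_names:
        s = fit.shrinkage_percent.get(p)
        if s is None or not np.isfinite(s):
            warnings.warn(f"shrinkage missing for {p}; excluded from covariate screening")
            continue
        if s < shrinkage_threshold:
            eligible.append(p)
    return tuple(eligible)


def apply_covariate(model: PopulationModel, spec: CovariateSpec) -> PopulationModel:
    """Model with the covariate effect added (β = 0 reproduces the base model)."""
    return model.with_term(spec)


def candidate_grid(
    parameters: Sequence[str],
    covariates: Sequence[str] = COVARIATE_ORDER,
) -> list[tuple[str, str]]:
    """(parameter, covariate) pairs in the documented tie-break order."""
    parameters = [p for p in PARAMETER_ORDER if p in parameters]
    covariates = [c for c in COVARIATE_ORDER if c in covariates] + [
        c for c in covariates if c not in COVARIATE_ORDER
    ]
    return [(p, c) for p in parameters for c in covariates]


def _forms_for(covariate: str, references: dict, forms: str = "auto") -> list[CovariateSpec]:
    if covariate in _CATEGORICAL:
        return [CovariateSpec("cl", covariate, "indicator")]
    ref = references.get(covariate)
    if ref is None:
        raise ValueError(f"no reference value for continuous covariate {covariate!r}")
    names = ("linear", "power") if forms == "auto" else (forms,)
    return [CovariateSpec("cl", covariate, f, reference=ref) for f in names]


def _fit_with(model, subjects, settings, design_factory):
    return fit_population(subjects, model, settings=settings, design_factory=design_factory)


def _evaluate_candidate(
    current_model,
    current_ofv,
    parameter,
    covariate,
    subjects,
    settings,
    references,
    design_factory,
    forms="auto",
):
    """Best (fit, spec, ΔOFV) over the admissible forms of one candidate."""
    best = None
    for proto in _forms_for(covariate, references, forms):
        spec = CovariateSpec(
            parameter, covariate, proto.form, beta=0.0, reference=proto.reference
        )
        try:
            fit = _fit_with(
                apply_covariate(current_model, spec), subjects, settings, design_factory
            )
        except Exception as exc:  # candidate models may be unfittable
            warnings.warn(f"candidate {spec.label} failed: {exc}")
            continue
        if not (fit.converged and np.isfinite(fit.ofv)):
            continue
        if best is None or fit.ofv < best[0].ofv:
            best = (fit, next(t for t in fit.model.covariate_terms
                              if (t.parameter, t.covariate) == (parameter, covariate)))
    if best is None:
        return None
    fit, spec = best
    return fit, spec, current_ofv - fit.ofv


def forward_selection(
    base_fit: PopulationFit,
    candidates: Sequence[tuple[str, str]],
    subjects: Sequence[SubjectData] | None = None,
    threshold: float = FORWARD_THRESHOLD,
    settings: FitSettings | None = None,
    references: dict | None = None,
    design_factory=None,
    forms: str = "auto",
) -> SearchTrace:
    """Stepwise forward inclusion of covariate effects.

    At each step every remaining candidate is fitted on top of the current
    model; the candidate with the largest OFV drop is included if the drop
    exceeds ``threshold`` (the nominal p < 0.05 rule).  Candidates whose
    fits do not converge are skipped for that step and logged.  ``forms``
    restricts continuous covariates to a single functional form ("linear"
    or "power") instead of the default try-both rule.
    """
    subjects = list(subjects) if subjects is not None else base_fit._design.subjects
    settings = settings or FitSettings()
    references = references or DEFAULT_REFERENCES
    trace = SearchTrace()
    current_model, current_fit, current_ofv = base_fit.model, base_fit, base_fit.ofv
    remaining = list(candidates)
    step = 0
    while remaining:
        step += 1
        results = {}
        for parameter, covariate in remaining:
            out = _evaluate_candidate(
                current_model, current_ofv, parameter, covariate,
                subjects, settings, references, design_factory, forms,
            )
            label = f"{covariate}~{parameter}"
            if out is None:
                trace.steps.append(
                    SearchStep(step, "forward", label, np.nan, np.nan, "failed")
                )
                continue
            fit, spec, delta = out
            results[(parameter, covariate)] = (fit, spec, delta)
        if not results:
            break
        # max ΔOFV wins; dict preserves candidate enumeration order for ties
        best_key = max(results, key=lambda k: results[k][2])
        for key, (fit, spec, delta) in results.items():
            if key == best_key:
                continue
            trace.steps.append(
                SearchStep(step, "forward", spec.label, fit.ofv, delta, "rejected")
            )
        fit, spec, delta = results[best_key]
        if delta > threshold:
            trace.steps.append(
                SearchStep(step, "forward", spec.label, fit.ofv, delta, "included")
            )
            current_model, current_fit, current_ofv = fit.model, fit, fit.ofv
            remaining.remove(best_key)
        else:
            trace.steps.append(
                SearchStep(step, "forward", spec.label, fit.ofv, delta, "rejected")
            )
            break
    trace.final_model, trace.final_fit = current_model, current_fit
    return trace


def backward_elimination(
    full_fit: PopulationFit,
    subjects: Sequence[SubjectData] | None = None,
    threshold: float = BACKWARD_THRESHOLD,
    settings: FitSettings | None = None,
    design_factory=None,
) -> SearchTrace:
    """Stepwise backward deletion of included covariate effects.

    Iteratively removes the term whose deletion raises the OFV the least,
    as long as that rise stays below ``threshold`` (the nominal p < 0.01
    retention rule); terms whose removal is costlier are retained.
    """
    subjects = list(subjects) if subjects is not None else full_fit._design.subjects
    settings = settings or FitSettings()
    trace = SearchTrace()
    current_model, current_fit, current_ofv = full_fit.model, full_fit, full_fit.ofv
    step = 0
    while current_model.covariate_terms:
        step += 1
        results = {}
        for term in current_model.covariate_terms:
            try:
                fit = _fit_with(
                    current_model.without_term(term), subjects, settings, design_factory
                )
            except Exception as exc:
                warnings.warn(f"reduced model without {term.label} failed: {exc}")
                trace.steps.append(
                    SearchStep(step, "backward", term.label, np.nan, np.nan, "failed")
                )
                continue
            if not (fit.converged and np.isfinite(fit.ofv)):
                trace.steps.append(
                    SearchStep(step, "backward", term.label, np.nan, np.nan, "failed")
                )
                continue
            results[term] = (fit, fit.ofv - current_ofv)
        if not results:
            break
        cheapest = min(results, key=lambda t: results[t][1])
        fit, rise = results[cheapest]
        if rise < threshold:
            trace.steps.append(
                SearchStep(step, "backward", cheapest.label, fit.ofv, rise, "removed")
            )
            current_model, current_fit, current_ofv = fit.model, fit, fit.ofv
        else:
            for term, (fit_t, rise_t) in results.items():
                trace.steps.append(
                    SearchStep(step, "backward", term.label, fit_t.ofv, rise_t, "retained")
                )
            break
    trace.final_model, trace.final_fit = current_model, current_fit
    return trace


def run_covariate_search(
    base_fit: PopulationFit,
    subjects: Sequence[SubjectData] | None = None,
    covariates: Sequence[str] = COVARIATE_ORDER,
    shrinkage_threshold: float = 25.0,
    forward_threshold: float = FORWARD_THRESHOLD,
    backward_threshold: float = BACKWARD_THRESHOLD,
    settings: FitSettings | None = None,
    references: dict | None = None,
    design_factory=None,
) -> SearchTrace:
    """Full screen → forward → backward covariate search."""
    eligible = screen_parameters(base_fit, shrinkage_threshold)
    grid = candidate_grid(eligible, covariates)
    fwd = forward_selection(
        base_fit, grid, subjects, forward_threshold, settings, references, design_factory
    )
    bwd = backward_elimination(
        fwd.final_fit, subjects, backward_threshold, settings, design_factory
    )
    merged = SearchTrace(steps=fwd.steps + bwd.steps)
    merged.final_model, merged.final_fit = bwd.final_model, bwd.final_fit
    return merged
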