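"""Nonparametric case-resampling bootstrap for parameter uncertainty.

Whole subjects are resampled with replacement (the standard case bootstrap
for hierarchical data — a subject drawn twice enters as two independent
subjects under fresh ids), each replicate cohort is refitted starting from
the base-model optimum, and percentile confidence intervals are formed over
the converged replicates.  Replicates that terminate early — optimizer
non-convergence, non-finite OFV, or a variance pinned at its transformed
bound — are counted and excluded from the percentiles, mirroring run-record
bookkeeping practice.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd

from .estimation import FitSettings, fit_population
from .model import PopulationModel, SubjectData

__all__ = ["BootstrapResult", "nonparametric_bootstrap"]


@dataclass
class BootstrapResult:
    """Replicate estimates, percentile summary and failure bookkeeping."""

    n_requested: int
    n_converged: int
    estimates: pd.DataFrame  # converged replicates × flat parameter labels
    summary: pd.DataFrame  # per parameter: median, ci5, ci95
    failures: list[tuple[int, str]]
    seed: int | None
    unreliable: bool

    @property
    def n_failed(self) -> int:
        return self.n_requested - self.n_converged


def _flat_estimates(model: PopulationModel) -> dict:
    out = {f"theta_{p}": model.theta[p] for p in model.param_names}
    for t in model.covariate_terms:
        out[f"beta_{t.label}"] = t.beta
    for p in model.param_names:
        out[f"omega2_{p}"] = model.omega2.get(p, 0.0)
    out["sigma2"] = model.sigma2
    return out


def nonparametric_bootstrap(
    subjects: Sequence[SubjectData],
    model: PopulationModel,
    fit_settings: FitSettings | None = None,
    n_reps: int = 1000,
    seed: int | None = None,
    strata: Sequence | None = None,
    design_factory=None,
    ci: tuple[float, float] = (5.0, 95.0),
) -> BootstrapResult:
    """Case bootstrap of a fitted population model.

    Parameters
    ----------
    subjects
        The original cohort (resampled at its own size).
    model
        The base-model optimum; every replicate fit starts here, which
        mirrors common practice and sharply reduces replicate failures.
    strata
        Optional per-subject labels (e.g. sampling protocol); when given,
        resampling happens within each stratum so the design mix of every
        replicate matches the original cohort.
    ci
        Percentile interval bounds; the default (5, 95) gives the 90%
        interval.

    All resampling randomness comes from ``seed``: the full index matrix is
    drawn up front, so results are bit-reproducible.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    subjects = list(subjects)
    n = len(subjects)
    fit_settings = fit_settings or FitSettings()
    rng = np.random.default_rng(seed)

    if strata is None:
        index_matrix = rng.integers(0, n, size=(n_reps, n))
    else:
        strata = np.asarray(strata)
        if strata.shape[0] != n:
            raise ValueError("strata must align with subjects")
        index_matrix = np.empty((n_reps, n), dtype=int)
        col = 0
        for value in pd.unique(strata):
            members = np.flatnonzero(strata == value)
            k = members.size
            index_matrix[:, col : col + k] = members[
                rng.integers(0, k, size=(n_reps, k))
            ]
            col += k

    rows, failures = [], []
    for rep in range(n_reps):
        resampled = [
            dc_replace(subjects[j], id=f"{rep}:{slot}")
            for slot, j in enumerate(index_matrix[rep])
        ]
        try:
            fit = fit_population(
                resampled, model, settings=fit_settings, design_factory=design_factory
            )
        except Exception as exc:
            failures.append((rep, f"error: {exc}"))
            continue
        if not np.isfinite(fit.ofv):
            failures.append((rep, "non-finite OFV"))
            continue
        if not fit.converged:
            failures.append((rep, "optimizer did not converge"))
            continue
        if fit._objective is not None and fit._objective.boundary_hit(fit._x_opt):
            failures.append((rep, "variance at its transformed-scale boundary"))
            continue
        rows.append({"replicate": rep, **_flat_estimates(fit.model)})

    estimates = pd.DataFrame(rows).set_index("replicate") if rows else pd.DataFrame()
    lo, hi = ci
    summary_rows = []
    for col in estimates.columns:
        vals = estimates[col].to_numpy()
        summary_rows.append(
            {
                "parameter": col,
                "median": float(np.percentile(vals, 50)),
                f"ci{lo:g}": float(np.percentile(vals, lo)),
                f"ci{hi:g}": float(np.percentile(vals, hi)),
            }
        )
    summary = pd.DataFrame(summary_rows)
    n_conv = len(rows)
    return BootstrapResult(
        n_requested=n_reps,
        n_converged=n_conv,
        estimates=estimates,
        summary=summary,
        failures=failures,
        seed=seed,
        unreliable=n_conv < n_reps / 2,
    )
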