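"""Nonlinear mixed-effects estimation for the infusion PK model.

The marginal likelihood of each subject's concentration vector requires
integrating the conditional likelihood over the subject's random effects η.
Two classical approximations are implemented:

``foce_i``
    First-order conditional estimation with interaction: the structural
    model is linearized in η around the per-subject posterior mode η̂, and
    the proportional residual variance is evaluated at η̂, giving a
    closed-form Gaussian marginal per subject.
``laplace``
    Second-order (mode + curvature) approximation using the full numerical
    Hessian of the joint −2·log-likelihood at η̂.

Both are exact when the model is linear-Gaussian in η, which the test
oracles exploit.  The objective function value (OFV) is −2·(approximate log
marginal likelihood) *including* all 2π normalizing constants, so absolute
OFVs differ from NONMEM's by n·log(2π) but OFV differences between nested
models — the only quantity used for model selection — do not.

The engine works on a :class:`CohortDesign`, a batched evaluation structure
that turns per-subject dosing schedules and sampling times into flat arrays
so that a full cohort's predictions (and their finite-difference η
sensitivities) are computed in a handful of vectorized operations.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import roots_hermite

from .model import PopulationModel, SubjectData
from .pk import EIGEN_GAP_SWITCH, disposition_eigenvalues

__all__ = [
    "CohortDesign",
    "FitSettings",
    "PopulationFit",
    "ofv",
    "fit_population",
    "evaluate_model",
    "naive_two_stage_init",
    "subject_joint_neg2ll",
    "compute_rse",
    "compute_shrinkage",
    "residual_diagnostics",
    "ofv_quadrature",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_F_FLOOR = 1e-12  # floor on predictions entering the proportional variance
_PENALTY = 1e10  # finite stand-in for an infeasible OFV (keeps line searches sane)


class DesignBase:
    """Flat per-observation arrays with segmented per-subject reductions.

    Observations are stored sorted by subject.  Subclasses provide
    ``param_names`` and ``predict``, mapping an ``(n_subjects, n_params)``
    matrix of individual parameters to the flat prediction vector; the
    estimation machinery is agnostic to the structural model behind it.
    """

    param_names: tuple[str, ...] = ()

    def __init__(self, subjects: Sequence[SubjectData]):
        if not subjects:
            raise ValueError("at least one subject is required")
        for s in subjects:
            if s.n_obs == 0:
                raise ValueError(f"subject {s.id} has no observations")
        self.subjects = list(subjects)
        self.n_subjects = len(subjects)
        self.subject_ids = [s.id for s in subjects]
        self.y = np.concatenate([s.dv for s in subjects])
        self.t = np.concatenate([s.obs_times for s in subjects])
        self.obs_counts = np.array([s.n_obs for s in subjects])
        self.n_obs = int(self.obs_counts.sum())
        self.sidx = np.repeat(np.arange(self.n_subjects), self.obs_counts)
        self.offsets = np.concatenate([[0], np.cumsum(self.obs_counts)[:-1]])
        self.covariates = pd.DataFrame(
            [s.covariates for s in subjects], index=pd.RangeIndex(self.n_subjects)
        )

    def per_subject_sum(self, values: np.ndarray) -> np.ndarray:
        """Sum a flat per-observation array (any trailing shape) by subject."""
        return np.add.reduceat(values, self.offsets, axis=0)

    def predict(self, params: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class CohortDesign(DesignBase):
    """Batched closed-form predictor for one- or two-compartment cohorts.

    The elapsed times since every infusion-segment start/stop are padded
    into rectangular arrays once at construction, so each prediction over
    the whole cohort is a handful of vectorized exponentials.
    """

    def __init__(self, subjects: Sequence[SubjectData], n_compartments: int = 2):
        if n_compartments not in (1, 2):
            raise ValueError("n_compartments must be 1 or 2")
        super().__init__(subjects)
        self.n_compartments = n_compartments
        self.param_names = ("cl", "v_c", "v_t", "q") if n_compartments == 2 else ("cl", "v_c")

        max_seg = max(len(s.schedule.segments) for s in subjects) or 1
        ts = np.zeros((self.n_subjects, max_seg))
        te = np.zeros((self.n_subjects, max_seg))
        rate = np.zeros((self.n_subjects, max_seg))
        for i, s in enumerate(subjects):
            for j, (a, b, r) in enumerate(s.schedule.segments):
                ts[i, j], te[i, j], rate[i, j] = a, b, r
        # elapsed time since each segment start/stop, clipped at zero; these
        # never change during estimation, so they are precomputed once
        self.tau_start = np.maximum(self.t[:, None] - ts[self.sidx], 0.0)
        self.tau_end = np.maximum(self.t[:, None] - te[self.sidx], 0.0)
        self.rate_obs = rate[self.sidx]

    def predict(self, params: np.ndarray) -> np.ndarray:
        """Central concentrations (flat) for individual parameters ``params``.

        ``params`` has one row per subject, columns in ``param_names``
        order.  Must be strictly positive; non-finite inputs propagate to
        the caller as non-finite outputs (checked by the objective).
        """
        if self.n_compartments == 1:
            cl, v_c = params[:, 0], params[:, 1]
            k10 = cl / v_c
            ko = k10[self.sidx][:, None]
            contrib = self.rate_obs * (
                np.exp(-ko * self.tau_end) - np.exp(-ko * self.tau_start)
            )
            return contrib.sum(axis=1) / cl[self.sidx]

        cl, v_c, v_t, q = params.T
        k10, k12, k21 = cl / v_c, q / v_c, q / v_t
        lam1, lam2 = disposition_eigenvalues(k10, k12, k21)
        gap = (lam1 - lam2) / lam1
        safe = gap >= EIGEN_GAP_SWITCH
        lam2s = np.where(safe, lam2, lam1 * (1.0 - EIGEN_GAP_SWITCH))
        a1 = (k21 - lam1) / (lam1 * (lam2s - lam1))
        a2 = (k21 - lam2s) / (lam2s * (lam1 - lam2s))

        l1 = lam1[self.sidx][:, None]
        l2 = lam2s[self.sidx][:, None]
        e1 = np.exp(-l1 * self.tau_end) - np.exp(-l1 * self.tau_start)
        e2 = np.exp(-l2 * self.tau_end) - np.exp(-l2 * self.tau_start)
        contrib = self.rate_obs * (
            a1[self.sidx][:, None] * e1 + a2[self.sidx][:, None] * e2
        )
        f = contrib.sum(axis=1) / v_c[self.sidx]

        if not np.all(safe):  # confluent eigenvalues: series limit branch
            for i in np.flatnonzero(~safe):
                lam = 0.5 * (lam1[i] + lam2[i])
                rows = self.sidx == i
                tau_s, tau_e = self.tau_start[rows], self.tau_end[rows]

                def step(tau):
                    e = np.exp(-lam * tau)
                    return (k21[i] / lam**2) * (1.0 - e) - (
                        k21[i] / lam - 1.0
                    ) * tau * e

                f[rows] = (self.rate_obs[rows] * (step(tau_s) - step(tau_e))).sum(
                    axis=1
                ) / v_c[i]
        return f


# ---------------------------------------------------------------------------
# joint per-subject objective h(η) = −2 log p(y, η)
# ---------------------------------------------------------------------------


def _h_terms(y, f, sigma2, error_model):
    """Per-observation −2·log-likelihood terms and the residual variance."""
    if error_model == "proportional":
        fv = np.maximum(f, _F_FLOOR)
        v = sigma2 * fv * fv
    else:
        fv = f
        v = np.full_like(f, sigma2)
    r = y - f
    return _LOG2PI + np.log(v) + r * r / v, v, r, fv


def _h_per_subject(design, tv, eta_full, omega2, sigma2, error_model, active):
    f = design.predict(tv * np.exp(eta_full))
    terms, _, _, _ = _h_terms(design.y, f, sigma2, error_model)
    h = design.per_subject_sum(terms)
    if active.any():
        om = omega2[active]
        h = h + np.sum(
            _LOG2PI + np.log(om) + eta_full[:, active] ** 2 / om, axis=1
        )
    return h, f


def _expand_eta(eta, active, n_subjects, n_params):
    full = np.zeros((n_subjects, n_params))
    if eta.size:
        full[:, active] = eta
    return full


def _grad_weights(y, f, sigma2, error_model):
    """∂h/∂f and a positive curvature proxy ∂²h/∂f² per observation."""
    _, v, r, fv = _h_terms(y, f, sigma2, error_model)
    if error_model == "proportional":
        w = 2.0 / fv - 2.0 * r / v - 2.0 * r * r / (fv * v)
        curv = 2.0 / v - 2.0 / fv**2 + 8.0 * r / (fv * v) + 6.0 * r * r / (fv * fv * v)
        curv = np.maximum(curv, 0.2 / v)
    else:
        w = -2.0 * r / v
        curv = 2.0 / v
    return w, curv, v


def _solve_inner(
    design,
    tv,
    omega2,
    sigma2,
    error_model,
    eta0,
    active,
    gtol=3e-7,
    maxiter=60,
    fd_step=1e-4,
):
    """Batched optimization of every subject's joint objective h(η).

    Two phases, both with per-subject backtracking: a Gauss–Newton phase
    using the exact residual curvature ∂²h/∂f² (ignoring ∂²f/∂η², always
    positive definite with the prior term) to approach the modes from η=0
    or a warm start, then full Newton steps with a finite-difference
    Hessian of h for quadratic terminal convergence.  Returns the modes,
    the predictions and FD Jacobian ``∂f/∂η`` at the modes, per-subject h,
    and the final per-subject gradient norms.
    """
    n, d = design.n_subjects, int(active.sum())
    npar = len(design.param_names)
    if d == 0:
        eta = np.zeros((n, 0))
        h, f = _h_per_subject(design, tv, np.zeros((n, npar)), omega2, sigma2, error_model, active)
        return eta, f, np.zeros((design.n_obs, 0)), h, np.zeros(n)

    om = omega2[active]
    eta = eta0.copy()
    h, f = _h_per_subject(
        design, tv, _expand_eta(eta, active, n, npar), omega2, sigma2, error_model, active
    )

    def hfun(e):
        return _h_per_subject(
            design, tv, _expand_eta(e, active, n, npar), omega2, sigma2, error_model, active
        )[0]

    def jacobian(eta, f=None):
        """FD Jacobian of predictions w.r.t. active η.  Central differences
        when ``f`` is None; one-sided (reusing ``f``) otherwise — accurate
        enough for the Gauss–Newton phase at half the cost."""
        J = np.empty((design.n_obs, d))
        for p in range(d):
            pert = np.zeros(d)
            pert[p] = fd_step
            f_hi = design.predict(tv * np.exp(_expand_eta(eta + pert, active, n, npar)))
            if f is None:
                f_lo = design.predict(tv * np.exp(_expand_eta(eta - pert, active, n, npar)))
                J[:, p] = (f_hi - f_lo) / (2.0 * fd_step)
            else:
                J[:, p] = (f_hi - f) / fd_step
        return J

    def backtrack(eta, h, f, step):
        alpha = np.ones(n)
        # zero-step subjects (converged or frozen) are not line-searched
        improved = ~step.any(axis=1)
        eta_new, h_new, f_new = eta.copy(), h.copy(), f.copy()
        for _bt in range(15):
            trial = np.where(improved[:, None], eta_new, eta + alpha[:, None] * step)
            h_t, f_t = _h_per_subject(
                design, tv, _expand_eta(trial, active, n, npar),
                omega2, sigma2, error_model, active,
            )
            better = (~improved) & (h_t <= h + 1e-12)
            if better.any():
                eta_new[better] = trial[better]
                h_new[better] = h_t[better]
                f_mask = better[design.sidx]
                f_new[f_mask] = f_t[f_mask]
                improved |= better
            if improved.all():
                break
            alpha[~improved] *= 0.5
        return eta_new, h_new, f_new, improved

    diag = np.arange(d)
    J = np.zeros((design.n_obs, d))
    gnorm = np.full(n, np.inf)
    phase = 1
    phase2_iters = 0
    # subjects whose full line search fails are frozen for the rest of the
    # phase: retrying the same failing step every iteration is pure waste
    frozen = np.zeros(n, dtype=bool)
    for _it in range(maxiter):
        J = jacobian(eta, f=f if (phase == 1 and _it > 0) else None)
        w, curv, _ = _grad_weights(design.y, f, sigma2, error_model)
        grad = design.per_subject_sum(J * w[:, None]) + 2.0 * eta / om
        gnorm = np.abs(grad).max(axis=1)
        if gnorm.max() < gtol:
            break
        settled = frozen | (gnorm < gtol)
        if settled.all():
            if phase == 1:
                phase, frozen[:] = 2, False  # full Newton may unstick them
                continue
            break
        if phase == 2:
            phase2_iters += 1
            # full Newton either converges within a few steps or the modes
            # sit at the finite-difference noise floor; iterating further
            # burns Hessian stencils for nothing
            if phase2_iters > 5:
                break
        if phase == 1:
            jw = J * curv[:, None]
            H = design.per_subject_sum(J[:, :, None] * jw[:, None, :])
            H[:, diag, diag] += 2.0 / om
        else:
            H = _fd_hessian_h(hfun, eta)
            # fall back to the GN surrogate where the exact Hessian is not PD
            bad = ~np.isfinite(H).all(axis=(1, 2))
            if not bad.all():
                try:
                    bad[~bad] |= np.linalg.eigvalsh(H[~bad])[:, 0] <= 0
                except np.linalg.LinAlgError:
                    bad[:] = True
            if bad.any():
                jw = J * curv[:, None]
                Hgn = design.per_subject_sum(J[:, :, None] * jw[:, None, :])
                Hgn[:, diag, diag] += 2.0 / om
                H[bad] = Hgn[bad]
        try:
            step = -np.linalg.solve(H, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = -grad / np.maximum(H[:, diag, diag], 1e-8)
        step[settled] = 0.0
        eta_new, h_new, f_new, improved = backtrack(eta, h, f, step)
        moved = improved & ~settled
        frozen |= ~settled & ~improved  # full line search failed
        per_decrease = h - h_new
        decrease = per_decrease.max()
        eta, h, f = eta_new, h_new, f_new
        if phase == 1 and (gnorm.max() < 1.0 or decrease < 1e-9 or not moved.any()):
            phase = 2
            frozen[:] = False
            phase2_iters = 0
        elif phase == 2 and (decrease < 1e-9 or not moved.any()):
            break
    # the FOCE linearization and the reported gradient always use a fresh
    # central-difference Jacobian at the final modes
    J = jacobian(eta)
    w, _, _ = _grad_weights(design.y, f, sigma2, error_model)
    grad = design.per_subject_sum(J * w[:, None]) + 2.0 * eta / om
    gnorm = np.abs(grad).max(axis=1)
    return eta, f, J, h, gnorm


# ---------------------------------------------------------------------------
# OFV assembly
# ---------------------------------------------------------------------------


def _ofv_foce(design, f, J, eta, omega2_active, sigma2, error_model):
    """FOCE-I objective from the linearization at the per-subject modes."""
    _, v, _, _ = _h_terms(design.y, f, sigma2, error_model)
    d = eta.shape[1]
    n_i = design.obs_counts
    if d == 0:
        r = design.y - f
        per = design.per_subject_sum(_LOG2PI + np.log(v) + r * r / v)
        return float(per.sum()), per
    rlin = design.y - f + np.einsum("op,op->o", J, eta[design.sidx])
    dinv = 1.0 / v
    b = design.per_subject_sum(J * (dinv * rlin)[:, None])
    jdj = design.per_subject_sum(J[:, :, None] * (J * dinv[:, None])[:, None, :])
    m = jdj.copy()
    m[:, np.arange(d), np.arange(d)] += 1.0 / omega2_active
    try:
        chol = np.linalg.cholesky(m)
    except np.linalg.LinAlgError:
        return np.inf, np.full(design.n_subjects, np.inf)
    logdet_m = 2.0 * np.log(np.einsum("ipp->ip", chol)).sum(axis=1)
    sol = np.linalg.solve(m, b[..., None])[..., 0]
    quad = design.per_subject_sum(dinv * rlin * rlin) - np.einsum("ip,ip->i", b, sol)
    logdet_v = logdet_m + np.log(omega2_active).sum() + design.per_subject_sum(np.log(v))
    per = n_i * _LOG2PI + logdet_v + quad
    return float(per.sum()), per


def _fd_hessian_h(hfun, eta, delta=5e-3):
    """Batched central-difference Hessian of per-subject scalars h(η)."""
    n, d = eta.shape
    H = np.zeros((n, d, d))
    h0 = hfun(eta)
    for p in range(d):
        ep = np.zeros(d)
        ep[p] = delta
        hp = hfun(eta + ep)
        hm = hfun(eta - ep)
        H[:, p, p] = (hp - 2.0 * h0 + hm) / delta**2
    for p, q_ in itertools.combinations(range(d), 2):
        ep, eq = np.zeros(d), np.zeros(d)
        ep[p], eq[q_] = delta, delta
        hpp = hfun(eta + ep + eq)
        hpm = hfun(eta + ep - eq)
        hmp = hfun(eta - ep + eq)
        hmm = hfun(eta - ep - eq)
        H[:, p, q_] = H[:, q_, p] = (hpp - hpm - hmp + hmm) / (4.0 * delta**2)
    return H


def _ofv_laplace(design, tv, eta, h, omega2, sigma2, error_model, active):
    n, d = eta.shape
    npar = len(design.param_names)
    if d == 0:
        return float(h.sum()), h

    def hfun(e):
        return _h_per_subject(
            design, tv, _expand_eta(e, active, n, npar), omega2, sigma2, error_model, active
        )[0]

    H = _fd_hessian_h(hfun, eta)
    sign, logdet = np.linalg.slogdet(0.5 * H)
    if np.any(sign <= 0):
        return np.inf, h
    per = h + logdet - d * _LOG2PI
    return float(per.sum()), per


# ---------------------------------------------------------------------------
# settings / fit result containers
# ---------------------------------------------------------------------------


@dataclass
class FitSettings:
    """Optimizer configuration for :func:`fit_population`.

    Outer optimization runs on log-transformed (θ, ω², σ²) — positivity by
    construction — with covariate coefficients β unconstrained.  Inner
    (η-mode) Newton iterations are warm-started across outer iterations.
    """

    method: str = "foce_i"  # "foce_i" | "laplace"
    outer_maxiter: int = 300
    outer_ftol: float = 1e-9
    outer_gtol: float = 1e-4
    outer_restarts: int = 3  # re-runs of L-BFGS-B from the incumbent optimum
    restart_min_decrease: float = 0.01  # OFV gain below which restarting stops
    fd_rel_step: float = 1e-4  # central-difference step of the outer gradient
    inner_gtol: float = 3e-7
    inner_maxiter: int = 60


@dataclass
class PopulationFit:
    """Result of a population fit: estimates, OFV, EBEs and diagnostics."""

    model: PopulationModel
    ofv: float
    converged: bool
    method: str
    n_subjects: int
    n_obs: int
    eta_hat: pd.DataFrame
    shrinkage_percent: dict
    se: dict | None = None
    rse_percent: dict | None = None
    message: str = ""
    _design: CohortDesign | None = field(default=None, repr=False)
    _objective: "_OuterObjective | None" = field(default=None, repr=False)
    _x_opt: np.ndarray | None = field(default=None, repr=False)


class _OuterObjective:
    """OFV as a function of the packed outer parameter vector.

    Packing order: log θ (model parameter order), covariate β's (term
    order), log ω² (parameters with nonzero IIV), log σ².  Caches the
    η modes between calls for warm starting.
    """

    def __init__(self, design: CohortDesign, template: PopulationModel, settings: FitSettings):
        if tuple(template.param_names) != tuple(design.param_names):
            raise ValueError("model parameterization does not match the design")
        self.design = design
        self.template = template
        self.settings = settings
        self.param_names = design.param_names
        self.active = template.omega2_vector() > 0
        self.n_theta = len(self.param_names)
        self.terms = template.covariate_terms
        self.error_model = template.error_model
        self.term_x = [
            design.covariates[t.covariate].to_numpy(dtype=float) for t in self.terms
        ]
        self.eta_cache = np.zeros((design.n_subjects, int(self.active.sum())))
        self.n_x = self.n_theta + len(self.terms) + int(self.active.sum()) + 1
        self._h_ref = np.inf  # best joint-objective total seen so far

    def bounds(self) -> list[tuple[float, float]]:
        """Box bounds in transformed space.

        The likelihood is flat in log ω² once a variance is effectively
        zero; without a floor the optimizer crawls toward −∞ burning
        iterations.  The floor (log ω² = −8, about 1.8% CV) is
        scientifically indistinguishable from zero and is what the
        boundary bookkeeping reports as a variance on its bound.
        """
        nt, nb = self.n_theta, len(self.terms)
        nw = int(self.active.sum())
        return (
            [(-10.0, 15.0)] * nt
            + [(-50.0, 50.0)] * nb
            + [(-8.0, 3.0)] * nw
            + [(-15.0, 3.0)]
        )

    def boundary_hit(self, x: np.ndarray, tol: float = 1e-6) -> bool:
        """True when any variance sits on its lower transformed bound."""
        nt, nb = self.n_theta, len(self.terms)
        variances = x[nt + nb :]
        lows = np.array([b[0] for b in self.bounds()[nt + nb :]])
        return bool(np.any(variances <= lows + tol))

    def pack(self, model: PopulationModel) -> np.ndarray:
        x = list(np.log(model.theta_vector()))
        x += [t.beta for t in model.covariate_terms]
        x += list(np.log(model.omega2_vector()[self.active]))
        x.append(np.log(model.sigma2))
        return np.asarray(x)

    def unpack(self, x: np.ndarray):
        nt, nb = self.n_theta, len(self.terms)
        theta = np.exp(x[:nt])
        betas = x[nt : nt + nb]
        omega2 = np.zeros(nt)
        omega2[self.active] = np.exp(x[nt + nb : -1])
        sigma2 = float(np.exp(x[-1]))
        return theta, betas, omega2, sigma2

    def to_model(self, x: np.ndarray) -> PopulationModel:
        theta, betas, omega2, sigma2 = self.unpack(x)
        terms = tuple(
            replace(t, beta=float(b)) for t, b in zip(self.terms, betas)
        )
        return replace(
            self.template,
            theta=dict(zip(self.param_names, theta)),
            omega2=dict(zip(self.param_names, omega2)),
            sigma2=sigma2,
            covariate_terms=terms,
        )

    def typical_values(self, theta: np.ndarray, betas: np.ndarray) -> np.ndarray | None:
        tv = np.tile(theta, (self.design.n_subjects, 1))
        for term, x, b in zip(self.terms, self.term_x, betas):
            j = self.param_names.index(term.parameter)
            tv[:, j] *= term.multiplier(x, beta=float(b))
        if not np.all(np.isfinite(tv)) or np.any(tv <= 0):
            return None
        return tv

    def evaluate(self, x: np.ndarray, want_state: bool = False):
        if not np.all(np.isfinite(x)) or np.any(np.abs(x) > 40.0):
            return (_PENALTY, None) if want_state else _PENALTY
        theta, betas, omega2, sigma2 = self.unpack(x)
        with np.errstate(all="ignore"):
            tv = self.typical_values(theta, betas)
            if tv is None:
                return (_PENALTY, None) if want_state else _PENALTY
            s = self.settings
            eta, f, J, h, gnorm = _solve_inner(
                self.design, tv, omega2, sigma2, self.error_model,
                self.eta_cache, self.active,
                gtol=s.inner_gtol, maxiter=s.inner_maxiter,
            )
            bad_h = not np.all(np.isfinite(h))
            # a stranded warm start both fails to converge AND lands far
            # above anything seen before; a merely FD-limited gradient
            # plateau or a legitimately distant line-search point does
            # neither, so only the combination triggers a cold retry
            if bad_h or (
                np.any(gnorm > 1e-3) and np.nansum(h) > self._h_ref + 50.0
            ):
                eta2, f2, J2, h2, gnorm2 = _solve_inner(
                    self.design, tv, omega2, sigma2, self.error_model,
                    np.zeros_like(self.eta_cache), self.active,
                    gtol=s.inner_gtol, maxiter=s.inner_maxiter,
                )
                with np.errstate(invalid="ignore"):
                    use2 = ~(h <= h2 + 1e-9)
                if use2.any():
                    eta[use2], h[use2], gnorm[use2] = eta2[use2], h2[use2], gnorm2[use2]
                    rows = use2[self.design.sidx]
                    f[rows] = f2[rows]
                    J[rows] = J2[rows]
        if not np.all(np.isfinite(f)) or not np.all(np.isfinite(h)):
            return (_PENALTY, None) if want_state else _PENALTY
        self._h_ref = min(self._h_ref, float(h.sum()))
        self.eta_cache = eta
        if s.method not in ("foce_i", "laplace"):
            raise ValueError(f"unknown estimation method {s.method!r}")
        with np.errstate(all="ignore"):
            if s.method == "foce_i":
                value, per = _ofv_foce(
                    self.design, f, J, eta, omega2[self.active], sigma2, self.error_model
                )
            else:
                value, per = _ofv_laplace(
                    self.design, tv, eta, h, omega2, sigma2, self.error_model, self.active
                )
        if not np.isfinite(value):
            value = _PENALTY
        if want_state:
            state = {
                "eta": eta, "f": f, "J": J, "h": h, "gnorm": gnorm,
                "per_subject": per, "tv": tv, "omega2": omega2, "sigma2": sigma2,
            }
            return value, state
        return value

    __call__ = evaluate


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def naive_two_stage_init(
    subjects: Sequence[SubjectData],
    n_compartments: int = 2,
    sigma2: float = 0.04,
    omega2_default: float = 0.1,
) -> PopulationModel:
    """Data-driven starting model from per-subject curve fits.

    Each subject's profile is fitted by unweighted least squares on the log
    scale (log-parameters, so positivity is automatic); typical values are
    the geometric medians of the per-subject estimates, falling back to
    magnitude heuristics (CL from mean infusion rate over mean
    concentration) for subjects whose individual fit is not identifiable.
    IIV starts at ``omega2_default`` and σ² at ``sigma2`` — deliberately
    modest values that the population fit then refines.
    """
    from scipy.optimize import least_squares

    from .cohort import _individual_profile

    names = ("cl", "v_c", "v_t", "q")[: 2 * n_compartments]
    rows = []
    for s in subjects:
        span = s.schedule.end - s.schedule.start
        mean_rate = s.schedule.total_dose / span if span > 0 else np.nan
        cl0 = mean_rate / float(np.mean(s.dv))
        if not (np.isfinite(cl0) and cl0 > 0):
            continue
        x0 = np.log([cl0, cl0, 3.0 * cl0, cl0][: len(names)])

        def resid(logp, s=s):
            f = _individual_profile(
                dict(zip(names, np.exp(logp))), s.schedule, s.obs_times
            )
            return np.log(np.maximum(f, 1e-9)) - np.log(s.dv)

        try:
            sol = least_squares(resid, x0, method="lm", max_nfev=200)
            est = np.exp(sol.x)
            ok = sol.status > 0 and np.all((est > 1e-2) & (est < 1e4))
        except Exception:
            ok = False
        rows.append(np.log(est) if ok else x0)
    if not rows:
        raise ValueError("no subject allowed even a crude initial estimate")
    logs = np.vstack(rows)
    theta = dict(zip(names, np.exp(np.median(logs, axis=0))))
    # the spread of two-stage estimates includes estimation noise on top of
    # true IIV, so the starting omega^2 is capped at a modest value and the
    # population fit expands it where the data support more
    omega2 = {
        p: float(np.clip(np.var(logs[:, j], ddof=1), 0.02, 0.5))
        if len(rows) > 2
        else omega2_default
        for j, p in enumerate(names)
    }
    return PopulationModel(theta=theta, omega2=omega2, sigma2=sigma2)


def _default_factory(model: PopulationModel):
    ncpt = len(model.theta) // 2
    return lambda subjects: CohortDesign(subjects, n_compartments=ncpt)


def ofv(
    model: PopulationModel,
    subjects: Sequence[SubjectData],
    method: str = "foce_i",
    settings: FitSettings | None = None,
    design: DesignBase | None = None,
) -> float:
    """Objective function value of ``model`` on ``subjects`` (no fitting).

    −2·approximate log marginal likelihood summed over subjects, including
    the 2π constants; invariant to subject ordering.
    """
    settings = replace(settings or FitSettings(), method=method)
    design = design or _default_factory(model)(subjects)
    obj = _OuterObjective(design, model, settings)
    return float(obj.evaluate(obj.pack(model)))


def subject_joint_neg2ll(
    eta, model: PopulationModel, subject: SubjectData
) -> float:
    """−2·[log p(dv | η) + log p(η)] for one subject.

    ``eta`` maps parameter names to random-effect values; parameters with
    zero IIV must have η = 0 (they carry no prior term).  Non-finite
    predictions yield +inf.
    """
    design = CohortDesign([subject], n_compartments=len(model.theta) // 2)
    names = model.param_names
    omega2 = model.omega2_vector()
    active = omega2 > 0
    eta_full = np.array([[float(eta.get(p, 0.0)) for p in names]])
    tv = model.typical_values(design.covariates)
    h, f = _h_per_subject(
        design, tv, eta_full, omega2, model.sigma2, model.error_model, active
    )
    if not np.all(np.isfinite(f)):
        return np.inf
    return float(h[0])


def evaluate_model(
    model: PopulationModel,
    subjects: Sequence[SubjectData],
    settings: FitSettings | None = None,
    design_factory=None,
) -> PopulationFit:
    """Evaluation-only fit: OFV, empirical Bayes modes and shrinkage at a
    *fixed* model, without touching the population parameters.

    Useful for diagnostics and predictive checks of an externally given
    model (e.g. simulating from known truth).
    """
    settings = settings or FitSettings()
    design = (design_factory or _default_factory(model))(subjects)
    obj = _OuterObjective(design, model, settings)
    x = obj.pack(model)
    value, state = obj.evaluate(x, want_state=True)
    if state is None:
        raise ValueError("model yields a non-finite OFV on these subjects")
    eta_df = pd.DataFrame(
        _expand_eta(state["eta"], obj.active, design.n_subjects, obj.n_theta),
        index=design.subject_ids,
        columns=obj.param_names,
    )
    fit = PopulationFit(
        model=model,
        ofv=float(value),
        converged=True,
        method=settings.method,
        n_subjects=design.n_subjects,
        n_obs=design.n_obs,
        eta_hat=eta_df,
        shrinkage_percent={},
        message="evaluation only (no optimization)",
        _design=design,
        _objective=obj,
        _x_opt=x,
    )
    fit.shrinkage_percent = compute_shrinkage(fit)
    return fit


def fit_population(
    subjects: Sequence[SubjectData],
    init: PopulationModel,
    settings: FitSettings | None = None,
    design_factory=None,
) -> PopulationFit:
    """Maximum-(approximate)-likelihood population fit.

    Optimizes the OFV over (θ, β, ω², σ²) with L-BFGS-B in transformed
    space.  A non-converged optimization still returns a result with
    ``converged=False`` (needed for bootstrap bookkeeping).
    """
    settings = settings or FitSettings()
    design = (design_factory or _default_factory(init))(subjects)
    obj = _OuterObjective(design, init, settings)
    x0 = np.clip(obj.pack(init), *zip(*obj.bounds()))
    f0 = obj(x0)
    if not np.isfinite(f0) or f0 >= _PENALTY:
        raise ValueError("initial model yields a non-finite OFV")
    options = {
        "maxiter": settings.outer_maxiter,
        "ftol": settings.outer_ftol,
        "gtol": settings.outer_gtol,
        "finite_diff_rel_step": settings.fd_rel_step,
    }
    # L-BFGS-B line searches can stall on the finite-difference gradient
    # noise of the approximate marginal likelihood; restarting from the
    # incumbent optimum resets the curvature memory and reliably recovers
    # the remaining OFV points
    bounds = obj.bounds()
    lows, highs = np.array([b[0] for b in bounds]), np.array([b[1] for b in bounds])
    x_cur, f_cur = x0, f0
    res = None
    stationary = False
    for _round in range(max(settings.outer_restarts, 1)):
        # central differences: the OFV carries small inner-solver noise that
        # forward differences amplify into a useless gradient.  The search
        # itself is unconstrained — L-BFGS-B's bounded line search proved
        # fragile on this objective, silently abandoning healthy fits —
        # with the finite penalty beyond |x| = 40 containing runaways; the
        # box is used only to recognize variances parked at their floor
        r = minimize(obj, x_cur, method="L-BFGS-B", jac="3-point", options=options)
        if res is None or r.fun <= f_cur:
            res = r
        decrease = f_cur - r.fun
        if r.fun <= f_cur:
            x_cur, f_cur = r.x, r.fun
        if decrease < settings.restart_min_decrease:
            # a fresh optimization run cannot improve the incumbent: the
            # fit is stationary to within the restart resolution
            stationary = True
            break
    x_opt = x_cur if f_cur <= f0 else x0
    value, state = obj.evaluate(x_opt, want_state=True)
    model_opt = obj.to_model(x_opt)
    converged = bool(
        np.isfinite(value)
        and value < _PENALTY
        and state is not None
        and (res.success or stationary or np.max(np.abs(res.jac)) < 0.5)
    )
    eta_df = pd.DataFrame(
        _expand_eta(state["eta"], obj.active, design.n_subjects, obj.n_theta),
        index=design.subject_ids,
        columns=obj.param_names,
    )
    fit = PopulationFit(
        model=model_opt,
        ofv=float(value),
        converged=converged,
        method=settings.method,
        n_subjects=design.n_subjects,
        n_obs=design.n_obs,
        eta_hat=eta_df,
        shrinkage_percent={},
        message=str(res.message),
        _design=design,
        _objective=obj,
        _x_opt=x_opt,
    )
    fit.shrinkage_percent = compute_shrinkage(fit)
    return fit


def compute_shrinkage(fit: PopulationFit) -> dict:
    """η-shrinkage per IIV parameter: 100·(1 − SD(η̂)/ω).

    The SD uses the population denominator (ddof=0).  Parameters with zero
    IIV have undefined shrinkage and are reported as NaN.
    """
    out = {}
    for p in fit.model.param_names:
        om2 = fit.model.omega2.get(p, 0.0)
        if om2 <= 0:
            warnings.warn(f"shrinkage undefined for {p}: omega^2 is zero")
            out[p] = float("nan")
            continue
        sd = float(np.std(fit.eta_hat[p].to_numpy(), ddof=0))
        out[p] = 100.0 * (1.0 - sd / np.sqrt(om2))
    return out


def _natural_vector(fit: PopulationFit):
    """Natural-scale parameter vector and labels for standard errors."""
    m = fit.model
    labels = [f"theta_{p}" for p in m.param_names]
    values = list(m.theta_vector())
    for t in m.covariate_terms:
        labels.append(f"beta_{t.label}")
        values.append(t.beta)
    obj = fit._objective
    for p, a in zip(m.param_names, obj.active):
        if a:
            labels.append(f"omega2_{p}")
            values.append(m.omega2[p])
    labels.append("sigma2")
    values.append(m.sigma2)
    return np.asarray(values), labels


def compute_rse(fit: PopulationFit, rel_step: float = 5e-3) -> dict:
    """Percent relative standard errors from the numerically differentiated
    Hessian of OFV/2 at the optimum (natural parameter scale).

    A non-positive-definite Hessian yields NaN entries with a warning —
    standard errors are never fabricated.  Results are stored on the fit
    (``fit.se``, ``fit.rse_percent``) and returned.
    """
    obj = fit._objective
    p0, labels = _natural_vector(fit)
    nt, nb = obj.n_theta, len(obj.terms)

    def x_of(p):
        x = np.empty_like(p)
        x[:nt] = np.log(p[:nt])
        x[nt : nt + nb] = p[nt : nt + nb]
        x[nt + nb :] = np.log(p[nt + nb :])
        return x

    def half_ofv(p):
        if np.any(p[:nt] <= 0) or np.any(p[nt + nb :] <= 0):
            return np.inf
        return 0.5 * obj(x_of(p))

    m = p0.size
    steps = rel_step * np.maximum(np.abs(p0), 1e-3)
    H = np.zeros((m, m))
    f0 = half_ofv(p0)
    fp = np.empty(m)
    fm = np.empty(m)
    for i in range(m):
        ei = np.zeros(m)
        ei[i] = steps[i]
        fp[i] = half_ofv(p0 + ei)
        fm[i] = half_ofv(p0 - ei)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / steps[i] ** 2
    for i, j in itertools.combinations(range(m), 2):
        ei, ej = np.zeros(m), np.zeros(m)
        ei[i], ej[j] = steps[i], steps[j]
        fpp = half_ofv(p0 + ei + ej)
        fmm = half_ofv(p0 - ei - ej)
        H[i, j] = H[j, i] = (
            fpp - fp[i] - fp[j] + 2.0 * f0 - fm[i] - fm[j] + fmm
        ) / (2.0 * steps[i] * steps[j])

    se = np.full(m, np.nan)
    try:
        eigvals = np.linalg.eigvalsh(H)
        if np.all(eigvals > 0):
            cov = np.linalg.inv(H)
            se = np.sqrt(np.diag(cov))
        else:
            warnings.warn("OFV Hessian not positive definite; RSEs reported missing")
    except np.linalg.LinAlgError:
        warnings.warn("OFV Hessian inversion failed; RSEs reported missing")
    fit.se = dict(zip(labels, se))
    fit.rse_percent = {
        k: (100.0 * s / abs(v) if np.isfinite(s) and v != 0 else float("nan"))
        for (k, s), v in zip(fit.se.items(), p0)
    }
    return fit.rse_percent


def residual_diagnostics(fit: PopulationFit) -> pd.DataFrame:
    """Tidy goodness-of-fit table: PRED (η=0), IPRED (η=η̂), residuals.

    Weighted residual WRES = (dv − PRED)/(PRED·σ); IWRES analogously with
    IPRED.  Rows where the population prediction is zero get NaN residuals
    with a warning.
    """
    design = fit._design
    obj = fit._objective
    m = fit.model
    tv = obj.typical_values(m.theta_vector(), np.array([t.beta for t in m.covariate_terms]))
    pred = design.predict(tv)
    ipred = design.predict(tv * np.exp(fit.eta_hat.to_numpy()))
    sigma = np.sqrt(m.sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        if m.error_model == "proportional":
            wres = (design.y - pred) / (pred * sigma)
            iwres = (design.y - ipred) / (ipred * sigma)
        else:
            wres = (design.y - pred) / sigma
            iwres = (design.y - ipred) / sigma
    if np.any(pred == 0):
        warnings.warn("PRED = 0 at some observations; weighted residuals set to NaN")
        wres = np.where(pred == 0, np.nan, wres)
    return pd.DataFrame(
        {
            "id": np.asarray(design.subject_ids, dtype=object)[design.sidx],
            "time": design.t,
            "dv": design.y,
            "pred": pred,
            "ipred": ipred,
            "wres": wres,
            "iwres": iwres,
        }
    )


def ofv_quadrature(
    model: PopulationModel,
    subjects: Sequence[SubjectData],
    n_nodes: int = 41,
    design_factory=None,
) -> float:
    """Adaptive Gauss–Hermite OFV, the engine-independent oracle.

    Centers a tensor-product Gauss–Hermite rule on each subject's posterior
    mode, scaled by the curvature there, and integrates the exact joint
    likelihood (quadrature points are evaluated through a design holding
    one clone of the subject per point).  Practical for ≤ 3 active random
    effects; used to validate the FOCE-I and Laplace approximations on toy
    problems.
    """
    factory = design_factory or _default_factory(model)
    total = 0.0
    nodes, weights = roots_hermite(n_nodes)
    omega2 = model.omega2_vector()
    active = omega2 > 0
    d = int(active.sum())
    npar = len(model.param_names)
    for subject in subjects:
        design = factory([subject])
        tv = model.typical_values(design.covariates)

        def hfun(e, design=design, tv=tv):
            return _h_per_subject(
                design, tv, _expand_eta(e, active, e.shape[0], npar),
                omega2, model.sigma2, model.error_model, active,
            )[0]

        eta, _, _, h, _ = _solve_inner(
            design, tv, omega2, model.sigma2, model.error_model,
            np.zeros((1, d)), active,
        )
        if d == 0:
            total += float(h[0])
            continue
        H = _fd_hessian_h(hfun, eta)[0]
        L = np.linalg.cholesky(H)
        grid = np.array(list(itertools.product(range(n_nodes), repeat=d)))
        z = nodes[grid].reshape(-1, d)
        w_log = np.log(weights)[grid].reshape(-1, d).sum(axis=1)
        # substitution η = η̂ + 2 L^{-T} z  ⇒  dη = 2^d det(H)^{-1/2} dz
        etas = eta[0] + 2.0 * np.linalg.solve(L.T, z.T).T
        clones = factory([subject] * len(etas))
        tv_c = model.typical_values(clones.covariates)
        hv = _h_per_subject(
            clones, tv_c, _expand_eta(etas, active, len(etas), npar),
            omega2, model.sigma2, model.error_model, active,
        )[0]
        log_terms = w_log - 0.5 * hv + np.einsum("ij,ij->i", z, z)
        mx = log_terms.max()
        log_integral = (
            d * np.log(2.0)
            - 0.5 * np.linalg.slogdet(H)[1]
            + mx
            + np.log(np.exp(log_terms - mx).sum())
        )
        total += -2.0 * float(log_integral)
    return total
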