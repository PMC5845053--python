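"""Two-compartment disposition under piecewise-constant intravenous infusion.

Units are fixed package-wide: dose amounts in μg, volumes in L, time in
hours, concentrations in μg/L (numerically identical to ng/mL).  With this
choice the dexmedetomidine literature values plug in without conversion.

The central-compartment concentration ``C_P`` and tissue concentration
``C_T`` obey the linear system

    V_C dC_P/dt = R(t) − CL·C_P − Q·C_P + Q·C_T        C_P(0) = 0
    V_T dC_T/dt = Q·C_P − Q·C_T                         C_T(0) = 0

where ``R(t)`` is the (piecewise-constant) infusion rate in μg/h, ``CL`` the
systemic clearance and ``Q`` the inter-compartmental clearance.  The closed
form used throughout is the bi-exponential unit-step response superposed over
segment start/stop events; an adaptive ODE integrator is provided as an
independent numerical oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "DispositionParams",
    "InfusionSchedule",
    "ConcProfile",
    "predict_concentrations",
    "integrate_ode_oracle",
    "hybrid_constants",
    "InvalidParameterError",
    "InvalidInputError",
]

#: relative eigen-gap below which the confluent (repeated-eigenvalue) series
#: branch of the step response is used instead of the bi-exponential formula
EIGEN_GAP_SWITCH = 1e-7


class InvalidParameterError(ValueError):
    """A disposition parameter violates positivity."""


class InvalidInputError(ValueError):
    """Requested evaluation times or schedule segments are malformed."""


@dataclass(frozen=True)
class DispositionParams:
    """Structural parameters of the two-compartment model for one subject.

    Attributes
    ----------
    cl : float
        Systemic (elimination) clearance, L/h.
    q : float
        Inter-compartmental (distribution) clearance, L/h.
    v_c : float
        Volume of the central compartment, L.
    v_t : float
        Volume of the peripheral (tissue) compartment, L.
    """

    cl: float
    q: float
    v_c: float
    v_t: float

    def __post_init__(self) -> None:
        for name in ("cl", "q", "v_c", "v_t"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise InvalidParameterError(
                    f"{name} must be strictly positive and finite, got {value!r}"
                )

    def micro_constants(self) -> tuple[float, float, float]:
        """Return the micro rate constants ``(k10, k12, k21)`` in 1/h."""
        return self.cl / self.v_c, self.q / self.v_c, self.q / self.v_t


@dataclass(frozen=True)
class InfusionSchedule:
    """Ordered, non-overlapping constant-rate infusion segments.

    Each segment is ``(t_start, t_end, rate)`` with times in hours and the
    rate in μg/h.  Zero-rate segments are permitted (they contribute
    nothing) so schedules can be concatenated freely.
    """

    segments: tuple[tuple[float, float, float], ...]

    def __init__(self, segments: Iterable[Sequence[float]]) -> None:
        segs = tuple(
            (float(s), float(e), float(r)) for s, e, r in segments
        )
        for s, e, r in segs:
            if not (np.isfinite(s) and np.isfinite(e) and np.isfinite(r)):
                raise InvalidInputError("segment entries must be finite")
            if e <= s:
                raise InvalidInputError(f"segment end {e} must exceed start {s}")
            if r < 0:
                raise InvalidInputError(f"negative infusion rate {r}")
        for (s0, e0, _), (s1, _, _) in zip(segs, segs[1:]):
            if s1 < s0:
                raise InvalidInputError("segments must be sorted by start time")
            if s1 < e0:
                raise InvalidInputError("segments must not overlap")
        object.__setattr__(self, "segments", segs)

    @property
    def start(self) -> float:
        return self.segments[0][0] if self.segments else np.inf

    @property
    def end(self) -> float:
        return self.segments[-1][1] if self.segments else -np.inf

    @property
    def total_dose(self) -> float:
        """Total infused amount in μg."""
        return float(sum(r * (e - s) for s, e, r in self.segments))

    def rate_at(self, t: float) -> float:
        """Infusion rate at time ``t`` (right-continuous at boundaries)."""
        for s, e, r in self.segments:
            if s <= t < e:
                return r
        return 0.0

    def dose_infused_by(self, t: float) -> float:
        """Cumulative amount infused up to time ``t`` in μg."""
        total = 0.0
        for s, e, r in self.segments:
            if t <= s:
                break
            total += r * (min(t, e) - s)
        return total

    def scaled(self, factor: float) -> "InfusionSchedule":
        """Schedule with every rate multiplied by ``factor``."""
        return InfusionSchedule(
            [(s, e, r * factor) for s, e, r in self.segments]
        )

    def combine(self, other: "InfusionSchedule") -> "InfusionSchedule":
        """Piecewise-constant sum of two schedules (rates add where they overlap)."""
        edges = sorted(
            {t for s, e, _ in self.segments + other.segments for t in (s, e)}
        )
        out = []
        for a, b in zip(edges, edges[1:]):
            mid = 0.5 * (a + b)
            rate = self.rate_at(mid) + other.rate_at(mid)
            if rate > 0:
                out.append((a, b, rate))
        return InfusionSchedule(out)


@dataclass(frozen=True)
class ConcProfile:
    """Central-compartment concentrations (μg/L ≡ ng/mL) at sorted times (h)."""

    times: np.ndarray
    conc_central: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(
            self, "conc_central", np.asarray(self.conc_central, dtype=float)
        )


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise InvalidInputError("times must be one-dimensional")
    if times.size and (np.any(np.diff(times) < 0) or times[0] < 0):
        raise InvalidInputError("times must be sorted and non-negative")
    return times


def disposition_eigenvalues(
    k10: np.ndarray, k12: np.ndarray, k21: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitudes (λ1 ≥ λ2 > 0) of the disposition-matrix eigenvalues.

    Vieta identities: λ1·λ2 = k10·k21 and λ1+λ2 = k10+k12+k21.  The
    discriminant is computed in a cancellation-free arrangement,
    (k10+k12−k21)² + 4·k12·k21, which is exact for all positive rates.
    """
    s = k10 + k12 + k21
    disc = np.sqrt((k10 + k12 - k21) ** 2 + 4.0 * k12 * k21)
    lam1 = 0.5 * (s + disc)
    lam2 = np.where(lam1 > 0, (k10 * k21) / np.where(lam1 > 0, lam1, 1.0), 0.0)
    return lam1, lam2


def hybrid_constants(params: DispositionParams) -> tuple[float, float]:
    """Hybrid rate constants (λ1, λ2) in 1/h, λ1 > λ2 > 0.

    These are the distribution- and terminal-phase exponents of the
    bi-exponential disposition; ``ln 2 / λ2`` is the terminal half-life.
    """
    k10, k12, k21 = params.micro_constants()
    lam1, lam2 = disposition_eigenvalues(
        np.asarray(k10), np.asarray(k12), np.asarray(k21)
    )
    return float(lam1), float(lam2)


def _unit_step_response(
    tau: np.ndarray,
    k21: float,
    lam1: float,
    lam2: float,
    v_c: float,
) -> np.ndarray:
    """Central concentration at time ``tau`` after the start of a unit-rate
    (1 μg/h) infusion that runs forever, zero initial state.

    Bi-exponential branch:
        f(τ) = [A1 (1 − e^{−λ1 τ}) + A2 (1 − e^{−λ2 τ})] / V_C
        A1 = (k21 − λ1) / (λ1 (λ2 − λ1)),   A2 = (k21 − λ2) / (λ2 (λ1 − λ2))

    When the eigen-gap |λ1−λ2|/λ1 falls below ``EIGEN_GAP_SWITCH`` the
    confluent limit λ2→λ1=λ is used:
        f(τ) = [ (k21/λ²)(1 − e^{−λτ}) − (k21/λ − 1) τ e^{−λτ} ] / V_C
    """
    tau = np.maximum(tau, 0.0)
    gap = (lam1 - lam2) / lam1
    if gap < EIGEN_GAP_SWITCH:
        lam = 0.5 * (lam1 + lam2)
        e = np.exp(-lam * tau)
        f = (k21 / lam**2) * (1.0 - e) - (k21 / lam - 1.0) * tau * e
        return f / v_c
    a1 = (k21 - lam1) / (lam1 * (lam2 - lam1))
    a2 = (k21 - lam2) / (lam2 * (lam1 - lam2))
    f = a1 * (1.0 - np.exp(-lam1 * tau)) + a2 * (1.0 - np.exp(-lam2 * tau))
    return f / v_c


def predict_concentrations(
    params: DispositionParams,
    schedule: InfusionSchedule,
    times: Sequence[float] | np.ndarray,
) -> ConcProfile:
    """Closed-form central concentrations under a piecewise-constant regimen.

    Each segment ``(t_s, t_e, R)`` is the superposition of a step of rate
    ``+R`` at ``t_s`` and ``−R`` at ``t_e``; concentrations are the sum of
    the unit-step response over all such events (the solution is exactly
    linear in the rates).  Concentration is continuous across segment
    boundaries — only its derivative jumps — so boundary times need no
    left/right convention.
    """
    times = _check_times(times)
    k10, k12, k21 = params.micro_constants()
    lam1, lam2 = hybrid_constants(params)
    conc = np.zeros_like(times)
    for t_s, t_e, rate in schedule.segments:
        if rate == 0.0:
            continue
        conc += rate * (
            _unit_step_response(times - t_s, k21, lam1, lam2, params.v_c)
            - _unit_step_response(times - t_e, k21, lam1, lam2, params.v_c)
        )
    return ConcProfile(times=times, conc_central=np.maximum(conc, 0.0))


def integrate_ode_oracle(
    params: DispositionParams,
    schedule: InfusionSchedule,
    times: Sequence[float] | np.ndarray,
    tol: float = 1e-10,
    full_state: bool = False,
):
    """Numerical reference solution of the disposition ODEs.

    Integrates segment-by-segment with an adaptive stiff solver so that no
    integration step straddles a rate discontinuity.  The state is augmented
    with the cumulative eliminated amount ``CL·∫C_P dt`` so mass balance

        V_C·C_P(t) + V_T·C_T(t) + eliminated(t) = dose infused by t

    can be verified exactly.

    Parameters
    ----------
    tol : float
        Relative tolerance of the integrator (absolute tolerance is tied to
        it); must be positive.
    full_state : bool
        When true, return ``(profile, c_tissue, eliminated)`` instead of the
        profile alone.

    Raises
    ------
    RuntimeError
        If the integrator reports failure on any segment (never silently
        clipped).
    """
    if not tol > 0:
        raise InvalidInputError("tol must be positive")
    times = _check_times(times)
    if not times.size:
        prof = ConcProfile(times=times, conc_central=np.zeros(0))
        return (prof, np.zeros(0), np.zeros(0)) if full_state else prof
    cl, q, v_c, v_t = params.cl, params.q, params.v_c, params.v_t
    t_max = float(times[-1])

    edges = sorted(
        {0.0, t_max}
        | {float(t) for seg in schedule.segments for t in seg[:2] if t < t_max}
    )

    def rhs(t, y, rate):
        c_p, c_t, _ = y
        return (
            (rate - cl * c_p - q * c_p + q * c_t) / v_c,
            (q * c_p - q * c_t) / v_t,
            cl * c_p,
        )

    state = np.zeros(3)
    out = np.zeros((3, times.size))
    out[:, times <= 0.0] = 0.0
    for a, b in zip(edges, edges[1:]):
        rate = schedule.rate_at(0.5 * (a + b))
        mask = (times > a) & (times <= b)
        t_req = times[mask]
        t_eval = np.unique(np.append(t_req, b))
        sol = solve_ivp(
            rhs,
            (a, b),
            state,
            method="LSODA",
            t_eval=t_eval,
            rtol=tol,
            atol=tol * max(1.0, schedule.total_dose / v_c),
            args=(rate,),
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed on [{a}, {b}]: {sol.message}")
        if t_req.size:
            out[:, np.where(mask)[0]] = sol.y[:, np.searchsorted(sol.t, t_req)]
        state = sol.y[:, -1]

    profile = ConcProfile(times=times, conc_central=np.maximum(out[0], 0.0))
    if full_state:
        return profile, out[1], out[2]
    return profile
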