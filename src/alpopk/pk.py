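"""Structural pharmacokinetic model: one compartment, zero-order absorption, linear elimination.

The drug enters the central compartment at a constant rate ``dose / tk0`` for
``tk0`` hours after each administration (no lag time) and is eliminated with
first-order rate constant ``ke = cl / v``.  The single-dose concentration at
time ``u`` after a dose of ``D`` mg is available in closed form:

    C(u) = 0                                                    u < 0
    C(u) = D / (tk0 * cl) * (1 - exp(-ke * u))                  0 <= u <= tk0
    C(u) = D / (tk0 * cl) * (1 - exp(-ke * tk0)) * exp(-ke * (u - tk0))
                                                                u > tk0

Multi-dose profiles are plain superposition of shifted single-dose profiles
(the model is linear).  :func:`ode_oracle` integrates the equivalent two-state
ODE system numerically and serves as an independent cross-check of the closed
form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "StructuralParams",
    "DoseEvent",
    "concentration",
    "cmax",
    "ode_oracle",
]


@dataclass(frozen=True)
class StructuralParams:
    """One subject's PK parameter triple.

    Parameters
    ----------
    tk0 : float
        Duration of zero-order absorption, hours (> 0; a zero-duration bolus
        is outside the model).
    v : float
        Apparent volume of distribution, litres (> 0).
    cl : float
        Clearance, litres/hour (> 0).
    """

    tk0: float
    v: float
    cl: float

    def __post_init__(self) -> None:
        for name in ("tk0", "v", "cl"):
            val = getattr(self, name)
            if not math.isfinite(val):
                raise ValueError(f"{name} must be finite, got {val!r}")
            if val <= 0:
                raise ValueError(f"{name} must be > 0, got {val!r}")

    @property
    def ke(self) -> float:
        """First-order elimination rate constant, 1/h."""
        return self.cl / self.v


@dataclass(frozen=True)
class DoseEvent:
    """A single oral administration: ``amount`` mg given at ``time`` hours.

    ``amount == 0`` encodes a skipped dose (contributes nothing).
    """

    time: float
    amount: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.time) and math.isfinite(self.amount)):
            raise ValueError("dose time and amount must be finite")
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")
        if self.amount < 0:
            raise ValueError(f"dose amount must be >= 0, got {self.amount}")


def _check_schedule(doses: Sequence[DoseEvent]) -> None:
    times = [d.time for d in doses]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("dose times must be strictly increasing")


def _single_dose(tk0: float, ke: float, cl: float, amount: float, u: np.ndarray) -> np.ndarray:
    """Closed-form single-dose concentration at time-since-dose ``u`` (vectorised)."""
    scale = amount / (tk0 * cl)
    uc = np.clip(u, 0.0, None)
    during = scale * -np.expm1(-ke * np.minimum(uc, tk0))
    after = scale * -np.expm1(-ke * tk0) * np.exp(-ke * np.maximum(uc - tk0, 0.0))
    out = np.where(uc <= tk0, during, after)
    return np.where(u < 0.0, 0.0, out)


def concentration(
    params: StructuralParams, doses: Sequence[DoseEvent], t: float | np.ndarray
) -> float | np.ndarray:
    """Concentration (mg/L) at time(s) ``t`` under superposition of ``doses``.

    ``t`` is hours since the start of the schedule; scalar in, scalar out.
    """
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("query times must be finite")
    if np.any(t_arr < 0):
        raise ValueError("query times must be >= 0")
    _check_schedule(doses)
    total = np.zeros_like(t_arr)
    for d in doses:
        if d.amount == 0.0:
            continue
        total = total + _single_dose(params.tk0, params.ke, params.cl, d.amount, t_arr - d.time)
    return float(total) if np.isscalar(t) or t_arr.ndim == 0 else total


def cmax(
    params: StructuralParams,
    doses: Sequence[DoseEvent],
    window: tuple[float, float],
    grid_step: float = 0.01,
) -> tuple[float, float]:
    """Maximum concentration and its time over ``window = (t_start, t_end)``.

    Candidate times are every absorption end ``td + tk0`` inside the window
    (where the single-dose maxima sit) plus a dense fallback grid of
    ``grid_step`` hours, plus the window endpoints.  If every dose amount is
    zero the profile is identically zero and ``(0.0, t_start)`` is returned.
    """
    t_start, t_end = float(window[0]), float(window[1])
    if not (t_end > t_start):
        raise ValueError("window must satisfy t_end > t_start")
    if len(doses) == 0:
        raise ValueError("at least one dose event is required")
    _check_schedule(doses)
    if all(d.amount == 0.0 for d in doses):
        return 0.0, t_start

    candidates = [t_start, t_end]
    for d in doses:
        tc = d.time + params.tk0
        if d.amount > 0.0 and t_start <= tc <= t_end:
            candidates.append(tc)
    grid = np.arange(t_start, t_end, grid_step)
    times = np.concatenate([np.asarray(candidates), grid])
    conc = np.zeros_like(times)
    for d in doses:
        if d.amount == 0.0:
            continue
        conc += _single_dose(params.tk0, params.ke, params.cl, d.amount, times - d.time)
    i = int(np.argmax(conc))
    return float(conc[i]), float(times[i])


def ode_oracle(
    params: StructuralParams,
    doses: Sequence[DoseEvent],
    times: Sequence[float],
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Numerically integrated concentration series (independent oracle).

    Integrates ``dC/dt = R(t)/V - ke*C`` where ``R(t)`` is the summed
    piecewise-constant absorption rate (``amount / tk0`` over each dose's
    absorption window).  Integration is split at every rate breakpoint so the
    adaptive solver never steps across a discontinuity.  Raises ``RuntimeError``
    on solver failure.
    """
    _check_schedule(doses)
    t_eval = np.asarray(times, dtype=float)
    if np.any(t_eval < 0) or not np.all(np.isfinite(t_eval)):
        raise ValueError("query times must be finite and >= 0")
    if np.any(np.diff(t_eval) < 0):
        raise ValueError("query times must be non-decreasing")
    active = [d for d in doses if d.amount > 0.0]
    if not active or t_eval.size == 0:
        return np.zeros_like(t_eval)

    ke = params.ke

    def rate(t: float) -> float:
        # summed zero-order input, mg/h
        return sum(d.amount / params.tk0 for d in active if d.time <= t < d.time + params.tk0)

    breaks = sorted(
        {0.0, float(t_eval[-1])}
        | {d.time for d in active}
        | {d.time + params.tk0 for d in active}
    )
    breaks = [b for b in breaks if 0.0 <= b <= t_eval[-1]]
    if breaks[-1] < t_eval[-1]:
        breaks.append(float(t_eval[-1]))

    out = np.empty_like(t_eval)
    out[t_eval == 0.0] = 0.0
    c = 0.0
    for a, b in zip(breaks, breaks[1:]):
        r = rate(0.5 * (a + b))  # constant on (a, b)

        def rhs(t: float, y: np.ndarray) -> list[float]:
            return [r / params.v - ke * y[0]]

        sel = (t_eval > a) & (t_eval <= b)
        seg = t_eval[sel]
        if seg.size == 0 or seg[-1] < b:
            seg = np.append(seg, b)  # always integrate through to b
        sol = solve_ivp(
            rhs, (a, b), [c], t_eval=seg,
            rtol=rtol, atol=atol, method="DOP853",
        )
        if not sol.success:
            raise RuntimeError(f"ODE solver failed on segment [{a}, {b}]: {sol.message}")
        out[sel] = sol.y[0][: int(sel.sum())]
        c = float(sol.y[0, -1])
    out[t_eval > breaks[-1]] = np.nan  # unreachable by construction
    return out
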