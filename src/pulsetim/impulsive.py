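"""Simulation of the model under periodically pulsed immunotherapy.

Therapy is modelled as instantaneous additions of CD4+ T cells and/or
cytokine every ``tau`` days (a Dirac-comb forcing): the state jumps by
the dose at each pulse time and follows the smooth autonomous flow in
between.  The first pulse is applied at t = 0, and the stroboscopic
(Poincare) section is taken just *before* each pulse, so a fixed point of
:func:`stroboscopic_map` is a pre-pulse state of a tau-periodic solution.

Integration between pulses uses a stiff-capable solver with the analytic
Jacobian; the default tolerances (rtol 1e-9, atol 1e-12) are tight because
bifurcation localization downstream differentiates these flows.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from .model import ModelParams, _f, _jac, as_state_array

__all__ = [
    "DoseSchedule",
    "NumericPolicy",
    "Trajectory",
    "AttractorReport",
    "IntegrationError",
    "integrate_segment",
    "apply_pulse",
    "stroboscopic_map",
    "simulate",
    "classify_attractor",
]


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the failure time."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


@dataclass(frozen=True)
class DoseSchedule:
    """Per-pulse doses (cm^3) and the pulse interval tau (days).

    ``d_cd4`` is the CD4+ T cell dose and ``d_il4`` the antitumor
    cytokine dose added instantaneously at t = 0, tau, 2 tau, ...
    The default one-week cycle matches common vaccination practice.
    """

    d_cd4: float = 0.0
    d_il4: float = 0.0
    tau: float = 7.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.tau) and self.tau > 0):
            raise ValueError(f"tau must be positive and finite, got {self.tau}")
        for name in ("d_cd4", "d_il4"):
            v = float(getattr(self, name))
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"dose {name!r} must be nonnegative and finite, got {v}")
            object.__setattr__(self, name, v)
        object.__setattr__(self, "tau", float(self.tau))

    def replace(self, **changes) -> "DoseSchedule":
        return replace(self, **changes)

    def dose_array(self) -> np.ndarray:
        return np.array([0.0, self.d_cd4, self.d_il4])


@dataclass(frozen=True)
class NumericPolicy:
    """Numerical policy for integration and attractor classification.

    ``transient_cycles`` strobe-map iterations are allowed before a
    non-converging orbit is classified; fixed points are accepted earlier
    once ``fp_consecutive`` successive iterates move less than ``tol_fp``
    (relative).  ``tol_curve`` is the relative recurrence tolerance for
    closed-curve detection and ``divergence_factor`` * K the runaway guard.
    """

    rtol: float = 1e-9
    atol: float = 1e-12
    transient_cycles: int = 2000
    fp_consecutive: int = 10
    tol_fp: float = 1e-7
    tol_curve: float = 0.05
    curve_samples: int = 100
    divergence_factor: float = 10.0

    def replace(self, **changes) -> "NumericPolicy":
        return replace(self, **changes)


DEFAULT_POLICY = NumericPolicy()


def diverged(s: np.ndarray, params: ModelParams, factor: float = 10.0) -> bool:
    """Runaway guard: non-finite state, tumor beyond ``factor * K`` (the
    only component bounded by the carrying capacity), or any component at
    an absurd magnitude (T cells and cytokine legitimately exceed K on
    large oscillations)."""
    return (
        not bool(np.all(np.isfinite(s)))
        or s[0] > factor * params.K
        or bool(np.max(s) > 1e9)
    )

# integrator undershoot below this magnitude is clipped to zero; anything
# more negative indicates solver failure and raises
_CLIP_TOL = 1e-9


def _clip_nonneg(s: np.ndarray, t: float) -> np.ndarray:
    if np.any(s < -_CLIP_TOL):
        raise IntegrationError(f"integrator produced negative state {s} at t={t}", t)
    return np.maximum(s, 0.0)


def integrate_segment(
    state,
    params: ModelParams,
    duration: float,
    policy: NumericPolicy = DEFAULT_POLICY,
    t_eval: np.ndarray | None = None,
):
    """Advance ``state`` by the autonomous flow for ``duration`` days.

    Returns the end state (shape (3,) array), or (times, states) when
    ``t_eval`` is given.  The tumor-free plane x = 0 is exactly invariant:
    if the initial tumor volume is zero it is pinned to zero throughout.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    s0 = as_state_array(state)
    if np.any(s0 < -_CLIP_TOL) or not np.all(np.isfinite(s0)):
        raise ValueError(f"invalid initial state {s0}")
    s0 = np.maximum(s0, 0.0)
    tumor_free = s0[0] == 0.0

    sol = solve_ivp(
        lambda t, s: _f(s, params),
        (0.0, float(duration)),
        s0,
        method="LSODA",
        jac=lambda t, s: _jac(s, params),
        rtol=policy.rtol,
        atol=policy.atol,
        t_eval=t_eval,
        dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}", float(sol.t[-1]))
    states = sol.y.T.copy()
    if tumor_free:
        states[:, 0] = 0.0  # invariant plane, exact
    states = np.array([_clip_nonneg(row, t) for row, t in zip(states, sol.t)])
    if t_eval is None:
        return states[-1]
    return sol.t.copy(), states


def apply_pulse(state, schedule: DoseSchedule) -> np.ndarray:
    """Instantaneous dose: (x, y, z) -> (x, y + d_cd4, z + d_il4)."""
    s = as_state_array(state)
    return s + schedule.dose_array()


def stroboscopic_map(state, params: ModelParams, schedule: DoseSchedule,
                     policy: NumericPolicy = DEFAULT_POLICY) -> np.ndarray:
    """One cycle of the pulsed system: pulse, then flow for tau days.

    Input and output are pre-pulse states; iterating this map generates
    the strobe orbit whose fixed points are tau-periodic solutions.
    """
    return integrate_segment(apply_pulse(state, schedule), params, schedule.tau, policy)


@dataclass
class Trajectory:
    """Densely sampled pulsed trajectory.

    ``pulse_indices`` mark the sample rows taken immediately after a
    pulse; ``strobe_states`` are the pre-pulse states at t = n tau (the
    stroboscopic section).
    """

    times: np.ndarray
    states: np.ndarray
    pulse_indices: np.ndarray
    strobe_times: np.ndarray
    strobe_states: np.ndarray

    def to_frame(self):
        """Return a pandas DataFrame with columns t, x, y, z, pulse_flag."""
        import pandas as pd

        flag = np.zeros(len(self.times), dtype=int)
        flag[self.pulse_indices] = 1
        return pd.DataFrame(
            {
                "t": self.times,
                "x": self.states[:, 0],
                "y": self.states[:, 1],
                "z": self.states[:, 2],
                "pulse_flag": flag,
            }
        )

    def strobe_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.strobe_times,
                "x": self.strobe_states[:, 0],
                "y": self.strobe_states[:, 1],
                "z": self.strobe_states[:, 2],
            }
        )


def simulate(
    state0,
    params: ModelParams,
    schedule: DoseSchedule,
    horizon: float,
    samples_per_cycle: int = 50,
    policy: NumericPolicy = DEFAULT_POLICY,
) -> Trajectory:
    """Simulate the pulsed system from a pre-pulse initial state.

    Pulses fire at t = 0, tau, 2 tau, ... (the initial state is the state
    just before the first dose).  Within each cycle the flow is sampled at
    ``samples_per_cycle`` points; the pre-pulse state at each t = n tau is
    recorded as the strobe series.
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    s = as_state_array(state0)
    tau = schedule.tau
    n_cycles = int(math.ceil(horizon / tau - 1e-12))

    times: list[float] = []
    rows: list[np.ndarray] = []
    pulse_idx: list[int] = []
    strobe_t: list[float] = []
    strobe_s: list[np.ndarray] = []

    t0 = 0.0
    for n in range(n_cycles):
        strobe_t.append(t0)
        strobe_s.append(s.copy())
        s_post = apply_pulse(s, schedule)
        pulse_idx.append(len(times))
        seg_end = min(t0 + tau, horizon)
        dt = seg_end - t0
        t_eval = np.linspace(0.0, dt, samples_per_cycle + 1)
        seg_t, seg_states = integrate_segment(s_post, params, dt, policy, t_eval=t_eval)
        seg_states[0] = np.maximum(s_post, 0.0)  # sample at t = n*tau is the exact post-pulse state
        times.extend((t0 + seg_t).tolist())
        rows.extend(seg_states)
        s = seg_states[-1]
        t0 = seg_end
    strobe_t.append(t0)
    strobe_s.append(s.copy())

    return Trajectory(
        times=np.asarray(times),
        states=np.asarray(rows),
        pulse_indices=np.asarray(pulse_idx, dtype=int),
        strobe_times=np.asarray(strobe_t),
        strobe_states=np.asarray(strobe_s),
    )


@dataclass
class AttractorReport:
    """Long-run behaviour of a strobe orbit.

    ``kind`` is ``fixed_point`` (a tau-periodic solution), ``closed_curve``
    (a bounded, recurrent, non-convergent strobe orbit -- a quasiperiodic
    or long-period oscillation), or ``unresolved``.
    """

    kind: str
    representative: np.ndarray
    orbit: np.ndarray | None = None
    period_estimate: float | None = None
    transient_used: float = 0.0
    detail: str = ""


def classify_attractor(
    state0,
    params: ModelParams,
    schedule: DoseSchedule,
    policy: NumericPolicy = DEFAULT_POLICY,
) -> AttractorReport:
    """Iterate the strobe map and label the attractor reached from ``state0``.

    A fixed point is declared when successive strobe states move less
    than ``policy.tol_fp`` (relative) for ``policy.fp_consecutive``
    consecutive cycles.  Otherwise, after ``policy.transient_cycles``
    cycles, a bounded orbit whose recent points recur near earlier ones
    (within ``policy.tol_curve`` of the orbit diameter) without converging
    is labelled a closed curve.  Orbits exceeding
    ``policy.divergence_factor * K`` in any component are unresolved.
    """
    s = as_state_array(state0).copy()
    consecutive = 0
    n = 0
    for n in range(1, policy.transient_cycles + 1):
        s_next = stroboscopic_map(s, params, schedule, policy)
        if diverged(s_next, params, policy.divergence_factor):
            return AttractorReport(
                kind="unresolved",
                representative=s_next,
                transient_used=n * schedule.tau,
                detail=f"orbit exceeded divergence guard at cycle {n}",
            )
        step = np.linalg.norm(s_next - s) / max(1.0, np.linalg.norm(s))
        s = s_next
        if step < policy.tol_fp:
            consecutive += 1
            if consecutive >= policy.fp_consecutive:
                return AttractorReport(
                    kind="fixed_point",
                    representative=s,
                    transient_used=n * schedule.tau,
                    detail=f"strobe convergence after {n} cycles (relative step < {policy.tol_fp})",
                )
        else:
            consecutive = 0

    # non-convergent: collect a window of strobe points and test recurrence
    orbit = np.empty((policy.curve_samples, 3))
    for i in range(policy.curve_samples):
        s = stroboscopic_map(s, params, schedule, policy)
        if diverged(s, params, policy.divergence_factor):
            return AttractorReport(
                kind="unresolved",
                representative=s,
                transient_used=(n + i) * schedule.tau,
                detail="orbit exceeded divergence guard during sampling",
            )
        orbit[i] = s
    diam = float(np.max(np.ptp(orbit, axis=0)))
    scale = max(diam, 1e-12)
    last = orbit[-1]
    # nearest return among earlier samples, excluding immediate neighbours
    dists = np.linalg.norm(orbit[:-5] - last, axis=1)
    nearest = int(np.argmin(dists))
    recur = float(dists[nearest]) / scale
    transient_days = (policy.transient_cycles + policy.curve_samples) * schedule.tau
    if diam > policy.tol_fp * max(1.0, float(np.linalg.norm(last))) and recur < policy.tol_curve:
        period = (policy.curve_samples - 1 - nearest) * schedule.tau
        return AttractorReport(
            kind="closed_curve",
            representative=last,
            orbit=orbit,
            period_estimate=float(period),
            transient_used=transient_days,
            detail=f"bounded non-convergent strobe orbit, nearest return {recur:.3g} of diameter",
        )
    return AttractorReport(
        kind="unresolved",
        representative=last,
        orbit=orbit,
        transient_used=transient_days,
        detail=f"no convergence and no recurrence (nearest return {recur:.3g} of diameter)",
    )
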