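"""Analytic stability thresholds and closed-form pulsed-therapy results.

Two groups of results live here.

Autonomous (no-treatment) system
    * the transcritical threshold ``beta_c = a (k + K) / K`` at which the
      tumor-at-carrying-capacity state exchanges stability with the
      interior state;
    * the Hopf condition of the slow-manifold reduced system, expressed
      as a scalar residual whose sign decides local stability of the
      interior state and whose roots are Hopf points;
    * the Hopf surface ``b(m, beta)`` solving that condition for the
      cytokine half-saturation constant.

Pulsed therapy (dose d every tau days, modelled as instantaneous jumps)
    * the tumor-free fixed point of the stroboscopic map, in closed form;
    * its tumor-direction Floquet multiplier exp(r tau - delta d_IL4/(m mu)),
      which is < 1 exactly when the per-pulse cytokine dose exceeds
      ``r tau mu m / delta`` -- the minimal dose for which a cleared tumor
      cannot regrow.  Pulsed T cells alone never stabilize the tumor-free
      state: with d_IL4 = 0 the multiplier is e^{r tau} > 1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Equilibrium, ModelParams, SystemState, interior_equilibrium_x, slow_manifold

__all__ = [
    "StabilityVerdict",
    "beta_c",
    "hopf_residual",
    "reduced_trace",
    "reduced_jacobian",
    "reduced_stability",
    "hopf_surface_b",
    "TumorFreeFixedPoint",
    "tumor_free_pulsed_fixed_point",
    "tumor_free_multiplier",
    "il4_clearance_threshold",
]


@dataclass(frozen=True)
class StabilityVerdict:
    """Outcome of a stability test.

    ``mechanism`` records how the verdict was reached: ``"eigenvalues"``
    (continuous-time spectrum; stable iff leading real part < 0),
    ``"floquet"`` (multiplier moduli; stable iff leading modulus < 1), or
    ``"closed_form"`` (an analytic criterion, with the same multiplier
    convention).
    """

    stable: bool
    mechanism: str
    leading_value: float
    detail: str = ""


def beta_c(params: ModelParams) -> float:
    """Transcritical antigenicity threshold a (k + K) / K (day^-1).

    For beta below this value the immune response cannot establish and
    the tumor-at-carrying-capacity state is asymptotically stable; above
    it an interior coexistence state exists.
    """
    return params.a * (params.k + params.K) / params.K


def _hopf_bracket(x: float, params: ModelParams) -> float:
    K, b, m = params.K, params.b, params.m
    return 1.0 + b * (K - x) / (x * (b + x)) - (K - x) / (m + x)


def hopf_residual(params: ModelParams) -> float:
    """Hopf condition of the reduced system, as a signed residual.

    Evaluates ``1 + b(K - x)/(x(b + x)) - (K - x)/(m + x)`` at the
    interior tumor volume x = k a / (beta - a).  Zero at a Hopf point;
    positive implies the interior state of the reduced system is locally
    stable (the trace of its Jacobian is this residual times a negative
    factor, and the determinant is always positive).
    """
    x = interior_equilibrium_x(params)
    return _hopf_bracket(x, params)


def reduced_trace(params: ModelParams) -> float:
    """Trace of the reduced-system Jacobian at the interior state (day^-1).

    Equals ``-(r x / K) * hopf_residual`` with x = k a / (beta - a); its
    sign decides stability since the determinant is positive.
    """
    x = interior_equilibrium_x(params)
    return -(params.r * x / params.K) * _hopf_bracket(x, params)


def reduced_jacobian(params: ModelParams) -> np.ndarray:
    """2x2 Jacobian of the slow-manifold reduced system at its interior state.

    The reduced system evolves (x, y) with the cytokine slaved to the
    slow manifold z = S(x, y).  At the interior equilibrium the diagonal
    (y, y) entry vanishes because T cell proliferation exactly balances
    death there.
    """
    x = interior_equilibrium_x(params)
    if x >= params.K:
        raise ValueError("interior equilibrium requires beta > beta_c (x < K)")
    p = params
    y = (
        p.r * p.mu * (p.m + x) * (p.b + x) * (p.K - x)
        / (p.K * p.alpha * p.delta * x)
    )
    S = slow_manifold(x, y, p)
    Sx = p.alpha * y * p.b / (p.mu * (p.b + x) ** 2)
    Sy = p.alpha * x / (p.mu * (p.b + x))
    mx = p.m + x
    j11 = x * (-p.r / p.K - (mx * p.delta * Sx - p.delta * S) / (mx * mx))
    j12 = -p.delta * x / mx * Sy
    j21 = p.k * p.beta * y / (p.k + x) ** 2
    return np.array([[j11, j12], [j21, 0.0]])


def reduced_stability(params: ModelParams) -> StabilityVerdict:
    """Stability verdict for the interior state of the reduced system."""
    eigs = np.linalg.eigvals(reduced_jacobian(params))
    lead = float(np.max(eigs.real))
    return StabilityVerdict(
        stable=lead < 0.0,
        mechanism="eigenvalues",
        leading_value=lead,
        detail=f"reduced 2x2 eigenvalues {eigs}",
    )


def hopf_surface_b(m: float, beta: float, params: ModelParams):
    """The cytokine half-saturation ``b`` putting (m, beta) on the Hopf surface.

    Solves the Hopf condition for b at x = k a / (beta - a):
    ``b = x^2 (K - m - 2x) / (x^2 + m K)``.  Returns None when no positive
    solution exists (K - m - 2x <= 0), i.e. when the killing saturation m
    is too large for oscillations regardless of b.
    """
    if m <= 0:
        raise ValueError("m must be positive")
    p = params.replace(m=m, beta=beta)
    x = interior_equilibrium_x(p)
    K = params.K
    value = x * x * (K - m - 2.0 * x) / (x * x + m * K)
    if value <= 0.0:
        return None
    return value


@dataclass(frozen=True)
class TumorFreeFixedPoint:
    """Tumor-free fixed point of the stroboscopic map, in closed form.

    Pre-pulse values (the state just before each injection, the canonical
    fixed-point convention here) are
    ``y0 = d_cd4 / (e^{a tau} - 1)`` and ``z0 = d_il4 / (e^{mu tau} - 1)``;
    post-pulse values add one dose.  ``verdict`` is the closed-form
    Floquet stability of the fixed point (tumor direction dominates).
    """

    pre_pulse: SystemState
    post_pulse: SystemState
    multiplier: float
    verdict: StabilityVerdict

    def as_equilibrium(self) -> Equilibrium:
        return Equilibrium("tumor_free_pulsed", True, self.pre_pulse)


def tumor_free_pulsed_fixed_point(schedule, params: ModelParams) -> TumorFreeFixedPoint:
    """Closed-form tumor-free fixed point for a pulse schedule.

    On the tumor-free plane the T cell and cytokine dynamics are linear
    decays punctuated by additive doses, so the periodic orbit is exact:
    pre-pulse ``y0 = d/(e^{a tau} - 1)`` (geometric sum of decayed doses),
    and identically for z with rate mu.
    """
    if schedule.tau <= 0:
        raise ValueError(f"pulse interval tau must be positive, got {schedule.tau}")
    a, mu, tau = params.a, params.mu, schedule.tau
    # d/(e^{rate*tau} - 1), written to avoid overflow for large rate*tau
    y0 = schedule.d_cd4 * np.exp(-a * tau) / -np.expm1(-a * tau)
    z0 = schedule.d_il4 * np.exp(-mu * tau) / -np.expm1(-mu * tau)
    pre = SystemState(0.0, y0, z0)
    post = SystemState(0.0, y0 + schedule.d_cd4, z0 + schedule.d_il4)
    mult = tumor_free_multiplier(schedule, params)
    verdict = StabilityVerdict(
        stable=mult < 1.0,
        mechanism="closed_form",
        leading_value=mult,
        detail="tumor-direction Floquet multiplier exp(r tau - delta d_il4 / (m mu))",
    )
    return TumorFreeFixedPoint(pre, post, mult, verdict)


def tumor_free_multiplier(schedule, params: ModelParams) -> float:
    """Per-cycle growth factor of an infinitesimal tumor at the tumor-free state.

    An infinitesimal tumor grows at rate r and is killed at rate
    (delta/m) z(t); integrating the periodic cytokine decay over one cycle
    gives the exact multiplier ``exp(r tau - delta d_il4 / (m mu))``.
    The tumor-free fixed point is stable iff this is < 1.  It does not
    involve d_cd4: pulsed T cells alone leave the multiplier e^{r tau} > 1.
    """
    if schedule.tau <= 0:
        raise ValueError(f"pulse interval tau must be positive, got {schedule.tau}")
    return float(
        np.exp(params.r * schedule.tau - params.delta * schedule.d_il4 / (params.m * params.mu))
    )


def il4_clearance_threshold(params: ModelParams, tau: float) -> float:
    """Minimal per-pulse cytokine dose stabilizing the tumor-free state (cm^3).

    ``r tau mu m / delta``: the dose at which the tumor-direction
    multiplier equals exactly 1.  The same condition governs combined
    dosing, since added T cells do not change the tumor-direction
    linearization on the tumor-free plane.
    """
    if tau <= 0:
        raise ValueError(f"pulse interval tau must be positive, got {tau}")
    return params.r * tau * params.mu * params.m / params.delta
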