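"""Bifurcation machinery for the autonomous flow and the stroboscopic map.

Fixed points of the one-cycle (pulse + tau-day flow) map are found by
Newton iteration; their Floquet multipliers come from the monodromy
matrix, obtained by integrating the variational equations alongside the
flow (the pulse jump has identity Jacobian, so the monodromy of the cycle
is the flow's fundamental matrix).  On top of these primitives:

* :func:`locate_transcritical` -- the closed-form tumor-free stability
  boundary d_il4 = r tau mu m / delta, with a numeric monodromy
  cross-check;
* :func:`locate_hopf_ode` -- roots of the reduced-system Hopf condition
  along any model parameter;
* :func:`locate_fold` -- bisection for the dose at which a stable
  small-tumor fixed-point branch of the strobe map is born or destroyed
  (a real multiplier crossing +1);
* one-parameter sweeps, an adaptive-grid two-parameter region map, and
  the analytic three-parameter (m, beta, b) bifurcation surfaces.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model import ModelParams, _f, _jac, as_state_array
from .impulsive import (
    DEFAULT_POLICY,
    DoseSchedule,
    NumericPolicy,
    apply_pulse,
    classify_attractor,
)
from .stability import (
    StabilityVerdict,
    beta_c,
    hopf_residual,
    hopf_surface_b,
    il4_clearance_threshold,
    tumor_free_multiplier,
    tumor_free_pulsed_fixed_point,
)

__all__ = [
    "MapFixedPoint",
    "BifurcationPoint",
    "RegionMap",
    "BracketError",
    "flow_with_monodromy",
    "map_with_monodromy",
    "solve_map_fixed_point",
    "tumor_free_multiplier_numeric",
    "locate_transcritical",
    "locate_hopf_ode",
    "locate_fold",
    "sweep_one_parameter",
    "region_map_two_parameters",
    "three_parameter_surfaces",
]


class BracketError(ValueError):
    """Raised when a bracket does not straddle the sought bifurcation."""


@dataclass(frozen=True)
class MapFixedPoint:
    """A fixed point of the stroboscopic map (pre-pulse convention)."""

    state: np.ndarray
    multipliers: np.ndarray
    stability: StabilityVerdict
    converged: bool
    residual: float
    iterations: int
    branch_label: str = ""

    @property
    def leading_modulus(self) -> float:
        return float(np.max(np.abs(self.multipliers)))


@dataclass(frozen=True)
class BifurcationPoint:
    """A located bifurcation along one parameter.

    ``kind`` is one of ``fold`` (real multiplier through +1, branch pair
    birth/death), ``neimark_sacker`` (complex multiplier pair through the
    unit circle; called a Hopf of the map in outputs), ``transcritical``
    (tumor-direction multiplier through 1), or ``hopf_ode`` (trace of the
    reduced Jacobian through 0 with positive determinant).
    """

    kind: str
    parameter_name: str
    parameter_value: float
    bracket: tuple[float, float]
    witness: object = None
    detail: str = ""


# ---------------------------------------------------------------------------
# monodromy / variational integration
# ---------------------------------------------------------------------------

def _extended_rhs(t: float, w: np.ndarray, p: ModelParams) -> np.ndarray:
    s = w[:3]
    J = _jac(s, p)
    out = np.empty(12)
    out[:3] = _f(s, p)
    out[3:] = (J @ w[3:].reshape(3, 3)).ravel()
    return out


def flow_with_monodromy(
    state,
    params: ModelParams,
    duration: float,
    policy: NumericPolicy = DEFAULT_POLICY,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance the autonomous flow and its fundamental matrix together.

    Returns ``(end_state, Phi)`` where Phi is the 3x3 fundamental
    (monodromy) matrix of the variational equations along the trajectory,
    initialized at the identity.
    """
    s0 = as_state_array(state)
    w0 = np.concatenate([np.maximum(s0, 0.0), np.eye(3).ravel()])
    sol = solve_ivp(
        _extended_rhs,
        (0.0, float(duration)),
        w0,
        args=(params,),
        method="LSODA",
        rtol=policy.rtol,
        atol=policy.atol,
    )
    if not sol.success:
        from .impulsive import IntegrationError

        raise IntegrationError(f"variational integration failed: {sol.message}", float(sol.t[-1]))
    w = sol.y[:, -1]
    end = w[:3].copy()
    if s0[0] == 0.0:
        end[0] = 0.0
    return end, w[3:].reshape(3, 3).copy()


def map_with_monodromy(
    state,
    params: ModelParams,
    schedule: DoseSchedule,
    policy: NumericPolicy = DEFAULT_POLICY,
) -> tuple[np.ndarray, np.ndarray]:
    """One strobe-map application F(s) together with its Jacobian dF/ds.

    The pulse is an additive shift (identity Jacobian), so dF/ds is the
    fundamental matrix of the tau-day flow started at the post-pulse state.
    """
    post = apply_pulse(state, schedule)
    return flow_with_monodromy(post, params, schedule.tau, policy)


def _classify_branch(state: np.ndarray, params: ModelParams) -> str:
    x = state[0]
    if x < 1e-6:
        return "tumor_free"
    if x > 0.5 * params.K:
        return "E3_star"
    return "small_tumor"


def solve_map_fixed_point(
    guess,
    params: ModelParams,
    schedule: DoseSchedule,
    policy: NumericPolicy = DEFAULT_POLICY,
    tol: float = 1e-9,
    max_iter: int = 30,
) -> MapFixedPoint:
    """Newton iteration on F(s) - s = 0 for the stroboscopic map.

    Returns the fixed point with its three Floquet multipliers (eigenvalues
    of the monodromy matrix) and a stability verdict by leading modulus.
    Non-convergence is reported on the result, not raised, so sweeps can
    use failure as a branch-existence signal.
    """
    s = np.maximum(as_state_array(guess), 0.0).astype(float)
    converged = False
    residual = math.inf
    n_done = 0
    Phi = np.eye(3)
    for n_done in range(1, max_iter + 1):
        Fs, Phi = map_with_monodromy(s, params, schedule, policy)
        G = Fs - s
        residual = float(np.linalg.norm(G) / max(1.0, np.linalg.norm(s)))
        if residual < tol:
            converged = True
            break
        A = Phi - np.eye(3)
        try:
            step = np.linalg.solve(A, -G)
        except np.linalg.LinAlgError:
            break
        # positivity-preserving damping: a strictly positive component may
        # shrink by at most 90% per step (x = 0 is an invariant plane, so a
        # step that zeroes the tumor volume would silently change branch)
        lam = 1.0
        for i in range(3):
            if s[i] > 0.0 and step[i] < 0.0 and s[i] + step[i] < 0.1 * s[i]:
                lam = min(lam, 0.9 * s[i] / -step[i])
        s = np.maximum(s + lam * step, 0.0)
    mult = np.linalg.eigvals(Phi)
    lead = float(np.max(np.abs(mult)))
    verdict = StabilityVerdict(
        stable=lead < 1.0,
        mechanism="floquet",
        leading_value=lead,
        detail=f"multipliers {mult}",
    )
    return MapFixedPoint(
        state=s,
        multipliers=mult,
        stability=verdict,
        converged=converged,
        residual=residual,
        iterations=n_done,
        branch_label=_classify_branch(s, params) if converged else "",
    )


def tumor_free_multiplier_numeric(
    schedule: DoseSchedule,
    params: ModelParams,
    policy: NumericPolicy = DEFAULT_POLICY,
) -> float:
    """Tumor-direction Floquet multiplier at the tumor-free fixed point,
    computed from the monodromy matrix rather than the closed form.

    On the tumor-free plane the variational Jacobian is lower triangular,
    so the (x, x) entry of the monodromy matrix is exactly the tumor
    multiplier.
    """
    fp = tumor_free_pulsed_fixed_point(schedule, params)
    _, Phi = map_with_monodromy(fp.pre_pulse.to_array(), params, schedule, policy)
    return float(Phi[0, 0])


# ---------------------------------------------------------------------------
# bifurcation locators
# ---------------------------------------------------------------------------

def locate_transcritical(
    params: ModelParams,
    tau: float,
    cross_check: bool = False,
    policy: NumericPolicy = DEFAULT_POLICY,
) -> BifurcationPoint:
    """Tumor-free stability boundary in the per-pulse cytokine dose.

    The closed form is d_il4 = r tau mu m / delta (independent of the
    T cell dose).  With ``cross_check`` the boundary is also located
    numerically as the root of the monodromy tumor multiplier minus one,
    and the mismatch is recorded in ``detail``.
    """
    d_star = il4_clearance_threshold(params, tau)
    detail = "closed form r*tau*mu*m/delta"
    if cross_check:
        def g(d: float) -> float:
            return math.log(
                tumor_free_multiplier_numeric(DoseSchedule(0.0, d, tau), params, policy)
            )

        d_num = brentq(g, 0.5 * d_star, 1.5 * d_star, xtol=1e-10 * d_star, rtol=1e-12)
        detail += f"; numeric monodromy root {d_num!r} (rel. diff {abs(d_num - d_star) / d_star:.3e})"
    return BifurcationPoint(
        kind="transcritical",
        parameter_name="d_il4",
        parameter_value=d_star,
        bracket=(d_star, d_star),
        witness=tumor_free_pulsed_fixed_point(DoseSchedule(0.0, d_star, tau), params),
        detail=detail,
    )


def locate_hopf_ode(
    params_template: ModelParams,
    sweep_parameter: str,
    bracket: tuple[float, float],
) -> BifurcationPoint:
    """Root of the reduced-system Hopf condition along one model parameter.

    The residual must change sign over the bracket; the root is refined
    to ~1e-10 relative by Brent's method.
    """
    lo, hi = float(bracket[0]), float(bracket[1])

    def g(v: float) -> float:
        return hopf_residual(params_template.replace(**{sweep_parameter: v}))

    glo, ghi = g(lo), g(hi)
    if glo == 0.0:
        root = lo
    elif ghi == 0.0:
        root = hi
    elif glo * ghi > 0:
        raise BracketError(
            f"Hopf residual does not change sign over {sweep_parameter} in [{lo}, {hi}] "
            f"(residuals {glo:.4g}, {ghi:.4g})"
        )
    else:
        root = brentq(g, lo, hi, xtol=1e-14, rtol=1e-12)
    return BifurcationPoint(
        kind="hopf_ode",
        parameter_name=sweep_parameter,
        parameter_value=float(root),
        bracket=(lo, hi),
        witness=params_template.replace(**{sweep_parameter: float(root)}),
        detail=f"reduced-trace zero with positive determinant; residual {g(float(root)):.3e}",
    )


@dataclass(frozen=True)
class FoldPolicy:
    """Policy for :func:`locate_fold` branch probing and bisection."""

    settle_cycles: int = 300
    warm_cycles: int = 100
    settle_init: tuple[float, float, float] = (0.1, 0.01, 0.0)
    max_bisections: int = 40
    bracket_rtol: float = 1e-3
    newton_tol: float = 1e-9
    x_min: float = 1e-6
    x_max_fraction: float = 0.5


def _probe_branch(
    value: float,
    params: ModelParams,
    schedule_template: DoseSchedule,
    sweep_parameter: str,
    seed: np.ndarray | None,
    fold_policy: FoldPolicy,
    policy: NumericPolicy,
) -> MapFixedPoint | None:
    """Look for a *stable* small-tumor fixed point at the given dose.

    The sought branch is attracting, so the probe first iterates the
    strobe map from the seed -- the orbit flows onto the node when it
    exists, keeping a subsequent Newton solve inside the right basin --
    and falls back to settling afresh from a small tumor burden.
    Returns the fixed point or None.
    """
    from .impulsive import diverged, stroboscopic_map

    schedule = schedule_template.replace(**{sweep_parameter: value})

    def settle_then_newton(s: np.ndarray, cycles: int) -> MapFixedPoint | None:
        for _ in range(cycles):
            s = stroboscopic_map(s, params, schedule, policy)
            if diverged(s, params):
                return None
        fp = solve_map_fixed_point(s, params, schedule, policy, tol=fold_policy.newton_tol)
        if not fp.converged:
            return None
        if not (fold_policy.x_min < fp.state[0] < fold_policy.x_max_fraction * params.K):
            return None
        if fp.leading_modulus >= 1.0:
            return None
        return fp

    if seed is not None:
        fp = settle_then_newton(np.asarray(seed, dtype=float), fold_policy.warm_cycles)
        if fp is not None:
            return fp
    return settle_then_newton(
        np.asarray(fold_policy.settle_init, dtype=float), fold_policy.settle_cycles
    )


def locate_fold(
    params: ModelParams,
    schedule_template: DoseSchedule,
    sweep_parameter: str,
    bracket: tuple[float, float],
    fold_policy: FoldPolicy = FoldPolicy(),
    policy: NumericPolicy = DEFAULT_POLICY,
) -> BifurcationPoint:
    """Bisect for the dose at which the stable small-tumor branch appears.

    ``sweep_parameter`` is ``"d_il4"`` or ``"d_cd4"``.  Exactly one
    bracket endpoint must carry a stable small-tumor fixed point of the
    strobe map (the attracting branch born at the fold); bisection with
    warm-started Newton then shrinks the bracket around the fold, where
    the branch's leading real multiplier crosses +1 and the fixed-point
    pair is born or destroyed.
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise BracketError(f"bracket must satisfy lo < hi, got ({lo}, {hi})")
    fp_lo = _probe_branch(lo, params, schedule_template, sweep_parameter, None, fold_policy, policy)
    fp_hi = _probe_branch(hi, params, schedule_template, sweep_parameter, None, fold_policy, policy)
    if (fp_lo is None) == (fp_hi is None):
        raise BracketError(
            f"bracket ({lo}, {hi}) does not straddle a fold in {sweep_parameter}: "
            f"branch at lo={fp_lo is not None}, at hi={fp_hi is not None}"
        )
    branch_at_hi = fp_hi is not None
    witness = fp_hi if branch_at_hi else fp_lo
    width0 = hi - lo
    for _ in range(fold_policy.max_bisections):
        if hi - lo < fold_policy.bracket_rtol * width0:
            break
        mid = 0.5 * (lo + hi)
        fp_mid = _probe_branch(
            mid, params, schedule_template, sweep_parameter, witness.state, fold_policy, policy
        )
        if fp_mid is not None:
            witness = fp_mid
            if branch_at_hi:
                hi = mid
            else:
                lo = mid
        else:
            if branch_at_hi:
                lo = mid
            else:
                hi = mid
    value = 0.5 * (lo + hi)
    return BifurcationPoint(
        kind="fold",
        parameter_name=sweep_parameter,
        parameter_value=value,
        bracket=(lo, hi),
        witness=witness,
        detail=(
            f"stable small-tumor branch exists on the "
            f"{'upper' if branch_at_hi else 'lower'} side; leading multiplier at witness "
            f"{witness.leading_modulus:.6f}"
        ),
    )


# ---------------------------------------------------------------------------
# sweeps, region maps, surfaces
# ---------------------------------------------------------------------------

@dataclass
class SweepRecord:
    value: float
    init: tuple[float, float, float]
    kind: str
    representative: np.ndarray
    x_min: float
    x_max: float


def sweep_one_parameter(
    params_template: ModelParams,
    schedule_template: DoseSchedule,
    sweep_parameter: str,
    grid: Sequence[float],
    inits: Sequence[Sequence[float]],
    policy: NumericPolicy = DEFAULT_POLICY,
    warm_start: bool = True,
) -> tuple[list[SweepRecord], list[tuple[float, float]]]:
    """Classify the attractor at each grid value, from each initial state.

    ``sweep_parameter`` may name a model parameter (e.g. ``beta``) or a
    schedule field (``d_cd4``/``d_il4``).  Returns the per-point records
    (attractor kind and the strobe extrema of the tumor volume) plus the
    grid intervals across which the attractor type changes -- candidate
    brackets for the locate_* routines.
    """
    records: list[SweepRecord] = []
    brackets: list[tuple[float, float]] = []
    schedule_fields = {"d_cd4", "d_il4", "tau"}
    warm: dict[int, np.ndarray] = {}
    prev_kinds: list[str] | None = None
    prev_value: float | None = None
    for value in grid:
        if sweep_parameter in schedule_fields:
            params, schedule = params_template, schedule_template.replace(**{sweep_parameter: value})
        else:
            params, schedule = params_template.replace(**{sweep_parameter: value}), schedule_template
        kinds_here = []
        for i, init in enumerate(inits):
            s0 = warm.get(i, np.asarray(init, dtype=float)) if warm_start else np.asarray(init, dtype=float)
            report = classify_attractor(s0, params, schedule, policy)
            pts = report.orbit if report.orbit is not None else report.representative[None, :]
            records.append(
                SweepRecord(
                    value=float(value),
                    init=tuple(float(v) for v in init),
                    kind=report.kind,
                    representative=report.representative,
                    x_min=float(np.min(pts[:, 0])),
                    x_max=float(np.max(pts[:, 0])),
                )
            )
            kinds_here.append(report.kind)
            if report.kind != "unresolved":
                warm[i] = report.representative
        if prev_kinds is not None and kinds_here != prev_kinds:
            brackets.append((float(prev_value), float(value)))
        prev_kinds, prev_value = kinds_here, value
    return records, brackets


@dataclass
class RegionMap:
    """Adaptive-grid classification of a two-parameter plane.

    ``cells`` are leaf rectangles ``(x0, x1, y0, y1, label)``; a label is
    the frozen set of features shared by all four corners, or
    ``"boundary"`` where corners disagree at the maximum refinement
    depth.  ``boundary_points`` carries analytically sharpened boundary
    locations where available.
    """

    axes: tuple[str, str]
    ranges: tuple[tuple[float, float], tuple[float, float]]
    cells: list[tuple[float, float, float, float, str]]
    boundary_points: list[BifurcationPoint]
    refinement_depth: int

    def labels(self) -> set[str]:
        return {c[4] for c in self.cells if c[4] != "boundary"}


def _signature(
    point: dict[str, float],
    params_template: ModelParams,
    schedule_template: DoseSchedule,
    fold_policy: FoldPolicy,
    policy: NumericPolicy,
) -> str:
    """Region signature at one (parameter, parameter) point.

    Combines the closed-form tumor-free verdict with probes for the
    stable small-tumor branch and the large-tumor branch of the strobe
    map, yielding labels like ``E0s`` / ``E1*`` / ``E3*`` combinations.
    """
    schedule_fields = {"d_cd4", "d_il4", "tau"}
    params = params_template
    schedule = schedule_template
    for name, value in point.items():
        if name in schedule_fields:
            schedule = schedule.replace(**{name: value})
        else:
            params = params.replace(**{name: value})
    feats = []
    tf_stable = tumor_free_multiplier(schedule, params) < 1.0
    feats.append("E0-stable" if tf_stable else "E0-unstable")
    # probe the small branch by settling from a small tumor burden
    fp_small = _settle_and_solve(np.array([0.1, 0.01, 0.0]), params, schedule, fold_policy, policy)
    if fp_small is not None and fold_policy.x_min < fp_small.state[0] < fold_policy.x_max_fraction * params.K:
        feats.append("small-branch")
    fp_large = _settle_and_solve(np.array([0.9 * params.K, 0.01, 0.0]), params, schedule, fold_policy, policy)
    if fp_large is not None and fp_large.state[0] >= fold_policy.x_max_fraction * params.K:
        feats.append("large-branch")
    return "+".join(feats)


def _settle_and_solve(
    s0: np.ndarray,
    params: ModelParams,
    schedule: DoseSchedule,
    fold_policy: FoldPolicy,
    policy: NumericPolicy,
) -> MapFixedPoint | None:
    from .impulsive import diverged, stroboscopic_map

    s = s0.astype(float)
    for _ in range(fold_policy.settle_cycles):
        s = stroboscopic_map(s, params, schedule, policy)
        if diverged(s, params):
            return None
    fp = solve_map_fixed_point(s, params, schedule, policy, tol=fold_policy.newton_tol)
    if not fp.converged or fp.leading_modulus >= 1.0:
        return None
    return fp


def region_map_two_parameters(
    params_template: ModelParams,
    schedule_template: DoseSchedule,
    axes: tuple[str, str],
    ranges: tuple[tuple[float, float], tuple[float, float]],
    coarse: int = 17,
    max_depth: int = 5,
    fold_policy: FoldPolicy = FoldPolicy(settle_cycles=150),
    policy: NumericPolicy = DEFAULT_POLICY,
    sharpen: bool = False,
) -> RegionMap:
    """Adaptive-grid two-parameter region map.

    Starts from a ``coarse`` x ``coarse`` corner grid, classifies each
    corner by its region signature, and recursively splits cells whose
    corners disagree up to ``max_depth`` levels.  When ``sharpen`` is set
    and one axis is ``d_il4``, the tumor-free boundary is added from its
    closed form.
    """
    (x0, x1), (y0, y1) = ranges
    cache: dict[tuple[float, float], str] = {}

    def sig(px: float, py: float) -> str:
        key = (round(px, 12), round(py, 12))
        if key not in cache:
            cache[key] = _signature(
                {axes[0]: px, axes[1]: py},
                params_template,
                schedule_template,
                fold_policy,
                policy,
            )
        return cache[key]

    cells: list[tuple[float, float, float, float, str]] = []

    def refine(ax0: float, ax1: float, ay0: float, ay1: float, depth: int) -> None:
        corners = {sig(ax0, ay0), sig(ax1, ay0), sig(ax0, ay1), sig(ax1, ay1)}
        if len(corners) == 1:
            cells.append((ax0, ax1, ay0, ay1, corners.pop()))
            return
        if depth >= max_depth:
            cells.append((ax0, ax1, ay0, ay1, "boundary"))
            return
        mx, my = 0.5 * (ax0 + ax1), 0.5 * (ay0 + ay1)
        refine(ax0, mx, ay0, my, depth + 1)
        refine(mx, ax1, ay0, my, depth + 1)
        refine(ax0, mx, my, ay1, depth + 1)
        refine(mx, ax1, my, ay1, depth + 1)

    xs = np.linspace(x0, x1, coarse)
    ys = np.linspace(y0, y1, coarse)
    for i in range(coarse - 1):
        for j in range(coarse - 1):
            refine(xs[i], xs[i + 1], ys[j], ys[j + 1], 0)

    boundary_points: list[BifurcationPoint] = []
    if sharpen and "d_il4" in axes:
        boundary_points.append(
            locate_transcritical(params_template, schedule_template.tau, policy=policy)
        )
    return RegionMap(
        axes=axes,
        ranges=ranges,
        cells=cells,
        boundary_points=boundary_points,
        refinement_depth=max_depth,
    )


def three_parameter_surfaces(
    params_template: ModelParams,
    box: dict[str, tuple[float, float]] | None = None,
    resolution: int = 60,
) -> dict[str, object]:
    """Analytic bifurcation surfaces over the (m, beta, b) box.

    Returns the transcritical plane (a constant beta = beta_c, independent
    of m and b) and the Hopf surface b(m, beta) sampled on a
    ``resolution`` x ``resolution`` mesh, masked (NaN) where beta <= a or
    where no positive b solves the Hopf condition.
    """
    if box is None:
        box = {"m": (1.0, 200.0), "beta": (0.0, 1.0), "b": (1.0, 300.0)}
    m_lo, m_hi = box["m"]
    be_lo, be_hi = box["beta"]
    b_lo, b_hi = box["b"]
    ms = np.linspace(m_lo, m_hi, resolution)
    betas = np.linspace(max(be_lo, params_template.a * (1.0 + 1e-9)), be_hi, resolution)
    # exclude beta <= a, where no interior state exists
    betas = betas[betas > params_template.a]
    B = np.full((len(ms), len(betas)), np.nan)
    for i, m in enumerate(ms):
        for j, be in enumerate(betas):
            val = hopf_surface_b(m, be, params_template)
            if val is not None and b_lo <= val <= b_hi:
                B[i, j] = val
    return {
        "transcritical_beta": beta_c(params_template),
        "m": ms,
        "beta": betas,
        "hopf_b": B,
    }
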