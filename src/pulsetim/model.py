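"""Core tumor--CD4+ T cell--antitumor cytokine interaction model.

The model tracks three volumes (cm^3): tumor cells ``x``, tumor-specific
CD4+ T cells ``y``, and a Th2-type antitumor cytokine such as IL-4 ``z``.
The tumor grows logistically and is killed by the cytokine through
saturating (Michaelis--Menten) kinetics; T cells proliferate in response
to tumor antigen and secrete the cytokine, again with saturating kinetics:

    dx/dt = r x (1 - x/K) - delta x z / (m + x)
    dy/dt = beta x y / (k + x) - a y + l1(t)
    dz/dt = alpha x y / (b + x) - mu z + l2(t)

``l1`` and ``l2`` are external infusions of T cells and cytokine
(cm^3/day); they are zero for the autonomous (no-treatment) analysis and
Dirac-comb pulses under therapy (see :mod:`pulsetim.impulsive`).

Time is measured in days and every population in cm^3 of volume; no
nondimensionalization is applied, so all thresholds come out in the same
units they are quoted in.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "SystemState",
    "Equilibrium",
    "PRESETS",
    "preset",
    "vector_field",
    "slow_manifold",
    "equilibria",
    "jacobian",
]

_PARAM_FIELDS = ("r", "K", "delta", "m", "beta", "k", "a", "alpha", "b", "mu")


@dataclass(frozen=True)
class ModelParams:
    """The ten positive rate and saturation constants of the model.

    Attributes
    ----------
    r : float
        Intrinsic tumor growth rate (day^-1).
    K : float
        Tumor carrying capacity (cm^3).
    delta : float
        Maximum tumor kill rate by the cytokine (day^-1).
    m : float
        Half-saturation constant of tumor killing (cm^3).
    beta : float
        Maximum CD4+ T cell production rate, i.e. tumor antigenicity
        (day^-1).
    k : float
        Half-saturation constant of T cell production (cm^3).
    a : float
        CD4+ T cell death rate (day^-1).
    alpha : float
        Maximum cytokine production rate (day^-1).
    b : float
        Half-saturation constant of cytokine production (cm^3).
    mu : float
        Cytokine loss rate (day^-1).
    """

    r: float
    K: float
    delta: float
    m: float
    beta: float
    k: float
    a: float
    alpha: float
    b: float
    mu: float

    def __post_init__(self) -> None:
        for name in _PARAM_FIELDS:
            value = getattr(self, name)
            try:
                value = float(value)
            except (TypeError, ValueError):
                raise ValueError(f"parameter {name!r} must be a real number, got {value!r}")
            if not math.isfinite(value) or value <= 0.0:
                raise ValueError(
                    f"parameter {name!r} must be strictly positive and finite, got {value!r}"
                )
            object.__setattr__(self, name, value)

    def replace(self, **changes: float) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in _PARAM_FIELDS}

    @classmethod
    def from_dict(cls, data: dict[str, float]) -> "ModelParams":
        unknown = set(data) - set(_PARAM_FIELDS)
        if unknown:
            raise ValueError(
                f"unknown parameter name(s) {sorted(unknown)}; valid names are {_PARAM_FIELDS}"
            )
        missing = set(_PARAM_FIELDS) - set(data)
        if missing:
            raise ValueError(f"missing parameter(s) {sorted(missing)}")
        return cls(**{name: data[name] for name in _PARAM_FIELDS})


# Published parameter sets.  ``beta`` (tumor antigenicity) is the main
# patient-variability parameter and is supplied by the caller, not the
# preset.  "table2" is the baseline therapy-study set; "section4" is the
# same set with the T cell death rate lowered to 0.02/day, the value used
# for the pulsed-therapy thresholds; "fig2" is the slower-growth set used
# for the no-treatment bifurcation study.
PRESETS: dict[str, dict[str, float]] = {
    "table2": dict(alpha=0.1, a=0.03, b=0.1, delta=0.1, k=10.0, mu=50.0, m=1.0, K=1000.0, r=0.027),
    "section4": dict(alpha=0.1, a=0.02, b=0.1, delta=0.1, k=10.0, mu=50.0, m=1.0, K=1000.0, r=0.027),
    "fig2": dict(alpha=0.01, a=0.03, b=100.0, delta=0.1, k=1000.0, mu=50.0, m=100.0, K=1000.0, r=0.01),
}


def preset(name: str, beta: float, **overrides: float) -> ModelParams:
    """Build a :class:`ModelParams` from a named preset.

    Parameters
    ----------
    name : str
        One of ``"table2"``, ``"section4"``, ``"fig2"``.
    beta : float
        Tumor antigenicity (day^-1); not part of any preset because it is
        the primary patient-to-patient variable.
    **overrides
        Individual parameter overrides applied on top of the preset.
    """
    try:
        base = dict(PRESETS[name])
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    base["beta"] = beta
    base.update(overrides)
    return ModelParams.from_dict(base)


@dataclass(frozen=True)
class SystemState:
    """A point (x, y, z) = (tumor, CD4+ T cells, cytokine), each in cm^3."""

    x: float
    y: float
    z: float

    _NEG_TOL = 1e-9

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            value = float(getattr(self, name))
            if not math.isfinite(value):
                raise ValueError(f"state component {name!r} must be finite, got {value!r}")
            if value < -self._NEG_TOL:
                raise ValueError(f"state component {name!r} must be nonnegative, got {value!r}")
            object.__setattr__(self, name, max(value, 0.0))

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "SystemState":
        x, y, z = arr
        return cls(float(x), float(y), float(z))


@dataclass(frozen=True)
class Equilibrium:
    """An equilibrium of the autonomous system (or a reported absence).

    ``label`` is one of ``E0`` (extinction), ``E1`` (tumor at carrying
    capacity, no immune response), ``E_star`` (interior coexistence
    state) or ``E_bar_star`` (the interior state of the slow-manifold
    reduced system; identical to ``E_star`` in exact arithmetic).
    ``exists`` is False with a ``reason`` when the parameter values do
    not admit the state.
    """

    label: str
    exists: bool
    state: SystemState | None = None
    reason: str = ""


def as_state_array(state) -> np.ndarray:
    """Coerce a SystemState / sequence to a float array of shape (3,)."""
    if isinstance(state, SystemState):
        return state.to_array()
    arr = np.asarray(state, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"state must have exactly three components, got shape {arr.shape}")
    return arr


# ---------------------------------------------------------------------------
# fast internal kernels (no validation) -- used by the integrators
# ---------------------------------------------------------------------------

def _f(s: np.ndarray, p: ModelParams, l1: float = 0.0, l2: float = 0.0) -> np.ndarray:
    x, y, z = s
    dx = p.r * x * (1.0 - x / p.K) - p.delta * x * z / (p.m + x)
    dy = p.beta * x * y / (p.k + x) - p.a * y + l1
    dz = p.alpha * x * y / (p.b + x) - p.mu * z + l2
    return np.array([dx, dy, dz])


def _jac(s: np.ndarray, p: ModelParams) -> np.ndarray:
    x, y, z = s
    mx = p.m + x
    kx = p.k + x
    bx = p.b + x
    return np.array(
        [
            [p.r * (1.0 - 2.0 * x / p.K) - p.delta * z * p.m / (mx * mx), 0.0, -p.delta * x / mx],
            [p.beta * y * p.k / (kx * kx), p.beta * x / kx - p.a, 0.0],
            [p.alpha * y * p.b / (bx * bx), p.alpha * x / bx, -p.mu],
        ]
    )


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def vector_field(state, params: ModelParams, infusion_rates: Sequence[float] = (0.0, 0.0)) -> np.ndarray:
    """Evaluate (dx/dt, dy/dt, dz/dt) at ``state``.

    ``infusion_rates`` = (l1, l2) are constant external infusion rates of
    T cells and cytokine (cm^3/day); both zero for the autonomous system.
    """
    s = as_state_array(state)
    if not np.all(np.isfinite(s)):
        raise ValueError(f"state must be finite, got {s}")
    if np.any(s < -SystemState._NEG_TOL):
        raise ValueError(f"state components must be nonnegative, got {s}")
    l1, l2 = float(infusion_rates[0]), float(infusion_rates[1])
    if l1 < 0.0 or l2 < 0.0:
        raise ValueError("infusion rates must be nonnegative")
    return _f(np.maximum(s, 0.0), params, l1, l2)


def slow_manifold(x: float, y: float, params: ModelParams) -> float:
    """Quasi-steady cytokine level S(x, y) = alpha x y / (mu (b + x)).

    For large cytokine turnover ``mu`` the cytokine relaxes fast and
    trajectories collapse onto the surface z = S(x, y), which justifies
    a two-variable reduction of the model.
    """
    if x < 0.0 or y < 0.0:
        raise ValueError("slow_manifold requires x >= 0 and y >= 0")
    return params.alpha * x * y / (params.mu * (params.b + x))


def jacobian(state, params: ModelParams) -> np.ndarray:
    """Analytic 3x3 Jacobian of the autonomous vector field."""
    s = as_state_array(state)
    if not np.all(np.isfinite(s)):
        raise ValueError(f"state must be finite, got {s}")
    return _jac(s, params)


def _beta_c(p: ModelParams) -> float:
    return p.a * (p.k + p.K) / p.K


def interior_equilibrium_x(params: ModelParams) -> float:
    """Tumor volume of the interior equilibrium, x* = k a / (beta - a).

    Requires ``beta > a``; raises ValueError otherwise.
    """
    if params.beta <= params.a:
        raise ValueError(
            "interior equilibrium requires beta > a "
            f"(beta={params.beta}, a={params.a})"
        )
    return params.k * params.a / (params.beta - params.a)


def equilibria(params: ModelParams) -> list[Equilibrium]:
    """All equilibria of the autonomous system.

    ``E0`` (origin) and ``E1`` (tumor at carrying capacity) exist for every
    parameter set.  The interior state ``E_star`` exists iff the tumor
    antigenicity exceeds the transcritical threshold beta_c = a (k + K)/K,
    in which case its tumor component satisfies 0 < x* < K.  The reduced
    system's interior state ``E_bar_star`` coincides with ``E_star``
    (the slow-manifold reduction is exact at equilibrium) and is reported
    under its own label for use with the 2D stability analysis.
    """
    out = [
        Equilibrium("E0", True, SystemState(0.0, 0.0, 0.0)),
        Equilibrium("E1", True, SystemState(params.K, 0.0, 0.0)),
    ]
    bc = _beta_c(params)
    if params.beta <= params.a:
        reason = (
            f"no interior equilibrium: beta={params.beta} <= a={params.a} "
            "(T cell proliferation cannot offset death)"
        )
        out.append(Equilibrium("E_star", False, reason=reason))
        out.append(Equilibrium("E_bar_star", False, reason=reason))
        return out
    x = params.k * params.a / (params.beta - params.a)
    if params.beta <= bc:
        reason = (
            f"no interior equilibrium: beta={params.beta} <= beta_c={bc} "
            f"(would require tumor volume {x} >= carrying capacity {params.K})"
        )
        out.append(Equilibrium("E_star", False, reason=reason))
        out.append(Equilibrium("E_bar_star", False, reason=reason))
        return out
    z = params.r * (1.0 - x / params.K) * (params.m + x) / params.delta
    y = z * params.mu * (params.b + x) / (params.alpha * x)
    state = SystemState(x, y, z)
    out.append(Equilibrium("E_star", True, state))
    # reduced-system form: y from dx/dt = 0 with z on the slow manifold
    y_bar = (
        params.r * params.mu * (params.m + x) * (params.b + x) * (params.K - x)
        / (params.K * params.alpha * params.delta * x)
    )
    out.append(Equilibrium("E_bar_star", True, SystemState(x, y_bar, slow_manifold(x, y_bar, params))))
    return out


def equilibrium(params: ModelParams, label: str) -> Equilibrium:
    """Return a single labelled equilibrium (see :func:`equilibria`)."""
    for eq in equilibria(params):
        if eq.label == label:
            return eq
    raise ValueError(f"unknown equilibrium label {label!r}")
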