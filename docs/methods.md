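# Methods

## Model

`pulsetim` analyses a three-compartment model of tumor--immune
interaction. The state is a triple of volumes (cm³): tumor cells `x`,
tumor-specific CD4⁺ T cells `y`, and a Th2-type antitumor cytokine
(IL-4) `z`. Time is in days.

    dx/dt = r x (1 − x/K) − δ x z / (m + x)
    dy/dt = β x y / (k + x) − a y + l₁(t)
    dz/dt = α x y / (b + x) − μ z + l₂(t)

The tumor grows logistically (rate `r`, capacity `K`) and is killed by
the cytokine with saturating kinetics (maximum rate `δ`,
half-saturation `m`). T cells proliferate in proportion to tumor
antigen load (maximum rate `β`, the *antigenicity*; half-saturation
`k`) and die at rate `a`. The cytokine is secreted by T cells in the
presence of tumor (rate `α`, half-saturation `b`) and cleared at rate
`μ`. `l₁`, `l₂` are external infusions of T cells and cytokine.

All ten constants are strictly positive. Interaction between T cells
and tumor is indirect: T cells act only through the cytokine, so a
state with `x = 0` keeps `x = 0` forever (the tumor-free plane is
invariant), and the integrator pins it there exactly.

### Parameter presets

Three named presets ship with the package (`pulsetim.preset(name, beta=...)`);
`β` is always supplied by the caller because it is the main
patient-to-patient variable:

| preset | α | a | b | δ | k | μ | m | K | r |
|---|---|---|---|---|---|---|---|---|---|
| `table2` | 0.1 | 0.03 | 0.1 | 0.1 | 10 | 50 | 1 | 1000 | 0.027 |
| `section4` | 0.1 | 0.02 | 0.1 | 0.1 | 10 | 50 | 1 | 1000 | 0.027 |
| `fig2` | 0.01 | 0.03 | 100 | 0.1 | 1000 | 50 | 100 | 1000 | 0.01 |

`section4` differs from `table2` only in the T cell death rate
(a = 0.02/day rather than 0.03/day); it is the set under which the
pulsed-therapy thresholds quoted below (β_c = 0.0202, fold doses 76.2
and ≈32 cm³) are reproduced, and the package's own fold computations
confirm that only a = 0.02 yields those values. Both sets are kept so
either convention can be selected explicitly.

## Autonomous analysis

Equilibria are closed-form. `E0 = (0,0,0)` and `E1 = (K,0,0)` always
exist; the interior state `E* = (x*, y*, z*)` with

    x* = k a / (β − a),
    z* = r (1 − x*/K)(m + x*) / δ,
    y* = z* μ (b + x*) / (α x*)

exists iff `β > β_c = a (k + K)/K` (the transcritical threshold at
which `E1` loses stability), and then `0 < x* < K`. `β ≤ a` and
`β ≤ β_c` are reported as structured absences with a reason string,
never exceptions, because parameter sweeps cross these values
routinely.

### Slow-manifold reduction and the Hopf condition

For large cytokine turnover `μ` the `z` dynamics are fast and
trajectories collapse quickly onto the surface
`S(x, y) = α x y / (μ (b + x))`. Substituting `z = S(x, y)` yields a
planar system in `(x, y)` whose interior equilibrium coincides exactly
with `E*` (the reduction is exact at equilibrium; `equilibria` reports
it as `E_bar_star` and tests assert the coincidence). Its Jacobian has
positive determinant, so stability is decided by the trace, which is
`−(r x/K)` times the bracket

    H(x) = 1 + b (K − x) / (x (b + x)) − (K − x) / (m + x),   x = k a/(β − a).

`H > 0` ⇒ stable; `H = 0` is a Hopf point. `H` is exposed as
`hopf_residual`; root-finding in any parameter (Brent, relative
tolerance ~1e-10) is `locate_hopf_ode`. Solving `H = 0` for `b` gives
the Hopf surface `b(m, β) = x²(K − m − 2x)/(x² + mK)`, clipped to
positive values. The `x² + mK` denominator follows from the algebra of
the trace condition and is verified by substituting the returned `b`
back into `hopf_residual` (residual < 1e-9); for the `fig2` set, where
k = K, the distinction between `mk` and `mK` is immaterial.

With the `fig2` set at m = 100, b = 100 the two Hopf roots in β are
0.1129 and 0.2471; the reduced-system values are used as-is because
μ = 50 makes the reduction tight (the quoted tolerance on these points
is ±5%, far wider than the reduction error).

## Pulsed therapy

Doses `d_cd4`, `d_il4` (cm³) are added instantaneously every `τ` days
(default 7), the first pulse at t = 0. The stroboscopic map `F` sends
a *pre-pulse* state through one pulse and one τ-day flow; its fixed
points are τ-periodic solutions. The pre-pulse section is the
canonical convention throughout (post-pulse values are pre-pulse plus
one dose and are also reported where relevant).

On the tumor-free plane the dynamics are linear, so the tumor-free
fixed point is exact: `y₀ = d_cd4/(e^{aτ} − 1)`,
`z₀ = d_il4/(e^{μτ} − 1)`. Linearizing the tumor direction along this
periodic orbit gives the per-cycle growth factor of an infinitesimal
tumor,

    Λ = exp(r τ − δ d_il4 / (m μ)),

so the tumor-free state is stable iff `d_il4 > r τ μ m / δ`
(94.5 cm³ for the `table2`/`section4` rates at τ = 7). T cell pulses
do not enter Λ: adoptive T cells alone can never stabilize a cleared
tumor in this model.

### Numerics

* **Integration.** `scipy.integrate.solve_ivp` with LSODA and the
  analytic Jacobian; μ = 50 gives a fast cytokine mode, and LSODA
  switches to BDF where needed. Defaults rtol 1e-9, atol 1e-12
  (configurable via `NumericPolicy`); these are deliberately tight
  because bifurcation localization differentiates the flow.
  Integrator undershoot below zero is clipped only within 1e-9;
  anything larger raises, so solver failure is never masked.
* **Monodromy.** Floquet multipliers come from integrating the 3×3
  variational equations alongside the state (a 12-dimensional system);
  the pulse jump is additive, hence has identity Jacobian, and the
  cycle monodromy is the flow's fundamental matrix. Finite differences
  of `F` are used only as a test oracle. At the tumor-free point the
  variational matrix is lower triangular, so the (x,x) entry of the
  monodromy *is* the tumor multiplier; tests confirm it matches Λ to
  1e-6 relative.
* **Fixed points.** Newton iteration on `F(s) − s` with the monodromy
  as Jacobian, scaled residual tolerance 1e-9. Damping is
  positivity-preserving: a strictly positive component may shrink by
  at most 90% per step. This matters: the tumor-free plane is
  invariant, so a Newton step that zeroes `x` silently changes branch
  and can never come back.
* **Attractor classification.** The strobe orbit is iterated; a fixed
  point is declared after 10 consecutive relative steps below 1e-7; a
  bounded, non-convergent orbit whose latest point returns within 5%
  of the orbit diameter to an earlier point is a closed curve (an
  invariant curve of the map / limit cycle of the flow). The runaway
  guard watches the tumor volume against 10·K — the tumor is the only
  component bounded by the carrying capacity; T cells and cytokine
  legitimately exceed K many-fold on large oscillations — plus
  non-finite or absurd (>1e9) values in any component. Default transient 2000 cycles;
  the shipped tests and the acceptance script use 120–600 cycles,
  which the convergence rates of the cases involved make ample — these
  problem sizes are the package's own choice and are stated here so
  reruns can scale them up.
* **Fold location.** The stable small-tumor branch born at a fold is
  *attracting*, which the probe exploits: from a warm seed it iterates
  the map (flowing onto the node if it exists, staying in the right
  Newton basin) and then polishes with Newton, falling back to a fresh
  settle from a small tumor burden (0.1, 0.01, 0). A probe succeeds
  only if Newton converges to a point with `1e-6 < x < K/2` and
  leading multiplier modulus < 1. Bisection on probe success shrinks
  the bracket to 1e-3 of its initial width (≤ 40 iterations); at the
  fold the leading real multiplier crosses +1 and the fixed-point pair
  is born/destroyed. Detecting existence of the *stable* point rather
  than a multiplier sign change avoids tracking through the
  near-singular fold neighbourhood.
* **Region maps.** The two-parameter dose plane is classified on a
  coarse corner grid by a signature combining (i) the closed-form
  tumor-free verdict, (ii) a stable small-tumor branch probe, and
  (iii) a large-tumor branch probe; cells whose corners disagree are
  quadtree-refined to a configurable depth, and undecidable cells are
  labelled `boundary` rather than erroring. This refinement scheme is
  the package's own; any scheme reproducing the same labels would do.
  For the low-antigenicity dose plane it recovers the three-region
  structure: uncontrollable (only the large-tumor state stable),
  bistable (small- and large-tumor states stable), and clearable
  (tumor-free state stable), with the clearable boundary at
  d_il4 = 94.5 independent of d_cd4.
* **Neimark–Sacker detection** (a complex multiplier pair crossing the
  unit circle) is labelled "Hopf of the map" in outputs. The
  fold-on-invariant-curve scenario seen at high antigenicity is
  identified operationally — a fold located on the branch while the
  pre-fold attractor is a closed curve — with no homoclinic-orbit
  computation.

## Determinism

There is no randomness anywhere in the computational path; repeated
runs with the same configuration produce byte-identical outputs. Test
suites seed their auxiliary draws (random parameter sets for property
checks) explicitly.

## What the tests do and do not show

All verification is against the model's own mathematics: closed forms,
independent high-accuracy integrations, finite-difference and spectral
oracles, and substitution identities. The model itself is a coarse
caricature of tumor--immune biology — no CD8⁺/Treg compartments, no
spatial structure, no pharmacokinetics of the injected agents (pulses
are instantaneous), no stochastic extinction at small tumor volumes
(volumes below one cell are meaningful in the ODE). Passing tests
therefore validate the implementation of the model, not the model's
clinical accuracy. Known numerical limitations: fold location assumes
the born branch is attracting (true in the regimes studied here);
closed-curve detection is recurrence-based and will report
`unresolved` for strongly quasiperiodic orbits with slow returns at
the default window.
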