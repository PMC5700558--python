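"""Floquet machinery, bifurcation locators, sweeps, and region maps."""
import numpy as np
import pytest
from scipy.optimize import brentq

from pulsetim import (
    DoseSchedule,
    NumericPolicy,
    equilibrium,
    jacobian,
    preset,
    tumor_free_multiplier,
    tumor_free_pulsed_fixed_point,
)
from pulsetim.bifurcation import (
    BracketError,
    FoldPolicy,
    locate_hopf_ode,
    locate_transcritical,
    map_with_monodromy,
    region_map_two_parameters,
    solve_map_fixed_point,
    sweep_one_parameter,
    three_parameter_surfaces,
    tumor_free_multiplier_numeric,
)
from pulsetim.stability import beta_c, hopf_residual


def _match_spectra(mults, targets, rel=1e-6, floor=1e-10):
    """Each target eigenvalue has a multiplier within rel (or floor, if tiny)."""
    mults = list(mults)
    for w in targets:
        dists = [abs(m - w) for m in mults]
        i = int(np.argmin(dists))
        assert dists[i] <= max(rel * abs(w), floor)
        mults.pop(i)


class TestFloquetMachinery:
    def test_spectral_mapping_at_interior_equilibrium(self, table2):
        # with zero doses the strobe map is the time-tau flow, so its
        # multipliers are exp(tau * lambda_i) of the ODE Jacobian
        s = equilibrium(table2, "E_star").state.to_array()
        _, Phi = map_with_monodromy(s, table2, DoseSchedule(0, 0, 7))
        lam = np.linalg.eigvals(jacobian(s, table2))
        _match_spectra(np.linalg.eigvals(Phi), np.exp(7 * lam))

    def test_spectral_mapping_on_random_sets(self, rng):
        for _ in range(5):
            p = preset(
                "table2",
                beta=rng.uniform(0.05, 0.3),
                r=rng.uniform(0.01, 0.05),
                mu=rng.uniform(5, 30),
            )
            eq = equilibrium(p, "E_star")
            assert eq.exists
            s = eq.state.to_array()
            tau = rng.uniform(1.0, 4.0)
            _, Phi = map_with_monodromy(s, p, DoseSchedule(0, 0, tau))
            lam = np.linalg.eigvals(jacobian(s, p))
            _match_spectra(np.linalg.eigvals(Phi), np.exp(tau * lam))

    def test_tumor_direction_multiplier_matches_closed_form(self, table2, rng):
        for _ in range(20):
            sch = DoseSchedule(
                d_cd4=rng.uniform(0, 80), d_il4=rng.uniform(0, 150), tau=rng.uniform(2, 10)
            )
            p = table2.replace(r=rng.uniform(0.01, 0.06), delta=rng.uniform(0.05, 0.3))
            numeric = tumor_free_multiplier_numeric(sch, p)
            closed = tumor_free_multiplier(sch, p)
            assert numeric == pytest.approx(closed, rel=1e-6)

    def test_t_cell_direction_multiplier_is_pure_decay(self, section4):
        sch = DoseSchedule(d_cd4=20, d_il4=40, tau=7)
        fp = tumor_free_pulsed_fixed_point(sch, section4)
        _, Phi = map_with_monodromy(fp.pre_pulse.to_array(), section4, sch)
        mults = np.linalg.eigvals(Phi)
        target = np.exp(-section4.a * 7)
        assert min(abs(m - target) for m in mults) < 1e-8


class TestFixedPointSolver:
    def test_recovers_interior_equilibrium_with_zero_doses(self, table2):
        s = equilibrium(table2, "E_star").state.to_array()
        fp = solve_map_fixed_point(s * 1.02, table2, DoseSchedule(0, 0, 7))
        assert fp.converged and fp.residual < 1e-9
        assert np.max(np.abs(fp.state - s) / np.maximum(s, 1.0)) < 1e-7

    def test_recovers_tumor_free_fixed_point(self, section4):
        sch = DoseSchedule(d_cd4=20, d_il4=30, tau=7)
        closed = tumor_free_pulsed_fixed_point(sch, section4)
        guess = closed.pre_pulse.to_array() * [0.0, 1.1, 1.3]
        fp = solve_map_fixed_point(guess, section4, sch)
        assert fp.converged and fp.branch_label == "tumor_free"
        assert fp.state[1] == pytest.approx(closed.pre_pulse.y, rel=1e-8)
        tumor_mult = max(m.real for m in fp.multipliers if abs(m.imag) < 1e-12)
        assert tumor_mult == pytest.approx(tumor_free_multiplier(sch, section4), rel=1e-6)


class TestTranscritical:
    def test_closed_form_boundary(self, table2):
        bp = locate_transcritical(table2, 7.0)
        assert bp.kind == "transcritical"
        assert bp.parameter_value == pytest.approx(94.5, rel=1e-12)

    def test_numeric_monodromy_root_agrees(self, table2):
        d_star = locate_transcritical(table2, 7.0).parameter_value

        def log_mult(d):
            return np.log(tumor_free_multiplier_numeric(DoseSchedule(0, d, 7), table2))

        d_num = brentq(log_mult, 60.0, 130.0, xtol=1e-8, rtol=1e-12)
        assert d_num == pytest.approx(d_star, rel=1e-6)

    def test_boundary_independent_of_t_cell_dose(self, table2):
        for d_cd4 in (0.0, 20.0, 80.0):
            mult = tumor_free_multiplier(DoseSchedule(d_cd4, 94.5, 7), table2)
            assert mult == pytest.approx(1.0, abs=1e-12)


class TestHopfLocation:
    def test_both_reported_hopf_points(self, fig2):
        p = fig2.replace(m=100.0, b=100.0)
        lo = locate_hopf_ode(p, "beta", (0.05, 0.15))
        hi = locate_hopf_ode(p, "beta", (0.15, 0.35))
        assert lo.parameter_value == pytest.approx(0.113, rel=0.05)
        assert hi.parameter_value == pytest.approx(0.247, rel=0.05)
        for bp in (lo, hi):
            assert abs(hopf_residual(bp.witness)) < 1e-9

    def test_bracket_without_sign_change_rejected(self, fig2):
        with pytest.raises(BracketError):
            locate_hopf_ode(fig2.replace(m=100.0, b=100.0), "beta", (0.13, 0.14))


class TestFold:
    def test_bracket_without_fold_rejected(self):
        p = preset("section4", beta=0.015)
        with pytest.raises(BracketError):
            from pulsetim.bifurcation import locate_fold

            locate_fold(
                p,
                DoseSchedule(0, 0, 7),
                "d_cd4",
                (2.0, 10.0),
                fold_policy=FoldPolicy(settle_cycles=120),
            )


class TestSweepAndRegions:
    def test_empty_grid_gives_empty_result(self, section4):
        records, brackets = sweep_one_parameter(
            section4, DoseSchedule(0, 0, 7), "d_il4", [], [(0.1, 0.01, 0.0)]
        )
        assert records == [] and brackets == []

    def test_low_antigenicity_attractor_is_carrying_capacity(self):
        fast = NumericPolicy(transient_cycles=400, curve_samples=40)
        p = preset("fig2", beta=0.05, m=100.0, b=100.0)
        records, _ = sweep_one_parameter(
            p, DoseSchedule(0, 0, 7), "beta", [0.04, 0.05], [(0.5, 0.01, 0.0)],
            policy=fast,
        )
        for r in records:  # beta < beta_c = 0.06: no immune control
            assert r.kind == "fixed_point"
            assert r.representative[0] == pytest.approx(p.K, rel=1e-3)

    def test_three_region_structure_low_antigenicity(self):
        # dose plane for weak antigenicity: uncontrollable / bistable /
        # clearable regions, separated by fold and transcritical boundaries
        p = preset("section4", beta=0.015)
        rmap = region_map_two_parameters(
            p,
            DoseSchedule(0, 0, 7),
            axes=("d_cd4", "d_il4"),
            ranges=((5.0, 60.0), (5.0, 200.0)),
            coarse=3,
            max_depth=2,
            fold_policy=FoldPolicy(settle_cycles=120, warm_cycles=40),
        )
        labels = rmap.labels()
        assert "E0-unstable+large-branch" in labels          # uncontrollable
        assert "E0-unstable+small-branch+large-branch" in labels  # bistable
        assert any(lab.startswith("E0-stable") for lab in labels)  # clearable

    def test_transcritical_boundary_in_sharpened_map(self, table2):
        bp = locate_transcritical(table2, 7.0)
        assert bp.parameter_value == pytest.approx(94.5, rel=1e-12)


class TestSurfaces:
    def test_transcritical_plane_constant_and_correct(self, fig2):
        surf = three_parameter_surfaces(fig2, resolution=12)
        assert surf["transcritical_beta"] == pytest.approx(beta_c(fig2), rel=1e-14)

    def test_mesh_points_satisfy_hopf_condition(self, fig2):
        surf = three_parameter_surfaces(fig2, resolution=12)
        B = surf["hopf_b"]
        count = 0
        for i, m in enumerate(surf["m"]):
            for j, be in enumerate(surf["beta"]):
                if np.isfinite(B[i, j]):
                    count += 1
                    p = fig2.replace(m=m, beta=be, b=B[i, j])
                    assert abs(hopf_residual(p)) < 1e-9
        assert count > 0

    def test_mesh_excludes_beta_at_or_below_death_rate(self, fig2):
        surf = three_parameter_surfaces(fig2, resolution=12)
        assert np.all(surf["beta"] > fig2.a)
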