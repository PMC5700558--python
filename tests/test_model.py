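"""Vector field, equilibria, slow manifold, and Jacobian of the core model."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulsetim import (
    ModelParams,
    SystemState,
    equilibria,
    equilibrium,
    jacobian,
    preset,
    slow_manifold,
    vector_field,
)
from pulsetim.stability import beta_c


def _random_params(rng):
    return ModelParams(
        r=rng.uniform(0.005, 0.1),
        K=rng.uniform(100, 2000),
        delta=rng.uniform(0.01, 1.0),
        m=rng.uniform(0.5, 200),
        beta=rng.uniform(0.005, 1.0),
        k=rng.uniform(1, 2000),
        a=rng.uniform(0.01, 0.2),
        alpha=rng.uniform(0.005, 0.5),
        b=rng.uniform(0.05, 300),
        mu=rng.uniform(1, 80),
    )


class TestVectorField:
    def test_origin_is_equilibrium(self, table2):
        assert np.allclose(vector_field((0, 0, 0), table2), 0.0)

    def test_carrying_capacity_state_is_equilibrium(self, table2):
        assert np.allclose(vector_field((table2.K, 0, 0), table2), 0.0)

    def test_hand_evaluated_rates(self, table2):
        # r x (1 - x/K) - delta x z/(m+x) etc. at (1, 1, 1)
        dx, dy, dz = vector_field((1.0, 1.0, 1.0), table2)
        assert dx == pytest.approx(0.027 * (1 - 1e-3) - 0.1 / 2, abs=1e-15)
        assert dy == pytest.approx(0.1 / 11 - 0.03, abs=1e-15)
        assert dz == pytest.approx(0.1 / 1.1 - 50.0, abs=1e-12)

    def test_tumor_free_plane_invariance(self, table2, rng):
        for _ in range(50):
            y, z = rng.uniform(0, 1000, 2)
            assert vector_field((0.0, y, z), table2)[0] == 0.0

    def test_infusion_rates_enter_additively(self, table2):
        base = vector_field((1, 1, 1), table2)
        dosed = vector_field((1, 1, 1), table2, infusion_rates=(2.0, 3.0))
        assert dosed[0] == base[0]
        assert dosed[1] == pytest.approx(base[1] + 2.0)
        assert dosed[2] == pytest.approx(base[2] + 3.0)

    def test_invalid_states_rejected(self, table2):
        with pytest.raises(ValueError):
            vector_field((np.nan, 0, 0), table2)
        with pytest.raises(ValueError):
            vector_field((-1.0, 0, 0), table2)
        with pytest.raises(ValueError):
            vector_field((1, 1, 1), table2, infusion_rates=(-1.0, 0.0))


class TestSlowManifold:
    def test_vanishes_without_tumor(self, table2):
        assert slow_manifold(0.0, 123.0, table2) == 0.0

    def test_hand_evaluated_value(self, table2):
        # alpha x y / (mu (b + x)) = 0.1*1*50 / (50*1.1)
        assert slow_manifold(1.0, 50.0, table2) == pytest.approx(1 / 11, rel=1e-14)

    def test_equilibrium_lies_on_manifold(self, table2):
        st_ = equilibrium(table2, "E_star").state
        assert st_.z == pytest.approx(slow_manifold(st_.x, st_.y, table2), rel=1e-12)


class TestEquilibria:
    def test_boundary_states_always_exist(self, rng):
        for _ in range(30):
            p = _random_params(rng)
            eqs = {e.label: e for e in equilibria(p)}
            assert eqs["E0"].exists and eqs["E0"].state.to_array().tolist() == [0, 0, 0]
            assert eqs["E1"].exists and eqs["E1"].state.x == p.K

    def test_interior_closed_form(self, table2):
        e = equilibrium(table2, "E_star")
        assert e.exists
        assert e.state.x == pytest.approx(10 * 0.03 / 0.07, rel=1e-14)
        assert e.state.z == pytest.approx(0.027 * (1 - 0.0042857142857) * (1 + 30 / 7) / 0.1, rel=1e-10)
        assert e.state.y == pytest.approx(727.0919081632651, rel=1e-10)

    def test_interior_residual_below_tolerance(self, table2, fig2):
        for p in (table2, fig2):
            e = equilibrium(p, "E_star")
            assert np.max(np.abs(vector_field(e.state, p))) < 1e-9

    def test_absent_when_beta_at_or_below_death_rate(self, table2):
        for beta in (0.03, 0.02):
            e = equilibrium(table2.replace(beta=beta), "E_star")
            assert not e.exists and "beta" in e.reason

    def test_absent_between_death_rate_and_threshold(self, table2):
        bc = beta_c(table2)
        p = table2.replace(beta=0.5 * (table2.a + bc))
        e = equilibrium(p, "E_star")
        assert not e.exists and "carrying capacity" in e.reason

    def test_interior_tumor_below_carrying_capacity(self, rng):
        count = 0
        while count < 1000:
            p = _random_params(rng)
            if p.beta <= beta_c(p):
                continue
            count += 1
            e = equilibrium(p, "E_star")
            assert e.exists
            assert 0 < e.state.x < p.K

    def test_reduced_interior_state_matches_full(self, rng):
        for _ in range(200):
            p = _random_params(rng)
            if p.beta <= beta_c(p):
                continue
            eqs = {e.label: e for e in equilibria(p)}
            full, red = eqs["E_star"].state, eqs["E_bar_star"].state
            assert red.x == full.x  # both are k a/(beta - a), bitwise
            assert red.y == pytest.approx(full.y, rel=1e-12)


class TestJacobian:
    def test_linearization_at_origin(self, table2):
        J = jacobian((0, 0, 0), table2)
        assert J[0, 0] == table2.r
        assert J[1, 1] == -table2.a
        assert J[2, 2] == -table2.mu

    def test_transcritical_entry_at_carrying_capacity(self, table2):
        p = table2.replace(beta=beta_c(table2))
        J = jacobian((p.K, 0, 0), p)
        assert J[1, 1] == pytest.approx(0.0, abs=1e-15)

    def test_matches_finite_differences(self, rng):
        for _ in range(100):
            p = _random_params(rng)
            s = rng.uniform(0.1, 500, 3)
            J = jacobian(s, p)
            Jfd = np.empty((3, 3))
            for j in range(3):
                h = 1e-6 * max(1.0, abs(s[j]))
                sp, sm = s.copy(), s.copy()
                sp[j] += h
                sm[j] -= h
                Jfd[:, j] = (vector_field(sp, p) - vector_field(sm, p)) / (2 * h)
            scale = np.maximum(np.abs(J), 1.0)
            assert np.max(np.abs(J - Jfd) / scale) < 1e-5


class TestParamsAndState:
    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(ValueError, match="delta"):
            preset("table2", beta=0.1, delta=-0.1)
        with pytest.raises(ValueError, match="mu"):
            preset("table2", beta=0.1, mu=0.0)

    def test_unknown_parameter_name_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ModelParams.from_dict({"r": 1.0, "bogus": 2.0})

    def test_preset_values(self):
        t2 = preset("table2", beta=0.1)
        assert (t2.alpha, t2.a, t2.b, t2.delta, t2.k, t2.mu, t2.m, t2.K, t2.r) == (
            0.1, 0.03, 0.1, 0.1, 10.0, 50.0, 1.0, 1000.0, 0.027,
        )
        f2 = preset("fig2", beta=0.1)
        assert (f2.alpha, f2.a, f2.b, f2.delta, f2.k, f2.mu, f2.m, f2.K, f2.r) == (
            0.01, 0.03, 100.0, 0.1, 1000.0, 50.0, 100.0, 1000.0, 0.01,
        )
        assert preset("section4", beta=0.1).a == 0.02

    def test_state_validation(self):
        with pytest.raises(ValueError):
            SystemState(-1.0, 0.0, 0.0)
        s = SystemState(-1e-12, 2.0, 3.0)  # integrator-level undershoot is clipped
        assert s.x == 0.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    y=st.floats(0, 1e4, allow_nan=False),
    z=st.floats(0, 1e4, allow_nan=False),
    beta=st.floats(0.001, 1.0),
)
def test_tumor_free_plane_invariant_for_any_antigenicity(y, z, beta):
    p = preset("table2", beta=beta)
    assert vector_field((0.0, y, z), p)[0] == 0.0
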