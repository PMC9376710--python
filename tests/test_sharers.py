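"""Resource sharers: ODE/DDE composition, coercion, simulation."""

import numpy as np
import pytest

from opetri import fixtures as fx
from opetri.mass_action import petri_to_sharer
from opetri.open_net import oapply
from opetri.sharers import (
    DelaySharer,
    ResourceSharer,
    RossMacdonaldParams,
    build_sharer,
    ode_to_dde,
    sharer_oapply,
    simulate_sharer,
)
from opetri.uwd import UWD, Port

ROSS_P = dict(a=1.0, b=1.0, c=1.0, g=1.0, r=1.0, H=10.0, V=100.0)


def ross_reference(u, p=ROSS_P):
    """The composite host/vector equations, written out by hand:
    dIH/dt = a*b*(IV/H)*(H-IH) - r*IH,  dIV/dt = a*c*(IH/H)*(V-IV) - g*IV."""
    ih, iv = u
    return np.array(
        [
            p["a"] * p["b"] * (iv / p["H"]) * (p["H"] - ih) - p["r"] * ih,
            p["a"] * p["c"] * (ih / p["H"]) * (p["V"] - iv) - p["g"] * iv,
        ]
    )


class TestSharerOapply:
    def test_ross_macdonald_hand_value(self):
        rm = fx.ross_macdonald_ode()
        du = rm.field(0.0, np.array([1.0, 5.0]), ROSS_P)
        np.testing.assert_allclose(du, [3.5, 4.5], atol=1e-15)

    def test_ross_macdonald_random_states(self, rng):
        rm = fx.ross_macdonald_ode()
        for _ in range(100):
            u = rng.random(2) * np.array([10.0, 100.0])
            np.testing.assert_allclose(
                rm.field(0.0, u, ROSS_P), ross_reference(u), atol=1e-12
            )

    def test_single_box_identity_is_unit(self, rng):
        comp = fx.ross_macdonald_ode()
        d = UWD(["box"], [], ["dummy"], [])  # no ports: nothing identified
        d = UWD(["box"], [], [], [])
        composite = sharer_oapply(d, [ResourceSharer(comp.state_labels, [], {}, comp.field)])
        for _ in range(10):
            u = rng.random(2)
            np.testing.assert_array_equal(
                composite.field(0.0, u, ROSS_P), comp.field(0.0, u, ROSS_P)
            )

    def test_box_permutation_invariance(self, rng):
        from opetri.sharers import _ross_bloodmeal, _ross_host, _ross_vector

        d1 = fx.uwd_fig3a()
        # permute boxes: bloodmeal, host, vector
        d2 = UWD(
            ["bloodmeal", "host", "vector"],
            [Port(0, 0), Port(0, 1), Port(1, 0), Port(2, 1)],
            ["IH", "IV"],
            [],
        )
        s1 = sharer_oapply(d1, [_ross_host(), _ross_vector(), _ross_bloodmeal()])
        s2 = sharer_oapply(d2, [_ross_bloodmeal(), _ross_host(), _ross_vector()])
        assert s1.state_labels == s2.state_labels  # junction order fixes states
        for _ in range(20):
            u = rng.random(2)
            np.testing.assert_allclose(
                s1.field(0.0, u, ROSS_P), s2.field(0.0, u, ROSS_P), atol=1e-15
            )

    def test_parameter_collision_detected(self):
        a = ResourceSharer(["x"], [0], {"k": 1.0}, lambda t, u, p: -u)
        b = ResourceSharer(["y"], [0], {"k": 2.0}, lambda t, u, p: -u)
        d = UWD(["a", "b"], [Port(0, 0), Port(1, 0)], ["x"], [])
        with pytest.raises(ValueError, match="conflicting"):
            sharer_oapply(d, [a, b])

    def test_mixed_ode_dde_composite_is_dde(self):
        rm = fx.ross_macdonald_dde(tau=0.5)
        assert isinstance(rm, DelaySharer)
        assert rm.delays == [0.5]


class TestCoercion:
    def test_field_unchanged_by_coercion(self, rng):
        s = fx.ross_macdonald_ode()
        dde = ode_to_dde(s)
        assert dde.delays == []
        for _ in range(20):
            u = rng.random(2)
            np.testing.assert_array_equal(
                dde.field(0.0, u, ROSS_P, []), s.field(0.0, u, ROSS_P)
            )

    def test_coerce_then_compose_equals_compose_then_coerce(self, rng):
        from opetri.sharers import _ross_bloodmeal, _ross_host, _ross_vector

        d = fx.uwd_fig3a()
        comps = [_ross_host(), _ross_vector(), _ross_bloodmeal()]
        a = ode_to_dde(sharer_oapply(d, comps))
        b = sharer_oapply(d, [ode_to_dde(c) for c in comps])
        for _ in range(20):
            u = rng.random(2)
            np.testing.assert_allclose(
                a.field(0.0, u, ROSS_P, []), b.field(0.0, u, ROSS_P, []), atol=1e-12
            )


class TestSimulate:
    def test_unit_delay_negative_feedback_closed_form(self):
        # du/dt = -u(t-1), u == 1 on [-1, 0]: solution 1 - t on [0, 1]
        s = DelaySharer(["u"], [0], {}, lambda t, u, p, h: -h[0], delays=[1.0])
        traj = simulate_sharer(s, {}, np.array([1.0]), (0.0, 1.0), n_points=101)
        assert abs(traj.states[-1, 0]) < 1e-6
        np.testing.assert_allclose(traj.states[:, 0], 1 - traj.times, atol=1e-6)

    def test_sharer_matches_mass_action_integration(self, sir_net):
        from opetri.mass_action import RateAssignment, simulate_ode
        from opetri.open_net import make_open

        beta = np.array([0.3, 0.1])
        u0 = np.array([0.99, 0.01, 0.0])
        direct = simulate_ode(sir_net, RateAssignment(beta, u0), (0, 40), 81)
        sharer = petri_to_sharer(make_open(sir_net, []), beta)
        via_sharer = simulate_sharer(sharer, {}, u0, (0, 40), 81)
        np.testing.assert_allclose(direct.states, via_sharer.states, atol=1e-9)

    def test_zero_field_is_constant(self):
        s = ResourceSharer(["x", "y"], [], {}, lambda t, u, p: np.zeros(2))
        traj = simulate_sharer(s, {}, np.array([1.0, 2.0]), (0, 3), 31)
        np.testing.assert_array_equal(traj.states, np.tile([1.0, 2.0], (31, 1)))

    def test_missing_history_length_raises(self):
        s = DelaySharer(["u"], [0], {}, lambda t, u, p, h: -h[0], delays=[1.0])
        with pytest.raises(ValueError):
            simulate_sharer(s, {}, np.array([1.0, 2.0]), (0, 1))

    def test_dde_composite_converges_to_ode_composite_as_delay_vanishes(self):
        # prevalences on the unit scale (H = V = 1) so the sup-norm bound
        # is scale-free
        p = dict(a=1.0, b=1.0, c=1.0, g=1.0, r=1.0, H=1.0, V=1.0)
        u0 = np.array([0.1, 0.5])
        ode = simulate_sharer(fx.ross_macdonald_ode(), p, u0, (0, 0.5), 51)
        dde = simulate_sharer(fx.ross_macdonald_dde(tau=1e-4), p, u0, (0, 0.5), 51)
        assert np.max(np.abs(ode.states - dde.states)) < 1e-3

    def test_zero_effective_delay_dde_reproduces_ode(self):
        s = fx.ross_macdonald_ode()
        dde = ode_to_dde(s)
        u0 = np.array([1.0, 5.0])
        a = simulate_sharer(s, ROSS_P, u0, (0, 2), 51)
        b = simulate_sharer(dde, ROSS_P, u0, (0, 2), 51)
        np.testing.assert_allclose(a.states, b.states, atol=1e-8)


class TestFunctoriality:
    def test_mass_action_commutes_with_composition(self, sviivr, rng):
        """Reinterpretation then composition equals composition then
        reinterpretation: the two routes to the vaccination model's ODE."""
        d, comps = sviivr
        betas = [
            np.array([0.3, 0.1]),
            np.array([0.05, 0.08]),
            np.array([0.02, 0.1, 0.03]),
        ]
        route1 = petri_to_sharer(oapply(d, comps), np.concatenate(betas))
        route2 = sharer_oapply(
            d, [petri_to_sharer(c, b) for c, b in zip(comps, betas)]
        )
        assert route1.state_labels == route2.state_labels
        for _ in range(100):
            u = rng.random(5)
            np.testing.assert_allclose(
                route1.field(0.0, u, {}), route2.field(0.0, u, {}), atol=1e-12
            )


class TestRegistry:
    def test_params_dataclass_validation(self):
        with pytest.raises(ValueError):
            RossMacdonaldParams(a=1, b=1, c=1, H=0, V=1, r=1, g=1)
        p = RossMacdonaldParams(a=0.3, b=0.5, c=0.5, H=100, V=1000, r=0.1, g=0.2)
        assert p.as_dict()["H"] == 100

    def test_build_sharer_from_descriptor(self):
        s = build_sharer({"schema": "sharer-v1", "field": "ross_host", "params": {"r": 0.1}})
        np.testing.assert_allclose(s.field(0.0, np.array([2.0]), s.params), [-0.2])

    def test_unknown_field_id(self):
        with pytest.raises(KeyError, match="unknown field id"):
            build_sharer({"field": "nope"})
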