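"""Typed Petri nets: type checking, typed composition, pullback stratification."""

import numpy as np
import pytest
from oracles import oracle_pullback_counts

from opetri import fixtures as fx
from opetri.fixtures import make_typing, net_from_reactions
from opetri.mass_action import RateAssignment, simulate_ode
from opetri.open_net import open_by_labels
from opetri.petri import (
    PetriMorphism,
    check_morphism,
    find_morphisms,
    petri_isomorphic,
)
from opetri.typed import (
    TypedPetriNet,
    check_typing,
    stratify,
    typed_oapply,
    untypable_transitions,
)
from opetri.uwd import UWD, Port


class TestCheckTyping:
    def test_canonical_sir_typing_valid(self):
        ok, v = check_typing(fx.sir_typed())
        assert ok and v == []

    def test_interaction_with_one_input_is_an_arity_violation(self, p_inf):
        net = net_from_reactions(["a"], [("lonely", ["a"], ["a", "a"])])
        typing = PetriMorphism((0,), (p_inf.transition_index("interaction"),), (0,), (0, 1))
        ok, v = check_typing(TypedPetriNet(net, p_inf, typing))
        assert not ok
        assert any("arity" in x for x in v)

    def test_forbidden_net_admits_no_typing(self):
        net, pvb = fx.vector_sis(), fx.p_vector_borne()
        assert find_morphisms(net, pvb) == []
        bad = untypable_transitions(net, pvb, fx.vector_sis_species_typing())
        labels = {net.transitions[t].label for t in bad}
        assert labels == {"become_vector", "vector_to_vector"}

    def test_typeable_subnet_recovers_typings(self):
        # dropping the two forbidden transitions leaves a well-typed net
        pvb = fx.p_vector_borne()
        net = net_from_reactions(
            ["SH", "IH", "SV", "IV"],
            [
                ("infect_host", ["IV", "SH"], ["IV", "IH"]),
                ("recover_host", ["IH"], ["SH"]),
                ("infect_vector", ["IH", "SV"], ["IH", "IV"]),
                ("recover_vector", ["IV"], ["SV"]),
            ],
        )
        constrained = find_morphisms(
            net, pvb, species_map_constraints=fx.vector_sis_species_typing()
        )
        assert len(constrained) > 0


class TestTypedOapply:
    def _host_component(self):
        pvb = fx.p_vector_borne()
        net = net_from_reactions(
            ["SH", "IH"],
            [
                ("infection", ["IH", "SH"], ["IH", "IH"]),
                ("recovery", ["IH"], ["SH"]),
            ],
        )
        # infection is host-to-host: not typable by the vector-borne system,
        # so use the SIS pattern with the interaction via a vector instead
        net = net_from_reactions(["SH", "IH"], [("recovery", ["IH"], ["SH"])])
        typing = make_typing(
            net, pvb, {"SH": "host", "IH": "host"}, {"recovery": "host_disease"}
        )
        return open_by_labels(net, ["IH"]), typing

    def _vector_component(self):
        pvb = fx.p_vector_borne()
        net = net_from_reactions(["SV", "IV"], [("death", ["IV"], ["SV"])])
        typing = make_typing(
            net, pvb, {"SV": "vector", "IV": "vector"}, {"death": "vector_disease"}
        )
        return open_by_labels(net, ["IV"]), typing

    def test_same_type_gluing_succeeds(self):
        pvb = fx.p_vector_borne()
        d = UWD(["a", "b"], [Port(0, 0), Port(1, 0)], ["IH"], [])
        tp = typed_oapply(d, [self._host_component()] * 2, pvb)
        assert check_typing(tp)[0]
        assert tp.net.n_species == 3 and tp.net.n_transitions == 2

    def test_host_vector_junction_clash_raises(self):
        pvb = fx.p_vector_borne()
        d = UWD(["a", "b"], [Port(0, 0), Port(1, 0)], ["shared"], [])
        with pytest.raises(ValueError, match="type clash"):
            typed_oapply(d, [self._host_component(), self._vector_component()], pvb)

    def test_forgetful_consistency_with_untyped_oapply(self):
        from opetri.open_net import oapply

        pvb = fx.p_vector_borne()
        d = UWD(["a", "b"], [Port(0, 0), Port(1, 0)], ["IH"], [])
        comps = [self._host_component(), self._host_component()]
        typed = typed_oapply(d, comps, pvb)
        untyped = oapply(d, [c for c, _ in comps])
        assert typed.net.species == untyped.net.species
        assert [t.label for t in typed.net.transitions] == [
            t.label for t in untyped.net.transitions
        ]


class TestStratify:
    def test_sir_by_quarantine_counts_and_projections(self):
        disease, scheme = fx.sir_typed(), fx.quarantine()
        result, p1, p2 = stratify(disease, scheme)
        assert result.net.n_species == 6
        assert result.net.n_transitions == 9
        ns, nt, ni, no = oracle_pullback_counts(disease, scheme)
        assert (result.net.n_species, result.net.n_transitions) == (ns, nt)
        assert (len(result.net.input_arcs), len(result.net.output_arcs)) == (ni, no)
        assert check_morphism(p1, result.net, disease.net) == (True, [])
        assert check_morphism(p2, result.net, scheme.net) == (True, [])
        assert check_typing(result)[0]

    def test_infection_only_among_non_quarantining(self):
        result, _, _ = stratify(fx.sir_typed(), fx.quarantine())
        interaction_labels = [
            t.label for t in result.net.transitions if "infection" in t.label
        ]
        assert interaction_labels == ["infection_contact"]
        t = result.net.transition_index("infection_contact")
        species = {result.net.species[s] for s in result.net.inputs(t)}
        assert species == {"S_notQ", "I_notQ"}

    def test_identity_stratification_is_unit(self, p_inf):
        disease = fx.sir_typed()
        identity_scheme = TypedPetriNet(p_inf, p_inf, PetriMorphism.identity(p_inf))
        result, _, _ = stratify(disease, identity_scheme)
        assert petri_isomorphic(result.net, disease.net)

    def test_sis_by_flux_counts(self):
        result, p1, p2 = stratify(fx.sis_typed(), fx.flux(2))
        assert result.net.n_species == 4
        assert result.net.n_transitions == 8
        assert oracle_pullback_counts(fx.sis_typed(), fx.flux(2))[:2] == (4, 8)

    def test_commutative_up_to_isomorphism(self):
        pairs = [
            (fx.sir_typed(), fx.quarantine()),
            (fx.sis_typed(), fx.flux(2)),
            (fx.sis_typed(), fx.age()),
        ]
        for a, b in pairs:
            ab, _, _ = stratify(a, b)
            ba, _, _ = stratify(b, a)
            assert petri_isomorphic(ab.net, ba.net)

    def test_associative_up_to_isomorphism(self):
        a, b, c = fx.sis_typed(), fx.quarantine(), fx.flux(2)
        left, _, _ = stratify(stratify(a, b)[0], c)
        right, _, _ = stratify(a, stratify(b, c)[0])
        assert petri_isomorphic(left.net, right.net)

    def test_mismatched_type_systems_rejected(self):
        pvb = fx.p_vector_borne()
        other = TypedPetriNet(pvb, pvb, PetriMorphism.identity(pvb))
        with pytest.raises(ValueError, match="same type system"):
            stratify(fx.sir_typed(), other)

    def test_place_count_bounded_by_product(self):
        for a, b in [
            (fx.sir_typed(), fx.quarantine()),
            (fx.sis_typed(), fx.flux(2)),
        ]:
            result, _, _ = stratify(a, b)
            assert result.net.n_species <= a.net.n_species * b.net.n_species
            # the infectious-disease type system has one place type, so the
            # bound is attained
            assert result.net.n_species == a.net.n_species * b.net.n_species

    def test_universal_property_on_small_instance(self, p_inf):
        """Any cone over the two factors (commuting over the type system)
        factors uniquely through the pullback."""
        a, b = fx.sis_typed(), fx.quarantine()
        pb, p1, p2 = stratify(a, b)
        # cone apex: any typed net with morphisms into both factors that
        # agree over the type system; enumerate cones from a small apex
        apex = net_from_reactions(["x", "y"], [("d", ["x"], ["y"])])
        into_a = find_morphisms(apex, a.net)
        into_b = find_morphisms(apex, b.net)
        into_pb = find_morphisms(apex, pb.net)
        checked = 0
        for f in into_a:
            for g in into_b:
                if f.compose(a.typing) != g.compose(b.typing):
                    continue
                mediators = [
                    h for h in into_pb if h.compose(p1) == f and h.compose(p2) == g
                ]
                assert len(mediators) == 1
                checked += 1
        assert checked > 0

    def test_stratified_mass_action_conserves_population(self):
        result, _, _ = stratify(fx.sir_typed(), fx.quarantine())
        net = result.net
        ra = RateAssignment(
            np.linspace(0.1, 0.9, net.n_transitions),
            np.linspace(0.05, 0.3, net.n_species),
        )
        traj = simulate_ode(net, ra, (0, 10))
        totals = traj.states.sum(axis=1)
        np.testing.assert_allclose(totals, totals[0], atol=1e-9)
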