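"""Typed Petri nets and stratification by pullback.

A typed Petri net is a Petri net together with a morphism into a fixed
*type system* net, which assigns every place, transition and arc a type.
Typing enforces domain discipline: an interaction-typed transition must
have exactly the interaction type's arity (two inputs and two outputs for
the infectious-disease type system), and a vector-borne type system keeps
host and vector populations apart.

Stratification combines a disease model and a stratification scheme typed
by the same type system into their pullback: places are pairs of
same-typed places, transitions pairs of same-typed transitions, and arcs
pairs of arcs lying over the same type arc, with endpoints computed
componentwise.  Pullback is associative and commutative up to isomorphism,
so the order in which strata are applied never matters.
"""

from __future__ import annotations

from dataclasses import dataclass

from .open_net import OpenPetriNet, oapply_with_inclusions
from .petri import Arc, PetriMorphism, PetriNet, Transition, check_morphism
from .uwd import UWD

__all__ = [
    "TypedPetriNet",
    "check_typing",
    "typed_oapply",
    "stratify",
    "untypable_transitions",
]


@dataclass
class TypedPetriNet:
    """A Petri net, a type-system net, and the typing morphism between them."""

    net: PetriNet
    type_net: PetriNet
    typing: PetriMorphism


def check_typing(tp: TypedPetriNet) -> tuple[bool, list[str]]:
    """Validate the typing morphism; violations name rows and broken rules."""
    return check_morphism(tp.typing, tp.net, tp.type_net)


def untypable_transitions(
    net: PetriNet, type_net: PetriNet, species_typing: dict[int, int]
) -> list[int]:
    """Transitions admitting no type, given the intended species types.

    A transition is typable when some type-system transition has exactly
    the transition's typed input and output multisets (the arity-preserving
    condition restricted to one transition).
    """
    from collections import Counter

    bad = []
    cod_in = [type_net.inputs(t) for t in range(type_net.n_transitions)]
    cod_out = [type_net.outputs(t) for t in range(type_net.n_transitions)]
    for t in range(net.n_transitions):
        tin = Counter()
        for s, m in net.inputs(t).items():
            tin[species_typing[s]] += m
        tout = Counter()
        for s, m in net.outputs(t).items():
            tout[species_typing[s]] += m
        if not any(cod_in[u] == tin and cod_out[u] == tout for u in range(type_net.n_transitions)):
            bad.append(t)
    return bad


def typed_oapply(
    d: UWD,
    components: list[tuple[OpenPetriNet, PetriMorphism]],
    type_net: PetriNet,
) -> TypedPetriNet:
    """Compose typed open Petri nets, refusing to merge differently-typed places.

    All components must be typed into the identical ``type_net``.  The
    composite typing is the induced map (well defined because every
    junction merges only same-typed species) and is returned checked.
    """
    for k, (comp, typing) in enumerate(components):
        ok, v = check_morphism(typing, comp.net, type_net)
        if not ok:
            raise ValueError(f"component {k} typing invalid: {v}")

    composite, inclusions = oapply_with_inclusions(d, [c for c, _ in components])

    n_comp_species = composite.net.n_species
    species_type: list[int | None] = [None] * n_comp_species
    species_source: list[tuple[int, int] | None] = [None] * n_comp_species
    for b, (comp, typing) in enumerate(components):
        inc = inclusions[b]
        for s in range(comp.net.n_species):
            g = inc.species_map[s]
            ty = typing.species_map[s]
            if species_type[g] is None:
                species_type[g] = ty
                species_source[g] = (b, s)
            elif species_type[g] != ty:
                b0, s0 = species_source[g]
                # find the junction responsible for the merge
                jlabel = composite.net.species[g]
                raise ValueError(
                    f"type clash at junction {jlabel!r}: species "
                    f"{components[b0][0].net.species[s0]!r} (component {b0}) and "
                    f"{comp.net.species[s]!r} (component {b}) have different types"
                )

    tmap: list[int] = []
    imap: list[int] = []
    omap: list[int] = []
    for b, (comp, typing) in enumerate(components):
        tmap.extend(typing.transition_map)
        imap.extend(typing.input_arc_map)
        omap.extend(typing.output_arc_map)

    typing = PetriMorphism(
        tuple(t if t is not None else 0 for t in species_type),
        tuple(tmap),
        tuple(imap),
        tuple(omap),
    )
    tp = TypedPetriNet(net=composite.net, type_net=type_net, typing=typing)
    ok, v = check_typing(tp)
    if not ok:
        raise AssertionError(f"induced typing failed validation: {v}")
    return tp


def stratify(
    disease: TypedPetriNet, strata: TypedPetriNet
) -> tuple[TypedPetriNet, PetriMorphism, PetriMorphism]:
    """The pullback of two typed Petri nets over their shared type system.

    Places are the pairs of same-typed places in lexicographic order of
    (disease index, strata index), labelled ``"<d>_<s>"``; transitions and
    arcs analogously, arcs paired over the same type arc with endpoints
    computed componentwise.  The result is typed by projecting to the
    disease factor and composing with its typing.  Both projection
    morphisms are returned.

    Raises when the two type nets are not the same object or table-equal.
    """
    if disease.type_net is not strata.type_net and not _nets_equal(
        disease.type_net, strata.type_net
    ):
        raise ValueError("disease and strata must be typed by the same type system")
    P, Q = disease.net, strata.net
    ft, gt = disease.typing, strata.typing

    species_pairs = [
        (s, s2)
        for s in range(P.n_species)
        for s2 in range(Q.n_species)
        if ft.species_map[s] == gt.species_map[s2]
    ]
    sp_index = {pair: i for i, pair in enumerate(species_pairs)}
    trans_pairs = [
        (t, t2)
        for t in range(P.n_transitions)
        for t2 in range(Q.n_transitions)
        if ft.transition_map[t] == gt.transition_map[t2]
    ]
    tr_index = {pair: i for i, pair in enumerate(trans_pairs)}

    def arc_pairs(p_arcs, q_arcs, p_map, q_map):
        pairs = [
            (i, i2)
            for i in range(len(p_arcs))
            for i2 in range(len(q_arcs))
            if p_map[i] == q_map[i2]
            and (p_arcs[i].transition, q_arcs[i2].transition) in tr_index
        ]
        arcs = [
            Arc(
                sp_index[(p_arcs[i].species, q_arcs[i2].species)],
                tr_index[(p_arcs[i].transition, q_arcs[i2].transition)],
            )
            for i, i2 in pairs
        ]
        return pairs, arcs

    in_pairs, input_arcs = arc_pairs(P.input_arcs, Q.input_arcs, ft.input_arc_map, gt.input_arc_map)
    out_pairs, output_arcs = arc_pairs(
        P.output_arcs, Q.output_arcs, ft.output_arc_map, gt.output_arc_map
    )

    net = PetriNet(
        species=[f"{P.species[s]}_{Q.species[s2]}" for s, s2 in species_pairs],
        transitions=[
            Transition(f"{P.transitions[t].label}_{Q.transitions[t2].label}")
            for t, t2 in trans_pairs
        ],
        input_arcs=input_arcs,
        output_arcs=output_arcs,
    )
    proj1 = PetriMorphism(
        tuple(s for s, _ in species_pairs),
        tuple(t for t, _ in trans_pairs),
        tuple(i for i, _ in in_pairs),
        tuple(i for i, _ in out_pairs),
    )
    proj2 = PetriMorphism(
        tuple(s2 for _, s2 in species_pairs),
        tuple(t2 for _, t2 in trans_pairs),
        tuple(i2 for _, i2 in in_pairs),
        tuple(i2 for _, i2 in out_pairs),
    )
    typing = proj1.compose(ft)
    return TypedPetriNet(net=net, type_net=disease.type_net, typing=typing), proj1, proj2


def _nets_equal(a: PetriNet, b: PetriNet) -> bool:
    return (
        a.species == b.species
        and a.transitions == b.transitions
        and a.input_arcs == b.input_arcs
        and a.output_arcs == b.output_arcs
    )
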