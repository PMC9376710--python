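"""Open Petri nets (structured multicospans) and UWD composition.

An open Petri net is a Petri net together with *feet* — finite interface
sets — and *legs* mapping each foot into the species table, selecting which
places are exposed for gluing.  `oapply` is the operad-algebra action: given
a wiring diagram and one open net per box, it glues the disjoint union of
the component nets by identifying the places exposed by ports wired to a
common junction (computed with union–find).  Transitions are never merged,
so the composite has exactly the sum of the component transition counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .petri import Arc, PetriMorphism, PetriNet, Transition, validate_petri
from .uwd import UWD, _UnionFind

__all__ = ["OpenPetriNet", "make_open", "open_by_labels", "oapply", "oapply_with_inclusions"]


@dataclass
class OpenPetriNet:
    """A Petri net with feet (given by cardinality) and legs into its species."""

    net: PetriNet
    feet: list[int] = field(default_factory=list)  # cardinalities
    legs: list[list[int]] = field(default_factory=list)  # per foot: element -> species

    def validate(self) -> list[str]:
        out = validate_petri(self.net)
        if len(self.feet) != len(self.legs):
            out.append(f"feet count {len(self.feet)} != legs count {len(self.legs)}")
            return out
        for k, (card, leg) in enumerate(zip(self.feet, self.legs)):
            if len(leg) != card:
                out.append(f"legs row {k}: length {len(leg)} != foot cardinality {card}")
            for e, s in enumerate(leg):
                if not 0 <= s < self.net.n_species:
                    out.append(f"legs row {k} element {e}: species index {s} out of range")
        return out


def make_open(net: PetriNet, exposed: list[list[int]]) -> OpenPetriNet:
    """Expose the listed species: one foot per entry, legs as given."""
    for k, leg in enumerate(exposed):
        for s in leg:
            if not 0 <= s < net.n_species:
                raise IndexError(f"exposed list {k}: species index {s} out of range")
    return OpenPetriNet(net=net, feet=[len(l) for l in exposed], legs=[list(l) for l in exposed])


def open_by_labels(net: PetriNet, labels: list[str]) -> OpenPetriNet:
    """Expose one singleton foot per label, in the given order."""
    return make_open(net, [[net.species_index(l)] for l in labels])


def _dedupe(labels: list[str], tag: list[int]) -> list[str]:
    """Suffix duplicate labels with their component index, deterministically."""
    from collections import Counter

    counts = Counter(labels)
    return [
        f"{lbl}[{tag[i]}]" if counts[lbl] > 1 else lbl for i, lbl in enumerate(labels)
    ]


def oapply_with_inclusions(
    d: UWD, components: list[OpenPetriNet]
) -> tuple[OpenPetriNet, list[PetriMorphism]]:
    """`oapply` returning, for each component, its inclusion into the composite."""
    if len(components) != len(d.boxes):
        raise ValueError(
            f"{len(components)} components supplied for {len(d.boxes)} boxes"
        )
    for b, comp in enumerate(components):
        bports = d.box_ports(b)
        if len(comp.feet) != len(bports):
            raise ValueError(
                f"box {b} ({d.boxes[b]!r}) has {len(bports)} ports but component "
                f"has {len(comp.feet)} feet"
            )
        for k, card in enumerate(comp.feet):
            if card != 1:
                raise ValueError(
                    f"component {b} foot {k} has cardinality {card}; composition "
                    "requires singleton feet (each port exposes exactly one place)"
                )

    uf = _UnionFind()
    for b, comp in enumerate(components):
        for k, port in enumerate(d.box_ports(b)):
            uf.union(("s", b, comp.legs[k][0]), ("j", d.ports[port].junction))

    used_junctions = {d.ports[p].junction for p in range(len(d.ports))}
    outer_junctions = set(d.outer_ports)

    # species: junction classes in junction order, then unexposed species
    species_of_root: dict = {}
    labels: list[str] = []
    comp_tag: list[int] = []
    for j in range(len(d.junctions)):
        if j not in used_junctions and j not in outer_junctions:
            continue  # phantom junction: dropped
        root = uf.find(("j", j))
        if root not in species_of_root:
            species_of_root[root] = len(labels)
            labels.append(d.junctions[j])
            comp_tag.append(-1)
    species_map_per_comp: list[list[int]] = []
    for b, comp in enumerate(components):
        smap = []
        for s in range(comp.net.n_species):
            root = uf.find(("s", b, s))
            if root not in species_of_root:
                species_of_root[root] = len(labels)
                labels.append(comp.net.species[s])
                comp_tag.append(b)
            smap.append(species_of_root[root])
        species_map_per_comp.append(smap)
    labels = _dedupe(labels, [max(t, 0) for t in comp_tag])

    transitions: list[Transition] = []
    t_labels: list[str] = []
    t_tag: list[int] = []
    input_arcs: list[Arc] = []
    output_arcs: list[Arc] = []
    inclusions: list[PetriMorphism] = []
    for b, comp in enumerate(components):
        t_off = len(transitions)
        i_off = len(input_arcs)
        o_off = len(output_arcs)
        smap = species_map_per_comp[b]
        for t in comp.net.transitions:
            transitions.append(t)
            t_labels.append(t.label)
            t_tag.append(b)
        for a in comp.net.input_arcs:
            input_arcs.append(Arc(smap[a.species], t_off + a.transition))
        for a in comp.net.output_arcs:
            output_arcs.append(Arc(smap[a.species], t_off + a.transition))
        inclusions.append(
            PetriMorphism(
                tuple(smap),
                tuple(range(t_off, t_off + comp.net.n_transitions)),
                tuple(range(i_off, i_off + len(comp.net.input_arcs))),
                tuple(range(o_off, o_off + len(comp.net.output_arcs))),
            )
        )
    t_labels = _dedupe(t_labels, t_tag)
    transitions = [
        Transition(lbl, t.rate) for lbl, t in zip(t_labels, transitions)
    ]

    net = PetriNet(
        species=labels,
        transitions=transitions,
        input_arcs=input_arcs,
        output_arcs=output_arcs,
    )
    legs = [[species_of_root[uf.find(("j", j))]] for j in d.outer_ports]
    composite = OpenPetriNet(net=net, feet=[1] * len(legs), legs=legs)
    return composite, inclusions


def oapply(d: UWD, components: list[OpenPetriNet]) -> OpenPetriNet:
    """Compose open Petri nets along the wiring diagram ``d``.

    The composite's species are the junction equivalence classes (in
    junction order, labelled by the junction) followed by the unexposed
    component species in (component, local) order; transitions and arcs are
    the disjoint unions with reindexed endpoints.  One singleton foot is
    created per outer port of ``d``.
    """
    return oapply_with_inclusions(d, components)[0]
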