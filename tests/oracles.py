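"""Independent oracles used to cross-check the library.

These deliberately re-derive results from first principles (full product
enumeration, naive equivalence closure, pair enumeration, Richardson
extrapolation) rather than calling the code paths they check.
"""

from __future__ import annotations

from collections import Counter
from itertools import product

import numpy as np

from opetri.open_net import OpenPetriNet
from opetri.petri import PetriNet
from opetri.uwd import UWD


def oracle_is_morphism(smap, tmap, imap, omap, dom: PetriNet, cod: PetriNet) -> bool:
    """First-principles morphism check: endpoint squares commute and the
    arc maps restrict to bijections between corresponding fibers."""
    for arcs, cod_arcs, amap in (
        (dom.input_arcs, cod.input_arcs, imap),
        (dom.output_arcs, cod.output_arcs, omap),
    ):
        for i, a in enumerate(arcs):
            b = cod_arcs[amap[i]]
            if b.species != smap[a.species] or b.transition != tmap[a.transition]:
                return False
        for t in range(dom.n_transitions):
            fiber = [amap[i] for i, a in enumerate(arcs) if a.transition == t]
            cod_fiber = [
                j for j, b in enumerate(cod_arcs) if b.transition == tmap[t]
            ]
            if sorted(fiber) != sorted(cod_fiber) or len(set(fiber)) != len(fiber):
                return False
    return True


def oracle_morphisms(dom: PetriNet, cod: PetriNet) -> set[tuple]:
    """Exhaustive morphism enumeration by per-arc candidate products."""
    out: set[tuple] = set()
    if (dom.n_species and not cod.n_species) or (
        dom.n_transitions and not cod.n_transitions
    ):
        return out
    for smap in product(range(cod.n_species), repeat=dom.n_species):
        for tmap in product(range(cod.n_transitions), repeat=dom.n_transitions):
            i_cands = [
                [
                    j
                    for j, b in enumerate(cod.input_arcs)
                    if b.species == smap[a.species] and b.transition == tmap[a.transition]
                ]
                for a in dom.input_arcs
            ]
            o_cands = [
                [
                    j
                    for j, b in enumerate(cod.output_arcs)
                    if b.species == smap[a.species] and b.transition == tmap[a.transition]
                ]
                for a in dom.output_arcs
            ]
            if any(not c for c in i_cands) or any(not c for c in o_cands):
                continue
            for imap in product(*i_cands):
                for omap in product(*o_cands):
                    if oracle_is_morphism(smap, tmap, imap, omap, dom, cod):
                        out.add((smap, tmap, imap, omap))
    return out


def oracle_glued_species_count(d: UWD, components: list[OpenPetriNet]) -> int:
    """Species count of the composite by naive equivalence closure.

    Nodes are junctions and (component, species) pairs; relations connect a
    junction with every species exposed at it.  Classes are closed by
    repeated scanning until fixpoint; the composite species are the classes
    containing a species, plus isolated outer junctions.
    """
    nodes: list = [("j", j) for j in range(len(d.junctions))]
    for b, comp in enumerate(components):
        nodes += [("s", b, s) for s in range(comp.net.n_species)]
    classes = [{n} for n in nodes]
    pairs = []
    for b, comp in enumerate(components):
        for k, port in enumerate(d.box_ports(b)):
            pairs.append((("j", d.ports[port].junction), ("s", b, comp.legs[k][0])))
    changed = True
    while changed:
        changed = False
        for x, y in pairs:
            cx = next(c for c in classes if x in c)
            cy = next(c for c in classes if y in c)
            if cx is not cy:
                cx |= cy
                classes.remove(cy)
                changed = True
    outer = set(d.outer_ports)
    n = 0
    for c in classes:
        if any(t[0] == "s" for t in c):
            n += 1
        elif any(t[0] == "j" and t[1] in outer for t in c):
            n += 1  # isolated outer junction becomes a phantom place
    return n


def oracle_pullback_counts(disease, strata) -> tuple[int, int, int, int]:
    """(places, transitions, input arcs, output arcs) of the pullback by
    direct pair enumeration over equal types."""
    P, Q = disease.net, strata.net
    f, g = disease.typing, strata.typing
    ns = sum(
        1
        for s in range(P.n_species)
        for s2 in range(Q.n_species)
        if f.species_map[s] == g.species_map[s2]
    )
    trans = [
        (t, t2)
        for t in range(P.n_transitions)
        for t2 in range(Q.n_transitions)
        if f.transition_map[t] == g.transition_map[t2]
    ]
    tset = set(trans)
    ni = sum(
        1
        for i in range(len(P.input_arcs))
        for i2 in range(len(Q.input_arcs))
        if f.input_arc_map[i] == g.input_arc_map[i2]
        and (P.input_arcs[i].transition, Q.input_arcs[i2].transition) in tset
    )
    no = sum(
        1
        for i in range(len(P.output_arcs))
        for i2 in range(len(Q.output_arcs))
        if f.output_arc_map[i] == g.output_arc_map[i2]
        and (P.output_arcs[i].transition, Q.output_arcs[i2].transition) in tset
    )
    return ns, len(trans), ni, no


def richardson_derivative(J, beta: np.ndarray, t: int, h: float) -> float:
    """Richardson-extrapolated central difference of J in coordinate t."""

    def central(step: float) -> float:
        bp = beta.copy()
        bp[t] += step
        bm = beta.copy()
        bm[t] -= step
        return (J(bp) - J(bm)) / (2 * step)

    d1 = central(h)
    d2 = central(h / 2)
    return (4 * d2 - d1) / 3


def random_open_components(rng: np.random.Generator):
    """A random small UWD plus matching open Petri nets with singleton feet."""
    from opetri.open_net import make_open
    from opetri.petri import Arc, PetriNet, Transition
    from opetri.uwd import Port

    n_boxes = int(rng.integers(1, 4))
    n_junctions = int(rng.integers(1, 5))
    boxes = [f"b{i}" for i in range(n_boxes)]
    junctions = [f"j{i}" for i in range(n_junctions)]
    ports = []
    components = []
    for b in range(n_boxes):
        n_sp = int(rng.integers(1, 4))
        n_tr = int(rng.integers(0, 3))
        species = [f"x{b}_{s}" for s in range(n_sp)]
        transitions = [Transition(f"t{b}_{t}") for t in range(n_tr)]
        input_arcs = [
            Arc(int(rng.integers(n_sp)), t)
            for t in range(n_tr)
            for _ in range(int(rng.integers(0, 3)))
        ]
        output_arcs = [
            Arc(int(rng.integers(n_sp)), t)
            for t in range(n_tr)
            for _ in range(int(rng.integers(0, 3)))
        ]
        net = PetriNet(species, transitions, input_arcs, output_arcs)
        n_ports = int(rng.integers(0, n_sp + 1))
        exposed = [[int(rng.integers(n_sp))] for _ in range(n_ports)]
        components.append(make_open(net, exposed))
        ports += [Port(b, int(rng.integers(n_junctions))) for _ in range(n_ports)]
    n_outer = int(rng.integers(0, n_junctions + 1))
    outer = [int(rng.integers(n_junctions)) for _ in range(n_outer)]
    return UWD(boxes, ports, junctions, outer), components
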