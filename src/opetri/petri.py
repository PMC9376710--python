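"""Whole-grain Petri nets and their morphisms.

A whole-grain Petri net is four finite sets — species, transitions, input
arcs and output arcs — with maps sending each arc to its species and its
transition.  Arc multiplicity encodes stoichiometry: the infection process
of an SIR model has two input arcs (one from S, one from I) and two output
arcs (both to I), so it consumes one susceptible and one infected individual
and produces two infected individuals.

Morphisms map the four tables compatibly, preserving arc endpoints and
restricting to a bijection on the arcs over each transition (arity
preservation).  They are purely combinatorial: transition rates and labels
are ignored.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import product
from typing import Iterator, Sequence

import networkx as nx

__all__ = [
    "Transition",
    "Arc",
    "PetriNet",
    "PetriMorphism",
    "validate_petri",
    "transition_stoichiometry",
    "check_morphism",
    "find_morphisms",
    "petri_isomorphic",
]


@dataclass(frozen=True)
class Transition:
    """A transition row: a label and an optional nonnegative rate constant."""

    label: str
    rate: float | None = None


@dataclass(frozen=True)
class Arc:
    """An arc row: the species and transition it connects."""

    species: int
    transition: int


@dataclass
class PetriNet:
    """A whole-grain Petri net given by four ordered tables.

    Parameters
    ----------
    species:
        Species labels, pairwise distinct.
    transitions:
        Transition rows (label, optional rate), labels pairwise distinct.
    input_arcs, output_arcs:
        Arc rows; ``Arc(species=s, transition=t)`` records one unit of
        stoichiometry between species row ``s`` and transition row ``t``.
        All indices are 0-based.
    """

    species: list[str] = field(default_factory=list)
    transitions: list[Transition] = field(default_factory=list)
    input_arcs: list[Arc] = field(default_factory=list)
    output_arcs: list[Arc] = field(default_factory=list)

    # -- accessors -------------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    def species_index(self, label: str) -> int:
        return self.species.index(label)

    def transition_index(self, label: str) -> int:
        for i, t in enumerate(self.transitions):
            if t.label == label:
                return i
        raise KeyError(label)

    def inputs(self, t: int) -> Counter:
        """Multiset of input species of transition ``t`` (the map r)."""
        self._check_transition(t)
        return Counter(a.species for a in self.input_arcs if a.transition == t)

    def outputs(self, t: int) -> Counter:
        """Multiset of output species of transition ``t``."""
        self._check_transition(t)
        return Counter(a.species for a in self.output_arcs if a.transition == t)

    def producers(self, s: int) -> Counter:
        """Multiset of transitions producing species ``s`` (the map p)."""
        self._check_species(s)
        return Counter(a.transition for a in self.output_arcs if a.species == s)

    def consumers(self, s: int) -> Counter:
        """Multiset of transitions consuming species ``s`` (weighted preimage of r)."""
        self._check_species(s)
        return Counter(a.transition for a in self.input_arcs if a.species == s)

    def _check_transition(self, t: int) -> None:
        if not 0 <= t < self.n_transitions:
            raise IndexError(f"transition index {t} out of range")

    def _check_species(self, s: int) -> None:
        if not 0 <= s < self.n_species:
            raise IndexError(f"species index {s} out of range")


def validate_petri(net: PetriNet) -> list[str]:
    """Return descriptions of every invariant violation (empty list if valid).

    Checked: arc indices in range, distinct labels per table, rates >= 0.
    Violations name the table, row and broken rule; nothing is raised.
    """
    out: list[str] = []
    seen: dict[str, int] = {}
    for i, lbl in enumerate(net.species):
        if lbl in seen:
            out.append(f"species row {i}: duplicate label {lbl!r} (also row {seen[lbl]})")
        seen[lbl] = i
    seen = {}
    for i, t in enumerate(net.transitions):
        if t.label in seen:
            out.append(
                f"transitions row {i}: duplicate label {t.label!r} (also row {seen[t.label]})"
            )
        seen[t.label] = i
        if t.rate is not None and t.rate < 0:
            out.append(f"transitions row {i}: negative rate {t.rate}")
    for table, arcs in (("input_arcs", net.input_arcs), ("output_arcs", net.output_arcs)):
        for i, a in enumerate(arcs):
            if not 0 <= a.species < net.n_species:
                out.append(f"{table} row {i}: species index {a.species} out of range")
            if not 0 <= a.transition < net.n_transitions:
                out.append(f"{table} row {i}: transition index {a.transition} out of range")
    return out


def transition_stoichiometry(net: PetriNet, t: int) -> tuple[Counter, Counter]:
    """Input and output multisets (over species indices) of transition ``t``."""
    return net.inputs(t), net.outputs(t)


@dataclass(frozen=True)
class PetriMorphism:
    """A morphism of whole-grain Petri nets as four index maps.

    Entry ``species_map[i]`` is the codomain species row that domain species
    row ``i`` is sent to, and likewise for the other three tables.
    """

    species_map: tuple[int, ...]
    transition_map: tuple[int, ...]
    input_arc_map: tuple[int, ...]
    output_arc_map: tuple[int, ...]

    @classmethod
    def identity(cls, net: PetriNet) -> "PetriMorphism":
        return cls(
            tuple(range(net.n_species)),
            tuple(range(net.n_transitions)),
            tuple(range(len(net.input_arcs))),
            tuple(range(len(net.output_arcs))),
        )

    def compose(self, other: "PetriMorphism") -> "PetriMorphism":
        """The composite ``other ∘ self`` (apply self first)."""
        return PetriMorphism(
            tuple(other.species_map[i] for i in self.species_map),
            tuple(other.transition_map[i] for i in self.transition_map),
            tuple(other.input_arc_map[i] for i in self.input_arc_map),
            tuple(other.output_arc_map[i] for i in self.output_arc_map),
        )


def check_morphism(
    f: PetriMorphism, dom: PetriNet, cod: PetriNet
) -> tuple[bool, list[str]]:
    """Check that ``f`` is a valid Petri-net morphism from ``dom`` to ``cod``.

    Conditions: all indices in range and map lengths matching the domain
    tables; the endpoint squares commute (an arc's image has the image
    species and image transition); and over each domain transition the arc
    maps restrict to bijections onto the arcs of the image transition
    (arity preservation).

    Returns ``(ok, violations)``.
    """
    v: list[str] = []
    lengths = (
        ("species_map", f.species_map, dom.n_species, cod.n_species),
        ("transition_map", f.transition_map, dom.n_transitions, cod.n_transitions),
        ("input_arc_map", f.input_arc_map, len(dom.input_arcs), len(cod.input_arcs)),
        ("output_arc_map", f.output_arc_map, len(dom.output_arcs), len(cod.output_arcs)),
    )
    for name, m, n_dom, n_cod in lengths:
        if len(m) != n_dom:
            raise ValueError(f"{name} has length {len(m)}, expected {n_dom}")
        for i, j in enumerate(m):
            if not 0 <= j < n_cod:
                v.append(f"{name} entry {i}: codomain index {j} out of range")
    if v:
        return False, v

    for table, arcs, cod_arcs, arc_map in (
        ("input_arcs", dom.input_arcs, cod.input_arcs, f.input_arc_map),
        ("output_arcs", dom.output_arcs, cod.output_arcs, f.output_arc_map),
    ):
        for i, a in enumerate(arcs):
            img = cod_arcs[arc_map[i]]
            if img.species != f.species_map[a.species]:
                v.append(f"{table} row {i}: species square does not commute")
            if img.transition != f.transition_map[a.transition]:
                v.append(f"{table} row {i}: transition square does not commute")
        # fibrewise bijection over each transition
        for t in range(dom.n_transitions):
            fiber = [i for i, a in enumerate(arcs) if a.transition == t]
            image = [arc_map[i] for i in fiber]
            cod_fiber = [
                j for j, a in enumerate(cod_arcs) if a.transition == f.transition_map[t]
            ]
            if len(set(image)) != len(image) or sorted(image) != sorted(cod_fiber):
                v.append(
                    f"transition {t}: {table} not mapped bijectively onto arcs of "
                    f"transition {f.transition_map[t]} (arity violation)"
                )
    return not v, v


def _arc_map_candidates(
    dom_arcs: Sequence[Arc],
    cod_arcs: Sequence[Arc],
    smap: Sequence[int],
    tmap: Sequence[int],
) -> list[list[int]] | None:
    """Per-arc codomain candidates consistent with the endpoint squares."""
    cands: list[list[int]] = []
    for a in dom_arcs:
        c = [
            j
            for j, b in enumerate(cod_arcs)
            if b.species == smap[a.species] and b.transition == tmap[a.transition]
        ]
        if not c:
            return None
        cands.append(c)
    return cands


def _enumerate_arc_maps(
    dom_arcs: Sequence[Arc],
    cands: list[list[int]],
    n_trans: int,
) -> Iterator[tuple[int, ...]]:
    """Lexicographic arc maps that are injective within each transition fiber."""
    fibers: list[list[int]] = [[] for _ in range(n_trans)]
    for i, a in enumerate(dom_arcs):
        fibers[a.transition].append(i)
    fiber_of = [a.transition for a in dom_arcs]

    def rec(i: int, chosen: list[int], used: list[set]) -> Iterator[tuple[int, ...]]:
        if i == len(dom_arcs):
            yield tuple(chosen)
            return
        for j in cands[i]:
            if j in used[fiber_of[i]]:
                continue
            used[fiber_of[i]].add(j)
            chosen.append(j)
            yield from rec(i + 1, chosen, used)
            chosen.pop()
            used[fiber_of[i]].remove(j)

    yield from rec(0, [], [set() for _ in range(n_trans)])


def find_morphisms(
    dom: PetriNet,
    cod: PetriNet,
    species_map_constraints: dict[int, int] | None = None,
) -> list[PetriMorphism]:
    """Exhaustively enumerate the morphisms ``dom -> cod``.

    Backtracking over the species map (optionally pinned on some species via
    ``species_map_constraints``), then the transition map pruned by mapped
    input/output multisets, then the fibrewise arc bijections.  Results come
    out in lexicographic order of
    (species_map, transition_map, input_arc_map, output_arc_map).
    Worst case is exponential; intended for the small nets used as type
    systems and disease/stratification components.
    """
    constraints = species_map_constraints or {}
    results: list[PetriMorphism] = []
    if dom.n_species > 0 and cod.n_species == 0:
        return results
    if dom.n_transitions > 0 and cod.n_transitions == 0:
        return results

    dom_in = [dom.inputs(t) for t in range(dom.n_transitions)]
    dom_out = [dom.outputs(t) for t in range(dom.n_transitions)]
    cod_in = [cod.inputs(t) for t in range(cod.n_transitions)]
    cod_out = [cod.outputs(t) for t in range(cod.n_transitions)]

    species_choices = [
        [constraints[s]] if s in constraints else list(range(cod.n_species))
        for s in range(dom.n_species)
    ]
    for smap in product(*species_choices):
        # transition candidates: image multisets must match exactly
        t_cands: list[list[int]] = []
        ok = True
        for t in range(dom.n_transitions):
            mapped_in = Counter()
            for s, m in dom_in[t].items():
                mapped_in[smap[s]] += m
            mapped_out = Counter()
            for s, m in dom_out[t].items():
                mapped_out[smap[s]] += m
            c = [
                u
                for u in range(cod.n_transitions)
                if cod_in[u] == mapped_in and cod_out[u] == mapped_out
            ]
            if not c:
                ok = False
                break
            t_cands.append(c)
        if not ok:
            continue
        for tmap in product(*t_cands):
            in_cands = _arc_map_candidates(dom.input_arcs, cod.input_arcs, smap, tmap)
            if in_cands is None:
                continue
            out_cands = _arc_map_candidates(dom.output_arcs, cod.output_arcs, smap, tmap)
            if out_cands is None:
                continue
            for imap in _enumerate_arc_maps(dom.input_arcs, in_cands, dom.n_transitions):
                for omap in _enumerate_arc_maps(
                    dom.output_arcs, out_cands, dom.n_transitions
                ):
                    results.append(PetriMorphism(tuple(smap), tuple(tmap), imap, omap))
    return results


def _as_multigraph(net: PetriNet) -> nx.DiGraph:
    g = nx.DiGraph()
    for i in range(net.n_species):
        g.add_node(("s", i), kind="species")
    for j in range(net.n_transitions):
        g.add_node(("t", j), kind="transition")
    for a in net.input_arcs:
        u, v = ("s", a.species), ("t", a.transition)
        g.add_edge(u, v, m=g.get_edge_data(u, v, {"m": 0})["m"] + 1)
    for a in net.output_arcs:
        u, v = ("t", a.transition), ("s", a.species)
        g.add_edge(u, v, m=g.get_edge_data(u, v, {"m": 0})["m"] + 1)
    return g


def petri_isomorphic(a: PetriNet, b: PetriNet) -> bool:
    """Whether an invertible morphism exists between ``a`` and ``b``.

    Labels and rates are ignored.  Because arcs within a fiber are
    interchangeable, an invertible morphism exists exactly when the species/
    transition multigraphs with stoichiometric edge weights are isomorphic,
    which is decided with the VF2 matcher.
    """
    if (
        a.n_species != b.n_species
        or a.n_transitions != b.n_transitions
        or len(a.input_arcs) != len(b.input_arcs)
        or len(a.output_arcs) != len(b.output_arcs)
    ):
        return False
    return nx.is_isomorphic(
        _as_multigraph(a),
        _as_multigraph(b),
        node_match=lambda x, y: x["kind"] == y["kind"],
        edge_match=lambda x, y: x["m"] == y["m"],
    )
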