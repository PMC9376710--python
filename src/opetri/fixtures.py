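"""Built-in model catalog.

Every model exercised by the package — the SIR/SIS/VIvR disease models,
the vaccination composition and its wiring diagram, the vector-borne
composition diagrams, the infectious-disease and vector-borne type
systems, the stratification schemes (quarantine, age, flux, simple trip)
and the Ross–Macdonald sharers — is constructed programmatically here.

Conventions:

* Reactions are written as ordered input/output label lists; arcs are laid
  out transition by transition in that order.  For interaction-typed
  transitions the input order is (infector, infectee), and typings match
  same-typed arcs in listed order, so the arc maps record who infects whom.
* Stratification schemes carry disease-typed self-loops on each stratum
  place so that disease-status transitions survive stratification in every
  stratum.
"""

from __future__ import annotations

from .mass_action import petri_to_sharer
from .open_net import OpenPetriNet, make_open, oapply
from .petri import Arc, PetriMorphism, PetriNet, Transition, check_morphism
from .sharers import (
    DelaySharer,
    ResourceSharer,
    _ross_bloodmeal,
    _ross_bloodmeal_delay,
    _ross_host,
    _ross_vector,
    sharer_oapply,
)
from .typed import TypedPetriNet
from .uwd import UWD, Port

__all__ = ["fixture", "fixture_names", "FIXTURES", "net_from_reactions", "make_typing"]


def net_from_reactions(
    species: list[str],
    reactions: list[tuple[str, list[str], list[str]]],
    rates: dict[str, float] | None = None,
) -> PetriNet:
    """Build a net from (label, input labels, output labels) triples.

    Arcs are created transition by transition, inputs in listed order then
    outputs, so the arc tables have a deterministic, typing-friendly order.
    """
    rates = rates or {}
    idx = {s: i for i, s in enumerate(species)}
    transitions = []
    input_arcs = []
    output_arcs = []
    for t, (label, ins, outs) in enumerate(reactions):
        transitions.append(Transition(label, rates.get(label)))
        input_arcs.extend(Arc(idx[s], t) for s in ins)
        output_arcs.extend(Arc(idx[s], t) for s in outs)
    return PetriNet(list(species), transitions, input_arcs, output_arcs)


def make_typing(
    net: PetriNet,
    type_net: PetriNet,
    species_types: dict[str, str],
    transition_types: dict[str, str],
) -> PetriMorphism:
    """Construct the typing morphism from label-level type assignments.

    Arc maps are derived per transition: each domain arc, in table order,
    is matched to the first unused codomain arc of the type transition with
    the matching species type.  The result is validated.
    """
    smap = tuple(type_net.species_index(species_types[s]) for s in net.species)
    tmap = tuple(
        type_net.transition_index(transition_types[t.label]) for t in net.transitions
    )

    # distinct cod arcs within one domain transition's fiber; the 'used'
    # set resets between domain transitions sharing a type transition
    def match_fibrewise(arcs, cod_arcs):
        out = [0] * len(arcs)
        for t in range(net.n_transitions):
            fiber = [i for i, a in enumerate(arcs) if a.transition == t]
            used: set[int] = set()
            for i in fiber:
                a = arcs[i]
                for j, b in enumerate(cod_arcs):
                    if (
                        j in used
                        or b.transition != tmap[t]
                        or b.species != smap[a.species]
                    ):
                        continue
                    out[i] = j
                    used.add(j)
                    break
                else:
                    raise ValueError(
                        f"no free codomain arc for arc row {i} of transition "
                        f"{net.transitions[t].label!r}"
                    )
        return tuple(out)

    f = PetriMorphism(
        smap,
        tmap,
        match_fibrewise(net.input_arcs, type_net.input_arcs),
        match_fibrewise(net.output_arcs, type_net.output_arcs),
    )
    ok, violations = check_morphism(f, net, type_net)
    if not ok:
        raise ValueError(f"constructed typing is invalid: {violations}")
    return f


# ---------------------------------------------------------------------------
# type systems


def p_infectious() -> PetriNet:
    """One place type; transition types: disease-status change, strata
    change, pairwise interaction (two inputs, two outputs)."""
    return net_from_reactions(
        ["pop"],
        [
            ("disease", ["pop"], ["pop"]),
            ("strata", ["pop"], ["pop"]),
            ("interaction", ["pop", "pop"], ["pop", "pop"]),
        ],
    )


def p_vector_borne() -> PetriNet:
    """Host and vector place types; disease-status change within each
    population, and interactions only between a host and a vector."""
    return net_from_reactions(
        ["host", "vector"],
        [
            ("host_disease", ["host"], ["host"]),
            ("vector_disease", ["vector"], ["vector"]),
            ("interaction", ["host", "vector"], ["host", "vector"]),
        ],
    )


# ---------------------------------------------------------------------------
# disease models


def sir() -> PetriNet:
    return net_from_reactions(
        ["S", "I", "R"],
        [("infection", ["I", "S"], ["I", "I"]), ("recovery", ["I"], ["R"])],
    )


def sis() -> PetriNet:
    return net_from_reactions(
        ["S", "I"],
        [("infection", ["I", "S"], ["I", "I"]), ("recovery", ["I"], ["S"])],
    )


def vivr() -> PetriNet:
    return net_from_reactions(
        ["V", "Iv", "R"],
        [("infection_v", ["Iv", "V"], ["Iv", "Iv"]), ("recovery_v", ["Iv"], ["R"])],
    )


def cross_exposure() -> PetriNet:
    """Vaccination plus cross transmission between the vaccinated and
    unvaccinated populations (arc choice is a convention of this catalog)."""
    return net_from_reactions(
        ["S", "I", "V", "Iv"],
        [
            ("vaccination", ["S"], ["V"]),
            ("expose_unvaccinated", ["Iv", "S"], ["Iv", "I"]),
            ("expose_vaccinated", ["I", "V"], ["I", "Iv"]),
        ],
    )


def sir_typed() -> TypedPetriNet:
    """SIR with strata self-loops on every place, typed by p_infectious."""
    net = net_from_reactions(
        ["S", "I", "R"],
        [
            ("infection", ["I", "S"], ["I", "I"]),
            ("recovery", ["I"], ["R"]),
            ("strata_S", ["S"], ["S"]),
            ("strata_I", ["I"], ["I"]),
            ("strata_R", ["R"], ["R"]),
        ],
    )
    tnet = p_infectious()
    typing = make_typing(
        net,
        tnet,
        {s: "pop" for s in net.species},
        {
            "infection": "interaction",
            "recovery": "disease",
            "strata_S": "strata",
            "strata_I": "strata",
            "strata_R": "strata",
        },
    )
    return TypedPetriNet(net, tnet, typing)


def sis_typed() -> TypedPetriNet:
    net = net_from_reactions(
        ["S", "I"],
        [
            ("infection", ["I", "S"], ["I", "I"]),
            ("recovery", ["I"], ["S"]),
            ("strata_S", ["S"], ["S"]),
            ("strata_I", ["I"], ["I"]),
        ],
    )
    tnet = p_infectious()
    typing = make_typing(
        net,
        tnet,
        {s: "pop" for s in net.species},
        {
            "infection": "interaction",
            "recovery": "disease",
            "strata_S": "strata",
            "strata_I": "strata",
        },
    )
    return TypedPetriNet(net, tnet, typing)


# ---------------------------------------------------------------------------
# stratification schemes (all typed by p_infectious)


def quarantine() -> TypedPetriNet:
    """Quarantine status: movement in and out of quarantine, interaction
    only among the non-quarantining, disease loops on both strata."""
    net = net_from_reactions(
        ["Q", "notQ"],
        [
            ("leave_quarantine", ["Q"], ["notQ"]),
            ("enter_quarantine", ["notQ"], ["Q"]),
            ("contact", ["notQ", "notQ"], ["notQ", "notQ"]),
            ("disease_Q", ["Q"], ["Q"]),
            ("disease_notQ", ["notQ"], ["notQ"]),
        ],
    )
    tnet = p_infectious()
    typing = make_typing(
        net,
        tnet,
        {s: "pop" for s in net.species},
        {
            "leave_quarantine": "strata",
            "enter_quarantine": "strata",
            "contact": "interaction",
            "disease_Q": "disease",
            "disease_notQ": "disease",
        },
    )
    return TypedPetriNet(net, tnet, typing)


def age() -> TypedPetriNet:
    """Two age groups with all ordered (infector, infectee) interactions and
    no strata movement: children never spontaneously become adults."""
    net = net_from_reactions(
        ["child", "adult"],
        [
            ("contact_child_child", ["child", "child"], ["child", "child"]),
            ("contact_child_adult", ["child", "adult"], ["child", "adult"]),
            ("contact_adult_child", ["adult", "child"], ["adult", "child"]),
            ("contact_adult_adult", ["adult", "adult"], ["adult", "adult"]),
            ("disease_child", ["child"], ["child"]),
            ("disease_adult", ["adult"], ["adult"]),
        ],
    )
    tnet = p_infectious()
    typing = make_typing(
        net,
        tnet,
        {s: "pop" for s in net.species},
        {
            t.label: ("interaction" if t.label.startswith("contact") else "disease")
            for t in net.transitions
        },
    )
    return TypedPetriNet(net, tnet, typing)


def flux(n: int = 2) -> TypedPetriNet:
    """Flux metapopulation model: n patches, movement between every ordered
    pair, interaction within each patch, disease loops on each patch."""
    if n < 1:
        raise ValueError("need at least one patch")
    places = [f"patch{i}" for i in range(n)]
    reactions: list[tuple[str, list[str], list[str]]] = []
    ttypes: dict[str, str] = {}
    for i in range(n):
        for j in range(n):
            if i != j:
                name = f"move_{i}_{j}"
                reactions.append((name, [places[i]], [places[j]]))
                ttypes[name] = "strata"
    for i in range(n):
        name = f"contact_{i}"
        reactions.append((name, [places[i], places[i]], [places[i], places[i]]))
        ttypes[name] = "interaction"
    for i in range(n):
        name = f"disease_{i}"
        reactions.append((name, [places[i]], [places[i]]))
        ttypes[name] = "disease"
    net = net_from_reactions(places, reactions)
    tnet = p_infectious()
    typing = make_typing(net, tnet, {s: "pop" for s in places}, ttypes)
    return TypedPetriNet(net, tnet, typing)


def simple_trip(n: int = 2) -> TypedPetriNet:
    """Simple-trip metapopulation model: place P_ij holds people currently
    in patch i whose residence is patch j; travel changes the current patch
    only, and interactions pair places with the same current patch."""
    if n < 1:
        raise ValueError("need at least one patch")
    places = [f"P{i}{j}" for i in range(n) for j in range(n)]
    reactions: list[tuple[str, list[str], list[str]]] = []
    ttypes: dict[str, str] = {}
    for j in range(n):  # residence preserved
        for i in range(n):
            for k in range(n):
                if i != k:
                    name = f"travel_{i}_{k}_res{j}"
                    reactions.append((name, [f"P{i}{j}"], [f"P{k}{j}"]))
                    ttypes[name] = "strata"
    for i in range(n):  # same current patch, all ordered residence pairs
        for j in range(n):
            for l in range(n):
                name = f"contact_{i}_res{j}_{l}"
                reactions.append(
                    (name, [f"P{i}{j}", f"P{i}{l}"], [f"P{i}{j}", f"P{i}{l}"])
                )
                ttypes[name] = "interaction"
    for p in places:
        name = f"disease_{p}"
        reactions.append((name, [p], [p]))
        ttypes[name] = "disease"
    net = net_from_reactions(places, reactions)
    tnet = p_infectious()
    typing = make_typing(net, tnet, {s: "pop" for s in places}, ttypes)
    return TypedPetriNet(net, tnet, typing)


def vector_sis() -> PetriNet:
    """A host/vector SIS net including two transitions that violate the
    vector-borne type discipline: a species change SH -> SV and
    vector-to-vector transmission IV + SV -> 2 IV."""
    return net_from_reactions(
        ["SH", "IH", "SV", "IV"],
        [
            ("infect_host", ["IV", "SH"], ["IV", "IH"]),
            ("recover_host", ["IH"], ["SH"]),
            ("infect_vector", ["IH", "SV"], ["IH", "IV"]),
            ("recover_vector", ["IV"], ["SV"]),
            ("become_vector", ["SH"], ["SV"]),
            ("vector_to_vector", ["IV", "SV"], ["IV", "IV"]),
        ],
    )


def vector_sis_species_typing() -> dict[int, int]:
    """The intended species types of `vector_sis` in `p_vector_borne`:
    SH, IH are hosts; SV, IV are vectors."""
    net = vector_sis()
    tnet = p_vector_borne()
    ty = {"SH": "host", "IH": "host", "SV": "vector", "IV": "vector"}
    return {
        net.species_index(s): tnet.species_index(t) for s, t in ty.items()
    }


# ---------------------------------------------------------------------------
# wiring diagrams


def uwd_fig2a() -> UWD:
    """Three boxes (SIR, VIvR, cross exposure), ten ports, five junctions."""
    junctions = ["S", "I", "R", "V", "Iv"]
    j = {l: i for i, l in enumerate(junctions)}
    ports = (
        [Port(0, j[x]) for x in ("S", "I", "R")]
        + [Port(1, j[x]) for x in ("V", "Iv", "R")]
        + [Port(2, j[x]) for x in ("S", "I", "V", "Iv")]
    )
    return UWD(
        boxes=["sir", "vivr", "cross_exposure"],
        ports=ports,
        junctions=junctions,
        outer_ports=[],
    )


def uwd_fig3a() -> UWD:
    """Host, vector and bloodmeal boxes sharing the infected-host and
    infected-vector populations."""
    return UWD(
        boxes=["host", "vector", "bloodmeal"],
        ports=[Port(0, 0), Port(1, 1), Port(2, 0), Port(2, 1)],
        junctions=["IH", "IV"],
        outer_ports=[],
    )


def uwd_fig3f_outer() -> UWD:
    """Three-box vector-borne syntax with the susceptible and incubating
    populations also shared between the boxes."""
    junctions = ["SH", "SV", "EV", "IH", "IV"]
    j = {l: i for i, l in enumerate(junctions)}
    ports = (
        [Port(0, j[x]) for x in ("SH", "IH")]
        + [Port(1, j[x]) for x in ("SV", "EV", "IV")]
        + [Port(2, j[x]) for x in ("SH", "IH", "SV", "EV", "IV")]
    )
    return UWD(
        boxes=["host", "vector", "bloodmeal"],
        ports=ports,
        junctions=junctions,
        outer_ports=[],
    )


def uwd_fig3f_vector() -> UWD:
    """Vector dynamics split into aquatic stages and the adult epidemic;
    exposes (SV, EV, IV) to slot into the vector box of the outer syntax."""
    junctions = ["SV", "EV", "IV"]
    j = {l: i for i, l in enumerate(junctions)}
    ports = [Port(0, j["SV"])] + [Port(1, j[x]) for x in ("SV", "EV", "IV")]
    return UWD(
        boxes=["aquatic", "adult"],
        ports=ports,
        junctions=junctions,
        outer_ports=[j["SV"], j["EV"], j["IV"]],
    )


def uwd_fig3f() -> UWD:
    """The flattened hierarchical syntax: four boxes, five junctions."""
    from .uwd import uwd_substitute

    return uwd_substitute(uwd_fig3f_outer(), 1, uwd_fig3f_vector())


# ---------------------------------------------------------------------------
# open components and Ross–Macdonald semantics


def sviivr_components() -> list[OpenPetriNet]:
    """The three open submodels of the vaccination composite, in the box
    order of `uwd_fig2a`."""
    from .open_net import open_by_labels

    return [
        open_by_labels(sir(), ["S", "I", "R"]),
        open_by_labels(vivr(), ["V", "Iv", "R"]),
        open_by_labels(cross_exposure(), ["S", "I", "V", "Iv"]),
    ]


def ross_macdonald_petri() -> OpenPetriNet:
    """A Petri-net rendering of the Ross–Macdonald decomposition.

    Only the infected populations IH and IV are shared; the susceptible
    pools live inside the bloodmeal box (a reconstruction recorded as a
    catalog convention)."""
    host = net_from_reactions(["IH"], [("host_recovery", ["IH"], [])])
    vector = net_from_reactions(["IV"], [("vector_death", ["IV"], [])])
    bloodmeal = net_from_reactions(
        ["SH", "IH", "SV", "IV"],
        [
            ("infect_host", ["IV", "SH"], ["IV", "IH"]),
            ("infect_vector", ["IH", "SV"], ["IH", "IV"]),
        ],
    )
    from .open_net import open_by_labels

    return oapply(
        uwd_fig3a(),
        [
            open_by_labels(host, ["IH"]),
            open_by_labels(vector, ["IV"]),
            open_by_labels(bloodmeal, ["IH", "IV"]),
        ],
    )


def ross_macdonald_ode() -> ResourceSharer:
    """The Ross–Macdonald ODE composite: host recovery, vector mortality and
    bloodmeal transmission summed on the shared IH, IV states."""
    return sharer_oapply(uwd_fig3a(), [_ross_host(), _ross_vector(), _ross_bloodmeal()])


def ross_macdonald_dde(tau: float = 1.0) -> DelaySharer:
    """As `ross_macdonald_ode` but with the incubation-delay bloodmeal."""
    return sharer_oapply(
        uwd_fig3a(), [_ross_host(), _ross_vector(), _ross_bloodmeal_delay(tau)]
    )


# ---------------------------------------------------------------------------
# catalog

FIXTURES: dict[str, tuple] = {
    # name: (builder, provenance one-liner)
    "sir": (sir, "three-place susceptible-infected-recovered net (Fig 1)"),
    "sis": (sis, "two-place susceptible-infected-susceptible net (Fig 5a.i core)"),
    "vivr": (vivr, "vaccinated-population disease net (Fig 2b)"),
    "cross_exposure": (cross_exposure, "vaccination and cross-transmission net (Fig 2b)"),
    "sviivr_components": (sviivr_components, "open submodels of the vaccination composite (Fig 2b)"),
    "uwd_fig2a": (uwd_fig2a, "three-box vaccination wiring diagram (Fig 2a)"),
    "uwd_fig3a": (uwd_fig3a, "host/vector/bloodmeal wiring diagram (Fig 3a)"),
    "uwd_fig3f_outer": (uwd_fig3f_outer, "outer diagram of the hierarchical syntax (Fig 3f)"),
    "uwd_fig3f_vector": (uwd_fig3f_vector, "vector-dynamics inner diagram (Fig 3f)"),
    "uwd_fig3f": (uwd_fig3f, "flattened hierarchical syntax (Fig 3f)"),
    "p_infectious": (p_infectious, "infectious-disease type system (Fig 4a)"),
    "p_vector_borne": (p_vector_borne, "vector-borne type system (Fig 4c)"),
    "sir_typed": (sir_typed, "SIR with strata loops typed by p_infectious (Fig 4b)"),
    "sis_typed": (sis_typed, "SIS with strata loops typed by p_infectious (Fig 5a.i)"),
    "quarantine": (quarantine, "quarantine-status stratification scheme (Fig 5b.i)"),
    "age": (age, "two-age-group stratification scheme (Fig 5b.ii)"),
    "flux": (flux, "flux metapopulation scheme, n patches (Fig 5b.iii)"),
    "simple_trip": (simple_trip, "simple-trip metapopulation scheme, n patches (Fig 5b.iv)"),
    "vector_sis": (vector_sis, "host/vector SIS with type-forbidden transitions (Fig 4d)"),
    "ross_macdonald_petri": (ross_macdonald_petri, "Petri rendering of Ross-Macdonald (Fig 3b)"),
    "ross_macdonald_ode": (ross_macdonald_ode, "Ross-Macdonald ODE composite (Fig 3d)"),
    "ross_macdonald_dde": (ross_macdonald_dde, "Ross-Macdonald with incubation delay (Fig 3e)"),
}


def fixture_names() -> list[str]:
    return sorted(FIXTURES)


def fixture(name: str, **options):
    """Build a catalog model by name (freshly constructed on each call)."""
    if name not in FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; catalog: {', '.join(fixture_names())}"
        )
    return FIXTURES[name][0](**options)
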