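"""Open dynamical systems (resource sharers) over ODEs and DDEs.

A resource sharer is a state space with named variables, a list of ports
exposing some of those variables, named parameters, and a vector field.
Sharers compose along an undirected wiring diagram exactly like open Petri
nets: states exposed at a common junction are identified and the rates of
change contributed by each component are *summed* on the identified state.

Delay sharers additionally declare a list of fixed positive delays; their
field receives, besides the current state, the state evaluated at each
delayed time.  An ODE sharer coerces trivially into a delay sharer (empty
delay list, history ignored), which lets ODE and DDE submodels mix freely
inside one composite.  DDE trajectories are computed by the method of
steps: integration proceeds in windows no longer than the shortest delay,
with history lookups served by the dense interpolant of the accumulated
solution.

A small registry of named fields ships the Ross–Macdonald components: host
(dIH/dt = -r*IH), vector (dIV/dt = -g*IV) and bloodmeal
(dIH/dt += a*b*(IV/H)*(H-IH), dIV/dt += a*c*(IH/H)*(V-IV)), plus a delayed
bloodmeal in which new vector infections reflect the force of infection one
incubation period ago, discounted by vector survival exp(-g*tau).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .mass_action import Trajectory
from .uwd import UWD, _UnionFind

__all__ = [
    "ResourceSharer",
    "DelaySharer",
    "RossMacdonaldParams",
    "sharer_oapply",
    "ode_to_dde",
    "simulate_sharer",
    "FIELD_REGISTRY",
    "build_sharer",
]


@dataclass
class ResourceSharer:
    """An open ODE: states, exposed ports, named parameters and a field.

    ``field(t, u, params)`` must return the derivative vector, one entry per
    state.
    """

    state_labels: list[str]
    ports: list[int]
    params: dict[str, float]
    field: Callable

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    def validate(self) -> list[str]:
        return [
            f"ports row {k}: state index {p} out of range"
            for k, p in enumerate(self.ports)
            if not 0 <= p < self.n_states
        ]


@dataclass
class DelaySharer(ResourceSharer):
    """An open DDE: as ResourceSharer plus fixed positive delays.

    ``field(t, u, params, hist)`` receives ``hist``, a list with one state
    vector per declared delay: ``hist[k]`` approximates ``u(t - delays[k])``.
    A zero delay is expressed by coercing an ODE sharer, never by a 0 entry.
    """

    delays: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.delays):
            raise ValueError("delays must be strictly positive")


@dataclass
class RossMacdonaldParams:
    """Parameters of the Ross–Macdonald vector-borne transmission model.

    a: biting rate; b: infection efficacy for hosts; c: infection efficacy
    for vectors; H: total host population; V: total vector population;
    r: host recovery rate; g: vector mortality rate.  All nonnegative with
    H, V > 0.
    """

    a: float
    b: float
    c: float
    H: float
    V: float
    r: float
    g: float

    def __post_init__(self) -> None:
        vals = (self.a, self.b, self.c, self.H, self.V, self.r, self.g)
        if any(x < 0 for x in vals):
            raise ValueError("Ross–Macdonald parameters must be nonnegative")
        if self.H <= 0 or self.V <= 0:
            raise ValueError("total populations H and V must be positive")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in "abcHVrg"}


def ode_to_dde(s: ResourceSharer) -> DelaySharer:
    """Coerce an ODE sharer into a DDE sharer with trivial history dependence."""
    return DelaySharer(
        state_labels=list(s.state_labels),
        ports=list(s.ports),
        params=dict(s.params),
        field=lambda t, u, p, hist, _f=s.field: _f(t, u, p),
        delays=[],
    )


def _merge_params(components: Sequence[ResourceSharer]) -> dict[str, float]:
    merged: dict[str, float] = {}
    for c in components:
        for k, v in c.params.items():
            if k in merged and merged[k] != v:
                raise ValueError(
                    f"parameter {k!r} bound to conflicting values "
                    f"{merged[k]} and {v} by different components"
                )
            merged[k] = v
    return merged


def sharer_oapply(
    d: UWD, components: Sequence[ResourceSharer]
) -> ResourceSharer:
    """Compose sharers along the wiring diagram ``d``.

    States wired to a common junction are identified (junction classes in
    junction order first, labelled by the junction, then unshared states in
    component order); the composite field routes each component's
    derivative through the identification and sums contributions.  If any
    component is a DelaySharer the others are coerced and the result is a
    DelaySharer whose delay list is the sorted deduplication of the
    component delays.
    """
    if len(components) != len(d.boxes):
        raise ValueError(f"{len(components)} components for {len(d.boxes)} boxes")
    for b, comp in enumerate(components):
        if len(comp.ports) != len(d.box_ports(b)):
            raise ValueError(
                f"box {b} ({d.boxes[b]!r}) has {len(d.box_ports(b))} ports but "
                f"component exposes {len(comp.ports)} states"
            )

    uf = _UnionFind()
    for b, comp in enumerate(components):
        for k, port in enumerate(d.box_ports(b)):
            uf.union(("s", b, comp.ports[k]), ("j", d.ports[port].junction))

    used = {p.junction for p in d.ports}
    outer = set(d.outer_ports)
    index_of_root: dict = {}
    labels: list[str] = []
    for j in range(len(d.junctions)):
        if j not in used and j not in outer:
            continue
        root = uf.find(("j", j))
        if root not in index_of_root:
            index_of_root[root] = len(labels)
            labels.append(d.junctions[j])
    state_maps: list[list[int]] = []
    for b, comp in enumerate(components):
        m = []
        for s in range(comp.n_states):
            root = uf.find(("s", b, s))
            if root not in index_of_root:
                index_of_root[root] = len(labels)
                labels.append(comp.state_labels[s])
            m.append(index_of_root[root])
        state_maps.append(m)

    n = len(labels)
    params = _merge_params(components)
    any_delay = any(isinstance(c, DelaySharer) for c in components)
    ports = [index_of_root[uf.find(("j", j))] for j in d.outer_ports]
    idx_arrays = [np.array(m, dtype=int) for m in state_maps]

    if not any_delay:
        fields = [c.field for c in components]

        def composite_field(t, u, p):
            du = np.zeros(n)
            for f, idx in zip(fields, idx_arrays):
                np.add.at(du, idx, np.asarray(f(t, u[idx], p), dtype=float))
            return du

        return ResourceSharer(labels, ports, params, composite_field)

    coerced = [c if isinstance(c, DelaySharer) else ode_to_dde(c) for c in components]
    delays = sorted({tau for c in coerced for tau in c.delays})
    delay_pos = {tau: k for k, tau in enumerate(delays)}
    comp_delay_idx = [[delay_pos[tau] for tau in c.delays] for c in coerced]

    def composite_field_dde(t, u, p, hist):
        du = np.zeros(n)
        for c, idx, didx in zip(coerced, idx_arrays, comp_delay_idx):
            local_hist = [np.asarray(hist[k])[idx] for k in didx]
            np.add.at(du, idx, np.asarray(c.field(t, u[idx], p, local_hist), dtype=float))
        return du

    return DelaySharer(labels, ports, params, composite_field_dde, delays=delays)


def _resolve_history(u0_or_history, n: int) -> Callable[[float], np.ndarray]:
    if callable(u0_or_history):
        return lambda t: np.asarray(u0_or_history(t), dtype=float)
    u0 = np.asarray(u0_or_history, dtype=float)
    if u0.shape != (n,):
        raise ValueError(f"initial state has shape {u0.shape}, expected ({n},)")
    return lambda t: u0


def simulate_sharer(
    s: ResourceSharer,
    params: dict[str, float] | None,
    u0_or_history,
    t_span: tuple[float, float],
    n_points: int = 201,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Simulate an ODE or DDE sharer on ``t_span``.

    ODE sharers integrate adaptively (Dormand–Prince).  DDE sharers use the
    method of steps: windows of length min(delays), history lookups served
    by the supplied history function before t0 (a constant vector or a
    callable of time) and by the dense solution interpolant afterwards.
    """
    p = dict(s.params)
    if params:
        p.update(params)
    t0, t1 = float(t_span[0]), float(t_span[1])
    t_eval = np.linspace(t0, t1, n_points)

    if not isinstance(s, DelaySharer):
        u0 = np.asarray(u0_or_history, dtype=float)
        if callable(u0_or_history):
            u0 = np.asarray(u0_or_history(t0), dtype=float)
        sol = solve_ivp(
            lambda t, u: np.asarray(s.field(t, u, p), dtype=float),
            (t0, t1), u0, t_eval=t_eval, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        return Trajectory(sol.t, sol.y.T, list(s.state_labels))

    history = _resolve_history(u0_or_history, s.n_states)
    segments: list[tuple[float, float, Callable]] = []
    seg_starts: list[float] = []

    def u_at(t: float) -> np.ndarray:
        if t <= t0:
            return history(t)
        if not segments:
            return history(t0)
        k = min(bisect.bisect_right(seg_starts, t), len(segments)) - 1
        a, b, interp = segments[max(k, 0)]
        return interp(min(max(t, a), b))

    delays = list(s.delays)

    def rhs(t, u):
        hist = [u_at(t - tau) for tau in delays]
        return np.asarray(s.field(t, u, p, hist), dtype=float)

    if not delays:
        u0 = history(t0)
        sol = solve_ivp(
            lambda t, u: np.asarray(s.field(t, u, p, []), dtype=float),
            (t0, t1), u0, t_eval=t_eval, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"DDE integration failed: {sol.message}")
        return Trajectory(sol.t, sol.y.T, list(s.state_labels))

    step = min(delays)
    t = t0
    y = history(t0)
    while t < t1 - 1e-12 * max(1.0, abs(t1)):
        tb = min(t + step, t1)
        sol = solve_ivp(rhs, (t, tb), y, dense_output=True, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"DDE integration failed on [{t}, {tb}]: {sol.message}")
        segments.append((t, tb, sol.sol))
        seg_starts.append(t)
        y = sol.y[:, -1]
        t = tb
    states = np.stack([u_at(t) for t in t_eval])
    return Trajectory(t_eval, states, list(s.state_labels))


# ---------------------------------------------------------------------------
# field registry for JSON descriptors and the fixture catalog


def _ross_host() -> ResourceSharer:
    return ResourceSharer(
        state_labels=["IH"],
        ports=[0],
        params={},
        field=lambda t, u, p: np.array([-p["r"] * u[0]]),
    )


def _ross_vector() -> ResourceSharer:
    return ResourceSharer(
        state_labels=["IV"],
        ports=[0],
        params={},
        field=lambda t, u, p: np.array([-p["g"] * u[0]]),
    )


def _ross_bloodmeal() -> ResourceSharer:
    def f(t, u, p):
        ih, iv = u
        return np.array(
            [
                p["a"] * p["b"] * (iv / p["H"]) * (p["H"] - ih),
                p["a"] * p["c"] * (ih / p["H"]) * (p["V"] - iv),
            ]
        )

    return ResourceSharer(state_labels=["IH", "IV"], ports=[0, 1], params={}, field=f)


def _ross_bloodmeal_delay(tau: float = 1.0) -> DelaySharer:
    """Bloodmeal with incubation: vector infections lag by tau and are
    discounted by the probability exp(-g*tau) that the vector survives
    incubation.  A reconstruction used for limit and consistency checks."""

    def f(t, u, p, hist):
        ih, iv = u
        ih_d, iv_d = hist[0]
        return np.array(
            [
                p["a"] * p["b"] * (iv / p["H"]) * (p["H"] - ih),
                p["a"]
                * p["c"]
                * (ih_d / p["H"])
                * (p["V"] - iv_d)
                * np.exp(-p["g"] * tau),
            ]
        )

    return DelaySharer(
        state_labels=["IH", "IV"], ports=[0, 1], params={}, field=f, delays=[tau]
    )


def _mass_action_sharer(net_doc: dict, beta: list[float]) -> ResourceSharer:
    from .io import petri_from_dict
    from .mass_action import petri_to_sharer
    from .open_net import make_open

    net = petri_from_dict(net_doc)
    return petri_to_sharer(make_open(net, []), np.asarray(beta, dtype=float))


FIELD_REGISTRY: dict[str, Callable] = {
    "ross_host": _ross_host,
    "ross_vector": _ross_vector,
    "ross_bloodmeal": _ross_bloodmeal,
    "ross_bloodmeal_delay": _ross_bloodmeal_delay,
    "mass_action": _mass_action_sharer,
}


def build_sharer(doc: dict) -> ResourceSharer:
    """Build a sharer from a ``sharer-v1`` descriptor.

    ``{"schema": "sharer-v1", "field": <registry id>, "options": {...},
    "params": {...}}`` — the registry id selects a built-in field; options
    are forwarded to its builder; params are attached to the result.
    """
    fid = doc.get("field")
    if fid not in FIELD_REGISTRY:
        raise KeyError(
            f"unknown field id {fid!r}; known: {sorted(FIELD_REGISTRY)}"
        )
    sharer = FIELD_REGISTRY[fid](**doc.get("options", {}))
    sharer.params.update(doc.get("params", {}))
    return sharer
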