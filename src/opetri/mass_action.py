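"""Mass-action semantics for Petri nets.

The law of mass action interprets a Petri net as the ODE

    du_s/dt = sum over transitions producing s of phi_t
            - sum over transitions consuming s of phi_t,
    phi_t   = beta_t * prod over input species of u_s ** m(s, t),

where m(s, t) is the stoichiometric multiplicity (number of input arcs from
s to t) and beta_t the rate constant.  Deterministic fluxes use plain powers
of concentrations; the stochastic (Gillespie direct method) propensities use
falling factorials of integer token counts, the standard SSA convention for
sampling exact jump processes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .open_net import OpenPetriNet
from .petri import PetriNet

__all__ = [
    "RateAssignment",
    "Trajectory",
    "stoichiometry_matrices",
    "vectorfield",
    "simulate_ode",
    "gillespie_simulate",
    "petri_to_sharer",
]


@dataclass
class RateAssignment:
    """Rate constants (one per transition) and initial values (one per species)."""

    beta: np.ndarray
    u0: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.u0 = np.asarray(self.u0, dtype=float)
        if np.any(self.beta < 0) or np.any(self.u0 < 0):
            raise ValueError("rate constants and initial values must be nonnegative")

    @classmethod
    def from_labels(
        cls, net: PetriNet, beta: dict[str, float], u0: dict[str, float]
    ) -> "RateAssignment":
        """Build a complete assignment from label->value maps.

        Every transition and species of ``net`` must be covered; transition
        rates stored on the net serve as fallback for omitted transitions.
        Omitted species default to 0.
        """
        b = np.empty(net.n_transitions)
        for i, t in enumerate(net.transitions):
            if t.label in beta:
                b[i] = beta[t.label]
            elif t.rate is not None:
                b[i] = t.rate
            else:
                raise KeyError(f"no rate for transition {t.label!r}")
        unknown = set(beta) - {t.label for t in net.transitions}
        if unknown:
            raise KeyError(f"unknown transition labels: {sorted(unknown)}")
        unknown = set(u0) - set(net.species)
        if unknown:
            raise KeyError(f"unknown species labels: {sorted(unknown)}")
        u = np.array([u0.get(s, 0.0) for s in net.species], dtype=float)
        return cls(b, u)


@dataclass
class Trajectory:
    """Time points (strictly increasing) and the state at each time."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, n_species)
    labels: list[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.states.shape != (self.times.size, len(self.labels)):
            raise ValueError("states shape does not match times/labels")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.states, columns=self.labels).assign(time=self.times)[
            ["time", *self.labels]
        ]

    def column(self, label: str) -> np.ndarray:
        return self.states[:, self.labels.index(label)]


def stoichiometry_matrices(net: PetriNet) -> tuple[np.ndarray, np.ndarray]:
    """(input, output) multiplicity matrices of shape (n_species, n_transitions)."""
    m_in = np.zeros((net.n_species, net.n_transitions))
    m_out = np.zeros((net.n_species, net.n_transitions))
    for a in net.input_arcs:
        m_in[a.species, a.transition] += 1
    for a in net.output_arcs:
        m_out[a.species, a.transition] += 1
    return m_in, m_out


def vectorfield(net: PetriNet, beta: np.ndarray):
    """The mass-action vector field ``u -> du/dt`` of ``net``.

    No clipping is applied: negative states are propagated as-is (useful as
    a modelling diagnostic).  The per-transition flux phi_t is computed once
    and added to producers and subtracted from consumers, so any transition
    with equal total input and output multiplicity conserves the population
    sum exactly, including in floating point.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (net.n_transitions,):
        raise ValueError(
            f"beta has shape {beta.shape}, expected ({net.n_transitions},)"
        )
    m_in, m_out = stoichiometry_matrices(net)
    net_stoich = m_out - m_in
    n = net.n_species

    def field(u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        if u.shape != (n,):
            raise ValueError(f"state has shape {u.shape}, expected ({n},)")
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = beta * np.prod(
                np.power(u[:, None], m_in), axis=0
            )
        return net_stoich @ phi

    return field


def simulate_ode(
    net: PetriNet,
    ra: RateAssignment,
    t_span: tuple[float, float],
    n_points: int = 201,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "RK45",
) -> Trajectory:
    """Integrate the mass-action ODE adaptively; report at evenly spaced times.

    Dormand–Prince adaptive Runge–Kutta with rtol 1e-8 / atol 1e-10 by
    default.  Integration failure raises with the solver's diagnostic.
    """
    if ra.beta.shape != (net.n_transitions,) or ra.u0.shape != (net.n_species,):
        raise ValueError("rate assignment does not match the net")
    f = vectorfield(net, ra.beta)
    t_eval = np.linspace(t_span[0], t_span[1], n_points)
    sol = solve_ivp(
        lambda t, u: f(u), t_span, ra.u0, t_eval=t_eval, rtol=rtol, atol=atol,
        method=method,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return Trajectory(times=sol.t, states=sol.y.T, labels=list(net.species))


def _falling_factorial(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    out = np.ones_like(n, dtype=float)
    kmax = int(k.max(initial=0))
    for i in range(kmax):
        out *= np.where(k > i, n - i, 1.0)
    return out


def gillespie_simulate(
    net: PetriNet,
    ra: RateAssignment,
    t_max: float,
    seed: int,
) -> list[tuple[float, int]]:
    """Exact stochastic simulation (Gillespie's direct method).

    Initial values must be integer token counts.  Propensities are
    a_t = beta_t * prod falling_factorial(n_s, m(s, t)); waiting times are
    sampled by inverse transform from a single seeded stream, so runs are
    bit-reproducible.  Returns the (time, transition index) event list.
    """
    u0 = ra.u0
    if np.any(u0 != np.round(u0)):
        raise ValueError("Gillespie simulation requires integer initial counts")
    counts = u0.astype(np.int64).astype(float)
    m_in, m_out = stoichiometry_matrices(net)
    delta = (m_out - m_in).T  # per transition
    rng = np.random.default_rng(seed)
    events: list[tuple[float, int]] = []
    t = 0.0
    while True:
        a = ra.beta * np.prod(
            _falling_factorial(counts[:, None] * np.ones_like(m_in), m_in), axis=0
        )
        a_total = a.sum()
        if a_total <= 0:
            break
        t += -np.log(1.0 - rng.random()) / a_total
        if t > t_max:
            break
        which = int(np.searchsorted(np.cumsum(a), rng.random() * a_total, side="right"))
        which = min(which, len(a) - 1)
        counts += delta[which]
        events.append((t, which))
    return events


def petri_to_sharer(o: OpenPetriNet, beta: np.ndarray):
    """Reinterpret an open Petri net as a resource sharer.

    One state per species, one port per (singleton) foot, dynamics given by
    the mass-action vector field with the supplied rate constants.  This is
    the reinterpretation map that commutes with composition: composing the
    Petri nets and then taking mass action equals taking mass action
    componentwise and composing the sharers.
    """
    from .sharers import ResourceSharer

    if any(card != 1 for card in o.feet):
        raise ValueError("petri_to_sharer requires singleton feet")
    f = vectorfield(o.net, beta)
    return ResourceSharer(
        state_labels=list(o.net.species),
        ports=[leg[0] for leg in o.legs],
        params={},
        field=lambda t, u, p: f(u),
    )
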