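"""Rate calibration against trajectory observations and outcome sensitivity.

Calibration fits selected rate constants and/or initial values by bounded
least squares on the observed species' trajectories (sum of squared
residuals at the observation times, unweighted), restarted from several
seeded log-uniform draws inside the bounds to escape poor local minima.

The analysis outcome is the time integral of the proportion of a chosen
species subset (e.g. the non-infectious population) over a simulation;
its sensitivity to each rate constant is estimated by central finite
differences with a per-parameter step scaled to the rate's magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .mass_action import RateAssignment, Trajectory, simulate_ode
from .petri import PetriNet

__all__ = [
    "Observations",
    "SensitivityReport",
    "FitResult",
    "outcome_integral",
    "sensitivity",
    "fit_rates",
]


@dataclass
class Observations:
    """Observed values of a subset of species at increasing times."""

    times: np.ndarray
    values: pd.DataFrame  # one column per observed species label

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if len(self.values) != self.times.size:
            raise ValueError("values row count does not match times")

    @property
    def observed(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_csv(cls, path) -> "Observations":
        df = pd.read_csv(path)
        if "time" not in df.columns:
            raise ValueError("observations CSV must have a 'time' column")
        return cls(df["time"].to_numpy(), df.drop(columns="time"))

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "time", self.times)
        out.to_csv(path, index=False)


@dataclass
class SensitivityReport:
    """Outcome J, per-transition dJ/dbeta_t, and the steps used."""

    outcome: float
    per_transition: dict[str, float]
    step_sizes: dict[str, float]


@dataclass
class FitResult:
    assignment: RateAssignment
    loss: float
    start_losses: list[float]
    free: list[str]
    estimates: dict[str, float]


def outcome_integral(
    traj: Trajectory, species_subset: list[str], total: float
) -> float:
    """Trapezoidal integral of (sum of subset)/total over the trajectory."""
    if not species_subset:
        raise ValueError("species subset must be non-empty")
    if total <= 0:
        raise ValueError("total must be positive")
    for lbl in species_subset:
        if lbl not in traj.labels:
            raise KeyError(f"unknown species label {lbl!r}")
    cols = [traj.labels.index(l) for l in species_subset]
    frac = traj.states[:, cols].sum(axis=1) / total
    return float(np.trapezoid(frac, traj.times))


def sensitivity(
    net: PetriNet,
    ra: RateAssignment,
    species_subset: list[str],
    total: float,
    t_span: tuple[float, float],
    n_points: int = 201,
    rel_step: float = 1e-4,
) -> SensitivityReport:
    """Central-difference sensitivities of the outcome integral to each rate.

    Per-transition step h = rel_step * max(|beta_t|, 1); the outcome is
    J(beta) = integral of the subset proportion over t_span.  Deterministic.
    """

    def J(beta: np.ndarray) -> float:
        traj = simulate_ode(net, RateAssignment(beta, ra.u0), t_span, n_points)
        return outcome_integral(traj, species_subset, total)

    base = J(ra.beta)
    per = {}
    steps = {}
    for t, tr in enumerate(net.transitions):
        h = rel_step * max(abs(ra.beta[t]), 1.0)
        bp = ra.beta.copy()
        bp[t] += h
        bm = ra.beta.copy()
        bm[t] = max(bm[t] - h, 0.0)
        actual = bp[t] - bm[t]
        per[tr.label] = float((J(bp) - J(bm)) / actual)
        steps[tr.label] = float(h)
    return SensitivityReport(outcome=base, per_transition=per, step_sizes=steps)


def _split_key(key: str, net: PetriNet) -> tuple[str, int]:
    if key.startswith("rate:"):
        return "rate", net.transition_index(key[5:])
    if key.startswith("init:"):
        return "init", net.species_index(key[5:])
    raise KeyError(
        f"free parameter {key!r} must be 'rate:<transition>' or 'init:<species>'"
    )


def fit_rates(
    net: PetriNet,
    obs: Observations,
    free: list[str],
    bounds: dict[str, tuple[float, float]],
    seed: int,
    base: RateAssignment | None = None,
    n_starts: int = 8,
    n_points_sim: int | None = None,
) -> FitResult:
    """Fit the free rates/initial values to the observations.

    ``free`` lists parameters as ``"rate:<transition label>"`` or
    ``"init:<species label>"``; each must carry finite positive-width
    bounds.  Starting points are log-uniform draws within the bounds from a
    generator seeded with ``seed`` (first start included), each polished by
    bounded least squares on the residuals at the observation times; the
    best final loss wins.  Identical seeds give bit-identical results.
    """
    for lbl in obs.observed:
        if lbl not in net.species:
            raise KeyError(f"observed label {lbl!r} not a species of the model")
    if base is None:
        base = RateAssignment(
            np.array([t.rate if t.rate is not None else 0.0 for t in net.transitions]),
            np.zeros(net.n_species),
        )
    if not free:
        loss = float(np.sum(_residuals(net, base, obs) ** 2))
        return FitResult(base, loss, [loss], [], {})

    keys = [_split_key(k, net) for k in free]
    lo = np.empty(len(free))
    hi = np.empty(len(free))
    for i, k in enumerate(free):
        if k not in bounds:
            raise ValueError(f"free parameter {k!r} has no bounds")
        lo[i], hi[i] = bounds[k]
        if not (np.isfinite(lo[i]) and np.isfinite(hi[i]) and 0 <= lo[i] < hi[i]):
            raise ValueError(f"bounds for {k!r} must be finite with 0 <= lo < hi")

    def assignment(x: np.ndarray) -> RateAssignment:
        beta = base.beta.copy()
        u0 = base.u0.copy()
        for (kind, idx), v in zip(keys, x):
            if kind == "rate":
                beta[idx] = v
            else:
                u0[idx] = v
        return RateAssignment(beta, u0)

    def residual(x: np.ndarray) -> np.ndarray:
        return _residuals(net, assignment(x), obs, n_points_sim)

    rng = np.random.default_rng(seed)
    lo_pos = np.maximum(lo, 1e-12)  # log-uniform needs a positive floor
    starts = np.exp(
        np.log(lo_pos) + rng.random((n_starts, len(free))) * (np.log(hi) - np.log(lo_pos))
    )
    best = None
    start_losses = []
    for x0 in starts:
        try:
            res = least_squares(residual, x0, bounds=(lo, hi), method="trf")
            loss = float(np.sum(res.fun**2))
        except RuntimeError:
            loss = np.inf
            res = None
        start_losses.append(loss)
        if res is not None and (best is None or loss < best[0]):
            best = (loss, res.x.copy())
    if best is None:
        raise RuntimeError("every start failed to integrate")
    loss, x = best
    return FitResult(
        assignment=assignment(x),
        loss=loss,
        start_losses=start_losses,
        free=list(free),
        estimates={k: float(v) for k, v in zip(free, x)},
    )


def _residuals(
    net: PetriNet,
    ra: RateAssignment,
    obs: Observations,
    n_points_sim: int | None = None,
) -> np.ndarray:
    t0 = min(0.0, obs.times[0])
    traj = _simulate_at(net, ra, t0, obs.times, n_points_sim)
    res = []
    for lbl in obs.observed:
        res.append(traj[:, net.species_index(lbl)] - obs.values[lbl].to_numpy())
    return np.concatenate(res)


def _simulate_at(
    net: PetriNet,
    ra: RateAssignment,
    t0: float,
    times: np.ndarray,
    n_points_sim: int | None = None,
) -> np.ndarray:
    from scipy.integrate import solve_ivp

    from .mass_action import vectorfield

    f = vectorfield(net, ra.beta)
    t_eval = times if times[0] > t0 else times
    sol = solve_ivp(
        lambda t, u: f(u),
        (t0, times[-1]),
        ra.u0,
        t_eval=t_eval,
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y.T
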