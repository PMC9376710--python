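# opetri — compositional epidemic modelling with open Petri nets

Compartmental epidemic models (SIR and its many relatives) are usually
written down monolithically: every compartment and every flow in one flat
system of equations.  That style scales badly — adding vaccination, a
second species, or an age structure forces global edits.  `opetri` instead
builds models *compositionally*: small submodels are written independently,
opened along explicit interfaces, and glued together by a wiring diagram.
The same gluing syntax drives Petri nets, ordinary differential equations
and delay differential equations, and a pullback construction stratifies a
disease model by quarantine status, age, or spatial movement schemes
without hand-editing the product model.

The package is aimed at modellers who want the structure of a model — its
submodels and their shared populations — to be a first-class, manipulable
object rather than a comment in the code.

## The core constructions

**Whole-grain Petri nets.**  A net is four finite tables: species `S`,
transitions `T`, input arcs `I` and output arcs `O`, with maps sending each
arc to its species and its transition.  Arc multiplicity is stoichiometry:
infection has input arcs from `S` and `I` and two output arcs to `I`
(one susceptible plus one infected individual become two infected).

**Mass-action semantics.**  Each transition `t` with rate constant `β_t`
fires at flux `φ_t = β_t · ∏_{s ∈ r(t)} u_s` (product over the input
multiset, multiplicities as exponents), giving

```
du_s/dt = Σ_{t producing s} φ_t − Σ_{t consuming s} φ_t .
```

A Gillespie direct-method sampler provides the exact stochastic semantics,
with falling-factorial propensities on integer token counts.

**Open nets and wiring diagrams.**  An *open* Petri net designates exposed
places (feet/legs of a structured multicospan).  An undirected wiring
diagram (UWD) has boxes, ports and junctions; `oapply` fills each box with
an open net and identifies all places wired to a common junction.
Composition is associative and order-independent, and commutes with the
mass-action interpretation: compose-then-interpret equals
interpret-then-compose (checked pointwise to 1e-12 in the tests).

**Resource sharers.**  General ODE/DDE submodels compose by the same
syntax: identified state variables sum their rates of change.  The
Ross–Macdonald vector-borne model is shipped as three sharers (host,
vector, bloodmeal) whose composite is

```
dIH/dt = a·b·(IV/H)·(H − IH) − r·IH
dIV/dt = a·c·(IH/H)·(V − IV) − g·IV
```

**Typed nets and stratification.**  A typing is a morphism into a type
system net (e.g. one place type with transition types
disease-change / strata-change / pairwise interaction).  Typings are
model-checkable guardrails — a host/vector type system rejects
vector-to-vector transmission outright — and two models typed by the same
system stratify by pullback: pairs of same-typed places, transitions and
arcs.  SIR × quarantine yields the familiar 6-place, 9-transition model.

**Calibration and sensitivity.**  Rate constants and initial values are
fitted to trajectory observations by bounded multi-start least squares,
and the sensitivity of an outcome functional (the integral of a population
fraction) to each rate is computed by central finite differences.

## Worked example

```python
import numpy as np
import opetri as op
from opetri import fixtures as fx

# vaccination model: SIR + VIvR + cross exposure glued along 5 junctions
d = fx.fixture("uwd_fig2a")                  # 3 boxes, 10 ports, 5 junctions
composite = op.oapply(d, fx.fixture("sviivr_components"))
print(composite.net.species)
# ['S', 'I', 'R', 'V', 'Iv']

beta = np.array([0.3, 0.1, 0.05, 0.08, 0.02, 0.1, 0.03])
ra = op.RateAssignment(beta, np.array([0.94, 0.01, 0.0, 0.05, 0.0]))
traj = op.simulate_ode(composite.net, ra, (0, 160), 5)
print(np.round(traj.states, 4))
# [[0.94   0.01   0.     0.05   0.    ]
#  [0.1648 0.0802 0.3258 0.414  0.0153]
#  [0.0495 0.005  0.4803 0.46   0.0052]
#  [0.0217 0.0002 0.4937 0.4837 0.0007]
#  [0.0097 0.     0.4949 0.4953 0.0001]]

# stratify SIR by quarantine status
sq, _, _ = op.stratify(fx.fixture("sir_typed"), fx.fixture("quarantine"))
print(sq.net.species)
# ['S_Q', 'S_notQ', 'I_Q', 'I_notQ', 'R_Q', 'R_notQ']   (9 transitions)
```

The trajectory rows are the states at t = 0, 40, 80, 120, 160: the
unvaccinated susceptibles are depleted by infection and vaccination, the
epidemic passes (I returns to 0), and the population ends split between
recovered and vaccinated compartments; every row sums to 1 because each
transition conserves the total population.

The same operations are available from a shell:

```
opetri compose --uwd uwd_fig2a --components sir --components vivr \
       --components cross_exposure
# species=5, transitions=7
opetri stratify --disease sir_typed --strata quarantine --out strat.json
# species=6, transitions=9
```

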