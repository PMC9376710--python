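# Methods

This note records the modelling conventions, numerical choices and known
limitations of `opetri`.

## Data model

A whole-grain Petri net is stored as four ordered tables (species,
transitions, input arcs, output arcs) with 0-based index columns; an arc
appears once per unit of stoichiometry.  Labels are mandatory and unique
per table, although the mathematics would allow anonymous elements:
unique labels make serialization deterministic and composite models
readable.  Transition rates are optional annotations; they never
participate in morphisms or isomorphism, which are purely combinatorial.

A morphism maps the four tables so that arc endpoints are respected and,
over each transition, the arc maps restrict to a bijection onto the arcs
of the image transition.  The fibrewise-bijection reading of "preserves
arities" is a deliberate design choice: without it a binary interaction
could be typed by a unary transition type, which would defeat the purpose
of type systems (an interaction must have exactly two inputs and two
outputs).  `find_morphisms` backtracks over species assignments, then
transitions pruned by typed input/output multisets, then per-fiber arc
bijections; the worst case is exponential, which is acceptable because
every net it is pointed at (type systems, disease components,
stratification schemes) has at most a handful of transitions.
Isomorphism of nets is decided separately via VF2 on the
species/transition multigraph with stoichiometric edge weights, which is
equivalent because arcs within a fiber are interchangeable.

## Composition

Undirected wiring diagrams are the composition syntax.  Ports are
assigned to boxes and wired to junctions; an optional ordered outer-port
table exposes junctions as the composite's interface, and a diagram
without outer ports denotes a closed system (the shipped vaccination and
vector-borne diagrams are closed, since their composites are not glued
further).  Hierarchical substitution replaces a box by an inner diagram,
merging the inner interface junctions with the box's junctions; ordering
is deterministic (surviving outer rows first, then unmerged inner rows).

`oapply` glues component nets with union–find over junctions and exposed
species.  Conventions:

* Each port must expose exactly one place (singleton feet).  General
  finite-set feet are representable in `OpenPetriNet` but rejected by
  `oapply`, because no canonical gluing rule exists for unequal foot
  cardinalities.
* Junction labels win over component place labels on merged places: the
  wiring diagram is the shared vocabulary and components may use
  divergent naming conventions.
* A junction wired to no port is dropped unless it is an outer junction,
  in which case it contributes an isolated place — closed composites do
  not grow phantom places.
* Transitions are never merged, so composite transition count is the sum
  of component counts.  Transition (and unexposed-species) labels that
  would collide across components are suffixed with the component index
  (`infection[1]`), keeping the per-table uniqueness invariant.

Typed composition adds the constraint that places identified at a
junction must have the same type, and the composite then inherits a
typing by disjoint union of the component typings.

## Dynamics

The mass-action vector field uses plain powers of concentrations as the
deterministic rate law.  The flux of each transition is computed once and
then added to its producers and subtracted from its consumers, so any
transition with equal total input and output multiplicity conserves the
population sum *exactly in floating point* — conservation tests at 1e-9
pass by construction, not by solver accuracy.  States are not clipped at
zero; negativity is a useful modelling diagnostic.

The stochastic sampler implements Gillespie's direct method with
falling-factorial propensities (`n(n-1)` for a doubled input), the
standard convention for exact jump processes on token counts; this
deliberately differs from the deterministic semantics' plain powers.
Waiting times use inverse-transform sampling from one seeded NumPy
generator per call, so runs are bit-reproducible.

ODE integration uses adaptive Dormand–Prince (SciPy `RK45`) with
`rtol=1e-8`, `atol=1e-10` — tight enough that closed-form checks at 1e-6
pass with margin.  DDEs are integrated by the method of steps: windows no
longer than the shortest delay, each solved with dense output, history
lookups served by the supplied history function before `t0` and by the
accumulated dense interpolants afterwards (binary search over segments).
Only constant, fixed delays are supported; a zero delay is expressed by
coercing an ODE sharer (empty delay list), never by a `0` entry.

Resource-sharer composition merges parameter namespaces by name; a name
bound to different values by different components is an error rather
than a silent override.

## Stratification

Stratification of two models typed by the same type system is their
pullback: places are pairs of same-typed places (lexicographic order,
labels joined with `_`), transitions pairs of same-typed transitions, and
arcs pairs of arcs over the same type arc, with endpoints computed
componentwise.  Because the typings commute with sources and targets,
those endpoints are always valid pairs.  Both projections are returned
and are checked morphisms.

Scheme conventions (recorded here because the schemes are conventions,
not derived data):

* Every stratification scheme carries a disease-typed self-loop on each
  stratum place, so that disease-status transitions survive
  stratification in every stratum (otherwise SIR × quarantine would lose
  recovery inside quarantine).
* The age scheme includes both ordered (infector, infectee) interactions
  between the groups; the arc maps of the typing record the direction.
* `flux(n)`: n patch places, movement between every ordered pair
  (n(n−1) strata transitions), one interaction and one disease loop per
  patch.
* `simple_trip(n)`: places `P_ij` (currently in patch i, resident in j);
  travel changes i only; interactions pair places with equal current
  patch over all ordered residence pairs; disease loops on every place.
  For n = 2: 4 places, 4 travel, 8 interaction, 4 disease transitions.

The vector-borne composition fixtures share only the infected host and
vector populations between boxes; the susceptible pools sit inside the
bloodmeal component.  The delayed bloodmeal variant lags new vector
infections by the incubation time τ and discounts them by the survival
probability `exp(−g·τ)`; it is a reconstruction used for limit and
consistency checks only, never as a source of reference numbers.

## Calibration and sensitivity

The loss is the unweighted sum of squared residuals over the observed
species at the observation times.  Free parameters — rates and/or initial
values, addressed as `rate:<transition>` / `init:<species>` — require
finite bounds; optimization is SciPy bounded least squares (`trf`)
restarted from 8 log-uniform draws inside the bounds (seeded, so results
are bit-stable), keeping the best final loss.  On noiseless synthetic SIR
data (β = 0.3, 0.1; 20 post-initial observation times over [0, 160]) both
rates are recovered to machine precision; with 1% multiplicative noise
they are recovered within 5%.

Sensitivities of the outcome `J = ∫ (Σ subset u_s)/N dt` (trapezoidal on
the reported grid) use central differences with per-parameter step
`h = 1e-4·max(|β_t|, 1)`, cross-checked against Richardson-extrapolated
differences to 1e-4 relative.  One caveat: a transition that is
mathematically disconnected from the outcome still shifts the adaptive
integrator's step sequence, so its finite-difference sensitivity is zero
only up to integrator noise (~1e-7 at the default tolerances); it is
exactly zero when the decoupled flux itself vanishes.

## What the synthetic data does and does not show

All calibration and stochastic tests run on data generated by the models
themselves: recovery of known rates from noiseless or mildly noisy model
output demonstrates that the optimizer and the simulation agree, not that
any particular epidemic is well described.  Real surveillance data brings
reporting delays, overdispersion and model misspecification that these
tests deliberately exclude; fitting such data is out of scope here.

## Problem sizes

The shipped experiments are desk-scale by design: nets with ≤ 16 places,
morphism searches over a few hundred candidates, ODE horizons of 10–160
time units, 2 000 stochastic replicates for waiting-time statistics, and
a delay-limit check at τ = 1e-4 over half a time unit.

## Known limitations

* No tau-leaping, jump/stochastic differential equations, or SBML
  interop.
* No state-dependent or distributed delays, and no event handling in the
  DDE integrator.
* Composition along transitions (rather than places) and general
  colimit machinery are out of scope; `oapply` covers exactly the
  port-per-place gluing used by the shipped syntaxes.
* Morphism search is exponential in principle; it is an oracle for small
  type systems, not a subgraph-matching engine.
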