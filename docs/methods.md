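# Methods

## Scope

sarconet implements the computational layer of a tissue-crossing disease
map: reaction-network ingestion, signed-graph topology, synchronous
Boolean simulation with an integer storage element, and frequency-based
perturbation sweeps.  It ships no curated biological content; the bundled
toy map is a structural stand-in used for testing and demonstration.

## Network construction

Reactions come in two shapes.  *Activity-flow* arrows carry one source,
one target and a sign.  *Enzymatic* reactions keep substrates, products
and catalysts because metabolic regulation cannot be expressed as single
arrows.  Conversion to edges follows the triplet rule: substrate→product
(+1), enzyme→product (+1), enzyme→substrate (−1, consumption).  Substrate
sets of size ≥ 2 are fused into an auto-complex whose id is
`"cplx:" + sorted substrate ids joined by "+"`, which makes rebuilds and
submap merges byte-deterministic.  Duplicate `(s, r, t)` triples are
collapsed (set semantics), so multi-product reactions share one
consumption edge and path counts are not inflated by redundant curation.
Interactions sourced at disease-class elements are flagged as disease
inputs automatically; the merge of submaps unifies elements by id and
treats conflicting class/compartment metadata as an error rather than
guessing.

## Topology

`shortest_paths` is a breadth-first sweep that records *all* parent
interactions at each node's discovery depth and reconstructs every
minimal-length path backwards; for a self-query it searches the shortest
cycle through the node and never returns the empty path.  `extended_paths`
enumerates every path in which no interaction repeats (elements may
repeat, so feedback loops are traversable once).  "Stop at visited
interactions" is inherently ambiguous if edges are marked globally — the
result would depend on traversal order — so the implementation uses
per-path edge-distinctness, which is order-independent and reproducible,
with a length cap (default 8) and a path-count ceiling (default 10 000)
that flags truncation instead of silently dropping paths.  Through-element
filtering splits each surviving path at the *first* occurrence of the
element, preserving the identities `T = T_in · T_out` and
`L = L_in + L_out`.  Element ranking uses per-type denominators: the
positive fraction is computed over positive-type paths only, and a type
with zero paths reports "not applicable" rather than 0.  No edge weights,
centralities, or overrepresentation corrections are computed.

## Boolean semantics

Rules are synthesized per element: each producing reaction contributes one
AND-clause (substrate-or-complex plus catalysts), plain positive arrows
contribute singleton clauses, clauses combine by OR, and explicit negative
regulators become NOT terms.  Three deliberate choices:

* **OR across reactions, AND within one.**  Alternative biological routes
  to the same product are independent mechanisms; requiring all of them
  would conflate curation redundancy with biological necessity.
* **Consumption edges are not NOT-gates by default.**  If every enzyme
  switched its substrate OFF one step after activating, a storage element
  could never net-fill: its fill rule needs substrate AND enzyme ON in the
  same state, but the consumption gate forces them into antiphase, so the
  +1/−1 counter oscillates around zero instead of accumulating.  Negative
  *regulation* (inhibition modifiers, negative arrows, disease inputs) is
  gated; mass-flow bookkeeping is topological only.  The strict reading is
  available via `synthesize_rules(..., consumption_as_inhibition=True)`.
* **Disease precedence.**  Disease inhibitors are evaluated first and
  force the target OFF — including the ON-contribution of a storage
  element, whose counter still drains.  Ordinary inhibitors merely block
  rule satisfaction.

Elements with no inputs hold their initial state unless clamped (they are
the model's boundary: digestive enzymes, transporters, food).  Elements
with only NOT terms are constitutive-unless-inhibited, which is how
fasting responses (ketogenesis, glucagon) are expressed.  Updates are
strictly synchronous; no asynchronous or probabilistic schemes are
offered.

**Storage counters.**  A storage element's counter gains 1 each step its
rule is satisfied and loses 1 (floored at 0) otherwise, and the element
feeds downstream rules while the counter is positive.  An m-step stimulus
therefore fills to exactly m and drains back over the next m steps; the
counter is positive in 2m − 1 states (1..m rising, m−1..1 falling).
Counters are unbounded during simulation — a frequently-fed reserve grows
without limit by design — and are capped (default 64) only inside the
state hash used for cycle detection, so `find_attractor` always
terminates: a perpetually filling reserve is reported as a repeating state
with a pegged counter.  `find_attractor` hashes (state, schedule phase)
pairs, so periodic forcing schedules are handled exactly; if no repeat
occurs within `max_steps` it returns a "none" result instead of raising.

**Activity** is the fraction of ON states over the final n steps of a run
(default n = 100), with no burn-in: measurement starts at step 1, matching
the convention that a sweep simulation is exactly n steps long.  Burn-in
is configurable by simulating longer and keeping the final-n window.

## Perturbation sweeps

Forcing sequences are generated by a Bresenham-style ceiling accumulator:
step i is ON iff `ceil((i−1)p) < ceil(ip)` (computed in exact rational
arithmetic to dodge float edge cases).  For p = 1/k this puts one ON step
at the head of every k-block; for arbitrary p it spreads exactly
`ceil(np)` ON steps over any n-window, so the realized frequency is always
within 1/n of p.  Inhibition uses the same marks as forced-OFF steps and
leaves the element free otherwise — which also means inhibiting a
rule-governed element lets it recover between marks, while p = 1 is a full
knockout.

A sweep runs one independent simulation per grid level (default 0–100 %
in 1 % steps), always restarting from the initial state so levels cannot
contaminate each other.  Schedules compose in a fixed order — nutrition
pattern, then the swept perturbation, then user clamps — with disease
precedence applied inside the engine.  The correlation x-variable is the
imposed forcing level (equal to the realized source activity for
set-activity mode, and the imposed deficiency for inhibition mode).
Pearson r on a constant activity series is reported as *undefined*, not
zero: zero would claim "tested, no correlation".  Transmitter ranking
scores each candidate e as `|r(e, source)| · |r(e, target)|` over the
sweep's activity curves, with the sign pair classifying the transmission
mode; the product-of-correlations form is this package's concretization
of "correlates with both ends".  No multiple-testing correction is
applied across targets.

Nutrition presets are periodic block patterns on the food-intake element:
undernourished 5 ON / 25 OFF, well-nourished 5 ON / 10 OFF, overnourished
5 ON / 2 OFF steps.

## The toy map

The fixture map wires a recognizable carbohydrate backbone: food intake →
luminal glucose → SGLT1 (SLC5A1) absorption → blood glucose →
insulin/glucagon counter-regulation → hepatic glucose → glycogen (the
storage element, built by glycogen synthase, released by glucagon-driven
glycogenolysis), hepatic glycolysis with ATP product-inhibition (the
negative feedback that makes the fed steady state oscillate between
glycolysis and glycogen synthesis), ketogenesis as a fasting response,
GLUT4 (SLC2A4) muscle uptake, the four muscle phenotypes and their
catabolism/anabolism/sarcopenia read-outs, and two disease nodes: LC
suppressing hepatic glucose handling and driving systemic inflammation,
ID suppressing absorption and driving inflammation.  Three wiring choices
carry the qualitative regimes:

* insulin responds to gut glucose and food ingestion ahead of the blood
  peak (incretin-like and cephalic-phase signals), which lets the reserve
  start filling early in a feeding block;
* fasting glucose comes *only* from the glycogen pool (glycogenolysis
  requires the counter to be positive), so blood glucose oscillates during
  depletion and dies out when the reserve empties — there is no
  glucose-conservation-violating loop between compartments;
* while food is coming in, dietary glucose spares the reserve (a
  food-gated self-maintenance clause on glycogen), so brief feeding gaps
  do not drain it.

Under the three presets the reserve then shows three regimes: full
depletion every period (undernourished), a positive steady trough
(well-nourished), and unbounded growth (overnourished).  The steady-state
checks exclude the first two feeding periods as cold-start transient,
since the model starts with an empty reserve.  Intracellular elements of
different tissues never share a reaction; all cross-tissue communication
travels through extracellular species (hormones, metabolites,
inflammation), which is what makes the three-submap split merge back
losslessly.

What the toy map does **not** emulate: the size and redundancy of a real
curated map (hundreds of elements, many parallel routes), quantitative
kinetics, nutrient composition beyond carbohydrates, and any specific
literature-derived edge.  Passing tests on it demonstrate that the
algorithms honor their contracts and that the qualitative carbohydrate /
disease logic is reproducible — not that any particular biological claim
holds in vivo.

## Random-network fixtures

Property tests run against seeded Erdős–Rényi-style signed digraphs
(each ordered pair, self-pairs included, carries an edge with probability
`density`, negative with probability `negative_fraction`).  The same spec
always serializes identically.  Path searches are cross-checked against
networkx (shortest) and an independent recursive enumerator (extended);
attractor detection is checked against brute-force trajectory analysis
over the full state space of ≤ 10-element networks.

## Numerical and degenerate-input choices

Frequencies are converted to exact fractions
(`Fraction(p).limit_denominator(10**6)`) before the accumulator, so
IEEE-754 noise cannot shift a mark.  Ties in element rankings and
transmitter tables break lexicographically by id.  Empty path sets rank
nothing; through-filtering an endpoint is an error; sweeps with n < 2 or
unknown sources are errors.  SBML ingestion ignores stoichiometry and
boundary conditions (the model is qualitative), treats reversible
reactions as forward-only with a warning, defaults unknown species
classes to protein, and maps unknown compartments to extracellular with a
logged warning.  The SBML reader/writer is built directly on lxml and
covers SBML L2/L3 core plus the small CellDesigner annotation subset the
toolkit uses (species class, storage flag, modification types).

## Known limitations

* Storage drain is at most 1 per step; inhibitors do not accelerate it.
* The well-nourished regime drifts upward slowly rather than reaching a
  bounded cycle: with ±1 counter dynamics, an exactly balanced period is
  a knife-edge, so "continuous storage" is realized as
  positive-trough-with-drift, clearly separated from the undernourished
  (periodic zero) and overnourished (fast growth) regimes.
* Global edge-marked BFS variants of the extended search are not offered;
  results would depend on traversal order.
* No SBML-qual import/export; Boolean rules exist only in-memory and in
  the JSON dialect.
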