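# Methods

This note records the model, the conventions and defaults the package
commits to, and what the shipped synthetic data can and cannot show.

## The model

A fault tree is a DAG whose nodes are failure events: one **top event**,
**intermediate events** produced by AND/OR gates, and **basic events** at
the leaves.  `failed = True` means the event occurs (FTA convention);
functionality is the complement.  Gates take one or more inputs (a
one-input gate is a pass-through, which keeps sparsely described subtrees
encodable without inventing structure).  Only AND and OR are supported —
the food-system model uses nothing else — so every tree is monotone
(coherent): failing more components can never un-fail the system.  That
monotonicity is what makes minimal cut sets, path-set duality, and the
bounds used in testing meaningful.

Trees are partitioned into subtrees; a gate input written
`subtree:<id>` substitutes that subtree's top event (a transfer
reference).  Transfers create genuinely *repeated* events — in the shipped
tree, production failure feeds both the supply chain and the
decreased-supply path to high food prices — and repeated events are exactly
what invalidates the closed-form probability recursion (see below).

**Population groups.**  A gate may carry per-group type overrides.  In the
food-system tree, availability fails for the donation-reliant group when
*either* the supply chain or the donation system fails (OR), but for the
rest of the population only when *both* fail (AND).  Group weights are a
partition of the community (sum to 1) and drive population-weighted
functionality curves.

**Indicators and thresholds.**  A basic event may be backed by a
quantitative indicator with a direction (`ge`/`le`) and threshold.
Comparison is *inclusive*: a threshold that is reached counts as attained.
An optional `population_fraction_threshold` encodes the requirement that an
event only counts as a *system* failure when enough people are affected;
it is applied at basic events only (applying such guards at intermediate
events is a possible extension, not implemented).  Missing basic-event
states are an error by default; the `default_operational` policy is an
explicit opt-in, so modelling gaps cannot pass silently.

## The shipped food-system tree

The fixture transcribes a published conceptual fault-tree model of an
urban (Baltimore-style) food system: 12 subtrees, 81 events, top event
"food system failure", first level OR over inaccessibility, unavailability
and unacceptability.  Subtree interiors that the source narrative does not
describe are filled with clearly named placeholder basic events so the
structure is complete and analyzable; `provenance.csv` records for every
event whether it is text-attested or a placeholder, with a short citation
locator.  Placeholders default to operational in all shipped scenarios.

Choices the source leaves open, fixed here once:

- **Thresholds are illustrative** (road obstruction ≥ 0.5 of streets,
  water-supply deficit ≥ 0.2, farm-count decline ≥ 0.10, seasonal yield
  loss ≥ 0.5, transit service ≤ 0.5 of nominal).  The source model
  explicitly defers empirical threshold-setting; these values exist so the
  case studies are mechanically evaluable and are flagged in the tree
  metadata.
- **Group weights** (general 0.8 / donation-reliant 0.2) are illustrative.
- **Restaurants** are not a separate retail sibling (the source treats
  them as covered by retail).

## Case-study scenarios

**Blizzard (hourly, t=0 at storm end, span −48..240 h).**  Road
obstruction is 1.00 through day 5, then steps to 0.15 (the midpoint of the
reported "80–90% passable" range) and to 0.00 at 216 h.  Values between
anchors are stepwise constant (right-continuous): holding the last
reported value fabricates less than interpolating.  Transit is fully shut
down through the two storm days, then restored in graded steps reaching
nominal at 96 h; the 96-hour restoration is encoded as *following* the
shutdown (the narrative is ambiguous about whether it includes it — the
alternative reading would make restoration end at 48 h).  Full road
clearance is anchored at 216 h (9 days) measured from the scenario's t0 at
storm end; the narrative's "9 days after the storm's initial start" admits
an alternative anchor 48 h earlier.  Delivery-truck access is blocked
while side streets remain uncleared (through 216 h).

**Drought (monthly, 52 months).**  The declared-emergency window spans
months 12–50.  During it the water-deficit indicator (0.35) exceeds its
threshold and the extreme-weather basic event is failed, while farm-count
decline stays at 0.0 (farm numbers remained stable) and yield loss at 0.12
stays below its 0.5 threshold.  Replaying this through the tree reproduces
the documented cascade shape: resource depletion and productivity
decreases trigger, farm business failure and single season failure do not,
and the community-level top event never fails.  An optional
`price_spike_variant` additionally fails the supply-chain-cost basic event
during the window, encoding the documented expectation that food prices
react before production fails outright; it is off by default because the
source phrases it conditionally.

## Quantitative engine

Basic events are independent Bernoulli failures over an unqualified
analysis horizon; the engine is agnostic about what the horizon means
(per-event vs per-season probabilities), and dependence between basics
(common-cause failures) is out of scope — both are contracts, documented
not checked.  Methods:

- `bottom_up`: P(AND) = ∏pᵢ, P(OR) = 1 − ∏(1 − pᵢ); valid only when no
  event reaches the top twice, which is detected structurally and refused
  otherwise.
- `enumeration`: exact weighted sum over all 2ⁿ assignments, vectorized in
  chunks; default limit n ≤ 20.
- `monte_carlo`: vectorized Bernoulli sampling; binomial standard error;
  reproducible at a fixed seed.  `auto` prefers bottom-up, then
  enumeration, then Monte Carlo.

Birnbaum importance uses two conditioned evaluations sharing method and
seed (common random numbers under Monte Carlo).  Fussell–Vesely computes
the numerator P(∪ cut sets containing b all fail) exactly over the
involved basics when ≤ 20, else by Monte Carlo; FV is reported NaN when
P(top) = 0 (undefined).  Cut-set enumeration guards against combinatorial
blow-up with a working-set cap (10⁶) and an optional `max_order`
truncation (complete up to that order).

## Resilience operationalization

Functionality of a node is 1 − failed; per-group curves are binary, the
population-weighted curve is the convex combination with group weights.
The resilience index is the normalized area under the step-interpolated
(zero-order-hold) curve over a window — a resilience-triangle-style
metric, this package's operationalization of "functioning over time", not
a formula inherited from the source model.  Recovery-time modes:

- `outage` (Boolean series): first failure to first *sustained* recovery;
  relapses restart the clock; never-failed → 0; never-recovered → `None`.
- `restoration_interval` (indicator): end of the worst-value plateau to
  first return to nominal — the graded-restoration phase length.
- `full_restoration` (indicator): from t0 to first sustained return to
  nominal.  Nominal values come from the scenario header, defaulting to
  the first observation.

## Hazard simulator

Single-onset hazards: each covered event fails at t=0 with its onset
probability and recovers after a draw from its recovery distribution
(`fixed`; `geometric` on support {1, 2, ...} with mean 1/p;
`lognormal` discretized by ceiling).  Every event consumes exactly two
uniforms in sorted order via inverse-transform sampling, so hazards
compared under one seed share common random numbers, and per-run seeds
derive from the master seed by a counter-based scheme
(`SeedSequence([seed, run])`).  Mid-horizon re-failures and correlated
failures are out of scope.  The per-event contribution table is an
observational split of runs (mean R with vs without the event's onset
failure), not a causal decomposition.

## Numerical and testing choices

Canonical serialization is JSON with sorted keys and events sorted by id,
so structurally equal trees serialize byte-identically.  Validation never
raises; findings are ordered by (location, code).  Weight-sum tolerance is
1e−9; step-curve integration is exact for step functions, and tests check
it against dense midpoint Riemann sums aligned to the breakpoints (1e−9).

Test oracles are independent of the code paths they check: naive
unmemoized recursion for evaluation, exhaustive truth tables with subset
minimalization for cut sets (trees up to 12 basics, 200 random trees in
the end-to-end suite), weighted truth-table sums for probabilities and
importance, and a hand-rolled DFS for cycle detection.  Monte-Carlo
calibration checks that 100 seeded trials cover the exact value within 4
standard errors at least 95 times.  Problem sizes (random trees of 2–12
basics, 20 000-sample Monte Carlo, 400-run simulations) are chosen so the
whole suite runs in well under a minute while the oracles remain
exhaustive rather than sampled.

**What the synthetic data does not show.**  The shipped tree is a
*conceptual* model with illustrative thresholds: passing case-study
replays demonstrates that the encoded logic reproduces the documented
cascade shapes, not that the thresholds, weights, or placeholder interiors
are empirically right for any real city.  Random-tree tests establish
correctness of the algorithms on small trees; they say nothing about the
tractability of cut-set enumeration on very large industrial trees (a BDD
backend would be the natural extension there).
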