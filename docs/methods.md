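# Methods

## Model and update semantics

The package simulates deterministic Boolean networks of the Kauffman
family with a signed-threshold update rule. Nodes are partitioned into
control nodes (inputs, held fixed per run) and internal nodes. At every
step each internal node computes the signed sum of its regulators'
current states, `r_i = Σ_j s_j w_ij` with `w_ij = ±1`, and takes the
value 1 exactly when `r_i` strictly exceeds `n_i/2 − m_i`, the midpoint
of its attainable range (`n_i` regulators, `m_i` inhibitory). Two
consequences of this rule are worth stating explicitly:

- **Ties go to 0.** A node with two activators of which exactly one is
  active sits on the midpoint and stays off; activators behave
  conjunctively near the threshold.
- **Regulator-free internal nodes collapse to 0** after one step
  (`r = 0` is not strictly greater than the threshold 0). They are
  permitted but flagged here because the behaviour follows from the
  rule, not from a modelling choice.

Updates are synchronous: all internal nodes read the same current
state. The rule is defined node-locally from current values, which is
only self-consistent under a simultaneous update; no node ordering is
defined anywhere, so an asynchronous scheme would have been an
arbitrary extension. Only the single step function would need changing
if one were wanted.

The threshold comparison is evaluated as the integer inequality
`2 r_i > n_i − 2 m_i`; thresholds are exposed as exact `Fraction`
values (integer for even `n_i`, half-integer for odd). No floating
point enters the dynamics, basin weights or activities — floats appear
only in the combined reporter statistic and in reporting.

## Attractors, basins and ensemble averages

Every trajectory of the finite deterministic map ends in a steady state
(period 1) or limit cycle. Attractor identity is the canonical rotation
(lexicographically minimal encoded-integer sequence) of the *full*
state — internal plus control bits — so the same internal cycle reached
under two control states counts as two final states; a merged
convention (internal bits only) is available as an option where
cross-control deduplication is wanted.

For one control state all `2^N_int` initial conditions are enumerated.
Basin weights `p(F) = I(F)/2^N_int` are exact rationals and are checked
to sum to 1. Ensemble activities `ᾱ_i(C) = Σ p(F) α_i(F)` are likewise
exact; they equal the arithmetic mean over initial conditions, which
the tests verify directly on small fixtures.

**Engine.** States of the free internal nodes are packed into unsigned
integers. Per control state the full next-state map is materialized
once by a numba kernel that walks the state space in gray-code order
(each step flips one source bit, so only that bit's targets update
their regulator sums), then attractors and basins are recovered by a
linear-time functional-graph traversal with an explicit path stack.
Complexity is O(2^n_free) time and memory per control state; a guard
refuses runs above a configurable cap (default 2^28 states). The
24-free-bit CARENET space takes roughly half a second per control
state on one CPU. A naive per-initial-condition engine written against
the high-level dynamics layer serves as an independent oracle; the two
are required to agree exactly on randomized networks with up to 12
internal nodes.

**Clamps.** Control actions override a node after each update;
permanent clamps emulate knockout (0) or constitutive (1) alleles.
Permanently clamped internal nodes are excluded from the enumerated
initial-condition bits — their initial value is the clamp value — and
the basin-weight denominator counts free internal nodes only. This
halves the space per clamp and cannot change reachable attractors or
averages. Time-windowed clamps are honoured in single-trajectory
simulation only (recurrence detection starts after the last window
expires); attractors under temporary overrides are not well defined,
so windowed actions are rejected in ensemble runs.

## Reporters, combined activity and bins

Cambium proliferation is read out through WOX4 and HB8 (ATHB8). The
combined proliferation activity is by default the quadratic mean
`sqrt((ᾱ_WOX4² + ᾱ_HB8²)/2)`, chosen because it preserves scale (both
reporters at `x` give `x`, so bin boundaries mean the same thing for
single and combined reporters); the plain mean-square variant without
the root is selectable (`combined_variant="mean-square"`) since both
readings of a quadratic-mean statistic are defensible. Activity bins
are none `[0, 0.25)`, low `[0.25, 0.5)`, medium `[0.5, 0.75)`, high
`[0.75, 1]`: closed below with the top endpoint included, so the four
bins exactly cover `[0, 1]`.

## Perturbation protocols

The hormone-effect profile fixes one control node at 1 versus 0 while
every remaining free control varies over all assignments; the reporter's
ensemble activity is averaged *unweighted* over those assignments (no
weighting across control states is defined by the biology, so each is
treated as equally likely). The two-hormone interaction scan fixes all
other controls and reports the reporter activity on the 2×2 on/off
grid. Both accept a precomputed scan to avoid re-enumeration.

## Chi-squared association tests

Continuous activities are discretized with the same equal-width binning
convention as above (binary variables pass through). Expected counts
use the standard row×column marginal products — the named test is
Pearson's independence test, and a uniform-expectation goodness-of-fit
mode is kept behind a flag for comparison only. All-zero rows/columns
are dropped before computing `dof = (r−1)(c−1)`; tables left with fewer
than two non-empty rows or columns are flagged inconclusive rather than
tested. Direction of a significant association uses an ordinal
heuristic: the mean category index of variable 1 conditional on each
level of variable 2 must be strictly increasing (positive) or strictly
decreasing (negative); anything else is indeterminate. No
multiple-testing correction is applied; decisions are per test at the
stated level (default 0.05). Monte-Carlo calibration on
independence-sampled tables is part of the acceptance suite.

For association reports, pairs involving a plain internal node are
observed per *distinct final state*, unweighted (each attractor of the
whole scan once; its combined activity is computed from its own
reporter activities); all other pairs are observed per control state.
Basin-weighted counting is available as an option. The choice of
observation unit is a genuinely open point — per-attractor and
basin-weighted conventions can disagree — and both are exposed.

## The bundled CARENET definition

The 30-node cambium network (6 hormonal controls, 24 internal nodes)
ships as a plain data file in the package's own definition format, not
as code: the edge list is curated from prose-level experimental
evidence on cytokinin, auxin, ethylene, brassinosteroid, gibberellin
and TDIF/PXY signalling, and single-file edits are the intended way to
refine it. The least-constrained choices (endocytosis wiring
RRB→ENDO⊣PIN, HB8 regulated by ARF alone, WOX14 as a sink) are marked
provisional in the file.

Consequences of this provisional wiring, measured by the acceptance
script, should be read as properties of *this* edge list rather than of
cambium: the full scan yields 134 distinct final states (124 limit
cycles, periods up to 8); WOX4 strictly requires PXY and ERF jointly,
so control states without TDIF score zero WOX4 activity; the wild-type
response of WOX4 to external auxin comes out slightly negative (the
PIN-mediated efflux loop dominates), whereas the other five inputs are
positive; and the unconditioned auxin–cytokinin association across
final states rejects independence but with non-monotone (U-shaped)
conditional means, while the same test conditioned on CK0=0, IAA0=1 is
cleanly negative. The structural mutant results are wiring-robust:
knocking out PXY removes all TDIF sensitivity and knocking out WRKY all
brassinosteroid sensitivity, exactly.

## Random fixtures

The generator draws, per internal node, a Poisson(mean in-degree)
number of distinct regulators uniformly from all nodes (self-loops
allowed, controls never targeted) with each edge inhibitory with the
stated probability. Defaults used in the test suite (2–12 internal
nodes, mean in-degree 2, inhibition fraction ~0.3) keep fixture
networks in the sparse, mixed-sign regime the bundled model inhabits:
42 edges over 24 internal nodes, 9/42 inhibitory. Everything is driven
by an explicit seed; there is no global random state. What passing
fixture-based tests show is correctness of the engines on this class of
random threshold networks — not biological adequacy of any particular
wiring, which only the curated edge list addresses.

## Problem sizes and determinism

The test suite runs the truth-table oracle on 200 random regulator
sets (all configurations up to n=8), the engine-equivalence oracle on
50 random networks, the two CARENET mutant protocols (64 half-space
enumerations each) and one full CARENET scan; the whole suite completes
in a few minutes on one CPU. The acceptance script repeats the full
scan, both mutant protocols and a 2000-table calibration in about a
minute. Every computation is deterministic given the seed; reruns are
bit-identical.

## Known limitations

- Synchronous updates only; asynchronous/stochastic schemes and
  continuous-time logical semantics are out of scope.
- Binary states cannot express partial-strength or dominant-negative
  alleles.
- Equiprobable initial conditions are hard-wired into the basin
  weights; non-uniform priors are not supported.
- The edge list is evidence-limited as described above; quantitative
  CARENET numbers are conditional on it.
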