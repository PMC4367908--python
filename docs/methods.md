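# Methods

## The discrete model

The network couples two functional modules of a *C. elegans* vulval
precursor cell: fate determination (Ras/MAPK and Notch signalling: LIN-3,
MPK-1, LIN-39, LS, LIN-12m, LIN-12i) and cell-cycle control (CKI-1, EFL-1,
LIN-35, SCF, APC and the three CDK/cyclin complexes). Node levels are
discrete — LIN-3 has four levels because graded Ras signalling selects
between tertiary (0), secondary (1) and primary (2) outcomes, with a fourth
level (3) for signalling strong enough to override negative regulation;
MPK-1 and LIN-39 carry three levels as its downstream readouts; everything
else is Boolean. Updates are synchronous and deterministic: the model's
dynamics is the iteration of a single total function on 73,728 states.
Asynchronous and stochastic update schemes are deliberately out of scope;
the continuous model below addresses the one artifact synchrony could
introduce.

Two textual ambiguities in the rule set are resolved as follows:

* **CKI-1 rule grouping.** The activating condition is read as
  `CYD = 0 AND (APC = 1 OR CYB = 1)`. The continuous counterpart
  `ω_CKI-1 = min(1 − CYD, max(APC, CYB))` fixes this grouping, and under it
  the isolated module reproduces the canonical 11-state cycle
  (G1-1 … G1-6, S1, S2, G2, M1, M2) exactly.
* **Sigmoid normalization.** The SQUAD activation is implemented as
  `A_h(ω) = (−e^{h/2} + e^{−h(ω−1/2)}) / ((1 − e^{h/2})(1 + e^{−h(ω−1/2)}))`,
  which satisfies A(0) = 0, A(1/2) = 1/2 and A(1) = 1 exactly. The variant
  with the opposite exponent sign in the denominator (which is not
  normalized) is kept behind `ContinuousParams(legacy_denominator=True)`
  for comparison only.

## Variants: mutants, removals, Wnt loss

A **clamp** pins one node at one level, overriding its rule; the 32 single
clamps (the sum of the node cardinalities, input parameters included) form
the mutant screen. An **interaction removal** substitutes the regulator's
inactive level 0 for every occurrence of the regulator inside the *target's*
rule only — this simultaneously withdraws activations and permanently
disarms inhibitions through that arrow, and leaves every other rule intact
(removing LIN-3 → LIN-12i, for instance, touches only the LIN-12i rule).
The basal ("otherwise") level of LIN-39 is a model parameter: 1 in the wild
type, 0 to emulate loss of Wnt input, which exposes the fusion fate.

## Attractor engine and its oracle

The synchronous map is materialized as a successor-index table (vectorized
evaluation of all 14 rules over the decoded state space, mixed-radix encode
back). States on cycles are found by iteratively peeling in-degree-zero
states (vectorized Kahn elimination): what survives is exactly the union of
attractors. Basins follow by propagating attractor labels backwards through
the table until fixpoint. Attractors are canonically rotated to start at
their lexicographically smallest state; attractor identity across model
variants means equality of these canonical state sequences. The engine is
cross-checked, on the isolated module and on hundreds of seeded random
multi-valued networks, against an independent oracle that follows the
trajectory from every state with a visited-set; the two share no code.

Exhaustive enumeration refuses (rather than silently samples) above a
configurable state-space bound, default 2²⁴.

## Phases, fates, screen classification

Phase labels use marker precedence M (CDK-1/CYB-3) > S (CDK-2/CYE-1) > G2
(SCF) > G1; the resulting G1 criterion (CYE = CYB = SCF = 0) reproduces the
canonical G1-1 … G1-6 block of the module cycle, which is why it is the
operational phase boundary — the phases have no other formal definition in
a logical model. Fate precedence is primary (max LIN-39 = 2) > secondary
(LIN-12i active anywhere in the cycle) > fusion (LIN-39 = 0 throughout) >
tertiary; precedence matters because the primary attractors never raise
LIN-12i while LIN-39 is high, and tertiary is the default background.

Screens compare each perturbed attractor landscape with wild type at two
strengths:

* `attractors_identical` — strict state-by-state equality of canonical
  attractor sets;
* `no_effect` — equality of the attractor *landscape*: per-microenvironment
  attractor counts, periods and fates.

The landscape reading is the package's operational definition of "no effect
on the dynamics": it tolerates a single marker toggling in one or two cycle
states while every period, attractor count and fate is preserved. Under it,
12 of the 38 removals are neutral (10 of them already strictly); the two
landscape-only cases are MPK-1 → LIN-12m (LIN-12m becomes constitutive in
the primary attractors, where it tracked CDK-4/CYD-1) and
CDK-1/CYB-3 → CKI-1 (CKI-1 no longer anticipates M-exit by one step in the
low-Ras attractors). Cell-cycle behaviour classes: *quiescent* (only fixed
points, or no S/M marker ever fires), *endoreplication* (the S marker
oscillates, the M marker never fires), *short/long cycle* (complete
G1-S-G2-M progression in every microenvironment, uniformly faster/slower
than wild type), *other* (anything else, e.g. coexisting extra attractors).
The aggregate class counts in the screen reports depend on these operational
thresholds and are reported, not asserted, except where an individual
perturbation's behaviour is itself a stated model prediction.

## Signed graph and circuits

Interaction signs are derived from the rules by the discrete-derivative
definition: regulator *i* activates (inhibits) target *j* if some
configuration and level pair a > b makes `f_j` increase (decrease) in *i*;
both together make the interaction ambiguous. The derivation is exhaustive
(all configurations, all level pairs) and finds exactly one ambiguous
interaction, LIN-3 → LIN-12i. The curated 38-edge map is shipped as data
(`data/curated_interactions.tsv`) so the census can be re-run on edited
graphs; it excludes the two input identity self-loops and a rule-implied
positive MPK-1 self-influence, and includes the three genuine self-loops
(LIN-39, LIN-12i, CDK-1/CYB-3). `compare_graphs` reports all differences
between the rule-derived and curated graphs.

Circuits are simple directed cycles (networkx's Johnson enumeration,
deduplicated by rotation to the smallest node; a DFS-with-path-masking
oracle cross-checks the enumeration), signed by the parity of their
inhibitory edges; cycles crossing an ambiguous edge are refused a sign and
reported separately (none arise on the curated graph, as the ambiguous edge
leaves an input node). The packaged loop catalogue
(`data/published_feedback_loops.tsv`) pins the expected 111 memberships;
its per-row glyphs disagree with the rule-derived sign of
LIN-35 → CDK-2/CYE-1 in four rows and misfile one further row against its
own glyphs, which is why the catalogue's 60/51 positive/negative split is
not reproducible from any consistent edge signing — the parity counts under
the rule-derived signs are 59/52, and the five affected rows are reported
by the circuit analysis rather than silently adopted.

## Continuous validation

The eight cell-cycle rules are relaxed to `dXᵢ/dt = A_h(ωᵢ) − γXᵢ` with
h = 10 and γ = 0.95 (so a fully driven node saturates at 1/γ ≈ 1.053). The
ω-algebra uses min for AND, max for OR, 1 − x for NOT; at every Boolean
corner it equals the discrete rule with MPK-1 = 0, LIN-39 = 1 (a tested
invariant). Integration uses adaptive Runge–Kutta (scipy `solve_ivp`,
rtol 1e-8, atol 1e-10, max step 1.0), with state components clipped to
[0, 1] inside the ω evaluation to guard against solver overshoot.

Started from the quiescent G1 corner (CKI-1 = LIN-35 = APC = 1, rest 0),
the module sustains a limit cycle for the full 200-time-unit run: all eight
components keep peak-to-trough amplitudes above 0.4 in the trailing half,
with period ≈ 9.7 against the 11 synchronous steps of the discrete module.
Oscillation detection requires amplitude ≥ 0.2 in ≥ 2 components over the
trailing half — thresholds at which the oscillating regime and a fixed
point are separated by more than a factor of two in either direction (the
overdamped γ = 10 control decays below 0.1 everywhere). The thresholded
(0.5) limit cycle dips briefly (≈ 0.6 time units) below both S and G2
markers between its two S/G2 excursions, so the phase-order check reads the
*first-visit* order of phases between successive M episodes, a
parameter-free statistic; it is G1 → S → G2 → M, matching the discrete
progression. State-by-state identity with the discrete cycle is not
expected and not required. Only the eight cell-cycle nodes are continuized;
the fate module has no published fuzzy logic and stays discrete.

## Synthetic networks

The random-network generator emulates the structural class the engine
assumes — synchronous multi-valued networks with per-node cardinalities and
identity-held inputs — as explicit lookup tables, reproducible from a
single seed. Outputs are uniform per configuration with an optional
`zero_bias` knob concentrating mass on level 0: uniform tables almost
always collapse to short transients and fixed points, while sparse biased
ones oscillate, so the test battery mixes biases. These fixtures exercise
the engine/oracle equivalence across cardinal structures (including input
nodes) up to 2¹⁶ states; they make no attempt to mimic biological rule
structure (canalization, monotonicity), so passing them validates the
*engine*, not the biology. The 11-state expected time series of the module
is a hand-derived fixture checked to close cyclically under the rules and
to coincide with the engine's module attractor up to rotation.

## Numerical and reporting conventions

All iteration orders are sorted and all screens are deterministic;
re-running any analysis yields byte-identical tables. Floating-point output
uses nine significant digits. Attractor tables, screen tables and the
basin map (behind a flag: 73,728 rows) are TSV; network exports are SIF and
GraphML; each CLI run writes a manifest echoing its configuration and the
package version.

## Known limitations

* Boolean LIN-12i cannot express partial loss of its activation, so
  removals that experimentally lower (rather than abolish) LIN-12i levels
  register as no-effect.
* Clinical phenotype vocabulary (Muv/Vul) is derived from fate maps and
  reported as annotation only; concordance scoring against literature
  phenotypes is out of scope, as are double mutants, dosage effects,
  asynchronous updating, bifurcation analysis and parameter fitting of
  h/γ.
* The screen behaviour classes are operational definitions over attractor
  landscapes; borderline perturbations (e.g. mixed-period landscapes) fall
  into *other* by construction.
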