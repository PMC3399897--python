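# Methods

## Model

`procnet` works with two objects: a *Boolean process* — a T x N matrix
S, where S_i(t) in {0, 1} is the observed state of molecule i at discrete
time t — and a *signed interaction network* over the same nodes, described
by three Boolean families: inhibitory edges a_ji, stimulatory edges b_ji
(ordered pairs, j != i) and per-node self-degradation bits r_ii.  The
dynamics are synchronous and assume *dominant inhibition*: any active
inhibitory input switches a node off regardless of stimulation,

    S_i(t+1) = [ for all j: NOT (a_ji AND S_j(t)) ]
               AND [ (exists j: b_ji AND S_j(t)) OR (S_i(t) AND NOT r_ii) ].

A node turns on only when stimulated and uninhibited; an on node stays on
while uninhibited unless it self-degrades with no active stimulator.
Self-activation is excluded (a self-activating molecule can always be split
into two nodes); self-influence is carried entirely by r_ii.

A weighted threshold variant is provided in which stimulation contributes
+1, inhibition -R (R >= 1, the dominance weight), thresholded by sign with
ties keeping the state unless the node self-degrades.  The printed algebra
of the threshold rule admits several equivalent renderings; the one
implemented is pinned by the property the rest of the stack relies on and
which the test suite checks exhaustively at small N: for R >= N the
threshold rule coincides bit-for-bit with the Boolean rule.

A network *realizes* a process when it reproduces every observed row
transition.  *Canonical* networks never carry both signs on one ordered
pair; non-canonical networks are representable (they arise naturally as
satisfiability witnesses) and are dynamically indistinguishable from their
canonical form because inhibition dominates.  Solution counting is always
over canonical networks.

## Feasibility in polynomial time

For a target node i, write U_i(t) for the nodes other than i active at time
t, W_i for the union of U_i(t) over transitions whose successor has i on
(these nodes provably cannot inhibit i), and V_i(t) = U_i(t) \ W_i.  Each
observed transition of node i yields one constraint over i's incoming
variables:

* 0->1: some b over U(t); no a over U(t)
* 1->1: (some b over U(t)) or r_ii = 0; no a over U(t)
* 1->0: some a over V(t), or (r_ii = 1 and no b over U(t))
* 0->0: some a over V(t), or no b over U(t)

Distributing the last two gives CNF with at most |U(t)| + 1 clauses per
transition — O(N^2 T) literals overall.  A single global change of
variables (prime every a and b: a' = NOT a, b' = NOT b; leave r) turns every
clause family into Horn form (at most one positive literal), so
satisfiability is decided by unit propagation in time linear in the formula.
Correctness of the flip is enforced by an exhaustive solution-set
preservation test at small N rather than by clause-by-clause bookkeeping.

Unit propagation also yields the unique *least model*, whose inverse image
under the flip is the deterministic *witness network*: forced assignments
are pinned, every free or unmentioned edge variable defaults to "edge
present", every free r to 0.  The witness is dense by design; sparsity is
the minimality module's job.  Probing each variable with both unit pins
(both remain Horn) classifies the *backbone*: edges present in all
solutions, edges absent from all solutions, free edges.  Probing quantifies
over all solutions including non-canonical ones; the forced classifications
transfer verbatim to the canonical solution set.

Degenerate inputs: a one-row process has no transitions and is feasible by
definition; a 0->1 transition with nothing else active yields an empty
disjunction, kept as an explicit false clause.

## Minimality

The per-node constraints never couple different target nodes, so the
minimal realizing network decomposes into per-node minima.  Exact per-node
optimization enumerates all 2 * 3^(N-1) canonical assignments, vectorized
as bitmask arrays and filtered transition by transition; pairs in W drop
from three states to two.  The enumerator refuses nodes whose reduced
search space exceeds a configurable cap (default 8 x 10^6 assignments).
Deterministic tie-break: the lexicographically smallest optimal assignment
(r = 0 preferred, pair states ordered none < inhibit < stimulate along
ascending source index).  The count of per-node optima multiplies into the
number of distinct minimal networks.

The greedy heuristic runs per node and per r branch: phase 1 covers the
rows that need a stimulator (all 0->1 rows; also 1->1 rows when r = 1) by
greedy set cover over candidate sources; phase 2 covers the inhibitor
obligations that follow (0-target rows where a chosen stimulator fires, and
1->0 rows when r = 0) by greedy set cover over sources outside W.  Both r
branches are tried and the smaller edge set kept; r is not part of the
objective (degradation is free), which is also why the exact oracle
branches on r and compares edge counts only.  Greedy ties prefer the
candidate inducing fewer phase-2 obligations, then the lowest node index;
r ties prefer r = 0 (fewer assumed mechanisms).  In rare adversarial
columns both greedy branches can fail even though the column is feasible
(a tie-broken stimulator choice can strand an obligation); such nodes fall
back to the exact per-node optimum so the returned network always realizes
the process, and the result records which nodes used the fallback.

The deviation harness reports greedy-minus-exact totals (nonnegative by
construction) over a seeded ensemble as counts and fractions at 0, 1 and
>= 2.  Some published summaries of this experiment use the opposite sign
convention (actual minus estimated); the report notes its own.

## The set-cover reduction

Minimal-network inference is NP-hard; the executable reduction compiles a
coverable minimum-set-cover instance (n elements, m sets) into a gadget
process whose collector node Z turns on after every element's pattern row.
Z's 0->1 constraints are then exactly the cover clauses, one per element,
over the stimulatory set-node edges S_k -> Z.

The layout uses two helper tiers because a single driver creates activation
conflicts: even-row relays E_e accompany each element pattern and stimulate
the odd-row driver D_{e+1}, which stimulates the next pattern.  Two tail
rows (all relays on, then everything off) leave Z and the set nodes with no
inhibitor able to explain a stray stimulation, which forces b(E_e -> Z) = 0
and b(Z -> S_k) = 0; this pins Z's clauses to the set nodes alone and makes
every helper column cost-constant across minimal solutions.  Consequently
the S -> Z stimulatory edges of *every* exact-minimal gadget network form a
minimum cover, which `recover_cover_from_network` reads back.  The gadget
has m + 2n nodes and 2n + 2 rows — polynomial in the instance.  Its
correctness is enforced semantically (random instances, double brute
force) rather than by matching any particular figure layout.

## Designability

The number of canonical networks realizing a process (its designability D)
is the product of per-node enumeration counts; it is zero exactly when the
process is infeasible.  Exact counting is exponential in N, so a
polynomial-time estimator regresses ln D on six solution-space features,
counted over ordered pairs via enumeration at small N or Horn probing at
scale (the two routes are tested to agree):

* M1 / M2 — pairs forced inhibitory / stimulatory in every solution,
* M3 / M4 — pairs where inhibition / stimulation is impossible
  (inclusive: these counts contain the M5 pairs),
* M5 — pairs where any connection is impossible,
* M6 — pairs where all three states remain possible.

"Inhibition attainable" needs only the a-pin: a solution with a = 1 maps to
a canonical solution with the pair inhibitory, because the stimulation bit
is inert under dominant inhibition.  The model is ordinary least squares of
ln D on (1, M1..M6); natural log, recorded in the model object together
with the feature-definition version so fits are self-describing.  Ensembles
generated by network-mode simulation are often feature-collinear (some
feature is constant or dependent), in which case the minimum-norm solution
is returned with a warning — predictions are unaffected.  Reference
coefficients are not shipped: the fit is always recomputed from a seeded
generator, and quality is judged by the in-sample Pearson correlation
between predicted and exact log-designability.

## Synthetic ensembles

`GeneratorConfig` fixes the study conditions: N = 5, T = 6 for the witness
and minimality ensembles and N = 4, T = 5 for the regression ensemble
(sizes at which the exhaustive oracles stay comfortably tractable on one
CPU), edge density 0.3 per ordered pair, 40% of edges inhibitory, and
degradation probability 0.5 — sparse, inhibition-lean wiring of the kind
biological Boolean models typically exhibit, chosen once and reported with
every experiment.  Two ensemble modes exist because "random feasible
process" is underdetermined: `network` simulates a random canonical network
from a random initial state (feasible by construction, the distribution is
biased toward dynamically reachable processes, and trajectories often
settle into fixed points early, as real regulatory snapshots do);
`rejection` draws uniform 0/1 matrices and keeps feasible ones (unbiased
over feasible processes but exponentially expensive as N or T grows; the
retry cap fails loudly and suggests network mode).  Every experiment
records which mode produced its data.  What these synthetic ensembles do
not emulate: measurement noise, missing observations, asynchronous or
stochastic update order, and multi-valued expression levels — results on
them certify the algorithms, not robustness to dirty data.

## Reference fixture

The budding yeast cell-cycle trajectory (13 steps x 11 regulators) is
transcribed from the published synchronous Boolean cell-cycle model of Li,
Long, Lu, Ouyang and Tang (PNAS 101:4781, 2004, Table 2).  The
transcription is verified in-repo by reconstructing the published network
and checking that its majority-rule trajectory from the START state
reproduces the transcribed table bit-for-bit.  On this trajectory the
exhaustive oracle computes an exact minimality of 18 edges and 640 distinct
minimal networks under the dominant-inhibition model; both numbers are
recomputed, never stored.  These computed values differ from some published
reference figures for "the" yeast cell-cycle process (23 edges; 40,300 or
40,320 minimal networks), which were obtained on a process table that is
not printed in the corresponding articles and is evidently not identical to
Li's Table 2; the discrepancy is stable under dominance-weight changes,
fixed-point extension and degradation-counting variants, so this package
reports what its own oracle computes.

## Numerical and engineering choices

* All dynamics are int8 numpy arrays; enumeration uses int64 bitmasks with
  `np.bitwise_count` for edge totals.
* HORNSAT is the classical counter-based unit propagation: linear in total
  literal count; the least model is unique, which makes witnesses and
  backbones deterministic.
* Clauses are deduplicated order-preservingly; DIMACS export writes the
  flipped (Horn) formula plus a sidecar variable map sufficient for exact
  re-import.
* Backbone probing costs two HORNSAT calls per variable — quadratic-ish but
  simple and exactly polynomial; no incremental propagation is attempted.
* Enumeration caps raise a typed error advising the greedy / probing routes
  rather than silently degrading.

## Known limitations

* Exact minimality, exact counting and enumeration-based features are
  exponential in N and guarded by caps; beyond them only the greedy
  heuristic, Horn probing and the regression estimator apply.
* The greedy heuristic carries no approximation guarantee on edges (only
  its set-cover subroutine has the classical logarithmic bound), and its
  exact-fallback path means worst-case cost can briefly touch the
  enumeration cap.
* The regression coefficients depend on (N, T) and on the generator mode;
  the package deliberately refuses to pretend otherwise by shipping
  constants.
* Asynchronous updates, probabilistic dynamics, attractor analysis and
  noisy/partial observations are out of scope.
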