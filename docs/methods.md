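# Methods

## Scope and definitions

A **motif** here is an isomorphism class of a small connected digraph
(sizes 1–4 supported for exact canonicalization; statistics run at size
≤ 3). Two motifs A and B form a **combination** when they share `Nv`
nodes, `1 ≤ Nv ≤ min(nA, nB) − 1`: sharing all of the smaller motif's
nodes would absorb it into the larger one, so at least one node of each
motif must remain exclusive. They form an **interaction** when they stay
node-disjoint and at least one directed cross-edge links them; `nA·nB`
node pairs and two directions give `2^(2·nA·nB)` labeled directed
interaction topologies (`2^(nA·nB)` undirected), counting the empty set
and isomorphic duplicates exactly as the closed form does.

### Core-topology enumeration

`enumerate_combinations` generates every injective identification of
`Nv` positions of A with `Nv` positions of B and keeps an identification
only if **both motifs remain induced occurrences on their designated
node sets** — i.e. the merged graph restricted to a motif's nodes
carries that motif's edges and nothing else. Concretely, when two
identified node pairs carry an edge in both motifs, the edges must
coincide in direction; identifying an X→Y pair of one FFL with the Y→X
pair of another would create a mutual edge inside both motifs and is
excluded. Merged graphs are then deduplicated by exact canonical form
(minimum adjacency encoding over all permutations), which also quotients
the A/B exchange symmetry when the two motifs are the same class. Under
this convention two FFLs yield 6 one-node and 6 two-node core
topologies (12 total), two mutual dyads yield 1, and a dyad with an FFL
yields 3 — while a shared *aligned* edge (e.g. two 3-cycles sharing two
nodes) remains a valid core. The alternative convention that tolerates
conflicting shared edges would yield 18 FFL×FFL patterns; it is not
used.

**Extensions** add any subset of admissible cross-edges (directed edges
between one motif's exclusive nodes and the other's) to a core,
deduplicated up to isomorphism; every extension contains its core as a
subgraph.

## Census and roles

Connected k-node subgraphs are enumerated exactly with the ESU algorithm
on the weak skeleton; "connected" means weakly connected, the standard
motif convention. Canonical keys are exact (all k! permutations; cheap
for k ≤ 4), and each occurrence is stored as a node tuple in canonical
position order with ties inside automorphism orbits broken
lexicographically, so every subgraph is reported exactly once.

Motif **roles** are automorphism orbits of the motif's positions,
computed by exhaustive permutation check. Roles are purely structural
(unsigned topology); edge signs enter only in the dynamics module.
Known classes carry conventional labels (FFL: input / intermediate /
output; chain: the same; V-out: input + one symmetric output role;
mutual dyad and 3-cycle: a single symmetric role); unknown classes get
`orbit0, orbit1, …`.

## Enrichment pipeline

1. Designate motif classes: user-specified, or auto-called as connected
   2- and 3-node classes with Z > 2 against a degree-preserving
   edge-switching null (the calling cutoff is a configurable default;
   20 null samples by default for this step).
2. Assign every motif-participating node to its role(s); a node's
   multiplicity in a role is the number of instances in which it plays
   that role.
3. For every unordered pair of distinct roles compute the Jaccard index
   of the deduplicated node sets. For each role's diagonal compute the
   fraction of its nodes appearing in that role more than once.
4. Generate 100 random networks preserving N, E, per-node in/out
   degrees, self-loops and the full connected 3-node census (below);
   recompute all statistics on each.
5. `Z = (observed − null mean)/null sd`; one-sided normal tail in the
   direction of Z (the over/under split makes the sided choice);
   Benjamini–Hochberg jointly across all off-diagonal and diagonal
   statistics; call `over` (Z > 0) or `under` (Z < 0) when q < alpha
   (default 0.05). Statistics with zero null variance or empty role
   sets are flagged degenerate and excluded from the correction.

### The census-preserving null

Preserving the triad census exactly is what separates hypermotif
enrichment from ordinary motif statistics: the null must be allowed to
re-place motifs anywhere the degrees permit, while keeping the *number*
of each small subgraph fixed. The sampler is a Metropolis random walk
over degree-preserving double-edge swaps whose energy is the L1
distance between the current and original 3-node class-count vectors:

- an **exploration phase** starts from the original network (distance 0)
  and runs `6·E` proposals at temperature 0.6, which typically relocates
  over 90% of edges while staying within a few census counts of the
  target;
- an **annealing phase** (geometric cooling from T = 0.3 to a floor of
  0.05) returns the walker to distance exactly 0, usually within a few
  thousand proposals; a sample that fails to close within the step
  budget is retried from a fresh substream and an error is raised after
  repeated failures.

Each proposal's census change is computed incrementally: a swap
`(a→b, c→d) → (a→d, c→b)` can change the class only of triples
containing one of the four touched node pairs, so only ~4·N triples are
reclassified per proposal, via a 512-entry lookup table indexed by the
6 off-diagonal and 3 self-loop bits of a triple. Self-loops are never
touched by swaps. A full scramble-then-anneal variant was evaluated and
rejected: from a fully scrambled state the anneal frequently fails to
reach distance 0 within practical budgets, whereas the walk above closes
every sample and passes the identical contract (degrees, E, census all
exactly preserved; samples differ from the original).

### What a green detection test establishes

The synthetic benchmark plants combination patterns onto background
nodes chosen to have no pre-existing edges among them, so each planted
occurrence is induced-exact and the planted nodes also carry background
degree. That last point matters: if plantings are placed on *fresh*
nodes, the degree sequence plus census pins the motif junctions to the
planted nodes and the null reproduces the overlap almost exactly —
correctly reporting "no enrichment beyond lower-order structure". The
benchmark therefore emulates a network whose motif arrangement is a
genuine degree of freedom. It does not emulate heavy-tailed degree
distributions, modular structure, or signed/weighted edges.

## Hill-function circuit models

Every non-input node obeys `dX/dt = β_X · G_X − α_X · X` with
`G_X` the AND (product) or OR (`1 − Π(1 − h_i)`) combination of Hill
terms: activation `Y^n/(k^n + Y^n)`, repression `k^n/(k^n + Y^n)`.
Parameters: `k` half-effect (concentration units), `n ≥ 1` cooperativity
(dimensionless), `β` maximal production, `α` linear removal (1/time).
Defaults are β = α = 1, k = 0.5, n = 2; a node may be declared an
external input driven by a step function and is then not integrated.

Integration uses LSODA (rtol 1e-8, atol 1e-10), states clipped at zero.
Fixed points come from multi-start `hybr` root solving on a grid scaled
by max β/α, deduplicated at 1e-6, RHS tolerance 1e-9, classified by
Jacobian eigenvalues (stable node/spiral, saddle, unstable, marginal;
eigenvalue real parts within 1e-7 of zero are "marginal"). Trajectory
labels ignore the first 30% as transient; a pulse is a single interior
maximum with final level below half the peak; sustained vs damped
oscillation is decided by the trend of successive peak-to-trough
amplitudes (ratio ≥ 0.9 sustained). Phase relations use the
cross-correlation peak lag relative to the period estimated from peak
spacing: |lag|/T < 0.1 in-phase, |lag/T − 0.5| < 0.1 anti-phase.

### Fixture parameters and why

The reference parameter tables for the original figure panels are not
available, so each named fixture carries parameters tuned once to place
it in its characteristic regime, frozen in the registry, and never
revisited:

- **Feedback pairs (TMFL, LMFL, OMFL)**: β = 2. At the default β = 1
  (k = 0.5, n = 2) the symmetric fixed point of a mutual-feedback pair
  is exactly marginal (the loop gain equals removal), so β = 2 places
  the switches safely inside bistability. OMFL uses n = 4 so the stable
  spiral's frequency clearly exceeds its decay and the damped ring-down
  shows several peaks.
- **Self-loop combinations**: added self-edges use k = 0.3. At
  k = 0.5 the self-activation gain at the interior fixed point exactly
  cancels removal, leaving it marginal; k = 0.3 keeps it hyperbolic.
  With these, the toggle switch gains exactly the OFF–OFF state, the
  Lock-ON gains nothing, and the oscillator gains exactly two states
  (OFF–OFF and activator-only-ON; a repressor-only-ON state is
  impossible because the repressor needs the activator to rise).
- **FFL + self-loop on the intermediate (I1FFL+SLY)**: β_Y = 4,
  β_Z = 2, and a sensitized input→output edge (k = 0.05). The
  self-loop makes the repressor Y bistable in the input level: a strong
  step (X = 0.5) pushes Y over its threshold and the output pulses; a
  weak step (X = 0.1) lets Y collapse, the repression lifts, and the
  output rises to a high steady state with a delay.
- **Shared-edge 3-loop pair (3LOOP-PAIR)**: n = 4 throughout (a
  three-stage negative loop needs loop gain above the secant bound to
  sustain oscillation); the all-positive loop's return edge W→X has
  k = 4 and X combines its activators by OR, so the positive loop reads
  the oscillation without flooding X's production and quenching the
  negative loop. The exclusive nodes of the two loops (Z and W)
  oscillate in anti-phase: W follows Y while Z is repressed by Y.
- **Double-mutual-feedback pair (DMF-PAIR)**: heterogeneous k, β, α
  found by seeded random search and frozen verbatim. At these values
  the single circuit only rings down, while the pair — whose shared
  repression edge lets each motif's third node add drive through X's OR
  gate — sustains oscillation with the two exclusive nodes exactly in
  phase (they are dynamically symmetric).
- **Mutually interacting FFLs (FFL-PAIR)**: heterogeneous parameters
  frozen from a seeded search. The coherent FFL's output activates the
  incoherent FFL's input and the incoherent FFL's output represses the
  coherent FFL's input, closing a six-stage negative loop that
  oscillates — something no feedforward circuit can do alone, since a
  strictly feedforward system has a permutation-triangular Jacobian
  with real negative eigenvalues.

## Downsampling

The neighborhood random-walk sampler takes `sz` steps; each new entry is
a uniform neighbor (in- or out-; direction is irrelevant for coverage)
of the previous entry with probability 0.85, otherwise of the current
anchor. At one third of the walk the sampler re-anchors if fewer than
`(sz/3)/2` unique nodes have been collected; at two thirds, if fewer
than `sz/3` (integer floor in both). The result is the induced subgraph
on the unique sampled nodes, capped at `sz`. Measured on a homogeneous
300-node benchmark, sampled out-degree histograms sit within L1 distance
~0.25 of the full network's (recorded baseline 0.4): the walk mildly
oversamples high-degree nodes, which is inherent to neighborhood
sampling.

## Known limitations

- Census preservation (and hence enrichment) is limited to 3-node
  subgraphs; 4-node-preserving nulls are an open problem.
- Exact canonicalization and combination enumeration stop at motif size
  4; interaction enumeration is guarded by a subset budget.
- Interaction patterns (linking edges) are enumerated and modeled but
  not statistically tested; the detection pipeline covers combinations.
- The ODE models are deterministic; noise-driven conversion of damped to
  sustained oscillation is out of scope.
- Sampling variability of the enrichment Z depends on the annealer's
  mixing; ensembles are seed-reproducible but not exchangeable with
  other samplers' ensembles.
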