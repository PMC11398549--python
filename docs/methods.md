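# Methods

This note documents the models, algorithms and numerical choices behind
`fibsym`, in the order the pipeline runs them.

## Graphs and the baseline connectome

Graphs are simple, unweighted and directed; an anatomically undirected
white-matter track is represented as two opposite arcs, expanded when an
edge-list TSV is loaded. Node order is fixed and defines row/column order of
every matrix downstream, so runs are reproducible bit-for-bit.

The packaged 11-ROI dorsal-stream language connectome contains, per
hemisphere: the arcuate fasciculus direct segment (Broca–Wernicke), the
arcuate/SLF branches to the inferior parietal areas (Broca–SMG, Broca–AG,
SMG–Wernicke posterior segment), the superior longitudinal fasciculus
(premotor–SMG, premotor–AG), dorsal pathway I (premotor–Wernicke), and the
frontal aslant tract (SMA–Broca); homotopic callosal connections join every
bilateral ROI pair, and two directed premotor→SMA arcs complete the graph
(11 nodes, 44 arcs). No machine-readable edge list of this network is
published, so the fixture is a reconstruction from the anatomical track
descriptions; it is validated by three independent checks: (a) its coarsest
balanced coloring has the five known classes, with Wernicke and supramarginal
areas merging into one 4-ROI fiber; (b) its automorphism orbits equal the
same five classes (group symmetry = fibration symmetry, group order 4,
including the hemispheric mirror and the Wernicke/SMG swap); (c) the
resting-state and task target colorings are reachable by arc removals alone.
A user-supplied edge list overrides the fixture everywhere.

## Fibers, orbits, input trees

The coarsest balanced coloring is computed by iterated refinement from the
monochrome coloring: split classes by the multiset of in-neighbor colors
(encoded as sorted count vectors) until a fixed point; the fixed point is the
unique coarsest equitable partition and is re-verified by an independent
balance check after every run. Color ids are canonicalized by smallest member
index.

Input trees are built bottom-up to a default depth |V|−1 — the refinement
provably stabilizes within that many rounds, so the finite truncation induces
the same node partition as the (conceptually infinite) trees. The canonical
encoding sorts child encodings, making it invariant under child order.

Automorphisms are found by backtracking over node images, pruned two ways:
images are restricted to the candidate's fiber (orbits refine fibers, and the
coarsest coloring is canonical, so every automorphism fixes each fiber
setwise), and partial maps are rejected at the first adjacency violation. All
automorphisms are enumerated — practical for the ≤16-node graphs this package
targets (a hard cap guards the exponential worst case) — and orbits are the
union-find closure of node images. Correctness is anchored to brute-force
enumeration over all node permutations on random ≤7-node digraphs, not to an
external canonical-labeling tool.

## Phases, PLV, surrogates

Signals are demeaned, optionally band-passed with a zero-phase 4th-order
Butterworth filter (applied forward–backward; the default 0.01–0.1 Hz band at
TR = 2.5 s matches the slow-fluctuation regime of resting-state BOLD), and
Hilbert-transformed; the phase is the argument of the analytic signal.
Constant (or in-band-constant) series are rejected rather than producing
undefined phases.

The PLV of a pair is the modulus of the time-mean unit phasor of the phase
difference; the full matrix is computed in one complex Gram product. Group
averaging is the arithmetic mean over subjects with strict label checking.

Surrogate significance: per permutation, one series of each pair is
circularly shifted by a random offset and, with probability 1/2,
time-reversed. A circular shift commutes with the DFT-based analytic signal,
so null phases are shifts of the observed phase series (the reversed variant
gets its own transform); this preserves the autocorrelation structure of the
null, unlike a full shuffle (available behind a flag). Empirical p-values use
the add-one rule p = (1 + #{null ≥ obs})/(n_perm + 1). When p would fall
below 10/n_perm the tail is re-estimated by a generalized Pareto fit to
exceedances above the null's 90th percentile (both thresholds configurable),
p = 0.1 · GPD tail probability. Family-wise control uses the 95th percentile
of the per-permutation maximum PLV across pairs; a Benjamini–Hochberg mask is
provided separately because max-statistic (FWE) control and FDR are distinct
procedures and the literature sometimes conflates them.

## Cluster-synchronization detection

A CS is a clique of the functional network whose total internal
synchronization dominates every link leaving it: for an N-clique,
Σ_{i<j} σ_ij ≥ [N(N−1)/2] · σ(k, k′) for every member k and outside
neighbor k′. Detection is a percolation: off-diagonal PLVs enter a growing
graph in decreasing order, and maximal cliques among unassigned nodes are
tested largest-first after each addition.

Two numerical choices matter here.

*Quantization.* PLVs are rounded to 3 decimals before percolation (the
precision at which PLVs are conventionally reported). A PLV estimated from
~160 samples carries sampling error orders of magnitude above 10⁻³, so links
whose weights agree at that resolution are statistically indistinguishable
and enter the percolation as ties, added as one batch. Reported Cluster PLVs
(the mean internal PLV that orders the CS hierarchy) use the unquantized
entries. The precision is a parameter of `detect_cs`.

*Deferred freezing.* A naive rule — freeze any clique the moment the
domination condition holds — degenerates: the very first link added always
forms a 2-clique that trivially dominates its (empty or weaker) boundary, so
no cluster larger than a pair could ever form. Instead, while links remain, a
clique freezes only when it strictly dominates a non-empty boundary in the
current graph, and an isolated clique (a connected component, still growing)
freezes once the next weight level to be added is strictly too weak to grow
it profitably. When the links are exhausted, remaining cliques resolve with
the inclusive ≥ convention: ties pass, and an isolated clique passes
vacuously (hence a matrix with all-equal off-diagonal entries yields a single
all-node CS, the fully symmetric reading of the condition). Frozen nodes
leave the pool; leftovers become singletons. Tie-breaks are deterministic
(size, then mean PLV, then lexicographic node order).

## MILP inference

Variables: r_ij for every arc (removal), a_ij for every ordered non-edge
(addition; absent in removal-only mode), and indicator pairs s_pq^R for every
ordered cross-color node pair and color. Constraints: (i) for every
same-color pair p, q and every color S, surviving-plus-added in-arcs into p
from S equal those into q (balance); (ii) every node with positive baseline
in-degree keeps in-degree ≥ 1 — a node with no baseline in-arcs is a
free-running source that could never satisfy the floor in removal-only mode,
and exempting it in both modes keeps the modes comparable (relaxing
removal-only to removal-and-addition can then never worsen the optimum);
(iii) optionally, for every cross-color pair and every color R,
in_R(p) − in_R(q) ≥ s_pq^R − n·s_qp^R and symmetrically, with
s_pq^R + s_qp^R ≤ 1 per color and Σ_R (s_pq^R + s_qp^R) ≥ 1 across colors,
forcing an imbalance on at least one color — necessary but *not sufficient*
for the target coloring to be coarsest. Objective: α·removals + β·additions,
defaults α = β = 1. The big-M multiplier is n = |V|. An optional flag ties
the two directions of an anatomically undirected track.

The solver is HiGHS through `scipy.optimize.milp` (deterministic,
single-threaded). Because the minimality indicators are only necessary, every
optimum is re-validated outside the solver: balance re-checked directly, the
coarsest coloring of the perturbed graph compared to the target (the
authoritative minimality check), in-degrees re-counted, and the orbit count
reported for the symmetry read-out. If the coloring is balanced but not
coarsest, a no-good cut excluding the incumbent is added and the solve
repeats (bounded retries); the validation report carries any residual
failure. Removal-only infeasibility is reported prominently: it is the
falsification branch of the hypothesis that function selects routes from a
fixed structural highway.

A brute-force oracle (exhaustive enumeration of removal subsets by size,
capped at 16 arcs) certifies MILP optima and probes optimum uniqueness on
small instances. The 44-arc fixture is beyond exhaustive reach; its
resting-state optimum (10 removals) is certified by the solver's optimality
status and by the post-hoc validation. Alternate optima exist in general; all
counts asserted by the tests (inferred fiber counts 4 and 5) are invariant
across optima we have probed, while the orbit counts of the inferred networks
depend on which optimum the solver returns and are reported informationally
only.

## Synthetic data

The generator runs the logic in reverse so every stage is testable without
any external data.

*Structure.* A base graph (classes with in-arc multiplicities) is lifted to a
full graph: each lifted node of class T draws multiplicity(S→T) in-arcs from
distinct members of fiber S uniformly at random. The planted coloring is
balanced by construction (asserted on every draw); a draw whose *coarsest*
coloring is strictly coarser than planted is rejected and regenerated. The
default condition has four fibers of sizes 4/3/2/2 (11 nodes, mirroring the
language network size); its base multiplicities form a chain with distinct
per-class in-profiles, so the planted partition provably equals the coarsest
coloring, while keeping within-fiber wiring dominant — the regime in which
shared drives produce detectable cluster synchronization.

*Dynamics.* Identical Kuramoto-type phase oscillators,
θ_i′ = ω + K Σ_j A_ij sin(θ_j − θ_i) + σ_shared·ξ_fiber(i) + σ_ind·ξ_i,
integrated by Euler–Maruyama (dt = 0.1 s, K·dt < 1 enforced; burn-in 50 s
discarded; phases emitted on the TR grid, default 160 samples at 2.5 s).
Identical node equations make the dynamics admissible: with zero noise and
fiber-equal initial conditions the fiber-synchrony subspace is flow-invariant
to machine precision (tested). The per-fiber shared noise (σ_shared = 0.3) is
the mechanism that makes *fibers* — rather than the globally locked state —
visible in the PLV matrix, emulating common within-cluster drive; the
independent noise (σ_ind = 0.05) sets the within-fiber PLV below 1. Initial
within-fiber jitter is 10⁻³ rad so synchrony is dynamically maintained rather
than an artifact of identical states. ω defaults to 2π·0.05 rad/s, the middle
of the analysis band. The observable is sin θ, band-passed to 0.01–0.1 Hz and
written as time-series CSV.

*Recovery.* Partition agreement is scored as exact-match plus the adjusted
Rand index. At the default condition, the full loop (lift → simulate → PLV →
CS detection) recovers the planted partition in roughly 90–100% of 20 seeded
runs; failures are fragmentations of the largest fiber when its internal PLVs
straddle a quantization boundary.

What the generator does *not* emulate: hemodynamic convolution (the
observable is a phase readout, not a balloon model), inter-subject
variability, task block structure, measurement noise with realistic spectra,
and negative or lagged couplings. Passing recovery tests therefore
demonstrates the internal consistency of the pipeline under its own
admissible-dynamics assumptions, not performance on real BOLD data.

## Pipeline and determinism

The `fibsym` CLI exposes each stage as a subcommand (`phases`, `plv`, `cs`,
`infer`, `symmetry`, `simulate`, `run`); a YAML config drives the full run,
with defaults mirroring the target regime (1,000 permutations, 0.01–0.1 Hz,
TR 2.5 s, 160 volumes). Runs starting from a printed coloring (no time
series) are first-class. Every source of randomness takes an explicit seed;
re-running a config reproduces byte-identical JSON reports. Stage failures
abort with the stage name attached.

## Known limitations

- The automorphism search is exponential and intended for mesoscopic graphs
  (≤ ~16 nodes); it is not a general graph-isomorphism tool.
- The MILP grows as O(|𝒮|·|V|²) indicator variables with the minimality
  constraints on; for much larger graphs the constraints should be disabled
  and minimality enforced by the no-good-cut loop alone.
- The coarsest-coloring match after inference can fail in principle (the
  indicator constraints are not sufficient); the package surfaces this in the
  validation report rather than silently accepting the solution.
- CS detection on matrices whose cluster structure is weaker than the
  quantization step (10⁻³ by default) degenerates toward the all-equal
  reading; the precision parameter should then be raised.
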