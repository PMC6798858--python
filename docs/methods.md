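# Methods

## The model

`tumorca` simulates avascular tumor growth as a stochastic cellular
automaton on a finite 2-D lattice ζ with site states ε = {0, 1} (empty /
one tumor cell).  Once per discrete step, every live cell draws a fate
from four biologically motivated outcomes:

* **death** — with probability `1 − W`, where `W = p_survive` is the
  per-step survival probability;
* **proliferation signal** — with probability `W′ = p_signal` the cell
  receives a mitogenic signal; its counter PH is incremented and, once
  `PH ≥ NP` (`np_threshold`), the cell attempts mitosis: a daughter is
  placed in an empty neighboring site and PH resets to 0;
* **migration** — a surviving, non-signaled cell attempts, with
  probability `W″ = p_migrate`, to move to an empty neighboring site;
* **quiescence (G₀)** — anything else, including attempts that found no
  empty site.

A single uniform draw `rr ∈ [0, 1)` partitions the first three branches:
`[0, W′)` → signal, `[W′, W)` → migration branch (a second draw gates
the migration attempt), `[W, 1)` → death.  With the default values the
intervals are disjoint, so the rule is a genuine categorical
distribution with P(die) = 0.2 and P(signal) = 0.2; an equivalent
formulation with independent draws per branch would instead give
P(divide | survive) = W′·W = 0.16 and was deliberately not used — the
one-draw partition is the literal reading of the reference algorithm,
and the fate-distribution test pins it (DIE/PROLIFERATE/MIGRATE =
0.20/0.20/0.15 with all neighbors empty).

### Parameters

| name           | meaning                                   | default | units  |
|----------------|-------------------------------------------|---------|--------|
| `p_survive`    | per-step survival probability W           | 0.8     | —      |
| `p_signal`     | proliferation-signal probability W′       | 0.2     | —      |
| `p_migrate`    | migration probability W″                  | 0.25    | —      |
| `np_threshold` | signals needed to leave G₀ (NP)           | 1       | count  |
| `ph_init`      | initial signal counter (PH) of seeds and daughters | 1 | count |
| `delta`        | longest per-step displacement δ           | 1       | rows   |
| `neighborhood` | candidate-target set                      | von Neumann | — |
| `rho`          | imbalance threshold triggering balancing  | 10      | %      |

The defaults are the reference parameterization of the growth
experiment this package reproduces.  Target sites for mitosis and
migration are the 4 axial neighbors scanned in a uniformly random order
(one integer draw selects one of the 24 orders); the attempt succeeds
with the first empty site found, so a cell fails only when every
candidate is occupied.  An 8-site Moore candidate set is available via
`neighborhood="moore"`.  Borders are fixed and non-periodic:
out-of-bounds sites count as permanently occupied.

PH semantics beyond NP = 1 are an under-determined corner of the model
family; this package resets PH to 0 on successful mitosis and gives
daughters `ph_init`, which reduces to "every signal triggers an
attempt" at the default NP = 1.

### Criticality of the default parameterization

Under the defaults the model cannot sustain growth.  Each cell dies
with probability 0.2 per step and divides with probability at most 0.2
(exactly 0.2 only while an empty neighbor exists), so the expected
population change per step is ≤ 0: the live count is a supermartingale,
critical only for a fully uncrowded population.  From a single seed the
population is a critical branching process (offspring 0/1/2 with
probabilities 0.2/0.6/0.2) and goes extinct almost surely; an
established mass decays because crowded interior cells die without
compensating divisions.  The suite computes both facts: a ~1250-cell
disk loses > 75 % of its cells within 500 steps, and 4000-step
single-seed runs end with zero cells after a few dozen evaluations.
Consequently the published final-size range (103,704–133,964 cells
after 4000 steps) and processed-cells range (115.6M–159.8M) are not
reachable by the literal rule at the stated parameters; the acceptance
script reports the values the rule actually produces, and the engines'
correctness is carried by the exact and distributional property tests
instead.  Growth regimes (e.g. `p_survive = 1`) are fully supported and
used throughout the suite where an expanding mass is needed.

## Engines

### Sequential two-list engine

The live cells sit in a list; a step consumes the list in order,
applying the fate rule to each cell against the *current* lattice
(updates are in place), and appends survivors and daughters to the next
step's list.  Work per step is proportional to the live-cell count, not
the lattice area.  In-place updating means a target chosen as empty can
be taken before the fate is applied; the cell then stays quiescent for
the step — the same conflict semantics the parallel engine relies on.
Daughters are appended to the next list and first evaluated one step
after birth (born quiescent).  Processing order is list insertion
order; order affects individual trajectories but not the distribution
of interest, and a row-major pre-sort exists for exact comparison with
the scan oracle.

### Naive-scan oracle

`step_oracle` scans every lattice site in row-major order and evaluates
live cells only, consuming RNG draws exactly as the list engine does.
Started from the same RNG state with a row-major-sorted list, both
engines produce bit-identical next states; the suite asserts this on
100+ randomized states.  It exists purely as an independent oracle for
the list engine's bookkeeping.

### JIT path

`run_fast` is the identical two-list algorithm compiled with numba on
flat arrays, used for full-scale runs (10⁸ cell evaluations in tens of
seconds).  It draws from numba's own seeded RNG, so for a fixed seed it
is reproducible but does not match the Python engine draw-for-draw;
agreement is asserted distributionally (KS test on final sizes over 40
paired short runs) plus exactly on deterministic-growth scenarios.  The
fast path covers the default rule (von Neumann, δ = 1) only.

## Parallel scheme

### Geometry

For `t` workers the lattice is cut into `t` horizontal regions, each
split into top-seam / center / bottom-seam parts; the two seam parts at
a region boundary form a seam.  Every part is at least δ rows tall, so
between any two same-type parts lie at least two other parts (≥ 2δ
rows).  Since no cell moves more than δ rows per step, two workers
processing same-type parts can never write into each other's target
subregions — this is the invariant that makes the phase-ordered update
lock-free.

Initial placement: with the seed mass spanning rows
`[row_min, row_max]`, the internal boundaries are spaced evenly inside
a band of height `H⁰ = max(row_max − row_min, 3δt)` centered on the
mass (3δt is the minimum height that fits t three-part regions), and
the outer regions are extended to the lattice edges.  Integer spacing
uses floors, which keeps every internal region ≥ 3δ rows.

### Stepping

A step runs three phases — all bottom seam parts, then all centers,
then all top seam parts — with a barrier between phases; worker *i*
consumes region *i*'s current list for the phase's part type and routes
every output record (survivor or daughter) to the next list of the
subregion containing its position under the geometry of that moment.
After the third phase a coordinator records metrics, starts/advances
seam moves and swaps the current/next lists.

The engine realizes this contract serially: workers run in index order
inside each phase.  Barriers make within-phase interleaving
unobservable provided no two workers share a next list — exactly the
spacing guarantee, which a debug mode verifies by tagging every append
with its writer and raising on conflict.  The serial realization buys
bit-exact reproducibility: worker *i* draws from a dedicated stream
derived from `(master seed, region index, step)`
(`numpy.random.SeedSequence` spawn keys), so a fixed `(seed, t)` gives
a fixed trajectory.  A thread-pool realization would satisfy the same
post-conditions but not reproducibility, which is why the package does
not use one — with Python's GIL it would add nondeterminism and no
throughput.

### Load balancing

After each step the coordinator computes per-region live counts from
the lattice census (cell lists may be stale).  A seam qualifies for
adjustment when the relative difference `100·|cᵢ − cᵢ₊₁| /
max(cᵢ, cᵢ₊₁, 1)` exceeds the threshold ρ (percent).  The `max(·, 1)`
denominator is a choice: it bounds the statistic in [0, 100] and is
well-defined for empty regions.  Qualifying seams are started in
decreasing order of imbalance (ties to the lower index), never two
adjacent seams at once, and never when the shrinking region's center
could not spare δ rows.

A move advances one phase per step (three steps total) as described
above, transferring exactly δ rows between the two adjoining centers.
Moves are aborted (geometry rolled back to the last phase boundary) if
a center would drop below δ — in practice only reachable at phase 1,
where rollback is a no-op.  Seam moves never relabel cells; a cell is
processed from whatever list it is on and its output re-routed by
current geometry.  This lazy reconciliation is safe precisely because
membership can be stale by at most one δ-row boundary shift per step.

## Equivalence testing

Worker scheduling makes parallel trajectories non-reproducible in
principle (and our per-worker streams differ from the sequential stream
by construction), so sequential and parallel engines are compared
distributionally: n runs per engine with independently derived seeds,
two-sample Kolmogorov–Smirnov test on final tumor sizes, non-rejection
at α = 0.01.  The suite runs this at 200×200, 300 steps, 30 runs per
engine, t ∈ {2, 4}.  Runs are seeded with a radius-20 central disk
(~1250 cells) rather than a single cell: under the default
parameterization a single seed is extinct by step 300 in ~98 % of runs
(critical-branching survival decays like 2/(σ²·step)), which would make
any two engines trivially indistinguishable; the disk keeps every
region populated so the comparison actually exercises all workers and
the seam machinery.  KS null calibration uses random half-splits of one
engine's own sample; with discrete (tied) sizes the test is
conservative, so the observed rejection rate at α = 0.01 is bounded by
about α and the suite asserts ≤ 5 %.

## Problem sizes

Full-scale growth runs (acceptance script and the two published-range
tests): 600×600 lattice, one central seed, 4000 steps, 5 seeds —
matching the reference experiment's setup.  Distributional equivalence:
200×200, 300 steps, 30 runs/engine.  Oracle equivalence: 100 randomized
20×20 states.  Partition invariants: 1000 randomized
(t ≤ 6, δ ≤ 3) geometries under random move traffic.  Fate
distribution: 10⁶ single-cell evaluations against the analytic
0.20/0.20/0.15 partition (tolerance ±0.005, ≈ 12σ at n = 10⁶).

## Known limitations

* 2-D lattices only; no nutrient fields, proliferation-capacity
  (telomere) counters, cell ageing or apoptosis/necrosis distinction.
* Row-band (1-D) decomposition only; no checkerboard decomposition and
  at most one in-flight move per seam.
* The JIT path covers the default von Neumann, δ = 1 rule.
* Wall-clock throughput of the serialized parallel realization is not
  meaningful; the `cells_per_sec` sweep column is informational only.
* The synthetic dynamics emulate lattice contact-inhibited growth with
  a handful of homogeneous probabilities; passing tests show engine
  correctness and internal consistency, not calibration to any real
  tumor's kinetics.
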