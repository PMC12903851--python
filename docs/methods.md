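# Methods

## The protocol and its assumptions

The package implements a replay-buffer Monte Carlo refinement of docked
protein–ligand poses. The object it manipulates is an append-only buffer of
configurations, each annotated with an *averaged interaction energy* and its
lineage (origin pose, MC step, parent entry). Initialization runs
`n_init_replicates` independent free+restrained blocks per docked pose; the
MC loop repeatedly draws a start configuration **uniformly at random** from
the current buffer, runs one more block, and appends the result.

Two properties of this scheme shape everything downstream:

* **No detailed balance.** Every successful step is appended; nothing is
  rejected. The buffer's occupancy distribution is therefore *not* the
  Boltzmann distribution — it is biased toward basins that are easy to
  reach and hard to leave from the seeded poses. Cluster occupancies are a
  pose-plausibility measure, not free energies, and the documentation and
  tests treat them as such (order assertions only against equilibrium
  weights).
* **Uniform parent selection** is the minimal reading of "randomly selected
  from the buffer". An energy-biased alternative
  (`parent_selection: boltzmann`, P(i) ∝ exp(−E_i/kT_sel)) is provided as a
  clearly labelled off-by-default extension.

The restrained segment exists to average the interaction-energy observable
over fast environmental fluctuations (solvent, in production) while pinning
the solute: the observable's mean is attributed to the *configuration*, not
to one instantaneous snapshot. The averaging is an arithmetic mean over
`n_energy_samples = 10` snapshots evenly spaced across the segment (the
snapshot frequency is a package choice; every 0.2 ps for a 2 ps segment).

## Propagation layer

The MC engine consumes a two-method contract: `propagate_free(state,
duration, seed)` and `propagate_restrained_average(state, duration,
restraint, n_samples, seed)`. The shipped reference implementation is an
Euler–Maruyama integrator of overdamped Langevin dynamics,

    dx = −(1/γ) ∇E(x) dt + sqrt(2 kT dt / γ) dW,

on analytic landscapes (sums of Gaussian wells/barriers, optional harmonic
confinement, or a plain harmonic well). It was chosen because its stationary
distribution exp(−E/kT) is known in closed form, which turns the whole
protocol into something that can be checked against analytic oracles:

* **Equipartition**: on a harmonic well the canonical mean landscape energy
  is D·kT/2. The validation uses a weak restraint (k_r = 0.01·k_well)
  because a positional restraint perturbs the sampled ensemble — with
  restraint stiffness k_r the exact mean is reduced by roughly
  k/(k+k_r); at 1 % stiffness the bias (~0.5 % of the mean) is far below
  the 3-standard-error test tolerance. Strong restraints are covered by a
  separate monotonicity check (mean displacement strictly decreasing over
  k_r ∈ {1, 10, 100}).
* **Stability substepping**: Euler–Maruyama diverges when dt·k/γ approaches
  2. The restrained segment therefore substeps automatically so that
  dt_eff·k_r/γ ≤ 0.2, making stiff restraints (e.g. the MD-style default of
  1000 energy/length²) integrate correctly instead of silently exploding.
  Toy-scale runs in the tests use k_r = 5–10 in landscape units, which
  needs no substepping and keeps runtimes in seconds.
* Free-segment durations, kT and dt are config values; the integrator's
  discretization bias in the sampled variance is O(dt·k/γ), so defaults
  keep that product ≤ 0.1.

The restraint anchors at the segment-start positions (harmonic, isotropic,
all coordinates by default — the protocol restrains both protein and
ligand; an index subset is supported). The energy observable defaults to
the landscape energy for the toy propagator; for an MD adapter the
documented observable is the ligand–receptor nonbonded (LJ +
electrostatic) interaction energy, and the contract leaves it configurable
because solvent terms can legitimately be included or excluded. No MD
adapter ships in the core package; the contract plus the toy propagator
define the integration surface.

## Seed discipline

A root seed expands into per-task seeds through `SeedSequence` keyed on
(stage, pose/step index, replicate/attempt), so results are independent of
execution order, a failed attempt retries under a fresh derived seed (3
attempts, then abort — partial buffers are never returned), and the full
toy pipeline is bitwise reproducible under one root seed. All derived seeds
stay below 2³¹.

## Clustering

The RMSD matrix uses all ligand atoms by default; an optional alignment
selection triggers Kabsch superposition (fit on the alignment atoms,
evaluate on the RMSD atoms). For toy states the distance is Euclidean in
landscape units. Affinity: A_ij = exp(−d_ij²/(σ_i σ_j)) with σ_i the
distance to the k_nn-th nearest neighbor (k_nn = 10), floored at 1e−8 for
degenerate coincident points. This is the canonical locally scaled affinity
of self-tuning spectral clustering; the original method's rotation-based
model selection is deliberately out of scope.

Model selection works on the **symmetric normalized Laplacian** spectrum
(ascending λ₁ ≤ … ≤ λₙ). The affinity matrix itself could be decomposed
instead; the gap structures are equivalent and L_sym is the numerically
standard choice. Candidate cluster counts k ∈ [2, min(25, n−1)] are ranked
by descending eigengap λ_{k+1} − λ_k, ties toward smaller k; the top 5
candidates are kept (n_candidates is configurable). k = 1 is never returned
— the silhouette is undefined there — but when the dominant gap sits at
k = 1 a warning reports that the ensemble shows no cluster structure. The
two-point edge case returns [2] directly.

"Repeated 25 times using these candidate cluster numbers" is implemented as
25 (k, restart-seed) trials cycling the ranked candidate list while varying
the k-means seed; each trial's k and silhouette are logged so the selection
is auditable. The winner is the maximum-silhouette partition, ties toward
smaller k then the earlier trial. Spectral partitioning embeds points in
the k lowest eigenvectors, row-normalizes, and runs seeded k-means with 10
restarts. The silhouette uses the standard conventions: singleton clusters
and 0/0 cases contribute 0.

## Ranking

Cluster probability = occupancy / total entries; initialization entries are
counted by default (switchable), since the reference protocol clusters
"all states stored in the replay buffer". The representative is the medoid
(summed-RMSD argmin), ties broken by lower averaged energy then lower
index; without a distance matrix the lowest-energy member stands in.
Geometry reports resolve each atom reference to exactly one atom and
measure Euclidean distances and three-point angles.

## Synthetic systems: what they do and do not show

* **Gaussian blob ensembles** emulate the RMSD-space structure of a refined
  pose ensemble with planted labels. Default separation ratio 10 (pairwise
  center distance / within-cluster SD) gives unambiguous recovery targets.
  They do not emulate anisotropic or overlapping pose families.
* **Two-basin landscape** (1-D): Gaussian wells of depth 4 and 1 (kT = 1)
  at ±1.5, width 0.6, inside a harmonic confinement of k = 0.5. The
  confinement emulates the bounded binding-site region — without it,
  particles that leave a well diffuse away forever, which no pocket-bound
  ligand does, and the buffer fills with unbound wanderers. The shallow
  well's depth ≈ kT makes it leaky within one free segment, while escape
  from the deep well (4 kT) is rare, so the deep basin accumulates
  occupancy across seeds. Reference basin weights come from trapezoid
  quadrature of exp(−E/kT) on a dense grid, with a grid-halving convergence
  check at 1e−6 of total mass; because the MC scheme is not Boltzmann, the
  weights back only *ordering* assertions on pipeline output.
* **Toy complexes** are syntactically valid miniature receptor/ligand files
  (including a FAD residue with a C4A atom) that exercise parsing,
  selections, serialization and geometry end to end. They carry no physics:
  molecular CLI runs use a harmonic-well landscape over ligand coordinates,
  which validates plumbing and reproducibility, not binding energetics.

Passing these tests shows the machinery is correct and deterministic; it
does not show that the protocol ranks real binding modes correctly — that
depends on the force field and sampling scale of a production MD adapter.

## Problem sizes in the validation suite

Protocol-scale checks run the full 25 × 10 + 1000 bookkeeping with
shortened toy segments (0.05/0.02 time units), which preserves every
combinatorial property (buffer size, lineage, parent-selection statistics)
at negligible cost. The two-basin pipeline panel uses 2 poses × 5
replicates + 200 steps per seed over 5 seeds; clustering validation uses
50–100-point ensembles. Silhouette equivalence is checked against an
independent O(n²) loop implementation at 1e−12 on 100 random 50-point
instances.

## Known limitations

* Occupancy probabilities are not thermodynamic weights (no detailed
  balance); comparing them across different run lengths is not meaningful.
* The uniform parent selection means early-discovered basins accumulate
  entries ~linearly in buffer age; very late-discovered basins are
  under-represented.
* RMSD-based clustering treats the ligand as one rigid body per state;
  symmetric ligands would need symmetry-corrected RMSD, which is not
  implemented.
* PDBQT is not parsed; mmCIF, bond-order perception and protonation
  assignment are out of scope.
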