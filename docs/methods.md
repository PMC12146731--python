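# Methods

This note documents the models behind `campath`, the parameter choices
that matter, what the synthetic generators do and do not emulate, and the
numerical conventions adopted where more than one reasonable choice
existed.

## Free-energy grids

An `EnergyGrid` is a regular N-dimensional grid of free energies
(kJ/mol) over declared collective-variable axes (default unit Å), with a
boolean exclusion mask. Non-periodic axes carry nodes at both range ends
(spacing = (max−min)/(n−1)); periodic axes omit the duplicate endpoint.
Two text dialects are supported: the de-facto PLUMED grid layout
(`#! FIELDS` / `#! SET` headers, first field varying fastest, derivative
columns ignored) and a TSV with a one-line JSON header and an explicit
mask column. The PLUMED dialect has no mask concept, so masked nodes
serialize with a 10⁹ kJ/mol sentinel and are re-masked on read; the TSV
dialect writes `inf` plus the mask flag. Consequence: round-trips are
exact on axes, mask and unmasked values; energies *under* the mask are
not preserved, by construction.

High-energy masking (`mask_high_energy`) excludes nodes above a
threshold from all path searches. It is idempotent and monotone in the
threshold; values are never altered.

## Minimum free energy paths

The MFEP between two CV points minimizes the resistance
∫ exp(E/RT) ds, discretized per grid edge as the trapezoid
½·(e^{E_u/RT} + e^{E_v/RT})·‖x_u − x_v‖. The search:

1. **Successor map** — each unmasked node points to the lowest-energy
   member of {itself} ∪ {unmasked neighbors}; ties break toward the
   smallest flat index. Plateau nodes whose neighbors are all ≥ their own
   energy therefore become fixed points; this is documented behavior, not
   corrected.
2. **Basins** — fixed points are nodes that are their own successor;
   pointer-jumping resolves every node's terminal fixed point.
3. **CG network** — basins sharing adjacent nodes are connected.
4. **Segments** — for each adjacent basin pair, the whole-grid
   minimum-resistance path between their fixed points (Dijkstra).
5. **Splice and verify** — a shortest-path search on the CG network (edge
   weight = segment resistance) picks the basin sequence and the segments
   are spliced. Because forcing passage through intermediate fixed points
   can exceed the true whole-space optimum, the spliced cost is always
   checked against an exact whole-space Dijkstra between the terminal
   fixed points; the exact path is returned and the spliced cost plus an
   agreement flag (`cg_log_cost`, `cg_matches_exact`) are reported on the
   result rather than hidden. The two provably coincide whenever the
   terminal basins are adjacent, and empirically coincide on the large
   majority of random multi-well landscapes.

Numerical choices:

* **Log-space accumulation.** exp(E/RT) overflows double precision for
  E/RT ≳ 700 (e.g. any interesting barrier at 1 K), so edge and path
  costs are kept as logarithms and combined with log-sum-exp. Dijkstra
  remains exact because log-sum-exp is a monotone, order-preserving cost
  composition. In the T → 0 limit the accumulated cost is dominated by
  the path's maximum energy, so the search converges to the minimax
  (lowest-barrier) crossing; this is verified against a brute-force
  threshold-percolation oracle.
* **Connectivity.** Default is the full Moore neighborhood (3^d − 1
  neighbors, diagonals included), configurable to axis-only. Diagonal
  moves avoid staircase artifacts on fine grids.
* **Determinism.** All ties break toward the smaller flat node index.
* **Endpoints.** Query points snap to the nearest unmasked node; the
  reported path runs fixed point to fixed point, with an option to
  prepend/append steepest-descent segments from the raw query nodes.
* **Periodicity.** Axes are non-periodic unless declared otherwise;
  periodic axes wrap neighbor computation.

Profiles map a path onto (normalized cumulative arc length, energy);
the barrier is max(profile) − energy at the chosen reference (start
fixed point by default, global minimum optionally). `profile_statistics`
resamples profiles onto a common reaction coordinate by linear
interpolation and reports the pointwise mean and *population* SD
(divide by n), the convention appropriate for fluctuation statistics
over snapshots of one run.

## Permeation events and conductance

Event counting uses a per-ion two-plane state machine: an inward event
completes when an ion last seen above the upper plane is next seen below
the lower plane (direction +1), and symmetrically for reverse events
(−1). The hysteresis between planes prevents double-counting of ions
dithering at a single plane. Frame-to-frame jumps with |Δz| > box_z/2
are treated as periodic wraps: they reset the ion's arming state and
never register as crossings. The net count N = inward − reverse enters

g = (N·q·e/t) / (E·L_z·f_ECC),

reported in pS. q is the nominal integer charge (charge scaling adjusts
the effective dielectric, not the charge physically transported), E·L_z
is the nominal voltage, and 1/f_ECC accounts for the scaled charges
feeling an effective field E·f_ECC. Replicate uncertainty is the sample
SD (ddof = 1) across replicate conductances. I–V fits are least-squares
through the origin (g = ΣVI/ΣV²), matching ohmic behavior.

Selectivity is reported as an event-count ratio (flagged infinite when
the denominator is zero). Mutant fold-changes g_mut/g_WT carry a
first-order (delta-method) SD. Concordance with experiment averages
replicate experimental values per mutant before computing Pearson's r.
The Arrhenius ratio exp(ΔΔG/RT) for ΔΔG = 19 kJ/mol evaluates to
~1.6·10³ at 310 K and ~2.0·10³ at 300 K — both conventions circulate
for this quantity; the package computes whichever temperature is passed.

## Selectivity-filter analysis

The z origin is the declared filter center. Densities are per-bin
time-averaged ion counts (default bin 0.2 Å), so the bin sum equals the
mean ion count in the profiled region. Binding sites are density peaks
passing prominence and separation filters (scipy `find_peaks`), ranked
by height.

Coordination numbers count labelled oxygens within 3.0 Å of an ion
(cutoff closed at the boundary — 3.0 Å counts; minimum-image convention
when a box is supplied), split by oxygen class (carboxylate, carbonyl,
water) and residue, averaged per ion z-bin. The same cutoff applies to
all oxygen classes unless configured.

Occupancy states use a configurable `SiteDefinition`; the shipped
default places the SF extent at [−5, +5] Å with S2L [−4, −1.5],
S2U [−1.5, +0.5], S1L [+0.5, +2.5], S1U [+2.5, +5] and the vestibule
site above — anchored to the observed two-ion site peaks near −2.8 and
+1.7 Å and to the mutual exclusivity of each site pair. The exact
interval boundaries are a declared convention of this package, not a
published quantity, and are user-tunable. Frames with more than two
filter ions are labelled "other"; the vestibule ion sits outside the SF
extent and does not affect the label.

The transition-rate estimator is per-time: k(s→s′) = (count of s→s′
frame transitions) / (dt · frames in s, final frame excluded), in ns⁻¹,
with Poisson SE √count on the numerator. Two systematic effects are
inherent to frame sampling and documented rather than corrected: an
O(k·dt) discretization bias (≈1% at k = 20 ns⁻¹ and dt = 1 ps, ≈9% at
dt = 10 ps), and spurious one-frame "shortcut" transitions when two
jumps fall within one frame interval. Rate-recovery analyses therefore
sample at dt = 1 ps; the 10 ps default of the kMC resampler mimics
typical saved-frame spacing.

## Synthetic generators

The generators produce every input the analyses need; none of them
emulate a real channel's energetics or geometry, so passing tests
demonstrate correctness of the *estimators and searches*, not agreement
with any particular protein system.

* **Toy landscapes** (`toy_landscape`): closed-form families
  (2D double well with analytic saddle, bowl, ridge-with-corridor, 1D
  triple well, and a 3-CV three-basin surrogate of concerted multi-ion
  translocation) with their analytic facts embedded in grid metadata.
  `random_smooth_landscape` draws 2–3 Gaussian wells of random position,
  depth (6–14 kJ/mol) and width inside a confining bowl — a few deep
  basins, matching the structure of converged free-energy surfaces,
  rather than fine-grained noise.
* **Well-tempered metadynamics toy** (`wt_metadynamics_1d`): an
  overdamped Langevin walker on a 1D potential (nm, kJ/mol) with
  reflective walls and adaptive Gaussian hills (defaults: height
  5 kJ/mol, width 0.02 nm, bias factor γ = 5, 1 ps deposition stride,
  310 K, 20 ns). Hills are mirrored across the walls so the deposited
  bias matches the reflected dynamics. The estimate is the well-tempered
  identity F = −γ/(γ−1)·V_bias, time-averaged over the last half of the
  run (pointwise SD kept in metadata), shifted to minimum 0. The
  integration timestep (0.005 ps) is chosen so the drift step over the
  steepest instantaneous bias slope (≈ hill height / hill width) stays
  well below the hill width; larger steps mis-sample the rugged bias and
  freeze ripple of order kT into the estimate. With these settings a
  flat potential reconstructs flat within 1 kJ/mol and a 10 kJ/mol
  double-well barrier is recovered within ~0.5 kJ/mol at 20 ns.
* **Knock-on kMC** (`simulate_knockon_kmc`): exact Gillespie simulation
  of the cycle 1 → 2U → 2L → 1 (with optional reverse rates), resampled
  onto a uniform frame grid; a permeation event fires on each completed
  2L → 1 exit. For the irreversible cycle the stationary occupancies are
  proportional to the dwell times 1/k and the event rate is the inverse
  cycle time — both used as analytic ground truth in tests.
* **Multi-ion Langevin** (`simulate_multi_ion_langevin`):
  Euler–Maruyama integration of single-file ions in a 1D potential under
  an applied field (force −q·E·9.6485 kJ/mol/Å per V/nm), with
  screened-Coulomb pair repulsion A·sign(d)·e^{−|d|/λ}/d² — an explicit
  surrogate for full electrostatics whose defaults keep ions ordered in
  single file — and periodic re-entry across the box. Construction
  rejects timesteps whose free-flight displacement SD reaches 0.5 Å,
  and integration aborts if any step exceeds box_z/4.
* **Coordination fixtures** (`synthetic_coordination_frames`): labelled
  oxygen layouts jittered with Gaussian noise, with the brute-force
  ground-truth coordination count emitted per frame.
* **Synthetic topology** (`synthetic_topology`): a hand-written,
  reduced-grammar molecular topology (one Ca²⁺ ion, one glutamate with a
  net −1 terminal group, Ca/Na/K-oxygen pair overrides) for exercising
  the ECC patcher.

All generators take explicit seeds and are bit-reproducible given
(seed, config).

## ECC topology edits

The patcher operates on a restricted GROMACS-style grammar (bracketed
section headers, whitespace-separated records, `;` comments), holding
the file line-by-line so that unedited lines round-trip byte-for-byte.
Charge scaling multiplies the charges of ion residues and of the
charge-bearing terminal atoms of charged residues by f_ECC, returning
an audit list; an empty selection raises rather than silently doing
nothing. Ions are matched by *residue* name only — protein alpha
carbons are also named `CA` and must never be caught by the calcium
selection. The shipped terminal-atom table (carboxylate + attached
hydrogens for Asp/Glu, ammonium for Lys, guanidinium for Arg,
imidazolium for protonated His) reproduces net ±1 terminal-group charges
under the CHARMM charge layout and is editable, since force fields vary
in where they place the formal charge. The calcium σ patch rewrites the
second-to-last numeric field of the Ca atomtype record (ε untouched);
NBFIX removal deletes `nonbond_params` records whose either type matches
a listed species, leaving overrides between other species intact.

## Problem sizes and runtime

Analyses in the test suite and the reproduction script run at desk
scale, chosen for statistical adequacy: random landscapes ≤ 30×30 (2D)
and ≤ 12³ (3D); kMC trajectories of 150 ns sampled at 1 ps (1.5·10⁵
frames, ~430 permeation events); 200 independent 50 ns event streams for
the conductance calibration; 20 ns of toy metadynamics (20,000 hills).
Statistical tolerances are 3 standard errors wherever an estimator is
compared with its programmed truth.

## Known limitations

* The CG path search is heuristic; exactness is restored by the built-in
  whole-space verification, at the cost of one extra Dijkstra run per
  query.
* The transition-rate estimator is per-time, not per-visit, and carries
  the frame-discretization bias quantified above.
* The Langevin generator is overdamped and 1D with a phenomenological
  repulsion; it produces knock-on-like single-file kinetics but no
  hydration, geometry or field-coupling effects.
* The topology grammar covers atoms / atomtypes / nonbond_params
  records; exotic directives pass through verbatim but are not
  interpreted.
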