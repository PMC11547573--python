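# Methods

This note records the model assumptions, parameter choices, and numerical
conventions behind the package, and what the synthetic test systems do and
do not establish about behaviour on real molecular data.

## Conformational metric

Two conformations are compared either by the flat Euclidean norm (analytic
systems) or by superposed RMSD: a Kabsch superposition (SVD with reflection
correction — the smallest singular axis is flipped when the determinant is
negative) on an *align set* of particles, followed by the RMSD over a
possibly different *RMS set*. The split mirrors the common practice for
nucleoprotein complexes of aligning on protein Cα and nucleic-acid P atoms
while measuring RMSD over a per-residue key-atom selection; a two-column
text table maps residue names to align/RMS atoms. No mass weighting is
applied. The squared variant (mean-square deviation) is exposed separately
because the path collective variables, and hence the z-wall, live in
squared-distance units.

## Path collective variables

For nodes `1..N`, `s` is the soft-min-weighted node index and `z` the
soft minimum of the squared distances (definitions in the README). Design
choices:

* **Squared-distance convention for `Mᵢ`** — fixes the units of `z` to
  squared length, matching the convention in which z-wall positions are
  quoted (e.g. 0.0064 nm² for an all-atom complex).
* **Node indexing 1..N** with `s_norm = (s−1)/(N−1)`; the initial state is
  node 1, the final state node N.
* **λ selection**: `λ = 2.3 / mean(adjacent squared distance)`, so that a
  configuration sitting on a node sees its neighbours with weight
  `e^{−2.3} ≈ 0.1`. λ is refreshed after every reparameterization because
  node spacing changes.
* Analytic gradients of `s` and `z` (chain rule through the metric) are
  implemented for the Euclidean metric — the only one the Langevin sampler
  needs — and validated against finite differences in the tests.

One caveat worth recording: with the soft-min definition, `s(x)` saturates
near the terminal nodes (the index cannot leave `[1, N]`), so free-energy
profiles within roughly half a node of either end are distorted. The
end-to-end tests therefore either restrict comparisons to the interior of
the node range or add one flanking node beyond each physical endpoint.

## Biased sampling

The sampler integrates overdamped (Brownian) dynamics with Euler–Maruyama:

    x ← x − (Δt/γf)·∇(U + V_bias) + √(2 kB T Δt / γf)·ξ

An overdamped integrator was chosen over velocity Verlet plus a thermostat
because only the equilibrium distribution enters free-energy
reconstruction; inertial dynamics would add thermostat choices without
changing any quantity computed here. kB = 0.0083144621 kJ/mol/K; energies
are internal in kJ/mol and reported in kcal/mol (÷ 4.184); the default
temperature is 310 K.

Biases compose in a stack evaluated in the (s, z) plane:

* **Well-tempered metadynamics on s**: Gaussians of initial height 2 kJ/mol
  and width 1.0 deposited every 5 ps by default, with bias factor γ = 10;
  the height of a new hill is damped by `exp(−V_hills/( (γ−1) kB T ))`
  evaluated at the current `s` (the standard well-tempered rule). The pace
  is converted to steps by rounding `pace/Δt`.
* **One-sided harmonic z-wall**, `k_wall·(z − z_wall)²` for `z > z_wall`
  (C¹ at the wall). Default position 0.0064 squared units with
  k = 2×10⁷ kJ/mol per squared-unit² — the parameter-table value; an
  alternative 2×10⁶ circulates in prose descriptions and both are accepted
  through configuration. Toy systems use much softer walls scaled to their
  curvatures.
* **Umbrella restraint** `k_s·(s − s₀)²/2`.
* **Targeted MD**: a harmonic restraint `k(t)·d(x, target)²/2` with a
  piecewise-constant, right-continuous spring schedule. The reference
  ladder for the all-atom system lists eight spring constants against seven
  times; this is resolved as k = 0 before the first time (0.2 ns) with the
  seven non-zero values holding from their printed times onward.

Determinism: every stochastic stage consumes a dedicated
`numpy.random.Generator` seeded from one master seed through
`SeedSequence(master, spawn_key=(crc32(stage), index))`; identical inputs
and seeds give bit-identical trajectories. Umbrella windows and TAPS node
walkers of equal length on Euclidean metrics are integrated as one
vectorized batch, each walker drawing from its own seeded stream, so
batching changes performance, not statistics.

## The TAPS iteration

Per iteration, one metadynamics walker starts at every node and all
recorded frames are pooled into per-node bins by rounded `s` (the
description "sampling each node" leaves the walker/bin accounting open;
one-walker-per-node with pooled binning keeps every bin populated).
Interior nodes are replaced by the **medoid** of the frames whose `z` lies
in the central `median_band` quantile interval (default 0.2, i.e.
quantiles 0.4–0.6) around the median `z`. A medoid rather than a
coordinate average is used because averaging conformations can create
unphysical structures; "centroid" is interpreted as the band's most
central member. Node ordering is an open TSP with fixed endpoints: exact
Held–Karp dynamic programming up to 13 nodes, nearest-neighbor seeding
plus 2-opt beyond (the result is flagged heuristic and never longer than
the input order). Reparameterization inserts `ceil(d/tol) − 1` nodes into
any gap `d > tol`, either linearly or from a short targeted-MD run between
the two nodes (10 ps, k = 150,000 kJ/mol·unit² by default, with the frames
nearest the evenly spaced target distances; if the run cannot supply
distinct intermediates it falls back to linear interpolation with a
warning). Before reparameterization, nodes closer than `tol/2` to their
predecessor are merged — adjacent bins sometimes elect the same or nearly
the same medoid, and without pruning the node count grows without bound.
Endpoints are never modified. Convergence is declared when the mean node
displacement stays below `convergence_tol` (default `gap_tolerance/4` —
the reference workflow reports only MDS/PCV-z inspection, so the threshold
is this package's own) for two consecutive iterations; non-convergence
returns diagnostics rather than raising. Classical (Torgerson) MDS to 2D
is provided for visual convergence checks.

The per-node sampling time default (4000 ps) is read as *per node*; whether
the reference workflow means per node or per iteration total is ambiguous,
and the value is configurable.

## Umbrella sampling and WHAM

Windows tile `(0, N]` at centers `gap·i`, giving `round(N/gap)` windows —
the convention that reproduces the documented base counts for 64-, 66- and
55-node paths at gap 0.25 (256, 264, 220). `s` is treated as a
dimensionless node index throughout (one source quotes the window size in
nm; the parameter table's "0.25 PCV-s" is followed). Per-window seeds
derive from the master seed. WHAM iterates the standard self-consistent
equations (unnormalized bin densities and per-window offsets) to an offset
tolerance of 1e-8 kT (max 10⁵ iterations); the profile is reported in
kcal/mol with F = 0 at the initial state (or at the global minimum on
request). Disconnected histogram support is an error naming the gap, but
only when the gap separates two regions that each carry at least 5% of all
counts — empty bins in sparse tails are left unresolved instead.

State location smooths the profile with a moving average (default 5 bins),
finds interior extrema by discrete sign changes, and merges features
shallower than `min_depth` (default 0.5 kcal/mol — no criterion for
calling a feature a state is given in the reference workflow) into their
neighbours, enforcing alternation; endpoints always appear as the Ini/Fin
minima. Barrier statistics follow from the alternating chain; the
telescoping identity Δ = Σforward − Σbackward holds exactly by
construction.

## Synthetic study systems and calibration

* **Registry potentials**: harmonic well, quartic 1D/2D double wells, and
  the standard four-Gaussian Müller–Brown surface (dimensionless
  coordinates; energies mapped to kJ/mol by a configurable scale).
* **Staircase landscape**: a 1D sum of Gaussians hitting a prescribed
  ladder of basin/barrier values (kcal/mol), built by least squares on
  value and zero-slope conditions at every extremum with an overcomplete
  basis (anchors plus three interior centers per gap), then refined by
  re-locating the realized extrema; construction is verified to 1% and in
  practice is accurate to ~1e-9. One-sided quadratic walls confine
  sampling beyond the endpoint basins. The test ladder uses five interior
  basins and six barriers with forward barriers 6.15, 6.37, 5.47, 5.24,
  9.90, 7.16 and backward barriers 4.28, 4.24, 4.06, 4.06, 13.99, 6.10
  kcal/mol (endpoint difference 3.56, total forward 40.29); the fifth
  basin depth is a free choice (2.50 kcal/mol) since only the sums
  constrain it, made once so that the fifth intermediate is markedly
  stable.
* **Bead models**: random clouds plus a rotated/translated/perturbed copy.
  The noise field is post-processed (zero mean, symmetric cross-covariance
  with the reference) so the applied rigid motion is *exactly* the optimal
  superposition, making the recorded displacement RMSD the exact minimum
  RMSD — an oracle for the metric code.

Toy-run calibration follows two rules rather than the all-atom defaults,
whose magnitudes belong to nm-scale metrics:

1. **Window stiffness**: `k_s` must exceed the largest negative curvature
   of `F(s)` along the profile (otherwise a window centered on a barrier
   top is bimodal and its mean unreliable), while the window spread
   `√(kBT/k_s)` must stay comparable to the insert gap for histogram
   overlap. The staircase runs use k_s = 500 kJ/mol per s-unit².
2. **Statistical accuracy**: the end-to-end error of a WHAM profile grows
   like a random walk over windows with step `k_s·δ⟨s⟩·gap`, where
   `δ⟨s⟩ ∝ √(2τ/T_window)`; the staircase runs use 150 ps per window
   (friction 1/ps, Δt 1.5e-4 ps), which brings the endpoint-difference
   error to ~0.1 kcal/mol, comfortably inside the 0.3 kcal/mol check.

For the Müller–Brown TAPS benchmark the surface energies are scaled by
0.3. Two opposing requirements set this number. The node-sampling protocol
assumes walkers can move along the path tube — true for the projected
free-energy relief of a large complex, but not for the raw Müller–Brown
energies, whose ~60 kT tilts pin every walker at a path end and starve the
interior s-bins. Against that, the median-z node update migrates the path
only as fast as the transverse free-energy drop across the tube biases the
within-bin samples; at one tenth scale that signal is a fraction of kT per
tube radius near the ridge and the famous hook toward the first saddle is
found only by favourable seeds. At 0.3 the relief along the path
(~18 kT before metadynamics filling) stays within the hills' reach while
the transverse drift signal is of order kT, and the optimization reaches
both saddles reliably across seeds. The minimum-energy path itself is
invariant under the scaling. The z-wall (0.0064, i.e. a tube radius of
0.08) both confines sampling and limits per-iteration migration, which
sets the iteration budget (24, with early stopping) for the straight-line
start.

## What the synthetic tests do and do not show

They verify the machinery: CV definitions and gradients, the sampling
distribution of the integrator, the well-tempered decay rule, WHAM
consistency against exact oracles, state/barrier extraction, TSP and
medoid correctness, determinism, and that the full TAPS loop finds a
curved MFEP from a bad straight-line guess. They do not exercise
force-field physics, explicit solvent, metric noise from imperfect
superposition of flexible regions, or the cluster-scale sampling budgets a
~10⁶-atom complex needs; quantitative free energies of any real effector
complex are out of scope.

## Known limitations

* Biased dynamics (and PCV gradients) require the Euclidean metric; for
  molecular conformations the package computes path CVs, metrics and
  analyses, but does not itself run restrained all-atom dynamics.
* The moving-average smoothing in state location biases barrier heights
  low by O(F''·w²) (≈0.1–0.2 kcal/mol at the test resolutions); reduce
  `smoothing_window` on clean profiles when that matters.
* The TSP stage above 13 nodes is a 2-opt local optimum, not provably
  optimal (checked against brute force only at small N).
* WHAM reports no per-bin error bars; block-averaged standard errors can
  be computed from the retained window samples if needed.
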