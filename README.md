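# tapspath

Minimum-free-energy-path (MFEP) search on path collective variables, with
the full free-energy workflow around it: traveling-salesman-based automated
path searching (TAPS), well-tempered metadynamics, umbrella sampling with
WHAM reconstruction, and the profile/trajectory analytics used to read a
multi-step conformational mechanism off the result.

## Who this is for

Computational structural biologists and method developers who study large
conformational transitions — for example, how a CRISPR effector loads a DNA
strand into its nuclease site — where the transition is far too slow for
brute-force molecular dynamics and the right collective variables are not
known in advance. TAPS needs only a conformational distance metric: an
*align set* of atoms that defines the rigid superposition and an *RMS set*
over which the RMSD is measured.

Because production runs of such systems need cluster-scale MD engines, this
package ships self-contained synthetic systems — analytic multi-well
landscapes with an overdamped Langevin sampler, and bead "molecules" with
known superposition RMSD — on which every pipeline stage runs and is
verified on a desk machine. The same library code accepts molecular
conformations as multi-model PDB with per-residue align/RMS atom tables.

## The method

A path is an ordered set of reference conformations (nodes) `1..N` with a
metric `d`. The two path collective variables of a configuration `x` are

    s(x) = Σᵢ i·exp(−λ·Mᵢ) / Σᵢ exp(−λ·Mᵢ)        (progress, 1 ≤ s ≤ N)
    z(x) = −(1/λ)·ln Σᵢ exp(−λ·Mᵢ)                  (squared distance from path)

with `Mᵢ = d(x, nodeᵢ)²` and smoothing parameter `λ` (chosen so adjacent
nodes contribute with weight ratio ≈ 10). Each TAPS iteration:

1. samples around every node with well-tempered metadynamics on `s` plus a
   one-sided harmonic wall on `z`,
2. replaces each interior node by the **medoid** of the frames whose `z`
   lies in a central quantile band around the median `z`,
3. re-orders the nodes as an open traveling-salesman tour with fixed
   endpoints (exact Held–Karp for small N, nearest-neighbor + 2-opt above),
4. reparameterizes: inserts nodes (linear or targeted-MD) wherever adjacent
   nodes are farther apart than a tolerance, and refreshes `λ`.

Iterations stop when the mean node displacement stays below a tolerance for
two consecutive rounds. The free energy along the converged path comes from
umbrella windows tiled every 0.25 `s`-units (`k_s·(s−s₀)²/2` restraints plus
the `z`-wall), recombined by WHAM; the profile analytics then identify
intermediate states (IS, interior minima) and transition states (TS,
interior maxima) and tabulate per-step forward/backward barriers, the
endpoint difference Δ = F(Fin) − F(Ini), and the total forward barrier.

## Worked example

Optimize a path on the Müller–Brown surface (scaled so its relief stays
within reach of the metadynamics bias while leaving a clear transverse
free-energy signal — the regime the node-sampling protocol assumes; see
`docs/methods.md`) and locate the two known saddle points:

```python
import numpy as np
import tapspath as tp

mb = tp.get_potential("mueller_brown", {"scale": 0.3})
a = np.array([-0.558, 1.442])           # deep minimum
c = np.array([0.623, 0.028])            # far minimum
nodes = a + np.linspace(0, 1, 13)[:, None] * (c - a)
path = tp.PathDefinition(nodes=nodes, lam=tp.suggest_lambda(nodes))

cfg = tp.TapsConfig(
    sampling_time=15.0, gap_tolerance=0.15, median_band=0.5,
    max_iterations=24, convergence_tol=0.01,
    metad=tp.MetadParams(initial_height=2.0, width=1.0, bias_factor=10.0, pace=0.5),
    wall=tp.WallParams(z_wall=0.0064, k_wall=3e4),
    seed=42, temperature=310.0, friction=5.0, timestep=2e-4, record_interval=0.02,
)
result = tp.run_taps(path, mb, cfg)
print(result.final_path.n_nodes, "nodes,",
      f"path length {result.final_path.length():.2f}")
for saddle in ([-0.822, 0.624], [0.212, 0.293]):
    d = min(np.linalg.norm(result.final_path.nodes - saddle, axis=1))
    print(f"nearest node to saddle {saddle}: {d:.3f}")
```

Output (fixed seed):

```
33 nodes, path length 3.25
nearest node to saddle [-0.822, 0.624]: 0.084
nearest node to saddle [0.212, 0.293]: 0.076
```

Starting from a straight line that cuts across high ground, the optimized
path has migrated to the curved valley route: it hooks left through the
first saddle and crosses the second, reproducing the textbook MFEP of this
surface (the test suite compares it against an independent string-method
path; mean node deviation ≈ 0.03 in the dimensionless units of the surface).

The same stages are exposed as a CLI over a single YAML config —
`taps init-path` (targeted MD), `taps optimize`, `taps fes`, `taps analyze`,
`taps traj-metrics` — each writing a manifest (config snapshot + derived
seeds + version) next to its outputs so deterministic stages can be
reproduced exactly.

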