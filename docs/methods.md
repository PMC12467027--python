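# Methods

This document describes the models implemented in `fragsite`, the default
parameters and why they were chosen, what the synthetic generator does and
does not emulate, and the main numerical decisions.

## 1. FragMaps and the GFE transform

A *FragMap* is a rectilinear grid of voxel occupancies for one probe-atom
type, produced (in real applications) by cosolvent molecular dynamics. The
package works with eight map types covering the usual functional classes:

| Map type | Probe character |
|----------|-----------------|
| APOLAR   | aromatic / aliphatic carbon |
| GEHC     | generic nonpolar hydrogen-rich carbon |
| HBDON    | neutral hydrogen-bond donor |
| HBACC    | neutral hydrogen-bond acceptor |
| MAMN     | positively charged amine nitrogen |
| ACEC     | negatively charged carboxylate oxygen |
| MEOO     | hydroxyl oxygen |
| FORC     | formamide carbonyl |

Occupancies are converted to **grid free energies** by the Boltzmann inverse

```
GFE(v) = -kB * T * ln( occ(v) / bulk )
```

with `kB = 0.0019872041 kcal/(mol K)` and `T = 300 K`, clamped to
`±gfe_cap` (default 3 kcal/mol). The clamp mirrors standard practice: voxel
occupancies are noisy counts, and without a cap a single empty voxel maps to
+∞ while an over-sampled voxel dominates every score. Zero-occupancy voxels
clamp to `+gfe_cap`.

A separate boolean **exclusion map** marks the protein interior. Exclusion is
deliberately not a map value: any heavy atom inside it contributes a flat
penalty (below).

Grids are read and written as OpenDX files via `gridData`
(GridDataFormats), so maps interoperate with standard visualization tools.
The **overlap coefficient** between two same-geometry maps,
`O = Σ min(pi, qi)` over voxel distributions normalized from favorable
(negative) GFE regions, quantifies map similarity in [0, 1].

## 2. Ligand model and LGFE scoring

A ligand is a list of atoms (element, optional explicit atom class), bonds,
and coordinates. Atom classes map heavy atoms to FragMap types through
`ClassificationRules`; hydrogens are never scored. Rotatable dihedrals are
detected automatically: a bond is rotatable when it is acyclic (checked with
`networkx` cycle basis) and both ends have at least one further heavy
neighbor; each dihedral stores its downstream atom set so a move rotates one
rigid fragment.

The **ligand grid free energy** of a pose is

```
LGFE = Σ_heavy atoms  gfe(map[class(a)], x_a)  (+ 1000 if x_a excluded)
```

The 1000 kcal/mol exclusion penalty is part of the LGFE itself, not a
separate term, so a single clashing atom dominates any achievable map reward
and MC trajectories are pushed out of the protein interior without hard
rejection (which would break detailed balance bookkeeping). Atoms outside
the grid score the bulk value 0. Lookups are nearest-voxel by default with a
trilinear option (Section 5); exclusion is always nearest-voxel because
interpolating a boolean is not meaningful.

Flexible ligands additionally carry an **intramolecular surrogate**

```
E_intra = Σ_rotatable (barrier/2) (1 + cos 3φ)
        + Σ_{nonbonded heavy pairs, d < d_clash} k (d_clash - d)^2
```

with `barrier = 1.0 kcal/mol`, `d_clash = 2.5 Å`, `k = 10 kcal/mol/Å²`,
summed over heavy-atom pairs separated by more than two bonds. This is a
deliberately minimal stand-in for a force field: enough to keep dihedral
moves from collapsing the molecule onto itself, invariant under rigid
motion, and cheap.

## 3. Monte-Carlo docking

Docking runs repeated **cycles** of a three-stage Metropolis protocol from a
random placement (random COM in a start sphere, uniform random orientation,
uniform random rotatable dihedrals):

| Stage | Steps | Max transl. | Max rot. | Max dihedral | Temperature |
|-------|-------|-------------|----------|--------------|-------------|
| 1 broad search | 10,000 | 1.0 Å | 180° | 180° | 300 K |
| 2 refinement   | 10,000 | 0.2 Å | 9°   | 60°  | 300 K |
| 3 annealing    | 40,000 | 0.2 Å | 9°   | 9°   | 300 → 0 K linear |

Each step perturbs translation, orientation (rotation about a random axis
through the COM), or one dihedral, and accepts with the Metropolis
criterion on `LGFE + E_intra`; at `T = 0` only downhill moves are accepted,
so stage 3 ends in a local quench. The best pose seen anywhere in a cycle is
kept.

Convergence is checked every `check_interval = 100` cycles: the run stops
when the mean LGFE of the top `k = 3` distinct poses (pairwise COM distance
≥ 0.5 Å) changes by less than `convergence_tol = 0.03 kcal/mol` between
checks, up to `max_cycles = 1000`. `DockingProtocol.reduced()` divides the
stage lengths by 5 and the cycle budget by 10 for tests and quick studies;
the acceptance studies show the reduced protocol already recovers planted
wells reliably at the problem sizes used here.

An optional **confinement radius** adds a steep quadratic penalty on the COM
outside a sphere around the start center. It exists for block-wise hotspot
scans (Section 4), where each dock should characterize its own block rather
than drift to the globally deepest site.

The inner loop is a Numba-compiled kernel (`_mc_kernel.py`) operating on
flat arrays (map stack, CSR downstream sets, nonbonded pair list). It is
validated against the pure-Python scorer to ~1e-14 per evaluation and is
~100× faster, which is what makes multi-seed recovery studies affordable.
The kernel draws from `numpy.random.seed`-style legacy state seeded once per
stage from the caller's `Generator`, so runs are reproducible from a single
integer seed.

## 4. Hotspot identification

`identify_hotspots` characterizes a whole map set:

1. **Partition** the grid box into cubic blocks of edge `block_edge`
   (default 14 Å) overlapping by `block_overlap` (default 2 Å), so sites on
   block boundaries are still covered by some block.
2. **Dock a ligand panel** in every block (confined to the block), keeping
   up to `poses_per_dock` best distinct poses per ligand.
3. **Cluster** retained poses (LGFE ≤ `lgfe_cutoff`) by COM with two rounds
   of leader clustering at `cluster_radius` (default 3.5 Å): candidate
   leaders are the poses with the most neighbors within the radius (ties go
   to the lower LGFE); a second round re-assigns poses to the nearest final
   leader. Two rounds remove the order dependence of plain leader
   clustering.
4. **Rank** clusters by average member LGFE (most favorable first). Each
   hotspot reports its center, member count, contributing ligands, and
   average/best LGFE.

## 5. Numerical choices

- **Nearest vs. trilinear lookup.** Nearest-voxel lookup (`floor(u + 0.5)`)
  is the default because it makes scoring exactly equal to the brute-force
  per-voxel definition and lets probe docking be checked against exhaustive
  voxel enumeration. For *recovery* studies with flexible ligands, nearest
  lookup creates 1 Å-wide score plateaus on which the COM can sit anywhere;
  trilinear interpolation restores a smooth gradient toward the well center
  and is used whenever sub-voxel COM accuracy matters.
- **Exact-equality checks** (scoring vs. brute force at 1e-9, kernel vs.
  reference scorer at ~1e-12) are per-atom; totals are compared at 1e-12
  because summation order differs between implementations.
- **Kabsch superposition** uses `scipy.spatial.transform.Rotation.align_vectors`
  conventions with an explicit determinant correction, so reflections are
  never returned.

## 6. Trajectory metrics

`Trajectory` holds `(n_frames, n_atoms, 3)` coordinates plus a pandas atom
table. Metrics:

- **RMSD series** to a reference frame after optional Kabsch fit;
- **RMSF** per atom (and residue aggregates/distribution) about the mean
  structure;
- **COM distance series** between two selections (mass-weighted);
- **Contact fraction**: percentage of frames in which any ligand heavy atom
  is within `cutoff = 3.0 Å` (boundary inclusive) of any heavy atom of a
  given residue;
- **Activation trace**: per-frame distance between an "ionic lock" pair of
  selections and RMSD of an NPxxY-style motif to a reference, with a
  moving-average smoother (window expressed in ns, e.g. 15 ns blocks);
- **LMI**: linearized mutual information between residue displacement
  vectors, `I = ½(ln det Ci + ln det Cj − ln det Cij)` from Gaussian
  covariance estimators, reported as the generalized correlation
  `r = sqrt(1 − exp(−2 I / 3)) ∈ [0, 1]`. `high_correlation_regions`
  thresholds the matrix (default 0.625), maps residues to named domains,
  and reports the contributing residue pairs per domain pair.

## 7. Synthetic data: what it emulates, and what it does not

The generator produces inputs whose correct analysis results are known
exactly:

- **FragMaps** are sums of Gaussian wells `depth · exp(−|x−c|²/(2(w/4)²))`
  plus optional voxel noise, clamped like real maps; the truth record names
  the deepest well per map. This emulates the *shape* of probe free-energy
  basins, not their physics — there is no water competition, no entropy,
  no map cross-correlation from shared probe molecules.
- **Exclusion shapes** (spheres, slabs) stand in for a protein surface.
- **Ligand templates** (`probe_atom`, `rigid_rod`, `steroid_skeleton`,
  `steroid_acid`, `steroid_amine`, `steroid_taurine`) are schematic: a fused
  four-ring carbon skeleton with charged/polar tails of increasing
  flexibility. Geometry is idealized; no stereochemistry, no hydrogens
  beyond placeholders, bond lengths merely plausible (0.8–2.1 Å checks).
- **The receptor fixture** is a toy 7-helix bundle with named TM domains and
  residue selections for lock/motif analyses; it provides realistic
  bookkeeping (resids, chains, masses), not realistic structure.
- **Trajectories** draw i.i.d. (optionally AR(1)) Gaussian displacements
  with a planted block covariance. Closed forms: per-atom RMSF `= σ√3`, LMI
  correlation `= |ρ|` for planted pairs and 0 for independent ones. AR(1)
  frames keep the same marginals, so the truth values are unchanged while
  adding time correlation. No solvent, no inertia, no conformational
  substates.

Problem sizes in the tests and acceptance studies (20–33 voxel grids, 1 Å
spacing, panels of three ligands, 10–20 seeds, 10,000-frame trajectories)
are the package's own choice: the smallest sizes at which every estimator's
statistical tolerance is met with a wide margin while the full suite stays
in the minutes range on one CPU.

## 8. Limitations

- LGFE is additive per atom; cooperative or anti-cooperative effects between
  functional groups are not representable.
- The intramolecular surrogate has no electrostatics, no 1-4 scaling, and a
  single 3-fold torsion profile for every rotatable bond.
- The docking protocol anneals to a local quench; it reports the best of
  many cycles, not a free energy, and pose "convergence" is heuristic.
- Leader clustering is resolution-limited by `cluster_radius`; two sites
  closer than the radius merge.
- LMI assumes Gaussian displacements; nonlinear couplings are attenuated.
- The synthetic generator cannot validate anything the model does not
  contain (e.g., water-mediated contacts); it validates the *numerics and
  statistics* of the pipeline, not its physics.
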