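"""LGFE scoring against FragMaps.

The ligand grid free energy (LGFE) is the sum over classified non-hydrogen
atoms of the matching map's GFE at the atom position.  Heavy atoms that fall
on the exclusion map contribute a large positive penalty (default
1000 kcal/mol) that is part of the LGFE itself, not just of the acceptance
energy.  A simple internal energy (torsion cosines plus a soft-sphere clash
penalty) stands behind a pluggable contract and is combined with the LGFE in
the Metropolis criterion; it is deliberately minimal — no electrostatics, no
force-field parameters — and is invariant under rigid motion by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gridmaps import FragMapSet, GridError, gfe_at, is_excluded
from .ligand_model import (UNMAPPED, ClassificationRules, Ligand, Pose, classify)


@dataclass
class ScoringConfig:
    """Knobs of the scoring function.

    exclusion_penalty : kcal/mol added per heavy atom overlapping the
        exclusion map (default 1000).
    dihedral_barrier : kcal/mol barrier height of the 3-fold torsion term.
    clash_distance : Å below which nonbonded heavy-atom pairs are penalized.
    clash_stiffness : kcal/mol/Å² harmonic stiffness of the clash penalty.
    intramolecular_weight : weight of the internal energy in the acceptance
        energy (the LGFE always enters with weight 1).
    lookup_mode : 'nearest' (voxel-binned map semantics, default) or
        'trilinear' (sub-voxel interpolation; exclusion stays nearest-voxel).
    strict : unmapped-map-type lookups raise instead of scoring 0.
    """

    exclusion_penalty: float = 1000.0
    dihedral_barrier: float = 2.0
    clash_distance: float = 2.5
    clash_stiffness: float = 10.0
    intramolecular_weight: float = 1.0
    lookup_mode: str = "nearest"
    strict: bool = False

    def __post_init__(self):
        if self.exclusion_penalty <= 0:
            raise ValueError("exclusion_penalty must be positive")
        if self.lookup_mode not in ("nearest", "trilinear"):
            raise ValueError(f"unknown lookup_mode {self.lookup_mode!r}")


def atomic_gfe(
    atom_coord: np.ndarray,
    map_type: str,
    fragmaps: FragMapSet,
    config: ScoringConfig | None = None,
) -> float:
    """GFE contribution of one heavy atom at ``atom_coord``.

    Exclusion dominates: an excluded location scores the penalty regardless of
    class.  Unmapped atoms score 0; otherwise the matching map is looked up
    (bulk 0 outside the box).
    """
    config = config or ScoringConfig()
    if is_excluded(fragmaps.exclusion, atom_coord):
        return config.exclusion_penalty
    if map_type == UNMAPPED:
        return 0.0
    if map_type not in fragmaps.maps:
        if config.strict:
            raise GridError(f"map type {map_type!r} missing from FragMapSet")
        return 0.0
    return float(gfe_at(fragmaps.maps[map_type], atom_coord, mode=config.lookup_mode))


def lgfe(
    pose: Pose,
    fragmaps: FragMapSet,
    rules: ClassificationRules,
    config: ScoringConfig | None = None,
) -> tuple[float, np.ndarray]:
    """LGFE of a pose and its per-atom breakdown.

    The breakdown has one entry per atom (hydrogens 0) and sums to the LGFE
    exactly; only non-hydrogen atoms contribute.
    """
    config = config or ScoringConfig()
    assignment = classify(pose.ligand, rules)
    per_atom = np.zeros(pose.ligand.n_atoms)
    for i in pose.ligand.heavy_indices:
        per_atom[i] = atomic_gfe(pose.coords[i], assignment[i], fragmaps, config)
    return float(per_atom.sum()), per_atom


def intramolecular_energy(pose: Pose, config: ScoringConfig | None = None) -> float:
    """Internal strain surrogate: 3-fold torsion cosines + soft-sphere clashes.

    ``E = sum_torsions (barrier/2) (1 + cos 3φ)
        + sum_{nonbonded heavy pairs, d < d_clash} k (d_clash - d)²``

    Nonbonded pairs exclude 1-2 (bonded) and 1-3 (angle) neighbors.  The
    energy depends only on internal coordinates, hence is rigid-motion
    invariant.
    """
    return intramolecular_energy_coords(pose.ligand, pose.coords, config)


def intramolecular_energy_coords(
    lig: Ligand, coords: np.ndarray, config: ScoringConfig | None = None
) -> float:
    """Coordinate-array core of :func:`intramolecular_energy`."""
    config = config or ScoringConfig()
    e = 0.0
    tor_idx = _torsion_indices(lig)
    if len(tor_idx):
        p0, p1, p2, p3 = (coords[tor_idx[:, k]] for k in range(4))
        b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
        n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
        b1n = b1 / np.linalg.norm(b1, axis=1, keepdims=True)
        m1 = np.cross(n1, b1n)
        phi = np.arctan2(np.einsum("ij,ij->i", m1, n2),
                         np.einsum("ij,ij->i", n1, n2))
        e += 0.5 * config.dihedral_barrier * np.sum(1.0 + np.cos(3.0 * phi))
    pairs = _nonbonded_heavy_pairs(lig)
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        close = d < config.clash_distance
        if close.any():
            e += config.clash_stiffness * np.sum(
                (config.clash_distance - d[close]) ** 2)
    return float(e)


def _torsion_indices(lig: Ligand) -> np.ndarray:
    cache = getattr(lig, "_torsion_idx_cache", None)
    if cache is None:
        cache = np.asarray([t.indices for t in lig.rotatable_dihedrals],
                           dtype=np.intp).reshape(-1, 4)
        lig._torsion_idx_cache = cache
    return cache


def dihedral_angle(coords: np.ndarray, indices: tuple[int, int, int, int]) -> float:
    """Signed torsion angle (radians) for an atom quadruple."""
    p = coords[list(indices)]
    b0, b1, b2 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    return float(np.arctan2(m1 @ n2, n1 @ n2))


def _nonbonded_heavy_pairs(lig: Ligand) -> np.ndarray:
    """Heavy-atom index pairs that are neither bonded nor 1-3 neighbors."""
    cache = getattr(lig, "_nb_pairs_cache", None)
    if cache is not None:
        return cache
    n = lig.n_atoms
    bonded = {frozenset(b) for b in lig.bonds}
    neighbors: dict[int, set[int]] = {i: set() for i in range(n)}
    for i, j in lig.bonds:
        neighbors[i].add(j)
        neighbors[j].add(i)
    onethree = set()
    for j in range(n):
        nb = sorted(neighbors[j])
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                onethree.add(frozenset((nb[a], nb[b])))
    heavy = lig.heavy_indices
    pairs = [(int(i), int(j)) for ai, i in enumerate(heavy) for j in heavy[ai + 1:]
             if frozenset((int(i), int(j))) not in bonded
             and frozenset((int(i), int(j))) not in onethree]
    out = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
    lig._nb_pairs_cache = out
    return out


class FastScorer:
    """Vectorized per-pose scorer used by the MC engine.

    Precomputes the heavy-atom map assignment and stacks the map arrays so a
    full-pose LGFE is a single fancy-indexing gather.  Agrees with
    :func:`lgfe` bit-for-bit on nearest-voxel lookups (asserted in tests).
    """

    def __init__(self, ligand: Ligand, fragmaps: FragMapSet,
                 rules: ClassificationRules, config: ScoringConfig | None = None):
        self.ligand = ligand
        self.config = config or ScoringConfig()
        self.spec = fragmaps.spec
        assignment = classify(ligand, rules)
        self.heavy = ligand.heavy_indices
        order = sorted(fragmaps.maps)
        self._stack = (np.stack([fragmaps.maps[k].values for k in order])
                       if order else np.zeros((0,) + tuple(self.spec.dims)))
        map_index = {k: i for i, k in enumerate(order)}
        midx = []
        for i in self.heavy:
            mt = assignment[i]
            if mt == UNMAPPED:
                midx.append(-1)
            elif mt in map_index:
                midx.append(map_index[mt])
            elif self.config.strict:
                raise GridError(f"map type {mt!r} missing from FragMapSet")
            else:
                midx.append(-1)
        self._midx = np.asarray(midx, dtype=np.intp)
        self._grids = [fragmaps.maps[k] for k in order]
        self._excl = fragmaps.exclusion.mask
        self._origin = np.asarray(self.spec.origin)
        self._dims = np.asarray(self.spec.dims)
        self._spacing = self.spec.spacing
        self._trilinear = self.config.lookup_mode == "trilinear"

    def lgfe_of(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        """LGFE + per-heavy-atom breakdown (aligned with ``ligand.heavy_indices``)."""
        h = coords[self.heavy]
        u = (h - self._origin) / self._spacing
        idx = np.floor(u + 0.5).astype(np.intp)
        inside = np.all((idx >= 0) & (idx < self._dims), axis=1)
        gfe = np.zeros(len(h))
        excluded = np.zeros(len(h), dtype=bool)
        if inside.any():
            ii = idx[inside]
            excluded[inside] = self._excl[ii[:, 0], ii[:, 1], ii[:, 2]]
        if self._trilinear:
            from .gridmaps import _trilinear
            free = ~excluded
            for m in np.unique(self._midx):
                if m < 0:
                    continue
                sel = free & (self._midx == m)
                if sel.any():
                    gfe[sel] = _trilinear(self._grids[m], h[sel])
        else:
            free = inside & ~excluded
            mm = self._midx
            mapped = free & (mm >= 0)
            if mapped.any():
                jj = idx[mapped]
                gfe[mapped] = self._stack[mm[mapped], jj[:, 0], jj[:, 1], jj[:, 2]]
        gfe[excluded] = self.config.exclusion_penalty
        return float(gfe.sum()), gfe

    def energy_of(self, coords: np.ndarray, intra: float | None = None
                  ) -> tuple[float, float, float]:
        """(acceptance energy, lgfe, intramolecular) for a coordinate set."""
        lg, _ = self.lgfe_of(coords)
        if intra is None:
            intra = intramolecular_energy_coords(self.ligand, coords, self.config)
        return lg + self.config.intramolecular_weight * intra, lg, intra
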