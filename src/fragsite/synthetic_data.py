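"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here with a seed: FragMap
sets with planted Gaussian free-energy wells, exclusion masks from geometric
shapes, schematic ligand templates (a probe atom, a rigid rod, and
steroid-skeleton ligands with acid / glycine / taurine tails), a toy
seven-helix receptor fixture with labeled activation-relevant residues, and
multivariate-Gaussian trajectories whose per-residue RMSF and pairwise LMI
have closed-form truth.

Wells are isotropic Gaussians *in free energy* (not occupancy): they directly
control the scoring landscape the docking engine sees.  Trajectory frames are
i.i.d. draws by default, which is what makes the RMSF (σ√3) and LMI (|ρ|)
truths exact; an AR(1) mode adds frame-to-frame memory for moving-average
tests but carries no analytic LMI claim beyond the unchanged marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gridmaps import (DEFAULT_GFE_CAP, ExclusionMap, FragMapSet, GFEGrid,
                       GridError, GridSpec, MAP_TYPES)
from .ligand_model import Atom, Ligand, find_rotatable_dihedrals
from .trajectory_metrics import Trajectory, TrajectoryError


# ---------------------------------------------------------------------------
# FragMaps with planted wells
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedWell:
    """An isotropic Gaussian free-energy well planted in one map type."""

    center: tuple[float, float, float]
    depth: float          # kcal/mol; negative = favorable
    width: float          # Gaussian sigma, Å
    map_type: str = "APOLAR"

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError(f"well width must be positive, got {self.width}")
        if self.map_type not in MAP_TYPES:
            raise ValueError(
                f"map_type {self.map_type!r} not one of {MAP_TYPES}")

    def profile(self, points: np.ndarray) -> np.ndarray:
        d2 = np.sum((points - np.asarray(self.center)) ** 2, axis=-1)
        return self.depth * np.exp(-d2 / (2.0 * self.width ** 2))


def make_fragmap_set(
    wells: list[PlantedWell],
    grid_spec: GridSpec,
    noise_sd: float = 0.0,
    seed: int | None = None,
    map_types: tuple[str, ...] | None = None,
    exclusion: ExclusionMap | None = None,
) -> tuple[FragMapSet, dict]:
    """Build a FragMapSet whose maps are sums of planted wells plus noise.

    Each generated map type's grid equals the sum of its wells' Gaussian
    profiles evaluated at voxel centers, plus i.i.d. normal noise of the given
    standard deviation.  Map types default to those appearing in ``wells``.
    Identical ``(wells, grid_spec, noise_sd, seed)`` give bit-identical grids.

    Returns the set plus a ground-truth record listing well centers, depths
    and widths per map type and the overall deepest-well center.
    """
    lo = np.asarray(grid_spec.origin)
    hi = grid_spec.upper
    for w in wells:
        c = np.asarray(w.center)
        if np.any(c < lo - 1e-9) or np.any(c > hi + 1e-9):
            raise GridError(
                f"well center {w.center} lies outside the grid box [{tuple(lo)}, {tuple(hi)}]")
    if map_types is None:
        map_types = tuple(t for t in MAP_TYPES if any(w.map_type == t for w in wells))
        if not map_types:
            map_types = ("APOLAR",)
    rng = np.random.default_rng(seed)
    centers = grid_spec.voxel_centers()
    maps: dict[str, GFEGrid] = {}
    truth: dict = {"wells": {}, "deepest": None}
    for mt in map_types:  # fixed order => seed-reproducible noise
        values = np.zeros(grid_spec.dims)
        mt_wells = [w for w in wells if w.map_type == mt]
        for w in mt_wells:
            values += w.profile(centers)
        if noise_sd > 0:
            values += rng.normal(0.0, noise_sd, size=grid_spec.dims)
        cap = max(DEFAULT_GFE_CAP, float(np.abs(values).max()) + 1e-9)
        maps[mt] = GFEGrid(spec=grid_spec, map_type=mt, values=values, cap=cap)
        truth["wells"][mt] = [
            {"center": w.center, "depth": w.depth, "width": w.width} for w in mt_wells]
    if wells:
        deepest = min(wells, key=lambda w: w.depth)
        truth["deepest"] = {"center": deepest.center, "depth": deepest.depth,
                            "map_type": deepest.map_type}
    if exclusion is None:
        exclusion = ExclusionMap(spec=grid_spec,
                                 mask=np.zeros(grid_spec.dims, dtype=bool))
    return FragMapSet(maps=maps, exclusion=exclusion), truth


# ---------------------------------------------------------------------------
# Exclusion shapes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float

    def covers(self, points: np.ndarray) -> np.ndarray:
        d2 = np.sum((points - np.asarray(self.center)) ** 2, axis=-1)
        return d2 <= self.radius ** 2


@dataclass(frozen=True)
class Slab:
    """Half-open axis-aligned slab: covers points with lo <= x_axis < hi."""

    axis: int
    lo: float = -np.inf
    hi: float = np.inf

    def covers(self, points: np.ndarray) -> np.ndarray:
        x = points[..., self.axis]
        return (x >= self.lo) & (x < self.hi)


def make_exclusion(shapes: list, grid_spec: GridSpec) -> ExclusionMap:
    """Boolean mask true exactly where a shape covers the voxel center."""
    centers = grid_spec.voxel_centers()
    mask = np.zeros(grid_spec.dims, dtype=bool)
    for shape in shapes:
        mask |= shape.covers(centers)
    return ExclusionMap(spec=grid_spec, mask=mask)


# ---------------------------------------------------------------------------
# Ligand templates
# ---------------------------------------------------------------------------

LIGAND_TEMPLATES = ("probe_atom", "rigid_rod", "steroid_acid",
                    "steroid_glycine", "steroid_taurine")


def make_ligand(template_name: str) -> Ligand:
    """Build one of the schematic ligand templates.

    ``probe_atom`` is a single apolar carbon; ``rigid_rod`` three collinear
    carbons (no rotatable torsions); the three steroid templates share a
    17-carbon fused four-ring core with a 3-hydroxyl and differ only in the
    tail: free carboxylic acid, glycine amide, or taurine amide.  Geometry is
    schematic (≈1.4–1.5 Å bonds); atom classes follow the built-in rule table.
    """
    if template_name == "probe_atom":
        return Ligand(name="probe_atom",
                      atoms=[Atom("C", "c_apolar", False, "C1")],
                      coords=np.zeros((1, 3)), bonds=[])
    if template_name == "rigid_rod":
        atoms = [Atom("C", "c_apolar", False, f"C{i+1}") for i in range(3)]
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0], [3.0, 0, 0]])
        bonds = [(0, 1), (1, 2)]
        return Ligand(name="rigid_rod", atoms=atoms, coords=coords, bonds=bonds,
                      rotatable_dihedrals=find_rotatable_dihedrals(atoms, bonds))
    if template_name in ("steroid_acid", "steroid_glycine", "steroid_taurine"):
        return _steroid(template_name)
    raise ValueError(
        f"unknown ligand template {template_name!r}; valid: {LIGAND_TEMPLATES}")


def _steroid_core() -> tuple[list[Atom], list[list[float]], list[tuple[int, int]], int]:
    """Fused four-ring (6-6-6-5) carbon skeleton + 3-hydroxyl, schematic."""
    coords: list[list[float]] = []
    bonds: list[tuple[int, int]] = []
    index: dict[tuple[float, float], int] = {}

    def vertex(x: float, y: float) -> int:
        key = (round(x, 3), round(y, 3))
        if key not in index:
            index[key] = len(coords)
            coords.append([x, y, 0.0])
        return index[key]

    r = 1.5
    angles = np.deg2rad([30, 90, 150, 210, 270, 330])
    for cx in (0.0, 2.598, 5.196):  # three edge-fused hexagons
        ids = [vertex(cx + r * np.cos(a), r * np.sin(a)) for a in angles]
        for a, b in zip(ids, ids[1:] + ids[:1]):
            if (a, b) not in bonds and (b, a) not in bonds:
                bonds.append((a, b))
    # five-membered D ring fused on the right vertical edge
    top, bot = vertex(6.495, 0.75), vertex(6.495, -0.75)
    p1, apex, p2 = vertex(7.9, 1.0), vertex(8.6, 0.0), vertex(7.9, -1.0)
    bonds += [(top, p1), (p1, apex), (apex, p2), (p2, bot)]
    atoms = [Atom("C", "c_apolar", False, f"C{i+1}") for i in range(len(coords))]
    apex_index = apex
    # 3-hydroxyl on the far-left ring carbon, plus its hydrogen
    oh_on = vertex(-1.299, -0.75)
    o_idx = len(coords)
    atoms.append(Atom("O", "o_hydroxyl", False, "O3"))
    coords.append([-2.35, -1.55, 0.0])
    bonds.append((oh_on, o_idx))
    atoms.append(Atom("H", "h_polar", True, "HO3"))
    coords.append([-2.25, -2.5, 0.1])
    bonds.append((o_idx, o_idx + 1))
    return atoms, coords, bonds, apex_index


def _steroid(name: str) -> Ligand:
    atoms, coords, bonds, apex = _steroid_core()

    def add(atom: Atom, xyz, bond_to: int) -> int:
        idx = len(coords)
        atoms.append(atom)
        coords.append(list(xyz))
        bonds.append((bond_to, idx))
        return idx

    t1 = add(Atom("C", "c_apolar", False, "C20"), (10.0, 0.45, 0.3), apex)
    t2 = add(Atom("C", "c_apolar", False, "C22"), (11.3, -0.3, -0.2), t1)
    if name == "steroid_acid":
        cx = add(Atom("C", "c_carboxyl", False, "C24"), (12.7, 0.4, 0.2), t2)
        add(Atom("O", "o_acid", False, "O24A"), (13.4, 1.2, 0.7), cx)
        add(Atom("O", "o_acid", False, "O24B"), (13.2, -0.5, -0.5), cx)
    else:
        cam = add(Atom("C", "c_amide", False, "C24"), (12.7, 0.4, 0.2), t2)
        add(Atom("O", "o_carbonyl", False, "O24"), (13.0, 1.5, 0.6), cam)
        nam = add(Atom("N", "n_amide", False, "N25"), (13.7, -0.5, -0.1), cam)
        ca = add(Atom("C", "c_apolar", False, "C26"), (15.1, -0.1, 0.1), nam)
        if name == "steroid_glycine":
            cg = add(Atom("C", "c_carboxyl", False, "C27"), (16.1, -1.2, -0.1), ca)
            add(Atom("O", "o_acid", False, "O27A"), (17.3, -1.0, 0.2), cg)
            add(Atom("O", "o_acid", False, "O27B"), (15.7, -2.35, -0.5), cg)
        else:  # taurine: extra methylene + sulfonate
            cb = add(Atom("C", "c_apolar", False, "C27"), (16.0, -1.3, -0.2), ca)
            s = add(Atom("S", "s_sulfonate", False, "S28"), (17.6, -0.9, 0.0), cb)
            add(Atom("O", "o_acid", False, "O28A"), (18.4, -2.05, 0.3), s)
            add(Atom("O", "o_acid", False, "O28B"), (18.1, -0.25, -1.2), s)
            add(Atom("O", "o_acid", False, "O28C"), (17.8, 0.0, 1.15), s)
    arr = np.asarray(coords)
    return Ligand(name=name, atoms=atoms, coords=arr, bonds=bonds,
                  rotatable_dihedrals=find_rotatable_dihedrals(atoms, bonds))


# ---------------------------------------------------------------------------
# Gaussian trajectories with closed-form truth
# ---------------------------------------------------------------------------

@dataclass
class CovarianceSpec:
    """Displacement statistics for a synthetic residue trajectory.

    Residues fluctuate isotropically about fixed mean positions with per-axis
    standard deviation ``sigma``.  ``block_pairs`` plants inter-domain
    correlation: for each ``(domain_a, domain_b, rho)`` the k-th residue of
    domain_a is correlated (per matching axis, coefficient ρ) with the k-th
    residue of domain_b.  With this construction the normalized LMI of a
    planted pair is exactly |ρ| and every residue's RMSF is σ√3.
    """

    n_residues: int
    sigma: float = 0.5
    block_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    frame_interval: float = 1.0      # ns per frame
    domains: dict[str, list[int]] = field(default_factory=dict)
    ar1: float = 0.0                 # frame-to-frame memory; 0 = i.i.d.

    def __post_init__(self):
        if self.n_residues < 1:
            raise TrajectoryError("n_residues must be >= 1")
        if self.sigma < 0:
            raise TrajectoryError("sigma must be non-negative")
        if not (0.0 <= self.ar1 < 1.0):
            raise TrajectoryError("ar1 coefficient must lie in [0, 1)")
        for da, db, rho in self.block_pairs:
            if not (0.0 <= rho < 1.0):
                raise TrajectoryError(f"rho must lie in [0, 1), got {rho}")
            for d in (da, db):
                if d not in self.domains:
                    raise TrajectoryError(f"domain {d!r} not defined in domains")
        # positive definiteness of the per-axis correlation structure
        np.linalg.cholesky(self.correlation_matrix() + 0.0)

    def correlation_matrix(self) -> np.ndarray:
        """Per-axis residue-residue correlation matrix (unit diagonal)."""
        corr = np.eye(self.n_residues)
        for da, db, rho in self.block_pairs:
            for i, j in zip(self.domains[da], self.domains[db]):
                corr[i, j] = corr[j, i] = rho
        return corr

    def lmi_truth(self) -> np.ndarray:
        """Analytic normalized LMI: |ρ| on planted pairs, 0 elsewhere, 1 diag."""
        truth = np.eye(self.n_residues)
        for da, db, rho in self.block_pairs:
            for i, j in zip(self.domains[da], self.domains[db]):
                truth[i, j] = truth[j, i] = abs(rho)
        return truth

    def rmsf_truth(self) -> np.ndarray:
        return np.full(self.n_residues, self.sigma * np.sqrt(3.0))


def make_trajectory(
    spec: CovarianceSpec, n_frames: int, seed: int | None = None
) -> tuple[Trajectory, dict]:
    """Draw a synthetic residue trajectory with the given covariance.

    Frames are i.i.d. (or AR(1) with coefficient ``spec.ar1``) Gaussian
    displacements about mean positions laid out on a 5 Å line, one Cα-labelled
    pseudo-atom per residue.  Returns the trajectory plus the analytic truth:
    per-residue RMSF (σ√3) and the pairwise normalized LMI matrix.
    """
    if n_frames < 2:
        raise TrajectoryError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    n = spec.n_residues
    corr = spec.correlation_matrix()
    L = np.linalg.cholesky(corr)
    means = np.zeros((n, 3))
    means[:, 0] = 5.0 * np.arange(n)
    z = rng.standard_normal(size=(n_frames, 3, n))  # per frame, per axis
    if spec.ar1 > 0.0:
        phi = spec.ar1
        for f in range(1, n_frames):
            z[f] = phi * z[f - 1] + np.sqrt(1.0 - phi ** 2) * z[f]
    disp = spec.sigma * np.einsum("rk,fak->far", L, z)  # (frames, 3, n)
    coords = means[None] + np.transpose(disp, (0, 2, 1))
    table = pd.DataFrame({
        "resid": np.arange(1, n + 1),
        "resname": "ALA",
        "atom_name": "CA",
        "element": "C",
        "heavy": True,
        "mass": 12.011,
    })
    traj = Trajectory(coordinates=coords, atom_table=table,
                      time_per_frame=spec.frame_interval)
    truth = {
        "rmsf": pd.Series(spec.rmsf_truth(),
                          index=pd.Index(np.arange(1, n + 1), name="resid")),
        "lmi": spec.lmi_truth(),
        "resids": list(range(1, n + 1)),
    }
    return traj, truth


# ---------------------------------------------------------------------------
# Receptor fixture
# ---------------------------------------------------------------------------

#: Residue-id ranges of the seven toy helices (inclusive).
TM_RANGES = {
    "TM1": (20, 31), "TM2": (68, 79), "TM3": (116, 127), "TM4": (143, 154),
    "TM5": (201, 212), "TM6": (356, 367), "TM7": (410, 421),
}

#: Labeled roles inside the fixture.
FIXTURE_SELECTIONS = {
    "ionic_lock_arg": [123],                 # TM3 arginine of the ionic lock
    "ionic_lock_glu": [360],                 # TM6 glutamate partner
    "npxxy": [414, 415, 416, 417, 418],      # TM7 NPxxY stand-in
    "as34": [118, 121, 125, 126, 144, 147, 148, 151],  # TM3/TM4 groove
    "as56": [204, 207, 208, 211, 212, 361, 364, 365, 367],  # TM5/TM6 groove
}

_SPECIAL_RESNAMES = {123: "ARG", 360: "GLU", 414: "ASN", 415: "PRO", 418: "TYR"}


@dataclass
class ReceptorFixture:
    """Toy seven-helix bundle: Cα trace + named functional selections."""

    coordinates: np.ndarray
    atom_table: pd.DataFrame
    selections: dict[str, list[int]]
    domains: dict[int, str]

    def select(self, name: str) -> np.ndarray:
        resids = set(self.selections[name])
        return np.flatnonzero(self.atom_table["resid"].isin(resids).to_numpy())

    def as_trajectory(self, coords_frames: np.ndarray,
                      time_per_frame: float = 1.0) -> Trajectory:
        return Trajectory(coordinates=coords_frames, atom_table=self.atom_table,
                          time_per_frame=time_per_frame)


def make_receptor_fixture() -> ReceptorFixture:
    """Deterministic toy receptor: 7 ideal helices on a 12 Å circle.

    One Cα per residue (rise 1.5 Å, 100°/turn, helix radius 2.3 Å), 1-based
    residue ids in the canonical ranges of :data:`TM_RANGES`, orthogonal Å
    coordinates, no altlocs.  The ionic-lock partners (Arg 123 on TM3,
    Glu 360 on TM6), the NPxxY stand-in (residues 414–418) and the two
    allosteric-groove residue sets are labeled selections.
    """
    rows = []
    coords = []
    domains: dict[int, str] = {}
    for h, (tm, (lo, hi)) in enumerate(TM_RANGES.items()):
        angle = 2 * np.pi * h / 7.0
        cx, cy = 12.0 * np.cos(angle), 12.0 * np.sin(angle)
        for k, resid in enumerate(range(lo, hi + 1)):
            phi = np.deg2rad(100.0 * k)
            coords.append([cx + 2.3 * np.cos(phi), cy + 2.3 * np.sin(phi), 1.5 * k])
            rows.append({
                "resid": resid,
                "resname": _SPECIAL_RESNAMES.get(resid, "ALA"),
                "atom_name": "CA", "element": "C", "heavy": True, "mass": 12.011,
            })
            domains[resid] = tm
    return ReceptorFixture(
        coordinates=np.asarray(coords),
        atom_table=pd.DataFrame(rows),
        selections={k: list(v) for k, v in FIXTURE_SELECTIONS.items()},
        domains=domains,
    )
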