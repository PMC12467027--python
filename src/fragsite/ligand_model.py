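"""Ligand representation: classified atoms, bonds, rotatable dihedrals, moves.

Atom classes are *inputs* (no chemical perception is done); a rule table maps
each class to one of the eight FragMap types, or leaves it unmapped.  Only
non-hydrogen atoms are ever scored; hydrogens are carried for geometry only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy.spatial.transform import Rotation

from .gridmaps import MAP_TYPES

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974,
}


class LigandError(ValueError):
    """Raised for invalid ligand topology or moves."""


@dataclass(frozen=True)
class Atom:
    element: str
    atom_class: str
    is_hydrogen: bool
    name: str = ""

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES.get(self.element, 12.011)


@dataclass(frozen=True)
class RotatableDihedral:
    """Atom quadruple (i, j, k, l) around bond j-k plus the moved downstream set."""

    indices: tuple[int, int, int, int]
    downstream: frozenset[int]


@dataclass
class Ligand:
    """Topology + reference coordinates.

    ``coords`` are the template coordinates; a :class:`Pose` carries a placed
    copy.  Rotatable dihedrals follow the rule: non-ring bonds where both bond
    atoms have at least one further heavy neighbor (terminal torsions are not
    rotatable).
    """

    name: str
    atoms: list[Atom]
    coords: np.ndarray
    bonds: list[tuple[int, int]]
    rotatable_dihedrals: list[RotatableDihedral] = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.atoms)
        if self.coords.shape != (n, 3):
            raise LigandError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise LigandError("ligand coordinates must be finite")
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise LigandError(f"invalid bond ({i}, {j}) for {n} atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if not a.is_hydrogen],
                        dtype=np.intp)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(self.bonds)
        return g


def find_rotatable_dihedrals(
    atoms: list[Atom], bonds: list[tuple[int, int]]
) -> list[RotatableDihedral]:
    """Detect rotatable torsions: non-ring bonds between non-terminal heavy atoms.

    A bond (j, k) qualifies when it is in no ring (networkx cycle basis) and
    each of j, k has at least one *other* heavy neighbor.  The reported
    quadruple uses the lowest-index heavy neighbor on each side; the downstream
    set is the connected component containing k after removing the bond.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(atoms)))
    g.add_edges_from(bonds)
    ring_edges = set()
    for cycle in nx.cycle_basis(g):
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            ring_edges.add(frozenset((a, b)))
    out: list[RotatableDihedral] = []
    for j, k in sorted(tuple(sorted(b)) for b in bonds):
        if frozenset((j, k)) in ring_edges:
            continue
        heavy_nb_j = sorted(n for n in g.neighbors(j)
                            if n != k and not atoms[n].is_hydrogen)
        heavy_nb_k = sorted(n for n in g.neighbors(k)
                            if n != j and not atoms[n].is_hydrogen)
        if not heavy_nb_j or not heavy_nb_k:
            continue  # terminal torsion
        h = g.copy()
        h.remove_edge(j, k)
        downstream = frozenset(nx.node_connected_component(h, k))
        out.append(RotatableDihedral(
            indices=(heavy_nb_j[0], j, k, heavy_nb_k[0]), downstream=downstream))
    return out


# ---------------------------------------------------------------------------
# Classification rules: atom class -> FragMap type
# ---------------------------------------------------------------------------

UNMAPPED = "unmapped"


@dataclass
class ClassificationRules:
    """Table mapping atom classes to FragMap types (or ``unmapped``)."""

    entries: dict[str, str]
    provenance: str = ""
    strict: bool = False

    def __post_init__(self):
        for cls, mt in self.entries.items():
            if mt != UNMAPPED and mt not in MAP_TYPES:
                raise LigandError(
                    f"rule for class {cls!r} names unknown map type {mt!r}")

    @classmethod
    def from_text(cls, text: str, provenance: str = "", strict: bool = False
                  ) -> "ClassificationRules":
        """Parse a rule table: one ``<class> <map_type>`` pair per line.

        Blank lines and ``#`` comments are ignored.  Example::

            # class      map_type
            c_apolar     APOLAR
            c_carboxyl   ACEC
            o_hydroxyl   MEOO
            n_amide      HBDON
            o_carbonyl   HBACC
        """
        entries = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            s = line.split("#", 1)[0].strip()
            if not s:
                continue
            parts = s.split()
            if len(parts) != 2:
                raise LigandError(f"rule line {lineno} malformed: {line!r}")
            entries[parts[0]] = parts[1]
        return cls(entries=entries, provenance=provenance, strict=strict)

    @classmethod
    def from_file(cls, path, strict: bool = False) -> "ClassificationRules":
        with open(path) as fh:
            return cls.from_text(fh.read(), provenance=str(path), strict=strict)

    @classmethod
    def default(cls, strict: bool = False) -> "ClassificationRules":
        return cls.from_text(DEFAULT_RULES_TEXT,
                             provenance="fragsite built-in synthetic-template rules",
                             strict=strict)


#: Built-in rule table covering the synthetic ligand templates.  These are
#: honest schematic stand-ins, not a full force-field atom-type table.
DEFAULT_RULES_TEXT = """\
# atom class -> FragMap type for the synthetic ligand templates
c_apolar      APOLAR    # aliphatic / skeleton carbon
c_ring_het    GEHC      # heterocycle-like ring carbon
c_carboxyl    ACEC      # carboxylate carbon (acetate-like, negative)
s_sulfonate   ACEC      # sulfonate sulfur, scored as the acidic group carrier
o_hydroxyl    MEOO      # alcohol hydroxyl oxygen
c_amide       FORC      # amide (formamide-like) carbon
n_amide       HBDON     # amide N-H donor nitrogen
o_carbonyl    HBACC     # carbonyl acceptor oxygen
n_ammonium    MAMN      # protonated amine nitrogen (positive)
o_acid        unmapped  # carboxylate/sulfonate oxygens ride on the carbon/sulfur
"""


def classify(ligand: Ligand, rules: ClassificationRules) -> list[str]:
    """Per-atom FragMap type assignment.

    Hydrogens are always unmapped.  Heavy atoms whose class is absent from the
    table are unmapped in permissive mode and an error in strict mode.
    """
    out = []
    for atom in ligand.atoms:
        if atom.is_hydrogen:
            out.append(UNMAPPED)
            continue
        mt = rules.entries.get(atom.atom_class)
        if mt is None:
            if rules.strict:
                raise LigandError(
                    f"atom class {atom.atom_class!r} not in rules "
                    f"({rules.provenance or 'unnamed table'})")
            mt = UNMAPPED
        out.append(mt)
    return out


# ---------------------------------------------------------------------------
# Poses and Monte-Carlo moves
# ---------------------------------------------------------------------------

@dataclass
class Pose:
    """A placed ligand conformation with its score breakdown."""

    ligand: Ligand
    coords: np.ndarray
    lgfe: float = np.nan
    atomic_gfe: np.ndarray | None = None
    intramolecular_energy: float = np.nan

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.ligand.n_atoms, 3):
            raise LigandError("pose coords shape mismatch with ligand")

    def com(self) -> np.ndarray:
        return center_of_mass(self.coords, self.ligand.masses)


MOVE_KINDS = ("translate", "rotate", "dihedral")


@dataclass(frozen=True)
class Move:
    """One proposed MC move: kind, concrete magnitude(s), and target."""

    kind: str
    translation: np.ndarray | None = None    # (3,) Å, kind="translate"
    axis: np.ndarray | None = None           # unit vector, kind="rotate"
    angle_deg: float = 0.0                   # rotate / dihedral angle
    dihedral_index: int = -1                 # kind="dihedral"


def sample_move(
    rng: np.random.Generator,
    max_translation: float,
    max_rotation: float,
    max_dihedral: float,
    n_dihedrals: int,
) -> Move:
    """Draw one move: uniform kind, then uniform magnitude within the cap.

    Translations use a uniform direction with magnitude uniform in
    ``[0, max_translation]``; rotations a uniform axis with angle uniform in
    ``[-max_rotation, +max_rotation]`` degrees; dihedral moves a uniform
    torsion index and angle.  Dihedral moves are unavailable for rigid ligands.
    """
    kinds = ["translate", "rotate"] + (["dihedral"] if n_dihedrals else [])
    kind = kinds[rng.integers(len(kinds))]
    if kind == "translate":
        v = _random_unit(rng) * rng.uniform(0.0, max_translation)
        return Move(kind="translate", translation=v)
    if kind == "rotate":
        return Move(kind="rotate", axis=_random_unit(rng),
                    angle_deg=rng.uniform(-max_rotation, max_rotation))
    return Move(kind="dihedral", axis=None,
                angle_deg=rng.uniform(-max_dihedral, max_dihedral),
                dihedral_index=int(rng.integers(n_dihedrals)))


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - probability ~0
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def apply_move(pose: Pose, move: Move) -> Pose:
    """Apply a move to a pose, returning a new (unscored) pose.

    Rigid moves preserve all internal coordinates; a dihedral move rotates only
    the bond's downstream atom set about the bond axis.
    """
    coords = apply_move_coords(pose.coords, move, pose.ligand)
    return Pose(ligand=pose.ligand, coords=coords)


def apply_move_coords(coords: np.ndarray, move: Move, ligand: Ligand) -> np.ndarray:
    """Coordinate-array core of :func:`apply_move` (used by the MC engine)."""
    if move.kind == "translate":
        return coords + np.asarray(move.translation)
    if move.kind == "rotate":
        com = center_of_mass(coords, ligand.masses)
        rot = Rotation.from_rotvec(np.deg2rad(move.angle_deg) * np.asarray(move.axis))
        return (coords - com) @ rot.as_matrix().T + com
    if move.kind == "dihedral":
        if not (0 <= move.dihedral_index < len(ligand.rotatable_dihedrals)):
            raise LigandError(
                f"dihedral index {move.dihedral_index} out of range "
                f"(ligand has {len(ligand.rotatable_dihedrals)} rotatable torsions)")
        tor = ligand.rotatable_dihedrals[move.dihedral_index]
        _, j, k, _ = tor.indices
        axis = coords[k] - coords[j]
        norm = np.linalg.norm(axis)
        if norm < 1e-9:
            raise LigandError("degenerate dihedral axis (coincident bond atoms)")
        rot = Rotation.from_rotvec(np.deg2rad(move.angle_deg) * axis / norm)
        out = coords.copy()
        ds = sorted(tor.downstream)
        out[ds] = (coords[ds] - coords[k]) @ rot.as_matrix().T + coords[k]
        return out
    raise LigandError(f"unknown move kind {move.kind!r}")


def center_of_mass(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-weighted mean position; equal masses reduce to the centroid."""
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if coords.ndim != 2 or len(coords) == 0:
        raise LigandError("center_of_mass requires a non-empty (N, 3) array")
    return masses @ coords / masses.sum()
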