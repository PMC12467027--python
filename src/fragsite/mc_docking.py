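"""Metropolis Monte-Carlo docking against FragMaps.

The default protocol follows the exhaustive-mode recipe: per cycle, a random
placement is refined by (1) 10,000 broad MC steps at 300 K with moves up to
1 Å / 180° / 180°, (2) 10,000 local MC steps at 300 K up to 0.2 Å / 9° / 60°,
and (3) 40,000 simulated-annealing steps cooled linearly 300 → 0 K up to
0.2 Å / 9° / 9°.  Cycles repeat up to 1000 times; every 100th cycle the LGFE
spread among the top three (COM-deduplicated) poses is checked and sampling
stops once it falls below 0.03 kcal/mol.  The lowest-LGFE pose is the binding
mode prediction.  The acceptance energy is LGFE plus the internal-strain
surrogate; the exclusion penalty rides inside the LGFE.

A ``reduced()`` protocol with the same stage structure but shorter chains is
provided for desk-scale experiments and the synthetic recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .gridmaps import KB, FragMapSet
from .ligand_model import (ClassificationRules, Ligand, Pose, center_of_mass)
from .gfe_scoring import FastScorer, ScoringConfig


@dataclass(frozen=True)
class ProtocolStage:
    """One MC stage: chain length, temperature (fixed or linear ramp), move caps."""

    n_steps: int
    temperature_start: float
    temperature_end: float
    max_translation: float
    max_rotation: float
    max_dihedral: float

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if min(self.max_translation, self.max_rotation, self.max_dihedral) < 0:
            raise ValueError("move caps must be non-negative")
        if min(self.temperature_start, self.temperature_end) < 0:
            raise ValueError("temperatures must be non-negative")

    def temperature_at(self, step: int) -> float:
        """Linear ramp across the chain; fixed stages return the constant."""
        if self.n_steps == 1 or self.temperature_start == self.temperature_end:
            return self.temperature_start
        f = step / (self.n_steps - 1)
        return self.temperature_start + f * (self.temperature_end - self.temperature_start)


def default_stages() -> tuple[ProtocolStage, ProtocolStage, ProtocolStage]:
    """The three standard stages: broad MC, local MC, simulated annealing."""
    return (
        ProtocolStage(10_000, 300.0, 300.0, 1.0, 180.0, 180.0),
        ProtocolStage(10_000, 300.0, 300.0, 0.2, 9.0, 60.0),
        ProtocolStage(40_000, 300.0, 0.0, 0.2, 9.0, 9.0),
    )


@dataclass
class DockingProtocol:
    """Full sampling protocol: stages + cycle/convergence constants."""

    stages: tuple[ProtocolStage, ...] = field(default_factory=default_stages)
    max_cycles: int = 1000
    check_interval: int = 100
    convergence_tol: float = 0.03
    top_k: int = 3
    dedup_radius: float = 0.5
    seed: int | None = None

    def __post_init__(self):
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")
        if not (1 <= self.check_interval <= self.max_cycles):
            raise ValueError("check_interval must be in [1, max_cycles]")

    @classmethod
    def reduced(cls, scale: int = 5, max_cycles: int = 100,
                check_interval: int = 10, **kw) -> "DockingProtocol":
        """Same stage structure with chains shortened by ``scale``.

        Temperatures and move caps are untouched; only chain lengths and the
        cycle budget shrink.  Used for desk-scale synthetic studies.
        """
        stages = tuple(replace(s, n_steps=max(1, s.n_steps // scale))
                       for s in default_stages())
        return cls(stages=stages, max_cycles=max_cycles,
                   check_interval=check_interval, **kw)


@dataclass
class DockingResult:
    """Outcome of a docking run."""

    best_pose: Pose
    top_poses: list[Pose]
    n_cycles_run: int
    converged: bool
    rng_seed: int | None
    cycle_lgfes: list[float] = field(default_factory=list)


def metropolis_accept(delta_energy: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Metropolis criterion: downhill always; uphill with exp(-ΔE / kB T).

    At T = 0 every uphill move is rejected (strictly downhill chain).
    """
    if delta_energy <= 0.0:
        return True
    if temperature <= 0.0:
        return False
    return rng.random() < np.exp(-delta_energy / (KB * temperature))


def _kernel_args(scorer: FastScorer) -> dict:
    """Assemble (once per scorer) the typed arrays the JIT stage kernel needs."""
    cached = getattr(scorer, "_kernel_args_cache", None)
    if cached is not None:
        return cached
    lig = scorer.ligand
    tor_idx = np.asarray([t.indices for t in lig.rotatable_dihedrals],
                         dtype=np.int64).reshape(-1, 4)
    tor_jk = tor_idx[:, 1:3].copy()
    ds_lists = [np.fromiter(sorted(t.downstream), dtype=np.int64)
                for t in lig.rotatable_dihedrals]
    ds_off = np.zeros(len(ds_lists) + 1, dtype=np.int64)
    for i, d in enumerate(ds_lists):
        ds_off[i + 1] = ds_off[i] + len(d)
    ds_flat = (np.concatenate(ds_lists) if ds_lists
               else np.zeros(0, dtype=np.int64))
    from .gfe_scoring import _nonbonded_heavy_pairs
    args = {
        "stack": np.ascontiguousarray(scorer._stack, dtype=np.float64),
        "excl": np.ascontiguousarray(scorer._excl),
        "midx": scorer._midx.astype(np.int64),
        "heavy": scorer.heavy.astype(np.int64),
        "origin": scorer._origin.astype(np.float64),
        "spacing": float(scorer._spacing),
        "dims": scorer._dims.astype(np.int64),
        "penalty": float(scorer.config.exclusion_penalty),
        "w_intra": float(scorer.config.intramolecular_weight),
        "trilinear": bool(scorer._trilinear),
        "masses": lig.masses.astype(np.float64),
        "tor_idx": tor_idx,
        "tor_jk": tor_jk,
        "ds_flat": ds_flat,
        "ds_off": ds_off,
        "nb_pairs": _nonbonded_heavy_pairs(lig).astype(np.int64).reshape(-1, 2),
        "barrier": float(scorer.config.dihedral_barrier),
        "clash_d": float(scorer.config.clash_distance),
        "clash_k": float(scorer.config.clash_stiffness),
    }
    scorer._kernel_args_cache = args
    return args


def run_stage(
    start: Pose,
    stage: ProtocolStage,
    scorer: FastScorer,
    rng: np.random.Generator,
    confinement_center: np.ndarray | None = None,
    confinement_radius: float | None = None,
) -> tuple[Pose, Pose]:
    """Run one MC stage; return (final pose, best-LGFE pose seen).

    Exactly ``n_steps`` proposals are made, each a uniformly chosen move kind
    within the stage caps (translations: uniform direction, magnitude uniform
    in [0, cap]; rigid rotations about the COM and dihedral twists: angle
    uniform in [-cap, +cap]).  The acceptance energy is LGFE + weighted
    internal energy; the internal term changes only under dihedral moves.
    The loop runs in a compiled kernel whose RNG is seeded from ``rng``, so a
    fixed seed reproduces the chain bit-for-bit.  With a confinement sphere
    given, poses whose COM leaves it take the exclusion penalty.
    """
    from . import _mc_kernel
    args = _kernel_args(scorer)
    lig = scorer.ligand
    center = (np.zeros(3) if confinement_center is None
              else np.asarray(confinement_center, dtype=float))
    radius = -1.0 if confinement_radius is None else float(confinement_radius)
    seed = int(rng.integers(2 ** 31))
    (final_c, final_lgfe, final_intra, best_c, best_lgfe, best_intra
     ) = _mc_kernel.mc_stage(
        np.ascontiguousarray(start.coords, dtype=np.float64),
        int(stage.n_steps),
        float(stage.temperature_start), float(stage.temperature_end),
        float(stage.max_translation), float(stage.max_rotation),
        float(stage.max_dihedral),
        args["stack"], args["excl"], args["midx"], args["heavy"],
        args["origin"], args["spacing"], args["dims"],
        args["penalty"], args["w_intra"], args["trilinear"],
        args["masses"], args["tor_idx"], args["tor_jk"],
        args["ds_flat"], args["ds_off"], args["nb_pairs"],
        args["barrier"], args["clash_d"], args["clash_k"],
        center, radius, KB, seed)
    final = _scored_pose(lig, final_c, scorer, final_lgfe, final_intra)
    best = _scored_pose(lig, best_c, scorer, best_lgfe, best_intra)
    return final, best


def _scored_pose(lig: Ligand, coords: np.ndarray, scorer: FastScorer,
                 lgfe_val: float, intra: float) -> Pose:
    per_atom = np.zeros(lig.n_atoms)
    _, gfe_heavy = scorer.lgfe_of(coords)
    per_atom[scorer.heavy] = gfe_heavy
    return Pose(ligand=lig, coords=coords, lgfe=lgfe_val,
                atomic_gfe=per_atom, intramolecular_energy=intra)


@dataclass(frozen=True)
class StartRegion:
    """Spherical placement region: random COM inside, random orientation."""

    center: tuple[float, float, float]
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("start region must have positive radius (non-empty)")


def random_placement(ligand: Ligand, region: StartRegion,
                     rng: np.random.Generator) -> Pose:
    """Uniform random COM inside the region sphere + uniform random orientation."""
    while True:
        u = rng.uniform(-1.0, 1.0, size=3)
        if u @ u <= 1.0:
            break
    target_com = np.asarray(region.center) + region.radius * u
    rot = Rotation.random(rng=rng).as_matrix()
    com0 = center_of_mass(ligand.coords, ligand.masses)
    coords = (ligand.coords - com0) @ rot.T + target_com
    return Pose(ligand=ligand, coords=coords)


def dock(
    ligand: Ligand,
    start_region: StartRegion,
    maps: FragMapSet,
    rules: ClassificationRules,
    protocol: DockingProtocol | None = None,
    config: ScoringConfig | None = None,
    seed: int | None = None,
    confinement_radius: float | None = None,
) -> DockingResult:
    """Full docking run: cycles of (broad MC, local MC, SA) with convergence.

    Each cycle starts from a fresh random placement and runs the protocol's
    stages; the best-seen pose of the cycle is retained for ranking.  The
    ranked list is deduplicated by COM distance (keeping the lower LGFE) so
    the top-3 convergence test compares genuinely distinct poses; every
    ``check_interval`` cycles, sampling stops once rank-3 minus rank-1 LGFE
    drops below ``convergence_tol``.

    ``confinement_radius``, when given, rejects moves that take the ligand COM
    farther than that distance from the start-region center (keeps chains from
    wandering into featureless bulk in open synthetic landscapes).
    """
    protocol = protocol or DockingProtocol()
    config = config or ScoringConfig()
    if seed is None:
        seed = protocol.seed
    rng = np.random.default_rng(seed)
    scorer = FastScorer(ligand, maps, rules, config)
    confine_center = (np.asarray(start_region.center, dtype=float)
                      if confinement_radius is not None else None)
    retained: list[Pose] = []
    cycle_lgfes: list[float] = []
    converged = False
    n_cycles = 0
    for cycle in range(1, protocol.max_cycles + 1):
        pose = random_placement(ligand, start_region, rng)
        cycle_best: Pose | None = None
        for stage in protocol.stages:
            pose, stage_best = run_stage(pose, stage, scorer, rng,
                                         confinement_center=confine_center,
                                         confinement_radius=confinement_radius)
            if cycle_best is None or stage_best.lgfe < cycle_best.lgfe:
                cycle_best = stage_best
        retained.append(cycle_best)
        cycle_lgfes.append(cycle_best.lgfe)
        n_cycles = cycle
        if cycle % protocol.check_interval == 0:
            top = dedup_poses(retained, protocol.dedup_radius)
            if (len(top) >= protocol.top_k and
                    top[protocol.top_k - 1].lgfe - top[0].lgfe < protocol.convergence_tol):
                converged = True
                break
    top = dedup_poses(retained, protocol.dedup_radius)
    return DockingResult(best_pose=top[0], top_poses=top, n_cycles_run=n_cycles,
                         converged=converged, rng_seed=seed, cycle_lgfes=cycle_lgfes)


def dedup_poses(poses: list[Pose], radius: float) -> list[Pose]:
    """Sort by LGFE and drop poses whose COM sits within ``radius`` of a keeper."""
    order = sorted(poses, key=lambda p: p.lgfe)
    kept: list[Pose] = []
    coms: list[np.ndarray] = []
    for p in order:
        c = p.com()
        if all(np.linalg.norm(c - k) >= radius for k in coms):
            kept.append(p)
            coms.append(c)
    return kept
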