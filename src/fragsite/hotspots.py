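"""Global binding-site search: block docking + two-round clustering.

The region of interest is tiled with cubic blocks; every ligand of a panel is
docked in every block; the resulting poses are clustered first per ligand
(local binding sites) and then the per-ligand cluster centers are clustered
across ligands (common binding sites).  Each final cluster is scored by the
mean over contributing ligands of that ligand's best member LGFE and the
clusters are ranked ascending (rank 1 = most favorable).

Clustering is iterative leader clustering: the pose with the most neighbors
(COM distance within the cluster radius) becomes a center, it and its
neighbors are removed, and the scan repeats.  Neighbor-count ties go to the
pose with the lower LGFE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gridmaps import FragMapSet
from .ligand_model import ClassificationRules, Ligand, Pose
from .gfe_scoring import ScoringConfig
from .mc_docking import DockingProtocol, StartRegion, dock


@dataclass(frozen=True)
class Block:
    """One cubic subspace of the search box."""

    center: tuple[float, float, float]
    edge: float
    id: int


@dataclass
class HotspotCluster:
    """A putative binding site: center pose + per-ligand members + rank score."""

    center_pose: Pose
    members: dict[str, list[Pose]]
    avg_lgfe: float
    rank: int = 0

    @property
    def center(self) -> np.ndarray:
        return self.center_pose.com()


def partition_space(
    bounding_box: tuple[np.ndarray, np.ndarray],
    edge: float,
    overlap: float = 0.0,
) -> list[Block]:
    """Tile a box with cubes of the given edge on a stride of ``edge - overlap``.

    Centers start at ``min + edge/2`` and advance by the stride while they
    remain inside the box; if the last block still leaves part of the box
    uncovered, one extra block is appended per axis.  The union of blocks
    always covers the box.
    """
    if edge <= 0:
        raise ValueError(f"block edge must be positive, got {edge}")
    if not overlap < edge:
        raise ValueError(f"overlap ({overlap}) must be smaller than edge ({edge})")
    lo = np.asarray(bounding_box[0], dtype=float)
    hi = np.asarray(bounding_box[1], dtype=float)
    stride = edge - overlap
    axes = []
    for k in range(3):
        centers = []
        c = lo[k] + edge / 2.0
        while c <= hi[k] + 1e-9:
            centers.append(c)
            c += stride
        if not centers:
            centers.append(lo[k] + edge / 2.0)
        if centers[-1] + edge / 2.0 < hi[k] - 1e-9:  # coverage guarantee
            centers.append(centers[-1] + stride)
        axes.append(centers)
    blocks = []
    bid = 0
    for x in axes[0]:
        for y in axes[1]:
            for z in axes[2]:
                blocks.append(Block(center=(x, y, z), edge=edge, id=bid))
                bid += 1
    return blocks


def cluster_poses(poses: list[Pose], radius: float) -> list[list[Pose]]:
    """Iterative leader clustering on pose COM positions.

    Returns clusters as lists whose first element is the center pose.  A pose
    counts as its own neighbor; ties on neighbor count are broken by lower
    LGFE, then by input order.
    """
    if radius <= 0:
        raise ValueError(f"cluster radius must be positive, got {radius}")
    if not poses:
        return []
    coms = np.array([p.com() for p in poses])
    lgfes = np.array([p.lgfe for p in poses])
    alive = np.ones(len(poses), dtype=bool)
    d = np.linalg.norm(coms[:, None, :] - coms[None, :, :], axis=-1)
    within = d <= radius
    clusters = []
    while alive.any():
        counts = (within & alive[None, :]).sum(axis=1)
        counts[~alive] = -1
        best_count = counts.max()
        tied = np.flatnonzero(counts == best_count)
        center = tied[np.argmin(lgfes[tied])]
        member_idx = np.flatnonzero(within[center] & alive)
        ordered = [center] + [i for i in member_idx if i != center]
        clusters.append([poses[i] for i in ordered])
        alive[member_idx] = False
    return clusters


def identify_hotspots(
    ligand_panel: list[Ligand],
    maps: FragMapSet,
    rules: ClassificationRules,
    protocol: DockingProtocol | None = None,
    cluster_radius: float = 3.5,
    block_edge: float = 12.0,
    block_overlap: float = 3.0,
    bounding_box: tuple[np.ndarray, np.ndarray] | None = None,
    config: ScoringConfig | None = None,
    seed: int | None = None,
    poses_per_dock: int = 3,
    lgfe_cutoff: float | None = None,
    confine_to_blocks: bool = True,
) -> list[HotspotCluster]:
    """Run the full hotspot search over a ligand panel.

    Defaults: 12 Å blocks with 3 Å overlap and a 3.5 Å COM cluster radius;
    per-block docking uses a reduced protocol unless one is supplied.  With
    ``lgfe_cutoff`` set, poses scoring at or above the cutoff are dropped
    before clustering (restricts hotspots to favorable sites).  Per-block
    docking seeds derive deterministically from ``seed``.
    """
    if not ligand_panel:
        raise ValueError("ligand panel must be non-empty")
    protocol = protocol or DockingProtocol.reduced()
    if bounding_box is None:
        spec = maps.spec
        bounding_box = (np.asarray(spec.origin), spec.upper)
    blocks = partition_space(bounding_box, block_edge, block_overlap)
    ss = np.random.SeedSequence(seed)
    dock_seeds = ss.generate_state(len(blocks) * len(ligand_panel))
    # Per block x ligand: dock and collect the top distinct poses.
    per_ligand_poses: dict[str, list[Pose]] = {lig.name: [] for lig in ligand_panel}
    k = 0
    for block in blocks:
        region = StartRegion(center=block.center, radius=block.edge / 2.0)
        confine = block.edge * 0.75 if confine_to_blocks else None
        for lig in ligand_panel:
            result = dock(lig, region, maps, rules, protocol=protocol,
                          config=config, seed=int(dock_seeds[k] % (2**31)),
                          confinement_radius=confine)
            k += 1
            for pose in result.top_poses[:poses_per_dock]:
                if lgfe_cutoff is None or pose.lgfe < lgfe_cutoff:
                    per_ligand_poses[lig.name].append(pose)
    # Round 1: cluster per ligand; keep each cluster's center pose.
    round1_centers: list[tuple[str, Pose]] = []
    for name, poses in per_ligand_poses.items():
        for cluster in cluster_poses(poses, cluster_radius):
            round1_centers.append((name, cluster[0]))
    # Round 2: cluster the round-1 centers across ligands.
    center_poses = [p for _, p in round1_centers]
    name_of = {id(p): n for n, p in round1_centers}
    hotspots: list[HotspotCluster] = []
    for cluster in cluster_poses(center_poses, cluster_radius):
        members: dict[str, list[Pose]] = {}
        for p in cluster:
            members.setdefault(name_of[id(p)], []).append(p)
        per_ligand_best = [min(ps, key=lambda p: p.lgfe).lgfe
                           for ps in members.values()]
        hotspots.append(HotspotCluster(center_pose=cluster[0], members=members,
                                       avg_lgfe=float(np.mean(per_ligand_best))))
    hotspots.sort(key=lambda h: (h.avg_lgfe, tuple(h.center)))
    for rank, h in enumerate(hotspots, start=1):
        h.rank = rank
    return hotspots
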