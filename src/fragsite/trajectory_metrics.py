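"""Trajectory analyses for receptor activation studies.

Implements the metric set used to monitor Class A GPCR activation in MD
trajectories: Kabsch superposition and RMSD traces, per-residue RMSF and
site-restricted RMSF distributions, center-of-mass distance traces (the
TM3–TM6 ionic lock), heavy-atom close-contact percentages (3 Å criterion),
the two-dimensional ionic-lock-distance vs NPxxY-RMSD activation metric,
non-overlapping moving averages (15 ns convention), linear mutual information
(LMI) residue-residue correlation with the Gaussian estimator, and detection
of high-LMI off-diagonal inter-domain regions (threshold 0.625).

Trajectories are assumed pre-imaged: no periodic-boundary unwrapping is done.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .gridmaps import KB  # noqa: F401  (re-exported for energy-scale users)


class TrajectoryError(ValueError):
    """Raised for invalid trajectories, selections, or configurations."""


@dataclass
class Trajectory:
    """Frames × atoms × 3 coordinate sets (Å) with a per-atom table.

    ``atom_table`` columns: resid, resname, atom_name, element, heavy (bool),
    mass.  ``time_per_frame`` is in ns.
    """

    coordinates: np.ndarray
    atom_table: pd.DataFrame
    time_per_frame: float = 1.0

    REQUIRED_COLUMNS = ("resid", "resname", "atom_name", "element", "heavy", "mass")

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise TrajectoryError(
                f"coordinates must be (frames, atoms, 3), got {self.coordinates.shape}")
        if self.coordinates.shape[0] < 1:
            raise TrajectoryError("trajectory needs at least one frame")
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.atom_table]
        if missing:
            raise TrajectoryError(f"atom table missing columns {missing}")
        if len(self.atom_table) != self.coordinates.shape[1]:
            raise TrajectoryError("atom table length != atom count")
        if self.time_per_frame <= 0:
            raise TrajectoryError("time_per_frame must be positive")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.time_per_frame

    def select(self, resids=None, atom_names=None, heavy_only=False) -> np.ndarray:
        """Atom indices matching the given residue ids / atom names."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if resids is not None:
            mask &= self.atom_table["resid"].isin(list(resids)).to_numpy()
        if atom_names is not None:
            mask &= self.atom_table["atom_name"].isin(list(atom_names)).to_numpy()
        if heavy_only:
            mask &= self.atom_table["heavy"].to_numpy().astype(bool)
        return np.flatnonzero(mask)


@dataclass
class AnalysisConfig:
    """Metric parameters.

    contact_cutoff : heavy-atom close-contact distance (Å, default 3.0;
        boundary counts as contact).
    lmi_threshold : high-correlation threshold on normalized LMI (default 0.625).
    ma_window : moving-average window (ns, default 15).
    reference : optional reference structure (e.g. the inactive conformation)
        used by RMSD-based metrics when no explicit reference is passed.
    """

    contact_cutoff: float = 3.0
    lmi_threshold: float = 0.625
    ma_window: float = 15.0
    reference: np.ndarray | None = None

    def __post_init__(self):
        if self.contact_cutoff <= 0:
            raise TrajectoryError("contact_cutoff must be positive")
        if not (0.0 <= self.lmi_threshold <= 1.0):
            raise TrajectoryError("lmi_threshold must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Superposition / RMSD / RMSF
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the (weighted) RMSD.  The
    rotation is proper (det +1).  Requires at least three non-collinear points.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise TrajectoryError("mobile/reference must be matching (N, 3) arrays")
    if len(mob) < 3:
        raise TrajectoryError("superposition requires at least 3 atoms")
    cm = mob.mean(axis=0) if weights is None else np.average(mob, 0, weights)
    cr = ref.mean(axis=0) if weights is None else np.average(ref, 0, weights)
    a, b = mob - cm, ref - cr
    if np.linalg.matrix_rank(a, tol=1e-8) < 2:
        raise TrajectoryError("selection is collinear; superposition is degenerate")
    rot, _ = Rotation.align_vectors(b, a, weights=weights)
    R = rot.as_matrix()
    t = cr - cm @ R.T
    moved = mob @ R.T + t
    d2 = np.sum((moved - ref) ** 2, axis=1)
    rmsd = float(np.sqrt(np.average(d2, weights=weights)))
    return R, t, rmsd


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray,
    fit_selection: np.ndarray,
    measure_selection: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD: fit each frame on ``fit_selection``, measure on
    ``measure_selection`` (defaults to the fit selection).

    ``reference`` holds full-system coordinates (atoms × 3).
    """
    fit_sel = np.asarray(fit_selection, dtype=np.intp)
    meas_sel = (fit_sel if measure_selection is None
                else np.asarray(measure_selection, dtype=np.intp))
    if len(fit_sel) == 0 or len(meas_sel) == 0:
        raise TrajectoryError("selections must be non-empty")
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (traj.n_atoms, 3):
        raise TrajectoryError(
            f"reference shape {reference.shape} != (n_atoms, 3) = ({traj.n_atoms}, 3)")
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        R, t, _ = kabsch_superpose(traj.coordinates[f, fit_sel], reference[fit_sel])
        moved = traj.coordinates[f, meas_sel] @ R.T + t
        out[f] = np.sqrt(np.mean(np.sum((moved - reference[meas_sel]) ** 2, axis=1)))
    return out


def rmsf(traj: Trajectory, selection: np.ndarray | None = None,
         fit: bool = True) -> pd.Series:
    """Per-residue RMSF (Å): √⟨|r − ⟨r⟩|²⟩ per atom, averaged over the
    residue's selected atoms.

    With ``fit=True`` every frame is first superposed (two passes: onto frame
    0, then onto the resulting mean structure) so rigid-body motion does not
    inflate the fluctuations.
    """
    if traj.n_frames < 2:
        raise TrajectoryError("RMSF needs at least 2 frames")
    sel = (np.arange(traj.n_atoms) if selection is None
           else np.asarray(selection, dtype=np.intp))
    if len(sel) == 0:
        raise TrajectoryError("empty selection")
    X = traj.coordinates[:, sel, :]
    if fit:
        X = _superpose_frames(X, X[0])
        X = _superpose_frames(X, X.mean(axis=0))
    mean = X.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0))
    resids = traj.atom_table["resid"].to_numpy()[sel]
    return pd.Series(per_atom, index=pd.Index(resids, name="resid"),
                     name="rmsf").groupby(level=0).mean()


def _superpose_frames(X: np.ndarray, ref: np.ndarray) -> np.ndarray:
    out = np.empty_like(X)
    for f in range(X.shape[0]):
        R, t, _ = kabsch_superpose(X[f], ref)
        out[f] = X[f] @ R.T + t
    return out


def rmsf_distribution(rmsf_values: pd.Series, site_resids) -> dict[str, float]:
    """Summary (mean and quartiles) of RMSF over one site's residues."""
    site = [r for r in site_resids if r in rmsf_values.index]
    if not site:
        raise TrajectoryError(f"no site residues {list(site_resids)!r} in RMSF index")
    v = rmsf_values.loc[site].to_numpy(dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {"mean": float(v.mean()), "q1": float(q1), "median": float(med),
            "q3": float(q3), "n": len(v)}


# ---------------------------------------------------------------------------
# Distances and contacts
# ---------------------------------------------------------------------------

def _masses(traj: Trajectory, sel: np.ndarray) -> np.ndarray:
    return traj.atom_table["mass"].to_numpy(dtype=float)[sel]


def com_distance_series(traj: Trajectory, sel_a: np.ndarray,
                        sel_b: np.ndarray) -> np.ndarray:
    """Per-frame distance between the mass-weighted COMs of two selections."""
    sel_a = np.asarray(sel_a, dtype=np.intp)
    sel_b = np.asarray(sel_b, dtype=np.intp)
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise TrajectoryError("both selections must be non-empty")
    ma, mb = _masses(traj, sel_a), _masses(traj, sel_b)
    ca = np.einsum("fij,i->fj", traj.coordinates[:, sel_a], ma) / ma.sum()
    cb = np.einsum("fij,i->fj", traj.coordinates[:, sel_b], mb) / mb.sum()
    return np.linalg.norm(ca - cb, axis=1)


def contact_fraction(
    traj: Trajectory,
    ligand_selection: np.ndarray,
    residue_list,
    cutoff: float = 3.0,
) -> pd.Series:
    """Close-contact percentage per residue.

    A frame counts as a contact when *any* non-hydrogen ligand atom lies
    within ``cutoff`` Å (boundary inclusive) of *any* non-hydrogen atom of the
    residue.  Values are percentages of the total frame count.
    """
    lig = np.asarray(ligand_selection, dtype=np.intp)
    heavy = traj.atom_table["heavy"].to_numpy().astype(bool)
    lig = lig[heavy[lig]]
    if len(lig) == 0:
        raise TrajectoryError("ligand selection has no heavy atoms")
    known = set(traj.atom_table["resid"].tolist())
    out = {}
    L = traj.coordinates[:, lig]  # (F, nl, 3)
    for resid in residue_list:
        if resid not in known:
            raise TrajectoryError(f"residue {resid!r} absent from topology")
        res_sel = traj.select(resids=[resid], heavy_only=True)
        R = traj.coordinates[:, res_sel]  # (F, nr, 3)
        d = np.linalg.norm(L[:, :, None, :] - R[:, None, :, :], axis=-1)
        mind = d.reshape(traj.n_frames, -1).min(axis=1)
        out[resid] = 100.0 * np.count_nonzero(mind <= cutoff) / traj.n_frames
    return pd.Series(out, name="contact_pct")


# ---------------------------------------------------------------------------
# Activation metric
# ---------------------------------------------------------------------------

@dataclass
class ActivationTrace:
    """Paired per-frame activation descriptors plus reference markers.

    ``lock_distance`` is the COM distance between the two ionic-lock residues
    (TM3 Arg – TM6 Glu); ``npxxy_rmsd`` is the NPxxY-motif RMSD against the
    inactive reference.  Markers give the same two numbers evaluated on the
    inactive and active reference structures.
    """

    lock_distance: np.ndarray
    npxxy_rmsd: np.ndarray
    inactive_marker: tuple[float, float] = (np.nan, np.nan)
    active_marker: tuple[float, float] = (np.nan, np.nan)

    def __post_init__(self):
        if len(self.lock_distance) != len(self.npxxy_rmsd):
            raise TrajectoryError("activation trace series lengths differ")


def activation_trace(
    traj: Trajectory,
    lock_sel_a: np.ndarray,
    lock_sel_b: np.ndarray,
    npxxy_selection: np.ndarray,
    inactive_ref: np.ndarray,
    active_ref: np.ndarray | None = None,
    fit_selection: np.ndarray | None = None,
) -> ActivationTrace:
    """Two-dimensional activation metric along a trajectory.

    The NPxxY RMSD is measured against the inactive reference after fitting on
    ``fit_selection`` (defaults to the NPxxY selection itself).  Marker values
    for the references are reported alongside: the inactive marker's RMSD
    component is 0 by construction.
    """
    fit_sel = (np.asarray(npxxy_selection, dtype=np.intp)
               if fit_selection is None else np.asarray(fit_selection, dtype=np.intp))
    lock = com_distance_series(traj, lock_sel_a, lock_sel_b)
    nprmsd = rmsd_series(traj, inactive_ref, fit_sel, npxxy_selection)
    inactive_marker = (_static_lock(inactive_ref, traj, lock_sel_a, lock_sel_b), 0.0)
    active_marker = (np.nan, np.nan)
    if active_ref is not None:
        ref_traj = Trajectory(coordinates=active_ref[None], atom_table=traj.atom_table,
                              time_per_frame=traj.time_per_frame)
        active_marker = (
            _static_lock(active_ref, traj, lock_sel_a, lock_sel_b),
            float(rmsd_series(ref_traj, inactive_ref, fit_sel, npxxy_selection)[0]),
        )
    return ActivationTrace(lock_distance=lock, npxxy_rmsd=nprmsd,
                           inactive_marker=inactive_marker, active_marker=active_marker)


def _static_lock(ref: np.ndarray, traj: Trajectory, sa, sb) -> float:
    one = Trajectory(coordinates=np.asarray(ref)[None], atom_table=traj.atom_table,
                     time_per_frame=traj.time_per_frame)
    return float(com_distance_series(one, sa, sb)[0])


def moving_average(series: np.ndarray, window: float,
                   time_per_frame: float) -> np.ndarray:
    """Non-overlapping block means: one value per ``window`` of simulation time.

    The block length is ``floor(window / time_per_frame)`` frames; a trailing
    partial block is averaged over its actual length.  A one-frame window is
    the identity.
    """
    if window < time_per_frame:
        raise TrajectoryError("window must be at least one frame long")
    series = np.asarray(series, dtype=float)
    block = int(window // time_per_frame)
    return np.array([series[i:i + block].mean()
                     for i in range(0, len(series), block)])


# ---------------------------------------------------------------------------
# Linear mutual information
# ---------------------------------------------------------------------------

@dataclass
class LMIMatrix:
    """Normalized residue-residue LMI: symmetric, values in [0, 1], diagonal 1."""

    values: np.ndarray
    resids: list

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise TrajectoryError("LMI matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise TrajectoryError("LMI matrix must be symmetric")
        if v.min() < -1e-10 or v.max() > 1.0 + 1e-10:
            raise TrajectoryError("LMI values must lie in [0, 1]")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.resids, columns=self.resids)


def lmi_matrix(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    fit: bool = False,
    point: str = "atom",
) -> LMIMatrix:
    """Gaussian-estimator linear mutual information between residues.

    One representative 3D point per residue: either the single selected atom
    per residue (``point='atom'``, e.g. a Cα selection) or the residue COM
    (``point='com'``).  For residues i, j with displacement covariances
    ``C_i``, ``C_j`` and joint 6×6 covariance ``C_ij``::

        I_ij = 1/2 (ln det C_i + ln det C_j − ln det C_ij)
        r_ij = sqrt(1 − exp(−2 I_ij / 3))

    The diagonal is 1; with ``fit=True`` frames are superposed first so the
    matrix is invariant under global rigid motion.
    """
    if traj.n_frames < 7:
        raise TrajectoryError("LMI needs more frames than the 6 joint dimensions")
    sel = (np.arange(traj.n_atoms) if selection is None
           else np.asarray(selection, dtype=np.intp))
    resids_all = traj.atom_table["resid"].to_numpy()[sel]
    X = traj.coordinates[:, sel, :]
    if fit:
        X = _superpose_frames(X, X[0])
        X = _superpose_frames(X, X.mean(axis=0))
    resids = list(dict.fromkeys(resids_all.tolist()))
    if point == "atom":
        pts = np.empty((traj.n_frames, len(resids), 3))
        for k, r in enumerate(resids):
            idx = np.flatnonzero(resids_all == r)
            pts[:, k] = X[:, idx].mean(axis=1)
    elif point == "com":
        masses = traj.atom_table["mass"].to_numpy(dtype=float)[sel]
        pts = np.empty((traj.n_frames, len(resids), 3))
        for k, r in enumerate(resids):
            idx = np.flatnonzero(resids_all == r)
            w = masses[idx] / masses[idx].sum()
            pts[:, k] = np.einsum("fij,i->fj", X[:, idx], w)
    else:
        raise TrajectoryError(f"unknown representative point {point!r}")
    disp = pts - pts.mean(axis=0)
    n_res = len(resids)
    flat = disp.reshape(traj.n_frames, n_res * 3)
    C = np.cov(flat, rowvar=False)  # (3n, 3n)
    vals = np.eye(n_res)
    logdets = np.empty(n_res)
    for i in range(n_res):
        s, ld = np.linalg.slogdet(C[3 * i:3 * i + 3, 3 * i:3 * i + 3])
        if s <= 0:
            raise TrajectoryError(
                f"singular marginal covariance for residue {resids[i]!r}; "
                "use more frames or add fluctuation")
        logdets[i] = ld
    for i in range(n_res):
        for j in range(i + 1, n_res):
            block = np.empty((6, 6))
            bi, bj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
            block[:3, :3] = C[bi, bi]
            block[3:, 3:] = C[bj, bj]
            block[:3, 3:] = C[bi, bj]
            block[3:, :3] = C[bj, bi]
            s, ld = np.linalg.slogdet(block)
            if s <= 0:
                raise TrajectoryError(
                    f"singular joint covariance for residues "
                    f"{resids[i]!r}, {resids[j]!r}; use more frames")
            mi = max(0.0, 0.5 * (logdets[i] + logdets[j] - ld))
            vals[i, j] = vals[j, i] = np.sqrt(1.0 - np.exp(-2.0 * mi / 3.0))
    return LMIMatrix(values=vals, resids=resids)


@dataclass(frozen=True)
class CorrelatedRegion:
    """One inter-domain block of residue pairs above the LMI threshold."""

    domain_a: str
    domain_b: str
    pairs: frozenset
    runs_a: tuple[tuple[int, int], ...]
    runs_b: tuple[tuple[int, int], ...]
    max_lmi: float


def high_correlation_regions(
    lmi: LMIMatrix,
    threshold: float,
    domain_map: dict,
) -> list[CorrelatedRegion]:
    """Inter-domain residue pairs with LMI above the threshold, grouped by
    domain pair.

    ``domain_map`` assigns residues to named domains (e.g. TM1..TM7);
    unmapped residues fall into ``"other"``.  For each domain pair the
    involved residues are summarized as contiguous runs (first, last), mirroring
    the tabulated presentation of correlated TM regions.
    """
    resids = lmi.resids
    n = len(resids)
    grouped: dict[tuple[str, str], list[tuple]] = {}
    maxes: dict[tuple[str, str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            if lmi.values[i, j] <= threshold:
                continue
            da = str(domain_map.get(resids[i], "other"))
            db = str(domain_map.get(resids[j], "other"))
            if da == db:
                continue
            key, pair = ((da, db), (resids[i], resids[j])) if da <= db else \
                        ((db, da), (resids[j], resids[i]))
            grouped.setdefault(key, []).append(pair)
            maxes[key] = max(maxes.get(key, 0.0), float(lmi.values[i, j]))
    regions = []
    for (da, db), pairs in sorted(grouped.items()):
        ra = _contiguous_runs(sorted({p[0] for p in pairs}))
        rb = _contiguous_runs(sorted({p[1] for p in pairs}))
        regions.append(CorrelatedRegion(domain_a=da, domain_b=db,
                                        pairs=frozenset(pairs),
                                        runs_a=ra, runs_b=rb,
                                        max_lmi=maxes[(da, db)]))
    return regions


def _contiguous_runs(sorted_ids: list) -> tuple[tuple[int, int], ...]:
    runs = []
    start = prev = None
    for r in sorted_ids:
        if start is None:
            start = prev = r
        elif isinstance(r, (int, np.integer)) and r == prev + 1:
            prev = r
        else:
            runs.append((start, prev))
            start = prev = r
    if start is not None:
        runs.append((start, prev))
    return tuple(runs)
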