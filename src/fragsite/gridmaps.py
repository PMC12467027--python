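"""Voxelized free-energy maps (FragMaps) and the exclusion mask.

A FragMap is a regular lattice of grid free energies (GFE, kcal/mol) for one
functional-group class.  Maps are produced by Boltzmann-transforming
bulk-normalized fragment occupancies; eight map types are supported: four
generic (APOLAR, GEHC, HBDON, HBACC) and four specific (MAMN, ACEC, MEOO,
FORC).  The exclusion map is a boolean mask of solute/water-forbidden voxels.

Conventions
-----------
* ``GridSpec.origin`` is the *center* of voxel ``(0, 0, 0)``; voxel centers sit
  at ``origin + index * spacing``.
* Point lookups use nearest-voxel rounding by default (half-up via
  ``np.rint`` banker's rounding is avoided: we use ``floor(x + 0.5)`` so the
  tie-break rule is stated and testable).  Trilinear interpolation is offered
  as an option and agrees with nearest-voxel at voxel centers.
* Points outside the lattice are bulk: GFE 0, not excluded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from gridData import Grid as _DXGrid

#: Boltzmann constant in kcal/(mol K).
KB = 0.0019872041

#: Default temperature (K) for Boltzmann transforms and overlap weights.
DEFAULT_TEMPERATURE = 300.0

#: The eight FragMap types: four generic, four specific.
MAP_TYPES = ("APOLAR", "GEHC", "HBDON", "HBACC", "MAMN", "ACEC", "MEOO", "FORC")

#: Default symmetric clamp on |GFE| in kcal/mol.
DEFAULT_GFE_CAP = 3.0


class GridError(ValueError):
    """Raised for invalid grid specifications or malformed grid files."""


@dataclass(frozen=True)
class GridSpec:
    """Regular cubic lattice: origin (voxel-0 center), spacing (Å), dims."""

    origin: tuple[float, float, float]
    spacing: float = 1.0
    dims: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self):
        if self.spacing <= 0:
            raise GridError(f"grid spacing must be positive, got {self.spacing}")
        if any(d < 1 for d in self.dims):
            raise GridError(f"grid dims must all be >= 1, got {self.dims}")
        object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))

    @property
    def upper(self) -> np.ndarray:
        """Center of the last voxel along each axis."""
        return np.asarray(self.origin) + (np.asarray(self.dims) - 1) * self.spacing

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        o = np.asarray(self.origin)
        return tuple(o[i] + self.spacing * np.arange(self.dims[i]) for i in range(3))

    def voxel_centers(self) -> np.ndarray:
        """All voxel centers, shape ``dims + (3,)``."""
        ax, ay, az = self.axes()
        gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def nearest_index(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest voxel indices and an in-box mask for an (N, 3) point array.

        Midpoints round up (toward the higher index): index = floor(u + 0.5).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        u = (pts - np.asarray(self.origin)) / self.spacing
        idx = np.floor(u + 0.5).astype(np.intp)
        inside = np.all((idx >= 0) & (idx < np.asarray(self.dims)), axis=1)
        return idx, inside


def _require_same_spec(a: "GridSpec", b: "GridSpec") -> None:
    if a != b:
        raise GridError(f"grid specs differ: {a} vs {b}")


@dataclass
class GFEGrid:
    """One FragMap: a rank-3 field of grid free energies (kcal/mol)."""

    spec: GridSpec
    map_type: str
    values: np.ndarray
    cap: float = DEFAULT_GFE_CAP

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.spec.dims):
            raise GridError(
                f"values shape {self.values.shape} != grid dims {self.spec.dims}"
            )
        if not np.all(np.isfinite(self.values)):
            raise GridError("GFE values must be finite")
        if np.any(np.abs(self.values) > self.cap + 1e-12):
            raise GridError(f"|GFE| exceeds cap {self.cap}")


@dataclass
class ExclusionMap:
    """Boolean mask of forbidden voxels (solute/water-excluded region)."""

    spec: GridSpec
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != tuple(self.spec.dims):
            raise GridError(
                f"mask shape {self.mask.shape} != grid dims {self.spec.dims}"
            )


@dataclass
class FragMapSet:
    """A consistent collection of FragMaps plus the exclusion map."""

    maps: dict[str, GFEGrid]
    exclusion: ExclusionMap
    temperature: float = DEFAULT_TEMPERATURE
    boltzmann_constant: float = KB

    def __post_init__(self):
        spec = self.exclusion.spec
        for name, g in self.maps.items():
            if name not in MAP_TYPES:
                raise GridError(f"unknown map type {name!r}; expected one of {MAP_TYPES}")
            _require_same_spec(g.spec, spec)

    @property
    def spec(self) -> GridSpec:
        return self.exclusion.spec


def occupancy_to_gfe(
    occupancy: np.ndarray,
    bulk_value: float,
    temperature: float = DEFAULT_TEMPERATURE,
    cap: float = DEFAULT_GFE_CAP,
    spec: GridSpec | None = None,
    map_type: str = "APOLAR",
) -> GFEGrid:
    """Boltzmann-transform a bulk-normalized occupancy field into a GFE grid.

    ``GFE = -kB * T * ln(occupancy / bulk)``, clamped to ``[-cap, +cap]``;
    zero occupancy maps to ``+cap``.
    """
    occ = np.asarray(occupancy, dtype=float)
    if bulk_value <= 0:
        raise GridError(f"bulk_value must be positive, got {bulk_value}")
    if temperature <= 0:
        raise GridError(f"temperature must be positive, got {temperature}")
    if np.any(occ < 0):
        raise GridError("occupancy must be non-negative")
    with np.errstate(divide="ignore"):
        gfe = -KB * temperature * np.log(occ / bulk_value)
    gfe = np.clip(gfe, -cap, cap)  # +inf from occ=0 clamps to +cap
    if spec is None:
        spec = GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=occ.shape)
    return GFEGrid(spec=spec, map_type=map_type, values=gfe, cap=cap)


def gfe_at(grid: GFEGrid, points: np.ndarray, mode: str = "nearest") -> np.ndarray | float:
    """GFE at arbitrary points: nearest-voxel (default) or trilinear.

    Outside the lattice the bulk convention applies (0.0 kcal/mol).
    Accepts a single 3-vector or an (N, 3) array.
    """
    pts = np.asarray(points, dtype=float)
    scalar = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if mode == "nearest":
        idx, inside = grid.spec.nearest_index(pts)
        out = np.zeros(len(pts))
        if inside.any():
            ii = idx[inside]
            out[inside] = grid.values[ii[:, 0], ii[:, 1], ii[:, 2]]
    elif mode == "trilinear":
        out = _trilinear(grid, pts)
    else:
        raise GridError(f"unknown lookup mode {mode!r}")
    return float(out[0]) if scalar else out


def _trilinear(grid: GFEGrid, pts: np.ndarray) -> np.ndarray:
    """Trilinear interpolation with bulk (0) padding outside the lattice."""
    spec = grid.spec
    u = (pts - np.asarray(spec.origin)) / spec.spacing
    lo = np.floor(u).astype(np.intp)
    frac = u - lo
    out = np.zeros(len(pts))
    dims = np.asarray(spec.dims)
    for corner in range(8):
        off = np.array([(corner >> k) & 1 for k in range(3)])
        idx = lo + off
        w = np.prod(np.where(off, frac, 1.0 - frac), axis=1)
        ok = np.all((idx >= 0) & (idx < dims), axis=1)
        if ok.any():
            ii = idx[ok]
            out[ok] += w[ok] * grid.values[ii[:, 0], ii[:, 1], ii[:, 2]]
    return out


def is_excluded(excl: ExclusionMap, points: np.ndarray) -> np.ndarray | bool:
    """Nearest-voxel exclusion lookup; outside the lattice is never excluded."""
    pts = np.asarray(points, dtype=float)
    scalar = pts.ndim == 1
    pts = np.atleast_2d(pts)
    idx, inside = excl.spec.nearest_index(pts)
    out = np.zeros(len(pts), dtype=bool)
    if inside.any():
        ii = idx[inside]
        out[inside] = excl.mask[ii[:, 0], ii[:, 1], ii[:, 2]]
    return bool(out[0]) if scalar else out


def boltzmann_weights(grid: GFEGrid, temperature: float = DEFAULT_TEMPERATURE) -> np.ndarray:
    """Voxel probabilities p_v ∝ exp(-GFE_v / kB T), normalized to sum 1."""
    w = np.exp(-grid.values / (KB * temperature))
    return w / w.sum()


def overlap_coefficient(
    a: GFEGrid, b: GFEGrid, temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """Similarity of two maps of the same type on the same lattice, in [0, 1].

    ``OC = sum_v min(p_v(a), p_v(b))`` over Boltzmann-normalized voxel
    probabilities.  1 iff the normalized weight fields are identical; values
    above ~0.7 are conventionally read as converged map pairs.
    """
    _require_same_spec(a.spec, b.spec)
    if a.map_type != b.map_type:
        raise GridError(f"map types differ: {a.map_type} vs {b.map_type}")
    pa = boltzmann_weights(a, temperature)
    pb = boltzmann_weights(b, temperature)
    return float(np.minimum(pa, pb).sum())


# ---------------------------------------------------------------------------
# DX (OpenDX) volumetric I/O
# ---------------------------------------------------------------------------

_DX_HEADER_PATTERNS = {
    "counts": re.compile(
        r"object\s+1\s+class\s+gridpositions\s+counts\s+(\d+)\s+(\d+)\s+(\d+)"
    ),
    "origin": re.compile(r"origin\s+(\S+)\s+(\S+)\s+(\S+)"),
    "delta": re.compile(r"delta\s+(\S+)\s+(\S+)\s+(\S+)"),
}


def _validate_dx_header(path: Path) -> None:
    """Pre-validate the DX header so malformed files fail naming the line."""
    seen = {"counts": False, "origin": False, "delta": 0}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if s.startswith("object 1"):
                m = _DX_HEADER_PATTERNS["counts"].match(s)
                if not m:
                    raise GridError(f"{path}: malformed gridpositions line {lineno}: {s!r}")
                if any(int(g) < 1 for g in m.groups()):
                    raise GridError(f"{path}: non-positive grid counts at line {lineno}: {s!r}")
                seen["counts"] = True
            elif s.startswith("origin"):
                if not _DX_HEADER_PATTERNS["origin"].match(s):
                    raise GridError(f"{path}: malformed origin line {lineno}: {s!r}")
                seen["origin"] = True
            elif s.startswith("delta"):
                m = _DX_HEADER_PATTERNS["delta"].match(s)
                if not m:
                    raise GridError(f"{path}: malformed delta line {lineno}: {s!r}")
                try:
                    vals = [float(g) for g in m.groups()]
                except ValueError:
                    raise GridError(f"{path}: non-numeric delta at line {lineno}: {s!r}")
                if max(abs(v) for v in vals) <= 0:
                    raise GridError(f"{path}: zero delta row at line {lineno}: {s!r}")
                seen["delta"] += 1
            elif s.startswith("object 3"):
                break
    if not seen["counts"]:
        raise GridError(f"{path}: missing 'object 1 class gridpositions counts' header line")
    if not seen["origin"]:
        raise GridError(f"{path}: missing 'origin' header line")
    if seen["delta"] < 3:
        raise GridError(f"{path}: expected 3 'delta' header lines, found {seen['delta']}")


def read_dx(path, map_type: str = "APOLAR", cap: float | None = None) -> GFEGrid:
    """Read a GFE grid from an OpenDX file (header validated line-by-line)."""
    path = Path(path)
    _validate_dx_header(path)
    g = _DXGrid(str(path))
    deltas = np.asarray(g.delta)
    if deltas.ndim == 2:
        deltas = np.diag(deltas)
    if not np.allclose(deltas, deltas[0]):
        raise GridError(f"{path}: anisotropic spacing {deltas} not supported")
    spec = GridSpec(origin=tuple(g.origin), spacing=float(deltas[0]), dims=g.grid.shape)
    values = np.asarray(g.grid, dtype=float)
    if cap is None:
        cap = max(DEFAULT_GFE_CAP, float(np.abs(values).max()))
    return GFEGrid(spec=spec, map_type=map_type, values=values, cap=cap)


def write_dx(grid: GFEGrid, path) -> None:
    """Write a GFE grid as OpenDX (lossless round trip within float precision)."""
    g = _DXGrid(grid.values, origin=np.asarray(grid.spec.origin),
                delta=grid.spec.spacing)
    g.export(str(path), typequote='"')


def read_exclusion_dx(path) -> ExclusionMap:
    """Read an exclusion mask stored as a 0/1-valued DX grid."""
    g = read_dx(path, map_type="APOLAR", cap=np.inf)
    return ExclusionMap(spec=g.spec, mask=g.values > 0.5)


def write_exclusion_dx(excl: ExclusionMap, path) -> None:
    g = _DXGrid(excl.mask.astype(float), origin=np.asarray(excl.spec.origin),
                delta=excl.spec.spacing)
    g.export(str(path), typequote='"')
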