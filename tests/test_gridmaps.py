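import numpy as np
import pytest
from hypothesis import given, strategies as st

from fragsite.gridmaps import (DEFAULT_GFE_CAP, KB, ExclusionMap, FragMapSet,
                               GFEGrid, GridError, GridSpec, boltzmann_weights,
                               gfe_at, is_excluded, occupancy_to_gfe,
                               overlap_coefficient, read_dx, read_exclusion_dx,
                               write_dx, write_exclusion_dx)
from conftest import random_gfe_grid


# ---------------------------------------------------------------------------
# GridSpec
# ---------------------------------------------------------------------------

class TestGridSpec:
    def test_invalid_spacing_rejected(self):
        with pytest.raises(GridError, match="spacing"):
            GridSpec(origin=(0, 0, 0), spacing=0.0)
        with pytest.raises(GridError, match="spacing"):
            GridSpec(origin=(0, 0, 0), spacing=-1.0)

    def test_invalid_dims_rejected(self):
        with pytest.raises(GridError, match="dims"):
            GridSpec(origin=(0, 0, 0), dims=(0, 3, 3))

    def test_upper_is_last_voxel_center(self):
        spec = GridSpec(origin=(1.0, 2.0, 3.0), spacing=0.5, dims=(3, 4, 5))
        assert np.allclose(spec.upper, [2.0, 3.5, 5.0])

    def test_voxel_centers_shape_and_values(self):
        spec = GridSpec(origin=(0, 0, 0), spacing=2.0, dims=(2, 2, 2))
        c = spec.voxel_centers()
        assert c.shape == (2, 2, 2, 3)
        assert np.allclose(c[1, 0, 1], [2.0, 0.0, 2.0])

    def test_nearest_index_midpoint_rounds_up(self):
        spec = GridSpec(origin=(0, 0, 0), spacing=1.0, dims=(4, 4, 4))
        idx, inside = spec.nearest_index([[0.5, 0.499, 1.5]])
        assert inside[0]
        assert idx[0].tolist() == [1, 0, 2]

    def test_nearest_index_outside(self):
        spec = GridSpec(origin=(0, 0, 0), spacing=1.0, dims=(4, 4, 4))
        _, inside = spec.nearest_index([[-0.6, 0, 0], [3.4, 0, 0], [3.6, 0, 0]])
        assert inside.tolist() == [False, True, False]


# ---------------------------------------------------------------------------
# GFEGrid / ExclusionMap / FragMapSet validation
# ---------------------------------------------------------------------------

class TestContainers:
    def test_shape_mismatch_rejected(self, small_spec):
        with pytest.raises(GridError, match="shape"):
            GFEGrid(spec=small_spec, map_type="APOLAR", values=np.zeros((2, 2, 2)))

    def test_cap_enforced(self, small_spec):
        vals = np.zeros(small_spec.dims)
        vals[0, 0, 0] = 4.0
        with pytest.raises(GridError, match="cap"):
            GFEGrid(spec=small_spec, map_type="APOLAR", values=vals)
        GFEGrid(spec=small_spec, map_type="APOLAR", values=vals, cap=4.0)

    def test_non_finite_rejected(self, small_spec):
        vals = np.zeros(small_spec.dims)
        vals[1, 1, 1] = np.nan
        with pytest.raises(GridError, match="finite"):
            GFEGrid(spec=small_spec, map_type="APOLAR", values=vals)

    def test_fragmapset_rejects_unknown_type(self, small_spec):
        g = GFEGrid(spec=small_spec, map_type="APOLAR",
                    values=np.zeros(small_spec.dims))
        excl = ExclusionMap(spec=small_spec,
                            mask=np.zeros(small_spec.dims, dtype=bool))
        with pytest.raises(GridError, match="unknown map type"):
            FragMapSet(maps={"BOGUS": g}, exclusion=excl)

    def test_fragmapset_rejects_spec_mismatch(self, small_spec):
        other = GridSpec(origin=(0, 0, 0), dims=(3, 3, 3))
        g = GFEGrid(spec=other, map_type="APOLAR", values=np.zeros((3, 3, 3)))
        excl = ExclusionMap(spec=small_spec,
                            mask=np.zeros(small_spec.dims, dtype=bool))
        with pytest.raises(GridError, match="specs differ"):
            FragMapSet(maps={"APOLAR": g}, exclusion=excl)


# ---------------------------------------------------------------------------
# Boltzmann transform
# ---------------------------------------------------------------------------

class TestOccupancyToGFE:
    def test_formula_and_bulk_zero(self):
        occ = np.full((2, 2, 2), 2.0)
        g = occupancy_to_gfe(occ, bulk_value=1.0, temperature=300.0)
        expected = -KB * 300.0 * np.log(2.0)
        assert np.allclose(g.values, expected)
        g_bulk = occupancy_to_gfe(np.ones((2, 2, 2)), bulk_value=1.0)
        assert np.allclose(g_bulk.values, 0.0)

    def test_zero_occupancy_clamps_to_plus_cap(self):
        occ = np.zeros((2, 2, 2))
        g = occupancy_to_gfe(occ, bulk_value=1.0, cap=3.0)
        assert np.allclose(g.values, 3.0)

    def test_clamp_both_sides(self):
        occ = np.array([[[1e9, 1e-9]]])
        g = occupancy_to_gfe(occ, bulk_value=1.0, cap=2.0)
        assert g.values[0, 0, 0] == -2.0
        assert g.values[0, 0, 1] == 2.0

    def test_invalid_inputs(self):
        with pytest.raises(GridError, match="bulk"):
            occupancy_to_gfe(np.ones((2, 2, 2)), bulk_value=0.0)
        with pytest.raises(GridError, match="temperature"):
            occupancy_to_gfe(np.ones((2, 2, 2)), 1.0, temperature=-1.0)
        with pytest.raises(GridError, match="non-negative"):
            occupancy_to_gfe(-np.ones((2, 2, 2)), 1.0)


# ---------------------------------------------------------------------------
# Point lookups
# ---------------------------------------------------------------------------

class TestLookup:
    def test_nearest_at_voxel_centers(self, rng):
        g = random_gfe_grid(rng)
        centers = g.spec.voxel_centers().reshape(-1, 3)
        assert np.allclose(gfe_at(g, centers), g.values.ravel())

    def test_trilinear_agrees_at_centers(self, rng):
        g = random_gfe_grid(rng)
        centers = g.spec.voxel_centers().reshape(-1, 3)
        assert np.allclose(gfe_at(g, centers, mode="trilinear"),
                           g.values.ravel(), atol=1e-12)

    def test_trilinear_midpoint_is_mean(self):
        spec = GridSpec(origin=(0, 0, 0), spacing=1.0, dims=(2, 1, 1))
        g = GFEGrid(spec=spec, map_type="APOLAR",
                    values=np.array([1.0, 3.0]).reshape(2, 1, 1))
        assert gfe_at(g, np.array([0.5, 0.0, 0.0]), mode="trilinear") == \
            pytest.approx(2.0)

    def test_outside_is_bulk_zero(self, rng):
        g = random_gfe_grid(rng)
        far = np.asarray(g.spec.origin) - 100.0
        assert gfe_at(g, far) == 0.0
        assert gfe_at(g, far, mode="trilinear") == 0.0

    def test_unknown_mode(self, rng):
        g = random_gfe_grid(rng)
        with pytest.raises(GridError, match="mode"):
            gfe_at(g, np.zeros(3), mode="cubic")

    def test_exclusion_lookup(self, small_spec):
        mask = np.zeros(small_spec.dims, dtype=bool)
        mask[5, 5, 5] = True  # voxel center (0,0,0)
        excl = ExclusionMap(spec=small_spec, mask=mask)
        assert is_excluded(excl, np.zeros(3))
        assert not is_excluded(excl, np.array([2.0, 0, 0]))
        assert not is_excluded(excl, np.array([100.0, 0, 0]))  # outside: bulk


# ---------------------------------------------------------------------------
# Overlap coefficient
# ---------------------------------------------------------------------------

class TestOverlap:
    def test_identical_grids_give_one(self, rng):
        g = random_gfe_grid(rng)
        assert overlap_coefficient(g, g) == pytest.approx(1.0, abs=1e-12)

    def test_weights_normalized(self, rng):
        g = random_gfe_grid(rng)
        assert boltzmann_weights(g).sum() == pytest.approx(1.0)

    @given(seed=st.integers(0, 50))
    def test_symmetric_and_bounded(self, seed):
        r = np.random.default_rng(seed)
        spec = GridSpec(origin=(0, 0, 0), dims=(4, 4, 4))
        a = random_gfe_grid(r, spec)
        b = random_gfe_grid(r, spec)
        oc = overlap_coefficient(a, b)
        assert 0.0 <= oc <= 1.0 + 1e-12
        assert oc == pytest.approx(overlap_coefficient(b, a), abs=1e-12)

    def test_disjoint_concentration_gives_small_overlap(self):
        spec = GridSpec(origin=(0, 0, 0), dims=(2, 1, 1))
        cap = 50.0
        a = GFEGrid(spec=spec, map_type="APOLAR", cap=cap,
                    values=np.array([-cap, cap]).reshape(2, 1, 1))
        b = GFEGrid(spec=spec, map_type="APOLAR", cap=cap,
                    values=np.array([cap, -cap]).reshape(2, 1, 1))
        assert overlap_coefficient(a, b) < 1e-10

    def test_mismatches_rejected(self, rng):
        spec = GridSpec(origin=(0, 0, 0), dims=(3, 3, 3))
        a = random_gfe_grid(rng, spec)
        b = GFEGrid(spec=spec, map_type="ACEC", values=np.zeros((3, 3, 3)))
        with pytest.raises(GridError, match="types differ"):
            overlap_coefficient(a, b)
        c = random_gfe_grid(rng, GridSpec(origin=(1, 0, 0), dims=(3, 3, 3)))
        with pytest.raises(GridError, match="specs differ"):
            overlap_coefficient(a, c)


# ---------------------------------------------------------------------------
# DX I/O
# ---------------------------------------------------------------------------

class TestDX:
    def test_round_trip(self, rng, tmp_path):
        g = random_gfe_grid(rng)
        p = tmp_path / "map.dx"
        write_dx(g, p)
        g2 = read_dx(p, map_type="APOLAR")
        # text format carries finite decimal precision in the header
        assert g2.spec.dims == g.spec.dims
        assert np.allclose(g2.spec.origin, g.spec.origin, atol=1e-5)
        assert g2.spec.spacing == pytest.approx(g.spec.spacing, abs=1e-5)
        assert np.allclose(g2.values, g.values, atol=1e-9)

    def test_exclusion_round_trip(self, small_spec, tmp_path):
        mask = np.zeros(small_spec.dims, dtype=bool)
        mask[2:4, 3, 3] = True
        excl = ExclusionMap(spec=small_spec, mask=mask)
        p = tmp_path / "excl.dx"
        write_exclusion_dx(excl, p)
        excl2 = read_exclusion_dx(p)
        assert np.array_equal(excl2.mask, mask)

    GOOD_HEADER = (
        "object 1 class gridpositions counts 2 2 2\n"
        "origin 0.0 0.0 0.0\n"
        "delta 1.0 0.0 0.0\n"
        "delta 0.0 1.0 0.0\n"
        "delta 0.0 0.0 1.0\n"
        "object 2 class gridconnections counts 2 2 2\n"
        "object 3 class array type double rank 0 items 8 data follows\n"
        "0.0 0.0 0.0\n0.0 0.0 0.0\n0.0 0.0\n")

    @pytest.mark.parametrize("mutate,msg", [
        (lambda t: t.replace("origin", "orygin"), "origin"),
        (lambda t: "\n".join(l for l in t.splitlines()
                             if not l.startswith("delta")), "delta"),
        (lambda t: t.replace("counts 2 2 2", "counts 2 x 2", 1), "gridpositions"),
        (lambda t: t.replace("counts 2 2 2", "counts 0 2 2", 1), "counts"),
        (lambda t: t.replace("delta 1.0 0.0 0.0", "delta 0.0 0.0 0.0"), "delta"),
    ])
    def test_malformed_header_rejected_naming_line(self, tmp_path, mutate, msg):
        bad = tmp_path / "bad.dx"
        bad.write_text(mutate(self.GOOD_HEADER))
        with pytest.raises(GridError, match=msg):
            read_dx(bad)

    def test_good_minimal_header_accepted(self, tmp_path):
        p = tmp_path / "good.dx"
        p.write_text(self.GOOD_HEADER)
        g = read_dx(p)
        assert g.spec.dims == (2, 2, 2)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_dx(tmp_path / "nope.dx")
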