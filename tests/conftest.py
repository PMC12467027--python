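import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fragsite.gridmaps import ExclusionMap, FragMapSet, GFEGrid, GridSpec
from fragsite.ligand_model import Atom, ClassificationRules, Ligand
from fragsite.synthetic_data import PlantedWell, make_fragmap_set, make_ligand

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rules():
    return ClassificationRules.default()


@pytest.fixture(scope="session")
def small_spec():
    return GridSpec(origin=(-5.0, -5.0, -5.0), spacing=1.0, dims=(11, 11, 11))


@pytest.fixture(scope="session")
def well_maps(small_spec):
    """Two-type map set with one well per type, no noise."""
    wells = [PlantedWell((0.0, 0.0, 0.0), -2.5, 2.0, "APOLAR"),
             PlantedWell((2.0, 0.0, 0.0), -1.5, 1.5, "ACEC")]
    fm, truth = make_fragmap_set(wells, small_spec)
    return fm, truth


@pytest.fixture(scope="session")
def steroid():
    return make_ligand("steroid_acid")


@pytest.fixture(scope="session")
def probe():
    return make_ligand("probe_atom")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_gfe_grid(rng, spec=None, cap=3.0):
    if spec is None:
        spec = GridSpec(origin=tuple(rng.uniform(-3, 0, 3)),
                        spacing=float(rng.uniform(0.5, 1.5)),
                        dims=tuple(int(d) for d in rng.integers(4, 9, 3)))
    values = rng.uniform(-cap, cap, size=spec.dims)
    return GFEGrid(spec=spec, map_type="APOLAR", values=values, cap=cap)


def flat_mapset(spec, map_types=("APOLAR",)):
    maps = {mt: GFEGrid(spec=spec, map_type=mt, values=np.zeros(spec.dims))
            for mt in map_types}
    excl = ExclusionMap(spec=spec, mask=np.zeros(spec.dims, dtype=bool))
    return FragMapSet(maps=maps, exclusion=excl)


def tripeptide_ligand():
    """Small flexible test ligand: 4 heavy atoms in a chain + 1 hydrogen."""
    atoms = [
        Atom("C", "c_apolar", False, "C1"),
        Atom("C", "c_apolar", False, "C2"),
        Atom("O", "o_hydroxyl", False, "O3"),
        Atom("C", "c_carboxyl", False, "C4"),
        Atom("H", "h_polar", True, "H5"),
    ]
    coords = np.array([
        [0.0, 0.0, 0.0],
        [1.5, 0.0, 0.0],
        [2.2, 1.2, 0.3],
        [3.6, 1.2, 0.1],
        [1.9, 2.0, 0.8],
    ])
    bonds = [(0, 1), (1, 2), (2, 3), (2, 4)]
    from fragsite.ligand_model import find_rotatable_dihedrals
    return Ligand(name="chain4", atoms=atoms, coords=coords, bonds=bonds,
                  rotatable_dihedrals=find_rotatable_dihedrals(atoms, bonds))
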