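import numpy as np
import pytest

from confcube.core import Frame, Topology
from confcube.ensemble import make_basin_targets, make_reference_bundle


def bead_frame(coords, res_ids=None, element="C", atom_name="CA", masses=None,
               dihedrals=None, time_ps=0.0):
    """Minimal bead-model frame for toy geometries (coords in nm)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if res_ids is None:
        res_ids = np.arange(1, n + 1)
    top = Topology(
        atom_names=np.full(n, atom_name),
        res_names=np.full(n, "ALA"),
        res_ids=np.asarray(res_ids),
        chain_ids=np.full(n, "A"),
        elements=np.full(n, element),
        masses=masses,
    )
    return Frame(top, coords, time_ps=time_ps, dihedrals=dihedrals)


@pytest.fixture(scope="session")
def reference():
    return make_reference_bundle()


@pytest.fixture(scope="session")
def basins(reference):
    return make_basin_targets(reference)
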