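import numpy as np
import pandas as pd
import pytest

from aquagate.structures import StructureModel, Trajectory

TINY_PDB = """\
ATOM      1  CA  ALA A   1      10.000  20.000  30.000  1.00  0.00           C
ATOM      2  CB  ALA A   1      11.500  20.000  30.000  1.00  0.00           C
ATOM      3  CA  GLY A   2      14.000  24.000  30.000  1.00  0.00           C
END
"""


@pytest.fixture
def tiny_pdb_path(tmp_path):
    p = tmp_path / "tiny.pdb"
    p.write_text(TINY_PDB)
    return p


def make_structure(rows):
    """rows: (atom_id, name, resname, resnum, chain, element, x, y, z)."""
    return StructureModel(
        pd.DataFrame(
            rows,
            columns=[
                "atom_id",
                "atom_name",
                "residue_name",
                "residue_number",
                "chain_id",
                "element",
                "x",
                "y",
                "z",
            ],
        )
    )


@pytest.fixture
def square_structure():
    """Four non-coplanar points, known coordinates in nm."""
    return make_structure(
        [
            (1, "CA", "ALA", 1, "A", "C", 0.0, 0.0, 0.0),
            (2, "CA", "ALA", 2, "A", "C", 1.0, 0.0, 0.1),
            (3, "CA", "ALA", 3, "A", "C", 1.0, 1.0, 0.0),
            (4, "CA", "ALA", 4, "A", "C", 0.0, 1.0, 0.3),
        ]
    )


def single_water_trajectory(zs, xs=None, ys=None, frame_period_ps=10.0):
    """Trajectory of one particle following the given per-frame coordinates."""
    n = len(zs)
    coords = np.zeros((n, 1, 3))
    coords[:, 0, 2] = zs
    if xs is not None:
        coords[:, 0, 0] = xs
    if ys is not None:
        coords[:, 0, 1] = ys
    return Trajectory(atom_ids=np.array([1]), coords=coords, frame_period_ps=frame_period_ps)


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
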