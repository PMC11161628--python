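import numpy as np
import pytest

import myoconf as mc


@pytest.fixture(scope="session")
def default_model() -> mc.Structure:
    """The default two-domain motor model at the primed lever angle."""
    return mc.make_motor_model()


@pytest.fixture(scope="session")
def noiseless_swing(default_model):
    """A 30-frame noiseless swing trajectory with a known angle schedule."""
    spec = mc.SyntheticSpec(noise_sigma=0.0, n_frames=30, seed=3)
    return mc.make_swing_trajectory(default_model, spec)


@pytest.fixture()
def tiny_pdb(tmp_path):
    """Minimal 3-atom single-model PDB file."""
    text = (
        "ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N\n"
        "ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C\n"
        "ATOM      3  C   ALA A   1      10.570   5.702  -4.130  1.00  0.00           C\n"
        "END\n"
    )
    path = tmp_path / "tiny.pdb"
    path.write_text(text)
    return path


@pytest.fixture()
def altloc_pdb(tmp_path):
    """One residue with an altloc'd CA: B has the higher occupancy."""
    text = (
        "ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N\n"
        "ATOM      2  CA ASER A   1       1.000   0.000   0.000  0.40  0.00           C\n"
        "ATOM      3  CA BSER A   1       2.000   0.000   0.000  0.60  0.00           C\n"
        "ATOM      4  OG ASER A   1       3.000   0.000   0.000  0.50  0.00           O\n"
        "ATOM      5  OG BSER A   1       4.000   0.000   0.000  0.50  0.00           O\n"
        "END\n"
    )
    path = tmp_path / "altloc.pdb"
    path.write_text(text)
    return path


def rigid_transform(coords: np.ndarray, seed: int = 0) -> np.ndarray:
    """Apply a random proper rotation + translation (helper for invariance
    tests)."""
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.uniform(-30, 30, 3)
    return coords @ rot.T + trans
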