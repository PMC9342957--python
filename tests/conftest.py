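import numpy as np
import pandas as pd
import pytest

from pepmem.synthetic import BilayerSpec, SyntheticTruth, make_bilayer_trajectory
from pepmem.traj_analysis import Trajectory


def build_traj(coords, box=(100.0, 100.0, 100.0), rows=None):
    """Assemble a Trajectory from bare arrays for hand-built geometry tests."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n_frames, n_atoms = coords.shape[:2]
    if rows is None:
        rows = [
            {"name": f"A{i}", "element": "C", "resid": i + 1, "chain": "X",
             "role": "peptide", "radius": 1.7}
            for i in range(n_atoms)
        ]
    boxes = np.tile(np.asarray(box, dtype=float), (n_frames, 1))
    return Trajectory(coords=coords, box=boxes, atoms=pd.DataFrame(rows), meta={})


def lipid_row(name, element, resid, role):
    return {"name": name, "element": element, "resid": resid, "chain": "L",
            "role": role, "radius": 1.8}


def peptide_row(name, resid, chain="P01"):
    return {"name": name, "element": "C", "resid": resid, "chain": chain,
            "role": "peptide", "radius": 1.7}


@pytest.fixture
def zero_noise_truth():
    """Frozen geometry: phosphate planes at ±19 Å, no jitter anywhere."""
    return SyntheticTruth(
        seed=0,
        depth_jitter=0.0,
        lipid_z_jitter=0.0,
        lipid_xy_jitter=0.0,
        peptide_xy_jitter=0.0,
        apl_jitter=0.0,
    )


@pytest.fixture
def small_bilayer(zero_noise_truth):
    return make_bilayer_trajectory(BilayerSpec(), 20, zero_noise_truth, 5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
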