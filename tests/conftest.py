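import numpy as np
import pytest

from femstrength.calibration import calibrate_volume
from femstrength.material_model import MaterialTable
from femstrength.synthetic_data import (default_phantom, generate_column_volume,
                                        generate_femur_volume)
from femstrength.voxel_mesh import build_mesh


@pytest.fixture(scope="session")
def femur_bundle():
    """Synthetic femur volume with truth, phantom and calibrated densities."""
    vol, truth, phantom = generate_femur_volume(seed=1)
    dv, line = calibrate_volume(vol, phantom)
    return {"volume": vol, "truth": truth, "phantom": phantom,
            "dv": dv, "line": line}


@pytest.fixture()
def column_model_factory():
    """Build a uniform column mesh plus a single-material table on demand."""

    def make(column_shape=(4, 4, 8), E=5000.0, sigma_y=np.inf, poisson=0.0,
             rho_apparent=0.8):
        vol, truth, phantom = generate_column_volume(
            column_shape=column_shape, rho_apparent=rho_apparent)
        dv, _ = calibrate_volume(vol, phantom)
        model = build_mesh(dv, truth.bone_mask)
        n = int((~model.is_pad).sum())
        mats = MaterialTable(
            n_bins=1, bin_edges=np.array([0.0, 2.0]), rho_mid=np.array([1.0]),
            E=np.array([float(E)]), sigma_y=np.array([float(sigma_y)]),
            poisson=float(poisson), element_to_bin=np.zeros(n, dtype=int))
        return model, mats

    return make


@pytest.fixture(scope="session")
def small_phantom():
    return default_phantom((48, 48, 96), roi_size=10)
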