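import numpy as np
import pandas as pd
import pytest

from fiberalign import ChainParams, ReferenceMap, simulation_params


@pytest.fixture
def worked_params() -> ChainParams:
    """The parameterization of the printed worked examples: bare B-DNA
    compaction, 150-bp persistence length, 100-nm pixels."""
    return ChainParams(tau=0.34, l_p=150.0, pixel_nm=100.0)


@pytest.fixture
def sim_params() -> ChainParams:
    return simulation_params()


@pytest.fixture
def small_ref() -> ReferenceMap:
    """Ten irregularly spaced loci spanning ~10 Mb."""
    pos = np.array([3.0, 3.8, 5.1, 5.9, 7.4, 8.1, 9.6, 10.4, 11.9, 13.0]) * 1e6
    return ReferenceMap("chrT", pos)


def spot_frame(orders, xyz, cell_id=0, chrom="chrT", sigma=50.0,
               labels=None, fibers=None) -> pd.DataFrame:
    """Helper to build a spot table from raw arrays."""
    xyz = np.asarray(xyz, dtype=float)
    n = len(orders)
    df = pd.DataFrame({
        "cell_id": cell_id, "chromosome": chrom,
        "locus_order": np.asarray(orders, dtype=int),
        "x_nm": xyz[:, 0], "y_nm": xyz[:, 1], "z_nm": xyz[:, 2],
        "sigma_x_nm": sigma, "sigma_y_nm": sigma, "sigma_z_nm": sigma,
    })
    df["label"] = labels if labels is not None else "TP"
    df["fiber_id"] = fibers if fibers is not None else 0
    return df
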