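import numpy as np
import pytest

import oximap as om


@pytest.fixture(scope="session")
def ext_table() -> om.ExtinctionTable:
    return om.ExtinctionTable.default()


@pytest.fixture(scope="session")
def lut(ext_table) -> om.InversionLUT:
    return om.build_inversion_lut(ext_table)


@pytest.fixture(scope="session")
def lut_config() -> om.LutConfig:
    return om.LutConfig()


def make_flat_scene(sto2_pct: float, shape=(48, 48), thb=None, baseline=0.5) -> om.ScenePhantom:
    """Uniform phantom with no texture, no speculars (helper, not a fixture)."""
    cfg = om.LutConfig()
    return om.ScenePhantom(
        sto2_truth=np.full(shape, float(sto2_pct)),
        thb_truth=np.full(shape, cfg.thb_ref_g_per_l if thb is None else float(thb)),
        baseline_truth=np.full(shape, baseline),
        specular_mask=np.zeros(shape, dtype=bool),
    )


@pytest.fixture()
def flat_scene_52():
    return make_flat_scene(52.6)


def noiseless_pair(scene, ext_table, seed=0):
    strm = om.simulate_stream(
        scene, 2, noise_config=om.NoiseConfig.disabled(), seed=seed, table=ext_table
    )
    return om.pair_frames(strm)[0]
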