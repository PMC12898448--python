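import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_bundle(tmp_path_factory):
    """A small toy membrane written to disk and re-read through the loaders."""
    import memperm as mp

    composition = {"POPC": 3, "CHOL": 3, "OSM": 2, "SAPE": 2}
    toy = mp.make_toy_membrane(composition, n_solute=4, seed=11, n_frames=5,
                               solute_depths=[0.0, 1.0, -2.0, 4.5])
    d = tmp_path_factory.mktemp("toy")
    paths = toy.write(str(d))
    reader = mp.load_system(paths["gro"], paths["trajectory"])
    return {"toy": toy, "paths": paths, "reader": reader}


@pytest.fixture(scope="session")
def flat_langevin():
    """Shared flat-landscape Langevin run (8 particles, 400 ns)."""
    import memperm as mp

    params = mp.LangevinParams(0.5, 440.0, 0.01, 40000, 8, 12.0, seed=23,
                               sample_every=1)
    return mp.simulate_langevin(mp.PMFSpec.flat((-2.0, 2.0)), params)
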