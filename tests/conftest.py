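import pytest

import qspectcal as q

CF_TRUE = 9.36          # cps/MBq, simulator default
TAU_TRUE = 0.550e-6     # s, simulator default


@pytest.fixture(scope="session")
def camera():
    return q.CameraTruth()


@pytest.fixture(scope="session")
def scheme():
    return q.default_scheme()


@pytest.fixture(scope="session")
def noisefree_series(camera):
    """Exact (noise-off) planar series over the default activity ladder."""
    plan = q.default_planar_plan(seed=0, noise=False)
    return q.generate_series(camera, q.air_2d(), plan)


@pytest.fixture(scope="session")
def noisy_series(camera):
    plan = q.default_planar_plan(seed=42)
    return q.generate_series(camera, q.air_2d(), plan)
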