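import numpy as np
import pytest

import phasebasket as pb


@pytest.fixture(scope="session")
def sphere_geometry():
    return pb.make_basket_geometry("sphere", 25.0, seed=1)


@pytest.fixture(scope="session")
def basket(sphere_geometry):
    return pb.BasketMesh.build(sphere_geometry, rounds=3)


@pytest.fixture(scope="session")
def grid():
    return pb.GridMesh2D.build()


@pytest.fixture(scope="session")
def spiral_case(sphere_geometry):
    """Full pipeline run on a clean synthetic spiral (T=180 ms, 4 s, 1 kHz)."""
    model = pb.ActivationModel(kind="spiral", period_ms=180.0, chirality=1)
    egm, truth = pb.synth_electrograms(
        model, sphere_geometry, duration_s=4.0, fs=1000.0, seed=1
    )
    result = pb.run_case(egm, sphere_geometry)
    return model, egm, truth, result


def random_phase_frame_2d(rng):
    return pb.PhaseFrame2D(
        phases=rng.uniform(-np.pi, np.pi, (29, 29)), time_ms=0.0
    )
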