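import numpy as np
import pytest

import trex


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_labelmap(rng, shape=(16, 8), scan_id="s", grading_id="g"):
    return trex.CompartmentLabelMap(
        rng.integers(0, 4, size=shape), scan_id=scan_id, grading_id=grading_id
    )


def random_boundaries(rng, height, width):
    """Random monotone boundary triple within the grid."""
    cuts = np.sort(rng.integers(0, height + 1, size=(3, width)), axis=0)
    return trex.BoundarySet(cuts[0], cuts[1], cuts[2])


def flat_map(ilm, cci, csi, height=512, width=512, scan_id="s", grading_id="g"):
    b = trex.BoundarySet(
        np.full(width, float(ilm)), np.full(width, float(cci)), np.full(width, float(csi))
    )
    return trex.lines_to_labelmap(b, height, width, scan_id, grading_id)


@pytest.fixture
def small_study():
    """A small but fully structured synthetic study (3 graders + model)."""
    cfg = trex.SceneConfig(
        height=96, width=96, mean_rows=(30.0, 48.0, 60.0),
        undulation_amplitude=3.0, undulation_periods=1.5, n_scans=6, seed=7,
    )
    graders = [
        trex.GraderProfile("g1", bias=(0.0, 0.0, 3.0), noise_sd=0.8, correlation_length=16),
        trex.GraderProfile("g2", bias=(0.0, 1.0, 0.0), noise_sd=0.8, correlation_length=16),
        trex.GraderProfile("g3", bias=(0.0, -1.0, -3.0), noise_sd=0.8, correlation_length=16),
    ]
    ensemble, boundaries = trex.simulate_study(cfg, graders, trex.default_model())
    return cfg, graders, ensemble, boundaries
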