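import numpy as np
import pytest

import ulmflow as uf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bifurcation_net():
    """Equal-width 45-degree bifurcation with symmetric flow at 0.02 mL/min."""
    net = uf.build_bifurcation(300, 300, 45, lengths_mm=(0.5, 1.0, 1.0))
    return uf.flow_split(net, uf.FlowConfig(0.02, "symmetric"))


@pytest.fixture(scope="session")
def tiny_run():
    """One fully processed tiny experiment, shared across tests.

    300/300 um, 45 deg, 0.02 mL/min, 300 frames at 64 x 64 px — the smoke
    scale; simulation through saturation analysis.
    """
    cfg = uf.recipe_config("bifurcation-45", seed=3, scale="tiny")
    return uf.run_experiment(cfg)


def gaussian_frame(shape, centers, amps, sigma):
    """Direct Gaussian PSF oracle: sum of sampled Gaussians at (row, col)."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    frame = np.zeros(shape, float)
    for (r, c), a in zip(centers, amps):
        frame += a * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma**2))
    return frame
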