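import numpy as np
import pytest

from nisp.models import (
    EnzymeKineticsModel,
    EnzymeMode,
    PhotophysicsModel,
    SubstrateSpec,
)


@pytest.fixture
def clean_photo():
    """No bleaching, no noise: every drop is enzymatic and exact."""
    return PhotophysicsModel(noise_sd=0.0, k_bleach=0.0)


@pytest.fixture
def default_photo():
    return PhotophysicsModel()


@pytest.fixture
def substrate18():
    return SubstrateSpec(spacing=18)


@pytest.fixture
def fast_enzyme():
    """Prebound processive enzyme with no label-bond delay."""
    return EnzymeKineticsModel(
        mode=EnzymeMode.PROCESSIVE, tau_bond=0.159, tau_label=0.0, prebound=True
    )


def make_step_trace(drop_frames, unit=1000.0, n=1000, dt=0.1, noise=0.0, seed=0):
    """Piecewise-constant two-unit trace with drops at the given frames."""
    y = np.full(n, 2.0 * unit)
    for f in drop_frames:
        y[f:] -= unit
    if noise > 0:
        y = y + np.random.default_rng(seed).normal(0, noise, n)
    from nisp.models import Trace

    return Trace(times=(np.arange(n) + 0.5) * dt, intensities=y)
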