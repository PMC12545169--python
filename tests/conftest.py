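"""Shared fixtures: small image/feature banks and simulated sessions.

Everything is generated programmatically at test time; session-scoped
fixtures cache the expensive banks so the suite stays fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from shrewhier.synthetic import (
    GroundTruthNeuron,
    extract_features,
    make_object_bank,
    make_texture_bank,
)


@pytest.fixture(scope="session")
def small_object_bank():
    """300-image object bank (240 objects + 60 faces) at 48 px."""
    return make_object_bank(240, 60, (48, 48), seed=11)


@pytest.fixture(scope="session")
def small_features(small_object_bank):
    """Layer-3 feature bank (512-D readout, 50 PCs) for the small bank."""
    return extract_features(
        small_object_bank, layers=(3,), n_pcs=50, out_dim=512, seed=12
    )["layer3"]


@pytest.fixture(scope="session")
def texture_bank():
    return make_texture_bank(15, 5, (48, 48), seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_axis_cell(axis, gain=10.0, nonlinearity="rectified", unit_id=0, **kw):
    """Convenience: a ground-truth cell with a given preferred axis."""
    return GroundTruthNeuron(
        unit_id=unit_id,
        area="V2",
        axis_true=np.asarray(axis, dtype=float),
        axis_gain=gain,
        axis_nonlinearity=nonlinearity,
        baseline_rate=3.0,
        **kw,
    )
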