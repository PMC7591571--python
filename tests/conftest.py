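import numpy as np
import pytest

import jhtriage as j


@pytest.fixture
def layout384():
    return j.build_default_layout(384)


@pytest.fixture
def layout96():
    return j.build_default_layout(96)


@pytest.fixture
def sim_config():
    return j.SimulationConfig(seed=101)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_control_plate(pos_values, neg_values, compound_values=(), plate_id="P1"):
    """Minimal plate: controls in columns 11/12 (spilling to 9/10 beyond 8
    wells per role), compounds from column 1."""
    wells = []
    for i, v in enumerate(pos_values):
        wells.append(
            j.WellRecord(
                j.WellAddress(plate_id, "ABCDEFGH"[i % 8], 11 if i < 8 else 9),
                "positive_control", None, 0.0, 0.0, float(v), float(v),
            )
        )
    for i, v in enumerate(neg_values):
        wells.append(
            j.WellRecord(
                j.WellAddress(plate_id, "ABCDEFGH"[i % 8], 12 if i < 8 else 10),
                "negative_control", None, 0.0, 1e-9, float(v), float(v),
            )
        )
    for i, (cid, v) in enumerate(compound_values):
        wells.append(
            j.WellRecord(
                j.WellAddress(plate_id, "ABCDEFGH"[i % 8], 1 + i // 8),
                "compound", cid, 5e-6, 1e-9, float(v), float(v),
            )
        )
    return j.Plate(plate_id=plate_id, format=96, wells=wells)


@pytest.fixture
def control_plate_factory():
    return make_control_plate
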