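import numpy as np
import pytest

from earsim.core import Hypnogram, ScorerPanel
from earsim.synth import ConfusionSpec, SimConfig, generate_recording_pair


@pytest.fixture(scope="session")
def small_pair():
    """One 12-epoch recording pair with a fixed stage sequence (4 epochs per
    stage), shared across tests that only read it."""
    cfg = SimConfig(
        n_epochs=12,
        seed=42,
        stage_sequence=("W",) * 4 + ("NREM",) * 4 + ("REM",) * 4,
    )
    psg, inear, truth = generate_recording_pair(cfg)
    return cfg, psg, inear, truth


@pytest.fixture()
def identity_spec():
    return ConfusionSpec(np.eye(3))


def make_panel(label_rows, source="PSG"):
    """Panel from a list of per-scorer label sequences."""
    return ScorerPanel(
        [
            Hypnogram(np.array(row, dtype=object), source=source, scorer=j)
            for j, row in enumerate(label_rows)
        ]
    )


@pytest.fixture()
def worked_panel():
    """The 4-epoch, 3-scorer panel whose scorer-A soft-agreement is 0.75 by
    hand evaluation."""
    return make_panel(
        [
            ["W", "W", "NREM", "REM"],
            ["W", "NREM", "NREM", "REM"],
            ["W", "NREM", "REM", "REM"],
        ]
    )
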