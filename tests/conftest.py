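import numpy as np
import pytest

from ddicpi import CPIMatrix, DrugRecord, TargetRecord, gen_planted_world


@pytest.fixture
def tiny_cpi() -> CPIMatrix:
    """3 drugs x 2 targets, hand-written scores, one missing cell."""
    scores = np.array([
        [-7.0, -5.0],
        [-8.0, -6.5],
        [-6.0, np.nan],
    ])
    return CPIMatrix(
        [DrugRecord("dA"), DrugRecord("dB"), DrugRecord("dC")],
        [TargetRecord("t1", "PK"), TargetRecord("t2", "PD")],
        scores,
    )


@pytest.fixture(scope="session")
def default_world():
    """Planted world at the default study conditions (2000 pairs, 20 targets,
    oracle AUROC calibrated into [0.85, 0.88])."""
    return gen_planted_world(seed=0)
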