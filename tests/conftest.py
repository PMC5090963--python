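import numpy as np
import pytest

from cpirank import CPIMatrix, IndicationLabels


@pytest.fixture
def toy_cpi() -> CPIMatrix:
    """3 drugs x 2 targets with distinct, hand-checkable scores."""
    return CPIMatrix(
        drug_ids=["D1", "D2", "D3"],
        target_ids=["T1", "T2"],
        scores=np.array([[-7.5, -6.0], [-8.25, -5.5], [-6.0, -9.0]]),
    )


@pytest.fixture
def toy_labels() -> IndicationLabels:
    return IndicationLabels(
        drug_universe=frozenset({"D1", "D2", "D3", "D4", "D5", "D6"}),
        positives=frozenset(
            {
                ("D1", "250.00"),
                ("D2", "250.00"),
                ("D3", "250.00"),
                ("D4", "250.10"),
                ("D5", "250.10"),
                ("D6", "250.10"),
            }
        ),
    )
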