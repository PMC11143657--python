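import numpy as np
import pytest

from aerisk import TrialDataset


@pytest.fixture
def toy4():
    """Four subjects, one arm: AE at 1, CE at 2, censored at 3, AE at 4."""
    return TrialDataset.from_arrays(
        {"experimental": ([1.0, 2.0, 3.0, 4.0], [1, 2, 0, 1])}, trial_id="toy4", ae_id="AE1"
    )


@pytest.fixture
def toy_two_arm():
    """Small two-arm dataset with events of both types in both arms."""
    return TrialDataset.from_arrays(
        {
            "experimental": ([1.0, 2.0, 2.0, 3.5, 5.0, 6.0], [1, 1, 2, 0, 1, 2]),
            "control": ([1.5, 2.5, 3.0, 4.0, 5.5, 7.0], [1, 0, 2, 1, 0, 2]),
        },
        trial_id="toy2arm",
        ae_id="AE1",
    )
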