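import numpy as np
import pandas as pd
import pytest

from decaplex import LfqMatrix, SampleDesign, SampleInfo, default_design


@pytest.fixture
def design_3v3():
    """Triplicate bait + parental + eYFP controls."""
    return default_design()


@pytest.fixture
def toy_matrix():
    """Small hand-written log2 matrix with known missingness."""
    values = pd.DataFrame(
        {
            "bait1_1": [10.0, 12.0, np.nan, 8.0, np.nan],
            "bait1_2": [10.5, 11.5, np.nan, 8.2, 9.0],
            "bait1_3": [9.5, 12.5, 7.0, np.nan, np.nan],
            "wt_1": [10.1, 8.0, 7.2, 8.1, np.nan],
            "wt_2": [9.9, 8.5, np.nan, 8.0, np.nan],
            "wt_3": [10.0, 7.5, 7.1, np.nan, 9.1],
        },
        index=pd.Index([f"P{i}" for i in range(5)], name="protein_id"),
    )
    return LfqMatrix(values=values, log_transformed=True)


def make_design(samples):
    """Design from {name: (experiment, group, replicate)} tuples."""
    return SampleDesign({n: SampleInfo(*info) for n, info in samples.items()})
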