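import numpy as np
import pytest

from offsetdge import CountMatrix, StudyDesign
import pandas as pd

#: single fixed seed for every stochastic test in the suite
SEED = 20260923


@pytest.fixture
def tiny_counts() -> CountMatrix:
    return CountMatrix(
        gene_ids=["G1", "G2"],
        sample_ids=["S1", "S2"],
        counts=np.array([[1, 2], [3, 4]]),
    )


@pytest.fixture
def four_sample_design() -> StudyDesign:
    rows = []
    for pid in ("P01", "P02"):
        for leg, sets in (("left", "single"), ("right", "multiple")):
            for time in ("w0", "w2pre"):
                rows.append(
                    {
                        "sample_id": f"{pid}_{leg}_{time}",
                        "participant_id": pid,
                        "leg": leg,
                        "sets": sets,
                        "time": time,
                        "tissue_mg": 2.5,
                        "library_size": 1e6,
                    }
                )
    return StudyDesign(pd.DataFrame(rows))
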