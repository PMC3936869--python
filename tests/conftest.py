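import numpy as np
import pandas as pd
import pytest

from txdynamics.datamodel import CountMatrix, StudyDesign


@pytest.fixture
def four_stage_design() -> StudyDesign:
    return StudyDesign(
        stages={
            10.0: ["d10_r1", "d10_r2"],
            20.0: ["d20_r1", "d20_r2"],
            40.0: ["d40_r1", "d40_r2"],
            60.0: ["d60_r1", "d60_r2"],
        }
    )


@pytest.fixture
def small_counts(four_stage_design) -> CountMatrix:
    rng = np.random.default_rng(42)
    libs = [l for libs in four_stage_design.stages.values() for l in libs]
    counts = pd.DataFrame(
        rng.poisson(50, size=(30, 8)),
        index=[f"g{i}" for i in range(30)],
        columns=libs,
    )
    return CountMatrix(counts=counts)
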