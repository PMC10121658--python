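import numpy as np
import pandas as pd
import pytest

from mfscreen.io import CountTable, ExpressionMatrix, SampleMeta, STAGES


def make_expression(rows: dict[str, dict[str, list[float]]],
                    n_replicates: int = 3) -> ExpressionMatrix:
    """Build a matrix from {ref_id: {stage: [replicate values]}}.

    Stages absent from a row default to zeros.
    """
    samples = [
        SampleMeta(f"{stage}_r{rep}", stage, rep)
        for stage in STAGES
        for rep in range(1, n_replicates + 1)
    ]
    data = {}
    for ref, stage_vals in rows.items():
        vals = []
        for stage in STAGES:
            vals.extend(stage_vals.get(stage, [0.0] * n_replicates))
        data[ref] = vals
    df = pd.DataFrame(data, index=[s.sample_id for s in samples]).T
    df.columns = [s.sample_id for s in samples]
    return ExpressionMatrix(df.astype(float), samples)


@pytest.fixture
def small_counts() -> CountTable:
    df = pd.DataFrame(
        {"male_count": [100, 50, 5], "female_count": [0, 60, 4]},
        index=pd.Index(["t1", "t2", "t3"], name="id"),
    )
    return CountTable(df, male_total=10**6, female_total=10**6)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
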