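import numpy as np
import pandas as pd
import pytest

from prognoset import ExpressionMatrix, generate_meta_set, presets
from prognoset.cohorts import KmRecord


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples over two cohorts."""
    values = pd.DataFrame(
        np.array(
            [
                [8.0, 8.5, 7.9, 8.2],
                [6.1, 6.4, 6.0, 6.2],
                [9.3, 9.1, 9.4, 9.0],
            ]
        ),
        index=["GA", "GB", "GC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    cohorts = {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}
    return ExpressionMatrix(values=values, cohort_of_sample=cohorts)


@pytest.fixture(scope="session")
def strong_meta():
    """One labeled desk-scale meta-set with the planted two-gene signature."""
    sm = generate_meta_set(presets()["strong"].replace(seed=11))
    meta, removed = sm.build_meta_set()
    return meta


@pytest.fixture(scope="session")
def null_meta():
    sm = generate_meta_set(presets()["null"].replace(seed=11))
    meta, _ = sm.build_meta_set()
    return meta


def km(records: list[tuple[bool, float]], prefix: str = "s") -> list[KmRecord]:
    """Shorthand for building KM record lists in tests."""
    return [KmRecord(f"{prefix}{i}", e, t) for i, (e, t) in enumerate(records)]
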