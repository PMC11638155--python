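import numpy as np
import pandas as pd
import pytest

from cognigraph import (build_feature_matrix, build_graph, default_config,
                        generate_cohort, stratified_split)
from cognigraph.cohort import CohortTable
from cognigraph.pipeline import LABEL_TO_INT


@pytest.fixture(scope="session")
def cohort():
    """The default study-like synthetic cohort (seed 0)."""
    return generate_cohort(default_config(seed=0))


@pytest.fixture(scope="session")
def features(cohort):
    return build_feature_matrix(cohort)


@pytest.fixture(scope="session")
def graph(features):
    return build_graph(features.values)


@pytest.fixture(scope="session")
def labels(cohort):
    return cohort.records["diagnosis"].map(LABEL_TO_INT).to_numpy()


@pytest.fixture(scope="session")
def masks(cohort, features):
    split = stratified_split(cohort, seed=1)
    return {p: split.mask(features.row_ids, p) for p in ("train", "val", "test")}


def make_table(rows: list[dict]) -> CohortTable:
    """Small hand-specified cohorts for oracle tests."""
    defaults = dict(age=75.0, education=9.0, sex="F", mmse=25, moca=22,
                    fab=13, hdrs=5, comorbidity=0, treatment=0,
                    rehabilitation=0, diagnosis="MCI")
    records = []
    for k, row in enumerate(rows):
        rec = {**defaults, **row}
        rec.setdefault("id", f"T{k:03d}")
        records.append(rec)
    from cognigraph.cohort import COHORT_COLUMNS
    return CohortTable(records=pd.DataFrame(records)[COHORT_COLUMNS])
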