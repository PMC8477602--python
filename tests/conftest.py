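import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pstfst.studydb import StudyRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_record(**overrides) -> StudyRecord:
    """A valid StudyRecord with sensible defaults, field-overridable."""
    base = dict(
        paper_id="p1",
        species="sp1",
        phenotype_id="t1",
        pop_a="A",
        pop_b="B",
        pst=0.4,
        fst_neutral=0.05,
        fst_nonneutral=0.2,
        n_loci_nonneutral=10,
        n_loci_total=100,
        mean_n_individuals=30.0,
        method="outlier",
        marker="snp",
        analysis_group="non_bayesian",
        common_garden=False,
    )
    base.update(overrides)
    return StudyRecord(**base)


@pytest.fixture
def six_row_table() -> pd.DataFrame:
    """Small fixed modeling table for exact-arithmetic model checks."""
    return pd.DataFrame(
        {
            "logit_pst": [-0.2, 0.3, -1.1, 0.8, -0.5, 1.4],
            "logit_fst_nonneutral": [-2.0, -1.0, -3.0, -0.5, -2.5, 0.0],
            "logit_fst_neutral": [-3.0, -2.2, -3.8, -1.9, -3.1, -1.2],
            "logit_prop_nonneutral": [-2.0, -2.5, -1.5, -3.0, -1.0, -2.2],
            "marker": ["snp", "snp", "aflp", "aflp", "msat", "msat"],
        }
    )


@pytest.fixture(scope="session")
def default_db_rows():
    """Modeling table from the default synthetic database (seed 0), shared
    across tests to avoid refitting-time waste."""
    from pstfst import (
        DatabaseGenConfig,
        average_per_comparison,
        simulate_study_database,
        to_model_rows,
    )

    records = simulate_study_database(DatabaseGenConfig(seed=0))
    return to_model_rows(average_per_comparison(records))
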