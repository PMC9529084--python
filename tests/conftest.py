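import numpy as np
import pandas as pd
import pytest

from matriscore import DriverEffect, SimConfig, simulate_cohort
from matriscore.data_io import ExpressionMatrix


DRIVER = "G0001"
DRIVER_CANCERS = ("C01", "C02", "C03")


def driver_config(seed: int) -> SimConfig:
    """Study conditions for driver recovery: one pan-cancer driver amplified at
    0.3 with a +1.5 log2 expression shift and log-HR 0.7 in 3 of 5 cancers."""
    return SimConfig(
        drivers={
            DRIVER: DriverEffect(
                amp_prob=0.3,
                expression_shift=1.5,
                cna_coupling=0.2,
                log_hazard_ratio=0.7,
                cancers=DRIVER_CANCERS,
            )
        },
        seed=seed,
    )


@pytest.fixture(scope="session")
def driver_cohort():
    return simulate_cohort(driver_config(seed=11))


@pytest.fixture(scope="session")
def null_cohort():
    """All effects zero: one cancer, 200 genes, 60 tumour / 30 normal samples."""
    return simulate_cohort(SimConfig(n_cancers=1, n_tumour=60, n_normal=30, n_genes=200, seed=5))


def make_expression(values: pd.DataFrame, cancer: str = "C01", tumour_cols=None) -> ExpressionMatrix:
    """Wrap a gene x sample grid as an ExpressionMatrix with simple annotations."""
    tumour_cols = set(values.columns if tumour_cols is None else tumour_cols)
    ann = pd.DataFrame(
        {
            "cancer_type": cancer,
            "is_tumour": [c in tumour_cols for c in values.columns],
        },
        index=pd.Index(values.columns, name="sample"),
    )
    return ExpressionMatrix(values, ann)
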