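"""Shared fixtures: small synthetic cohorts and a pre-trained model.

Session scope keeps the expensive pieces (simulation, SVM fits) to one run.
"""

import warnings

import numpy as np
import pandas as pd
import pytest

from bdc import (
    ExpressionMatrix,
    SimConfig,
    SVMHyperparams,
    simulate_cohort,
    train_classifier,
)

# sklearn deprecation chatter from SVC(probability=True); the libSVM Platt
# path is exactly what we want while it exists.
warnings.filterwarnings("ignore", category=FutureWarning, module="sklearn")


SMALL_CONFIG = SimConfig(
    n_genes=300,
    n_signature=15,
    n_bl=40,
    n_dlbcl=40,
    n_intermediate=10,
    effect_size=2.0,
    seed=7,
)

# sane fixed hyperparameters for unit tests that don't exercise the grid
FIXED_HP = SVMHyperparams(c=1.0, gamma=1.0 / 15)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SMALL_CONFIG)


@pytest.fixture(scope="session")
def trained_model(small_cohort):
    """Z-score model grid-trained on platform A of the small cohort."""
    return train_classifier(
        small_cohort.platform_a,
        small_cohort.annotations,
        small_cohort.signature_genes,
        normalization="zscore",
        threshold=0.95,
        seed=7,
    )


@pytest.fixture()
def tiny_matrix():
    """3 genes x 4 samples with hand-set values."""
    data = pd.DataFrame(
        np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [10.0, 20.0, 30.0, 40.0],
                [5.0, 5.0, 7.0, 9.0],
            ]
        ),
        index=pd.Index(["G1", "G2", "G3"], name="gene_id"),
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(data=data, dataset_tag="tiny")
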