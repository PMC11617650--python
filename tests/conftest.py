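"""Shared fixtures: a small synthetic study and marker set, plus a stub bank."""

import numpy as np
import pandas as pd
import pytest

from enviromics.eem import EemSet, cluster_and_aggregate, fit_tree_bank
from enviromics.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic study (fast; shared read-only across tests)."""
    cfg = SimConfig(
        n_trials=25, n_hybrids=40, n_parents=14, area_deg=1.5,
        n_noise=10, n_collinear_per_causal=2,
    )
    return simulate_dataset(cfg, seed=7)


@pytest.fixture(scope="session")
def small_eset(small_bundle):
    bank = fit_tree_bank(
        small_bundle.trial_covariates, small_bundle.phenotypes, n_trees=300, seed=7
    )
    return cluster_and_aggregate(bank, 7, small_bundle.covariates)


@pytest.fixture
def trial_markers(small_bundle, small_eset):
    tc = small_bundle.trial_covariates
    return small_eset.values_at(tc).set_axis(pd.Index(tc["location_id"], name="trial_id"))


class StubBank:
    """Minimal tree-bank stand-in with a designed prediction matrix.

    ``matrix`` has one column per "tree" over the reference locations;
    predictions at other location sets are produced by a supplied function
    or by index lookup into the reference table.
    """

    def __init__(self, matrix: pd.DataFrame, importances=None, covariate_names=None):
        self.matrix = matrix
        self.covariate_names = covariate_names or ["sat_cv000"]
        n_cov = len(self.covariate_names)
        self.importances = (
            importances if importances is not None
            else np.ones((matrix.shape[1], n_cov))
        )
        self.feature_subsets = [np.arange(n_cov)] * matrix.shape[1]
        self.genotype_subsamples = [[] for _ in range(matrix.shape[1])]

    @property
    def n_trees(self):
        return self.matrix.shape[1]

    def predict(self, covariates):
        return self.matrix.loc[covariates["location_id"]].to_numpy(dtype=float)


@pytest.fixture
def stub_bank_factory():
    return StubBank
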