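"""Marker engineering: environment means, tree banks, clustering, EWAS."""

import numpy as np
import pandas as pd
import pytest

from enviromics.eem import (
    MarkerError,
    cluster_and_aggregate,
    environment_means,
    ewas_tally,
    fit_tree_bank,
    validate_eems,
)


class TestEnvironmentMeans:
    def test_full_fraction_is_plain_trial_mean(self, small_bundle):
        phen = small_bundle.phenotypes
        m, sample = environment_means(phen, subsample_fraction=1.0, seed=0)
        expected = phen.groupby("trial_id")["yield_blue"].mean()
        pd.testing.assert_series_equal(
            m.sort_index(), expected.sort_index(), check_names=False
        )
        assert len(sample) == phen["genotype_id"].nunique()

    def test_spread_shrinks_with_fraction(self, small_bundle):
        phen = small_bundle.phenotypes
        trial = phen["trial_id"].iloc[0]

        def spread(frac):
            vals = [
                environment_means(phen, frac, seed=s)[0][trial] for s in range(200)
            ]
            return np.std(vals)

        assert spread(0.9) < spread(0.3)

    def test_small_trials_excluded_with_warning(self):
        phen = pd.DataFrame(
            {
                "trial_id": ["T1", "T1", "T2"],
                "genotype_id": ["G1", "G2", "G1"],
                "year": 2020,
                "irrigated": False,
                "region": "N",
                "lat": 0.0,
                "lon": 0.0,
                "yield_blue": [1.0, 3.0, 9.0],
            }
        )
        with pytest.warns(UserWarning, match="excluding"):
            m, _ = environment_means(phen, subsample_fraction=1.0, seed=0)
        assert list(m.index) == ["T1"]
        assert m["T1"] == 2.0


class TestTreeBank:
    def test_constant_covariate_gives_constant_predictions(self, small_bundle):
        tc = small_bundle.trial_covariates[["location_id", "lat", "lon"]].copy()
        tc["sat_const"] = 1.0
        bank = fit_tree_bank(tc, small_bundle.phenotypes, n_trees=5,
                             subsample_fraction=1.0, seed=0)
        P = bank.predict(tc)
        grand = small_bundle.phenotypes.groupby("trial_id")["yield_blue"].mean().mean()
        assert np.ptp(P, axis=0).max() < 1e-12           # flat over locations
        assert P[0, 0] == pytest.approx(grand, abs=1e-9)

    def test_single_tree_bank_prediction(self, small_bundle):
        bank = fit_tree_bank(small_bundle.trial_covariates, small_bundle.phenotypes,
                             n_trees=1, seed=4)
        P = bank.predict(small_bundle.covariates)
        W = small_bundle.covariates[bank.covariate_names].to_numpy()
        direct = bank.trees[0].predict(W[:, bank.feature_subsets[0]])
        assert np.array_equal(P[:, 0], direct)

    def test_too_few_trials_rejected(self, small_bundle):
        tc = small_bundle.trial_covariates.iloc[:3]
        with pytest.raises(MarkerError, match="at least 5"):
            fit_tree_bank(tc, small_bundle.phenotypes, n_trees=2, seed=0)


class TestClusterAndAggregate:
    def _ref(self, n_loc=40, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "location_id": [f"L{i}" for i in range(n_loc)],
                "lat": rng.normal(size=n_loc),
                "lon": rng.normal(size=n_loc),
            }
        )

    def test_identical_trees_collapse_to_wide_gradient(self, stub_bank_factory):
        ref = self._ref()
        base = np.sin(np.linspace(0, 6, len(ref)))
        mat = pd.DataFrame(
            np.tile(base[:, None], (1, 8)), index=ref["location_id"]
        )
        bank = stub_bank_factory(mat)
        with pytest.warns(UserWarning, match="distinct tree families"):
            eset = cluster_and_aggregate(bank, 3, ref)
        assert eset.n_markers == 1
        assert np.allclose(eset.eem_values.iloc[:, 0], eset.wide_gradient)

    def test_anticorrelated_families_recovered(self, stub_bank_factory):
        ref = self._ref()
        rng = np.random.default_rng(1)
        f = rng.normal(size=len(ref))
        cols = [f + 0.01 * rng.normal(size=len(f)) for _ in range(5)]
        cols += [-f + 0.01 * rng.normal(size=len(f)) for _ in range(5)]
        mat = pd.DataFrame(np.column_stack(cols), index=ref["location_id"])
        eset = cluster_and_aggregate(stub_bank_factory(mat), 2, ref)
        labels = eset.cluster_of_tree
        assert len(set(labels[:5])) == 1
        assert len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_markers_standardized_on_reference(self, small_eset):
        vals = small_eset.eem_values
        assert vals.mean().abs().max() < 1e-9
        assert (vals.std(ddof=0) - 1.0).abs().max() < 1e-9

    def test_cluster_size_weighted_mean_reproduces_wide_gradient(self, small_eset):
        # un-restandardized markers, weighted by cluster size, equal the raw
        # mean of all standardized tree predictions
        sizes = np.array(
            [(small_eset.cluster_of_tree == k + 1).sum() for k in range(small_eset.n_markers)]
        )
        raw = small_eset.eem_values.to_numpy() * small_eset.eem_sd + small_eset.eem_mean
        recon = raw @ (sizes / sizes.sum())
        wide_raw = (
            small_eset.wide_gradient.to_numpy() * small_eset.wide_sd + small_eset.wide_mean
        )
        assert np.abs(recon - wide_raw).max() < 1e-9

    def test_k_larger_than_bank_rejected(self, stub_bank_factory):
        ref = self._ref()
        mat = pd.DataFrame(np.ones((len(ref), 2)), index=ref["location_id"])
        with pytest.raises(MarkerError):
            cluster_and_aggregate(stub_bank_factory(mat), 5, ref)

    def test_values_at_permuted_locations_permute_rows(self, small_bundle, small_eset):
        cov = small_bundle.covariates
        perm = cov.sample(frac=1.0, random_state=0)
        a = small_eset.values_at(cov)
        b = small_eset.values_at(perm)
        pd.testing.assert_frame_equal(a.loc[b.index], b)

    def test_ensemble_stable_under_tenfold_tree_reduction(self, small_bundle):
        big = fit_tree_bank(small_bundle.trial_covariates, small_bundle.phenotypes,
                            n_trees=2000, seed=5)
        sml = fit_tree_bank(small_bundle.trial_covariates, small_bundle.phenotypes,
                            n_trees=200, seed=6)
        e_big = cluster_and_aggregate(big, 7, small_bundle.covariates)
        e_sml = cluster_and_aggregate(sml, 7, small_bundle.covariates)
        r = np.corrcoef(e_big.wide_gradient, e_sml.wide_gradient)[0, 1]
        assert r > 0.95


class TestEwas:
    def test_single_covariate_always_rank_one(self, stub_bank_factory):
        mat = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 6)),
                           index=[f"L{i}" for i in range(10)])
        bank = stub_bank_factory(mat, covariate_names=["sat_only"])
        tally, shares = ewas_tally(bank)
        assert tally.loc["sat_only", "rank1"] == bank.n_trees
        assert shares.sum() == pytest.approx(100.0, abs=1e-9)

    def test_shares_sum_to_100(self, small_eset):
        assert small_eset.source_shares.sum() == pytest.approx(100.0, abs=1e-9)

    def test_importance_tracks_association_with_true_gradient(self, small_bundle, small_eset):
        # a smooth random field can rival the causal covariates by chance on
        # a small area, so the robust claim is rank agreement: covariates
        # more associated with the true environmental gradients must receive
        # more importance, and the causal family as a whole must collect the
        # majority of rank-1 finishes
        from scipy.stats import spearmanr

        tally = small_eset.importance_tally
        cov = small_bundle.covariates
        tc = small_bundle.trial_covariates
        m = (
            small_bundle.phenotypes.groupby("trial_id")["yield_blue"].mean()
            .reindex(tc["location_id"]).to_numpy()
        )
        assoc = [abs(np.corrcoef(tc[c], m)[0, 1]) for c in tally.index]
        rho = spearmanr(assoc, tally["mean_importance"])[0]
        assert rho > 0.4

        causal_family = set(small_bundle.truth.causal_covariates)
        n_copies = small_bundle.config.n_collinear_per_causal
        names = [c for c in cov.columns if c not in ("location_id", "lat", "lon")]
        for c in list(causal_family):
            k = names.index(c)
            causal_family.update(names[k + 1:k + 1 + n_copies])
        in_family = tally.index.isin(causal_family)
        assert tally.loc[in_family, "rank1"].sum() > tally.loc[~in_family, "rank1"].sum()


class TestValidateEems:
    def test_perfect_construction_gives_unit_fit_correlation(self, small_bundle, stub_bank_factory):
        tc = small_bundle.trial_covariates
        m, _ = environment_means(small_bundle.phenotypes, 1.0, seed=0)
        mat = pd.DataFrame({0: m.reindex(tc["location_id"]).to_numpy()},
                           index=tc["location_id"])
        bank = stub_bank_factory(mat)
        out = validate_eems(tc, small_bundle.phenotypes, bank=bank, seed=0, loo_n_trees=20)
        assert out["fit_correlation"] == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_means_reported_missing(self, small_bundle):
        phen = small_bundle.phenotypes.copy()
        phen["yield_blue"] = 2.5
        out = validate_eems(small_bundle.trial_covariates, phen, loo_n_trees=5, seed=0)
        assert np.isnan(out["fit_correlation"])
        assert np.isnan(out["loo_correlation"])
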