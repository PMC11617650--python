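"""Statistical ties, geographic representativeness, occupation, parents."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from enviromics.grid import build_prediction_grid
from enviromics.recommend import (
    RecommendationError,
    occupation_summary,
    parental_recommendation,
    recommend_genotypes,
    representativeness_select,
    statistical_ties,
)


def _series(d):
    return pd.Series(d, dtype=float)


class TestStatisticalTies:
    def test_zero_se_distinct_means_only_best(self):
        tied = statistical_ties(_series({"a": 1.0, "b": 0.5}), _series({"a": 0.0, "b": 0.0}),
                                alpha=0.05, df=100)
        assert tied == ["a"]

    def test_equal_means_all_tied(self):
        tied = statistical_ties(_series({"a": 1.0, "b": 1.0, "c": 1.0}),
                                _series({"a": 0.1, "b": 0.1, "c": 0.1}), alpha=0.05, df=50)
        assert sorted(tied) == ["a", "b", "c"]

    def test_boundary_difference_excluded_at_large_df(self):
        # mu_best - mu_g = z_{0.975} * sqrt(2) * SE sits exactly at the normal
        # 5% boundary; with slightly larger t quantiles at finite df the gap
        # just beyond it must exclude, just below must tie
        se = 0.2
        z = norm.ppf(0.975)
        gap = z * np.sqrt(2.0) * se
        means = _series({"best": 1.0, "g": 1.0 - gap * 1.05})
        ses = _series({"best": se, "g": se})
        assert statistical_ties(means, ses, alpha=0.05, df=10_000) == ["best"]
        means_close = _series({"best": 1.0, "g": 1.0 - gap * 0.95})
        assert "g" in statistical_ties(means_close, ses, alpha=0.05, df=10_000)

    def test_df_required(self):
        with pytest.raises(RecommendationError):
            statistical_ties(_series({"a": 1.0}), _series({"a": 0.1}), df=0)


class TestRepresentativeness:
    def test_nearer_genotype_wins(self):
        means = _series({"near": 0.5, "far": 0.9})
        bin_row = np.array([1.0, 100.0])
        geno_trials = {"near": np.array([0]), "far": np.array([1])}
        winner, d = representativeness_select(["near", "far"], means, bin_row, geno_trials)
        assert winner == "near" and d == 1.0

    def test_distance_tie_breaks_by_mean_then_id(self):
        bin_row = np.array([5.0])
        geno_trials = {"a": np.array([0]), "b": np.array([0])}
        means = _series({"a": 0.1, "b": 0.9})
        assert representativeness_select(["a", "b"], means, bin_row, geno_trials)[0] == "b"
        means_eq = _series({"a": 0.5, "b": 0.5})
        assert representativeness_select(["a", "b"], means_eq, bin_row, geno_trials)[0] == "a"

    def test_untrialed_genotype_cannot_beat_trialed(self):
        means = _series({"ghost": 2.0, "real": 0.1})
        winner, _ = representativeness_select(
            ["ghost", "real"], means, np.array([50.0]), {"real": np.array([0])}
        )
        assert winner == "real"

    def test_knearest_mode_averages(self):
        means = _series({"a": 0.0})
        bin_row = np.array([1.0, 3.0, 50.0])
        geno_trials = {"a": np.array([0, 1, 2])}
        _, d = representativeness_select(["a"], means, bin_row, geno_trials,
                                         mode="knearest", k_nearest=2)
        assert d == pytest.approx(2.0)


@pytest.fixture(scope="module")
def setup():
    pts = [(0.0, 0.0), (0.0, 0.4), (0.4, 0.0), (0.4, 0.4)]
    grid = build_prediction_grid(pts, cell_size_km=15.0, buffer_km=0.0)
    phen = pd.DataFrame(
        {
            "trial_id": ["T1", "T1", "T2", "T2"],
            "genotype_id": ["G1", "G2", "G1", "G2"],
            "year": 2020,
            "irrigated": False,
            "region": "N",
            "lat": [0.0, 0.0, 0.4, 0.4],
            "lon": [0.0, 0.0, 0.4, 0.4],
            "yield_blue": [1.0, 0.5, 1.2, 0.8],
        }
    )
    return grid, phen


class TestRecommendationMap:

    def test_alpha_widens_ties_and_never_raises_winner_mean(self, setup):
        grid, phen = setup
        rng = np.random.default_rng(0)
        mean = pd.DataFrame(
            rng.normal(size=(2, grid.n_bins)),
            index=pd.Index(["G1", "G2"], name="genotype_id"), columns=grid.bin_ids,
        )
        se = mean * 0.0 + 0.5
        prev_means = None
        for alpha in (0.5, 0.05, 1e-6):
            winners = recommend_genotypes(mean, se, phen, grid, n_runs=30, alpha=alpha)
            wmean = np.array([mean.at[w, b] for b, w in winners["winner"].items()])
            if prev_means is not None:
                # smaller alpha -> fewer ties -> winner mean can only rise
                assert (wmean >= prev_means - 1e-12).all()
            prev_means = wmean
        # with essentially no ties the best-mean genotype wins everywhere
        best = mean.idxmax(axis=0)
        assert (winners["winner"].to_numpy() == best.to_numpy()).all()

    def test_winner_in_tied_set_and_distance_finite(self, setup):
        grid, phen = setup
        mean = pd.DataFrame(
            np.ones((2, grid.n_bins)),
            index=pd.Index(["G1", "G2"], name="genotype_id"), columns=grid.bin_ids,
        )
        winners = recommend_genotypes(mean, mean * 0.1, phen, grid, n_runs=20)
        assert winners["n_tied"].eq(2).all()
        assert np.isfinite(winners["distance_km"]).all()


class TestOccupation:
    def test_single_genotype_occupies_everything(self):
        winners = pd.DataFrame(
            {"winner": ["G1"] * 7, "n_tied": 1, "distance_km": 1.0},
            index=pd.Index([f"b{i}" for i in range(7)], name="bin_id"),
        )
        phen = pd.DataFrame(
            {
                "trial_id": ["T1"], "genotype_id": ["G1"], "year": [2020],
                "irrigated": [False], "region": ["N"], "lat": [0.0], "lon": [0.0],
                "yield_blue": [1.0],
            }
        )
        occ = occupation_summary(winners, phen, pd.Series({"T1": "b0"}))
        assert occ.loc["G1", "occupation_pct"] == 100.0
        assert occ.loc["G1", "trial_bins_measured"] == 1
        assert occ["bins_won"].sum() == 7

    def test_sign_split_matches_occupation_fractions(self, small_bundle, small_eset):
        # two synthetic genotypes splitting the grid by the sign of marker 1
        eps = small_eset.eem_values["eem_1"]
        mean = pd.DataFrame(
            [np.where(eps > 0, 1.0, 0.0), np.where(eps > 0, 0.0, 1.0)],
            index=pd.Index(
                list(small_bundle.phenotypes["genotype_id"].unique()[:2]),
                name="genotype_id",
            ),
            columns=eps.index,
        )
        se = mean * 0.0
        winners = recommend_genotypes(
            mean, se, small_bundle.phenotypes, small_bundle.grid, n_runs=10, alpha=0.05
        )
        occ = occupation_summary(winners, small_bundle.phenotypes, small_bundle.trial_bins)
        g1 = mean.index[0]
        assert occ.loc[g1, "bins_won"] == int((eps > 0).sum())


class TestParents:
    def test_high_yield_hybrids_lift_their_parent(self, small_bundle, trial_markers):
        # boost every hybrid descended from one focal parent and refit
        from enviromics.reem import fit_reem, predict_bins

        ped = small_bundle.pedigree
        focal = ped.loc[ped["dam_id"] != "UNKNOWN", "dam_id"].value_counts().index[0]
        children = ped.loc[
            (ped["dam_id"] == focal) | (ped["sire_id"] == focal), "genotype_id"
        ]
        phen = small_bundle.phenotypes.copy()
        phen.loc[phen["genotype_id"].isin(children), "yield_blue"] += 3.0
        fit = fit_reem(phen, trial_markers, small_bundle.kinship)
        U = pd.DataFrame(fit.U, index=fit.genotype_ids)
        others = [p for p in ped.loc[ped["genotype_id"].str.startswith("P"), "genotype_id"]
                  if p != focal]
        assert U.loc[focal, 0] > U.loc[others, 0].max()

    def test_isolated_parent_has_null_surface(self, small_bundle, trial_markers):
        from enviromics.reem import fit_reem

        ped = pd.concat(
            [small_bundle.pedigree,
             pd.DataFrame({"genotype_id": ["P999"], "dam_id": ["UNKNOWN"], "sire_id": ["UNKNOWN"]})],
            ignore_index=True,
        )
        from enviromics.kinship import additive_relationship, psd_repair

        kin = psd_repair(additive_relationship(ped))
        fit = fit_reem(small_bundle.phenotypes, trial_markers, kin)
        U = pd.DataFrame(fit.U, index=fit.genotype_ids)
        assert np.abs(U.loc["P999"]).max() < 1e-10

    def test_top1_top2_distinct_and_cross_is_midparent(self, small_bundle):
        rng = np.random.default_rng(1)
        parents = [f"P{i:03d}" for i in range(1, 15)]
        pred = pd.DataFrame(
            rng.normal(size=(14, 6)), index=pd.Index(parents, name="genotype_id"),
            columns=pd.Index([f"b{i}" for i in range(6)], name="bin_id"),
        )
        out = parental_recommendation(pred, small_bundle.pedigree)
        assert (out["top1"] != out["top2"]).all()
        for b, row in out.iterrows():
            assert row["midparent_value"] == pytest.approx(
                0.5 * (pred.at[row["top1"], b] + pred.at[row["top2"], b])
            )

    def test_no_parents_rejected(self):
        pred = pd.DataFrame([[1.0]], index=pd.Index(["G1"], name="genotype_id"),
                            columns=pd.Index(["b0"], name="bin_id"))
        ped = pd.DataFrame({"genotype_id": ["G1"], "dam_id": ["UNKNOWN"], "sire_id": ["UNKNOWN"]})
        with pytest.raises(RecommendationError):
            parental_recommendation(pred, ped)
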