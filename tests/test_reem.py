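"""Reaction-norm model: design assembly, ensemble, stability, comparators."""

import numpy as np
import pandas as pd
import pytest

from enviromics.eem import cluster_and_aggregate
from enviromics.io import LinkageError
from enviromics.kinship import KinshipMatrix, additive_relationship, psd_repair
from enviromics.lmm import conditional_mean_oracle
from enviromics.reem import (
    assemble_design,
    baseline_gxe_fit,
    ensemble_reem,
    fit_reem,
    kernel_gxe_fit,
    predict_bins,
    solve_reem_fixed,
    stability_angles,
)


def _toy_phenotypes():
    return pd.DataFrame(
        {
            "trial_id": ["T1", "T1", "T2", "T2"],
            "genotype_id": ["G1", "G2", "G1", "G2"],
            "year": [2020, 2020, 2021, 2021],
            "irrigated": [False, False, True, True],
            "region": ["N", "N", "S", "S"],
            "lat": [0.0, 0.0, 0.1, 0.1],
            "lon": [0.0, 0.0, 0.1, 0.1],
            "yield_blue": [1.0, 2.0, 3.0, 4.0],
        }
    )


def _toy_kin():
    return KinshipMatrix(ids=["G1", "G2"], values=np.eye(2))


class TestAssembleDesign:
    def test_hand_assembled_blocks(self):
        markers = pd.DataFrame({"eem_1": [0.5, -0.5]},
                               index=pd.Index(["T1", "T2"], name="trial_id"))
        d = assemble_design(_toy_phenotypes(), markers, _toy_kin())
        assert d.X.shape == (4, 2)                       # one column per year
        assert np.array_equal(d.M[:, 0], np.ones(4))     # leading intercept
        assert np.array_equal(d.M[:, 1], [0.5, 0.5, -0.5, -0.5])
        assert d.M.shape[1] * 2 == 4                     # (K+1) x genotypes columns

    def test_k_zero_reduces_to_classic_blup_design(self):
        markers = pd.DataFrame(index=pd.Index(["T1", "T2"], name="trial_id"))
        d = assemble_design(_toy_phenotypes(), markers, _toy_kin())
        assert d.M.shape == (4, 1)
        assert np.array_equal(d.M[:, 0], np.ones(4))

    def test_missing_trial_raises_linkage_error(self):
        markers = pd.DataFrame({"eem_1": [0.5]},
                               index=pd.Index(["T1"], name="trial_id"))
        with pytest.raises(LinkageError, match="T2"):
            assemble_design(_toy_phenotypes(), markers, _toy_kin())

    def test_unknown_genotype_raises(self):
        markers = pd.DataFrame({"eem_1": [0.5, -0.5]},
                               index=pd.Index(["T1", "T2"], name="trial_id"))
        kin = KinshipMatrix(ids=["G1"], values=np.eye(1))
        with pytest.raises(LinkageError):
            assemble_design(_toy_phenotypes(), markers, kin)


class TestFixedSolveOracle:
    def test_blup_equals_dense_conditional_mean(self):
        # tiny instance, variance components held fixed
        rng = np.random.default_rng(8)
        phen = _toy_phenotypes()
        extra = phen.copy()
        extra["trial_id"] = extra["trial_id"].map({"T1": "T3", "T2": "T4"})
        extra["yield_blue"] = rng.normal(size=4)
        phen = pd.concat([phen, extra], ignore_index=True)
        markers = pd.DataFrame({"eem_1": [0.5, -0.5, 1.2, -0.9]},
                               index=pd.Index(["T1", "T2", "T3", "T4"], name="trial_id"))
        kin = _toy_kin()
        Sigma = np.array([[1.0, 0.2], [0.2, 0.6]])
        se2 = 0.3
        b, U = solve_reem_fixed(phen, markers, kin, Sigma, se2)
        d = assemble_design(phen, markers, kin)
        n, r, G = len(phen), 2, 2
        Z = np.zeros((n, r * G))
        Z[np.arange(n)[:, None], np.arange(r)[None, :] * G + d.geno_idx[:, None]] = d.M
        b2, u2 = conditional_mean_oracle(d.y, d.X, Z, np.kron(Sigma, kin.values), se2)
        assert np.abs(b - b2).max() < 1e-6
        assert np.abs(U.T.ravel() - u2).max() < 1e-6


class TestPredictBins:
    def _fit(self, U, years=("year_2020",)):
        from enviromics.lmm import ReemFit

        return ReemFit(
            b=np.zeros(len(years)), fixed_names=list(years),
            Sigma=np.eye(U.shape[1]), sigma_e2=0.1, U=U,
            genotype_ids=[f"G{i}" for i in range(U.shape[0])],
            loglik_reml=0.0, converged=True, n_iter=1,
        )

    def test_zero_slopes_give_flat_surfaces(self):
        U = np.array([[1.0, 0.0], [2.0, 0.0]])
        markers = pd.DataFrame({"eem_1": [0.3, -0.8, 1.5]},
                               index=pd.Index(["b1", "b2", "b3"], name="bin_id"))
        surf = predict_bins(self._fit(U), markers)
        assert np.ptp(surf.to_numpy(), axis=1).max() == 0.0

    def test_unit_slope_tracks_marker_differences(self):
        U = np.array([[0.0, 1.0]])
        markers = pd.DataFrame({"eem_1": [0.3, -0.8]},
                               index=pd.Index(["b1", "b2"], name="bin_id"))
        surf = predict_bins(self._fit(U), markers)
        assert surf.at["G0", "b1"] - surf.at["G0", "b2"] == pytest.approx(1.1)

    def test_year_policy_lookup(self):
        U = np.zeros((1, 2))
        markers = pd.DataFrame({"eem_1": [0.0]}, index=pd.Index(["b1"], name="bin_id"))
        fit = self._fit(U, years=("year_2020", "year_2021"))
        fit.b = np.array([1.0, 3.0])
        assert predict_bins(fit, markers).iloc[0, 0] == pytest.approx(2.0)  # mean policy
        assert predict_bins(fit, markers, year_policy="year_2021").iloc[0, 0] == 3.0
        with pytest.raises(KeyError):
            predict_bins(fit, markers, year_policy="year_1999")


class TestStabilityAngles:
    def test_canonical_angles(self):
        draws = np.array([[[1.0, 0.0, -1.0]]])   # one run, one genotype, 3 markers
        angles, summary = stability_angles(draws, ["G1"])
        assert np.allclose(angles.ravel(), [45.0, 0.0, -45.0])
        assert summary.loc["G1", "angle_min"] == -45.0
        assert summary.loc["G1", "angle_max"] == 45.0
        assert summary.loc["G1", "angle_mean"] == 0.0

    def test_angles_bounded(self, small_bundle):
        draws = np.random.default_rng(0).normal(0, 10, size=(5, 4, 3))
        angles, _ = stability_angles(draws, list("abcd"))
        assert angles.max() < 90.0 and angles.min() > -90.0


class TestEnsemble:
    def test_identical_trees_make_degenerate_ensemble(self, small_bundle, stub_bank_factory):
        # all trees equal -> single cluster, every run identical, zero SE
        cov = small_bundle.covariates
        base = np.linspace(-1, 1, len(cov))
        mat = pd.DataFrame(np.tile(base[:, None], (1, 6)), index=cov["location_id"])
        # the stub must also answer at trial locations (same value as the
        # trial's bin)
        trial_rows = mat.loc[small_bundle.trial_bins.to_numpy()].set_axis(
            small_bundle.trial_bins.index
        )
        mat = pd.concat([mat, trial_rows])
        with pytest.warns(UserWarning, match="distinct tree families"):
            eset = cluster_and_aggregate(stub_bank_factory(mat), 3, cov)
        kin = small_bundle.kinship.submatrix(sorted(small_bundle.phenotypes["genotype_id"].unique()))
        ens = ensemble_reem(
            small_bundle.phenotypes, eset, kin,
            small_bundle.trial_covariates, cov, n_runs=4, seed=0,
        )
        # every sampled tree carries the same gradient; surfaces differ only
        # by REML optimizer tolerance across warm restarts
        g0 = eset.sampled_tree_markers(cov, ens.run_markers[0])
        for m in ens.run_markers[1:]:
            assert np.allclose(g0, eset.sampled_tree_markers(cov, m))
        assert ens.se.to_numpy().max() < 1e-3

    def test_single_run_equals_single_fit(self, small_bundle, small_eset):
        kin = small_bundle.kinship
        tc = small_bundle.trial_covariates
        ens = ensemble_reem(small_bundle.phenotypes, small_eset, kin, tc,
                            small_bundle.covariates, n_runs=1, seed=12)
        tree_idx = ens.run_markers[0]
        mk = small_eset.sampled_tree_markers(tc, tree_idx)
        m_trials = pd.DataFrame(mk, index=pd.Index(tc["location_id"], name="trial_id"),
                                columns=[f"tree_{t}" for t in tree_idx])
        fit = fit_reem(small_bundle.phenotypes, m_trials, kin)
        mg = small_eset.sampled_tree_markers(small_bundle.covariates, tree_idx)
        m_bins = pd.DataFrame(mg, index=pd.Index(small_bundle.covariates["location_id"]),
                              columns=m_trials.columns)
        direct = predict_bins(fit, m_bins)
        assert np.abs(ens.mean.to_numpy() - direct.to_numpy()).max() < 1e-8

    def test_single_marker_mode_fits_one_reaction_norm_per_run(self, small_bundle, small_eset):
        ens = ensemble_reem(
            small_bundle.phenotypes, small_eset, small_bundle.kinship,
            small_bundle.trial_covariates, small_bundle.covariates,
            n_runs=3, seed=4, run_mode="single_marker",
        )
        assert ens.Sigma_pooled.shape == (2, 2)
        assert ens.slope_draws.shape[2] == 1
        assert all(len(m) == 1 for m in ens.run_markers)

    def test_pooled_sigma_is_symmetric_psd(self, small_bundle, small_eset):
        kin = small_bundle.kinship
        ens = ensemble_reem(small_bundle.phenotypes, small_eset, kin,
                            small_bundle.trial_covariates, small_bundle.covariates,
                            n_runs=3, seed=2)
        S = ens.Sigma_pooled
        assert np.allclose(S, S.T)
        assert np.linalg.eigvalsh(S).min() > -1e-8


class TestBaseline:
    def test_new_trial_predictions_constant_within_irrigation_level(self, small_bundle):
        fit = baseline_gxe_fit(small_bundle.phenotypes, small_bundle.kinship)
        g = small_bundle.phenotypes["genotype_id"].iloc[0]
        p_dry = fit.predict([g, g], [False, False])
        p_wet = fit.predict([g], [True])
        assert p_dry[0] == p_dry[1]
        assert p_wet[0] != p_dry[0]

    def test_ranking_equals_blup_ranking(self, small_bundle):
        fit = baseline_gxe_fit(small_bundle.phenotypes, small_bundle.kinship)
        ids = sorted(small_bundle.phenotypes["genotype_id"].unique())
        preds = fit.predict(ids, [False] * len(ids))
        blups = fit.genotype_blup.reindex(ids).to_numpy()
        assert np.array_equal(np.argsort(preds), np.argsort(blups))

    def test_no_gxe_interaction_variance_reported_zero(self):
        # trial-level BLUEs carry one record per cell: the interaction is
        # dropped as confounded and reported as exactly zero
        rng = np.random.default_rng(3)
        ids = [f"G{i}" for i in range(12)]
        rows = []
        for t in range(10):
            for g in ids:
                rows.append((f"T{t}", g, 2020, t % 2 == 0, "N", 0.0, 0.0,
                             rng.normal()))
        phen = pd.DataFrame(rows, columns=["trial_id", "genotype_id", "year",
                                           "irrigated", "region", "lat", "lon", "yield_blue"])
        kin = KinshipMatrix(ids=ids, values=np.eye(12))
        with pytest.warns(UserWarning, match="confounded"):
            fit = baseline_gxe_fit(phen, kin)
        assert fit.variances["gxe"] == 0.0

    def test_single_irrigation_level_dropped(self, small_bundle):
        phen = small_bundle.phenotypes.copy()
        phen["irrigated"] = False
        with pytest.warns(UserWarning, match="irrigation"):
            fit = baseline_gxe_fit(phen, small_bundle.kinship)
        assert not fit.has_irrigation


class TestKernel:
    def test_kernel_covariance_equals_random_regression_covariance(self):
        # diagonal-Sigma random regression and the genotype+interaction kernel
        # model induce the same phenotypic covariance, hence the same
        # conditional-mean predictions at fixed variances
        rng = np.random.default_rng(7)
        G_n, n = 6, 20
        ped_ids = [f"G{i}" for i in range(G_n)]
        A = 0.25 * np.ones((G_n, G_n)) + 0.75 * np.eye(G_n)
        geno = rng.integers(0, G_n, n)
        eps = rng.normal(size=n)                      # one marker at each record
        s0, s1, se2 = 0.9, 0.5, 0.2
        X = np.ones((n, 1))
        y = rng.normal(size=n)

        # random-regression route
        M = np.column_stack([np.ones(n), eps])
        Z = np.zeros((n, 2 * G_n))
        Z[np.arange(n)[:, None], np.arange(2)[None, :] * G_n + geno[:, None]] = M
        Gmat = np.kron(np.diag([s0, s1]), A)
        V_rr = Z @ Gmat @ Z.T

        # kernel route: genotype main + hadamard interaction
        A_rec = A[np.ix_(geno, geno)]
        E_rec = np.outer(eps, eps)
        V_k = s0 * A_rec + s1 * (A_rec * E_rec)
        assert np.abs(V_rr - V_k).max() < 1e-12

        b1, u1 = conditional_mean_oracle(y, X, Z, Gmat, se2)
        pred_rr = X @ b1 + Z @ u1
        Zk = np.eye(n)
        b2, u2 = conditional_mean_oracle(y, X, Zk, V_k, se2)
        pred_k = X @ b2 + Zk @ u2
        assert np.abs(pred_rr - pred_k).max() < 1e-4

    def test_in_sample_predictions_track_data(self, small_bundle, trial_markers):
        fit = kernel_gxe_fit(small_bundle.phenotypes, trial_markers, small_bundle.kinship)
        assert fit.converged
        phen = small_bundle.phenotypes
        yhat = fit.predict(phen["genotype_id"], trial_markers.loc[phen["trial_id"]])
        r = np.corrcoef(yhat, phen["yield_blue"])[0, 1]
        assert r > 0.7

    def test_identical_markers_kill_interaction(self, small_bundle):
        tc = small_bundle.trial_covariates
        markers = pd.DataFrame(
            {"eem_1": np.ones(len(tc))}, index=pd.Index(tc["location_id"], name="trial_id")
        )
        fit = kernel_gxe_fit(small_bundle.phenotypes, markers, small_bundle.kinship)
        # constant environment vectors: environment term absorbs a constant,
        # the interaction reduces to the genotype term (no extra signal)
        assert fit.variances["gxe"] + fit.variances["environment"] >= 0  # fits without error
        yhat = fit.predict(
            small_bundle.phenotypes["genotype_id"],
            markers.loc[small_bundle.phenotypes["trial_id"]],
        )
        # predictions vary only through genotype
        df = pd.DataFrame({"g": small_bundle.phenotypes["genotype_id"], "p": yhat})
        assert df.groupby("g")["p"].std(ddof=0).max() < 1e-8
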