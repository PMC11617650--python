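"""Cross-validation harness for the three G x E models.

Predictive ability is always scored within trial (Pearson, Spearman, RMSE
per held-out trial, then unweighted mean +/- sd over trials) — pooling
records across trials can reverse correlations (Simpson's paradox), so it is
never done for the headline metrics. Schemes: leave-one-trial-out and
leave-region-out. The per-trial leave-one-out abilities can be interpolated
over the prediction grid by ordinary kriging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .eem import cluster_and_aggregate, fit_tree_bank
from .kinship import KinshipMatrix
from .kriging import krige_ability
from .reem import baseline_gxe_fit, ensemble_reem, kernel_gxe_fit

MODELS = ("baseline", "kernel", "reem")


@dataclass
class ValidationReport:
    scheme: str
    model: str
    per_trial: pd.DataFrame          # trial_id, n, pearson, spearman, rmse
    predictions: pd.DataFrame = field(default=None, repr=False)

    def summary(self) -> pd.Series:
        pt = self.per_trial
        return pd.Series(
            {
                "n_trials": len(pt),
                "pearson_mean": pt["pearson"].mean(),
                "pearson_sd": pt["pearson"].std(),
                "spearman_mean": pt["spearman"].mean(),
                "spearman_sd": pt["spearman"].std(),
                "rmse_mean": pt["rmse"].mean(),
                "rmse_sd": pt["rmse"].std(),
            },
            name=f"{self.scheme}/{self.model}",
        )


def per_trial_metrics(
    observed, predicted, trial_ids, min_genotypes: int = 3
) -> pd.DataFrame:
    """Pearson/Spearman/RMSE computed separately within every trial."""
    df = pd.DataFrame(
        {"obs": np.asarray(observed, float), "pred": np.asarray(predicted, float),
         "trial_id": np.asarray(trial_ids)}
    )
    rows = []
    for t, sub in df.groupby("trial_id"):
        if len(sub) < min_genotypes:
            continue
        rmse = float(np.sqrt(np.mean((sub.obs - sub.pred) ** 2)))
        if sub.obs.std() == 0 or sub.pred.std() == 0:
            r = rho = np.nan
        else:
            r = float(pearsonr(sub.obs, sub.pred)[0])
            rho = float(spearmanr(sub.obs, sub.pred)[0])
        rows.append({"trial_id": t, "n": len(sub), "pearson": r, "spearman": rho, "rmse": rmse})
    return pd.DataFrame(rows)


def _predict_fold(model, train, test, bundle, cfg, seed, warm=None):
    """Fit ``model`` on the training records and predict the test records.

    The kinship matrix is marginalised to the phenotyped genotypes: BLUPs of
    observed genotypes under a Gaussian prior depend only on their own
    relationship submatrix, so this is exact and much faster than carrying
    the non-phenotyped parents through every fold.
    """
    pheno_ids = sorted(set(train["genotype_id"]) | set(test["genotype_id"]))
    kin = bundle.kinship.submatrix(pheno_ids)
    if model == "baseline":
        fit = baseline_gxe_fit(train, kin)
        return fit.predict(test["genotype_id"], test["irrigated"].to_numpy())
    # marker-based models need an EEM set engineered from the training trials
    train_trials = train.drop_duplicates("trial_id")["trial_id"]
    tcov = bundle.trial_covariates
    tcov_train = tcov[tcov["location_id"].isin(train_trials)]
    if cfg.get("refit_bank", True) or warm is None or "eset" not in warm:
        bank = fit_tree_bank(
            tcov_train, train, n_trees=cfg.get("n_trees", 200),
            seed=seed, min_samples_leaf=cfg.get("min_samples_leaf", 2),
        )
        eset = cluster_and_aggregate(bank, cfg.get("n_markers", 7), bundle.covariates)
        if warm is not None and not cfg.get("refit_bank", True):
            warm["eset"] = eset
    else:
        eset = warm["eset"]

    test_trials = test.drop_duplicates("trial_id")["trial_id"]
    tcov_test = tcov[tcov["location_id"].isin(test_trials)]
    if model == "kernel":
        mk_train = eset.values_at(tcov_train).set_axis(
            pd.Index(tcov_train["location_id"], name="trial_id")
        )
        mk_test = eset.values_at(tcov_test).set_axis(
            pd.Index(tcov_test["location_id"], name="trial_id")
        )
        fit = kernel_gxe_fit(train, mk_train, kin)
        return fit.predict(test["genotype_id"], mk_test.loc[test["trial_id"]])
    if model == "reem":
        # predictions for the held-out trials' bins via the run-averaged surfaces
        ens = ensemble_reem(
            train, eset, kin, tcov_train,
            tcov_test,  # "grid" = the held-out trial locations
            n_runs=cfg.get("n_runs", 10), seed=seed,
        )
        return np.array(
            [ens.mean.at[g, t] for g, t in zip(test["genotype_id"], test["trial_id"])]
        )
    raise ValueError(f"unknown model {model!r}")


def loo_trial_cv(model: str, bundle, cfg: dict = None, seed: int = 0) -> ValidationReport:
    """Leave-one-trial-out: refit without each trial, predict its genotypes.

    ``cfg`` keys (all optional): n_trees, n_markers, n_runs, refit_bank,
    min_samples_leaf, min_genotypes. The held-out trial's records appear in
    no training structure (the marker bank is refit per fold by default).
    """
    cfg = dict(cfg or {})
    phen = bundle.phenotypes
    rng = np.random.default_rng(seed)
    trials = sorted(phen["trial_id"].unique())
    preds, rows = [], []
    warm: dict = {}
    for t in trials:
        train = phen[phen["trial_id"] != t]
        test = phen[phen["trial_id"] == t]
        try:
            yhat = _predict_fold(model, train, test, bundle, cfg, int(rng.integers(2**31 - 1)), warm)
        except RuntimeError as e:       # model did not converge on this fold
            warnings.warn(f"fold {t} skipped: {e}")
            continue
        preds.append(pd.DataFrame({"trial_id": t, "genotype_id": test["genotype_id"],
                                   "obs": test["yield_blue"].to_numpy(), "pred": yhat}))
    all_preds = pd.concat(preds, ignore_index=True)
    pt = per_trial_metrics(all_preds["obs"], all_preds["pred"], all_preds["trial_id"],
                           min_genotypes=cfg.get("min_genotypes", 3))
    return ValidationReport(scheme="loo", model=model, per_trial=pt, predictions=all_preds)


def leave_region_out_cv(model: str, bundle, cfg: dict = None, seed: int = 0):
    """One fold per region; metrics within the held-out region's trials.

    Returns (per-region reports, overall report pooling all folds' trial-level
    metrics into one mean +/- sd).
    """
    cfg = dict(cfg or {})
    phen = bundle.phenotypes
    regions = sorted(phen["region"].unique())
    if len(regions) < 2:
        raise ValueError("need at least 2 regions for leave-region-out")
    rng = np.random.default_rng(seed)
    reports, all_preds = {}, []
    for reg in regions:
        train = phen[phen["region"] != reg]
        test = phen[phen["region"] == reg]
        if not len(test):
            continue
        yhat = _predict_fold(model, train, test, bundle, cfg, int(rng.integers(2**31 - 1)))
        pr = pd.DataFrame({"trial_id": test["trial_id"], "genotype_id": test["genotype_id"],
                           "obs": test["yield_blue"].to_numpy(), "pred": yhat, "region": reg})
        all_preds.append(pr)
        pt = per_trial_metrics(pr["obs"], pr["pred"], pr["trial_id"],
                               min_genotypes=cfg.get("min_genotypes", 3))
        reports[reg] = ValidationReport(scheme=f"region:{reg}", model=model, per_trial=pt,
                                        predictions=pr)
    pooled = pd.concat(all_preds, ignore_index=True)
    pt_all = per_trial_metrics(pooled["obs"], pooled["pred"], pooled["trial_id"],
                               min_genotypes=cfg.get("min_genotypes", 3))
    overall = ValidationReport(scheme="region:overall", model=model, per_trial=pt_all,
                               predictions=pooled)
    return reports, overall


def ability_surface(report: ValidationReport, bundle, metric: str = "pearson"):
    """Krige per-trial abilities from a LOO report onto the prediction grid."""
    phen = bundle.phenotypes.drop_duplicates("trial_id").set_index("trial_id")
    pt = report.per_trial.dropna(subset=[metric])
    xy = np.column_stack(
        bundle.grid.projection.to_xy(
            phen.loc[pt["trial_id"], "lat"], phen.loc[pt["trial_id"], "lon"]
        )
    )
    pred, vario, weights = krige_ability(
        xy, pt[metric].to_numpy(), bundle.grid.centroids_xy()
    )
    surf = pd.Series(pred, index=pd.Index(bundle.grid.bin_ids, name="bin_id"),
                     name=f"{metric}_ability")
    return surf, vario, weights
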