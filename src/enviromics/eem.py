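"""Engineered enviromic markers (EEMs) from regression-tree ensembles.

A large bank of CART regression trees is fitted to predict trial-level
environment means (computed over random genotype subsamples) from the
environmental covariates, each tree seeing a random covariate subset. The
trees' standardized prediction vectors over a reference location set are
hierarchically clustered into K "forests"; each forest's mean prediction,
re-standardized, is one engineered enviromic marker — a one-dimensional
environmental gradient. The standardized mean over all trees is the
wide-environment gradient used for charting. Per-tree impurity importances
are tallied into an envirome-wide association summary (how often each
covariate ranks 1st..5th) and into per-source importance shares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr
from sklearn.tree import DecisionTreeRegressor

from .io import covariate_columns, covariate_source


class MarkerError(ValueError):
    pass


def environment_means(
    phenotypes: pd.DataFrame,
    subsample_fraction: float = 0.5,
    seed: int = 0,
    max_resample: int = 100,
) -> tuple[pd.Series, list]:
    """Per-trial mean yield over a random genotype subsample.

    Trials with fewer than 2 records are excluded (with a warning). The
    genotype subsample is redrawn until every remaining trial retains at
    least 2 sampled genotypes; if that fails, the subsample is topped up with
    genotypes from the deficient trials.
    """
    counts = phenotypes.groupby("trial_id")["genotype_id"].size()
    small = counts[counts < 2].index
    if len(small):
        warnings.warn(f"excluding {len(small)} trial(s) with < 2 records")
        phenotypes = phenotypes[~phenotypes["trial_id"].isin(small)]
    genotypes = np.array(sorted(phenotypes["genotype_id"].unique()))
    n_keep = max(2, int(round(subsample_fraction * len(genotypes))))
    rng = np.random.default_rng(seed)

    wide = phenotypes.pivot(index="trial_id", columns="genotype_id", values="yield_blue")
    present = wide.notna()
    for _ in range(max_resample):
        sample = rng.choice(genotypes, size=n_keep, replace=False)
        per_trial = present[sample].sum(axis=1)
        if (per_trial >= 2).all():
            break
    else:
        sample = set(sample)
        for t in per_trial[per_trial < 2].index:
            have = present.columns[present.loc[t]].to_numpy()
            sample.update(rng.choice(have, size=min(2, len(have)), replace=False))
        sample = np.array(sorted(sample))
    m = wide[np.asarray(sample)].mean(axis=1)
    return m, list(sample)


@dataclass
class TreePredictorBank:
    """A fitted ensemble of single regression-tree predictors of m."""

    trees: list
    feature_subsets: list          # per tree: covariate column indices
    genotype_subsamples: list      # per tree: sampled genotype ids
    covariate_names: list
    importances: np.ndarray        # n_trees x n_covariates (impurity decrease)
    seed: int = 0

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def predict(self, covariates: pd.DataFrame) -> np.ndarray:
        """Prediction matrix (locations x trees) on any covariate table."""
        W = covariates[self.covariate_names].to_numpy(dtype=float)
        P = np.empty((W.shape[0], self.n_trees))
        for t, (tree, cols) in enumerate(zip(self.trees, self.feature_subsets)):
            P[:, t] = tree.predict(W[:, cols])
        return P


def fit_tree_bank(
    trial_covariates: pd.DataFrame,
    phenotypes: pd.DataFrame,
    n_trees: int = 10_000,
    subsample_fraction: float = 0.5,
    min_samples_leaf: int = 2,
    max_features: str = "sqrt",
    seed: int = 0,
) -> TreePredictorBank:
    """Fit the bank of CART trees of environment means on covariates.

    Each tree draws its own genotype subsample (a fresh realisation of the
    environment mean m) and a random covariate subset of size ``sqrt(p)``
    (the standard random-forest rule), then fits an unpruned CART with
    ``min_samples_leaf`` trials per leaf.
    """
    cov_cols = covariate_columns(trial_covariates)
    trials = trial_covariates["location_id"].to_numpy()
    if len(trials) < 5:
        raise MarkerError("need at least 5 trials to engineer markers")
    W = trial_covariates[cov_cols].to_numpy(dtype=float)
    p = len(cov_cols)
    n_sub = max(1, int(round(np.sqrt(p)))) if max_features == "sqrt" else p

    rng = np.random.default_rng(seed)
    trees, subsets, samples = [], [], []
    imp = np.zeros((n_trees, p))
    for t in range(n_trees):
        m, sample = environment_means(
            phenotypes, subsample_fraction, seed=int(rng.integers(2**31 - 1))
        )
        mv = m.reindex(trials).to_numpy()
        ok = np.isfinite(mv)
        cols = np.sort(rng.choice(p, size=n_sub, replace=False))
        tree = DecisionTreeRegressor(
            min_samples_leaf=min_samples_leaf, random_state=int(rng.integers(2**31 - 1))
        )
        tree.fit(W[ok][:, cols], mv[ok])
        trees.append(tree)
        subsets.append(cols)
        samples.append(sample)
        imp[t, cols] = tree.feature_importances_ * tree.tree_.impurity[0]
    return TreePredictorBank(
        trees=trees,
        feature_subsets=subsets,
        genotype_subsamples=samples,
        covariate_names=cov_cols,
        importances=imp,
        seed=seed,
    )


def _safe_standardize(P: np.ndarray, mean=None, sd=None):
    if mean is None:
        mean = P.mean(axis=0)
        sd = P.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (P - mean) / sd_safe, mean, sd


@dataclass
class EemSet:
    """K engineered markers plus the tree->cluster map and scalings.

    Marker values at arbitrary locations are reproducible from the bank and
    the stored standardizations (per-tree over the reference location set,
    then per-marker): see :meth:`values_at`.
    """

    bank: TreePredictorBank
    cluster_of_tree: np.ndarray    # 1..K per tree
    n_markers: int
    tree_mean: np.ndarray
    tree_sd: np.ndarray
    eem_mean: np.ndarray
    eem_sd: np.ndarray
    wide_mean: float
    wide_sd: float
    reference_ids: list
    eem_values: pd.DataFrame = field(repr=False, default=None)   # reference locations x K
    wide_gradient: pd.Series = field(repr=False, default=None)
    importance_tally: pd.DataFrame = field(repr=False, default=None)
    source_shares: pd.Series = field(repr=False, default=None)

    @property
    def marker_names(self) -> list:
        return [f"eem_{k + 1}" for k in range(self.n_markers)]

    def _standardized_trees(self, covariates: pd.DataFrame) -> np.ndarray:
        P = self.bank.predict(covariates)
        Z, _, _ = _safe_standardize(P, self.tree_mean, self.tree_sd)
        return Z

    def values_at(self, covariates: pd.DataFrame) -> pd.DataFrame:
        """Marker values (standardized on the reference set) at new locations."""
        Z = self._standardized_trees(covariates)
        raw = np.column_stack(
            [Z[:, self.cluster_of_tree == k + 1].mean(axis=1) for k in range(self.n_markers)]
        )
        vals, _, _ = _safe_standardize(raw, self.eem_mean, self.eem_sd)
        return pd.DataFrame(
            vals, index=pd.Index(covariates["location_id"], name="location_id"),
            columns=self.marker_names,
        )

    def wide_at(self, covariates: pd.DataFrame) -> pd.Series:
        Z = self._standardized_trees(covariates)
        raw = Z.mean(axis=1)
        sd = self.wide_sd if self.wide_sd > 0 else 1.0
        return pd.Series(
            (raw - self.wide_mean) / sd,
            index=pd.Index(covariates["location_id"], name="location_id"),
            name="wide_gradient",
        )

    def sampled_tree_markers(self, covariates: pd.DataFrame, tree_idx) -> np.ndarray:
        """Standardized single-tree gradients (one column per chosen tree)."""
        Z = self._standardized_trees(covariates)
        return Z[:, np.asarray(tree_idx, dtype=int)]


def cluster_and_aggregate(
    bank: TreePredictorBank, K: int, reference_covariates: pd.DataFrame
) -> EemSet:
    """Cluster tree predictors into K forests and aggregate them into markers.

    Distance between trees is one minus the Pearson correlation of their
    standardized prediction vectors over the reference locations; linkage is
    average. Each marker is the cluster-mean standardized prediction,
    re-standardized to mean 0 / sd 1 over the reference set.
    """
    if K > bank.n_trees:
        raise MarkerError(f"K={K} exceeds the number of trees ({bank.n_trees})")
    P = bank.predict(reference_covariates)
    Z, tree_mean, tree_sd = _safe_standardize(P)
    if bank.n_trees == 1:
        labels = np.array([1])
    else:
        const = tree_sd == 0
        # correlation distance is undefined for constant trees; they join cluster 1
        D = pdist(Z[:, ~const].T, metric="correlation") if (~const).sum() > 1 else None
        labels = np.ones(bank.n_trees, dtype=int)
        if D is not None:
            sub = fcluster(linkage(np.clip(D, 0, None), method="average"), min(K, (~const).sum()), criterion="maxclust")
            labels[~const] = sub
    K_eff = labels.max()
    if K_eff < K:
        warnings.warn(f"only {K_eff} distinct tree families; using {K_eff} markers")
    raw = np.column_stack([Z[:, labels == k + 1].mean(axis=1) for k in range(K_eff)])
    vals, eem_mean, eem_sd = _safe_standardize(raw)
    wide_raw = Z.mean(axis=1)
    wide_mean, wide_sd = wide_raw.mean(), wide_raw.std()

    ids = list(reference_covariates["location_id"])
    eset = EemSet(
        bank=bank,
        cluster_of_tree=labels,
        n_markers=K_eff,
        tree_mean=tree_mean,
        tree_sd=tree_sd,
        eem_mean=eem_mean,
        eem_sd=eem_sd,
        wide_mean=float(wide_mean),
        wide_sd=float(wide_sd),
        reference_ids=ids,
    )
    eset.eem_values = pd.DataFrame(
        _safe_standardize(raw, eem_mean, eem_sd)[0],
        index=pd.Index(ids, name="location_id"),
        columns=eset.marker_names,
    )
    eset.wide_gradient = pd.Series(
        (wide_raw - wide_mean) / (wide_sd if wide_sd > 0 else 1.0),
        index=pd.Index(ids, name="location_id"),
        name="wide_gradient",
    )
    tally, shares = ewas_tally(bank)
    eset.importance_tally = tally
    eset.source_shares = shares
    return eset


def ewas_tally(bank: TreePredictorBank, top: int = 5) -> tuple[pd.DataFrame, pd.Series]:
    """Envirome-wide association tally of covariate importances.

    For every tree the covariates are ranked by impurity importance; the
    tally counts, per covariate, how often it occupied rank 1..``top``
    (covariates with zero importance in a tree are never ranked). Mean
    importances aggregated by source tag give shares summing to 100.
    """
    imp = bank.importances
    names = bank.covariate_names
    counts = np.zeros((len(names), top), dtype=int)
    for row in imp:
        order = np.argsort(-row)
        for r in range(min(top, len(order))):
            if row[order[r]] <= 0:
                break
            counts[order[r], r] += 1
    tally = pd.DataFrame(
        counts, index=pd.Index(names, name="covariate"),
        columns=[f"rank{r + 1}" for r in range(top)],
    )
    tally["mean_importance"] = imp.mean(axis=0)
    tally["source"] = [covariate_source(c) for c in names]

    by_source = tally.groupby("source")["mean_importance"].sum()
    total = by_source.sum()
    shares = (100.0 * by_source / total) if total > 0 else by_source * 0.0
    return tally.sort_values("mean_importance", ascending=False), shares.rename("share_pct")


def validate_eems(
    trial_covariates: pd.DataFrame,
    phenotypes: pd.DataFrame,
    bank: TreePredictorBank = None,
    loo_n_trees: int = 200,
    subsample_fraction: float = 0.5,
    min_samples_leaf: int = 2,
    seed: int = 0,
) -> dict:
    """Fit and leave-one-trial-out validation of the marker-engineering stage.

    ``fit_correlation`` is the Pearson r between observed trial means and the
    in-sample ensemble mean prediction. ``loo_correlation`` refits a reduced
    bank (``loo_n_trees`` trees) without each trial in turn and correlates
    the held-out means with their predictions.
    """
    m_obs, _ = environment_means(phenotypes, subsample_fraction=1.0, seed=seed)
    trials = trial_covariates["location_id"]
    m_obs = m_obs.reindex(trials).to_numpy()
    if np.nanstd(m_obs) == 0:
        return {"fit_correlation": np.nan, "loo_correlation": np.nan}

    if bank is None:
        bank = fit_tree_bank(
            trial_covariates, phenotypes, n_trees=loo_n_trees,
            subsample_fraction=subsample_fraction,
            min_samples_leaf=min_samples_leaf, seed=seed,
        )
    fit_hat = bank.predict(trial_covariates).mean(axis=1)
    fit_r = float(pearsonr(m_obs, fit_hat)[0])

    rng = np.random.default_rng(seed)
    preds = np.empty(len(trials))
    for i, t in enumerate(trials):
        keep = trials != t
        sub_bank = fit_tree_bank(
            trial_covariates[keep],
            phenotypes[phenotypes["trial_id"] != t],
            n_trees=loo_n_trees,
            subsample_fraction=subsample_fraction,
            min_samples_leaf=min_samples_leaf,
            seed=int(rng.integers(2**31 - 1)),
        )
        preds[i] = sub_bank.predict(trial_covariates[~keep]).mean()
    loo_r = float(pearsonr(m_obs, preds)[0])
    return {"fit_correlation": fit_r, "loo_correlation": loo_r, "loo_predictions": preds, "observed_means": m_obs}
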