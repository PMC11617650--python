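"""Per-bin genotype recommendation with geographic representativeness.

Two-step rule per bin: (1) find the set of genotypes statistically tied with
the best predicted genotype (two-sided t-test on the ensemble run-to-run
standard errors); (2) among the tied set, pick the genotype with the highest
geographic representativeness — by default the one whose nearest trial is
closest to the bin. Occupation summaries and parental-line recommendations
(additive mid-parent logic through the pedigree) complete the stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .grid import PredictionGrid
from .io import UNKNOWN_PARENT


class RecommendationError(ValueError):
    pass


def statistical_ties(
    means: pd.Series, ses: pd.Series, alpha: float = 0.05, df: int = None
) -> list:
    """Genotypes statistically tied with the best one at a single bin.

    A genotype g is tied when the two-sided t-test of ``mu_best - mu_g``
    with standard error ``sqrt(se_best^2 + se_g^2)`` is not significant at
    ``alpha``. The best genotype is always in the set; zero pooled SE with a
    nonzero difference excludes.
    """
    if df is None or df < 1:
        raise RecommendationError("df must be >= 1 (ensemble runs - 1)")
    best = means.idxmax()
    diff = means[best] - means
    pooled = np.sqrt(ses[best] ** 2 + ses**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = diff / pooled
    pvals = 2.0 * t_dist.sf(np.abs(tval), df)
    pvals = pd.Series(np.where(pooled > 0, pvals, np.where(diff > 0, 0.0, 1.0)),
                      index=means.index)
    tied = list(means.index[(pvals > alpha)])
    if best not in tied:
        tied.append(best)
    return tied


def trial_distance_table(
    phenotypes: pd.DataFrame, grid: PredictionGrid
) -> tuple[np.ndarray, dict]:
    """Planar km distances bin x trial plus genotype -> trial-row map."""
    trials = phenotypes.drop_duplicates("trial_id")[["trial_id", "lat", "lon"]]
    tx, ty = grid.projection.to_xy(trials["lat"], trials["lon"])
    cxy = grid.centroids_xy()
    d = np.sqrt((cxy[:, [0]] - tx[None, :]) ** 2 + (cxy[:, [1]] - ty[None, :]) ** 2)
    trial_pos = {t: i for i, t in enumerate(trials["trial_id"])}
    geno_trials = {
        g: np.array([trial_pos[t] for t in sub["trial_id"].unique()])
        for g, sub in phenotypes.groupby("genotype_id")
    }
    return d, geno_trials


def representativeness_select(
    tied: list,
    means: pd.Series,
    bin_row: np.ndarray,        # distances from this bin to every trial
    geno_trials: dict,
    mode: str = "min",
    k_nearest: int = 3,
) -> tuple[str, float]:
    """Winner among the tied set: smallest distance to its own trials.

    ``mode="min"`` uses the nearest trial containing the genotype;
    ``mode="knearest"`` the mean of its k nearest trials. Distance ties break
    by higher predicted mean, then lexicographic id. Genotypes never trialed
    cannot win (unless no tied genotype was trialed, in which case the
    highest mean wins at infinite distance).
    """
    best_g, best_key = None, None
    for g in sorted(tied):
        rows = geno_trials.get(g)
        if rows is None or len(rows) == 0:
            d = np.inf
        elif mode == "min":
            d = float(bin_row[rows].min())
        elif mode == "knearest":
            d = float(np.sort(bin_row[rows])[: max(1, k_nearest)].mean())
        else:
            raise RecommendationError(f"unknown representativeness mode {mode!r}")
        key = (d, -float(means[g]), g)
        if best_key is None or key < best_key:
            best_g, best_key = g, key
    return best_g, best_key[0]


def recommend_genotypes(
    prediction_mean: pd.DataFrame,    # genotypes x bins
    prediction_se: pd.DataFrame,
    phenotypes: pd.DataFrame,
    grid: PredictionGrid,
    n_runs: int,
    alpha: float = 0.05,
    mode: str = "min",
    k_nearest: int = 3,
) -> pd.DataFrame:
    """Winner per bin: ``bin_id, winner, n_tied, distance_km``.

    Only phenotyped genotypes compete (prediction rows are subset to them).
    """
    pheno_g = sorted(set(phenotypes["genotype_id"]) & set(prediction_mean.index))
    if not pheno_g:
        raise RecommendationError("no phenotyped genotypes among predictions")
    mean = prediction_mean.loc[pheno_g]
    se = prediction_se.loc[pheno_g]
    df = max(n_runs - 1, 1)
    dists, geno_trials = trial_distance_table(phenotypes, grid)

    rows = []
    for j, bin_id in enumerate(mean.columns):
        mu = mean.iloc[:, j]
        tied = statistical_ties(mu, se.iloc[:, j], alpha=alpha, df=df)
        winner, d = representativeness_select(
            tied, mu, dists[j], geno_trials, mode=mode, k_nearest=k_nearest
        )
        rows.append((bin_id, winner, len(tied), d))
    return pd.DataFrame(rows, columns=["bin_id", "winner", "n_tied", "distance_km"]).set_index("bin_id")


def occupation_summary(
    winners: pd.DataFrame,
    phenotypes: pd.DataFrame,
    trial_bins: pd.Series,
    stability: pd.DataFrame = None,
) -> pd.DataFrame:
    """Per winning genotype: area occupation and measurement provenance.

    Columns mirror a top-genotype table: bins won and % of grid, number of
    distinct trial bins where the genotype was measured, measured years, and
    (when supplied) the stability-angle summary.
    """
    n_bins = len(winners)
    occ = winners.groupby("winner").size().sort_values(ascending=False)
    geno_bins = phenotypes.merge(
        trial_bins.rename("trial_bin"), left_on="trial_id", right_index=True
    )
    trial_bin_count = geno_bins.groupby("genotype_id")["trial_bin"].nunique()
    years = phenotypes.groupby("genotype_id")["year"].agg(
        lambda s: ",".join(str(v) for v in sorted(s.unique()))
    )
    out = pd.DataFrame(
        {
            "bins_won": occ,
            "occupation_pct": 100.0 * occ / n_bins,
            "trial_bins_measured": trial_bin_count.reindex(occ.index).fillna(0).astype(int),
            "measured_years": years.reindex(occ.index),
        }
    )
    out.index.name = "genotype_id"
    if stability is not None:
        out = out.join(stability, how="left")
    return out


def parental_recommendation(
    prediction_mean: pd.DataFrame,    # genotypes x bins, parents included via A
    pedigree: pd.DataFrame,
) -> pd.DataFrame:
    """Top-1/top-2 parental lines per bin and the suggested cross.

    Parents are genotypes that appear as dam or sire of some hybrid; their
    surfaces come from BLUPs propagated through the relationship matrix even
    though they carry no phenotypes. The suggested cross is additive
    (mid-parent): its expected surface is the average of the two parents'.
    """
    parents = sorted(
        (set(pedigree["dam_id"]) | set(pedigree["sire_id"])) - {UNKNOWN_PARENT}
    )
    parents = [p for p in parents if p in prediction_mean.index]
    if not parents:
        raise RecommendationError("no parental lines found in the predictions")
    P = prediction_mean.loc[parents]
    order = np.argsort(-P.to_numpy(), axis=0)
    top1 = [parents[i] for i in order[0]]
    if len(parents) > 1:
        top2 = [parents[i] for i in order[1]]
        cross = [f"{a}x{b}" if a != b else "" for a, b in zip(top1, top2)]
        mid = [
            0.5 * (P.at[a, c] + P.at[b, c])
            for a, b, c in zip(top1, top2, P.columns)
        ]
    else:
        top2 = [""] * len(top1)
        cross = [""] * len(top1)
        mid = [np.nan] * len(top1)
    return pd.DataFrame(
        {"top1": top1, "top2": top2, "cross": cross, "midparent_value": mid},
        index=pd.Index(P.columns, name="bin_id"),
    )
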