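"""Canonical demo study: the full pipeline at its default synthetic scale.

One function runs the whole chain — simulate, engineer markers, fit the
reaction-norm ensemble, delineate zones, recommend genotypes, cross-validate
— at the package's demo conditions (about 500 grid bins, 40 trials, 60
phenotyped hybrids, 1000 trees, 50 ensemble runs) and returns the headline
numbers. The analysis scripts, the acceptance script and the end-to-end test
all drive this same code path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .eem import cluster_and_aggregate, fit_tree_bank, validate_eems
from .recommend import occupation_summary, parental_recommendation, recommend_genotypes
from .reem import ensemble_reem, stability_angles
from .simulate import SimConfig, simulate_dataset
from .validate import ability_surface, loo_trial_cv
from .zones import GeneticSurface, ward_zones, zone_summary


def run_demo_chain(
    seed: int = 1,
    n_trees: int = 1000,
    n_markers: int = 7,
    n_runs: int = 50,
    cv_models=("baseline", "reem"),
    cv_cfg: dict = None,
    sim: SimConfig = None,
    with_eem_validation: bool = False,
) -> dict:
    """Run the full demo pipeline and collect its headline quantities.

    Returns a dict with the intermediate objects (``bundle``, ``eset``,
    ``ensemble``, ``zones`` ...) and a flat ``metrics`` sub-dict of scalar
    results (per-model LOO predictive abilities, occupation of the top
    genotype, zone count, etc.).
    """
    rng = np.random.default_rng(seed)
    seeds = {name: int(s) for name, s in zip(
        ("sim", "bank", "ensemble", "zones", "cv"), rng.integers(0, 2**31 - 1, 5)
    )}
    bundle = simulate_dataset(sim or SimConfig(), seed=seeds["sim"])
    bank = fit_tree_bank(
        bundle.trial_covariates, bundle.phenotypes, n_trees=n_trees, seed=seeds["bank"]
    )
    eset = cluster_and_aggregate(bank, n_markers, bundle.covariates)
    ens = ensemble_reem(
        bundle.phenotypes, eset, bundle.kinship,
        bundle.trial_covariates, bundle.covariates,
        n_runs=n_runs, seed=seeds["ensemble"],
    )
    _, stability = stability_angles(ens.slope_draws, ens.genotype_ids)

    surface = GeneticSurface(Sigma=ens.Sigma_pooled, markers=eset.eem_values)
    zones = ward_zones(surface, ens.yield_potential(), n_zones=4, seed=seeds["zones"])
    zone_table = zone_summary(zones, ens.mean, bundle.trial_bins)

    winners = recommend_genotypes(
        ens.mean, ens.se, bundle.phenotypes, bundle.grid, n_runs=ens.n_runs
    )
    occupation = occupation_summary(
        winners, bundle.phenotypes, bundle.trial_bins, stability=stability
    )
    parents = parental_recommendation(ens.mean, bundle.pedigree)

    cv_cfg = dict(cv_cfg or {"n_trees": 200, "n_markers": n_markers, "n_runs": 5})
    reports = {}
    for model in cv_models:
        reports[model] = loo_trial_cv(model, bundle, cfg=cv_cfg, seed=seeds["cv"])

    metrics = {
        "n_bins": bundle.grid.n_bins,
        "n_trials": int(bundle.phenotypes["trial_id"].nunique()),
        "n_records": len(bundle.phenotypes),
        "ensemble_runs_kept": ens.n_runs,
        "top1_occupation_pct": float(occupation["occupation_pct"].iloc[0]),
        "n_zones": int(zones.n_zones),
        "zone_gain_abs_max": float(zone_table["gain_abs"].max()),
    }
    for model, rep in reports.items():
        s = rep.summary()
        metrics[f"loo_pearson_{model}"] = float(s["pearson_mean"])
        metrics[f"loo_spearman_{model}"] = float(s["spearman_mean"])
        metrics[f"loo_rmse_{model}"] = float(s["rmse_mean"])

    out = {
        "bundle": bundle,
        "eset": eset,
        "ensemble": ens,
        "stability": stability,
        "zones": zones,
        "zone_table": zone_table,
        "winners": winners,
        "occupation": occupation,
        "parents": parents,
        "cv_reports": reports,
        "metrics": metrics,
    }
    if with_eem_validation:
        v = validate_eems(
            bundle.trial_covariates, bundle.phenotypes, bank=bank,
            loo_n_trees=150, seed=seeds["bank"],
        )
        metrics["eem_fit_correlation"] = float(v["fit_correlation"])
        metrics["eem_loo_correlation"] = float(v["loo_correlation"])
    if "reem" in reports:
        surf, vario, _ = ability_surface(reports["reem"], bundle)
        out["ability_surface"] = surf
        metrics["kriged_ability_mean"] = float(surf.mean())
    return out
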