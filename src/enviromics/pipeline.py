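"""Pipeline stages over a run directory.

Each stage reads its inputs from (and writes its outputs to) one run
directory, so the chain ``simulate -> eem -> fit -> predict -> zones ->
recommend -> validate`` can be driven from the CLI, from the analysis
scripts, or from tests. Every stage is deterministic given the resolved
configuration (which includes the seed) stored in the run directory.
"""

from __future__ import annotations

import pickle
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .config import RunConfig
from .eem import cluster_and_aggregate, fit_tree_bank, validate_eems
from .grid import LocalProjection, PredictionGrid
from .kinship import additive_relationship, psd_repair
from .recommend import occupation_summary, parental_recommendation, recommend_genotypes
from .reem import ensemble_reem, stability_angles
from .simulate import DataBundle, SimConfig, simulate_dataset
from .validate import ability_surface, leave_region_out_cv, loo_trial_cv
from .zones import GeneticSurface, variance_gradient_profile, ward_zones, zone_summary


class MissingInputError(FileNotFoundError):
    """A stage was invoked before the stage that produces its inputs."""


def _need(run_dir: Path, name: str, producer: str) -> Path:
    path = Path(run_dir) / name
    if not path.exists():
        raise MissingInputError(
            f"missing {name!r} in {run_dir} — run the '{producer}' stage first"
        )
    return path


def stage_simulate(run_dir, config: RunConfig = None, sim: SimConfig = None) -> DataBundle:
    """Generate a synthetic study and write every pipeline input table."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig()
    sim = sim or SimConfig()
    bundle = simulate_dataset(sim, seed=config.seed)

    io.write_phenotypes(bundle.phenotypes, run_dir / "phenotypes.csv")
    io.write_pedigree(bundle.pedigree, run_dir / "pedigree.csv")
    io.write_covariates(bundle.covariates, run_dir / "covariates_grid.csv")
    io.write_covariates(bundle.trial_covariates, run_dir / "covariates_trials.csv")
    bundle.grid.bins.to_csv(run_dir / "grid.csv", index=False)
    with open(run_dir / "grid_meta.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "cell_size_km": bundle.grid.cell_size_km,
                "buffer_km": bundle.grid.buffer_km,
                "lat0": bundle.grid.projection.lat0,
                "lon0": bundle.grid.projection.lon0,
                **bundle.grid.meta,
            },
            fh,
        )
    bundle.trial_bins.rename_axis("trial_id").to_csv(run_dir / "trial_bins.csv")
    bundle.truth.U_true.to_csv(run_dir / "truth.csv")
    config.to_yaml(run_dir / "config.yaml")
    with open(run_dir / "sim_meta.yaml", "w") as fh:
        yaml.safe_dump(asdict(sim), fh, sort_keys=False)
    return bundle


def load_bundle(run_dir) -> DataBundle:
    """Reassemble the data bundle a run directory describes (truth omitted)."""
    run_dir = Path(run_dir)
    phen = io.read_phenotypes(_need(run_dir, "phenotypes.csv", "simulate"))
    ped = io.read_pedigree(_need(run_dir, "pedigree.csv", "simulate"))
    cov = io.read_covariates(_need(run_dir, "covariates_grid.csv", "simulate"))
    bins = pd.read_csv(_need(run_dir, "grid.csv", "simulate"), dtype={"bin_id": str})
    with open(_need(run_dir, "grid_meta.yaml", "simulate")) as fh:
        gm = yaml.safe_load(fh)
    grid = PredictionGrid(
        bins=bins,
        cell_size_km=gm["cell_size_km"],
        buffer_km=gm["buffer_km"],
        projection=LocalProjection(lat0=gm["lat0"], lon0=gm["lon0"]),
        meta={k: v for k, v in gm.items() if k not in ("cell_size_km", "buffer_km", "lat0", "lon0")},
    )
    tb = pd.read_csv(_need(run_dir, "trial_bins.csv", "simulate"), index_col="trial_id")["bin_id"]
    kin = psd_repair(additive_relationship(ped))
    return DataBundle(
        grid=grid, covariates=cov, pedigree=ped, kinship=kin,
        phenotypes=phen, trial_bins=tb, truth=None,
    )


def load_config(run_dir) -> RunConfig:
    return RunConfig.from_yaml(_need(Path(run_dir), "config.yaml", "simulate"))


def stage_eem(run_dir, config: RunConfig = None, validate: bool = False):
    """Engineer the enviromic markers; write marker tables and the bank."""
    run_dir = Path(run_dir)
    config = config or load_config(run_dir)
    bundle = load_bundle(run_dir)
    bank = fit_tree_bank(
        bundle.trial_covariates,
        bundle.phenotypes,
        n_trees=config.n_trees,
        subsample_fraction=config.genotype_subsample_fraction,
        min_samples_leaf=config.min_samples_leaf,
        seed=config.seed,
    )
    eset = cluster_and_aggregate(bank, config.n_markers, bundle.covariates)
    eset.eem_values.to_csv(run_dir / "eem_values.csv")
    eset.values_at(bundle.trial_covariates).set_axis(
        pd.Index(bundle.trial_covariates["location_id"], name="trial_id")
    ).to_csv(run_dir / "eem_trials.csv")
    eset.wide_gradient.to_csv(run_dir / "wide_gradient.csv")
    eset.importance_tally.to_csv(run_dir / "importance_tally.csv")
    eset.source_shares.to_csv(run_dir / "source_shares.csv")
    with open(run_dir / "eem_bank.pkl", "wb") as fh:
        pickle.dump(eset, fh)
    if validate:
        v = validate_eems(
            bundle.trial_covariates, bundle.phenotypes,
            loo_n_trees=config.loo_n_trees, seed=config.seed,
        )
        pd.Series(
            {"fit_correlation": v["fit_correlation"], "loo_correlation": v["loo_correlation"]}
        ).to_csv(run_dir / "eem_validation.csv")
    return eset


def load_eem(run_dir):
    with open(_need(Path(run_dir), "eem_bank.pkl", "eem"), "rb") as fh:
        return pickle.load(fh)


def stage_fit(run_dir, config: RunConfig = None):
    """Run the reaction-norm ensemble; write fit summaries and surfaces."""
    run_dir = Path(run_dir)
    config = config or load_config(run_dir)
    bundle = load_bundle(run_dir)
    eset = load_eem(run_dir)
    ens = ensemble_reem(
        bundle.phenotypes, eset, bundle.kinship,
        bundle.trial_covariates, bundle.covariates,
        n_runs=config.n_runs, seed=config.seed,
        structure=None if config.sigma_structure == "unstructured" else config.sigma_structure,
        max_iter=config.max_reml_iter, tol=config.reml_tol,
        run_mode=config.ensemble_run_mode,
    )
    ens.fit_summary.to_csv(run_dir / "fit_summary.csv", index=False)
    pd.DataFrame(ens.Sigma_pooled).to_csv(run_dir / "sigma_pooled.csv", index=False)
    _, stab = stability_angles(ens.slope_draws, ens.genotype_ids)
    stab.to_csv(run_dir / "stability.csv")
    with open(run_dir / "ensemble.pkl", "wb") as fh:
        pickle.dump(ens, fh)
    return ens


def load_ensemble(run_dir):
    with open(_need(Path(run_dir), "ensemble.pkl", "fit"), "rb") as fh:
        return pickle.load(fh)


def stage_predict(run_dir, config: RunConfig = None):
    """Write the genotype x bin prediction table and the yield-potential map."""
    run_dir = Path(run_dir)
    bundle = load_bundle(run_dir)
    ens = load_ensemble(run_dir)
    long = (
        ens.mean.stack().rename("mean").to_frame()
        .join(ens.se.stack().rename("se"))
        .reset_index()
    )
    long.to_csv(run_dir / "predictions.csv", index=False)
    io.write_grid_layer(bundle.grid, ens.yield_potential().to_numpy(), run_dir / "yield_potential.csv")
    return long


def stage_zones(run_dir, config: RunConfig = None):
    """Delineate breeding zones and write zone maps and summaries."""
    run_dir = Path(run_dir)
    config = config or load_config(run_dir)
    bundle = load_bundle(run_dir)
    ens = load_ensemble(run_dir)
    eset = load_eem(run_dir)
    surface = GeneticSurface(Sigma=ens.Sigma_pooled, markers=eset.eem_values)
    zones = ward_zones(
        surface, ens.yield_potential(),
        n_zones=config.n_zones, subsample=config.zone_subsample_bins, seed=config.seed,
    )
    zones.zone_of_bin.to_csv(run_dir / "zones.csv")
    table = zone_summary(zones, ens.mean, bundle.trial_bins)
    table.to_csv(run_dir / "zone_table.csv")
    profile = variance_gradient_profile(surface, eset.wide_gradient)
    profile.to_csv(run_dir / "variance_profile.csv")
    zones.within_between.to_csv(run_dir / "zone_correlations.csv")
    return zones, table


def stage_recommend(run_dir, config: RunConfig = None):
    """Write per-bin winners, occupation table and parental recommendations."""
    run_dir = Path(run_dir)
    config = config or load_config(run_dir)
    bundle = load_bundle(run_dir)
    ens = load_ensemble(run_dir)
    winners = recommend_genotypes(
        ens.mean, ens.se, bundle.phenotypes, bundle.grid,
        n_runs=ens.n_runs, alpha=config.alpha,
        mode=config.representativeness, k_nearest=config.k_nearest,
    )
    winners.to_csv(run_dir / "winners.csv")
    stab = pd.read_csv(_need(run_dir, "stability.csv", "fit"), index_col="genotype_id")
    occ = occupation_summary(winners, bundle.phenotypes, bundle.trial_bins, stability=stab)
    occ.to_csv(run_dir / "occupation.csv")
    parents = parental_recommendation(ens.mean, bundle.pedigree)
    parents.to_csv(run_dir / "parents_top.csv")
    return winners, occ, parents


def stage_validate(run_dir, config: RunConfig = None, models=("baseline", "kernel", "reem"),
                   schemes=("loo", "region")):
    """Cross-validate the requested models; write the per-trial CV report."""
    run_dir = Path(run_dir)
    config = config or load_config(run_dir)
    bundle = load_bundle(run_dir)
    cfg = {
        "n_trees": config.cv_n_trees,
        "n_markers": config.n_markers,
        "n_runs": config.cv_n_runs,
        "refit_bank": config.cv_refit_bank,
        "min_samples_leaf": config.min_samples_leaf,
    }
    rows = []
    loo_reports = {}
    for model in models:
        if "loo" in schemes:
            rep = loo_trial_cv(model, bundle, cfg=cfg, seed=config.seed)
            loo_reports[model] = rep
            for _, r in rep.per_trial.iterrows():
                rows.append({"scheme": "loo", "model": model, **r.to_dict()})
        if "region" in schemes:
            per_region, overall = leave_region_out_cv(model, bundle, cfg=cfg, seed=config.seed)
            for reports in (*per_region.values(), overall):
                for _, r in reports.per_trial.iterrows():
                    rows.append({"scheme": reports.scheme, "model": model, **r.to_dict()})
    report = pd.DataFrame(rows)
    report.to_csv(run_dir / "cv_report.csv", index=False)

    if "reem" in loo_reports:
        surf, vario, _ = ability_surface(loo_reports["reem"], bundle)
        surf.to_csv(run_dir / "ability_surface.csv")
        pd.Series(
            {"nugget": vario.nugget, "partial_sill": vario.partial_sill, "range_km": vario.range_}
        ).to_csv(run_dir / "variogram.csv")
    summary = (
        report.groupby(["scheme", "model"])[["pearson", "spearman", "rmse"]]
        .agg(["mean", "std"])
    )
    summary.to_csv(run_dir / "cv_summary.csv")
    return report, summary
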