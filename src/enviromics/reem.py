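"""Reaction-norm random-regression model over engineered enviromic markers.

One model run fits ``y = Xb + Zu + e`` where X carries one intercept per
year, each genotype's random effect is an intercept plus K reaction-norm
slopes on the markers, and ``u ~ N(0, Sigma (x) A)`` ties genotypes through
the pedigree relationship matrix A. The ensemble repeats the fit ``n_runs``
times, each run sampling one tree-predictor per marker cluster as its K
gradients, and averages the genotype x bin prediction surfaces; run-to-run
dispersion gives the prediction standard errors used by the recommendation
stage, and the pooled slope draws give the stability angles.

The baseline comparator (irrigation fixed; genotype random via A; no
covariates) and the kernel comparator (genotype, environment and interaction
kernels built from the same markers) share the REML machinery in
:mod:`enviromics.lmm`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LinkageError
from .kinship import KinshipMatrix, psd_repair
from .lmm import ReemFit, fit_reml_components, fit_reml_kron, solve_mme_kron


@dataclass
class Design:
    y: np.ndarray
    X: np.ndarray
    M: np.ndarray            # (n, K+1) with leading 1s column
    geno_idx: np.ndarray
    fixed_names: list
    marker_names: list


def assemble_design(
    phenotypes: pd.DataFrame, markers_at_trials: pd.DataFrame, kin: KinshipMatrix
) -> Design:
    """Build y, the year design X and the per-record marker covariables.

    ``markers_at_trials`` is indexed by trial_id with one column per marker
    (K = 0 markers reduces the model to classic pedigree BLUP). Every
    phenotyped genotype must appear in ``kin``; every trial must have marker
    values.
    """
    missing_t = set(phenotypes["trial_id"]) - set(markers_at_trials.index)
    if missing_t:
        raise LinkageError(f"trial(s) missing from marker table: {sorted(missing_t)[:3]}")
    missing_g = set(phenotypes["genotype_id"]) - set(kin.ids)
    if missing_g:
        raise LinkageError(f"genotype(s) missing from kinship: {sorted(missing_g)[:3]}")

    y = phenotypes["yield_blue"].to_numpy(dtype=float)
    years = sorted(phenotypes["year"].unique())
    X = np.column_stack([(phenotypes["year"] == yr).to_numpy(float) for yr in years])
    eps = markers_at_trials.loc[phenotypes["trial_id"]].to_numpy(dtype=float)
    M = np.column_stack([np.ones(len(y)), eps])
    geno_idx = kin.index_of(phenotypes["genotype_id"])
    return Design(
        y=y,
        X=X,
        M=M,
        geno_idx=geno_idx,
        fixed_names=[f"year_{yr}" for yr in years],
        marker_names=list(markers_at_trials.columns),
    )


def fit_reem(
    phenotypes: pd.DataFrame,
    markers_at_trials: pd.DataFrame,
    kin: KinshipMatrix,
    structure: str = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    init_Sigma=None,
    init_sigma_e2=None,
) -> ReemFit:
    """REML fit of the reaction-norm model for one marker set.

    ``structure=None`` selects unstructured Sigma, falling back to a diagonal
    Sigma when the phenotyped-genotype count is below 5(K+1) (too few
    genotypes to support a full covariance).
    """
    d = assemble_design(phenotypes, markers_at_trials, kin)
    r = d.M.shape[1]
    n_pheno = phenotypes["genotype_id"].nunique()
    if structure is None:
        structure = "unstructured" if n_pheno >= 5 * r else "diagonal"
        if structure == "diagonal":
            warnings.warn(
                f"{n_pheno} phenotyped genotypes < 5 x {r}; using diagonal Sigma"
            )
    fit = fit_reml_kron(
        d.y, d.X, d.M, d.geno_idx, kin.values,
        structure=structure, max_iter=max_iter, tol=tol,
        init_Sigma=init_Sigma, init_sigma_e2=init_sigma_e2,
        fixed_names=d.fixed_names, genotype_ids=kin.ids,
    )
    fit.markers_used = d.marker_names
    return fit


def solve_reem_fixed(phenotypes, markers_at_trials, kin, Sigma, sigma_e2):
    """BLUE/BLUP at fixed (Sigma, sigma_e2) — no variance estimation."""
    d = assemble_design(phenotypes, markers_at_trials, kin)
    return solve_mme_kron(d.y, d.X, d.M, d.geno_idx, kin.values, Sigma, sigma_e2)


def predict_bins(
    fit: ReemFit, markers_at_bins: pd.DataFrame, year_policy: str = "mean"
) -> pd.DataFrame:
    """Genotype x bin predicted yields from one fit.

    ``yhat(g, bin) = b_bar + u0_g + sum_k u_kg eps_k(bin)`` with ``b_bar``
    the mean fitted year intercept (``year_policy="mean"``) or a named year.
    """
    if year_policy == "mean":
        b_bar = float(np.mean(fit.b))
    else:
        try:
            b_bar = float(fit.b[fit.fixed_names.index(str(year_policy))])
        except ValueError as e:
            raise KeyError(f"unknown year policy {year_policy!r}") from e
    E = markers_at_bins.to_numpy(dtype=float)        # bins x K
    surf = b_bar + fit.U[:, [0]] + fit.U[:, 1:] @ E.T  # genotypes x bins
    return pd.DataFrame(surf, index=pd.Index(fit.genotype_ids, name="genotype_id"),
                        columns=markers_at_bins.index)


@dataclass
class EnsemblePrediction:
    """Averaged genotype x bin surfaces over the ensemble runs."""

    genotype_ids: list
    bin_ids: list
    mean: pd.DataFrame            # genotypes x bins
    se: pd.DataFrame              # run-to-run standard error of the mean
    Sigma_pooled: np.ndarray
    sigma_e2_pooled: float
    slope_draws: np.ndarray       # (runs, genotypes, K)
    run_markers: list             # per run: sampled tree indices
    fit_summary: pd.DataFrame
    n_runs: int
    year_mean: float

    def yield_potential(self) -> pd.Series:
        """Per-bin mean prediction over genotypes (the 'yield potential' map)."""
        return self.mean.mean(axis=0).rename("yield_potential")


def ensemble_reem(
    phenotypes: pd.DataFrame,
    eset,
    kin: KinshipMatrix,
    trial_covariates: pd.DataFrame,
    grid_covariates: pd.DataFrame,
    n_runs: int = 1000,
    seed: int = 0,
    structure: str = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    max_dropped_fraction: float = 0.2,
    run_mode: str = "per_cluster",
) -> EnsemblePrediction:
    """Run the reaction-norm ensemble over sampled tree-gradients.

    ``run_mode="per_cluster"`` (default) draws one tree-predictor from every
    marker cluster per run, so each run regresses on K gradients;
    ``run_mode="single_marker"`` draws one cluster (then one of its trees)
    per run, so each run carries a single reaction norm. Gradients are
    standardized on the grid reference; fits are warm-started from the
    previous run. Non-converged runs are dropped; more than
    ``max_dropped_fraction`` dropped is an error.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if run_mode not in ("per_cluster", "single_marker"):
        raise ValueError(f"unknown run_mode {run_mode!r}")
    rng = np.random.default_rng(seed)
    K = eset.n_markers
    clusters = [np.flatnonzero(eset.cluster_of_tree == k + 1) for k in range(K)]
    trial_ids = trial_covariates["location_id"].to_numpy()
    bin_ids = list(grid_covariates["location_id"])
    G = kin.n
    r_dim = (K + 1) if run_mode == "per_cluster" else 2

    sum_surf = np.zeros((G, len(bin_ids)))
    sumsq_surf = np.zeros_like(sum_surf)
    slope_draws = []
    run_markers = []
    rows = []
    Sig_sum = np.zeros((r_dim, r_dim))
    se2_sum = 0.0
    year_means = []
    init_S, init_e = None, None
    kept = 0
    for run in range(n_runs):
        if run_mode == "per_cluster":
            tree_idx = np.array([c[rng.integers(len(c))] for c in clusters])
        else:
            c = clusters[rng.integers(K)]
            tree_idx = np.array([c[rng.integers(len(c))]])
        Mt = eset.sampled_tree_markers(trial_covariates, tree_idx)
        Mg = eset.sampled_tree_markers(grid_covariates, tree_idx)
        mk = [f"tree_{t}" for t in tree_idx]
        m_trials = pd.DataFrame(Mt, index=pd.Index(trial_ids, name="trial_id"), columns=mk)
        m_bins = pd.DataFrame(Mg, index=pd.Index(bin_ids, name="bin_id"), columns=mk)
        fit = fit_reem(
            phenotypes, m_trials, kin, structure=structure,
            max_iter=max_iter, tol=tol, init_Sigma=init_S, init_sigma_e2=init_e,
        )
        init_S, init_e = fit.Sigma, fit.sigma_e2
        rows.append(
            {
                "run": run,
                "converged": fit.converged,
                "n_iter": fit.n_iter,
                "loglik": fit.loglik_reml,
                "sigma_e2": fit.sigma_e2,
                **{f"sigma_{i}{j}": fit.Sigma[i, j] for i in range(r_dim) for j in range(i, r_dim)},
            }
        )
        if not fit.converged:
            continue
        kept += 1
        surf = predict_bins(fit, m_bins).to_numpy()
        sum_surf += surf
        sumsq_surf += surf**2
        slope_draws.append(fit.U[:, 1:].copy())
        run_markers.append(tree_idx)
        Sig_sum += fit.Sigma
        se2_sum += fit.sigma_e2
        year_means.append(float(np.mean(fit.b)))

    if kept < (1.0 - max_dropped_fraction) * n_runs or kept == 0:
        raise RuntimeError(f"only {kept}/{n_runs} ensemble runs converged")
    mean = sum_surf / kept
    if kept > 1:
        var_runs = np.clip(sumsq_surf / kept - mean**2, 0.0, None) * kept / (kept - 1)
        se = np.sqrt(var_runs / kept)
    else:
        se = np.zeros_like(mean)
    gidx = pd.Index(kin.ids, name="genotype_id")
    bidx = pd.Index(bin_ids, name="bin_id")
    return EnsemblePrediction(
        genotype_ids=list(kin.ids),
        bin_ids=bin_ids,
        mean=pd.DataFrame(mean, index=gidx, columns=bidx),
        se=pd.DataFrame(se, index=gidx, columns=bidx),
        Sigma_pooled=Sig_sum / kept,
        sigma_e2_pooled=se2_sum / kept,
        slope_draws=np.array(slope_draws),
        run_markers=run_markers,
        fit_summary=pd.DataFrame(rows),
        n_runs=kept,
        year_mean=float(np.mean(year_means)),
    )


def stability_angles(slope_draws: np.ndarray, genotype_ids) -> tuple[np.ndarray, pd.DataFrame]:
    """Reaction-norm slopes as angular degrees, with per-genotype summary.

    ``angle = arctan(slope)`` in degrees: 0 is a perfectly stable genotype,
    +/-45 a strongly reactive one (negative angles mean yield decreases along
    a positive gradient). The summary pools every sampled marker of every
    run, mirroring a min/max/mean adaptability-stability table.
    """
    draws = np.asarray(slope_draws, dtype=float)
    angles = np.degrees(np.arctan(draws))
    flat = angles.reshape(-1, angles.shape[1], angles.shape[2]) if angles.ndim == 3 else angles[None]
    per_geno = flat.transpose(1, 0, 2).reshape(flat.shape[1], -1)
    summary = pd.DataFrame(
        {
            "angle_min": per_geno.min(axis=1),
            "angle_max": per_geno.max(axis=1),
            "angle_mean": per_geno.mean(axis=1),
        },
        index=pd.Index(genotype_ids, name="genotype_id"),
    )
    return angles, summary


# ---------------------------------------------------------------------------
# comparator models


@dataclass
class BaselineFit:
    """Irrigation (fixed) + pedigree genotype main effect; no covariates.

    With one record per (trial, genotype) cell the iid trial x genotype
    interaction is confounded with the residual and is dropped (reported 0).
    """

    b: np.ndarray
    fixed_names: list
    genotype_blup: pd.Series
    variances: dict
    sigma_e2: float
    converged: bool
    has_irrigation: bool

    def predict(self, genotype_ids, irrigated) -> np.ndarray:
        g = self.genotype_blup.reindex(genotype_ids).fillna(0.0).to_numpy()
        mu = self.b[0] + (self.b[1] * np.asarray(irrigated, dtype=float) if self.has_irrigation else 0.0)
        return mu + g


def baseline_gxe_fit(phenotypes: pd.DataFrame, kin: KinshipMatrix, max_iter: int = 1000) -> BaselineFit:
    y = phenotypes["yield_blue"].to_numpy(dtype=float)
    irr = phenotypes["irrigated"].to_numpy(dtype=bool)
    has_irr = 0 < irr.sum() < len(irr)
    if not has_irr:
        warnings.warn("single irrigation level; dropping the irrigation effect")
    X = np.column_stack([np.ones(len(y))] + ([irr.astype(float)] if has_irr else []))

    La = np.linalg.cholesky(psd_repair(kin).values)
    geno_idx = kin.index_of(phenotypes["genotype_id"])
    Zg = np.zeros((len(y), kin.n))
    Zg[np.arange(len(y)), geno_idx] = 1.0
    factors = {"genotype": Zg @ La}

    cells = phenotypes.groupby(["trial_id", "genotype_id"]).size()
    if (cells > 1).any():
        combos = phenotypes["trial_id"].astype(str) + "|" + phenotypes["genotype_id"].astype(str)
        codes, _ = pd.factorize(combos)
        Zge = np.zeros((len(y), codes.max() + 1))
        Zge[np.arange(len(y)), codes] = 1.0
        factors["gxe"] = Zge
    else:
        warnings.warn(
            "one record per (trial, genotype): the iid G x E interaction is "
            "confounded with the residual and is dropped (variance reported 0)"
        )
    fit = fit_reml_components(y, X, factors, max_iter=max_iter)
    g_blup = pd.Series(La @ fit.blups["genotype"], index=pd.Index(kin.ids, name="genotype_id"))
    variances = {
        "genotype": fit.variances["genotype"],
        "gxe": fit.variances.get("gxe", 0.0),
    }
    return BaselineFit(
        b=fit.b,
        fixed_names=["intercept"] + (["irrigated"] if has_irr else []),
        genotype_blup=g_blup,
        variances=variances,
        sigma_e2=fit.sigma_e2,
        converged=fit.converged,
        has_irrigation=has_irr,
    )


@dataclass
class KernelFit:
    """Genotype (A), environment (marker kernel) and interaction components."""

    b: np.ndarray
    variances: dict
    sigma_e2: float
    converged: bool
    kin: KinshipMatrix
    La: np.ndarray
    marker_scale: float           # 1/sqrt(mean diagonal) of the env kernel
    u_geno: np.ndarray
    u_env: np.ndarray
    u_int: np.ndarray

    def predict(self, genotype_ids, markers: pd.DataFrame) -> np.ndarray:
        """Predict records given genotype ids and their locations' markers."""
        gi = self.kin.index_of(genotype_ids)
        S = self.La[gi]                                   # n x G
        F = markers.to_numpy(dtype=float) * self.marker_scale
        T = S[:, :, None] * F[:, None, :]
        T = T.reshape(len(gi), -1)
        return self.b[0] + S @ self.u_geno + F @ self.u_env + T @ self.u_int


def kernel_gxe_fit(
    phenotypes: pd.DataFrame,
    markers_at_trials: pd.DataFrame,
    kin: KinshipMatrix,
    max_iter: int = 1000,
) -> KernelFit:
    """Kernel comparator built from the same markers as the reaction-norm model.

    The environment kernel is the linear kernel of the standardized marker
    vectors scaled to unit mean diagonal; the interaction kernel is the
    elementwise product of the genotype and environment covariances. All
    three enter REML through their factor matrices.
    """
    y = phenotypes["yield_blue"].to_numpy(dtype=float)
    X = np.ones((len(y), 1))
    E_trials = markers_at_trials.loc[phenotypes["trial_id"]].to_numpy(dtype=float)
    mean_diag = float(np.mean(np.sum(markers_at_trials.to_numpy(dtype=float) ** 2, axis=1)))
    if mean_diag <= 0:
        scale = 1.0
        warnings.warn("all marker vectors are zero; environment kernel is degenerate")
    else:
        scale = 1.0 / np.sqrt(mean_diag)
    F = E_trials * scale

    La = np.linalg.cholesky(psd_repair(kin).values)
    gi = kin.index_of(phenotypes["genotype_id"])
    S = La[gi]
    T = (S[:, :, None] * F[:, None, :]).reshape(len(y), -1)
    fit = fit_reml_components(y, X, {"genotype": S, "environment": F, "gxe": T}, max_iter=max_iter)
    return KernelFit(
        b=fit.b,
        variances={k: fit.variances[k] for k in ("genotype", "environment", "gxe")},
        sigma_e2=fit.sigma_e2,
        converged=fit.converged,
        kin=kin,
        La=La,
        marker_scale=scale,
        u_geno=fit.blups["genotype"],
        u_env=fit.blups["environment"],
        u_int=fit.blups["gxe"],
    )
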