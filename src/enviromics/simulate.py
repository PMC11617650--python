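"""Synthetic trial networks with the statistical structure the pipeline assumes.

The generator emulates, at configurable scale, the kind of data the method
targets: a geographic grid of bins carrying smooth, mutually collinear
environmental covariate fields; a pedigree of founder lines crossed into
hybrids (plus "competitor" hybrids of unknown parentage); genotype intercepts
and reaction-norm slopes drawn from ``N(0, Sigma (x) A)``; year and
irrigation effects; and unbalanced trial placement. The true environmental
gradients are saturating (tanh) transforms of linear combinations of a few
causal covariate fields, so a nonparametric tree ensemble can recover them
while no single raw covariate equals them.

Every function is deterministic given its seed; the same seed reproduces the
same tables byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import PredictionGrid, build_prediction_grid
from .io import UNKNOWN_PARENT, validate_phenotypes
from .kinship import KinshipMatrix, additive_relationship, psd_repair

_SOURCES = ("sat", "clim", "soil", "wx")


class ConfigError(ValueError):
    pass


@dataclass
class SimulationTruth:
    """Generative ground truth kept for oracle checks in tests."""

    Sigma_true: np.ndarray          # (K_true+1) x (K_true+1), intercept first
    U_true: pd.DataFrame            # genotype x (intercept, slope_1..K_true)
    mean_slopes: np.ndarray         # average reaction norm (environment main effect)
    year_effects: dict              # year -> fixed offset
    irrigation_effect: float
    sigma_e: float
    causal_covariates: list
    gradients: pd.DataFrame         # bin_id-indexed true gradients (standardized)
    A_true: KinshipMatrix = None

    def env_mean(self, bin_ids) -> np.ndarray:
        """True environment mean (genotype-average, year-free) per bin."""
        g = self.gradients.loc[list(bin_ids)].to_numpy()
        return g @ self.mean_slopes

    def to_csv(self, path) -> None:
        self.U_true.to_csv(path)


@dataclass
class SimConfig:
    """Demo-scale study conditions (full pipeline runs in minutes)."""

    # study area: ~500 bins
    area_deg: float = 2.2
    cell_size_km: float = 10.0
    buffer_km: float = 20.0
    n_area_points: int = 40  # dense enough that the hull (hence bin count) is stable across seeds
    # covariates
    n_causal: int = 3
    n_noise: int = 20
    n_collinear_per_causal: int = 3
    range_km: float = 60.0
    # census
    n_parents: int = 20
    n_hybrids: int = 60
    competitor_fraction: float = 0.1
    # genetics: K_true gradients with substantial slope variance (strong G x E,
    # rank switching along the gradients)
    k_true: int = 2
    intercept_var: float = 1.0
    slope_var: float = 0.64
    intercept_slope_corr: float = -0.2
    mean_slope: float = 0.8
    # trials
    n_trials: int = 40
    genotypes_per_trial: int = 15
    years: tuple = (2019, 2020, 2021)
    year_sd: float = 0.3
    irrigated_fraction: float = 0.25
    irrigation_effect: float = 0.2
    sigma_e: float = 0.5
    placement_bias: float = 0.0   # >0 biases trials toward favourable bins

    @property
    def sigma_true(self) -> np.ndarray:
        r = self.k_true + 1
        S = np.eye(r) * self.slope_var
        S[0, 0] = self.intercept_var
        c = self.intercept_slope_corr * np.sqrt(self.intercept_var * self.slope_var)
        S[0, 1:] = c
        S[1:, 0] = c
        return S


@dataclass
class DataBundle:
    """Everything one pipeline run consumes, plus the generative truth."""

    grid: PredictionGrid
    covariates: pd.DataFrame        # grid bins (location_id = bin_id)
    pedigree: pd.DataFrame
    kinship: KinshipMatrix
    phenotypes: pd.DataFrame
    trial_bins: pd.Series           # trial_id -> bin_id
    truth: SimulationTruth
    config: SimConfig = field(default_factory=SimConfig)

    @property
    def trial_covariates(self) -> pd.DataFrame:
        cov = self.covariates.set_index("location_id").loc[self.trial_bins.to_numpy()]
        cov = cov.reset_index(drop=True)
        cov.insert(0, "location_id", self.trial_bins.index.to_numpy())
        return cov

    @property
    def phenotyped_genotypes(self) -> list:
        return sorted(self.phenotypes["genotype_id"].unique())


def _standardize(v: np.ndarray) -> np.ndarray:
    s = v.std()
    return (v - v.mean()) / s if s > 0 else v - v.mean()


def _gaussian_field(xy: np.ndarray, range_km: float, rng) -> np.ndarray:
    """Low-rank Gaussian random field with correlation range ``range_km``."""
    n_anchor = 150
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    anchors = rng.uniform(lo, hi, size=(n_anchor, 2))
    d2 = ((xy[:, None, :] - anchors[None, :, :]) ** 2).sum(axis=2)
    basis = np.exp(-0.5 * d2 / range_km**2)
    return _standardize(basis @ rng.normal(size=n_anchor))


def simulate_covariate_fields(
    grid: PredictionGrid,
    n_causal: int = 3,
    n_noise: int = 20,
    n_collinear_per_causal: int = 3,
    range_km: float = 60.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list]:
    """Smooth, collinear covariate fields over the grid bins.

    Returns the covariate table (``location_id, lat, lon, <covariates>``) and
    the names of the causal columns. Collinear copies are their parent field
    plus independent noise targeting a pairwise correlation of about 0.9.
    """
    if grid.n_bins == 0:
        raise ConfigError("cannot simulate covariates on an empty grid")
    if min(n_causal, n_noise, n_collinear_per_causal) < 0 or range_km <= 0:
        raise ConfigError("covariate counts must be >= 0 and range_km > 0")
    rng = np.random.default_rng(seed)
    xy = grid.centroids_xy()
    cols: dict[str, np.ndarray] = {}
    causal: list[str] = []
    k = 0
    # noise sd for target r ~= 0.9 between a parent field and its copy
    s_collin = np.sqrt(1.0 / 0.9**2 - 1.0)
    for c in range(n_causal):
        f = _gaussian_field(xy, range_km, rng)
        name = f"{_SOURCES[k % 4]}_cv{k:03d}"
        cols[name] = f
        causal.append(name)
        k += 1
        for _ in range(n_collinear_per_causal):
            name = f"{_SOURCES[k % 4]}_cv{k:03d}"
            cols[name] = _standardize(f + s_collin * rng.normal(size=grid.n_bins))
            k += 1
    for _ in range(n_noise):
        name = f"{_SOURCES[k % 4]}_cv{k:03d}"
        cols[name] = _gaussian_field(xy, range_km, rng)
        k += 1
    out = grid.bins[["bin_id", "lat", "lon"]].rename(columns={"bin_id": "location_id"})
    return pd.concat([out.reset_index(drop=True), pd.DataFrame(cols)], axis=1), causal


def simulate_pedigree(
    n_parents: int,
    n_hybrids: int,
    seed: int = 0,
    competitor_fraction: float = 0.0,
) -> pd.DataFrame:
    """Founder parents plus hybrids from random two-parent crosses.

    A ``competitor_fraction`` of the hybrids get both parents unknown,
    mirroring competitor material of undisclosed parentage.
    """
    if n_parents < 2 and n_hybrids > 0:
        raise ConfigError("need at least 2 parents to make hybrids")
    rng = np.random.default_rng(seed)
    rows = [(f"P{i + 1:03d}", UNKNOWN_PARENT, UNKNOWN_PARENT) for i in range(n_parents)]
    n_comp = int(round(competitor_fraction * n_hybrids))
    for h in range(n_hybrids):
        hid = f"H{h + 1:03d}"
        if h >= n_hybrids - n_comp:
            rows.append((hid, UNKNOWN_PARENT, UNKNOWN_PARENT))
        else:
            dam, sire = rng.choice(n_parents, size=2, replace=False)
            rows.append((hid, f"P{dam + 1:03d}", f"P{sire + 1:03d}"))
    return pd.DataFrame(rows, columns=["genotype_id", "dam_id", "sire_id"])


def simulate_genetic_effects(
    kin: KinshipMatrix, Sigma_true: np.ndarray, seed: int = 0
) -> pd.DataFrame:
    """Draw per-genotype (intercept, slopes) from the matrix normal.

    Rows covary by ``A`` and columns by ``Sigma_true``; the draw uses the
    Cholesky factors ``U = L_A Z L_Sigma'`` with iid standard normal ``Z``.
    """
    Sigma_true = np.asarray(Sigma_true, dtype=float)
    r = Sigma_true.shape[0]
    if not np.allclose(Sigma_true, Sigma_true.T):
        raise ConfigError("Sigma_true must be symmetric")
    rng = np.random.default_rng(seed)
    if not Sigma_true.any():
        U = np.zeros((kin.n, r))
    else:
        w, V = np.linalg.eigh(Sigma_true)
        if w.min() < -1e-8 * max(w.max(), 1.0):
            raise ConfigError("Sigma_true is not positive semidefinite")
        Ls = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
        La = np.linalg.cholesky(psd_repair(kin).values)
        U = La @ rng.normal(size=(kin.n, r)) @ Ls.T
    cols = ["intercept"] + [f"slope_{k + 1}" for k in range(r - 1)]
    return pd.DataFrame(U, index=pd.Index(kin.ids, name="genotype_id"), columns=cols)


def _true_gradients(covariates: pd.DataFrame, causal: list, k_true: int, rng) -> pd.DataFrame:
    """Standardized saturating gradients from linear blends of causal fields."""
    C = covariates[causal].to_numpy()
    grads = {}
    for k in range(k_true):
        w = rng.normal(size=len(causal))
        w /= np.linalg.norm(w)
        raw = _standardize(C @ w)
        grads[f"gradient_{k + 1}"] = _standardize(np.tanh(1.2 * raw))
    return pd.DataFrame(grads, index=pd.Index(covariates["location_id"], name="bin_id"))


def simulate_trials_and_phenotypes(
    grid: PredictionGrid,
    covariates: pd.DataFrame,
    truth: SimulationTruth,
    n_trials: int,
    genotypes_per_trial: int,
    years,
    seed: int = 0,
    phenotyped_ids=None,
    irrigated_fraction: float = 0.25,
    placement_bias: float = 0.0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Place unbalanced trials on the grid and generate their BLUEs.

    phenotype = year effect + irrigation effect + (mean reaction norm +
    genotype slopes) . gradients(bin) + genotype intercept + N(0, sigma_e^2).

    Returns (phenotype table, trial -> bin map, per-trial true environment
    mean for oracle checks).
    """
    if n_trials > grid.n_bins:
        raise ConfigError("more trials than grid bins")
    ids = list(truth.U_true.index) if phenotyped_ids is None else list(phenotyped_ids)
    if genotypes_per_trial > len(ids):
        raise ConfigError("genotypes_per_trial exceeds the phenotyped census")
    rng = np.random.default_rng(seed)

    env = truth.env_mean(grid.bin_ids)
    if placement_bias > 0:
        w = np.exp(placement_bias * (env - env.max()))
        p = w / w.sum()
    else:
        p = None
    chosen = rng.choice(grid.n_bins, size=n_trials, replace=False, p=p)
    bins = grid.bins.iloc[chosen]

    # synthetic "states": quadrants of the study area
    medx, medy = np.median(grid.bins["x_km"]), np.median(grid.bins["y_km"])
    region = np.where(
        bins["y_km"] >= medy,
        np.where(bins["x_km"] >= medx, "NE", "NW"),
        np.where(bins["x_km"] >= medx, "SE", "SW"),
    )

    years = list(years)
    lo = max(2, int(np.floor(0.6 * genotypes_per_trial)))
    hi = min(len(ids), int(np.ceil(1.4 * genotypes_per_trial)))
    U = truth.U_true.loc[ids].to_numpy()
    grads = truth.gradients.loc[bins["bin_id"]].to_numpy()

    records = []
    trial_bin = {}
    env_means = {}
    for t in range(n_trials):
        tid = f"T{t + 1:03d}"
        trial_bin[tid] = bins["bin_id"].iloc[t]
        year = years[rng.integers(len(years))]
        irr = bool(rng.random() < irrigated_fraction)
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(ids), size=size, replace=False)
        g_effect = U[members, 0] + U[members, 1:] @ grads[t]
        mu_env = float(truth.mean_slopes @ grads[t])
        env_means[tid] = mu_env
        yvals = (
            truth.year_effects[year]
            + (truth.irrigation_effect if irr else 0.0)
            + mu_env
            + g_effect
            + rng.normal(0.0, truth.sigma_e, size)
        )
        for m, yv in zip(members, yvals):
            records.append(
                (
                    tid,
                    ids[m],
                    year,
                    irr,
                    region[t],
                    bins["lat"].iloc[t],
                    bins["lon"].iloc[t],
                    yv,
                )
            )
    phen = pd.DataFrame(
        records,
        columns=["trial_id", "genotype_id", "year", "irrigated", "region", "lat", "lon", "yield_blue"],
    )
    return (
        validate_phenotypes(phen),
        pd.Series(trial_bin, name="bin_id"),
        pd.Series(env_means, name="env_mean"),
    )


def simulate_dataset(cfg: SimConfig = None, seed: int = 1) -> DataBundle:
    """Generate one complete synthetic study under the default conditions."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=6)

    pts_rng = np.random.default_rng(seeds[0])
    pts = pts_rng.uniform(-cfg.area_deg / 2, cfg.area_deg / 2, size=(cfg.n_area_points, 2))
    pts = [(lat - 25.0, lon - 52.0) for lat, lon in pts]  # southern-Brazil-like box
    grid = build_prediction_grid(pts, cell_size_km=cfg.cell_size_km, buffer_km=cfg.buffer_km)

    covariates, causal = simulate_covariate_fields(
        grid,
        n_causal=cfg.n_causal,
        n_noise=cfg.n_noise,
        n_collinear_per_causal=cfg.n_collinear_per_causal,
        range_km=cfg.range_km,
        seed=int(seeds[1]),
    )
    pedigree = simulate_pedigree(
        cfg.n_parents, cfg.n_hybrids, seed=int(seeds[2]), competitor_fraction=cfg.competitor_fraction
    )
    kin = psd_repair(additive_relationship(pedigree))

    U = simulate_genetic_effects(kin, cfg.sigma_true, seed=int(seeds[3]))
    yr_rng = np.random.default_rng(seeds[4])
    year_effects = {y: float(yr_rng.normal(0.0, cfg.year_sd)) for y in cfg.years}
    gradients = _true_gradients(covariates, causal, cfg.k_true, yr_rng)
    truth = SimulationTruth(
        Sigma_true=cfg.sigma_true,
        U_true=U,
        mean_slopes=np.full(cfg.k_true, cfg.mean_slope),
        year_effects=year_effects,
        irrigation_effect=cfg.irrigation_effect,
        sigma_e=cfg.sigma_e,
        causal_covariates=causal,
        gradients=gradients,
        A_true=kin,
    )

    hybrids = [g for g in kin.ids if g.startswith("H")]
    phen, trial_bins, env_means = simulate_trials_and_phenotypes(
        grid,
        covariates,
        truth,
        n_trials=cfg.n_trials,
        genotypes_per_trial=cfg.genotypes_per_trial,
        years=cfg.years,
        seed=int(seeds[5]),
        phenotyped_ids=hybrids,
        irrigated_fraction=cfg.irrigated_fraction,
        placement_bias=cfg.placement_bias,
    )
    truth.gradients.attrs["env_means"] = env_means
    return DataBundle(
        grid=grid,
        covariates=covariates,
        pedigree=pedigree,
        kinship=kin,
        phenotypes=phen,
        trial_bins=trial_bins,
        truth=truth,
        config=cfg,
    )


def simulate_reference_census(seed: int = 1) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A phenotype + pedigree pair with the reference census shape.

    Synthetic stand-in for the real supplementary BLUE table (which is
    proprietary): 85 founder parents, 79 phenotyped hybrids, 183 unbalanced
    trials over 2017-2021 in four regions, 48 of them irrigated, and exactly
    12 400 yield records. Yield values are standard-normal draws; only the
    census structure is meaningful.
    """
    rng = np.random.default_rng(seed)
    ped = simulate_pedigree(85, 79, seed=seed, competitor_fraction=0.1)
    hybrids = [g for g in ped["genotype_id"] if g.startswith("H")]

    n_trials, total = 183, 12_400
    sizes = rng.integers(56, 80, size=n_trials)
    # adjust to the exact record total while staying within [2, 79]
    while sizes.sum() != total:
        i = int(rng.integers(n_trials))
        step = int(np.sign(total - sizes.sum()))
        if 2 <= sizes[i] + step <= len(hybrids):
            sizes[i] += step

    irrigated = np.zeros(n_trials, dtype=bool)
    irrigated[rng.choice(n_trials, size=48, replace=False)] = True
    regions = np.array(["SP", "PR", "SC", "RS"])[rng.integers(0, 4, n_trials)]
    years = rng.integers(2017, 2022, n_trials)
    lat = rng.uniform(-30.0, -21.0, n_trials)
    lon = rng.uniform(-55.0, -47.0, n_trials)

    records = []
    for t in range(n_trials):
        members = rng.choice(hybrids, size=sizes[t], replace=False)
        for g in members:
            records.append(
                (f"T{t + 1:03d}", g, years[t], irrigated[t], regions[t], lat[t], lon[t], rng.normal())
            )
    phen = pd.DataFrame(
        records,
        columns=["trial_id", "genotype_id", "year", "irrigated", "region", "lat", "lon", "yield_blue"],
    )
    return validate_phenotypes(phen), ped
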