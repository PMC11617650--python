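"""Breeding zones: genetic variance/correlation surfaces and Ward clustering.

With marker vector ``z(bin) = (1, eps_1..eps_K)'`` and genetic covariance
``Sigma`` of (intercept, slopes), the additive genetic variance at a bin is
``z' Sigma z`` and the genetic covariance between two bins is
``z_i' Sigma z_j``; the implied correlation matrix over bins is fed (on a
subsample) to Ward clustering to delineate zones within which genotype
rankings are consistent. The full bin-by-bin matrix is never materialised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


class ZoneError(ValueError):
    pass


@dataclass
class GeneticSurface:
    """Lazy evaluator of genetic variance / correlation over grid bins."""

    Sigma: np.ndarray
    markers: pd.DataFrame          # bins x K (standardized marker values)

    def _z(self, bin_ids=None) -> np.ndarray:
        E = self.markers if bin_ids is None else self.markers.loc[list(bin_ids)]
        E = E.to_numpy(dtype=float)
        return np.column_stack([np.ones(len(E)), E])

    def variance(self, bin_ids=None) -> pd.Series:
        z = self._z(bin_ids)
        v = np.einsum("ij,jk,ik->i", z, self.Sigma, z)
        idx = self.markers.index if bin_ids is None else pd.Index(bin_ids)
        return pd.Series(np.clip(v, 0.0, None), index=idx, name="genetic_variance")

    def covariance(self, bin_ids_a, bin_ids_b) -> np.ndarray:
        za, zb = self._z(bin_ids_a), self._z(bin_ids_b)
        return za @ self.Sigma @ zb.T

    def correlation(self, bin_ids_a, bin_ids_b) -> np.ndarray:
        """Pairwise genetic correlation; NaN where a bin has zero variance."""
        cov = self.covariance(bin_ids_a, bin_ids_b)
        va = self.variance(bin_ids_a).to_numpy()
        vb = self.variance(bin_ids_b).to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            r = cov / np.sqrt(np.outer(va, vb))
        r[~np.isfinite(r)] = np.nan
        return np.clip(r, -1.0, 1.0)


@dataclass
class ZoneMap:
    zone_of_bin: pd.Series         # bin_id -> 1..n_zones (1 = most productive)
    n_zones: int
    subsample_ids: list
    centroids: np.ndarray          # zone centroids in marker space
    within_between: pd.DataFrame   # zone x zone mean genetic correlations

    @property
    def counts(self) -> pd.Series:
        return self.zone_of_bin.value_counts().sort_index()


def ward_zones(
    surface: GeneticSurface,
    yield_potential: pd.Series,
    n_zones: int = 4,
    subsample: int = 2000,
    seed: int = 0,
) -> ZoneMap:
    """Cluster bins into breeding zones by Ward linkage on genetic correlation.

    Distance is ``sqrt(2 (1 - r))`` over a random bin subsample; remaining
    bins join the nearest zone centroid in marker space. Zone labels are
    reordered so zone 1 has the highest mean yield potential.
    """
    bins = list(surface.markers.index)
    if n_zones < 2:
        raise ZoneError("n_zones must be >= 2")
    rng = np.random.default_rng(seed)
    if len(bins) > subsample:
        sub = sorted(rng.choice(len(bins), size=subsample, replace=False))
        sub_ids = [bins[i] for i in sub]
    else:
        sub_ids = bins

    E = surface.markers.loc[sub_ids].to_numpy(dtype=float)
    if len(np.unique(np.round(E, 12), axis=0)) < n_zones:
        raise ZoneError("fewer distinct marker profiles than requested zones")
    R = surface.correlation(sub_ids, sub_ids)
    R = np.nan_to_num(R, nan=0.0)
    D = np.sqrt(np.clip(2.0 * (1.0 - R), 0.0, None))
    np.fill_diagonal(D, 0.0)
    labels = fcluster(linkage(squareform(D, checks=False), method="ward"),
                      n_zones, criterion="maxclust")

    centroids = np.vstack([E[labels == k + 1].mean(axis=0) for k in range(n_zones)])
    allE = surface.markers.to_numpy(dtype=float)
    d2 = ((allE[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    assigned = d2.argmin(axis=1) + 1
    # bins in the subsample keep their Ward label
    pos = {b: i for i, b in enumerate(bins)}
    for b, lab in zip(sub_ids, labels):
        assigned[pos[b]] = lab

    # relabel zones by descending mean yield potential
    yp = yield_potential.reindex(bins).to_numpy()
    order = np.argsort([-np.nanmean(yp[assigned == k + 1]) for k in range(n_zones)])
    relabel = {int(old) + 1: int(new) + 1 for new, old in enumerate(order)}
    final = np.array([relabel[a] for a in assigned])
    zone_of_bin = pd.Series(final, index=pd.Index(bins, name="bin_id"), name="zone")

    # within/between mean correlations on the subsample
    sub_final = zone_of_bin.loc[sub_ids].to_numpy()
    wb = np.full((n_zones, n_zones), np.nan)
    for a in range(1, n_zones + 1):
        ia = sub_final == a
        for b2 in range(a, n_zones + 1):
            ib = sub_final == b2
            if ia.sum() == 0 or ib.sum() == 0:
                continue
            block = R[np.ix_(ia, ib)]
            if a == b2:
                m = block[np.triu_indices(ia.sum(), k=1)].mean() if ia.sum() > 1 else 1.0
            else:
                m = block.mean()
            wb[a - 1, b2 - 1] = wb[b2 - 1, a - 1] = m
    zlabels = [f"zone_{k}" for k in range(1, n_zones + 1)]
    centroids_final = np.vstack(
        [allE[final == k].mean(axis=0) for k in range(1, n_zones + 1)]
    )
    return ZoneMap(
        zone_of_bin=zone_of_bin,
        n_zones=n_zones,
        subsample_ids=sub_ids,
        centroids=centroids_final,
        within_between=pd.DataFrame(wb, index=zlabels, columns=zlabels),
    )


def zone_summary(
    zones: ZoneMap,
    predictions: pd.DataFrame,       # genotypes x bins (mean surfaces)
    trial_bins: pd.Series,           # trial_id -> bin_id
    back_transform=None,
) -> pd.DataFrame:
    """Per-zone bin/trial counts and top-1 selection gain.

    Gain compares the zone mean of the per-bin best genotype against the
    zone mean of the all-genotype average. On the standardized yield scale
    the gain is reported as an absolute difference (``gain_abs``); a
    percentage (``gain_pct``) is added only when a positive-scale
    ``back_transform`` (an (offset, scale) affine map) is supplied or the
    predictions are already positive.
    """
    pred = predictions
    if back_transform is not None:
        offset, scale = back_transform
        pred = pred * scale + offset
    bin_ids = pred.columns
    zone = zones.zone_of_bin.reindex(bin_ids)
    top1 = pred.max(axis=0)
    overall = pred.mean(axis=0)
    trial_zone = zones.zone_of_bin.reindex(trial_bins.to_numpy())

    rows = []
    positive = bool((overall > 0).all())
    for k in range(1, zones.n_zones + 1):
        mask = (zone == k).to_numpy()
        mean_top = float(top1[mask].mean())
        mean_all = float(overall[mask].mean())
        row = {
            "zone": k,
            "bin_count": int(mask.sum()),
            "trial_count": int((trial_zone == k).sum()),
            "yield_potential": mean_all,
            "top1_mean": mean_top,
            "gain_abs": mean_top - mean_all,
        }
        if positive:
            row["gain_pct"] = 100.0 * (mean_top - mean_all) / abs(mean_all)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("zone")
    wb = zones.within_between
    out["within_zone_corr"] = [wb.iloc[k - 1, k - 1] for k in out.index]
    if not positive and back_transform is None:
        out.attrs["gain_scale"] = (
            "standardized scale: gain reported as absolute difference, not %"
        )
    return out


def variance_gradient_profile(
    surface: GeneticSurface,
    wide_gradient: pd.Series,
    bandwidth: float = None,
    n_eval: int = 100,
) -> pd.DataFrame:
    """Genetic variance against the wide-environment gradient, with smoother.

    Returns the raw (gradient, variance) pairs plus a Gaussian-kernel
    (Nadaraya-Watson) trend evaluated on a regular gradient lattice; as the
    bandwidth grows the trend flattens to the global mean variance.
    """
    v = surface.variance().reindex(wide_gradient.index)
    g = wide_gradient.to_numpy(dtype=float)
    raw = pd.DataFrame({"wide_gradient": g, "genetic_variance": v.to_numpy()},
                       index=wide_gradient.index)
    if bandwidth is None:
        spread = np.subtract(*np.percentile(g, [75, 25]))
        bandwidth = max(0.4 * spread, 1e-6)
    grid = np.linspace(g.min(), g.max(), n_eval)
    w = np.exp(-0.5 * ((grid[:, None] - g[None, :]) / bandwidth) ** 2)
    trend = (w @ v.to_numpy()) / w.sum(axis=1)
    raw.attrs["trend"] = pd.DataFrame({"wide_gradient": grid, "trend": trend})
    raw.attrs["bandwidth"] = float(bandwidth)
    return raw
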