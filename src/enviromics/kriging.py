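"""Ordinary kriging with a spherical variogram for ability surfaces.

The empirical semivariogram is binned (equal-width lags to half the maximum
pairwise distance) and a spherical model gamma(h) = nugget + partial_sill *
(1.5 h/range - 0.5 (h/range)^3), capped at the sill beyond the range, is
fitted by weighted least squares with pair counts as weights. The ordinary
kriging system (weights constrained to sum to one through a Lagrange
multiplier) is solved per prediction point; with a zero nugget the predictor
interpolates the data exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist


@dataclass
class SphericalVariogram:
    nugget: float
    partial_sill: float
    range_: float

    def __call__(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        hr = np.clip(h / max(self.range_, 1e-12), 0.0, 1.0)
        gamma = self.nugget + self.partial_sill * (1.5 * hr - 0.5 * hr**3)
        return np.where(h > 0, gamma, 0.0)


def empirical_semivariogram(xy: np.ndarray, values: np.ndarray, n_lags: int = 15):
    """Binned (lag, gamma, count) triples to half the maximum distance."""
    d = cdist(xy, xy)
    iu = np.triu_indices(len(values), k=1)
    h = d[iu]
    g = 0.5 * (values[iu[0]] - values[iu[1]]) ** 2
    hmax = h.max() / 2.0
    edges = np.linspace(0.0, hmax, n_lags + 1)
    lags, gammas, counts = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (h > lo) & (h <= hi)
        if mask.any():
            lags.append(h[mask].mean())
            gammas.append(g[mask].mean())
            counts.append(int(mask.sum()))
    return np.array(lags), np.array(gammas), np.array(counts)


def fit_spherical(lags, gammas, counts) -> SphericalVariogram:
    """WLS fit of the spherical model (weights = pair counts)."""
    sill0 = max(gammas.max(), 1e-12)
    x0 = np.array([0.0, sill0, max(lags.max(), 1e-6)])

    def resid(p):
        v = SphericalVariogram(abs(p[0]), abs(p[1]), abs(p[2]))
        return np.sqrt(counts) * (v(lags) - gammas)

    sol = least_squares(resid, x0, bounds=([0, 0, 1e-9], [np.inf, np.inf, np.inf]))
    return SphericalVariogram(*np.abs(sol.x))


def krige_ability(
    trial_xy: np.ndarray,
    abilities: np.ndarray,
    target_xy: np.ndarray,
    n_lags: int = 15,
    variogram: SphericalVariogram = None,
):
    """Ordinary kriging of per-trial predictive abilities onto grid points.

    Returns (predicted values at targets, fitted variogram, weight matrix of
    shape targets x trials). Identical abilities short-circuit to a constant
    surface (pure-nugget degenerate case).
    """
    trial_xy = np.asarray(trial_xy, dtype=float)
    abilities = np.asarray(abilities, dtype=float)
    ok = np.isfinite(abilities)
    trial_xy, abilities = trial_xy[ok], abilities[ok]
    m = len(abilities)
    if m < 5:
        raise ValueError("need at least 5 trials with finite ability to krige")
    if np.allclose(abilities, abilities[0]):
        const = np.full(len(target_xy), abilities[0])
        w = np.full((len(target_xy), m), 1.0 / m)
        return const, SphericalVariogram(0.0, 0.0, 1.0), w

    if variogram is None:
        lags, gammas, counts = empirical_semivariogram(trial_xy, abilities, n_lags)
        variogram = fit_spherical(lags, gammas, counts)

    # ordinary kriging system in semivariance form with unbiasedness row
    Gmat = np.empty((m + 1, m + 1))
    Gmat[:m, :m] = variogram(cdist(trial_xy, trial_xy))
    Gmat[m, :m] = Gmat[:m, m] = 1.0
    Gmat[m, m] = 0.0
    rhs = np.empty((m + 1, len(target_xy)))
    rhs[:m] = variogram(cdist(trial_xy, target_xy))
    rhs[m] = 1.0
    try:
        sol = np.linalg.solve(Gmat, rhs)
    except np.linalg.LinAlgError:
        # singular configuration (e.g. colocated points): least-squares weights
        sol = np.linalg.lstsq(Gmat, rhs, rcond=None)[0]
    weights = sol[:m].T
    pred = weights @ abilities
    return pred, variogram, weights
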