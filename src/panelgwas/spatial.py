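"""Spatial-heterogeneity diagnostics for field trials.

The residuals of the best plot-level model are summarized by an empirical
semivariogram over the (row, rank) grid; several parametric variogram
families are fitted by weighted least squares on the binned values, the best
(smallest weighted SSE) is selected, and ordinary kriging interpolates the
surface under that model.  These are diagnostics: the pipeline uses them to
decide whether a spatial correction would be warranted, not to correct the
panel data.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "VariogramModel",
    "empirical_variogram",
    "fit_variogram",
    "krige",
    "variogram_and_krige",
]

_FAMILIES = ("exponential", "spherical", "gaussian", "matern_stein")


def _correlation(family: str, h: np.ndarray, rng: float, nu: float) -> np.ndarray:
    h = np.asarray(h, dtype=float)
    rng = max(rng, 1e-12)
    if family == "exponential":
        return np.exp(-h / rng)
    if family == "gaussian":
        return np.exp(-((h / rng) ** 2))
    if family == "spherical":
        x = np.clip(h / rng, 0.0, 1.0)
        return 1.0 - (1.5 * x - 0.5 * x**3)
    if family == "matern_stein":
        # Matern correlation in Stein's parameterization of the range
        x = np.sqrt(2.0 * nu) * h / rng
        out = np.ones_like(h)
        pos = x > 0
        xp = x[pos]
        out[pos] = (2.0 ** (1.0 - nu) / special.gamma(nu)) * (xp**nu) * special.kv(nu, xp)
        return np.clip(out, 0.0, 1.0)
    raise ValueError(f"unknown variogram family {family!r}")


@dataclasses.dataclass
class VariogramModel:
    """Fitted semivariogram: gamma(h) = nugget + psill * (1 - rho(h))."""

    family: str
    nugget: float
    partial_sill: float
    range: float
    sse: float
    nu: float = 0.5  # Matern smoothness (matern_stein only)

    def semivariance(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        g = self.nugget + self.partial_sill * (
            1.0 - _correlation(self.family, h, self.range, self.nu)
        )
        return np.where(h <= 0, 0.0, g)

    def covariance(self, h: np.ndarray) -> np.ndarray:
        """Stationary covariance C(h) = sill - gamma(h); C(0) includes nugget."""
        h = np.asarray(h, dtype=float)
        sill = self.nugget + self.partial_sill
        return np.where(h <= 0, sill, sill - self.semivariance(h))


def empirical_variogram(
    coords: np.ndarray, values: np.ndarray, n_bins: int = 15,
    max_dist: float | None = None,
) -> pd.DataFrame:
    """Binned Matheron semivariogram of point data.

    Returns a table of bin centers, semivariance means and pair counts; the
    default maximum lag is half the largest pairwise distance.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(values) < 30:
        raise ValueError("need at least 30 points for a variogram")
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    iu = np.triu_indices(len(values), k=1)
    dist = d[iu]
    if float(dist.max()) <= 0:
        raise ValueError("all points are colocated")
    gamma = 0.5 * (values[iu[0]] - values[iu[1]]) ** 2
    if max_dist is None:
        max_dist = 0.5 * float(dist.max())
    sel = dist <= max_dist
    dist, gamma = dist[sel], gamma[sel]
    edges = np.linspace(0.0, max_dist, n_bins + 1)
    which = np.clip(np.digitize(dist, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = which == b
        if m.sum() > 0:
            rows.append(((edges[b] + edges[b + 1]) / 2.0, float(gamma[m].mean()), int(m.sum())))
    return pd.DataFrame(rows, columns=["dist", "gamma", "count"])


def _fit_family(emp: pd.DataFrame, family: str) -> VariogramModel:
    h = emp["dist"].to_numpy()
    g = emp["gamma"].to_numpy()
    w = np.sqrt(emp["count"].to_numpy(dtype=float))
    gmax = max(g.max(), 1e-12)
    hmax = h.max()

    def resid(theta):
        nugget, psill, rng = theta[:3]
        nu = theta[3] if family == "matern_stein" else 0.5
        model = nugget + psill * (1.0 - _correlation(family, h, rng, nu))
        return w * (model - g)

    x0 = [0.1 * gmax, 0.9 * gmax, hmax / 3.0]
    lb, ub = [0.0, 0.0, 1e-9], [np.inf, np.inf, 10.0 * hmax]
    if family == "matern_stein":
        # smoothness bounded away from 0.5: the nu = 0.5 member IS the
        # exponential model, which is fitted as its own family
        x0.append(1.5)
        lb.append(0.75)
        ub.append(5.0)
    res = optimize.least_squares(resid, x0, bounds=(lb, ub), max_nfev=2000)
    nugget, psill, rng = res.x[:3]
    nu = res.x[3] if family == "matern_stein" else 0.5
    return VariogramModel(
        family=family, nugget=float(nugget), partial_sill=float(psill),
        range=float(rng), sse=float(np.sum(res.fun**2)), nu=float(nu),
    )


def fit_variogram(
    emp: pd.DataFrame, families: tuple[str, ...] = _FAMILIES
) -> tuple[VariogramModel, list[VariogramModel]]:
    """Fit each family by weighted least squares; best = smallest SSE."""
    fits = [_fit_family(emp, f) for f in families]
    best = min(fits, key=lambda m: m.sse)
    return best, fits


def krige(
    coords_obs: np.ndarray, values_obs: np.ndarray,
    coords_new: np.ndarray, model: VariogramModel,
) -> np.ndarray:
    """Ordinary kriging prediction at new locations under a fitted model.

    With a zero-nugget model, prediction at an observed location returns the
    observation (exact interpolation); a pure-nugget model returns the
    global mean everywhere.
    """
    coords_obs = np.asarray(coords_obs, dtype=float)
    coords_new = np.asarray(coords_new, dtype=float)
    values_obs = np.asarray(values_obs, dtype=float)
    n = len(values_obs)
    d_oo = np.linalg.norm(coords_obs[:, None, :] - coords_obs[None, :, :], axis=-1)
    d_on = np.linalg.norm(coords_obs[:, None, :] - coords_new[None, :, :], axis=-1)
    C = model.covariance(d_oo) + 1e-10 * max(model.nugget + model.partial_sill, 1.0) * np.eye(n)
    # RHS covariance excludes the nugget: we predict the smooth component, so
    # a pure-nugget model kriges to the global mean and a zero-nugget model
    # interpolates observations exactly
    c0 = model.partial_sill * _correlation(model.family, d_on, model.range, model.nu)
    K = np.zeros((n + 1, n + 1))
    K[:n, :n] = C
    K[n, :n] = K[:n, n] = 1.0
    rhs = np.vstack([c0, np.ones(coords_new.shape[0])])
    wts = np.linalg.solve(K, rhs)
    return wts[:n].T @ values_obs


def variogram_and_krige(
    residuals: np.ndarray,
    coords: np.ndarray,
    families: tuple[str, ...] = _FAMILIES,
    new_coords: np.ndarray | None = None,
    n_bins: int = 15,
) -> tuple[VariogramModel, np.ndarray]:
    """Fit the best variogram to residuals and krige a surface.

    ``new_coords`` defaults to the observation locations themselves.
    """
    emp = empirical_variogram(coords, residuals, n_bins=n_bins)
    best, _ = fit_variogram(emp, families)
    targets = coords if new_coords is None else new_coords
    surface = krige(coords, residuals, targets, best)
    return best, surface
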