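"""Machine-learning geostatistical interpolation (MLGI) of index surfaces.

Two-stage interpolation of a per-site pollution or risk index (MPI, NPI, HI,
TCR) over a planar grid:

1. **Trend** — a single-hidden-layer feedforward network (2 inputs -> tanh
   hidden layer -> linear output) whose weights are trained by global-best
   particle swarm optimisation (PSO) with the constriction defaults
   (inertia 0.729, cognitive = social = 1.494).  Inputs and target are
   standardised internally; hidden-layer sizes from 1 to 30 are compared by
   AIC = n * ln(MSE_train) + 2k with k = 4*n_hidden + 1 free weights.

2. **Residual** — ordinary kriging of the trend residuals with an
   exponential variogram gamma(h) = nugget + psill * (1 - exp(-h/range))
   fitted by Cressie-style weighted least squares to the empirical
   semivariogram.  An "EBK-flavoured" option refits the variogram on B
   bootstrap subsamples and averages the B prediction surfaces, mimicking
   empirical-Bayesian treatment of variogram uncertainty with fully open
   math.

The surface is trend + kriged residual; both layers are stored, and grid
cells outside the convex hull of the sites are flagged as extrapolated.
Coordinates must be planar; lon/lat input is projected by a local
equirectangular transform about the domain centroid.
"""

from __future__ import annotations

import math
import time
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.spatial import Delaunay, QhullError, distance_matrix

__all__ = [
    "NNModel",
    "TrainReport",
    "GridSpec",
    "GridSurface",
    "Variogram",
    "train_nn_pso",
    "select_architecture",
    "fit_variogram",
    "krige_residuals",
    "build_surface",
    "idw_predict",
    "lonlat_to_planar",
]


def lonlat_to_planar(lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local equirectangular projection (km) about the centroid.

    Adequate at island scale; kriging distances assume a metric plane.
    """
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    lat0, lon0 = lat.mean(), lon.mean()
    kx = 111.32 * math.cos(math.radians(lat0))
    return (lon - lon0) * kx, (lat - lat0) * 111.32


# --- neural trend -----------------------------------------------------------


@dataclass(frozen=True)
class NNModel:
    """2 -> n_hidden (tanh) -> 1 (linear) network with recorded scalings."""

    n_hidden: int
    w1: np.ndarray  # (n_hidden, 2)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden,)
    b2: float
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    activation: str = "tanh"

    @property
    def n_weights(self) -> int:
        return 4 * self.n_hidden + 1

    def predict(self, xy: np.ndarray) -> np.ndarray:
        """Predict index values (original units) at (n, 2) planar coordinates."""
        xy = np.atleast_2d(np.asarray(xy, float))
        z = (xy - self.x_mean) / self.x_std
        h = np.tanh(z @ self.w1.T + self.b1)
        out = h @ self.w2 + self.b2
        return out * self.y_std + self.y_mean


@dataclass(frozen=True)
class TrainReport:
    """Provenance and fit quality of one PSO training run."""

    n_hidden: int
    n_particles: int
    n_iterations: int
    elapsed_seconds: float
    mse_train: float
    mse_validation: float
    r_validation: float
    r_testing: float
    aic: float
    seed: int
    best_mse_trace: np.ndarray = field(repr=False, default=None)


def _unpack(theta: np.ndarray, h: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    w1 = theta[: 2 * h].reshape(h, 2)
    b1 = theta[2 * h: 3 * h]
    w2 = theta[3 * h: 4 * h]
    b2 = theta[4 * h]
    return w1, b1, w2, b2


def _forward_all(theta: np.ndarray, h: int, z: np.ndarray) -> np.ndarray:
    """Vectorised forward pass for a population: theta (P, k), z (n, 2) -> (P, n)."""
    P = theta.shape[0]
    w1 = theta[:, : 2 * h].reshape(P, h, 2)
    b1 = theta[:, 2 * h: 3 * h]
    w2 = theta[:, 3 * h: 4 * h]
    b2 = theta[:, 4 * h]
    act = np.tanh(np.einsum("phi,ni->pnh", w1, z) + b1[:, None, :])
    return np.einsum("pnh,ph->pn", act, w2) + b2[:, None]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def train_nn_pso(
    sites: np.ndarray,
    values: np.ndarray,
    n_hidden: int = 5,
    n_particles: int = 30,
    n_iterations: int = 300,
    seed: int = 0,
    split: tuple[float, float, float] = (0.70, 0.15, 0.15),
) -> tuple[NNModel, TrainReport]:
    """Train the trend network by global-best PSO.

    ``sites``: (n, 2) planar coordinates; ``values``: (n,) index values.
    Data are split train/validation/test (seeded shuffle); the swarm
    minimises training MSE in standardised units.  Deterministic given
    (seed, config).  Degenerate all-equal values yield a constant model.
    """
    sites = np.atleast_2d(np.asarray(sites, float))
    values = np.asarray(values, float).ravel()
    n = sites.shape[0]
    if n < 5:
        raise ValueError("need at least 5 sites")
    if not 1 <= n_hidden <= 30:
        raise ValueError("n_hidden must be in 1..30")
    k = 4 * n_hidden + 1
    if n < k:
        warnings.warn(
            f"{n} sites < {k} weights: fit proceeds, AIC penalises the excess"
        )

    rng = np.random.default_rng(seed)
    x_mean, x_std = sites.mean(axis=0), sites.std(axis=0)
    x_std = np.where(x_std == 0.0, 1.0, x_std)
    y_mean, y_std = float(values.mean()), float(values.std())

    t0 = time.perf_counter()
    if y_std == 0.0:
        # constant field: constant model, zero error everywhere
        model = NNModel(n_hidden, np.zeros((n_hidden, 2)), np.zeros(n_hidden),
                        np.zeros(n_hidden), 0.0, x_mean, x_std, y_mean, 1.0)
        report = TrainReport(n_hidden, n_particles, n_iterations,
                             time.perf_counter() - t0, 0.0, 0.0, 0.0, 0.0,
                             -math.inf, seed, np.zeros(1))
        return model, report

    z = (sites - x_mean) / x_std
    t = (values - y_mean) / y_std

    order = rng.permutation(n)
    n_tr = max(int(round(split[0] * n)), 1)
    n_va = max(int(round(split[1] * n)), 1)
    idx_tr = order[:n_tr]
    idx_va = order[n_tr: n_tr + n_va]
    idx_te = order[n_tr + n_va:]
    if idx_te.size == 0:
        idx_te = idx_va

    z_tr, t_tr = z[idx_tr], t[idx_tr]

    # global-best PSO, constriction coefficients
    w, c1, c2 = 0.729, 1.494, 1.494
    pos = rng.uniform(-1.0, 1.0, size=(n_particles, k))
    vel = rng.uniform(-0.1, 0.1, size=(n_particles, k))

    def mse_of(population: np.ndarray) -> np.ndarray:
        pred = _forward_all(population, n_hidden, z_tr)
        return ((pred - t_tr) ** 2).mean(axis=1)

    pbest = pos.copy()
    pbest_f = mse_of(pos)
    g = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
    trace = np.empty(n_iterations + 1)
    trace[0] = gbest_f
    vmax = 1.0
    for it in range(n_iterations):
        r1 = rng.uniform(size=(n_particles, k))
        r2 = rng.uniform(size=(n_particles, k))
        vel = w * vel + c1 * r1 * (pbest - pos) + c2 * r2 * (gbest - pos)
        np.clip(vel, -vmax, vmax, out=vel)
        pos = pos + vel
        f = mse_of(pos)
        better = f < pbest_f
        pbest[better] = pos[better]
        pbest_f[better] = f[better]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
        trace[it + 1] = gbest_f

    w1, b1, w2, b2 = _unpack(gbest, n_hidden)
    model = NNModel(n_hidden, w1.copy(), b1.copy(), w2.copy(), float(b2),
                    x_mean, x_std, y_mean, y_std)

    pred_all = model.predict(sites)
    mse_tr = float((((pred_all[idx_tr] - values[idx_tr]) / y_std) ** 2).mean())
    mse_va = float((((pred_all[idx_va] - values[idx_va]) / y_std) ** 2).mean())
    r_va = _pearson(pred_all[idx_va], values[idx_va])
    r_te = _pearson(pred_all[idx_te], values[idx_te])
    aic = n_tr * math.log(max(mse_tr, 1e-300)) + 2 * k
    report = TrainReport(n_hidden, n_particles, n_iterations,
                         time.perf_counter() - t0, mse_tr, mse_va,
                         r_va, r_te, aic, seed, trace)
    return model, report


def select_architecture(
    sites: np.ndarray,
    values: np.ndarray,
    n_hidden_range: Sequence[int] = range(1, 31),
    n_particles: int = 30,
    n_iterations: int = 300,
    seed: int = 0,
) -> tuple[NNModel, TrainReport, list[TrainReport]]:
    """Sweep hidden-layer sizes and return the minimum-AIC model.

    Ties on AIC go to the smaller network.  The full sweep (one report per
    candidate) is returned for AIC-curve inspection/plotting.
    """
    candidates = list(n_hidden_range)
    if not candidates:
        raise ValueError("empty hidden-neuron range")
    if any(h < 1 or h > 30 for h in candidates):
        raise ValueError("hidden-neuron range must lie in 1..30")
    reports: list[TrainReport] = []
    models: list[NNModel] = []
    for h in candidates:
        m, rep = train_nn_pso(sites, values, n_hidden=h, n_particles=n_particles,
                              n_iterations=n_iterations, seed=seed)
        models.append(m)
        reports.append(rep)
    aics = [r.aic for r in reports]
    best = min(range(len(candidates)), key=lambda i: (aics[i], candidates[i]))
    return models[best], reports[best], reports


# --- residual kriging -------------------------------------------------------


@dataclass(frozen=True)
class Variogram:
    """Exponential semivariogram gamma(h) = nugget + psill*(1 - exp(-h/range_))."""

    nugget: float
    psill: float
    range_: float

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, float)
        g = self.nugget + self.psill * (1.0 - np.exp(-h / self.range_))
        return np.where(h == 0.0, 0.0, g)

    def covariance(self, h: np.ndarray) -> np.ndarray:
        sill = self.nugget + self.psill
        return sill - self(h)


def empirical_variogram(
    sites: np.ndarray, values: np.ndarray, n_bins: int = 12
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned empirical semivariogram: (lag centers, gamma, pair counts)."""
    sites = np.atleast_2d(np.asarray(sites, float))
    values = np.asarray(values, float)
    d = distance_matrix(sites, sites)
    iu = np.triu_indices_from(d, k=1)
    h = d[iu]
    sq = 0.5 * (values[:, None] - values[None, :]) ** 2
    g = sq[iu]
    hmax = h.max() / 2.0
    edges = np.linspace(0.0, hmax, n_bins + 1)
    centers, gamma, counts = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (h > lo) & (h <= hi)
        if mask.sum() == 0:
            continue
        centers.append(h[mask].mean())
        gamma.append(g[mask].mean())
        counts.append(int(mask.sum()))
    return np.array(centers), np.array(gamma), np.array(counts)


def fit_variogram(
    sites: np.ndarray, values: np.ndarray, n_bins: int = 12
) -> Variogram:
    """Weighted-least-squares fit of the exponential model.

    Cressie weights N(h)/gamma_model(h)^2; zero-variance residual fields get a
    degenerate (0, 0, 1) variogram.
    """
    values = np.asarray(values, float)
    if np.ptp(values) == 0.0:
        return Variogram(0.0, 0.0, 1.0)
    centers, gamma, counts = empirical_variogram(sites, values, n_bins)
    var = float(values.var())
    h_scale = max(float(centers.max()), 1e-9) if centers.size else 1.0
    fallback = Variogram(0.0, max(var, 1e-12), h_scale / 3.0)
    if centers.size < 4:  # fewer lags than parameters: method-of-moments guess
        return fallback

    def resid(p):
        nug, psill, rng_ = p
        model = nug + psill * (1.0 - np.exp(-centers / max(rng_, 1e-9)))
        w = np.sqrt(counts) / np.maximum(model, 1e-12)
        return w * (model - gamma)

    p0 = np.array([0.1 * var + 1e-12, max(var, 1e-12), h_scale / 3.0])
    sol = optimize.least_squares(
        resid, p0, bounds=([0.0, 1e-12, 1e-9], np.inf), max_nfev=2000
    )
    nug, psill, rng_ = sol.x
    if not (np.isfinite(psill) and np.isfinite(rng_)) or psill <= 0.0:
        return fallback
    return Variogram(float(nug), float(psill), float(max(rng_, 1e-9)))


def _ok_predict(
    sites: np.ndarray, resid: np.ndarray, targets: np.ndarray, vgm: Variogram
) -> np.ndarray:
    """Ordinary-kriging prediction of residuals at target points."""
    n = sites.shape[0]
    C = vgm.covariance(distance_matrix(sites, sites))
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = C
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0
    b = np.empty((n + 1, targets.shape[0]))
    b[:n] = vgm.covariance(distance_matrix(sites, targets))
    b[n] = 1.0
    try:
        lam = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        warnings.warn("singular kriging system: adding diagonal jitter")
        A[:n, :n] += 1e-8 * np.eye(n) * max(C.max(), 1.0)
        lam = np.linalg.solve(A, b)
    return lam[:n].T @ resid


def krige_residuals(
    sites: np.ndarray,
    residuals: np.ndarray,
    targets: np.ndarray,
    *,
    variogram: Variogram | None = None,
    ebk_bootstrap: int = 0,
    seed: int = 0,
) -> np.ndarray:
    """Ordinary kriging of trend residuals at target points.

    With ``variogram=None`` an exponential model is WLS-fitted to the data.
    ``ebk_bootstrap=B`` activates the EBK-flavoured mode: B bootstrap
    subsamples (80% of sites, seeded) each refit the variogram, and the B
    prediction surfaces are averaged.
    """
    sites = np.atleast_2d(np.asarray(sites, float))
    residuals = np.asarray(residuals, float)
    targets = np.atleast_2d(np.asarray(targets, float))
    if sites.shape[0] < 5:
        raise ValueError("need at least 5 residual sites")
    if np.ptp(residuals) == 0.0:
        # constant residual field (incl. all-zero): OK returns the constant
        return np.full(targets.shape[0], residuals[0])
    if ebk_bootstrap > 0:
        rng = np.random.default_rng(seed)
        n = sites.shape[0]
        m = max(int(0.8 * n), 5)
        preds = np.zeros(targets.shape[0])
        for _ in range(ebk_bootstrap):
            idx = rng.choice(n, size=m, replace=False)
            vgm_b = fit_variogram(sites[idx], residuals[idx])
            preds += _ok_predict(sites, residuals, targets, vgm_b)
        return preds / ebk_bootstrap
    vgm = variogram if variogram is not None else fit_variogram(sites, residuals)
    return _ok_predict(sites, residuals, targets, vgm)


def idw_predict(
    sites: np.ndarray, values: np.ndarray, targets: np.ndarray, power: float = 2.0
) -> np.ndarray:
    """Inverse-distance-weighted baseline interpolator (for benchmarking)."""
    d = distance_matrix(np.atleast_2d(targets), np.atleast_2d(sites))
    out = np.empty(d.shape[0])
    for i in range(d.shape[0]):
        di = d[i]
        if di.min() == 0.0:
            out[i] = values[int(np.argmin(di))]
        else:
            w = 1.0 / di**power
            out[i] = float(w @ values / w.sum())
    return out


# --- surfaces ---------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Regular grid: origin (x0, y0), square cell size, n_rows x n_cols."""

    x0: float
    y0: float
    cell: float
    n_rows: int
    n_cols: int

    def centers(self) -> np.ndarray:
        xs = self.x0 + (np.arange(self.n_cols) + 0.5) * self.cell
        ys = self.y0 + (np.arange(self.n_rows) + 0.5) * self.cell
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass(frozen=True)
class GridSurface:
    """Interpolated index surface with its trend/residual decomposition."""

    spec: GridSpec
    values: np.ndarray  # (n_rows*n_cols,)
    trend: np.ndarray
    residual: np.ndarray
    extrapolated: np.ndarray  # bool: outside convex hull of sites
    provenance: dict

    def to_frame(self):
        import pandas as pd

        xy = self.spec.centers()
        return pd.DataFrame(
            {
                "x": xy[:, 0],
                "y": xy[:, 1],
                "value": self.values,
                "trend": self.trend,
                "residual": self.residual,
                "extrapolated": self.extrapolated,
            }
        )

    def to_geojson(self) -> dict:
        """Grid cells as GeoJSON polygon features."""
        feats = []
        half = self.spec.cell / 2.0
        xy = self.spec.centers()
        for i in range(xy.shape[0]):
            cx, cy = xy[i]
            ring = [
                [cx - half, cy - half], [cx + half, cy - half],
                [cx + half, cy + half], [cx - half, cy + half],
                [cx - half, cy - half],
            ]
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": {
                        "value": float(self.values[i]),
                        "trend": float(self.trend[i]),
                        "residual": float(self.residual[i]),
                        "extrapolated": bool(self.extrapolated[i]),
                    },
                }
            )
        return {"type": "FeatureCollection", "features": feats,
                "properties": dict(self.provenance)}


def build_surface(
    sites: np.ndarray,
    values: np.ndarray,
    spec: GridSpec,
    *,
    n_hidden: int = 5,
    n_particles: int = 30,
    n_iterations: int = 300,
    select_hidden: Sequence[int] | None = None,
    ebk_bootstrap: int = 0,
    seed: int = 0,
) -> GridSurface:
    """NN trend + kriged residual surface of an index over a grid.

    With ``select_hidden`` the architecture is chosen by AIC over that range;
    otherwise ``n_hidden`` is used directly.  The residual layer kriges
    (value - trend) at the sites; surface = trend + residual.
    """
    sites = np.atleast_2d(np.asarray(sites, float))
    values = np.asarray(values, float)
    if select_hidden is not None:
        model, report, _ = select_architecture(
            sites, values, select_hidden, n_particles, n_iterations, seed
        )
    else:
        model, report = train_nn_pso(
            sites, values, n_hidden, n_particles, n_iterations, seed
        )
    targets = spec.centers()
    trend_grid = model.predict(targets)
    resid_site = values - model.predict(sites)
    if np.ptp(resid_site) == 0.0:
        resid_grid = np.full(targets.shape[0], resid_site[0] if resid_site.size else 0.0)
    else:
        resid_grid = krige_residuals(
            sites, resid_site, targets, ebk_bootstrap=ebk_bootstrap, seed=seed
        )
    try:
        hull = Delaunay(sites)
        inside = hull.find_simplex(targets) >= 0
    except (QhullError, ValueError):
        inside = np.zeros(targets.shape[0], dtype=bool)
    return GridSurface(
        spec=spec,
        values=trend_grid + resid_grid,
        trend=trend_grid,
        residual=resid_grid,
        extrapolated=~inside,
        provenance={
            "n_hidden": model.n_hidden,
            "n_particles": report.n_particles,
            "n_iterations": report.n_iterations,
            "aic": report.aic,
            "seed": seed,
            "ebk_bootstrap": ebk_bootstrap,
        },
    )
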