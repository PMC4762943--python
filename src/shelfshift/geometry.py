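"""Shift geometry: along-/cross-shelf re-gridding, biomass-weighted
centroids, great-circle shift vectors, circular statistics, and centroid
trend regressions (ordinary and truncated).

Distances use a spherical Earth of radius 6371.0 km.  Centers of biomass
are computed in re-gridded along-/cross-shelf space and mapped back to
latitude/longitude, which keeps them inside the surveyed corridor even
when a species' range is crescent-shaped around a coastline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .survey import PeriodScheme

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0
KM_PER_DEG = np.pi * EARTH_RADIUS_KM / 180.0


# ---------------------------------------------------------------------------
# Great-circle primitives (geosphere-equivalent formulas)

def haversine_km(lat1, lon1, lat2, lon2, radius: float = EARTH_RADIUS_KM):
    """Great-circle distance in km between points in decimal degrees."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return 2 * radius * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def initial_bearing_deg(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing from point 1 to point 2, in
    [0, 360) degrees clockwise from north."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dlmb = np.radians(np.asarray(lon2) - np.asarray(lon1))
    y = np.sin(dlmb) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlmb)
    return np.mod(np.degrees(np.arctan2(y, x)), 360.0)


# ---------------------------------------------------------------------------
# Along-/cross-shelf axis

@dataclass
class ShelfAxis:
    """A shelf-following polyline used to re-grid positions.

    Vertices run along the shelf (by convention from southwest to
    northeast with the open ocean to the right, so positive cross-shelf
    distance is offshore).  Projection onto each segment uses a local
    equirectangular approximation (longitude scaled by cos latitude),
    accurate to well under a km at the ~100 km scales involved and
    exactly invertible.
    """

    lats: np.ndarray
    lons: np.ndarray

    def __post_init__(self):
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        if self.lats.size < 2:
            raise ValueError("axis needs at least 2 vertices")
        self._reflat = np.radians(0.5 * (self.lats[:-1] + self.lats[1:]))
        # segment endpoints in each segment's local plane (km)
        self._dx = ((self.lons[1:] - self.lons[:-1])
                    * np.cos(self._reflat) * KM_PER_DEG)
        self._dy = (self.lats[1:] - self.lats[:-1]) * KM_PER_DEG
        self._seglen = np.hypot(self._dx, self._dy)
        if np.any(self._seglen <= 0):
            raise ValueError("axis has zero-length segment")
        self.cum_along = np.concatenate([[0.0], np.cumsum(self._seglen)])

    @property
    def length_km(self) -> float:
        return float(self.cum_along[-1])

    def regrid(self, lat, lon, return_clamped: bool = False):
        """Project points onto the axis: returns (along km, cross km).

        Cross is signed, positive to the right of the axis direction
        (offshore for a coast-left axis).  Points projecting beyond the
        axis ends are clamped to the end vertices with a warning; with
        ``return_clamped`` a boolean mask of those points is appended
        (the regrid/inverse round trip is exact only for covered,
        i.e. unclamped, points).
        """
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        n, m = lat.size, self._seglen.size
        # local plane coords of the point relative to each segment start
        px = ((lon[:, None] - self.lons[None, :-1])
              * np.cos(self._reflat)[None, :] * KM_PER_DEG)
        py = (lat[:, None] - self.lats[None, :-1]) * KM_PER_DEG
        t = (px * self._dx + py * self._dy) / self._seglen ** 2
        tc = np.clip(t, 0.0, 1.0)
        ex = px - tc * self._dx
        ey = py - tc * self._dy
        d2 = ex ** 2 + ey ** 2
        # prefer segments whose orthogonal projection is interior: those
        # are exactly invertible; corner-wedge/end points fall back to the
        # nearest clamped vertex and are flagged
        interior = (t >= 0.0) & (t <= 1.0)
        d2_int = np.where(interior, d2, np.inf)
        has_int = interior.any(axis=1)
        best = np.where(has_int, np.argmin(d2_int, axis=1),
                        np.argmin(d2, axis=1))
        rows = np.arange(n)
        tb = tc[rows, best]
        along = self.cum_along[best] + tb * self._seglen[best]
        cross = (px[rows, best] * self._dy[best]
                 - py[rows, best] * self._dx[best]) / self._seglen[best]
        clamped = ~has_int
        if clamped.any():
            warnings.warn(f"{int(clamped.sum())} point(s) have no orthogonal "
                          "projection onto the axis; clamped to the nearest "
                          "vertex", stacklevel=2)
        if return_clamped:
            return along, cross, clamped
        return along, cross

    def inverse_regrid(self, along, cross) -> tuple[np.ndarray, np.ndarray]:
        """Map (along km, cross km) back to (lat, lon)."""
        along = np.atleast_1d(np.asarray(along, dtype=float))
        cross = np.atleast_1d(np.asarray(cross, dtype=float))
        seg = np.clip(np.searchsorted(self.cum_along, along, side="right") - 1,
                      0, self._seglen.size - 1)
        t = (along - self.cum_along[seg]) / self._seglen[seg]
        # unit vectors along / right-normal in the segment plane
        ux, uy = self._dx[seg] / self._seglen[seg], self._dy[seg] / self._seglen[seg]
        x = t * self._seglen[seg] * ux + cross * uy
        y = t * self._seglen[seg] * uy - cross * ux
        lat = self.lats[seg] + y / KM_PER_DEG
        lon = self.lons[seg] + x / (np.cos(self._reflat[seg]) * KM_PER_DEG)
        return lat, lon

    @classmethod
    def for_region(cls, region: str) -> "ShelfAxis":
        """Built-in shelf-following axes for the synthetic domains."""
        if region == "south":
            return cls(np.array([35.8, 37.5, 39.2, 40.8, 41.6]),
                       np.array([-75.8, -74.3, -72.3, -70.3, -68.3]))
        if region == "north":
            return cls(np.array([42.0, 43.0, 43.8, 44.4]),
                       np.array([-70.6, -69.6, -68.0, -66.2]))
        raise ValueError(f"unknown region {region!r}")


# ---------------------------------------------------------------------------
# Centroids and shift vectors

def biomass_centroid(hauls: pd.DataFrame, catches: pd.DataFrame, species: str,
                     years: tuple[int, int], axis: ShelfAxis) -> pd.Series | None:
    """Biomass-weighted center of a species over a year span.

    Along/cross are biomass-weighted means in re-gridded space, mapped
    back to lat/lon; latitude and depth are also direct weighted means
    (the depth and latitude rates reported downstream use these).
    Returns None when the species has no positive haul in the span.
    """
    sub = catches[(catches["species"] == species) & (catches["biomass"] > 0)]
    j = sub.merge(hauls, on="haul_id")
    j = j[(j["year"] >= years[0]) & (j["year"] <= years[1])]
    if j.empty:
        return None
    w = j["biomass"].to_numpy()
    along, cross = axis.regrid(j["latitude"].to_numpy(), j["longitude"].to_numpy())
    a = float(np.average(along, weights=w))
    c = float(np.average(cross, weights=w))
    lat_b, lon_b = axis.inverse_regrid(a, c)
    return pd.Series({
        "species": species, "along": a, "cross": c,
        "latitude_regrid": float(lat_b[0]), "longitude_regrid": float(lon_b[0]),
        "latitude": float(np.average(j["latitude"], weights=w)),
        "depth": float(np.average(j["depth"], weights=w)),
        "biomass": float(w.sum()), "n_hauls": int(len(j)),
    })


def centroid_series(hauls: pd.DataFrame, catches: pd.DataFrame, species: str,
                    scheme: PeriodScheme, axis: ShelfAxis) -> pd.DataFrame:
    """Per-five-year-block biomass-weighted centroids for one species."""
    rows = []
    for b, span in enumerate(scheme.blocks, start=1):
        c = biomass_centroid(hauls, catches, species, span, axis)
        if c is not None:
            c["block"] = b
            c["year_mid"] = scheme.block_midpoint(b)
            rows.append(c)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ShiftVector:
    species: str
    bearing: float      # degrees in [0, 360); NaN when undefined
    distance: float     # km
    defined: bool = True


def shift_vector(c_first: pd.Series, c_last: pd.Series) -> ShiftVector:
    """Bearing and great-circle distance between two period centroids
    (back-transformed re-gridded positions)."""
    lat1, lon1 = c_first["latitude_regrid"], c_first["longitude_regrid"]
    lat2, lon2 = c_last["latitude_regrid"], c_last["longitude_regrid"]
    d = float(haversine_km(lat1, lon1, lat2, lon2))
    if d == 0.0:
        return ShiftVector(str(c_first["species"]), np.nan, 0.0, defined=False)
    b = float(initial_bearing_deg(lat1, lon1, lat2, lon2))
    return ShiftVector(str(c_first["species"]), b % 360.0, d)


# ---------------------------------------------------------------------------
# Circular statistics

@dataclass(frozen=True)
class CircularTest:
    n: int
    rbar: float          # mean resultant length in [0, 1]
    mean_deg: float      # mean direction
    z: float             # Rayleigh statistic n * rbar^2
    p: float


def rayleigh_test(bearings, method: str = "approx", n_mc: int = 20000,
                  seed: int = 0) -> CircularTest:
    """Rayleigh test of circular uniformity for a set of bearings (deg).

    ``method='approx'`` uses the standard small-sample approximation
    p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n)) with resultant
    length R = n*rbar; ``method='mc'`` estimates p by Monte-Carlo
    sampling of uniform angles (slow reference).  Rotation-invariant.
    """
    th = np.radians(np.asarray(bearings, dtype=float))
    n = th.size
    if n < 2:
        raise ValueError("rayleigh_test needs at least 2 bearings")
    C, S = np.cos(th).sum(), np.sin(th).sum()
    R = np.hypot(C, S)
    rbar = R / n
    z = n * rbar ** 2
    mean_deg = float(np.degrees(np.arctan2(S, C)) % 360.0)
    if method == "approx":
        p = np.exp(np.sqrt(1 + 4 * n + 4 * (n ** 2 - R ** 2)) - (1 + 2 * n))
    elif method == "mc":
        rng = np.random.default_rng(seed)
        u = rng.uniform(0, 2 * np.pi, size=(n_mc, n))
        zs = (np.cos(u).sum(axis=1) ** 2 + np.sin(u).sum(axis=1) ** 2) / n
        p = (1 + np.sum(zs >= z)) / (1 + n_mc)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CircularTest(n, float(rbar), mean_deg, float(z),
                        float(min(max(p, np.finfo(float).tiny), 1.0)))


def circular_mean_deg(bearings) -> float:
    th = np.radians(np.asarray(bearings, dtype=float))
    return float(np.degrees(np.arctan2(np.sin(th).sum(), np.cos(th).sum())) % 360.0)


# ---------------------------------------------------------------------------
# Trend regressions

@dataclass(frozen=True)
class TrendFit:
    slope: float
    intercept: float
    se: float
    p: float
    r2: float
    n: int
    truncated: bool = False
    bound: float | None = None
    converged: bool = True


def trend_regression(years, values, truncation: float | None = None,
                     side: str = "left") -> TrendFit:
    """Slope of centroid value against time.

    Untruncated series use ordinary least squares.  When the sampled
    domain cuts off the distribution at a known bound (e.g. the survey's
    southern edge), a truncated-normal regression is fitted by maximum
    likelihood: y ~ Normal(a + b x, sigma) observed only when y is above
    (``side='left'``) or below (``side='right'``) the bound.  Wald
    standard errors come from the inverse Hessian; non-convergence falls
    back to OLS with a warning.
    """
    x = np.asarray(years, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("trend_regression needs >= 3 points")
    res = stats.linregress(x, y)
    if truncation is None:
        return TrendFit(float(res.slope), float(res.intercept),
                        float(res.stderr), float(res.pvalue),
                        float(res.rvalue ** 2), int(x.size))

    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")

    def nll(theta):
        a, b, logs = theta
        s = np.exp(logs)
        mu = a + b * x
        ll = stats.norm.logpdf(y, mu, s)
        if side == "left":      # observed only above the bound
            ll = ll - stats.norm.logsf((truncation - mu) / s)
        else:                   # observed only below the bound
            ll = ll - stats.norm.logcdf((truncation - mu) / s)
        return -np.sum(ll)

    s0 = max(np.std(y - res.intercept - res.slope * x), 1e-6)
    opt = optimize.minimize(nll, [res.intercept, res.slope, np.log(s0)],
                            method="BFGS")
    if not np.all(np.isfinite(opt.x)) or not opt.success and opt.status != 2:
        logger.warning("truncated regression did not converge; OLS fallback")
        return TrendFit(float(res.slope), float(res.intercept),
                        float(res.stderr), float(res.pvalue),
                        float(res.rvalue ** 2), int(x.size),
                        truncated=True, bound=truncation, converged=False)
    a, b, _ = opt.x
    try:
        se = float(np.sqrt(opt.hess_inv[1, 1]))
    except Exception:
        se = np.nan
    tstat = b / se if se and np.isfinite(se) and se > 0 else np.nan
    p = 2 * stats.t.sf(abs(tstat), x.size - 2) if np.isfinite(tstat) else np.nan
    yhat = a + b * x
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return TrendFit(float(b), float(a), se, float(p), float(r2), int(x.size),
                    truncated=True, bound=truncation)


def deepening_flag(trend: TrendFit, alpha: float = 0.05) -> bool:
    """Significant deepening over the series: positive depth slope with
    p below *alpha*."""
    return bool(trend.slope > 0 and trend.p < alpha)
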