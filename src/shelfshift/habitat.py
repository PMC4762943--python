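"""Assemblage range area, thermal habitat area, and the mixed-effects
area model.

For each assemblage, season, region, and five-year block, haul
locations are projected to a local equal-area plane and smoothed into
two weighted kernel-density surfaces: one weighted by summed core-
species catch biomass (where the assemblage *was*) and one weighted by
summed envelope predictions (where its thermal habitat was).  The
"core" area of a surface is the area of cells whose density exceeds
the domain mean by more than one standard deviation.  A linear mixed
model then asks whether assemblage range area follows thermal habitat
area or assemblage biomass:

    kernel_area ~ thermal_area + biomass + (1 | region/season)
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.spatial import cKDTree

from .geometry import EARTH_RADIUS_KM

logger = logging.getLogger(__name__)


def laea_project(lat, lon, lat0: float, lon0: float,
                 radius: float = EARTH_RADIUS_KM) -> tuple[np.ndarray, np.ndarray]:
    """Spherical Lambert azimuthal equal-area projection centered at
    (lat0, lon0); returns (x, y) in km, equal-area by construction."""
    phi, lam = np.radians(lat), np.radians(lon)
    phi0, lam0 = np.radians(lat0), np.radians(lon0)
    cosc = (np.sin(phi0) * np.sin(phi)
            + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0))
    k = np.sqrt(2.0 / np.clip(1.0 + cosc, 1e-12, None))
    x = radius * k * np.cos(phi) * np.sin(lam - lam0)
    y = radius * k * (np.cos(phi0) * np.sin(phi)
                      - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0))
    return x, y


@dataclass
class KernelField:
    """A weighted Gaussian product-kernel density on a regular grid.

    ``density`` integrates to ~1 over the grid (weights are normalized
    before smoothing); ``mask`` marks cells inside the survey domain
    (within ``mask_radius`` of any data point) over which threshold
    statistics are computed.
    """

    x: np.ndarray            # cell-center coordinates, km
    y: np.ndarray
    density: np.ndarray      # shape (ny, nx)
    cell_km: float
    bandwidth: tuple[float, float]
    mask: np.ndarray         # bool, shape (ny, nx)
    weight_kind: str = "biomass"
    meta: dict | None = None

    def integral(self) -> float:
        return float(self.density.sum() * self.cell_km ** 2)


def scott_bandwidth(points: np.ndarray, weights: np.ndarray,
                    floor_km: float = 5.0) -> tuple[float, float]:
    """Per-axis Scott's rule on the weighted point set with a floor.

    h_j = sigma_j * n_eff^(-1/6) for 2-D data, with the effective sample
    size n_eff = (sum w)^2 / sum w^2; the floor keeps surfaces from
    collapsing onto sparse point sets.
    """
    w = weights / weights.sum()
    neff = 1.0 / np.sum(w ** 2)
    mu = np.average(points, axis=0, weights=w)
    var = np.average((points - mu) ** 2, axis=0, weights=w)
    h = np.sqrt(var) * neff ** (-1.0 / 6.0)
    return (max(float(h[0]), floor_km), max(float(h[1]), floor_km))


def weighted_kde(points: np.ndarray, weights: np.ndarray,
                 cell_km: float = 2.0, bandwidth: tuple[float, float] | None = None,
                 pad_bw: float = 3.0, mask_radius_km: float = 25.0,
                 weight_kind: str = "biomass", **meta) -> KernelField:
    """Weighted Gaussian product-kernel density, evaluated on a regular
    equal-area grid padded *pad_bw* bandwidths beyond the points.

    Weights are normalized to sum to one before smoothing, so the field
    is invariant to uniform weight scaling and integrates to ~1 (edge
    truncation aside).
    """
    points = np.asarray(points, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if points.shape[0] < 5:
        raise ValueError("weighted_kde needs >= 5 points")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    keep = weights > 0
    points, weights = points[keep], weights[keep]
    w = weights / weights.sum()
    hx, hy = bandwidth if bandwidth is not None else scott_bandwidth(points, weights)
    x0, x1 = points[:, 0].min() - pad_bw * hx, points[:, 0].max() + pad_bw * hx
    y0, y1 = points[:, 1].min() - pad_bw * hy, points[:, 1].max() + pad_bw * hy
    gx = np.arange(x0, x1 + cell_km, cell_km)
    gy = np.arange(y0, y1 + cell_km, cell_km)
    # product kernel factorizes: (ny, n) @ (n, nx)
    kx = np.exp(-0.5 * ((gx[None, :] - points[:, 0][:, None]) / hx) ** 2) \
        / (hx * np.sqrt(2 * np.pi))
    ky = np.exp(-0.5 * ((gy[:, None] - points[:, 1][None, :]) / hy) ** 2) \
        / (hy * np.sqrt(2 * np.pi))
    dens = ky @ (w[:, None] * kx)
    xg, yg = np.meshgrid(gx, gy)
    tree = cKDTree(points)
    d, _ = tree.query(np.column_stack([xg.ravel(), yg.ravel()]),
                      distance_upper_bound=mask_radius_km)
    mask = np.isfinite(d).reshape(dens.shape)
    return KernelField(gx, gy, dens, cell_km, (hx, hy), mask,
                       weight_kind=weight_kind, meta=meta or None)


@dataclass(frozen=True)
class CoreArea:
    area_km2: float
    threshold: float
    n_cells: int
    weight_kind: str
    degenerate: bool = False
    meta: dict | None = None


def core_area(field: KernelField, multiplier: float = 1.0) -> CoreArea:
    """Area where the density surface exceeds its mean + multiplier·SD.

    Statistics are computed over cells inside the survey-domain mask so
    empty ocean does not dilute them.  A constant field has SD 0 and no
    cell strictly above the threshold: area 0, flagged degenerate.
    """
    vals = field.density[field.mask]
    mu, sd = float(vals.mean()), float(vals.std(ddof=0))
    thr = mu + multiplier * sd
    above = (field.density > thr) & field.mask
    n = int(above.sum())
    degenerate = sd <= 1e-12 * max(abs(mu), 1e-300)
    return CoreArea(n * field.cell_km ** 2, thr, n, field.weight_kind,
                    degenerate=degenerate, meta=field.meta)


def assemblage_surfaces(hauls: pd.DataFrame, catches: pd.DataFrame,
                        predictions: dict[str, np.ndarray] | pd.DataFrame,
                        species: list[str], block_years: tuple[int, int],
                        region: str, season: str, cell_km: float = 2.0,
                        **kde_kwargs
                        ) -> tuple[KernelField, KernelField, float] | None:
    """Biomass and thermal-habitat surfaces for one assemblage-block.

    ``predictions`` gives per-haul envelope weights per core species,
    either a mapping species -> array aligned with the region/season
    haul subset, or a DataFrame indexed like that subset with one column
    per species.  Species predictions are summed raw (the thermal field
    represents overall assemblage habitat).  Returns (biomass field,
    thermal field, total biomass) or None for an empty assemblage-block.
    """
    h = hauls[(hauls["region"] == region)
              & (hauls["season"] == season)].reset_index(drop=True)
    inblk = h["year"].between(*block_years).to_numpy()
    hb = h[inblk]
    if hb.empty:
        return None
    sub = catches[(catches["species"].isin(species)) & (catches["biomass"] > 0)]
    bio = (sub.groupby("haul_id")["biomass"].sum()
           .reindex(hb["haul_id"]).fillna(0.0).to_numpy())
    if isinstance(predictions, pd.DataFrame):
        thermal = predictions.loc[inblk, [s for s in species
                                          if s in predictions.columns]] \
            .sum(axis=1).to_numpy()
    else:
        thermal = np.zeros(len(h))
        for s in species:
            if s in predictions:
                thermal = thermal + np.asarray(predictions[s])
        thermal = thermal[inblk]
    if bio.sum() <= 0 or thermal.sum() <= 0:
        return None
    lat0 = float(h["latitude"].mean())
    lon0 = float(h["longitude"].mean())
    x, y = laea_project(hb["latitude"].to_numpy(), hb["longitude"].to_numpy(),
                        lat0, lon0)
    pts = np.column_stack([x, y])
    bio_field = weighted_kde(pts, bio, cell_km=cell_km,
                             weight_kind="biomass", **kde_kwargs)
    th_field = weighted_kde(pts, thermal, cell_km=cell_km,
                            weight_kind="thermal", **kde_kwargs)
    return bio_field, th_field, float(bio.sum())


class AssemblageAreaModel:
    """Mixed-effects model of assemblage range area.

        kernel_area = α + β1·thermal_area + β2·biomass + a_i + ε_ij

    with random intercepts for region and for season nested within
    region, fitted by REML.  Predictors are used on their natural scale
    (km², kg); set ``standardize=True`` to z-score them for
    conditioning.
    """

    def __init__(self, rows: pd.DataFrame, standardize: bool = False):
        need = {"kernel_area", "thermal_area", "biomass", "region", "season"}
        missing = need - set(rows.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if len(rows) < 10:
            raise ValueError("need >= 10 rows to fit the area model")
        self.rows = rows.reset_index(drop=True).copy()
        self.standardize = standardize
        if standardize:
            for c in ("kernel_area", "thermal_area", "biomass"):
                v = self.rows[c]
                self.rows[c] = (v - v.mean()) / v.std(ddof=0)

    @classmethod
    def from_dataframe(cls, rows: pd.DataFrame, **kwargs) -> "AssemblageAreaModel":
        return cls(rows, **kwargs)

    def fit(self, reml: bool = True) -> "AreaModelResults":
        formula = "kernel_area ~ thermal_area + biomass"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                md = smf.mixedlm(formula, self.rows, groups=self.rows["region"],
                                 re_formula="1",
                                 vc_formula={"season": "0 + C(season)"})
                res = md.fit(reml=reml)
                singular = (not np.all(np.isfinite(res.bse.iloc[:3]))
                            or not res.converged)
            except Exception:
                res, singular = None, True
            if singular:
                logger.warning("nested random-effects fit singular; refitting "
                               "with region-only intercept")
                md = smf.mixedlm(formula, self.rows,
                                 groups=self.rows["region"], re_formula="1")
                res = md.fit(reml=reml)
        return AreaModelResults(self, res, region_only=singular)


@dataclass
class AreaModelResults:
    """Fitted area model.  ``tvalues``/``pvalues`` are Wald statistics
    for the fixed effects (Intercept, thermal_area, biomass)."""

    model: AssemblageAreaModel
    _res: object
    region_only: bool = False

    @property
    def params(self) -> pd.Series:
        return self._res.params[:3]

    @property
    def bse(self) -> pd.Series:
        return self._res.bse[:3]

    @property
    def tvalues(self) -> pd.Series:
        return self._res.tvalues[:3]

    @property
    def pvalues(self) -> pd.Series:
        return self._res.pvalues[:3]

    @property
    def random_effects(self) -> dict:
        return self._res.random_effects

    def summary(self):
        return self._res.summary()
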