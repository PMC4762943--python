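"""Delta-lognormal thermal-envelope models and taxon-specific climate
velocities.

Trawl catches are dominated by zeros, so each species' thermal envelope
is modeled in two parts (a hurdle):

* a **presence** submodel — binomial GAM (logit link) of catch
  presence on penalized spline smooths of surface and bottom
  temperature, plus habitat stratum and the species' mean annual
  region-wide abundance as parametric terms;
* a **positive** submodel — Gaussian GAM of log positive biomass on
  the same covariates.

The delta prediction p̂ · exp(μ̂ + σ̂²/2) (lognormal mean
back-transform) weights every haul; prediction-weighted mean latitude
and depth per five-year block form the envelope-centroid series whose
regression slope against time is the species' climate velocity (°N/yr,
m/yr), compared against the observed biomass-centroid slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.gam.api import BSplines, GLMGam

from .geometry import TrendFit, trend_regression
from .survey import PeriodScheme

logger = logging.getLogger(__name__)


def delta_weight(p, mu, sigma2):
    """Delta-lognormal mean: presence probability times the lognormal
    mean back-transform, p * exp(mu + sigma2/2)."""
    return np.asarray(p) * np.exp(np.asarray(mu) + np.asarray(sigma2) / 2.0)


def _design(df: pd.DataFrame, strata: list[str]) -> np.ndarray:
    """Parametric design: intercept, mean annual abundance, stratum
    dummies (first level is the baseline)."""
    cols = [np.ones(len(df)), df["abundance"].to_numpy(dtype=float)]
    for s in strata[1:]:
        cols.append((df["stratum"] == s).to_numpy(dtype=float))
    return np.column_stack(cols)


class DeltaLognormalEnvelope:
    """Delta-lognormal thermal envelope for one species.

    Build with :meth:`from_survey`, then :meth:`fit` to obtain an
    :class:`EnvelopeResults`.

    Parameters
    ----------
    frame : DataFrame
        One row per haul with columns ``present`` (0/1), ``logbio``
        (NaN where absent), ``sst``, ``bt``, ``stratum``, ``abundance``.
    k_basis : int
        B-spline basis dimension per temperature smooth.
    alpha : float
        Smoothing penalty weight applied to both smooths.
    clamp_pct : (float, float)
        Prediction covariates are clamped to these percentiles of the
        training values to avoid spline extrapolation.
    """

    def __init__(self, species: str, frame: pd.DataFrame, k_basis: int = 5,
                 alpha: float = 1.0, clamp_pct: tuple[float, float] = (1, 99),
                 min_stratum_positives: int = 5):
        self.species = species
        self.frame = frame.reset_index(drop=True)
        self.k_basis = int(k_basis)
        self.alpha = float(alpha)
        self.clamp_pct = clamp_pct
        pos = self.frame[self.frame["present"] == 1]
        counts = pos.groupby("stratum").size()
        good = counts[counts >= min_stratum_positives].index
        # strata with too few positive hauls are pooled into the baseline
        self.frame["stratum"] = np.where(self.frame["stratum"].isin(good),
                                         self.frame["stratum"], "_pooled")
        self.strata = sorted(self.frame["stratum"].unique())
        lo, hi = clamp_pct
        pos = self.frame[self.frame["present"] == 1]
        # separate clamp ranges: each submodel's spline basis only covers
        # its own training covariate range
        self.clamp_lo = self.frame[["sst", "bt"]].quantile(lo / 100.0)
        self.clamp_hi = self.frame[["sst", "bt"]].quantile(hi / 100.0)
        self.clamp_lo_pos = pos[["sst", "bt"]].quantile(lo / 100.0)
        self.clamp_hi_pos = pos[["sst", "bt"]].quantile(hi / 100.0)

    @classmethod
    def from_survey(cls, species: str, hauls: pd.DataFrame,
                    catches: pd.DataFrame, region: str, season: str,
                    min_positive: int = 50, **kwargs
                    ) -> "DeltaLognormalEnvelope":
        """Assemble the model frame from haul/catch tables.

        The abundance covariate is the species' region-wide mean biomass
        per haul in each year (zero hauls included), which absorbs
        region-wide abundance trends (e.g. exploitation) so the smooths
        capture the thermal response.  Raises ``ValueError`` when the
        species has fewer than *min_positive* positive hauls or only one
        presence class.
        """
        h = hauls[(hauls["region"] == region)
                  & (hauls["season"] == season)].reset_index(drop=True)
        sub = catches[(catches["species"] == species) & (catches["biomass"] > 0)]
        bio = sub.groupby("haul_id")["biomass"].sum()
        frame = h[["haul_id", "year", "latitude", "depth", "sst", "bt",
                   "stratum"]].copy()
        frame["biomass"] = frame["haul_id"].map(bio).fillna(0.0)
        frame["present"] = (frame["biomass"] > 0).astype(int)
        frame["logbio"] = np.where(frame["present"] == 1,
                                   np.log(frame["biomass"].where(frame["biomass"] > 0)),
                                   np.nan)
        ann = frame.groupby("year")["biomass"].mean()
        frame["abundance"] = frame["year"].map(ann)
        npos = int(frame["present"].sum())
        if npos < min_positive:
            raise ValueError(f"{species}: only {npos} positive hauls "
                             f"(< {min_positive})")
        return cls(species, frame, **kwargs)

    def _smoother(self, df: pd.DataFrame) -> BSplines:
        x = df[["sst", "bt"]].to_numpy(dtype=float)
        return BSplines(x, df=[self.k_basis] * 2, degree=[3, 3])

    def fit(self) -> "EnvelopeResults":
        """Fit both submodels; returns an :class:`EnvelopeResults`."""
        frame = self.frame
        exog = _design(frame, self.strata)
        constant_presence = frame["present"].nunique() == 1
        pres_res = None
        if constant_presence:
            logger.warning("%s: single presence class; presence submodel "
                           "treated as constant", self.species)
        else:
            bs = self._smoother(frame)
            pres_res = GLMGam(frame["present"].to_numpy(dtype=float),
                              exog=exog, smoother=bs,
                              alpha=[self.alpha] * 2,
                              family=sm.families.Binomial()).fit()
        pos = frame[frame["present"] == 1]
        bs_pos = self._smoother(pos)
        pos_res = GLMGam(pos["logbio"].to_numpy(dtype=float),
                         exog=_design(pos, self.strata), smoother=bs_pos,
                         alpha=[self.alpha] * 2,
                         family=sm.families.Gaussian()).fit()
        resid = pos["logbio"].to_numpy() - pos_res.predict()
        sigma2 = float(np.var(resid, ddof=1))
        return EnvelopeResults(self, pres_res, pos_res, sigma2,
                               constant_presence=constant_presence,
                               constant_presence_value=float(frame["present"].iloc[0])
                               if constant_presence else np.nan)


@dataclass
class EnvelopeResults:
    """Fitted delta-lognormal envelope: presence and positive submodels
    plus the lognormal variance used in the back-transform."""

    model: DeltaLognormalEnvelope
    presence: object | None
    positive: object
    sigma2: float
    constant_presence: bool = False
    constant_presence_value: float = np.nan
    clamp_count_: int = dfield(default=0, init=False)

    def _clamped(self, hauls: pd.DataFrame, submodel: str) -> pd.DataFrame:
        df = hauls.copy()
        lo = self.model.clamp_lo if submodel == "presence" else self.model.clamp_lo_pos
        hi = self.model.clamp_hi if submodel == "presence" else self.model.clamp_hi_pos
        before = df[["sst", "bt"]].to_numpy()
        for c in ("sst", "bt"):
            df[c] = df[c].clip(lo[c], hi[c])
        self.clamp_count_ += int((df[["sst", "bt"]].to_numpy() != before).sum())
        return df

    def predict(self, hauls: pd.DataFrame) -> np.ndarray:
        """Per-haul envelope weight p̂ · exp(μ̂ + σ̂²/2) ≥ 0.

        Requires columns sst, bt, stratum, abundance (``abundance`` is
        filled from the training annual means by year when absent).
        Covariates outside the training 1st-99th percentiles are clamped
        and counted in ``clamp_count_``.
        """
        df = hauls.copy()
        if "abundance" not in df.columns:
            ann = self.model.frame.groupby("year")["abundance"].first()
            df["abundance"] = df["year"].map(ann).fillna(ann.mean())
        df["stratum"] = np.where(df["stratum"].isin(self.model.strata),
                                 df["stratum"], "_pooled")
        if "_pooled" not in self.model.strata:
            df.loc[~df["stratum"].isin(self.model.strata), "stratum"] = \
                self.model.strata[0]
        self.clamp_count_ = 0
        dfp = self._clamped(df, "presence")
        exog = _design(dfp, self.model.strata)
        if self.constant_presence:
            p = np.full(len(df), self.constant_presence_value)
        else:
            xs = dfp[["sst", "bt"]].to_numpy(dtype=float)
            p = np.asarray(self.presence.predict(exog=exog, exog_smooth=xs))
        dpos = self._clamped(df, "positive")
        xs_pos = dpos[["sst", "bt"]].to_numpy(dtype=float)
        mu = np.asarray(self.positive.predict(exog=_design(dpos, self.model.strata),
                                              exog_smooth=xs_pos))
        return np.clip(delta_weight(p, mu, self.sigma2), 0.0, None)

    def summary(self) -> str:
        lines = [f"Delta-lognormal envelope: {self.model.species}",
                 f"  hauls: {len(self.model.frame)}, positives: "
                 f"{int(self.model.frame['present'].sum())}",
                 f"  sigma^2 (log scale): {self.sigma2:.4f}"]
        if self.constant_presence:
            lines.append(f"  presence: constant {self.constant_presence_value:.0f}")
        else:
            lines.append("  presence submodel (binomial GAM):")
            lines.append(str(self.presence.summary()))
        lines.append("  positive submodel (Gaussian GAM on log biomass):")
        lines.append(str(self.positive.summary()))
        return "\n".join(lines)


def envelope_centroids(results: EnvelopeResults, hauls: pd.DataFrame,
                       scheme: PeriodScheme, region: str, season: str
                       ) -> pd.DataFrame:
    """Prediction-weighted mean latitude and depth per five-year block.

    The prediction domain is the actual haul set of each block, so the
    envelope centroid responds to where suitable temperatures were
    located in that block.  Blocks with zero total weight are absent.
    """
    h = hauls[(hauls["region"] == region) & (hauls["season"] == season)]
    rows = []
    for b, (a, z) in enumerate(scheme.blocks, start=1):
        hb = h[h["year"].between(a, z)]
        if hb.empty:
            continue
        w = results.predict(hb)
        if w.sum() <= 0:
            continue
        rows.append({"block": b, "year_mid": scheme.block_midpoint(b),
                     "latitude": float(np.average(hb["latitude"], weights=w)),
                     "depth": float(np.average(hb["depth"], weights=w)),
                     "weight_sum": float(w.sum()), "n_hauls": len(hb)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class VelocityEstimate:
    """Taxon-specific climate velocity: slopes of envelope-centroid
    latitude and depth against block midpoint year, paired with the
    observed biomass-centroid slopes for the same species."""

    species: str
    lat: TrendFit
    depth: TrendFit
    observed_lat: TrendFit | None = None
    observed_depth: TrendFit | None = None

    def ci(self, axis: str = "lat", level: float = 0.95) -> tuple[float, float]:
        fit = self.lat if axis == "lat" else self.depth
        half = stats.t.ppf(0.5 + level / 2, fit.n - 2) * fit.se
        return fit.slope - half, fit.slope + half


def climate_velocity(centroids: pd.DataFrame, species: str,
                     observed: pd.DataFrame | None = None) -> VelocityEstimate:
    """Regress envelope-centroid latitude and depth on time (°N/yr and
    m/yr); attach observed-centroid slopes when given."""
    lat = trend_regression(centroids["year_mid"], centroids["latitude"])
    dep = trend_regression(centroids["year_mid"], centroids["depth"])
    obs_lat = obs_dep = None
    if observed is not None and len(observed) >= 3:
        obs_lat = trend_regression(observed["year_mid"], observed["latitude"])
        obs_dep = trend_regression(observed["year_mid"], observed["depth"])
    return VelocityEstimate(species, lat, dep, obs_lat, obs_dep)


def compare_observed_vs_velocity(pairs: pd.DataFrame) -> dict:
    """OLS of observed shift rate on predicted climate velocity across
    species (one axis at a time).

    *pairs* needs columns ``predicted`` and ``observed``.  Returns the
    fitted slope/intercept, r² (and adjusted), p of the slope, and the
    deviation of the fitted line from the 1:1 line at the mean
    predicted velocity.
    """
    if len(pairs) < 3:
        raise ValueError("need >= 3 species pairs")
    x = pairs["predicted"].to_numpy(dtype=float)
    y = pairs["observed"].to_numpy(dtype=float)
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    xbar = x.mean()
    return {"slope": float(res.params[1]), "intercept": float(res.params[0]),
            "r2": float(res.rsquared), "r2_adj": float(res.rsquared_adj),
            "p": float(res.pvalues[1]), "n": int(len(pairs)),
            "deviation_from_1to1": float(res.params[0]
                                         + res.params[1] * xbar - xbar)}


@dataclass(frozen=True)
class GroupComparison:
    h: float
    df: int
    p: float
    groups: tuple[str, ...]


def kruskal_wallis(values: pd.Series, groups: pd.Series,
                   min_group: int = 2) -> GroupComparison:
    """Kruskal-Wallis rank-sum test of velocity differences between
    assemblages, with tie correction; groups smaller than *min_group*
    are dropped with a warning."""
    df = pd.DataFrame({"v": np.asarray(values, dtype=float),
                       "g": np.asarray(groups)}).dropna()
    sizes = df.groupby("g").size()
    keep = sizes[sizes >= min_group].index
    dropped = sorted(set(sizes.index) - set(keep))
    if dropped:
        logger.warning("kruskal_wallis dropping small groups: %s", dropped)
    df = df[df["g"].isin(keep)]
    samples = [g["v"].to_numpy() for _, g in df.groupby("g")]
    if len(samples) < 2:
        raise ValueError("need >= 2 groups of sufficient size")
    h, p = stats.kruskal(*samples)
    return GroupComparison(float(h), len(samples) - 1, float(p),
                           tuple(str(k) for k in sorted(keep)))
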