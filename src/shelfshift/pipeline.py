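"""End-to-end orchestration: survey in, assemblage climate-response
tables out.

``run_all`` executes the full chain — read/simulate survey, rare-
species filter, dual clustering and core species per decadal period,
biomass-centroid shift geometry, delta-lognormal envelopes and climate
velocities, kernel areas and the mixed-effects area model — and writes
every table as delimited text plus a JSON manifest carrying the config
hash and seed, so identical config + seed reproduce an identical
bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, envelope, geometry, habitat, survey, synthetic

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One config for the whole pipeline; YAML-loadable via
    :meth:`from_yaml`.  Unknown keys are rejected so typos fail fast."""

    # input: either simulate or read files
    simulate: bool = True
    haul_path: str | None = None
    catch_path: str | None = None
    stratum_region: dict | None = None
    axis_vertices: dict | None = None      # region -> {lats: [...], lons: [...]}
    # simulation scale
    years_start: int = 1968
    years_end: int = 2012
    hauls_per_year: int = 70
    warm_rate: float = 2.0 / 45.0
    species_per_assemblage: int = 4
    seasons: tuple = ("fall",)
    regions: tuple = ("north", "south")
    # filtering / clustering
    min_years: int = 10
    k: int = 4
    n_restarts: int = 25
    standardize: bool = True
    min_core_periods: int = 3
    # shift geometry / velocity
    min_blocks: int = 6
    envelope_min_positive: int = 50
    envelope_k_basis: int = 5
    envelope_alpha: float = 1.0
    # habitat
    cell_km: float = 2.0
    mask_radius_km: float = 25.0
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not self.simulate:
            for name in ("haul_path", "catch_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"config field '{name}' required when "
                                     "simulate is false")
                if not Path(p).exists():
                    raise ValueError(f"{name}: file not found: {p}")
        if self.simulate is False and self.axis_vertices is None:
            raise ValueError("config field 'axis_vertices' required when "
                             "reading external surveys")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("seasons", "regions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]

    def axis_for(self, region: str) -> geometry.ShelfAxis:
        if self.axis_vertices and region in self.axis_vertices:
            v = self.axis_vertices[region]
            return geometry.ShelfAxis(np.asarray(v["lats"]), np.asarray(v["lons"]))
        return geometry.ShelfAxis.for_region(region)


def _substream(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the global seed."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def load_inputs(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict | None]:
    if cfg.simulate:
        hauls, catches, truth = synthetic.two_region_world(
            seed=_substream(cfg.seed, "simulate"),
            years=range(cfg.years_start, cfg.years_end + 1),
            hauls_per_year=cfg.hauls_per_year, warm_rate=cfg.warm_rate,
            n_per=cfg.species_per_assemblage, seasons=cfg.seasons)
        return hauls, catches, truth
    hauls, catches, _ = survey.read_survey(
        cfg.haul_path, cfg.catch_path,
        config={"stratum_region": cfg.stratum_region})
    return hauls, catches, None


def cluster_stage(hauls: pd.DataFrame, catches: pd.DataFrame, cfg: RunConfig,
                  region: str, season: str, scheme: survey.PeriodScheme
                  ) -> dict:
    """Niche vectors, dual clustering, and core species for one
    region/season."""
    niche_frames, solutions = [], {}
    seed = _substream(cfg.seed, f"cluster:{region}:{season}")
    for period in range(1, len(scheme.decadal_periods) + 1):
        nv = clustering.compute_niche_vectors(hauls, catches, scheme,
                                              period, region, season)
        if len(nv) < cfg.k:
            logger.warning("%s/%s period %d: %d species < k; skipped",
                           region, season, period, len(nv))
            continue
        km, hc = clustering.cluster_dual(nv, k=cfg.k, seed=seed,
                                         standardize=cfg.standardize,
                                         n_restarts=cfg.n_restarts,
                                         region=region, season=season,
                                         period=period)
        solutions[("kmeans", period)] = km
        solutions[("hclust", period)] = hc
        nv = nv.copy()
        nv["period"] = period
        nv["kmeans"] = km.labels
        nv["hclust"] = hc.labels
        niche_frames.append(nv.reset_index())
    core_table, assemblages = clustering.core_species(
        solutions, min_periods=cfg.min_core_periods,
        n_periods=len(scheme.decadal_periods), region=region, season=season)
    return {"niches": pd.concat(niche_frames, ignore_index=True)
            if niche_frames else pd.DataFrame(),
            "solutions": solutions, "core_table": core_table,
            "assemblages": assemblages}


def shift_stage(hauls: pd.DataFrame, catches: pd.DataFrame, cfg: RunConfig,
                region: str, season: str, scheme: survey.PeriodScheme,
                core_table: pd.DataFrame) -> dict:
    """Shift vectors, Rayleigh tests per assemblage, and observed
    centroid trend regressions for the core species of one
    region/season."""
    axis = cfg.axis_for(region)
    h = hauls[(hauls["region"] == region) & (hauls["season"] == season)]
    core = core_table[core_table["core"]]
    p_first = scheme.period_years(1)
    p_last = scheme.period_years(len(scheme.decadal_periods))
    shift_rows, trend_rows, series = [], [], {}
    for sp, row in core.iterrows():
        c1 = geometry.biomass_centroid(h, catches, sp, p_first, axis)
        c4 = geometry.biomass_centroid(h, catches, sp, p_last, axis)
        cs = geometry.centroid_series(h, catches, sp, scheme, axis)
        series[sp] = cs
        rec = {"species": sp, "assemblage": int(row["label"]),
               "bearing": np.nan, "distance_km": np.nan,
               "deepening": False}
        if c1 is not None and c4 is not None:
            sv = geometry.shift_vector(c1, c4)
            rec["bearing"], rec["distance_km"] = sv.bearing, sv.distance
        if len(cs) >= max(3, cfg.min_blocks):
            lat_fit = geometry.trend_regression(cs["year_mid"], cs["latitude"])
            dep_fit = geometry.trend_regression(cs["year_mid"], cs["depth"])
            rec["deepening"] = geometry.deepening_flag(dep_fit)
            trend_rows.append({
                "species": sp, "assemblage": int(row["label"]),
                "lat_slope": lat_fit.slope, "lat_se": lat_fit.se,
                "lat_p": lat_fit.p, "depth_slope": dep_fit.slope,
                "depth_se": dep_fit.se, "depth_p": dep_fit.p,
                "n_blocks": len(cs)})
        shift_rows.append(rec)
    shifts = pd.DataFrame(shift_rows)
    circ_rows = []
    if not shifts.empty:
        for lab, g in shifts.dropna(subset=["bearing"]).groupby("assemblage"):
            if len(g) < 2:
                continue
            ct = geometry.rayleigh_test(g["bearing"].to_numpy())
            circ_rows.append({"assemblage": lab, "n": ct.n, "rbar": ct.rbar,
                              "mean_bearing": ct.mean_deg, "z": ct.z,
                              "p": ct.p})
    return {"shifts": shifts, "circular": pd.DataFrame(circ_rows),
            "trends": pd.DataFrame(trend_rows), "series": series}


def velocity_stage(hauls: pd.DataFrame, catches: pd.DataFrame, cfg: RunConfig,
                   region: str, season: str, scheme: survey.PeriodScheme,
                   core_table: pd.DataFrame, series: dict) -> dict:
    """Envelope fits, climate velocities, observed-vs-predicted
    comparisons, and Kruskal-Wallis contrasts for one region/season."""
    core = core_table[core_table["core"]]
    h = hauls[(hauls["region"] == region) & (hauls["season"] == season)]
    vel_rows, predictions = [], {}
    for sp, row in core.iterrows():
        try:
            model = envelope.DeltaLognormalEnvelope.from_survey(
                sp, hauls, catches, region, season,
                min_positive=cfg.envelope_min_positive,
                k_basis=cfg.envelope_k_basis, alpha=cfg.envelope_alpha)
            res = model.fit()
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("envelope skipped for %s: %s", sp, exc)
            continue
        predictions[sp] = res.predict(h)
        cents = envelope.envelope_centroids(res, hauls, scheme, region, season)
        obs = series.get(sp)
        if len(cents) < max(3, cfg.min_blocks) or obs is None \
                or len(obs) < max(3, cfg.min_blocks):
            continue
        ve = envelope.climate_velocity(cents, sp, observed=obs)
        lo_lat, hi_lat = ve.ci("lat")
        vel_rows.append({
            "species": sp, "assemblage": int(row["label"]),
            "pred_lat_slope": ve.lat.slope, "pred_lat_se": ve.lat.se,
            "pred_lat_lo": lo_lat, "pred_lat_hi": hi_lat,
            "pred_depth_slope": ve.depth.slope, "pred_depth_se": ve.depth.se,
            "obs_lat_slope": ve.observed_lat.slope,
            "obs_depth_slope": ve.observed_depth.slope})
    velocities = pd.DataFrame(vel_rows)
    comparisons, kw_rows = [], []
    if len(velocities) >= 3:
        for axis_name in ("lat", "depth"):
            pairs = velocities.rename(columns={
                f"pred_{axis_name}_slope": "predicted",
                f"obs_{axis_name}_slope": "observed"})
            fit = envelope.compare_observed_vs_velocity(pairs)
            fit.update(region=region, season=season, axis=axis_name)
            comparisons.append(fit)
            if velocities["assemblage"].nunique() >= 2:
                try:
                    kw = envelope.kruskal_wallis(
                        velocities[f"pred_{axis_name}_slope"],
                        velocities["assemblage"])
                    kw_rows.append({"region": region, "season": season,
                                    "axis": axis_name, "H": kw.h,
                                    "df": kw.df, "p": kw.p})
                except ValueError:
                    pass
    return {"velocities": velocities, "comparisons": pd.DataFrame(comparisons),
            "kruskal": pd.DataFrame(kw_rows), "predictions": predictions}


def area_stage(hauls: pd.DataFrame, catches: pd.DataFrame, cfg: RunConfig,
               region: str, season: str, scheme: survey.PeriodScheme,
               assemblages, predictions: dict) -> pd.DataFrame:
    """Kernel core areas, thermal areas and total biomass per
    assemblage-block for one region/season."""
    rows = []
    for asm in assemblages:
        sp_with_pred = [s for s in asm.core_species if s in predictions]
        if not sp_with_pred:
            continue
        for b, span in enumerate(scheme.blocks, start=1):
            out = habitat.assemblage_surfaces(
                hauls, catches, predictions, sp_with_pred, span, region,
                season, cell_km=cfg.cell_km,
                mask_radius_km=cfg.mask_radius_km)
            if out is None:
                continue
            bio_field, th_field, total_bio = out
            rows.append({
                "region": region, "season": season, "assemblage": asm.label,
                "block": b, "year_mid": scheme.block_midpoint(b),
                "kernel_area": habitat.core_area(bio_field).area_km2,
                "thermal_area": habitat.core_area(th_field).area_km2,
                "biomass": total_bio})
    return pd.DataFrame(rows)


def run_all(cfg: RunConfig, out_dir=None) -> dict:
    """Run every stage for every configured region/season; returns the
    result bundle and optionally writes it under *out_dir*."""
    scheme = survey.PeriodScheme()
    hauls, catches, truth = load_inputs(cfg)
    catches = survey.filter_rare_species(catches, hauls,
                                         min_years=cfg.min_years)
    logger.info("inputs: %d hauls, %d catch rows after rare filter",
                len(hauls), len(catches))
    bundle: dict = {"hauls": hauls, "catches": catches, "truth": truth,
                    "tables": {}}
    area_rows = []
    for region in cfg.regions:
        for season in cfg.seasons:
            key = f"{region}_{season}"
            cl = cluster_stage(hauls, catches, cfg, region, season, scheme)
            sh = shift_stage(hauls, catches, cfg, region, season, scheme,
                             cl["core_table"])
            ve = velocity_stage(hauls, catches, cfg, region, season, scheme,
                                cl["core_table"], sh["series"])
            ar = area_stage(hauls, catches, cfg, region, season, scheme,
                            cl["assemblages"], ve["predictions"])
            area_rows.append(ar)
            bundle["tables"][f"niches_{key}"] = cl["niches"]
            bundle["tables"][f"core_{key}"] = cl["core_table"].reset_index()
            bundle["tables"][f"shifts_{key}"] = sh["shifts"]
            bundle["tables"][f"circular_{key}"] = sh["circular"]
            bundle["tables"][f"trends_{key}"] = sh["trends"]
            bundle["tables"][f"velocity_{key}"] = ve["velocities"]
            bundle["tables"][f"comparison_{key}"] = ve["comparisons"]
            bundle["tables"][f"kruskal_{key}"] = ve["kruskal"]
    areas = pd.concat(area_rows, ignore_index=True) if area_rows else pd.DataFrame()
    bundle["tables"]["areas"] = areas
    if len(areas) >= 10 and areas["region"].nunique() >= 2:
        fit = habitat.AssemblageAreaModel.from_dataframe(areas).fit()
        bundle["area_model"] = fit
        bundle["tables"]["area_model"] = pd.DataFrame({
            "term": fit.params.index, "estimate": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(), "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy()})
    if out_dir is not None:
        write_bundle(bundle, cfg, out_dir)
    return bundle


def write_bundle(bundle: dict, cfg: RunConfig, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": cfg.digest(), "seed": cfg.seed, "tables": {}}
    survey.write_survey(bundle["hauls"], bundle["catches"],
                        out / "hauls.csv", out / "catches.csv")
    for name, table in bundle["tables"].items():
        path = out / f"{name}.csv"
        table.to_csv(path, index=False)
        manifest["tables"][name] = {
            "rows": int(len(table)),
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest()[:16]}
    if bundle.get("truth") is not None:
        (out / "truth.json").write_text(
            json.dumps(bundle["truth"], indent=1, default=float))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("bundle written to %s", out)
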