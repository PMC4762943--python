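"""Survey and catch table I/O, validation, and temporal schemes.

The canonical in-memory containers are two pandas DataFrames:

* **hauls** — one row per sampled tow, columns ``haul_id, year, season,
  region, latitude, longitude, depth, sst, bt, stratum``.
* **catches** — one row per (haul, species) with positive biomass,
  columns ``haul_id, species, biomass``.  Hauls absent from the catch
  table for a species are implicit zero catches.

Depth is in meters (positive down), temperatures in °C, biomass in kg
per standardized tow, coordinates in decimal degrees with longitude
negative west.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HAUL_COLUMNS = [
    "haul_id", "year", "season", "region", "latitude", "longitude",
    "depth", "sst", "bt", "stratum",
]
CATCH_COLUMNS = ["haul_id", "species", "biomass"]

SEASONS = ("spring", "fall")
REGIONS = ("north", "south")


def _default_periods() -> list[tuple[int, int]]:
    return [(1968, 1978), (1979, 1989), (1990, 2000), (2001, 2012)]


def _default_blocks() -> list[tuple[int, int]]:
    return [(y, y + 4) for y in range(1968, 2012, 5)]


@dataclass(frozen=True)
class PeriodScheme:
    """Temporal partition of the survey: four roughly decadal periods used
    for assemblage definition, and contiguous five-year blocks used for
    centroid time series.

    Defaults cover 1968-2012: periods 1968-1978, 1979-1989, 1990-2000,
    2001-2012 and nine five-year blocks 1968-1972 ... 2008-2012.
    """

    decadal_periods: list[tuple[int, int]] = field(default_factory=_default_periods)
    blocks: list[tuple[int, int]] = field(default_factory=_default_blocks)

    def __post_init__(self) -> None:
        for name, spans in (("decadal_periods", self.decadal_periods),
                            ("blocks", self.blocks)):
            for (a, b) in spans:
                if b < a:
                    raise ValueError(f"{name}: invalid span ({a}, {b})")
            for (a0, b0), (a1, b1) in zip(spans, spans[1:]):
                if a1 != b0 + 1:
                    raise ValueError(f"{name}: spans not contiguous at {b0}/{a1}")

    @property
    def year_min(self) -> int:
        return self.decadal_periods[0][0]

    @property
    def year_max(self) -> int:
        return self.decadal_periods[-1][1]

    def assign_period(self, year: int) -> int:
        """1-based decadal period index for *year*."""
        for i, (a, b) in enumerate(self.decadal_periods, start=1):
            if a <= year <= b:
                return i
        raise ValueError(f"year {year} outside period scheme "
                         f"({self.year_min}-{self.year_max})")

    def assign_block(self, year: int) -> int:
        """1-based five-year block index for *year*."""
        for i, (a, b) in enumerate(self.blocks, start=1):
            if a <= year <= b:
                return i
        raise ValueError(f"year {year} outside block scheme")

    def block_midpoint(self, block: int) -> float:
        a, b = self.blocks[block - 1]
        return (a + b) / 2.0

    def period_years(self, period: int) -> tuple[int, int]:
        return self.decadal_periods[period - 1]

    def periods_of(self, years: pd.Series) -> pd.Series:
        edges = [a for a, _ in self.decadal_periods] + [self.year_max + 1]
        return pd.Series(
            np.searchsorted(edges, np.asarray(years), side="right"),
            index=years.index,
        )

    def blocks_of(self, years: pd.Series) -> pd.Series:
        edges = [a for a, _ in self.blocks] + [self.blocks[-1][1] + 1]
        return pd.Series(
            np.searchsorted(edges, np.asarray(years), side="right"),
            index=years.index,
        )


def validate_hauls(hauls: pd.DataFrame, scheme: PeriodScheme | None = None
                   ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop haul rows violating invariants; return (clean, rejection counts)."""
    counts: dict[str, int] = {}
    df = hauls.copy()
    n0 = len(df)
    df = df.dropna(subset=[c for c in HAUL_COLUMNS if c in df.columns])
    counts["missing_values"] = n0 - len(df)

    bad = ~df["season"].isin(SEASONS)
    counts["bad_season"] = int(bad.sum())
    df = df[~bad]
    bad = ~df["region"].isin(REGIONS)
    counts["bad_region"] = int(bad.sum())
    df = df[~bad]

    bad = ~(df["depth"] > 0)
    counts["nonpositive_depth"] = int(bad.sum())
    df = df[~bad]
    bad = ~df["latitude"].between(-90, 90)
    counts["bad_latitude"] = int(bad.sum())
    df = df[~bad]
    if scheme is not None:
        bad = ~df["year"].between(scheme.year_min, scheme.year_max)
        counts["year_out_of_range"] = int(bad.sum())
        df = df[~bad]
    dup = df["haul_id"].duplicated()
    counts["duplicate_haul_id"] = int(dup.sum())
    df = df[~dup]

    dropped = {k: v for k, v in counts.items() if v}
    if dropped:
        logger.warning("validate_hauls rejected rows: %s", dropped)
    return df.reset_index(drop=True), counts


def validate_catches(catches: pd.DataFrame, hauls: pd.DataFrame
                     ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop catch rows with negative biomass or unknown haul ids."""
    counts: dict[str, int] = {}
    df = catches.copy()
    n0 = len(df)
    df = df.dropna(subset=CATCH_COLUMNS)
    counts["missing_values"] = n0 - len(df)
    bad = df["biomass"] < 0
    counts["negative_biomass"] = int(bad.sum())
    df = df[~bad]
    known = df["haul_id"].isin(set(hauls["haul_id"]))
    counts["unknown_haul_id"] = int((~known).sum())
    df = df[known]
    dropped = {k: v for k, v in counts.items() if v}
    if dropped:
        logger.warning("validate_catches rejected rows: %s", dropped)
    return df.reset_index(drop=True), counts


def read_survey(haul_path, catch_path, config: dict | None = None,
                scheme: PeriodScheme | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Read haul and catch tables from delimited text files.

    ``config`` may carry ``sep`` (default ``,``) and ``stratum_region``,
    a mapping stratum id -> region used when the haul table has no
    ``region`` column.  Rows failing invariants are dropped and counted
    in the returned log; missing required columns are fatal.
    """
    config = config or {}
    sep = config.get("sep", ",")
    hauls = pd.read_csv(haul_path, sep=sep, dtype={"haul_id": str, "stratum": str})
    catches = pd.read_csv(catch_path, sep=sep, dtype={"haul_id": str})

    if "region" not in hauls.columns:
        mapping = config.get("stratum_region")
        if mapping is None:
            raise ValueError("haul table has no 'region' column and no "
                             "'stratum_region' mapping was supplied")
        hauls["region"] = hauls["stratum"].map(mapping)

    missing = [c for c in HAUL_COLUMNS if c not in hauls.columns]
    if missing:
        raise ValueError(f"haul table missing columns: {missing}")
    missing = [c for c in CATCH_COLUMNS if c not in catches.columns]
    if missing:
        raise ValueError(f"catch table missing columns: {missing}")

    for c in ("latitude", "longitude", "depth", "sst", "bt"):
        hauls[c] = pd.to_numeric(hauls[c], errors="coerce")
    hauls["year"] = pd.to_numeric(hauls["year"], errors="coerce").astype("Int64")
    catches["biomass"] = pd.to_numeric(catches["biomass"], errors="coerce")

    hauls, hcounts = validate_hauls(hauls, scheme)
    hauls["year"] = hauls["year"].astype(int)
    catches, ccounts = validate_catches(catches, hauls)
    log = {"hauls_read": len(hauls), "catches_read": len(catches),
           "haul_rejections": hcounts, "catch_rejections": ccounts}
    return hauls, catches, log


def write_survey(hauls: pd.DataFrame, catches: pd.DataFrame,
                 haul_path, catch_path, sep: str = ",") -> None:
    hauls.to_csv(haul_path, sep=sep, index=False)
    catches.to_csv(catch_path, sep=sep, index=False)


def filter_rare_species(catches: pd.DataFrame, hauls: pd.DataFrame,
                        min_years: int = 10, per_region: bool = True
                        ) -> pd.DataFrame:
    """Remove species caught (biomass > 0) in fewer than *min_years*
    distinct years.

    Applied within each region when ``per_region`` is set, since all
    downstream analyses are regional; a species may pass in one region
    and be dropped in the other.
    """
    if min_years <= 0:
        return catches.copy()
    joined = catches[catches["biomass"] > 0].merge(
        hauls[["haul_id", "year", "region"]], on="haul_id", how="inner")
    if per_region:
        ny = joined.groupby(["region", "species"])["year"].nunique()
        keep = set(ny[ny >= min_years].index)  # (region, species) pairs
        tagged = catches.merge(hauls[["haul_id", "region"]], on="haul_id")
        mask = [(r, s) in keep for r, s in zip(tagged["region"], tagged["species"])]
        out = catches[np.asarray(mask)]
    else:
        ny = joined.groupby("species")["year"].nunique()
        keep_sp = set(ny[ny >= min_years].index)
        out = catches[catches["species"].isin(keep_sp)]
    n_dropped = catches["species"].nunique() - out["species"].nunique()
    if n_dropped:
        logger.info("filter_rare_species removed %d species entirely", n_dropped)
    return out.reset_index(drop=True)
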