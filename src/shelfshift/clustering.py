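"""Bathy-thermal niche vectors and dual-method assemblage clustering.

Each species in a period is summarized by its abundance-weighted mean
depth, surface temperature, and bottom temperature over the hauls where
it was caught — its realized bathy-thermal niche.  Species are then
clustered with both k-means and complete-linkage hierarchical
clustering on z-scored features; cluster labels are renumbered so label
1 is the shallowest assemblage.  "Core" species are those the two
methods co-assign to the same depth-ordered label in at least three of
the four decadal periods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .survey import PeriodScheme

logger = logging.getLogger(__name__)

FEATURES = ["mean_depth_w", "mean_sst_w", "mean_bt_w"]


def compute_niche_vectors(hauls: pd.DataFrame, catches: pd.DataFrame,
                          scheme: PeriodScheme, period: int,
                          region: str, season: str) -> pd.DataFrame:
    """Abundance-weighted mean depth/SST/BT per species for one decadal
    period, region, and season.

    Each component is sum(biomass * x) / sum(biomass) over the hauls
    with positive catch.  Species with zero total biomass in the period
    are omitted with a warning.
    """
    a, b = scheme.period_years(period)
    h = hauls[(hauls["region"] == region) & (hauls["season"] == season)
              & hauls["year"].between(a, b)]
    j = catches[catches["biomass"] > 0].merge(h, on="haul_id")
    if j.empty:
        return pd.DataFrame(columns=FEATURES + ["n_hauls"])
    rows = {}
    for sp, g in j.groupby("species"):
        w = g["biomass"].to_numpy()
        if w.sum() <= 0:
            logger.warning("species %s has zero biomass in period %d; omitted",
                           sp, period)
            continue
        rows[sp] = {
            "mean_depth_w": float(np.average(g["depth"], weights=w)),
            "mean_sst_w": float(np.average(g["sst"], weights=w)),
            "mean_bt_w": float(np.average(g["bt"], weights=w)),
            "n_hauls": int(len(g)),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "species"
    return out.sort_index()


@dataclass
class ClusterSolution:
    method: str                     # 'kmeans' | 'hclust'
    k: int
    labels: pd.Series               # species -> depth-ordered label 1..k
    region: str | None = None
    season: str | None = None
    period: int | None = None


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _depth_order(labels: np.ndarray, niches: pd.DataFrame) -> np.ndarray:
    """Renumber labels so mean cluster depth increases with label; ties
    broken by mean bottom temperature ascending."""
    df = pd.DataFrame({"lab": labels,
                       "depth": niches["mean_depth_w"].to_numpy(),
                       "bt": niches["mean_bt_w"].to_numpy()})
    order = (df.groupby("lab")[["depth", "bt"]].mean()
             .sort_values(["depth", "bt"]).index)
    remap = {old: new for new, old in enumerate(order, start=1)}
    return np.array([remap[v] for v in labels])


def cluster_dual(niches: pd.DataFrame, k: int = 4, seed: int = 0,
                 standardize: bool = True, n_restarts: int = 25,
                 **meta) -> tuple[ClusterSolution, ClusterSolution]:
    """Cluster niche vectors with k-means (25 restarts, best SSE) and
    complete-linkage hierarchical clustering on Euclidean distances of
    z-scored features, both cut at *k* and depth-order relabeled."""
    if len(niches) < k:
        raise ValueError(f"need at least k={k} species, have {len(niches)}")
    X = niches[FEATURES].to_numpy(dtype=float)
    if standardize:
        X = _standardize(X)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
    km_labels = _depth_order(km.labels_, niches)
    Z = hierarchy.linkage(X, method="complete", metric="euclidean")
    hc = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    hc_labels = _depth_order(hc, niches)
    mk = dict(meta, k=k)
    return (ClusterSolution("kmeans", labels=pd.Series(km_labels, index=niches.index), **mk),
            ClusterSolution("hclust", labels=pd.Series(hc_labels, index=niches.index), **mk))


def _connectivity(D: np.ndarray, labels: np.ndarray, L: int = 10) -> float:
    """clValid-style connectivity: for each observation, penalty 1/j for
    each of its j = 1..L nearest neighbors not in the same cluster.
    Lower is better."""
    n = D.shape[0]
    L = min(L, n - 1)
    conn = 0.0
    for i in range(n):
        nn = np.argsort(D[i])
        nn = nn[nn != i][:L]
        for j, idx in enumerate(nn, start=1):
            if labels[idx] != labels[i]:
                conn += 1.0 / j
    return conn


def _compactness(D: np.ndarray, labels: np.ndarray) -> float:
    """Average within-cluster pairwise dissimilarity (lower is better)."""
    vals, wsum, cnt = np.unique(labels), 0.0, 0
    for v in vals:
        idx = np.flatnonzero(labels == v)
        if idx.size < 2:
            continue
        sub = D[np.ix_(idx, idx)]
        iu = np.triu_indices(idx.size, k=1)
        wsum += sub[iu].sum()
        cnt += iu[0].size
    return wsum / cnt if cnt else 0.0


def _dunn(D: np.ndarray, labels: np.ndarray) -> float:
    """Dunn index: min between-cluster distance / max within-cluster
    diameter (higher is better); reported alongside compactness since
    the named validity measure is ambiguous between the two."""
    vals = np.unique(labels)
    if vals.size < 2:
        return np.nan
    min_between, max_within = np.inf, 0.0
    for a_i, va in enumerate(vals):
        ia = np.flatnonzero(labels == va)
        if ia.size > 1:
            max_within = max(max_within, D[np.ix_(ia, ia)].max())
        for vb in vals[a_i + 1:]:
            ib = np.flatnonzero(labels == vb)
            min_between = min(min_between, D[np.ix_(ia, ib)].min())
    return min_between / max_within if max_within > 0 else np.nan


def validate_k(niches: pd.DataFrame, k_range, seed: int = 0,
               standardize: bool = True, neighbors: int = 10) -> pd.DataFrame:
    """Internal validation of cluster counts for both methods.

    Returns one row per (method, k) with connectivity (lower better),
    compactness (mean within-cluster distance, lower better), Dunn
    index (higher better), and mean silhouette width.  Degenerate
    solutions (a single effective cluster) are flagged with NaN
    silhouette rather than raising.
    """
    X = niches[FEATURES].to_numpy(dtype=float)
    if standardize:
        X = _standardize(X)
    D = squareform(pdist(X))
    rows = []
    for k in k_range:
        if not 2 <= k <= len(niches) - 1:
            raise ValueError(f"k={k} outside [2, n_species-1]")
        for sol in cluster_dual(niches, k=k, seed=seed, standardize=standardize):
            lab = sol.labels.to_numpy()
            if np.unique(lab).size < 2:
                sil = np.nan
                logger.warning("degenerate %s solution at k=%d", sol.method, k)
            else:
                sil = float(silhouette_score(X, lab, metric="euclidean"))
            rows.append({"method": sol.method, "k": k,
                         "connectivity": _connectivity(D, lab, neighbors),
                         "compactness": _compactness(D, lab),
                         "dunn": _dunn(D, lab),
                         "silhouette": sil})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Assemblage:
    region: str | None
    season: str | None
    label: int
    core_species: tuple[str, ...]


def core_species(solutions: dict[tuple[str, int], ClusterSolution],
                 min_periods: int = 3, n_periods: int = 4,
                 region: str | None = None, season: str | None = None,
                 ) -> tuple[pd.DataFrame, list[Assemblage]]:
    """Persistent core species across periods and methods.

    ``solutions`` maps (method, period) -> ClusterSolution with
    depth-ordered labels.  A species is *stable* in a period when both
    methods give it the same label; it is *core* when it has the same
    stable label in at least *min_periods* periods.  Returns the
    per-species table and the assemblage list.
    """
    records = []
    species = sorted(set().union(*(set(s.labels.index)
                                   for s in solutions.values())))
    for sp in species:
        stable = {}
        for period in range(1, n_periods + 1):
            km = solutions.get(("kmeans", period))
            hc = solutions.get(("hclust", period))
            if km is None or hc is None:
                continue
            if sp in km.labels.index and sp in hc.labels.index \
                    and km.labels[sp] == hc.labels[sp]:
                lab = int(km.labels[sp])
                stable[lab] = stable.get(lab, 0) + 1
        if stable:
            lab, cnt = max(stable.items(), key=lambda kv: kv[1])
            records.append({"species": sp, "label": lab, "stable_periods": cnt,
                            "core": cnt >= min_periods})
        else:
            records.append({"species": sp, "label": pd.NA,
                            "stable_periods": 0, "core": False})
    table = pd.DataFrame(records).set_index("species")
    assemblages = []
    core = table[table["core"]]
    for lab, g in core.groupby("label"):
        assemblages.append(Assemblage(region, season, int(lab),
                                      tuple(sorted(g.index))))
    return table, sorted(assemblages, key=lambda a: a.label)
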