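"""Seasonal water-stress pattern classification.

A season is a daily fraction-of-transpirable-soil-water (FTSW) trajectory
aligned on days after sowing, with phenology landmarks (panicle initiation,
flowering, maturity).  FTSW below 0.3 marks the onset of water stress — the
level below which transpiration starts to drop.  Seasons are grouped by
average-linkage hierarchical clustering of pairwise dynamic-time-warping
(DTW) distances and labelled early-stress / late-stress / no-stress from
when stress days fall relative to phenology; yield and biomass penalties are
computed against the no-stress seasons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "FTSWSeries",
    "StressClassification",
    "sowing_day",
    "rain_gap",
    "dtw_distance",
    "cluster_seasons",
    "classify_stress",
    "stress_impact",
    "StressPatternModel",
    "StressPatternResult",
]

LABELS = ("early_stress", "late_stress", "no_stress")


@dataclass
class FTSWSeries:
    """One season's daily FTSW indexed by days after sowing."""

    season: str
    ftsw: np.ndarray
    panicle_initiation_day: int | None = None
    flowering_day: int | None = None
    maturity_day: int | None = None
    yield_t_ha: float | None = None
    biomass_t_ha: float | None = None

    def __post_init__(self) -> None:
        self.ftsw = np.asarray(self.ftsw, dtype=float)
        if ((self.ftsw < 0) | (self.ftsw > 1)).any():
            raise ValueError("FTSW values must lie in [0, 1]")
        days = [d for d in (self.panicle_initiation_day, self.flowering_day,
                            self.maturity_day) if d is not None]
        if days != sorted(days):
            raise ValueError("phenology days must be ordered")

    @property
    def has_phenology(self) -> bool:
        return None not in (self.panicle_initiation_day, self.flowering_day,
                            self.maturity_day)


@dataclass(frozen=True)
class StressClassification:
    season: str
    label: str
    cluster: int | None
    onset_day: int | None
    yield_t_ha: float | None = None
    biomass_t_ha: float | None = None


# ---------------------------------------------------------------------------
# Season landmarks
# ---------------------------------------------------------------------------

def sowing_day(rain: np.ndarray, atsw: np.ndarray,
               threshold: float = 10.0) -> int | None:
    """First day (1-based) with ATSW ≥ threshold — the first significant rain
    that wets the profile enough to sow; None when never reached."""
    atsw = np.asarray(atsw, dtype=float)
    if atsw.size == 0:
        raise ValueError("empty season")
    hits = np.nonzero(atsw >= threshold)[0]
    return int(hits[0]) + 1 if hits.size else None


def rain_gap(rain: np.ndarray, significant: float = 10.0) -> int | None:
    """Days strictly between the first and second rain > ``significant`` mm;
    None with fewer than two such events."""
    rain = np.asarray(rain, dtype=float)
    events = np.nonzero(rain > significant)[0]
    if events.size < 2:
        return None
    return int(events[1] - events[0] - 1)


# ---------------------------------------------------------------------------
# DTW and clustering
# ---------------------------------------------------------------------------

def dtw_distance(a: np.ndarray, b: np.ndarray,
                 window: int | None = None) -> float:
    """Dynamic-time-warping distance with absolute-difference local cost.

    Classic symmetric step pattern (match / insert / delete), no warping
    window by default (``window`` enables a Sakoe–Chiba band).  Zero iff the
    two series match exactly after monotone warping.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty series")
    n, m = a.size, b.size
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        j_lo, j_hi = 1, m
        if window is not None:
            j_lo = max(1, i - window)
            j_hi = min(m, i + window)
        cost_row = np.abs(a[i - 1] - b[j_lo - 1:j_hi])
        for j, c in zip(range(j_lo, j_hi + 1), cost_row):
            D[i, j] = c + min(D[i - 1, j], D[i, j - 1], D[i - 1, j - 1])
    return float(D[n, m])


def _pairwise_dtw(series: list[np.ndarray],
                  window: int | None = None) -> np.ndarray:
    n = len(series)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dtw_distance(series[i], series[j], window)
    return d


def _mean_silhouette(dist: np.ndarray, labels: np.ndarray) -> float:
    from sklearn.metrics import silhouette_score

    return float(silhouette_score(dist, labels, metric="precomputed"))


def cluster_seasons(series: list[FTSWSeries] | list[np.ndarray],
                    k: int | str = "auto", seed: int = 0,
                    window: int | None = None,
                    ) -> tuple[np.ndarray, dict]:
    """Average-linkage hierarchical clustering on pairwise DTW distances.

    ``k="auto"`` picks k ∈ {2..6} (bounded by the number of seasons)
    maximising the mean silhouette on the DTW distance matrix.  Identical
    seasons collapse to a single degenerate cluster.  Deterministic; the
    seed is accepted for interface uniformity only.  Returns (labels, info)
    with info containing k, silhouette and the distance matrix.
    """
    arrays = [s.ftsw if isinstance(s, FTSWSeries) else np.asarray(s, float)
              for s in series]
    n = len(arrays)
    if n < 3:
        raise ValueError("need at least three seasons to cluster")
    if isinstance(k, int) and k > n:
        raise ValueError(f"cannot form {k} clusters from {n} seasons")
    dist = _pairwise_dtw(arrays, window)
    if np.allclose(dist, 0):
        return np.zeros(n, dtype=int), {"k": 1, "silhouette": float("nan"),
                                        "degenerate": True, "distances": dist}
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    if k == "auto":
        best, best_sil = None, -np.inf
        for kk in range(2, min(6, n - 1) + 1):
            labels = hierarchy.fcluster(link, kk, criterion="maxclust")
            if len(np.unique(labels)) < 2:
                continue
            sil = _mean_silhouette(dist, labels)
            if sil > best_sil:
                best, best_sil = labels, sil
        labels, sil = best, best_sil
    else:
        labels = hierarchy.fcluster(link, k, criterion="maxclust")
        sil = _mean_silhouette(dist, labels) if len(np.unique(labels)) > 1 \
            else float("nan")
    return labels - labels.min(), {"k": int(len(np.unique(labels))),
                                   "silhouette": float(sil),
                                   "degenerate": False, "distances": dist}


# ---------------------------------------------------------------------------
# Classification and impact
# ---------------------------------------------------------------------------

def classify_stress(series: FTSWSeries, onset: float = 0.3,
                    early_boundary: str = "flowering",
                    cluster: int | None = None) -> StressClassification:
    """Label a season early-stress / late-stress / no-stress.

    A day is stressed when FTSW < ``onset``.  Early stress: any stressed day
    before the early boundary (flowering by default, so stress between
    panicle initiation and flowering counts as early; set
    ``early_boundary="panicle_initiation"`` for the strict variant).  Late
    stress: any stressed day from flowering through maturity.  Otherwise no
    stress.
    """
    if not series.has_phenology:
        raise ValueError(f"season {series.season}: phenology required")
    stressed = np.nonzero(series.ftsw < onset)[0]
    onset_day = int(stressed[0]) if stressed.size else None
    boundary = (series.flowering_day if early_boundary == "flowering"
                else series.panicle_initiation_day)
    label = "no_stress"
    if stressed.size:
        if (stressed < boundary).any():
            label = "early_stress"
        elif ((stressed >= series.flowering_day)
              & (stressed <= series.maturity_day)).any():
            label = "late_stress"
    return StressClassification(season=series.season, label=label,
                                cluster=cluster, onset_day=onset_day,
                                yield_t_ha=series.yield_t_ha,
                                biomass_t_ha=series.biomass_t_ha)


def stress_impact(classified: list[StressClassification]) -> pd.DataFrame:
    """Per-label frequency and mean relative yield/biomass penalty.

    penalty = 100 × (mean(no-stress) − mean(label)) / mean(no-stress).
    Requires at least one no-stress season with a yield as baseline.
    """
    df = pd.DataFrame([c.__dict__ for c in classified])
    base = df.loc[(df["label"] == "no_stress") & df["yield_t_ha"].notna()]
    if base.empty:
        raise ValueError("no no-stress season with yield to use as baseline")
    base_yield = base["yield_t_ha"].mean()
    base_biomass = base["biomass_t_ha"].mean() \
        if base["biomass_t_ha"].notna().any() else np.nan
    rows = []
    n = len(df)
    for label in LABELS:
        sub = df.loc[df["label"] == label]
        freq = 100.0 * len(sub) / n
        y = sub["yield_t_ha"].mean() if len(sub) else np.nan
        b = sub["biomass_t_ha"].mean() if len(sub) else np.nan
        rows.append({
            "label": label,
            "n_seasons": len(sub),
            "frequency_pct": freq,
            "yield_penalty_pct": 100.0 * (base_yield - y) / base_yield
            if np.isfinite(y) else np.nan,
            "biomass_penalty_pct": 100.0 * (base_biomass - b) / base_biomass
            if np.isfinite(b) and np.isfinite(base_biomass) else np.nan,
        })
    return pd.DataFrame(rows).set_index("label")


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

@dataclass
class StressPatternResult:
    """Clustered and labelled seasons with impact summaries."""

    classifications: list[StressClassification]
    cluster_info: dict
    impact: pd.DataFrame | None
    params: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.__dict__ for c in self.classifications])

    def summary(self) -> str:
        df = self.frame()
        lines = [
            "Seasonal water-stress patterns",
            f"  seasons    : {len(df)}",
            f"  clusters   : {self.cluster_info.get('k')} "
            f"(mean silhouette {self.cluster_info.get('silhouette'):.3f})"
            if np.isfinite(self.cluster_info.get("silhouette", np.nan))
            else f"  clusters   : {self.cluster_info.get('k')}",
        ]
        for label in LABELS:
            n = int((df["label"] == label).sum())
            lines.append(f"  {label:<13s}: {n} ({100 * n / len(df):.0f}%)")
        if self.impact is not None:
            for label, row in self.impact.iterrows():
                if np.isfinite(row["yield_penalty_pct"]) and label != "no_stress":
                    lines.append(f"  {label} yield penalty: "
                                 f"{row['yield_penalty_pct']:.0f}%")
        return "\n".join(lines)


class StressPatternModel:
    """Cluster and classify a set of seasonal FTSW trajectories."""

    def __init__(self, seasons: list[FTSWSeries], onset: float = 0.3,
                 k: int | str = "auto", dtw_window: int | None = None,
                 early_boundary: str = "flowering"):
        if len(seasons) < 3:
            raise ValueError("need at least three seasons")
        self.seasons = seasons
        self.onset = onset
        self.k = k
        self.dtw_window = dtw_window
        self.early_boundary = early_boundary

    def fit(self, seed: int = 0) -> StressPatternResult:
        labels, info = cluster_seasons(self.seasons, self.k, seed,
                                       self.dtw_window)
        classifications = [
            classify_stress(s, self.onset, self.early_boundary, int(c))
            for s, c in zip(self.seasons, labels)]
        impact = None
        has_yield = any(s.yield_t_ha is not None for s in self.seasons)
        if has_yield and any(c.label == "no_stress" and c.yield_t_ha is not None
                             for c in classifications):
            impact = stress_impact(classifications)
        return StressPatternResult(
            classifications=classifications, cluster_info=info, impact=impact,
            params={"onset": self.onset, "k": self.k,
                    "early_boundary": self.early_boundary})
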