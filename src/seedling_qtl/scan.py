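"""Bulk-segregant Euclidean-distance QTL scan.

At each biallelic marker the statistic is the Euclidean distance between the
two bulks' allele-frequency vectors,

    ED = sqrt((fa_H − fa_L)² + (fA_H − fA_L)²) = √2 · |fa_H − fa_L|,

where fa/fA are the alternate/reference allele read frequencies in the
high (H) and low (L) bulk.  To suppress sequencing noise the per-marker ED
values are summed over sliding windows of 100 consecutive markers and the
sum is raised to the fourth power; significance is judged against a
simulation-based null threshold (unlinked genome, finite bulks, finite
depth).  Significant windows are dilated by a ±8 Mbp flank and merged into
QTL regions.

The :class:`BulkSegregantScan` model wraps the individual operations; its
:meth:`~BulkSegregantScan.fit` returns a :class:`BsaScanResult`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import CrossDesign, SequencingModel

__all__ = [
    "allele_frequencies",
    "euclidean_distance",
    "windowed_statistic",
    "null_threshold",
    "call_regions",
    "intersect_gwas",
    "genotype_class_percentages",
    "BulkSegregantScan",
    "BsaScanResult",
    "QTLRegion",
]


# ---------------------------------------------------------------------------
# Per-marker statistics
# ---------------------------------------------------------------------------

def allele_frequencies(markers: pd.DataFrame) -> pd.DataFrame:
    """Bulk allele frequencies from read counts.

    Markers with zero depth in either bulk are dropped (their count is stored
    in ``result.attrs["n_zero_depth_dropped"]``); fa is the alternate-allele
    read fraction, fA its complement.
    """
    tot_h = markers["alt_bulk_high"] + markers["ref_bulk_high"]
    tot_l = markers["alt_bulk_low"] + markers["ref_bulk_low"]
    ok = (tot_h > 0) & (tot_l > 0)
    m = markers.loc[ok]
    out = pd.DataFrame({
        "chrom": m["chrom"].to_numpy(),
        "pos": m["pos"].to_numpy(),
        "fa_H": (m["alt_bulk_high"] / tot_h[ok]).to_numpy(),
        "fa_L": (m["alt_bulk_low"] / tot_l[ok]).to_numpy(),
    })
    out["fA_H"] = 1.0 - out["fa_H"]
    out["fA_L"] = 1.0 - out["fa_L"]
    out.attrs["n_zero_depth_dropped"] = int((~ok).sum())
    return out


def euclidean_distance(freqs: pd.DataFrame) -> pd.DataFrame:
    """Append the per-marker between-bulk Euclidean distance column ``ed``."""
    out = freqs.copy()
    out["ed"] = np.sqrt((out["fa_H"] - out["fa_L"]) ** 2
                        + (out["fA_H"] - out["fA_L"]) ** 2)
    return out


def _sliding_window_sums(values: np.ndarray, window: int) -> np.ndarray:
    # direct per-window summation: no cumulative-difference cancellation
    view = np.lib.stride_tricks.sliding_window_view(values, window)
    return view.sum(axis=1)


def windowed_statistic(profile: pd.DataFrame, window: int = 100,
                       sliding: bool = True) -> pd.DataFrame:
    """Fourth power of the windowed cumulative ED.

    Windows hold ``window`` consecutive markers of one chromosome, advance
    one marker at a time (or tile disjointly when ``sliding`` is False) and
    never span chromosomes; the statistic is assigned to the window's
    midpoint marker.  A chromosome with fewer than ``window`` markers yields
    a single whole-chromosome window flagged ``partial``.
    """
    if profile.empty:
        return pd.DataFrame(columns=["chrom", "window_start_idx", "mid_pos",
                                     "w_stat", "partial"])
    rows = []
    for chrom, sub in profile.groupby("chrom", sort=False):
        ed = sub["ed"].to_numpy()
        pos = sub["pos"].to_numpy()
        n = ed.size
        if n < window:
            rows.append((chrom, 0, pos[(n - 1) // 2], float(ed.sum() ** 4), True))
            continue
        sums = _sliding_window_sums(ed, window)
        starts = np.arange(n - window + 1)
        if not sliding:
            keep = starts % window == 0
            starts, sums = starts[keep], sums[keep]
        mids = pos[starts + (window - 1) // 2]
        for s, mp, w in zip(starts, mids, sums):
            rows.append((chrom, int(s), int(mp), float(w ** 4), False))
    return pd.DataFrame(rows, columns=["chrom", "window_start_idx", "mid_pos",
                                       "w_stat", "partial"])


# ---------------------------------------------------------------------------
# Null threshold by simulation
# ---------------------------------------------------------------------------

def _simulate_null_wstats(design: CrossDesign, seqmodel: SequencingModel,
                          n_markers: int, window: int, n_sim: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Windowed null statistics, shape (n_sim, n_windows).

    Null model: unlinked markers; each bulk's true alternate frequency is the
    allele count of ``2 × bulk_size`` fair draws, read counts binomial at the
    model's depths with error folded in.
    """
    two_n = 2 * design.bulk_size
    e = seqmodel.error_rate
    w = np.empty((n_sim, n_markers - window + 1))
    for i in range(n_sim):
        f_h = rng.binomial(two_n, 0.5, n_markers) / two_n
        f_l = rng.binomial(two_n, 0.5, n_markers) / two_n
        d_h = seqmodel.draw_depths(seqmodel.mean_depth_high, n_markers, rng)
        d_l = seqmodel.draw_depths(seqmodel.mean_depth_low, n_markers, rng)
        d_h = np.maximum(d_h, 1)
        d_l = np.maximum(d_l, 1)
        a_h = rng.binomial(d_h, f_h * (1 - e) + (1 - f_h) * e)
        a_l = rng.binomial(d_l, f_l * (1 - e) + (1 - f_l) * e)
        ed = np.sqrt(2.0) * np.abs(a_h / d_h - a_l / d_l)
        w[i] = _sliding_window_sums(ed, window) ** 4
    return w


def _simulate_null_wstats_linked(design: CrossDesign,
                                 seqmodel: SequencingModel,
                                 pos_cm: np.ndarray, window: int, n_sim: int,
                                 rng: np.random.Generator) -> np.ndarray:
    """Null windowed statistics for one linked chromosome.

    Without a QTL the two bulks are random disjoint sets of F2 individuals,
    so each simulation draws the bulks' genotypes directly: 2 × bulk_size
    individuals recombining along the marker map.  Linkage makes bulk
    allele-frequency fluctuations autocorrelated along the chromosome, which
    inflates windowed sums relative to the unlinked null.
    """
    from .simulate import _simulate_gametes

    n_markers = pos_cm.size
    n_ind = 2 * design.bulk_size
    e = seqmodel.error_rate
    w = np.empty((n_sim, max(1, n_markers - window + 1)))
    for i in range(n_sim):
        dosage = (_simulate_gametes(pos_cm, n_ind, rng)
                  + _simulate_gametes(pos_cm, n_ind, rng))
        f_h = dosage[:design.bulk_size].sum(axis=0) / (2.0 * design.bulk_size)
        f_l = dosage[design.bulk_size:].sum(axis=0) / (2.0 * design.bulk_size)
        d_h = np.maximum(seqmodel.draw_depths(seqmodel.mean_depth_high,
                                              n_markers, rng), 1)
        d_l = np.maximum(seqmodel.draw_depths(seqmodel.mean_depth_low,
                                              n_markers, rng), 1)
        a_h = rng.binomial(d_h, f_h * (1 - e) + (1 - f_h) * e)
        a_l = rng.binomial(d_l, f_l * (1 - e) + (1 - f_l) * e)
        ed = np.sqrt(2.0) * np.abs(a_h / d_h - a_l / d_l)
        w[i] = _sliding_window_sums(ed, min(window, n_markers)) ** 4
    return w


def null_threshold(design: CrossDesign, seqmodel: SequencingModel,
                   n_markers: int = 2000, window: int = 100,
                   n_sim: int = 500, q: float = 0.95, seed: int = 0,
                   mode: str = "pooled",
                   pos_cm: np.ndarray | None = None) -> float:
    """Simulation-based significance threshold for the windowed statistic.

    ``mode="pooled"`` (default) takes the q-quantile of all null window
    statistics pooled over simulations — the per-window confidence bound.
    ``mode="familywise"`` takes the q-quantile of each simulation's maximum
    window statistic, controlling the genome-wide error rate.

    By default markers are simulated unlinked.  Passing ``pos_cm`` (genetic
    marker positions of one representative chromosome) switches to a linked
    null in which the bulks are random F2 individuals recombining along the
    map; this captures the bulk-drift autocorrelation that an unlinked null
    misses and yields a markedly higher, genome-wide-honest threshold.
    """
    if n_sim < 200:
        raise ValueError("n_sim must be at least 200 for a stable quantile")
    rng = np.random.default_rng(seed)
    if pos_cm is not None:
        w = _simulate_null_wstats_linked(design, seqmodel,
                                         np.asarray(pos_cm, float), window,
                                         n_sim, rng)
    else:
        w = _simulate_null_wstats(design, seqmodel, n_markers, window, n_sim,
                                  rng)
    if mode == "pooled":
        return float(np.quantile(w.ravel(), q))
    if mode == "familywise":
        return float(np.quantile(w.max(axis=1), q))
    raise ValueError(f"unknown threshold mode {mode!r}")


# ---------------------------------------------------------------------------
# Region calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QTLRegion:
    """A merged interval of significance (1-based, closed coordinates)."""

    chrom: str
    start: int
    end: int
    peak_pos: int
    peak_stat: float
    n_significant_markers: int


def call_regions(windows: pd.DataFrame, threshold: float,
                 flank: int = 8_000_000,
                 chrom_lengths: dict[str, int] | None = None,
                 ) -> list[QTLRegion]:
    """Merge ±flank intervals around significant windows into QTL regions.

    A window is significant when its statistic exceeds the threshold; each
    contributes [mid_pos − flank, mid_pos + flank] clipped to the chromosome;
    overlapping intervals merge.  The region peak is the maximal window
    statistic (leftmost on ties).
    """
    sig = windows.loc[windows["w_stat"] > threshold]
    regions: list[QTLRegion] = []
    for chrom, sub in sig.groupby("chrom", sort=False):
        sub = sub.sort_values(["mid_pos", "window_start_idx"])
        pos = sub["mid_pos"].to_numpy()
        stat = sub["w_stat"].to_numpy()
        chrom_end = chrom_lengths.get(chrom) if chrom_lengths else None
        starts = np.maximum(1, pos - flank)
        ends = pos + flank if chrom_end is None else np.minimum(chrom_end, pos + flank)
        cur_s, cur_e = starts[0], ends[0]
        members = [0]
        for i in range(1, pos.size):
            if starts[i] <= cur_e:  # closed intervals: touching merges
                cur_e = max(cur_e, ends[i])
                members.append(i)
            else:
                regions.append(_make_region(chrom, cur_s, cur_e, pos, stat, members))
                cur_s, cur_e, members = starts[i], ends[i], [i]
        regions.append(_make_region(chrom, cur_s, cur_e, pos, stat, members))
    return regions


def _make_region(chrom: str, start: int, end: int, pos: np.ndarray,
                 stat: np.ndarray, members: list[int]) -> QTLRegion:
    m = np.asarray(members)
    best = m[np.argmax(stat[m])]  # argmax returns first max → leftmost tie
    return QTLRegion(chrom=chrom, start=int(start), end=int(end),
                     peak_pos=int(pos[best]), peak_stat=float(stat[best]),
                     n_significant_markers=len(members))


def intersect_gwas(regions: list[QTLRegion],
                   gwas_hits: pd.DataFrame,
                   chromosomes: set[str] | None = None) -> pd.DataFrame:
    """Annotate GWAS hits (columns chrom, pos[, pvalue]) with containing regions.

    Region intervals are closed on both ends.  When ``chromosomes`` is given,
    hits on unknown chromosomes raise with the offending names listed.
    """
    if chromosomes is not None:
        bad = sorted(set(gwas_hits["chrom"]) - set(chromosomes))
        if bad:
            raise ValueError(f"GWAS hits on unknown chromosomes: {bad}")
    labels = []
    for hit in gwas_hits.itertuples(index=False):
        match = None
        for i, r in enumerate(regions):
            if r.chrom == hit.chrom and r.start <= hit.pos <= r.end:
                match = i
                break
        labels.append(match)
    out = gwas_hits.copy()
    out["region"] = [None if i is None else f"{regions[i].chrom}:"
                     f"{regions[i].start}-{regions[i].end}" for i in labels]
    out["region_index"] = pd.array(labels, dtype="Int64")
    return out


def genotype_class_percentages(class_counts: dict[str, int],
                               n_total: int) -> dict[str, float]:
    """Percentage of individuals per genotype class, to one decimal.

    Used to summarise allelic classes at a locus in a panel, e.g. homozygote
    class shares at a candidate SNP.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return {k: round(100.0 * v / n_total, 1) for k, v in class_counts.items()}


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

@dataclass
class BsaScanResult:
    """Fitted scan: per-marker ED profile, windowed statistic, threshold and
    called regions."""

    ed_profile: pd.DataFrame
    windows: pd.DataFrame
    threshold: float
    regions: list[QTLRegion]
    n_zero_depth_dropped: int
    params: dict = field(default_factory=dict)

    @property
    def n_significant_windows(self) -> int:
        return int((self.windows["w_stat"] > self.threshold).sum())

    def summary(self) -> str:
        lines = [
            "Bulk-segregant Euclidean-distance scan",
            f"  markers scanned     : {len(self.ed_profile)}",
            f"  zero-depth dropped  : {self.n_zero_depth_dropped}",
            f"  window size         : {self.params.get('window')}",
            f"  threshold ({self.params.get('threshold_mode', 'pooled')}, "
            f"q={self.params.get('quantile')}) : {self.threshold:.4g}",
            f"  significant windows : {self.n_significant_windows}",
            f"  QTL regions         : {len(self.regions)}",
        ]
        for r in self.regions:
            lines.append(f"    {r.chrom}:{r.start}-{r.end}  "
                         f"peak {r.peak_pos} ({r.peak_stat:.4g}), "
                         f"{r.n_significant_markers} significant windows")
        return "\n".join(lines)

    def regions_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.regions])

    def to_bed(self, path: str | Path) -> None:
        """Regions as BED6 (0-based half-open; score = scaled peak stat)."""
        top = max((r.peak_stat for r in self.regions), default=1.0) or 1.0
        with open(path, "w") as fh:
            for i, r in enumerate(self.regions):
                score = int(round(1000 * r.peak_stat / top))
                fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\tregion_{i + 1}\t"
                         f"{score}\t.\n")

    def write_manifest(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"threshold": self.threshold, **self.params}, fh, indent=2)

    def plot(self, ax=None):
        """Windowed-statistic profile across chromosomes with the threshold."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        offset = 0
        for chrom, sub in self.windows.groupby("chrom", sort=False):
            ax.plot(sub["mid_pos"].to_numpy() + offset, sub["w_stat"], ".",
                    ms=2, label=chrom)
            offset += sub["mid_pos"].max()
        ax.axhline(self.threshold, ls="--", color="red")
        ax.set_xlabel("genome position (bp, concatenated)")
        ax.set_ylabel("(cumulative ED)$^4$")
        return ax


class BulkSegregantScan:
    """Euclidean-distance BSA scan model over a filtered marker table.

    Parameters
    ----------
    markers : DataFrame
        Filtered marker table with bulk read-depth columns
        (see :mod:`seedling_qtl.filtering`).
    design, seqmodel :
        Cross and sequencing models used by the null simulation.
    window : int
        Markers per window (sum of ED raised to the 4th power).
    flank : int
        Half-width (bp) of the significance interval around each
        significant window.
    """

    def __init__(self, markers: pd.DataFrame,
                 design: CrossDesign = CrossDesign(),
                 seqmodel: SequencingModel = SequencingModel(),
                 window: int = 100, flank: int = 8_000_000,
                 n_sim: int = 500, quantile: float = 0.95,
                 threshold_mode: str = "pooled", sliding: bool = True,
                 chrom_lengths: dict[str, int] | None = None,
                 genetic_map=None):
        self.markers = markers
        self.design = design
        self.seqmodel = seqmodel
        self.window = window
        self.flank = flank
        self.n_sim = n_sim
        self.quantile = quantile
        self.threshold_mode = threshold_mode
        self.sliding = sliding
        self.chrom_lengths = chrom_lengths
        self.genetic_map = genetic_map  # enables the linked null threshold

    def fit(self, seed: int = 0, threshold: float | None = None) -> BsaScanResult:
        """Run the scan; ``threshold`` overrides the null simulation."""
        freqs = allele_frequencies(self.markers)
        profile = euclidean_distance(freqs)
        windows = windowed_statistic(profile, self.window, self.sliding)
        if threshold is None:
            n_markers = max(self.window,
                            int(self.markers.groupby("chrom").size().mean()))
            pos_cm = None
            if self.genetic_map is not None:
                gpos = self.genetic_map.positions()
                first = gpos["chrom"].iloc[0]
                pos_cm = gpos.loc[gpos["chrom"] == first, "pos_cm"].to_numpy()
            threshold = null_threshold(self.design, self.seqmodel, n_markers,
                                       self.window, self.n_sim, self.quantile,
                                       seed, self.threshold_mode, pos_cm)
        regions = call_regions(windows, threshold, self.flank, self.chrom_lengths)
        return BsaScanResult(
            ed_profile=profile, windows=windows, threshold=float(threshold),
            regions=regions,
            n_zero_depth_dropped=profile.attrs.get("n_zero_depth_dropped", 0),
            params={"window": self.window, "flank": self.flank,
                    "n_sim": self.n_sim, "quantile": self.quantile,
                    "threshold_mode": self.threshold_mode,
                    "sliding": self.sliding, "seed": seed})
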