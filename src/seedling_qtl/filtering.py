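"""Variant ingestion and the bulk-segregant filtering cascade.

The marker table is a plain :class:`pandas.DataFrame` with one row per site
and columns::

    chrom  pos  ref  alt  multiallelic
    ref_bulk_high  alt_bulk_high  ref_bulk_low  alt_bulk_low
    ref_parent_low alt_parent_low ref_parent_high alt_parent_high

Depths are read counts from the AD field of a VCF.  The cascade applied by
:func:`filter_frequency_depth` follows, in order: multi-allelic removal,
pooled bulk alternate-allele frequency, total-depth percentile window
(nearest-rank percentiles computed after the frequency step, boundaries kept),
missingness, and minor-allele frequency on pooled counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SAMPLE_ROLES = ("bulk_high", "bulk_low", "parent_low", "parent_high")

DEPTH_COLUMNS = [f"{a}_{role}" for role in SAMPLE_ROLES for a in ("ref", "alt")]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filtering cascade.

    ``depth_min``/``depth_max`` are absolute read-depth bounds; when unset the
    depth window is resolved from the dataset's nearest-rank percentiles on
    first application and the resolved bounds are reported back, so the
    cascade re-applied with its resolved configuration is a no-op.
    """

    af_min: float = 0.25
    depth_low_pct: float = 25.0
    depth_high_pct: float = 95.0
    missing_max: float = 0.5
    maf_min: float = 0.05
    depth_min: float | None = None
    depth_max: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.af_min < 1:
            raise ValueError("af_min must lie in [0, 1)")
        if not 0 <= self.depth_low_pct < self.depth_high_pct <= 100:
            raise ValueError("percentiles must satisfy 0 <= low < high <= 100")

    def resolved(self, depth_min: float, depth_max: float) -> "FilterConfig":
        from dataclasses import replace
        return replace(self, depth_min=depth_min, depth_max=depth_max)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_variants(path: str | Path,
                  sample_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a VCF with per-sample allelic depths into a marker table.

    ``sample_map`` maps the roles bulk_high / bulk_low / parent_low /
    parent_high to VCF sample names; by default the roles themselves are
    expected as sample names.  Multi-allelic records are kept but flagged
    (their first ALT depth is recorded).  Positions stay 1-based.
    """
    from cyvcf2 import VCF

    sample_map = sample_map or {r: r for r in SAMPLE_ROLES}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    try:
        idx = {role: samples.index(name) for role, name in sample_map.items()}
    except ValueError as exc:
        missing = [n for n in sample_map.values() if n not in samples]
        raise ValueError(f"samples {missing} not found in {path}") from exc

    rows = []
    last: dict[str, int] = {}
    for v in vcf:
        if v.POS < last.get(v.CHROM, 0):
            raise ValueError(f"VCF not position-sorted at {v.CHROM}:{v.POS}")
        last[v.CHROM] = v.POS
        ad = v.format("AD")
        if ad is None:
            raise ValueError(
                f"AD field absent at {v.CHROM}:{v.POS} "
                f"(samples {list(sample_map.values())})")
        ad = np.asarray(ad)
        row = {
            "chrom": v.CHROM, "pos": v.POS,
            "ref": v.REF, "alt": v.ALT[0] if v.ALT else ".",
            "multiallelic": len(v.ALT) > 1,
        }
        for role, i in idx.items():
            ref_d, alt_d = int(ad[i, 0]), int(ad[i, 1]) if ad.shape[1] > 1 else 0
            row[f"ref_{role}"] = max(ref_d, 0)  # cyvcf2 encodes missing as <0
            row[f"alt_{role}"] = max(alt_d, 0)
        rows.append(row)
    cols = ["chrom", "pos", "ref", "alt", "multiallelic"] + DEPTH_COLUMNS
    return pd.DataFrame(rows, columns=cols)


def write_variants(markers: pd.DataFrame, path: str | Path,
                   sample_map: dict[str, str] | None = None) -> None:
    """Write a marker table as a minimal VCF 4.2 with AD-only genotype data."""
    sample_map = sample_map or {r: r for r in SAMPLE_ROLES}
    names = [sample_map[r] for r in SAMPLE_ROLES]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths">\n')
        for chrom in markers["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        for row in markers.itertuples(index=False):
            ads = "\t".join(
                f"{getattr(row, f'ref_{role}')},{getattr(row, f'alt_{role}')}"
                for role in SAMPLE_ROLES)
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t"
                     f".\tAD\t{ads}\n")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def _parent_state(ref_d: np.ndarray, alt_d: np.ndarray,
                  hom_fraction: float = 0.9,
                  min_depth: int = 5) -> np.ndarray:
    """Per-site parent call: 0 = ref hom, 2 = alt hom, -1 = not confident."""
    total = ref_d + alt_d
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_frac = np.where(total > 0, alt_d / np.maximum(total, 1), np.nan)
    state = np.full(ref_d.shape, -1, dtype=np.int8)
    ok = total >= min_depth
    state[ok & (alt_frac <= 1 - hom_fraction)] = 0
    state[ok & (alt_frac >= hom_fraction)] = 2
    return state


def filter_biallelic_parental(markers: pd.DataFrame,
                              hom_fraction: float = 0.9,
                              min_parent_depth: int = 5) -> pd.DataFrame:
    """Keep biallelic sites segregating between confidently homozygous parents.

    A parent is called homozygous when its major-allele read fraction is at
    least ``hom_fraction`` at depth ≥ ``min_parent_depth``; the two parents
    must carry opposite alleles.  Sites are re-polarized so the low-growth
    parent carries the reference allele, matching its use as the reference
    genome of the cross.
    """
    m = markers.copy()
    low = _parent_state(m["ref_parent_low"].to_numpy(),
                        m["alt_parent_low"].to_numpy(),
                        hom_fraction, min_parent_depth)
    high = _parent_state(m["ref_parent_high"].to_numpy(),
                         m["alt_parent_high"].to_numpy(),
                         hom_fraction, min_parent_depth)
    keep = (~m["multiallelic"].to_numpy()
            & (low >= 0) & (high >= 0) & (low != high))
    m = m.loc[keep].copy()
    flip = low[keep] == 2  # low parent holds the alt allele: swap polarity
    if flip.any():
        fl = m.index[flip]
        m.loc[fl, ["ref", "alt"]] = m.loc[fl, ["alt", "ref"]].to_numpy()
        for role in SAMPLE_ROLES:
            m.loc[fl, [f"ref_{role}", f"alt_{role}"]] = \
                m.loc[fl, [f"alt_{role}", f"ref_{role}"]].to_numpy()
    return m.reset_index(drop=True)


def _nearest_rank(values: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile (1-based rank ceil(p/100 * n))."""
    v = np.sort(np.asarray(values))
    if v.size == 0:
        raise ValueError("empty sample")
    rank = max(1, math.ceil(pct / 100.0 * v.size))
    return float(v[rank - 1])


def filter_frequency_depth(markers: pd.DataFrame,
                           cfg: FilterConfig = FilterConfig(),
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the frequency/depth/missingness/MAF cascade.

    Steps run in the documented order; depth percentiles are computed on the
    table as it stands after the allele-frequency step and sites exactly at a
    percentile boundary are retained.  Returns the filtered table and a
    report frame with columns ``step, removed, remaining``.
    """
    if markers.empty:
        raise ValueError("cannot filter an empty marker table")
    report = []
    m = markers

    def record(step: str, kept: pd.DataFrame) -> pd.DataFrame:
        report.append((step, len(m) - len(kept), len(kept)))
        return kept

    kept = m.loc[~m["multiallelic"]]
    m = record("multiallelic", kept)

    bulk_alt = m["alt_bulk_high"] + m["alt_bulk_low"]
    bulk_tot = bulk_alt + m["ref_bulk_high"] + m["ref_bulk_low"]
    with np.errstate(invalid="ignore"):
        af = np.where(bulk_tot > 0, bulk_alt / bulk_tot.replace(0, 1), 0.0)
    m = record("allele_frequency", m.loc[af >= cfg.af_min])

    lo, hi = cfg.depth_min, cfg.depth_max
    if not m.empty:
        total_depth = sum(m[c] for c in DEPTH_COLUMNS)
        if lo is None:
            lo = _nearest_rank(total_depth.to_numpy(), cfg.depth_low_pct)
        if hi is None:
            hi = _nearest_rank(total_depth.to_numpy(), cfg.depth_high_pct)
        m = record("depth_percentile",
                   m.loc[(total_depth >= lo) & (total_depth <= hi)])
    else:
        m = record("depth_percentile", m)

    sample_tot = [(m[f"ref_{r}"] + m[f"alt_{r}"]).to_numpy() for r in SAMPLE_ROLES]
    missing_frac = np.mean([t == 0 for t in sample_tot], axis=0) \
        if len(m) else np.zeros(0)
    m = record("missingness", m.loc[missing_frac <= cfg.missing_max])

    alt_all = sum(m[f"alt_{r}"] for r in SAMPLE_ROLES)
    tot_all = alt_all + sum(m[f"ref_{r}"] for r in SAMPLE_ROLES)
    with np.errstate(invalid="ignore"):
        p = np.where(tot_all > 0, alt_all / tot_all.replace(0, 1), 0.0)
    maf = np.minimum(p, 1 - p)
    m = record("maf", m.loc[maf >= cfg.maf_min])

    if m.empty:
        logger.warning("filter cascade removed every site")
    report_df = pd.DataFrame(report, columns=["step", "removed", "remaining"])
    if lo is not None and hi is not None:
        report_df.attrs["resolved_config"] = cfg.resolved(float(lo), float(hi))
    return m.reset_index(drop=True), report_df


def apply_filters(markers: pd.DataFrame,
                  cfg: FilterConfig = FilterConfig(),
                  hom_fraction: float = 0.9,
                  min_parent_depth: int = 5,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full cascade: parental/biallelic step then frequency/depth cascade."""
    m = filter_biallelic_parental(markers, hom_fraction, min_parent_depth)
    n_removed = len(markers) - len(m)
    filtered, report = filter_frequency_depth(m, cfg)
    head = pd.DataFrame([("parental_biallelic", n_removed, len(m))],
                        columns=report.columns)
    return filtered, pd.concat([head, report], ignore_index=True)
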