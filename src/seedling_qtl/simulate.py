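"""Synthetic study designs: F2 crosses, pooled sequencing, line panels, cell
profiles and soil-water seasons.

Every generator here emulates one input of the analysis pipeline with the
statistical structure the downstream method assumes: an F2 population from two
fully homozygous parents recombining under the Haldane map function, 10 %-tail
bulks pool-sequenced at great depth, a replicated inbred-line panel with random
line effects, logistic cell-length profiles along a root axis, and a one-bucket
soil-water balance driven by daily rainfall.  All functions take an explicit
integer seed and are deterministic given it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Chromosome",
    "GeneticMapSpec",
    "CrossDesign",
    "SequencingModel",
    "PanelDesign",
    "BucketSoilParams",
    "F2Genotypes",
    "BulkMembership",
    "haldane_recombination",
    "simulate_f2_population",
    "simulate_phenotypes",
    "select_bulks",
    "simulate_pooled_reads",
    "simulate_panel_phenotypes",
    "simulate_cell_profile",
    "simulate_weather_ftsw",
    "generate_rain_series",
]


# ---------------------------------------------------------------------------
# Design dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Chromosome:
    """One linkage group with a genetic and a physical length."""

    name: str
    length_cm: float
    length_bp: int

    def __post_init__(self) -> None:
        if self.length_cm <= 0 or self.length_bp <= 0:
            raise ValueError(f"chromosome {self.name}: lengths must be positive")


def default_genome(n_chrom: int = 7, length_cm: float = 150.0,
                   length_bp: int = 230_000_000) -> list[Chromosome]:
    """Seven equally sized chromosomes at the pearl-millet genome scale
    (~1.6 Gb total)."""
    return [Chromosome(f"chr{i + 1}", length_cm, length_bp) for i in range(n_chrom)]


@dataclass(frozen=True)
class GeneticMapSpec:
    """Marker map: evenly spaced markers on each chromosome.

    Genetic (cM) and physical (bp) positions are co-monotone by construction;
    marker i of m sits at fraction (i+1)/(m+1) of the chromosome length.
    """

    chromosomes: list[Chromosome] = field(default_factory=default_genome)
    markers_per_chrom: int = 2000
    map_function: str = "haldane"

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")
        if self.markers_per_chrom < 1:
            raise ValueError("each chromosome needs at least one marker")
        if self.map_function != "haldane":
            raise ValueError(f"unsupported map function {self.map_function!r}")

    def positions(self) -> pd.DataFrame:
        """Marker table with columns chrom, pos_cm, pos_bp."""
        frames = []
        m = self.markers_per_chrom
        frac = (np.arange(m) + 1.0) / (m + 1.0)
        for c in self.chromosomes:
            frames.append(pd.DataFrame({
                "chrom": c.name,
                "pos_cm": frac * c.length_cm,
                "pos_bp": np.maximum(1, (frac * c.length_bp).astype(np.int64)),
            }))
        return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class CrossDesign:
    """A bi-parental F2 design with tail bulks.

    Defaults follow the mapping population of the study: 737 F2 seedlings,
    10 % tails, 75 plants per bulk.  ``qtl_loci`` are (chrom, pos_bp,
    additive_effect, dominance_effect) tuples; effects act on the dosage of
    the alternate (high-parent) allele.
    """

    n_f2: int = 737
    tail_fraction: float = 0.10
    bulk_size: int = 75
    qtl_loci: tuple = ()
    residual_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_f2 < 2:
            raise ValueError("need at least two F2 individuals")
        if not 0 < self.tail_fraction <= 0.5:
            raise ValueError("tail_fraction must lie in (0, 0.5]")
        # allow the bulk to exceed the nominal tail by a small rounding margin
        if self.bulk_size > math.ceil(self.tail_fraction * self.n_f2) + 2:
            raise ValueError(
                f"bulk_size {self.bulk_size} exceeds the {self.tail_fraction:.0%} "
                f"tail of {self.n_f2} individuals")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")


@dataclass(frozen=True)
class SequencingModel:
    """Pooled GBS depth and error model.

    Site depth is negative-binomial (mean, dispersion) by default — GBS depth
    is overdispersed relative to Poisson — with ``depth_dispersion = 0``
    selecting pure Poisson.  Sequencing error is folded into the binomial
    read-sampling success probability.
    """

    mean_depth_high: float = 1028.0
    mean_depth_low: float = 814.0
    depth_dispersion: float = 0.2
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.mean_depth_high <= 0 or self.mean_depth_low <= 0:
            raise ValueError("mean depths must be positive")
        if not 0 <= self.error_rate < 0.01:
            raise ValueError("error_rate must lie in [0, 0.01)")
        if self.depth_dispersion < 0:
            raise ValueError("depth_dispersion must be non-negative")

    def draw_depths(self, mean: float, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.depth_dispersion == 0:
            return rng.poisson(mean, n)
        # NB with mean m and dispersion a: var = m + a m^2
        r = 1.0 / self.depth_dispersion
        p = r / (r + mean)
        return rng.negative_binomial(r, p, n)


@dataclass(frozen=True)
class PanelDesign:
    """Replicated inbred-line panel (default: 122 lines, ~7 plants/line)."""

    n_lines: int = 122
    plants_per_line_mean: float = 7.0
    var_line: float = 1.0
    var_res: float = 1.0
    n_years: int = 1
    n_blocks: int = 1
    mu: float = 50.0

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("need at least two lines")
        if self.var_line < 0 or self.var_res < 0:
            raise ValueError("variances must be non-negative")


@dataclass(frozen=True)
class BucketSoilParams:
    """One-bucket soil water balance.

    ``ttsw`` is the total transpirable soil water of the rooted profile (mm);
    transpiration proceeds at ``daily_demand`` while FTSW is above
    ``stress_onset_ftsw`` and declines linearly to zero below it.
    """

    ttsw: float = 100.0
    initial_fill: float = 0.25
    daily_demand: float = 5.0
    stress_onset_ftsw: float = 0.3
    season_start_doy: int = 100  # April 10

    def __post_init__(self) -> None:
        if self.ttsw <= 0:
            raise ValueError("ttsw must be positive")
        if not 0 <= self.initial_fill <= 1:
            raise ValueError("initial_fill must lie in [0, 1]")
        if not 0 < self.stress_onset_ftsw < 1:
            raise ValueError("stress_onset_ftsw must lie in (0, 1)")
        if self.daily_demand < 0:
            raise ValueError("daily_demand must be non-negative")


# ---------------------------------------------------------------------------
# F2 cross
# ---------------------------------------------------------------------------

@dataclass
class F2Genotypes:
    """Dosage matrix (n_f2 × n_markers) of the alternate (high-parent) allele."""

    markers: pd.DataFrame  # chrom, pos_cm, pos_bp
    dosage: np.ndarray     # int8, values in {0, 1, 2}

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def marker_index(self, chrom: str, pos_bp: int) -> int:
        """Index of the marker nearest to (chrom, pos_bp)."""
        sel = self.markers["chrom"] == chrom
        if not sel.any():
            raise KeyError(f"no markers on chromosome {chrom!r}")
        sub = self.markers.loc[sel]
        return int((sub["pos_bp"] - pos_bp).abs().idxmin())


def haldane_recombination(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a genetic distance in cM (no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def _simulate_gametes(pos_cm: np.ndarray, n_gametes: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Gamete haplotypes along one chromosome as a (n_gametes, n_markers)
    0/1 array; crossovers between adjacent markers are independent Bernoulli
    with the Haldane fraction."""
    n_markers = pos_cm.size
    if n_markers == 0:
        raise ValueError("chromosome carries no markers")
    first = rng.integers(0, 2, size=(n_gametes, 1), dtype=np.int8)
    if n_markers == 1:
        return first
    r = haldane_recombination(np.diff(pos_cm))
    switches = (rng.random((n_gametes, n_markers - 1)) < r)
    # parity of crossovers since the first marker decides the current parent
    parity = np.cumsum(switches, axis=1, dtype=np.int32) & 1
    haplo = np.empty((n_gametes, n_markers), dtype=np.int8)
    haplo[:, 0] = first[:, 0]
    haplo[:, 1:] = first ^ parity.astype(np.int8)
    return haplo


def simulate_f2_population(genetic_map: GeneticMapSpec, design: CrossDesign,
                           seed: int) -> F2Genotypes:
    """Simulate F2 dosages from two fully homozygous opposite parents.

    Each individual is the union of two independently recombined gametes; the
    dosage counts alternate (high-parent) alleles, so the parents themselves
    would score 0 and 2 everywhere.
    """
    rng = np.random.default_rng(seed)
    markers = genetic_map.positions()
    dosage = np.empty((design.n_f2, len(markers)), dtype=np.int8)
    col = 0
    for chrom in genetic_map.chromosomes:
        pos_cm = markers.loc[markers["chrom"] == chrom.name, "pos_cm"].to_numpy()
        g1 = _simulate_gametes(pos_cm, design.n_f2, rng)
        g2 = _simulate_gametes(pos_cm, design.n_f2, rng)
        dosage[:, col:col + pos_cm.size] = g1 + g2
        col += pos_cm.size
    return F2Genotypes(markers=markers, dosage=dosage)


def simulate_phenotypes(genos: F2Genotypes, design: CrossDesign,
                        seed: int) -> np.ndarray:
    """Additive + dominance phenotypes with Gaussian residuals.

    phenotype = Σ_q [a_q (dosage_q − 1) + d_q 1{dosage_q = 1}] + N(0, σ²).
    """
    rng = np.random.default_rng(seed)
    pheno = rng.normal(0.0, design.residual_sd, genos.n_individuals)
    for chrom, pos_bp, add, dom in design.qtl_loci:
        idx = genos.marker_index(chrom, pos_bp)
        dos = genos.dosage[:, idx].astype(float)
        pheno += add * (dos - 1.0) + dom * (dos == 1)
    return pheno


@dataclass(frozen=True)
class BulkMembership:
    """Disjoint index sets of the phenotypic extremes."""

    high: np.ndarray
    low: np.ndarray

    def __post_init__(self) -> None:
        if np.intersect1d(self.high, self.low).size:
            raise ValueError("bulks overlap")


def select_bulks(phenotypes: np.ndarray, design: CrossDesign) -> BulkMembership:
    """Pick the ``bulk_size`` highest and lowest individuals.

    Ties are broken by the lower individual index; the low bulk is filled
    first and its members are excluded from the high bulk, so the two are
    disjoint even when all phenotypes are equal.
    """
    phenotypes = np.asarray(phenotypes, dtype=float)
    n = phenotypes.size
    if n < 2 * design.bulk_size:
        raise ValueError(
            f"cannot form two disjoint bulks of {design.bulk_size} from {n} plants")
    order = np.lexsort((np.arange(n), phenotypes))  # ascending, stable in index
    low = np.sort(order[:design.bulk_size])
    remaining = order[design.bulk_size:]
    # highest phenotypes; among ties prefer the lowest index
    rem_pheno = phenotypes[remaining]
    order_desc = remaining[np.lexsort((remaining, -rem_pheno))]
    high = np.sort(order_desc[:design.bulk_size])
    return BulkMembership(high=high, low=low)


# ---------------------------------------------------------------------------
# Pooled sequencing
# ---------------------------------------------------------------------------

def _pool_reads(freq: np.ndarray, depth: np.ndarray, error_rate: float,
                rng: np.random.Generator) -> np.ndarray:
    p = freq * (1.0 - error_rate) + (1.0 - freq) * error_rate
    return rng.binomial(depth, p)


def simulate_pooled_reads(genos: F2Genotypes, bulks: BulkMembership,
                          seqmodel: SequencingModel, seed: int) -> pd.DataFrame:
    """Pool-sequence the two bulks into a marker table.

    Per marker and bulk the true alternate frequency is the mean allele dosage
    over bulk members; site depth is drawn from the sequencing model and
    alternate reads are binomial with error folded in.  Parents are emitted as
    perfectly homozygous (reference for the low parent, alternate for the
    high parent) at a fixed depth equal to the mean of the two bulk depths.

    Returns a marker table compatible with :mod:`seedling_qtl.filtering`.
    """
    if bulks.high.size == 0 or bulks.low.size == 0:
        raise ValueError("empty bulk")
    rng = np.random.default_rng(seed)
    n_markers = genos.n_markers

    out = genos.markers[["chrom", "pos_bp"]].rename(columns={"pos_bp": "pos"}).copy()
    # alternate fixed in the high-growth parent; arbitrary A/G nucleotides
    out["ref"] = "A"
    out["alt"] = "G"
    out["multiallelic"] = False

    for name, members, mean_depth in (
            ("bulk_high", bulks.high, seqmodel.mean_depth_high),
            ("bulk_low", bulks.low, seqmodel.mean_depth_low)):
        freq = genos.dosage[members].sum(axis=0) / (2.0 * members.size)
        depth = seqmodel.draw_depths(mean_depth, n_markers, rng)
        alt = _pool_reads(freq, depth, seqmodel.error_rate, rng)
        out[f"alt_{name}"] = alt
        out[f"ref_{name}"] = depth - alt

    parent_depth = int(round((seqmodel.mean_depth_high + seqmodel.mean_depth_low) / 2))
    out["ref_parent_low"] = parent_depth
    out["alt_parent_low"] = 0
    out["ref_parent_high"] = 0
    out["alt_parent_high"] = parent_depth
    return out


# ---------------------------------------------------------------------------
# Line panel
# ---------------------------------------------------------------------------

def simulate_panel_phenotypes(design: PanelDesign, seed: int,
                              trait: str = "root_length") -> pd.DataFrame:
    """Phenotype records for a replicated line panel.

    value = μ + line + year + block(year) + residual, with line effects
    N(0, var_line) and residuals N(0, var_res).  Year and block-within-year
    effects are small fixed shifts so adjusted-means machinery has design
    factors to absorb.  Plants per line are Poisson around the mean, min 1.
    """
    rng = np.random.default_rng(seed)
    line_eff = rng.normal(0.0, math.sqrt(design.var_line), design.n_lines)
    year_eff = rng.normal(0.0, 0.5, design.n_years) if design.n_years > 1 else np.zeros(1)
    block_eff = rng.normal(0.0, 0.25, (design.n_years, design.n_blocks)) \
        if design.n_blocks > 1 else np.zeros((design.n_years, 1))

    records = []
    for i in range(design.n_lines):
        for y in range(design.n_years):
            for b in range(design.n_blocks):
                n_plants = max(1, rng.poisson(design.plants_per_line_mean /
                                              (design.n_years * design.n_blocks)))
                vals = (design.mu + line_eff[i] + year_eff[y] + block_eff[y, b]
                        + rng.normal(0.0, math.sqrt(design.var_res), n_plants))
                for p, v in enumerate(vals):
                    records.append((f"L{i + 1:03d}", y + 1, b + 1, p + 1, trait, v))
    return pd.DataFrame(records,
                        columns=["line", "year", "block", "plant", "trait", "value"])


# ---------------------------------------------------------------------------
# Cell-length profile
# ---------------------------------------------------------------------------

def logistic_cell_length(x: np.ndarray, l_min: float, l_max: float,
                         k: float, x0: float) -> np.ndarray:
    """Cell length at distance x from the quiescent center."""
    z = np.clip(-k * (np.asarray(x, float) - x0), -700, 700)
    return l_min + (l_max - l_min) / (1.0 + np.exp(z))


def simulate_cell_profile(l_min: float = 10.0, l_max: float = 200.0,
                          k: float = 0.005, x0: float = 3000.0,
                          n_cells: int = 350, noise_sd: float = 0.0,
                          seed: int = 0) -> pd.DataFrame:
    """Consecutive cell lengths along a root axis following a logistic curve.

    Cells are laid end to end from the quiescent center: each cell's distance
    is the midpoint of the interval it occupies, its length is the logistic
    value there plus Gaussian noise, truncated at 1 µm.  With the default
    meristem cell size (~10 µm) and transition midpoint, a few hundred cells
    are needed to span both shoulders of the sigmoid.  Returns a frame with
    ``distance`` and ``length`` columns (µm).
    """
    if not l_max > l_min > 0:
        raise ValueError("require l_max > l_min > 0")
    if k <= 0:
        raise ValueError("k must be positive")
    rng = np.random.default_rng(seed)
    distances = np.empty(n_cells)
    lengths = np.empty(n_cells)
    cursor = 0.0
    for i in range(n_cells):
        # fixed-point midpoint: mid = cursor + l(mid)/2, so the recorded
        # (distance, length) pair lies exactly on the logistic curve
        mid = cursor + logistic_cell_length(cursor, l_min, l_max, k, x0) / 2.0
        for _ in range(50):
            new_mid = cursor + logistic_cell_length(mid, l_min, l_max, k, x0) / 2.0
            if abs(new_mid - mid) < 1e-12:
                break
            mid = new_mid
        length = logistic_cell_length(mid, l_min, l_max, k, x0)
        if noise_sd > 0:
            length = max(1.0, length + rng.normal(0.0, noise_sd))
            mid = cursor + length / 2.0
        distances[i] = mid
        lengths[i] = length
        cursor += length
    return pd.DataFrame({"distance": distances, "length": lengths})


# ---------------------------------------------------------------------------
# Weather and soil water
# ---------------------------------------------------------------------------

def generate_rain_series(n_days: int, seed: int, p_wet: float = 0.3,
                         gamma_shape: float = 0.8,
                         gamma_scale: float = 12.0) -> np.ndarray:
    """Daily rainfall (mm): Bernoulli wet days with gamma depths.

    A generic semi-arid rainy-season stand-in, not a calibration to any
    station record.
    """
    rng = np.random.default_rng(seed)
    wet = rng.random(n_days) < p_wet
    return np.where(wet, rng.gamma(gamma_shape, gamma_scale, n_days), 0.0)


def simulate_weather_ftsw(soil: BucketSoilParams, rain: np.ndarray,
                          seed: int = 0) -> pd.DataFrame:
    """Run the one-bucket soil-water balance over a daily rain series.

    Day t applies rain_t then transpiration T_t = demand × min(1,
    FTSW/onset) evaluated at the start-of-day water content, limited to the
    water actually available; surplus above ``ttsw`` leaves as overflow.
    Returns a frame indexed by day (0 = initial state, no fluxes) with
    columns rain, transpiration, overflow, atsw, ftsw.  Water is conserved
    exactly: Σrain − ΣT − Σoverflow = ATSW_end − ATSW_0.
    """
    rain = np.asarray(rain, dtype=float)
    if (rain < 0).any():
        raise ValueError("negative rainfall")
    n = rain.size
    atsw = np.empty(n + 1)
    ftsw = np.empty(n + 1)
    transp = np.zeros(n + 1)
    overflow = np.zeros(n + 1)
    atsw[0] = soil.initial_fill * soil.ttsw
    ftsw[0] = soil.initial_fill
    for t in range(n):
        supply_factor = min(1.0, ftsw[t] / soil.stress_onset_ftsw)
        demand = soil.daily_demand * supply_factor
        t_act = min(demand, atsw[t] + rain[t])
        new = atsw[t] + rain[t] - t_act
        over = max(0.0, new - soil.ttsw)
        atsw[t + 1] = new - over
        ftsw[t + 1] = atsw[t + 1] / soil.ttsw
        transp[t + 1] = t_act
        overflow[t + 1] = over
    return pd.DataFrame({
        "rain": np.concatenate(([0.0], rain)),
        "transpiration": transp,
        "overflow": overflow,
        "atsw": atsw,
        "ftsw": ftsw,
    }, index=pd.RangeIndex(n + 1, name="day"))
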