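"""Variance components, broad-sense heritability, adjusted means, correlations.

The phenotype model is the one-way random-effects layout

    value = μ + α_line + ε,   α_line ~ N(0, Var(line)),  ε ~ N(0, Var(res)),

and broad-sense heritability on a line-mean basis is

    H² = Var(line) / (Var(line) + Var(res) / n̄),

with n̄ the average number of plants measured per line.  Components are
estimated by the method of moments (expected mean squares of the unbalanced
one-way ANOVA); REML via a linear mixed model is available behind a flag and
agrees with the moment estimator on balanced designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VarianceComponents",
    "variance_components",
    "broad_sense_heritability",
    "adjusted_line_means",
    "correlate_traits",
    "LineVarianceModel",
    "HeritabilityResult",
]


@dataclass
class VarianceComponents:
    var_line: float
    var_res: float
    n_plant_per_line: float
    h2: float = float("nan")
    truncated: bool = False   # negative moment estimate clipped to 0
    degenerate: bool = False  # both components zero


def _select_trait(table: pd.DataFrame, trait: str | None) -> pd.DataFrame:
    if trait is not None and "trait" in table.columns:
        table = table.loc[table["trait"] == trait]
    if table.empty:
        raise ValueError(f"no records for trait {trait!r}")
    return table


def variance_components(table: pd.DataFrame,
                        trait: str | None = None) -> VarianceComponents:
    """Method-of-moments components from line-replicated records.

    Unbalanced one-way ANOVA: Var(res) = MS_within and
    Var(line) = (MS_between − MS_within) / n₀ with
    n₀ = (N − Σnᵢ²/N)/(k − 1).  A negative line-variance estimate is
    truncated to zero and flagged.
    """
    table = _select_trait(table, trait)
    groups = table.groupby("line")["value"]
    k = groups.ngroups
    if k < 2:
        raise ValueError("need at least two lines")
    n_i = groups.size().to_numpy(dtype=float)
    if (n_i < 2).all():
        raise ValueError("residual variance inestimable: every line is a singleton")
    N = n_i.sum()
    means = groups.mean().to_numpy()
    grand = table["value"].mean()

    ss_within = float(((table["value"] - groups.transform("mean")) ** 2).sum())
    ss_between = float((n_i * (means - grand) ** 2).sum())
    ms_within = ss_within / (N - k)
    ms_between = ss_between / (k - 1)
    n0 = (N - (n_i ** 2).sum() / N) / (k - 1)

    var_res = ms_within
    var_line = (ms_between - ms_within) / n0
    truncated = var_line < 0
    if truncated:
        warnings.warn("negative line-variance moment estimate truncated to 0")
        var_line = 0.0
    vc = VarianceComponents(var_line=var_line, var_res=var_res,
                            n_plant_per_line=N / k, truncated=truncated,
                            degenerate=(var_line == 0 and var_res == 0))
    vc.h2 = broad_sense_heritability(vc)
    return vc


def broad_sense_heritability(vc: VarianceComponents) -> float:
    """H² = Var(line) / (Var(line) + Var(res)/n̄); 0 when both components vanish."""
    denom = vc.var_line + vc.var_res / vc.n_plant_per_line
    if denom == 0:
        vc.degenerate = True
        return 0.0
    return vc.var_line / denom


def _reml_components(table: pd.DataFrame) -> tuple[float, float]:
    """REML line/residual variances via a random-intercept mixed model."""
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.mixedlm("value ~ 1", table, groups=table["line"]).fit(reml=True)
    return float(fit.cov_re.iloc[0, 0]), float(fit.scale)


def adjusted_line_means(table: pd.DataFrame,
                        trait: str | None = None) -> pd.Series:
    """Least-squares (adjusted) line means from value ~ line + year×block.

    Ordinary least squares with treatment coding; the adjusted mean of a line
    is its prediction averaged with equal weight over the year×block cells
    observed anywhere in the data.  On balanced designs this reduces to the
    arithmetic line mean.  A rank-deficient design (e.g. a line absent from
    every block of a year) is solved by pseudo-inverse with a warning.
    """
    table = _select_trait(table, trait).copy()
    for col in ("year", "block"):
        if col not in table.columns:
            table[col] = 1
    table["_yb"] = table["year"].astype(str) + ":" + table["block"].astype(str)

    lines = pd.Categorical(table["line"])
    cells = pd.Categorical(table["_yb"])
    X_line = pd.get_dummies(lines, drop_first=True, dtype=float)
    X_cell = pd.get_dummies(cells, drop_first=True, dtype=float)
    X = np.column_stack([np.ones(len(table)), X_line.to_numpy(), X_cell.to_numpy()])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient design; adjusted means use a pseudo-inverse")
    beta, *_ = np.linalg.lstsq(X, table["value"].to_numpy(), rcond=None)

    n_line = len(lines.categories)
    n_cell = len(cells.categories)
    # predicted value for line i in cell j, averaged over observed cells j
    line_block = np.vstack([np.zeros(n_line - 1),
                            np.eye(n_line - 1)])          # (n_line, n_line-1)
    cell_block = np.vstack([np.zeros(n_cell - 1),
                            np.eye(n_cell - 1)])          # (n_cell, n_cell-1)
    cell_mean = cell_block.mean(axis=0)
    design = np.column_stack([
        np.ones(n_line), line_block,
        np.tile(cell_mean, (n_line, 1)),
    ])
    means = design @ beta
    return pd.Series(means, index=lines.categories, name="adjusted_mean")


def correlate_traits(means_a: pd.Series, means_b: pd.Series) -> tuple[float, int]:
    """Pearson correlation over pairwise-complete lines; (nan, n) when a
    trait has zero variance."""
    from scipy import stats

    joined = pd.concat([means_a, means_b], axis=1, join="inner").dropna()
    n = len(joined)
    if n < 3:
        raise ValueError("need at least three paired lines")
    a, b = joined.iloc[:, 0], joined.iloc[:, 1]
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero variance in a trait; correlation undefined")
        return float("nan"), n
    r, _ = stats.pearsonr(a, b)
    return float(r), n


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

@dataclass
class HeritabilityResult:
    """Estimated components and broad-sense heritability for one trait."""

    components: VarianceComponents
    trait: str | None
    n_lines: int
    n_records: int
    method: str
    adjusted_means: pd.Series | None = None
    params: dict = field(default_factory=dict)

    @property
    def h2(self) -> float:
        return self.components.h2

    def summary(self) -> str:
        c = self.components
        lines = [
            f"Line variance decomposition ({self.method})"
            + (f" — trait {self.trait!r}" if self.trait else ""),
            f"  lines / records     : {self.n_lines} / {self.n_records}",
            f"  Var(line)           : {c.var_line:.4f}"
            + ("  [truncated at 0]" if c.truncated else ""),
            f"  Var(res)            : {c.var_res:.4f}",
            f"  plants per line (n̄) : {c.n_plant_per_line:.2f}",
            f"  H²                  : {c.h2:.3f}"
            + ("  [degenerate]" if c.degenerate else ""),
        ]
        return "\n".join(lines)


class LineVarianceModel:
    """Random line-effect model for a replicated panel.

    Built from a long-format phenotype table with columns ``line`` and
    ``value`` (plus optional ``trait``, ``year``, ``block``).
    """

    def __init__(self, table: pd.DataFrame, trait: str | None = None):
        self.table = table
        self.trait = trait

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame,
                       trait: str | None = None) -> "LineVarianceModel":
        return cls(table, trait)

    def fit(self, method: str = "mom",
            adjusted_means: bool = False) -> HeritabilityResult:
        """Estimate components (``method`` = "mom" or "reml") and H²."""
        sub = _select_trait(self.table, self.trait)
        if method == "mom":
            vc = variance_components(sub)
        elif method == "reml":
            var_line, var_res = _reml_components(sub)
            vc = VarianceComponents(
                var_line=var_line, var_res=var_res,
                n_plant_per_line=len(sub) / sub["line"].nunique(),
                degenerate=(var_line == 0 and var_res == 0))
            vc.h2 = broad_sense_heritability(vc)
        else:
            raise ValueError(f"unknown method {method!r}")
        means = adjusted_line_means(sub) if adjusted_means else None
        return HeritabilityResult(
            components=vc, trait=self.trait, n_lines=sub["line"].nunique(),
            n_records=len(sub), method=method, adjusted_means=means)
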