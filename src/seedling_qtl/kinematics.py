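"""Root-tip growth kinematics from cell-length profiles.

Cell walls are detected as intensity peaks along a line traced from the
quiescent center (QC) toward the mature zone; consecutive wall positions
give cell lengths, to which a four-parameter logistic

    l(x) = l_min + (l_max − l_min) / (1 + exp(−k (x − x0)))

is fitted (x = distance from the QC, µm).  Under steady-state growth the
cell production rate of the meristem is the externally measured root
elongation rate divided by the mature (maximum) cell length:

    production (cells/day) = elongation rate (µm/day) / l_max (µm).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .simulate import logistic_cell_length

__all__ = [
    "detect_cell_walls",
    "cell_lengths_from_walls",
    "fit_logistic",
    "kinematic_rates",
    "LogisticFit",
    "KinematicsResult",
    "CellProfileModel",
]


@dataclass
class LogisticFit:
    """Fitted logistic cell-length curve."""

    l_min: float
    l_max: float
    k: float
    x0: float
    rss: float
    converged: bool

    def predict(self, x: np.ndarray) -> np.ndarray:
        return logistic_cell_length(x, self.l_min, self.l_max, self.k, self.x0)


@dataclass(frozen=True)
class KinematicsResult:
    """Elongation and cell-production rates of one root sample."""

    elongation_rate: float   # µm/day
    max_cell_length: float   # µm
    cell_production: float   # cells/day


def detect_cell_walls(intensity: np.ndarray, spacing: float,
                      min_prominence: float,
                      min_separation: float) -> np.ndarray:
    """Positions of cell walls along an intensity transect.

    Walls are local maxima with at least ``min_prominence`` prominence and
    ``min_separation`` (µm) pairwise distance; where two candidates are
    closer, the higher survives.  Plateaus resolve to their leftmost sample.
    Returns positions in µm from the start of the transect.
    """
    intensity = np.asarray(intensity, dtype=float)
    if intensity.size < 3:
        raise ValueError("need at least three samples")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    distance = max(1, math.ceil(min_separation / spacing))
    peaks, props = signal.find_peaks(intensity, prominence=min_prominence,
                                     distance=distance, plateau_size=1)
    # leftmost sample of a plateau rather than its middle
    idx = props["left_edges"]
    return idx * spacing


def cell_lengths_from_walls(walls: np.ndarray) -> pd.DataFrame:
    """Cell lengths between consecutive walls.

    The first wall is taken as the QC origin; each cell's distance is the
    midpoint between its bounding walls, measured from that origin.
    """
    walls = np.sort(np.asarray(walls, dtype=float))
    if walls.size < 2:
        raise ValueError("need at least two walls to delimit a cell")
    if np.any(np.diff(walls) == 0):
        raise ValueError("duplicate wall positions")
    lengths = np.diff(walls)
    mids = (walls[:-1] + walls[1:]) / 2.0 - walls[0]
    return pd.DataFrame({"distance": mids, "length": lengths})


def fit_logistic(profile: pd.DataFrame,
                 four_parameter: bool = True) -> LogisticFit:
    """Least-squares logistic fit to a cell-length profile.

    Initialisation is data-driven (l_min/l_max from the 5th/95th length
    percentile, x0 at the half-range crossing, k from the central slope);
    bounds keep l_min ≥ 0.1 µm and k > 0.  With ``four_parameter=False``
    l_min is pinned at 0.1 µm (a curve rising from ~zero length).
    Non-convergence or a degenerate (flat) profile yields
    ``converged=False`` rather than an exception.
    """
    x = profile["distance"].to_numpy(dtype=float)
    y = profile["length"].to_numpy(dtype=float)
    lo, hi = np.percentile(y, [5, 95])
    span = hi - lo
    if span <= 1e-9 * max(abs(hi), 1.0):  # flat profile: no sigmoid to fit
        return LogisticFit(l_min=float(lo), l_max=float(hi), k=1e-6,
                           x0=float(np.median(x)),
                           rss=float(((y - y.mean()) ** 2).sum()),
                           converged=False)
    x0_guess = float(x[np.argmin(np.abs(y - (lo + span / 2)))])
    dy = np.gradient(y, x)
    k_guess = max(4.0 * float(np.max(dy)) / span, 1e-6)

    # floor keeps lengths positive; scales down with the data so a coherent
    # unit change (µm→mm) does not clamp the fit
    floor = min(0.1, 1e-3 * float(np.max(y)))
    if four_parameter:
        p0 = [max(lo, floor), hi, k_guess, x0_guess]
        bounds = ([floor, floor, 1e-12, -np.inf], [np.inf] * 4)
        model = logistic_cell_length
    else:
        def model(xx, l_max, k, x0):  # noqa: ANN001
            return logistic_cell_length(xx, floor, l_max, k, x0)
        p0 = [hi, k_guess, x0_guess]
        bounds = ([floor, 1e-12, -np.inf], [np.inf] * 3)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(model, x, y, p0=p0, bounds=bounds,
                                         maxfev=20000)
        resid = y - model(x, *popt)
        rss = float((resid ** 2).sum())
        if four_parameter:
            l_min, l_max, k, x0 = popt
        else:
            l_min, (l_max, k, x0) = floor, popt
        converged = l_max > l_min
        return LogisticFit(float(l_min), float(l_max), float(k), float(x0),
                           rss, bool(converged))
    except RuntimeError:
        return LogisticFit(float(lo), float(hi), k_guess, x0_guess,
                           rss=float("inf"), converged=False)


def kinematic_rates(fit: LogisticFit, elongation_rate: float,
                    profile: pd.DataFrame | None = None,
                    fallback: str | None = None) -> KinematicsResult:
    """Cell production from the fitted maximum cell length.

    With an unconverged fit, pass ``fallback="observed"`` (and the profile)
    to use the 95th percentile of observed lengths instead of the asymptote.
    """
    if elongation_rate <= 0:
        raise ValueError("elongation_rate must be positive")
    if fit.converged:
        l_max = fit.l_max
    elif fallback == "observed":
        if profile is None:
            raise ValueError("observed-length fallback requires the profile")
        l_max = float(np.percentile(profile["length"], 95))
    else:
        raise ValueError(
            "logistic fit did not converge; pass fallback='observed' with the "
            "profile to use the 95th percentile of observed cell lengths")
    return KinematicsResult(elongation_rate=float(elongation_rate),
                            max_cell_length=float(l_max),
                            cell_production=float(elongation_rate) / float(l_max))


class CellProfileModel:
    """Logistic growth model of one root's cell-length profile.

    Built either from a (distance, length) profile or from a raw intensity
    transect via :meth:`from_intensity`.
    """

    def __init__(self, profile: pd.DataFrame, sample: str | None = None):
        if len(profile) < 2:
            raise ValueError("profile needs at least two cells")
        self.profile = profile
        self.sample = sample

    @classmethod
    def from_intensity(cls, intensity: np.ndarray, spacing: float,
                       min_prominence: float, min_separation: float,
                       sample: str | None = None) -> "CellProfileModel":
        walls = detect_cell_walls(intensity, spacing, min_prominence,
                                  min_separation)
        return cls(cell_lengths_from_walls(walls), sample=sample)

    def fit(self, four_parameter: bool = True) -> LogisticFit:
        return fit_logistic(self.profile, four_parameter=four_parameter)

    def rates(self, elongation_rate: float,
              fallback: str | None = None) -> KinematicsResult:
        fit = self.fit()
        return kinematic_rates(fit, elongation_rate, self.profile, fallback)
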