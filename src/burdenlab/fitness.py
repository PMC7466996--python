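"""Competition-assay fitness and scaled epistasis.

Fitness of a burden strain relative to a wild-type (WT) reference is read
from a co-culture: the slope of log2-odds of the WT frequency against
generations is the WT's per-generation advantage, so the burden strain's
fitness advantage is its negation.  Under constant selection the log-odds
of the frequency is exactly linear in generations (log-frequency is not),
which is why the odds ratio is the fitted quantity.

Epistasis between the burden (fitness wx per copy) and a deletion mutant
(wy) is scored by the scaled statistic

    eps~ = (wxy - wx*wy) / |w~xy - wx*wy|

with w~xy = min(wx, wy) on the positive (buffering) side — appropriate for
small single effects — and w~xy = 0 (synthetic lethality) on the negative
side, so eps~ lands in [-1, +1] with 0 meaning multiplicative
(non-interacting) fitness.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CompetitionSeries",
    "FitnessResult",
    "BurdenFitCurve",
    "generations_from_dilution",
    "competition_fitness",
    "burden_per_copy",
    "scaled_epistasis",
]


@dataclass
class CompetitionSeries:
    """WT frequencies along a serial-dilution competition."""

    generations: np.ndarray  # cumulative generation counts
    f_wt: np.ndarray  # WT frequency in [0, 1]

    def __post_init__(self) -> None:
        self.generations = np.asarray(self.generations, dtype=float)
        self.f_wt = np.asarray(self.f_wt, dtype=float)
        if self.generations.shape != self.f_wt.shape:
            raise ValueError("generations and f_wt must have equal length")
        if np.any(np.diff(self.generations) < 0):
            raise ValueError("generations must be non-decreasing")
        if np.any((self.f_wt < 0) | (self.f_wt > 1)):
            raise ValueError("frequencies must lie in [0, 1]")


@dataclass(frozen=True)
class FitnessResult:
    slope: float  # log2-odds of WT per generation
    fitness_advantage: float  # of the competing (burden) strain, per generation
    pct_wt_division_rate: float  # 100 * (1 + fitness_advantage)


@dataclass(frozen=True)
class BurdenFitCurve:
    copy_numbers: np.ndarray
    relative_mu: np.ndarray
    S: float  # slope of relative growth rate per integrated copy
    per_copy_fitness: float  # wx = 1 + S


def generations_from_dilution(dilution_factor: float) -> float:
    """Generations elapsed per growth-dilution cycle: log2(dilution)."""
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    return math.log2(dilution_factor)


def competition_fitness(series: CompetitionSeries) -> FitnessResult:
    """Fit the log2-odds WT-frequency slope; derive the strain's fitness.

    Timepoints at frequency exactly 0 or 1 carry no finite log-odds and
    are excluded (logged).  At least two informative points are required.
    """
    keep = (series.f_wt > 0) & (series.f_wt < 1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("competition_fitness: dropped %d boundary frequencies",
                    n_dropped)
    gen, f = series.generations[keep], series.f_wt[keep]
    if gen.size < 2:
        raise ValueError("need >= 2 informative timepoints")
    log_odds = np.log2(f / (1.0 - f))
    slope = float(np.polyfit(gen, log_odds, 1)[0])
    advantage = -slope
    return FitnessResult(slope, advantage, 100.0 * (1.0 + advantage))


def burden_per_copy(copy_numbers, relative_mu) -> BurdenFitCurve:
    """Linear burden cost: slope S of relative growth rate per copy.

    The per-copy fitness of the burden is wx = 1 + S (S is expected
    negative).  Requires >= 3 strains including the 0-copy reference.
    """
    copies = np.asarray(copy_numbers, dtype=float)
    mu = np.asarray(relative_mu, dtype=float)
    if copies.size < 3:
        raise ValueError("need >= 3 strains")
    if 0 not in copies:
        raise ValueError("a 0-copy (WT) strain is required")
    if np.allclose(copies, copies[0]):
        raise ValueError("copy numbers are degenerate")
    fit = stats.linregress(copies, mu)
    return BurdenFitCurve(copies, mu, float(fit.slope), 1.0 + float(fit.slope))


def scaled_epistasis(wx: float, wy: float, wxy: float,
                     rel_tol: float = 1e-12) -> float:
    """Scaled epistasis eps~ in [-1, 1] for a fitness triplet.

    eps = wxy - wx*wy.  On the boundary (|eps| within ``rel_tol`` of 0)
    the result is 0.  For eps > 0 the denominator is |min(wx,wy) - wx*wy|
    (buffering bound); for eps < 0 it is wx*wy (synthetic-lethal bound,
    giving -1 at wxy = 0).  Values outside [-1, 1] are clamped (logged).
    """
    for name, w in (("wx", wx), ("wy", wy), ("wxy", wxy)):
        if not 0.0 <= w <= 1.5:
            raise ValueError(f"{name}={w} outside [0, 1.5]")
    expected = wx * wy
    eps = wxy - expected
    if abs(eps) <= rel_tol * max(1.0, expected):
        return 0.0
    if eps > 0:
        denom = abs(min(wx, wy) - expected)
        if denom == 0.0:
            raise ValueError("undefined: min(wx, wy) == wx*wy with positive epistasis")
    else:
        denom = expected  # |0 - wx*wy|; eps < 0 implies expected > 0
    value = eps / denom
    if value > 1.0 or value < -1.0:
        logger.info("scaled_epistasis: clamped %.4f into [-1, 1]", value)
        value = max(-1.0, min(1.0, value))
    return value
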