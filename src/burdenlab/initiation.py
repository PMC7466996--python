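"""Stochastic transcription initiation gated by promoter clearance.

A promoter receives initiation *attempts* as a Poisson process with rate
``a`` (attempts/s).  After a successful initiation the polymerase must
elongate its own footprint away from the start site before another
polymerase can load; this imposes a *dead time* ``tau`` (seconds) during
which every attempt fails.  The dead time is non-paralyzable: the clock
restarts only on a success, never on a rejected attempt.  The successful
initiations therefore form a renewal process with inter-event intervals
``tau + Exp(a)``, whose long-run rate is the closed form

    r(a) = a / (1 + a * tau),

saturating at ``1/tau`` — the maximal initiation rate set by the
polymerase footprint divided by its elongation velocity.

The module also contains an optional two-state (telegraph) promoter in
which attempts occur only while the promoter is ON, and a piecewise
critical-cell-size growth model: growth stays at its optimum while the
cell's ribosome count can be accommodated on the available transcripts,
and declines inversely with protein content beyond that point.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "InitiationParams",
    "ClearanceConstants",
    "SimResult",
    "SizeModelParams",
    "clearance_time",
    "analytic_effective_rate",
    "simulate_initiation",
    "rate_response_curve",
    "burden_fold_change",
    "critical_size_curve",
]


@dataclass(frozen=True)
class InitiationParams:
    """Kinetic parameters of a single promoter.

    Parameters
    ----------
    attempt_rate
        Rate of stochastic initiation attempts (attempts/s).
    dead_time
        Promoter-clearance dead time tau (s); minimal spacing between
        successful initiations.
    burst_on_rate, burst_off_rate
        Optional telegraph-promoter switching rates (1/s).  Attempts are
        only productive while the promoter is ON.  Either both are given
        or neither.
    """

    attempt_rate: float
    dead_time: float
    burst_on_rate: float | None = None
    burst_off_rate: float | None = None

    def __post_init__(self) -> None:
        if self.attempt_rate < 0:
            raise ValueError("attempt_rate must be >= 0")
        if self.dead_time <= 0:
            raise ValueError("dead_time must be > 0")
        if (self.burst_on_rate is None) != (self.burst_off_rate is None):
            raise ValueError("burst_on_rate and burst_off_rate must be set together")
        if self.burst_on_rate is not None:
            if self.burst_on_rate <= 0 or self.burst_off_rate <= 0:
                raise ValueError("burst rates must be > 0")

    @property
    def is_bursty(self) -> bool:
        return self.burst_on_rate is not None


@dataclass(frozen=True)
class ClearanceConstants:
    """Physical constants determining the promoter-clearance time.

    Defaults are the literature values for RNA polymerase II in budding
    yeast: a ~35 bp DNA footprint and an average elongation velocity of
    2 kb/min.
    """

    footprint_bp: float = 35.0
    elongation_bp_per_min: float = 2000.0

    def __post_init__(self) -> None:
        if self.footprint_bp <= 0:
            raise ValueError("footprint_bp must be > 0")
        if self.elongation_bp_per_min <= 0:
            raise ValueError("elongation_bp_per_min must be > 0")


def clearance_time(constants: ClearanceConstants) -> float:
    """Dead time (s) implied by the polymerase footprint and elongation speed.

    Returns ``footprint_bp / (elongation_bp_per_min / 60)``.  Its
    reciprocal is the maximal achievable initiation rate.
    """
    return constants.footprint_bp / (constants.elongation_bp_per_min / 60.0)


def analytic_effective_rate(params: InitiationParams) -> float:
    """Closed-form mean successful-initiation rate ``a / (1 + a*tau)``.

    Only defined for constitutive promoters; the telegraph model has no
    closed form implemented here.
    """
    if params.is_bursty:
        raise ValueError("no closed form for bursty promoters; use simulate_initiation")
    a, tau = params.attempt_rate, params.dead_time
    return a / (1.0 + a * tau)


@dataclass
class SimResult:
    """Outcome of one stochastic initiation run."""

    duration_s: float
    n_attempts: int
    n_success: int
    effective_rate: float
    success_times: np.ndarray

    def to_dict(self) -> dict:
        return {
            "duration_s": self.duration_s,
            "n_attempts": self.n_attempts,
            "n_success": self.n_success,
            "effective_rate": self.effective_rate,
        }

    def rate_standard_error(self) -> float:
        """Monte-Carlo SE of ``effective_rate`` from the success-gap spread.

        For a renewal process observed over a fixed window the rate
        estimate N/T has asymptotic variance ``T * var(gap) / mean(gap)^3``;
        this plugs in the empirical gap moments.
        """
        gaps = np.diff(self.success_times)
        if gaps.size < 2:
            return float("inf")
        m = gaps.mean()
        return float(np.sqrt(gaps.var(ddof=1) * self.duration_s / m**3) / self.duration_s)


_CHUNK = 4_000_000


def _filter_dead_time(times: np.ndarray, tau: float, next_allowed: float,
                      out: list) -> float:
    """Greedy dead-time thinning of sorted attempt times; returns new bound."""
    i = int(np.searchsorted(times, next_allowed, side="left"))
    n = times.size
    while i < n:
        t = float(times[i])
        out.append(t)
        next_allowed = t + tau
        i = int(np.searchsorted(times, next_allowed, side="left"))
    return next_allowed


def _simulate_constitutive(a: float, tau: float, duration_s: float,
                           rng: np.random.Generator) -> tuple[int, list]:
    successes: list[float] = []
    n_attempts = 0
    t = 0.0
    next_allowed = -np.inf  # first attempt always succeeds
    while t < duration_s:
        remaining = duration_s - t
        # expected attempts left, padded; bounded chunk keeps memory flat
        size = min(_CHUNK, int(a * remaining * 1.1) + 64)
        times = t + np.cumsum(rng.exponential(1.0 / a, size))
        t = float(times[-1])
        if t >= duration_s:
            times = times[times < duration_s]
        n_attempts += times.size
        if times.size:
            next_allowed = _filter_dead_time(times, tau, next_allowed, successes)
    return n_attempts, successes


def _simulate_bursty(params: InitiationParams, duration_s: float,
                     rng: np.random.Generator) -> tuple[int, list]:
    a = params.attempt_rate
    kon, koff = params.burst_on_rate, params.burst_off_rate
    p_on = kon / (kon + koff)
    on = bool(rng.random() < p_on)  # start from the stationary state
    t = 0.0
    pieces = []
    while t < duration_s:
        dwell = rng.exponential(1.0 / (koff if on else kon))
        end = min(t + dwell, duration_s)
        if on and a > 0 and end > t:
            k = rng.poisson(a * (end - t))
            if k:
                pieces.append(rng.uniform(t, end, k))
        t += dwell
        on = not on
    if pieces:
        times = np.sort(np.concatenate(pieces))
    else:
        times = np.empty(0)
    successes: list[float] = []
    if times.size:
        _filter_dead_time(times, params.dead_time, -np.inf, successes)
    return times.size, successes


def simulate_initiation(params: InitiationParams, duration_s: float,
                        seed: int) -> SimResult:
    """Event-level simulation of dead-time-gated initiation.

    Attempts arrive as a Poisson process at ``attempt_rate`` (restricted
    to ON periods for a telegraph promoter).  An attempt succeeds iff at
    least ``dead_time`` has elapsed since the previous success; the first
    attempt of a run always succeeds.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    rng = np.random.default_rng(seed)
    if params.attempt_rate == 0:
        return SimResult(duration_s, 0, 0, 0.0, np.empty(0))
    if params.is_bursty:
        n_attempts, successes = _simulate_bursty(params, duration_s, rng)
    else:
        n_attempts, successes = _simulate_constitutive(
            params.attempt_rate, params.dead_time, duration_s, rng)
    times = np.asarray(successes)
    return SimResult(duration_s, n_attempts, times.size,
                     times.size / duration_s, times)


def rate_response_curve(a_grid, dead_time: float, duration_s: float,
                        seed: int) -> pd.DataFrame:
    """Simulated successful-initiation rate across a grid of attempt rates.

    One independent simulation per grid point (seeded ``seed + index``).
    The curve rises with the attempt rate, is concave, and plateaus at
    ``1/dead_time``.
    """
    a_grid = np.asarray(a_grid, dtype=float)
    if a_grid.size == 0:
        raise ValueError("a_grid is empty")
    if np.any(np.diff(a_grid) < 0):
        raise ValueError("a_grid must be sorted ascending")
    rows = []
    for i, a in enumerate(a_grid):
        res = simulate_initiation(InitiationParams(a, dead_time), duration_s,
                                  seed + i)
        rows.append({"attempt_rate": a, "effective_rate": res.effective_rate,
                     "n_success": res.n_success})
    return pd.DataFrame(rows)


def burden_fold_change(params: InitiationParams, g: float) -> float:
    """Expression fold change when the attempt rate is scaled by ``g``.

    Burdened cells raise overall transcription capacity, multiplying every
    promoter's attempt rate by ``g >= 1``.  The realized fold change

        [g*a / (1 + g*a*tau)] / [a / (1 + a*tau)]

    equals ``g`` for rarely attempted promoters and decays to 1 for
    promoters already saturating the dead time.
    """
    if params.is_bursty:
        raise ValueError("closed-form fold change requires a constitutive promoter")
    if g < 1:
        warnings.warn("capacity factor g < 1 (capacity loss); computed anyway",
                      stacklevel=2)
    a, tau = params.attempt_rate, params.dead_time
    if a == 0:
        return g
    return (g * a / (1.0 + g * a * tau)) / (a / (1.0 + a * tau))


@dataclass(frozen=True)
class SizeModelParams:
    """Parameters of the critical-cell-size growth model.

    The model ties growth to translation: the cell keeps a fixed
    ribosomal proteome fraction, so its ribosome count grows linearly
    with total protein content ``P``.  Transcripts can engage at most
    ``max_ribosomes_per_transcript`` ribosomes each, capping the number
    of translating ribosomes at ``C = mrna_count * max_ribosomes_per_transcript``.
    Below the critical content ``P*`` (where the ribosome count hits C)
    growth is at its optimum; beyond it the translating fraction — and
    growth — fall off as ``C / R(P)``.

    Defaults hold the documented literature scales for budding yeast
    (~35,000 transcripts, ~200,000 ribosomes, i.e. the often-quoted ~8
    ribosomes/mRNA even though 200,000/35,000 is nearer 5.7; they are
    stored as published, not re-derived).
    """

    mrna_count: float = 35_000.0
    max_ribosomes_per_transcript: float = 8.0
    ribosomal_fraction: float = 0.3
    proteins_per_ribosome_unit: float = 12.0
    mu_opt: float = 0.4  # 1/h

    def __post_init__(self) -> None:
        for name in ("mrna_count", "max_ribosomes_per_transcript",
                     "ribosomal_fraction", "proteins_per_ribosome_unit",
                     "mu_opt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.ribosomal_fraction >= 1:
            raise ValueError("ribosomal_fraction must be < 1")

    @property
    def ribosome_capacity(self) -> float:
        """Maximal number of simultaneously translating ribosomes."""
        return self.mrna_count * self.max_ribosomes_per_transcript

    @property
    def critical_protein_content(self) -> float:
        """P* at which the cell's ribosome count equals the mRNA capacity."""
        return (self.ribosome_capacity * self.proteins_per_ribosome_unit
                / self.ribosomal_fraction)


def critical_size_curve(params: SizeModelParams,
                        protein_content_grid) -> tuple[pd.DataFrame, float]:
    """Growth rate vs protein content under the critical-size model.

    Returns the (protein_content, growth_rate) curve and the critical
    content ``P*``.  mu(P) = mu_opt for P <= P*, else mu_opt * C / R(P);
    the curve is continuous and non-increasing.
    """
    grid = np.asarray(protein_content_grid, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("protein content grid must be positive")
    ribosomes = params.ribosomal_fraction * grid / params.proteins_per_ribosome_unit
    cap = params.ribosome_capacity
    mu = np.where(ribosomes <= cap, params.mu_opt,
                  params.mu_opt * cap / ribosomes)
    curve = pd.DataFrame({"protein_content": grid, "growth_rate": mu})
    return curve, params.critical_protein_content
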