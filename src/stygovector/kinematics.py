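"""Swimming-speed kinematics and comparison against groundwater advection.

Free-swimming speed is measured from tracked 2-D positions as total path
length over elapsed time, converted from cm min^-1 to m yr^-1 (365-day
year).  Because an animal moving through the aquifer matrix cannot swim in a
straight line, the free speed is deflated by the medium's tortuosity tau
(path length / straight-line distance, 2-4 for sand and gravel) to give an
effective migration speed, which is then compared with bulk advective
transport (1-1000 m yr^-1) as a fold-enhancement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "SpeedSummary",
    "TortuosityCorrection",
    "TransportComparison",
    "CM_PER_MIN_TO_M_PER_YR",
    "replicate_speed",
    "individual_summary",
    "cohort_summary",
    "tortuosity_correct",
    "enhancement_ratio",
    "summarize_speeds",
    "transport_comparison",
]

#: cm min^-1 -> m yr^-1: 0.01 m/cm x 525,600 min/yr (365-day year).
CM_PER_MIN_TO_M_PER_YR = 5256.0


@dataclass(frozen=True)
class Trajectory:
    """Tracked 2-D positions of one swimming replicate.

    ``t_s`` are strictly increasing timestamps in seconds; ``x_cm``/``y_cm``
    the tracked coordinates in centimetres.
    """

    individual_id: str
    replicate: int
    t_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t_s, dtype=float)
        x = np.asarray(self.x_cm, dtype=float)
        y = np.asarray(self.y_cm, dtype=float)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1:
            raise ValueError("t_s, x_cm, y_cm must be 1-D arrays of equal length")
        object.__setattr__(self, "t_s", t)
        object.__setattr__(self, "x_cm", x)
        object.__setattr__(self, "y_cm", y)

    def __len__(self) -> int:
        return self.t_s.size

    def path_length_cm(self) -> float:
        """Total path length: sum of consecutive Euclidean step lengths."""
        return float(np.hypot(np.diff(self.x_cm), np.diff(self.y_cm)).sum())


@dataclass(frozen=True)
class SpeedSummary:
    """Per-individual and cohort speed statistics (units follow the input)."""

    per_individual: pd.DataFrame  # index individual_id; columns mean, sd, n_replicates
    cohort_mean: float
    cohort_sd: float


@dataclass(frozen=True)
class TortuosityCorrection:
    """Migration speeds after deflating the free speed by tortuosity tau."""

    tau_min: float
    tau_max: float
    corrected_at_tau_min: float  # larger speed (divided by the smaller tau)
    corrected_at_tau_max: float

    def __post_init__(self) -> None:
        if not self.corrected_at_tau_min >= self.corrected_at_tau_max:
            raise ValueError("corrected speed at tau_min must be >= at tau_max")


@dataclass(frozen=True)
class TransportComparison:
    """Fold-enhancement of migration over advective transport."""

    advection_min_m_yr: float
    advection_max_m_yr: float
    enhancement_min: int
    enhancement_max: int


def replicate_speed(track: Trajectory) -> float:
    """Speed of one replicate in m yr^-1 from total path length.

    (sum of consecutive Euclidean step lengths in cm / elapsed minutes)
    x 5256 converts cm min^-1 to m yr^-1.

    Raises
    ------
    ValueError
        Fewer than two points, or timestamps not strictly increasing.
    """
    if len(track) < 2:
        raise ValueError("speed needs at least 2 tracked points")
    dt = np.diff(track.t_s)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    elapsed_min = (track.t_s[-1] - track.t_s[0]) / 60.0
    return track.path_length_cm() / elapsed_min * CM_PER_MIN_TO_M_PER_YR


def individual_summary(replicate_speeds) -> tuple[float, float]:
    """Mean and sample SD (n-1) of one individual's replicate speeds.

    With a single replicate the SD is reported as 0.0 and a warning is
    emitted (no dispersion is estimable from n=1).
    """
    speeds = np.asarray(replicate_speeds, dtype=float)
    if speeds.size == 0:
        raise ValueError("no replicate speeds given")
    if speeds.size == 1:
        warnings.warn("single replicate: SD reported as 0", stacklevel=2)
        return float(speeds[0]), 0.0
    return float(speeds.mean()), float(speeds.std(ddof=1))


def cohort_summary(per_individual_means) -> tuple[float, float]:
    """Cohort mean and sample SD over per-individual mean speeds.

    The cohort statistics are taken over the individuals' means, not over
    the pooled replicates, so each animal counts once.
    """
    return individual_summary(per_individual_means)


def tortuosity_correct(speed: float, tau: float) -> float:
    """Deflate a free-swimming speed by the medium tortuosity (speed / tau)."""
    if tau < 1:
        raise ValueError(f"tortuosity must be >= 1, got {tau}")
    return speed / tau


def enhancement_ratio(corrected_speed: float, advection: float) -> int:
    """Fold-enhancement of migration over advection, truncated to an integer."""
    if advection <= 0:
        raise ValueError("advection must be positive")
    if corrected_speed <= 0:
        raise ValueError("corrected speed must be positive")
    return math.floor(corrected_speed / advection)


def summarize_speeds(replicate_speeds_by_individual: dict[str, list[float]]) -> SpeedSummary:
    """Full per-individual and cohort summary from replicate speeds.

    Parameters
    ----------
    replicate_speeds_by_individual
        Mapping individual id -> list of replicate speeds (any consistent unit).
    """
    if not replicate_speeds_by_individual:
        raise ValueError("no individuals given")
    rows = {}
    for ind, speeds in replicate_speeds_by_individual.items():
        mean, sd = individual_summary(speeds)
        rows[ind] = {"mean": mean, "sd": sd, "n_replicates": len(np.atleast_1d(speeds))}
    per_ind = pd.DataFrame.from_dict(rows, orient="index")
    cohort_mean, cohort_sd = cohort_summary(per_ind["mean"].to_numpy())
    return SpeedSummary(per_individual=per_ind, cohort_mean=cohort_mean, cohort_sd=cohort_sd)


def transport_comparison(
    cohort_mean_speed_m_yr: float,
    tau_min: float = 2.0,
    tau_max: float = 4.0,
    advection_min_m_yr: float = 1.0,
    advection_max_m_yr: float = 1000.0,
) -> tuple[TortuosityCorrection, TransportComparison]:
    """Tortuosity-corrected migration speeds and advection fold-enhancements.

    The conservative enhancement range compares the slowest migration speed
    (free speed / tau_max) and the fastest (free speed / tau_min) against the
    fastest advection, so the printed "min-max x faster" range is with
    respect to the upper advection bound.
    """
    if not 1 <= tau_min <= tau_max:
        raise ValueError("need 1 <= tau_min <= tau_max")
    if not 0 < advection_min_m_yr <= advection_max_m_yr:
        raise ValueError("need 0 < advection_min <= advection_max")
    corr = TortuosityCorrection(
        tau_min=tau_min,
        tau_max=tau_max,
        corrected_at_tau_min=tortuosity_correct(cohort_mean_speed_m_yr, tau_min),
        corrected_at_tau_max=tortuosity_correct(cohort_mean_speed_m_yr, tau_max),
    )
    comp = TransportComparison(
        advection_min_m_yr=advection_min_m_yr,
        advection_max_m_yr=advection_max_m_yr,
        enhancement_min=enhancement_ratio(corr.corrected_at_tau_max, advection_max_m_yr),
        enhancement_max=enhancement_ratio(corr.corrected_at_tau_min, advection_max_m_yr),
    )
    return corr, comp
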