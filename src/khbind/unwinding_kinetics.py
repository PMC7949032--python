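"""Helicase unwinding time-course quantification.

Gel lanes yield product (unwound, P) and substrate (duplex, S) band
intensities; % unwinding = 100·P/(S+P) after subtracting the no-enzyme
background from P and the heat-denatured control background from S.  Rates
in bp/min follow the reference-level procedure: the slowest protein sets the
reference unwinding level at the last time point, its rate is duplex length
over that time, and every faster protein's rate is duplex length over the
time its linear fit reaches the same level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LaneQuant",
    "UnwindingTimeCourse",
    "RateEstimate",
    "percent_unwound",
    "timecourse_from_lanes",
    "fit_linear",
    "estimate_rates",
    "read_timecourses",
]


@dataclass
class LaneQuant:
    """Band intensities for one gel lane plus its control lanes.

    P_ne: product intensity in the no-enzyme control lane.
    S_hd: substrate intensity in the heat-denatured control lane.
    """

    P: float
    S: float
    P_ne: float = 0.0
    S_hd: float = 0.0

    def __post_init__(self):
        if min(self.P, self.S, self.P_ne, self.S_hd) < 0:
            raise ValueError("intensities must be nonnegative")


@dataclass
class UnwindingTimeCourse:
    times: np.ndarray  # minutes
    percent_unwound: np.ndarray  # %
    protein: str
    substrate: str
    duplex_length: int  # bp

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.percent_unwound = np.asarray(self.percent_unwound, dtype=float)
        if self.times.shape != self.percent_unwound.shape:
            raise ValueError("times and percent_unwound must have equal length")
        if self.duplex_length <= 0:
            raise ValueError("duplex_length must be positive")


@dataclass
class RateEstimate:
    protein: str
    rate: float | None  # bp/min
    crossing_time: float | None  # minutes
    reference_level: float  # %
    slope: float  # %/min
    intercept: float  # %
    flags: list = field(default_factory=list)


def percent_unwound(lane: LaneQuant) -> float:
    """Background-corrected % unwinding, 100·P'/(S'+P').

    P' = max(0, P − P_ne), S' = max(0, S − S_hd); negative corrected
    intensities are clamped because background can exceed signal in noisy
    lanes.  Returns NaN (a flagged missing value) when both corrected
    intensities vanish.
    """
    P = max(0.0, lane.P - lane.P_ne)
    S = max(0.0, lane.S - lane.S_hd)
    if P + S == 0:
        return float("nan")
    return 100.0 * P / (S + P)


def timecourse_from_lanes(
    times: Sequence[float],
    lanes: Sequence[LaneQuant],
    protein: str,
    substrate: str,
    duplex_length: int,
) -> UnwindingTimeCourse:
    """Quantify a series of lanes into a background-corrected time course."""
    if len(times) != len(lanes):
        raise ValueError("times and lanes must align")
    pct = np.array([percent_unwound(l) for l in lanes])
    return UnwindingTimeCourse(
        times=np.asarray(times, dtype=float),
        percent_unwound=np.clip(pct, 0.0, 100.0),
        protein=protein,
        substrate=substrate,
        duplex_length=duplex_length,
    )


def fit_linear(tc: UnwindingTimeCourse, t_max: float) -> tuple[float, float]:
    """OLS line (slope %/min, intercept %) through points with t <= t_max."""
    mask = (tc.times <= t_max) & np.isfinite(tc.percent_unwound)
    if mask.sum() < 2:
        raise ValueError("need at least 2 points with t <= t_max for a linear fit")
    slope, intercept = np.polyfit(tc.times[mask], tc.percent_unwound[mask], 1)
    return float(slope), float(intercept)


def estimate_rates(
    tcs: Sequence[UnwindingTimeCourse], max_time: float = 45.0
) -> dict[str, RateEstimate]:
    """Reference-level unwinding rates (bp/min) for a set of proteins.

    All time courses must share the substrate and duplex length.  The protein
    whose linear fit gives the smallest % unwound at ``max_time`` is the
    slowest; its rate is duplex_length / max_time and its fitted level at
    ``max_time`` is the reference.  Every other protein's crossing time
    solves its linear fit = reference level; rate = duplex_length /
    crossing_time.  Crossing times outside (0, max_time] are extrapolations
    and are flagged; a non-positive slope leaves the rate undefined.
    """
    if not tcs:
        raise ValueError("no time courses given")
    if len({tc.substrate for tc in tcs}) > 1 or len({tc.duplex_length for tc in tcs}) > 1:
        raise ValueError("all time courses must share substrate and duplex length")
    duplex = tcs[0].duplex_length

    fits = {tc.protein: fit_linear(tc, max_time) for tc in tcs}
    level = {p: s * max_time + b for p, (s, b) in fits.items()}
    slowest = min(level, key=lambda p: level[p])
    reference = level[slowest]

    out: dict[str, RateEstimate] = {}
    for tc in tcs:
        p = tc.protein
        slope, intercept = fits[p]
        if p == slowest:
            out[p] = RateEstimate(
                protein=p, rate=duplex / max_time, crossing_time=max_time,
                reference_level=reference, slope=slope, intercept=intercept,
            )
            continue
        flags = []
        if slope <= 0:
            out[p] = RateEstimate(
                protein=p, rate=None, crossing_time=None, reference_level=reference,
                slope=slope, intercept=intercept, flags=["non-positive slope; rate undefined"],
            )
            continue
        t_cross = (reference - intercept) / slope
        if t_cross <= 0:
            flags.append("crossing time <= 0; extrapolated")
            rate = None
        else:
            if t_cross > max_time:
                flags.append("crossing time beyond max_time; extrapolated")
            rate = duplex / t_cross
        out[p] = RateEstimate(
            protein=p, rate=rate, crossing_time=t_cross, reference_level=reference,
            slope=slope, intercept=intercept, flags=flags,
        )
    return out


def read_timecourses(path, substrate: str = "substrate", duplex_length: int | None = None):
    """Read time courses from TSV.

    Accepts either raw lane intensities (protein, time_min, P, S, P_ne, S_hd)
    or pre-quantified (protein, time_min, percent_unwound).  An optional
    duplex_length column overrides the argument.
    """
    df = pd.read_csv(path, sep="\t")
    tcs = []
    for protein, grp in df.groupby("protein", sort=False):
        grp = grp.sort_values("time_min")
        dl = int(grp["duplex_length"].iloc[0]) if "duplex_length" in grp else duplex_length
        if dl is None:
            raise ValueError("duplex_length needed (column or argument)")
        if "percent_unwound" in grp:
            pct = grp["percent_unwound"].to_numpy(dtype=float)
            tcs.append(
                UnwindingTimeCourse(grp["time_min"].to_numpy(dtype=float), pct, str(protein), substrate, dl)
            )
        else:
            lanes = [
                LaneQuant(r.P, r.S, getattr(r, "P_ne", 0.0), getattr(r, "S_hd", 0.0))
                for r in grp.itertuples()
            ]
            tcs.append(timecourse_from_lanes(grp["time_min"].tolist(), lanes, str(protein), substrate, dl))
    return tcs


def rates_report(rates: Mapping[str, RateEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein": r.protein,
                "rate_bp_per_min": r.rate,
                "crossing_time_min": r.crossing_time,
                "reference_level_pct": r.reference_level,
                "slope_pct_per_min": r.slope,
                "intercept_pct": r.intercept,
                "flags": ";".join(r.flags),
            }
            for r in rates.values()
        ]
    )
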