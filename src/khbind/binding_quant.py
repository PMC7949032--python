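"""Equilibrium binding quantification from EMSA / filter-binding intensities.

The bound fraction at each protein concentration comes straight from the two
band (or dot) intensities; Kd is then estimated by least squares against a
hyperbolic or Hill dose-response curve.  The protein is titrated in large
excess over the labelled substrate (micromolar protein vs sub-nanomolar
probe), so free protein is taken equal to total protein and no depletion
correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = ["DoseResponse", "EquilibriumFit", "fraction_bound", "fit_equilibrium_kd", "read_dose_response"]


def fraction_bound(bound_signal: float, free_signal: float) -> float:
    """bound/(bound+free); NaN (flagged) when both signals are zero."""
    if bound_signal < 0 or free_signal < 0:
        raise ValueError("signals must be nonnegative")
    total = bound_signal + free_signal
    if total == 0:
        warnings.warn("both signals zero; fraction bound undefined")
        return float("nan")
    return bound_signal / total


@dataclass
class DoseResponse:
    protein_concs: np.ndarray  # μM
    fraction_bound: np.ndarray  # [0, 1]
    substrate: str = ""

    def __post_init__(self):
        self.protein_concs = np.asarray(self.protein_concs, dtype=float)
        self.fraction_bound = np.asarray(self.fraction_bound, dtype=float)
        if self.protein_concs.shape != self.fraction_bound.shape:
            raise ValueError("concentration and fraction lists must align")
        if np.any(self.protein_concs < 0):
            raise ValueError("concentrations must be nonnegative")
        if np.any(np.diff(self.protein_concs) <= 0):
            raise ValueError("concentrations must be strictly increasing")


@dataclass
class EquilibriumFit:
    kd: float  # μM
    kd_se: float
    bmax: float
    bmax_se: float
    hill: float | None  # None for the hyperbolic model
    hill_se: float | None
    rss: float
    reliable: bool
    flags: list = field(default_factory=list)

    def predict(self, conc):
        n = 1.0 if self.hill is None else self.hill
        conc = np.asarray(conc, dtype=float)
        return self.bmax * conc**n / (self.kd**n + conc**n)


def _hyperbola(P, kd, bmax):
    return bmax * P / (kd + P)


def _hill(P, kd, bmax, n):
    with np.errstate(divide="ignore", invalid="ignore"):
        out = bmax * P**n / (kd**n + P**n)
    return np.where(P == 0, 0.0, out)


def fit_equilibrium_kd(dr: DoseResponse, model: str = "hyperbolic") -> EquilibriumFit:
    """Least-squares Kd from a protein-titration dose-response curve.

    model="hyperbolic" fits f([P]) = Bmax·[P]/(Kd+[P]); model="hill" frees
    the Hill coefficient n.  Bmax is fitted rather than fixed at 1 because
    incomplete shifting is common in EMSA.  A fit reaching < 20% of Bmax at
    the highest concentration, or a failed optimisation, is flagged
    unreliable.
    """
    P, f = dr.protein_concs, dr.fraction_bound
    if len(P) < 4 or not np.any(P > 0):
        raise ValueError("need >= 4 points with at least one nonzero concentration")

    bmax0 = max(float(np.nanmax(f)), 1e-3)
    half = bmax0 / 2
    above = P[f >= half]
    kd0 = float(above[0]) if above.size and above[0] > 0 else float(np.median(P[P > 0]))

    flags: list = []
    try:
        if model == "hyperbolic":
            popt, pcov = curve_fit(
                _hyperbola, P, f, p0=[kd0, bmax0],
                bounds=([1e-6, 1e-6], [1e6, 1.05]), maxfev=10000,
            )
            kd, bmax = popt
            hill = hill_se = None
        elif model == "hill":
            popt, pcov = curve_fit(
                _hill, P, f, p0=[kd0, bmax0, 1.0],
                bounds=([1e-6, 1e-6, 0.1], [1e6, 1.05, 10.0]), maxfev=10000,
            )
            kd, bmax, hill = popt
        else:
            raise ValueError(f"unknown model {model!r}")
    except RuntimeError:
        return EquilibriumFit(
            kd=float("nan"), kd_se=float("nan"), bmax=float("nan"), bmax_se=float("nan"),
            hill=None, hill_se=None, rss=float("nan"), reliable=False,
            flags=["optimizer failed to converge"],
        )

    ses = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    if model == "hill":
        hill_se = float(ses[2])
    n_exp = 1.0 if hill is None else hill
    pred = _hill(P, kd, bmax, n_exp)
    rss = float(np.nansum((pred - f) ** 2))
    saturation = pred[-1] / bmax if bmax > 0 else 0.0
    reliable = True
    if saturation < 0.20:
        flags.append("saturation < 20% at highest concentration; Kd unreliable")
        reliable = False
    return EquilibriumFit(
        kd=float(kd), kd_se=float(ses[0]), bmax=float(bmax), bmax_se=float(ses[1]),
        hill=None if hill is None else float(hill), hill_se=hill_se,
        rss=rss, reliable=reliable, flags=flags,
    )


def read_dose_response(path, substrate: str = "") -> DoseResponse:
    """Read (conc_uM, bound, free) or (conc_uM, fraction_bound) TSV."""
    df = pd.read_csv(path, sep="\t").sort_values("conc_uM")
    if "fraction_bound" in df:
        frac = df["fraction_bound"].to_numpy(dtype=float)
    else:
        frac = np.array([fraction_bound(b, fr) for b, fr in zip(df["bound"], df["free"])])
    return DoseResponse(df["conc_uM"].to_numpy(dtype=float), frac, substrate=substrate)
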