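"""Chemical-shift-perturbation (CSP) analysis for protein–oligonucleotide titrations.

A ligand binding in the NMR fast-exchange regime shifts each amide resonance
continuously from its free position toward its bound position; the observed
combined shift is the bound fraction times the maximal shift.  This module
assembles per-residue titration trajectories from HSQC peak lists, maps
binding residues from the CSP profile, and estimates the dissociation
constant Kd by least-squares under the single-site isotherm with ligand
depletion (protein and ligand concentrations are comparable, so free ligand
is not total ligand).

Concentrations are in mM throughout; chemical shifts in ppm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "PeakList",
    "TitrationSeries",
    "CSPProfile",
    "BindingFit",
    "Trajectories",
    "combined_shift",
    "bound_fraction",
    "track_peaks",
    "csp_profile",
    "classify_binding_residues",
    "fit_kd",
    "read_peak_list",
    "load_titration_series",
]

#: nitrogen shifts are down-weighted by 1/25 in the combined-shift variance,
#: i.e. scaled by 1/5 in distance computations.
NITROGEN_SCALE = 5.0

KD_BOUNDS = (1e-4, 1e3)  # mM
KD_MULTISTART = (0.01, 0.1, 1.0, 10.0)  # mM


def combined_shift(delta_H, delta_N):
    """Combined amide chemical-shift change, sqrt((ΔδH² + ΔδN²/25)/2) in ppm.

    Symmetric in the sign of both inputs and homogeneous of degree 1.
    Accepts scalars or arrays.
    """
    delta_H = np.asarray(delta_H, dtype=float)
    delta_N = np.asarray(delta_N, dtype=float)
    out = np.sqrt((delta_H**2 + delta_N**2 / NITROGEN_SCALE**2) / 2.0)
    return float(out) if out.ndim == 0 else out


def bound_fraction(protein_total, ligand_total, kd, model: str = "quadratic"):
    """Fraction of protein bound at total concentrations P, L and constant Kd.

    The quadratic (ligand-depletion) form solves the single-site mass-balance
    exactly; written as 2L / (b + sqrt(b² − 4PL)) with b = P + L + Kd, which
    is algebraically identical to the usual (b − sqrt(...)) / 2P but stable
    as P → 0, where it reduces to the hyperbola L / (L + Kd).
    """
    P = np.asarray(protein_total, dtype=float)
    L = np.asarray(ligand_total, dtype=float)
    if model == "hyperbolic":
        out = L / (L + kd)
    elif model == "quadratic":
        b = P + L + kd
        disc = np.maximum(b**2 - 4.0 * P * L, 0.0)
        out = 2.0 * L / (b + np.sqrt(disc))
    else:
        raise ValueError(f"unknown model {model!r}")
    out = np.asarray(out, dtype=float)
    return float(out) if out.ndim == 0 else out


@dataclass
class PeakList:
    """Amide peak positions at one titration point.

    ``entries`` maps residue id -> (δH, δN) for assigned peaks;
    ``unassigned`` holds (δH, δN) pairs without residue ids (peak lists from
    later titration points are often unassigned because peaks move).
    """

    entries: dict
    ligand_total: float
    protein_total: float
    unassigned: list = field(default_factory=list)

    def __post_init__(self):
        if self.ligand_total < 0 or self.protein_total < 0:
            raise ValueError("concentrations must be nonnegative")
        normalized = {}
        for key, val in self.entries.items():
            rid = str(key)
            if rid in normalized:
                raise ValueError(f"duplicate residue id {rid!r} in peak list")
            normalized[rid] = val
        self.entries = normalized


@dataclass
class TitrationSeries:
    """Ordered peak lists across ligand concentrations at constant protein."""

    points: list
    protein_total: float

    def __post_init__(self):
        if not self.points:
            raise ValueError("empty titration series")
        ligs = [p.ligand_total for p in self.points]
        if ligs[0] != 0:
            raise ValueError("first titration point must be the ligand-free reference")
        if any(b <= a for a, b in zip(ligs, ligs[1:])):
            raise ValueError("ligand totals must be strictly increasing")
        for p in self.points:
            if not np.isclose(p.protein_total, self.protein_total):
                raise ValueError("protein concentration must be constant across points")

    @property
    def ligand_totals(self):
        return np.array([p.ligand_total for p in self.points])


@dataclass
class CSPProfile:
    """Per-residue combined shift at a chosen endpoint relative to reference."""

    values: dict  # residue -> Δδ (ppm)
    n_omitted: int = 0


@dataclass
class BindingFit:
    kd: float
    kd_se: float
    ddmax: dict  # residue -> fitted maximal combined shift (ppm)
    ddmax_se: dict
    rss: float
    converged: bool
    model: str = "quadratic"
    warnings: list = field(default_factory=list)

    def predict(self, residue, ligand_total, protein_total):
        fb = bound_fraction(protein_total, ligand_total, self.kd, self.model)
        return self.ddmax[residue] * fb


@dataclass
class Trajectories:
    """Per-residue shift trajectories across a titration.

    ``delta_H``/``delta_N`` are (n_residues, n_points) arrays of shift changes
    relative to the reference point; ``combined`` the combined shift.
    """

    residues: list
    ligand_totals: np.ndarray
    protein_total: float
    delta_H: np.ndarray
    delta_N: np.ndarray
    ambiguous: set = field(default_factory=set)

    @property
    def combined(self):
        return combined_shift(self.delta_H, self.delta_N)

    def as_dict(self):
        """residue -> (ligand totals, combined Δδ) for fitting."""
        comb = self.combined
        return {r: (self.ligand_totals, comb[i]) for i, r in enumerate(self.residues)}


def track_peaks(
    series: TitrationSeries,
    ambiguity_factor: float = 1.5,
    ambiguity_radius: float = 0.05,
) -> Trajectories:
    """Join peaks across titration points into per-residue trajectories.

    Assigned peaks join by residue id.  Points whose peaks carry no ids are
    matched to the previous point's positions by nearest neighbour in
    (δH, δN/5) space — the same weighting as the combined-shift formula —
    greedily by ascending distance, each peak used once.  A match whose peak
    lies within ``ambiguity_factor`` times the matched distance, or within
    the absolute ``ambiguity_radius`` (weighted ppm), of a second trajectory
    is flagged ambiguous rather than silently accepted; flagged residues are
    reported in ``Trajectories.ambiguous``.
    """
    ref = series.points[0]
    residues = sorted(ref.entries)
    n_res, n_pts = len(residues), len(series.points)
    dH = np.zeros((n_res, n_pts))
    dN = np.zeros((n_res, n_pts))
    ref_pos = {r: np.array(ref.entries[r], dtype=float) for r in residues}
    prev_pos = dict(ref_pos)
    ambiguous: set = set()

    for j, point in enumerate(series.points[1:], start=1):
        if point.entries:
            cur = {r: np.array(v, dtype=float) for r, v in point.entries.items()}
        else:
            cur = _match_unassigned(
                prev_pos, point.unassigned, ambiguity_factor, ambiguity_radius, ambiguous
            )
        for i, r in enumerate(residues):
            if r in cur:
                dH[i, j] = cur[r][0] - ref_pos[r][0]
                dN[i, j] = cur[r][1] - ref_pos[r][1]
                prev_pos[r] = cur[r]
            else:
                dH[i, j] = np.nan
                dN[i, j] = np.nan

    return Trajectories(
        residues=residues,
        ligand_totals=series.ligand_totals,
        protein_total=series.protein_total,
        delta_H=dH,
        delta_N=dN,
        ambiguous=ambiguous,
    )


def _match_unassigned(prev_pos, peaks, ambiguity_factor, ambiguity_radius, ambiguous):
    """Greedy nearest-neighbour assignment of unlabelled peaks to trajectories."""
    peaks = [np.array(p, dtype=float) for p in peaks]
    if not peaks:
        return {}
    res_ids = list(prev_pos)
    prev = np.array([prev_pos[r] for r in res_ids])  # (R, 2)
    pk = np.array(peaks)  # (K, 2)
    scale = np.array([1.0, 1.0 / NITROGEN_SCALE])
    dist = np.linalg.norm((prev[:, None, :] - pk[None, :, :]) * scale, axis=-1)
    pairs = sorted(
        ((dist[i, k], i, k) for i in range(len(res_ids)) for k in range(len(pk))),
        key=lambda t: t[0],
    )
    used_r, used_k, match = set(), set(), {}
    for d, i, k in pairs:
        if i in used_r or k in used_k:
            continue
        used_r.add(i)
        used_k.add(k)
        match[res_ids[i]] = pk[k]
        # a second trajectory nearly as close to this peak -> ambiguous
        others = [j for j in range(len(res_ids)) if j != i]
        if others:
            d_others = dist[others, k]
            if d_others.min() <= max(d * ambiguity_factor, ambiguity_radius):
                ambiguous.add(res_ids[i])
                ambiguous.add(res_ids[others[int(np.argmin(d_others))]])
    return match


def csp_profile(series: TitrationSeries, endpoint_index: int = -1) -> CSPProfile:
    """Per-residue combined shift between an endpoint and the reference point.

    Residues present at the reference but missing at the endpoint are omitted
    with a warning; the omission count is recorded on the profile.
    """
    ref = series.points[0]
    end = series.points[endpoint_index]
    values, omitted = {}, 0
    for r, (h0, n0) in ref.entries.items():
        if r not in end.entries:
            omitted += 1
            continue
        h1, n1 = end.entries[r]
        values[r] = combined_shift(h1 - h0, n1 - n0)
    if omitted:
        warnings.warn(f"{omitted} residue(s) missing at endpoint; omitted from profile")
    return CSPProfile(values=values, n_omitted=omitted)


def classify_binding_residues(
    profile: CSPProfile, rule: Callable[[np.ndarray], tuple] | None = None
) -> dict:
    """Flag residues with outstanding shifts as putative binding residues.

    Default rule: tier 1 = Δδ > mean + 1·SD of the profile, tier 2 = Δδ >
    mean + 2·SD (tier 2 ⊆ tier 1).  A custom ``rule`` maps the vector of
    shifts to (tier1_threshold, tier2_threshold).
    """
    if not profile.values:
        raise ValueError("empty CSP profile")
    vals = np.array(list(profile.values.values()))
    if np.allclose(vals, 0):
        return {"tier1": set(), "tier2": set()}
    if rule is None:
        t1, t2 = vals.mean() + vals.std(), vals.mean() + 2 * vals.std()
    else:
        t1, t2 = rule(vals)
    tier1 = {r for r, v in profile.values.items() if v > t1}
    tier2 = {r for r, v in profile.values.items() if v > t2}
    return {"tier1": tier1, "tier2": tier2}


def fit_kd(
    trajectories: Mapping,
    protein_total: float,
    shared_kd: bool = True,
    model: str = "quadratic",
) -> BindingFit:
    """Fit the single-site fast-exchange isotherm Δδ(L) = Δδmax·f_b(P, L, Kd).

    Parameters
    ----------
    trajectories
        residue -> (ligand totals in mM, combined Δδ in ppm).  Points with
        non-finite shifts are dropped per residue.
    protein_total
        total protein concentration P in mM.
    shared_kd
        fit one Kd across all residues with per-residue Δδmax (default);
        with False each residue is fitted independently and the
        inverse-variance-weighted mean Kd is reported.
    model
        "quadratic" (ligand depletion, default) or "hyperbolic".

    The optimiser is bounded nonlinear least squares with multi-start over a
    Kd grid spanning four decades, which makes the fit robust to the poor
    initial curvature typical of weak binders.
    """
    clean = {}
    for r, (L, dd) in trajectories.items():
        L = np.asarray(L, dtype=float)
        dd = np.asarray(dd, dtype=float)
        ok = np.isfinite(dd)
        L, dd = L[ok], dd[ok]
        if len(np.unique(L)) < 3:
            raise ValueError(f"residue {r}: need >= 3 titration points with distinct ligand totals")
        if np.allclose(dd, 0):
            raise ValueError(f"residue {r}: degenerate (all-zero) trajectory")
        clean[r] = (L, dd)
    if not clean:
        raise ValueError("no usable trajectories")

    if not shared_kd and len(clean) > 1:
        fits = [fit_kd({r: tr}, protein_total, shared_kd=True, model=model) for r, tr in clean.items()]
        w = np.array([1.0 / max(f.kd_se, 1e-12) ** 2 for f in fits])
        kd = float(np.sum(w * [f.kd for f in fits]) / w.sum())
        return BindingFit(
            kd=kd,
            kd_se=float(np.sqrt(1.0 / w.sum())),
            ddmax={r: f.ddmax[r] for r, f in zip(clean, fits)},
            ddmax_se={r: f.ddmax_se[r] for r, f in zip(clean, fits)},
            rss=float(sum(f.rss for f in fits)),
            converged=all(f.converged for f in fits),
            model=model,
            warnings=[w_ for f in fits for w_ in f.warnings],
        )

    residues = list(clean)
    n_res = len(residues)

    def residuals(theta):
        kd = theta[0]
        out = []
        for i, r in enumerate(residues):
            L, dd = clean[r]
            out.append(theta[1 + i] * bound_fraction(protein_total, L, kd, model) - dd)
        return np.concatenate(out)

    best = None
    for kd0 in KD_MULTISTART:
        x0 = [kd0] + [
            max(clean[r][1].max(), 1e-6)
            / max(bound_fraction(protein_total, clean[r][0].max(), kd0, model), 1e-6)
            for r in residues
        ]
        lo = [KD_BOUNDS[0]] + [0.0] * n_res
        hi = [KD_BOUNDS[1]] + [np.inf] * n_res
        x0 = np.clip(x0, lo, np.where(np.isinf(hi), np.asarray(x0, float), hi))
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None or not best.success:
        return BindingFit(
            kd=float("nan"), kd_se=float("nan"), ddmax={}, ddmax_se={},
            rss=float("nan"), converged=False, model=model,
            warnings=["optimizer failed to converge"],
        )

    rss = float(2 * best.cost)
    n_obs = sum(len(clean[r][0]) for r in residues)
    n_par = 1 + n_res
    dof = max(n_obs - n_par, 1)
    # covariance from the Jacobian at the optimum
    J = best.jac
    try:
        cov = np.linalg.inv(J.T @ J) * rss / dof
        ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        ses = np.full(n_par, np.nan)

    kd = float(best.x[0])
    fit_warnings = []
    max_sat = max(
        bound_fraction(protein_total, clean[r][0].max(), kd, model) for r in residues
    )
    if max_sat < 0.20:
        msg = "Kd poorly constrained: saturation < 20% at the highest ligand concentration"
        warnings.warn(msg)
        fit_warnings.append(msg)

    return BindingFit(
        kd=kd,
        kd_se=float(ses[0]),
        ddmax={r: float(best.x[1 + i]) for i, r in enumerate(residues)},
        ddmax_se={r: float(ses[1 + i]) for i, r in enumerate(residues)},
        rss=rss,
        converged=True,
        model=model,
        warnings=fit_warnings,
    )


# ---------------------------------------------------------------------------
# peak-list I/O: TSV with '#ligand_total_mM=' / '#protein_total_mM=' header
# ---------------------------------------------------------------------------

def read_peak_list(path) -> PeakList:
    """Read one peak list from TSV (columns residue, dH_ppm, dN_ppm).

    Header comment lines ``#ligand_total_mM=<x>`` and ``#protein_total_mM=<x>``
    carry the concentrations.
    """
    path = Path(path)
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = float(val)
    df = pd.read_csv(path, sep="\t", comment="#")
    entries = {
        str(row.residue): (float(row.dH_ppm), float(row.dN_ppm)) for row in df.itertuples()
    }
    return PeakList(
        entries=entries,
        ligand_total=meta["ligand_total_mM"],
        protein_total=meta["protein_total_mM"],
    )


def write_peak_list(peaklist: PeakList, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#ligand_total_mM={peaklist.ligand_total!r}\n")
        fh.write(f"#protein_total_mM={peaklist.protein_total!r}\n")
        fh.write("residue\tdH_ppm\tdN_ppm\n")
        for r, (h, n) in peaklist.entries.items():
            fh.write(f"{r}\t{h!r}\t{n!r}\n")


def load_titration_series(paths: Iterable) -> TitrationSeries:
    """Load a series from peak-list files, ordered by ligand concentration."""
    points = sorted((read_peak_list(p) for p in paths), key=lambda p: p.ligand_total)
    if not points:
        raise ValueError("no peak lists found")
    return TitrationSeries(points=points, protein_total=points[0].protein_total)
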