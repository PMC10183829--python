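"""Binding isotherms, NMR chemical-shift-perturbation analysis and
monoisotopic remnant-adduct masses.

The binding model is the exact 1:1 equilibrium with ligand depletion
(quadratic root), fitted to fluorescence-anisotropy titrations by bounded
nonlinear least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

# Standard monoisotopic residue (water-free) masses, Da.
MONOISOTOPIC_RESIDUE_MASS = {
    "G": 57.021464, "A": 71.037114, "S": 87.032028, "P": 97.052764,
    "V": 99.068414, "T": 101.047679, "C": 103.009185, "L": 113.084064,
    "I": 113.084064, "N": 114.042927, "D": 115.026943, "Q": 128.058578,
    "K": 128.094963, "E": 129.042593, "M": 131.040485, "H": 137.058912,
    "F": 147.068414, "R": 156.101111, "Y": 163.063329, "W": 186.079313,
}


def remnant_mass(peptide: str) -> float:
    """Monoisotopic mass added by an isopeptide-linked peptide remnant.

    The sum of water-free residue masses of the peptide, i.e. the mass a
    remnant such as VG or DRVG deposits on a modified lysine.
    """
    if not peptide:
        raise ValueError("peptide must be non-empty")
    total = 0.0
    for aa in peptide:
        try:
            total += MONOISOTOPIC_RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r}") from None
    return round(total, 6)


# ---------------------------------------------------------------------------
# 1:1 binding with ligand depletion

def fraction_bound(P: float, L: float, Kd: float) -> float:
    """Fraction of labeled species P bound at total ligand L (molar).

    fb = ((P+L+Kd) - sqrt((P+L+Kd)^2 - 4PL)) / (2P); the P -> 0 limit is
    L / (L + Kd).
    """
    if Kd <= 0:
        raise ValueError("Kd must be positive")
    if P < 0 or L < 0:
        raise ValueError("concentrations must be non-negative")
    if P == 0.0:
        return L / (L + Kd)
    s = P + L + Kd
    disc = max(s * s - 4.0 * P * L, 0.0)
    return (s - math.sqrt(disc)) / (2.0 * P)


@dataclass
class TitrationCurve:
    """An anisotropy titration at fixed labeled-species concentration."""

    concentrations: np.ndarray   # molar, strictly increasing
    responses: np.ndarray        # anisotropy
    labeled_concentration: float  # molar

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if c.shape != r.shape:
            raise ValueError("concentration and response lengths differ")
        if (c <= 0).any() or (np.diff(c) <= 0).any():
            raise ValueError("concentrations must be positive and increasing")
        self.concentrations, self.responses = c, r


@dataclass
class BindingFit:
    kd: float
    r_free: float
    r_bound: float
    rss: float
    converged: bool
    saturated: bool
    max_fraction_bound: float


def simulate_titration(Kd: float, r_free: float, r_bound: float, P: float,
                       concs: Sequence[float], noise_sd: float = 0.0,
                       seed: int = 0) -> TitrationCurve:
    """Model responses plus seeded Gaussian noise."""
    concs = np.asarray(concs, dtype=float)
    fb = np.array([fraction_bound(P, L, Kd) for L in concs])
    r = r_free + (r_bound - r_free) * fb
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, noise_sd, size=r.shape)
    return TitrationCurve(concentrations=concs, responses=r,
                          labeled_concentration=P)


def fit_kd(curve: TitrationCurve, saturation_threshold: float = 0.8) -> BindingFit:
    """Nonlinear least squares for (Kd, r_free, r_bound).

    Initialisation: r_free/r_bound from the response extremes, Kd from the
    concentration nearest the half-response; Kd is bounded positive. A flat
    curve returns a non-converged fit rather than raising. Fits where the
    model predicts < ``saturation_threshold`` fraction bound at the top
    concentration are flagged unsaturated.
    """
    c = curve.concentrations
    r = curve.responses
    P = curve.labeled_concentration
    if c.size < 5:
        raise ValueError("need at least 5 titration points")
    r_free0, r_bound0 = float(r[0]), float(r[-1])
    span = r_bound0 - r_free0
    if abs(span) < 1e-12:
        return BindingFit(kd=math.nan, r_free=r_free0, r_bound=r_bound0,
                          rss=0.0, converged=False, saturated=False,
                          max_fraction_bound=0.0)
    half = r_free0 + 0.5 * span
    kd0 = float(c[int(np.argmin(np.abs(r - half)))])

    def residuals(params: np.ndarray) -> np.ndarray:
        kd, rf, rb = params
        fb = np.array([fraction_bound(P, L, kd) for L in c])
        return rf + (rb - rf) * fb - r

    lo = [1e-12, -np.inf, -np.inf]
    hi = [np.inf, np.inf, np.inf]
    sol = least_squares(residuals, x0=[kd0, r_free0, r_bound0],
                        bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    kd, rf, rb = sol.x
    max_fb = fraction_bound(P, float(c[-1]), float(kd))
    return BindingFit(kd=float(kd), r_free=float(rf), r_bound=float(rb),
                      rss=float(2.0 * sol.cost), converged=bool(sol.success),
                      saturated=bool(max_fb >= saturation_threshold),
                      max_fraction_bound=float(max_fb))


# ---------------------------------------------------------------------------
# NMR chemical shift perturbation and intensities

@dataclass
class PeakList:
    """Backbone amide peaks: residue id -> (dH ppm, dN ppm, intensity)."""

    peaks: Dict[str, Tuple[float, float, float]]

    def __post_init__(self) -> None:
        for rid, (_, _, inten) in self.peaks.items():
            if inten < 0:
                raise ValueError(f"negative intensity for residue {rid!r}")

    def residues(self) -> set:
        return set(self.peaks)


def csp(free: PeakList, bound: PeakList, alpha: float = 0.2,
        ) -> Dict[str, float]:
    """Combined chemical shift perturbation per shared residue.

    CSP = sqrt(ddH^2 + (alpha * ddN)^2), with the conventional 15N scaling
    alpha = 0.2. Residues missing from either list are omitted (unassigned).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    shared = sorted(free.residues() & bound.residues())
    if not shared:
        raise ValueError("peak lists share no residues")
    out = {}
    for rid in shared:
        h0, n0, _ = free.peaks[rid]
        h1, n1, _ = bound.peaks[rid]
        out[rid] = math.sqrt((h1 - h0) ** 2 + (alpha * (n1 - n0)) ** 2)
    return out


CSP_CLASSES = ("slight", "intermediate", "strong")


def classify_csp(csp_map: Mapping[str, float],
                 thresholds: Tuple[float, float]) -> Dict[str, str]:
    """Three-way classification by the printed open-interval thresholds.

    slight: CSP <= t1; intermediate: t1 < CSP <= t2; strong: CSP > t2.
    Boundary values go to the lower class.
    """
    t1, t2 = thresholds
    if not 0 < t1 < t2:
        raise ValueError("need 0 < t1 < t2")
    out = {}
    for rid, value in csp_map.items():
        if value <= t1:
            out[rid] = "slight"
        elif value <= t2:
            out[rid] = "intermediate"
        else:
            out[rid] = "strong"
    return out


def intensity_ratio(bound: PeakList, free: PeakList,
                    cap: Optional[float] = None) -> Dict[str, float]:
    """Per-residue bound/free intensity ratios, optionally capped.

    Residues with zero free intensity map to NaN (flagged-missing).
    """
    shared = sorted(free.residues() & bound.residues())
    if not shared:
        raise ValueError("peak lists share no residues")
    out = {}
    for rid in shared:
        i_free = free.peaks[rid][2]
        i_bound = bound.peaks[rid][2]
        if i_free == 0:
            out[rid] = math.nan
            continue
        ratio = i_bound / i_free
        if cap is not None:
            ratio = min(ratio, cap)
        out[rid] = ratio
    return out
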