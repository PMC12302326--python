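"""Quantitative evaluation of enzyme variants.

Covers the measurement chain for interfacial depolymerase screening:
amine-labelling calibration, background correction, specific activities
(μmol 6-AHA-equivalents h⁻¹ mg_enzyme⁻¹), fold-changes with error
propagation, conventional and inverse Michaelis-Menten fits, degree of
depolymerization, melting-temperature extraction from melt curves, and
epistasis classification of recombined substitutions.

Conventions: the multiplicative null for epistasis (fold-changes are ratios,
so additivity of improvements is additivity in log space); 6-AHA molar mass
131.17 g mol⁻¹; polyamide repeat-unit mass 113.16 g mol⁻¹ (condensation
subtracts one water), so 100% degree of depolymerization corresponds to the
full solid mass released as repeat units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

MOLAR_MASS_6AHA = 131.17        # g/mol, free monomer
MOLAR_MASS_REPEAT = 113.16      # g/mol, in-chain repeat unit

#: repeat units per product species of PA 6 hydrolysis
PRODUCT_UNITS = {"6-AHA": 1, "dimer": 2, "PA66-monomer": 2}


class KineticsError(ValueError):
    """Raised for invalid kinetics inputs or failed fits."""


# ---------------------------------------------------------------------------
# quantification chain
# ---------------------------------------------------------------------------

def calibrate_and_quantify(absorbances, standards, min_r2: float = 0.98):
    """Map absorbances to released-amine concentrations via a linear standard.

    ``standards`` is a sequence of (concentration μM, absorbance) pairs; the
    fit keeps a free intercept.  Returns (concentrations μM, flags) where a
    flag marks samples outside the calibrated range (floored at 0 when below
    the blank).
    """
    standards = np.asarray(standards, dtype=float)
    if standards.shape[0] < 3:
        raise KineticsError("need at least 3 calibration standards")
    conc, absb = standards[:, 0], standards[:, 1]
    res = stats.linregress(conc, absb)
    if res.rvalue**2 < min_r2:
        raise KineticsError(
            f"calibration R²={res.rvalue ** 2:.4f} below {min_r2}"
        )
    absorbances = np.asarray(absorbances, dtype=float)
    out = (absorbances - res.intercept) / res.slope
    lo, hi = conc.min(), conc.max()
    flags = (out < lo) | (out > hi)
    out = np.where(out < 0, 0.0, out)
    return out, flags


def background_correct(sample_series, blank_series):
    """Pointwise blank subtraction on matched time grids.

    Series are (time, value) arrays; negatives are floored at 0 and counted.
    Returns (corrected series, n_floored).
    """
    sample = np.asarray(sample_series, dtype=float)
    blank = np.asarray(blank_series, dtype=float)
    if sample.shape != blank.shape or not np.allclose(sample[:, 0], blank[:, 0]):
        raise KineticsError("sample and blank time grids differ")
    corrected = sample[:, 1] - blank[:, 1]
    n_floored = int(np.sum(corrected < 0))
    corrected = np.maximum(corrected, 0.0)
    return np.column_stack([sample[:, 0], corrected]), n_floored


def specific_activity(records) -> tuple[float, float | None]:
    """Specific activity in μmol h⁻¹ mg_enzyme⁻¹, replicate mean ± SEM.

    ``records`` is a DataFrame (or list of dicts) with columns ``amine_uM``,
    ``enzyme_mg_per_L``, ``time_h`` and optionally ``replicate``.  Since
    released amine (μmol L⁻¹) and enzyme load (mg L⁻¹) share the reaction
    volume, the volume cancels.
    """
    df = pd.DataFrame(records)
    if (df["time_h"] <= 0).any() or (df["enzyme_mg_per_L"] <= 0).any():
        raise KineticsError("time and enzyme concentration must be positive")
    per_rep = df["amine_uM"] / (df["enzyme_mg_per_L"] * df["time_h"])
    vals = per_rep.to_numpy(dtype=float)
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else None
    return mean, sem


def enzyme_mass_concentration(conc_nM: float, mw_kda: float) -> float:
    """Convert a molar enzyme concentration (nM) to mg L⁻¹ given the MW."""
    # nM * kDa: 1e-9 mol/L * 1e3 g/mol = 1e-6 g/L = 1e-3 mg/L
    return conc_nM * mw_kda * 1e-3


def mass_to_molar_activity(activity_mg: float,
                           molar_mass: float = MOLAR_MASS_6AHA) -> float:
    """Convert mg h⁻¹ mg⁻¹ to μmol h⁻¹ mg⁻¹ for a product of given molar mass."""
    return activity_mg * 1e3 / molar_mass


def fold_change(variant: tuple, parent: tuple) -> tuple[float, float]:
    """Ratio of variant to parent activity with first-order SEM propagation."""
    v, sv = variant
    p, sp = parent
    if p <= 0:
        raise KineticsError("parent activity must be positive")
    ratio = v / p
    sv = 0.0 if sv is None else sv
    sp = 0.0 if sp is None else sp
    sem = ratio * np.sqrt((sv / v) ** 2 + (sp / p) ** 2) if v > 0 else 0.0
    return float(ratio), float(sem)


# ---------------------------------------------------------------------------
# Michaelis-Menten (conventional and inverse)
# ---------------------------------------------------------------------------

@dataclass
class KineticsFit:
    """Michaelis-Menten fit result.

    For the conventional form x is substrate loading (g L⁻¹) at fixed enzyme;
    for the inverse form x is enzyme concentration at fixed excess solid
    substrate, and Vmax reflects the density of attackable sites.
    """

    model: str
    vmax: float
    km: float
    vmax_se: float
    km_se: float
    r_squared: float


def fit_mm(points, model: str = "convMM") -> KineticsFit:
    """Nonlinear least-squares fit of v = Vmax·x/(Km+x)."""
    if model not in ("convMM", "invMM"):
        raise KineticsError(f"unknown model '{model}'")
    pts = np.asarray(points, dtype=float)
    x, v = pts[:, 0], pts[:, 1]
    if len(np.unique(x)) < 4:
        raise KineticsError("need at least 4 distinct x values")

    def mm(x, vmax, km):
        return vmax * x / (km + x)

    p0 = (float(v.max()), float(np.median(x)))
    last_exc = None
    for scale in (1.0, 0.3, 3.0):
        try:
            popt, pcov = optimize.curve_fit(
                mm, x, v, p0=(p0[0], p0[1] * scale),
                bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=20000,
            )
            break
        except RuntimeError as exc:  # pragma: no cover - rare non-convergence
            last_exc = exc
    else:  # pragma: no cover
        raise KineticsError(f"Michaelis-Menten fit did not converge: {last_exc}")
    resid = v - mm(x, *popt)
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    se = np.sqrt(np.diag(pcov))
    return KineticsFit(model=model, vmax=float(popt[0]), km=float(popt[1]),
                       vmax_se=float(se[0]), km_se=float(se[1]), r_squared=r2)


# ---------------------------------------------------------------------------
# degree of depolymerization
# ---------------------------------------------------------------------------

@dataclass
class DepolymerizationState:
    time_h: float
    degree_of_depolymerization: float  # % w/w
    monomer_fraction: float            # % of released repeat mass that is 6-AHA
    released_mass_g_per_L: float


def degree_of_depolymerization(products: dict, substrate_loading: float,
                               time_h: float = 0.0,
                               basis: str = "repeat") -> DepolymerizationState:
    """Convert a product composition into a degree of depolymerization.

    ``products`` maps species (``"6-AHA"``, ``"dimer"``, ``"PA66-monomer"``)
    to released amounts in μmol per litre of reaction; ``substrate_loading``
    is in g L⁻¹.  With the default repeat-unit basis, released mass is
    counted as in-chain repeat units (113.16 g mol⁻¹ each) so that complete
    depolymerization gives 100%; the free-monomer basis uses 131.17 g mol⁻¹.
    """
    if substrate_loading <= 0:
        raise KineticsError("substrate loading must be positive")
    unit_mass = MOLAR_MASS_REPEAT if basis == "repeat" else MOLAR_MASS_6AHA
    total_units = 0.0
    monomer_units = 0.0
    for species, umol in products.items():
        if umol < 0:
            raise KineticsError(f"negative product amount for {species}")
        units = PRODUCT_UNITS.get(species)
        if units is None:
            raise KineticsError(f"unknown product species '{species}'")
        total_units += umol * units
        if species == "6-AHA":
            monomer_units += umol * units
    released_g = total_units * 1e-6 * unit_mass  # μmol/L -> mol/L -> g/L
    dod = 100.0 * released_g / substrate_loading
    mono_frac = 100.0 * monomer_units / total_units if total_units > 0 else 0.0
    return DepolymerizationState(
        time_h=time_h, degree_of_depolymerization=float(dod),
        monomer_fraction=float(mono_frac), released_mass_g_per_L=float(released_g),
    )


# ---------------------------------------------------------------------------
# melting temperature
# ---------------------------------------------------------------------------

def _boltzmann(t, tm, slope, low, high):
    return low + (high - low) / (1.0 + np.exp((tm - t) / slope))


def extract_tm(curve, refine: bool = True, smooth_window: int = 7):
    """Melting temperature from a melt curve (temperature °C, signal).

    The primary estimate is the argmax of the smoothed first derivative;
    a two-state Boltzmann fit refines it and provides a standard error.
    Raises when the transition is not inside the scanned range.
    """
    pts = np.asarray(curve, dtype=float)
    t, y = pts[:, 0], pts[:, 1]
    if len(t) < 5 or np.any(np.diff(t) <= 0):
        raise KineticsError("need a monotone temperature grid with ≥ 5 points")
    win = min(smooth_window, len(y) - (1 - len(y) % 2))
    if win >= 5:
        ys = signal.savgol_filter(y, win, polyorder=3)
    else:
        ys = y
    dy = np.gradient(ys, t)
    k = int(np.argmax(np.abs(dy)))
    if k == 0 or k == len(t) - 1:
        raise KineticsError("no transition inside the scanned temperature range")
    tm0 = float(t[k])
    se = float(t[1] - t[0])
    if refine:
        span = y.max() - y.min()
        p0 = (tm0, max((t[-1] - t[0]) / 20.0, 0.5), float(y[0]), float(y[-1]))
        try:
            popt, pcov = optimize.curve_fit(_boltzmann, t, y, p0=p0, maxfev=20000)
            if t[0] < popt[0] < t[-1]:
                tm0 = float(popt[0])
                se = float(np.sqrt(pcov[0, 0])) if span > 0 else 0.0
        except RuntimeError:
            pass  # fall back to the derivative estimate
    return tm0, se


# ---------------------------------------------------------------------------
# epistasis
# ---------------------------------------------------------------------------

def classify_epistasis(singles, combo, k_sigma: float = 2.0):
    """Classify a combined variant against the multiplicative null.

    ``singles`` is a list of (fold, SEM) for the constituent single
    substitutions, ``combo`` the (fold, SEM) of the combined variant.  The
    expected fold is the product of the single folds; the combination is
    negative/positive when the combined fold falls below/above the expectation
    by more than ``k_sigma`` propagated standard errors, else additive.
    Returns (class, expected fold, expected SEM).
    """
    if len(singles) < 2:
        raise KineticsError("need at least 2 single-substitution folds")
    folds = np.array([f for f, _ in singles], dtype=float)
    sems = np.array([0.0 if s is None else s for _, s in singles], dtype=float)
    cf, _ = combo
    if np.any(folds <= 0) or cf <= 0:
        raise KineticsError("fold-changes must be positive")
    expected = float(np.prod(folds))
    sigma = expected * float(np.sqrt(np.sum((sems / folds) ** 2)))
    if cf < expected - k_sigma * sigma:
        cls = "negative"
    elif cf > expected + k_sigma * sigma:
        cls = "positive"
    else:
        cls = "additive"
    return cls, expected, sigma


def round_fold(x: float) -> float:
    """One-decimal half-up rounding used for reported fold-changes."""
    return float(np.floor(x * 10 + 0.5) / 10)
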