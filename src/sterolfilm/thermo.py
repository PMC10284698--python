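"""Adsorption thermodynamics and the entropic repulsion barrier.

The chain implemented here turns temperature-resolved QCM adsorption data
into an estimate of the repulsive entropy barrier that an orientationally
fluctuating sterol multilayer opposes to protein adsorption:

1. Sauerbrey conversion of frequency shifts to areal mass.
2. Langmuir inversion of coverage to the Gibbs free energy of adsorption,
   theta/(1-theta) = K x, dG = -R T ln K, with a mole-fraction standard
   state (x = c / 55.5 M) so K is dimensionless.
3. Linear fit dG(T) = dH - T dS per surface; dS is minus the slope.
4. Barrier = dS(mobile multilayer) - mean dS(orientationally fixed
   monolayer controls), errors propagated in quadrature.

Only the slopes of dG(T) enter the barrier, so the result is invariant to
the (convention-dependent) additive constant in dG.

A geometric counterpart estimates the same entropy loss from the ratio of
the constrained to the freely fluctuating interfacial area per molecule,
dS = R ln(A_constr/A_fluct), scaled by the number of molecules immobilized
under one adsorbed protein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import (R_GAS, QUARTZ_DENSITY, QUARTZ_SHEAR_MODULUS,
                        STEROL_CROSS_SECTION_NM2, STEROL_LENGTH_NM,
                        STEROL_WIDTH_NM)

#: Default areas (nm^2) for the geometric entropy estimate: an upright
#: sterol presents its ring cross-section to a bound protein, while a
#: cooperatively fluctuating one sweeps roughly its side-on molecular
#: dimension.
DEFAULT_AREA_CONSTRAINED = STEROL_CROSS_SECTION_NM2
DEFAULT_AREA_FLUCTUATING = STEROL_LENGTH_NM * STEROL_WIDTH_NM
#: Interfacial molecules immobilized per adsorbed lysozyme (six cooperative
#: trios under a ~7 nm^2 footprint).
DEFAULT_FOOTPRINT_UNITS = 18
DEFAULT_COOPERATIVITY = 3


def sauerbrey_mass(frequency_shift: float, overtone: int,
                   fundamental_mhz: float = 5.0) -> float:
    """Areal mass (ng cm^-2) from a QCM frequency shift via Sauerbrey.

    delta_m = -C * delta_f / n with C = sqrt(rho_q mu_q) / (2 f0^2); for a
    5 MHz AT-cut crystal C is about 17.7 ng cm^-2 Hz^-1. Valid for rigid,
    thin films only.
    """
    overtone = int(overtone)
    if overtone < 1 or overtone % 2 == 0:
        raise ValueError("overtone must be an odd integer >= 1")
    f0 = fundamental_mhz * 1e6
    c_kg_m2 = math.sqrt(QUARTZ_DENSITY * QUARTZ_SHEAR_MODULUS) / (2.0 * f0**2)
    c_ng_cm2 = c_kg_m2 * 1e8  # kg m^-2 -> ng cm^-2
    return -c_ng_cm2 * frequency_shift / overtone


def coverage_to_dG(areal_mass, gamma_max: float, bulk_mole_fraction: float,
                   temperature) -> float | np.ndarray:
    """Gibbs free energy of adsorption (J mol^-1) from fractional coverage.

    theta = mass/gamma_max; K = theta/((1-theta) x); dG = -R T ln K.
    Rejects saturated (mass >= gamma_max) or nonpositive masses, where the
    Langmuir inversion has no solution.
    """
    mass = np.asarray(areal_mass, dtype=float)
    T = np.asarray(temperature, dtype=float)
    if gamma_max <= 0:
        raise ValueError("gamma_max must be positive")
    if not (0.0 < bulk_mole_fraction < 1.0):
        raise ValueError("bulk_mole_fraction must be in (0, 1)")
    if np.any(mass <= 0) or np.any(mass >= gamma_max):
        raise ValueError("areal mass must lie strictly between 0 and gamma_max")
    theta = mass / gamma_max
    K = theta / ((1.0 - theta) * bulk_mole_fraction)
    out = -R_GAS * T * np.log(K)
    return out if out.ndim else float(out)


def langmuir_coverage(dG, bulk_mole_fraction: float, temperature):
    """Forward Langmuir isotherm: theta = Kx/(1+Kx), K = exp(-dG/RT)."""
    dG = np.asarray(dG, dtype=float)
    T = np.asarray(temperature, dtype=float)
    Kx = np.exp(-dG / (R_GAS * T)) * bulk_mole_fraction
    out = Kx / (1.0 + Kx)
    return out if out.ndim else float(out)


@dataclass
class SlopeFit:
    """dG(T) = dH - T dS regression result (J mol^-1, J mol^-1 K^-1)."""

    dH: float
    dH_se: float
    dS: float
    dS_se: float
    n: int


def fit_dG_slope(temperature, dG, dG_se=None) -> SlopeFit:
    """Linear regression of dG on T; dS = -slope, dH = intercept.

    Inverse-variance weighted when per-point errors are given. Requires at
    least 3 distinct temperatures.
    """
    T = np.asarray(temperature, dtype=float)
    y = np.asarray(dG, dtype=float)
    if np.unique(T).size < 3:
        raise ValueError("need >= 3 distinct temperatures for the slope fit")
    w = None
    if dG_se is not None:
        se = np.asarray(dG_se, dtype=float)
        if np.any(se <= 0):
            raise ValueError("dG_se must be positive")
        w = 1.0 / se**2
    X = np.column_stack([np.ones_like(T), T])
    if w is None:
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = max(len(y) - 2, 1)
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(X.T @ X)
    else:
        W = np.diag(w)
        xtwx_inv = np.linalg.inv(X.T @ W @ X)
        beta = xtwx_inv @ X.T @ W @ y
        resid = y - X @ beta
        dof = max(len(y) - 2, 1)
        s2 = float(resid @ (w * resid)) / dof
        cov = xtwx_inv * s2
    dH, slope = beta
    dH_se, slope_se = np.sqrt(np.diag(cov))
    return SlopeFit(dH=float(dH), dH_se=float(dH_se),
                    dS=float(-slope), dS_se=float(slope_se), n=len(y))


def entropic_barrier(dS_scl: float, dS_scl_se: float,
                     dS_controls, dS_controls_se) -> tuple[float, float]:
    """Repulsive entropy barrier: dS(multilayer) - mean dS(controls).

    Errors propagate in quadrature; the control mean averages the
    orientationally fixed monolayer references.
    """
    controls = np.atleast_1d(np.asarray(dS_controls, dtype=float))
    controls_se = np.atleast_1d(np.asarray(dS_controls_se, dtype=float))
    if controls.size == 0:
        raise ValueError("at least one control surface is required")
    barrier = float(dS_scl - controls.mean())
    se = math.sqrt(dS_scl_se**2 + float(np.sum(controls_se**2)) / controls.size**2)
    return barrier, se


@dataclass
class GeometricEntropyInput:
    """Areas (nm^2) and counts for the configurational entropy estimate."""

    area_constrained: float = DEFAULT_AREA_CONSTRAINED
    area_fluctuating: float = DEFAULT_AREA_FLUCTUATING
    cooperativity: int = DEFAULT_COOPERATIVITY
    footprint_units: int = DEFAULT_FOOTPRINT_UNITS

    def __post_init__(self) -> None:
        if self.area_constrained <= 0 or self.area_fluctuating <= 0:
            raise ValueError("areas must be positive")
        if self.cooperativity < 1 or self.footprint_units < 1:
            raise ValueError("counts must be >= 1")


def geometric_entropy(inp: GeometricEntropyInput | None = None) -> tuple[float, float]:
    """(per-unit, per-protein) entropy change, J mol^-1 K^-1.

    per-unit dS = R ln(A_constr/A_fluct); per-protein multiplies by the
    number of interfacial molecules constrained under one adsorbed protein.
    Antisymmetric under swapping the two areas.
    """
    inp = inp or GeometricEntropyInput()
    # difference of logs keeps the swap antisymmetry bit-exact
    per_unit = R_GAS * (math.log(inp.area_constrained)
                        - math.log(inp.area_fluctuating))
    return per_unit, inp.footprint_units * per_unit


def hydrogen_bond_equivalent(dS: float, temperature: float,
                             e_hb_kj: float = 20.0) -> float:
    """Number of hydrogen bonds with energy comparable to T|dS|.

    e_hb_kj is the energy per bond in kJ mol^-1 (default 20).
    """
    if e_hb_kj <= 0:
        raise ValueError("e_hb must be positive")
    return temperature * abs(dS) / (e_hb_kj * 1e3)


def estimate_gamma_max(masses) -> float:
    """Plateau-based monolayer capacity estimate: 5% above the observed max.

    A pragmatic fallback when no capacity is supplied; biased when the data
    never approach saturation.
    """
    m = np.asarray(masses, dtype=float)
    if m.size == 0 or np.any(m <= 0):
        raise ValueError("masses must be positive")
    return 1.05 * float(m.max())


def dG_from_replicates(masses, gamma_max: float, bulk_mole_fraction: float,
                       temperature: float) -> tuple[float, float]:
    """(dG, se) at one temperature from replicate masses, bias corrected.

    The log transform of a noisy coverage is biased upward near
    saturation; the second-order delta-method term
    0.5 g''(m_bar) Var(m_bar) removes the O(sigma^2) bias, with g the
    mass -> dG map and Var(m_bar) = s^2/k from the replicate spread. The
    returned s.e. is |g'(m_bar)| s/sqrt(k) (zero for a single replicate).
    """
    m = np.asarray(masses, dtype=float)
    k = m.size
    m_bar = float(m.mean())
    dG = coverage_to_dG(m_bar, gamma_max, bulk_mole_fraction, temperature)
    if k < 2:
        return float(dG), 0.0
    var_mean = float(m.var(ddof=1)) / k
    RT = R_GAS * temperature
    g1 = -RT * (1.0 / m_bar + 1.0 / (gamma_max - m_bar))
    g2 = -RT * (-1.0 / m_bar**2 + 1.0 / (gamma_max - m_bar) ** 2)
    return float(dG - 0.5 * g2 * var_mean), abs(g1) * math.sqrt(var_mean)


def adsorption_thermo(table: pd.DataFrame, scl_surface: str, control_surfaces,
                      bulk_mole_fraction: float,
                      gamma_max: float | str = "auto") -> dict:
    """Full barrier chain on a temperature-adsorption table.

    ``table`` needs columns temperature_K, mass_ng_cm2, surface. gamma_max
    may be a number (shared capacity) or "auto" for the plateau estimate.
    Replicates at one temperature are pooled through
    :func:`dG_from_replicates` (bias-corrected mean, propagated s.e.) and
    the dG(T) fit is inverse-variance weighted when every temperature has
    replicates. Returns a report dict with per-surface dH/dS and the
    barrier.
    """
    controls = list(control_surfaces)
    if not controls:
        raise ValueError("at least one control surface is required")
    surfaces = [scl_surface] + controls
    missing = set(surfaces) - set(table["surface"])
    if missing:
        raise ValueError(f"surfaces absent from table: {sorted(missing)}")
    if gamma_max == "auto":
        gamma = estimate_gamma_max(table["mass_ng_cm2"])
    else:
        gamma = float(gamma_max)
    per_surface = {}
    for surf in surfaces:
        sub = table[table["surface"] == surf]
        temps, dGs, ses = [], [], []
        for T, grp in sub.groupby("temperature_K"):
            dG, se = dG_from_replicates(grp["mass_ng_cm2"].to_numpy(), gamma,
                                        bulk_mole_fraction, float(T))
            temps.append(float(T))
            dGs.append(dG)
            ses.append(se)
        se_arr = np.asarray(ses)
        fit = fit_dG_slope(np.asarray(temps), np.asarray(dGs),
                           se_arr if np.all(se_arr > 0) else None)
        per_surface[surf] = fit
    barrier, barrier_se = entropic_barrier(
        per_surface[scl_surface].dS, per_surface[scl_surface].dS_se,
        [per_surface[c].dS for c in controls],
        [per_surface[c].dS_se for c in controls])
    return {
        "gamma_max_ng_cm2": gamma,
        "bulk_mole_fraction": bulk_mole_fraction,
        "per_surface": {s: vars(f) for s, f in per_surface.items()},
        "scl_surface": scl_surface,
        "control_surfaces": controls,
        "barrier_J_mol_K": barrier,
        "barrier_se_J_mol_K": barrier_se,
    }
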