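"""Synthetic-data generators for every pipeline input class.

Each generator emulates the statistical structure its analysis stage
assumes, with defaults matching the study conditions of the system being
modelled: third-order bond-formation force curves over a 0-60 s contact
window, Langmuir-type temperature-dependent lysozyme adsorption (288-313 K)
with an additive entropic barrier of -200 J mol^-1 K^-1 on the mobile
multilayer class, circular-spot FRAP recovery from explicit 2D Brownian
particles (10 um spot, 1 s frames, 300 s), and replicate-level multi-assay
adhesion tables. All generators are deterministic given their seed; every
tabular output records generator name, seed and parameters in its header.

The rotor multilayer generator lives in :mod:`sterolfilm.rotor`.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .constants import WATER_MOLARITY
from .kinetics import ForceTimeSeries, force_model
from .mobility import FrapCurve
from .thermo import langmuir_coverage

#: 100 ug/ml lysozyme (14.3 kDa) as a mole fraction: 7.0e-6 M / 55.5 M.
DEFAULT_LYSOZYME_MOLE_FRACTION = (0.1 / 14300.0) / WATER_MOLARITY


class KineticsParams(BaseModel):
    """Force-curve generator parameters (order-n adaptation kinetics)."""

    order: int = Field(default=3, ge=1)
    rate: float = Field(default=0.3, ge=0.0)    # k, (density)^(1-n) s^-1
    sigma0: float = Field(default=1.0, gt=0.0)
    force_scale: float = Field(default=1.5, gt=0.0)  # F_inf, nN
    noise_cv: float = Field(default=0.05, ge=0.0)
    seed: int = 0


#: Default contact-time grid (s): 12 points spanning 0-60 s, geometrically
#: spaced so the early-time curvature — where adjacent reaction orders
#: actually differ — is well sampled.
DEFAULT_CONTACT_TIMES = (0.0, 0.5, 1.0, 2.0, 4.0, 7.0, 12.0, 20.0, 30.0,
                         40.0, 50.0, 60.0)


def default_contact_times() -> np.ndarray:
    """Contact-time grid spanning the 0-60 s assay window."""
    return np.asarray(DEFAULT_CONTACT_TIMES)


def gen_adhesion_force_curves(params: KineticsParams, times=None,
                              n_curves: int = 1) -> list[ForceTimeSeries]:
    """Noisy order-n force-time curves F(t) = F_inf (1 - sigma(t)/sigma0).

    Multiplicative lognormal noise with the stated coefficient of
    variation (unit mean); F(0) = 0 exactly in every realization.
    """
    t = default_contact_times() if times is None else np.asarray(times, dtype=float)
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("times must be nonnegative and strictly increasing")
    rng = np.random.default_rng(params.seed)
    kappa = params.rate * params.sigma0 ** (params.order - 1)
    clean = force_model(t, params.force_scale, kappa, params.order)
    if params.noise_cv > 0:
        s = np.sqrt(np.log1p(params.noise_cv**2))
        mu = -0.5 * s**2
    curves = []
    for i in range(n_curves):
        f = clean.copy()
        if params.noise_cv > 0:
            f = f * rng.lognormal(mean=mu, sigma=s, size=t.size)
        curves.append(ForceTimeSeries(t, f, condition="synthetic",
                                      replicate_id=f"rep{i:03d}"))
    return curves


class SurfaceSpec(BaseModel):
    name: str
    klass: str  # "scl" (mobile multilayer) or "control" (fixed monolayer)

    @model_validator(mode="after")
    def _check(self):
        if self.klass not in ("scl", "control"):
            raise ValueError("surface class must be 'scl' or 'control'")
        return self


DEFAULT_SURFACES = (SurfaceSpec(name="cholesterol_scl", klass="scl"),
                    SurfaceSpec(name="thiocholesterol_sam", klass="control"),
                    SurfaceSpec(name="thiocholenic_sam", klass="control"))


class ThermoGenParams(BaseModel):
    """Temperature-series adsorption generator parameters.

    dG(T) = dH - T (dS_intrinsic + dS_barrier*[scl]); the scl class also
    receives the compensating enthalpy T_comp*dS_barrier so that both
    surface classes sit at measurable Langmuir coverage — without it a
    -200 J mol^-1 K^-1 barrier puts the classes ~60 kJ mol^-1 apart and
    one of them always saturates or vanishes. Slopes, the only quantity
    the barrier chain consumes, are unaffected.
    """

    dH: float = -55_000.0             # J mol^-1
    dS_intrinsic: float = -50.0       # J mol^-1 K^-1
    dS_barrier: float = -200.0        # J mol^-1 K^-1, scl class only
    compensation_T: float = 300.5     # K
    temps: tuple[float, ...] = (288.15, 293.15, 298.15, 303.15, 308.15, 313.15)
    bulk_mole_fraction: float = Field(default=DEFAULT_LYSOZYME_MOLE_FRACTION, gt=0.0)
    gamma_max: float = Field(default=250.0, gt=0.0)  # ng cm^-2
    noise_sd: float = Field(default=0.02, ge=0.0)    # fraction of gamma_max
    replicates: int = Field(default=3, ge=1)
    protein: str = "lysozyme"
    seed: int = 42

    @model_validator(mode="after")
    def _check_temps(self):
        t = np.asarray(self.temps)
        if np.any(np.diff(t) <= 0):
            raise ValueError("temps must be strictly increasing")
        if t.min() < 270.0 or t.max() > 330.0:
            raise ValueError("temps must lie within 270-330 K")
        return self


def thermo_dG(params: ThermoGenParams, temperature, klass: str):
    """Ground-truth dG(T) (J mol^-1) for a surface class."""
    T = np.asarray(temperature, dtype=float)
    dH = params.dH
    dS = params.dS_intrinsic
    if klass == "scl":
        dH = dH + params.compensation_T * params.dS_barrier
        dS = dS + params.dS_barrier
    out = dH - T * dS
    return out if out.ndim else float(out)


def gen_temperature_adsorption(params: ThermoGenParams,
                               surfaces=None) -> pd.DataFrame:
    """Replicate-level areal adsorbed mass per temperature and surface.

    Gamma(T) = gamma_max * Kx/(1+Kx) + Gaussian noise (sd = noise_sd *
    gamma_max); values are kept strictly inside (0, gamma_max) so the
    Langmuir inversion stays defined.
    """
    surfaces = list(DEFAULT_SURFACES if surfaces is None else surfaces)
    if not any(s.klass == "scl" for s in surfaces):
        raise ValueError("need at least one scl-class surface")
    if not any(s.klass == "control" for s in surfaces):
        raise ValueError("need at least one control-class surface")
    rng = np.random.default_rng(params.seed)
    T = np.asarray(params.temps)
    rows = []
    for surf in surfaces:
        dG = thermo_dG(params, T, surf.klass)
        clean = params.gamma_max * langmuir_coverage(
            dG, params.bulk_mole_fraction, T)
        for rep in range(params.replicates):
            mass = clean + rng.normal(0.0, params.noise_sd * params.gamma_max,
                                      size=T.size) if params.noise_sd > 0 else clean.copy()
            mass = np.clip(mass, 1e-3 * params.gamma_max,
                           0.999 * params.gamma_max)
            for Ti, mi in zip(T, mass):
                rows.append(dict(temperature_K=Ti, mass_ng_cm2=mi,
                                 surface=surf.name, surface_class=surf.klass,
                                 protein=params.protein, replicate=f"rep{rep}"))
    return pd.DataFrame(rows)


class FrapGenParams(BaseModel):
    """Particle-level FRAP experiment generator parameters."""

    diffusion: float = Field(default=0.35, gt=0.0)       # um^2 s^-1
    mobile_fraction: float = Field(default=1.0, ge=0.0, le=1.0)
    spot_diameter: float = Field(default=10.0, gt=0.0)   # um
    frame_interval: float = Field(default=1.0, gt=0.0)   # s
    n_frames: int = Field(default=300, ge=10)
    n_particles: int = Field(default=200_000, ge=100)
    noise_sd: float = Field(default=0.002, ge=0.0)
    field_size: float = Field(default=80.0, gt=0.0)      # um, periodic square
    seed: int = 0

    @model_validator(mode="after")
    def _check_geometry(self):
        if self.spot_diameter >= self.field_size / 2:
            raise ValueError("bleach spot must fit well inside the field of view")
        return self


def gen_frap_experiment(params: FrapGenParams) -> FrapCurve:
    """Brownian-particle FRAP: bleach a disc, watch bright particles return.

    Particles are uniform in a periodic square field; all particles inside
    the disc at t = 0 are bleached dark. A ``mobile_fraction`` subset
    diffuses with per-frame Gaussian steps of variance 2 D dt per axis.
    Intensity per frame = bright count inside the disc / (total particle
    density * disc area), i.e. normalized to the pre-bleach level; Gaussian
    measurement noise added on top.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    expected_in_disc = p.n_particles * np.pi * (p.spot_diameter / 2) ** 2 / p.field_size**2
    if expected_in_disc < 200:
        warnings.warn("fewer than ~200 particles in the bleach spot; counting "
                      "noise will swamp the stated noise_sd", stacklevel=2)
    pos = rng.uniform(0.0, p.field_size, size=(p.n_particles, 2))
    center = p.field_size / 2.0
    r2 = (p.spot_diameter / 2.0) ** 2
    inside0 = ((pos[:, 0] - center) ** 2 + (pos[:, 1] - center) ** 2) < r2
    dark = inside0.copy()
    mobile = rng.random(p.n_particles) < p.mobile_fraction

    step_sd = np.sqrt(2.0 * p.diffusion * p.frame_interval)
    density = p.n_particles / p.field_size**2
    norm = density * np.pi * r2
    times = p.frame_interval * np.arange(1, p.n_frames + 1)
    intensity = np.empty(p.n_frames)
    m = int(mobile.sum())
    for f in range(p.n_frames):
        if m:
            pos[mobile] = (pos[mobile] + rng.normal(0.0, step_sd, size=(m, 2))) % p.field_size
        inside = ((pos[:, 0] - center) ** 2 + (pos[:, 1] - center) ** 2) < r2
        intensity[f] = np.count_nonzero(inside & ~dark) / norm
    if p.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, p.noise_sd, size=p.n_frames)
    return FrapCurve(times, intensity, spot_radius=p.spot_diameter / 2.0,
                     prebleach=1.0)


#: Default per-surface, per-assay mean effects (arbitrary units) for index
#: plumbing: a mobile cholesterol multilayer resists all five assays, the
#: analogue and reference surfaces do not. Invented fixture values.
DEFAULT_ASSAY_EFFECTS: dict[str, dict[str, float]] = {
    "cholesterol_scl": {"ecoli_adhesion": 1.0, "sepidermidis_adhesion": 1.0,
                        "bsa": 1.0, "lysozyme": 1.0, "fbs": 1.0},
    "dehydrocholesterol_scl": {"ecoli_adhesion": 1.6, "sepidermidis_adhesion": 1.4,
                               "bsa": 1.5, "lysozyme": 1.7, "fbs": 1.3},
    "stigmasterol_scl": {"ecoli_adhesion": 6.0, "sepidermidis_adhesion": 5.0,
                         "bsa": 4.0, "lysozyme": 5.5, "fbs": 4.5},
    "stearyl_palmitate_scl": {"ecoli_adhesion": 9.0, "sepidermidis_adhesion": 8.0,
                              "bsa": 7.0, "lysozyme": 8.5, "fbs": 7.5},
    "SiO2": {"ecoli_adhesion": 10.0, "sepidermidis_adhesion": 10.0,
             "bsa": 6.0, "lysozyme": 6.0, "fbs": 6.0},
    "gold": {"ecoli_adhesion": 8.0, "sepidermidis_adhesion": 9.0,
             "bsa": 10.0, "lysozyme": 10.0, "fbs": 10.0},
}


def gen_assay_table(effects: dict[str, dict[str, float]] | None = None,
                    noise_cv: float = 0.1, n_replicates: int = 6,
                    reference_surfaces=("SiO2", "gold"),
                    seed: int = 0) -> pd.DataFrame:
    """Replicate-level assay values drawn around surface x assay means."""
    effects = DEFAULT_ASSAY_EFFECTS if effects is None else effects
    if not effects:
        raise ValueError("need at least one surface")
    missing = [r for r in reference_surfaces if r not in effects]
    if missing:
        raise ValueError(f"reference surfaces missing from effects: {missing}")
    rng = np.random.default_rng(seed)
    rows = []
    for surface, per_assay in effects.items():
        if not per_assay:
            raise ValueError(f"surface {surface!r} has no assays")
        for assay, mean in per_assay.items():
            for rep in range(n_replicates):
                value = mean * (1.0 + noise_cv * rng.standard_normal()) \
                    if noise_cv > 0 else mean
                rows.append(dict(surface=surface, assay=assay,
                                 value=max(value, 0.0), replicate=rep,
                                 n=n_replicates))
    return pd.DataFrame(rows)
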