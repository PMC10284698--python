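"""FRAP recovery modelling: lateral diffusion coefficient and mobile fraction.

Recovery of a uniformly bleached circular spot by pure 2D diffusion follows
the Soumpasis closed form

    f(t) = exp(-2 tau_D / t) [ I0(2 tau_D / t) + I1(2 tau_D / t) ],

with tau_D = w^2 / (4 D) the characteristic diffusion time for spot radius
w. The measured normalized intensity is modelled as
mobile_fraction * plateau * f(t): immobile molecules bleached inside the
spot never recover. Fitting is nonlinear least squares in (tau_D,
mobile_fraction); D = w^2 / (4 tau_D).

Implementation note: exp(-x)(I0(x)+I1(x)) is evaluated with the
exponentially scaled Bessel functions i0e/i1e, which is stable for the
small t (large x) limit where the naive product overflows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Model
from scipy.special import i0e, i1e


@dataclass
class FrapCurve:
    """Normalized recovery curve; times in s (post-bleach), spot radius um."""

    times: np.ndarray
    intensity: np.ndarray
    spot_radius: float
    prebleach: float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.times.shape != self.intensity.shape:
            raise ValueError("times and intensity must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")
        if self.spot_radius <= 0:
            raise ValueError("spot_radius must be positive")


@dataclass
class FrapFit:
    diffusion: float          # um^2 s^-1; NaN when not estimable
    diffusion_se: float
    mobile_fraction: float
    mobile_fraction_se: float
    tau_d: float              # s
    r_squared: float
    flags: list[str] = field(default_factory=list)


def frap_recovery_model(t, tau_d: float, mobile_fraction: float = 1.0,
                        plateau: float = 1.0):
    """Soumpasis circular-spot recovery, scaled by mobile fraction.

    f(0) = 0, monotone nondecreasing, f(inf) = mobile_fraction * plateau.
    """
    if tau_d <= 0:
        raise ValueError("tau_d must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    out = np.zeros_like(t)
    pos = t > 0
    x = 2.0 * tau_d / t[pos]
    out[pos] = i0e(x) + i1e(x)
    out *= mobile_fraction * plateau
    return out if out.ndim else float(out)


def fit_frap(curve: FrapCurve, fit_plateau: bool = False) -> FrapFit:
    """Fit (tau_D, mobile fraction) to a recovery curve; D = w^2/(4 tau_D).

    A curve flat at the bleach level is reported as immobile
    (mobile_fraction ~ 0, D not estimable) with a flag rather than an
    error; non-convergence is likewise flagged.
    """
    if curve.times.size < 20:
        raise ValueError("need at least 20 post-bleach points")
    t = curve.times
    y = curve.intensity
    flags: list[str] = []

    recovery_range = float(y[-5:].mean() - y[:3].mean())
    if recovery_range < 0.02 * max(curve.prebleach, 1e-12):
        return FrapFit(float("nan"), float("nan"),
                       max(float(y[-5:].mean()), 0.0), float("nan"),
                       float("nan"), float("nan"), flags=["immobile"])

    # crude tau0: time to reach half the apparent plateau
    plateau_est = float(y[-5:].mean())
    half_idx = np.nonzero(y >= 0.5 * plateau_est)[0]
    tau0 = float(t[half_idx[0]]) if half_idx.size else float(t[t.size // 2])
    tau0 = max(tau0, float(t[0]))

    model = Model(lambda t, tau_d, mobile_fraction, plateau:
                  frap_recovery_model(t, tau_d, mobile_fraction, plateau),
                  independent_vars=["t"])
    params = model.make_params(tau_d=tau0, mobile_fraction=min(plateau_est, 1.0),
                               plateau=1.0)
    params["tau_d"].set(min=1e-6)
    params["mobile_fraction"].set(min=0.0, max=1.0)
    params["plateau"].set(vary=fit_plateau, min=0.1)
    result = model.fit(y, params, t=t)
    if not result.success:
        flags.append("no_convergence")

    tau = float(result.params["tau_d"].value)
    tau_se = result.params["tau_d"].stderr
    mf = float(result.params["mobile_fraction"].value)
    mf_se = result.params["mobile_fraction"].stderr
    w = curve.spot_radius
    D = w**2 / (4.0 * tau)
    D_se = float(D * tau_se / tau) if tau_se else float("nan")
    resid = y - result.best_fit
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return FrapFit(D, D_se, mf, float(mf_se) if mf_se else float("nan"),
                   tau, r2, flags=flags)
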