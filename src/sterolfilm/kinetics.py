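"""Bond-formation / interfacial-adaptation kinetics.

Contact-time-dependent adhesion forces between a probe (colloid or single
bacterium) and a sterol multilayer are modelled by an order-``n`` decay of
the surface density sigma of not-yet-adapted cooperative sites,

    d(sigma)/dt = -k sigma**n,

with the measured force proportional to the density of adapted sites,
F(t) = F_inf * (1 - sigma(t)/sigma0). Third order (n = 3) corresponds to
cooperative reorientation of trios of sterol molecules. Because force data
constrain only the product kappa = k * sigma0**(n-1), fits report that
lumped rate; sigma0 enters solely through the normalization.

Model-order selection uses AICc (small-sample corrected), appropriate for
the short (~12-16 point) force-time curves this assay produces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Model


@dataclass
class ForceTimeSeries:
    """One adhesion force vs contact time curve.

    contact_time in seconds (nonnegative, strictly increasing), force in nN.
    """

    contact_time: np.ndarray
    force: np.ndarray
    condition: str = ""
    replicate_id: str = ""
    force_sem: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.contact_time = np.asarray(self.contact_time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.contact_time.shape != self.force.shape:
            raise ValueError("contact_time and force must have equal length")
        if self.contact_time.size and self.contact_time[0] < 0:
            raise ValueError("contact times must be nonnegative")
        if np.any(np.diff(self.contact_time) <= 0):
            raise ValueError("contact times must be strictly increasing")
        if not np.all(np.isfinite(self.force)):
            raise ValueError("forces must be finite")
        if self.force_sem is not None:
            self.force_sem = np.asarray(self.force_sem, dtype=float)
            if self.force_sem.shape != self.force.shape:
                raise ValueError("force_sem length mismatch")

    def __len__(self) -> int:
        return self.contact_time.size


@dataclass
class RepeatForceSeries:
    """Sequentially repeated forces at one location (variability assay)."""

    sequence_index: np.ndarray
    force: np.ndarray
    location_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.sequence_index = np.asarray(self.sequence_index, dtype=int)
        self.force = np.asarray(self.force, dtype=float)
        if self.sequence_index.shape != self.force.shape:
            raise ValueError("index and force must have equal length")
        expected = np.arange(1, self.sequence_index.size + 1)
        if not np.array_equal(self.sequence_index, expected):
            raise ValueError("sequence_index must be consecutive from 1")


@dataclass
class KineticsFit:
    order: int
    rate_kappa: float
    rate_kappa_se: float
    force_scale: float
    force_scale_se: float
    r_squared: float
    aicc: float
    n_points: int
    success: bool = True
    message: str = ""
    flags: list[str] = field(default_factory=list)


def bond_density_solution(t, k: float, sigma0: float, order: int):
    """Closed-form sigma(t) for d(sigma)/dt = -k sigma**order.

    order 1: sigma0*exp(-k t); order n>1:
    sigma0*[1 + (n-1) k sigma0**(n-1) t]**(-1/(n-1)).
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if sigma0 <= 0:
        raise ValueError("sigma0 must be positive")
    if k < 0:
        raise ValueError("rate k must be nonnegative")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    if order == 1:
        out = sigma0 * np.exp(-k * t)
    else:
        n = order
        out = sigma0 * (1.0 + (n - 1) * k * sigma0 ** (n - 1) * t) ** (-1.0 / (n - 1))
    return out if out.ndim else float(out)


def force_model(t, force_scale: float, kappa: float, order: int):
    """Adhesion force F(t) = F_inf * (1 - sigma(t)/sigma0).

    ``kappa`` is the lumped rate k*sigma0**(order-1); F(0) = 0 and
    F -> force_scale monotonically for k > 0.
    """
    # sigma(t)/sigma0 depends on k and sigma0 only through kappa
    frac = bond_density_solution(t, kappa, 1.0, order)
    return force_scale * (1.0 - frac)


def fit_kinetics(series: ForceTimeSeries, order: int, weighted: bool = True) -> KineticsFit:
    """Least-squares fit of the order-``order`` force model to one curve.

    Inverse-variance weighting is applied when the series carries per-point
    s.e.m. and ``weighted`` is true. Non-convergence and low-information
    inputs are reported through ``success``/``flags`` rather than raised.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if len(series) < 4:
        raise ValueError("need at least 4 points to fit")
    t = series.contact_time
    f = series.force

    flags: list[str] = []
    fmax = float(np.max(np.abs(f)))
    if fmax < 1e-12:
        return KineticsFit(order, 0.0, 0.0, 0.0, 0.0, float("nan"),
                           float("inf"), len(series), success=False,
                           message="constant-zero force series",
                           flags=["low_information"])

    f_scale0 = 1.05 * float(np.max(f))
    # half-rise time -> initial lumped rate
    above = np.nonzero(f >= 0.5 * f_scale0)[0]
    t_half = t[above[0]] if above.size and t[above[0]] > 0 else max(t[-1] / 4.0, 1e-6)
    if order == 1:
        kappa0 = math.log(2.0) / t_half
    else:
        kappa0 = (2.0 ** (order - 1) - 1.0) / ((order - 1) * t_half)

    model = Model(lambda t, force_scale, kappa: force_model(t, force_scale, kappa, order),
                  independent_vars=["t"])
    params = model.make_params(force_scale=f_scale0, kappa=kappa0)
    params["force_scale"].set(min=0.0)
    params["kappa"].set(min=0.0)
    weights = None
    if weighted and series.force_sem is not None and np.all(series.force_sem > 0):
        weights = 1.0 / series.force_sem
    try:
        result = model.fit(f, params, t=t, weights=weights)
    except Exception as exc:  # fit blew up: flagged, not silent
        return KineticsFit(order, float("nan"), float("nan"), float("nan"),
                           float("nan"), float("nan"), float("inf"),
                           len(series), success=False, message=str(exc),
                           flags=["fit_failed"])

    resid = f - result.best_fit
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    n = len(series)
    p = 3  # kappa, force_scale, residual variance
    # AICc on the objective actually minimized: weighted chi^2 when
    # per-point errors are available, plain RSS otherwise
    obj = float(np.sum((weights * resid) ** 2)) if weights is not None else ss_res
    aicc = n * math.log(max(obj, 1e-300) / n) + 2 * p
    if n - p - 1 > 0:
        aicc += 2 * p * (p + 1) / (n - p - 1)
    else:
        flags.append("aicc_undefined_small_n")
        aicc = float("inf")

    def stderr(name: str) -> float:
        se = result.params[name].stderr
        return float(se) if se is not None else float("nan")

    if not result.success:
        flags.append("no_convergence")
    return KineticsFit(order=order,
                       rate_kappa=float(result.params["kappa"].value),
                       rate_kappa_se=stderr("kappa"),
                       force_scale=float(result.params["force_scale"].value),
                       force_scale_se=stderr("force_scale"),
                       r_squared=r2, aicc=aicc, n_points=n,
                       success=bool(result.success),
                       message=result.message or "", flags=flags)


@dataclass
class OrderSelection:
    best_order: int
    per_curve_orders: list[int]
    table: pd.DataFrame


def pool_curves(curves: list[ForceTimeSeries]) -> ForceTimeSeries:
    """Pool replicate curves into mean force with per-point s.e.m.

    Requires a shared time grid. The pooled curve is what a mean +/- s.e.m.
    plot shows, and its s.e.m. drives inverse-variance weighting in fits —
    the informative route for model-order selection, since replicate
    averaging beats down the noise that otherwise masks the subtle shape
    differences between adjacent orders.
    """
    if len(curves) < 2:
        raise ValueError("pooling needs at least 2 curves")
    t = curves[0].contact_time
    for c in curves[1:]:
        if not np.array_equal(c.contact_time, t):
            raise ValueError("curves must share one time grid for pooling")
    F = np.vstack([c.force for c in curves])
    sem = F.std(axis=0, ddof=1) / math.sqrt(F.shape[0])
    positive = sem[sem > 0]
    # points with zero spread (e.g. F(0)=0 exactly) get the smallest
    # observed s.e.m. so weights stay finite
    sem[sem == 0] = positive.min() if positive.size else 1.0
    return ForceTimeSeries(t, F.mean(axis=0), condition=curves[0].condition,
                           replicate_id="pooled", force_sem=sem)


def select_order(data: ForceTimeSeries | list[ForceTimeSeries],
                 orders=(1, 2, 3, 4), mode: str = "pooled") -> OrderSelection:
    """AICc model-order selection.

    For a collection, ``mode="pooled"`` (default) fits the replicate mean
    with s.e.m. weights and selects on that single informative curve,
    while ``mode="majority"`` selects per curve and takes the modal order.
    The per-curve table is retained either way.
    """
    orders = list(orders)
    if not orders:
        raise ValueError("orders must be nonempty")
    if mode not in ("pooled", "majority"):
        raise ValueError("mode must be 'pooled' or 'majority'")
    curves = [data] if isinstance(data, ForceTimeSeries) else list(data)
    if mode == "pooled" and len(curves) > 1:
        pooled = pool_curves(curves)
        fits = {n: fit_kinetics(pooled, n) for n in orders}
        ok = {n: f for n, f in fits.items() if f.success and np.isfinite(f.aicc)}
        if not ok:
            raise RuntimeError("all pooled kinetics fits failed")
        best = min(ok, key=lambda n: ok[n].aicc)
        rows = [dict(curve="pooled", condition=pooled.condition,
                     replicate="pooled", order=n, aicc=f.aicc,
                     r_squared=f.r_squared, rate_kappa=f.rate_kappa,
                     force_scale=f.force_scale, success=f.success,
                     selected=(n == best)) for n, f in fits.items()]
        return OrderSelection(best_order=best, per_curve_orders=[best],
                              table=pd.DataFrame(rows))
    rows = []
    per_curve = []
    failures = []
    for i, curve in enumerate(curves):
        fits = {n: fit_kinetics(curve, n) for n in orders}
        ok = {n: f for n, f in fits.items() if f.success and np.isfinite(f.aicc)}
        if not ok:
            failures.append(f"curve {i} ({curve.condition}/{curve.replicate_id}): "
                            + "; ".join(f"order {n}: {f.message}" for n, f in fits.items()))
            continue
        best = min(ok, key=lambda n: ok[n].aicc)
        per_curve.append(best)
        for n, f in fits.items():
            rows.append(dict(curve=i, condition=curve.condition,
                             replicate=curve.replicate_id, order=n,
                             aicc=f.aicc, r_squared=f.r_squared,
                             rate_kappa=f.rate_kappa, force_scale=f.force_scale,
                             success=f.success, selected=(n == best)))
    if not per_curve:
        raise RuntimeError("all kinetics fits failed:\n" + "\n".join(failures))
    counts = np.bincount(per_curve)
    majority = int(np.argmax(counts))
    return OrderSelection(best_order=majority, per_curve_orders=per_curve,
                          table=pd.DataFrame(rows))


def normalize_repeat_forces(series: RepeatForceSeries) -> tuple[RepeatForceSeries, float]:
    """Normalize a repeated-force series by its mean; returns (series, CV).

    The coefficient of variation of the normalized values quantifies
    temporal heterogeneity of the interface at one location.
    """
    if series.force.size < 2:
        raise ValueError("need at least 2 points")
    mean = float(series.force.mean())
    if mean == 0:
        raise ValueError("zero-mean series cannot be normalized")
    norm = series.force / mean
    cv = float(np.std(norm))  # population CV: sd/mean of the raw series
    out = RepeatForceSeries(series.sequence_index.copy(), norm,
                            location_id=series.location_id,
                            condition=series.condition)
    return out, cv


def pooled_repeat_cv(series_list: list[RepeatForceSeries]) -> pd.DataFrame:
    """Per-location CV plus pooled mean CV per condition."""
    rows = []
    for s in series_list:
        _, cv = normalize_repeat_forces(s)
        rows.append(dict(condition=s.condition, location_id=s.location_id, cv=cv))
    df = pd.DataFrame(rows)
    pooled = df.groupby("condition")["cv"].mean().rename("pooled_cv")
    return df.merge(pooled, on="condition")
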