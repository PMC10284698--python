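"""Orientational and height-fluctuation observables of multilayer interfaces.

Operates on :class:`~sterolfilm.trajectory.LayerTrajectory` objects from the
rotor simulator or imported coordinate files. Observables:

* tilt angles between the molecular axis and the interface normal (z),
* the lateral orientational pair-correlation function C_r and its decay
  distance (the cooperativity length of interfacial fluctuations),
* the RMSD over time of interfacial head heights (roughness/fluctuation),
* reorientation ("flip") events of initially head-down molecules, detected
  with a hysteresis band so angular noise near the equator never counts
  as a flip.

Lateral distances use the minimum-image convention in x and y only; the
interface is treated as a quasi-2D system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .trajectory import LayerTrajectory


def select_interface(traj: LayerTrajectory, cutoff: float | None = None) -> np.ndarray:
    """Frozen id set of interfacial molecules (reference = first frame).

    Molecules of the highest layer index are selected; for imported
    trajectories without layer structure (all ids in one layer), molecules
    whose head z lies within ``cutoff`` nm of the maximum head height in
    the first frame are taken instead (default cutoff 0.5 nm).
    """
    if traj.n_frames < 1:
        raise ValueError("trajectory has no frames")
    layers = np.unique(traj.layer)
    if layers.size > 1 and cutoff is None:
        sel = np.nonzero(traj.layer == layers.max())[0]
    else:
        c = 0.5 if cutoff is None else float(cutoff)
        z0 = traj.head_z[0]
        sel = np.nonzero(z0 >= z0.max() - c)[0]
    if sel.size == 0:
        raise ValueError("interface selection is empty")
    return sel


def tilt_angles(traj: LayerTrajectory, selection: np.ndarray) -> np.ndarray:
    """(n_frames, n_selected) tilt angles in degrees, arccos(u.z) in [0, 180]."""
    uz = np.clip(traj.axes[:, selection, 2], -1.0, 1.0)
    return np.degrees(np.arccos(uz))


@dataclass
class CorrelationCurve:
    bin_centers: np.ndarray
    values: np.ndarray          # NaN where a bin is empty
    dispersion: np.ndarray      # s.d. of per-window means
    pair_counts: np.ndarray     # pairs per bin per frame
    empty_bins: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def _minimum_image_distances(xy: np.ndarray, box_xy: tuple[float, float]) -> np.ndarray:
    """Condensed pairwise lateral distances with periodic wrapping."""
    i, j = np.triu_indices(xy.shape[0], k=1)
    d = xy[i] - xy[j]
    for axis, L in enumerate(box_xy):
        d[:, axis] -= L * np.round(d[:, axis] / L)
    return np.linalg.norm(d, axis=1), i, j


def orientation_correlation(traj: LayerTrajectory, selection: np.ndarray,
                            bin_width: float = 0.1, max_distance: float = 3.0,
                            estimator: str = "dot",
                            n_windows: int = 5) -> CorrelationCurve:
    """Orientational pair correlation C_r vs lateral pair distance.

    C_r(d) is the mean over frames and over pairs in distance bin d of
    u_i . u_j ("dot", default) or of the second Legendre polynomial
    P2(u_i . u_j) ("p2"). Dispersion is the s.d. of per-time-window means
    (frames split into ``n_windows`` contiguous blocks). Empty bins carry
    NaN and are listed in ``empty_bins`` — never silently zero.
    """
    if selection.size < 2:
        raise ValueError("need at least 2 selected molecules")
    if estimator not in ("dot", "p2"):
        raise ValueError("estimator must be 'dot' or 'p2'")
    box_xy = (traj.box[0], traj.box[1])
    edges = np.arange(0.0, max_distance + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_bins = centers.size

    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    window_sums = np.zeros((n_windows, n_bins))
    window_counts = np.zeros((n_windows, n_bins))
    F = traj.n_frames
    for f in range(F):
        dist, i, j = _minimum_image_distances(traj.xy[f, selection], box_xy)
        keep = dist < max_distance
        bins = np.floor(dist[keep] / bin_width).astype(int)
        u = traj.axes[f, selection]
        dots = np.einsum("ij,ij->i", u[i[keep]], u[j[keep]])
        if estimator == "p2":
            dots = 1.5 * dots**2 - 0.5
        np.add.at(sums, bins, dots)
        np.add.at(counts, bins, 1.0)
        w = min(f * n_windows // F, n_windows - 1)
        np.add.at(window_sums[w], bins, dots)
        np.add.at(window_counts[w], bins, 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        wmeans = np.where(window_counts > 0,
                          window_sums / np.maximum(window_counts, 1), np.nan)
    dispersion = np.full(n_bins, np.nan)
    ok = counts > 0
    if F > 1:
        dispersion[ok] = np.nanstd(wmeans[:, ok], axis=0, ddof=0)
    empty = np.nonzero(~ok)[0]
    return CorrelationCurve(centers, values, dispersion, counts, empty)


@dataclass
class DecayDistance:
    distance: float          # nm; inf when censored
    censored: bool
    threshold: float
    max_distance: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.censored:
            return f"> {self.max_distance:g} nm"
        return f"{self.distance:.3f} nm"


def decay_distance(curve: CorrelationCurve,
                   threshold_fraction: float = 1.0 / math.e) -> DecayDistance:
    """Distance at which C_r first falls below a fraction of its first bin.

    Linear interpolation between the straddling populated bins; censored
    (distance = inf) when the curve never drops below the threshold within
    the measured range.
    """
    ok = np.nonzero(curve.pair_counts > 0)[0]
    if ok.size == 0:
        raise ValueError("correlation curve has no populated bins")
    x = curve.bin_centers[ok]
    y = curve.values[ok]
    threshold = float(y[0] * threshold_fraction)
    max_d = float(curve.bin_centers[-1])
    below = np.nonzero(y < threshold)[0]
    if below.size == 0:
        return DecayDistance(math.inf, True, threshold, max_d)
    b = below[0]
    if b == 0:
        return DecayDistance(float(x[0]), False, threshold, max_d)
    x0, x1 = x[b - 1], x[b]
    y0, y1 = y[b - 1], y[b]
    frac = (y0 - threshold) / (y0 - y1) if y0 != y1 else 0.0
    return DecayDistance(float(x0 + frac * (x1 - x0)), False, threshold, max_d)


@dataclass
class FluctuationCurve:
    times: np.ndarray
    rmsd: np.ndarray         # nm, mean over trajectories
    sem: np.ndarray          # across trajectories (0 for a single one)


def interface_z_rmsd(trajs: LayerTrajectory | list[LayerTrajectory],
                     selection: np.ndarray, stride: int = 1,
                     reference: str = "first") -> FluctuationCurve:
    """RMSD over time of interfacial head heights.

    Per frame: RMSD over selected molecules of (head z - reference z), the
    reference being the first analysed frame ("first", default) or the
    per-molecule time mean ("mean"). With several trajectories the curves
    are averaged and the s.e.m. across them reported; frame counts and
    selections must match.
    """
    if isinstance(trajs, LayerTrajectory):
        trajs = [trajs]
    if reference not in ("first", "mean"):
        raise ValueError("reference must be 'first' or 'mean'")
    curves = []
    times = None
    for traj in trajs:
        if traj.n_frames < 2:
            raise ValueError("need at least 2 frames")
        z = traj.head_z[::stride, selection]
        t = traj.times[::stride]
        ref = z[0] if reference == "first" else z.mean(axis=0)
        rmsd = np.sqrt(np.mean((z - ref) ** 2, axis=1))
        if times is None:
            times = t
        elif t.shape != times.shape:
            raise ValueError("trajectories have mismatched frame grids")
        curves.append(rmsd)
    arr = np.vstack(curves)
    sem = (arr.std(axis=0, ddof=1) / math.sqrt(arr.shape[0])
           if arr.shape[0] > 1 else np.zeros(arr.shape[1]))
    return FluctuationCurve(times, arr.mean(axis=0), sem)


@dataclass
class FlipEvent:
    molecule_id: int
    frame: int
    direction: str  # "down_to_up" or "up_to_down"


@dataclass
class FlipEvents:
    events: list[FlipEvent]
    recovered_fraction: float
    mean_first_passage_frames: float  # NaN when no recoveries
    initially_reverted: np.ndarray


def detect_flips(traj: LayerTrajectory, selection: np.ndarray,
                 aligned_threshold: float = 60.0,
                 reverted_threshold: float = 120.0,
                 budget_frames: int | None = None) -> FlipEvents:
    """Hysteresis-based reorientation detection on tilt-angle series.

    A molecule is in the aligned state below ``aligned_threshold`` degrees
    and in the reverted state above ``reverted_threshold``; excursions
    inside the band change nothing. A down->up event fires when a molecule
    last seen reverted first drops below the aligned threshold (and vice
    versa). ``recovered_fraction`` counts initially reverted molecules with
    a down->up event within ``budget_frames`` (default: whole trajectory).
    """
    if not aligned_threshold < reverted_threshold:
        raise ValueError("aligned_threshold must be below reverted_threshold")
    angles = tilt_angles(traj, selection)
    F, n = angles.shape
    budget = F if budget_frames is None else min(budget_frames, F)

    state = np.zeros(n, dtype=int)  # +1 aligned, -1 reverted, 0 band
    state[angles[0] < aligned_threshold] = 1
    state[angles[0] > reverted_threshold] = -1
    initially_reverted = selection[state == -1]

    events: list[FlipEvent] = []
    first_passage = {}
    for f in range(1, F):
        up = (angles[f] < aligned_threshold) & (state == -1)
        down = (angles[f] > reverted_threshold) & (state == 1)
        for idx in np.nonzero(up)[0]:
            mol = int(selection[idx])
            events.append(FlipEvent(mol, f, "down_to_up"))
            if mol not in first_passage:
                first_passage[mol] = f
        for idx in np.nonzero(down)[0]:
            events.append(FlipEvent(int(selection[idx]), f, "up_to_down"))
        state[up] = 1
        state[down] = -1
        # entering the band keeps the previous committed state (hysteresis)
        newly_aligned = (angles[f] < aligned_threshold) & (state == 0)
        newly_reverted = (angles[f] > reverted_threshold) & (state == 0)
        state[newly_aligned] = 1
        state[newly_reverted] = -1

    if initially_reverted.size:
        rec = [m for m in initially_reverted if first_passage.get(int(m), F + 1) < budget]
        frac = len(rec) / initially_reverted.size
        mfp = (float(np.mean([first_passage[int(m)] for m in rec]))
               if rec else float("nan"))
    else:
        frac, mfp = 0.0, float("nan")
    return FlipEvents(events, frac, mfp, initially_reverted)
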