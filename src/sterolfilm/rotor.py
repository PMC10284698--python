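"""Coarse-grained rotor Monte Carlo model of a sterol multilayer interface.

Each molecule of the topmost (water-facing) layer is a unit-vector rotor
``u`` on a fixed 2D lattice, plus a scalar head-height excursion ``dz``.
Lower layers are frozen, mirroring the substrate restraint of the system
being emulated. The reduced energy (units of kT) is

    E = - sum_<ij> J_ij (u_i . u_j)  -  h sum_i u_iz  +  (kz/2) sum_i dz_i^2

with nearest-neighbour alignment couplings J_ij, a polarity field h that
favours the hydroxyl head pointing at the water (u_z > 0), and a harmonic
restraint on head excursions. Because 128 molecules per layer factor as a
16 x 8 grid in the square box, bond couplings are scaled as
J_ij = J (a/d_ij)^2 with ``a`` the shortest lattice spacing, keeping the
lateral correlation roughly isotropic.

Dynamics are Metropolis with two proposal kinds: small-angle axis
perturbations and axis inversions (u -> -u plus noise). Any proposal that
carries the axis through the equator (sign change of u_z) is additionally
damped by a kinetic prefactor exp(-flip_barrier). The prefactor multiplies
the Metropolis ratio symmetrically, so detailed balance with respect to E
is preserved exactly while flip *kinetics* slow down by exp(-B) — this is
what distinguishes a cholesterol-like interface (low barrier, spontaneous
back-reorientation of head-down molecules) from a stigmasterol-like one
(high barrier, reverted molecules stay trapped). Head-height updates are
independent Gaussian-step Metropolis moves.

Updates are applied in a checkerboard pattern so that simultaneously
updated sites never interact, which keeps the vectorized sweep a valid
Metropolis kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .constants import STEROL_LENGTH_NM
from .trajectory import LayerTrajectory

#: Analogue presets: flip kinetics and interfacial stiffness differ, the
#: equilibrium Hamiltonian is otherwise shared.
PRESETS: dict[str, dict[str, float]] = {
    "cholesterol": {"flip_barrier": 1.5, "z_stiffness": 10.0},
    "stigmasterol": {"flip_barrier": 12.0, "z_stiffness": 45.0},
}


class RotorConfig(BaseModel):
    """Geometry, Hamiltonian and schedule of one rotor simulation."""

    box_xy: tuple[float, float] = (7.1554, 7.1554)
    n_layers: int = Field(default=4, ge=1)
    per_layer: int = Field(default=128, ge=4)
    lattice_spacing: float | None = None  # derived from box when None
    coupling_J: float = 0.4          # kT per nearest-neighbour bond
    polarity_field_h: float = 0.15   # kT, favours heads toward water
    flip_barrier: float = Field(default=1.5, ge=0.0)  # kT, equator crossing
    z_stiffness: float = Field(default=10.0, gt=0.0)  # kT nm^-2
    reverted_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    sweeps: int = Field(default=20_000, ge=0)
    burn_in: int = Field(default=2_000, ge=0)
    sample_stride: int = Field(default=50, ge=1)
    seed: int = 0
    type_label: str = "cholesterol"
    rotation_sigma: float = 0.35     # rad-scale axis perturbation
    invert_probability: float = 0.1  # fraction of inversion proposals
    z_step: float = 0.12             # nm, head-height proposal width

    @model_validator(mode="after")
    def _check_box(self):
        if self.box_xy[0] <= 0 or self.box_xy[1] <= 0:
            raise ValueError("box dimensions must be positive")
        return self

    @classmethod
    def preset(cls, name: str, **overrides) -> "RotorConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
        kwargs = dict(PRESETS[name])
        kwargs.setdefault("type_label", name)
        kwargs.update(overrides)
        return cls(**kwargs)

    def grid_shape(self) -> tuple[int, int]:
        """(ny, nx) factorization of per_layer best matching the box aspect."""
        target = self.box_xy[0] / self.box_xy[1]
        best, best_err = None, math.inf
        for nx in range(1, self.per_layer + 1):
            if self.per_layer % nx:
                continue
            ny = self.per_layer // nx
            err = abs(math.log((nx / ny) / target))
            if err < best_err:
                best, best_err = (ny, nx), err
        ny, nx = best
        dx, dy = self.box_xy[0] / nx, self.box_xy[1] / ny
        if max(dx, dy) / min(dx, dy) > 4.0:
            raise ValueError(
                f"per_layer={self.per_layer} admits no near-square lattice "
                f"in box {self.box_xy} (best {nx}x{ny})")
        return ny, nx


@dataclass
class MCStats:
    """Acceptance bookkeeping and a proposal log for balance checks."""

    sweeps: int
    accepted_axis: int = 0
    proposed_axis: int = 0
    accepted_z: int = 0
    proposed_z: int = 0
    flips_observed: int = 0
    # columns: delta_E, crossed_equator (0/1), acceptance probability
    proposal_log: np.ndarray | None = None

    @property
    def axis_acceptance(self) -> float:
        return self.accepted_axis / max(self.proposed_axis, 1)


def build_multilayer(config: RotorConfig) -> LayerTrajectory:
    """Construct the initial multilayer as a single-frame trajectory.

    Layers stack along z as two tail-to-tail double layers: heads point
    down/up/down/up from the substrate, so hydroxyls meet at the inner
    interface and face the water at the top. ``reverted_fraction`` of the
    top-layer molecules start head-down (axis inverted); their ids are
    recorded in ``meta['reverted_ids']``.
    """
    ny, nx = config.grid_shape()
    dx, dy = config.box_xy[0] / nx, config.box_xy[1] / ny
    L = STEROL_LENGTH_NM
    M = config.n_layers * config.per_layer
    rng = np.random.default_rng(config.seed)

    gx, gy = np.meshgrid((np.arange(nx) + 0.5) * dx, (np.arange(ny) + 0.5) * dy)
    xy_layer = np.column_stack([gx.ravel(), gy.ravel()])

    xy = np.tile(xy_layer, (config.n_layers, 1))
    layer = np.repeat(np.arange(config.n_layers), config.per_layer)
    # heads alternate down/up so double layers are tail-to-tail
    head_sign = np.where(layer % 2 == 0, -1.0, 1.0)
    axes = np.zeros((M, 3))
    axes[:, 2] = head_sign
    z_center = 1.0 + layer * L
    head_z = z_center + 0.5 * L * axes[:, 2]

    top = np.nonzero(layer == config.n_layers - 1)[0]
    # ceiling reproduces the reference counts 13/39/64 at 10/30/50% of 128
    n_rev = math.ceil(config.reverted_fraction * config.per_layer - 1e-9)
    reverted = rng.choice(top, size=n_rev, replace=False) if n_rev else np.array([], dtype=int)
    axes[reverted] *= -1.0
    head_z[reverted] = z_center[reverted] + 0.5 * L * axes[reverted, 2]

    box = (config.box_xy[0], config.box_xy[1], 50.0)
    meta = {"config": config.model_dump(), "reverted_ids": reverted.tolist(),
            "grid_shape": [ny, nx]}
    labels = np.asarray([config.type_label] * M, dtype=object)
    return LayerTrajectory(box, np.array([0.0]), xy[None], head_z[None],
                           axes[None], layer, labels, meta)


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def rotor_mc_simulate(start: LayerTrajectory, config: RotorConfig,
                      log_proposals: int = 0) -> tuple[LayerTrajectory, MCStats]:
    """Run Metropolis dynamics on the interfacial layer of ``start``.

    Returns the sampled trajectory (frames every ``sample_stride`` sweeps
    after ``burn_in``; lower layers frozen) and acceptance statistics.
    Deterministic for a given config seed. With ``log_proposals`` > 0 the
    first proposals are recorded as (delta_E, crossed, acc_prob) rows for
    detailed-balance verification.
    """
    if config.sweeps <= 0:
        raise ValueError("sweeps must be positive")
    if start.n_frames != 1:
        raise ValueError("start must be a single frame")
    if start.n_molecules != config.n_layers * config.per_layer:
        raise ValueError("start geometry does not match config")

    ny, nx = config.grid_shape()
    dx, dy = config.box_xy[0] / nx, config.box_xy[1] / ny
    a = min(dx, dy)
    Jx = config.coupling_J * (a / dx) ** 2
    Jy = config.coupling_J * (a / dy) ** 2
    h = config.polarity_field_h
    kz = config.z_stiffness
    barrier_damp = math.exp(-config.flip_barrier)

    top_ids = np.nonzero(start.layer == config.n_layers - 1)[0]
    order = np.lexsort((start.xy[0, top_ids, 0], start.xy[0, top_ids, 1]))
    top_ids = top_ids[order]  # row-major grid order
    u = start.axes[0, top_ids].reshape(ny, nx, 3).copy()
    base_head_z = start.head_z[0, top_ids].reshape(ny, nx).copy()
    # reverted molecules start with the head at the lattice height of the
    # aligned state; their recorded head excursion starts at zero
    dz = np.zeros((ny, nx))

    iy, ix = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    color = (iy + ix) % 2
    rng = np.random.default_rng(config.seed)

    n_samples = max((config.sweeps - config.burn_in) // config.sample_stride, 0)
    F = n_samples
    axes_out = np.empty((F, start.n_molecules, 3))
    head_out = np.empty((F, start.n_molecules))
    times = np.empty(F)

    stats = MCStats(sweeps=config.sweeps)
    log_rows: list[np.ndarray] = []
    logged = 0

    frame = 0
    for sweep in range(config.sweeps):
        for c in (0, 1):
            mask = color == c
            noise = rng.normal(scale=config.rotation_sigma, size=(ny, nx, 3))
            invert = rng.random((ny, nx)) < config.invert_probability
            base = np.where(invert[..., None], -u, u)
            u_prop = _normalize(base + noise)
            nb = (Jx * (np.roll(u, 1, axis=1) + np.roll(u, -1, axis=1))
                  + Jy * (np.roll(u, 1, axis=0) + np.roll(u, -1, axis=0)))
            du = u_prop - u
            dE = -(du * nb).sum(axis=-1) - h * du[..., 2]
            crossed = (u_prop[..., 2] * u[..., 2]) < 0
            acc = np.minimum(1.0, np.exp(-dE))
            acc = np.where(crossed, acc * barrier_damp, acc)
            accept = (rng.random((ny, nx)) < acc) & mask
            if logged < log_proposals:
                take = min(log_proposals - logged, int(mask.sum()))
                rows = np.column_stack([dE[mask][:take],
                                        crossed[mask][:take].astype(float),
                                        acc[mask][:take]])
                log_rows.append(rows)
                logged += take
            stats.proposed_axis += int(mask.sum())
            stats.accepted_axis += int(accept.sum())
            stats.flips_observed += int((accept & crossed).sum())
            u = np.where(accept[..., None], u_prop, u)

        # head-height moves: sites are independent, update all at once
        dz_prop = dz + rng.normal(scale=config.z_step, size=(ny, nx))
        dEz = 0.5 * kz * (dz_prop**2 - dz**2)
        accept_z = rng.random((ny, nx)) < np.minimum(1.0, np.exp(-dEz))
        stats.proposed_z += dz.size
        stats.accepted_z += int(accept_z.sum())
        dz = np.where(accept_z, dz_prop, dz)

        if sweep >= config.burn_in and (sweep - config.burn_in) % config.sample_stride == 0 \
                and frame < F:
            axes_out[frame] = start.axes[0]
            axes_out[frame, top_ids] = u.reshape(-1, 3)
            head_out[frame] = start.head_z[0]
            head_out[frame, top_ids] = (base_head_z + dz).ravel()
            times[frame] = float(sweep + 1)
            frame += 1

    if log_rows:
        stats.proposal_log = np.vstack(log_rows)

    xy = np.broadcast_to(start.xy[0], (F, start.n_molecules, 2)).copy()
    meta = dict(start.meta)
    meta.update({"config": config.model_dump(),
                 "axis_acceptance": stats.axis_acceptance,
                 "seed": config.seed})
    traj = LayerTrajectory(start.box, times[:frame], xy[:frame],
                           head_out[:frame], axes_out[:frame], start.layer,
                           start.type_label, meta)
    return traj, stats


def rotor_energy(u: np.ndarray, dz: np.ndarray, config: RotorConfig) -> float:
    """Total reduced energy (kT) of a top-layer configuration on the grid."""
    ny, nx = config.grid_shape()
    dx, dy = config.box_xy[0] / nx, config.box_xy[1] / ny
    a = min(dx, dy)
    Jx = config.coupling_J * (a / dx) ** 2
    Jy = config.coupling_J * (a / dy) ** 2
    e = -(Jx * (u * np.roll(u, -1, axis=1)).sum()
          + Jy * (u * np.roll(u, -1, axis=0)).sum())
    e -= config.polarity_field_h * u[..., 2].sum()
    e += 0.5 * config.z_stiffness * (dz**2).sum()
    return float(e)
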