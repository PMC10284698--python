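"""Multilayer trajectory container and serialization.

A :class:`LayerTrajectory` holds time-ordered frames of a sterol multilayer:
per molecule a lateral position, a head-atom height, a unit orientation axis
(pointing from tail to hydroxyl head), a layer index and a type label. The
box is periodic in x and y. Frames are stored as dense numpy arrays.

On-disk format: one long-form CSV (frame, time, molecule_id, layer, x, y,
z_head, axis_x, axis_y, axis_z, type) written through :mod:`sterolfilm.io`
with a JSON sidecar carrying box dimensions and the generating
configuration. Single frames can be exported to / imported from GRO-style
coordinate files (import requires MDAnalysis and residues with named C3,
C17 and O3 atoms).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio

_AXIS_TOL = 1e-6


@dataclass
class LayerTrajectory:
    box: tuple[float, float, float]
    times: np.ndarray           # (F,)
    xy: np.ndarray              # (F, M, 2) lateral positions, wrapped
    head_z: np.ndarray          # (F, M)
    axes: np.ndarray            # (F, M, 3) unit vectors
    layer: np.ndarray           # (M,) int
    type_label: np.ndarray      # (M,) str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        self.head_z = np.asarray(self.head_z, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        self.layer = np.asarray(self.layer, dtype=int)
        self.type_label = np.asarray(self.type_label, dtype=object)
        F, M = self.head_z.shape
        if self.xy.shape != (F, M, 2) or self.axes.shape != (F, M, 3):
            raise ValueError("inconsistent frame/molecule dimensions")
        if self.times.shape != (F,):
            raise ValueError("times length mismatch")
        if F > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be increasing")
        norms = np.linalg.norm(self.axes, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-5):
            raise ValueError("axis vectors must be unit norm")

    @property
    def n_frames(self) -> int:
        return self.head_z.shape[0]

    @property
    def n_molecules(self) -> int:
        return self.head_z.shape[1]

    def frame(self, i: int) -> "LayerTrajectory":
        return LayerTrajectory(self.box, self.times[i:i + 1],
                               self.xy[i:i + 1], self.head_z[i:i + 1],
                               self.axes[i:i + 1], self.layer,
                               self.type_label, dict(self.meta))

    # ---------------------------------------------------------------- I/O
    def save(self, path: str | Path) -> None:
        """Write the long-form CSV plus a ``<path>.json`` sidecar."""
        path = Path(path)
        F, M = self.head_z.shape
        frame_idx = np.repeat(np.arange(F), M)
        mol_idx = np.tile(np.arange(M), F)
        df = pd.DataFrame({
            "frame": frame_idx,
            "time": np.repeat(self.times, M),
            "molecule_id": mol_idx,
            "layer": np.tile(self.layer, F),
            "x_nm": self.xy[..., 0].ravel(),
            "y_nm": self.xy[..., 1].ravel(),
            "z_head_nm": self.head_z.ravel(),
            "axis_x": self.axes[..., 0].ravel(),
            "axis_y": self.axes[..., 1].ravel(),
            "axis_z": self.axes[..., 2].ravel(),
            "type": np.tile(self.type_label, F),
        })
        sio.write_table(df, path, {"artifact": "LayerTrajectory"})
        sidecar = {"box_nm": list(self.box), "meta": self.meta}
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "LayerTrajectory":
        path = Path(path)
        df, _ = sio.read_table(path)
        sidecar = json.loads(Path(str(path) + ".json").read_text())
        frames = np.sort(df["frame"].unique())
        F = frames.size
        M = df["molecule_id"].nunique()
        df = df.sort_values(["frame", "molecule_id"])
        xy = df[["x_nm", "y_nm"]].to_numpy().reshape(F, M, 2)
        head_z = df["z_head_nm"].to_numpy().reshape(F, M)
        axes = df[["axis_x", "axis_y", "axis_z"]].to_numpy().reshape(F, M, 3)
        times = df.groupby("frame")["time"].first().to_numpy()
        first = df[df["frame"] == frames[0]]
        return cls(tuple(sidecar["box_nm"]), times, xy, head_z, axes,
                   first["layer"].to_numpy(), first["type"].to_numpy(),
                   sidecar.get("meta", {}))

    def to_gro(self, path: str | Path, frame: int = 0) -> None:
        """Export one frame as a GRO-style file (3 pseudo-atoms/molecule).

        Each molecule becomes a residue with atoms O3 (head), C3 and C17
        placed along its axis; fixed-width GRO columns, nm coordinates.
        """
        i = frame
        lines = [f"sterolfilm frame {i}, t= {self.times[i]:.3f}",
                 str(3 * self.n_molecules)]
        half = 0.855  # half molecular length, nm
        serial = 1
        for m in range(self.n_molecules):
            x, y = self.xy[i, m]
            hz = self.head_z[i, m]
            ax = self.axes[i, m]
            res = str(self.type_label[m])[:5].upper() or "STRL"
            head = np.array([x, y, hz])
            c3 = head - 0.1 * half * ax * 2
            c17 = head - 2 * half * ax
            for name, pos in (("O3", head), ("C3", c3), ("C17", c17)):
                lines.append(f"{m + 1:>5d}{res:<5s}{name:>5s}{serial:>5d}"
                             f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}")
                serial += 1
        lines.append(f"{self.box[0]:10.5f}{self.box[1]:10.5f}{self.box[2]:10.5f}")
        Path(path).write_text("\n".join(lines) + "\n")


def from_gro(path: str | Path, type_label: str | None = None) -> LayerTrajectory:
    """Import a GRO-style coordinate file as a single-frame trajectory.

    Uses MDAnalysis; each residue must contain atoms named C3, C17 and O3.
    The molecular axis is the normalized C17->C3 (tail-to-head) vector so
    that a head-up interfacial molecule has a tilt near 0 degrees; O3 gives
    the head height.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    box = u.dimensions[:3] / 10.0  # Angstrom -> nm
    xy, head_z, axes, labels = [], [], [], []
    for res in u.residues:
        names = {a.name: a for a in res.atoms}
        for req in ("C3", "C17", "O3"):
            if req not in names:
                raise ValueError(f"residue {res.resid} lacks atom {req}")
        c3 = names["C3"].position / 10.0
        c17 = names["C17"].position / 10.0
        o3 = names["O3"].position / 10.0
        v = c3 - c17
        axes.append(v / np.linalg.norm(v))
        xy.append(o3[:2] % box[:2])
        head_z.append(o3[2])
        labels.append(type_label or res.resname)
    M = len(labels)
    return LayerTrajectory(tuple(float(b) for b in box), np.array([0.0]),
                           np.asarray(xy)[None], np.asarray(head_z)[None],
                           np.asarray(axes)[None],
                           np.zeros(M, dtype=int), np.asarray(labels, dtype=object))
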