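"""Bioadhesion assay normalization and index aggregation.

Bacterial-adhesion and protein-adsorption results from heterogeneous assays
are made comparable by normalizing each surface x assay mean to the mobile
cholesterol multilayer's result for that assay, then aggregating the
normalized components into a single bioadhesion index per surface
(arithmetic mean by default; geometric mean optional). A separate reference
value is computed the same way from per-assay control surfaces (bare
substrate for bacterial counts, bare metal for adsorption).

Normalization uses per-group means by default; medians are available for
count-type data dominated by outliers. The choice is recorded in every
report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def scale_cell_counts(count: int, counted_area_um2: float) -> float:
    """Cells per mm^2 from a raw count over a counted area in um^2."""
    if counted_area_um2 <= 0:
        raise ValueError("counted area must be positive")
    if count < 0:
        raise ValueError("count must be nonnegative")
    return count * 1e6 / counted_area_um2


def _center(values: pd.Series, statistic: str) -> float:
    return float(values.median() if statistic == "median" else values.mean())


def normalize_assays(table: pd.DataFrame, reference_surface: str,
                     statistic: str = "mean") -> pd.DataFrame:
    """Surface x assay means divided by the reference surface's means.

    ``table`` needs columns surface, assay, value. Returns a tidy frame
    (surface, assay, normalized) where the reference surface is exactly 1
    in every assay.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    if reference_surface not in set(table["surface"]):
        raise ValueError(f"reference surface {reference_surface!r} absent from table")
    centers = (table.groupby(["surface", "assay"])["value"]
               .apply(lambda v: _center(v, statistic)).rename("center")
               .reset_index())
    ref = centers[centers["surface"] == reference_surface].set_index("assay")["center"]
    zero = ref[ref == 0]
    if not zero.empty:
        raise ValueError(f"reference mean is zero for assay(s): {list(zero.index)}")
    out = centers.copy()
    out["normalized"] = out.apply(lambda r: r["center"] / ref[r["assay"]], axis=1)
    return out[["surface", "assay", "normalized"]]


@dataclass
class BioadhesionIndex:
    per_surface: pd.Series          # index value per surface
    components: pd.DataFrame        # normalized surface x assay values
    reference_value: float | None   # composite control surface index
    aggregation: str
    statistic: str


def bioadhesion_index(normalized: pd.DataFrame, aggregation: str = "mean",
                      reference_controls: dict[str, str] | None = None,
                      statistic: str = "mean") -> BioadhesionIndex:
    """Aggregate normalized assay components into one index per surface.

    Every surface must carry every assay present in the table. The
    ``reference_controls`` mapping (assay -> control surface) builds a
    composite reference value from the per-assay controls, aggregated the
    same way; those control surfaces are excluded from the main index.
    """
    if aggregation not in ("mean", "geometric"):
        raise ValueError("aggregation must be 'mean' or 'geometric'")
    wide = normalized.pivot(index="surface", columns="assay", values="normalized")
    incomplete = wide[wide.isna().any(axis=1)]
    if not incomplete.empty:
        surf = incomplete.index[0]
        assay = wide.columns[incomplete.iloc[0].isna()][0]
        raise ValueError(f"surface {surf!r} is missing assay {assay!r}")

    def agg(frame: pd.DataFrame) -> pd.Series:
        if aggregation == "geometric":
            return np.exp(np.log(frame).mean(axis=1))
        return frame.mean(axis=1)

    reference_value = None
    controls = set()
    if reference_controls:
        missing = set(reference_controls) - set(wide.columns)
        if missing:
            raise ValueError(f"reference mapping names unknown assays: {sorted(missing)}")
        comp = {}
        for assay, ctrl in reference_controls.items():
            if ctrl not in wide.index:
                raise ValueError(f"control surface {ctrl!r} absent from table")
            comp[assay] = wide.loc[ctrl, assay]
            controls.add(ctrl)
        row = pd.DataFrame([comp])
        reference_value = float(agg(row).iloc[0])
    body = wide.drop(index=[c for c in controls if c in wide.index])
    return BioadhesionIndex(per_surface=agg(body), components=normalized,
                            reference_value=reference_value,
                            aggregation=aggregation, statistic=statistic)
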