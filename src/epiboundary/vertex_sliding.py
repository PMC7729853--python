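"""Vertex-sliding productivity at the compartment boundary (Δd).

For a reference cell adjacent to the A/P interface, each of its boundary
vertices is scored per frame interval:

* ``d`` — actual radial displacement: the vertex displacement projected on
  the unit vector from the cell centroid (at the interval's start) to the
  vertex, positive outward;
* ``d_iso`` — the displacement the vertex would undergo if the cell changed
  area isotropically: every vertex shifted radially about the centroid by
  the scaling factor s = sqrt(A(t+dt)/A(t)), giving d_iso = (s-1)|p - c|;
* ``Δd = d - d_iso`` — the productivity of vertex sliding.  Δd < 0 during
  area expansion means the boundary vertex moves outward less than the
  cell's own area change would predict, i.e. something resists its sliding.

Radial axis and centroid are taken at the interval's start frame, matching
the isotropic construction.  Vertex coordinate series are Savitzky-Golay
smoothed before d and d_iso are computed (``smooth_positions=True``, the
default): with raw positions, positional measurement noise enters both the
radial axis and the displacement and regresses Δd toward negative values by
about σ²/r per interval, which masquerades as resistance.  Smoothing the
coordinate series (as segmentation pipelines conventionally do) suppresses
this bias; set ``smooth_positions=False`` for the raw-geometry identity
d ≡ d_iso under exact isotropic deformation.  Reference cells are selected
by compartment and a mixing-index cutoff (γ > 0.55 by default, the
protruding-cell configuration).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .boundary_metrics import mixing_index
from .core_geometry import (
    InvalidGeometryError,
    MeshFrame,
    TissueTimeSeries,
    polygon_area_centroid,
)
from .pulsation_dynamics import PhaseSegmentation, detect_phases

GAMMA_SELECT_CUTOFF = 0.55


def isotropic_positions(ring_coords, area_ratio: float) -> np.ndarray:
    """Virtual vertex positions under isotropic area change by ``area_ratio``.

    Each vertex is moved radially about the ring's area centroid by the
    scaling factor sqrt(area_ratio); the recomputed polygon area is exactly
    ``area_ratio`` times the original.
    """
    if not area_ratio > 0:
        raise InvalidGeometryError(f"area ratio must be positive, got {area_ratio}")
    ring = np.asarray(ring_coords, dtype=float)
    _, c = polygon_area_centroid(ring)
    s = np.sqrt(area_ratio)
    return c + s * (ring - c)


def radial_displacement(centroid, p_t, p_t1) -> float:
    """Projection of the move ``p_t -> p_t1`` on the outward radial axis.

    The axis is the unit vector from ``centroid`` to ``p_t``; positive means
    away from the centroid.  NaN if the vertex sits on the centroid
    (direction undefined).
    """
    c = np.asarray(centroid, dtype=float)
    p0 = np.asarray(p_t, dtype=float)
    p1 = np.asarray(p_t1, dtype=float)
    rad = p0 - c
    norm = float(np.hypot(*rad))
    if norm == 0.0:
        return float("nan")
    return float(np.dot(p1 - p0, rad / norm))


def _boundary_vertex_ids(frame: MeshFrame) -> set[int]:
    ids: set[int] = set()
    for j in frame.heterotypic_junctions():
        ids.add(j.v1)
        ids.add(j.v2)
    return ids


def select_reference_cells(series: TissueTimeSeries, compartment: str = "A",
                           gamma_cutoff: float = GAMMA_SELECT_CUTOFF,
                           selection: str = "initial",
                           window: float = 15.0) -> list[int]:
    """Tracked cells of ``compartment`` passing the γ selection cutoff.

    ``selection="initial"`` uses γ at the first frame (γ0 > cutoff);
    ``selection="max"`` uses the maximum γ within the leading time window.
    """
    chosen = []
    for cid in series.tracked_cells():
        if series.frames[0].cell(cid).compartment != compartment:
            continue
        if selection == "initial":
            g = mixing_index(series.frames[0], cid)
        elif selection == "max":
            n = int(round(window / series.dt)) + 1
            g = max(mixing_index(f, cid) for f in series.frames[:n])
        else:
            raise ValueError(f"unknown selection {selection!r}")
        if np.isfinite(g) and g > gamma_cutoff:
            chosen.append(cid)
    return chosen


def sliding_records(series: TissueTimeSeries, compartment: str = "A",
                    gamma_cutoff: float = GAMMA_SELECT_CUTOFF,
                    selection: str = "initial",
                    segmentations: dict[int, PhaseSegmentation] | None = None,
                    smooth_positions: bool = True,
                    sg_window: int = 5, sg_polyorder: int = 2,
                    ) -> pd.DataFrame:
    """Per boundary vertex per interval: d, d_iso, Δd, phase, γ0.

    One row per (reference cell, boundary vertex, interval).  Reference
    cells without any boundary vertex are skipped and counted in
    ``df.attrs["n_skipped_cells"]``.  With ``smooth_positions`` (default)
    each vertex coordinate series is Savitzky-Golay smoothed before d,
    d_iso, centroid and area ratio are computed.
    """
    from .pulsation_dynamics import smooth_series

    cells = select_reference_cells(series, compartment, gamma_cutoff, selection)
    boundary_sets = [_boundary_vertex_ids(f) for f in series.frames]
    rows, n_skipped = [], 0
    for cid in cells:
        areas = series.cell_area_series(cid)
        seg = (segmentations or {}).get(cid)
        if seg is None:
            seg = detect_phases(areas, series.dt, cell_id=cid)
        ring_ids = series.frames[0].cell(cid).ring
        if smooth_positions and len(series.frames) >= sg_window:
            track = {v: np.column_stack([
                smooth_series([f.vertices[v][k] for f in series.frames],
                              sg_window, sg_polyorder) for k in (0, 1)])
                for v in ring_ids}
        else:
            track = {v: np.array([f.vertices[v] for f in series.frames])
                     for v in ring_ids}
        ring_stack = np.stack([track[v] for v in ring_ids], axis=1)  # (t, ring, 2)
        touched = False
        for i in range(len(series.frames) - 1):
            f0 = series.frames[i]
            a0, c0 = polygon_area_centroid(ring_stack[i])
            a1, _ = polygon_area_centroid(ring_stack[i + 1])
            s = np.sqrt(a1 / a0)
            g0 = mixing_index(f0, cid)
            for k, v in enumerate(ring_ids):
                if v not in boundary_sets[i]:
                    continue
                touched = True
                p0, p1 = ring_stack[i, k], ring_stack[i + 1, k]
                d = radial_displacement(c0, p0, p1)
                if not np.isfinite(d):
                    continue
                d_iso = (s - 1.0) * float(np.hypot(*(p0 - c0)))
                rows.append({"cell": cid, "vertex": v, "frame": i,
                             "phase": seg.phase_of_interval(i),
                             "d": d, "d_iso": d_iso, "delta_d": d - d_iso,
                             "gamma0": g0})
        if not touched:
            n_skipped += 1
    df = pd.DataFrame(rows, columns=["cell", "vertex", "frame", "phase",
                                     "d", "d_iso", "delta_d", "gamma0"])
    df.attrs["n_skipped_cells"] = n_skipped
    return df


def delta_d_phase_stats(series: TissueTimeSeries, compartment: str = "A",
                        gamma_cutoff: float = GAMMA_SELECT_CUTOFF,
                        selection: str = "initial",
                        smooth_positions: bool = True,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-phase mean ± SEM of Δd plus the per-record table.

    Returns ``(summary, records)``; summary rows are the expansion and
    contraction phases with mean, sem and n of Δd.
    """
    records = sliding_records(series, compartment, gamma_cutoff, selection,
                              smooth_positions=smooth_positions)
    rows = []
    for phase in ("expansion", "contraction"):
        vals = records.loc[records["phase"] == phase, "delta_d"].to_numpy()
        n = len(vals)
        rows.append({"phase": phase,
                     "mean": float(np.mean(vals)) if n else float("nan"),
                     "sem": float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
                     "n": n})
    return pd.DataFrame(rows, columns=["phase", "mean", "sem", "n"]), records
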