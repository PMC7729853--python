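"""Boundary-sharpness readouts: boundary angles and the cell mixing index.

Two complementary quantifications of how sharp the A/P compartment interface
is at the cell scale:

* the **boundary angle** θ at each interface vertex — the non-reflex angle
  between the straight chords to its two neighbouring boundary vertices.
  θ = 180° marks a locally straight boundary, small θ a local distortion.
  Vertices are conventionally binned as small (θ < 100°), intermediate
  (100° ≤ θ ≤ 160°) and large (θ > 160°).
* the **cell mixing index** γ — the fraction of a cell's junctional length
  shared with cells of the opposite compartment, among its two-sided
  junctions (tissue-edge junctions are excluded from both numerator and
  denominator).  γ = 0 for an interior cell, γ → 1 for a cell engulfed by
  the other compartment.

Change statistics (Δθ, Δγ over a short interval, 3 min by default) are
computed on raw values; series smoothing is reserved for area and γ time
series in the pulsation analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_geometry import (
    BoundaryPath,
    MeshFrame,
    TissueTimeSeries,
    build_boundary_path,
    junction_length,
    vertex_angle,
)

THETA_SMALL_MAX = 100.0   # degrees; below -> "small" bin
THETA_LARGE_MIN = 160.0   # degrees; above -> "large" bin
GAMMA_BIN_EDGES = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


def theta_bin(theta: float) -> str:
    """Bin a boundary angle: small (<100°), intermediate, large (>160°)."""
    if theta < THETA_SMALL_MAX:
        return "small"
    if theta > THETA_LARGE_MIN:
        return "large"
    return "intermediate"


def gamma_bin(gamma: float) -> str | None:
    """Half-open γ bins [x, x+0.1) labelled ">x"; γ ≥ 0.5 -> ">0.5".

    Cells with γ ≤ 0 (no heterotypic contact) are outside all bins (None).
    """
    if not np.isfinite(gamma) or gamma <= 0.0:
        return None
    idx = min(int(np.floor(gamma * 10.0 + 1e-9)), 5)
    return f">{GAMMA_BIN_EDGES[idx]:g}"


# ---------------------------------------------------------------------------
# boundary angles
# ---------------------------------------------------------------------------

def boundary_angle(frame: MeshFrame, path: BoundaryPath, vertex_id: int) -> float:
    """θ at a boundary vertex: chord angle to its two boundary neighbours.

    Raises ``ValueError`` for a path endpoint (single neighbour), which is
    not measurable.
    """
    prev_v, next_v = path.neighbours(vertex_id)
    return vertex_angle(frame.vertices[prev_v], frame.vertices[vertex_id],
                        frame.vertices[next_v])


def boundary_angle_table(frame: MeshFrame, paths: list[BoundaryPath] | None = None) -> pd.DataFrame:
    """All measurable boundary angles of one frame (columns: vertex, theta, bin)."""
    if paths is None:
        paths = build_boundary_path(frame)
    rows = []
    for path in paths:
        for v in path.interior_vertices():
            th = boundary_angle(frame, path, v)
            rows.append({"vertex": v, "theta": th, "bin": theta_bin(th)})
    return pd.DataFrame(rows, columns=["vertex", "theta", "bin"])


def angle_change_records(series: TissueTimeSeries, interval: float = 3.0) -> pd.DataFrame:
    """Per-vertex Δθ = θ1 − θ0 over ``interval`` minutes, binned by θ0.

    A vertex contributes one record per frame pair in which it is an interior
    boundary vertex at both times; vertices lost to tracking (or no longer on
    the boundary) are excluded and counted in the ``lost`` attribute of the
    returned frame (``df.attrs["n_lost"]``).
    """
    step = interval / series.dt
    if abs(step - round(step)) > 1e-9:
        raise ValueError(f"interval {interval} min is not a multiple of dt={series.dt}")
    step = int(round(step))
    if step < 1:
        raise ValueError("interval must cover at least one frame step")

    per_frame: list[dict[int, float]] = []
    for frame in series.frames:
        thetas: dict[int, float] = {}
        for path in build_boundary_path(frame):
            for v in path.interior_vertices():
                thetas[v] = boundary_angle(frame, path, v)
        per_frame.append(thetas)

    rows, n_lost = [], 0
    for i in range(len(series.frames) - step):
        t0, t1 = per_frame[i], per_frame[i + step]
        for v, th0 in t0.items():
            if v in t1:
                rows.append({"frame": i, "vertex": v, "theta0": th0,
                             "theta1": t1[v], "dtheta": t1[v] - th0,
                             "bin": theta_bin(th0)})
            else:
                n_lost += 1
    df = pd.DataFrame(rows, columns=["frame", "vertex", "theta0", "theta1", "dtheta", "bin"])
    df.attrs["n_lost"] = n_lost
    return df


def angle_change_binned(series: TissueTimeSeries, interval: float = 3.0) -> pd.DataFrame:
    """Per-bin mean, SEM and n of Δθ over ``interval`` minutes."""
    records = angle_change_records(series, interval)
    return _binned_summary(records, "bin", "dtheta",
                           order=["small", "intermediate", "large"])


# ---------------------------------------------------------------------------
# cell mixing index
# ---------------------------------------------------------------------------

def mixing_index(frame: MeshFrame, cell_id: int, length_mode: str = "polyline") -> float:
    """γ: heterotypic fraction of a cell's two-sided junctional length.

    ``length_mode`` selects the junction length measure: ``"polyline"``
    (along the segmented curve, default) or ``"chord"`` (vertex to vertex).
    Returns NaN when the cell has no two-sided junction (undefined).
    """
    cell = frame.cell(cell_id)
    if cell.compartment not in ("A", "P"):
        raise ValueError(f"cell {cell_id} has no A/P compartment label")
    opposite = "P" if cell.compartment == "A" else "A"
    total = hetero = 0.0
    for j in frame.junctions_of_cell(cell_id):
        if j.is_tissue_edge:
            continue
        if length_mode == "polyline":
            length = junction_length(j.polyline)
        elif length_mode == "chord":
            length = junction_length([frame.vertices[j.v1], frame.vertices[j.v2]])
        else:
            raise ValueError(f"unknown length_mode {length_mode!r}")
        total += length
        other = j.other_cell(cell_id)
        if other is not None and frame.has_cell(other) \
                and frame.cell(other).compartment == opposite:
            hetero += length
    if total == 0.0:
        return float("nan")
    return hetero / total


def gamma_table(series: TissueTimeSeries, length_mode: str = "polyline") -> pd.DataFrame:
    """γ for every tracked A/P cell in every frame (frame, cell, gamma)."""
    rows = []
    for i, frame in enumerate(series.frames):
        for cell in frame.cells:
            if cell.compartment in ("A", "P"):
                rows.append({"frame": i, "cell": cell.id,
                             "gamma": mixing_index(frame, cell.id, length_mode)})
    return pd.DataFrame(rows, columns=["frame", "cell", "gamma"])


def gamma_change_records(series: TissueTimeSeries, interval: float = 3.0,
                         length_mode: str = "polyline",
                         smooth: bool = True) -> pd.DataFrame:
    """Per-cell Δγ over ``interval`` minutes, binned by the initial γ.

    With ``smooth`` (default) each fully tracked cell's γ series is
    Savitzky-Golay smoothed before differencing and binning, which damps
    the regression-to-the-mean artifact that selection on a noisy initial γ
    would otherwise impose on the top bins; cells not present in every
    frame keep raw values.
    """
    step = interval / series.dt
    if abs(step - round(step)) > 1e-9:
        raise ValueError(f"interval {interval} min is not a multiple of dt={series.dt}")
    step = int(round(step))

    gam = gamma_table(series, length_mode)
    if smooth:
        from .pulsation_dynamics import SG_WINDOW, smooth_series
        n_frames = len(series.frames)
        if n_frames >= SG_WINDOW:
            parts = []
            for cid, g in gam.groupby("cell"):
                g = g.sort_values("frame")
                vals = g["gamma"].to_numpy()
                if len(g) == n_frames and np.all(np.isfinite(vals)):
                    g = g.assign(gamma=np.clip(smooth_series(vals), 0.0, 1.0))
                parts.append(g)
            gam = pd.concat(parts, ignore_index=True)
    by_frame = {i: dict(zip(g["cell"], g["gamma"]))
                for i, g in gam.groupby("frame")}
    rows, n_lost = [], 0
    for i in range(len(series.frames) - step):
        g0, g1 = by_frame.get(i, {}), by_frame.get(i + step, {})
        for cell, v0 in g0.items():
            if cell not in g1:
                n_lost += 1
                continue
            b = gamma_bin(v0)
            if b is None:
                continue
            rows.append({"frame": i, "cell": cell, "gamma0": v0,
                         "gamma1": g1[cell], "dgamma": g1[cell] - v0, "bin": b})
    df = pd.DataFrame(rows, columns=["frame", "cell", "gamma0", "gamma1", "dgamma", "bin"])
    df.attrs["n_lost"] = n_lost
    return df


def gamma_change_binned(series: TissueTimeSeries, interval: float = 3.0,
                        length_mode: str = "polyline",
                        smooth: bool = True) -> pd.DataFrame:
    """Per-bin mean, SEM and n of Δγ over ``interval`` minutes."""
    records = gamma_change_records(series, interval, length_mode, smooth)
    order = [f">{e:g}" for e in GAMMA_BIN_EDGES]
    return _binned_summary(records, "bin", "dgamma", order=order)


def gamma_trend(times, gammas, window: float = 15.0, start: float | None = None) -> float:
    """OLS slope (per minute) of γ against time within a time window.

    Samples with ``start <= t <= start + window`` are fitted (``start``
    defaults to the first sample time).  Returns NaN with fewer than 3
    samples in the window.
    """
    t = np.asarray(times, dtype=float)
    g = np.asarray(gammas, dtype=float)
    if start is None:
        start = float(t[0]) if len(t) else 0.0
    mask = (t >= start - 1e-9) & (t <= start + window + 1e-9) & np.isfinite(g)
    if mask.sum() < 3:
        return float("nan")
    slope, _ = np.polyfit(t[mask], g[mask], 1)
    return float(slope)


def _binned_summary(records: pd.DataFrame, bin_col: str, value_col: str,
                    order: list[str]) -> pd.DataFrame:
    rows = []
    grouped = dict(iter(records.groupby(bin_col))) if len(records) else {}
    for b in order:
        vals = grouped[b][value_col].to_numpy() if b in grouped else np.array([])
        n = len(vals)
        rows.append({
            "bin": b,
            "mean": float(np.mean(vals)) if n else float("nan"),
            "sem": float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
            "n": n,
        })
    return pd.DataFrame(rows, columns=["bin", "mean", "sem", "n"])
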