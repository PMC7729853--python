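"""Synthetic two-compartment tissues with controlled ground truth.

The generator emulates the statistical structure the boundary analysis
assumes, standing in for segmented time-lapse microscopy of A/P histoblast
nests:

* a hexagonal cell lattice split into an anterior (A) and posterior (P)
  compartment, optionally with *protruding* cells — cells relabelled across
  the interface so they carry a high mixing index γ, the configuration the
  vertex-sliding analysis selects;
* pulsed apical-area oscillation: each cell follows a target area
  ``A0 * (1 + a_i * sin(2π t / T_i + φ_i))`` with per-cell amplitude/period
  jitter and random phase, mimicking asynchronous medial-actomyosin pulses;
* a kinematic update: every vertex moves by the average of its adjacent
  cells' radial sqrt(area-ratio) moves, plus Gaussian positional noise;
* differential adhesion as an explicit bias β: for a boundary vertex of a
  protruding cell whose other adjacent cells all belong to the opposite
  compartment, any outward radial component (which would stretch the
  homotypic contact behind the protrusion) is damped by (1 - β).  β = 0
  gives isotropic, compartment-symmetric dynamics; β > 0 makes pulsation
  productive for boundary smoothing — the effect the Δd statistic detects.

The generator is kinematic (prescribed pulses + biased moves), not a
force-based vertex model, so ground truth (phases, bias, per-cell
parameters) is exact and exactly seeded.  Cell division and T1 transitions
are not modelled.

Raster generators render junction skeletons into intensity images (with
point-spread blur and noise) and build aggregation-assay images with exact
component pixel counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import erf

from .boundary_metrics import boundary_angle, mixing_index
from .core_geometry import (
    CellPoly,
    InvalidGeometryError,
    Junction,
    MeshFrame,
    TissueTimeSeries,
    build_boundary_path,
    polygon_area_centroid,
)
from .intensity_quant import IntensityImage


class SimulationError(RuntimeError):
    """A simulation step produced an invalid (inverted/degenerate) mesh."""


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the synthetic tissue.

    Defaults model a proliferation-phase histoblast nest: ~12 µm² apical
    areas, 6-min pulsation period with ±20 % per-cell jitter, ±20 %
    amplitude jitter, 30-s frames over 18 min, and positional noise of
    0.5 % of the cell diameter.
    """

    rows: int = 8
    cols: int = 8
    split_col: int | None = None          # default: cols // 2
    base_area: float = 12.0               # µm²
    amplitude: float = 0.1                # relative pulse amplitude a
    amplitude_jitter: float = 0.2         # ± fraction, per cell
    period: float = 6.0                   # min
    period_jitter: float = 0.2            # ± fraction, per cell
    adhesion_bias: float = 0.0            # β in [0, 1)
    n_protrusions: int = 2
    gamma_protrude_cutoff: float = 0.5    # γ above which a cell counts as protruding
    noise_sigma: float | None = None      # length units; default 0.5 % of diameter
    dt: float = 0.5                       # min
    duration: float = 18.0                # min
    seed: int = 0
    distortions: tuple = ()               # ((vertex_id, (dx, dy)), ...)
    protrusion_amplitudes: tuple | None = None
    # exact pulse amplitudes assigned to the protruding cells (in id order,
    # cycled), overriding `amplitude`; models fluctuation heterogeneity
    # among the analyzed high-γ cells

    def __post_init__(self) -> None:
        if not 0.0 <= self.adhesion_bias < 1.0:
            raise ValueError("adhesion_bias must be in [0, 1)")
        for name in ("base_area", "period", "dt", "duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def side(self) -> float:
        """Hexagon side length realising ``base_area``."""
        return math.sqrt(2.0 * self.base_area / (3.0 * math.sqrt(3.0)))

    @property
    def sigma(self) -> float:
        if self.noise_sigma is not None:
            return self.noise_sigma
        return 0.005 * 2.0 * math.sqrt(self.base_area / math.pi)


# ---------------------------------------------------------------------------
# lattice construction
# ---------------------------------------------------------------------------

# flat-top hexagon corner offsets, CCW from angle 0, on the half-step grid
_CORNER_DX = (2, 1, -1, -2, -1, 1)     # units of side/2
_CORNER_DY = (0, 1, 1, 0, -1, -1)      # units of sqrt(3)*side/2


def make_lattice(params: SimParams) -> MeshFrame:
    """Hexagonal two-compartment lattice (A left of the split column).

    Cells in ``n_protrusions`` evenly spaced rows of the first P column are
    relabelled to A, creating high-γ protruding cells at the interface.
    Vertex dedup runs on an exact integer half-step grid, so the mesh is
    valid and deterministic.
    """
    rows, cols = params.rows, params.cols
    if rows < 2 or cols < 2:
        raise ValueError("lattice needs rows, cols >= 2")
    split = params.split_col if params.split_col is not None else cols // 2
    s = params.side
    hx, hy = s / 2.0, math.sqrt(3.0) * s / 2.0

    vkeys: dict[tuple[int, int], int] = {}
    rings: dict[int, tuple[int, ...]] = {}
    comps: dict[int, str] = {}

    def vid(key: tuple[int, int]) -> int:
        if key not in vkeys:
            vkeys[key] = len(vkeys)
        return vkeys[key]

    for r in range(rows):
        for c in range(cols):
            cid = r * cols + c
            cx, cy = 3 * c, 2 * r + (c % 2)
            ring = tuple(vid((cx + dx, cy + dy))
                         for dx, dy in zip(_CORNER_DX, _CORNER_DY))
            rings[cid] = ring
            comps[cid] = "A" if c < split else "P"

    if params.n_protrusions > 0 and 0 < split < cols:
        lo, hi = (2, rows - 3) if rows >= 6 else (1, rows - 2)
        prot_rows = sorted({min(max(round((k + 0.5) * rows / params.n_protrusions), lo), hi)
                            for k in range(params.n_protrusions)})
        for r in prot_rows:
            comps[r * cols + split] = "A"

    vertices = {i: np.array([kx * hx, ky * hy])
                for (kx, ky), i in vkeys.items()}
    cells = [CellPoly(cid, comps[cid], rings[cid]) for cid in sorted(rings)]

    edge_cells: dict[frozenset[int], set[int]] = {}
    for cid in sorted(rings):
        ring = rings[cid]
        for a, b in zip(ring, ring[1:] + ring[:1]):
            edge_cells.setdefault(frozenset((a, b)), set()).add(cid)
    junctions = []
    for jid, edge in enumerate(sorted(edge_cells, key=sorted)):
        a, b = sorted(edge)
        junctions.append(Junction(jid, a, b,
                                  np.array([vertices[a], vertices[b]]),
                                  frozenset(edge_cells[edge])))
    return MeshFrame(0.0, vertices, junctions, cells)


def _with_positions(frame: MeshFrame, positions: dict[int, np.ndarray],
                    time: float) -> MeshFrame:
    """Rebuild a frame with the same topology at new vertex positions."""
    junctions = [Junction(j.id, j.v1, j.v2,
                          np.array([positions[j.v1], positions[j.v2]]), j.cells)
                 for j in frame.junctions]
    cells = [CellPoly(c.id, c.compartment, c.ring) for c in frame.cells]
    return MeshFrame(time, {k: np.array(p) for k, p in positions.items()},
                     junctions, cells)


# ---------------------------------------------------------------------------
# kinematic simulation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthLog:
    """Exact per-cell kinematic parameters and phase labels of a run."""

    params: SimParams
    cell_params: pd.DataFrame      # cell, compartment, A0, amplitude, period, phase0
    true_phases: pd.DataFrame      # cell, interval, phase (from the target sine)
    protruding_cells: list[int]    # γ > cutoff at t = 0

    def true_phase(self, cell: int, interval: int) -> str:
        sel = self.true_phases[(self.true_phases["cell"] == cell)
                               & (self.true_phases["interval"] == interval)]
        return sel["phase"].iloc[0]


def simulate(frame0: MeshFrame, params: SimParams) -> tuple[TissueTimeSeries, GroundTruthLog]:
    """Run the kinematic pulsation model from ``frame0``.

    Per step: each cell proposes a radial sqrt(target-ratio) move of its
    vertices about its centroid; a vertex moves by the mean proposal of its
    adjacent cells; outward moves of protruding-cell boundary vertices are
    damped by (1 - β); Gaussian noise is added.  Same seed, same output,
    bit for bit.  A step that would invert a cell raises
    :class:`SimulationError` naming the frame.
    """
    rng = np.random.default_rng(params.seed)
    for vid_, off in params.distortions:
        frame0, _ = inject_distortion(frame0, vid_, off)

    cell_ids = sorted(c.id for c in frame0.cells)
    comp = {c.id: c.compartment for c in frame0.cells}
    jit = params.amplitude_jitter
    amp = {cid: params.amplitude * (1.0 + jit * rng.uniform(-1, 1)) for cid in cell_ids}
    per = {cid: params.period * (1.0 + params.period_jitter * rng.uniform(-1, 1))
           for cid in cell_ids}
    phi = {cid: rng.uniform(0.0, 2.0 * math.pi) for cid in cell_ids}
    area0 = {cid: frame0.cell_area(cid) for cid in cell_ids}

    def target(cid: int, t: float) -> float:
        return area0[cid] * (1.0 + amp[cid] * math.sin(2.0 * math.pi * t / per[cid] + phi[cid]))

    vertex_cells: dict[int, list[int]] = {v: [] for v in frame0.vertices}
    for c in frame0.cells:
        for v in c.ring:
            vertex_cells[v].append(c.id)

    def protruding(frame: MeshFrame) -> list[int]:
        het_cells = {c for j in frame.heterotypic_junctions() for c in j.cells}
        # small tolerance so exact-tie γ (regular lattice) stays below the cutoff
        return sorted(cid for cid in het_cells
                      if np.nan_to_num(mixing_index(frame, cid))
                      > params.gamma_protrude_cutoff + 1e-9)

    n_steps = int(round(params.duration / params.dt))
    frames = [frame0]
    phase_rows = []
    prot0 = protruding(frame0)
    if params.protrusion_amplitudes:
        for i, cid in enumerate(prot0):
            amp[cid] = float(params.protrusion_amplitudes[i % len(params.protrusion_amplitudes)])

    for k in range(n_steps):
        t0, t1 = k * params.dt, (k + 1) * params.dt
        frame = frames[-1]
        geom = {cid: polygon_area_centroid(frame.ring_coords(frame.cell(cid).ring))
                for cid in cell_ids}
        scale = {cid: math.sqrt(max(target(cid, t1), 1e-12) / geom[cid][0])
                 for cid in cell_ids}
        disp = {v: np.zeros(2) for v in frame.vertices}
        for v, cids in vertex_cells.items():
            p = frame.vertices[v]
            moves = [(scale[cid] - 1.0) * (p - geom[cid][1]) for cid in cids]
            disp[v] = np.mean(moves, axis=0)

        if params.adhesion_bias > 0.0:
            for pcid in protruding(frame):
                opp = "P" if comp[pcid] == "A" else "A"
                _, c_p = geom[pcid]
                for v in frame.cell(pcid).ring:
                    others = [c for c in vertex_cells[v] if c != pcid]
                    if not others or any(comp[c] != opp for c in others):
                        continue
                    rad = frame.vertices[v] - c_p
                    norm = float(np.hypot(*rad))
                    if norm == 0.0:
                        continue
                    u = rad / norm
                    rcomp = float(np.dot(disp[v], u))
                    if rcomp > 0.0:
                        disp[v] = disp[v] - params.adhesion_bias * rcomp * u

        noise = rng.normal(0.0, params.sigma, size=(len(disp), 2)) \
            if params.sigma > 0 else np.zeros((len(disp), 2))
        new_pos = {v: frame.vertices[v] + disp[v] + noise[i]
                   for i, v in enumerate(sorted(disp))}
        new_frame = _with_positions(frame, new_pos, t1)
        for cid in cell_ids:
            try:
                polygon_area_centroid(new_frame.ring_coords(new_frame.cell(cid).ring))
            except InvalidGeometryError as e:
                raise SimulationError(f"step to frame {k + 1}: cell {cid}: {e}") from e
        frames.append(new_frame)
        for cid in cell_ids:
            phase_rows.append({"cell": cid, "interval": k,
                               "phase": "expansion" if target(cid, t1) > target(cid, t0)
                               else "contraction"})

    series = TissueTimeSeries(frames, dt=params.dt)
    cell_params = pd.DataFrame(
        [{"cell": cid, "compartment": comp[cid], "A0": area0[cid],
          "amplitude": amp[cid], "period": per[cid], "phase0": phi[cid]}
         for cid in cell_ids])
    log = GroundTruthLog(params, cell_params, pd.DataFrame(phase_rows), prot0)
    return series, log


def run_simulation(params: SimParams) -> tuple[TissueTimeSeries, GroundTruthLog]:
    """Build the lattice for ``params`` and simulate it."""
    return simulate(make_lattice(params), params)


# ---------------------------------------------------------------------------
# local boundary distortion
# ---------------------------------------------------------------------------

def inject_distortion(frame: MeshFrame, vertex_id: int, offset) -> tuple[MeshFrame, float]:
    """Displace a boundary vertex and report the resulting boundary angle θ.

    ``offset`` is a 2-vector in mesh units (displace toward the opposite
    compartment to carve a local distortion).  Raises if the vertex is not
    on the A/P interface or if the move self-intersects an adjacent cell.
    Returns ``(new_frame, theta)``; θ is NaN when the vertex ends up as a
    path endpoint.
    """
    het_vertices = {v for j in frame.heterotypic_junctions() for v in (j.v1, j.v2)}
    if vertex_id not in het_vertices:
        raise ValueError(f"vertex {vertex_id} is not on the compartment boundary")
    positions = {v: np.array(p) for v, p in frame.vertices.items()}
    positions[vertex_id] = positions[vertex_id] + np.asarray(offset, dtype=float)
    new_frame = _with_positions(frame, positions, frame.time)
    for c in new_frame.cells:
        if vertex_id in c.ring:
            polygon_area_centroid(new_frame.ring_coords(c.ring))  # raises if invalid
    theta = float("nan")
    for path in build_boundary_path(new_frame):
        if vertex_id in path.interior_vertices():
            theta = boundary_angle(new_frame, path, vertex_id)
            break
    return new_frame, theta


# ---------------------------------------------------------------------------
# raster generators
# ---------------------------------------------------------------------------

def synth_intensity_image(frame: MeshFrame,
                          junction_intensities: dict[int, float] | float = 1.0,
                          pixel_scale: float = 10.0,
                          psf_sigma: float = 1.0,
                          noise_sigma: float = 0.0,
                          margin_px: int = 6,
                          rng: np.random.Generator | None = None,
                          ) -> tuple[IntensityImage, pd.DataFrame]:
    """Render junction polylines into an intensity raster.

    Junctions are rendered as analytically Gaussian-blurred lines: a
    segment painted at intensity v contributes
    ``v * exp(-d_perp^2 / (2 psf_sigma^2))`` scaled by an erf coverage term
    along the segment axis, so the cross-section profile is the exact 1-D
    Gaussian convolution of an ideal line and is independent of the
    segment's orientation (no rasterisation anisotropy).  Overlapping
    junctions combine by maximum (at shared vertices the brighter junction
    dominates, as in a cortical marker).  Gaussian noise is added last
    (clipped at zero).  Returns the image and the ground-truth per-junction
    intensity table.
    """
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be positive")
    coords = np.array(list(frame.vertices.values()))
    origin = coords.min(axis=0) - margin_px / pixel_scale
    extent = (coords.max(axis=0) - origin) * pixel_scale + margin_px
    w, h = int(math.ceil(extent[0])) + 1, int(math.ceil(extent[1])) + 1
    img = np.zeros((h, w))
    if not isinstance(junction_intensities, dict):
        junction_intensities = {j.id: float(junction_intensities) for j in frame.junctions}
    sig = max(float(psf_sigma), 1e-3)
    reach = int(math.ceil(4 * sig)) + 1
    rows = []
    for j in frame.junctions:
        val = junction_intensities.get(j.id, 0.0)
        rows.append({"junction": j.id, "intensity": val})
        if val == 0.0:
            continue
        px = (j.polyline - origin) * pixel_scale
        for p0, p1 in zip(px, px[1:]):
            seg = p1 - p0
            seg_len = float(np.hypot(*seg))
            if seg_len == 0.0:
                continue
            u = seg / seg_len
            x0 = max(int(math.floor(min(p0[0], p1[0]) - reach)), 0)
            x1 = min(int(math.ceil(max(p0[0], p1[0]) + reach)), w - 1)
            y0 = max(int(math.floor(min(p0[1], p1[1]) - reach)), 0)
            y1 = min(int(math.ceil(max(p0[1], p1[1]) + reach)), h - 1)
            xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
            rel = np.stack([xs - p0[0], ys - p0[1]], axis=-1)
            t = rel @ u                      # along-axis coordinate
            d = rel @ np.array([-u[1], u[0]])  # perpendicular distance
            prof = np.exp(-0.5 * (d / sig) ** 2)
            cover = 0.5 * (erf(t / (math.sqrt(2) * sig))
                           - erf((t - seg_len) / (math.sqrt(2) * sig)))
            patch = val * prof * cover
            img[y0:y1 + 1, x0:x1 + 1] = np.maximum(img[y0:y1 + 1, x0:x1 + 1], patch)
    if noise_sigma > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        img = np.clip(img + rng.normal(0.0, noise_sigma, img.shape), 0.0, None)
    image = IntensityImage(img, pixel_scale=pixel_scale, origin=origin)
    return image, pd.DataFrame(rows, columns=["junction", "intensity"])


def synth_aggregate_image(component_sizes, shape=(200, 200), gap: int = 3,
                          seed: int = 0) -> tuple[IntensityImage, list[int]]:
    """Binary image with non-touching components of exact pixel counts.

    Components are near-square blocks (last row partially filled, so each
    stays 4-connected) placed on a grid with ``gap`` background pixels
    between them; placement order is shuffled by ``seed``.  Raises when the
    canvas cannot hold all components without contact.
    """
    rng = np.random.default_rng(seed)
    sizes = [int(s) for s in component_sizes]
    order = list(rng.permutation(len(sizes)))
    img = np.zeros(shape)
    x, y, band = gap, gap, 0
    for idx in order:
        size = sizes[idx]
        wdt = int(math.ceil(math.sqrt(size)))
        hgt = int(math.ceil(size / wdt))
        if x + wdt + gap > shape[1]:
            x, y = gap, y + band + gap
            band = 0
        if y + hgt + gap > shape[0]:
            raise ValueError("cannot place components without contact; enlarge canvas")
        remaining = size
        for r in range(hgt):
            n = min(wdt, remaining)
            img[y + r, x:x + n] = 1.0
            remaining -= n
        x += wdt + gap
        band = max(band, hgt)
    return IntensityImage(img, pixel_scale=1.0), sizes
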