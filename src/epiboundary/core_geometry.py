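"""Geometric primitives and mesh containers for epithelial cell meshes.

The analysis operates on segmented, tracked apical cell meshes: vertices
(tricellular points), junctions (cell-cell interfaces, possibly curved
polylines), and cell polygons carrying a compartment label (anterior ``A``,
posterior ``P``, or ``other``).  Coordinates are continuous 2-D lengths in a
unit declared per dataset (micrometres by default); mesh space never uses
pixel/array indexing.

Cell rings are stored counter-clockwise; orientation is normalised when a
:class:`MeshFrame` is constructed.  Junctions bordering a single cell are
tissue-edge junctions (the mesh abuts cells that were not segmented) and are
excluded from compartment-interface logic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString as _ShapelyLineString
from shapely.geometry import Polygon as _ShapelyPolygon


class InvalidGeometryError(ValueError):
    """A ring or polyline violates a geometric precondition."""


class NoBoundaryError(ValueError):
    """The mesh contains no heterotypic (A|P) junction."""


COMPARTMENTS = ("A", "P", "other")


def _as_coords(points) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidGeometryError(f"expected (n, 2) coordinates, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidGeometryError("non-finite coordinates")
    return arr


# ---------------------------------------------------------------------------
# scalar geometry
# ---------------------------------------------------------------------------

def signed_polygon_area(ring) -> float:
    """Shoelace signed area; positive for counter-clockwise rings."""
    r = _as_coords(ring)
    x, y = r[:, 0], r[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_area_centroid(ring) -> tuple[float, np.ndarray]:
    """Area and area-centroid of a simple polygon ring.

    Orientation is normalised: the returned area is positive regardless of
    the winding of ``ring``.  Degenerate (zero-area) or self-intersecting
    rings raise :class:`InvalidGeometryError`.
    """
    r = _as_coords(ring)
    if len(r) < 3:
        raise InvalidGeometryError("polygon needs at least 3 points")
    a = signed_polygon_area(r)
    closed = np.vstack([r, r[:1]])
    if not _ShapelyLineString(closed).is_simple or (a != 0.0 and not _ShapelyPolygon(r).is_valid):
        raise InvalidGeometryError("self-intersecting ring")
    if a == 0.0:
        raise InvalidGeometryError("degenerate (zero-area) ring")
    x, y = r[:, 0], r[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    cx = float(np.sum((x + xn) * cross)) / (6.0 * a)
    cy = float(np.sum((y + yn) * cross)) / (6.0 * a)
    return abs(a), np.array([cx, cy])


def junction_length(polyline) -> float:
    """Total arc length of a polyline (sum of segment lengths)."""
    p = _as_coords(polyline)
    if len(p) < 2:
        raise InvalidGeometryError("polyline needs at least 2 points")
    return float(np.sum(np.hypot(*(np.diff(p, axis=0).T))))


def vertex_angle(p_prev, v, p_next) -> float:
    """Non-reflex angle (degrees, in (0, 180]) at ``v`` between its two arms.

    Returns 180 for collinear arms pointing in opposite directions (a locally
    straight configuration).  Zero-length arms are invalid.
    """
    a = np.asarray(p_prev, dtype=float) - np.asarray(v, dtype=float)
    b = np.asarray(p_next, dtype=float) - np.asarray(v, dtype=float)
    na, nb = np.hypot(*a), np.hypot(*b)
    if na == 0.0 or nb == 0.0:
        raise InvalidGeometryError("zero-length arm at vertex")
    cosang = float(np.dot(a, b) / (na * nb))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


# ---------------------------------------------------------------------------
# mesh containers
# ---------------------------------------------------------------------------

@dataclass
class Junction:
    """A cell-cell interface between two vertices.

    ``cells`` holds 1 or 2 adjacent cell ids; a single-cell junction lies on
    the tissue edge.  ``polyline`` runs from vertex ``v1`` to vertex ``v2``
    and may be curved (>2 points).
    """

    id: int
    v1: int
    v2: int
    polyline: np.ndarray
    cells: frozenset[int]

    def __post_init__(self) -> None:
        self.polyline = _as_coords(self.polyline)
        self.cells = frozenset(self.cells)
        if not 1 <= len(self.cells) <= 2:
            raise ValueError(f"junction {self.id}: needs 1-2 adjacent cells")

    @property
    def is_tissue_edge(self) -> bool:
        return len(self.cells) == 1

    @property
    def length(self) -> float:
        return junction_length(self.polyline)

    def other_cell(self, cell_id: int) -> int | None:
        rest = self.cells - {cell_id}
        return next(iter(rest)) if len(rest) == 1 else None


@dataclass
class CellPoly:
    """A cell's apical polygon: compartment label plus a CCW vertex ring."""

    id: int
    compartment: str
    ring: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"cell {self.id}: unknown compartment {self.compartment!r}")
        self.ring = tuple(int(v) for v in self.ring)
        if len(self.ring) < 3:
            raise ValueError(f"cell {self.id}: ring needs >=3 vertices")


@dataclass
class MeshFrame:
    """One time point of the tissue mesh.

    ``time`` is in minutes; vertex coordinates in the dataset's declared
    length unit.  Cell ring orientation is normalised to counter-clockwise on
    construction (when the ring resolves to valid coordinates).
    """

    time: float
    vertices: dict[int, np.ndarray]
    junctions: list[Junction]
    cells: list[CellPoly]

    _cell_index: dict = field(default=None, repr=False, compare=False)
    _cell_junctions: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = {int(k): np.asarray(v, dtype=float) for k, v in self.vertices.items()}
        for cell in self.cells:
            if all(v in self.vertices for v in cell.ring):
                if signed_polygon_area(self.ring_coords(cell.ring)) < 0:
                    cell.ring = cell.ring[::-1]
        self._cell_index = {c.id: c for c in self.cells}
        self._cell_junctions = {c.id: [] for c in self.cells}
        for j in self.junctions:
            for cid in j.cells:
                if cid in self._cell_junctions:
                    self._cell_junctions[cid].append(j)

    # -- lookups ------------------------------------------------------------
    def cell(self, cell_id: int) -> CellPoly:
        return self._cell_index[cell_id]

    def has_cell(self, cell_id: int) -> bool:
        return cell_id in self._cell_index

    def junctions_of_cell(self, cell_id: int) -> list[Junction]:
        return self._cell_junctions[cell_id]

    def ring_coords(self, ring) -> np.ndarray:
        return np.array([self.vertices[v] for v in ring])

    def cell_area(self, cell_id: int) -> float:
        area, _ = polygon_area_centroid(self.ring_coords(self.cell(cell_id).ring))
        return area

    def cell_centroid(self, cell_id: int) -> np.ndarray:
        _, c = polygon_area_centroid(self.ring_coords(self.cell(cell_id).ring))
        return c

    def heterotypic_junctions(self) -> list[Junction]:
        """Two-sided junctions separating an A cell from a P cell."""
        out = []
        for j in self.junctions:
            if j.is_tissue_edge:
                continue
            comps = {self.cell(c).compartment for c in j.cells if self.has_cell(c)}
            if comps == {"A", "P"}:
                out.append(j)
        return out


@dataclass
class TissueTimeSeries:
    """Tracked sequence of mesh frames at a constant frame interval.

    Entity ids (vertices, junctions, cells) are persistent across frames:
    an id present in several frames denotes the same tracked entity.  ``dt``
    is the frame interval in minutes; ``stage`` tags the developmental phase
    (nest fusion, proliferation, or tissue elongation).
    """

    frames: list[MeshFrame]
    dt: float
    stage: str = "proliferation"
    unit: str = "um"

    def __post_init__(self) -> None:
        if self.stage not in ("fusion", "proliferation", "elongation"):
            raise ValueError(f"unknown stage {self.stage!r}")
        times = [f.time for f in self.frames]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("frames must be strictly time-ordered")
        if times and not np.allclose(np.diff(times), self.dt, rtol=0, atol=1e-9):
            raise ValueError("frame times inconsistent with dt")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def tracked_cells(self) -> list[int]:
        """Cell ids present in every frame."""
        ids = set(self.frames[0]._cell_index)
        for f in self.frames[1:]:
            ids &= set(f._cell_index)
        return sorted(ids)

    def cell_area_series(self, cell_id: int) -> np.ndarray:
        return np.array([f.cell_area(cell_id) for f in self.frames])


# ---------------------------------------------------------------------------
# compartment boundary extraction
# ---------------------------------------------------------------------------

@dataclass
class BoundaryPath:
    """A maximal chain of heterotypic junctions along the A/P interface.

    ``vertex_ids`` is ordered end-to-end; ``junctions[i]`` links
    ``vertex_ids[i]`` and ``vertex_ids[i+1]``.  For a closed loop the first
    vertex is repeated at the end.
    """

    vertex_ids: list[int]
    junctions: list[Junction]
    closed: bool

    def __len__(self) -> int:
        return len(self.junctions)

    def interior_vertices(self) -> list[int]:
        """Vertices with two boundary neighbours (angle-measurable)."""
        if self.closed:
            return list(self.vertex_ids[:-1])
        return list(self.vertex_ids[1:-1])

    def neighbours(self, vertex_id: int) -> tuple[int, int]:
        seq = self.vertex_ids[:-1] if self.closed else self.vertex_ids
        i = seq.index(vertex_id)
        if self.closed:
            return seq[i - 1], seq[(i + 1) % len(seq)]
        if i == 0 or i == len(seq) - 1:
            raise ValueError(f"vertex {vertex_id} is a boundary endpoint")
        return seq[i - 1], seq[i + 1]


def build_boundary_path(frame: MeshFrame) -> list[BoundaryPath]:
    """Extract the A/P interface as maximal paths of heterotypic junctions.

    Each returned junction borders exactly one A and one P cell.  Open paths
    are oriented with the lexicographically lowest-coordinate endpoint first;
    closed loops start at their lowest-coordinate vertex and proceed toward
    the lower-coordinate neighbour.  Output is independent of junction-list
    order; at a branch point (vertex with >2 boundary junctions) paths are
    split so each stays simple.
    """
    het = frame.heterotypic_junctions()
    if not het:
        raise NoBoundaryError("mesh has no A|P junction")

    adj: dict[int, list[Junction]] = {}
    for j in het:
        adj.setdefault(j.v1, []).append(j)
        adj.setdefault(j.v2, []).append(j)

    def coord_key(v: int) -> tuple[float, float]:
        x, y = frame.vertices[v]
        return (float(x), float(y))

    ends = sorted((v for v, js in adj.items() if len(js) != 2), key=coord_key)
    used: set[int] = set()
    paths: list[BoundaryPath] = []

    def walk(start: int, first: Junction) -> tuple[list[int], list[Junction]]:
        verts, juncs = [start], []
        v, j = start, first
        while True:
            used.add(j.id)
            juncs.append(j)
            v = j.v2 if j.v1 == v else j.v1
            verts.append(v)
            nxt = [k for k in adj[v] if k.id not in used]
            if len(adj[v]) != 2 or not nxt:
                return verts, juncs
            j = nxt[0]

    # open (or branched) chains first, from every non-degree-2 endpoint
    for end in ends:
        for j in sorted(adj[end], key=lambda k: coord_key(k.v2 if k.v1 == end else k.v1)):
            if j.id in used:
                continue
            verts, juncs = walk(end, j)
            if coord_key(verts[-1]) < coord_key(verts[0]):
                verts, juncs = verts[::-1], juncs[::-1]
            paths.append(BoundaryPath(verts, juncs, closed=False))

    # remaining junctions form pure cycles
    remaining = {v for v, js in adj.items() if any(j.id not in used for j in js)}
    while remaining:
        start = min(remaining, key=coord_key)
        nbrs = sorted((j for j in adj[start] if j.id not in used),
                      key=lambda k: coord_key(k.v2 if k.v1 == start else k.v1))
        verts, juncs = walk(start, nbrs[0])
        paths.append(BoundaryPath(verts, juncs, closed=verts[0] == verts[-1]))
        remaining = {v for v in remaining if any(j.id not in used for j in adj[v])}

    paths.sort(key=lambda p: coord_key(p.vertex_ids[0]))
    return paths


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    issues: list[str]

    @property
    def ok(self) -> bool:
        return not self.issues

    def __str__(self) -> str:
        return "mesh OK" if self.ok else "\n".join(self.issues)


def validate_mesh(frame: MeshFrame) -> ValidationReport:
    """Report every mesh-invariant violation (empty report iff all hold).

    Checks: finite coordinates; junction endpoints resolve and coincide with
    the polyline ends; positive junction length; junction/cell adjacency
    consistency; rings resolve, are simple and have positive area.
    """
    issues: list[str] = []
    for vid, p in frame.vertices.items():
        if not np.all(np.isfinite(p)):
            issues.append(f"vertex {vid}: non-finite coordinates")

    cell_ids = {c.id for c in frame.cells}
    for j in frame.junctions:
        for v in (j.v1, j.v2):
            if v not in frame.vertices:
                issues.append(f"junction {j.id}: dangling vertex {v}")
        missing = j.cells - cell_ids
        if missing:
            issues.append(f"junction {j.id}: unknown adjacent cell(s) {sorted(missing)}")
        if j.v1 in frame.vertices and j.v2 in frame.vertices:
            for v, end in ((j.v1, j.polyline[0]), (j.v2, j.polyline[-1])):
                if not np.allclose(frame.vertices[v], end, atol=1e-9):
                    issues.append(f"junction {j.id}: polyline end off vertex {v}")
            if junction_length(j.polyline) <= 0:
                issues.append(f"junction {j.id}: zero length")

    for cell in frame.cells:
        missing = [v for v in cell.ring if v not in frame.vertices]
        if missing:
            issues.append(f"cell {cell.id}: missing ring vertices {missing}")
            continue
        ring = frame.ring_coords(cell.ring)
        try:
            polygon_area_centroid(ring)
        except InvalidGeometryError as e:
            issues.append(f"cell {cell.id}: {e}")
            continue
        # every ring edge must be realised by a junction adjacent to the cell
        edges = {frozenset(e) for e in zip(cell.ring, cell.ring[1:] + cell.ring[:1])}
        junc_edges = {frozenset((j.v1, j.v2)) for j in frame.junctions_of_cell(cell.id)}
        for e in sorted(edges - junc_edges, key=sorted):
            issues.append(f"cell {cell.id}: ring edge {sorted(e)} has no junction")

    return ValidationReport(issues)
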