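"""Raster-based quantifications around the compartment boundary.

Covers four image-derived readouts:

* junctional signal intensity as the mean over a wide line profile drawn on
  a junction (3-px wide for junctional Myosin II, 7-px for receptor
  recruitment), with two normalisation schemes for boundary enrichment;
* actomyosin-cable alignment of consecutive boundary-junction triplets
  (J1-J3): *aligned* when either internal boundary angle is >= 130 degrees,
  *misaligned* otherwise;
* the cell-aggregation assay quantifier: fraction of thresholded object
  area in components larger than 1000 px, among components larger than
  25 px (both strict inequalities);
* laser-ablation recoil: initial vertex-separation velocity from 500-ms
  frames, correlated against the pre-ablation boundary angle.

Image coordinates are (x, y) = (column, row) pixel units with pixel centers
at integer coordinates; mesh coordinates are mapped in with an origin and a
pixel scale (px per length unit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import stats as _stats
from shapely.geometry import LineString
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label

from .boundary_metrics import boundary_angle
from .core_geometry import BoundaryPath, Junction, MeshFrame, build_boundary_path

ALIGNED_ANGLE_CUTOFF = 130.0   # degrees, >= is "aligned"
MYOSIN_WIDTH_PX = 3
RECRUITMENT_WIDTH_PX = 7
OBJECT_MIN_PX = 25             # strictly larger -> counted as cell/aggregate
LARGE_MIN_PX = 1000            # strictly larger -> "large aggregate"
ABLATION_DT_S = 0.5


@dataclass
class IntensityImage:
    """2-D raster of nonnegative intensities with a pixel scale (px per unit)."""

    pixels: np.ndarray
    pixel_scale: float = 1.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("intensity image must be 2-D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("non-finite pixel values")

    def to_pixel_coords(self, points) -> np.ndarray:
        """Map mesh coordinates (length units) to (x, y) pixel coordinates."""
        return (np.asarray(points, dtype=float) - self.origin) * self.pixel_scale


def _as_image(image) -> IntensityImage:
    return image if isinstance(image, IntensityImage) else IntensityImage(image)


# ---------------------------------------------------------------------------
# wide-line profiles
# ---------------------------------------------------------------------------

def junction_profile_intensity(image, polyline_px, width_px: int) -> float:
    """Mean intensity over a ``width_px``-wide line drawn on a polyline.

    A pixel contributes (once) when its center lies within ``width_px / 2``
    of the polyline (Euclidean distance, so corners are not double counted).
    ``polyline_px`` is in (x, y) pixel coordinates and must lie inside the
    image; ``width_px`` must be odd.
    """
    img = _as_image(image).pixels
    line = np.asarray(polyline_px, dtype=float)
    if width_px % 2 == 0 or width_px < 1:
        raise ValueError("profile width must be a positive odd pixel count")
    h, w = img.shape
    if (line[:, 0].min() < 0 or line[:, 0].max() > w - 1
            or line[:, 1].min() < 0 or line[:, 1].max() > h - 1):
        raise ValueError("polyline outside image bounds")
    geom = LineString(line) if len(line) > 1 else shapely.points(line[0])
    half = width_px / 2.0
    x0 = max(int(np.floor(line[:, 0].min() - half)), 0)
    x1 = min(int(np.ceil(line[:, 0].max() + half)), w - 1)
    y0 = max(int(np.floor(line[:, 1].min() - half)), 0)
    y1 = min(int(np.ceil(line[:, 1].max() + half)), h - 1)
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    pts = shapely.points(np.column_stack([xs.ravel(), ys.ravel()]))
    dist = shapely.distance(pts, geom)
    mask = dist <= half
    if not np.any(mask):
        raise ValueError("profile covers no pixel center")
    return float(img[ys.ravel()[mask], xs.ravel()[mask]].mean())


# ---------------------------------------------------------------------------
# boundary enrichment
# ---------------------------------------------------------------------------

def _junction_px(image: IntensityImage, frame: MeshFrame, j: Junction) -> np.ndarray:
    return image.to_pixel_coords(j.polyline)


def myosin_boundary_enrichment(frame: MeshFrame, image,
                               width_px: int = MYOSIN_WIDTH_PX,
                               n_normalizer: int = 10) -> pd.DataFrame:
    """Relative junctional intensity on the boundary, both normalisations.

    For every heterotypic (boundary) junction:

    * ``boundary_vs_side`` — boundary-junction mean divided by the average
      of the per-side means of non-boundary junctions one cell row away
      (junctions of boundary-adjacent cells lying fully within A, resp. P);
    * ``ten_junction`` — boundary-junction mean divided by the mean of up to
      ``n_normalizer`` non-boundary junctions of its two adjacent cells
      (fewer available -> all are used; see the ``n_norm`` column).

    Returns one row per (junction, scheme) with mean and relative intensity.
    """
    img = _as_image(image)
    paths = build_boundary_path(frame)
    boundary = [j for p in paths for j in p.junctions]
    boundary_ids = {j.id for j in boundary}
    prof = {j.id: junction_profile_intensity(img, _junction_px(img, frame, j), width_px)
            for j in boundary}

    # one cell row away per side: non-boundary junctions of boundary-adjacent
    # cells whose adjacent cells all lie in a single compartment
    side_vals: dict[str, list[float]] = {"A": [], "P": []}
    seen: set[int] = set()
    flank_cells = {c for j in boundary for c in j.cells}
    for cid in sorted(flank_cells):
        if not frame.has_cell(cid):
            continue
        for j in frame.junctions_of_cell(cid):
            if j.id in boundary_ids or j.id in seen or j.is_tissue_edge:
                continue
            comps = {frame.cell(c).compartment for c in j.cells if frame.has_cell(c)}
            if len(comps) == 1 and comps <= {"A", "P"}:
                seen.add(j.id)
                side_vals[comps.pop()].append(
                    junction_profile_intensity(img, _junction_px(img, frame, j), width_px))
    side_means = [np.mean(v) for v in side_vals.values() if v]
    side_norm = float(np.mean(side_means)) if side_means else float("nan")

    rows = []
    for j in boundary:
        rows.append({"junction": j.id, "scheme": "boundary_vs_side",
                     "mean_intensity": prof[j.id],
                     "relative_intensity": prof[j.id] / side_norm if side_norm and np.isfinite(side_norm) else float("nan"),
                     "n_norm": sum(len(v) for v in side_vals.values())})
        cand = []
        for cid in sorted(j.cells):
            if not frame.has_cell(cid):
                continue
            for k in frame.junctions_of_cell(cid):
                if k.id not in boundary_ids and not k.is_tissue_edge and k.id not in {c[0] for c in cand}:
                    cand.append((k.id, k))
        cand.sort(key=lambda t: t[0])
        chosen = cand[:n_normalizer]
        vals = [junction_profile_intensity(img, _junction_px(img, frame, k), width_px)
                for _, k in chosen]
        norm = float(np.mean(vals)) if vals else float("nan")
        rows.append({"junction": j.id, "scheme": "ten_junction",
                     "mean_intensity": prof[j.id],
                     "relative_intensity": prof[j.id] / norm if norm and np.isfinite(norm) else float("nan"),
                     "n_norm": len(vals)})
    return pd.DataFrame(rows, columns=["junction", "scheme", "mean_intensity",
                                       "relative_intensity", "n_norm"])


# ---------------------------------------------------------------------------
# cable alignment (J1-J3 triplets)
# ---------------------------------------------------------------------------

def cable_alignment_score(frame: MeshFrame, path: BoundaryPath,
                          relative_intensity: dict[int, float]) -> pd.DataFrame:
    """Sliding J1-J3 triplets along a boundary path, classed by alignment.

    A triplet is *aligned* when either of its two internal boundary angles
    is >= 130 degrees.  ``relative_intensity`` maps junction id to its
    (already normalised) intensity; the triplet score is the arithmetic mean
    over J1-J3.  A path with fewer than 3 junctions yields an empty table.
    """
    rows = []
    for i in range(len(path.junctions) - 2):
        triplet = path.junctions[i:i + 3]
        shared = path.vertex_ids[i + 1:i + 3]
        angles = [boundary_angle(frame, path, v) for v in shared]
        aligned = any(a >= ALIGNED_ANGLE_CUTOFF for a in angles)
        rows.append({"j1": triplet[0].id, "j2": triplet[1].id, "j3": triplet[2].id,
                     "angle1": angles[0], "angle2": angles[1],
                     "alignment": "aligned" if aligned else "misaligned",
                     "mean_relative_intensity":
                         float(np.mean([relative_intensity[j.id] for j in triplet]))})
    return pd.DataFrame(rows, columns=["j1", "j2", "j3", "angle1", "angle2",
                                       "alignment", "mean_relative_intensity"])


# ---------------------------------------------------------------------------
# aggregation assay
# ---------------------------------------------------------------------------

@dataclass
class AggregateResult:
    component_sizes: np.ndarray   # px, all components above the object cutoff
    n_objects: int
    large_fraction: float         # NaN when no object passes the cutoff
    weighting: str                # "area" | "count"


def aggregate_fraction(image, threshold: float | None = None,
                       connectivity: int = 2,
                       weighting: str = "area") -> AggregateResult:
    """Large-aggregate fraction of a thresholded cell-aggregation image.

    Components (8-connected by default) strictly larger than 25 px count as
    cells/aggregates; those strictly larger than 1000 px are large
    aggregates.  ``weighting="area"`` (default) returns large-aggregate
    pixel area over total object pixel area; ``"count"`` returns the object
    count ratio.  ``threshold=None`` uses Otsu's method.
    """
    img = _as_image(image).pixels
    if threshold is None:
        threshold = threshold_otsu(img)
    binary = img > threshold
    labels = _cc_label(binary, connectivity=connectivity)
    sizes = np.bincount(labels.ravel())[1:]
    objects = sizes[sizes > OBJECT_MIN_PX]
    if objects.size == 0:
        return AggregateResult(objects, 0, float("nan"), weighting)
    large = objects[objects > LARGE_MIN_PX]
    if weighting == "area":
        frac = float(large.sum() / objects.sum())
    elif weighting == "count":
        frac = float(large.size / objects.size)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return AggregateResult(objects, int(objects.size), frac, weighting)


# ---------------------------------------------------------------------------
# laser-ablation recoil
# ---------------------------------------------------------------------------

@dataclass
class RecoilRecord:
    """Vertex-separation series after ablating one boundary junction.

    ``separations[0]`` is the pre-ablation vertex separation; subsequent
    entries are sampled every ``dt_s`` seconds (500 ms) after ablation.
    ``theta`` is the pre-ablation boundary angle between the ablated
    junction and its connected junction, in degrees.
    """

    theta: float
    separations: np.ndarray
    dt_s: float = ABLATION_DT_S

    def __post_init__(self) -> None:
        self.separations = np.asarray(self.separations, dtype=float)

    @property
    def initial_velocity(self) -> float:
        return float((self.separations[1] - self.separations[0]) / self.dt_s)


def recoil_velocity_stats(records: list[RecoilRecord]) -> tuple[pd.DataFrame, float, float]:
    """Initial recoil velocities and their Pearson correlation with θ.

    Records with fewer than 2 separation samples are skipped and counted
    (``df.attrs["n_skipped"]``).  Returns ``(per_record, r, p)``.
    """
    rows, n_skipped = [], 0
    for rec in records:
        if len(rec.separations) < 2:
            n_skipped += 1
            continue
        rows.append({"theta": rec.theta, "initial_velocity": rec.initial_velocity})
    df = pd.DataFrame(rows, columns=["theta", "initial_velocity"])
    df.attrs["n_skipped"] = n_skipped
    if len(df) >= 2 and df["theta"].nunique() > 1:
        r, p = _stats.pearsonr(df["theta"], df["initial_velocity"])
    else:
        r, p = float("nan"), float("nan")
    return df, float(r), float(p)
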