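# Methods

This note documents the models, conventions and numerical choices behind
`epiboundary`, in the order the pipeline runs.

## Mesh model and geometry

A tissue frame is a planar cell mesh: vertices (2-D points in a declared
length unit, µm by default), junctions (polylines between two vertices,
bordering one or two cells), and cell polygons stored as counter-clockwise
vertex rings with a compartment label A, P or `other`.  Orientation is
normalised at construction; areas and centroids come from the shoelace
formula, with shapely used to reject self-intersecting rings.  Junctions
bordering a single cell are tissue-edge junctions: the histoblast nest
abuts larval cells that are not part of the mesh, so these interfaces are
neither homotypic nor heterotypic and are excluded from all
compartment-interface logic.

The A/P boundary is the set of junctions separating an A from a P cell,
assembled into maximal end-to-end paths.  Orientation is deterministic
(lexicographically lowest endpoint first; loops start at their lowest
vertex), so path output is independent of junction-list order.  Boundary
angles use straight chords between consecutive boundary vertices, not the
curved junction polylines, and are non-reflex (in (0°, 180°]); all printed
thresholds (100°, 130°, 160°) live on that scale.  Bin edges: small
θ < 100°, intermediate 100° ≤ θ ≤ 160°, large θ > 160°.

## Mixing index γ

γ(cell) = (length of its junctions whose far side is the opposite
compartment) / (length of all its two-sided junctions).  Junction length is
measured along the polyline by default; a vertex-to-vertex chord mode is
available because segmentation exports differ in whether curves are
preserved.  Cells with only tissue-edge junctions have undefined γ (NaN).
Δγ over a 3-min interval is binned by initial γ into half-open bins
[x, x+0.1) labelled ">x" (x = 0 … 0.4) plus ">0.5" for γ ≥ 0.5; cells with
γ = 0 are outside all bins.  For change and trend statistics, each fully
tracked cell's γ series is Savitzky–Golay smoothed first (segmentation
noise otherwise injects a regression-to-the-mean artifact into the top
bins, because cells enter the ">0.5" bin preferentially on upward noise
excursions); raw values are available with `smooth=False`.  The mixing
trend is the OLS slope of γ against time in a 15-min window, requiring at
least 3 samples.

## Pulsation phases and the fluctuation degree

Apical-area series are smoothed with a Savitzky–Golay filter, window
5 frames, polynomial order 2, mirror-padded edges — the shortest window
that reproduces quadratic pulse peaks exactly at the default sampling.
Extrema are sign changes of the first difference of the smoothed series,
classified min/max by the second difference; flat plateaus resolve to their
middle frame; extrema closer than 2 frames are merged keeping the one
deviating more from the series median; strict min/max alternation is
enforced by dropping the lesser of same-kind neighbours.  Intervals inside
a min → max run are *expansion*, all others *contraction*; runs before the
first and after the last extremum are labelled by their slope
(rising → expansion), which makes time reversal swap the labels exactly.
Series ends cannot host extrema (no sign change is observable there), so
windows should extend a couple of frames past the interval of interest.

The degree of area fluctuation over a 15-min window is

    F = f · Σ|ΔA| / Ā

where Σ|ΔA| sums absolute area changes between adjacent extrema in the
window, Ā is the window's time-average area, and the frequency f counts
complete pulse cycles in the window — adjacent-extrema pairs are
half-cycles, so f = (pairs)/2.  The per-window cycle count (rather than a
per-minute rate) keeps F dimensionless, and under it the conventional 0.6
cutoff separates strongly pulsing cells (relative amplitude ≈ 0.1,
2–3 cycles per window, F ≈ 1–3) from near-quiescent ones (F ≲ 0.4).  With
a pair count instead, F doubles and the noise floor of weakly pulsing
cells straddles 0.6; with a per-minute rate, everything falls below it.
Cells with F > 0.6 are classed high-fluctuation.

## Vertex sliding Δd

For a reference cell adjacent to the boundary, each of its boundary
vertices is scored per frame interval t → t+dt:

* d — displacement projected on the unit vector from the cell centroid
  (at t) to the vertex (at t), positive outward;
* d<sup>iso</sup> = (s − 1)·|p − c| with s = √(A(t+dt)/A(t)) — the radial
  move the vertex would make if the cell deformed isotropically;
* Δd = d − d<sup>iso</sup>.

Centroid and radial axis are taken at the interval's start, matching the
isotropic construction.  Reference cells are the "protruding"
configuration: cells of the chosen compartment with γ above a cutoff
(0.55 by default; selection by initial γ or by the window maximum).
Positive Δd means the vertex outruns the isotropic prediction; negative Δd
during expansion means outward sliding is resisted.

Vertex coordinate series are Savitzky–Golay smoothed (same 5/2 filter)
before d and d<sup>iso</sup> are computed.  This matters: with raw
positions, positional measurement noise ε enters both the radial axis
(through p at t) and the displacement, and E[−ε·û(ε)] < 0 regresses Δd by
about −σ²/r per interval regardless of any biology — with σ at 0.5 % of a
cell diameter this fake "resistance" is of the same order as a real
β = 0.1 signal.  Smoothing the track suppresses it; `smooth_positions=False`
restores raw geometry (and the exact d ≡ d<sup>iso</sup> identity under
constructed isotropic deformations, which the tests use).

## Synthetic tissue generator

The generator is kinematic, not force-based: the analysis needs controlled,
exactly seeded statistical structure, and a mechanical vertex model would
add fitting burden without adding testability.  Defaults describe a
proliferation-phase histoblast nest and are fixed as the package's study
conditions:

| parameter | default | meaning |
|---|---|---|
| rows × cols | 8 × 8 | hexagonal lattice, A left of the split column |
| base area A₀ | 12 µm² | apical area scale (side ≈ 2.15 µm) |
| amplitude a | 0.10 (±20 % per cell) | relative pulse amplitude |
| period T | 6 min (±20 % per cell) | pulse period, random phase per cell |
| dt | 0.5 min | frame interval (pulsation-resolving cadence) |
| duration | 18 min | one 15-min analysis window plus margin |
| noise σ | 0.5 % of cell diameter (≈ 0.02 µm) | per-vertex Gaussian, per frame |
| β | 0 | adhesion bias in [0, 1) |
| protrusions | 2 | boundary cells relabelled across the interface |

Per step, each cell proposes moving its vertices radially by
√(target/current area); a vertex moves by the mean proposal of its adjacent
cells (this averaging damps each cell's realised amplitude to roughly a/3
and mixes neighbours' pulses into every area series — a deliberate feature
shared with real tissue, where a cell's apical area is not under its sole
control).  Differential adhesion enters as the bias β: for a vertex of a
protruding cell whose other adjacent cells all belong to the opposite
compartment, a positive (outward) radial component of the proposed move is
multiplied by (1 − β).  Over a full pulse this rectifies oscillation into
net retraction of the protrusion: expansion-phase Δd < 0, γ of protruding
cells declines, and high-fluctuation cells demix faster than
low-fluctuation ones — none of which occurs at β = 0.

Protrusions are topological: a boundary-adjacent cell is relabelled to the
opposite compartment, giving γ = 2/3 immediately (a single displaced vertex
cannot push γ past the 0.5 selection cutoff on a hex lattice).  Protrusion
rows are spaced so relabelled cells neither touch each other nor the
tissue edge; `protrusion_amplitudes` can assign exact pulse amplitudes to
the protruding cells for mixed-population studies.  `inject_distortion`
displaces a single boundary vertex instead, for boundary-angle
experiments.  Not modelled: cell division, T1 rearrangements, larval-cell
replacement — the statistics do not require them, and their absence means
topology is constant through a run (tracking is trivially exact).

At β = 0 a small phase-conditioned residual remains (expansion mean Δd
≈ −3·10⁻⁴ µm, contraction the mirror image, zero overall): conditioning on
the reference cell's *realised* expansion selects configurations where its
interior-side vertices carried more of the area change.  It is an honest
property of the averaged kinematics, an order of magnitude below the β = 0.5
signal, and the acceptance checks bound it rather than subtract it.

Raster generation draws each junction as an analytically Gaussian-blurred
line (exact 1-D Gaussian cross-section, erf-windowed along the segment,
overlaps combined by maximum), avoiding the orientation-dependent
deposition of Bresenham rasterisation, which alone distorts slanted-vs-
vertical intensity ratios by ~15 %.  Default sampling is 10 px/µm (0.1 µm
pixels); at much coarser sampling, endpoint cross-talk between bright and
dim junctions compresses recovered enrichment ratios.  Aggregation images
place near-square components with exact pixel counts and guaranteed gaps.

## Intensity, aggregation and ablation conventions

Wide-line profiles average every pixel whose center lies within width/2
(Euclidean distance to the polyline, each pixel counted once, so corners
are not double-weighted); widths are 3 px for junctional Myosin II and
7 px for receptor-recruitment profiles.  Boundary enrichment offers both
published normalisations: boundary mean over the mean of per-side
non-boundary junctions one cell row away, and per-junction normalisation
to up to ten non-boundary junctions of the two adjacent cells (fewer
available → all used and reported).  Cable triplets are *aligned* iff
either internal angle ≥ 130°, and depend only on angles.  The aggregation
quantifier thresholds (Otsu by default), labels 8-connected components,
keeps objects strictly larger than 25 px and reports the area-weighted
fraction in components strictly larger than 1000 px; a count-weighted
variant exists because reporting conventions differ on the weighting.
Ablation records hold vertex separations at 500-ms steps; initial velocity
is the first post-ablation difference over 0.5 s, correlated (Pearson)
against the pre-ablation boundary angle.

## Determinism and IO

All randomness flows through `numpy.random.default_rng` seeded from
explicit parameters; identical seed and configuration give bit-identical
simulations and byte-identical `summary.json` (sorted keys, fixed float
format, no timestamps).  Mesh series round-trip through CSV/JSON with
17-significant-digit floats (lossless well below 1e-9); the manifest
stores frame times, and a dt/times mismatch is rejected at load.

## What the synthetic tests do and do not show

Passing the recovery tests shows the statistics detect the *programmed*
effects at realistic noise, sampling and effect sizes, with correct nulls
(β = 0 centred at zero).  It does not show that real histoblast data meet
the generator's assumptions: constant topology, sinusoidal pulses,
isotropic noise, and a boundary-local adhesion bias are all idealisations,
and segmentation errors in real meshes (merged cells, lost tracks) are not
emulated.  Statistical utilities (t test, Mann–Whitney U, sign test) are
thin scipy wrappers provided for report parity, not contributions.
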