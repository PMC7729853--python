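import math

import numpy as np
import pytest

from epiboundary.core_geometry import BoundaryPath, Junction, MeshFrame, build_boundary_path
from epiboundary.intensity_quant import (
    IntensityImage,
    RecoilRecord,
    aggregate_fraction,
    cable_alignment_score,
    junction_profile_intensity,
    myosin_boundary_enrichment,
    recoil_velocity_stats,
)
from epiboundary.synthetic_data import (
    SimParams,
    make_lattice,
    synth_aggregate_image,
    synth_intensity_image,
)


class TestJunctionProfile:
    def test_uniform_image_any_width(self):
        img = np.full((30, 30), 4.2)
        line = [(5, 5), (20, 18)]
        for w in (1, 3, 7):
            assert junction_profile_intensity(img, line, w) == pytest.approx(4.2)

    def test_vertical_line_in_step_image_matches_pixel_enumeration(self):
        # left half 1, right half 3; vertical line on the step at x = 10
        img = np.ones((21, 21))
        img[:, 10:] = 3.0
        line = [(10, 3), (10, 17)]
        width = 3
        # oracle: enumerate pixel centers within width/2 of the segment
        chosen = []
        for y in range(21):
            for x in range(21):
                dx = abs(x - 10)
                dy = 0 if 3 <= y <= 17 else min(abs(y - 3), abs(y - 17))
                if math.hypot(dx, dy) <= width / 2:
                    chosen.append(img[y, x])
        assert junction_profile_intensity(img, line, width) == \
            pytest.approx(np.mean(chosen))

    def test_shift_and_scale_linearity(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(1, 5, (25, 25))
        line = [(4, 4), (20, 9)]
        base = junction_profile_intensity(img, line, 3)
        assert junction_profile_intensity(img + 2.5, line, 3) == pytest.approx(base + 2.5)
        assert junction_profile_intensity(3 * img, line, 3) == pytest.approx(3 * base)

    def test_out_of_bounds_polyline(self):
        with pytest.raises(ValueError):
            junction_profile_intensity(np.ones((10, 10)), [(5, 5), (12, 5)], 3)

    def test_even_width_rejected(self):
        with pytest.raises(ValueError):
            junction_profile_intensity(np.ones((10, 10)), [(2, 2), (8, 8)], 4)


@pytest.fixture(scope="module")
def painted_boundary():
    frame = make_lattice(SimParams(n_protrusions=0))
    boundary = {j.id for p in build_boundary_path(frame) for j in p.junctions}
    intensities = {j.id: (2.0 if j.id in boundary else 1.0) for j in frame.junctions}
    image, truth = synth_intensity_image(frame, intensities, psf_sigma=1.0)
    return frame, image, truth


class TestBoundaryEnrichment:
    def test_uniform_intensity_gives_one(self):
        frame = make_lattice(SimParams(n_protrusions=0))
        image, _ = synth_intensity_image(frame, 1.0, psf_sigma=1.0)
        df = myosin_boundary_enrichment(frame, image)
        for scheme in ("boundary_vs_side", "ten_junction"):
            vals = df.loc[df["scheme"] == scheme, "relative_intensity"]
            assert vals.mean() == pytest.approx(1.0, abs=0.05)

    def test_two_fold_boundary_recovered(self, painted_boundary):
        frame, image, _ = painted_boundary
        df = myosin_boundary_enrichment(frame, image)
        for scheme in ("boundary_vs_side", "ten_junction"):
            mean = df.loc[df["scheme"] == scheme, "relative_intensity"].mean()
            assert mean == pytest.approx(2.0, rel=0.10)

    def test_normalizer_capped_at_ten(self, painted_boundary):
        frame, image, _ = painted_boundary
        df = myosin_boundary_enrichment(frame, image)
        assert (df.loc[df["scheme"] == "ten_junction", "n_norm"] <= 10).all()


def chain_path(points):
    """BoundaryPath through given coordinates, with a minimal frame."""
    vertices = {i: np.asarray(p, float) for i, p in enumerate(points)}
    junctions = [Junction(i, i, i + 1, np.array([points[i], points[i + 1]]),
                          frozenset({100 + i, 200 + i}))
                 for i in range(len(points) - 1)]
    frame = MeshFrame(0.0, vertices, [], [])
    return frame, BoundaryPath(list(range(len(points))), junctions, closed=False)


class TestCableAlignment:
    def test_straight_triplet_aligned(self):
        frame, path = chain_path([(0, 0), (1, 0), (2, 0), (3, 0)])
        df = cable_alignment_score(frame, path, {j.id: 1.0 for j in path.junctions})
        assert list(df["alignment"]) == ["aligned"]

    def test_exactly_130_is_aligned(self):
        # internal angles exactly 130 deg at both shared vertices
        a = math.radians(50)
        pts = [(0.0, 0.0), (1.0, 0.0),
               (1.0 + math.cos(a), math.sin(a)),
               (1.0 + math.cos(a) + 1.0, math.sin(a))]
        frame, path = chain_path(pts)
        df = cable_alignment_score(frame, path, {j.id: 1.0 for j in path.junctions})
        assert df["angle1"].iloc[0] == pytest.approx(130.0)
        assert df["alignment"].iloc[0] == "aligned"

    def test_both_below_130_misaligned(self):
        a = math.radians(55)  # both internal angles 125 deg
        pts = [(0.0, 0.0), (1.0, 0.0),
               (1.0 + math.cos(a), math.sin(a)),
               (1.0 + 2 * math.cos(a) + 0.0, 0.0)]
        frame, path = chain_path(pts)
        df = cable_alignment_score(frame, path, {j.id: 1.0 for j in path.junctions})
        assert (df["angle1"] < 130).all() and (df["angle2"] < 130).all()
        assert df["alignment"].iloc[0] == "misaligned"

    def test_triplet_mean_is_arithmetic_mean(self):
        frame, path = chain_path([(0, 0), (1, 0), (2, 0), (3, 0), (4, 0)])
        inten = {0: 1.0, 1: 2.0, 2: 4.0, 3: 8.0}
        df = cable_alignment_score(frame, path, inten)
        assert df["mean_relative_intensity"].tolist() == \
            pytest.approx([7 / 3, 14 / 3])

    def test_short_path_empty(self):
        frame, path = chain_path([(0, 0), (1, 0), (2, 0)])
        assert len(cable_alignment_score(frame, path, {0: 1.0, 1: 1.0})) == 0

    def test_classification_ignores_intensities(self):
        frame, path = chain_path([(0, 0), (1, 0), (2, 0), (3, 0)])
        a = cable_alignment_score(frame, path, {j.id: 1.0 for j in path.junctions})
        b = cable_alignment_score(frame, path, {j.id: 9.0 for j in path.junctions})
        assert list(a["alignment"]) == list(b["alignment"])


class TestAggregateFraction:
    def test_single_large_blob(self):
        image, _ = synth_aggregate_image([2000])
        assert aggregate_fraction(image, 0.5).large_fraction == pytest.approx(1.0)

    def test_mixed_sizes_exact_fraction(self):
        image, _ = synth_aggregate_image([30, 500, 1500])
        res = aggregate_fraction(image, 0.5)
        assert res.n_objects == 3
        assert res.large_fraction == pytest.approx(1500 / 2030)

    def test_strict_cutoffs(self):
        # 25 px is NOT an object; 1000 px is NOT large
        image, _ = synth_aggregate_image([25, 26, 1000, 1001])
        res = aggregate_fraction(image, 0.5)
        assert res.n_objects == 3
        assert res.large_fraction == pytest.approx(1001 / (26 + 1000 + 1001))

    def test_no_objects_undefined(self):
        image, _ = synth_aggregate_image([10, 20])
        assert math.isnan(aggregate_fraction(image, 0.5).large_fraction)

    def test_count_weighting(self):
        image, _ = synth_aggregate_image([30, 500, 1500])
        res = aggregate_fraction(image, 0.5, weighting="count")
        assert res.large_fraction == pytest.approx(1 / 3)

    def test_translation_invariant(self):
        image, _ = synth_aggregate_image([40, 1200], shape=(120, 120))
        rolled = np.roll(image.pixels, (7, 11), axis=(0, 1))
        a = aggregate_fraction(image, 0.5).large_fraction
        b = aggregate_fraction(rolled, 0.5).large_fraction
        assert a == pytest.approx(b)

    def test_otsu_default_threshold(self):
        image, _ = synth_aggregate_image([30, 1500])
        res = aggregate_fraction(image)   # Otsu on a clean binary image
        assert res.large_fraction == pytest.approx(1500 / 1530)


class TestRecoil:
    def test_stationary_vertices_zero_velocity(self):
        rec = RecoilRecord(150.0, [2.0, 2.0, 2.0])
        assert rec.initial_velocity == 0.0

    def test_linear_separation_recovers_slope(self):
        k = 0.8   # length units per second; frames every 0.5 s
        t = np.arange(6) * 0.5
        rec = RecoilRecord(170.0, 3.0 + k * t)
        assert rec.initial_velocity == pytest.approx(k)

    def test_correlation_matches_closed_form(self):
        rng = np.random.default_rng(7)
        thetas = rng.uniform(90, 180, 15)
        records = []
        vels = []
        for th in thetas:
            v = 0.01 * th + rng.normal(0, 0.05)
            vels.append(v)
            records.append(RecoilRecord(th, [2.0, 2.0 + 0.5 * v]))
        df, r, p = recoil_velocity_stats(records)
        vx, vy = np.asarray(thetas), np.asarray(vels)
        expect = np.corrcoef(vx, vy)[0, 1]
        assert r == pytest.approx(expect, abs=1e-9)
        assert r > 0

    def test_short_records_skipped_and_counted(self):
        records = [RecoilRecord(120.0, [2.0]), RecoilRecord(140.0, [2.0, 2.4]),
                   RecoilRecord(160.0, [2.0, 2.2])]
        df, r, p = recoil_velocity_stats(records)
        assert len(df) == 2 and df.attrs["n_skipped"] == 1


def test_intensity_image_validation():
    with pytest.raises(ValueError):
        IntensityImage(np.ones((3, 3, 3)))
    with pytest.raises(ValueError):
        IntensityImage(np.array([[1.0, np.inf]]))
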