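import math

import numpy as np
import pytest

from epiboundary.boundary_metrics import (
    angle_change_records,
    boundary_angle,
    gamma_bin,
    gamma_change_records,
    gamma_table,
    gamma_trend,
    mixing_index,
    theta_bin,
)
from epiboundary.core_geometry import (
    TissueTimeSeries,
    build_boundary_path,
    vertex_angle,
)
from epiboundary.synthetic_data import (
    SimParams,
    _with_positions,
    inject_distortion,
    make_lattice,
    run_simulation,
)

from conftest import make_square_mesh, static_series


class TestBoundaryAngle:
    def test_straight_lattice_is_180(self, square_mesh):
        path = build_boundary_path(square_mesh)[0]
        for v in path.interior_vertices():
            assert boundary_angle(square_mesh, path, v) == pytest.approx(180.0)

    def test_calibrated_protrusion_hits_small_bin(self, square_mesh):
        # push one interface vertex sideways until the chords close to ~95 deg
        path = build_boundary_path(square_mesh)[0]
        v = path.interior_vertices()[0]
        # chords go to neighbours 1 unit above/below; offset x by 1/tan(47.5)
        dx = 1.0 / math.tan(math.radians(95.0 / 2))
        frame, theta = inject_distortion(square_mesh, v, (dx, 0.0))
        assert theta == pytest.approx(95.0, abs=1e-9)
        assert theta_bin(theta) == "small"

    def test_matches_vertex_angle_oracle(self, hex_frame):
        path = build_boundary_path(hex_frame)[0]
        for v in path.interior_vertices():
            prev_v, next_v = path.neighbours(v)
            expect = vertex_angle(hex_frame.vertices[prev_v], hex_frame.vertices[v],
                                  hex_frame.vertices[next_v])
            assert boundary_angle(hex_frame, path, v) == pytest.approx(expect)

    def test_endpoint_not_measurable(self, square_mesh):
        path = build_boundary_path(square_mesh)[0]
        with pytest.raises(ValueError):
            boundary_angle(square_mesh, path, path.vertex_ids[0])


class TestThetaBins:
    @pytest.mark.parametrize("theta,expected", [
        (90.0, "small"), (99.999, "small"), (100.0, "intermediate"),
        (160.0, "intermediate"), (160.001, "large"), (180.0, "large"),
    ])
    def test_edges(self, theta, expected):
        assert theta_bin(theta) == expected


class TestAngleChange:
    def test_static_mesh_all_zero(self, square_mesh):
        series = static_series(square_mesh)
        rec = angle_change_records(series, interval=1.0)
        assert len(rec) > 0
        assert np.allclose(rec["dtheta"], 0.0)

    def test_interval_must_divide_dt(self, square_mesh):
        series = static_series(square_mesh, dt=0.4)
        with pytest.raises(ValueError):
            angle_change_records(series, interval=1.0)

    def test_hand_tracked_frame_pair(self, square_mesh):
        # one distorted frame relaxing back to straight: Δθ computed by hand
        path = build_boundary_path(square_mesh)[0]
        v = path.interior_vertices()[0]
        distorted, theta0 = inject_distortion(square_mesh, v, (0.6, 0.0))
        frames = [distorted, _with_positions(square_mesh, square_mesh.vertices, 1.0)]
        frames[0] = _with_positions(distorted, distorted.vertices, 0.0)
        series = TissueTimeSeries(frames, dt=1.0)
        rec = angle_change_records(series, interval=1.0)
        row = rec[rec["vertex"] == v].iloc[0]
        assert row["theta0"] == pytest.approx(theta0)
        assert row["dtheta"] == pytest.approx(180.0 - theta0)
        assert row["bin"] == theta_bin(theta0)

    def test_time_reversal_negates_bin_means(self, small_run):
        _, series, _ = small_run
        fwd = angle_change_records(series, 3.0)
        rev = TissueTimeSeries(
            [_with_positions(f, f.vertices, i * series.dt)
             for i, f in enumerate(reversed(series.frames))], dt=series.dt)
        bwd = angle_change_records(rev, 3.0)
        # pair forward (t -> t+k) with backward (reversed index) records
        k = int(round(3.0 / series.dt))
        n = len(series.frames)
        bwd = bwd.assign(orig_frame=n - 1 - bwd["frame"] - k)
        merged = fwd.merge(bwd, left_on=["frame", "vertex"],
                           right_on=["orig_frame", "vertex"], suffixes=("_f", "_b"))
        assert len(merged) > 0
        assert np.allclose(merged["dtheta_f"], -merged["dtheta_b"], atol=1e-9)
        # and each backward record is binned by its own (reversed) θ0
        assert (merged["bin_b"] == merged["theta0_b"].map(theta_bin)).all()


class TestMixingIndex:
    def test_interior_cell_zero(self, square_mesh):
        assert mixing_index(square_mesh, 0) == 0.0    # all-homotypic corner cell

    def test_engulfed_cell_one(self):
        frame = make_square_mesh(rows=3, cols=3, split=0, compartments={4: "A"})
        assert mixing_index(frame, 4) == pytest.approx(1.0)

    def test_hexagon_two_of_six_edges(self):
        frame = make_lattice(SimParams(rows=4, cols=4, n_protrusions=0))
        # boundary-adjacent interior cell: 2 of 6 equal edges heterotypic
        cid = 1 * 4 + 1   # row 1, col 1 (A), touches col-2 P cells on 2 edges
        assert mixing_index(frame, cid) == pytest.approx(1 / 3)

    def test_rigid_transform_and_scale_invariant(self, hex_frame):
        th = 0.7
        R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        pos = {v: 2.5 * (R @ p) + np.array([10.0, -3.0])
               for v, p in hex_frame.vertices.items()}
        moved = _with_positions(hex_frame, pos, 0.0)
        for cell in hex_frame.cells:
            g0 = mixing_index(hex_frame, cell.id)
            g1 = mixing_index(moved, cell.id)
            assert g1 == pytest.approx(g0, abs=1e-12) or (np.isnan(g0) and np.isnan(g1))

    def test_chord_mode_equals_polyline_for_straight_junctions(self, hex_frame):
        for cell in hex_frame.cells[:8]:
            assert mixing_index(hex_frame, cell.id, "chord") == \
                pytest.approx(mixing_index(hex_frame, cell.id, "polyline"))

    def test_gamma_in_unit_interval(self, small_run):
        _, series, _ = small_run
        g = gamma_table(series)["gamma"].dropna()
        assert ((g >= 0) & (g <= 1)).all()


class TestGammaBins:
    @pytest.mark.parametrize("g,expected", [
        (0.0, None), (-0.1, None), (0.05, ">0"), (0.1, ">0.1"),
        (0.47, ">0.4"), (0.5, ">0.5"), (0.93, ">0.5"),
    ])
    def test_edges(self, g, expected):
        assert gamma_bin(g) == expected

    def test_static_mesh_dgamma_zero(self):
        frame = make_square_mesh(rows=3, cols=3, split=2)
        series = static_series(frame, n_frames=9)
        rec = gamma_change_records(series, interval=1.0)
        assert len(rec) > 0
        assert np.allclose(rec["dgamma"], 0.0)

    def test_adhesion_bias_drives_sorting_direction(self):
        # β > 0: protruding (>0.5 bin) cells lose heterotypic contact
        series, _ = run_simulation(SimParams(adhesion_bias=0.6, seed=5))
        rec = gamma_change_records(series, 3.0)
        top = rec[rec["bin"] == ">0.5"]
        assert len(top) > 20
        assert top["dgamma"].mean() < 0


class TestGammaTrend:
    def test_exact_linear_slope(self):
        t = np.arange(0, 16.0, 0.5)
        assert gamma_trend(t, 0.6 - 0.01 * t) == pytest.approx(-0.01, abs=1e-12)

    def test_constant_is_zero(self):
        t = np.arange(0, 16.0, 0.5)
        assert gamma_trend(t, np.full_like(t, 0.3)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(9)
        t = np.arange(0, 15.5, 0.5)
        g = 0.4 + 0.002 * t + rng.normal(0, 0.01, len(t))
        X = np.c_[t, np.ones_like(t)]
        slope = np.linalg.solve(X.T @ X, X.T @ g)[0]
        assert gamma_trend(t, g) == pytest.approx(slope, rel=1e-9)

    def test_too_few_samples_undefined(self):
        assert np.isnan(gamma_trend([0, 1], [0.1, 0.2]))


def test_turning_sum_around_embedded_cell():
    # closed boundary loop around one cell: Σ(180° − θ) = 360°
    frame = make_square_mesh(rows=3, cols=3, split=3, compartments={4: "P"})
    path = build_boundary_path(frame)[0]
    assert path.closed
    total = sum(180.0 - boundary_angle(frame, path, v)
                for v in path.interior_vertices())
    assert total == pytest.approx(360.0, abs=1e-9)
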