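"""State-space grid, overlap geometry and transition-matrix generation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import popgrid as pg
from popgrid.grid import ROW_SUM_TOL

from conftest import mc_overlap_fractions


class TestStateGrid:
    def test_cell_geometry(self):
        g = pg.build_grid((-72, -54, -1, 1), (100, 100))
        assert g.n_cells == 10_000
        assert g.cell_width == pytest.approx(0.18)
        assert g.cell_height == pytest.approx(0.02)

    def test_single_cell_grid(self):
        g = pg.build_grid((0, 1, 0, 1), (1, 1))
        assert g.n_cells == 1
        assert g.cell_of_point(0.5, 0.5) == 0

    def test_inverted_bounds_rejected(self):
        with pytest.raises(pg.ConfigurationError):
            pg.build_grid((1, 0, 0, 1), (10, 10))
        with pytest.raises(pg.ConfigurationError):
            pg.build_grid((0, 1, 0, 1), (0, 10))

    def test_half_open_cells_and_upper_edge(self):
        g = pg.build_grid((0.0, 1.0, 0.0, 1.0), (10, 10))
        # lower edge belongs to the cell, upper edge to the next
        assert g.column_of(0.1) == 1
        assert g.column_of(0.0999999999) == 0
        # a point exactly on the upper grid bound belongs to the last cell
        assert g.column_of(1.0) == 9
        assert g.row_of(1.0) == 9

    def test_linear_index_convention(self):
        g = pg.build_grid((0, 1, 0, 1), (7, 5))
        assert g.linear_index(3, 2) == 2 * 7 + 3
        assert g.cell_coords(17) == (3, 2)

    def test_boundary_policy_pin_below_wrap_above(self):
        g = pg.build_grid((0, 1, 0, 1), (10, 10))
        i, j, touched = g.resolve(-3, 4)
        assert (i, j, touched) == (0, 4, True)
        i, j, touched = g.resolve(12, 4)
        assert (i, j, touched) == (2, 4, True)


class TestTransformCell:
    def test_zero_field_is_identity(self, zero_field_model):
        g = pg.build_grid((0, 1, 0, 1), (10, 10))
        quad = pg.transform_cell(zero_field_model, g, (3, 4))
        assert np.allclose(quad, g.cell_vertices(3, 4))

    def test_uniform_translation_one_column(self):
        g = pg.build_grid((0.0, 1.0, 0.0, 1.0), (10, 10))
        # c * dt = cell_width exactly
        model = pg.NeuronModel(
            name="drift", vector_field=lambda y, t: (100.0 + 0.0 * y[0],
                                                     0.0 * y[1]),
            timestep=1e-3)
        quad = pg.transform_cell(model, g, (2, 5))
        assert np.allclose(quad, g.cell_vertices(3, 5))

    def test_cond2d_equilibrium_vertex_is_fixed(self, cond_model):
        g = pg.build_grid((-65.0, -55.0, 0.0, 1.0), (10, 10))
        quad = pg.transform_cell(cond_model, g, (0, 0))
        # the (E_l, 0) corner does not move; the others drift toward it
        assert tuple(quad[0]) == (-65.0, 0.0)
        orig = g.cell_vertices(0, 0)
        assert quad[1][0] < orig[1][0]

    def test_out_of_grid_cell_rejected(self, zero_field_model):
        g = pg.build_grid((0, 1, 0, 1), (10, 10))
        with pytest.raises(pg.ConfigurationError):
            pg.transform_cell(zero_field_model, g, (10, 0))


class TestOverlapFractions:
    def test_quad_equal_to_cell(self):
        g = pg.build_grid((0, 1, 0, 1), (10, 10))
        fr = pg.overlap_fractions(g.cell_vertices(4, 7), g)
        assert fr == [(g.linear_index(4, 7), pytest.approx(1.0))]

    @pytest.mark.parametrize("shift,expected", [
        # frozen from the construction; cross-checked by the MC oracle below
        ((0.5, 0.0), {(4, 7): 0.5, (5, 7): 0.5}),
        ((0.5, 0.5), {(4, 7): 0.25, (5, 7): 0.25, (4, 8): 0.25,
                      (5, 8): 0.25}),
    ])
    def test_fractional_shifts(self, shift, expected):
        g = pg.build_grid((0, 1, 0, 1), (10, 10))
        quad = g.cell_vertices(4, 7) + np.array(
            [shift[0] * g.cell_width, shift[1] * g.cell_height])
        fr = dict(pg.overlap_fractions(quad, g))
        assert len(fr) == len(expected)
        for (i, j), f in expected.items():
            assert fr[g.linear_index(i, j)] == pytest.approx(f, abs=1e-9)

    def test_agrees_with_monte_carlo_point_oracle(self):
        rng = np.random.default_rng(42)
        g = pg.build_grid((0.0, 1.0, 0.0, 1.0), (8, 8))
        n_pts = 40_000
        for _ in range(25):
            # random convex-ish quad spanning a few cells
            center = rng.uniform(0.2, 0.8, size=2)
            half = rng.uniform(0.02, 0.2, size=2)
            jitter = rng.uniform(-0.03, 0.03, size=(4, 2))
            base = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]]) * half
            quad = center + base + jitter
            exact = dict(pg.overlap_fractions(quad, g))
            approx = mc_overlap_fractions(quad, g, n_pts, rng)
            for cell in set(exact) | set(approx):
                p = exact.get(cell, 0.0)
                se = math.sqrt(max(p * (1 - p), 1e-4) / n_pts)
                assert abs(p - approx.get(cell, 0.0)) < 3.5 * se + 1e-3

    def test_agrees_with_shapely(self):
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import Polygon, box

        rng = np.random.default_rng(7)
        g = pg.build_grid((0.0, 1.0, 0.0, 1.0), (10, 10))
        for _ in range(40):
            center = rng.uniform(0.25, 0.75, size=2)
            half = rng.uniform(0.03, 0.18, size=2)
            jitter = rng.uniform(-0.02, 0.02, size=(4, 2))
            base = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]]) * half
            quad = center + base + jitter
            poly = Polygon(quad)
            if not poly.is_valid:
                continue
            exact = dict(pg.overlap_fractions(quad, g))
            for cell, frac in exact.items():
                i, j = g.cell_coords(cell)
                cell_box = box(g.v_min + i * g.cell_width,
                               g.h_min + j * g.cell_height,
                               g.v_min + (i + 1) * g.cell_width,
                               g.h_min + (j + 1) * g.cell_height)
                ref = poly.intersection(cell_box).area / poly.area
                assert frac == pytest.approx(ref, abs=1e-9)

    def test_non_convex_quad_mass_is_complete(self):
        g = pg.build_grid((0.0, 1.0, 0.0, 1.0), (10, 10))
        # an arrow-head (non-convex) quadrilateral
        quad = np.array([[0.31, 0.31], [0.55, 0.38], [0.79, 0.31],
                         [0.55, 0.62]])
        fr = pg.overlap_fractions(quad, g)
        assert sum(f for _, f in fr) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_quad_rejected(self):
        g = pg.build_grid((0, 1, 0, 1), (10, 10))
        flat = np.array([[0.1, 0.1], [0.2, 0.1], [0.3, 0.1], [0.2, 0.1]])
        with pytest.raises(pg.DegenerateCellError):
            pg.overlap_fractions(flat, g)


class TestDeterministicMatrix:
    def test_zero_field_gives_identity(self, zero_field_model):
        import scipy.sparse as sp
        g = pg.build_grid((0, 1, 0, 1), (12, 12))
        m = pg.generate_deterministic_matrix(zero_field_model, g)
        assert (m.matrix - sp.identity(g.n_cells)).nnz == 0

    def test_uniform_translation_is_permutation(self):
        g = pg.build_grid((0.0, 1.0, 0.0, 1.0), (10, 4))
        model = pg.NeuronModel(
            name="drift",
            vector_field=lambda y, t: (100.0 + 0.0 * y[0], 0.0 * y[1]),
            timestep=1e-3)
        m = pg.generate_deterministic_matrix(model, g)
        for j in range(g.n_h):
            for i in range(g.n_v - 1):
                fr = m.row_fractions(g.linear_index(i, j))
                assert fr == [(g.linear_index(i + 1, j),
                               pytest.approx(1.0))]

    def test_row_sums_are_one(self, cond_det_matrix, cond_grid):
        sums = np.asarray(cond_det_matrix.matrix.sum(axis=0)).ravel()
        assert np.abs(sums - 1.0).max() < ROW_SUM_TOL
        assert cond_det_matrix.matrix.data.min() >= 0

    def test_matrix_rows_match_per_cell_construction(self, cond_model,
                                                     cond_grid,
                                                     cond_det_matrix):
        # generation must be independent of traversal order: each row equals
        # the isolated transform-and-overlap of its source cell
        rng = np.random.default_rng(3)
        for cell in rng.integers(0, cond_grid.n_cells, size=30):
            quad = pg.transform_cell(cond_model, cond_grid, int(cell))
            expected = pg.overlap_fractions(quad, cond_grid)
            got = cond_det_matrix.row_fractions(int(cell))
            exp = {c: f for c, f in expected if f > 1e-12}
            total = sum(exp.values())
            assert set(c for c, _ in got) == set(exp)
            for c, f in got:
                assert f == pytest.approx(exp[c] / total, abs=1e-12)

    def test_dt_to_zero_approaches_identity(self, cond_model):
        g = pg.build_grid((-72.0, -54.0, -0.2, 1.0), (30, 30))
        prev = -1.0
        for dt in (4e-4, 2e-4, 1e-4, 1e-5):
            m = pg.generate_deterministic_matrix(
                cond_model.with_(timestep=dt), g)
            self_frac = m.matrix.diagonal().mean()
            assert self_frac > prev
            prev = self_frac
        assert prev > 0.9

    def test_blow_up_reports_cell(self):
        g = pg.build_grid((0.0, 1.0, 0.0, 1.0), (4, 4))
        model = pg.NeuronModel(
            name="explode",
            vector_field=lambda y, t: (np.exp(300 * (y[0] + 2.0)), 0.0 * y[1]),
            timestep=1.0)
        with pytest.raises(FloatingPointError):
            pg.generate_deterministic_matrix(model, g)


class TestFileDialects:
    def test_model_file_round_trip(self, cond_model, cond_grid, tmp_path):
        mapping = pg.build_reset_mapping(cond_grid, cond_model)
        path = tmp_path / "cond.model"
        pg.write_model_file(cond_grid, cond_model, path,
                            reset_mapping=mapping.pairs)
        info = pg.read_model_file(path)
        assert info.grid == cond_grid
        assert info.threshold_v == -55.0
        assert info.reset_v == -65.0
        assert info.dt == cond_model.timestep
        assert info.efficacy_orientation == "h"
        assert list(info.reset_mapping) == mapping.pairs

    def test_tmat_round_trip_bit_exact(self, cond_det_matrix, tmp_path):
        path = tmp_path / "cond.tmat"
        pg.write_tmat(cond_det_matrix, path)
        back = pg.read_tmat(path)
        assert back.dt == cond_det_matrix.dt
        assert (back.matrix != cond_det_matrix.matrix).nnz == 0

    def test_tmat_bad_row_sum_rejected(self, tmp_path):
        path = tmp_path / "bad.tmat"
        path.write_text("popgrid-tmat v1\ndt 0.001\nkind jump\ncells 2\n"
                        "0 0 0.9\n1 1 1.0\n")
        with pytest.raises(pg.FileFormatError, match="sums"):
            pg.read_tmat(path)

    def test_tmat_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.tmat"
        path.write_text("popgrid-tmat v1\ndt 0.001\nkind jump\ncells 1\n"
                        "0 zero 1.0\n")
        with pytest.raises(pg.FileFormatError, match="line 5"):
            pg.read_tmat(path)

    def test_dt_mismatch_signalled(self, cond_model, cond_grid,
                                   cond_det_matrix, tmp_path):
        pg.write_model_file(cond_grid, cond_model.with_(timestep=2e-3),
                            tmp_path / "m.model")
        info = pg.read_model_file(tmp_path / "m.model")
        with pytest.raises(pg.FileFormatError, match="dt"):
            pg.check_compatible(info, cond_det_matrix)

    def test_generate_grid_files(self, tmp_path, monkeypatch):
        monkeypatch.chdir(tmp_path)
        grid, matrix = pg.generate_grid_files(
            func=lambda y, t: (-y[0], 0.0 * y[1]),
            timestep=1e-3, basename="lif", threshold_v=1.0, reset_v=0.0,
            grid_v_min=-1.0, grid_v_max=1.1, grid_h_min=-1.0,
            grid_h_max=1.0, grid_v_res=20, grid_h_res=5)
        info = pg.read_model_file("lif.model")
        tmat = pg.read_tmat("lif.tmat")
        pg.check_compatible(info, tmat)
        assert info.grid == grid
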