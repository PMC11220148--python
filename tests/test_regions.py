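import numpy as np
import pytest

from mattforce.forcefield import VectorForceField
from mattforce.pressure import CELL_PITCH_MM, GRID_SHAPE, PressureGrid
from mattforce.regions import (
    RegionConfigError,
    RegionSpec,
    SingularWrenchError,
    cell_moment,
    cross_matrix,
    default_region_layout,
    export_boundary_conditions,
    import_boundary_conditions,
    load_region_layout,
    reduce_regions,
    region_resultant,
    solve_application_point,
)


def _make_field(cell_forces):
    forces = np.zeros(GRID_SHAPE + (3,))
    scalar = np.zeros(GRID_SHAPE)
    geom = PressureGrid(np.zeros(GRID_SHAPE))
    xc, yc = geom.cell_centers()
    positions = np.stack([xc, yc], axis=-1)
    for (i, j), f in cell_forces.items():
        forces[i, j] = f
        scalar[i, j] = np.linalg.norm(f)
    return VectorForceField(forces, positions, scalar, (scalar > 0).astype(int))


def _random_field(rng, n_cells=40):
    cells = {}
    for _ in range(n_cells):
        i, j = rng.integers(0, GRID_SHAPE[0]), rng.integers(0, GRID_SHAPE[1])
        f = rng.normal(0, 2, 3)
        f[2] = abs(f[2]) + 1.0
        cells[(int(i), int(j))] = f
    return _make_field(cells)


class TestCellMoment:
    def test_hand_cross_product(self):
        np.testing.assert_allclose(
            cell_moment([100.0, 0.0, 0.0], [0.0, 0.0, 10.0]), [0.0, -1000.0, 0.0]
        )

    def test_parallel_vectors_give_zero(self):
        np.testing.assert_allclose(
            cell_moment([1.0, 2.0, 3.0], [2.0, 4.0, 6.0]), np.zeros(3), atol=1e-12
        )

    def test_matches_determinant_expansion(self, rng):
        for _ in range(50):
            r, F = rng.normal(size=3), rng.normal(size=3)
            expected = np.array(
                [
                    r[1] * F[2] - r[2] * F[1],
                    r[2] * F[0] - r[0] * F[2],
                    r[0] * F[1] - r[1] * F[0],
                ]
            )
            np.testing.assert_allclose(cell_moment(r, F), expected, atol=1e-12)


class TestRegionResultant:
    def test_symmetric_pair_cancels_moment(self):
        """Equal vertical forces symmetric about mid-x leave no net x-moment
        about their midline; summed about the origin the moments match the
        resultant applied at the centroid."""
        fld = _make_field({(5, 10): (0.0, 0.0, 5.0), (7, 10): (0.0, 0.0, 5.0)})
        spec = RegionSpec("pair", 0, 0, 23, 47)
        F_A, M_A = region_resultant(fld, spec)
        np.testing.assert_allclose(F_A, [0.0, 0.0, 10.0])
        r_A, residual = solve_application_point(F_A, M_A)
        mid_x = 0.5 * (fld.positions[5, 10, 0] + fld.positions[7, 10, 0])
        np.testing.assert_allclose(r_A, [mid_x, fld.positions[5, 10, 1], 0.0])
        assert residual == pytest.approx(0.0, abs=1e-9)

    def test_singleton_region(self):
        fld = _make_field({(3, 4): (1.0, -2.0, 5.0)})
        spec = RegionSpec("one", 3, 4, 3, 4)
        F_A, M_A = region_resultant(fld, spec)
        np.testing.assert_allclose(F_A, [1.0, -2.0, 5.0])
        r = np.array([fld.positions[3, 4, 0], fld.positions[3, 4, 1], 0.0])
        np.testing.assert_allclose(M_A, np.cross(r, F_A))

    def test_matches_brute_force_double_loop(self, rng):
        fld = _random_field(rng)
        spec = RegionSpec("all", 0, 0, 23, 47)
        F_A, M_A = region_resultant(fld, spec)
        F_brute = np.zeros(3)
        M_brute = np.zeros(3)
        for i in range(GRID_SHAPE[0]):
            for j in range(GRID_SHAPE[1]):
                f = fld.forces[i, j]
                r = np.array([fld.positions[i, j, 0], fld.positions[i, j, 1], 0.0])
                F_brute += f
                M_brute += np.cross(r, f)
        np.testing.assert_allclose(F_A, F_brute, atol=1e-9)
        np.testing.assert_allclose(M_A, M_brute, atol=1e-6)

    def test_empty_region_yields_zero_wrench(self):
        fld = _make_field({(0, 0): (0.0, 0.0, 1.0)})
        wrenches = reduce_regions(fld, [RegionSpec("void", 10, 10, 12, 12)])
        assert np.all(wrenches[0].F_A == 0)


class TestApplicationPoint:
    def test_vertical_force_with_x_moment(self):
        """(0,0,10) N with couple (500,0,0) N*mm acts at (0, 50, 0) mm."""
        r_A, residual = solve_application_point([0.0, 0.0, 10.0], [500.0, 0.0, 0.0])
        np.testing.assert_allclose(r_A, [0.0, 50.0, 0.0], atol=1e-9)
        assert residual == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(
            np.cross(r_A, [0.0, 0.0, 10.0]), [500.0, 0.0, 0.0], atol=1e-9
        )

    def test_zero_moment_gives_origin(self):
        r_A, residual = solve_application_point([1.0, 2.0, 3.0], np.zeros(3))
        np.testing.assert_allclose(r_A, np.zeros(3), atol=1e-12)

    def test_zero_force_raises_singular(self):
        with pytest.raises(SingularWrenchError):
            solve_application_point(np.zeros(3), [1.0, 0.0, 0.0])

    def test_literal_cross_product_matrix_is_singular(self, rng):
        """The matrix form of 'cross with F' has rank 2 for every F, so the
        textbook inverse of the wrench equation cannot exist."""
        for _ in range(20):
            F = rng.normal(size=3)
            M = cross_matrix(F)
            assert np.linalg.matrix_rank(M) == 2
            assert abs(np.linalg.det(M)) < 1e-12

    def test_reconstruction_identity_on_random_wrenches(self, rng):
        for _ in range(50):
            F = rng.normal(size=3)
            F[2] = abs(F[2]) + 0.5
            M = rng.normal(0, 100, 3)
            r_A, residual = solve_application_point(F, M)
            f_hat = F / np.linalg.norm(F)
            recon = np.cross(r_A, F) + residual * f_hat
            np.testing.assert_allclose(recon, M, rtol=1e-6, atol=1e-6)

    def test_attains_brute_force_lattice_minimum(self, rng):
        """r_A minimizes |r x F - M| over the sensor plane: no 1 mm lattice
        point does better (beyond lattice resolution)."""
        for _ in range(5):
            fld = _random_field(rng, n_cells=25)
            F_A, M_A = region_resultant(fld, RegionSpec("all", 0, 0, 23, 47))
            r_A, _ = solve_application_point(F_A, M_A)
            obj = lambda r: np.linalg.norm(np.cross(r, F_A) - M_A)
            best = obj(r_A)
            xs = np.arange(r_A[0] - 20.0, r_A[0] + 20.0 + 0.5, 1.0)
            ys = np.arange(r_A[1] - 20.0, r_A[1] + 20.0 + 0.5, 1.0)
            X, Y = np.meshgrid(xs, ys, indexing="ij")
            lattice = np.stack([X, Y, np.zeros_like(X)], axis=-1).reshape(-1, 3)
            vals = np.linalg.norm(np.cross(lattice, F_A) - M_A, axis=1)
            # lattice can only beat the solution by discretization slack
            assert best <= vals.min() + 1e-6


class TestMomentConservation:
    def test_tiling_regions_conserve_total_moment(self, rng):
        fld = _random_field(rng, n_cells=60)
        specs = default_region_layout("supine")
        total_F = np.zeros(3)
        total_M = np.zeros(3)
        for w in reduce_regions(fld, specs):
            total_F += w.F_A
            total_M += w.M_A
        F_all, M_all = region_resultant(fld, RegionSpec("all", 0, 0, 23, 47))
        np.testing.assert_allclose(total_F, F_all, rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(total_M, M_all, rtol=1e-6, atol=1e-6)


class TestRegionConfig:
    def test_overlapping_regions_rejected(self):
        fld = _make_field({})
        specs = [RegionSpec("a", 0, 0, 10, 10), RegionSpec("b", 10, 10, 12, 12)]
        with pytest.raises(RegionConfigError):
            reduce_regions(fld, specs)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(RegionConfigError):
            RegionSpec("big", 0, 0, 24, 47)

    def test_default_layouts_tile_without_overlap(self):
        for posture in ("supine", "lateral"):
            specs = default_region_layout(posture)
            acc = np.zeros(GRID_SHAPE, dtype=int)
            for s in specs:
                acc += s.mask()
            assert acc.max() == 1
            assert {s.label for s in specs} == {"head", "chest", "waist", "hips", "legs"}

    def test_yaml_layout_round_trip(self, tmp_path):
        import yaml

        specs = default_region_layout("supine")
        p = tmp_path / "regions.yaml"
        p.write_text(
            yaml.safe_dump(
                [
                    {"label": s.label, "x_b": s.x_b, "y_b": s.y_b,
                     "x_e": s.x_e, "y_e": s.y_e}
                    for s in specs
                ]
            )
        )
        assert load_region_layout(p) == specs


class TestBoundaryConditionExport:
    def test_si_round_trip(self, rng, tmp_path):
        fld = _random_field(rng)
        wrenches = reduce_regions(fld, default_region_layout("supine"))
        p = tmp_path / "bc.json"
        export_boundary_conditions(wrenches, "supine", p)
        back = import_boundary_conditions(p)["supine"]
        for w, b in zip(wrenches, back):
            assert b.label == w.label
            np.testing.assert_allclose(b.F_A, w.F_A, rtol=1e-12)
            np.testing.assert_allclose(b.M_A, w.M_A, rtol=1e-9, atol=1e-9)
            np.testing.assert_allclose(b.r_A, w.r_A, rtol=1e-9, atol=1e-9)

    def test_two_postures_two_blocks(self, rng, tmp_path):
        import json

        fld = _random_field(rng)
        p = tmp_path / "bc.json"
        for posture in ("supine", "lateral"):
            wr = reduce_regions(fld, default_region_layout(posture))
            export_boundary_conditions(wr, posture, p)
        payload = json.loads(p.read_text())
        assert set(payload["postures"]) == {"supine", "lateral"}

    def test_empty_list_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_boundary_conditions([], "supine", tmp_path / "bc.json")
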