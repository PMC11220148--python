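import dataclasses

import numpy as np
import pytest

from mattforce.cloud import SurfaceCloud
from mattforce.forcefield import (
    CoverageError,
    DegenerateCellError,
    FrameMismatchError,
    VectorForceField,
    bin_points_to_cells,
    cell_mean_unit_normal,
    compute_cell_normals,
    compute_force_field,
    compute_vector_force,
)
from mattforce.pressure import CELL_PITCH_MM, GRID_SHAPE, PressureGrid


class TestBinning:
    def test_lower_left_corner_point_belongs_to_cell(self, simple_grid):
        """A point exactly on a cell's lower-left corner maps to that cell."""
        p = CELL_PITCH_MM
        cloud = SurfaceCloud(np.array([[3 * p, 7 * p, 0.0]]), frame="mat")
        binning = bin_points_to_cells(cloud, simple_grid)
        assert binning.counts[3, 7] == 1
        assert binning.counts.sum() == 1

    def test_uniform_sampling_gives_equal_counts(self, simple_grid):
        """A 1 mm lattice over the footprint fills every cell near-evenly."""
        xs = np.arange(0.5, GRID_SHAPE[0] * CELL_PITCH_MM, 1.0)
        ys = np.arange(0.5, GRID_SHAPE[1] * CELL_PITCH_MM, 1.0)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        cloud = SurfaceCloud(
            np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)]), frame="mat"
        )
        binning = bin_points_to_cells(cloud, simple_grid)
        assert binning.n_discarded == 0
        assert binning.counts.min() >= 36**2
        assert binning.counts.max() <= 37**2

    def test_outside_point_discarded_and_counted(self, simple_grid):
        cloud = SurfaceCloud(np.array([[-1.0, 10.0, 0.0], [10.0, 10.0, 0.0]]), frame="mat")
        binning = bin_points_to_cells(cloud, simple_grid)
        assert binning.n_discarded == 1
        assert binning.counts.sum() == 1

    def test_frame_mismatch_raises(self, simple_grid):
        cloud = SurfaceCloud(np.zeros((1, 3)), frame="scan")
        with pytest.raises(FrameMismatchError):
            bin_points_to_cells(cloud, simple_grid)


class TestCellMeanNormal:
    def test_identical_normals_pass_through(self):
        out = cell_mean_unit_normal(np.tile([0.0, 0.0, 1.0], (5, 1)))
        np.testing.assert_allclose(out, [0, 0, 1])

    def test_two_orthogonal_normals_average_to_diagonal(self):
        out = cell_mean_unit_normal(np.array([[1.0, 0, 0], [0, 0, 1.0]]))
        np.testing.assert_allclose(out, [0.7071, 0, 0.7071], atol=1e-4)

    def test_cancelling_normals_raise_degenerate(self):
        with pytest.raises(DegenerateCellError):
            cell_mean_unit_normal(np.array([[1.0, 0, 0], [-1.0, 0, 0]]))

    def test_result_is_unit_length(self, rng):
        v = rng.normal(size=(20, 3))
        v[:, 2] = np.abs(v[:, 2])
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        assert np.linalg.norm(cell_mean_unit_normal(v)) == pytest.approx(1.0, abs=1e-9)


class TestVectorForce:
    def test_flat_normal_gives_vertical_force(self):
        """5.38 N through a flat cell is purely vertical: (0, 0, 5.38)."""
        np.testing.assert_allclose(
            compute_vector_force(5.38, [0.0, 0.0, 1.0]), [0.0, 0.0, 5.38]
        )

    def test_zero_force_gives_zero_vector(self):
        np.testing.assert_allclose(
            compute_vector_force(0.0, [0.0, 0.0, 1.0]), np.zeros(3)
        )

    @pytest.mark.parametrize(
        "printed",
        [(-4.91, 1.67, 6.50), (-5.61, -1.90, 7.42)],
        ids=["tilted_left", "tilted_right"],
    )
    def test_printed_vector_decomposition_recomposes(self, printed):
        """Magnitude x unit-direction decomposition reproduces worked vectors.

        Splitting a known tilted cell force into F = |v| and n = v/|v| and
        recomposing via F*n must give the vector back to 2 decimals.
        """
        v = np.asarray(printed)
        F = np.linalg.norm(v)
        n = v / F
        out = compute_vector_force(F, n)
        np.testing.assert_allclose(out, v, atol=5e-3)

    def test_magnitude_equals_scalar_force(self, rng):
        for _ in range(20):
            n = rng.normal(size=3)
            n[2] = abs(n[2])
            n /= np.linalg.norm(n)
            F = rng.uniform(0, 50)
            assert np.linalg.norm(compute_vector_force(F, n)) == pytest.approx(F, abs=1e-9)

    def test_non_unit_normal_rejected(self):
        with pytest.raises(ValueError):
            compute_vector_force(1.0, [0.0, 0.0, 0.5])


def _flat_cloud_over(grid, z=0.0):
    xs = np.arange(2.0, GRID_SHAPE[0] * CELL_PITCH_MM, 7.0)
    ys = np.arange(2.0, GRID_SHAPE[1] * CELL_PITCH_MM, 7.0)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, z)])
    normals = np.tile([0.0, 0.0, 1.0], (pts.shape[0], 1))
    return SurfaceCloud(pts, normals, frame="mat")


class TestForceField:
    def test_flat_normals_give_vertical_field(self, simple_grid):
        cloud = _flat_cloud_over(simple_grid)
        normals = compute_cell_normals(cloud, simple_grid)
        field = compute_force_field(simple_grid, normals, cloud=cloud)
        np.testing.assert_allclose(field.forces[..., :2], 0.0, atol=1e-12)
        np.testing.assert_allclose(field.forces[..., 2], simple_grid.values)

    def test_zero_grid_gives_zero_field(self):
        grid = PressureGrid(np.zeros(GRID_SHAPE))
        cloud = _flat_cloud_over(grid)
        field = compute_force_field(grid, compute_cell_normals(cloud, grid), cloud=cloud)
        assert np.all(field.forces == 0)

    def test_magnitude_conservation_per_cell(self, supine_case):
        scenario, cloud, grid, truth = supine_case
        mat = dataclasses.replace(
            cloud,
            points=truth.true_transform.inverse().apply(cloud.points),
            normals=cloud.normals @ truth.true_transform.rotation,
            frame="mat",
        )
        field = compute_force_field(grid, compute_cell_normals(mat, grid), cloud=mat)
        mags = np.linalg.norm(field.forces, axis=-1)
        np.testing.assert_allclose(mags, field.scalar_forces, atol=1e-9)

    def test_total_magnitude_at_least_vertical_sum(self, supine_case):
        scenario, cloud, grid, truth = supine_case
        mat = dataclasses.replace(
            cloud,
            points=truth.true_transform.inverse().apply(cloud.points),
            normals=cloud.normals @ truth.true_transform.rotation,
            frame="mat",
        )
        field = compute_force_field(grid, compute_cell_normals(mat, grid), cloud=mat)
        total_mag = np.linalg.norm(field.forces, axis=-1).sum()
        assert total_mag >= field.forces[..., 2].sum()
        assert np.all(field.forces[..., 2] >= 0)

    def test_analytic_scenario_field_within_2pct_rms(self, supine_case):
        """With the true transform, per-cell forces match analytic F*n closely."""
        scenario, cloud, grid, truth = supine_case
        mat = dataclasses.replace(
            cloud,
            points=truth.true_transform.inverse().apply(cloud.points),
            normals=cloud.normals @ truth.true_transform.rotation,
            frame="mat",
        )
        field = compute_force_field(grid, compute_cell_normals(mat, grid), cloud=mat)
        m = truth.true_grid.values > 0
        err = field.forces[m] - truth.true_forces[m]
        rms = np.sqrt((err**2).sum(1).mean()) / np.sqrt(
            (truth.true_forces[m] ** 2).sum(1).mean()
        )
        assert rms < 0.02

    def test_empty_cell_policies(self, simple_grid):
        # cloud that covers everything except the loaded patch -> shadows
        cloud = _flat_cloud_over(simple_grid)
        keep = ~(
            (cloud.points[:, 0] >= 10 * CELL_PITCH_MM)
            & (cloud.points[:, 0] < 14 * CELL_PITCH_MM)
            & (cloud.points[:, 1] >= 20 * CELL_PITCH_MM)
            & (cloud.points[:, 1] < 28 * CELL_PITCH_MM)
        )
        shadowed = SurfaceCloud(cloud.points[keep], cloud.normals[keep], frame="mat")
        normals = compute_cell_normals(shadowed, simple_grid)
        with pytest.raises(CoverageError):
            compute_force_field(simple_grid, normals, cloud=shadowed, policy="strict")
        for policy in ("vertical", "nearest"):
            field = compute_force_field(
                simple_grid, normals, cloud=shadowed, policy=policy
            )
            # all shadowed neighbors are flat, so both policies give vertical
            np.testing.assert_allclose(field.forces[..., 2], simple_grid.values)

    def test_csv_round_trip(self, simple_grid, tmp_path):
        cloud = _flat_cloud_over(simple_grid)
        field = compute_force_field(
            simple_grid, compute_cell_normals(cloud, simple_grid), cloud=cloud
        )
        p = tmp_path / "field.csv"
        field.to_csv(p)
        back = VectorForceField.from_csv(p)
        np.testing.assert_allclose(back.forces, field.forces)
        np.testing.assert_allclose(back.scalar_forces, field.scalar_forces)
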