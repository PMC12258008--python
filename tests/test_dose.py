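import numpy as np
import pytest

from scenariofree import (
    Beam,
    GeometryError,
    KernelParams,
    PencilBeamEngine,
    RadiologicalDepthMap,
    Scenario,
    ValidationError,
    VoxelGrid,
    apply_range_error,
    compute_dose_influence,
    nominal_scenario,
    trace_radiological_depth,
)
from scenariofree.dose import _depth_dose


def _iso(grid):
    return tuple(d * s / 2.0 for d, s in zip(grid.dims, grid.spacing))


class TestRadiologicalDepth:
    @pytest.mark.parametrize("angle,axis", [(0.0, 0), (90.0, 1)])
    def test_water_phantom_rd_equals_geometric_depth(self, small_phantom, angle, axis):
        grid, _ = small_phantom
        water = VoxelGrid(grid.dims, grid.spacing, grid.origin, np.ones(grid.dims))
        beam = Beam("proton", angle, _iso(grid))
        rd = trace_radiological_depth(water, beam).rd
        depth = water.center_coords()[:, axis]  # entry plane at coordinate 0
        assert np.abs(rd - depth).max() <= 0.5 * grid.spacing[axis] + 1e-9

    def test_half_density_slab_vs_fine_ray_quadrature(self):
        dims = (20, 8, 8)
        spacing = (3.0, 3.0, 3.0)
        rho = np.ones(dims)
        rho[:10] = 0.5  # 30 mm slab of density 0.5 at the entry surface
        grid = VoxelGrid(dims, spacing, (1.5, 1.5, 1.5), rho)
        beam = Beam("proton", 0.0, _iso(grid))
        rd = trace_radiological_depth(grid, beam).rd.reshape(dims)

        # oracle: fine-step nearest-neighbor ray integration
        def oracle(depth_mm):
            h = 0.01
            pts = np.arange(0, depth_mm, h) + h / 2
            idx = np.clip((pts / 3.0).astype(int), 0, dims[0] - 1)
            dens = np.where(idx < 10, 0.5, 1.0)
            return dens.sum() * h

        for ix in (4, 9, 10, 15):
            depth = (ix + 0.5) * 3.0
            assert rd[ix, 4, 4] == pytest.approx(oracle(depth), abs=1.0)
        # the printed slab relation: rd at 30 mm geometric depth is 15 mm
        assert oracle(30.0) == pytest.approx(15.0, abs=0.01)

    def test_rd_nondecreasing_along_ray(self, small_phantom):
        grid, _ = small_phantom
        beam = Beam("proton", 0.0, _iso(grid))
        rd = trace_radiological_depth(grid, beam).rd.reshape(grid.dims)
        assert np.all(np.diff(rd, axis=0) >= -1e-9)


class TestRangeError:
    def test_identity_at_nominal(self):
        m = RadiologicalDepthMap(np.array([0.0, 50.0, 100.0]), np.ones(3, bool))
        out = apply_range_error(m, 0.0, 1.0)
        assert np.array_equal(out.rd, m.rd)

    def test_printed_arithmetic(self):
        m = RadiologicalDepthMap(np.array([100.0]), np.ones(1, bool))
        assert apply_range_error(m, 1.0, 1.035).rd[0] == pytest.approx(104.5)

    def test_negative_results_clamped(self):
        m = RadiologicalDepthMap(np.array([1.0]), np.ones(1, bool))
        assert apply_range_error(m, -5.0, 1.0).rd[0] == 0.0

    def test_invalid_parameters_raise(self):
        m = RadiologicalDepthMap(np.array([1.0]), np.ones(1, bool))
        with pytest.raises(ValidationError):
            apply_range_error(m, np.nan, 1.0)
        with pytest.raises(ValidationError):
            apply_range_error(m, 0.0, -0.5)


class TestDoseInfluence:
    def test_nominal_scenario_reproduces_nominal_matrix_exactly(self, small_engine):
        a = small_engine.influence(nominal_scenario()).matrix
        b = small_engine.influence(
            Scenario(shift=(0, 0, 0), c_abs=0.0, c_rel=1.0)
        ).matrix
        assert (a != b).nnz == 0

    def test_proton_rbe_scales_dose_by_1p1(self, small_phantom):
        grid, sset = small_phantom
        beam = Beam("proton", 0.0, _iso(grid), beamlet_spacing=6.0,
                    field_halfwidth=6.0, ranges=(30.0,))
        d_def = compute_dose_influence(small_phantom, [beam], nominal_scenario())
        d_one = compute_dose_influence(
            small_phantom, [beam], nominal_scenario(),
            kernel=KernelParams(rbe=1.0),
        )
        ratio = d_def.matrix.sum() / d_one.matrix.sum()
        assert ratio == pytest.approx(1.1, rel=1e-12)

    def test_column_sum_matches_analytic_kernel_quadrature(self):
        # single central beamlet on a water box
        dims, sp = (20, 20, 20), 3.0
        grid = VoxelGrid(dims, (sp,) * 3, (1.5, 1.5, 1.5), np.ones(dims))
        iso = _iso(grid)
        kernel = KernelParams(rbe=1.0, sparsity_cutoff=1e-8)
        beam = Beam("proton", 0.0, iso, beamlet_spacing=30.0,
                    field_halfwidth=10.0, ranges=(30.0,))
        D = PencilBeamEngine([(grid, _body_only(grid))], [beam], kernel,
                             reference_phase=0).influence(nominal_scenario())
        assert D.matrix.shape[1] == 1
        col_sum = float(D.matrix.sum()) * sp**3

        # oracle: fine-grid quadrature of the same analytic kernel in water
        h = 0.75
        xs = np.arange(h / 2, 60.0, h)
        ys = np.arange(h / 2, 60.0, h) - iso[1]
        zs = ys.copy()
        dd = _depth_dose(xs, "proton", 30.0, kernel)
        sig = kernel.lateral_sigma0 + kernel.lateral_growth * xs
        lat_y = np.exp(-(ys[None, :] ** 2) / (2 * sig[:, None] ** 2))
        lat_z = np.exp(-(zs[None, :] ** 2) / (2 * sig[:, None] ** 2))
        integral = float(
            np.einsum("x,xy,xz->", dd, lat_y, lat_z) * h**3
        )
        assert col_sum == pytest.approx(integral, rel=0.01)

    def test_whole_voxel_lateral_shift_translates_column(self):
        # static-dose-cloud check: valid on a *homogeneous* phantom
        dims, sp = (20, 20, 20), 3.0
        grid = VoxelGrid(dims, (sp,) * 3, (1.5, 1.5, 1.5), np.ones(dims))
        beam = Beam("proton", 0.0, _iso(grid), beamlet_spacing=6.0,
                    field_halfwidth=9.0)
        eng = PencilBeamEngine([(grid, _body_only(grid))], [beam],
                               reference_phase=0)
        central = next(
            j for j, (bi, a, b, r) in enumerate(eng.beamlets)
            if a == 0.0 and b == 0.0
        )
        nom = eng.influence(nominal_scenario()).matrix[:, central]
        shifted = eng.influence(Scenario(shift=(0.0, 3.0, 0.0))).matrix[:, central]
        nom3 = np.asarray(nom.todense()).reshape(grid.dims)
        sh3 = np.asarray(shifted.todense()).reshape(grid.dims)
        rolled = np.roll(nom3, 1, axis=1)
        rolled[:, 0, :] = sh3[:, 0, :]  # boundary plane enters the grid
        assert np.abs(sh3 - rolled).max() < 1e-10

    def test_along_axis_shift_translates_column_on_water(self):
        dims, sp = (20, 12, 12), 3.0
        grid = VoxelGrid(dims, (sp,) * 3, (1.5, 1.5, 1.5), np.ones(dims))
        beam = Beam("proton", 0.0, _iso(grid), beamlet_spacing=30.0,
                    field_halfwidth=10.0, ranges=(30.0,))
        eng = PencilBeamEngine([(grid, _body_only(grid))], [beam],
                               KernelParams(rbe=1.0), reference_phase=0)
        nom = np.asarray(
            eng.influence(nominal_scenario()).matrix[:, 0].todense()
        ).reshape(dims)
        sh = np.asarray(
            eng.influence(Scenario(shift=(3.0, 0.0, 0.0))).matrix[:, 0].todense()
        ).reshape(dims)
        rolled = np.roll(nom, 1, axis=0)
        rolled[0] = sh[0]
        assert np.abs(sh - rolled).max() < 1e-10

    def test_positive_c_abs_moves_bragg_peak_proximally(self):
        # rd' = rd * c_rel + c_abs: a positive absolute range error deepens
        # the water-equivalent depth, so the peak sits at a *shallower*
        # geometric depth (undershoot).
        dims, sp = (40, 12, 12), 3.0
        grid = VoxelGrid(dims, (sp,) * 3, (1.5, 1.5, 1.5), np.ones(dims))
        beam = Beam("proton", 0.0, _iso(grid), beamlet_spacing=40.0,
                    field_halfwidth=12.0, ranges=(60.0,))
        eng = PencilBeamEngine([(grid, _body_only(grid))], [beam],
                               KernelParams(), reference_phase=0)
        argmaxes = []
        for c_abs in (-6.0, -3.0, 0.0, 3.0, 6.0):
            col = np.asarray(
                eng.influence(Scenario(c_abs=c_abs)).matrix[:, 0].todense()
            ).reshape(dims)
            argmaxes.append(int(np.argmax(col[:, 6, 6])))
        assert all(a >= b for a, b in zip(argmaxes, argmaxes[1:]))

    def test_matrix_is_sparse_and_nonnegative(self, small_engine):
        D = small_engine.influence(nominal_scenario()).matrix
        assert D.data.min() >= 0
        assert 1.0 - D.nnz / (D.shape[0] * D.shape[1]) > 0.5

    def test_beam_missing_grid_raises(self, small_phantom):
        grid, _ = small_phantom
        beam = Beam("photon", 45.0, _iso(grid))
        bad = Beam.__new__(Beam)  # bypass init to craft an impossible direction
        with pytest.raises(GeometryError):
            rdm = trace_radiological_depth(
                grid, _degenerate_beam(_iso(grid))
            )

    def test_influence_matrix_market_round_trip(self, small_engine, tmp_path):
        from scenariofree.io import read_influence, write_influence

        D = small_engine.influence(Scenario(shift=(1.0, -2.0, 0.5), c_abs=0.3,
                                            c_rel=0.98))
        grid = small_engine.phases[0][0]
        write_influence(tmp_path / "d_s", D, grid.dims)
        D2, dims = read_influence(tmp_path / "d_s")
        assert dims == grid.dims
        assert (D.matrix != D2.matrix).nnz == 0
        assert D2.scenario == D.scenario
        assert D2.beamlets == D.beamlets


def _body_only(grid):
    from scenariofree import StructureSet

    idx = np.arange(grid.nvox, dtype=np.int64)
    target = np.array([np.ravel_multi_index(
        tuple(d // 2 for d in grid.dims), grid.dims)])
    return StructureSet({"body": idx, "target": target},
                        {"body": "body", "target": "target"})


class _degenerate_beam:
    """Beam stand-in whose direction has no in-plane component."""

    modality = "photon"

    def __init__(self, iso):
        self.isocenter = iso

    def frame(self):
        return (
            np.array([0.0, 0.0, 0.0]),
            np.array([0.0, 1.0, 0.0]),
            np.array([0.0, 0.0, 1.0]),
        )
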