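"""Freezing-rate extraction, the crystal-size correlation and averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryogel.pores import freezing_rate_field, pore_diameter, pore_map, volume_average
from cryogel.solver import CRYOGEL, AxiGrid, ProcessConfig, SimulationResult, _finalize


def _unit_cylinder_grid(nr=200, nz=1):
    """Axisymmetric r in [0,1], z in [0,1] grid, all gel."""
    r_faces = np.linspace(0.0, 1.0, nr + 1)
    z_faces = np.linspace(0.0, 1.0, nz + 1)
    region = np.full((nz, nr), CRYOGEL, dtype=int)
    vol = (np.pi * (r_faces[1:] ** 2 - r_faces[:-1] ** 2))[None, :] * np.diff(z_faces)[:, None]
    grid = AxiGrid(r_faces, z_faces, region, vol, axisymmetric=True)
    return _finalize(grid, lambda rf, zf: "adiabatic")


class TestPoreDiameter:
    @pytest.mark.parametrize("vc,dp", [(1.0, 50.0), (16.0, 25.0), (0.0625, 100.0)])
    def test_correlation_spot_values(self, vc, dp):
        assert pore_diameter(vc) == pytest.approx(dp, rel=1e-12)

    def test_nonpositive_rate_rejected(self):
        for bad in (0.0, -1.0, float("nan")):
            with pytest.raises(ValueError):
                pore_diameter(bad)

    @given(st.floats(min_value=1e-4, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_scale_covariance_and_monotonicity(self, v):
        assert pore_diameter(16.0 * v) == pytest.approx(pore_diameter(v) / 2.0, rel=1e-12)
        assert pore_diameter(2.0 * v) < pore_diameter(v)

    def test_uniform_rate_gives_uniform_diameter(self):
        v = np.full(7, 0.3)
        assert np.ptp(pore_diameter(v)) == 0.0


class TestVolumeAverage:
    def test_uniform_field_is_identity(self):
        grid = _unit_cylinder_grid()
        assert volume_average(np.full(grid.n_active, 3.7), grid) == pytest.approx(3.7)

    def test_radial_field_on_unit_cylinder(self):
        """f(r) = r averaged with 2*pi*r weight equals 2/3."""
        grid = _unit_cylinder_grid(nr=400)
        r, _ = grid.cell_coords()
        assert volume_average(r, grid) == pytest.approx(2.0 / 3.0, abs=1e-5)

    def test_matches_bruteforce_cell_sum(self):
        grid = _unit_cylinder_grid(nr=5, nz=5)
        rng = np.random.default_rng(42)
        field = rng.uniform(0.0, 1.0, grid.n_active)
        vol = grid.cell_volume_flat
        expected = sum(field[i] * vol[i] for i in range(grid.n_active)) / vol.sum()
        assert volume_average(field, grid) == pytest.approx(expected, abs=1e-12)

    def test_bounded_by_extremes(self):
        grid = _unit_cylinder_grid(nr=13, nz=3)
        rng = np.random.default_rng(1)
        f = rng.normal(size=grid.n_active)
        m = volume_average(f, grid)
        assert f.min() - 1e-12 <= m <= f.max() + 1e-12

    def test_missing_cells_reported(self):
        grid = _unit_cylinder_grid(nr=5)
        f = np.ones(grid.n_active)
        f[2] = np.nan
        with pytest.raises(ValueError, match="undefined"):
            volume_average(f, grid)


def _fake_result(times, T, theta):
    """Minimal SimulationResult carrying handcrafted per-cell histories."""
    return SimulationResult(
        config=ProcessConfig(), grid=None, times=times,
        cryogel_cells=np.arange(T.shape[1]), T_history=T, theta_history=theta,
        probe_traces=[], snapshot_times=np.array([]), energy_residual=0.0,
        fully_frozen=True, final_state=None,
    )


class TestFreezingRate:
    def test_constant_slope_recovered(self):
        """Linear T(t) with slope -0.02 degC/s across the window gives 0.02."""
        times = np.arange(0.0, 600.0, 1.5)
        T = 5.0 - 0.02 * times
        theta = np.clip((times - 100.0) / 300.0, 0.0, 1.0)
        res = _fake_result(times, T[:, None], theta[:, None])
        vc = freezing_rate_field(res)
        assert vc[0] == pytest.approx(0.02, rel=1e-6)

    def test_incomplete_cell_is_nan(self):
        times = np.arange(0.0, 100.0, 1.5)
        T = np.tile(5.0 - 0.02 * times, (2, 1)).T
        theta = np.zeros_like(T)
        theta[:, 0] = np.clip(times / 50.0, 0.0, 1.0)
        theta[:, 1] = np.clip(times / 1e5, 0.0, 1.0)  # never completes
        vc = freezing_rate_field(_fake_result(times, T, theta))
        assert np.isfinite(vc[0]) and np.isnan(vc[1])

    def test_no_completed_cell_raises(self):
        times = np.arange(0.0, 30.0, 1.5)
        T = np.zeros((times.size, 1))
        theta = np.zeros_like(T)
        with pytest.raises(ValueError, match="completed"):
            freezing_rate_field(_fake_result(times, T, theta))

    def test_endpoint_slope_method(self):
        times = np.arange(0.0, 600.0, 1.5)
        T = 5.0 - 0.02 * times
        theta = np.clip((times - 100.0) / 300.0, 0.0, 1.0)
        res = _fake_result(times, T[:, None], theta[:, None])
        vc = freezing_rate_field(res, method="endpoint_slope")
        assert vc[0] == pytest.approx(0.02, rel=1e-6)


class TestPoreMap:
    def test_spatial_pattern(self, sim_results):
        """Small crystals at the cooled wall, maximum between wall and core."""
        pf = pore_map(sim_results[-19.0])
        df = pf.to_dataframe()
        base = df[np.isclose(df.z_mm, df.z_mm.min())].sort_values("r_mm")
        dp = base.dp_um.to_numpy()
        r = base.r_mm.to_numpy()
        r_peak = r[np.argmax(dp)]
        assert 0.5 < r_peak < 9.5  # interior maximum
        assert dp[-1] < dp.max()  # small at the wall
        assert dp[0] < dp.max()  # smaller again toward the center

    def test_volume_average_ordering_with_bath(self, sim_results):
        """Colder bath = faster freezing = smaller volume-averaged pores."""
        means = {b: pore_map(r).mean_diameter() for b, r in sim_results.items()}
        assert means[-25.0] < means[-19.0] < means[-12.0]

    def test_dataframe_units_and_shape(self, sim_results):
        pf = pore_map(sim_results[-25.0])
        df = pf.to_dataframe()
        assert set(df.columns) == {"r_mm", "z_mm", "vc_degC_per_s", "dp_um"}
        assert len(df) == sim_results[-25.0].cryogel_cells.size
        assert (df.dp_um > 0).all() and (df.vc_degC_per_s > 0).all()

    def test_heatmap_export(self, sim_results, tmp_path):
        pf = pore_map(sim_results[-19.0])
        out = tmp_path / "pores.png"
        pf.plot(out)
        assert out.stat().st_size > 0

    def test_incomplete_freeze_raises(self):
        cfg = ProcessConfig(total_time=30.0, dt=1.0, grid_size=0.002)
        import warnings
        from cryogel.solver import run_simulation

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_simulation(cfg)
        with pytest.raises(ValueError):
            pore_map(res)
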