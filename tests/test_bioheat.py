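import numpy as np
import pytest
from scipy.integrate import quad

from mwaplan.bioheat import (
    SolverConfig,
    TemperatureField,
    TissueProperties,
    UniformSource,
    effective_cp,
    enthalpy_density,
    perfusion_rate,
    simulate,
)
from mwaplan.source import ApplicatorSource, SourceModel, UnitAbsorptionSource
from mwaplan.volumes import ApplicatorPose, VoxelGrid

# damage feedback (exp(-Omega)) is disabled in closed-form comparisons by
# making the Arrhenius frequency factor negligibly small
NO_DAMAGE = {"arrhenius_a": 1e-280}


class TestTissueProperties:
    @pytest.mark.parametrize("field", ["rho", "cp_baseline", "conductivity", "omega_b", "latent_heat"])
    def test_nonpositive_constants_rejected(self, field):
        with pytest.raises(ValueError):
            TissueProperties(**{field: 0.0})

    def test_vessel_sink_must_dominate_baseline(self):
        with pytest.raises(ValueError):
            TissueProperties(omega_b=0.01, omega_vessel=0.005)

    def test_body_temperature_range_enforced(self):
        with pytest.raises(ValueError):
            TissueProperties(t_b=25.0)

    def test_cb_less_sink_variant_drops_blood_specific_heat(self):
        props = TissueProperties(omit_sink_blood_heat=True)
        assert props.sink_c_b == 1.0
        assert TissueProperties().sink_c_b == pytest.approx(3617.0)


class TestPerfusionRate:
    def test_baseline_identity(self, props):
        assert perfusion_rate(props.t_b, 0.0, props) == pytest.approx(props.omega_b)

    def test_perfusion_ceases_with_coagulation(self, props):
        assert perfusion_rate(props.t_b, 50.0, props) < 1e-20

    def test_sublethal_hyperaemia_closed_form(self):
        props = TissueProperties(valvano_slope=0.02)
        got = perfusion_rate(props.t_b + 5.0, 0.0, props)
        assert got == pytest.approx(1.10 * props.omega_b, rel=1e-12)

    def test_vessel_voxels_use_elevated_coefficient(self, props):
        t = np.full((2, 2, 2), props.t_b)
        vessel = np.zeros((2, 2, 2), dtype=bool)
        vessel[0, 0, 0] = True
        rate = perfusion_rate(t, np.zeros_like(t), props, vessel)
        assert rate[0, 0, 0] == pytest.approx(props.omega_vessel)
        assert rate[1, 1, 1] == pytest.approx(props.omega_b)

    def test_rate_clamped_nonnegative_when_cold(self):
        props = TissueProperties(valvano_slope=0.05)
        assert perfusion_rate(props.t_b - 40.0, 0.0, props) == 0.0


class TestEffectiveCp:
    def test_far_from_evaporation_peak(self):
        props = TissueProperties(evap_width=2.0)
        assert effective_cp(37.0, props) == pytest.approx(props.cp_baseline, rel=1e-3)

    def test_peak_at_evaporation_center(self, props):
        temps = np.linspace(60.0, 140.0, 1601)
        cps = effective_cp(temps, props)
        assert temps[np.argmax(cps)] == pytest.approx(props.evap_center, abs=0.1)

    def test_bump_integrates_to_latent_heat_content(self, props):
        total, _ = quad(lambda t: effective_cp(t, props) - props.cp_baseline, 50.0, 150.0)
        assert total == pytest.approx(props.water_content * props.latent_heat, rel=0.01)

    def test_enthalpy_density_is_antiderivative(self, props):
        temps = np.linspace(40.0, 130.0, 4001)
        h = enthalpy_density(temps, props)
        dh_dt = np.gradient(h, temps)
        expected = props.rho * effective_cp(temps, props)
        assert np.allclose(dh_dt[2:-2], expected[2:-2], rtol=2e-3)


class TestSolverClosedForms:
    def test_equilibrium_field_unchanged(self, props):
        grid = VoxelGrid(shape=(12, 12, 12))
        res = simulate(grid, 30.0, props, None, SolverConfig(dt=5.0, snapshot_interval=30.0))
        assert np.allclose(res.final.values, props.t_b, atol=1e-9)

    def test_insulated_uniform_source_heating(self):
        props = TissueProperties(**NO_DAMAGE)
        grid = VoxelGrid(shape=(8, 8, 8))
        q = 1e5  # W/m^3
        cfg = SolverConfig(dt=1.0, boundary="insulated", enable_perfusion=False,
                           snapshot_interval=100.0)
        res = simulate(grid, 10.0, props, UniformSource(q), cfg)
        expected = props.t_b + q * 10.0 / (props.rho * props.cp_baseline)
        assert np.allclose(res.final.values, expected, rtol=1e-6)

    def test_perfusion_only_exponential_decay(self):
        props = TissueProperties(valvano_slope=1e-15, **NO_DAMAGE)
        grid = VoxelGrid(shape=(8, 8, 8))
        t0 = 45.0
        cfg = SolverConfig(dt=0.1, enable_diffusion=False, snapshot_interval=300.0)
        res = simulate(grid, 300.0, props, None, cfg, initial=t0)
        k = props.omega_b * props.rho_b * props.c_b / (props.rho * props.cp_baseline)
        exact = props.t_b + (t0 - props.t_b) * np.exp(-k * 300.0)
        rel_err = abs(res.final.values[4, 4, 4] - exact) / (exact - props.t_b)
        assert rel_err < 0.005

    def test_free_diffusion_matches_heat_kernel(self):
        props = TissueProperties(**NO_DAMAGE)
        alpha = props.conductivity / (props.rho * props.cp_baseline)
        grid = VoxelGrid(shape=(48, 48, 48), spacing=(0.5, 0.5, 0.5))
        c = grid.center()
        x, y, z = grid.coordinate_arrays()
        r2_m = ((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2) * 1e-6
        t0, dT, t_end = 15.0, 10.0, 10.0
        initial = props.t_b + dT * np.exp(-r2_m / (4 * alpha * t0))
        cfg = SolverConfig(dt=0.1, enable_perfusion=False, snapshot_interval=t_end, cg_tol=1e-9)
        res = simulate(grid, t_end, props, None, cfg,
                       initial=TemperatureField(grid=grid, values=initial))
        exact = props.t_b + dT * (t0 / (t0 + t_end)) ** 1.5 * np.exp(
            -r2_m / (4 * alpha * (t0 + t_end))
        )
        linf = np.abs(res.final.values - exact).max() / dT
        assert linf < 0.01


class TestSolverProperties:
    def test_maximum_principle_without_source(self, props):
        grid = VoxelGrid(shape=(20, 20, 20))
        rng = np.random.default_rng(3)
        from scipy.ndimage import gaussian_filter

        bump = gaussian_filter(rng.random(grid.shape), 3.0)
        initial = props.t_b + 30.0 * (bump - bump.min()) / (bump.max() - bump.min())
        cfg = SolverConfig(dt=2.0, snapshot_interval=10.0)
        res = simulate(grid, 60.0, props, None, cfg,
                       initial=TemperatureField(grid=grid, values=initial))
        maxima = [s.values.max() for s in res.snapshots]
        assert all(b <= a + 1e-9 for a, b in zip(maxima, maxima[1:]))
        assert all(s.values.min() >= props.t_b - 1e-9 for s in res.snapshots)

    def test_energy_balance_insulated_applicator_source(self):
        props = TissueProperties(**NO_DAMAGE)
        grid = VoxelGrid(shape=(48, 48, 48))
        pose = ApplicatorPose(tip=(34.0, 24.0, 24.0), direction=(1.0, 0.0, 0.0))
        power, t_end = 40.0, 30.0
        src = UnitAbsorptionSource(SourceModel(), pose, grid, power)
        cfg = SolverConfig(dt=0.5, boundary="insulated", enable_perfusion=False,
                           snapshot_interval=t_end)
        res = simulate(grid, t_end, props, src, cfg)
        vox_m3 = grid.voxel_volume_mm3 * 1e-9
        gain = (
            enthalpy_density(res.final.values, props).sum()
            - enthalpy_density(np.full(grid.shape, props.t_b), props).sum()
        ) * vox_m3
        assert gain == pytest.approx(power * t_end, rel=0.01)

    def test_vessel_branch_strictly_reduces_ablation(self, props, ref_model):
        grid = VoxelGrid(shape=(64, 64, 64))
        pose = ApplicatorPose(tip=(42.0, 32.0, 32.0), direction=(1.0, 0.0, 0.0))
        src = ApplicatorSource(ref_model, pose, grid, 100.0)
        cfg = SolverConfig(dt=5.0, snapshot_interval=60.0)
        res_free = simulate(grid, 180.0, props, src, cfg)
        vessel = np.zeros(grid.shape, dtype=bool)
        x, _, _ = grid.coordinate_arrays()
        y = grid.world_axes()[1][None, :, None]
        z = grid.world_axes()[2][None, None, :]
        # 3 mm-radius vessel running along x, 8 mm lateral to the applicator axis
        vessel |= ((y - 40.0) ** 2 + (z - 32.0) ** 2) <= 3.0**2
        res_vessel = simulate(grid, 180.0, props, src, cfg, vessel_mask=vessel)
        vol_free = int((res_free.damage_omega >= 1.0).sum())
        vol_vessel = int((res_vessel.damage_omega >= 1.0).sum())
        assert vol_vessel < vol_free

    def test_vessel_wall_stays_below_coagulation(self, props, ref_model):
        grid = VoxelGrid(shape=(64, 64, 64))
        pose = ApplicatorPose(tip=(42.0, 32.0, 32.0), direction=(1.0, 0.0, 0.0))
        src = ApplicatorSource(ref_model, pose, grid, 100.0)
        y = grid.world_axes()[1][None, :, None]
        z = grid.world_axes()[2][None, None, :]
        vessel = ((y - 40.0) ** 2 + (z - 32.0) ** 2) <= 3.0**2
        vessel = np.broadcast_to(vessel, grid.shape)
        res = simulate(grid, 300.0, props, src, SolverConfig(dt=5.0, snapshot_interval=300.0),
                       vessel_mask=vessel)
        assert res.peak.values[vessel].max() < 50.0

    def test_peak_temperature_converges_under_grid_refinement(self, props, ref_model):
        peaks = []
        for spacing in (1.0, 0.5):
            n = int(32 / spacing)
            grid = VoxelGrid(shape=(n,) * 3, spacing=(spacing,) * 3)
            c = grid.center()
            pose = ApplicatorPose(tip=tuple(c + np.array([8.0, 0, 0])),
                                  direction=(1.0, 0.0, 0.0), active_zone_length=16.0)
            src = ApplicatorSource(ref_model, pose, grid, 60.0)
            cfg = SolverConfig(dt=0.5, snapshot_interval=40.0)
            res = simulate(grid, 40.0, props, src, cfg)
            peaks.append(res.peak.values.max())
        assert abs(peaks[1] - peaks[0]) / peaks[1] < 0.02

    def test_determinism_bitwise(self, props, ref_model):
        grid = VoxelGrid(shape=(32, 32, 32))
        pose = ApplicatorPose(tip=(24.0, 16.0, 16.0), direction=(1.0, 0.0, 0.0))
        src = ApplicatorSource(ref_model, pose, grid, 80.0)
        cfg = SolverConfig(dt=2.0, snapshot_interval=30.0)
        a = simulate(grid, 60.0, props, src, cfg)
        b = simulate(grid, 60.0, props, src, cfg)
        assert np.array_equal(a.final.values, b.final.values)
        assert np.array_equal(a.damage_omega, b.damage_omega)
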