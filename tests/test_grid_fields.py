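"""Lattice geometry, indicator masks and reaction-diffusion oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from angiosim.cells import TumorCell
from angiosim.config import DiffusionParams, GridConfig, SimulationConfig
from angiosim.errors import ConfigurationError, ConsistencyError, NumericalError
from angiosim.grid import (Grid3D, Indicators, ScalarField, make_grid, rebuild_indicators,
                           stable_dt, step_drug_field, step_fibronectin_field,
                           step_nutrient_field, step_taf_field)
from angiosim.vessels import TipEC, VesselNetwork

from conftest import empty_indicators


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

class TestMakeGrid:
    def test_voxel_count(self):
        grid = make_grid(GridConfig(shape=(20, 20, 20), spacing=10.0))
        assert grid.n_voxels == 8000

    def test_smallest_legal_grid(self):
        assert make_grid(GridConfig(shape=(3, 3, 3))).n_voxels == 27

    @pytest.mark.parametrize("bad", [
        {"shape": (2, 3, 3)}, {"shape": (3, 3)}, {"spacing": 0.0}, {"spacing": -4.0},
    ])
    def test_invalid_geometry_names_offending_key(self, bad):
        with pytest.raises(ConfigurationError) as err:
            make_grid(GridConfig(**bad))
        assert list(bad)[0] in str(err.value)

    def test_index_location_mapping_is_bijective(self, small_grid):
        seen = set()
        for x in range(6):
            for y in range(6):
                for z in range(6):
                    pos = small_grid.voxel_center((x, y, z))
                    assert small_grid.locate(pos) == (x, y, z)
                    seen.add(pos)
        assert len(seen) == small_grid.n_voxels


class TestIndicators:
    def test_empty_system_all_zero(self, small_grid):
        ind = rebuild_indicators([], VesselNetwork(), small_grid)
        for mask in (ind.chi_ves, ind.chi_tum, ind.chi_tipEC):
            assert mask.sum() == 0

    def test_single_living_cell(self, small_grid):
        cell = TumorCell(id=0, position=(2, 3, 4))
        ind = rebuild_indicators([cell], VesselNetwork(), small_grid)
        assert ind.chi_tum[2, 3, 4] == 1 and ind.chi_tum.sum() == 1

    def test_apoptotic_agents_excluded(self, small_grid):
        dead_cell = TumorCell(id=0, position=(1, 1, 1), phenotype="apoptotic")
        net = VesselNetwork()
        net.tips.append(TipEC(position=(2, 2, 2), sprout_id=0, active=False))
        ind = rebuild_indicators([dead_cell], net, small_grid)
        assert ind.chi_tum.sum() == 0
        assert ind.chi_tipEC[2, 2, 2] == 0 and ind.chi_tipEC.sum() == 0

    def test_agent_outside_grid_raises(self, small_grid):
        with pytest.raises(ConsistencyError):
            rebuild_indicators([TumorCell(id=0, position=(9, 0, 0))],
                               VesselNetwork(), small_grid)


# ---------------------------------------------------------------------------
# solver oracles
# ---------------------------------------------------------------------------

def _field(grid, value=1.0, **params):
    return ScalarField("glucose", np.full(grid.shape, float(value)),
                       DiffusionParams(**params))


class TestSolverOracles:
    def test_all_rates_zero_is_identity(self, small_grid, rng):
        values = rng.uniform(0, 2, small_grid.shape)
        f = ScalarField("glucose", values.copy(), DiffusionParams())
        step_nutrient_field(f, empty_indicators(small_grid), small_grid, 0.5)
        np.testing.assert_array_equal(f.values, values)

    def test_pure_decay_matches_exponential(self, small_grid):
        delta, dt, n = 0.05, 0.02, 200
        f = _field(small_grid, value=2.0, delta=delta)
        for _ in range(n):
            step_nutrient_field(f, empty_indicators(small_grid), small_grid, dt)
        expected = 2.0 * np.exp(-delta * dt * n)
        np.testing.assert_allclose(f.values, expected, rtol=2e-3)

    def test_mass_conserved_without_reactions(self, small_grid, rng):
        f = ScalarField("glucose", rng.uniform(0, 1, small_grid.shape),
                        DiffusionParams(D=400.0))
        dt = stable_dt(f.params, small_grid)
        total = f.values.sum()
        for _ in range(100):
            step_nutrient_field(f, empty_indicators(small_grid), small_grid, dt)
            assert abs(f.values.sum() - total) <= 1e-10 * total
            total = f.values.sum()

    def test_vessel_exchange_relaxes_to_in_blood_level(self, small_grid):
        """Uniform vessel occupancy, no diffusion: every voxel follows the
        single-voxel exchange ODE dc/dt = q (H - c)."""
        q, H, dt, t_end = 2.0, 0.8, 0.02, 2.0
        ind = empty_indicators(small_grid)
        ind.chi_ves[:] = 1
        f = _field(small_grid, value=0.0, q=q, H=H)
        previous = 0.0
        for _ in range(int(t_end / dt)):
            step_drug_field(f, ind, small_grid, dt)
            assert f.values[0, 0, 0] >= previous  # monotone approach
            previous = f.values[0, 0, 0]
        ref = solve_ivp(lambda t, c: q * (H - c), (0, t_end), [0.0],
                        rtol=1e-10, atol=1e-12).y[0, -1]
        np.testing.assert_allclose(f.values, ref, rtol=0.02)

    def test_sink_only_mass_strictly_decreases(self, small_grid):
        ind = empty_indicators(small_grid)
        ind.chi_tum[3, 3, 3] = 1
        f = _field(small_grid, value=1.0, u=0.5)
        m0 = f.values.sum()
        step_nutrient_field(f, ind, small_grid, 0.5)
        assert f.values.sum() < m0

    def test_vessel_source_bound(self, small_grid, rng):
        """With sinks off, values never exceed max(initial, H)."""
        ind = empty_indicators(small_grid)
        ind.chi_ves[rng.uniform(size=small_grid.shape) < 0.3] = 1
        f = ScalarField("glucose", rng.uniform(0, 0.4, small_grid.shape),
                        DiffusionParams(D=300.0, q=1.5, H=0.9))
        bound = max(f.values.max(), 0.9)
        dt = stable_dt(f.params, small_grid)
        for _ in range(200):
            step_nutrient_field(f, ind, small_grid, dt)
        assert f.values.max() <= bound + 1e-12

    def test_unstable_dt_reports_admissible_bound(self, small_grid):
        f = _field(small_grid, D=1000.0)
        with pytest.raises(NumericalError) as err:
            step_nutrient_field(f, empty_indicators(small_grid), small_grid, dt=10.0)
        assert "maximum admissible" in str(err.value)


def _slab_steady_state(shape=(3, 3, 40), spacing=20.0, D=2000.0, delta=0.05,
                       q=2.0, H=1.0, n_steps=30000):
    grid = Grid3D(shape=shape, spacing=spacing)
    ind = Indicators(chi_ves=np.zeros(shape, np.uint8),
                     chi_tum=np.zeros(shape, np.uint8),
                     chi_tipEC=np.zeros(shape, np.uint8))
    ind.chi_ves[:, :, 0] = 1
    f = ScalarField("glucose", np.zeros(shape), DiffusionParams(D=D, q=q, H=H, delta=delta))
    dt = stable_dt(f.params, grid)
    for _ in range(n_steps):
        step_nutrient_field(f, ind, grid, dt)
    return grid, f


class TestSlabBoundaryLayer:
    """1-D slab with a vessel plane at z=0 and uniform decay: the steady
    state away from the source follows the analytic boundary-layer profile
    c(z) ~ cosh((L - z)/ell) with ell = sqrt(D/delta)."""

    def test_profile_matches_analytic_within_two_percent(self):
        grid, f = _slab_steady_state()
        D, delta = f.params.D, f.params.delta
        ell = np.sqrt(D / delta)
        profile = f.values[1, 1, :]
        z = (np.arange(40) + 0.5) * grid.spacing
        L = 40 * grid.spacing
        analytic = np.cosh((L - z) / ell)
        z0 = 2
        ratio = profile[z0:30] / profile[z0]
        expected = analytic[z0:30] / analytic[z0]
        np.testing.assert_allclose(ratio, expected, rtol=0.02)

    def test_refinement_changes_profile_within_scheme_order(self):
        coarse_grid, coarse = _slab_steady_state()
        fine_grid, fine = _slab_steady_state(shape=(3, 3, 80), spacing=10.0,
                                             n_steps=120000)
        cp = coarse.values[1, 1, 2:30] / coarse.values[1, 1, 2]
        # physical centres of coarse voxels 2.. coincide with fine voxel pairs
        fp = fine.values[1, 1, :].reshape(40, 2).mean(axis=1)
        fp = fp[2:30] / fp[2]
        assert np.max(np.abs(cp - fp) / fp) < 0.02


class TestTafField:
    def test_no_source_decays_to_zero(self, small_grid):
        f = ScalarField("taf", np.full(small_grid.shape, 0.5),
                        DiffusionParams(delta=0.1))
        for _ in range(100):
            step_taf_field(f, empty_indicators(small_grid), small_grid, 0.5)
        assert f.values.max() < 0.01

    def test_single_secreting_cell_mass_grows_linearly(self, small_grid):
        ind = empty_indicators(small_grid)
        ind.chi_tum[2, 2, 2] = 1
        rate = 0.04
        f = ScalarField("taf", np.zeros(small_grid.shape),
                        DiffusionParams(D=500.0, secretion=rate))
        dt = stable_dt(f.params, small_grid)
        masses = [f.values.sum()]
        for _ in range(50):
            step_taf_field(f, ind, small_grid, dt)
            masses.append(f.values.sum())
        increments = np.diff(masses)
        np.testing.assert_allclose(increments, rate * dt, rtol=1e-9)

    def test_starvation_weights_boost_secretion(self, small_grid):
        ind = empty_indicators(small_grid)
        ind.chi_tum[2, 2, 2] = 1
        ind.taf_secretion = ind.chi_tum.astype(float) * 2.0
        f = ScalarField("taf", np.zeros(small_grid.shape),
                        DiffusionParams(secretion=0.04))
        step_taf_field(f, ind, small_grid, 0.5)
        assert f.values[2, 2, 2] == pytest.approx(0.04)  # 2x rate x 0.5 h

    def test_mirrored_sources_give_mirrored_field(self):
        grid = Grid3D(shape=(8, 5, 5), spacing=20.0)
        ind = Indicators(chi_ves=np.zeros(grid.shape, np.uint8),
                         chi_tum=np.zeros(grid.shape, np.uint8),
                         chi_tipEC=np.zeros(grid.shape, np.uint8))
        ind.chi_tum[2, 2, 2] = ind.chi_tum[5, 2, 2] = 1  # mirror pair in x
        f = ScalarField("taf", np.zeros(grid.shape),
                        DiffusionParams(D=800.0, delta=0.01, secretion=0.05))
        dt = stable_dt(f.params, grid)
        for _ in range(200):
            step_taf_field(f, ind, grid, dt)
        np.testing.assert_allclose(f.values, f.values[::-1, :, :], rtol=1e-12)

    def test_tip_consumption_is_optional(self, small_grid):
        for consumed in (True, False):
            ind = empty_indicators(small_grid)
            ind.chi_tipEC[1, 1, 1] = 1
            f = ScalarField("taf", np.full(small_grid.shape, 1.0),
                            DiffusionParams(u=0.2))
            step_taf_field(f, ind, small_grid, 1.0, consumed_by_tips=consumed)
            if consumed:
                assert f.values[1, 1, 1] == pytest.approx(0.8)
            else:
                assert f.values[1, 1, 1] == pytest.approx(1.0)


class TestFibronectinField:
    def test_zero_kinetics_identity(self, small_grid, rng):
        values = rng.uniform(0, 1, small_grid.shape)
        f = ScalarField("fibronectin", values.copy(), DiffusionParams())
        step_fibronectin_field(f, empty_indicators(small_grid), small_grid, 1.0)
        np.testing.assert_array_equal(f.values, values)

    def test_deposition_localised_to_vessels(self, small_grid):
        ind = empty_indicators(small_grid)
        ind.chi_ves[0, :, :] = 1
        f = ScalarField("fibronectin", np.full(small_grid.shape, 0.1),
                        DiffusionParams(secretion=0.05))
        step_fibronectin_field(f, ind, small_grid, 1.0)
        assert f.values[0, 3, 3] > f.values[5, 3, 3]

    def test_tip_trail_is_transverse_minimum(self, small_grid):
        """A tip marching along a straight line digs a fibronectin trench."""
        ind = empty_indicators(small_grid)
        f = ScalarField("fibronectin", np.full(small_grid.shape, 0.5),
                        DiffusionParams(u=0.1))
        for z in range(6):  # scripted straight trajectory at x=3, y=3
            ind.chi_tipEC[:] = 0
            ind.chi_tipEC[3, 3, z] = 1
            for _ in range(5):
                step_fibronectin_field(f, ind, small_grid, 1.0)
        trail = f.values[3, 3, :]
        flank = f.values[3, 2, :]
        assert np.all(trail < flank)


# ---------------------------------------------------------------------------
# nonnegativity property
# ---------------------------------------------------------------------------

@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    D=st.floats(0, 2000), q=st.floats(0, 3), H=st.floats(0, 2),
    u=st.floats(0, 1), delta=st.floats(0, 0.5), init=st.floats(0, 2),
    seed=st.integers(0, 2**16),
)
def test_fields_stay_nonnegative_and_finite(D, q, H, u, delta, init, seed):
    grid = Grid3D(shape=(5, 5, 5), spacing=25.0)
    gen = np.random.default_rng(seed)
    ind = Indicators(
        chi_ves=(gen.uniform(size=grid.shape) < 0.3).astype(np.uint8),
        chi_tum=(gen.uniform(size=grid.shape) < 0.3).astype(np.uint8),
        chi_tipEC=(gen.uniform(size=grid.shape) < 0.2).astype(np.uint8))
    f = ScalarField("glucose", gen.uniform(0, init + 1e-9, grid.shape),
                    DiffusionParams(D=D, q=q, H=H, u=u, delta=delta))
    dt = min(stable_dt(f.params, grid), 1.0)
    for _ in range(10):
        step_nutrient_field(f, ind, grid, dt)
    assert np.all(f.values >= 0) and np.all(np.isfinite(f.values))
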