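"""Geometry, mesh, stepping and the solver's physical invariants."""

import numpy as np
import pytest

import cellsolute as cs
from cellsolute.fv_solver import (
    BoundaryConfig,
    FieldState,
    Mesh,
    Stepper,
    build_mesh,
    initial_state,
)
from cellsolute.model_core import O2_KG_M3_PER_PERCENT


class TestGeometry:
    def test_compression_concentrates_cells_fortyfold(self):
        assert cs.stabilized_density(0.5e6, 40) == pytest.approx(20e6)

    def test_unit_compression_is_identity(self):
        geom40 = cs.build_geometry(compression_factor=1.0)
        assert geom40.gel_volume == pytest.approx(240e-9)
        assert cs.stabilized_density(1.5e6, 1.0) == 1.5e6

    def test_gel_height_from_volume_over_area(self):
        geom = cs.build_geometry(gel_volume_prestab_ul=240, compression_factor=40,
                                 radius_m=3.175e-3)
        # 6 uL / (pi r^2)
        assert geom.gel_height == pytest.approx(6e-9 / (np.pi * 3.175e-3**2), rel=1e-12)
        assert geom.gel_height == pytest.approx(1.9e-4, rel=0.05)

    def test_subunit_compression_rejected(self):
        with pytest.raises(ValueError):
            cs.build_geometry(compression_factor=0.5)
        with pytest.raises(ValueError):
            cs.stabilized_density(1e6, 0.9)


class TestMesh:
    def test_reference_partition(self, geometry):
        mesh = build_mesh(geometry, n_cells=100, gel_fraction=0.2)
        assert mesh.n_gel == 20
        assert mesh.n_cells - mesh.n_gel == 80
        assert mesh.interface_index == 20

    def test_rounding_floor_case(self, geometry):
        assert build_mesh(geometry, n_cells=10, gel_fraction=0.2).n_gel == 2

    @pytest.mark.parametrize("n_cells,gel_fraction", [(10, 0.2), (57, 0.31), (200, 0.5)])
    def test_widths_partition_the_column(self, geometry, n_cells, gel_fraction):
        mesh = build_mesh(geometry, n_cells, gel_fraction)
        assert mesh.cell_widths.sum() == pytest.approx(geometry.total_height, rel=1e-12)
        assert np.all(np.diff(mesh.cell_centres) > 0)
        # the gel-medium interface coincides with a cell face
        face = mesh.cell_widths[: mesh.n_gel].sum()
        assert face == pytest.approx(geometry.gel_height, rel=1e-12)

    def test_too_few_gel_cells_rejected(self, geometry):
        with pytest.raises(ValueError):
            build_mesh(geometry, n_cells=10, gel_fraction=0.05)


class TestAverages:
    def test_uniform_field(self, geometry, final_params):
        mesh = build_mesh(geometry, 50, 0.2)
        state = initial_state(mesh, ambient_percent=5.0, n0_per_ml=0.0)
        assert cs.gel_average(state, "oxygen", mesh) == pytest.approx(
            12.0 * O2_KG_M3_PER_PERCENT, rel=1e-12)

    def test_two_equal_cells_arithmetic_mean(self):
        mesh = Mesh(cell_centres=np.array([0.5, 1.5, 2.5, 3.5]),
                    cell_widths=np.ones(4), n_gel=2)
        state = FieldState(0.0, np.array([1.0, 3.0, 0, 0]), np.zeros(4),
                           np.zeros(4), np.zeros(4))
        assert cs.gel_average(state, "oxygen", mesh) == pytest.approx(2.0)

    def test_nonuniform_widths_match_bruteforce_weighted_mean(self):
        rng = np.random.default_rng(7)
        widths = rng.uniform(0.5, 2.0, size=8)
        centres = np.cumsum(widths) - widths / 2
        mesh = Mesh(cell_centres=centres, cell_widths=widths, n_gel=5)
        vals = rng.uniform(0, 4, size=8)
        state = FieldState(0.0, vals, np.zeros(8), np.zeros(8), np.zeros(8))
        expected = sum(v * w for v, w in zip(vals[:5], widths[:5])) / sum(widths[:5])
        assert cs.gel_average(state, "oxygen", mesh) == pytest.approx(expected, rel=1e-12)

    def test_unknown_species_rejected(self, geometry):
        mesh = build_mesh(geometry, 50, 0.2)
        state = initial_state(mesh, 1.0, 0.0)
        with pytest.raises(ValueError):
            cs.gel_average(state, "lactate", mesh)
        with pytest.raises(ValueError):
            cs.medium_average(state, "cells", mesh)


def _reactionless(params):
    """Transport only: no consumption, secretion, degradation or death."""
    return params.replace(M_c=0.0, M_s=0.0, K_v=0.0, alpha=0.0, beta=0.0,
                          delta_0=0.0, delta_c=0.0, delta_s=0.0)


class TestStep:
    def test_equilibrium_fixed_point(self, geometry, final_params):
        """Acellular column uniformly at ambient does not move."""
        mesh = build_mesh(geometry, 50, 0.2)
        bc = BoundaryConfig(ambient_percent=3.0)
        state = initial_state(mesh, 3.0, 0.0, gel_o2_percent=3.0)
        out = cs.step(state, 100.0, final_params, bc, mesh)
        np.testing.assert_allclose(out.c, state.c, rtol=1e-12)

    def test_mass_conservation_closed_column(self, geometry, final_params):
        """Zero-flux everywhere, no reactions: solute mass is invariant."""
        mesh = build_mesh(geometry, 60, 0.2)
        bc = BoundaryConfig(ambient_percent=1.0, oxygen_top="zero_flux")
        p = _reactionless(final_params)
        state = initial_state(mesh, 1.0, 0.0)
        stepper = Stepper(mesh, p, bc)
        w = mesh.cell_widths
        for field in ("c", "s"):
            m0 = np.sum(getattr(state, field) * w)
            s2 = state.copy()
            for _ in range(50):
                s2 = stepper.step(s2, 500.0)
            m1 = np.sum(getattr(s2, field) * w)
            assert abs(m1 - m0) / m0 < 1e-10

    def test_nonpositive_dt_rejected(self, geometry, final_params):
        mesh = build_mesh(geometry, 50, 0.2)
        state = initial_state(mesh, 1.0, 0.0)
        with pytest.raises(ValueError):
            cs.step(state, 0.0, final_params, BoundaryConfig(1.0), mesh)

    def test_slab_diffusion_matches_fourier_series(self, final_params):
        """Single slab, fixed surface value, sealed base: the numerical
        profile matches the cosine-series solution within 1 % of the jump."""
        D = 1.0e-9
        geom = cs.WellGeometry(radius=3.175e-3, gel_height=1e-3, medium_height=4e-3)
        h = geom.total_height
        mesh = build_mesh(geom, 100, 0.2)
        p = _reactionless(final_params).replace(D_c_gel=D, D_c_med=D)
        c0, c_top = 10.0 * O2_KG_M3_PER_PERCENT, 2.0 * O2_KG_M3_PER_PERCENT
        bc = BoundaryConfig(ambient_percent=2.0)
        state = FieldState(0.0, np.full(mesh.n_cells, c0), np.zeros(mesh.n_cells),
                           np.zeros(mesh.n_cells), np.zeros(mesh.n_cells))
        t_final = h**2 / D
        stepper = Stepper(mesh, p, bc)
        n_steps = 500
        for _ in range(n_steps):
            state = stepper.step(state, t_final / n_steps)
        z = mesh.cell_centres
        exact = np.full_like(z, c_top)
        for m in range(200):
            lam = (2 * m + 1) * np.pi / (2 * h)
            coef = (-1) ** m * 4 / ((2 * m + 1) * np.pi)
            exact += (c0 - c_top) * coef * np.cos(lam * z) * np.exp(-D * lam**2 * t_final)
        assert np.max(np.abs(state.c - exact)) < 0.01 * (c0 - c_top)


class TestSimulate:
    def test_acellular_centre_equilibrates_within_five_hours(self, final_params):
        trace = cs.generate_acellular_trace(1.0, params=final_params)
        ambient = 7.6
        offset0 = abs(trace.value_mmhg.iloc[0] - ambient)
        within = trace[np.abs(trace.value_mmhg - ambient) <= 0.05 * offset0]
        assert not within.empty and within.time_h.iloc[0] <= 5.0

    def test_baseline_decay_closed_form(self, geometry, final_params, coarse_settings):
        """With consumption and nutrient-gated death off, the viable fraction
        is exactly exponential decay at the baseline rate."""
        p = final_params.replace(M_c=0.0, delta_c=0.0, delta_s=0.0)
        mesh = build_mesh(geometry, coarse_settings.n_cells, coarse_settings.gel_fraction)
        res = cs.simulate(p, ambient_O2=7.0, n0_per_ml=60e6, geom=geometry,
                          mesh=mesh, dt=coarse_settings.dt)
        expected = np.exp(-p.delta_0 * 86400)
        assert res.viable_fraction[-1] == pytest.approx(expected, rel=1e-4)

    def test_viable_density_pointwise_nonincreasing(self, geometry, final_params,
                                                    coarse_settings):
        mesh = build_mesh(geometry, coarse_settings.n_cells, coarse_settings.gel_fraction)
        bc = BoundaryConfig(ambient_percent=1.0)
        state = initial_state(mesh, 1.0, 60e6)
        stepper = Stepper(mesh, final_params, bc)
        for _ in range(40):
            nxt = stepper.step(state, 600.0)
            assert np.all(nxt.n <= state.n + 1e-30)
            state = nxt
        assert np.all(state.n[mesh.gel] > 0)

    def test_viability_monotone_in_ambient_oxygen(self, geometry, final_params,
                                                  coarse_settings):
        mesh = build_mesh(geometry, coarse_settings.n_cells, coarse_settings.gel_fraction)
        fracs = [
            cs.simulate(final_params, ambient_O2=a, n0_per_ml=60e6, geom=geometry,
                        mesh=mesh, dt=coarse_settings.dt, with_vegf=False,
                        ).viable_fraction[-1]
            for a in (1.0, 3.0, 7.0, 19.0)
        ]
        assert np.all(np.diff(fracs) >= 0)

    def test_viability_highest_at_gel_top(self, geometry, final_params, coarse_settings):
        """Oxygen arrives from above, so the top gel third retains the most
        viable cells."""
        mesh = build_mesh(geometry, coarse_settings.n_cells, coarse_settings.gel_fraction)
        res = cs.simulate(final_params, ambient_O2=1.0, n0_per_ml=60e6, geom=geometry,
                          mesh=mesh, dt=coarse_settings.dt, with_vegf=False)
        z = res.zone_viability
        assert z["top"] >= z["bottom"]

    def test_shortened_final_step_lands_on_output_times(self, geometry, final_params):
        mesh = build_mesh(geometry, 20, 0.2)
        res = cs.simulate(final_params, ambient_O2=3.0, n0_per_ml=20e6, geom=geometry,
                          mesh=mesh, t_end=7200.0, output_every=1800.0, dt=700.0,
                          with_vegf=False)
        np.testing.assert_allclose(res.times, [0, 1800, 3600, 5400, 7200])

    def test_refinement_converges_toward_a_limit(self, geometry, final_params):
        """Successive halving of dx and dt shrinks the change in the 24-h
        gel-average oxygen: the observable approaches a limit."""
        vals = [
            cs.simulate(final_params, ambient_O2=1.0, n0_per_ml=60e6, geom=geometry,
                        mesh=build_mesh(geometry, n, 0.2), dt=dt, with_vegf=False,
                        ).gel_averages["oxygen"][-1]
            for n, dt in ((50, 400.0), (100, 200.0), (200, 100.0))
        ]
        d1 = abs(vals[1] - vals[0])
        d2 = abs(vals[2] - vals[1])
        assert d2 < d1

    def test_invalid_ambient_rejected(self, final_params):
        with pytest.raises(ValueError):
            cs.simulate(final_params, ambient_O2=0.0, n0_per_ml=1e6)
        with pytest.raises(ValueError):
            cs.simulate(final_params, ambient_O2=25.0, n0_per_ml=1e6)
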