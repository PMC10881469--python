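"""2D DEP sorter: Laplace solve, fields, flow, mobility, particle transport."""

import numpy as np
import pytest
from shapely.geometry import box

from depsort.core import DomainError, first_crossover
from depsort.separation import (
    DeviceGeometry,
    Electrode,
    SimParticle,
    advect_particles,
    choose_operating_frequency,
    default_geometry,
    dep_mobility,
    e2_field,
    flow_field,
    flow_profile,
    grad_e2_field,
    make_sim_particles,
    parallel_plate_geometry,
    purity_yield,
    run_separation,
    solve_potential,
)
from depsort.synthetic import (
    dep_buffer,
    differentiated_like_population,
    msc_like_population,
)
from depsort.core import clausius_mossotti, dep_force_magnitude


@pytest.fixture(scope="module")
def fixture_pops():
    # popA operated at its crossover (higher first CO); popB in positive DEP
    return differentiated_like_population(), msc_like_population()


class TestGeometry:
    def test_electrode_outside_channel_rejected(self):
        with pytest.raises(DomainError):
            DeviceGeometry(
                electrodes=(Electrode("phase", box(-1e-3, 0, 1e-3, 1e-4)),)
            )

    def test_overlapping_roles_rejected(self):
        with pytest.raises(DomainError):
            DeviceGeometry(
                electrodes=(
                    Electrode("phase", box(1e-3, 0, 2e-3, 1e-4)),
                    Electrode("neutral", box(1.5e-3, 0, 2.5e-3, 1e-4)),
                )
            )

    def test_default_geometry_has_both_roles(self):
        g = default_geometry()
        roles = {e.role for e in g.electrodes}
        assert roles == {"phase", "neutral"}


class TestLaplaceSolver:
    def test_matches_analytic_plate_solution(self):
        # plate edges aligned with grid nodes: interior ramp is exact
        g = parallel_plate_geometry(plate_width=100e-6)
        v = solve_potential(g, resolution=51, v_rms=10.0)
        inner = (v.y >= 100e-6 - 1e-9) & (v.y <= 400e-6 + 1e-9)
        analytic = 10.0 * (1 - (v.y[inner] - 100e-6) / 300e-6)
        mid = v.values[len(v.x) // 2]
        assert np.abs(mid[inner] - analytic).max() < 1e-6 * 10.0

    def test_zero_voltage_gives_zero_field(self):
        v = solve_potential(default_geometry(), resolution=50, v_rms=0.0)
        assert np.all(v.values == 0.0)

    def test_linearity_in_voltage(self):
        g = default_geometry()
        v1 = solve_potential(g, resolution=50, v_rms=5.0)
        v2 = solve_potential(g, resolution=50, v_rms=10.0)
        assert np.allclose(v2.values, 2.0 * v1.values, rtol=1e-9, atol=1e-9)

    def test_no_electrodes_is_an_error(self):
        with pytest.raises(DomainError):
            solve_potential(DeviceGeometry(), resolution=50)

    def test_resolution_floor(self):
        with pytest.raises(DomainError):
            solve_potential(default_geometry(), resolution=20)


class TestFields:
    def test_uniform_field_region_has_zero_grad_e2(self):
        g = parallel_plate_geometry(plate_width=100e-6)
        v = solve_potential(g, resolution=51, v_rms=10.0)
        grad = grad_e2_field(v)
        iy = (v.y >= 150e-6) & (v.y <= 350e-6)  # deep interior of the gap
        mid = len(v.x) // 2
        e2_scale = float(e2_field(v).values.max())
        assert np.abs(grad.vx[mid, iy]).max() < 1e-6 * e2_scale / v.dy
        assert np.abs(grad.vy[mid, iy]).max() < 1e-6 * e2_scale / v.dy

    def test_quadratic_potential_symbolic_oracle(self):
        # V = x^2 (as data): |E|^2 = 4x^2, grad|E|^2 = (8x, 0); exact for
        # central differences on a quadratic, so check interior nodes only
        from depsort.separation import ScalarField2D

        x = np.linspace(0.0, 1.0, 21)
        y = np.linspace(0.0, 0.5, 11)
        vals = np.broadcast_to((x**2)[:, None], (21, 11)).copy()
        grad = grad_e2_field(ScalarField2D(x=x, y=y, values=vals))
        # one-sided boundary differences touch the first/last interior node
        assert np.allclose(grad.vx[2:-2, :], 8.0 * x[2:-2, None], rtol=1e-10, atol=1e-10)
        assert np.allclose(grad.vy, 0.0, atol=1e-10)

    def test_field_intensity_maximal_along_diagonal_gap(self):
        g = default_geometry()
        v = solve_potential(g, resolution=64, v_rms=10.0)
        e2 = e2_field(v)
        # the |E|^2 crest must track the oblique electrode gap: for axial
        # stations along the diagonal, the max-|E|^2 lateral position lies
        # between the phase finger tips and the neutral strip
        width, start_x, end_x, end_y = 500e-6, 0.5e-3, 4.5e-3, 50e-6

        def y_line(x):
            return width + (x - start_x) / (end_x - start_x) * (end_y - width)

        for x_st in np.linspace(1.2e-3, 3.8e-3, 6):
            ix = int(np.argmin(np.abs(e2.x - x_st)))
            iy = int(np.argmax(e2.values[ix]))
            assert abs(e2.y[iy] - y_line(x_st)) < 120e-6


class TestFlow:
    def test_parabolic_profile_properties(self):
        g = DeviceGeometry()
        assert flow_profile(g, 1e-3, g.width / 2) == pytest.approx(1.5e-3, rel=1e-12)
        assert flow_profile(g, 1e-3, 0.0) == 0.0
        assert flow_profile(g, 1e-3, g.width) == 0.0

    def test_cross_section_average_is_mean_speed(self):
        from scipy.integrate import quad

        g = DeviceGeometry()
        avg, _ = quad(lambda y: flow_profile(g, 1e-3, y), 0, g.width)
        assert avg / g.width == pytest.approx(1e-3, rel=1e-3)

    def test_flow_field_no_lateral_component(self):
        field = flow_field(DeviceGeometry(), 1e-3, resolution=50)
        assert np.all(field.vy == 0.0)


class TestDepMobility:
    def test_zero_at_crossover(self, msc_cell, buffer_004):
        f_co = first_crossover(msc_cell, buffer_004)
        assert abs(dep_mobility(msc_cell, buffer_004, f_co, 1e-3)) < 1e-25

    def test_sign_follows_re_k(self, msc_cell, buffer_004):
        f_co = first_crossover(msc_cell, buffer_004)
        assert dep_mobility(msc_cell, buffer_004, f_co / 2, 1e-3) < 0
        assert dep_mobility(msc_cell, buffer_004, f_co * 2, 1e-3) > 0

    def test_stokes_balance_identity(self, msc_cell, buffer_004):
        # 6 pi eta r (mu G) equals the DEP force at the same G
        eta, f, grad = 1e-3, 1e6, 3.7e14
        mu = dep_mobility(msc_cell, buffer_004, f, eta)
        drag = 6 * np.pi * eta * msc_cell.radius * mu * grad
        force = dep_force_magnitude(msc_cell, buffer_004, f, grad)
        assert drag == pytest.approx(force, rel=1e-12)


class TestOperatingFrequency:
    def test_identical_populations_rejected(self, buffer_004):
        pop = msc_like_population()
        with pytest.raises(DomainError, match="swap"):
            choose_operating_frequency(pop, pop, buffer_004)

    def test_fixture_roles(self, fixture_pops, buffer_004):
        pop_diff, pop_msc = fixture_pops
        f = choose_operating_frequency(pop_diff, pop_msc, buffer_004)
        assert abs(clausius_mossotti(pop_diff.mean_particle(), buffer_004, f).real) < 1e-9
        assert clausius_mossotti(pop_msc.mean_particle(), buffer_004, f).real > 0.1

    def test_swapped_roles_rejected_for_fixtures(self, fixture_pops, buffer_004):
        pop_diff, pop_msc = fixture_pops
        # at the MSC crossover the differentiated-like cells feel nDEP
        with pytest.raises(DomainError):
            choose_operating_frequency(pop_msc, pop_diff, buffer_004)


@pytest.fixture(scope="module")
def zero_field_setup():
    m = dep_buffer(0.04)
    g = default_geometry()
    v = solve_potential(g, resolution=64, v_rms=0.0)
    grad = grad_e2_field(v)
    flow = flow_field(g, 15e-3, resolution=64)
    return m, g, grad, flow


class TestAdvection:
    def test_tracers_keep_entry_position(self, zero_field_setup, fixture_pops):
        m, g, grad, flow = zero_field_setup
        f = choose_operating_frequency(*fixture_pops, m)
        particles = make_sim_particles(list(fixture_pops), 25, m, f, g, seed=4)
        _, out = advect_particles(particles, flow, grad, f, m, 1e-3, g)
        tb = out.table
        assert np.allclose(tb["exit_y"], tb["entry_y"], atol=1e-15)
        assert (tb["outlet"] == "right").all()  # right-band entrants exit right

    def test_purity_equals_input_mixture_without_field(self, zero_field_setup, fixture_pops):
        m, g, grad, flow = zero_field_setup
        f = choose_operating_frequency(*fixture_pops, m)
        particles = make_sim_particles(list(fixture_pops), 30, m, f, g, seed=5)
        _, out = advect_particles(particles, flow, grad, f, m, 1e-3, g)
        purity, yld = purity_yield(out, fixture_pops[0].label, "right")
        assert purity == pytest.approx(50.0)
        assert yld == pytest.approx(100.0)

    def test_crossover_particle_follows_tracer(self, fixture_pops, buffer_004):
        m = buffer_004
        g = default_geometry()
        f = choose_operating_frequency(*fixture_pops, m)
        cell = fixture_pops[0].mean_particle()  # exactly at crossover
        flow = flow_field(g, 15e-3, resolution=64)
        grad_on = grad_e2_field(solve_potential(g, resolution=64, v_rms=10.0))
        grad_off = grad_e2_field(solve_potential(g, resolution=64, v_rms=0.0))
        start = (0.0, 0.8 * g.width)
        re_k = clausius_mossotti(cell, m, f).real
        p = [SimParticle(cell, start, "x", re_k)]
        _, with_field = advect_particles(p, flow, grad_on, f, m, 1e-3, g)
        _, tracer = advect_particles(p, flow, grad_off, f, m, 1e-3, g)
        dy = abs(with_field.table["exit_y"][0] - tracer.table["exit_y"][0])
        assert dy < 1e-9 * g.width

    def test_dt_halving_convergence(self, fixture_pops, buffer_004):
        m = buffer_004
        g = default_geometry()
        f = choose_operating_frequency(*fixture_pops, m)
        v = solve_potential(g, resolution=64, v_rms=10.0)
        grad = grad_e2_field(v)
        flow = flow_field(g, 15e-3, resolution=64)
        particles = make_sim_particles(list(fixture_pops), 8, m, f, g, seed=6)
        dt0 = 2e-4
        _, a = advect_particles(particles, flow, grad, f, m, 1e-3, g, dt=dt0)
        _, b = advect_particles(particles, flow, grad, f, m, 1e-3, g, dt=dt0 / 2)
        exited = (a.table["outlet"] != "none") & (b.table["outlet"] != "none")
        dy = np.abs(a.table["exit_y"][exited] - b.table["exit_y"][exited])
        assert dy.max() < 0.01 * g.width

    def test_particle_conservation_and_determinism(self, fixture_pops, buffer_004):
        f1, _, out1 = run_separation(*fixture_pops, buffer_004, n_per_pop=15, seed=9)
        f2, _, out2 = run_separation(*fixture_pops, buffer_004, n_per_pop=15, seed=9)
        tb = out1.table
        assert len(tb) == 30
        assert set(tb["outlet"]).issubset({"left", "right", "none"})
        assert tb.equals(out2.table)  # bit-identical for a fixed seed

    def test_positive_dep_migrates_left_negative_stays_right(self, fixture_pops, buffer_004):
        # strong pDEP cells cross to the left of their no-field exit; the
        # near-crossover population does not move left of its entry band
        f, _, out = run_separation(*fixture_pops, buffer_004, n_per_pop=20, seed=10)
        tb = out.table
        g = default_geometry()
        msc = tb[tb["population"] == "MSC"]
        diff = tb[tb["population"] == fixture_pops[0].label]
        assert (msc["exit_y"] < msc["entry_y"]).all()
        # near-crossover cells drift only weakly and never cross the split
        assert (diff["exit_y"] > g.split_y).all()
        assert np.allclose(diff["exit_y"], diff["entry_y"], atol=0.15 * g.width)


class TestPurityYield:
    def test_homogeneous_run_is_pure(self, fixture_pops, buffer_004):
        import pandas as pd

        from depsort.separation import SeparationOutcome

        tb = pd.DataFrame(
            {
                "particle_id": range(4),
                "population": ["A"] * 4,
                "outlet": ["left"] * 4,
            }
        )
        out = SeparationOutcome(table=tb)
        assert purity_yield(out, "A", "left") == (100.0, 100.0)

    def test_empty_outlet_is_an_error(self):
        import pandas as pd

        from depsort.separation import SeparationOutcome

        tb = pd.DataFrame({"particle_id": [0], "population": ["A"], "outlet": ["left"]})
        with pytest.raises(DomainError):
            purity_yield(SeparationOutcome(table=tb), "A", "right")
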