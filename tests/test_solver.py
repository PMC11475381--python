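"""Coupled 1D-0D solver: oracles, conservation, symmetry, cFFR."""

import numpy as np
import pytest

import autoffr as af
from conftest import steady_tube_solution


def viscous_drop(mu, q, length, r):
    """Closed-form steady viscous pressure drop of the 1D momentum equation."""
    A = np.pi * r**2
    return 22 * np.pi * mu * q * length / A**2


class TestSteadyOracle:
    @pytest.mark.parametrize("r0", [0.1, 0.15, 0.2])
    def test_viscous_drop_matches_closed_form(self, r0, blood, rigid_wall):
        sol = steady_tube_solution(r0, blood, rigid_wall)
        dp = sol.P[0, 0] - sol.P[0, -1]
        assert dp == pytest.approx(viscous_drop(0.04, 1.0, 10.0, r0), rel=0.01)

    def test_zero_viscosity_uniform_tube_no_drop(self, blood, wall):
        sol = steady_tube_solution(0.15, blood, wall, mu=0.0)
        dp = abs(sol.P[0, 0] - sol.P[0, -1])
        assert dp <= 1e-6 * sol.P[0, 0]

    def test_outlet_pressure_equals_bed_identity(self, blood, wall):
        """1D outlet pressure equals Pven + Q * RTf at steady state."""
        mesh, _, _ = af.make_stenosed_mesh1d(r0=0.15, severity=0.0, length=4.0, spacing=0.02)
        rcor = af.total_resistance(af.PerfusionTargets(), "left")
        beds = af.distribute_terminals(mesh, rcor, blood, wall)
        s = af.CoronarySolver(mesh, af.InflowWaveform.constant(1.0), beds, blood, wall,
                              af.SolverConfig(steady=True))
        sol = s.solve()
        assert sol.P[0, -1] == pytest.approx(beds[0].Pven + 1.0 * beds[0].RTf, rel=1e-3)

    def test_pressure_monotone_along_uniform_tube(self, blood, wall):
        sol = steady_tube_solution(0.15, blood, wall)
        assert np.all(np.diff(sol.P[0]) < 0)


@pytest.fixture(scope="module")
def bifurcation_solution(blood, wall):
    mesh = af.make_bifurcation_mesh1d(lengths=(2.0, 2.0, 2.0), spacing=0.02)
    rcor = af.total_resistance(af.PerfusionTargets(), "left")
    beds = af.distribute_terminals(mesh, rcor, blood, wall, plv=af.scaled_plv("left"))
    s = af.CoronarySolver(mesh, af.InflowWaveform.default("left"), beds, blood, wall,
                          af.SolverConfig(dt=2e-3, n_cycles=4))
    return s.solve()


class TestBifurcation:
    def test_junction_mass_conserved(self, bifurcation_solution):
        assert bifurcation_solution.junction_mass_error() <= 1e-8

    def test_symmetric_daughters_carry_identical_flow(self, bifurcation_solution):
        sol = bifurcation_solution
        q1 = sol.Q[:, sol.vessel_nodes(1)]
        q2 = sol.Q[:, sol.vessel_nodes(2)]
        assert np.abs(q1 - q2).max() <= 1e-8 * np.abs(q1).max()

    def test_cycle_periodicity_below_tolerance(self, bifurcation_solution):
        assert bifurcation_solution.periodicity < 0.005

    def test_area_stays_positive(self, bifurcation_solution):
        assert bifurcation_solution.A.min() > 0


class TestPulsatileTube:
    def test_physiological_inlet_pressure_range(self, blood, wall):
        """Unobstructed tube at physiological settings: mean inlet pressure in
        a plausible arterial range and cFFR near 1."""
        mesh, _, _ = af.make_stenosed_mesh1d(r0=0.2, severity=0.0, length=5.0, spacing=0.025)
        rcor = af.total_resistance(af.PerfusionTargets(), "left")
        beds = af.distribute_terminals(mesh, rcor, blood, wall, plv=af.scaled_plv("left"))
        s = af.CoronarySolver(mesh, af.InflowWaveform.default("left"), beds, blood, wall,
                              af.SolverConfig(dt=2e-3, n_cycles=4))
        sol = s.solve()
        result = af.compute_cffr(sol, 0, 5.0)
        assert 60 < result.Pa_mean_mmhg < 160
        assert 0.9 < result.cffr <= 1.0 + 1e-9


class TestCFFR:
    def test_inlet_location_gives_exactly_one(self, blood, wall):
        sol = steady_tube_solution(0.15, blood, wall)
        assert af.compute_cffr(sol, 0, 0.0).cffr == 1.0

    def test_strictly_decreasing_with_severity(self, blood, wall):
        vals = []
        for sev in (0.0, 0.3, 0.5, 0.7):
            sol = steady_tube_solution(0.15, blood, wall, q=2.0, severity=sev)
            vals.append(af.compute_cffr(sol, 0, 10.0).cffr)
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(0 < v <= 1 + 1e-9 for v in vals)

    def test_stenosed_below_unobstructed(self, blood, wall):
        clean = af.compute_cffr(steady_tube_solution(0.15, blood, wall, q=2.0), 0, 10.0)
        sten = af.compute_cffr(
            steady_tube_solution(0.15, blood, wall, q=2.0, severity=0.6), 0, 10.0)
        assert sten.cffr < clean.cffr

    def test_zero_viscosity_cffr_one_everywhere(self, blood, wall):
        sol = steady_tube_solution(0.15, blood, wall, mu=0.0)
        v = sol.mesh.vessels[0]
        for x in (0.0, 2.5, 5.0, 10.0):
            assert af.compute_cffr(sol, 0, x).cffr == pytest.approx(1.0, abs=1e-6)

    def test_unknown_vessel_rejected_with_valid_ids(self, blood, wall):
        sol = steady_tube_solution(0.15, blood, wall)
        with pytest.raises(KeyError, match="valid ids"):
            af.compute_cffr(sol, 7, 1.0)


class TestSolverGuards:
    def test_multi_root_mesh_rejected(self, blood, wall):
        from autoffr.mesh import Mesh1D, Vessel1D

        x = np.linspace(0, 1, 11)
        mesh = Mesh1D([Vessel1D(0, x, np.full(11, 0.1)), Vessel1D(1, x, np.full(11, 0.1))],
                      0.1)
        with pytest.raises(ValueError, match="single-rooted"):
            af.CoronarySolver(mesh, af.InflowWaveform.constant(1.0), [], blood, wall)

    def test_beds_must_match_terminals(self, blood, wall):
        mesh, _, _ = af.make_stenosed_mesh1d(length=3.0, spacing=0.05)
        with pytest.raises(ValueError, match="terminals"):
            af.CoronarySolver(mesh, af.InflowWaveform.constant(1.0), [], blood, wall)
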