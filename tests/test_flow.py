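"""Solver assembly, linearity, Picard consistency, WSS, link statistics,
streamlines, regression, and the reservoir decay model."""

import numpy as np
import pytest

from vesselflow import flow as fl
from vesselflow.flow import (BoundaryConditions, LinkFlowStats, MaterialProps,
                             RegionProps, friction_factor)
from vesselflow.geometry import (INTERSTITIUM, LUMEN, LabelField,
                                 build_label_field)
from vesselflow.network import Link, Node, VesselGraph, measure_links
from vesselflow.synthetic import poiseuille_tube_field


def small_tube(cpd=8, length=100.0, radius=10.0):
    return poiseuille_tube_field(radius, length, cpd, axis=2)


def tube_bcs(dp=1.0):
    return BoundaryConditions(pressures={"inlet": {LUMEN: dp},
                                         "outlet": {LUMEN: 0.0}})


class TestFrictionFactor:
    def test_reference_porosity(self):
        assert friction_factor(0.265) == pytest.approx(1.0474, abs=1e-3)

    def test_unit_porosity(self):
        assert friction_factor(1.0) == pytest.approx(1.75 / np.sqrt(150),
                                                     rel=1e-9)

    def test_strictly_decreasing(self):
        eps = np.linspace(0.05, 1.0, 40)
        cf = np.array([friction_factor(e) for e in eps])
        assert np.all(np.diff(cf) < 0)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.2])
    def test_out_of_range(self, bad):
        with pytest.raises(ValueError):
            friction_factor(bad)


class TestAssembly:
    def test_tube_has_two_pressure_face_sets(self):
        field = small_tube()
        prob = fl.assemble_problem(field, MaterialProps.control(),
                                   tube_bcs())
        tagged_faces = 0
        for a in range(3):
            lo = np.take(prob.pbc[a], 0, axis=a)
            hi = np.take(prob.pbc[a], prob.pbc[a].shape[a] - 1, axis=a)
            tagged_faces += int(np.isfinite(lo).sum() > 0)
            tagged_faces += int(np.isfinite(hi).sum() > 0)
        # boundary ghost pressures appear on exactly the two end faces
        assert tagged_faces == 2

    def test_all_interstitium_block_is_pure_brinkman(self):
        labels = np.full((10, 6, 6), INTERSTITIUM, np.uint8)
        field = LabelField(labels, 10.0, face_tags={"x-": "inlet",
                                                    "x+": "outlet"})
        props = MaterialProps(regions={
            INTERSTITIUM: RegionProps(0.265, 1e-12, 1e-3)})
        bcs = BoundaryConditions({"inlet": {INTERSTITIUM: 1.0},
                                  "outlet": {INTERSTITIUM: 0.0}})
        prob = fl.assemble_problem(field, props, bcs)
        assert prob.n_p == labels.size

    def test_lumen_without_kappa_is_fine(self):
        field = small_tube()
        fl.assemble_problem(field, MaterialProps.control(), tube_bcs())

    def test_porous_region_without_kappa_rejected(self):
        labels = np.full((6, 6, 6), INTERSTITIUM, np.uint8)
        field = LabelField(labels, 10.0, face_tags={"x-": "inlet"})
        props = MaterialProps(regions={
            INTERSTITIUM: RegionProps(0.265, None, 1e-3)})
        with pytest.raises(ValueError):
            fl.assemble_problem(field, props,
                                BoundaryConditions(
                                    {"inlet": {INTERSTITIUM: 1.0}}))

    def test_no_pressure_boundary_rejected(self):
        field = small_tube()
        field.face_tags = {}
        with pytest.raises(ValueError):
            fl.assemble_problem(field, MaterialProps.control(),
                                BoundaryConditions({"inlet": {LUMEN: 1.0}}))


class TestSolve:
    def test_equal_pressures_give_rest(self):
        field = small_tube()
        bcs = BoundaryConditions(pressures={"inlet": {LUMEN: 2.0},
                                            "outlet": {LUMEN: 2.0}})
        sol = fl.solve_flow(fl.assemble_problem(
            field, MaterialProps.control(), bcs))
        assert max(np.abs(a).max() for a in sol.u) < 1e-15
        p = sol.p[np.isfinite(sol.p)]
        np.testing.assert_allclose(p, 2.0, atol=1e-10)

    def test_field_scales_linearly_with_pressure(self):
        field = small_tube()
        props = MaterialProps.control()
        s1 = fl.solve_flow(fl.assemble_problem(field, props, tube_bcs(1.0)))
        s2 = fl.solve_flow(fl.assemble_problem(field, props, tube_bcs(2.0)))
        for a in range(3):
            np.testing.assert_allclose(s2.u[a], 2 * s1.u[a], atol=1e-12)

    def test_picard_reduces_to_linear_as_rho_vanishes(self):
        field = small_tube(cpd=8, length=60.0)
        props = MaterialProps.control()
        props.rho = 0.0
        prob = fl.assemble_problem(field, props, tube_bcs())
        lin = fl.solve_flow(prob, mode="stokes_brinkman_linear")
        pic = fl.solve_flow(prob, mode="picard_full", tol=1e-10)
        num = sum(np.sum((a - b) ** 2) for a, b in zip(pic.u, lin.u))
        den = sum(np.sum(a**2) for a in lin.u)
        assert np.sqrt(num / den) < 1e-6

    def test_picard_negligible_inertia_at_device_scale(self):
        """At Re << 1 the full equations agree with the linear mode."""
        field = small_tube(cpd=8, length=60.0)
        props = MaterialProps.control()        # rho = 1000 kg/m^3
        prob = fl.assemble_problem(field, props, tube_bcs())
        lin = fl.solve_flow(prob)
        pic = fl.solve_flow(prob, mode="picard_full", tol=1e-10)
        assert pic.converged
        num = sum(np.sum((a - b) ** 2) for a, b in zip(pic.u, lin.u))
        den = sum(np.sum(a**2) for a in lin.u)
        assert np.sqrt(num / den) < 1e-4

    def test_unknown_mode_rejected(self):
        field = small_tube()
        prob = fl.assemble_problem(field, MaterialProps.control(),
                                   tube_bcs())
        with pytest.raises(ValueError):
            fl.solve_flow(prob, mode="turbulent")

    def test_divergence_free(self):
        field = small_tube()
        sol = fl.solve_flow(fl.assemble_problem(
            field, MaterialProps.control(), tube_bcs()))
        assert sol.div_max < 1e-8


class TestWSS:
    def test_zero_flow_zero_wss(self, poiseuille_solution):
        field = poiseuille_solution["field"]
        props = poiseuille_solution["props"]
        zero = fl.FlowField(tuple(np.zeros_like(a)
                                  for a in poiseuille_solution["solution"].u),
                            np.zeros(field.shape), field, 0.0, 0.0, 0.0,
                            "stokes_brinkman_linear")
        wss = fl.wall_shear_stress(zero, field, props)
        assert wss.mean == 0.0
        assert np.all(wss.values() == 0.0)

    def test_wss_doubles_with_pressure(self):
        field = small_tube()
        props = MaterialProps.control()
        s1 = fl.solve_flow(fl.assemble_problem(field, props, tube_bcs(1.0)))
        s2 = fl.solve_flow(fl.assemble_problem(field, props, tube_bcs(2.0)))
        w1 = fl.wall_shear_stress(s1, field, props)
        w2 = fl.wall_shear_stress(s2, field, props)
        np.testing.assert_allclose(w2.values(), 2 * w1.values(), rtol=1e-8)

    def test_dyn_cm2_conversion(self, poiseuille_solution):
        wss = poiseuille_solution["wss"]
        assert wss.mean_dyn_cm2 == pytest.approx(10 * wss.mean)


def straight_graph(radius, length, center):
    nodes = {0: Node(0, np.array([0.0, center[0], center[1]]), "terminal"),
             1: Node(1, np.array([length, center[0], center[1]]),
                     "terminal")}
    g = VesselGraph(nodes, [Link(0, 0, 1,
                                 np.array([[0.0, center[0], center[1]],
                                           [length, center[0], center[1]]]),
                                 radius=radius)])
    return measure_links(g)


class TestLinkStatistics:
    @pytest.fixture(scope="class")
    def permeable_tube(self):
        g = straight_graph(12.0, 150.0, (30.0, 30.0))
        field = build_label_field(g, (150, 60, 60), t_endo=5.0,
                                  resolution=2.5,
                                  face_tags={"x-": "inlet", "x+": "outlet"})
        props = MaterialProps.control()
        sol = fl.solve_flow(fl.assemble_problem(
            field, props, BoundaryConditions.control()))
        return g, field, props, sol

    def test_impermeable_tube_conserves_flux(self, poiseuille_solution):
        R = poiseuille_solution["radius"]
        L = poiseuille_solution["length"]
        g = straight_graph(R, L, (np.array(
            poiseuille_solution["field"].shape[1:]) / 2
            * poiseuille_solution["field"].h))
        stats = fl.link_statistics(poiseuille_solution["solution"],
                                   poiseuille_solution["field"], g)
        s = stats[0]
        assert s.leakage == 0.0
        assert abs(s.inflow - s.outflow) / s.inflow < 1e-6

    def test_poiseuille_mean_axial_velocity(self, poiseuille_solution):
        P = poiseuille_solution
        g = straight_graph(P["radius"], P["length"],
                           (np.array(P["field"].shape[1:]) / 2 *
                            P["field"].h))
        stats = fl.link_statistics(P["solution"], P["field"], g)
        R, L = P["radius"] * 1e-6, P["length"] * 1e-6
        exact = P["dp"] * R**2 / (8 * P["mu"] * L)
        assert abs(stats[0].mean_axial_velocity - exact) / exact < 0.05

    def test_permeable_shell_leaks_and_closes(self, permeable_tube):
        g, field, props, sol = permeable_tube
        s = fl.link_statistics(sol, field, g)[0]
        assert s.leakage > 0
        assert abs(s.inflow - s.outflow - s.leakage) / s.inflow < 1e-3


class TestStreamlines:
    def uniform_field(self, v=1e-4):
        labels = np.full((20, 10, 10), INTERSTITIUM, np.uint8)
        field = LabelField(labels, 10.0, face_tags={"x-": "inlet",
                                                    "x+": "outlet"})
        u = [np.zeros((21, 10, 10)), np.zeros((20, 11, 10)),
             np.zeros((20, 10, 11))]
        u[0][:] = v
        return fl.FlowField(tuple(u), np.zeros(labels.shape), field,
                            0.0, 0.0, 0.0, "stokes_brinkman_linear")

    def test_uniform_flow_gives_straight_lines(self):
        flow = self.uniform_field()
        lines = fl.streamlines(flow, [[10.0, 50.0, 50.0]], max_len_um=150)
        path = lines[0]
        assert np.allclose(path[:, 1], 50.0, atol=1e-9)
        assert np.allclose(path[:, 2], 50.0, atol=1e-9)
        assert path[-1, 0] > 150.0

    def test_axis_streamline_spans_tube(self, poiseuille_solution):
        P = poiseuille_solution
        c = np.array(P["field"].shape[1:]) / 2 * P["field"].h
        lines = fl.streamlines(P["solution"], [[2.0, c[0], c[1]]],
                               max_len_um=1e4)
        length = np.linalg.norm(np.diff(lines[0], axis=0), axis=1).sum()
        extent = P["field"].shape[0] * P["field"].h
        assert length > 0.95 * extent

    def test_zero_field_stays_at_seed(self):
        flow = self.uniform_field(v=0.0)
        lines = fl.streamlines(flow, [[10.0, 50.0, 50.0]])
        assert len(lines[0]) == 1

    def test_outside_seed_rejected(self):
        flow = self.uniform_field()
        with pytest.raises(ValueError):
            fl.streamlines(flow, [[1e4, 0.0, 0.0]])


class TestRegression:
    def make_stats(self, wss, v, leak, r):
        return [LinkFlowStats(i, r[i], v[i], 0, 0, leak[i], 0.0, wss[i], 10)
                for i in range(len(wss))]

    def test_exact_linear_relation(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(1e-5, 1e-3, 12)
        leak = rng.uniform(0.1, 1.0, 12)
        r = rng.uniform(5, 20, 12)
        wss = 2.0 * v
        out = fl.wss_regression(self.make_stats(wss, v, leak, r))
        assert out["r2"] == pytest.approx(1.0, abs=1e-9)
        assert out["coefficients"]["axial_velocity"] == pytest.approx(2.0)
        # the other predictors contribute nothing at the response scale
        scale = np.std(wss)
        assert abs(out["coefficients"]["wall_outflow"]) * np.std(leak) \
            < 1e-6 * scale
        assert abs(out["coefficients"]["radius"]) * np.std(r) < 1e-6 * scale

    def test_orthogonal_predictors_unit_vif(self):
        n = 8
        base = np.array([1.0, 1, 1, 1, -1, -1, -1, -1])
        v = np.array([1.0, 1, -1, -1, 1, 1, -1, -1])
        r = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
        wss = base + 0.5 * v + 0.25 * r
        out = fl.wss_regression(self.make_stats(wss, base, v, r))
        for val in out["vif"].values():
            assert val == pytest.approx(1.0, abs=1e-9)

    def test_noisy_coefficients_recovered(self):
        rng = np.random.default_rng(11)
        n = 60
        v = rng.uniform(0, 1, n)
        leak = rng.uniform(0, 1, n)
        r = rng.uniform(0, 1, n)
        wss = 1.5 * v + 0.2 * r + rng.normal(0, 0.02, n)
        out = fl.wss_regression(self.make_stats(wss, v, leak, r))
        m = out["model"]
        for name, target in (("axial_velocity", 1.5), ("radius", 0.2)):
            est = out["coefficients"][name]
            se = m.bse[name]
            assert abs(est - target) < 3 * se

    def test_rank_deficient_names_collinear_pair(self):
        v = np.linspace(0.1, 1.0, 10)
        out_err = None
        with pytest.raises(ValueError) as out_err:
            fl.wss_regression(self.make_stats(2 * v, v, 3 * v, 5 * v))
        assert "collinear" in str(out_err.value)

    def test_too_few_links_rejected(self):
        with pytest.raises(ValueError):
            fl.wss_regression(self.make_stats([1, 2], [1, 2], [1, 2],
                                              [1, 2]))


class TestReservoirDecay:
    def test_exponential_form_and_time_constant(self):
        C, A, dp0 = 1e-12, 2e-5, 3.15
        t = np.linspace(0, 1000, 5)
        dp, tau = fl.reservoir_pressure_decay(C, A, dp0, t)
        assert tau == pytest.approx(A / (2 * 1000 * 9.81 * C))
        np.testing.assert_allclose(dp, dp0 * np.exp(-t / tau))

    def test_higher_conductance_decays_faster(self):
        t = np.array([500.0])
        dp_lo, _ = fl.reservoir_pressure_decay(1e-12, 2e-5, 1.0, t)
        dp_hi, _ = fl.reservoir_pressure_decay(5e-12, 2e-5, 1.0, t)
        assert dp_hi[0] < dp_lo[0]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fl.reservoir_pressure_decay(0.0, 1e-5, 1.0, np.array([0.0]))


def test_vtk_export_is_readable_text(tmp_path, poiseuille_solution):
    path = tmp_path / "sol.vtk"
    fl.export_vtk(poiseuille_solution["solution"], path,
                  poiseuille_solution["wss"])
    head = path.read_text().splitlines()[:6]
    assert head[0].startswith("# vtk DataFile")
    assert "STRUCTURED_POINTS" in "".join(head)
    nx, ny, nz = poiseuille_solution["field"].shape
    assert f"DIMENSIONS {nx} {ny} {nz}" in "".join(head)
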