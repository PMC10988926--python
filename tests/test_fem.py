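"""Linear Laplace solves, discrete conservation, and the adaptive loop."""

import numpy as np
import pytest

import ectsim as es
from ectsim.fem import assemble_stiffness, assign_fixed_conductivities

TIGHT = es.SolverSettings(linear_tolerance=1e-12)


def uniform_column(sigma=0.01, length=0.01, side=0.01, element_size=0.001):
    mesh = es.build_column(
        [("skull", length)], cross_section=(side, side), element_size=element_size
    )
    return mesh, np.full(mesh.n_elements, sigma)


class TestLinearSolve:
    def test_single_tissue_column_matches_analytic_resistance(self):
        mesh, sigma = uniform_column()
        res = es.solve_linear(mesh, sigma, es.BoundaryCondition(1.0), TIGHT)
        assert res.impedance == pytest.approx(0.01 / (0.01 * 1e-4), rel=1e-6)

    def test_multilayer_column_matches_series_sum(self, tissues):
        layers = [
            ("superficial_scalp", 0.0035),
            ("deep_scalp", 0.0035),
            ("skull", 0.007),
            ("csf", 0.003),
            ("gray_matter", 0.010),
            ("white_matter", 0.010),
        ]
        mesh = es.build_column(layers, cross_section=(0.01, 0.01), element_size=0.0015)
        sigma_of = {
            "superficial_scalp": 5e-3,
            "deep_scalp": 2e-3,
            **{k: tissues[k] for k in ("skull", "csf", "gray_matter", "white_matter")},
        }
        sigma = np.array([sigma_of[lab] for lab in mesh.labels])
        expected = sum(t / (sigma_of[lab] * 1e-4) for lab, t in layers)
        res = es.solve_linear(mesh, sigma, es.BoundaryCondition(2e-6), TIGHT)
        assert res.impedance == pytest.approx(expected, rel=0.01)

    def test_conductivity_scaling_halves_impedance(self):
        mesh, sigma = uniform_column()
        bc = es.BoundaryCondition(1.0)
        z1 = es.solve_linear(mesh, sigma, bc, TIGHT).impedance
        z2 = es.solve_linear(mesh, 2 * sigma, bc, TIGHT).impedance
        assert z2 == pytest.approx(z1 / 2, rel=1e-9)

    def test_impedance_independent_of_applied_current(self):
        mesh, sigma = uniform_column()
        z1 = es.solve_linear(mesh, sigma, es.BoundaryCondition(1.0), TIGHT).impedance
        z2 = es.solve_linear(mesh, sigma, es.BoundaryCondition(2.0), TIGHT).impedance
        assert z2 == pytest.approx(z1, rel=1e-9)

    def test_sparse_path_agrees_with_dense_brute_force(self):
        mesh, sigma = uniform_column(element_size=0.002)  # 100 elements
        bc = es.BoundaryCondition(1.0)
        res = es.solve_linear(mesh, sigma, bc, TIGHT)

        k_mat = assemble_stiffness(mesh, sigma).toarray()
        n = len(mesh.nodes)
        areas = mesh.face_areas(mesh.driven_faces)
        b = np.zeros(n)
        np.add.at(
            b,
            mesh.driven_faces.ravel(),
            np.repeat(bc.applied_current * areas / areas.sum() / 4.0, 4),
        )
        free = np.ones(n, dtype=bool)
        free[np.unique(mesh.ground_faces)] = False
        v = np.zeros(n)
        v[free] = np.linalg.solve(k_mat[np.ix_(free, free)], b[free])
        scale = np.abs(v).max()
        assert np.abs(res.potentials - v).max() < 1e-10 * scale

    def test_current_conserved_through_cut_planes(self):
        mesh, sigma = uniform_column()
        bc = es.BoundaryCondition(0.9)
        res = es.solve_linear(mesh, sigma, bc, TIGHT)
        for z_cut in (0.0015, 0.0045, 0.0085):
            current = es.cut_plane_current(mesh, sigma, res.potentials, z_cut)
            assert current == pytest.approx(0.9, rel=1e-3)

    def test_mirror_symmetry_under_terminal_swap(self, slab_mesh, tissues):
        scalp = es.ScalpParams(2e-3, 0.25)
        sigma = assign_fixed_conductivities(slab_mesh, tissues, scalp)
        settings = es.SolverSettings(linear_tolerance=1e-9)
        z_fwd = es.solve_linear(
            slab_mesh, sigma, es.BoundaryCondition(2e-6), settings
        ).impedance
        z_rev = es.solve_linear(
            slab_mesh, sigma, es.BoundaryCondition(2e-6, swap_terminals=True), settings
        ).impedance
        assert z_rev == pytest.approx(z_fwd, rel=1e-6)

    def test_unreached_tolerance_raises(self):
        mesh, sigma = uniform_column()
        settings = es.SolverSettings(
            linear_tolerance=1e-12, max_linear_iterations=2
        )
        with pytest.raises(es.LinearSolveError, match="residual"):
            es.solve_linear(mesh, sigma, es.BoundaryCondition(1.0), settings)


class TestAdaptiveSolve:
    def test_static_drive_stays_at_floor(self, slab_mesh, tissues, tf, tight_settings):
        """At 2 uA, scalp fields stay far below the threshold, so the
        adaptive result equals the linear solve at the floor conductivity."""
        scalp = es.ScalpParams(2e-3, 0.25)
        bc = es.BoundaryCondition(es.STATIC_CURRENT)
        adaptive = es.solve_adaptive(
            slab_mesh, tissues, scalp, tf, bc, tight_settings
        )
        assert adaptive.iterations <= 2
        ss = slab_mesh.labels == "superficial_scalp"
        assert np.allclose(
            adaptive.conductivities[ss], tf.floor_conductivity, rtol=1e-9
        )
        sigma = assign_fixed_conductivities(slab_mesh, tissues, scalp)
        linear = es.solve_linear(slab_mesh, sigma, bc, tight_settings)
        assert adaptive.impedance == pytest.approx(linear.impedance, rel=1e-6)

    def test_dynamic_impedance_below_static(self, slab_mesh, tissues, tf, tight_settings):
        scalp = es.ScalpParams(2e-3, 0.25)
        z_static = es.solve_adaptive(
            slab_mesh, tissues, scalp, tf,
            es.BoundaryCondition(es.STATIC_CURRENT), tight_settings,
        ).impedance
        z_dynamic = es.solve_adaptive(
            slab_mesh, tissues, scalp, tf,
            es.BoundaryCondition(es.DYNAMIC_CURRENT), tight_settings,
        ).impedance
        assert z_dynamic < z_static

    def test_flat_transfer_function_gives_equal_impedances(
        self, slab_mesh, tissues, tf, tight_settings
    ):
        """sigma_ss_max at the floor removes all adaptivity."""
        scalp = es.ScalpParams(2e-3, tf.floor_conductivity)
        z_static = es.solve_adaptive(
            slab_mesh, tissues, scalp, tf,
            es.BoundaryCondition(es.STATIC_CURRENT), tight_settings,
        ).impedance
        z_dynamic = es.solve_adaptive(
            slab_mesh, tissues, scalp, tf,
            es.BoundaryCondition(es.DYNAMIC_CURRENT), tight_settings,
        ).impedance
        assert z_dynamic == pytest.approx(z_static, rel=1e-6)

    def test_impedance_non_increasing_in_intensity(self, slab_mesh, tissues, tf):
        settings = es.SolverSettings(
            linear_tolerance=1e-9, adaptive_tolerance=1e-5,
            max_adaptive_iterations=400,
        )
        scalp = es.ScalpParams(2e-3, 0.25)
        impedances = [
            es.solve_adaptive(
                slab_mesh, tissues, scalp, tf,
                es.BoundaryCondition(current), settings,
            ).impedance
            for current in (2e-6, 1e-3, 0.1, 0.9)
        ]
        assert all(b <= a * (1 + 1e-9) for a, b in zip(impedances, impedances[1:]))

    def test_trace_records_every_iteration(self, slab_mesh, tissues, tf, tight_settings):
        scalp = es.ScalpParams(2e-3, 0.25)
        result = es.solve_adaptive(
            slab_mesh, tissues, scalp, tf,
            es.BoundaryCondition(es.DYNAMIC_CURRENT), tight_settings,
        )
        assert result.converged
        assert len(result.trace) == result.iterations
        assert all(z > 0 for z, _ in result.trace)

    def test_iteration_cap_flags_not_converged(self, slab_mesh, tissues, tf):
        settings = es.SolverSettings(
            linear_tolerance=1e-9, adaptive_tolerance=1e-6, max_adaptive_iterations=2
        )
        scalp = es.ScalpParams(2e-3, 0.25)
        result = es.solve_adaptive(
            slab_mesh, tissues, scalp, tf,
            es.BoundaryCondition(es.DYNAMIC_CURRENT), settings,
        )
        assert not result.converged
        assert result.iterations == 2
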