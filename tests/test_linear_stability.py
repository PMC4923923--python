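"""Basal states, eigenspectra, parity classification, non-degeneracy."""

import numpy as np
import pytest

import minpat.model_core as mc
from minpat.linear_stability import (
    DispersionResult,
    Mode,
    _System,
    basal_state,
    dispersion,
    mode_parity,
    non_degeneracy,
    sweep_nondegeneracy,
)
from minpat.meshing import build_mesh


@pytest.fixture(scope="module")
def circle(pset):
    g = mc.CellGeometry("ellipse", 2.0, 2.0, 1.1, mesh_resolution=0.2)
    mesh = build_mesh(g)
    state, info = basal_state(g, pset=pset, mesh=mesh)
    return g, mesh, state, info


@pytest.fixture(scope="module")
def ellipse(pset):
    g = mc.CellGeometry("ellipse", 6.0, 2.0, 1.1, mesh_resolution=0.2)
    mesh = build_mesh(g)
    state, info = basal_state(g, pset=pset, mesh=mesh)
    return g, mesh, state, info


class TestBasalState:
    def test_residual_converged(self, circle, ellipse):
        for _, _, _, info in (circle, ellipse):
            assert info["residual"] < 1e-10

    def test_circle_membrane_uniform(self, circle):
        _, _, state, _ = circle
        # full rotational symmetry: membrane density uniform along the boundary
        assert state.u_d.std() / state.u_d.mean() < 1e-6

    def test_ellipse_membrane_nonuniform_pole_midcell_structure(self, ellipse):
        # no homogeneous steady state exists in a confined geometry with
        # nucleotide exchange: the membrane profile is non-uniform, mirror
        # symmetric, with its extrema at the poles and at midcell (in the
        # quasi-2D cross-section the poles carry the *minimum*)
        g, mesh, state, _ = ellipse
        x = np.abs(mesh.boundary_points[:, 0])
        mem = state.u_d + state.u_de
        assert (mem.max() - mem.min()) / mem.mean() > 0.05
        extremes = {x[np.argmax(mem)], x[np.argmin(mem)]}
        assert min(extremes) < 0.2 * x.max() and max(extremes) > 0.9 * x.max()
        brefl = mesh.reflection_map("y")  # x -> -x on bulk nodes
        inv = {int(b): i for i, b in enumerate(mesh.boundary_nodes)}
        perm = [inv[int(brefl[b])] for b in mesh.boundary_nodes]
        np.testing.assert_allclose(mem, mem[perm], rtol=1e-6)

    def test_stationary_under_the_integrator(self, ellipse, pset):
        from minpat.simulator import Trajectory, integrate

        g, mesh, state, _ = ellipse
        p2d = mc.quasi_2d_parameters(pset["kinetics"], g.height_H)
        traj = Trajectory(geometry=g, params=p2d, mesh=mesh)
        traj.snapshots.append(state.copy())
        dt = 1e-6
        integrate(traj, dt, dt=dt)
        num = den = 0.0
        for name in ("u_DD", "u_DT", "u_E", "u_d", "u_de"):
            a, b = getattr(traj.state, name), getattr(state, name)
            num += float(np.sum((a - b) ** 2))
            den += float(np.sum(b**2))
        assert np.sqrt(num / den) < 1e-8

    def test_mass_targets_respected(self, ellipse, pset):
        g, mesh, state, _ = ellipse
        M_D, M_E = mc.total_masses(state, mesh)
        assert M_D == pytest.approx(pset["rho_D"] * g.height_H * mesh.area, rel=1e-9)
        assert M_E == pytest.approx(pset["rho_E"] * g.height_H * mesh.area, rel=1e-9)


class TestModeParity:
    def test_symmetric_field_is_even(self, ellipse):
        _, mesh, _, _ = ellipse
        n, m = mesh.n_nodes, mesh.n_boundary
        v = np.concatenate([np.cos(mesh.points[:, 1])] * 3
                           + [np.cos(mesh.boundary_points[:, 1] * 0 + 1.0)] * 2)
        parity, rho = mode_parity(v, mesh)
        assert parity == "even" and rho == pytest.approx(1.0, abs=1e-9)

    def test_antisymmetric_field_is_odd(self, ellipse):
        _, mesh, _, _ = ellipse
        v = np.concatenate([mesh.points[:, 1]] * 3 + [mesh.boundary_points[:, 1]] * 2)
        parity, rho = mode_parity(v, mesh)
        assert parity == "odd" and rho == pytest.approx(-1.0, abs=1e-9)

    def test_ninety_ten_energy_split_scores_point_eight(self, ellipse):
        _, mesh, _, _ = ellipse
        even = np.concatenate([np.ones(mesh.n_nodes)] * 3 + [np.ones(mesh.n_boundary)] * 2)
        odd = np.concatenate([mesh.points[:, 1]] * 3 + [mesh.boundary_points[:, 1]] * 2)
        # normalize blocks in the same mass inner product used by the score
        wa, wb = mesh.lumped_bulk_weights(), mesh.boundary_weights()
        w = np.concatenate([wa, wa, wa, wb, wb])
        even /= np.sqrt(even @ (w * even))
        odd /= np.sqrt(odd @ (w * odd))
        v = np.sqrt(0.9) * even + np.sqrt(0.1) * odd
        parity, rho = mode_parity(v, mesh)
        assert parity == "even"
        assert rho == pytest.approx(0.8, abs=0.01)


class TestDispersion:
    def test_circle_even_odd_degenerate_pairs(self, circle, pset):
        g, mesh, state, _ = circle
        dr = dispersion(g, pset=pset, basal=state, mesh=mesh)
        ev = dr.by_parity("even")[:3]
        od = dr.by_parity("odd")[:3]
        assert len(ev) == 3 and len(od) == 3
        for e, o in zip(ev, od):
            assert abs(e.growth_rate - o.growth_rate) <= 0.01 * max(
                abs(e.growth_rate), abs(o.growth_rate), 1e-3)

    def test_eigenpair_residuals(self, ellipse, pset):
        g, mesh, state, _ = ellipse
        dr = dispersion(g, pset=pset, basal=state, mesh=mesh)
        sysm = _System(mesh, dr.params)
        J = sysm.jacobian(sysm.state_to_vector(state))
        Md = sysm.mass_diag()
        checked = 0
        for mode in dr.modes:
            sigma = complex(mode.growth_rate, mode.frequency)
            v = mode.eigenvector
            res = np.linalg.norm(J @ v - sigma * (Md * v)) / np.linalg.norm(Md * v)
            if mode.frequency != 0:  # conjugate ambiguity for real pairs
                assert min(
                    res,
                    np.linalg.norm(J @ v - np.conj(sigma) * (Md * v))
                    / np.linalg.norm(Md * v),
                ) < 1e-8
                checked += 1
        assert checked >= 3

    def test_pure_diffusion_spectrum_nonpositive(self, pset):
        g = mc.CellGeometry("ellipse", 2.0, 2.0, 1.1, mesh_resolution=0.25)
        mesh = build_mesh(g)
        tiny = 1e-12
        p = mc.KineticParameters(8.0, 8.0, 0.05, tiny, tiny, tiny, tiny, tiny)
        ps = {"kinetics": p, "rho_D": 100.0, "rho_E": 100.0, "height": 1.1,
              "provenance": "test"}
        dr = dispersion(g, pset=ps, mesh=mesh,
                        rho_D=100.0, rho_E=100.0, sigma_shift=-0.01)
        assert all(m.growth_rate <= 1e-9 for m in dr.modes)


class TestNonDegeneracy:
    def _dr(self, even, odd):
        modes = []
        for i, gr in enumerate(even):
            modes.append(Mode(i, "even", gr, 0.0, 1.0, np.zeros(1)))
        for i, gr in enumerate(odd):
            modes.append(Mode(i, "odd", gr, 0.0, -1.0, np.zeros(1)))
        return DispersionResult(modes=modes, geometry=None, params=None,
                                basal=None, mesh=None)

    def test_identical_triples_give_zero(self):
        assert non_degeneracy(self._dr([1, 2, 3], [1, 2, 3])) == 0.0

    def test_single_term(self):
        assert non_degeneracy(self._dr([1, 0, 0], [0, 0, 0])) == pytest.approx(1.0)

    def test_hand_evaluated_example(self):
        d = non_degeneracy(self._dr([0.3, 0.1, -0.2], [0.2, -0.1, -0.2]))
        assert d == pytest.approx(np.sqrt(0.05), rel=1e-12)

    def test_insufficient_modes_error(self):
        with pytest.raises(ValueError, match="n_modes"):
            non_degeneracy(self._dr([1, 2], [1, 2, 3]))

    def test_nonnegative(self, rng):
        for _ in range(20):
            e, o = rng.normal(size=3), rng.normal(size=3)
            assert non_degeneracy(self._dr(sorted(e)[::-1], sorted(o)[::-1])) >= 0


class TestSweep:
    def test_sweep_dataframe_and_circle_minimum(self, pset):
        geos = [mc.CellGeometry("ellipse", L, 2.0, 1.1, mesh_resolution=0.25)
                for L in (2.0, 4.0)]
        df = sweep_nondegeneracy(geos, [pset["kinetics"].k_dD], pset=pset)
        assert set(df.columns) >= {"L", "W", "aspect", "k_dD", "d",
                                   "sigma1_even", "sigma1_odd"}
        assert len(df) == 2
        d_circle = df[df.aspect == 1.0].d.iloc[0]
        d_long = df[df.aspect == 2.0].d.iloc[0]
        assert d_circle >= 0 and d_long >= 0
        assert d_circle <= d_long  # near-spherical cells are nearly degenerate
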