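"""Basal states, growth-rate spectra, mode parity, and the non-degeneracy d.

In a confined geometry with cytosolic nucleotide exchange there is no
homogeneous steady state: the stationary ("basal") state is spatially
non-uniform, with membrane MinD maximal at the poles. This module solves
for that state with a mass-constrained Newton iteration on the same
lumped-FEM discretization the simulator integrates, then computes the
leading eigenpairs of the linearization with a sparse shift-invert
Arnoldi solver. Eigenmodes are classified as even (symmetric) or odd
(antisymmetric) under long-axis reflection; even modes correspond to
longitudinal patterns and odd modes to transverse ones. The non-degeneracy

    d = sqrt( sum_{i=1..3} [Re sigma_i^e - Re sigma_i^o]^2 )

measures how far the leading three even and odd growth rates are from
coinciding: small d signals coexisting longitudinal/transverse
instabilities (multistability).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import model_core as mc
from .meshing import Mesh, build_mesh

__all__ = [
    "DispersionResult",
    "Mode",
    "basal_state",
    "dispersion",
    "mode_parity",
    "non_degeneracy",
    "sweep_nondegeneracy",
]

ZERO_MODE_TOL = 1e-7  # |sigma| below this is a conservation (zero) mode


# ---------------------------------------------------------------------------
# discrete right-hand side and Jacobian (matches the simulator's lumped FEM)
# ---------------------------------------------------------------------------


class _System:
    """F(U) and J(U) of the lumped bulk-boundary discretization.

    State layout: U = [u_DD (n), u_DT (n), u_E (n), u_d (m), u_de (m)].
    """

    def __init__(self, mesh: Mesh, p: mc.KineticParameters):
        self.mesh = mesh
        self.p = p
        _, self.K = mesh.bulk_matrices()
        _, self.Kb = mesh.boundary_matrices()
        self.ma = mesh.lumped_bulk_weights()
        self.mb = mesh.boundary_weights()
        self.b = mesh.boundary_nodes
        self.n = mesh.n_nodes
        self.m = mesh.n_boundary
        self.N = 3 * self.n + 2 * self.m
        # T: restriction of bulk vectors to the boundary ordering
        self.T = sp.coo_matrix(
            (np.ones(self.m), (np.arange(self.m), self.b)), shape=(self.m, self.n)
        ).tocsr()

    def split(self, U):
        n, m = self.n, self.m
        return (U[:n], U[n:2 * n], U[2 * n:3 * n], U[3 * n:3 * n + m], U[3 * n + m:])

    def mass_diag(self) -> np.ndarray:
        return np.concatenate([self.ma, self.ma, self.ma, self.mb, self.mb])

    def rhs(self, U) -> np.ndarray:
        """M dU/dt (the weak-form right-hand side, mass-weighted)."""
        p = self.p
        u_DD, u_DT, u_E, u_d, u_de = self.split(U)
        DT_b, E_b = u_DT[self.b], u_E[self.b]
        k_att = p.k_D + p.k_dD * u_d
        att = k_att * DT_b
        hyd = p.k_dE * u_d * E_b
        det = p.k_de * u_de
        f_DD = -p.D_D * (self.K @ u_DD) - p.lambda_exchange * self.ma * u_DD
        f_DD[self.b] += self.mb * det
        f_DT = -p.D_D * (self.K @ u_DT) + p.lambda_exchange * self.ma * u_DD
        f_DT[self.b] -= self.mb * att
        f_E = -p.D_E * (self.K @ u_E)
        f_E[self.b] += self.mb * (det - hyd)
        f_d = -p.D_m * (self.Kb @ u_d) + self.mb * (att - hyd)
        f_de = -p.D_m * (self.Kb @ u_de) + self.mb * (hyd - det)
        return np.concatenate([f_DD, f_DT, f_E, f_d, f_de])

    def jacobian(self, U) -> sp.csr_matrix:
        """d(rhs)/dU at U (mass-weighted Jacobian)."""
        p = self.p
        _, u_DT, u_E, u_d, _ = self.split(U)
        DT_b, E_b = u_DT[self.b], u_E[self.b]
        k_att = p.k_D + p.k_dD * u_d
        T, mb, ma = self.T, self.mb, self.ma
        Dmb = lambda v: T.T @ sp.diags(mb * v) @ T  # boundary diag into bulk block
        Bmb = lambda v: T.T @ sp.diags(mb * v)  # bulk row, membrane column
        Mb_ = lambda v: sp.diags(mb * v)

        Z_bb = None  # placeholders for readability
        J_DD = [-p.D_D * self.K - sp.diags(p.lambda_exchange * ma), None, None,
                None, Bmb(np.full(self.m, p.k_de))]
        J_DT = [sp.diags(p.lambda_exchange * ma), -p.D_D * self.K - Dmb(k_att), None,
                Bmb(-p.k_dD * DT_b), None]
        J_E = [None, None, -p.D_E * self.K - Dmb(p.k_dE * u_d),
               Bmb(-p.k_dE * E_b), Bmb(np.full(self.m, p.k_de))]
        J_d = [None, Mb_(k_att) @ T, Mb_(-p.k_dE * u_d) @ T,
               -p.D_m * self.Kb + Mb_(p.k_dD * DT_b - p.k_dE * E_b), None]
        J_de = [None, None, Mb_(p.k_dE * u_d) @ T,
                Mb_(p.k_dE * E_b), -p.D_m * self.Kb - Mb_(np.full(self.m, p.k_de))]
        del Z_bb
        return sp.bmat([J_DD, J_DT, J_E, J_d, J_de], format="csr")

    def mass_constraints(self) -> np.ndarray:
        """(2, N) rows: total MinD and total MinE as linear functionals."""
        n, m = self.n, self.m
        C = np.zeros((2, self.N))
        C[0, :n] = self.ma
        C[0, n:2 * n] = self.ma
        C[0, 3 * n:] = np.concatenate([self.mb, self.mb])
        C[1, 2 * n:3 * n] = self.ma
        C[1, 3 * n + m:] = self.mb
        return C

    def state_to_vector(self, s: mc.FieldState) -> np.ndarray:
        return np.concatenate([s.u_DD, s.u_DT, s.u_E, s.u_d, s.u_de])

    def vector_to_state(self, U, t=0.0) -> mc.FieldState:
        return mc.FieldState(t, *self.split(U))


# ---------------------------------------------------------------------------
# basal state
# ---------------------------------------------------------------------------


def basal_state(g: mc.CellGeometry, p: mc.KineticParameters | None = None,
                pset: dict | None = None, mesh: Mesh | None = None,
                rho_D: float | None = None, rho_E: float | None = None,
                height: float | None = None, tol: float = 1e-12,
                max_iter: int = 50) -> tuple[mc.FieldState, dict]:
    """Stationary (basal) state with the given total masses.

    Solves F(U) = 0 under two mass constraints by pseudo-transient
    continuation: a bordered implicit-Euler iteration whose pseudo-timestep
    grows as the residual falls, turning into a full Newton iteration near
    the solution. The continuation damps the oscillatory instability of
    the basal state that defeats plain Newton from a uniform guess, and it
    conserves both masses exactly at every iterate.

    Returns ``(state, info)`` where ``info`` carries the relative residual
    norm and the iteration count.
    """
    if pset is None and p is None:
        pset = mc.load_parameter_file()
    if pset is not None:
        p = mc.quasi_2d_parameters(pset["kinetics"], g.height_H)
        rho_D = pset["rho_D"] if rho_D is None else rho_D
        rho_E = pset["rho_E"] if rho_E is None else rho_E
    if rho_D is None or rho_E is None:
        raise ValueError("total densities rho_D, rho_E are required")
    h = g.height_H if height is None else height
    if mesh is None:
        mesh = build_mesh(g)
    sysm = _System(mesh, p)
    area = mesh.area
    M_D_target = rho_D * h * area
    M_E_target = rho_E * h * area

    # initial guess: uniform cytosol at the target masses, thin membrane film
    n, m = sysm.n, sysm.m
    U = np.concatenate([
        np.full(n, 0.2 * M_D_target / area),
        np.full(n, 0.6 * M_D_target / area),
        np.full(n, 0.9 * M_E_target / area),
        np.full(m, 0.2 * M_D_target / mesh.perimeter),
        np.full(m, 0.1 * M_E_target / mesh.perimeter),
    ])
    U, res, iters = _solve_stationary(sysm, U, (M_D_target, M_E_target), tol,
                                      max_iter=120)
    method = "ser"
    if res >= tol:
        # homotopy in cell size: shrink the domain (same mesh topology) to a
        # strongly stable regime, then grow it back carrying the solution
        U_h = U
        ok = True
        for scale_f in (0.3, 0.45, 0.6, 0.75, 0.9, 1.0):
            smesh = Mesh(points=mesh.points * scale_f, triangles=mesh.triangles,
                         boundary_nodes=mesh.boundary_nodes, geometry=g)
            ssys = _System(smesh, p)
            tgt = (rho_D * h * smesh.area, rho_E * h * smesh.area)
            if scale_f == 0.3:
                U_h = None
            U_h, r_h, _ = _solve_stationary(ssys, U_h, tgt, tol, max_iter=150)
            if r_h >= min(1e-6, tol * 1e4) and scale_f < 1.0:
                ok = False
                break
        if ok and r_h < res:
            U, res = U_h, r_h
            method = "ser+size-homotopy"
        iters = max_iter
    info = {"residual": res, "iterations": iters, "method": method}
    if res >= max(tol, 1e-10):
        warnings.warn(f"basal state residual {res:.2e} above tolerance")
    return sysm.vector_to_state(np.clip(U, 0.0, None)), info


def _solve_stationary(sysm: "_System", U0, targets, tol: float, max_iter: int = 150):
    """SER pseudo-transient iteration with best-point restarts."""
    targets = np.asarray(targets, dtype=float)
    C = sysm.mass_constraints()
    Csp = sp.csr_matrix(C)
    Mdiag = sysm.mass_diag()
    if U0 is None:
        n, m = sysm.n, sysm.m
        area = float(sysm.ma.sum())
        per = float(sysm.mb.sum())
        M_D, M_E = targets
        U0 = np.concatenate([
            np.full(n, 0.2 * M_D / area), np.full(n, 0.6 * M_D / area),
            np.full(n, 0.9 * M_E / area), np.full(m, 0.2 * M_D / per),
            np.full(m, 0.1 * M_E / per)])
    U = np.asarray(U0, dtype=float).copy()
    scale = float(np.linalg.norm(Mdiag * U))
    res0 = float(np.linalg.norm(sysm.rhs(U)) / scale)
    res = res0
    delta = 0.1
    cap = 1.0
    best = (res, U.copy())
    restarts = 0
    for it in range(max_iter):
        if res < tol:
            break
        J = sysm.jacobian(U)
        A = sp.bmat([[(sp.diags(Mdiag / delta) - J).tocsr(), sp.csr_matrix(C.T)],
                     [Csp, None]], format="csc")
        try:
            sol = spla.splu(A).solve(np.concatenate([sysm.rhs(U), targets - C @ U]))
        except RuntimeError:
            delta *= 0.25
            continue
        U = U + sol[:sysm.N]
        res = float(np.linalg.norm(sysm.rhs(U)) / scale)
        if res < best[0]:
            best = (res, U.copy())
        if res > 50 * best[0] and restarts < 20:
            U = best[1].copy()
            res = best[0]
            cap *= 0.3
            restarts += 1
        delta = float(min(2 * delta, 0.1 * res0 / max(res, 1e-300) * cap, 1e10))
    if best[0] < res:
        res, U = best
    return U, res, it


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Mode:
    index: int
    parity: str  # even | odd | mixed
    growth_rate: float  # Re sigma (1/s)
    frequency: float  # Im sigma (1/s)
    parity_score: float
    eigenvector: np.ndarray = field(repr=False, compare=False)


@dataclass
class DispersionResult:
    """Leading eigenmodes of the linearization about the basal state."""

    modes: list
    geometry: mc.CellGeometry
    params: mc.KineticParameters
    basal: mc.FieldState
    mesh: Mesh

    def by_parity(self, parity: str) -> list:
        sel = [m for m in self.modes if m.parity == parity]
        return sorted(sel, key=lambda m: -m.growth_rate)

    @property
    def leading(self) -> Mode:
        return max(self.modes, key=lambda m: m.growth_rate)


def _boundary_reflection(mesh: Mesh, axis: str = "x") -> np.ndarray:
    refl = mesh.reflection_map(axis)
    inv = {int(b): i for i, b in enumerate(mesh.boundary_nodes)}
    return np.array([inv[int(refl[b])] for b in mesh.boundary_nodes], dtype=int)


def mode_parity(eigvec: np.ndarray, mesh: Mesh, sysm: _System | None = None,
                threshold: float = 0.5) -> tuple[str, float]:
    """Even/odd classification under long-axis reflection.

    The parity score rho = Re<v, Rv> / <v, v> (mass-weighted over all five
    field blocks) is +1 for exactly symmetric and -1 for exactly
    antisymmetric fields; |rho| <= threshold is flagged "mixed".
    """
    n, m = mesh.n_nodes, mesh.n_boundary
    refl = mesh.reflection_map("x")
    brefl = _boundary_reflection(mesh, "x")
    wa = mesh.lumped_bulk_weights()
    wb = mesh.boundary_weights()
    num = 0.0
    den = 0.0
    for k in range(3):
        v = eigvec[k * n:(k + 1) * n]
        num += float(np.real(np.vdot(v, wa * v[refl])))
        den += float(np.real(np.vdot(v, wa * v)))
    for k in range(2):
        v = eigvec[3 * n + k * m:3 * n + (k + 1) * m]
        num += float(np.real(np.vdot(v, wb * v[brefl])))
        den += float(np.real(np.vdot(v, wb * v)))
    rho = num / den
    if rho > threshold:
        return "even", rho
    if rho < -threshold:
        return "odd", rho
    return "mixed", rho


def _full_reflection(mesh: Mesh) -> np.ndarray:
    """State-vector permutation of the long-axis reflection (all 5 blocks)."""
    n, m = mesh.n_nodes, mesh.n_boundary
    refl = mesh.reflection_map("x")
    brefl = _boundary_reflection(mesh, "x")
    return np.concatenate([refl, refl + n, refl + 2 * n,
                           brefl + 3 * n, brefl + 3 * n + m])


def _symmetrize_degenerate(modes: list, mesh: Mesh) -> list:
    """Split numerically degenerate eigenvalue groups into even/odd members.

    For (near-)degenerate eigenvalues -- e.g. every pair on a circle --
    the Arnoldi eigenvectors are arbitrary mixtures of the symmetric and
    antisymmetric eigenfields. Within each group the even and odd
    projections span the group's eigenspace, so the group is re-expressed
    as pure-parity modes with the same growth rate.
    """
    if not modes:
        return modes
    perm = _full_reflection(mesh)
    out = []
    used = [False] * len(modes)
    for i, mi in enumerate(modes):
        if used[i]:
            continue
        group = [i]
        si = complex(mi.growth_rate, mi.frequency)
        for j in range(i + 1, len(modes)):
            sj = complex(modes[j].growth_rate, modes[j].frequency)
            if not used[j] and abs(si - sj) <= max(1e-6, 1e-3 * abs(si)):
                group.append(j)
        if len(group) == 1 or all(modes[j].parity != "mixed" for j in group):
            out.extend(modes[j] for j in group)
            for j in group:
                used[j] = True
            continue
        vecs = np.stack([modes[j].eigenvector for j in group], axis=1)
        even = 0.5 * (vecs + vecs[perm])
        odd = 0.5 * (vecs - vecs[perm])
        for block, parity in ((even, "even"), (odd, "odd")):
            norms = np.linalg.norm(block, axis=0)
            if norms.max() < 1e-9 * np.linalg.norm(vecs, axis=0).max():
                continue
            u, sv, _ = np.linalg.svd(block, full_matrices=False)
            rank = int(np.sum(sv > 1e-6 * sv[0]))
            for r in range(rank):
                out.append(Mode(modes[group[0]].index, parity,
                                modes[group[0]].growth_rate,
                                modes[group[0]].frequency,
                                1.0 if parity == "even" else -1.0,
                                u[:, r]))
        for j in group:
            used[j] = True
    return sorted(out, key=lambda m: -m.growth_rate)


def dispersion(g: mc.CellGeometry, p: mc.KineticParameters | None = None,
               n_modes: int = 16, pset: dict | None = None,
               mesh: Mesh | None = None, basal: mc.FieldState | None = None,
               sigma_shift: float = 0.02, **basal_kw) -> DispersionResult:
    """Leading growth-rate spectrum of the linearization at the basal state.

    Uses a sparse shift-invert Arnoldi solve of the generalized problem
    J v = sigma M v near ``sigma_shift``; the two (numerically) zero
    conservation modes are discarded. Each reported eigenpair satisfies
    the residual check ||J v - sigma M v|| / ||M v|| < 1e-8.
    """
    if pset is None and p is None:
        pset = mc.load_parameter_file()
    if pset is not None:
        p2d = mc.quasi_2d_parameters(pset["kinetics"], g.height_H)
    else:
        p2d = p
    if mesh is None:
        mesh = build_mesh(g)
    if basal is None:
        basal, _ = basal_state(g, p=p2d if pset is None else None, pset=pset,
                               mesh=mesh, **basal_kw)
    sysm = _System(mesh, p2d)
    J = sysm.jacobian(sysm.state_to_vector(basal))
    Mdiag = sysm.mass_diag()
    Msp = sp.diags(Mdiag).tocsc()

    k = n_modes + 2  # room for the two conservation modes
    last_err = None
    # fixed Arnoldi start vector: deterministic spectra run-to-run
    v0 = np.random.default_rng(12345).standard_normal(sysm.N)
    for attempt in range(3):
        try:
            vals, vecs = spla.eigs(J.tocsc(), k=k, M=Msp, sigma=sigma_shift,
                                   which="LM", tol=0, maxiter=5000, v0=v0)
            break
        except (spla.ArpackNoConvergence, RuntimeError) as err:  # retry larger
            last_err = err
            k = int(k * 1.7) + 4
    else:
        raise RuntimeError(f"eigensolver failed after retries: {last_err}")

    order = np.argsort(-vals.real)
    modes = []
    idx = 0
    for j in order:
        sigma_j = vals[j]
        if abs(sigma_j) < ZERO_MODE_TOL:
            continue  # conservation mode
        if sigma_j.imag < -1e-12:
            continue  # keep one member of each conjugate pair
        v = vecs[:, j]
        resid = np.linalg.norm(J @ v - sigma_j * (Mdiag * v)) / np.linalg.norm(Mdiag * v)
        if resid > 1e-8:
            warnings.warn(f"eigenpair residual {resid:.1e} above 1e-8")
        parity, score = mode_parity(v, mesh, sysm)
        modes.append(Mode(idx, parity, float(sigma_j.real), float(abs(sigma_j.imag)),
                          score, v))
        idx += 1
    modes = _symmetrize_degenerate(modes, mesh)
    return DispersionResult(modes=modes, geometry=g, params=p2d, basal=basal, mesh=mesh)


def non_degeneracy(dr: DispersionResult) -> float:
    """Euclidean distance between the three leading even and odd growth rates.

    Mixed-parity modes are excluded (with a warning) before the leading
    three of each class are taken; raises if fewer than three per parity
    are available (increase ``n_modes``).
    """
    ev = dr.by_parity("even")
    od = dr.by_parity("odd")
    mixed = [m for m in dr.modes if m.parity == "mixed"]
    if mixed:
        warnings.warn(f"{len(mixed)} mixed-parity modes excluded from d")
    if len(ev) < 3 or len(od) < 3:
        raise ValueError(
            f"need >= 3 modes per parity (have {len(ev)} even, {len(od)} odd); "
            "recompute the dispersion with larger n_modes"
        )
    e = np.array([m.growth_rate for m in ev[:3]])
    o = np.array([m.growth_rate for m in od[:3]])
    return float(np.sqrt(np.sum((e - o) ** 2)))


def sweep_nondegeneracy(geometries, k_dD_values, pset: dict | None = None,
                        n_modes: int = 16) -> "pandas.DataFrame":
    """Non-degeneracy d over a geometry x recruitment-rate grid.

    ``geometries`` is an iterable of CellGeometry (typically ellipses of
    varying aspect); per-point failures are recorded as NaN rows, never
    aborting the sweep. Returns a tidy DataFrame with columns
    (L, W, aspect, k_dD, d, sigma1_even, sigma1_odd).
    """
    import pandas as pd

    if pset is None:
        pset = mc.load_parameter_file()
    rows = []
    for g in geometries:
        mesh = build_mesh(g)
        for k_dD in k_dD_values:
            ps = dict(pset)
            ps["kinetics"] = pset["kinetics"].replace(k_dD=float(k_dD))
            row = {"L": g.length_L, "W": g.width_W, "aspect": g.aspect_ratio,
                   "k_dD": float(k_dD), "d": np.nan,
                   "sigma1_even": np.nan, "sigma1_odd": np.nan}
            try:
                dr = dispersion(g, pset=ps, mesh=mesh, n_modes=n_modes)
                row["d"] = non_degeneracy(dr)
                ev, od = dr.by_parity("even"), dr.by_parity("odd")
                row["sigma1_even"] = ev[0].growth_rate
                row["sigma1_odd"] = od[0].growth_rate
            except Exception as err:  # recorded as missing
                warnings.warn(f"sweep point (L={g.length_L}, k_dD={k_dD}) failed: {err}")
            rows.append(row)
    return pd.DataFrame(rows)
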