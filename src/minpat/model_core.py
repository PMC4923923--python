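"""Reaction kinetics of the Min bulk-boundary model, independent of discretization.

The model follows the canalized-transfer reaction scheme for MinD/MinE
dynamics. Three species diffuse in the cytosol (bulk): MinD-ADP (``u_DD``),
MinD-ATP (``u_DT``) and MinE (``u_E``); two live on the membrane (boundary):
MinD (``u_d``) and MinDE complexes (``u_de``). Cytosolic dynamics are

    du_DD/dt = D_D lap(u_DD) - lambda u_DD
    du_DT/dt = D_D lap(u_DT) + lambda u_DD
    du_E/dt  = D_E lap(u_E)

membrane dynamics are

    du_d/dt  = D_m lap_m(u_d)  + (k_D + k_dD u_d) u_DT|_b - k_dE u_d u_E|_b
    du_de/dt = D_m lap_m(u_de) + k_dE u_d u_E|_b - k_de u_de

and the two layers are coupled through reactive flux boundary conditions

    D_D dn(u_DD) = k_de u_de
    D_D dn(u_DT) = -(k_D + k_dD u_d) u_DT|_b
    D_E dn(u_E)  = -k_dE u_d u_E|_b + k_de u_de

where dn is the outward normal derivative of the cytosolic domain, so a
positive right-hand side is a source of cytosolic material at the membrane.
Total MinD and total MinE are conserved by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "KineticParameters",
    "CellGeometry",
    "FieldState",
    "membrane_reaction_rates",
    "boundary_flux",
    "bulk_reaction_rates",
    "total_masses",
    "load_parameter_file",
    "default_parameter_file",
    "quasi_2d_parameters",
]


class DomainError(ValueError):
    """A physical-domain violation (negative density, bad rate)."""


def _check_nonneg(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise DomainError(f"field {name!r} contains negative values")
    return arr


@dataclass(frozen=True)
class KineticParameters:
    """The eight rate/diffusion constants of the Min model.

    All rates are strictly positive. In 3D, ``k_D`` has units um/s and the
    recruitment constants ``k_dD``/``k_dE`` um^3/s; in the quasi-2D
    reduction the recruitment constants are divided by the cell height
    (see :func:`quasi_2d_parameters`) and carry um^2/s.
    """

    D_D: float  # cytosolic MinD diffusion (um^2/s)
    D_E: float  # cytosolic MinE diffusion (um^2/s)
    D_m: float  # membrane diffusion (um^2/s)
    lambda_exchange: float  # cytosolic nucleotide exchange rate (1/s)
    k_D: float  # MinD attachment rate constant (um/s)
    k_dD: float  # MinD recruitment rate constant
    k_dE: float  # MinE recruitment rate constant
    k_de: float  # MinDE complex detachment rate (1/s)

    def __post_init__(self):
        for name in ("D_D", "D_E", "D_m", "lambda_exchange", "k_D", "k_dD", "k_dE", "k_de"):
            if getattr(self, name) <= 0:
                raise ValueError(f"kinetic parameter {name} must be strictly positive")
        if not (self.D_m < self.D_D and self.D_m < self.D_E):
            warnings.warn(
                "membrane diffusion D_m is not slower than cytosolic diffusion; "
                "this is outside the physiological regime",
                stacklevel=2,
            )

    def replace(self, **kw) -> "KineticParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class CellGeometry:
    """Shaped-cell geometry: lateral dimensions plus chamber height.

    ``height_H`` enters only the quasi-2D parameter reduction and
    bookkeeping; ``corner_radius`` rounds rectangle corners for mask
    rendering and area bookkeeping (the FEM mesh treats rectangle corners
    sharply, whose area deficit is below mesh tolerance for the small
    default rounding).
    """

    shape: str  # rectangle | ellipse | stadium
    length_L: float  # um, along x
    width_W: float  # um, along y
    height_H: float = 1.1  # um
    corner_radius: float = 0.1  # um, rectangles only
    mesh_resolution: float = 0.2  # target element edge (um)

    def __post_init__(self):
        if self.shape not in ("rectangle", "ellipse", "stadium"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if not (self.length_L >= self.width_W > 0):
            raise ValueError("require length_L >= width_W > 0")
        if self.height_H <= 0:
            raise ValueError("height_H must be positive")
        if self.shape == "rectangle" and not (0 < self.corner_radius <= self.width_W / 2):
            raise ValueError("require 0 < corner_radius <= width_W/2")

    @property
    def aspect_ratio(self) -> float:
        return self.length_L / self.width_W


@dataclass
class FieldState:
    """Densities of the five species on a meshed geometry at one time point.

    Bulk fields (``u_DD``, ``u_DT``, ``u_E``) are per-area densities in
    quasi-2D mode; membrane fields (``u_d``, ``u_de``) are per-length.
    """

    t: float
    u_DD: np.ndarray
    u_DT: np.ndarray
    u_E: np.ndarray
    u_d: np.ndarray
    u_de: np.ndarray

    def copy(self) -> "FieldState":
        return FieldState(
            self.t,
            self.u_DD.copy(),
            self.u_DT.copy(),
            self.u_E.copy(),
            self.u_d.copy(),
            self.u_de.copy(),
        )

    def bulk_fields(self):
        return self.u_DD, self.u_DT, self.u_E

    def membrane_fields(self):
        return self.u_d, self.u_de


# ---------------------------------------------------------------------------
# reaction terms
# ---------------------------------------------------------------------------


def membrane_reaction_rates(u_d, u_de, u_DT_b, u_E_b, p: KineticParameters, k_D_local):
    """Reaction part of the membrane dynamics (diffusion handled elsewhere).

    Returns ``(rate_d, rate_de)``:

        rate_d  = (k_D_local + k_dD u_d) u_DT|_b - k_dE u_d u_E|_b
        rate_de = k_dE u_d u_E|_b - k_de u_de
    """
    u_d = _check_nonneg("u_d", u_d)
    u_de = _check_nonneg("u_de", u_de)
    u_DT_b = _check_nonneg("u_DT_b", u_DT_b)
    u_E_b = _check_nonneg("u_E_b", u_E_b)
    k_D_local = _check_nonneg("k_D_local", k_D_local)
    hydrolysis = p.k_dE * u_d * u_E_b
    rate_d = (k_D_local + p.k_dD * u_d) * u_DT_b - hydrolysis
    rate_de = hydrolysis - p.k_de * u_de
    return rate_d, rate_de


def boundary_flux(u_d, u_de, u_DT_b, u_E_b, p: KineticParameters, k_D_local):
    """Outward-normal flux contracts for the three cytosolic species.

    Returns ``(flux_DD, flux_DT, flux_E)`` with the convention
    ``D dn(u) = flux``: a positive value is a source of cytosolic material
    at the membrane. Together with :func:`membrane_reaction_rates` these
    conserve MinD and MinE pointwise:
    ``flux_DD + flux_DT + rate_d + rate_de == 0`` and
    ``flux_E + rate_de == 0`` identically.
    """
    u_d = _check_nonneg("u_d", u_d)
    u_de = _check_nonneg("u_de", u_de)
    u_DT_b = _check_nonneg("u_DT_b", u_DT_b)
    u_E_b = _check_nonneg("u_E_b", u_E_b)
    k_D_local = _check_nonneg("k_D_local", k_D_local)
    detach = p.k_de * u_de
    flux_DD = detach
    flux_DT = -(k_D_local + p.k_dD * u_d) * u_DT_b
    flux_E = -p.k_dE * u_d * u_E_b + detach
    return flux_DD, flux_DT, flux_E


def bulk_reaction_rates(u_DD, u_DT, p: KineticParameters):
    """Cytosolic nucleotide exchange: MinD-ADP -> MinD-ATP at rate lambda.

    Returns ``(rate_DD, rate_DT, rate_E)``; the exchange conserves total
    cytosolic MinD pointwise (``rate_DD + rate_DT == 0``) and MinE is inert
    in the bulk.
    """
    u_DD = _check_nonneg("u_DD", u_DD)
    _check_nonneg("u_DT", u_DT)
    rate_DD = -p.lambda_exchange * u_DD
    return rate_DD, -rate_DD, np.zeros_like(rate_DD)


def total_masses(state: FieldState, mesh) -> tuple[float, float]:
    """Total MinD and MinE mass (bulk + membrane integrals).

    Uses the discretization's own quadrature (consistent P1 mass matrices),
    so that the masses the integrator conserves are exactly the ones
    audited here.
    """
    n, m = mesh.n_nodes, mesh.n_boundary
    for name, f, size in (
        ("u_DD", state.u_DD, n),
        ("u_DT", state.u_DT, n),
        ("u_E", state.u_E, n),
        ("u_d", state.u_d, m),
        ("u_de", state.u_de, m),
    ):
        if len(np.asarray(f)) != size:
            raise ValueError(f"field {name} does not match the mesh ({len(f)} vs {size})")
    wa = mesh.lumped_bulk_weights()
    wb = mesh.boundary_weights()
    M_D = float(wa @ (state.u_DD + state.u_DT) + wb @ (state.u_d + state.u_de))
    M_E = float(wa @ state.u_E + wb @ state.u_de)
    return M_D, M_E


# ---------------------------------------------------------------------------
# parameter files
# ---------------------------------------------------------------------------


def default_parameter_file() -> Path:
    """Path to the shipped default parameter set."""
    return Path(resources.files("minpat").joinpath("data/default_params.yaml"))


def load_parameter_file(path=None) -> dict:
    """Load a YAML parameter set.

    Returns a dict with keys ``kinetics`` (:class:`KineticParameters`, 3D
    units), ``rho_D``/``rho_E`` (mean total densities, 1/um^3), ``height``
    (um) and ``provenance``. Every value in the file is overridable; the
    provenance string is mandatory.
    """
    path = Path(path) if path is not None else default_parameter_file()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "provenance" not in raw or not str(raw["provenance"]).strip():
        raise ValueError("parameter file must carry a provenance string")
    kin = raw["kinetics"]
    p = KineticParameters(
        D_D=float(kin["D_D"]),
        D_E=float(kin["D_E"]),
        D_m=float(kin["D_m"]),
        lambda_exchange=float(kin["lambda_exchange"]),
        k_D=float(kin["k_D"]),
        k_dD=float(kin["k_dD"]),
        k_dE=float(kin["k_dE"]),
        k_de=float(kin["k_de"]),
    )
    return {
        "kinetics": p,
        "rho_D": float(raw["densities"]["rho_D"]),
        "rho_E": float(raw["densities"]["rho_E"]),
        "height": float(raw.get("height", 1.1)),
        "provenance": str(raw["provenance"]),
    }


def quasi_2d_parameters(p: KineticParameters, height: float) -> KineticParameters:
    """Rescale 3D kinetic constants for the quasi-2D (cross-section) mode.

    With areal bulk densities ``H * u_3D`` and lineal membrane densities
    ``H * u_mem``, the equations keep their form if the bimolecular
    recruitment constants are divided by the height H; attachment ``k_D``
    and all first-order rates are unchanged.
    """
    if height <= 0:
        raise ValueError("height must be positive")
    return p.replace(k_dD=p.k_dD / height, k_dE=p.k_dE / height)
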