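"""Diffusion of nanoparticles into a cell through a membrane pore.

The model is Fick's second law with a spatially varying diffusivity in an
axisymmetric cylindrical domain (coordinates r, z): a spherical cell of
radius ``cell_radius`` sits at the center of a cylindrical box filled
with particle suspension at unit concentration, the cell interior starts
empty, and a thin low-diffusivity shell represents the plasma membrane
(impermeable by default, D_membrane = 0).  A pore is a patch of the
shell on the symmetry axis restored to the bulk diffusivity.
Diffusivities follow the Stokes–Einstein relation

    D = k_B T / (3 pi mu d)

for particle diameter d in a medium of viscosity mu, or can be given
directly.

Discretization is a conservative finite-volume scheme on annular cells
(harmonic-mean face diffusivities, so a zero-D membrane blocks flux
exactly), stepped with Crank–Nicolson.  No-flux boundaries make total
mass conserved to solver round-off, which is monitored at every output
step.  Reported uptake is the mass inside the cell interior (excluding
the membrane shell), normalized by the bulk concentration times the
interior volume so that 1 means full equilibration with the bulk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csc_matrix, identity
from scipy.sparse.linalg import splu

__all__ = [
    "DiffusionDomain",
    "UptakeResult",
    "stokes_einstein_diffusivity",
    "build_domain",
    "solve",
    "uptake_ratio",
]

K_BOLTZMANN = 1.380649e-23  # J/K


def stokes_einstein_diffusivity(
    temperature_k: float, viscosity_pa_s: float, particle_diameter_nm: float
) -> float:
    """Diffusion coefficient (μm²/s) of a sphere from Stokes–Einstein."""
    if min(temperature_k, viscosity_pa_s, particle_diameter_nm) <= 0:
        raise ValueError("temperature, viscosity and diameter must be positive")
    d_m = particle_diameter_nm * 1e-9
    d_si = K_BOLTZMANN * temperature_k / (3.0 * np.pi * viscosity_pa_s * d_m)
    return d_si * 1e12  # m²/s → μm²/s


@dataclass
class DiffusionDomain:
    """Discretized axisymmetric domain with per-cell diffusivity (μm²/s)."""

    cell_radius: float
    membrane_thickness: float
    pore_diameter: float
    D_bulk: float
    D_membrane: float
    D_cell: float
    dr: float
    dz: float
    nr: int
    nz: int
    D_field: np.ndarray = field(repr=False)  # (nz, nr)
    interior: np.ndarray = field(repr=False)  # bool (nz, nr), inside membrane
    exterior: np.ndarray = field(repr=False)  # bool (nz, nr), outside membrane
    volumes: np.ndarray = field(repr=False)  # (nz, nr), μm³ per annular cell

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nz, self.nr)

    def initial_condition(self) -> np.ndarray:
        """Unit concentration outside the cell, zero inside and in the membrane."""
        c0 = np.zeros(self.shape)
        c0[self.exterior] = 1.0
        return c0


@dataclass(frozen=True)
class UptakeResult:
    """Intracellular uptake vs time from a diffusion run.

    ``intracellular_amount`` is normalized so 1 equals equilibration of
    the cell interior with the initial bulk concentration.
    ``total_mass`` tracks conservation (concentration × μm³ units).
    """

    times: np.ndarray
    intracellular_amount: np.ndarray
    total_mass: np.ndarray
    final_field: np.ndarray = field(repr=False)


def build_domain(
    *,
    cell_radius: float = 7.5,
    membrane_thickness: float = 0.25,
    pore_diameter: float = 1.5,
    particle_diameter_nm: float = 200.0,
    temperature_k: float = 310.0,
    viscosity_bulk_pa_s: float = 0.7e-3,
    viscosity_cell_factor: float = 3.0,
    D_bulk: float | None = None,
    D_membrane: float = 0.0,
    D_cell: float | None = None,
    domain_radius: float | None = None,
    domain_height: float | None = None,
    grid_spacing: float = 0.25,
) -> DiffusionDomain:
    """Assemble the axisymmetric cell-in-box diffusion domain.

    All lengths in μm.  Diffusivities default to Stokes–Einstein values
    for the given particle size at 37 °C (water-like bulk, 3× more
    viscous cytoplasm); pass ``D_bulk``/``D_cell`` to override.  The
    membrane shell is impermeable (D = 0) unless ``D_membrane`` is set;
    a nonzero ``pore_diameter`` opens a patch of bulk diffusivity on the
    symmetry axis at the top pole of the cell, and must span at least
    two grid cells across.
    """
    if cell_radius <= 0 or membrane_thickness <= 0 or grid_spacing <= 0:
        raise ValueError("lengths must be positive")
    if pore_diameter < 0:
        raise ValueError("pore_diameter must be non-negative")
    if pore_diameter > 0 and pore_diameter < 2 * grid_spacing:
        raise ValueError(
            f"under-resolved pore: diameter {pore_diameter} μm needs grid spacing "
            f"≤ {pore_diameter / 2:.3g} μm (≥ 2 cells across)"
        )
    if D_bulk is None:
        D_bulk = stokes_einstein_diffusivity(
            temperature_k, viscosity_bulk_pa_s, particle_diameter_nm
        )
    if D_cell is None:
        D_cell = stokes_einstein_diffusivity(
            temperature_k, viscosity_bulk_pa_s * viscosity_cell_factor, particle_diameter_nm
        )
    if D_membrane > D_bulk:
        raise ValueError("membrane must not be more diffusive than the bulk")

    R_dom = domain_radius if domain_radius is not None else 2.0 * cell_radius
    H_dom = domain_height if domain_height is not None else 4.0 * cell_radius
    dr = dz = grid_spacing
    nr = int(round(R_dom / dr))
    nz = int(round(H_dom / dz))
    r_cent = (np.arange(nr) + 0.5) * dr
    z_cent = (np.arange(nz) + 0.5) * dz
    z_c = H_dom / 2.0
    rr, zz = np.meshgrid(r_cent, z_cent - z_c)  # zz relative to cell center
    dist = np.sqrt(rr**2 + zz**2)

    half = membrane_thickness / 2.0
    interior = dist < cell_radius - half
    membrane = (dist >= cell_radius - half) & (dist <= cell_radius + half)
    exterior = dist > cell_radius + half

    D_field = np.full((nz, nr), D_bulk)
    D_field[interior] = D_cell
    D_field[membrane] = D_membrane
    if pore_diameter > 0:
        pore = membrane & (rr <= pore_diameter / 2.0) & (zz > 0)
        D_field[pore] = D_bulk

    volumes = 2.0 * np.pi * rr * dr * dz
    return DiffusionDomain(
        cell_radius=cell_radius,
        membrane_thickness=membrane_thickness,
        pore_diameter=pore_diameter,
        D_bulk=D_bulk,
        D_membrane=D_membrane,
        D_cell=D_cell,
        dr=dr,
        dz=dz,
        nr=nr,
        nz=nz,
        D_field=D_field,
        interior=interior,
        exterior=exterior,
        volumes=volumes,
    )


def _harmonic(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    s = a + b
    out = np.zeros_like(a)
    nz = s > 0
    out[nz] = 2.0 * a[nz] * b[nz] / s[nz]
    return out


def _assemble_operator(domain: DiffusionDomain) -> csc_matrix:
    """Sparse conservative operator L with dc/dt = L c (no-flux boundaries)."""
    nz, nr, dr, dz = domain.nz, domain.nr, domain.dr, domain.dz
    D = domain.D_field
    V = domain.volumes
    r_faces = np.arange(1, nr) * dr  # interior radial faces
    n = nz * nr

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    idx = np.arange(n).reshape(nz, nr)

    # radial faces between (i, j) and (i, j+1)
    Df = _harmonic(D[:, :-1], D[:, 1:])
    area = 2.0 * np.pi * r_faces[None, :] * dz  # (1, nr-1) broadcast over z
    g = Df * area / dr  # conductance, flux = g * (c_right - c_left)
    left, right = idx[:, :-1].ravel(), idx[:, 1:].ravel()
    gf = g.ravel()
    rows += [left, left, right, right]
    cols += [right, left, left, right]
    vals += [gf / V[:, :-1].ravel(), -gf / V[:, :-1].ravel(),
             gf / V[:, 1:].ravel(), -gf / V[:, 1:].ravel()]

    # axial faces between (i, j) and (i+1, j)
    Df = _harmonic(D[:-1, :], D[1:, :])
    r_cent = (np.arange(nr) + 0.5) * dr
    area = 2.0 * np.pi * r_cent[None, :] * dr
    g = Df * area / dz
    lo, hi = idx[:-1, :].ravel(), idx[1:, :].ravel()
    gf = g.ravel()
    rows += [lo, lo, hi, hi]
    cols += [hi, lo, lo, hi]
    vals += [gf / V[:-1, :].ravel(), -gf / V[:-1, :].ravel(),
             gf / V[1:, :].ravel(), -gf / V[1:, :].ravel()]

    return csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )


def solve(
    domain: DiffusionDomain,
    t_end: float,
    *,
    dt: float | None = None,
    n_out: int = 50,
    c0: np.ndarray | None = None,
    mass_tol: float = 1e-6,
) -> UptakeResult:
    """Run the diffusion to ``t_end`` seconds and record the uptake curve.

    Crank–Nicolson stepping (unconditionally stable); ``dt`` defaults to
    max(t_end/2000, 0.25·dx²/D_max), a compromise between temporal
    accuracy and runtime.  Relative total-mass drift beyond ``mass_tol``
    aborts with diagnostics.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    d_max = float(domain.D_field.max())
    if dt is None:
        dt = max(t_end / 2000.0, 0.25 * domain.dr**2 / d_max if d_max > 0 else t_end / 2000.0)
    n_steps = max(int(np.ceil(t_end / dt)), 1)
    dt = t_end / n_steps

    L = _assemble_operator(domain)
    n = L.shape[0]
    eye = identity(n, format="csc")
    lhs = splu((eye - 0.5 * dt * L).tocsc())
    rhs = (eye + 0.5 * dt * L).tocsc()

    c = (domain.initial_condition() if c0 is None else np.asarray(c0, dtype=float)).ravel().copy()
    if c.size != n:
        raise ValueError("c0 shape does not match the domain grid")
    vols = domain.volumes.ravel()
    interior = domain.interior.ravel()
    interior_volume = float(vols[interior].sum())
    mass0 = float(vols @ c)

    out_every = max(n_steps // n_out, 1)
    times = [0.0]
    amounts = [float(vols[interior] @ c[interior]) / interior_volume]
    masses = [mass0]
    for step in range(1, n_steps + 1):
        c = lhs.solve(rhs @ c)
        if step % out_every == 0 or step == n_steps:
            mass = float(vols @ c)
            if mass0 > 0 and abs(mass - mass0) / mass0 > mass_tol:
                raise RuntimeError(
                    f"mass drift {abs(mass - mass0) / mass0:.2e} exceeds {mass_tol:.0e} "
                    f"at t = {step * dt:.3g} s (instability or assembly error)"
                )
            times.append(step * dt)
            amounts.append(float(vols[interior] @ c[interior]) / interior_volume)
            masses.append(mass)

    return UptakeResult(
        times=np.array(times),
        intracellular_amount=np.array(amounts),
        total_mass=np.array(masses),
        final_field=c.reshape(domain.shape),
    )


def uptake_ratio(
    with_pore: UptakeResult, without_pore: UptakeResult, t: float
) -> float | None:
    """Ratio of intracellular amounts of two runs at time ``t``.

    Returns None (undefined) when the denominator is zero — e.g. a pore
    run compared against a sealed membrane.
    """
    if not np.allclose(with_pore.times, without_pore.times):
        raise ValueError("results must share a time grid")
    i = int(np.argmin(np.abs(with_pore.times - t)))
    num = float(with_pore.intracellular_amount[i])
    den = float(without_pore.intracellular_amount[i])
    if den == 0.0:
        return None
    return num / den
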