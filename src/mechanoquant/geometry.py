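"""Curvature model of the compressed cell as an oblate spheroid.

Under uniaxial viscoelastic compression a suspended, initially spherical
cell flattens into an oblate spheroid (equatorial semi-axes ``a = b``,
polar semi-axis ``c < a``).  Membrane bending — and hence the propensity
to porate — is governed by the principal curvatures of this surface,
which are largest on the equator.  This module computes the meridional
and prime-vertical radii of curvature as functions of the reduced
latitude ``phi`` (0° = equator, 90° = pole), the principal curvatures
``C1 = 1/rho1`` and ``C2 = 1/rho2``, and the total curvature
``J = C1 + C2``, together with the scaling law for the viscoelastic
compression force.

Conventions
-----------
The squared eccentricity ``e2 = (a² − c²)/a²`` enters the classical
radius formulas

    rho1(phi) = a (1 − e²) / (1 − e² sin²phi)^(3/2)
    rho2(phi) = a / (1 − e² sin²phi)^(1/2)

which reproduce the textbook limits rho1(0) = c²/a, rho2(0) = a at the
equator and rho1 = rho2 = a²/c at the pole, and collapse to rho = a for
a sphere.  A ``variant="literal"`` mode raises the rho2 denominator to
the 3/2 power instead (and re-squares the eccentricity), for auditing
against sources that print those forms; it does not satisfy the sphere
limit and is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OblateSpheroid",
    "CurvatureProfile",
    "ForceScaleParams",
    "make_oblate",
    "squared_eccentricity",
    "curvature_profile",
    "compression_force_scale",
    "curvature_table",
    "profiles_from_diameters",
]


class ShapeError(ValueError):
    """Raised when semi-axes violate the oblate-spheroid invariants."""


@dataclass(frozen=True)
class OblateSpheroid:
    """Oblate spheroid with equatorial semi-axes ``a = b`` and polar ``c`` (μm)."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.c > 0):
            raise ShapeError(f"semi-axes must be positive, got a={self.a}, c={self.c}")
        if self.a != self.b:
            raise ShapeError(f"equatorial semi-axes must be equal, got a={self.a}, b={self.b}")
        if self.c > self.a:
            raise ShapeError(
                f"prolate shape not allowed: polar semi-axis c={self.c} exceeds a={self.a}"
            )

    @property
    def is_sphere(self) -> bool:
        return self.a == self.c


@dataclass(frozen=True)
class ForceScaleParams:
    """Parameters of the viscoelastic compression-force scaling law.

    beta : confinement ratio, cell diameter / compression-channel height
    eta : fluid viscosity, Pa·s
    lam : fluid relaxation time, s
    u_max : maximum fluid velocity in the cross-section, m/s
    """

    beta: float
    eta: float
    lam: float
    u_max: float

    def __post_init__(self) -> None:
        for name in ("beta", "eta", "lam", "u_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class CurvatureProfile:
    """Principal curvature radii and total curvature along the meridian.

    ``phi`` is in degrees, 0 at the equator, 90 at the pole.  All radii in
    μm, curvatures in μm⁻¹.  ``parallel_curvature`` (1/a) is the constant
    curvature of the equatorial parallel circle; ``sphere_curvature`` is
    1/r0 and set only when the shape is a sphere.
    """

    phi: np.ndarray
    rho1: np.ndarray
    rho2: np.ndarray
    C1: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    C2: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    J: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    e2: float = 0.0
    parallel_curvature: float = 0.0
    sphere_curvature: float | None = None


def make_oblate(diameter_2a: float, diameter_2c: float) -> OblateSpheroid:
    """Build an :class:`OblateSpheroid` from the two measured diameters (μm).

    In-flow imaging measures the equatorial diameter ``2a`` and the polar
    diameter ``2c`` of the compressed cell; semi-axes are half of each.
    """
    if diameter_2a <= 0 or diameter_2c <= 0:
        raise ShapeError("diameters must be positive")
    if diameter_2c > diameter_2a:
        raise ShapeError("polar diameter exceeds equatorial diameter (prolate not allowed)")
    a = diameter_2a / 2.0
    return OblateSpheroid(a=a, b=a, c=diameter_2c / 2.0)


def squared_eccentricity(s: OblateSpheroid) -> float:
    """Squared first eccentricity e² = (a² − c²)/a², in [0, 1); 0 for a sphere."""
    return (s.a**2 - s.c**2) / s.a**2


def curvature_profile(
    s: OblateSpheroid,
    phi_grid: np.ndarray | None = None,
    *,
    variant: str = "default",
) -> CurvatureProfile:
    """Principal radii/curvatures of the spheroid on a grid of latitudes.

    Parameters
    ----------
    s :
        The compressed-cell shape.
    phi_grid :
        Latitudes in degrees within [0, 90]; default 0–90 in 1° steps.
        phi = 0 is the equator, where curvature (and bending) is maximal.
    variant :
        ``"default"`` uses the classical radii (rho2 exponent 1/2,
        eccentricity entering squared).  ``"literal"`` reproduces the
        printed-form alternative: the ratio (a²−c²)/a² is squared again
        and rho2 carries exponent 3/2.
    """
    if phi_grid is None:
        phi_grid = np.arange(0.0, 91.0, 1.0)
    phi = np.atleast_1d(np.asarray(phi_grid, dtype=float))
    if np.any(phi < 0) or np.any(phi > 90):
        raise ValueError("phi values must lie in [0, 90] degrees")

    ratio = squared_eccentricity(s)
    if variant == "default":
        e2 = ratio
        p2 = 0.5
    elif variant == "literal":
        e2 = ratio**2
        p2 = 1.5
    else:
        raise ValueError(f"unknown variant {variant!r}")

    s2 = np.sin(np.radians(phi)) ** 2
    w = 1.0 - e2 * s2
    rho1 = s.a * (1.0 - e2) / w**1.5
    rho2 = s.a / w**p2
    C1 = 1.0 / rho1
    C2 = 1.0 / rho2
    return CurvatureProfile(
        phi=phi,
        rho1=rho1,
        rho2=rho2,
        C1=C1,
        C2=C2,
        J=C1 + C2,
        e2=e2,
        parallel_curvature=1.0 / s.a,
        sphere_curvature=(1.0 / s.a) if s.is_sphere else None,
    )


def compression_force_scale(p: ForceScaleParams) -> float:
    """Relative viscoelastic compression force, F ∝ β³ η λ U_max².

    The proportionality constant is fixed at 1, so the return value is in
    arbitrary (relative) units: useful for comparing operating points,
    not as an absolute force.
    """
    return p.beta**3 * p.eta * p.lam * p.u_max**2


def curvature_table(profile: CurvatureProfile, cell_id: str = "cell") -> pd.DataFrame:
    """Long-format per-phi table of a curvature profile."""
    return pd.DataFrame(
        {
            "cell_id": cell_id,
            "phi_deg": profile.phi,
            "rho1_um": profile.rho1,
            "rho2_um": profile.rho2,
            "C1_per_um": profile.C1,
            "C2_per_um": profile.C2,
            "J_per_um": profile.J,
            "parallel_curvature_per_um": profile.parallel_curvature,
        }
    )


def profiles_from_diameters(
    diameters: pd.DataFrame, phi_grid: np.ndarray | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell curvature from a table of measured diameters.

    ``diameters`` needs columns ``cell_id``, ``d2a_um``, ``d2c_um``.
    Returns ``(summary, profiles)``: one row per cell with the equatorial
    total curvature J(0°) and the parallel curvature 1/a, and the
    long-format per-phi profiles of all cells.
    """
    required = {"cell_id", "d2a_um", "d2c_um"}
    missing = required - set(diameters.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    summaries = []
    tables = []
    for row in diameters.itertuples(index=False):
        s = make_oblate(row.d2a_um, row.d2c_um)
        prof = curvature_profile(s, phi_grid)
        j_equator = float(curvature_profile(s, np.array([0.0])).J[0])
        summaries.append(
            {
                "cell_id": row.cell_id,
                "a_um": s.a,
                "c_um": s.c,
                "e2": prof.e2,
                "J_equator_per_um": j_equator,
                "parallel_curvature_per_um": prof.parallel_curvature,
                "sphere_curvature_per_um": prof.sphere_curvature,
            }
        )
        tables.append(curvature_table(prof, cell_id=row.cell_id))
    return pd.DataFrame(summaries), pd.concat(tables, ignore_index=True)
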