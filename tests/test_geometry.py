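"""Oblate-spheroid curvature model and compression-force scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mechanoquant.geometry import (
    ForceScaleParams,
    ShapeError,
    compression_force_scale,
    curvature_profile,
    make_oblate,
    profiles_from_diameters,
    squared_eccentricity,
)


def meridian_curvature_radii_fd(a, c, phi_deg, h=2e-4):
    """Independent differential-geometry oracle for the principal radii.

    Finite-difference curvature of the parametrized meridian ellipse
    (x = a cos t, z = c sin t): the meridional radius is the inverse
    plane-curve curvature, the second radius is the distance to the
    rotation axis along the surface normal.  The parametric point is
    located from the geodetic latitude via tan(t) = (c/a) tan(phi).
    """
    phi = np.radians(phi_deg)
    t = np.arctan((c / a) * np.tan(np.clip(phi, 0, np.pi / 2 - 1e-12)))

    def x(tt):
        return a * np.cos(tt)

    def z(tt):
        return c * np.sin(tt)

    x1 = (x(t + h) - x(t - h)) / (2 * h)
    z1 = (z(t + h) - z(t - h)) / (2 * h)
    x2 = (x(t + h) - 2 * x(t) + x(t - h)) / h**2
    z2 = (z(t + h) - 2 * z(t) + z(t - h)) / h**2
    speed = np.hypot(x1, z1)
    kappa = abs(x1 * z2 - z1 * x2) / speed**3
    rho1 = 1.0 / kappa
    # the second radius is the distance to the rotation axis along the
    # normal; at the pole it degenerates to the meridional radius
    rho2 = rho1 if phi_deg >= 90 - 1e-9 else x(t) * speed / z1
    return rho1, rho2


class TestMakeOblate:
    @pytest.mark.parametrize(
        "d2a, d2c, a, c",
        [(20.0, 12.0, 10.0, 6.0), (16.66, 16.66, 8.33, 8.33)],
    )
    def test_halving(self, d2a, d2c, a, c):
        s = make_oblate(d2a, d2c)
        assert s.a == s.b == pytest.approx(a)
        assert s.c == pytest.approx(c)

    @pytest.mark.parametrize("d2a, d2c", [(12.0, 20.0), (-5.0, 3.0), (5.0, 0.0)])
    def test_invalid_shapes_rejected(self, d2a, d2c):
        with pytest.raises(ShapeError):
            make_oblate(d2a, d2c)


class TestEccentricity:
    def test_hand_value(self):
        assert squared_eccentricity(make_oblate(20, 12)) == pytest.approx(0.64)

    def test_sphere_is_zero(self):
        assert squared_eccentricity(make_oblate(15, 15)) == 0.0

    def test_degenerate_limit_approaches_one(self):
        assert squared_eccentricity(make_oblate(20, 1e-6)) == pytest.approx(1.0, abs=1e-6)


class TestCurvatureProfile:
    def test_sphere_constant_curvature(self):
        s = make_oblate(16.66, 16.66)
        for variant in ("default", "literal"):
            prof = curvature_profile(s, variant=variant)
            assert np.allclose(prof.C1, 1 / s.a)
            assert np.allclose(prof.C2, 1 / s.a)
            assert prof.sphere_curvature == pytest.approx(0.12, abs=0.001)

    def test_equator_and_pole_closed_forms(self):
        s = make_oblate(20, 12)
        prof = curvature_profile(s, np.array([0.0, 90.0]))
        assert prof.rho1[0] == pytest.approx(3.6)  # c^2/a
        assert prof.rho2[0] == pytest.approx(10.0)  # a
        assert prof.J[0] == pytest.approx(1 / 3.6 + 0.1)
        assert prof.rho1[1] == pytest.approx(100 / 6)  # a^2/c at the pole
        assert prof.rho2[1] == pytest.approx(100 / 6)
        assert prof.J[1] == pytest.approx(0.12)
        assert prof.parallel_curvature == pytest.approx(0.1)

    def test_agrees_with_differential_geometry_oracle(self):
        rng = np.random.default_rng(11)
        phi_grid = np.linspace(0.0, 90.0, 91)
        for _ in range(10):
            a = rng.uniform(5, 15)
            c = rng.uniform(0.3 * a, a)
            s = make_oblate(2 * a, 2 * c)
            prof = curvature_profile(s, phi_grid)
            for i, phi in enumerate(phi_grid):
                r1, r2 = meridian_curvature_radii_fd(s.a, s.c, phi)
                assert prof.rho1[i] == pytest.approx(r1, rel=1e-6)
                assert prof.rho2[i] == pytest.approx(r2, rel=1e-6)

    def test_total_curvature_maximal_at_equator(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.uniform(5, 15)
            c = rng.uniform(0.2 * a, a)
            prof = curvature_profile(make_oblate(2 * a, 2 * c))
            assert np.all(np.diff(prof.J) <= 1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(
        a=st.floats(min_value=2.0, max_value=30.0),
        ratio=st.floats(min_value=0.05, max_value=1.0),
    )
    def test_radii_positive_and_j_bracketed(self, a, ratio):
        """rho1, rho2 > 0 everywhere and J(pole) <= J(phi) <= J(equator)."""
        prof = curvature_profile(make_oblate(2 * a, 2 * a * ratio))
        assert np.all(prof.rho1 > 0) and np.all(prof.rho2 > 0)
        assert np.all(prof.J <= prof.J[0] + 1e-12)
        assert np.all(prof.J >= prof.J[-1] - 1e-12)

    def test_phi_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            curvature_profile(make_oblate(20, 12), np.array([-1.0]))
        with pytest.raises(ValueError):
            curvature_profile(make_oblate(20, 12), np.array([91.0]))


class TestForceScale:
    def test_identity_and_power_laws(self):
        base = ForceScaleParams(1, 1, 1, 1)
        assert compression_force_scale(base) == 1.0
        assert compression_force_scale(ForceScaleParams(2, 1, 1, 1)) == 8.0
        assert compression_force_scale(ForceScaleParams(1, 1, 1, 2)) == 4.0

    def test_log_slopes(self):
        # slopes (3, 1, 1, 2) in (beta, eta, lam, u_max)
        for i, expected in enumerate([3.0, 1.0, 1.0, 2.0]):
            args_lo = [1.0] * 4
            args_hi = [1.0] * 4
            args_hi[i] = np.e
            f_lo = compression_force_scale(ForceScaleParams(*args_lo))
            f_hi = compression_force_scale(ForceScaleParams(*args_hi))
            assert np.log(f_hi / f_lo) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ForceScaleParams(0, 1, 1, 1)


def test_profiles_from_diameters_table():
    diam = pd.DataFrame(
        {"cell_id": ["c1", "c2"], "d2a_um": [20.0, 16.66], "d2c_um": [12.0, 16.66]}
    )
    summary, profiles = profiles_from_diameters(diam)
    assert list(summary.cell_id) == ["c1", "c2"]
    c1 = summary.set_index("cell_id").loc["c1"]
    assert c1.J_equator_per_um == pytest.approx(1 / 3.6 + 0.1)
    c2 = summary.set_index("cell_id").loc["c2"]
    assert c2.sphere_curvature_per_um == pytest.approx(0.12, abs=0.001)
    assert set(profiles.cell_id) == {"c1", "c2"}
    assert (profiles.groupby("cell_id").size() == 91).all()
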