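"""MSD computation, power-law fitting, and transport classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mechanoquant.synthetic import gen_trajectories
from mechanoquant.transport import (
    PowerLawFit,
    Trajectory,
    TransportClassification,
    classify,
    classify_trajectories,
    compute_msd,
    fit_power_law,
    population_fractions,
    trajectories_from_table,
)


def make_traj(xy, dt=0.5):
    xy = np.asarray(xy, dtype=float)
    return Trajectory(t=np.arange(xy.shape[0]) * dt, xy=xy)


class TestTrajectory:
    def test_rejects_short_tracks(self):
        with pytest.raises(ValueError):
            make_traj(np.zeros((5, 2)))

    def test_rejects_nonuniform_sampling(self):
        t = np.arange(12) * 0.5
        t[6] += 0.2
        with pytest.raises(ValueError):
            Trajectory(t=t, xy=np.zeros((12, 2)))


class TestComputeMsd:
    def test_ballistic_closed_form(self):
        t = np.arange(20) * 0.5
        xy = np.column_stack([t * 1.0, np.zeros_like(t)])  # v = 1 μm/s along x
        lags, msd = compute_msd(make_traj(xy))
        assert np.allclose(msd, lags**2)

    def test_stationary_is_zero(self):
        lags, msd = compute_msd(make_traj(np.zeros((20, 2))))
        assert np.all(msd == 0)

    def test_time_origin_invariance(self):
        rng = np.random.default_rng(0)
        xy = np.cumsum(rng.normal(size=(30, 2)), axis=0)
        traj1 = Trajectory(t=np.arange(30) * 0.5, xy=xy)
        traj2 = Trajectory(t=np.arange(30) * 0.5 + 100.0, xy=xy)
        _, m1 = compute_msd(traj1)
        _, m2 = compute_msd(traj2)
        assert np.array_equal(m1, m2)

    def test_brownian_ensemble_matches_4dt(self):
        trajs, _ = gen_trajectories(n=200, frac_directed=0.0, D=0.1, seed=8)
        msds = np.array([compute_msd(t)[1] for t in trajs])
        lags = compute_msd(trajs[0])[0]
        ens = msds.mean(axis=0)
        sel = lags <= 5.0
        assert np.allclose(ens[sel], 4 * 0.1 * lags[sel], rtol=0.10)


class TestFitPowerLaw:
    def test_linear_closed_form(self):
        lags = np.arange(1, 11) * 0.5
        fit = fit_power_law(lags, 4 * 0.1 * lags)
        assert fit.alpha == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.D_est == pytest.approx(0.1)

    def test_ballistic_closed_form(self):
        lags = np.arange(1, 11) * 0.5
        fit = fit_power_law(lags, lags**2)
        assert fit.alpha == pytest.approx(2.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_weighted_fit_matches_on_exact_law(self):
        lags = np.arange(1, 11) * 0.5
        w = np.arange(10, 0, -1.0)
        fit = fit_power_law(lags, 2.0 * lags**1.5, weights=w)
        assert fit.alpha == pytest.approx(1.5, abs=1e-12)
        assert fit.prefactor == pytest.approx(2.0)

    def test_nonpositive_points_dropped(self):
        lags = np.arange(1, 6) * 0.5
        msd = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        fit = fit_power_law(lags, msd)  # first point dropped, 4 remain
        assert np.isfinite(fit.alpha)
        with pytest.raises(ValueError):
            fit_power_law(lags, np.array([0.0, 0.0, 0.0, 1.0, 2.0]))


@settings(max_examples=60, derandomize=True)
@given(
    alpha=st.floats(min_value=0.1, max_value=2.5),
    k=st.floats(min_value=0.01, max_value=10.0),
)
def test_exact_power_law_recovered_for_any_exponent(alpha, k):
    """The log-log regression is exact on noiseless power laws."""
    lags = np.arange(1, 15) * 0.5
    fit = fit_power_law(lags, k * lags**alpha)
    assert fit.alpha == pytest.approx(alpha, abs=1e-9)
    assert fit.prefactor == pytest.approx(k, rel=1e-9)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-9)


class TestClassify:
    @pytest.mark.parametrize(
        "alpha, r2, label",
        [(0.8, 0.9, "diffusive"), (1.0, 0.9, "diffusive"),
         (1.5, 0.9, "transported"), (1.5, 0.5, "rejected"), (1.5, 0.75, "rejected")],
    )
    def test_rule(self, alpha, r2, label):
        assert classify(PowerLawFit(alpha, 1.0, r2)).label == label

    def test_ballistic_boundary_warns(self):
        with pytest.warns(UserWarning):
            cls = classify(PowerLawFit(2.2, 1.0, 0.95))
        assert cls.label == "transported"


class TestPopulationFractions:
    def test_even_split(self):
        cls = [TransportClassification("diffusive", 0.9, 0.9)] * 40
        cls += [TransportClassification("transported", 1.5, 0.9)] * 40
        fr = population_fractions(cls)
        assert fr["pct_diffusive"] == 50.0
        assert fr["pct_transported"] == 50.0
        assert fr["n_accepted"] == 80

    def test_all_diffusive(self):
        fr = population_fractions([TransportClassification("diffusive", 0.9, 0.9)] * 5)
        assert fr["pct_diffusive"] == 100.0

    def test_all_rejected_raises_with_counts(self):
        with pytest.raises(ValueError, match="3"):
            population_fractions([TransportClassification("rejected", 1.0, 0.1)] * 3)


class TestClassifierRecovery:
    def test_directed_tracks_detected(self):
        trajs, labels = gen_trajectories(n=50, frac_directed=1.0, D=0.01, v=0.5, seed=2)
        table = classify_trajectories(trajs)
        assert (table.label == "transported").mean() >= 0.95

    def test_single_brownian_alpha_spread(self):
        # weighted per-track fits keep the anomalous exponent of a pure
        # Brownian 40-frame track within [0.6, 1.4] in >= 90% of replicates
        hits = 0
        n_rep = 200
        for k in range(n_rep):
            trajs, _ = gen_trajectories(n=1, frac_directed=0.0, D=0.05, seed=k)
            row = classify_trajectories(trajs).iloc[0]
            hits += 0.6 <= row.alpha <= 1.4
        assert hits / n_rep >= 0.90

    def test_ensemble_brownian_alpha_near_one(self):
        trajs, _ = gen_trajectories(n=200, frac_directed=0.0, D=0.05, seed=3)
        msds = np.array([compute_msd(t)[1] for t in trajs])
        lags = compute_msd(trajs[0])[0]
        fit = fit_power_law(lags, msds.mean(axis=0))
        assert 0.9 <= fit.alpha <= 1.1


def test_trajectories_from_table_roundtrip():
    import pandas as pd

    trajs, _ = gen_trajectories(n=3, frac_directed=0.0, D=0.05, seed=4)
    rows = []
    for tid, traj in enumerate(trajs):
        for f, (x, y) in enumerate(traj.xy):
            rows.append({"track_id": tid, "frame": f, "x_um": x, "y_um": y})
    back = trajectories_from_table(pd.DataFrame(rows), dt=0.5)
    assert len(back) == 3
    assert np.allclose(back[0].xy, trajs[0].xy)
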