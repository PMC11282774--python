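"""MSD-based classification of intracellular nanoparticle transport.

Delivered beads are video-tracked (0.5 s sampling over 20 s); from each
2-D trajectory the time-averaged mean squared displacement

    MSD(tau) = < |r(t + tau) - r(t)|^2 >_t

is computed and fitted to a power law MSD = K tau^alpha by linear
regression of log MSD on log tau.  Fits with R^2 <= 0.75 are rejected.
Accepted trajectories are classified by the anomalous exponent:
alpha <= 1 diffusive (free or hindered diffusion; for alpha ~ 1 the
2-D relation MSD = 4 D tau gives the diffusion coefficient), and
1 < alpha < 2 actively transported (motor-driven, superdiffusive).
Population fractions over accepted trajectories summarize the share of
passively diffusing cargo — high after mechanoporation, where delivery
bypasses endocytosis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Trajectory",
    "PowerLawFit",
    "TransportClassification",
    "compute_msd",
    "fit_power_law",
    "classify",
    "population_fractions",
    "classify_trajectories",
    "trajectories_from_table",
]

R2_THRESHOLD = 0.75


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled 2-D track: times (s) and (N, 2) positions (μm)."""

    t: np.ndarray
    xy: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        xy = np.asarray(self.xy, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "xy", xy)
        if t.ndim != 1 or xy.shape != (t.size, 2):
            raise ValueError("t must be (N,), xy must be (N, 2)")
        if t.size < 10:
            raise ValueError("at least 10 frames required")
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("sampling must be uniform and increasing")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass(frozen=True)
class PowerLawFit:
    """Power-law fit MSD = prefactor · tau^alpha with goodness R².

    ``D_est`` (μm²/s) is prefactor/4 (2-D) and is meaningful only for
    accepted diffusive fits.
    """

    alpha: float
    prefactor: float
    r_squared: float

    @property
    def D_est(self) -> float:
        return self.prefactor / 4.0


@dataclass(frozen=True)
class TransportClassification:
    label: str  # "diffusive" | "transported" | "rejected"
    alpha: float
    r_squared: float


def compute_msd(
    traj: Trajectory, max_lag_fraction: float = 0.5, return_counts: bool = False
):
    """Time-averaged MSD over all frame pairs at each lag.

    Lags run from one frame up to ``max_lag_fraction`` of the trajectory
    length (default half, limiting the large-lag estimator variance).
    Returns ``(lags_s, msd_um2)``, plus the number of averaged pairs per
    lag when ``return_counts`` is set (useful as fit weights).
    """
    if not 0 < max_lag_fraction <= 1:
        raise ValueError("max_lag_fraction must be in (0, 1]")
    n = traj.t.size
    max_lag = max(int(np.floor((n - 1) * max_lag_fraction)), 1)
    if max_lag < 2:
        raise ValueError("fewer than 2 usable lags")
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(lags.size)
    for i, lag in enumerate(lags):
        d = traj.xy[lag:] - traj.xy[:-lag]
        msd[i] = np.mean(np.sum(d**2, axis=1))
    if return_counts:
        return lags * traj.dt, msd, (n - lags).astype(float)
    return lags * traj.dt, msd


def fit_power_law(
    lags: np.ndarray, msd: np.ndarray, weights: np.ndarray | None = None
) -> PowerLawFit:
    """Fit MSD = K tau^alpha by log–log linear regression.

    ``weights`` (e.g. the number of averaged pairs per lag, which decays
    with lag for a time-averaged MSD) give a weighted regression;
    unweighted by default.  Non-positive MSD values are dropped before
    taking logs; fewer than 3 remaining points is an error.
    """
    lags = np.asarray(lags, dtype=float)
    msd = np.asarray(msd, dtype=float)
    keep = msd > 0
    if keep.sum() < 3:
        raise ValueError("fewer than 3 positive MSD points")
    x = np.log(lags[keep])
    y = np.log(msd[keep])
    if weights is None:
        res = stats.linregress(x, y)
        return PowerLawFit(
            alpha=float(res.slope),
            prefactor=float(np.exp(res.intercept)),
            r_squared=float(res.rvalue**2),
        )
    w = np.asarray(weights, dtype=float)[keep]
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    w = w / w.sum()
    xb, yb = float(w @ x), float(w @ y)
    sxx = float(w @ (x - xb) ** 2)
    sxy = float(w @ ((x - xb) * (y - yb)))
    slope = sxy / sxx
    intercept = yb - slope * xb
    ss_res = float(w @ (y - intercept - slope * x) ** 2)
    ss_tot = float(w @ (y - yb) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(alpha=slope, prefactor=float(np.exp(intercept)), r_squared=r2)


def classify(fit: PowerLawFit) -> TransportClassification:
    """Label a fitted trajectory as diffusive, transported, or rejected.

    Fits with R² ≤ 0.75 are rejected.  alpha ≤ 1 is diffusive (alpha = 1
    inclusive); 1 < alpha < 2 is actively transported.  alpha ≥ 2 falls
    outside the superdiffusive transport range and is labeled transported
    with a boundary warning rather than given a class of its own.
    """
    if fit.r_squared <= R2_THRESHOLD:
        return TransportClassification("rejected", fit.alpha, fit.r_squared)
    if fit.alpha <= 1.0:
        return TransportClassification("diffusive", fit.alpha, fit.r_squared)
    if fit.alpha >= 2.0:
        warnings.warn(f"alpha = {fit.alpha:.2f} at or beyond the ballistic boundary")
    return TransportClassification("transported", fit.alpha, fit.r_squared)


def population_fractions(
    classifications: list[TransportClassification],
) -> dict[str, float]:
    """Percentages of diffusive/transported over accepted trajectories.

    Returns a dict with ``pct_diffusive``, ``pct_transported``,
    ``n_tracked`` (all trajectories) and ``n_accepted``.  Raises when no
    trajectory is accepted, reporting the counts in the message.
    """
    if not classifications:
        raise ValueError("no classifications given")
    n_tracked = len(classifications)
    accepted = [c for c in classifications if c.label != "rejected"]
    if not accepted:
        raise ValueError(f"all {n_tracked} trajectories rejected (R² ≤ {R2_THRESHOLD})")
    n_diff = sum(1 for c in accepted if c.label == "diffusive")
    n_trans = len(accepted) - n_diff
    return {
        "pct_diffusive": 100.0 * n_diff / len(accepted),
        "pct_transported": 100.0 * n_trans / len(accepted),
        "n_tracked": n_tracked,
        "n_accepted": len(accepted),
    }


def classify_trajectories(
    trajectories: list[Trajectory], max_lag_fraction: float = 0.5
) -> pd.DataFrame:
    """Per-track table of (alpha, r_squared, label, D_est) for a set of tracks."""
    rows = []
    for i, traj in enumerate(trajectories):
        lags, msd, counts = compute_msd(traj, max_lag_fraction, return_counts=True)
        # variance of a time-averaged MSD point grows ~ k/(n-k) with lag
        # index k, so weight the log-log regression by its inverse
        weights = counts / np.arange(1, counts.size + 1)
        try:
            fit = fit_power_law(lags, msd, weights=weights)
        except ValueError:
            rows.append({"track_id": i, "alpha": np.nan, "r_squared": np.nan,
                         "label": "rejected", "D_est": np.nan})
            continue
        cls = classify(fit)
        rows.append(
            {
                "track_id": i,
                "alpha": cls.alpha,
                "r_squared": cls.r_squared,
                "label": cls.label,
                "D_est": fit.D_est if cls.label == "diffusive" else np.nan,
            }
        )
    return pd.DataFrame(rows)


def trajectories_from_table(df: pd.DataFrame, dt: float = 0.5) -> list[Trajectory]:
    """Build trajectories from a (track_id, frame, x_um, y_um) table."""
    required = {"track_id", "frame", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = []
    for _, g in df.sort_values(["track_id", "frame"]).groupby("track_id"):
        t = g["frame"].to_numpy(dtype=float) * dt
        xy = g[["x_um", "y_um"]].to_numpy(dtype=float)
        out.append(Trajectory(t=t, xy=xy))
    return out
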