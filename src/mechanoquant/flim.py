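"""Biexponential fluorescence-decay fitting for lifetime-based tension readout.

Planarizable push–pull membrane probes (e.g. Flipper-TR) report membrane
tension through their fluorescence lifetime: higher lipid packing/tension
lengthens the excited-state decay.  Measured photon decays are well
described by a double exponential

    f(t) = I1 exp(-t / tau1) + I2 exp(-t / tau2) [+ bg]

where the dominant component tau1 carries the large majority of the
signal and is the quantity reported as the tension readout; tau2 is a
minor fast component.  Components are canonically ordered by signal
share I·tau, so the reported tau1 is always the majority component
regardless of the optimiser's internal labelling.

Fitting is bounded nonlinear least squares on the binned decay with
Poisson-motivated weights sqrt(counts + mean counts) — the mean-count
floor keeps the weighting scale-equivariant — multi-started from a
small set of log-spaced lifetime pairs for robustness against local
minima.  No instrument-response deconvolution is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["DecayTrace", "BiexpFit", "fit_biexponential", "fit_lifetime_image"]


class DecayError(ValueError):
    """Raised for invalid decay traces."""


@dataclass(frozen=True)
class DecayTrace:
    """A binned photon decay: time-bin centers (ns) and counts per bin."""

    t: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "counts", counts)
        if t.ndim != 1 or counts.shape != t.shape:
            raise DecayError("t and counts must be 1-D arrays of equal length")
        if t.size < 8:
            raise DecayError("at least 8 time bins required")
        if np.any(np.diff(t) <= 0):
            raise DecayError("time bins must be strictly increasing")
        if np.any(counts < 0):
            raise DecayError("counts must be non-negative")
        if counts.sum() <= 0:
            raise DecayError("total counts must be positive")


@dataclass(frozen=True)
class BiexpFit:
    """Result of a biexponential fit, canonically ordered by signal share.

    ``tau1``/``I1`` is the majority-signal component (I1·tau1 ≥ I2·tau2);
    ``tau1`` is the reported lifetime.  ``converged`` is False when all
    restarts failed to converge; such fits are flagged, never silent.
    """

    tau1: float
    tau2: float
    I1: float
    I2: float
    residual_norm: float
    background: float = 0.0
    converged: bool = True

    @property
    def minor_signal_fraction(self) -> float:
        """Share of total signal carried by the minor component."""
        total = self.I1 * self.tau1 + self.I2 * self.tau2
        return 0.0 if total == 0 else (self.I2 * self.tau2) / total


def _model(t: np.ndarray, i1: float, tau1: float, i2: float, tau2: float, bg: float) -> np.ndarray:
    return i1 * np.exp(-t / tau1) + i2 * np.exp(-t / tau2) + bg


def fit_biexponential(
    d: DecayTrace,
    initial_guess: tuple[float, float] | None = None,
    *,
    fit_background: bool = False,
    n_restarts: int = 4,
) -> BiexpFit:
    """Fit ``I1 exp(-t/tau1) + I2 exp(-t/tau2)`` to a photon decay.

    Parameters
    ----------
    d :
        The binned decay trace.
    initial_guess :
        Optional lifetime pair (ns) tried first; log-spaced pairs spanning
        the observed time range are tried as additional starts.
    fit_background :
        Add a constant-background term to the model.
    n_restarts :
        Number of multi-start attempts beyond the user guess.

    Raises ``DecayError`` when the trace has fewer bins than free
    parameters.  Non-convergence of every start yields a fit flagged with
    ``converged=False`` rather than an exception.
    """
    n_params = 5 if fit_background else 4
    if d.t.size < n_params:
        raise DecayError("fewer bins than model parameters")

    t, counts = d.t, d.counts
    # Poisson-motivated weights with a mean-count variance floor; the floor
    # scales with the data, keeping the fit exactly scale-equivariant
    weights = np.sqrt(counts + counts.mean())
    span = t[-1] - t[0]
    amp0 = float(counts.max())

    starts: list[tuple[float, float]] = []
    if initial_guess is not None:
        starts.append((float(initial_guess[0]), float(initial_guess[1])))
    # log-spaced lifetime pairs spanning from one bin to the full window
    taus = np.geomspace(max(span / 50.0, 1e-3), span, n_restarts)
    for k in range(n_restarts):
        starts.append((float(taus[-(k + 1)]), float(taus[k // 2])))

    def residuals(p: np.ndarray) -> np.ndarray:
        bg = p[4] if fit_background else 0.0
        return (_model(t, p[0], p[1], p[2], p[3], bg) - counts) / weights

    lo = [0.0, 1e-4, 0.0, 1e-4]
    hi = [np.inf, 10 * span, np.inf, 10 * span]
    if fit_background:
        lo.append(0.0)
        hi.append(np.inf)

    best = None
    for tau_a, tau_b in starts:
        p0 = [0.8 * amp0, tau_a, 0.2 * amp0, tau_b]
        if fit_background:
            p0.append(max(float(counts.min()), 0.0))
        try:
            res = least_squares(residuals, p0, bounds=(lo, hi), max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None or not np.all(np.isfinite(best.x)):
        return BiexpFit(np.nan, np.nan, np.nan, np.nan, np.inf, converged=False)

    i1, tau1, i2, tau2 = best.x[:4]
    bg = float(best.x[4]) if fit_background else 0.0
    # canonical order: component 1 carries the majority of the signal I·tau
    if i1 * tau1 < i2 * tau2:
        i1, tau1, i2, tau2 = i2, tau2, i1, tau1
    # a biexponential fit to an effectively monoexponential decay is
    # unidentifiable in the amplitude split; merge near-equal lifetimes
    if tau1 > 0 and abs(tau1 - tau2) / tau1 < 0.05:
        i1, i2, tau2 = i1 + i2, 0.0, tau1
    resid_norm = float(np.sqrt(2.0 * best.cost) / np.sqrt(max(t.size - n_params, 1)))
    return BiexpFit(
        tau1=float(tau1),
        tau2=float(tau2),
        I1=float(i1),
        I2=float(i2),
        residual_norm=resid_norm,
        background=bg,
        converged=bool(best.success),
    )


def fit_lifetime_image(
    stack: np.ndarray,
    mask: np.ndarray,
    t: np.ndarray,
    **fit_kwargs,
) -> tuple[np.ndarray, float]:
    """Per-pixel tau1 map over a masked field of view, plus the region mean.

    ``stack`` is (n_time, ny, nx) photon counts; ``mask`` a boolean
    (ny, nx) cell-region mask; ``t`` the shared time-bin centers (ns).
    Pixels whose fit fails (non-convergence or zero counts) are NaN in
    the returned map and excluded from the mean.
    """
    stack = np.asarray(stack, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if stack.ndim != 3 or stack.shape[1:] != mask.shape:
        raise ValueError("stack (t, y, x) and mask (y, x) must share spatial shape")
    if not mask.any():
        raise ValueError("empty mask")

    tau_map = np.full(mask.shape, np.nan)
    for iy, ix in zip(*np.nonzero(mask)):
        counts = stack[:, iy, ix]
        if counts.sum() <= 0:
            continue
        try:
            fit = fit_biexponential(DecayTrace(t, counts), **fit_kwargs)
        except DecayError:
            continue
        if fit.converged:
            tau_map[iy, ix] = fit.tau1
    valid = np.isfinite(tau_map) & mask
    if not valid.any():
        raise ValueError("no pixel produced a valid fit")
    return tau_map, float(tau_map[valid].mean())
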