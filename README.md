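# mechanoquant

Quantitative analysis of microfluidic cell mechanoporation experiments —
for researchers who compress cells in viscoelastic flow to open
transient membrane pores and deliver nano- and macro-cargoes, and who
need the downstream image and trajectory analysis as tested, scriptable
code rather than ad-hoc macros.

The package covers the full measurement chain of such an experiment:

- **Geometry** — the compressed cell as an oblate spheroid (semi-axes
  a = b > c): squared eccentricity e² = (a² − c²)/a², principal
  curvature radii ρ₁(φ) = a(1−e²)/(1−e² sin²φ)^{3/2} and
  ρ₂(φ) = a/(1−e² sin²φ)^{1/2}, total curvature J = C₁ + C₂ (maximal at
  the equator, where pores form), and the compression-force scaling
  F ∝ β³ η λ U²max.
- **Lifetime fitting** — biexponential fits
  I₁e^{−t/τ₁} + I₂e^{−t/τ₂} of membrane-probe photon decays; the
  majority-signal lifetime τ₁ is the tension readout.
- **Tension-point mapping** — circle fit of the cell silhouette,
  detection of red-channel spots in the [120, 180] window, normalized
  polar coordinates, and concentration over eight 45° bins against the
  12.5% uniform baseline.
- **Cortex morphometry** — thickness (r_major − r_minor)/2 and
  area-normalized intensity of the annular actin ring.
- **Nanoparticle counting** — thresholded voxel volumes in an axial
  analysis slab converted to bead counts via the single-bead volume,
  with calibrated thresholds, delivery-efficiency ratios, and
  colocalization fractions.
- **Transport classification** — time-averaged MSD per trajectory,
  power-law fits MSD ∝ τ^α (R² > 0.75), α ≤ 1 diffusive vs 1 < α < 2
  actively transported.
- **Pore-diffusion simulation** — an axisymmetric finite-volume
  Crank–Nicolson solver for Fick diffusion of beads into a cell through
  a 0.5–1.5 μm membrane pore, with Stokes–Einstein diffusivities.
- **Synthetic data** — seeded generators for every input modality, so
  each stage is testable closed-loop against known ground truth.

See `docs/methods.md` for the models, defaults, numerical choices and
limitations.

## Worked example

```python
import numpy as np
from mechanoquant import make_oblate, curvature_profile
from mechanoquant import DecayTrace, fit_biexponential
from mechanoquant.synthetic import gen_decay

# a cell measured in-flow at 2a = 20 um, 2c = 12 um after compression
prof = curvature_profile(make_oblate(20.0, 12.0), np.array([0.0, 90.0]))
print(prof.rho1, prof.rho2, prof.J)

# membrane-tension readout from a photon decay (4.7 ns resting lifetime)
t, counts = gen_decay(tau1=4.7, tau2=1.0, i1=9, i2=1, n_photons=100_000, seed=1)
fit = fit_biexponential(DecayTrace(t, counts))
print(round(fit.tau1, 2), "ns")
```

prints

```
[ 3.6        16.66666667] [10.         16.66666667] [0.37777778 0.12      ]
4.68 ns
```

At the equator (φ = 0°) the meridional radius is c²/a = 3.6 μm and the
total curvature J ≈ 0.38 μm⁻¹ — three times the resting sphere's
0.12 μm⁻¹, the geometric driver of pore formation; at the pole both
radii equal a²/c.  The fitted 4.68 ns recovers the planted 4.7 ns
resting lifetime to ~1%; after compression the same readout rises by
~12%.

More narrative walk-throughs live in `examples/` (one script per
capability); `mechanoquant --help` exposes the same stages as a thin
command-line interface, including a manifest-driven `run` subcommand
that executes the full pipeline reproducibly.

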