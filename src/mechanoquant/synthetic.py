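"""Ground-truth generators for every input modality of the pipeline.

Each generator is a pure function of its parameters and a seed
(identical inputs give bit-identical output) and emulates one
acquisition mode of the mechanoporation experiments:

- photon decays: multinomial counts over time bins following a
  biexponential density, dominant lifetime ~4.7–6.5 ns;
- tension maps: an RGB cell silhouette with peripheral red spots at
  controlled angles inside the detection window;
- z-stacks: ellipsoidal cells containing non-overlapping fluorescent
  beads rendered with partial-volume occupancy, Gaussian PSF blur and
  additive Gaussian camera noise;
- trajectories: 2-D Brownian walks (0.5 s sampling over 20 s) with an
  optional directed-motion fraction;
- cortex rings: annuli of known radii and intensity.

Noise models are the simplest standard forms (multinomial photon
statistics, Gaussian camera noise, Gaussian PSF); none of the optics
beyond that (instrument response, spectral bleed-through, detector
afterpulsing) is simulated.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .npquant import ZStack
from .transport import Trajectory

__all__ = [
    "gen_decay",
    "gen_decay_stack",
    "gen_tension_image",
    "gen_zstack",
    "gen_reference_stack",
    "gen_reference_ensemble",
    "gen_trajectories",
    "gen_ring_image",
]


def gen_decay(
    tau1: float = 4.7,
    tau2: float = 1.0,
    i1: float = 9.0,
    i2: float = 1.0,
    n_photons: int = 100_000,
    n_bins: int = 256,
    t_max: float = 50.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Multinomial photon counts over time bins from a biexponential decay.

    Expected counts per bin are proportional to
    ``i1·exp(-t/tau1) + i2·exp(-t/tau2)`` at the bin center, so ``i1``
    and ``i2`` play the role of the fitted amplitudes.  Returns
    ``(t_centers_ns, counts)``.
    """
    if tau1 <= 0 or tau2 <= 0:
        raise ValueError("lifetimes must be positive")
    if n_photons <= 0:
        raise ValueError("n_photons must be positive")
    if i1 < 0 or i2 < 0 or i1 + i2 == 0:
        raise ValueError("amplitudes must be non-negative and not both zero")
    rng = np.random.default_rng(seed)
    edges = np.linspace(0.0, t_max, n_bins + 1)
    t = 0.5 * (edges[:-1] + edges[1:])
    weights = i1 * np.exp(-t / tau1) + i2 * np.exp(-t / tau2)
    p = weights / weights.sum()
    counts = rng.multinomial(n_photons, p)
    return t, counts


def gen_decay_stack(
    tau1_map: np.ndarray,
    n_photons: int = 20_000,
    n_bins: int = 64,
    t_max: float = 50.0,
    tau2: float = 1.0,
    minor_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel decay stack (t, y, x) from a map of dominant lifetimes.

    Pixels with non-finite tau1 get zero counts.  ``minor_fraction`` sets
    the amplitude share of the fast minor component.
    """
    tau1_map = np.asarray(tau1_map, dtype=float)
    stack = np.zeros((n_bins,) + tau1_map.shape)
    t = None
    rng_seed = np.random.default_rng(seed)
    for iy in range(tau1_map.shape[0]):
        for ix in range(tau1_map.shape[1]):
            tau1 = tau1_map[iy, ix]
            if not np.isfinite(tau1):
                continue
            sub = int(rng_seed.integers(0, 2**31 - 1))
            t, counts = gen_decay(
                tau1=tau1, tau2=tau2, i1=1.0 - minor_fraction, i2=minor_fraction,
                n_photons=n_photons, n_bins=n_bins, t_max=t_max, seed=sub,
            )
            stack[:, iy, ix] = counts
    if t is None:
        raise ValueError("tau1_map contains no finite lifetime")
    return t, stack


def gen_tension_image(
    cell_radius: float = 100.0,
    point_angles: tuple[float, ...] = (),
    point_red_value: int = 150,
    image_size: int = 512,
    cluster_size: int = 1,
    disk_value: int = 80,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """RGB tension map: a gray cell disk plus red peripheral spots.

    Spots of red intensity ``point_red_value`` are placed at
    ``norm_r = 1`` at the requested angles (degrees, mathematical
    convention: counter-clockwise from +x with image y flipped).  The
    disk's own red value (80) sits below the [120, 180] detection
    window.  Returns the image and a truth table of planted angles.
    """
    img = np.zeros((image_size, image_size, 3), dtype=np.uint8)
    c = image_size / 2.0
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    disk = (xx - c) ** 2 + (yy - c) ** 2 <= cell_radius**2
    img[disk] = disk_value

    half = cluster_size // 2
    planted = []
    for ang in point_angles:
        ang = float(ang) % 360.0
        x = int(round(c + cell_radius * np.cos(np.radians(ang))))
        y = int(round(c - cell_radius * np.sin(np.radians(ang))))
        y0, y1 = max(y - half, 0), min(y + half + 1, image_size)
        x0, x1 = max(x - half, 0), min(x + half + 1, image_size)
        img[y0:y1, x0:x1, 0] = point_red_value
        img[y0:y1, x0:x1, 1] = 30
        planted.append({"angle_deg": ang, "x": x, "y": y})
    truth = {
        "centroid": (c, c),
        "cell_radius": cell_radius,
        "angles_deg": [p["angle_deg"] for p in planted],
        "points": planted,
    }
    return img, truth


def _render_particles(
    shape: tuple[int, int, int],
    centers_um: np.ndarray,
    radius_um: float,
    dz: float,
    dxy: float,
    amplitude: float,
    supersample: int = 4,
) -> np.ndarray:
    """Additive partial-volume rendering of spheres onto a voxel grid."""
    nz, ny, nx = shape
    stack = np.zeros(shape)
    # margins of the local bounding box, in voxels
    mz = int(np.ceil(radius_um / dz)) + 1
    mxy = int(np.ceil(radius_um / dxy)) + 1
    off = (np.arange(supersample) + 0.5) / supersample  # subvoxel fractions
    oz, oy, ox = np.meshgrid(off, off, off, indexing="ij")
    for cx, cy, cz in centers_um:  # centers in μm, (x, y, z)
        kz, ky, kx = int(cz / dz), int(cy / dxy), int(cx / dxy)
        for iz in range(max(kz - mz, 0), min(kz + mz + 1, nz)):
            for iy in range(max(ky - mxy, 0), min(ky + mxy + 1, ny)):
                for ix in range(max(kx - mxy, 0), min(kx + mxy + 1, nx)):
                    zs = (iz + oz) * dz - cz
                    ys = (iy + oy) * dxy - cy
                    xs = (ix + ox) * dxy - cx
                    inside = zs**2 + ys**2 + xs**2 <= radius_um**2
                    frac = inside.mean()
                    if frac > 0:
                        stack[iz, iy, ix] += amplitude * frac
    return stack


def gen_zstack(
    n_particles: int = 30,
    np_diameter: int = 200,
    cell_semi_axes: tuple[float, float] = (7.0, 5.0),
    dz: float = 0.35,
    dxy: float = 0.05,
    psf_sigma: float = 1.0,
    psf_sigma_z_um: float = 0.27,
    snr: float = 10.0,
    amplitude: float = 1000.0,
    seed: int = 0,
    max_retries: int = 20_000,
) -> tuple[ZStack, dict]:
    """Z-stack of non-overlapping beads inside an ellipsoidal cell.

    ``cell_semi_axes`` is (equatorial a, polar c) in μm, sized like a
    compressed MCF-7 cell; bead centers are rejection-sampled inside the
    ellipsoid (shrunk by the bead radius) with no mutual overlap.  Beads
    are rendered with partial-volume occupancy, blurred with a Gaussian
    PSF of ``psf_sigma`` pixels laterally and ``psf_sigma_z_um`` μm
    axially (the elongated axial response of a high-NA confocal), and
    corrupted with additive Gaussian noise of
    sigma = blurred-single-bead-peak / snr (``snr=inf`` for clean
    stacks).  Returns the stack and the planted ground truth.
    """
    if n_particles < 0:
        raise ValueError("n_particles must be non-negative")
    a, c = cell_semi_axes
    radius_um = (np_diameter / 1000.0) / 2.0
    if a - radius_um <= 0 or c - radius_um <= 0:
        raise ValueError("cell too small for the requested bead size")
    rng = np.random.default_rng(seed)

    margin_um = 0.5
    nx = ny = int(np.ceil(2 * (a + margin_um) / dxy))
    nz = int(np.ceil(2 * (c + margin_um) / dz))
    center = np.array([(a + margin_um), (a + margin_um), (c + margin_um)])  # x, y, z μm

    centers: list[np.ndarray] = []
    min_sep = 2 * radius_um + 2 * dxy
    tries = 0
    while len(centers) < n_particles:
        if tries >= max_retries:
            raise RuntimeError(
                f"could not place {n_particles} non-overlapping beads after {max_retries} tries"
            )
        tries += 1
        u = rng.uniform(-1, 1, size=3)
        cand = center + u * np.array([a - radius_um, a - radius_um, c - radius_um])
        rel = (cand - center) / np.array([a - radius_um, a - radius_um, c - radius_um])
        if (rel**2).sum() > 1.0:
            continue
        if any(np.linalg.norm(cand - p) < min_sep for p in centers):
            continue
        centers.append(cand)
    centers_arr = np.array(centers).reshape(-1, 3)

    clean = _render_particles((nz, ny, nx), centers_arr, radius_um, dz, dxy, amplitude)
    sigma = (psf_sigma_z_um / dz, psf_sigma, psf_sigma)
    clean = gaussian_filter(clean, sigma=sigma)
    peak = float(clean.max()) if n_particles > 0 else amplitude
    noise_sigma = 0.0 if np.isinf(snr) else peak / snr
    noisy = clean + rng.normal(0.0, noise_sigma, size=clean.shape) if noise_sigma else clean

    stack = ZStack(voxels=noisy, dz=dz, dxy=dxy, np_diameter=np_diameter)
    truth = {
        "count": n_particles,
        "centers_um": centers_arr,
        "amplitude": amplitude,
        "noise_sigma": noise_sigma,
        "peak": peak,
    }
    return stack, truth


def gen_reference_stack(
    np_diameter: int = 200,
    dz: float = 0.35,
    dxy: float = 0.05,
    psf_sigma: float = 1.0,
    psf_sigma_z_um: float = 0.27,
    amplitude: float = 1000.0,
    snr: float = np.inf,
    seed: int = 0,
) -> ZStack:
    """Stack of one isolated bead at a random sub-voxel alignment.

    Used for threshold calibration; the seed controls the alignment and
    the noise realization (``snr=inf`` for a clean reference).
    """
    rng = np.random.default_rng(seed)
    radius_um = (np_diameter / 1000.0) / 2.0
    ext = max(4 * radius_um, 1.0)
    nxy = int(np.ceil(2 * ext / dxy))
    nz = max(int(np.ceil(2 * ext / dz)), 7)
    off = rng.uniform(0, 1, size=3)  # sub-voxel alignment (x, y, z)
    center = np.array(
        [[(nxy // 2 + off[0]) * dxy, (nxy // 2 + off[1]) * dxy, (nz // 2 + off[2]) * dz]]
    )
    clean = _render_particles((nz, nxy, nxy), center, radius_um, dz, dxy, amplitude)
    clean = gaussian_filter(clean, sigma=(psf_sigma_z_um / dz, psf_sigma, psf_sigma))
    if np.isinf(snr):
        return ZStack(voxels=clean, dz=dz, dxy=dxy, np_diameter=np_diameter)
    noise_sigma = float(clean.max()) / snr
    noisy = clean + rng.normal(0.0, noise_sigma, size=clean.shape)
    return ZStack(voxels=noisy, dz=dz, dxy=dxy, np_diameter=np_diameter)


def gen_reference_ensemble(
    n_refs: int = 60,
    np_diameter: int = 200,
    snr: float = 10.0,
    seed: int = 0,
    **kwargs,
) -> list[ZStack]:
    """Ensemble of isolated-bead stacks over random alignments and noise.

    The noise sigma is tied to the brightest alignment (as in
    :func:`gen_zstack`, where the stack peak sets the scale).
    """
    rng = np.random.default_rng(seed)
    seeds = [int(rng.integers(0, 2**31 - 1)) for _ in range(n_refs)]
    clean = [
        gen_reference_stack(np_diameter=np_diameter, snr=np.inf, seed=s, **kwargs)
        for s in seeds
    ]
    if np.isinf(snr):
        return clean
    peak = max(float(c.voxels.max()) for c in clean)
    noise_sigma = peak / snr
    out = []
    for s, c in zip(seeds, clean):
        sub = np.random.default_rng(s + 1)
        out.append(
            ZStack(
                voxels=c.voxels + sub.normal(0.0, noise_sigma, size=c.voxels.shape),
                dz=c.dz, dxy=c.dxy, np_diameter=c.np_diameter,
            )
        )
    return out


def gen_trajectories(
    n: int = 100,
    frac_directed: float = 0.4,
    D: float = 0.05,
    v: float = 0.5,
    dt: float = 0.5,
    n_frames: int = 40,
    D_directed: float | None = None,
    seed: int = 0,
) -> tuple[list[Trajectory], list[str]]:
    """Mixture of Brownian and directed 2-D tracks with ground-truth labels.

    Brownian steps are Normal(0, 2·D·dt) per axis; directed tracks add a
    constant drift of speed ``v`` along a random fixed direction on top
    of Brownian motion with ``D_directed`` (defaults to D).  Labels are
    ``"diffusive"`` / ``"transported"``.
    """
    if not 0 <= frac_directed <= 1:
        raise ValueError("frac_directed must be in [0, 1]")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_frames < 10:
        raise ValueError("n_frames must be at least 10")
    if D_directed is None:
        D_directed = D
    rng = np.random.default_rng(seed)
    n_directed = int(round(n * frac_directed))
    t = np.arange(n_frames) * dt
    trajectories, labels = [], []
    for k in range(n):
        directed = k < n_directed
        d_k = D_directed if directed else D
        steps = rng.normal(0.0, np.sqrt(2 * d_k * dt), size=(n_frames - 1, 2))
        if directed:
            ang = rng.uniform(0, 2 * np.pi)
            steps += v * dt * np.array([np.cos(ang), np.sin(ang)])
        xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        trajectories.append(Trajectory(t=t, xy=xy))
        labels.append("transported" if directed else "diffusive")
    # shuffle so labels are not positional
    order = rng.permutation(n)
    return [trajectories[i] for i in order], [labels[i] for i in order]


def gen_ring_image(
    r_major: float = 8.0,
    r_minor: float = 6.6,
    intensity: float = 100.0,
    dxy: float = 0.1,
    image_margin_um: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Grayscale annulus of given radii (μm) and per-pixel intensity.

    Returns the image and the ground truth (radii, total intensity, and
    the thickness (r_major − r_minor)/2 that cortex morphometry should
    recover).
    """
    if r_major <= r_minor:
        raise ValueError("r_major must exceed r_minor")
    size = int(np.ceil(2 * (r_major + image_margin_um) / dxy))
    c = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(xx - c, yy - c) * dxy
    ring = (r >= r_minor) & (r <= r_major)
    img = np.zeros((size, size))
    img[ring] = intensity
    truth = {
        "r_major": r_major,
        "r_minor": r_minor,
        "total_intensity": float(img.sum()),
        "thickness": (r_major - r_minor) / 2.0,
    }
    return img, truth
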