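"""Ground-truthed synthetic data: microscopy stacks, interval and plating fixtures.

The stack generator emulates wide-field z-stack acquisition of a fission-yeast
nucleus carrying a single fluorescently tagged chromatin locus: a membrane
channel showing the nuclear envelope as a thin bright shell, and a locus
channel with one diffraction-limited spot. Geometry defaults follow the
acquisition this package targets (40 z-sections at 0.26 µm spacing); the xy
pixel size defaults to typical 100x/EMCCD sampling and is configurable.

Noise is Poisson shot noise on the expected photon count followed by additive
Gaussian read noise; both are independently switchable so that noiseless
stacks can serve as exact oracles in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, optimize

from .io_formats import GenomicInterval, ImageStack

__all__ = [
    "SyntheticScene",
    "GroundTruth",
    "render_nucleus_stack",
    "sample_locus_positions",
    "make_interval_fixture",
    "make_colony_fixture",
    "nearest_distance_to_ellipsoid",
]


@dataclass
class SyntheticScene:
    """Full description of one synthetic two-channel nucleus stack.

    All lengths in micrometres, all amplitudes in photons. ``grid_shape`` is
    ``(nx, ny, nz)`` and ``voxel_size`` is ``(dx, dy, dz)``; internally stacks
    are stored (z, y, x). ``spot_scaled_depth`` is the dimensionless depth
    s in [0, 1]: 0 on the envelope, 1 at the center.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 40)
    voxel_size: tuple[float, float, float] = (0.1065, 0.1065, 0.26)
    nucleus_center: tuple[float, float, float] | None = None
    nucleus_radii: tuple[float, float, float] = (1.3, 1.3, 1.3)
    shell_thickness: float = 0.1
    membrane_amplitude: float = 150.0
    spot_scaled_depth: float = 0.3
    spot_direction: tuple[float, float, float] | str = "random"
    spot_amplitude: float = 200.0
    psf_sigma_xy: float = 0.13
    psf_sigma_z: float = 0.30
    background: float = 10.0
    read_noise_sd: float = 2.0
    poisson_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleus_center is None:
            self.nucleus_center = tuple(
                n * d / 2 for n, d in zip(self.grid_shape, self.voxel_size)
            )
        if any(r <= 0 for r in self.nucleus_radii):
            raise ValueError("nucleus radii must be positive")
        if not (0.0 <= self.spot_scaled_depth <= 1.0):
            raise ValueError("spot_scaled_depth must lie in [0, 1]")
        if self.spot_amplitude < 0 or self.membrane_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.background < 0 or self.read_noise_sd < 0:
            raise ValueError("background and read noise must be non-negative")
        self._check_margin()

    def _check_margin(self) -> None:
        # nucleus (plus 3 sigma of PSF blur) must sit fully inside the grid
        margins = (
            3 * self.psf_sigma_xy,
            3 * self.psf_sigma_xy,
            3 * self.psf_sigma_z,
        )
        for axis, (n, d, c, r, m) in enumerate(
            zip(self.grid_shape, self.voxel_size, self.nucleus_center,
                self.nucleus_radii, margins)
        ):
            extent = n * d
            if c - r - m < 0 or c + r + m > extent:
                raise ValueError(
                    f"nucleus clipped by grid along axis {axis}: "
                    f"center {c:.3f}, radius {r:.3f}, margin {m:.3f}, extent {extent:.3f}"
                )


@dataclass(frozen=True)
class GroundTruth:
    """Exact generating parameters recorded alongside a rendered stack."""

    spot_position: tuple[float, float, float]  # µm, (x, y, z)
    true_volume: float  # µm³
    true_effective_radius: float  # µm
    true_scaled_depth: float  # nearest-surface distance / effective radius


def _unit_direction(direction, rng: np.random.Generator) -> np.ndarray:
    if isinstance(direction, str):
        if direction != "random":
            raise ValueError(f"unknown spot_direction {direction!r}")
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)
    v = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("spot_direction must be a non-zero vector")
    return v / norm


def nearest_distance_to_ellipsoid(
    point: np.ndarray, radii: np.ndarray, center: np.ndarray | None = None
) -> float:
    """Exact distance from a point to the surface of an axis-aligned ellipsoid.

    Solves the classic Lagrange condition Σ rᵢ² pᵢ² / (rᵢ² + t)² = 1 for the
    unique root t > -min(rᵢ²) by bracketed root finding; for a sphere this
    reduces to \\|p - c\\| - R up to solver tolerance.
    """
    p = np.asarray(point, dtype=float)
    r = np.asarray(radii, dtype=float)
    if center is not None:
        p = p - np.asarray(center, dtype=float)
    if np.allclose(r, r[0]):
        return abs(float(np.linalg.norm(p)) - float(r[0]))
    if np.allclose(p, 0):
        return float(np.min(r))

    def g(t: float) -> float:
        return float(np.sum(r**2 * p**2 / (r**2 + t) ** 2) - 1.0)

    lo = -float(np.min(r) ** 2) + 1e-12
    hi = float(np.linalg.norm(r * p) + np.max(r) ** 2)
    while g(hi) > 0:
        hi *= 2
    t = optimize.brentq(g, lo, hi, xtol=1e-14, rtol=1e-14)
    q = r**2 * p / (r**2 + t)
    return float(np.linalg.norm(q - p))


def _voxel_center_grids(scene: SyntheticScene):
    nx, ny, nz = scene.grid_shape
    dx, dy, dz = scene.voxel_size
    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dy
    z = (np.arange(nz) + 0.5) * dz
    # broadcastable (z, y, x) grids
    return (
        z[:, None, None],
        y[None, :, None],
        x[None, None, :],
    )


def render_nucleus_stack(scene: SyntheticScene) -> tuple[ImageStack, GroundTruth]:
    """Render a two-channel stack (membrane shell + locus spot) with noise.

    The membrane channel is the indicator of a thin shell around the ellipsoid
    surface, convolved with the anisotropic Gaussian PSF and scaled so its
    brightest voxel equals ``membrane_amplitude`` above background. The locus
    channel is a single 3D Gaussian of the PSF widths centered at the exact
    continuous spot position. Per-voxel Poisson noise is applied to the
    expected photon count, then Gaussian read noise is added.
    """
    rng = np.random.default_rng(scene.seed)
    dx, dy, dz = scene.voxel_size
    a, b, c = scene.nucleus_radii
    cx, cy, cz = scene.nucleus_center
    zg, yg, xg = _voxel_center_grids(scene)

    # approximate signed distance to the ellipsoid surface via first-order
    # normalization of the level-set function rho; exact for a sphere
    ux, uy, uz = (xg - cx) / a, (yg - cy) / b, (zg - cz) / c
    rho = np.sqrt(ux**2 + uy**2 + uz**2)
    grad = np.sqrt((ux / a) ** 2 + (uy / b) ** 2 + (uz / c) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = np.where(grad > 0, (rho - 1.0) * rho / grad, -np.min([a, b, c]))
    shell = (np.abs(dist) < scene.shell_thickness / 2).astype(float)
    sigma_vox = (scene.psf_sigma_z / dz, scene.psf_sigma_xy / dy, scene.psf_sigma_xy / dx)
    blurred = ndimage.gaussian_filter(shell, sigma=sigma_vox, mode="constant")
    peak = blurred.max()
    membrane = scene.background + (
        scene.membrane_amplitude * blurred / peak if peak > 0 else 0.0
    )

    # spot: placed along a direction at scaled depth s from the surface
    direction = _unit_direction(scene.spot_direction, rng)
    r_dir = 1.0 / math.sqrt(
        (direction[0] / a) ** 2 + (direction[1] / b) ** 2 + (direction[2] / c) ** 2
    )
    pos = np.array([cx, cy, cz]) + direction * r_dir * (1.0 - scene.spot_scaled_depth)
    sx = sy = scene.psf_sigma_xy
    sz = scene.psf_sigma_z
    locus = scene.background + scene.spot_amplitude * np.exp(
        -((xg - pos[0]) ** 2 + (yg - pos[1]) ** 2) / (2 * sx**2)
        - (zg - pos[2]) ** 2 / (2 * sz**2)
    )

    expected = np.stack([membrane, locus])
    data = rng.poisson(expected).astype(float) if scene.poisson_noise else expected.copy()
    if scene.read_noise_sd > 0:
        data = data + rng.normal(0.0, scene.read_noise_sd, size=data.shape)
    data = np.clip(data, 0.0, None)

    volume = 4.0 / 3.0 * math.pi * a * b * c
    r_eff = (a * b * c) ** (1.0 / 3.0)
    d_surface = nearest_distance_to_ellipsoid(
        pos, np.array([a, b, c]), np.array([cx, cy, cz])
    )
    truth = GroundTruth(
        spot_position=tuple(float(v) for v in pos),
        true_volume=volume,
        true_effective_radius=r_eff,
        true_scaled_depth=d_surface / r_eff,
    )
    stack = ImageStack(
        data=data, voxel_size=scene.voxel_size, channel_names=("membrane", "locus")
    )
    return stack, truth


def sample_locus_positions(
    n: int,
    mode: str = "uniform_volume",
    depth_scale: float = 0.1,
    seed: int | None = None,
) -> np.ndarray:
    """Draw n scaled locus positions in the unit ball.

    ``uniform_volume`` is uniform in the ball (radius = U^{1/3}, uniform
    direction). ``periphery_biased`` draws scaled depth s from an exponential
    with the given scale truncated to [0, 1] and a uniform direction — a pure
    test harness for periphery-enriched cohorts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    if mode == "uniform_volume":
        radius = rng.uniform(size=n) ** (1.0 / 3.0)
    elif mode == "periphery_biased":
        if depth_scale <= 0:
            raise ValueError("depth_scale must be positive")
        # inverse-CDF sample of Exp(depth_scale) truncated to [0, 1]
        u = rng.uniform(size=n)
        cdf1 = 1.0 - math.exp(-1.0 / depth_scale)
        s = -depth_scale * np.log1p(-u * cdf1)
        radius = 1.0 - s
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return v * radius[:, None]


def make_interval_fixture(
    n_features: int,
    n_peaks: int,
    chrom_lengths: dict[str, int],
    planted_fraction: float,
    threshold_bp: int = 600,
    feature_length: int = 1000,
    peak_length: int = 200,
    seed: int | None = None,
) -> tuple[list[GenomicInterval], list[GenomicInterval], dict[str, bool]]:
    """Build a feature/peak fixture with a known fraction of near features.

    Exactly ``round(planted_fraction * n_features)`` features get a peak
    planted within ``threshold_bp``; every other feature is kept at least
    ``2 * threshold_bp`` away from *all* peaks, so the truth labels are
    unambiguous. Returns (features, peaks, truth) where truth maps feature
    name -> is-near flag.
    """
    if not (0.0 <= planted_fraction <= 1.0):
        raise ValueError("planted_fraction must lie in [0, 1]")
    if any(L <= 0 for L in chrom_lengths.values()):
        raise ValueError("chromosome lengths must be positive")
    rng = np.random.default_rng(seed)
    n_near = round(planted_fraction * n_features)
    # slot layout: features placed on a regular raster with enough spacing
    # that a peak planted next to one feature can never be near another
    slot = feature_length + peak_length + 6 * threshold_bp
    chroms = list(chrom_lengths)
    # every slot is wide enough that its occupant (feature + planted peak, or
    # a decoy peak) stays >= 2 * threshold from occupants of neighboring slots
    slots = [
        (ch, k * slot + 2 * threshold_bp)
        for ch in chroms
        for k in range(chrom_lengths[ch] // slot)
    ]
    n_extra = max(0, n_peaks - n_near)
    if len(slots) < n_features + n_extra:
        raise ValueError(
            "chromosomes too short to honor separation constraints; "
            f"need {n_features + n_extra} slots of {slot} bp, have {len(slots)}"
        )
    features: list[GenomicInterval] = []
    peaks: list[GenomicInterval] = []
    truth: dict[str, bool] = {}
    near_flags = np.zeros(n_features, dtype=bool)
    near_flags[:n_near] = True
    rng.shuffle(near_flags)
    for i in range(n_features):
        ch, start = slots[i]
        name = f"feat{i:04d}"
        features.append(
            GenomicInterval(chrom=ch, start=start, end=start + feature_length, name=name)
        )
        if near_flags[i]:
            gap = int(rng.integers(0, threshold_bp + 1))
            p_start = start + feature_length + gap
            peaks.append(
                GenomicInterval(ch, p_start, p_start + peak_length, name=f"peak_{name}")
            )
        truth[name] = bool(near_flags[i])
    # remaining peaks become decoys in unused slots, far from every feature
    for j in range(n_extra):
        ch, start = slots[n_features + j]
        peaks.append(GenomicInterval(ch, start, start + peak_length, name=f"decoy{j:03d}"))
    return features, peaks, truth


def make_colony_fixture(
    true_rate: float,
    cells_plated_selective: float = 1e6,
    cells_plated_permissive: float = 10.0,
    dilution_selective: float = 1e-2,
    dilution_permissive: float = 1e-7,
    n_cultures: int = 12,
    genotype: str = "WT",
    seed: int | None = None,
    start_index: int = 0,
):
    """Simulate a fluctuation-assay plating table.

    Selective-plate colony counts are Poisson with mean
    ``true_rate * cells_plated_selective``; permissive counts are Poisson with
    mean ``cells_plated_permissive`` (each plated cell forms a colony).
    Dilutions are recorded so the rate estimator can rescale to the undiluted
    culture.
    """
    if true_rate < 0:
        raise ValueError("true_rate must be non-negative")
    if cells_plated_selective <= 0 or cells_plated_permissive <= 0:
        raise ValueError("cells plated must be positive")
    if n_cultures < 1:
        raise ValueError("n_cultures must be >= 1")
    import pandas as pd

    rng = np.random.default_rng(seed)
    sel = rng.poisson(true_rate * cells_plated_selective, size=n_cultures)
    perm = rng.poisson(cells_plated_permissive, size=n_cultures)
    return pd.DataFrame(
        {
            "sample_id": [f"{genotype}_{start_index + i:03d}" for i in range(n_cultures)],
            "genotype": genotype,
            "colonies_selective": sel,
            "colonies_permissive": perm,
            "dilution_selective": dilution_selective,
            "dilution_permissive": dilution_permissive,
        }
    )
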