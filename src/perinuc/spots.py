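"""Sub-voxel 3D localization of tagged chromatin loci.

The pipeline: maximum-intensity projection over z, candidate detection as
thresholded local maxima in the projection (radius 1.5 px), then least-squares
fitting of an axis-aligned anisotropic 3D Gaussian (sigma_x = sigma_y != sigma_z,
matching microscope PSF anisotropy) inside a window of the full z-stack.
Positions are reported in physical micrometres.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .io_formats import ImageStack

logger = logging.getLogger(__name__)

__all__ = ["SpotFit", "SpotConfig", "max_project", "detect_candidates",
           "fit_gaussian_3d", "localize"]


@dataclass
class SpotConfig:
    """Tunables for detection and fitting.

    The detection threshold is robust: background = median of the projection,
    spread = 1.4826 * MAD, threshold = background + ``threshold_nsigma`` * spread.
    PSF priors initialize the Gaussian widths; fitted widths are bounded to
    [0.5, 4] times the priors.
    """

    locus_channel: str = "locus"
    threshold_nsigma: float = 5.0
    min_separation_px: float = 1.5
    window_voxels: tuple[int, int, int] = (7, 7, 9)  # (x, y, z)
    psf_sigma_xy: float = 0.13  # µm prior
    psf_sigma_z: float = 0.30  # µm prior
    max_iterations: int = 500
    ftol: float = 1e-10


@dataclass
class SpotFit:
    """One fitted locus: sub-voxel center plus fit diagnostics."""

    center: tuple[float, float, float]  # µm (x, y, z)
    sigma_xy: float
    sigma_z: float
    amplitude: float
    offset: float
    residual_ss: float
    converged: bool
    window: tuple[slice, slice, slice] | None = None  # (z, y, x) voxel box


def max_project(stack: ImageStack, channel: str | int = "locus") -> np.ndarray:
    """Maximum-intensity projection of one channel over z -> (y, x) image."""
    return stack.channel(channel).max(axis=0)


def _robust_threshold(image: np.ndarray, nsigma: float) -> float:
    med = float(np.median(image))
    mad = float(np.median(np.abs(image - med)))
    return med + nsigma * 1.4826 * mad


def detect_candidates(
    image2d: np.ndarray,
    threshold: float | None = None,
    min_separation_px: float = 1.5,
    threshold_nsigma: float = 5.0,
) -> list[tuple[int, int]]:
    """Find above-threshold local maxima, suppressed within a pixel radius.

    A pixel is a candidate when it is strictly above the threshold and equals
    the maximum of its neighborhood of the given radius. When two candidates
    fall within the radius of each other only the brighter survives; exact
    ties are broken toward the lowest row-major index. Returns (row, col)
    pixel coordinates; a flat or sub-threshold image yields an empty list.
    """
    img = np.asarray(image2d, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    if threshold is None:
        threshold = _robust_threshold(img, threshold_nsigma)
    r = float(min_separation_px)
    ri = int(math.floor(r))
    oy, ox = np.ogrid[-ri : ri + 1, -ri : ri + 1]
    footprint = (oy**2 + ox**2) <= r**2
    from scipy.ndimage import maximum_filter

    local_max = img >= maximum_filter(img, footprint=footprint, mode="nearest")
    ys, xs = np.nonzero(local_max & (img > threshold))
    if ys.size == 0:
        return []
    # greedy non-maximum suppression: brightest first, row-major index on ties
    flat = ys * img.shape[1] + xs
    order = np.lexsort((flat, -img[ys, xs]))
    kept: list[tuple[int, int]] = []
    for idx in order:
        y, x = int(ys[idx]), int(xs[idx])
        if all((y - ky) ** 2 + (x - kx) ** 2 > r**2 for ky, kx in kept):
            kept.append((y, x))
    kept.sort(key=lambda p: p[0] * img.shape[1] + p[1])
    return kept


def _gaussian_model(params, xg, yg, zg):
    x0, y0, z0, sxy, sz, amp, off = params
    return off + amp * np.exp(
        -((xg - x0) ** 2 + (yg - y0) ** 2) / (2 * sxy**2) - (zg - z0) ** 2 / (2 * sz**2)
    )


def fit_gaussian_3d(
    stack: ImageStack,
    candidate_px: tuple[int, int],
    config: SpotConfig | None = None,
) -> SpotFit:
    """Least-squares fit of a 3D Gaussian in a window around a 2D candidate.

    The window (config.window_voxels, in x/y/z) is centered laterally on the
    candidate pixel and axially on the brightest z-slice through it; a window
    clipped by the stack boundary is an error. Initialization: center at the
    intensity-weighted centroid of the window, offset at the window minimum,
    amplitude at max - min, widths at the configured PSF priors. Bounds keep
    the center inside the window and the widths within [0.5, 4] x priors.
    """
    config = config or SpotConfig()
    vol = stack.channel(config.locus_channel)
    dx, dy, dz = stack.voxel_size
    row, col = candidate_px
    wx, wy, wz = config.window_voxels
    hz, hy, hx = wz // 2, wy // 2, wx // 2
    z_peak = int(np.argmax(vol[:, row, col]))
    z0i, y0i, x0i = z_peak, row, col
    nz, ny, nx = vol.shape
    if (
        z0i - hz < 0 or z0i + hz >= nz
        or y0i - hy < 0 or y0i + hy >= ny
        or x0i - hx < 0 or x0i + hx >= nx
    ):
        raise ValueError(
            f"fit window out of bounds at candidate (z={z0i}, y={y0i}, x={x0i})"
        )
    window = (
        slice(z0i - hz, z0i + hz + 1),
        slice(y0i - hy, y0i + hy + 1),
        slice(x0i - hx, x0i + hx + 1),
    )
    sub = vol[window]
    # physical coordinates of voxel centers in the window
    zc = (np.arange(window[0].start, window[0].stop) + 0.5) * dz
    yc = (np.arange(window[1].start, window[1].stop) + 0.5) * dy
    xc = (np.arange(window[2].start, window[2].stop) + 0.5) * dx
    zg, yg, xg = np.meshgrid(zc, yc, xc, indexing="ij")

    offset0 = float(sub.min())
    amp0 = float(sub.max() - offset0)
    weights = np.clip(sub - offset0, 0, None)
    wsum = weights.sum()
    if wsum <= 0 or amp0 <= 0:
        return SpotFit(
            center=(float(xg.mean()), float(yg.mean()), float(zg.mean())),
            sigma_xy=config.psf_sigma_xy, sigma_z=config.psf_sigma_z,
            amplitude=0.0, offset=offset0, residual_ss=float(np.sum((sub - sub.mean()) ** 2)),
            converged=False, window=window,
        )
    x_init = float((weights * xg).sum() / wsum)
    y_init = float((weights * yg).sum() / wsum)
    z_init = float((weights * zg).sum() / wsum)
    p0 = np.array([x_init, y_init, z_init,
                   config.psf_sigma_xy, config.psf_sigma_z, amp0, offset0])
    lb = np.array([xc[0], yc[0], zc[0],
                   0.5 * config.psf_sigma_xy, 0.5 * config.psf_sigma_z, 0.0, -np.inf])
    ub = np.array([xc[-1], yc[-1], zc[-1],
                   4.0 * config.psf_sigma_xy, 4.0 * config.psf_sigma_z, np.inf, np.inf])
    p0 = np.clip(p0, lb, ub)
    data = sub.ravel()

    def residuals(params):
        return _gaussian_model(params, xg, yg, zg).ravel() - data

    result = optimize.least_squares(
        residuals, p0, bounds=(lb, ub), method="trf",
        ftol=config.ftol, xtol=1e-12, gtol=None,
        max_nfev=config.max_iterations,
    )
    x0, y0, z0, sxy, sz, amp, off = result.x
    converged = bool(result.success) and amp > 0
    return SpotFit(
        center=(float(x0), float(y0), float(z0)),
        sigma_xy=float(sxy), sigma_z=float(sz),
        amplitude=float(amp), offset=float(off),
        residual_ss=float(2 * result.cost), converged=converged, window=window,
    )


def localize(stack: ImageStack, config: SpotConfig | None = None) -> list[SpotFit]:
    """Full localization: project, detect, fit; drop failed fits with a reason.

    Returns one converged SpotFit per retained candidate, positions in µm.
    A blank stack yields an empty list (with a logged warning), not an error.
    """
    config = config or SpotConfig()
    proj = max_project(stack, config.locus_channel)
    candidates = detect_candidates(
        proj, min_separation_px=config.min_separation_px,
        threshold_nsigma=config.threshold_nsigma,
    )
    if not candidates:
        logger.warning("no candidate loci detected")
        return []
    fits: list[SpotFit] = []
    for cand in candidates:
        try:
            fit = fit_gaussian_3d(stack, cand, config)
        except ValueError as exc:
            logger.warning("dropping candidate %s: %s", cand, exc)
            continue
        if not fit.converged:
            logger.warning("dropping candidate %s: fit did not converge", cand)
            continue
        fits.append(fit)
    return fits
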