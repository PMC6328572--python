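"""Multiscale Hessian tube-enhancement (Frangi vesselness).

Second derivatives are taken against physical mm coordinates (Gaussian
derivative filters with per-axis sigma ``sigma_mm / spacing``), so the
filter honors anisotropic voxel spacing. Responses are gamma-normalized
(gamma = 1: Hessian scaled by sigma^2) and the per-voxel output is the
maximum over scales, together with the best-responding scale.

For a bright tube on a dark background the two large-magnitude eigenvalues
of the Hessian are strongly negative and the smallest is near zero; the
Frangi response combines three ratios gating plate-like (alpha), blob-like
(beta) and low-structure (c) patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import Grid, Volume


@dataclass
class VesselnessParams:
    scales: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5)  # mm
    alpha: float = 0.5
    beta: float = 0.5
    c: float | None = None          # None -> half max Frobenius norm per scale
    bright_on_dark: bool = True

    def __post_init__(self):
        if len(self.scales) == 0 or any(s <= 0 for s in self.scales):
            raise ValueError("scales must be non-empty and positive")
        if self.alpha <= 0 or self.beta <= 0 or (self.c is not None and self.c <= 0):
            raise ValueError("alpha, beta, c must be > 0")


@dataclass
class VesselnessImage:
    data: np.ndarray                 # values in [0, 1]
    grid: Grid
    scale_of_max: np.ndarray | None = None   # mm, best-responding sigma
    valid: np.ndarray | None = None  # False within one sigma_max of the border


def _hessian_mm(data: np.ndarray, spacing, sigma_mm: float) -> np.ndarray:
    """gamma-normalized Hessian (d2/dx_a dx_b in mm^-2 units) as (..., 3, 3)."""
    spacing = np.asarray(spacing, float)
    sigma_vox = sigma_mm / spacing
    H = np.empty(data.shape + (3, 3))
    orders = {(a, b): tuple(int(a == ax) + int(b == ax) for ax in range(3))
              for a in range(3) for b in range(3) if a <= b}
    for (a, b), order in orders.items():
        # truncate=8: the truncated derivative kernels otherwise leave a
        # ~1e-5 relative residual on constant regions
        d = gaussian_filter(data.astype(float), sigma=sigma_vox, order=order,
                            mode="reflect", truncate=8.0)
        d /= spacing[a] * spacing[b]
        H[..., a, b] = d
        if a != b:
            H[..., b, a] = d
    H *= sigma_mm ** 2  # gamma = 1 normalization
    return H


def _sorted_eigvals(H: np.ndarray) -> np.ndarray:
    """Eigenvalues sorted by increasing absolute value, shape (..., 3)."""
    lam = np.linalg.eigvalsh(H)
    order = np.argsort(np.abs(lam), axis=-1)
    return np.take_along_axis(lam, order, axis=-1)


def hessian_eigenvalues_at(volume: Volume, point, sigma: float) -> np.ndarray:
    """Eigenvalues (|l1|<=|l2|<=|l3|) of the gamma-normalized Hessian at one
    lattice index. Public so single-point eigen-analysis can serve as an
    independent check on the full filter.
    """
    point = tuple(int(round(p)) for p in point)
    spacing = np.asarray(volume.grid.spacing)
    halo = np.ceil(4 * sigma / spacing).astype(int) + 2
    lo = [max(p - h, 0) for p, h in zip(point, halo)]
    hi = [min(p + h + 1, n) for p, h, n in zip(point, halo, volume.grid.shape)]
    if any(point[a] < 0 or point[a] >= volume.grid.shape[a] for a in range(3)):
        raise ValueError(f"point {point} outside lattice {volume.grid.shape}")
    sub = volume.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    H = _hessian_mm(sub, spacing, sigma)
    center = tuple(point[a] - lo[a] for a in range(3))
    return _sorted_eigvals(H[center])


def frangi_vesselness(volume: Volume, params: VesselnessParams | None = None) -> VesselnessImage:
    """Frangi vesselness, maximum over scales, values in [0, 1]."""
    params = params or VesselnessParams()
    spacing = np.asarray(volume.grid.spacing)
    if min(params.scales) < 0:  # scales validated in params
        raise ValueError
    if any(n < 2 for n in volume.grid.shape):
        raise ValueError("volume too small for Hessian analysis")

    best = np.zeros(volume.grid.shape)
    best_scale = np.zeros(volume.grid.shape)
    for sigma in params.scales:
        H = _hessian_mm(volume.data, spacing, sigma)
        lam = _sorted_eigvals(H)
        l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
        if not params.bright_on_dark:
            l1, l2, l3 = -l1, -l2, -l3
        a2, a3 = np.abs(l2), np.abs(l3)
        with np.errstate(divide="ignore", invalid="ignore"):
            ra = np.where(a3 > 0, a2 / a3, 0.0)
            rb = np.where(a2 * a3 > 0, np.abs(l1) / np.sqrt(a2 * a3), 0.0)
        s2 = lam[..., 0] ** 2 + lam[..., 1] ** 2 + lam[..., 2] ** 2
        # floor against pure floating-point noise (constant or near-constant data)
        noise_floor = 1e-4 * max(1.0, float(np.abs(volume.data).max()))
        s_max = float(np.sqrt(s2.max()))
        c = params.c if params.c is not None else 0.5 * s_max
        if c <= 0 or s_max <= noise_floor:
            resp = np.zeros_like(s2)
        else:
            resp = ((1.0 - np.exp(-(ra ** 2) / (2 * params.alpha ** 2)))
                    * np.exp(-(rb ** 2) / (2 * params.beta ** 2))
                    * (1.0 - np.exp(-s2 / (2 * c ** 2))))
        resp[(l2 > 0) | (l3 > 0)] = 0.0  # wrong polarity
        take = resp > best
        best[take] = resp[take]
        best_scale[take] = sigma

    sig_max = max(params.scales)
    valid = np.ones(volume.grid.shape, bool)
    for ax in range(3):
        b = int(np.ceil(sig_max / spacing[ax]))
        if b > 0:
            sl = [slice(None)] * 3
            sl[ax] = slice(0, b)
            valid[tuple(sl)] = False
            sl[ax] = slice(volume.grid.shape[ax] - b, None)
            valid[tuple(sl)] = False

    return VesselnessImage(data=np.clip(best, 0.0, 1.0), grid=volume.grid,
                           scale_of_max=best_scale, valid=valid)
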