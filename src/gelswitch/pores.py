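"""Maximal-inscribed-circle ("bubble") pore analysis of fibril networks.

A pore is the largest circle fitting in the space between segmented fibrils;
its radius is the pore size.  The decomposition is greedy: repeatedly take
the circle at the global maximum of the Euclidean distance transform of the
unclaimed pore space (fibrils and previously accepted circles are
obstacles), until the maximum radius falls below ``r_min``.  Ties are broken
by the smallest (row, column) center.

Circle semantics (shared by the greedy route and the exhaustive reference
implementation): the radius at a center pixel is the exact Euclidean
distance to the nearest obstacle pixel center, and an accepted circle claims
the pixels strictly inside that radius.
"""
from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist
from scipy.stats import gaussian_kde
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .datatypes import AlignedSeries, Pore, PoreSizeDistribution
from .errors import InvalidParameterError

__all__ = [
    "segment_fibrils",
    "find_pores",
    "find_pores_reference",
    "pore_distribution",
    "pores_vs_temperature",
    "distribution_summary",
]


def segment_fibrils(
    image: np.ndarray,
    method: str = "otsu",
    fixed_level: Optional[float] = None,
    fibrils_bright: bool = True,
    min_speck: int = 4,
) -> np.ndarray:
    """Binary fibril mask (foreground True = fibrils, background = pore space).

    Specks smaller than ``min_speck`` pixels are removed.  A degenerate
    (single-intensity) image yields an all-background mask with a warning
    rather than an error.
    """
    img = np.asarray(image, dtype=float)
    if method == "fixed":
        if fixed_level is None:
            raise InvalidParameterError("fixed method requires fixed_level")
        level = float(fixed_level)
    elif method == "otsu":
        if np.ptp(img) == 0:
            warnings.warn("degenerate threshold: uniform image, returning empty mask")
            return np.zeros(img.shape, dtype=bool)
        level = float(threshold_otsu(img))
    else:
        raise InvalidParameterError(f"unknown segmentation method {method!r}")
    mask = img > level if fibrils_bright else img <= level
    if not mask.any():
        warnings.warn("segmentation found no foreground; returning empty mask")
        return mask
    if min_speck > 1:
        mask = remove_small_objects(mask, max_size=min_speck - 1)
    return mask


def _edge_distance(shape: tuple[int, int]) -> np.ndarray:
    """Per-pixel distance to the nearest border-row/column pixel of the frame."""
    h, w = shape
    rows = np.minimum(np.arange(h), np.arange(h)[::-1])[:, None]
    cols = np.minimum(np.arange(w), np.arange(w)[::-1])[None, :]
    return np.minimum(rows, cols).astype(float)


def _radius_map(free: np.ndarray, border_policy: str) -> np.ndarray:
    """Largest admissible circle radius centered at each free pixel.

    ``exclude_touching`` rejects circles that would cover a border pixel
    (truncated by the field of view); ``include`` caps the radius at the
    frame boundary instead.
    """
    obstacles = ~free
    d_edge = _edge_distance(free.shape)
    if obstacles.any():
        d_obs = ndi.distance_transform_edt(free)
    else:
        d_obs = np.full(free.shape, np.inf)
    if border_policy == "include":
        rmap = np.minimum(d_obs, d_edge + 1.0)
    elif border_policy == "exclude_touching":
        rmap = np.where(d_obs <= d_edge, d_obs, 0.0)
    else:
        raise InvalidParameterError(f"unknown border_policy {border_policy!r}")
    return np.where(free, rmap, 0.0)


def _claim(free: np.ndarray, cy: int, cx: int, r: float) -> None:
    """Mark pixels strictly inside the circle as claimed (in place)."""
    h, w = free.shape
    r_int = int(np.ceil(r))
    y0, y1 = max(0, cy - r_int), min(h, cy + r_int + 1)
    x0, x1 = max(0, cx - r_int), min(w, cx + r_int + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 < r ** 2
    free[y0:y1, x0:x1] &= ~inside
    free[cy, cx] = False  # the center itself is always claimed


def find_pores(
    mask: np.ndarray,
    pixel_size: float = 1.0,
    r_min: Optional[float] = None,
    border_policy: str = "exclude_touching",
    max_pores: int = 100000,
) -> list[Pore]:
    """Greedy maximal-inscribed-circle decomposition of the pore space.

    ``mask`` is the fibril foreground (True = fibril); ``r_min`` (um) is the
    stopping radius, default 2 pixels to suppress quantization pores.
    Returns pores in order of acceptance (radii non-increasing), with
    centers and radii in physical units.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise InvalidParameterError("empty mask")
    if pixel_size <= 0:
        raise InvalidParameterError("pixel_size must be positive")
    if r_min is None:
        r_min = 2.0 * pixel_size
    if r_min < pixel_size:
        raise InvalidParameterError("r_min must be at least one pixel")
    r_min_px = r_min / pixel_size
    free = ~mask
    pores: list[Pore] = []
    while len(pores) < max_pores:
        rmap = _radius_map(free, border_policy)
        r = rmap.max()
        if r < r_min_px:
            break
        cy, cx = np.unravel_index(int(np.argmax(rmap)), rmap.shape)
        pores.append(Pore(center_x=cx * pixel_size, center_y=cy * pixel_size,
                          radius=float(r) * pixel_size))
        _claim(free, int(cy), int(cx), float(r))
    return pores


def find_pores_reference(
    mask: np.ndarray,
    pixel_size: float = 1.0,
    r_min: Optional[float] = None,
    border_policy: str = "exclude_touching",
    max_pores: int = 100000,
) -> list[Pore]:
    """Exhaustive reference decomposition (no distance transform).

    For every free pixel the admissible radius is computed by brute-force
    scanning of all obstacle pixels; otherwise identical greedy loop and
    circle semantics as :func:`find_pores`.  Intended as an independent
    cross-check on small masks.
    """
    mask = np.asarray(mask, dtype=bool)
    if pixel_size <= 0:
        raise InvalidParameterError("pixel_size must be positive")
    if r_min is None:
        r_min = 2.0 * pixel_size
    if r_min < pixel_size:
        raise InvalidParameterError("r_min must be at least one pixel")
    r_min_px = r_min / pixel_size
    d_edge = _edge_distance(mask.shape)
    free = ~mask
    pores: list[Pore] = []
    while len(pores) < max_pores:
        free_pts = np.argwhere(free)
        if free_pts.size == 0:
            break
        obs_pts = np.argwhere(~free)
        if obs_pts.size:
            d_obs = cdist(free_pts.astype(float), obs_pts.astype(float)).min(axis=1)
        else:
            d_obs = np.full(len(free_pts), np.inf)
        de = d_edge[free_pts[:, 0], free_pts[:, 1]]
        if border_policy == "include":
            radii = np.minimum(d_obs, de + 1.0)
        elif border_policy == "exclude_touching":
            radii = np.where(d_obs <= de, d_obs, 0.0)
        else:
            raise InvalidParameterError(f"unknown border_policy {border_policy!r}")
        # Global max with smallest (row, col) tie-break: free_pts is in C order
        # and argmax returns the first maximum.
        i = int(np.argmax(radii))
        r = float(radii[i])
        if r < r_min_px:
            break
        cy, cx = int(free_pts[i, 0]), int(free_pts[i, 1])
        pores.append(Pore(center_x=cx * pixel_size, center_y=cy * pixel_size,
                          radius=r * pixel_size))
        _claim(free, cy, cx, r)
    return pores


def pore_distribution(
    pores: Sequence[Pore],
    grid: Optional[np.ndarray] = None,
    bandwidth: str | float = "auto",
    temperature: float = float("nan"),
) -> PoreSizeDistribution:
    """Gaussian kernel density of pore radii with modal size P_max.

    ``bandwidth='auto'`` uses Silverman's rule; a float gives the absolute
    bandwidth in um.  Fewer than 5 pores yields radii and histogram only
    (density absent, flagged).  The density is renormalized to integrate to
    one over the grid.
    """
    radii = np.array([p.radius for p in pores], dtype=float)
    if radii.size == 0:
        return PoreSizeDistribution(radii=radii, flagged=True, temperature=temperature)
    counts, edges = np.histogram(radii, bins="auto")
    if radii.size < 5:
        return PoreSizeDistribution(radii=radii, hist_counts=counts, hist_edges=edges,
                                    flagged=True, temperature=temperature)
    if grid is None:
        grid = np.linspace(0.0, 1.3 * radii.max(), 512)
    sd = radii.std(ddof=1)
    if sd == 0:
        # Degenerate: all radii equal; represent as a narrow peak at r0.
        r0 = radii[0]
        h = max(1e-3 * max(r0, 1.0), 1e-9)
        dens = np.exp(-0.5 * ((grid - r0) / h) ** 2)
    else:
        if bandwidth == "auto":
            kde = gaussian_kde(radii, bw_method="silverman")
        else:
            kde = gaussian_kde(radii, bw_method=float(bandwidth) / sd)
        h = float(kde.factor * sd)
        dens = kde(grid)
    integral = np.trapezoid(dens, grid)
    if integral <= 0:
        return PoreSizeDistribution(radii=radii, hist_counts=counts, hist_edges=edges,
                                    flagged=True, temperature=temperature)
    dens = dens / integral
    return PoreSizeDistribution(
        radii=radii,
        density_x=np.asarray(grid, dtype=float),
        density_y=dens,
        P_max=float(grid[int(np.argmax(dens))]),
        bandwidth=h,
        hist_counts=counts,
        hist_edges=edges,
        temperature=temperature,
    )


def pores_vs_temperature(
    series: AlignedSeries,
    pixel_size: Optional[float] = None,
    segmentation_method: str = "otsu",
    fixed_level: Optional[float] = None,
    r_min: Optional[float] = None,
    border_policy: str = "exclude_touching",
    grid: Optional[np.ndarray] = None,
    bandwidth: str | float = "auto",
) -> list[PoreSizeDistribution]:
    """Full segment -> find_pores -> pore_distribution chain per frame.

    Per-frame failures are flagged (empty, flagged distributions), not fatal.
    """
    px = pixel_size if pixel_size is not None else series.frames.pixel_size
    out: list[PoreSizeDistribution] = []
    for frame, temp in zip(series.frames.frames, series.frame_temps):
        try:
            mask = segment_fibrils(frame, method=segmentation_method, fixed_level=fixed_level)
            pores = find_pores(mask, pixel_size=px, r_min=r_min, border_policy=border_policy)
            out.append(pore_distribution(pores, grid=grid, bandwidth=bandwidth,
                                         temperature=float(temp)))
        except InvalidParameterError:
            out.append(PoreSizeDistribution(radii=np.empty(0), flagged=True,
                                            temperature=float(temp)))
    return out


def distribution_summary(dists: Sequence[PoreSizeDistribution]) -> pd.DataFrame:
    """Temperature-indexed table of pore counts, P_max and spread (IQR)."""
    rows = []
    for d in dists:
        rows.append({
            "temperature_C": d.temperature,
            "n_pores": d.n_pores,
            "P_max_um": d.P_max if d.P_max is not None else np.nan,
            "iqr_um": d.iqr,
            "flagged": d.flagged,
        })
    return pd.DataFrame(rows)
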