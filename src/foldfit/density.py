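"""Model-based density synthesis, interpolation and map-model correlation.

A model is turned into density by placing an isotropic Gaussian on every
atom.  The Gaussian width follows the nominal resolution ``d`` of the map:

    sigma = 0.425 * sqrt(2) / pi * d  ~=  0.191 * d

which makes the Fourier amplitude of the kernel fall to roughly 1/e around
spatial frequency ``1/d``.  The exact constant is a convention — any smooth
resolution-dependent kernel serves, since the procedure only ever compares
densities synthesised with the same kernel — and is held fixed here.
Amplitudes are proportional to the element electron count and each atom
integrates to that count, independent of resolution.

Map-model agreement is scored as a masked Pearson correlation (the CC_mask
convention): experimental versus model-computed density over the union of
spheres of ``mask_radius`` (default 2.5 Å) around the model's atoms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_core import ELECTRON_COUNTS, DensityMap, Model

__all__ = [
    "MaskedCC",
    "sigma_for_resolution",
    "synthesize_map",
    "interpolate_density",
    "atom_mask",
    "map_model_cc",
    "density_outlier_threshold",
]

SIGMA_PER_RESOLUTION = 0.425 * np.sqrt(2.0) / np.pi  # ~0.1913


@dataclass
class MaskedCC:
    """Pearson correlation inside an atom mask."""

    cc: float
    n_voxels: int
    mask_radius: float

    def __float__(self) -> float:
        return self.cc


def sigma_for_resolution(resolution: float) -> float:
    """Gaussian-atom standard deviation (Å) at a nominal resolution (Å)."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    return SIGMA_PER_RESOLUTION * resolution


def synthesize_map(model: Model, resolution: float,
                   template: DensityMap) -> DensityMap:
    """Gaussian-atom density for ``model`` on the geometry of ``template``.

    Atoms further than 10 Å outside the grid are clipped (with a warning);
    everything else contributes a Gaussian truncated at 4.5 sigma.
    """
    sigma = sigma_for_resolution(resolution)
    coords = model.atom_coords()
    weights = np.array([float(ELECTRON_COUNTS.get(el, 6))
                        for el in model.elements()])
    return _gaussian_density(coords, weights, sigma, template)


def _gaussian_density(coords: np.ndarray, weights: np.ndarray, sigma: float,
                      template: DensityMap) -> DensityMap:
    grid = np.zeros(template.shape, dtype=np.float64)
    shape = np.array(template.shape)
    voxel = template.voxel_size
    cutoff = 4.5 * sigma
    half = np.ceil(cutoff / voxel).astype(int)
    voxel_volume = float(np.prod(voxel))

    frac = template.to_fractional_index(coords)
    lower_ok = np.all(frac >= -10.0 / voxel, axis=1)
    upper_ok = np.all(frac <= shape - 1 + 10.0 / voxel, axis=1)
    keep = lower_ok & upper_ok
    if not np.all(keep):
        warnings.warn(f"{int(np.sum(~keep))} atoms lie more than 10 Å "
                      "outside the grid; contributions clipped")
    for center, w in zip(frac[keep], weights[keep]):
        nearest = np.round(center).astype(int)
        lo = np.maximum(nearest - half, 0)
        hi = np.minimum(nearest + half + 1, shape)
        if np.any(lo >= hi):
            continue
        # separable Gaussian on the local cube, normalised by the discrete
        # (untruncated) sum so each atom deposits exactly its weight on the
        # grid regardless of how coarsely the kernel is sampled
        parts = []
        norm = 1.0
        for ax in range(3):
            full = np.arange(nearest[ax] - half[ax],
                             nearest[ax] + half[ax] + 1)
            gauss = np.exp(-0.5 * (((full - center[ax]) * voxel[ax])
                                   / sigma) ** 2)
            norm *= float(gauss.sum())
            sel = (full >= lo[ax]) & (full < hi[ax])
            parts.append(gauss[sel])
        cube = (parts[0][:, None, None] * parts[1][None, :, None]
                * parts[2][None, None, :])
        grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += \
            w / (norm * voxel_volume) * cube
    return template.like(grid)


def interpolate_density(density_map: DensityMap, points: np.ndarray,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear interpolation of map values at Cartesian ``points``.

    Returns ``(values, inside)`` where ``inside`` flags points within the
    grid; outside points get the map minimum.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    frac = density_map.to_fractional_index(pts)
    shape = np.array(density_map.shape)
    inside = np.all((frac >= 0) & (frac <= shape - 1), axis=1)
    vals = ndimage.map_coordinates(density_map.grid.astype(np.float64),
                                   frac.T, order=1, mode="nearest")
    vals[~inside] = float(density_map.grid.min())
    return vals, inside


def atom_mask(model: Model, template: DensityMap,
              mask_radius: float = 2.5) -> np.ndarray:
    """Boolean grid: union of spheres of ``mask_radius`` about the atoms."""
    mask = np.zeros(template.shape, dtype=bool)
    shape = np.array(template.shape)
    voxel = template.voxel_size
    half = np.ceil(mask_radius / voxel).astype(int)
    frac = template.to_fractional_index(model.atom_coords())
    for center in frac:
        lo = np.maximum(np.round(center).astype(int) - half, 0)
        hi = np.minimum(np.round(center).astype(int) + half + 1, shape)
        if np.any(lo >= hi):
            continue
        ii, jj, kk = np.meshgrid(*(np.arange(lo[a], hi[a]) for a in range(3)),
                                 indexing="ij")
        d2 = (((ii - center[0]) * voxel[0]) ** 2
              + ((jj - center[1]) * voxel[1]) ** 2
              + ((kk - center[2]) * voxel[2]) ** 2)
        sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub |= d2 <= mask_radius ** 2
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = sub
    return mask


def map_model_cc(density_map: DensityMap, model: Model, resolution: float,
                 mask_radius: float = 2.5) -> MaskedCC:
    """Masked map-model correlation (CC_mask role).

    Pearson correlation between the experimental map and the model-based
    density over voxels within ``mask_radius`` of any model atom.
    """
    mask = atom_mask(model, density_map, mask_radius)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask: no model atoms inside the map")
    calc = synthesize_map(model, resolution, density_map)
    x = density_map.grid[mask].astype(np.float64)
    y = calc.grid[mask].astype(np.float64)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        warnings.warn("zero-variance region in map-model CC; returning 0")
        return MaskedCC(0.0, n, mask_radius)
    cc = float(np.dot(x - x.mean(), y - y.mean()) / (n * sx * sy))
    return MaskedCC(cc, n, mask_radius)


def density_outlier_threshold(values: np.ndarray, sd_ratio: float = 3.0,
                              ) -> float:
    """Low-density threshold from the "good" (upper) half of the values.

    The lower half (strictly below the median) is discarded; the threshold
    is ``mean(upper) - sd_ratio * sd(upper)``.  Used to flag residues whose
    CA density falls well below that of the well-fitting part of the model.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 4:
        raise ValueError("need at least 4 values")
    upper = vals[vals >= np.median(vals)]
    sd = float(upper.std())
    if sd == 0:
        warnings.warn("upper-half density values are identical; "
                      "threshold equals their common value")
    return float(upper.mean() - sd_ratio * sd)
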