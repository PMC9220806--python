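"""Density grid I/O and voxel-level operations.

Volumes are held in a single canonical convention: ``values[ix, iy, iz]``
with the world coordinate of voxel ``(i, j, k)`` equal to
``origin + (i, j, k) * voxel_size`` (all distances in Angstroms).  MRC/CCP4
files on disk may permute their axes; :func:`read_map` normalizes them on
the way in and :func:`write_map` always emits the canonical X/Y/Z order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import mrcfile
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "DensityGrid",
    "VoxelMask",
    "MapFormatError",
    "UnsupportedGeometryError",
    "ParameterError",
    "CongruenceError",
    "read_map",
    "write_map",
    "lowpass_filter",
    "mask_near_model",
    "halfmap_consistency",
]

DEFAULT_LOWPASS_RESOLUTION = 4.5
DEFAULT_HALF_THRESH = 0.5

#: Real-space Gaussian sd (A) used for a stated resolution d:  sigma = d / (pi * sqrt(2)).
#: The Fourier transfer function is H(f) = exp(-2 pi^2 sigma^2 f^2), i.e.
#: H(1/d) = exp(-1) for the lowpass filter at its nominal resolution.
RESOLUTION_SIGMA_FACTOR = 1.0 / (np.pi * np.sqrt(2.0))


class MapFormatError(ValueError):
    """Raised when a file cannot be interpreted as an MRC/CCP4 volume."""


class UnsupportedGeometryError(ValueError):
    """Raised for non-orthogonal unit cells."""


class ParameterError(ValueError):
    """Raised for out-of-contract numeric parameters."""


class CongruenceError(ValueError):
    """Raised when two grids that must share a lattice do not."""


@dataclass
class DensityGrid:
    """A 3D scalar field with voxel size and origin metadata.

    Attributes
    ----------
    values : ndarray
        Voxel values indexed ``[ix, iy, iz]``.
    voxel_size : ndarray
        Angstroms per voxel along x, y, z; all components positive.
    origin : ndarray
        World coordinate (A) of voxel (0, 0, 0).
    """

    values: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)
        ).copy()
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size components must be > 0")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3).copy()

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sigma(self) -> float:
        """Standard deviation over all voxels (the 'map sigma' unit)."""
        return float(self.values.std())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(ijk, dtype=float) * self.voxel_size

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin) / self.voxel_size

    def voxel_centers(self, where: np.ndarray | None = None) -> np.ndarray:
        """World coordinates of voxel centers; ``where`` is an optional boolean mask."""
        if where is None:
            idx = np.stack(
                np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
            ).reshape(-1, 3)
        else:
            idx = np.argwhere(where)
        return self.voxel_to_world(idx)

    def interpolate(self, xyz: np.ndarray) -> np.ndarray:
        """Trilinear density at world coordinates; zero outside the grid."""
        frac = self.world_to_voxel(np.atleast_2d(xyz)).T
        return ndimage.map_coordinates(
            self.values.astype(float), frac, order=1, mode="constant", cval=0.0
        )

    def congruent_with(self, other: "DensityGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size)
            and np.allclose(self.origin, other.origin)
        )

    def copy(self, values: np.ndarray | None = None) -> "DensityGrid":
        return DensityGrid(
            values=self.values.copy() if values is None else values,
            voxel_size=self.voxel_size.copy(),
            origin=self.origin.copy(),
        )


@dataclass
class VoxelMask:
    """Boolean keep-mask congruent with a parent grid."""

    keep: np.ndarray

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.keep.ndim != 3:
            raise ValueError("keep must be a 3D boolean array")


def read_map(path) -> DensityGrid:
    """Read an MRC/CCP4 volume, normalizing axis order to x, y, z.

    Raises
    ------
    MapFormatError
        If the file is unreadable or truncated.
    UnsupportedGeometryError
        If the unit cell is non-orthogonal.
    """
    try:
        with mrcfile.open(str(path), mode="r", permissive=False) as mrc:
            header = mrc.header
            data = np.asarray(mrc.data)
            voxel = mrc.voxel_size
    except (ValueError, OSError) as exc:
        raise MapFormatError(f"cannot read MRC/CCP4 volume {path!r}: {exc}") from exc
    if data is None or data.ndim != 3:
        raise MapFormatError(f"{path!r} does not contain a 3D volume")
    angles = np.array([header.cellb.alpha, header.cellb.beta, header.cellb.gamma])
    if not np.allclose(angles, 90.0, atol=1e-3):
        raise UnsupportedGeometryError(
            f"non-orthogonal cell angles {angles.tolist()} are not supported"
        )

    # Data axes are (sections, rows, columns) = (maps, mapr, mapc).
    axis_of_dim = [int(header.maps), int(header.mapr), int(header.mapc)]
    if sorted(axis_of_dim) != [1, 2, 3]:
        raise MapFormatError(f"invalid axis mapping {axis_of_dim}")
    perm = [axis_of_dim.index(a) for a in (1, 2, 3)]
    values = np.ascontiguousarray(np.transpose(data, axes=perm))

    voxel_size = np.array([voxel.x, voxel.y, voxel.z], dtype=float)
    if np.any(voxel_size <= 0):
        voxel_size = np.where(voxel_size <= 0, 1.0, voxel_size)

    # nstart fields follow column/row/section order; map them onto axes.
    nstart_crs = [int(header.nxstart), int(header.nystart), int(header.nzstart)]
    axis_of_crs = [int(header.mapc), int(header.mapr), int(header.maps)]
    nstart = np.zeros(3)
    for start, axis in zip(nstart_crs, axis_of_crs):
        nstart[axis - 1] = start
    origin = (
        np.array(
            [header.origin.x, header.origin.y, header.origin.z], dtype=float
        )
        + nstart * voxel_size
    )
    return DensityGrid(values=values, voxel_size=voxel_size, origin=origin)


def write_map(grid: DensityGrid, path) -> None:
    """Write a grid as MRC2014 (mode 2, canonical x/y/z axis order)."""
    data = np.ascontiguousarray(
        np.transpose(grid.values, axes=(2, 1, 0)).astype(np.float32)
    )
    try:
        with mrcfile.new(str(path), overwrite=True) as mrc:
            mrc.set_data(data)
            mrc.voxel_size = tuple(grid.voxel_size)
            mrc.header.origin.x = grid.origin[0]
            mrc.header.origin.y = grid.origin[1]
            mrc.header.origin.z = grid.origin[2]
            mrc.update_header_stats()
    except OSError as exc:
        raise IOError(f"cannot write map to {path!r}: {exc}") from exc


def lowpass_filter(
    grid: DensityGrid, resolution: float = DEFAULT_LOWPASS_RESOLUTION
) -> DensityGrid:
    """Gaussian low-pass filter to the stated resolution.

    The kernel sd is ``resolution / (pi * sqrt(2))`` A, giving the Fourier
    transfer function ``H(f) = exp(-2 pi^2 sigma^2 f^2)``; at the nominal
    frequency ``f = 1/resolution`` the amplitude is attenuated to ``1/e``.
    The DC component (map mean) is untouched.
    """
    nyquist = 2.0 * float(np.max(grid.voxel_size))
    if resolution <= nyquist:
        raise ParameterError(
            f"resolution {resolution} A must exceed the Nyquist limit {nyquist} A"
        )
    sigma_vox = (resolution * RESOLUTION_SIGMA_FACTOR) / grid.voxel_size
    spectrum = np.fft.rfftn(grid.values.astype(float))
    spectrum = ndimage.fourier_gaussian(
        spectrum, sigma=sigma_vox, n=grid.shape[2]
    )
    filtered = np.fft.irfftn(spectrum, s=grid.shape, axes=(0, 1, 2))
    return grid.copy(values=filtered)


def mask_near_model(
    grid: DensityGrid, atom_coords, radius: float
) -> DensityGrid:
    """Zero voxels whose centers lie within ``radius`` A of any atom."""
    if radius < 0:
        raise ParameterError("radius must be >= 0")
    atom_coords = np.atleast_2d(np.asarray(atom_coords, dtype=float))
    if atom_coords.size == 0:
        warnings.warn("mask_near_model called with no atoms; grid unchanged")
        return grid.copy()
    out = grid.copy()
    if radius == 0:
        return out
    tree = cKDTree(atom_coords)
    centers = out.voxel_centers()
    dist, _ = tree.query(centers, k=1, distance_upper_bound=radius)
    inside = np.isfinite(dist) & (dist <= radius)
    flat = out.values.reshape(-1).copy()
    flat[inside] = 0.0
    out.values = flat.reshape(out.shape)
    return out


def halfmap_consistency(
    half1: DensityGrid,
    half2: DensityGrid,
    half_thresh: float = DEFAULT_HALF_THRESH,
) -> VoxelMask:
    """Keep voxels whose half-map difference is below ``half_thresh`` map sigmas.

    Sigma is the standard deviation of the full map (the voxelwise average
    of the two half-maps).
    """
    if half1.shape != half2.shape or not np.allclose(
        half1.voxel_size, half2.voxel_size
    ):
        raise CongruenceError("half-maps are not congruent")
    full = (half1.values.astype(float) + half2.values.astype(float)) / 2.0
    sigma = float(full.std())
    diff = np.abs(half1.values.astype(float) - half2.values.astype(float))
    if sigma == 0.0:
        keep = diff == 0.0
    else:
        keep = diff / sigma < half_thresh
    return VoxelMask(keep=keep)
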