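"""Synthetic ground-truth systems: CA traces, simulated maps, half-maps,
planted ligands and waters.

Every generator is deterministic under its seed, and planted ground truth is
kept on the :class:`GroundTruthSystem` so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .map_core import DensityGrid, RESOLUTION_SIGMA_FACTOR
from .pdbio import HEAVY_ATOM_COUNT

__all__ = [
    "GroundTruthSystem",
    "GenerationError",
    "make_ca_trace",
    "simulate_map",
    "simulate_half_maps",
    "plant_nonprotein",
]

CA_CA_DISTANCE = 3.8
MIN_NONADJACENT_DISTANCE = 3.0
MAP_PADDING = 6.0  # A beyond coordinate extent (contract: >= 5)

# Ideal alpha-helix: rise 1.5 A, 99.6 deg/residue, radius fixed by the CA-CA bond.
_HELIX_RISE = 1.5
_HELIX_TWIST = np.deg2rad(99.6)
_HELIX_RADIUS = np.sqrt(CA_CA_DISTANCE**2 - _HELIX_RISE**2) / (
    2.0 * np.sin(_HELIX_TWIST / 2.0)
)

# Extended strand zigzag: 3.3 A axial rise.
_STRAND_RISE = 3.3
_STRAND_OFFSET = np.sqrt(CA_CA_DISTANCE**2 - _STRAND_RISE**2) / 2.0


class GenerationError(RuntimeError):
    """Raised when a synthetic system cannot be placed within bounded retries."""


@dataclass
class GroundTruthSystem:
    """A synthetic map with everything needed to score pipeline recovery."""

    ca_coords: np.ndarray
    sequence: str
    map: DensityGrid
    resolution: float
    rng_seed: int
    half1: DensityGrid | None = None
    half2: DensityGrid | None = None
    ligand_coords: dict = field(default_factory=dict)
    water_coords: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    inconsistent_blob: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.ca_coords) != len(self.sequence):
            raise ValueError("ca_coords and sequence lengths differ")

    def manifest(self) -> str:
        lines = [
            f"rng_seed={self.rng_seed}",
            f"n_residues={len(self.sequence)}",
            f"sequence={self.sequence}",
            f"resolution={self.resolution}",
            f"n_waters={len(self.water_coords)}",
            f"n_ligands={len(self.ligand_coords)}",
        ]
        for name, pts in self.ligand_coords.items():
            centroid = np.asarray(pts).mean(axis=0)
            lines.append(
                f"ligand_{name}_centroid={centroid[0]:.3f},{centroid[1]:.3f},{centroid[2]:.3f}"
            )
        for i, w in enumerate(np.atleast_2d(self.water_coords)):
            if w.size:
                lines.append(f"water_{i}={w[0]:.3f},{w[1]:.3f},{w[2]:.3f}")
        return "\n".join(lines) + "\n"


def _helix(n: int, phase: float = 0.0) -> np.ndarray:
    t = np.arange(n)
    return np.stack(
        [
            _HELIX_RADIUS * np.cos(_HELIX_TWIST * t + phase),
            _HELIX_RADIUS * np.sin(_HELIX_TWIST * t + phase),
            _HELIX_RISE * t,
        ],
        axis=1,
    )


def _strand(n: int) -> np.ndarray:
    t = np.arange(n)
    return np.stack(
        [_STRAND_RISE * t, _STRAND_OFFSET * (-1.0) ** t, np.zeros(n)], axis=1
    )


def _rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def _check_trace(coords: np.ndarray) -> bool:
    d = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    if np.any(np.abs(d - CA_CA_DISTANCE) > 0.01):
        return False
    n = len(coords)
    for i in range(n):
        for j in range(i + 2, n):
            if np.linalg.norm(coords[i] - coords[j]) < MIN_NONADJACENT_DISTANCE:
                return False
    return True


def _helix_turn_helix(n: int, rng: np.random.Generator) -> np.ndarray:
    n1 = n // 2
    n2 = n - n1
    for _ in range(50):
        a = _helix(n1)
        bend = rng.uniform(np.deg2rad(70), np.deg2rad(110))
        rot = _rotation(np.array([1.0, 0.0, 0.0]), bend)
        b = _helix(n2, phase=rng.uniform(0, 2 * np.pi)) @ rot.T
        # Attach second helix so the junction bond is exactly 3.8 A and the
        # helices diverge.
        direction = rot @ np.array([0.0, 0.0, 1.0])
        lateral = np.array([0.0, 1.0, 0.0]) + 0.3 * rng.standard_normal(3)
        step = 0.6 * direction + 0.4 * lateral / np.linalg.norm(lateral)
        step = step / np.linalg.norm(step) * CA_CA_DISTANCE
        b = b - b[0] + a[-1] + step
        coords = np.vstack([a, b])
        if _check_trace(coords):
            return coords
    raise GenerationError("could not build a clash-free helix-turn-helix")


def _random_walk(n: int, rng: np.random.Generator) -> np.ndarray:
    for _ in range(200):
        coords = [np.zeros(3)]
        prev_dir = None
        ok = True
        for _ in range(n - 1):
            placed = False
            for _ in range(60):
                v = rng.standard_normal(3)
                v /= np.linalg.norm(v)
                if prev_dir is not None and np.dot(v, prev_dir) < 0.0:
                    continue  # bias forward: keeps the chain open
                cand = coords[-1] + CA_CA_DISTANCE * v
                arr = np.array(coords[:-1])
                if len(arr) and np.min(
                    np.linalg.norm(arr - cand, axis=1)
                ) < MIN_NONADJACENT_DISTANCE:
                    continue
                coords.append(cand)
                prev_dir = v
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            arr = np.array(coords)
            if _check_trace(arr):
                return arr
    raise GenerationError("could not build a self-avoiding random walk")


def make_ca_trace(n_res: int, motif: str = "helix", seed: int = 0) -> np.ndarray:
    """Generate an ordered CA trace with 3.8 A consecutive spacing.

    Parameters
    ----------
    motif : {'helix', 'strand', 'helix-turn-helix', 'random-walk'}
    """
    if n_res < 3:
        raise ValueError("n_res must be >= 3")
    rng = np.random.default_rng(seed)
    if motif == "helix":
        coords = _helix(n_res)
    elif motif == "strand":
        coords = _strand(n_res)
    elif motif == "helix-turn-helix":
        coords = _helix_turn_helix(n_res, rng)
    elif motif == "random-walk":
        coords = _random_walk(n_res, rng)
    else:
        raise ValueError(f"unknown motif {motif!r}")
    if not _check_trace(coords):
        raise GenerationError(f"motif {motif!r} violated trace geometry")
    return coords


def simulate_map(
    coords,
    resolution: float,
    voxel_size: float = 1.0,
    weights=None,
    padding: float = MAP_PADDING,
) -> DensityGrid:
    """Sum one isotropic Gaussian per point onto a padded grid.

    Kernel sd = ``resolution / (pi * sqrt(2))`` A (the package-wide
    resolution convention); each kernel has unit peak height times its
    weight.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.size == 0:
        raise ValueError("simulate_map requires at least one point")
    if resolution < 2.0 * voxel_size:
        raise ValueError("resolution must be >= 2 * voxel_size")
    weights = (
        np.ones(len(coords))
        if weights is None
        else np.broadcast_to(np.asarray(weights, dtype=float), (len(coords),))
    )
    sigma = resolution * RESOLUTION_SIGMA_FACTOR
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    shape = np.ceil((hi - lo) / voxel_size).astype(int) + 1
    values = np.zeros(shape)
    reach = int(np.ceil(4.0 * sigma / voxel_size))
    axes = [np.arange(n) * voxel_size + lo[d] for d, n in enumerate(shape)]
    for point, w in zip(coords, weights):
        center_idx = np.round((point - lo) / voxel_size).astype(int)
        sl = []
        local_axes = []
        for d in range(3):
            a = max(0, center_idx[d] - reach)
            b = min(shape[d], center_idx[d] + reach + 1)
            sl.append(slice(a, b))
            local_axes.append(axes[d][a:b] - point[d])
        gx = np.exp(-(local_axes[0] ** 2) / (2 * sigma**2))
        gy = np.exp(-(local_axes[1] ** 2) / (2 * sigma**2))
        gz = np.exp(-(local_axes[2] ** 2) / (2 * sigma**2))
        values[tuple(sl)] += w * gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
    return DensityGrid(values=values, voxel_size=np.full(3, voxel_size), origin=lo)


def simulate_half_maps(
    grid: DensityGrid, noise_sigma: float, seed: int = 0
) -> tuple[DensityGrid, DensityGrid]:
    """Two independent noisy copies of a map (map + N(0, noise_sigma))."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    h1 = grid.copy(values=grid.values + noise_sigma * rng.standard_normal(grid.shape))
    h2 = grid.copy(values=grid.values + noise_sigma * rng.standard_normal(grid.shape))
    return h1, h2


def _random_sequence(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(HEAVY_ATOM_COUNT.keys()), size=n))


def make_system(
    n_res: int = 30,
    motif: str = "helix",
    resolution: float = 4.0,
    voxel_size: float = 1.0,
    seed: int = 0,
    sequence: str | None = None,
    size_weighted: bool = False,
    noise_sigma: float = 0.0,
    padding: float = MAP_PADDING,
) -> GroundTruthSystem:
    """Build a complete synthetic system: trace, sequence, map, half-maps."""
    rng = np.random.default_rng(seed)
    ca = make_ca_trace(n_res, motif=motif, seed=seed)
    if sequence is None:
        sequence = _random_sequence(n_res, rng)
    if len(sequence) != n_res:
        raise ValueError("sequence length must equal n_res")
    weights = None
    if size_weighted:
        weights = np.array([HEAVY_ATOM_COUNT[c] / 8.0 for c in sequence])
    grid = simulate_map(
        ca,
        resolution=resolution,
        voxel_size=voxel_size,
        weights=weights,
        padding=padding,
    )
    half1, half2 = simulate_half_maps(grid, noise_sigma=noise_sigma, seed=seed + 1)
    return GroundTruthSystem(
        ca_coords=ca,
        sequence=sequence,
        map=grid,
        resolution=resolution,
        rng_seed=seed,
        half1=half1,
        half2=half2,
    )


def _add_points_to_grid(grid: DensityGrid, points, resolution, weight=1.0) -> None:
    """Accumulate Gaussian kernels for ``points`` directly onto the grid lattice."""
    centers = grid.voxel_centers().reshape(*grid.shape, 3)
    sigma = resolution * RESOLUTION_SIGMA_FACTOR
    add = np.zeros(grid.shape)
    for p in np.atleast_2d(points):
        d2 = ((centers - p) ** 2).sum(axis=-1)
        add += weight * np.exp(-d2 / (2 * sigma**2))
    grid.values = grid.values + add


def plant_nonprotein(
    system: GroundTruthSystem,
    ligand_shape: str | None = "elongated",
    n_waters: int = 5,
    inconsistent_blob: bool = False,
    blob_resolution: float = 2.5,
    seed: int | None = None,
) -> GroundTruthSystem:
    """Plant a ligand, waters, and optionally a half-map-inconsistent blob.

    The ligand is a connected multi-point group near the protein surface;
    waters are isolated single points. Planted density is added to the map
    and both half-maps; the inconsistent blob goes into half1 only.
    """
    if system.map is None:
        raise ValueError("system has no map")
    rng = np.random.default_rng(system.rng_seed + 17 if seed is None else seed)
    ca = system.ca_coords
    placed: list[np.ndarray] = [c for c in ca]
    nonprotein: list[np.ndarray] = []

    def far_enough(p, min_d):
        return min(np.linalg.norm(np.array(placed) - p, axis=1)) >= min_d

    def clear_of_nonprotein(p, min_d=5.5):
        # keep planted features from touching: density blobs must stay
        # separable by contiguity-based clustering downstream
        if not nonprotein:
            return True
        return min(np.linalg.norm(np.array(nonprotein) - p, axis=1)) >= min_d

    def inside(p, margin=3.0):
        lo = system.map.origin + margin
        hi = system.map.origin + (np.array(system.map.shape) - 1) * system.map.voxel_size - margin
        return np.all(p >= lo) and np.all(p <= hi)

    def surface_distance(p):
        return float(np.min(np.linalg.norm(ca - p, axis=1)))

    def elongated_walk():
        """Connected 12-point chain hugging the protein surface (3.2-4.6 A)."""
        anchor = ca[rng.integers(len(ca))]
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        start = anchor + direction * rng.uniform(3.6, 4.4)
        if not (inside(start) and 3.2 <= surface_distance(start) <= 4.6):
            return None
        pts = [start]
        heading = None
        for _ in range(11):
            for _ in range(80):
                step = rng.standard_normal(3)
                step /= np.linalg.norm(step)
                if heading is not None:
                    step = 0.8 * heading + 0.2 * step
                    step /= np.linalg.norm(step)
                cand = pts[-1] + 1.4 * step
                if not inside(cand):
                    continue
                if not 3.2 <= surface_distance(cand) <= 4.6:
                    continue
                if len(pts) > 2 and np.min(
                    np.linalg.norm(np.array(pts[:-2]) - cand, axis=1)
                ) < 2.0:
                    continue
                pts.append(cand)
                heading = step
                break
            else:
                return None
        arr = np.array(pts)
        centered = arr - arr.mean(axis=0)
        eig = np.linalg.eigvalsh(centered.T @ centered / len(arr))
        if eig[2] < 5.0 * max(eig[0], 1e-6):  # demand a clearly elongated shape
            return None
        return arr

    ligand_coords: dict = {}
    if ligand_shape is not None:
        for _ in range(800):
            if ligand_shape == "elongated":
                pts = elongated_walk()
                if pts is None:
                    continue
            elif ligand_shape == "globular":
                anchor = ca[rng.integers(len(ca))]
                direction = rng.standard_normal(3)
                direction /= np.linalg.norm(direction)
                start = anchor + direction * rng.uniform(4.0, 5.0)
                pts = start + rng.uniform(-1.6, 1.6, size=(10, 3))
                if not all(inside(p) and surface_distance(p) <= 5.0 for p in pts):
                    continue
            else:
                raise ValueError(f"unknown ligand_shape {ligand_shape!r}")
            if all(far_enough(p, 3.0) for p in pts):
                ligand_coords["LIG1"] = pts
                placed.extend(pts)
                nonprotein.extend(pts)
                break
        else:
            raise GenerationError("no ligand placement found")

    waters = []
    for _ in range(n_waters):
        for _ in range(800):
            anchor = ca[rng.integers(len(ca))]
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            p = anchor + direction * rng.uniform(3.4, 4.6)
            if inside(p) and far_enough(p, 3.4) and clear_of_nonprotein(p):
                waters.append(p)
                placed.append(p)
                nonprotein.append(p)
                break
        else:
            raise GenerationError("no water placement found")
    waters = np.array(waters) if waters else np.empty((0, 3))

    new_map = system.map.copy()
    half1 = system.half1.copy() if system.half1 is not None else new_map.copy()
    half2 = system.half2.copy() if system.half2 is not None else new_map.copy()
    all_pts = []
    if ligand_coords:
        all_pts.append(ligand_coords["LIG1"])
    if len(waters):
        all_pts.append(waters)
    for pts in all_pts:
        for g in (new_map, half1, half2):
            _add_points_to_grid(g, pts, resolution=blob_resolution)

    blob_center = None
    if inconsistent_blob:
        for _ in range(500):
            anchor = ca[rng.integers(len(ca))]
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            p = anchor + direction * rng.uniform(3.5, 4.8)
            if inside(p) and far_enough(p, 3.4) and clear_of_nonprotein(p, 7.0):
                blob_center = p
                break
        else:
            raise GenerationError("no blob placement found")
        blob_pts = blob_center + np.array(
            [[0.0, 0, 0], [1.2, 0, 0], [0, 1.2, 0], [0, 0, 1.2]]
        )
        _add_points_to_grid(new_map, blob_pts, resolution=blob_resolution, weight=0.5)
        _add_points_to_grid(half1, blob_pts, resolution=blob_resolution, weight=1.0)
        # half2 intentionally left without the blob: voxel values disagree.

    return GroundTruthSystem(
        ca_coords=system.ca_coords,
        sequence=system.sequence,
        map=new_map,
        resolution=system.resolution,
        rng_seed=system.rng_seed,
        half1=half1,
        half2=half2,
        ligand_coords=ligand_coords,
        water_coords=waters,
        inconsistent_blob=blob_center,
    )
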