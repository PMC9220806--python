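"""Reduce above-threshold density to a fixed number of pseudoatom points.

Pseudoatoms are CA surrogates: the clustering representative of each group
of above-threshold voxel centers, weighted by density value. Five methods
are supported (kmeans, sc, ac, ms, gmm); methods that do not naturally
yield the requested count are reconciled by splitting the largest cluster
or merging the closest pair until the count is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import (
    AgglomerativeClustering,
    KMeans,
    MeanShift,
    SpectralClustering,
    estimate_bandwidth,
)
from sklearn.mixture import GaussianMixture

from .map_core import DensityGrid
from .pdbio import AtomRecord, read_atoms, write_pdb

__all__ = [
    "PseudoatomSet",
    "ThresholdError",
    "seed_pseudoatoms",
    "perturb_positions",
    "load_pseudoatoms",
    "write_pseudoatoms",
    "PA_METHODS",
]

PA_METHODS = ("kmeans", "sc", "ac", "ms", "gmm")
MAX_CANDIDATE_VOXELS = 200_000


class ThresholdError(ValueError):
    """Raised when too few voxels lie above the requested threshold."""


@dataclass
class PseudoatomSet:
    """A fixed-size set of 3D points serving as TSP nodes."""

    coords: np.ndarray
    n_target: int
    threshold: float = 0.0
    noise_level: float = 0.0
    method: str = "kmeans"
    seed: int = 0
    densities: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.coords) != self.n_target:
            raise ValueError(
                f"coordinate count {len(self.coords)} != n_target {self.n_target}"
            )

    def __len__(self) -> int:
        return len(self.coords)


def _candidate_voxels(
    grid: DensityGrid, threshold: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    above = grid.values > threshold
    n_above = int(above.sum())
    if n_above == 0:
        raise ThresholdError(f"no voxels above threshold {threshold}")
    points = grid.voxel_centers(where=above)
    weights = np.asarray(grid.values[above], dtype=float)
    if n_above > MAX_CANDIDATE_VOXELS:
        # density-weighted subsample keeps runtime desk-scale on big maps
        p = weights / weights.sum()
        idx = rng.choice(n_above, size=MAX_CANDIDATE_VOXELS, replace=False, p=p)
        points, weights = points[idx], weights[idx]
    return points, weights


def _weighted_centroids(
    points: np.ndarray, weights: np.ndarray, labels: np.ndarray
) -> np.ndarray:
    centers = []
    for lab in np.unique(labels):
        m = labels == lab
        w = weights[m]
        centers.append((points[m] * w[:, None]).sum(axis=0) / w.sum())
    return np.array(centers)


def _reconcile_count(
    points: np.ndarray, weights: np.ndarray, labels: np.ndarray, nres: int, seed: int
) -> np.ndarray:
    """Split largest / merge closest clusters until exactly ``nres`` remain."""
    labels = np.unique(labels, return_inverse=True)[1]
    n_clusters = labels.max() + 1
    while n_clusters < nres:
        sizes = np.bincount(labels, minlength=n_clusters)
        big = int(np.argmax(sizes))
        mask = labels == big
        if sizes[big] < 2:
            raise ThresholdError("cannot split singleton clusters further")
        sub = KMeans(n_clusters=2, n_init=3, random_state=seed).fit_predict(
            points[mask], sample_weight=weights[mask]
        )
        new = labels.copy()
        new[np.where(mask)[0][sub == 1]] = n_clusters
        labels = new
        n_clusters += 1
    while n_clusters > nres:
        centers = _weighted_centroids(points, weights, labels)
        dm = squareform(pdist(centers))
        np.fill_diagonal(dm, np.inf)
        i, j = np.unravel_index(np.argmin(dm), dm.shape)
        labels[labels == max(i, j)] = min(i, j)
        labels = np.unique(labels, return_inverse=True)[1]
        n_clusters -= 1
    return labels


def seed_pseudoatoms(
    grid: DensityGrid,
    threshold: float,
    nres: int,
    method: str = "kmeans",
    seed: int = 0,
) -> PseudoatomSet:
    """Cluster above-threshold voxel centers into exactly ``nres`` points.

    Raises
    ------
    ThresholdError
        If fewer than ``nres`` voxels lie above the threshold.
    """
    if method not in PA_METHODS:
        raise ValueError(f"method must be one of {PA_METHODS}, got {method!r}")
    rng = np.random.default_rng(seed)
    points, weights = _candidate_voxels(grid, threshold, rng)
    if len(points) < nres:
        raise ThresholdError(
            f"only {len(points)} voxels above threshold {threshold}; need {nres}"
        )
    if method == "kmeans":
        labels = KMeans(n_clusters=nres, n_init=10, random_state=seed).fit_predict(
            points, sample_weight=weights
        )
    elif method == "gmm":
        labels = GaussianMixture(
            n_components=nres, random_state=seed, covariance_type="spherical"
        ).fit_predict(points)
    elif method == "ac":
        labels = AgglomerativeClustering(n_clusters=nres, linkage="ward").fit_predict(
            points
        )
    elif method == "sc":
        sub = points
        subw = weights
        if len(points) > 4000:  # spectral is O(n^2); subsample for tractability
            idx = rng.choice(len(points), size=4000, replace=False)
            sub, subw = points[idx], weights[idx]
        sub_labels = SpectralClustering(
            n_clusters=nres,
            random_state=seed,
            affinity="nearest_neighbors",
            n_neighbors=min(20, len(sub) - 1),
            assign_labels="kmeans",
        ).fit_predict(sub)
        centers = _weighted_centroids(sub, subw, sub_labels)
        labels = np.argmin(
            ((points[:, None, :] - centers[None, :, :]) ** 2).sum(-1), axis=1
        )
    elif method == "ms":
        bw = estimate_bandwidth(points, quantile=0.05, random_state=seed)
        if not bw or bw <= 0:
            bw = 2.0 * float(np.min(grid.voxel_size))
        labels = MeanShift(bandwidth=bw, bin_seeding=True).fit_predict(points)
    labels = _reconcile_count(points, weights, labels, nres, seed)
    coords = _weighted_centroids(points, weights, labels)
    densities = grid.interpolate(coords)
    return PseudoatomSet(
        coords=coords,
        n_target=nres,
        threshold=threshold,
        method=method,
        seed=seed,
        densities=densities,
    )


def perturb_positions(
    pa: PseudoatomSet, noise_level: float, seed: int = 0
) -> PseudoatomSet:
    """Displace each point by isotropic zero-mean Gaussian noise (sd in A)."""
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    rng = np.random.default_rng(seed)
    coords = pa.coords + noise_level * rng.standard_normal(pa.coords.shape)
    return PseudoatomSet(
        coords=coords,
        n_target=pa.n_target,
        threshold=pa.threshold,
        noise_level=noise_level,
        method=pa.method,
        seed=seed,
        densities=pa.densities,
    )


def write_pseudoatoms(pa: PseudoatomSet, path, b_factors=None) -> None:
    """Write a pseudoatom set as a CA-only PDB, one residue per point."""
    b = np.zeros(len(pa)) if b_factors is None else np.asarray(b_factors, dtype=float)
    atoms = [
        AtomRecord(
            name="CA",
            res_name="ALA",
            chain="A",
            res_seq=i + 1,
            xyz=xyz,
            b_factor=float(b[i]),
            element="C",
        )
        for i, xyz in enumerate(pa.coords)
    ]
    write_pdb(atoms, path)


def load_pseudoatoms(path) -> PseudoatomSet:
    """Load a previously written pseudoatom set (CA-only PDB).

    Files containing multi-atom residues are rejected: externally produced
    models must be reduced to one CA per residue before scoring.
    """
    atoms = read_atoms(path)
    protein = [a for a in atoms if not a.hetatm]
    per_residue: dict[tuple, int] = {}
    for a in protein:
        key = (a.chain, a.res_seq)
        per_residue[key] = per_residue.get(key, 0) + 1
    if any(n > 1 for n in per_residue.values()):
        raise ValueError(
            "input must be a CA-only model with one atom per residue; "
            "found multi-atom residues"
        )
    coords = np.array([a.xyz for a in protein if a.name == "CA"], dtype=float)
    if len(coords) == 0:
        raise ValueError("no CA atoms found")
    return PseudoatomSet(coords=coords, n_target=len(coords))
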