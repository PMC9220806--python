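"""Locate waters/ions and ligands in residual (non-protein) density.

Pipeline: mask density near the protein model, seed one candidate point per
remaining above-threshold voxel (count is data-driven), filter candidates by
distance to the model and by half-map voxel consistency, mean-shift cluster
the survivors, classify clusters by size/shape, and emit two coordinate
files plus two masked maps (one pair for ligands, one for waters/ions).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist
from sklearn.cluster import MeanShift

from .map_core import (
    RESOLUTION_SIGMA_FACTOR,
    CongruenceError,
    DensityGrid,
    halfmap_consistency,
    mask_near_model,
    write_map,
)
from .pdbio import AtomRecord, write_pdb

__all__ = [
    "ResidualPointCloud",
    "DensityCluster",
    "seed_residual",
    "filter_points",
    "cluster_points",
    "classify_clusters",
    "emit_results",
    "score_template_fit",
    "DEFAULT_MASK_RADIUS",
    "DEFAULT_MODEL_DIST",
    "DEFAULT_BANDWIDTH_WEIGHT",
]

logger = logging.getLogger(__name__)

DEFAULT_MASK_RADIUS = 2.0  # A; protein-density shell removed before seeding
DEFAULT_MODEL_DIST = 5.0  # A; Table-style outer distance limit
DEFAULT_BANDWIDTH_WEIGHT = 10.0
WATER_EXTENT_MAX = 2.5  # A
WATER_MEMBERS_MAX = 3
MAP_CARVE_RADIUS = 2.0  # A around cluster points in the emitted maps
FIT_SHELL_RADIUS = 3.0  # A; correlation footprint around a template


@dataclass
class ResidualPointCloud:
    """Candidate non-protein points with per-point filter evidence."""

    points: np.ndarray
    density_value: np.ndarray
    halfmap_ok: np.ndarray | None = None
    model_distance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.density_value = np.asarray(self.density_value, dtype=float).reshape(-1)
        if len(self.points) != len(self.density_value):
            raise ValueError("points and density_value lengths differ")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class DensityCluster:
    """A clustered group of residual points plus size/shape descriptors."""

    members: np.ndarray
    center: np.ndarray
    pca_eigenvalues: np.ndarray
    extent: float
    label: str | None = None

    def __post_init__(self) -> None:
        ev = np.sort(np.asarray(self.pca_eigenvalues, dtype=float))[::-1]
        self.pca_eigenvalues = ev

    @property
    def n_members(self) -> int:
        return len(self.members)


def seed_residual(
    grid: DensityGrid,
    model_atoms,
    threshold: float,
    mask_radius: float = DEFAULT_MASK_RADIUS,
) -> ResidualPointCloud:
    """Mask protein density, then seed one point per residual voxel above
    threshold. The candidate count is automatic (data-driven)."""
    model_atoms = np.atleast_2d(np.asarray(model_atoms, dtype=float))
    if model_atoms.size == 0:
        raise ValueError("model must be non-empty")
    masked = mask_near_model(grid, model_atoms, radius=mask_radius)
    above = masked.values > threshold
    if not above.any():
        warnings.warn("no residual density above threshold; empty point cloud")
        return ResidualPointCloud(
            points=np.empty((0, 3)), density_value=np.empty(0)
        )
    points = masked.voxel_centers(where=above)
    values = np.asarray(masked.values[above], dtype=float)
    logger.info("seeded %d residual candidate points", len(points))
    return ResidualPointCloud(points=points, density_value=values)


def filter_points(
    cloud: ResidualPointCloud,
    model_atoms,
    model_dist: float = DEFAULT_MODEL_DIST,
    half1: DensityGrid | None = None,
    half2: DensityGrid | None = None,
    half_thresh: float = 0.5,
    grid: DensityGrid | None = None,
) -> ResidualPointCloud:
    """Drop points far from the model or at half-map-inconsistent voxels.

    Without half-maps only the distance filter applies (a warning is
    logged). ``grid`` supplies the lattice for voxel lookup; it defaults to
    half1's lattice.
    """
    if len(cloud) == 0:
        return cloud
    model_atoms = np.atleast_2d(np.asarray(model_atoms, dtype=float))
    tree = cKDTree(model_atoms)
    dist, _ = tree.query(cloud.points, k=1)
    keep = dist <= model_dist
    n_dist_removed = int((~keep).sum())

    halfmap_ok = np.ones(len(cloud), dtype=bool)
    if half1 is not None and half2 is not None:
        ref = grid or half1
        if half1.shape != half2.shape:
            raise CongruenceError("half-maps are not congruent")
        if ref.shape != half1.shape:
            raise CongruenceError("half-maps are not congruent with the map")
        mask = halfmap_consistency(half1, half2, half_thresh=half_thresh)
        idx = np.round(ref.world_to_voxel(cloud.points)).astype(int)
        idx = np.clip(idx, 0, np.array(ref.shape) - 1)
        halfmap_ok = mask.keep[idx[:, 0], idx[:, 1], idx[:, 2]]
    else:
        logger.warning("no half-maps given; skipping half-map consistency filter")
    n_half_removed = int((keep & ~halfmap_ok).sum())
    keep = keep & halfmap_ok
    logger.info(
        "filter_points: removed %d by distance, %d by half-map consistency; %d remain",
        n_dist_removed,
        n_half_removed,
        int(keep.sum()),
    )
    return ResidualPointCloud(
        points=cloud.points[keep],
        density_value=cloud.density_value[keep],
        halfmap_ok=halfmap_ok[keep],
        model_distance=dist[keep],
    )


def _describe(points: np.ndarray, values: np.ndarray) -> DensityCluster:
    center = (points * values[:, None]).sum(axis=0) / values.sum()
    centered = points - points.mean(axis=0)
    if len(points) > 1:
        cov = centered.T @ centered / len(points)
        eig = np.linalg.eigvalsh(cov)[::-1]
        extent = float(pdist(points).max())
    else:
        eig = np.zeros(3)
        extent = 0.0
    return DensityCluster(
        members=points, center=center, pca_eigenvalues=eig, extent=extent
    )


def cluster_points(
    cloud: ResidualPointCloud,
    bandwidth_weight: float = DEFAULT_BANDWIDTH_WEIGHT,
    voxel_size: float = 1.0,
    merge_factor: float = 2.0,
) -> list[DensityCluster]:
    """Mean-shift cluster the cloud, then merge contiguous clusters.

    Bandwidth (A) = ``bandwidth_weight * voxel_size / 10``, so the default
    weight of 10 gives a one-voxel bandwidth; higher-resolution (finer)
    maps need larger weights. Elongated density produces several mean-shift
    modes along its length, so clusters whose member points approach within
    ``merge_factor * voxel_size`` are merged afterwards (single linkage);
    the result is still a partition of the cloud.
    """
    if len(cloud) == 0:
        raise ValueError("cannot cluster an empty point cloud")
    bandwidth = bandwidth_weight * voxel_size / 10.0
    ms = MeanShift(bandwidth=bandwidth, bin_seeding=False, cluster_all=True)
    labels = ms.fit_predict(cloud.points)
    labels = np.unique(labels, return_inverse=True)[1]

    if merge_factor > 0:
        merge_dist = merge_factor * voxel_size
        n_lab = labels.max() + 1
        parent = list(range(n_lab))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        tree = cKDTree(cloud.points)
        for i, j in tree.query_pairs(merge_dist):
            ri, rj = find(labels[i]), find(labels[j])
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
        labels = np.array([find(l) for l in labels])

    clusters = []
    for lab in np.unique(labels):
        m = labels == lab
        clusters.append(_describe(cloud.points[m], cloud.density_value[m]))
    return clusters


def classify_clusters(
    clusters,
    water_extent_max: float = WATER_EXTENT_MAX,
    water_members_max: int = WATER_MEMBERS_MAX,
) -> list[DensityCluster]:
    """Label each cluster water_ion or ligand by size/shape (in place).

    A cluster is a water/ion iff its extent is at most ``water_extent_max``
    A and it has at most ``water_members_max`` member points (bounds
    inclusive); everything larger is a ligand.
    """
    for cl in clusters:
        small = cl.extent <= water_extent_max and cl.n_members <= water_members_max
        cl.label = "water_ion" if small else "ligand"
    return clusters


def _carve_map(grid: DensityGrid, points: np.ndarray, radius: float) -> DensityGrid:
    out = grid.copy()
    if len(points) == 0:
        out.values = np.zeros_like(out.values)
        return out
    tree = cKDTree(np.atleast_2d(points))
    centers = out.voxel_centers()
    dist, _ = tree.query(centers, k=1, distance_upper_bound=radius)
    inside = np.isfinite(dist) & (dist <= radius)
    flat = np.zeros(out.values.size)
    flat[inside] = out.values.reshape(-1)[inside]
    out.values = flat.reshape(out.shape)
    return out


def emit_results(grid: DensityGrid, clusters, out_prefix: str) -> dict:
    """Write waters PDB, ligand-points PDB, ligand map, and water map.

    Returns the four output paths keyed by kind.
    """
    waters = [c for c in clusters if c.label == "water_ion"]
    ligands = [c for c in clusters if c.label == "ligand"]

    water_atoms = [
        AtomRecord(
            name="O",
            res_name="HOH",
            chain="W",
            res_seq=i + 1,
            xyz=c.center,
            element="O",
            hetatm=True,
        )
        for i, c in enumerate(waters)
    ]
    ligand_atoms = []
    chains = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for ci, c in enumerate(ligands):
        chain = chains[ci % len(chains)]
        for pi, p in enumerate(c.members):
            ligand_atoms.append(
                AtomRecord(
                    name="C",
                    res_name="LIG",
                    chain=chain,
                    res_seq=ci + 1,
                    xyz=p,
                    element="C",
                    hetatm=True,
                )
            )

    paths = {
        "waters_pdb": f"{out_prefix}_waters.pdb",
        "ligands_pdb": f"{out_prefix}_ligands.pdb",
        "ligand_map": f"{out_prefix}_ligands.mrc",
        "water_map": f"{out_prefix}_waters.mrc",
    }
    write_pdb(water_atoms, paths["waters_pdb"])
    write_pdb(ligand_atoms, paths["ligands_pdb"])
    ligand_points = (
        np.vstack([c.members for c in ligands]) if ligands else np.empty((0, 3))
    )
    water_points = (
        np.array([c.center for c in waters]) if waters else np.empty((0, 3))
    )
    write_map(_carve_map(grid, ligand_points, MAP_CARVE_RADIUS), paths["ligand_map"])
    write_map(_carve_map(grid, water_points, MAP_CARVE_RADIUS), paths["water_map"])
    logger.info(
        "emitted %d water/ion and %d ligand clusters", len(waters), len(ligands)
    )
    return paths


def score_template_fit(
    template_atoms,
    grid: DensityGrid,
    pose: np.ndarray | None = None,
    resolution: float = 2.5,
) -> float:
    """Pearson correlation between the map and density simulated from the
    posed template, over voxels within 3 A of any template atom.

    ``pose`` is a 4x4 homogeneous transform applied to the template; the
    identity by default. Invariant under linear rescaling of map values.
    """
    template_atoms = np.atleast_2d(np.asarray(template_atoms, dtype=float))
    if template_atoms.size == 0:
        raise ValueError("template must be non-empty")
    if pose is not None:
        pose = np.asarray(pose, dtype=float)
        homog = np.hstack([template_atoms, np.ones((len(template_atoms), 1))])
        template_atoms = (homog @ pose.T)[:, :3]
    lo = grid.origin
    hi = grid.origin + (np.array(grid.shape) - 1) * grid.voxel_size
    if np.any(template_atoms < lo - 1e-6) or np.any(template_atoms > hi + 1e-6):
        raise ValueError("pose places the template outside the grid")
    centers = grid.voxel_centers()
    tree = cKDTree(template_atoms)
    dist, _ = tree.query(centers, k=1, distance_upper_bound=FIT_SHELL_RADIUS)
    within = np.isfinite(dist) & (dist <= FIT_SHELL_RADIUS)
    map_vals = grid.values.reshape(-1)[within].astype(float)
    # evaluate the template's Gaussian kernels exactly at the shell's
    # voxel centers (no lattice resampling error)
    sigma = resolution * RESOLUTION_SIGMA_FACTOR
    shell = centers[within]
    sim_vals = np.zeros(len(shell))
    for atom in template_atoms:
        d2 = ((shell - atom) ** 2).sum(axis=1)
        sim_vals += np.exp(-d2 / (2 * sigma**2))
    if np.std(map_vals) == 0 or np.std(sim_vals) == 0:
        return 0.0
    return float(np.corrcoef(map_vals, sim_vals)[0, 1])
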