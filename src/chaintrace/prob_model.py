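"""Decoy path ensembles and per-node connectivity probabilities.

A decoy is one backbone path solved from a perturbed pseudoatom set (one
per threshold x noise-level combination). Decoys are matched node-to-node
onto a reference decoy by optimal bijective assignment, averaged, and the
average path's local connectivity is scored against every decoy; the
resulting percentage is written to the B-factor column of a CA-only PDB.

Display convention for viewers: color by B-factor from 100 (blue) through
75 (white) down to 50 or below (red).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .map_core import DensityGrid
from .path_solver import (
    BackbonePath,
    DEFAULT_TIME_CAP,
    build_edge_matrix,
    open_path,
    solve_cycle,
)
from .pseudoatoms import (
    PseudoatomSet,
    ThresholdError,
    perturb_positions,
    seed_pseudoatoms,
)
from .pdbio import AtomRecord, write_pdb

__all__ = [
    "DecoyEnsemble",
    "ProbabilisticModel",
    "generate_decoys",
    "correspond_and_average",
    "connectivity_probability",
    "write_probabilistic_pdb",
    "default_noise_schedule",
    "bracket_thresholds",
]

DEFAULT_NOISE_LEVELS = 20
DEFAULT_NOISE_MAX = 5.0


def default_noise_schedule(
    n_levels: int = DEFAULT_NOISE_LEVELS, max_noise: float = DEFAULT_NOISE_MAX
) -> np.ndarray:
    """Evenly spaced positional-noise levels from 0 to ``max_noise`` A."""
    return np.linspace(0.0, max_noise, n_levels)


def bracket_thresholds(bracket: tuple[float, float, float]) -> np.ndarray:
    """Expand a (min, max, interval) bracket into a threshold list."""
    lo, hi, step = (float(v) for v in bracket)
    if step <= 0:
        raise ValueError("bracket interval must be > 0")
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


@dataclass
class DecoyEnsemble:
    """All decoys plus the node correspondence onto a reference decoy."""

    decoys: list
    thresholds: np.ndarray
    noise_levels: np.ndarray
    reference_index: int = -1
    correspondence: list | None = None

    def __post_init__(self) -> None:
        counts = {len(pa) for pa, _ in self.decoys}
        if len(counts) > 1:
            raise ValueError("all decoys must share one node count")

    def __len__(self) -> int:
        return len(self.decoys)

    @property
    def n_nodes(self) -> int:
        return len(self.decoys[0][0])


@dataclass
class ProbabilisticModel:
    """Average pseudoatom positions, the path over them, and per-node
    connectivity probability (percent)."""

    avg_coords: np.ndarray
    avg_path: BackbonePath
    probability: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.avg_coords = np.asarray(self.avg_coords, dtype=float).reshape(-1, 3)
        if self.probability is not None:
            p = np.asarray(self.probability, dtype=float)
            if np.any(p < 0) or np.any(p > 100):
                raise ValueError("probabilities must lie in [0, 100]")
            self.probability = p


def generate_decoys(
    grid: DensityGrid,
    threshold: float | None = None,
    bracket: tuple[float, float, float] | None = None,
    noise_levels=None,
    nres: int = 0,
    method: str = "kmeans",
    base_seed: int = 0,
    time_cap: float = DEFAULT_TIME_CAP,
    map_weight: bool = False,
) -> DecoyEnsemble:
    """One decoy per (threshold, noise level) pair.

    If only a single threshold is given, the bracket defaults to
    ``(threshold - sigma, threshold + sigma, sigma)``, i.e. three
    thresholds one map-sigma apart. The decoy count is always
    ``n_thresholds * n_noise_levels``.
    """
    if bracket is None:
        if threshold is None:
            raise ValueError("either threshold or bracket is required")
        sigma = grid.sigma
        thresholds = np.array([threshold - sigma, threshold, threshold + sigma])
    else:
        thresholds = bracket_thresholds(bracket)
    if noise_levels is None:
        noise_levels = default_noise_schedule()
    noise_levels = np.asarray(noise_levels, dtype=float)
    if nres < 3:
        raise ValueError("nres must be >= 3")

    # fail fast with the offending threshold named
    for tau in thresholds:
        n_above = int((grid.values > tau).sum())
        if n_above < nres:
            raise ThresholdError(
                f"threshold {tau:g} leaves {n_above} voxels; need >= {nres}"
            )

    decoys = []
    seed_counter = base_seed
    for tau in thresholds:
        base_pa = seed_pseudoatoms(
            grid, threshold=float(tau), nres=nres, method=method, seed=base_seed
        )
        for noise in noise_levels:
            seed_counter += 1
            pa = perturb_positions(base_pa, noise_level=float(noise), seed=seed_counter)
            m = build_edge_matrix(pa, grid=grid, map_weight=map_weight)
            tour = solve_cycle(m, time_cap=time_cap)
            path = open_path(tour, m, source=pa)
            decoys.append((pa, path))
    return DecoyEnsemble(
        decoys=decoys, thresholds=thresholds, noise_levels=noise_levels
    )


def _reference_index(e: DecoyEnsemble) -> int:
    """Prefer the zero-noise, central-threshold decoy as the anchor."""
    n_noise = len(e.noise_levels)
    zero_noise = np.where(np.isclose(e.noise_levels, 0.0))[0]
    central_t = len(e.thresholds) // 2
    if len(zero_noise):
        return central_t * n_noise + int(zero_noise[0])
    # fall back: decoy minimizing total matching cost to all others
    costs = []
    for i, (pa_i, _) in enumerate(e.decoys):
        total = 0.0
        for j, (pa_j, _) in enumerate(e.decoys):
            if i == j:
                continue
            c = ((pa_i.coords[:, None, :] - pa_j.coords[None, :, :]) ** 2).sum(-1)
            r, cc = linear_sum_assignment(c)
            total += c[r, cc].sum()
        costs.append(total)
    return int(np.argmin(costs))


def correspond_and_average(
    e: DecoyEnsemble, time_cap: float = DEFAULT_TIME_CAP
) -> ProbabilisticModel:
    """Match every decoy onto the reference and average matched positions.

    Correspondence is the minimum-total-squared-distance bijection (all
    decoys already share the map's coordinate frame). The average path is
    solved over the averaged coordinates with the standard solver.
    """
    if len(e) < 1:
        raise ValueError("need at least one decoy")
    ref_idx = _reference_index(e)
    ref = e.decoys[ref_idx][0].coords
    n = e.n_nodes
    sums = np.zeros((n, 3))
    correspondence = []
    for pa, _ in e.decoys:
        cost = ((ref[:, None, :] - pa.coords[None, :, :]) ** 2).sum(-1)
        rows, cols = linear_sum_assignment(cost)
        mapping = np.empty(n, dtype=int)
        mapping[rows] = cols  # reference index -> decoy node index
        correspondence.append(mapping)
        sums += pa.coords[mapping]
    e.reference_index = ref_idx
    e.correspondence = correspondence
    avg = sums / len(e)
    avg_pa = PseudoatomSet(coords=avg, n_target=n)
    m = build_edge_matrix(avg_pa)
    tour = solve_cycle(m, time_cap=time_cap)
    avg_path = open_path(tour, m, source=avg_pa)
    return ProbabilisticModel(avg_coords=avg, avg_path=avg_path)


def connectivity_probability(
    model: ProbabilisticModel, e: DecoyEnsemble
) -> ProbabilisticModel:
    """Percent of decoys agreeing with the average path's local connectivity.

    For node ``i`` let ``A(i)`` be its unordered neighbor set in the average
    path (one neighbor at the termini, two elsewhere). Each decoy scores
    ``|A(i) ∩ A_d(i)| / max(|A(i)|, |A_d(i)|)`` through the established
    correspondence — paths are direction-agnostic, so both neighbors count
    equally — and the probability is 100 times the mean decoy score. The
    symmetric normalization means a terminus that sits mid-chain in a decoy
    agrees only partially, so unstable termini read low, while ensembles of
    identical decoys still score 100 everywhere.
    """
    if e.correspondence is None:
        raise ValueError("run correspond_and_average first")
    n = e.n_nodes
    # average-path neighbors, in reference/average index space
    avg_neighbors = [set() for _ in range(n)]
    order = model.avg_path.order
    for pos, node in enumerate(order):
        avg_neighbors[int(node)] = model.avg_path.neighbors(pos)

    scores = np.zeros(n)
    for mapping, (_, path) in zip(e.correspondence, e.decoys):
        decoy_neighbors = [set() for _ in range(n)]
        for pos, node in enumerate(path.order):
            decoy_neighbors[int(node)] = path.neighbors(pos)
        inverse = np.empty(n, dtype=int)
        inverse[mapping] = np.arange(n)  # decoy node -> reference index
        for i in range(n):
            a = avg_neighbors[i]
            d_neigh = {int(inverse[x]) for x in decoy_neighbors[mapping[i]]}
            denom = max(len(a), len(d_neigh))
            scores[i] += len(a & d_neigh) / denom if denom else 1.0
    probability = 100.0 * scores / len(e)
    return ProbabilisticModel(
        avg_coords=model.avg_coords,
        avg_path=model.avg_path,
        probability=probability,
    )


def write_probabilistic_pdb(model: ProbabilisticModel, path) -> None:
    """CA-only PDB with connectivity percent in the B-factor column.

    Residues are numbered along the average path; B-factors carry two
    decimals (a node at 100% reads ``100.00``).
    """
    if model.probability is None:
        raise ValueError("probabilities not computed")
    atoms = []
    for res_seq, node in enumerate(model.avg_path.order, start=1):
        atoms.append(
            AtomRecord(
                name="CA",
                res_name="ALA",
                chain="A",
                res_seq=res_seq,
                xyz=model.avg_coords[int(node)],
                b_factor=float(model.probability[int(node)]),
                element="C",
            )
        )
    write_pdb(
        atoms,
        path,
        remarks=["B-FACTOR = CONNECTIVITY PROBABILITY (PERCENT)"],
    )
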