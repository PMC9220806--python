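"""Distance matrices, TSP solving, cycle-to-path conversion, and geometric
path refinement.

The solver is exact (Held-Karp dynamic programming) for small instances and
a deterministic greedy + 2-opt/Or-opt improvement heuristic for larger
ones, bounded by a wall-clock cap.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .map_core import DensityGrid, ParameterError
from .pseudoatoms import PseudoatomSet

__all__ = [
    "EdgeMatrix",
    "BackbonePath",
    "build_edge_matrix",
    "solve_cycle",
    "open_path",
    "refine_path",
    "brute_force_cycle",
    "DEFAULT_TIME_CAP",
]

DEFAULT_TIME_CAP = 30.0  # seconds
EXACT_N_MAX = 12
ILS_SEED = 1729  # pinned: solve_cycle must be reproducible
ILS_KICKS = 30
DENSITY_PENALTY_LAMBDA = 2.0
SEGMENT_SAMPLE_STEP = 0.5  # A
TARGET_CA_CA = 3.8


@dataclass
class EdgeMatrix:
    """Symmetric non-negative edge weights with zero diagonal."""

    weights: np.ndarray
    map_weighted: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n(self) -> int:
        return self.weights.shape[0]


@dataclass
class BackbonePath:
    """An open path (node ordering) over a pseudoatom set."""

    order: np.ndarray
    total_length: float
    source: PseudoatomSet | None = None

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        if len(np.unique(self.order)) != len(self.order):
            raise ValueError("order must be a permutation")

    def __len__(self) -> int:
        return len(self.order)

    @property
    def coords(self) -> np.ndarray:
        if self.source is None:
            raise ValueError("path has no source pseudoatom set")
        return self.source.coords[self.order]

    def neighbors(self, position: int) -> set:
        """Unordered neighbor node-ids of the node at path position ``position``."""
        out = set()
        if position > 0:
            out.add(int(self.order[position - 1]))
        if position < len(self.order) - 1:
            out.add(int(self.order[position + 1]))
        return out


def build_edge_matrix(
    pa: PseudoatomSet,
    grid: DensityGrid | None = None,
    map_weight: bool = False,
    threshold: float | None = None,
    penalty_lambda: float = DENSITY_PENALTY_LAMBDA,
) -> EdgeMatrix:
    """Pairwise Euclidean distances, optionally penalized by low density.

    With ``map_weight``, each edge is scaled by
    ``1 + lambda * max(0, 1 - rho_min / tau)`` where ``rho_min`` is the
    minimum density sampled every 0.5 A along the connecting segment and
    ``tau`` the working threshold: edges crossing density gaps grow.
    """
    n = len(pa)
    if n < 3:
        raise ValueError("need at least 3 pseudoatoms")
    dist = squareform(pdist(pa.coords))
    if not map_weight:
        return EdgeMatrix(weights=dist, map_weighted=False)
    if grid is None:
        raise ParameterError("map_weight requires a density grid")
    tau = pa.threshold if threshold is None else threshold
    if tau <= 0:
        tau = max(float(grid.sigma), 1e-9)
    weights = dist.copy()
    for i in range(n):
        for j in range(i + 1, n):
            d = dist[i, j]
            n_samples = max(int(np.ceil(d / SEGMENT_SAMPLE_STEP)) + 1, 2)
            t = np.linspace(0.0, 1.0, n_samples)
            seg = pa.coords[i] + t[:, None] * (pa.coords[j] - pa.coords[i])
            rho_min = float(grid.interpolate(seg).min())
            penalty = 1.0 + penalty_lambda * max(0.0, 1.0 - rho_min / tau)
            weights[i, j] = weights[j, i] = d * penalty
    return EdgeMatrix(weights=weights, map_weighted=True)


def brute_force_cycle(m: EdgeMatrix) -> tuple[np.ndarray, float]:
    """Exhaustive minimum over all (n-1)!/2 tours. Oracle use only."""
    n = m.n
    w = m.weights
    best_len = np.inf
    best = None
    for perm in itertools.permutations(range(1, n)):
        if perm[0] > perm[-1]:
            continue  # skip mirrored tours
        tour = (0,) + perm
        length = w[tour[-1], 0] + sum(w[tour[k], tour[k + 1]] for k in range(n - 1))
        if length < best_len - 1e-12:
            best_len = length
            best = tour
    return np.array(best), float(best_len)


def _held_karp(w: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact TSP via dynamic programming over subsets; O(2^n n^2)."""
    n = w.shape[0]
    full = 1 << (n - 1)  # subsets of nodes 1..n-1
    dp = np.full((full, n - 1), np.inf)
    parent = np.full((full, n - 1), -1, dtype=int)
    for j in range(n - 1):
        dp[1 << j, j] = w[0, j + 1]
    for mask in range(full):
        for j in range(n - 1):
            if not mask & (1 << j) or not np.isfinite(dp[mask, j]):
                continue
            base = dp[mask, j]
            for k in range(n - 1):
                if mask & (1 << k):
                    continue
                nm = mask | (1 << k)
                cand = base + w[j + 1, k + 1]
                if cand < dp[nm, k]:
                    dp[nm, k] = cand
                    parent[nm, k] = j
    final = dp[full - 1] + w[1:, 0]
    j = int(np.argmin(final))
    best_len = float(final[j])
    order = [j + 1]
    mask = full - 1
    while parent[mask, j] >= 0:
        pj = parent[mask, j]
        mask ^= 1 << j
        j = pj
        order.append(j + 1)
    order.append(0)
    return np.array(order[::-1]), best_len


def _tour_length(w: np.ndarray, tour: np.ndarray) -> float:
    return float(w[tour, np.roll(tour, -1)].sum())


def _greedy_tour(w: np.ndarray, start: int = 0) -> np.ndarray:
    n = w.shape[0]
    visited = np.zeros(n, dtype=bool)
    tour = [start]
    visited[start] = True
    for _ in range(n - 1):
        row = w[tour[-1]].copy()
        row[visited] = np.inf
        nxt = int(np.argmin(row))
        tour.append(nxt)
        visited[nxt] = True
    return np.array(tour)


def _two_opt(w: np.ndarray, tour: np.ndarray, deadline: float) -> np.ndarray:
    n = len(tour)
    improved = True
    while improved and time.monotonic() < deadline:
        improved = False
        for i in range(n - 1):
            a, b = tour[i], tour[(i + 1) % n]
            # vectorized gain over all j > i+1
            j = np.arange(i + 2, n)
            if i == 0:
                j = j[:-1]  # avoid wrapping onto the same edge
            if len(j) == 0:
                continue
            c = tour[j]
            d = tour[(j + 1) % n]
            gain = w[a, b] + w[c, d] - w[a, c] - w[b, d]
            k = int(np.argmax(gain))
            if gain[k] > 1e-10:
                jj = j[k]
                tour[i + 1 : jj + 1] = tour[i + 1 : jj + 1][::-1]
                improved = True
        if time.monotonic() >= deadline:
            break
    return tour


def _or_opt(w: np.ndarray, tour: np.ndarray, deadline: float) -> np.ndarray:
    """Relocate segments of length 1-3 while it improves the tour."""
    n = len(tour)
    improved = True
    while improved and time.monotonic() < deadline:
        improved = False
        for seg_len in (1, 2, 3):
            for i in range(n):
                if time.monotonic() >= deadline:
                    return tour
                seg = [tour[(i + k) % n] for k in range(seg_len)]
                prev = tour[(i - 1) % n]
                nxt = tour[(i + seg_len) % n]
                if prev in seg or nxt in seg:
                    continue
                removal = (
                    w[prev, seg[0]] + w[seg[-1], nxt] - w[prev, nxt]
                )
                rest = [t for t in tour if t not in seg]
                best_gain, best_pos = 0.0, None
                for p in range(len(rest)):
                    a, b = rest[p], rest[(p + 1) % len(rest)]
                    if a == prev:
                        continue
                    insertion = w[a, seg[0]] + w[seg[-1], b] - w[a, b]
                    gain = removal - insertion
                    if gain > best_gain + 1e-10:
                        best_gain, best_pos = gain, p
                if best_pos is not None:
                    new = rest[: best_pos + 1] + seg + rest[best_pos + 1 :]
                    tour = np.array(new)
                    improved = True
    return tour


def solve_cycle(
    m: EdgeMatrix, time_cap: float = DEFAULT_TIME_CAP
) -> np.ndarray:
    """Return a Hamiltonian cycle (node order); exact for n <= 12.

    Larger instances use greedy construction plus 2-opt and Or-opt
    improvement within ``time_cap`` seconds. Fully deterministic.
    """
    n = m.n
    if n < 3:
        raise ValueError("need at least 3 nodes")
    if n <= EXACT_N_MAX:
        tour, _ = _held_karp(m.weights)
        return tour
    deadline = time.monotonic() + time_cap
    starts = np.linspace(0, n - 1, num=min(n, 4), dtype=int)
    best_tour, best_len = None, np.inf
    greedy_best = np.inf
    for s in dict.fromkeys(starts.tolist()):
        tour = _greedy_tour(m.weights, start=int(s))
        greedy_best = min(greedy_best, _tour_length(m.weights, tour))
        tour = _two_opt(m.weights, tour.copy(), deadline)
        tour = _or_opt(m.weights, tour, deadline)
        tour = _two_opt(m.weights, tour.copy(), deadline)
        length = _tour_length(m.weights, tour)
        if length < best_len - 1e-12:
            best_tour, best_len = tour, length
        if time.monotonic() >= deadline:
            break
    # iterated local search: seeded double-bridge kicks + 2-opt re-descent
    rng = np.random.default_rng(ILS_SEED)
    for _ in range(ILS_KICKS):
        if time.monotonic() >= deadline:
            break
        cuts = np.sort(rng.choice(np.arange(1, n), size=3, replace=False))
        a, b, c = cuts
        t = best_tour
        kicked = np.concatenate([t[:a], t[b:c], t[a:b], t[c:]])
        kicked = _two_opt(m.weights, kicked, deadline)
        kicked = _or_opt(m.weights, kicked, deadline)
        length = _tour_length(m.weights, kicked)
        if length < best_len - 1e-12:
            best_tour, best_len = kicked, length
    assert best_len <= greedy_best + 1e-9
    return best_tour


def open_path(
    tour: np.ndarray, m: EdgeMatrix, source: PseudoatomSet | None = None
) -> BackbonePath:
    """Cut the cycle at its largest-weight edge to obtain an open path.

    Ties are broken by the smallest (i, j) node-index pair.
    """
    tour = np.asarray(tour, dtype=int)
    n = len(tour)
    edges = [(tour[k], tour[(k + 1) % n]) for k in range(n)]
    weights = np.array([m.weights[i, j] for i, j in edges])
    max_w = weights.max()
    candidates = [
        k for k in range(n) if np.isclose(weights[k], max_w, rtol=0, atol=1e-9)
    ]
    key = lambda k: tuple(sorted((int(edges[k][0]), int(edges[k][1]))))
    cut = min(candidates, key=key)
    order = np.roll(tour, -(cut + 1))
    total = float(weights.sum() - weights[cut])
    return BackbonePath(order=order, total_length=total, source=source)


def _solve_open(weights: np.ndarray, time_cap: float = DEFAULT_TIME_CAP) -> np.ndarray:
    """Minimum open path over all nodes, via a zero-cost dummy node.

    Used by the refinement re-solve, where the open-path objective (no
    closing edge) is the physically meaningful one.
    """
    n = weights.shape[0]
    aug = np.zeros((n + 1, n + 1))
    aug[:n, :n] = weights
    tour = solve_cycle(EdgeMatrix(weights=aug), time_cap=time_cap)
    cut = int(np.where(tour == n)[0][0])
    order = np.roll(tour, -(cut + 1))[:-1]
    return order.astype(int)


def solve_path(
    pa: PseudoatomSet,
    grid: DensityGrid | None = None,
    map_weight: bool = False,
    time_cap: float = DEFAULT_TIME_CAP,
) -> BackbonePath:
    """Convenience: matrix -> cycle -> open path."""
    m = build_edge_matrix(pa, grid=grid, map_weight=map_weight)
    tour = solve_cycle(m, time_cap=time_cap)
    return open_path(tour, m, source=pa)


def _relax_positions(
    coords: np.ndarray,
    grid: DensityGrid,
    weight: float,
    density_weight: float,
    n_steps: int = 20,
    step: float = 0.15,
) -> np.ndarray:
    """Relax interior nodes toward ideal CA-CA spacing and higher density.

    Per interior node the penalty combines squared deviation of the two
    adjacent distances from 3.8 A, an angle-strain term for angles below
    80 degrees, and the negative interpolated map density.
    """
    coords = coords.copy()
    eps = 1e-9
    h = 0.25  # finite-difference step for the density gradient (A)
    for _ in range(n_steps):
        new = coords.copy()
        for i in range(1, len(coords) - 1):
            p, a, b = coords[i], coords[i - 1], coords[i + 1]
            grad = np.zeros(3)
            for nb in (a, b):
                v = p - nb
                d = np.linalg.norm(v) + eps
                grad += 2.0 * weight * (d - TARGET_CA_CA) * v / d
            u = (a - p) / (np.linalg.norm(a - p) + eps)
            w_ = (b - p) / (np.linalg.norm(b - p) + eps)
            cosang = float(np.dot(u, w_))
            if cosang > np.cos(np.deg2rad(80.0)):  # angle tighter than 80 deg
                # push p away from the a-b midpoint to open the angle
                mid = (a + b) / 2.0
                away = p - mid
                norm = np.linalg.norm(away) + eps
                grad += -0.5 * weight * away / norm
            # density ascent via central differences
            dgrad = np.zeros(3)
            for d3 in range(3):
                dp = np.zeros(3)
                dp[d3] = h
                dgrad[d3] = float(
                    grid.interpolate(p + dp)[0] - grid.interpolate(p - dp)[0]
                ) / (2 * h)
            grad -= density_weight * dgrad
            move = -step * grad
            norm = np.linalg.norm(move)
            if norm > 0.5:
                move *= 0.5 / norm  # trust region: at most 0.5 A per sweep
            new[i] = p + move
        coords = new
    return coords


def refine_path(
    path: BackbonePath,
    pa: PseudoatomSet,
    grid: DensityGrid,
    rounds: int = 3,
    time_cap: float = DEFAULT_TIME_CAP,
    map_weight: bool | None = None,
) -> tuple[BackbonePath, PseudoatomSet]:
    """Alternate TSP re-solving and positional relaxation.

    Each round first re-solves the ordering on the current positions as an
    open-path problem (zero-cost dummy node) over Euclidean distances with
    a capped CA-CA spacing penalty -- the physical constraint, whose weight
    doubles each round (1, 2, 4, ...) -- then relaxes interior positions
    toward ideal spacing, relaxed angles, and higher map density. A round
    is rolled back if it increases the spread of consecutive distances.
    ``map_weight`` is accepted for interface symmetry with the initial
    solve; density enters refinement through the relaxation step.
    """
    if rounds < 1:
        raise ParameterError("rounds must be >= 1")
    del map_weight  # see docstring
    coords = pa.coords.copy()
    order = path.order.copy()

    def dist_sd(c, o):
        return float(np.linalg.norm(np.diff(c[o], axis=0), axis=1).std())

    density_scale = max(float(grid.values.max()), 1e-9)
    best_sd = dist_sd(coords, order)
    for r in range(rounds):
        weight = float(2**r)
        # (a) re-solve the ordering under the spacing constraint
        d_euclid = squareform(pdist(coords))
        spacing = weight * np.minimum((d_euclid - TARGET_CA_CA) ** 2, 4.0)
        np.fill_diagonal(spacing, 0.0)
        new_order = _solve_open(d_euclid + spacing, time_cap=time_cap)
        # (b) relax positions along the new ordering
        relaxed = _relax_positions(
            coords[new_order], grid, weight=weight, density_weight=2.0 / density_scale
        )
        cand = coords.copy()
        cand[new_order] = relaxed
        sd = dist_sd(cand, new_order)
        if sd <= best_sd + 1e-9:
            coords, order = cand, new_order
            best_sd = sd
    out_pa = PseudoatomSet(
        coords=coords,
        n_target=pa.n_target,
        threshold=pa.threshold,
        noise_level=pa.noise_level,
        method=pa.method,
        seed=pa.seed,
        densities=grid.interpolate(coords),
    )
    d = np.linalg.norm(np.diff(coords[order], axis=0), axis=1)
    return (
        BackbonePath(order=order, total_length=float(d.sum()), source=out_pa),
        out_pa,
    )
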