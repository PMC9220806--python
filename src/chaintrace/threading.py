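"""Thread a 1-letter sequence onto a backbone path and build a simple
all-atom model.

Direction choice: when both orientations are tried, each is scored by the
Pearson correlation between per-residue heavy-atom counts and the local
density mass in a 3 A sphere around each path node; the higher-scoring
orientation wins, with ties going forward. CA coordinates are never moved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .map_core import DensityGrid
from .path_solver import BackbonePath
from .pseudoatoms import PseudoatomSet
from .pdbio import AtomRecord, HEAVY_ATOM_COUNT, three_letter, write_pdb

__all__ = ["ThreadedModel", "thread_sequence", "build_all_atom", "read_sequence_file", "write_model_pdb"]

DENSITY_SPHERE_RADIUS = 3.0
GAP_DISTANCE = 4.5

# ideal backbone internal coordinates (A / degrees)
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_N_CA = 1.458
BOND_C_O = 1.231
ANGLE_CA_C_N = 116.2
ANGLE_N_C_O = 123.0
TARGET_CA_CA = 3.8


@dataclass
class ThreadedModel:
    path: BackbonePath
    sequence: str
    direction: str = "forward"
    direction_score: float = 0.0
    reverse_score: float | None = None
    atoms: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.path):
            raise ValueError("sequence length must equal path length")

    @property
    def ca_coords(self) -> np.ndarray:
        return self.path.coords


def read_sequence_file(path) -> str:
    """1-letter sequence from plain text; whitespace and FASTA headers ignored."""
    seq = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                continue
            seq.append("".join(line.split()))
    return "".join(seq).upper()


def _density_mass(grid: DensityGrid, center: np.ndarray) -> float:
    """Sum of voxel values within DENSITY_SPHERE_RADIUS of a point."""
    r = DENSITY_SPHERE_RADIUS
    lo_idx = np.floor(grid.world_to_voxel(center - r)).astype(int)
    hi_idx = np.ceil(grid.world_to_voxel(center + r)).astype(int)
    lo_idx = np.maximum(lo_idx, 0)
    hi_idx = np.minimum(hi_idx, np.array(grid.shape) - 1)
    if np.any(lo_idx > hi_idx):
        return 0.0
    sl = tuple(slice(a, b + 1) for a, b in zip(lo_idx, hi_idx))
    sub = grid.values[sl]
    idx = np.stack(
        np.meshgrid(*[np.arange(a, b + 1) for a, b in zip(lo_idx, hi_idx)], indexing="ij"),
        axis=-1,
    )
    centers = grid.voxel_to_world(idx.reshape(-1, 3))
    within = np.linalg.norm(centers - center, axis=1) <= r
    return float(np.asarray(sub, dtype=float).reshape(-1)[within].sum())


def _direction_score(grid: DensityGrid, coords: np.ndarray, sequence: str) -> float:
    masses = np.array([_density_mass(grid, c) for c in coords])
    counts = np.array([HEAVY_ATOM_COUNT.get(c, 8) for c in sequence], dtype=float)
    if np.std(masses) == 0 or np.std(counts) == 0:
        return 0.0
    return float(np.corrcoef(masses, counts)[0, 1])


def thread_sequence(
    path: BackbonePath,
    pa: PseudoatomSet,
    grid: DensityGrid,
    sequence: str,
    try_reverse: bool = False,
) -> ThreadedModel:
    """Assign residues 1:1 along the path, optionally testing both directions."""
    sequence = sequence.strip().upper()
    if len(sequence) != len(path):
        raise ValueError(
            f"sequence length {len(sequence)} != path length {len(path)}"
        )
    coords = pa.coords[path.order]
    forward = _direction_score(grid, coords, sequence)
    if not try_reverse:
        return ThreadedModel(
            path=path, sequence=sequence, direction="forward", direction_score=forward
        )
    backward = _direction_score(grid, coords, sequence[::-1])
    if backward > forward:
        return ThreadedModel(
            path=path,
            sequence=sequence[::-1],
            direction="backward",
            direction_score=backward,
            reverse_score=forward,
        )
    return ThreadedModel(
        path=path,
        sequence=sequence,
        direction="forward",
        direction_score=forward,
        reverse_score=backward,
    )


def _peptide_template() -> dict:
    """2D template of the trans peptide unit between two CAs 3.8 A apart.

    Solved once from the ideal internal coordinates; returns positions of
    C (bonded to CA1), O, and N (bonded to CA2) in the plane frame with
    CA1 at the origin and CA2 on the +x axis.
    """
    d = TARGET_CA_CA

    def residual(theta):
        c = np.array([BOND_CA_C * np.cos(theta), BOND_CA_C * np.sin(theta)])
        # N lies at distance BOND_C_N from C and BOND_N_CA from CA2=(d,0)
        ca2 = np.array([d, 0.0])
        v = ca2 - c
        L = np.linalg.norm(v)
        a = (BOND_C_N**2 - BOND_N_CA**2 + L**2) / (2 * L)
        h2 = BOND_C_N**2 - a**2
        if h2 < 0:
            return np.nan
        h = np.sqrt(h2)
        base = c + a * v / L
        perp = np.array([-v[1], v[0]]) / L
        n = base - h * perp  # N below the C apex keeps the unit extended
        u1 = -(c - np.zeros(2))  # C->CA1
        u2 = n - c  # C->N
        cosang = np.dot(u1, u2) / (np.linalg.norm(u1) * np.linalg.norm(u2))
        return np.degrees(np.arccos(np.clip(cosang, -1, 1))) - ANGLE_CA_C_N

    # the root lies near 20 deg; beyond ~39 deg the N circles no longer
    # intersect (residual undefined), so bracket tightly
    theta = brentq(residual, np.deg2rad(5), np.deg2rad(24))
    c = np.array([BOND_CA_C * np.cos(theta), BOND_CA_C * np.sin(theta)])
    ca2 = np.array([d, 0.0])
    v = ca2 - c
    L = np.linalg.norm(v)
    a = (BOND_C_N**2 - BOND_N_CA**2 + L**2) / (2 * L)
    h = np.sqrt(BOND_C_N**2 - a**2)
    base = c + a * v / L
    perp = np.array([-v[1], v[0]]) / L
    n = base - h * perp
    # carbonyl O: in-plane, BOND_C_O from C, angle N-C-O = ANGLE_N_C_O
    u_n = (n - c) / np.linalg.norm(n - c)
    ang = np.deg2rad(ANGLE_N_C_O)
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    o = c + BOND_C_O * (rot @ u_n)
    if o[1] < c[1]:  # keep O on the far side from the chain axis
        rot = rot.T
        o = c + BOND_C_O * (rot @ u_n)
    return {"C": c, "O": o, "N": n}


_TEMPLATE = None


def _get_template() -> dict:
    global _TEMPLATE
    if _TEMPLATE is None:
        _TEMPLATE = _peptide_template()
    return _TEMPLATE


def _plane_frame(ca1, ca2, ref) -> tuple[np.ndarray, np.ndarray]:
    """In-plane unit axes (x along CA1->CA2, y toward ref) for the peptide."""
    x = ca2 - ca1
    x = x / np.linalg.norm(x)
    r = ref - ca1
    y = r - np.dot(r, x) * x
    norm = np.linalg.norm(y)
    if norm < 1e-6:
        y = np.array([0.0, 0.0, 1.0]) - x[2] * x
        norm = np.linalg.norm(y)
    return x, y / norm


BOND_CA_CB = 1.53
ANGLE_X_CA_CB = 110.1  # target N-CA-CB and C-CA-CB angles


def _place_cb(n, ca, c) -> np.ndarray:
    """CB at exact bond length, making equal ~110 deg angles with N and C.

    Built in the (bisector, normal) frame of the N-CA-C angle so the bond
    length holds regardless of the emergent N-CA-C angle.
    """
    d1 = (n - ca) / np.linalg.norm(n - ca)
    d2 = (c - ca) / np.linalg.norm(c - ca)
    u = d1 + d2
    u /= np.linalg.norm(u)
    v = np.cross(d1, d2)
    v /= np.linalg.norm(v)
    half = np.arccos(np.clip(np.dot(d1, d2), -1, 1)) / 2.0
    a = -np.cos(np.deg2rad(ANGLE_X_CA_CB)) / max(np.cos(half), 1e-6)
    a = min(a, 1.0)
    b = np.sqrt(max(1.0 - a * a, 0.0))
    direction = -u * a + v * b
    return ca + BOND_CA_CB * direction / np.linalg.norm(direction)


def build_all_atom(model: ThreadedModel, gap_distance: float = GAP_DISTANCE) -> ThreadedModel:
    """Place backbone N, C, O and CB from consecutive CA triplets.

    Residues adjacent to a CA-CA gap longer than ``gap_distance`` keep only
    their CA (the gap is flagged); glycines get no CB. No refinement is
    performed.
    """
    coords = model.ca_coords
    n_res = len(coords)
    template = _get_template()
    atoms: list[AtomRecord] = []
    gaps = np.zeros(n_res, dtype=bool)
    d = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    for i, dist in enumerate(d):
        if dist > gap_distance:
            gaps[i] = gaps[i + 1] = True

    # peptide-unit atoms, keyed by residue index
    placed_n: dict[int, np.ndarray] = {}
    placed_c: dict[int, np.ndarray] = {}
    placed_o: dict[int, np.ndarray] = {}
    for i in range(n_res - 1):
        if gaps[i] or gaps[i + 1]:
            continue
        ca1, ca2 = coords[i], coords[i + 1]
        ref = coords[i - 1] if i > 0 else coords[min(i + 2, n_res - 1)]
        x, y = _plane_frame(ca1, ca2, ref)
        to_world = lambda p2: ca1 + p2[0] * x + p2[1] * y
        placed_c[i] = to_world(template["C"])
        placed_o[i] = to_world(template["O"])
        placed_n[i + 1] = ca2 + (
            (template["N"][0] - TARGET_CA_CA) * x + template["N"][1] * y
        )

    for i in range(n_res):
        res_name = three_letter(model.sequence[i])
        ca = coords[i]
        records = [("CA", ca)]
        if not gaps[i]:
            n_pos = placed_n.get(i)
            c_pos = placed_c.get(i)
            if n_pos is None and c_pos is not None and i + 1 < n_res:
                # chain start: mirror the N from the outgoing peptide frame
                x, y = _plane_frame(ca, coords[i + 1], coords[min(i + 2, n_res - 1)])
                n_pos = ca - BOND_N_CA * (0.5 * x + 0.7 * y) / np.linalg.norm(
                    0.5 * x + 0.7 * y
                )
            if n_pos is not None:
                records.insert(0, ("N", n_pos))
            if c_pos is not None:
                records.append(("C", c_pos))
                records.append(("O", placed_o[i]))
            if model.sequence[i] != "G" and n_pos is not None and c_pos is not None:
                records.append(("CB", _place_cb(n_pos, ca, c_pos)))
        for name, xyz in records:
            atoms.append(
                AtomRecord(
                    name=name,
                    res_name=res_name,
                    chain="A",
                    res_seq=i + 1,
                    xyz=np.asarray(xyz, dtype=float),
                    element=name[0],
                )
            )
    return ThreadedModel(
        path=model.path,
        sequence=model.sequence,
        direction=model.direction,
        direction_score=model.direction_score,
        reverse_score=model.reverse_score,
        atoms=atoms,
    )


def write_model_pdb(model: ThreadedModel, path) -> None:
    """Write a threaded model; falls back to CA-only records if no atoms built."""
    if model.atoms:
        write_pdb(model.atoms, path)
        return
    atoms = [
        AtomRecord(
            name="CA",
            res_name=three_letter(model.sequence[i]),
            chain="A",
            res_seq=i + 1,
            xyz=xyz,
            element="C",
        )
        for i, xyz in enumerate(model.ca_coords)
    ]
    write_pdb(atoms, path)
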