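"""Geometry-based pocket detection, comparison, calibration and clustering.

Detection is a grid scan in the protein-solvent-protein (PSP) style:
empty grid points are kept when at least ``psp_min`` of 7 scan directions
(3 axes + 4 body diagonals) are blocked by protein on both sides within
10 A; connected components of such points are pockets.  The grid lives in
a canonical frame (centroid origin, principal axes) so pocket counts and
volumes are invariant under rigid transforms of the structure.

Pockets are compared with a PS-like score

    score = (aligned fraction) x 1 / (1 + (rmsd / 2 A)^2)
            x (chemical-class agreement fraction)

maximised over residue correspondences; p-values come from the shared
background calibration (:mod:`foldfunc.calibration`), and representative
pockets from greedy leader clustering.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numba
import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from foldfunc import chem
from foldfunc.calibration import TailCalibrator
from foldfunc.structure import Structure, _kabsch_nb

_CLASS_ID = {c: i for i, c in enumerate(
    ("hydrophobic", "aromatic", "polar", "positive", "negative", "special"))}

DEFAULT_GRID_SPACING = 1.0   # A
DEFAULT_PSP_MIN = 5          # of 7 scan directions
DEFAULT_MIN_POINTS = 30      # grid points per pocket
DEFAULT_ATOM_RADIUS = 2.8    # A, protein occupancy radius around CA/CB
SCAN_RANGE = 10.0            # A, how far a blocking wall may be
LINING_CUTOFF = 5.0          # A, residue-to-grid-point distance

_SCAN_DIRECTIONS = np.array([
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
])


@dataclasses.dataclass
class Pocket:
    """A detected cavity: grid points, volume and lining residues."""

    grid_points: np.ndarray          # (m, 3), original frame
    spacing: float
    centroid: np.ndarray
    volume: float                    # A^3 = m * spacing^3
    lining_indices: tuple[int, ...]  # flat residue indices in the source
    lining_names: tuple[str, ...]
    lining_coords: np.ndarray        # (k, 3) interaction coordinates
    source_label: str = ""

    @property
    def n_lining(self) -> int:
        return len(self.lining_indices)


@dataclasses.dataclass
class PocketMatch:
    """Best correspondence between two pockets under the PS-like score."""

    ps_like_score: float
    aligned_pairs: list[tuple[int, int]]   # indices into the lining lists
    rmsd: float
    p_value: float | None = None


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _canonical_frame(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(rotation, centroid): x_canonical = R (x - centroid).

    Principal axes of the C-alpha cloud with signs fixed by the third
    moment, making the frame equivariant under rigid transforms.
    """
    c = ca.mean(axis=0)
    x = ca - c
    cov = x.T @ x / len(x)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    axes = v[:, order]
    for k in range(3):
        m3 = np.sum((x @ axes[:, k]) ** 3)
        if m3 < 0:
            axes[:, k] = -axes[:, k]
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    return axes.T, c


def _shifted_or(acc: np.ndarray, occ: np.ndarray, off: tuple[int, int, int]) -> None:
    """acc |= occ shifted by off (zero fill), in place."""
    sl_a = []
    sl_o = []
    for d, n in zip(off, occ.shape):
        if d >= 0:
            sl_a.append(slice(d, n))
            sl_o.append(slice(0, n - d))
        else:
            sl_a.append(slice(0, n + d))
            sl_o.append(slice(-d, n))
    acc[tuple(sl_a)] |= occ[tuple(sl_o)]


def detect_pockets(s: Structure, grid_spacing: float = DEFAULT_GRID_SPACING,
                   psp_min: int = DEFAULT_PSP_MIN,
                   min_points: int = DEFAULT_MIN_POINTS,
                   atom_radius: float = DEFAULT_ATOM_RADIUS) -> list[Pocket]:
    """Detect pockets by PSP grid scanning; sorted by volume descending."""
    if s.n_residues == 0:
        return []
    if not (0.5 <= grid_spacing <= 2.0):
        raise ValueError("grid_spacing must be in [0.5, 2.0] A")
    ca = s.ca_coords()
    inter = s.interaction_coords()
    atoms_orig = np.vstack([ca, inter])
    R, c = _canonical_frame(ca)
    atoms = (atoms_orig - c) @ R.T
    margin = 2.0 * grid_spacing
    lo = atoms.min(axis=0) - margin
    hi = atoms.max(axis=0) + margin
    shape = np.maximum(np.ceil((hi - lo) / grid_spacing).astype(int) + 1, 1)
    # occupancy: grid points within atom_radius of any atom
    axes = [lo[d] + grid_spacing * np.arange(shape[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    tree = cKDTree(atoms)
    occ = (tree.query(pts, k=1, distance_upper_bound=atom_radius)[0]
           < atom_radius).reshape(tuple(shape))

    k_axis = int(np.floor(SCAN_RANGE / grid_spacing))
    psp = np.zeros(tuple(shape), dtype=np.int8)
    for d in _SCAN_DIRECTIONS:
        step = np.linalg.norm(d.astype(float)) * grid_spacing
        kmax = int(np.floor(SCAN_RANGE / step))
        blocked_plus = np.zeros_like(occ)
        blocked_minus = np.zeros_like(occ)
        for k in range(1, kmax + 1):
            _shifted_or(blocked_plus, occ, tuple(-k * d))
            _shifted_or(blocked_minus, occ, tuple(k * d))
        psp += (blocked_plus & blocked_minus).astype(np.int8)
    pocket_mask = (~occ) & (psp >= psp_min)
    labels, n_comp = ndimage.label(pocket_mask, structure=np.ones((3, 3, 3), int))
    pockets: list[Pocket] = []
    res_tree = cKDTree(inter)
    names = s.residue_names()
    for comp in range(1, n_comp + 1):
        idx = np.argwhere(labels == comp)
        if len(idx) < min_points:
            continue
        grid_canon = lo + idx * grid_spacing
        grid = grid_canon @ R + c       # back to the original frame
        gtree = cKDTree(grid)
        near = gtree.query(inter, k=1)[0] <= LINING_CUTOFF
        lining = [int(i) for i in np.flatnonzero(near)]
        pockets.append(Pocket(
            grid_points=grid,
            spacing=grid_spacing,
            centroid=grid.mean(axis=0),
            volume=len(grid) * grid_spacing ** 3,
            lining_indices=tuple(lining),
            lining_names=tuple(names[i] for i in lining),
            lining_coords=inter[lining],
            source_label=s.label,
        ))
    pockets.sort(key=lambda p: (-p.volume, tuple(np.round(p.centroid, 6))))
    return pockets


def largest_pocket(s: Structure, **kwargs) -> Pocket | None:
    """The maximal-volume pocket, or None when no pocket is detected."""
    pockets = detect_pockets(s, **kwargs)
    return pockets[0] if pockets else None


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------

@numba.njit(cache=False)
def _prefix_rmsd(P: np.ndarray, Q: np.ndarray) -> np.ndarray:  # pragma: no cover
    """Optimal-superposition RMSD of every prefix P[:k] vs Q[:k], k >= 3.

    Incremental sums plus the closed-form minimum
    sum |p - pc|^2 + sum |q - qc|^2 - 2 (s1 + s2 +/- s3).
    """
    n = P.shape[0]
    out = np.full(n + 1, np.inf)
    sp = np.zeros(3)
    sq = np.zeros(3)
    C = np.zeros((3, 3))
    spp = 0.0
    sqq = 0.0
    for m in range(n):
        p = P[m]
        q = Q[m]
        sp += p
        sq += q
        for u in range(3):
            for v in range(3):
                C[u, v] += p[u] * q[v]
        spp += p[0] * p[0] + p[1] * p[1] + p[2] * p[2]
        sqq += q[0] * q[0] + q[1] * q[1] + q[2] * q[2]
        k = m + 1
        if k >= 3:
            pc = sp / k
            qc = sq / k
            Cc = np.empty((3, 3))
            for u in range(3):
                for v in range(3):
                    Cc[u, v] = C[u, v] - k * pc[u] * qc[v]
            U, S, Vt = np.linalg.svd(Cc)
            d = np.sign(np.linalg.det(Vt.T @ U.T))
            vp = spp - k * (pc[0] ** 2 + pc[1] ** 2 + pc[2] ** 2)
            vq = sqq - k * (qc[0] ** 2 + qc[1] ** 2 + qc[2] ** 2)
            e2 = vp + vq - 2.0 * (S[0] + S[1] + d * S[2])
            if e2 < 0.0:
                e2 = 0.0
            out[k] = np.sqrt(e2 / k)
    return out


def _search_direction(a: Pocket, b: Pocket, n_random_seeds: int = 8,
                      max_iter: int = 8) -> tuple[float, list[tuple[int, int]], float]:
    """ICP/assignment search for the best correspondence of a onto b."""
    pa = a.lining_coords - a.lining_coords.mean(axis=0)
    pb = b.lining_coords - b.lining_coords.mean(axis=0)
    na, nb = len(pa), len(pb)
    nmax = max(a.n_lining, b.n_lining)
    class_a = np.array([_CLASS_ID[chem.CHEMICAL_CLASS[n]] for n in a.lining_names])
    class_b = np.array([_CLASS_ID[chem.CHEMICAL_CLASS[n]] for n in b.lining_names])
    agree_matrix = class_a[:, None] == class_b[None, :]
    seeds = [np.eye(3)]
    _, va = np.linalg.eigh(pa.T @ pa)
    _, vb = np.linalg.eigh(pb.T @ pb)
    for sx in (1.0, -1.0):
        for sy in (1.0, -1.0):
            axes = va.copy()
            axes[:, 0] *= sx
            axes[:, 1] *= sy
            if np.linalg.det(axes) < 0:
                axes[:, 2] = -axes[:, 2]
            vbp = vb if np.linalg.det(vb) > 0 else vb * np.array([1.0, 1.0, -1.0])
            seeds.append(vbp @ axes.T)   # map a's principal frame onto b's
    rng = np.random.Generator(np.random.PCG64(12345))
    from foldfunc.structure import random_rotation
    for _ in range(n_random_seeds):
        seeds.append(random_rotation(rng))
    best_score, best_pairs, best_rmsd = 0.0, [], np.inf
    ks = np.arange(0, min(na, nb) + 1)
    for R0 in seeds:
        moved = pa @ R0.T
        for it in range(max_iter):
            dist = np.linalg.norm(moved[:, None, :] - pb[None, :, :], axis=2)
            # two assignment flavours: pure distance, and distance with a
            # bonus for chemical-class agreement (the score rewards both)
            cost = dist if it % 2 == 0 else dist - 2.0 * agree_matrix
            ri, ci = linear_sum_assignment(cost)
            order = np.argsort(dist[ri, ci], kind="stable")
            ri = ri[order]
            ci = ci[order]
            rmsd_k = _prefix_rmsd(np.ascontiguousarray(pa[ri]),
                                  np.ascontiguousarray(pb[ci]))
            agree_k = np.concatenate(([0.0], np.cumsum(agree_matrix[ri, ci]))) \
                / np.maximum(ks[: len(ri) + 1], 1)
            frac_k = ks[: len(ri) + 1] / nmax
            score_k = frac_k / (1.0 + (rmsd_k[: len(ri) + 1] / 2.0) ** 2) * agree_k
            score_k[:3] = 0.0
            k_best = int(np.argmax(score_k))
            if k_best < 3:
                break
            score = float(score_k[k_best])
            improved = False
            if score > best_score + 1e-12:
                best_pairs = [(int(ri[m]), int(ci[m])) for m in range(k_best)]
                best_score = score
                best_rmsd = float(rmsd_k[k_best])
                improved = True
            R, t, _ = _kabsch_nb(np.ascontiguousarray(pa[ri[:k_best]]),
                                 np.ascontiguousarray(pb[ci[:k_best]]))
            if not np.all(np.isfinite(R)):
                break
            moved = pa @ R.T + t
            if not improved:
                break
    return best_score, best_pairs, best_rmsd


def _exact_small(a: Pocket, b: Pocket) -> PocketMatch:
    """Exact maximisation over all correspondences (tiny pockets only)."""
    import itertools

    na, nb = a.n_lining, b.n_lining
    nmax = max(na, nb)
    class_a = [chem.CHEMICAL_CLASS[n] for n in a.lining_names]
    class_b = [chem.CHEMICAL_CLASS[n] for n in b.lining_names]
    best = (0.0, [], np.inf)
    for k in range(3, min(na, nb) + 1):
        for sub_a in itertools.combinations(range(na), k):
            pa = np.ascontiguousarray(a.lining_coords[list(sub_a)])
            for sub_b in itertools.permutations(range(nb), k):
                pb = np.ascontiguousarray(b.lining_coords[list(sub_b)])
                _, _, rmsd = _kabsch_nb(pa, pb)
                if not np.isfinite(rmsd):
                    continue
                agree = sum(class_a[i] == class_b[j]
                            for i, j in zip(sub_a, sub_b)) / k
                score = (k / nmax) / (1.0 + (rmsd / 2.0) ** 2) * agree
                if score > best[0]:
                    best = (score, list(zip(sub_a, sub_b)), float(rmsd))
    return PocketMatch(*best)


def compare_pockets(a: Pocket, b: Pocket) -> PocketMatch:
    """Best PS-like match between two pockets (symmetric in its arguments).

    Exact enumeration for tiny pockets (both <= 6 lining residues), an
    ICP/assignment search otherwise.
    """
    if a.n_lining < 3 or b.n_lining < 3:
        raise ValueError("pockets need >= 3 lining residues to compare")
    if a.n_lining <= 6 and b.n_lining <= 6:
        return _exact_small(a, b)
    s_ab, pairs_ab, rmsd_ab = _search_direction(a, b)
    s_ba, pairs_ba, rmsd_ba = _search_direction(b, a)
    if s_ba > s_ab:
        return PocketMatch(s_ba, [(j, i) for i, j in pairs_ba], rmsd_ba)
    return PocketMatch(s_ab, pairs_ab, rmsd_ab)


# ---------------------------------------------------------------------------
# calibration and clustering
# ---------------------------------------------------------------------------

def calibrate_pocket_pvalue(background_scores: np.ndarray,
                            min_n: int = 100) -> TailCalibrator:
    """Score -> p-value map calibrated on unrelated-pair pocket scores."""
    return TailCalibrator(background_scores, min_n=min_n)


def background_pocket_scores(pockets: Sequence[Pocket], n_pairs: int,
                             seed: int = 0) -> np.ndarray:
    """PS-like scores of random cross-structure pocket pairs (the null)."""
    rng = np.random.Generator(np.random.PCG64(seed))
    usable = [p for p in pockets if p.n_lining >= 3]
    if len(usable) < 2:
        raise ValueError("need at least two comparable pockets")
    out = np.empty(n_pairs)
    k = 0
    while k < n_pairs:
        i, j = rng.choice(len(usable), size=2, replace=False)
        if usable[i].source_label and usable[i].source_label == usable[j].source_label:
            continue
        out[k] = compare_pockets(usable[i], usable[j]).ps_like_score
        k += 1
    return out


def cluster_pockets(pockets: Sequence[Pocket], score_threshold: float
                    ) -> list[Pocket]:
    """Greedy leader clustering; returns the representative pockets.

    Pockets are visited largest-volume first; one joins an existing
    representative when their PS-like score reaches the threshold,
    otherwise it becomes a new representative.
    """
    if not (0.0 < score_threshold < 1.0):
        raise ValueError("score_threshold must be in (0, 1)")
    ordered = sorted(pockets, key=lambda p: (-p.volume,
                                             tuple(np.round(p.centroid, 6))))
    reps: list[Pocket] = []
    for p in ordered:
        if not any(compare_pockets(p, r).ps_like_score >= score_threshold
                   for r in reps):
            reps.append(p)
    return reps


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_pocket(p: Pocket, pdb_path, json_path) -> None:
    """Grid points as HETATM pseudo-atoms plus a JSON sidecar."""
    lines = []
    for i, (x, y, z) in enumerate(p.grid_points, start=1):
        lines.append(
            f"HETATM{i:5d}  O   HOH P{min(i, 9999):4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           O")
    lines.append("END")
    with open(pdb_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    with open(json_path, "w") as fh:
        json.dump({
            "volume": p.volume,
            "spacing": p.spacing,
            "centroid": [float(v) for v in p.centroid],
            "lining_residues": [
                {"index": int(i), "name": n}
                for i, n in zip(p.lining_indices, p.lining_names)],
            "source": p.source_label,
        }, fh, indent=1)
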