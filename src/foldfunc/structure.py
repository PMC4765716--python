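"""Reduced-representation structures and the geometric kernel.

Every stage of the pipeline speaks one structural currency: chains of
residues carrying a 3-letter identity, a C-alpha coordinate and (except
glycine) a C-beta coordinate.  This module provides that container, PDB
round-tripping through gemmi, Kabsch superposition, the TM-score, a
TM-align-style iterative structural aligner, and the shared contact
definition (C-beta pairs within 8 A, C-alpha for glycine).

Conventions: coordinates in Angstrom, residue numbering 1-based, intervals
closed.  The TM-score of an alignment is normalised by the length of the
*second* (target) structure.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import gemmi
import numba
import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation


class FoldFuncError(Exception):
    """Base class for all package errors."""


class PDBParseError(FoldFuncError):
    """Raised when PDB content cannot be read into a reduced structure."""


class DegenerateGeometryError(FoldFuncError):
    """Raised for superposition of degenerate (collinear / too few) point sets."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Chain:
    """One polymer chain in reduced representation."""

    chain_id: str
    names: list[str]
    resseq: np.ndarray          # (n,) int, strictly increasing
    ca: np.ndarray              # (n, 3) float
    cb: np.ndarray              # (n, 3) float, NaN rows where absent (Gly)

    def __post_init__(self) -> None:
        self.resseq = np.asarray(self.resseq, dtype=int)
        self.ca = np.asarray(self.ca, dtype=float)
        self.cb = np.asarray(self.cb, dtype=float)
        n = len(self.names)
        if self.resseq.shape != (n,) or self.ca.shape != (n, 3) or self.cb.shape != (n, 3):
            raise ValueError("inconsistent chain arrays")
        if n > 1 and not np.all(np.diff(self.resseq) > 0):
            raise ValueError("residue numbers must be strictly increasing within a chain")
        if not np.all(np.isfinite(self.ca)):
            raise ValueError("non-finite C-alpha coordinates")

    def __len__(self) -> int:
        return len(self.names)

    def interaction_coords(self) -> np.ndarray:
        """C-beta coordinates with C-alpha substituted where C-beta is absent."""
        out = self.cb.copy()
        missing = ~np.isfinite(out).all(axis=1)
        out[missing] = self.ca[missing]
        return out


@dataclasses.dataclass
class Structure:
    """An ordered list of chains; the universal structural object."""

    chains: list[Chain]
    label: str = ""

    @classmethod
    def from_arrays(cls, names: Sequence[str], ca: np.ndarray,
                    cb: np.ndarray | None = None, chain_id: str = "A",
                    label: str = "") -> "Structure":
        n = len(names)
        ca = np.asarray(ca, dtype=float)
        if cb is None:
            cb = np.full((n, 3), np.nan)
        chain = Chain(chain_id, list(names), np.arange(1, n + 1), ca,
                      np.asarray(cb, dtype=float))
        return cls([chain], label=label)

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def ca_coords(self) -> np.ndarray:
        return np.vstack([c.ca for c in self.chains]) if self.chains else np.zeros((0, 3))

    def interaction_coords(self) -> np.ndarray:
        return (np.vstack([c.interaction_coords() for c in self.chains])
                if self.chains else np.zeros((0, 3)))

    def residue_names(self) -> list[str]:
        return [name for c in self.chains for name in c.names]

    def chain_index(self) -> np.ndarray:
        """Per-residue chain index (flat order)."""
        return np.concatenate([np.full(len(c), i, dtype=int)
                               for i, c in enumerate(self.chains)]) if self.chains else np.zeros(0, int)

    def within_index(self) -> np.ndarray:
        """Per-residue 0-based position within its chain (flat order)."""
        return np.concatenate([np.arange(len(c)) for c in self.chains]) if self.chains else np.zeros(0, int)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigidly transformed copy (x -> R x + t)."""
        new_chains = []
        for c in self.chains:
            new_chains.append(Chain(c.chain_id, list(c.names), c.resseq.copy(),
                                    c.ca @ rotation.T + translation,
                                    c.cb @ rotation.T + translation))
        return Structure(new_chains, label=self.label)

    def copy(self) -> "Structure":
        return Structure([Chain(c.chain_id, list(c.names), c.resseq.copy(),
                                c.ca.copy(), c.cb.copy()) for c in self.chains],
                         label=self.label)


# ---------------------------------------------------------------------------
# PDB I/O (via gemmi)
# ---------------------------------------------------------------------------

def read_structure(pdb_text: str) -> Structure:
    """Parse PDB content into a reduced structure.

    Only CA and CB atoms of ATOM records are used; everything else is
    ignored.  Insertion codes and duplicate (chain, residue, atom) entries
    are rejected; content without a single CA atom is a parse error.
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"unreadable PDB content: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError("no model in PDB content")
    model = st[0]
    chains: list[Chain] = []
    seen: set[tuple[str, int, str]] = set()
    for chain in model:
        names: list[str] = []
        resseq: list[int] = []
        ca: list[np.ndarray] = []
        cb: list[np.ndarray] = []
        for res in chain:
            if res.het_flag == "H":
                continue
            if res.seqid.icode not in (" ", "\x00", ""):
                raise PDBParseError(
                    f"insertion code {res.seqid.icode!r} at {chain.name}{res.seqid.num}")
            ca_pos = None
            cb_pos = None
            for atom in res:
                if atom.name not in ("CA", "CB"):
                    continue
                key = (chain.name, res.seqid.num, atom.name)
                if key in seen:
                    raise PDBParseError(f"duplicate atom {key}")
                seen.add(key)
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                if atom.name == "CA":
                    ca_pos = pos
                else:
                    cb_pos = pos
            if ca_pos is None:
                continue
            names.append(res.name)
            resseq.append(res.seqid.num)
            ca.append(ca_pos)
            cb.append(cb_pos if cb_pos is not None else np.full(3, np.nan))
        if not names:
            continue
        order = np.argsort(np.asarray(resseq), kind="stable")
        chains.append(Chain(chain.name,
                            [names[i] for i in order],
                            np.asarray(resseq)[order],
                            np.vstack(ca)[order],
                            np.vstack(cb)[order]))
    if not chains:
        raise PDBParseError("no CA atoms found")
    return Structure(chains, label=st.name or "")


def write_structure(s: Structure) -> str:
    """Serialise a structure as fixed-column PDB ATOM records."""
    st = gemmi.Structure()
    st.name = s.label or "foldfunc"
    model = gemmi.Model("1")
    for c in s.chains:
        gchain = gemmi.Chain(c.chain_id)
        for i, name in enumerate(c.names):
            res = gemmi.Residue()
            res.name = name
            res.seqid = gemmi.SeqId(int(c.resseq[i]), " ")
            for atom_name, coord in (("CA", c.ca[i]), ("CB", c.cb[i])):
                if not np.all(np.isfinite(coord)):
                    continue
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element("C")
                atom.pos = gemmi.Position(*coord)
                atom.occ = 1.0
                atom.b_iso = 0.0
                res.add_atom(atom)
            gchain.add_residue(res)
        model.add_chain(gchain)
    st.add_model(model)
    return st.make_pdb_string(gemmi.PdbWriteOptions(minimal=True))


# ---------------------------------------------------------------------------
# superposition and scores
# ---------------------------------------------------------------------------

def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares rigid superposition of P onto Q.

    Returns ``(R, t, rmsd)`` with ``x -> R x + t`` mapping P into Q's frame,
    R a proper rotation, and rmsd the global minimum over all rigid
    transforms.  Degenerate (fewer than 3 or collinear) point sets raise
    :class:`DegenerateGeometryError`.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise DegenerateGeometryError(f"size mismatch {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 points in 3D")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    sv = np.linalg.svd(P0, compute_uv=False)
    if sv[1] <= 1e-8 * max(1.0, sv[0]):
        raise DegenerateGeometryError("collinear point set")
    rot, _ = Rotation.align_vectors(Q0, P0)
    R = rot.as_matrix()
    t = qc - R @ pc
    # recompute from residuals: the reported rssd loses precision near zero
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return R, t, rmsd


def tm_d0(l_target: int) -> float:
    """Length-dependent TM-score distance scale; clamped at 0.5 A."""
    if l_target <= 15:
        return 0.5
    return max(0.5, 1.24 * (l_target - 15) ** (1.0 / 3.0) - 1.8)


def tm_score(distances: np.ndarray, l_target: int) -> float:
    """TM-score of an alignment given its mapped-pair distances.

    ``score = (1/L_target) * sum 1/(1 + (d_i/d0)^2)``; unmapped target
    residues contribute zero.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty mapping")
    if l_target < d.size:
        raise ValueError("L_target smaller than the mapped pair count")
    d0 = tm_d0(l_target)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_target)


# ---------------------------------------------------------------------------
# iterative structural alignment
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AlignmentResult:
    """Outcome of a structural alignment of A onto B.

    ``mapping`` holds (index-in-A, index-in-B) pairs over flat residue
    indices; ``rotation``/``translation`` map A's coordinates into B's
    frame; ``tm`` is normalised by ``l_target`` (the length of B unless
    overridden).
    """

    mapping: list[tuple[int, int]]
    rmsd: float
    tm: float
    rotation: np.ndarray
    translation: np.ndarray
    l_target: int


@numba.njit(cache=False)
def _dp_core(S: np.ndarray, gap: float):  # pragma: no cover - numba kernel
    na, nb = S.shape
    H = np.zeros((na + 1, nb + 1))
    ptr = np.zeros((na, nb), dtype=np.int8)  # 0 diag, 1 up, 2 left
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            best = H[i - 1, j - 1] + S[i - 1, j - 1]
            p = 0
            up = H[i - 1, j] + gap
            if up > best:
                best = up
                p = 1
            left = H[i, j - 1] + gap
            if left > best:
                best = left
                p = 2
            H[i, j] = best
            ptr[i - 1, j - 1] = p
    return H, ptr


def _dp_trace(S: np.ndarray, gap: float) -> list[tuple[int, int]]:
    """Semi-global DP (free terminal gaps) maximising sum of S minus gaps.

    Ties broken diagonal > up > left, toward lower residue indices.
    """
    na, nb = S.shape
    H, ptr = _dp_core(np.ascontiguousarray(S, dtype=np.float64), float(gap))
    # free end gaps: start traceback at the best cell on the last row/column
    best = (na, int(np.argmax(H[na])))
    if np.max(H[:, nb]) > H[best[0], best[1]]:
        best = (int(np.argmax(H[:, nb])), nb)
    i, j = best
    pairs: list[tuple[int, int]] = []
    while i > 0 and j > 0:
        p = ptr[i - 1, j - 1]
        if p == 0:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif p == 1:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


@numba.njit(cache=False)
def _kabsch_nb(P: np.ndarray, Q: np.ndarray):  # pragma: no cover - numba kernel
    n = P.shape[0]
    pc = np.zeros(3)
    qc = np.zeros(3)
    for i in range(n):
        pc += P[i]
        qc += Q[i]
    pc /= n
    qc /= n
    P0 = P - pc
    Q0 = Q - qc
    Hm = P0.T @ Q0
    U, _, Vt = np.linalg.svd(Hm)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.eye(3)
    D[2, 2] = d
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    sq = 0.0
    for i in range(n):
        r = R @ P[i] + t - Q[i]
        sq += r[0] * r[0] + r[1] * r[1] + r[2] * r[2]
    return R, t, np.sqrt(sq / n)


def _score_mapping(ca_a: np.ndarray, ca_b: np.ndarray,
                   pairs: Sequence[tuple[int, int]], l_target: int
                   ) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Superpose on the mapped pairs and evaluate (tm, rmsd, R, t)."""
    if len(pairs) < 3:
        return 0.0, np.inf, np.eye(3), np.zeros(3)
    idx = np.asarray(pairs, dtype=np.int64)
    pa = ca_a[idx[:, 0]]
    pb = ca_b[idx[:, 1]]
    R, t, rmsd = _kabsch_nb(pa, pb)
    if not np.isfinite(rmsd):
        return 0.0, np.inf, np.eye(3), np.zeros(3)
    d = np.linalg.norm(pa @ R.T + t - pb, axis=1)
    return tm_score(d, l_target), rmsd, R, t


def structural_align(A: Structure, B: Structure, gap: float = -0.6,
                     max_iter: int = 20, l_target: int | None = None,
                     seed_stride: int | None = None,
                     thorough: bool = False) -> AlignmentResult:
    """TM-align-style iterative alignment of A onto B.

    Seeds rigid superpositions from gapless offset alignments (plus, in
    thorough mode, every 3-residue fragment-pair superposition), then
    iterates {superpose on current mapping -> rebuild the mapping by
    dynamic programming on the TM-score similarity matrix} until the
    mapping repeats or ``max_iter`` rounds.  Deterministic; the returned
    TM-score is the best over every seed and iteration, so it is never
    below the best single-seed rigid superposition.  ``thorough`` trades
    speed for exhaustiveness and suits small problems only.
    """
    ca_a = A.ca_coords()
    ca_b = B.ca_coords()
    na, nb = len(ca_a), len(ca_b)
    if na < 3 or nb < 3:
        raise ValueError("structures too small to align")
    lt = l_target if l_target is not None else nb
    d0 = tm_d0(lt)

    # seed mappings: gapless alignments at a set of offsets, plus short
    # fragment-pair superpositions
    nmin = min(na, nb)
    stride = seed_stride if seed_stride is not None else max(1, nmin // 4)
    seeds: list[list[tuple[int, int]]] = []
    for off in range(-(na - 3), nb - 2, stride):
        lo_a = max(0, -off)
        lo_b = max(0, off)
        length = min(na - lo_a, nb - lo_b)
        if length >= 3:
            seeds.append([(lo_a + k, lo_b + k) for k in range(length)])
    if thorough:
        frag = 3
        fstride = 1
    else:
        frag = min(8, nmin)
        fstride = max(1, (nmin - frag) // 2) if nmin > frag else 1
    n_deep = len(seeds)   # offset seeds get the full iteration budget
    for ia0 in range(0, na - frag + 1, fstride):
        for ib0 in range(0, nb - frag + 1, fstride):
            seeds.append([(ia0 + k, ib0 + k) for k in range(frag)])

    best = AlignmentResult([], np.inf, -1.0, np.eye(3), np.zeros(3), lt)
    for s_idx, seed_pairs in enumerate(seeds):
        pairs = seed_pairs
        prev: set[tuple[int, int]] | None = None
        budget = max_iter if (not thorough or s_idx < n_deep) else 2
        for _ in range(budget):
            tm, rmsd, R, t = _score_mapping(ca_a, ca_b, pairs, lt)
            if tm > best.tm:
                best = AlignmentResult(list(pairs), rmsd, tm, R, t, lt)
            if not np.isfinite(rmsd):
                break
            moved = ca_a @ R.T + t
            dist2 = np.sum((moved[:, None, :] - ca_b[None, :, :]) ** 2, axis=2)
            S = 1.0 / (1.0 + dist2 / d0 ** 2)
            pairs = _dp_trace(S, gap)
            key = set(pairs)
            if prev is not None and key == prev:
                tm, rmsd, R, t = _score_mapping(ca_a, ca_b, pairs, lt)
                if tm > best.tm:
                    best = AlignmentResult(list(pairs), rmsd, tm, R, t, lt)
                break
            prev = key
    return best


# ---------------------------------------------------------------------------
# geometry statistics and the shared contact definition
# ---------------------------------------------------------------------------

CONTACT_CUTOFF = 8.0       # A, C-beta/C-beta (C-alpha for Gly)
MIN_SEQ_SEPARATION = 3     # |i-j| >= 3 for intra-chain contacts


def radius_of_gyration(coords: np.ndarray) -> float:
    c = np.asarray(coords, dtype=float)
    centered = c - c.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered ** 2, axis=1))))


def contact_pairs(s: Structure, cutoff: float = CONTACT_CUTOFF,
                  min_sep: int = MIN_SEQ_SEPARATION) -> list[tuple[int, int]]:
    """Residue-residue contacts over flat indices (i < j).

    A contact is a C-beta pair (C-alpha for Gly) within ``cutoff``;
    intra-chain pairs additionally require sequence separation >= ``min_sep``.
    """
    coords = s.interaction_coords()
    if len(coords) == 0:
        return []
    chain_idx = s.chain_index()
    within = s.within_index()
    tree = cKDTree(coords)
    out = []
    for i, j in sorted(tree.query_pairs(cutoff)):
        if chain_idx[i] == chain_idx[j] and abs(int(within[i]) - int(within[j])) < min_sep:
            continue
        out.append((i, j))
    return out


def geometry_stats(s: Structure) -> tuple[float, list[tuple[int, int]]]:
    """Radius of gyration over C-alpha plus the residue contact list."""
    return radius_of_gyration(s.ca_coords()), contact_pairs(s)


def contact_numbers(s: Structure) -> np.ndarray:
    """Per-residue contact counts (burial proxy)."""
    n = s.n_residues
    counts = np.zeros(n, dtype=int)
    for i, j in contact_pairs(s):
        counts[i] += 1
        counts[j] += 1
    return counts


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    return Rotation.random(rng=rng).as_matrix()
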