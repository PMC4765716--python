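"""Synthetic-data generators: every input the analysis pipeline consumes.

This module emulates, at desk scale, the reference data a full study
would pull from structural and chemical databases:

* compact single-domain C-alpha/C-beta backbones of 40-250 residues,
  built by fragment assembly (ideal helix / strand / loop pieces) followed
  by Metropolis compaction and a constraint-projection polish;
* protein-like sequences selected for a stability proxy (Metropolis
  minimisation of the packaged residue-contact potential at fixed
  composition);
* planted catalytic constellations and cavities (test fixtures with a
  known ground truth);
* native-like dimer templates and ideal-B-DNA/protein complex templates;
* a toy ligand/pathway universe of fingerprint bitstrings with optional
  planted binding preferences.

Every generator is a pure function of its explicit seed; no global
random state is touched.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from foldfunc import chem
from foldfunc.structure import (
    FoldFuncError,
    Structure,
    kabsch_superpose,
    radius_of_gyration,
    random_rotation,
)


class GenerationError(FoldFuncError):
    """Raised when a generator cannot satisfy its constraints within budget."""


class PlantError(FoldFuncError):
    """Raised when a site constellation cannot be planted without clashes."""


class DockingError(FoldFuncError):
    """Raised when rigid docking cannot reach the requested contact count."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

BOND_LENGTH = 3.8  # A, consecutive C-alpha


@dataclasses.dataclass
class GeneratorConfig:
    """Parameters of the compact-backbone generator.

    ``compactness_coefficient`` bounds the radius of gyration at
    ``coefficient * N^(1/3)`` Angstrom; ``min_separation`` is the hard
    self-avoidance distance for non-adjacent residue pairs.
    """

    n_residues: int
    seed: int
    compactness_coefficient: float = 2.5
    min_separation: float = 4.0
    fragment_mix: tuple[float, float, float] = (0.45, 0.25, 0.30)
    mc_steps: int = 4000
    temperature_schedule: tuple[float, ...] = (2.0, 0.8, 0.3, 0.1, 0.03)
    max_attempts: int = 10

    def __post_init__(self) -> None:
        if not (40 <= self.n_residues <= 250):
            raise ValueError("n_residues must be in [40, 250]")
        if abs(sum(self.fragment_mix) - 1.0) > 1e-6:
            raise ValueError("fragment_mix must sum to 1")
        if self.min_separation <= 0 or self.compactness_coefficient <= 0:
            raise ValueError("geometric parameters must be positive")

    @property
    def rg_max(self) -> float:
        return self.compactness_coefficient * self.n_residues ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# fragment assembly
# ---------------------------------------------------------------------------

_HELIX_RADIUS = 3.4914 / (2.0 * math.sin(math.radians(50.0)))  # exact 3.8 A bond
_HELIX_RISE = 1.5
_HELIX_TWIST = math.radians(100.0)
_STRAND_RISE = 3.3
_STRAND_OFFSET = math.sqrt(BOND_LENGTH ** 2 - _STRAND_RISE ** 2) / 2.0


def _helix_fragment(length: int) -> np.ndarray:
    k = np.arange(length)
    pts = np.column_stack([
        _HELIX_RADIUS * np.cos(_HELIX_TWIST * k),
        _HELIX_RADIUS * np.sin(_HELIX_TWIST * k),
        _HELIX_RISE * k,
    ])
    return pts - pts[0]


def _strand_fragment(length: int) -> np.ndarray:
    k = np.arange(length)
    pts = np.column_stack([
        _STRAND_OFFSET * (-1.0) ** k,
        np.zeros(length),
        _STRAND_RISE * k,
    ])
    return pts - pts[0]


def _loop_fragment(length: int, rng: np.random.Generator) -> np.ndarray:
    pts = [np.zeros(3)]
    d = np.array([0.0, 0.0, 1.0])
    for _ in range(length - 1):
        # direction change <= 110 deg keeps |i, i+2| above 4 A
        bend = rng.uniform(math.radians(15.0), math.radians(105.0))
        azim = rng.uniform(0.0, 2.0 * math.pi)
        perp = np.cross(d, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(d, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        perp2 = np.cross(d, perp)
        d = (math.cos(bend) * d
             + math.sin(bend) * (math.cos(azim) * perp + math.sin(azim) * perp2))
        d /= np.linalg.norm(d)
        pts.append(pts[-1] + BOND_LENGTH * d)
    return np.asarray(pts)


def _assemble_fragments(config: GeneratorConfig, rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Initial chain from concatenated ideal fragments.

    Returns (coords, flexible_mask): flexible positions are loop residues
    and fragment junctions, the only pivot points of the compaction moves.
    """
    n = config.n_residues
    coords: list[np.ndarray] = []
    flexible = np.zeros(n, dtype=bool)
    while len(coords) < n:
        kind = rng.choice(3, p=config.fragment_mix)
        if kind == 0:
            length = int(rng.integers(6, 13))
            frag = _helix_fragment(length)
        elif kind == 1:
            length = int(rng.integers(4, 9))
            frag = _strand_fragment(length)
        else:
            length = int(rng.integers(2, 6))
            frag = _loop_fragment(length, rng)
        length = min(length, n - len(coords))
        frag = frag[:length]
        rot = random_rotation(rng)
        frag = frag @ rot.T
        if not coords:
            coords.extend(frag)
        else:
            start = len(coords)
            end = coords[-1]
            last_dir = (end - coords[-2]) if len(coords) > 1 else np.array([0.0, 0.0, 1.0])
            last_dir = last_dir / max(np.linalg.norm(last_dir), 1e-9)
            for _ in range(40):
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
                if np.dot(d, last_dir) > -0.4:
                    break
            first = end + BOND_LENGTH * d
            shifted = frag + first
            # local self-avoidance across the junction
            tail = np.asarray(coords[-4:])
            head = shifted[: min(4, len(shifted))]
            dmin = np.min(np.linalg.norm(tail[:, None] - head[None, :], axis=2))
            if dmin < 3.5:
                continue
            coords.extend(shifted)
            flexible[start - 1: start + 1] = True
        if kind == 2:
            flexible[max(0, len(coords) - length): len(coords)] = True
    x = np.asarray(coords[:n])
    flexible[0] = flexible[-1] = False
    return x, flexible


# ---------------------------------------------------------------------------
# compaction (Metropolis) and constraint projection
# ---------------------------------------------------------------------------

def _soft_energy(x: np.ndarray, rg_target: float, min_sep: float) -> float:
    rg = radius_of_gyration(x)
    e = 5.0 * max(0.0, rg - rg_target) ** 2
    d = pdist(x)
    n = len(x)
    # mask out consecutive pairs (|i-j| == 1)
    iu = np.triu_indices(n, k=1)
    nonadj = (iu[1] - iu[0]) >= 2
    close = d[nonadj]
    viol = min_sep - close
    e += float(np.sum(np.square(viol[viol > 0.0])))
    return e


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / max(np.linalg.norm(axis), 1e-12)
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def _compact(x: np.ndarray, flexible: np.ndarray, config: GeneratorConfig,
             rng: np.random.Generator) -> np.ndarray:
    n = len(x)
    rg_target = 0.95 * config.rg_max
    min_sep = config.min_separation
    flex_idx = np.flatnonzero(flexible)
    if flex_idx.size == 0:
        flex_idx = np.arange(1, n - 1)
    x = x.copy()
    e = _soft_energy(x, rg_target, min_sep)
    sched = np.asarray(config.temperature_schedule, dtype=float)
    for step in range(config.mc_steps):
        frac = step / max(1, config.mc_steps - 1)
        pos = frac * (len(sched) - 1)
        lo = int(pos)
        hi = min(lo + 1, len(sched) - 1)
        temp = sched[lo] * (sched[hi] / sched[lo]) ** (pos - lo)
        k = int(rng.choice(flex_idx))
        angle = rng.normal(0.0, 0.8)
        new = x.copy()
        if rng.random() < 0.65 or k >= n - 2:
            # pivot: rotate the tail about a random axis through x[k]
            rot = _axis_rotation(rng.normal(size=3), angle)
            new[k + 1:] = (new[k + 1:] - new[k]) @ rot.T + new[k]
        else:
            # crankshaft between k and a second flexible point
            j_candidates = flex_idx[(flex_idx > k) & (flex_idx <= k + 20)]
            if j_candidates.size == 0:
                continue
            j = int(rng.choice(j_candidates))
            if j - k < 2:
                continue
            axis = new[j] - new[k]
            if np.linalg.norm(axis) < 1e-6:
                continue
            rot = _axis_rotation(axis, angle)
            new[k + 1: j] = (new[k + 1: j] - new[k]) @ rot.T + new[k]
        e_new = _soft_energy(new, rg_target, min_sep)
        if e_new <= e or rng.random() < math.exp(-(e_new - e) / max(temp, 1e-9)):
            x, e = new, e_new
        if e == 0.0:
            break
    return x


def backbone_violations(x: np.ndarray, rg_max: float, min_sep: float = 4.0,
                        bond: float = BOND_LENGTH, bond_tol: float = 0.1
                        ) -> list[str]:
    """Hard-constraint report: empty list means a valid compact backbone."""
    out = []
    bonds = np.linalg.norm(np.diff(x, axis=0), axis=1)
    if np.any(np.abs(bonds - bond) > bond_tol):
        out.append(f"bond length outside {bond}+/-{bond_tol}")
    d = squareform(pdist(x))
    n = len(x)
    iu = np.triu_indices(n, k=2)
    if np.any(d[iu] < min_sep):
        out.append("self-avoidance violated")
    if radius_of_gyration(x) > rg_max:
        out.append("radius of gyration above bound")
    return out


def _project_constraints(x: np.ndarray, rg_max: float, min_sep: float,
                         frozen: np.ndarray | None = None,
                         max_sweeps: int = 400) -> np.ndarray:
    """Jacobi-style projection onto {bonds, self-avoidance, compactness}.

    Frozen positions (planted site anchors) are never moved; the sweep
    aims slightly inside each constraint so the hard checks pass with
    margin.
    """
    x = x.copy()
    n = len(x)
    free = np.ones(n, dtype=bool)
    if frozen is not None:
        free[frozen] = False
    for _ in range(max_sweeps):
        # compactness
        rg = radius_of_gyration(x)
        if rg > 0.985 * rg_max:
            c = x.mean(axis=0)
            scale = 0.98 * rg_max / rg
            shrunk = c + (x - c) * scale
            x[free] = shrunk[free]
        # self-avoidance
        tree = cKDTree(x)
        moved = np.zeros_like(x)
        n_clash = 0
        for i, j in tree.query_pairs(min_sep + 0.02):
            if j - i < 2:
                continue
            v = x[j] - x[i]
            dist = np.linalg.norm(v)
            if dist < 1e-9:
                v = np.array([min_sep, 0.0, 0.0])
                dist = 1e-9
            push = 0.55 * (min_sep + 0.05 - dist)
            u = v / dist
            n_clash += 1
            if free[i] and free[j]:
                moved[i] -= push * 0.5 * u
                moved[j] += push * 0.5 * u
            elif free[i]:
                moved[i] -= push * u
            elif free[j]:
                moved[j] += push * u
        x += moved
        # bonds
        vec = np.diff(x, axis=0)
        dist = np.linalg.norm(vec, axis=1)
        err = dist - BOND_LENGTH
        bad = np.abs(err) > 0.05
        for i in np.flatnonzero(bad):
            u = vec[i] / max(dist[i], 1e-9)
            corr = err[i]
            if free[i] and free[i + 1]:
                x[i] += 0.5 * corr * u
                x[i + 1] -= 0.5 * corr * u
            elif free[i + 1]:
                x[i + 1] -= corr * u
            elif free[i]:
                x[i] += corr * u
        if n_clash == 0 and not np.any(np.abs(np.linalg.norm(np.diff(x, axis=0), axis=1)
                                              - BOND_LENGTH) > 0.05):
            if radius_of_gyration(x) <= 0.995 * rg_max:
                break
    return x


# ---------------------------------------------------------------------------
# C-beta placement
# ---------------------------------------------------------------------------

CB_LENGTH = 1.53  # A


def place_cb(ca: np.ndarray, names: Sequence[str]) -> np.ndarray:
    """Pseudo C-beta at 1.53 A along a tetrahedral-like direction.

    Built from the local C-alpha trace: the out-of-plane tilt of the
    bisector of the two backbone bond directions.  Glycine rows are NaN.
    """
    n = len(ca)
    cb = np.full((n, 3), np.nan)
    for i in range(n):
        if names[i] == "GLY":
            continue
        if 0 < i < n - 1:
            u1 = ca[i - 1] - ca[i]
            u2 = ca[i + 1] - ca[i]
        elif i == 0 and n > 1:
            u1 = ca[1] - ca[0]
            u2 = u1
        elif i == n - 1 and n > 1:
            u1 = ca[n - 2] - ca[n - 1]
            u2 = u1
        else:
            cb[i] = ca[i] + np.array([CB_LENGTH, 0.0, 0.0])
            continue
        u1 = u1 / max(np.linalg.norm(u1), 1e-9)
        u2 = u2 / max(np.linalg.norm(u2), 1e-9)
        normal = np.cross(u1, u2)
        if np.linalg.norm(normal) < 1e-6:
            normal = np.cross(u1, [1.0, 0.0, 0.0])
            if np.linalg.norm(normal) < 1e-6:
                normal = np.cross(u1, [0.0, 1.0, 0.0])
        normal = normal / np.linalg.norm(normal)
        bis = -(u1 + u2)
        nb = np.linalg.norm(bis)
        bis = bis / nb if nb > 1e-6 else normal
        direction = 0.5757 * bis + 0.8177 * normal
        direction /= np.linalg.norm(direction)
        cb[i] = ca[i] + CB_LENGTH * direction
    return cb


# ---------------------------------------------------------------------------
# backbone generation
# ---------------------------------------------------------------------------

def generate_compact_backbone(config: GeneratorConfig) -> Structure:
    """Generate one compact self-avoiding C-alpha backbone.

    Fragment assembly, Metropolis compaction and constraint projection;
    retries with derived sub-seeds.  The result satisfies consecutive
    C-alpha distances of 3.8 +/- 0.1 A, non-adjacent separations of at
    least ``min_separation`` and Rg <= coefficient * N^(1/3), or a
    :class:`GenerationError` is raised (never a silently loose structure).
    """
    base = np.random.SeedSequence(config.seed)
    for attempt_seq in base.spawn(config.max_attempts):
        rng = np.random.Generator(np.random.PCG64(attempt_seq))
        x, flexible = _assemble_fragments(config, rng)
        x = _compact(x, flexible, config, rng)
        x = _project_constraints(x, config.rg_max, config.min_separation)
        if not backbone_violations(x, config.rg_max, config.min_separation):
            names = ["ALA"] * config.n_residues
            cb = place_cb(x, names)
            s = Structure.from_arrays(names, x, cb, chain_id="A",
                                      label=f"bb{config.seed}")
            return s
    raise GenerationError(
        f"could not generate a valid backbone for seed {config.seed} "
        f"within {config.max_attempts} attempts")


# ---------------------------------------------------------------------------
# sequence design (stability proxy)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DesignResult:
    """A designed sequence with its recorded contact energies."""

    structure: Structure
    initial_energy: float
    final_energy: float


def _composition_counts(composition: Mapping[str, float], n: int) -> list[str]:
    """Deterministic multiset of n residues matching a composition."""
    if not composition:
        raise ValueError("empty composition")
    total = sum(composition.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError("composition must sum to 1")
    aas = sorted(composition)
    raw = {aa: composition[aa] * n for aa in aas}
    counts = {aa: int(math.floor(raw[aa])) for aa in aas}
    remainder = n - sum(counts.values())
    by_frac = sorted(aas, key=lambda aa: (-(raw[aa] - counts[aa]), aa))
    for aa in by_frac[:remainder]:
        counts[aa] += 1
    out: list[str] = []
    for aa in aas:
        out.extend([aa] * counts[aa])
    return out


def sequence_energy(names: Sequence[str], contacts: Sequence[tuple[int, int]]) -> float:
    """Total contact energy of a sequence on a fixed backbone."""
    return float(sum(chem.contact_energy(names[i], names[j]) for i, j in contacts))


def design_stable_sequence(backbone: Structure,
                           composition: Mapping[str, float] | None = None,
                           mc_steps: int = 10000, seed: int = 0,
                           frozen: Mapping[int, str] | None = None
                           ) -> DesignResult:
    """Select a sequence for the stability proxy at fixed composition.

    Metropolis swap moves of residue identities on the fixed backbone,
    minimising the packaged contact potential under a decreasing
    temperature schedule; swap moves preserve the composition counts
    exactly.  ``frozen`` maps flat residue indices to identities held
    fixed (used for the frozen-catalytic-residue protocol); frozen
    positions never move.  With ``mc_steps=0`` the initial random
    sequence is returned unchanged.
    """
    if composition is None:
        composition = chem.DEFAULT_COMPOSITION
    frozen = dict(frozen or {})
    rng = np.random.Generator(np.random.PCG64(seed))
    n = backbone.n_residues
    free_idx = [i for i in range(n) if i not in frozen]
    multiset = _composition_counts(composition, len(free_idx))
    perm = rng.permutation(len(free_idx))
    names: list[str] = [""] * n
    for slot, i in enumerate(free_idx):
        names[i] = multiset[perm[slot]]
    for i, aa in frozen.items():
        names[i] = aa

    # the design energy uses the fixed contact graph of the input backbone,
    # so swap moves change identities but never the graph
    from foldfunc.structure import contact_pairs  # local to avoid cycles
    contacts = contact_pairs(backbone)
    neighbours: list[list[int]] = [[] for _ in range(n)]
    for i, j in contacts:
        neighbours[i].append(j)
        neighbours[j].append(i)

    e = sequence_energy(names, contacts)
    initial_e = e
    best_names = list(names)
    best_e = e
    if mc_steps > 0 and len(free_idx) >= 2:
        t_hi, t_lo = 1.0, 0.02
        for step in range(mc_steps):
            temp = t_hi * (t_lo / t_hi) ** (step / max(1, mc_steps - 1))
            a, b = rng.choice(len(free_idx), size=2, replace=False)
            ia, ib = free_idx[a], free_idx[b]
            if names[ia] == names[ib]:
                continue
            delta = 0.0
            for j in neighbours[ia]:
                if j == ib:
                    continue
                delta += chem.contact_energy(names[ib], names[j]) - \
                    chem.contact_energy(names[ia], names[j])
            for j in neighbours[ib]:
                if j == ia:
                    continue
                delta += chem.contact_energy(names[ia], names[j]) - \
                    chem.contact_energy(names[ib], names[j])
            if delta <= 0 or rng.random() < math.exp(-delta / temp):
                names[ia], names[ib] = names[ib], names[ia]
                e += delta
                if e < best_e:
                    best_e = e
                    best_names = list(names)
    final = backbone.copy()
    _apply_names(final, best_names)
    return DesignResult(final, initial_e, best_e)


def _apply_names(s: Structure, names: Sequence[str]) -> None:
    """Assign identities in flat order and rebuild C-beta coordinates."""
    k = 0
    for c in s.chains:
        c.names = list(names[k: k + len(c)])
        c.cb = place_cb(c.ca, c.names)
        k += len(c)


# ---------------------------------------------------------------------------
# planted catalytic constellations
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PlantSpec:
    """How to graft a site constellation into a structure."""

    template_id: str
    jitter_sd: float = 0.0
    anchor_residue_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


def choose_plant_anchors(structure: Structure, template_ca: np.ndarray,
                         seed: int = 0, tol: float = 2.5,
                         n_trials: int = 60) -> tuple[int, ...]:
    """Pick residues whose mutual C-alpha distances resemble the template's.

    Greedy distance-matrix matching from random seed residues; returns the
    best-matching anchor set (one target residue per template residue).
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    ca = structure.ca_coords()
    n = len(ca)
    k = len(template_ca)
    tdist = squareform(pdist(template_ca))
    sdist = squareform(pdist(ca))
    best: tuple[float, tuple[int, ...]] | None = None
    for _ in range(n_trials):
        r0 = int(rng.integers(n))
        chosen = [r0]
        err = 0.0
        ok = True
        for j in range(1, k):
            cand_err = np.full(n, np.inf)
            for r in range(n):
                # anchors closer than 3 in sequence either freeze a backbone
                # bond at the template distance or sandwich a free residue
                # between two frozen neighbours; repair cannot fix either
                if any(abs(r - c) < 3 for c in chosen):
                    continue
                errs = [abs(sdist[r, chosen[m]] - tdist[j, m]) for m in range(len(chosen))]
                if max(errs) < tol:
                    cand_err[r] = sum(errs)
            r_best = int(np.argmin(cand_err))
            if not np.isfinite(cand_err[r_best]):
                ok = False
                break
            chosen.append(r_best)
            err += cand_err[r_best]
        if ok and (best is None or err < best[0]):
            best = (err, tuple(chosen))
    if best is None:
        raise PlantError("no anchor set matches the template constellation")
    return best[1]


def plant_site(structure: Structure, template_names: Sequence[str],
               template_ca: np.ndarray, template_cb: np.ndarray | None,
               spec: PlantSpec, seed: int = 0) -> Structure:
    """Graft a residue constellation into a structure at the anchor positions.

    The template constellation is rigidly placed onto the anchors by
    optimal superposition, Gaussian coordinate jitter of ``spec.jitter_sd``
    is added, anchor identities are overwritten, and the rest of the chain
    is locally repaired (anchors frozen) to restore bond lengths and
    self-avoidance.  Raises :class:`PlantError` if the repair cannot
    remove anchor-involving clashes.
    """
    anchors = np.asarray(spec.anchor_residue_indices, dtype=int)
    if len(anchors) != len(template_names):
        raise ValueError("anchor count must equal template residue count")
    n = structure.n_residues
    if np.any(anchors < 0) or np.any(anchors >= n):
        raise ValueError("anchor indices outside chain")
    rng = np.random.Generator(np.random.PCG64(seed))
    work = structure.copy()
    if len(work.chains) != 1:
        raise ValueError("plant_site expects a single-chain structure")
    chain = work.chains[0]
    tca = np.asarray(template_ca, dtype=float)
    R, t, _ = kabsch_superpose(tca, chain.ca[anchors])
    placed_ca = tca @ R.T + t
    placed_ca = placed_ca + rng.normal(0.0, spec.jitter_sd, placed_ca.shape)
    if template_cb is not None:
        tcb = np.asarray(template_cb, dtype=float)
        placed_cb = tcb @ R.T + t + rng.normal(0.0, spec.jitter_sd, tcb.shape)
    else:
        placed_cb = None
    for m, idx in enumerate(anchors):
        chain.names[idx] = template_names[m]
        chain.ca[idx] = placed_ca[m]
    rg_bound = max(radius_of_gyration(chain.ca) * 1.05,
                   2.5 * n ** (1.0 / 3.0))
    repaired = None
    start = chain.ca
    for attempt in range(4):
        cand = _project_constraints(start, rg_bound, 4.0, frozen=anchors,
                                    max_sweeps=400 + 200 * attempt)
        if not backbone_violations(cand, rg_bound + 1e-6):
            repaired = cand
            break
        # perturb the free residues to escape a stalled projection
        start = chain.ca.copy()
        free = np.ones(n, dtype=bool)
        free[anchors] = False
        start[free] += rng.normal(0.0, 0.3 + 0.2 * attempt,
                                  (int(free.sum()), 3))
    if repaired is None:
        raise PlantError("could not repair the chain around the planted site")
    chain.ca = repaired
    chain.cb = place_cb(chain.ca, chain.names)
    if placed_cb is not None:
        for m, idx in enumerate(anchors):
            if np.all(np.isfinite(placed_cb[m])) and chain.names[idx] != "GLY":
                chain.cb[idx] = placed_cb[m]
    return work


# ---------------------------------------------------------------------------
# dimer templates
# ---------------------------------------------------------------------------

def _slide_dock(coords_a: np.ndarray, coords_b: np.ndarray,
                inter_a: np.ndarray, inter_b: np.ndarray,
                direction: np.ndarray, clash_dist: float = 4.0,
                contact_cutoff: float = 8.0, step: float = 0.4
                ) -> tuple[np.ndarray, int] | None:
    """Slide body B toward A along ``direction``; return (offset B, contacts).

    ``coords_*`` are the clash-checked coordinates (C-alpha); ``inter_*``
    the interaction coordinates used for contact counting.  Returns the
    last clash-free placement, or None if none was found.
    """
    direction = direction / np.linalg.norm(direction)
    span = (np.max(coords_a @ direction) - np.min(coords_b @ direction)) + 10.0
    tree_a = cKDTree(coords_a)
    best = None
    offset = span
    while offset > -span:
        shift = direction * offset
        dmin = tree_a.query(coords_b + shift, k=1)[0].min()
        if dmin < clash_dist:
            break
        best = shift
        offset -= step
    if best is None:
        return None
    itree = cKDTree(inter_a)
    contacts = sum(len(lst) for lst in itree.query_ball_point(inter_b + best,
                                                              contact_cutoff))
    return best, int(contacts)


def make_dimer_template(seedA: int, seedB: int, min_contacts: int = 10,
                        n_residues: int = 50, max_trials: int = 60):
    """Rigid-dock two designed monomers into a native-like dimer template.

    Returns a :class:`foldfunc.complexes.ComplexTemplate` with at least
    ``min_contacts`` inter-chain residue contacts and no inter-chain
    C-alpha pair below 3.5 A.
    """
    from foldfunc.complexes import ComplexTemplate

    if min_contacts < 1:
        raise ValueError("min_contacts must be >= 1")
    mon_a = designed_monomer(seedA, n_residues)
    mon_b = designed_monomer(seedB, n_residues)
    chain_a = mon_a.transformed(np.eye(3), -mon_a.ca_coords().mean(axis=0))
    rng = np.random.Generator(np.random.PCG64((seedA * 1000003 + seedB) % (2 ** 31)))
    best: tuple[float, object] | None = None
    n_valid = 0
    for _ in range(max_trials):
        rot = random_rotation(rng)
        cand_b = mon_b.transformed(rot, -rot @ mon_b.ca_coords().mean(axis=0))
        direction = rng.normal(size=3)
        res = _slide_dock(chain_a.ca_coords(), cand_b.ca_coords(),
                          chain_a.interaction_coords(),
                          cand_b.interaction_coords(), direction)
        if res is None:
            continue
        shift, contacts = res
        if contacts < min_contacts:
            continue
        moved_b = cand_b.transformed(np.eye(3), shift)
        moved_b.chains[0].chain_id = "B"
        template = ComplexTemplate(chain_a, moved_b)
        if len(template.interface_pairs) < min_contacts:
            continue
        # native-like templates favour energetically good interfaces:
        # keep the lowest-contact-energy docking among the valid trials
        names_a = chain_a.residue_names()
        names_b = moved_b.residue_names()
        energy = sum(chem.contact_energy(names_a[i], names_b[j])
                     for i, j in template.interface_pairs)
        n_valid += 1
        if best is None or energy < best[0]:
            best = (energy, template)
        if n_valid >= 8:
            break
    if best is None:
        raise DockingError(
            f"no docking with >= {min_contacts} contacts for seeds ({seedA}, {seedB})")
    return best[1]


def designed_monomer(seed: int, n_residues: int = 50,
                     mc_steps: int = 3000, design_steps: int = 4000) -> Structure:
    """Convenience: compact backbone plus stability-designed sequence."""
    cfg = GeneratorConfig(n_residues=n_residues, seed=seed, mc_steps=mc_steps)
    backbone = generate_compact_backbone(cfg)
    res = design_stable_sequence(backbone, mc_steps=design_steps, seed=seed + 7)
    res.structure.label = f"mono{seed}"
    return res.structure


# ---------------------------------------------------------------------------
# B-DNA / protein complex templates
# ---------------------------------------------------------------------------

def make_bdna_complex_template(n_bp: int, protein: Structure, seed: int = 0,
                               min_contacts: int = 5, max_trials: int = 60):
    """Dock an ideal B-DNA duplex against a protein.

    Returns a :class:`foldfunc.dna.DnaComplexTemplate` with at least
    ``min_contacts`` residue-nucleotide contacts (C-beta within 7 A of a
    phosphate or base centroid) and no clash.
    """
    from foldfunc.dna import DnaComplexTemplate, build_bdna, dna_site_coords

    if n_bp < 4:
        raise ValueError("n_bp must be >= 4")
    rng = np.random.Generator(np.random.PCG64(seed))
    prot = protein.transformed(np.eye(3), -protein.ca_coords().mean(axis=0))
    names = prot.residue_names()
    best: tuple[float, object] | None = None
    n_valid = 0
    for _ in range(max_trials):
        dna = build_bdna(n_bp, seed=int(rng.integers(2 ** 31)))
        rot = random_rotation(rng)
        sites = dna_site_coords(dna)
        center = sites.mean(axis=0)
        dna_rot = dna.transformed(rot, -rot @ center)
        direction = rng.normal(size=3)
        res = _slide_dock(prot.ca_coords(), dna_site_coords(dna_rot),
                          prot.interaction_coords(), dna_site_coords(dna_rot),
                          direction, clash_dist=4.0, contact_cutoff=7.0)
        if res is None:
            continue
        shift, _ = res
        moved = dna_rot.transformed(np.eye(3), shift)
        template = DnaComplexTemplate(prot, moved)
        if len(template.interface_pairs) < min_contacts:
            continue
        # native-like templates present energetically favourable faces
        energy = sum(chem.dna_contact_energy(names[ri], site)
                     for ri, _, site in template.interface_pairs)
        n_valid += 1
        if best is None or energy < best[0]:
            best = (energy, template)
        if n_valid >= 8:
            break
    if best is None:
        raise DockingError(
            f"no DNA docking with >= {min_contacts} contacts (seed {seed})")
    return best[1]


# ---------------------------------------------------------------------------
# toy ligand / pathway universe
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ToyLigandUniverse:
    """A small chemical universe with pathways and optional planted truth.

    ``fingerprints`` maps ligand id -> boolean bit array; ``pathways``
    maps pathway id -> ligand-id list (disjoint subsets of the ligands);
    ``planted_preferences`` maps (protein_id, ligand_id) -> affinity
    multiplier > 1 for pairs carrying a planted binding preference.
    """

    fingerprints: dict[str, np.ndarray]
    pathways: dict[str, list[str]]
    planted_preferences: dict[tuple[str, str], float]
    protein_ids: list[str]
    n_bits: int
    bit_prob: float

    def __post_init__(self) -> None:
        for pid, ligs in self.pathways.items():
            for lig in ligs:
                if lig not in self.fingerprints:
                    raise ValueError(f"pathway {pid} references unknown ligand {lig}")
        for mult in self.planted_preferences.values():
            if mult <= 0:
                raise ValueError("affinity multipliers must be > 0")


def make_ligand_pathway_universe(n_ligands: int, n_pathways: int,
                                 n_bits: int = 64, planted_fold: float = 1.0,
                                 seed: int = 0, bit_prob: float = 0.15,
                                 n_proteins: int = 20,
                                 pathway_fraction: float = 0.6,
                                 n_assoc_proteins: int = 3) -> ToyLigandUniverse:
    """Random fingerprints, disjoint pathways, and planted preferences.

    ``planted_fold`` > 1 plants a ground-truth binding preference between
    each pathway's ligands and a small set of pathway-associated proteins;
    at 1 the preference table is empty (the uniform null).
    """
    if n_bits < 32:
        raise ValueError("n_bits must be >= 32")
    if planted_fold < 1:
        raise ValueError("planted_fold must be >= 1")
    if n_pathways > n_ligands:
        raise ValueError("more pathways than ligands")
    rng = np.random.Generator(np.random.PCG64(seed))
    lig_ids = [f"lig{i:05d}" for i in range(n_ligands)]
    fingerprints = {lid: rng.random(n_bits) < bit_prob for lid in lig_ids}
    protein_ids = [f"prot{i:04d}" for i in range(n_proteins)]
    # disjoint pathways over a subset of the ligands
    n_in_pathways = max(n_pathways, int(round(pathway_fraction * n_ligands)))
    member_ids = list(rng.permutation(lig_ids)[:n_in_pathways])
    cuts = np.sort(rng.choice(np.arange(1, n_in_pathways), size=n_pathways - 1,
                              replace=False)) if n_pathways > 1 else np.array([], int)
    pathways: dict[str, list[str]] = {}
    start = 0
    for k, stop in enumerate(list(cuts) + [n_in_pathways]):
        pathways[f"path{k:03d}"] = member_ids[start:stop]
        start = stop
    planted: dict[tuple[str, str], float] = {}
    if planted_fold > 1.0:
        for pid, ligs in pathways.items():
            assoc = rng.choice(protein_ids, size=min(n_assoc_proteins, n_proteins),
                               replace=False)
            for prot in assoc:
                for lig in ligs:
                    planted[(str(prot), lig)] = planted_fold
    return ToyLigandUniverse(fingerprints, pathways, planted, protein_ids,
                             n_bits, bit_prob)


def write_ligand_tables(universe: ToyLigandUniverse, ligand_path, pathway_path) -> None:
    """TSV export: (ligand_id, bitstring) and (pathway_id, ligand_id)."""
    with open(ligand_path, "w") as fh:
        fh.write("ligand_id\tbitstring\n")
        for lid in sorted(universe.fingerprints):
            bits = "".join("1" if b else "0" for b in universe.fingerprints[lid])
            fh.write(f"{lid}\t{bits}\n")
    with open(pathway_path, "w") as fh:
        fh.write("pathway_id\tligand_id\n")
        for pid in sorted(universe.pathways):
            for lid in universe.pathways[pid]:
                fh.write(f"{pid}\t{lid}\n")
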