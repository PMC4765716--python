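"""Active-site template matching and the enzyme-class statistics.

A template is a small constellation (3-5 residues) of catalytic residue
identities with C-alpha/C-beta coordinates and an EC number.  A *hit* in
a target structure is an identity-consistent assignment of template
residues onto target residues whose optimal superposition RMSD falls
below a cutoff — matching demands 100% residue-identity and coverage, so
only geometry and chemistry, never sequence order, matter (constellations
are sequence-discontiguous).

On top of the matcher sit the survey statistics: per-target counts of
distinct enzyme classes hit at several RMSD cutoffs with cumulative
fraction curves, and the frozen-catalytic-residue experiment, which asks
how often stability-selected sequences on a fold carrying a grafted
constellation recapitulate the original enzyme's pocket.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from foldfunc.calibration import TailCalibrator
from foldfunc.structure import (
    DegenerateGeometryError,
    Structure,
    kabsch_superpose,
    structural_align,
)

PAIR_DISTANCE_TOLERANCE = 1.5   # A, pruning bound on C-alpha pair distances
DEFAULT_CUTOFFS = (0.5, 0.75, 1.0)   # A
FOLD_FILTER_TM = 0.4


@dataclasses.dataclass
class ActiveSiteTemplate:
    """A catalytic constellation with its EC number and source structure."""

    template_id: str
    ec_number: str                      # "a.b.c.d"
    residue_names: tuple[str, ...]
    ca: np.ndarray                      # (k, 3)
    cb: np.ndarray                      # (k, 3), NaN rows where absent
    source: Structure | None = None

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        self.cb = np.asarray(self.cb, dtype=float)
        if len(self.residue_names) < 3:
            raise ValueError("templates need >= 3 residues")
        parse_ec(self.ec_number)

    @property
    def size(self) -> int:
        return len(self.residue_names)


@dataclasses.dataclass
class SiteHit:
    """One matched occurrence of a template in a target structure."""

    template_id: str
    ec_number: str
    target_indices: tuple[int, ...]   # flat residue indices, template order
    rmsd: float
    identity_fraction: float = 1.0
    coverage_fraction: float = 1.0
    global_tm_to_source: float | None = None


def parse_ec(ec: str) -> tuple[int, ...]:
    parts = ec.split(".")
    if len(parts) != 4:
        raise ValueError(f"malformed EC number {ec!r}")
    try:
        digits = tuple(int(p) for p in parts)
    except ValueError as exc:
        raise ValueError(f"malformed EC number {ec!r}") from exc
    if any(d <= 0 for d in digits):
        raise ValueError(f"EC digits must be positive: {ec!r}")
    return digits


def _site_points(ca: np.ndarray, cb: np.ndarray, order: Sequence[int]
                 ) -> np.ndarray:
    """Stacked C-alpha(+C-beta where present) coordinates in a fixed order."""
    pts = [ca[i] for i in order]
    pts += [cb[i] for i in order if np.all(np.isfinite(cb[i]))]
    return np.asarray(pts)


def match_site(target: Structure, search_region: Iterable[int],
               template: ActiveSiteTemplate, rmsd_cutoff: float = 1.0
               ) -> list[SiteHit]:
    """All identity-consistent placements of a template below the cutoff.

    Candidate assignments are pruned by pairwise C-alpha distance
    compatibility (tolerance 1.5 A) before superposition; surviving
    assignments are scored by Kabsch RMSD over C-alpha plus C-beta
    (glycine contributes C-alpha only) and returned sorted by RMSD.
    A template larger than the region yields an empty list.
    """
    if rmsd_cutoff <= 0:
        raise ValueError("rmsd_cutoff must be positive")
    region = sorted(set(int(i) for i in search_region))
    if not region:
        raise ValueError("empty search region")
    if template.size > len(region):
        return []
    names = target.residue_names()
    ca_all = target.ca_coords()
    cb_all = np.vstack([c.cb for c in target.chains])
    reg_ca = ca_all[region]
    reg_dist = squareform(pdist(reg_ca)) if len(region) > 1 else np.zeros((1, 1))
    tdist = squareform(pdist(template.ca))
    # candidate region positions per template residue, by identity
    candidates = [
        [ri for ri, gi in enumerate(region) if names[gi] == tname]
        for tname in template.residue_names
    ]
    if any(not c for c in candidates):
        return []
    hits: list[SiteHit] = []
    k = template.size

    def backtrack(j: int, chosen: list[int]) -> None:
        if j == k:
            order = range(k)
            tpts = _site_points(template.ca, template.cb, order)
            gpts_ca = np.array([reg_ca[c] for c in chosen])
            gpts = [gpts_ca[m] for m in order]
            gpts += [cb_all[region[chosen[m]]] for m in order
                     if np.all(np.isfinite(template.cb[m]))]
            gpts = np.asarray(gpts)
            if not np.all(np.isfinite(gpts)):
                return
            try:
                _, _, rmsd = kabsch_superpose(tpts, gpts)
            except DegenerateGeometryError:
                return
            if rmsd < rmsd_cutoff:
                hits.append(SiteHit(template.template_id, template.ec_number,
                                    tuple(region[c] for c in chosen), rmsd))
            return
        for cand in candidates[j]:
            if cand in chosen:
                continue
            ok = True
            for m, prev in enumerate(chosen):
                if abs(reg_dist[cand, prev] - tdist[j, m]) > PAIR_DISTANCE_TOLERANCE:
                    ok = False
                    break
            if ok:
                backtrack(j + 1, chosen + [cand])

    backtrack(0, [])
    hits.sort(key=lambda h: (h.rmsd, h.target_indices))
    return hits


def brute_force_match(target: Structure, search_region: Iterable[int],
                      template: ActiveSiteTemplate, rmsd_cutoff: float = 1.0
                      ) -> list[SiteHit]:
    """Exhaustive enumeration over all identity-consistent tuples.

    Independent oracle for :func:`match_site` (no distance pruning);
    practical only for small regions and 3-4-residue templates.
    """
    region = sorted(set(int(i) for i in search_region))
    if template.size > len(region):
        return []
    names = target.residue_names()
    ca_all = target.ca_coords()
    cb_all = np.vstack([c.cb for c in target.chains])
    candidates = [
        [gi for gi in region if names[gi] == tname]
        for tname in template.residue_names
    ]
    hits: list[SiteHit] = []
    for combo in itertools.product(*candidates):
        if len(set(combo)) != len(combo):
            continue
        tpts = _site_points(template.ca, template.cb, range(template.size))
        gpts = [ca_all[g] for g in combo]
        gpts += [cb_all[g] for m, g in enumerate(combo)
                 if np.all(np.isfinite(template.cb[m]))]
        gpts = np.asarray(gpts)
        if not np.all(np.isfinite(gpts)):
            continue
        try:
            _, _, rmsd = kabsch_superpose(tpts, np.asarray(gpts))
        except DegenerateGeometryError:
            continue
        if rmsd < rmsd_cutoff:
            hits.append(SiteHit(template.template_id, template.ec_number,
                                tuple(combo), rmsd))
    hits.sort(key=lambda h: (h.rmsd, h.target_indices))
    return hits


def scan_target(target: Structure, library: Sequence[ActiveSiteTemplate],
                cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
                fold_filter_tm: float | None = FOLD_FILTER_TM,
                search_region: Iterable[int] | None = None
                ) -> dict[float, list[SiteHit]]:
    """Scan a template library against one target at several RMSD cutoffs.

    Hits whose source structure aligns to the target with TM-score at or
    above ``fold_filter_tm`` are discarded (only globally unrelated folds
    count); per-cutoff hit sets are nested by construction.  The search
    region defaults to the whole structure; callers restrict it to a
    pocket's lining residues to mirror the pocket-first protocol.
    """
    if not library:
        raise ValueError("empty template library")
    cutoffs = sorted(cutoffs)
    region = (list(search_region) if search_region is not None
              else list(range(target.n_residues)))
    out: dict[float, list[SiteHit]] = {c: [] for c in cutoffs}
    cmax = cutoffs[-1]
    for template in library:
        hits = match_site(target, region, template, rmsd_cutoff=cmax)
        if not hits:
            continue
        tm_to_source = None
        if fold_filter_tm is not None and template.source is not None:
            tm_to_source = structural_align(template.source, target).tm
            if tm_to_source >= fold_filter_tm:
                continue
        for h in hits:
            h.global_tm_to_source = tm_to_source
            for c in cutoffs:
                if h.rmsd < c:
                    out[c].append(h)
    return out


# ---------------------------------------------------------------------------
# class counting and cumulative curves
# ---------------------------------------------------------------------------

def count_enzyme_classes(hits_per_target: Mapping[str, Sequence[SiteHit]],
                         ec_digits: int = 2
                         ) -> tuple[dict[str, int], dict[int, float]]:
    """Distinct enzyme classes hit per target, plus the cumulative curve.

    Classes are EC prefixes at ``ec_digits`` depth, deduplicated per
    target; the curve gives, for each k >= 1, the fraction of targets
    hitting at least k classes.
    """
    if ec_digits not in (1, 2, 3, 4):
        raise ValueError("ec_digits must be 1-4")
    counts: dict[str, int] = {}
    for tgt, hits in hits_per_target.items():
        classes = set()
        for h in hits:
            digits = parse_ec(h.ec_number)
            classes.add(digits[:ec_digits])
        counts[tgt] = len(classes)
    n = len(counts)
    curve: dict[int, float] = {}
    if n:
        kmax = max(counts.values(), default=0)
        for k in range(1, max(kmax, 1) + 1):
            curve[k] = sum(1 for v in counts.values() if v >= k) / n
    return counts, curve


# ---------------------------------------------------------------------------
# synthetic CSA-like template library
# ---------------------------------------------------------------------------

_CATALYTIC_POOL = ("SER", "HIS", "ASP", "GLU", "LYS", "CYS", "ARG", "TYR",
                   "THR", "ASN")


def make_site_template_library(n_templates: int, seed: int = 0,
                               sizes: Sequence[int] = (3, 3, 4, 4, 5),
                               source_n_residues: int = 60,
                               with_sources: bool = True
                               ) -> list[ActiveSiteTemplate]:
    """A CSA-like library of catalytic constellations extracted from
    generated source structures.

    Each template takes a mutually proximate residue set from a designed
    synthetic structure, overwrites those identities with draws from a
    catalytic-residue pool, and attaches a random EC number.
    """
    from foldfunc.generate import designed_monomer
    rng = np.random.Generator(np.random.PCG64(seed))
    library: list[ActiveSiteTemplate] = []
    attempt = 0
    while len(library) < n_templates and attempt < 20 * n_templates:
        attempt += 1
        size = int(rng.choice(sizes))
        src_seed = int(rng.integers(2 ** 31))
        source = designed_monomer(src_seed, source_n_residues,
                                  mc_steps=2500, design_steps=3000)
        ca = source.ca_coords()
        centre = int(rng.integers(source.n_residues))
        d = np.linalg.norm(ca - ca[centre], axis=1)
        near = np.argsort(d)
        picked = [centre]
        for j in near[1:]:
            if len(picked) == size:
                break
            if all(4.5 <= np.linalg.norm(ca[j] - ca[p]) <= 11.0 for p in picked):
                picked.append(int(j))
        if len(picked) < size:
            continue
        picked = sorted(picked)
        chain = source.chains[0]
        for p in picked:
            chain.names[p] = str(rng.choice(_CATALYTIC_POOL))
        from foldfunc.generate import place_cb
        chain.cb = place_cb(chain.ca, chain.names)
        ec = ".".join(str(int(v)) for v in (rng.integers(1, 7),
                                            rng.integers(1, 21),
                                            rng.integers(1, 31),
                                            rng.integers(1, 100)))
        library.append(ActiveSiteTemplate(
            template_id=f"site{len(library):04d}",
            ec_number=ec,
            residue_names=tuple(chain.names[p] for p in picked),
            ca=ca[picked].copy(),
            cb=chain.cb[picked].copy(),
            source=source if with_sources else None,
        ))
    if len(library) < n_templates:
        raise RuntimeError("could not build the requested template library")
    return library


def save_template_library(library: Sequence[ActiveSiteTemplate], path) -> None:
    data = []
    for t in library:
        data.append({
            "template_id": t.template_id,
            "ec_number": t.ec_number,
            "residues": [
                {"name": n,
                 "ca": [float(v) for v in t.ca[i]],
                 "cb": ([float(v) for v in t.cb[i]]
                        if np.all(np.isfinite(t.cb[i])) else None)}
                for i, n in enumerate(t.residue_names)],
        })
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def load_template_library(path) -> list[ActiveSiteTemplate]:
    with open(path) as fh:
        data = json.load(fh)
    out = []
    for entry in data:
        names = tuple(r["name"] for r in entry["residues"])
        ca = np.array([r["ca"] for r in entry["residues"]])
        cb = np.array([r["cb"] if r["cb"] is not None else [np.nan] * 3
                       for r in entry["residues"]])
        out.append(ActiveSiteTemplate(entry["template_id"], entry["ec_number"],
                                      names, ca, cb))
    return out


# ---------------------------------------------------------------------------
# frozen-catalytic-residue experiment
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FrozenSiteRecord:
    """Per-sequence outcome of the frozen-residue experiment."""

    sequence_seed: int
    ps_like_score: float
    p_value: float
    success: bool


@dataclasses.dataclass
class FrozenSiteResult:
    success_fraction: float
    records: list[FrozenSiteRecord]


def frozen_site_pocket_experiment(native_pocket, art_backbone: Structure,
                                  site: ActiveSiteTemplate,
                                  n_sequences: int, seed: int,
                                  calibrator: TailCalibrator,
                                  p_threshold: float = 0.05,
                                  design_steps: int = 4000
                                  ) -> FrozenSiteResult:
    """Graft a site, regenerate stable sequences, and count pocket matches.

    The catalytic constellation is planted on the backbone and its
    residue identities are masked from the design swap moves; for each
    designed sequence the largest pocket is compared against the native
    enzyme's pocket and counted a success when the calibrated p-value
    falls below ``p_threshold``.  Raises if the site cannot be planted
    (no pocket can then match) or ``n_sequences`` < 1.
    """
    from foldfunc.generate import PlantSpec, choose_plant_anchors, plant_site
    from foldfunc.pockets import compare_pockets, largest_pocket

    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    anchors = choose_plant_anchors(art_backbone, site.ca, seed=seed)
    spec = PlantSpec(template_id=site.template_id, jitter_sd=0.0,
                     anchor_residue_indices=anchors)
    planted = plant_site(art_backbone, site.residue_names, site.ca, site.cb,
                         spec, seed=seed)
    frozen = {int(a): site.residue_names[m] for m, a in enumerate(anchors)}
    records: list[FrozenSiteRecord] = []
    rng = np.random.Generator(np.random.PCG64(seed))
    from foldfunc.generate import design_stable_sequence
    for _ in range(n_sequences):
        seq_seed = int(rng.integers(2 ** 31))
        res = design_stable_sequence(planted, mc_steps=design_steps,
                                     seed=seq_seed, frozen=frozen)
        pocket = largest_pocket(res.structure)
        if pocket is None or pocket.n_lining < 3:
            records.append(FrozenSiteRecord(seq_seed, 0.0, 1.0, False))
            continue
        match = compare_pockets(pocket, native_pocket)
        p = float(calibrator.pvalue(match.ps_like_score))
        records.append(FrozenSiteRecord(seq_seed, match.ps_like_score, p,
                                        p < p_threshold))
    frac = sum(r.success for r in records) / n_sequences
    return FrozenSiteResult(frac, records)
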