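"""Shared fixtures: small synthetic libraries and geometric test objects."""

from __future__ import annotations

import numpy as np
import pytest

from foldfunc.generate import (
    GeneratorConfig,
    design_stable_sequence,
    generate_compact_backbone,
)
from foldfunc.structure import Structure


def make_designed(seed: int, n_residues: int = 56, mc_steps: int = 2500,
                  design_steps: int = 3000) -> Structure:
    bb = generate_compact_backbone(GeneratorConfig(
        n_residues=n_residues, seed=seed, mc_steps=mc_steps))
    res = design_stable_sequence(bb, mc_steps=design_steps, seed=seed + 101)
    res.structure.label = f"fix{seed}"
    return res.structure


@pytest.fixture(scope="session")
def small_library() -> list[Structure]:
    """Eight designed monomers reused across unit tests."""
    return [make_designed(seed, n_residues=48 + 4 * (seed % 4))
            for seed in range(8)]


def cavity_blob(seed: int, r_cavity: float = 5.0, extent: float = 14.0,
                spacing: float = 4.3, jitter: float = 0.45,
                mouth_dir: np.ndarray | None = None,
                mouth_cos: float = 0.92) -> tuple[Structure, np.ndarray]:
    """Jittered-lattice pseudo-protein with a spherical cavity at the origin.

    Returns (structure, cavity centre).  Fast and deterministic; the
    residues are C-alpha-only placeholders (GLY).
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    ax = np.arange(-extent, extent + spacing, spacing)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    pts = pts + rng.uniform(-jitter, jitter, pts.shape)
    r = np.linalg.norm(pts, axis=1)
    keep = (r >= r_cavity) & (r <= extent)
    if mouth_dir is not None:
        u = pts / np.maximum(r[:, None], 1e-9)
        keep &= ~((u @ mouth_dir) > mouth_cos)
    pts = pts[keep]
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
    pts = pts[order]
    return Structure.from_arrays(["GLY"] * len(pts), pts), np.zeros(3)


def lattice_ball(radius: float = 12.0, spacing: float = 3.4) -> Structure:
    """A densely packed convex solid ball of pseudo-residues."""
    ax = np.arange(-radius, radius + spacing, spacing)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= radius]
    return Structure.from_arrays(["GLY"] * len(pts), pts)


def random_pocket(rng: np.random.Generator, n_res: int = 10,
                  spread: float = 6.0, label: str = ""):
    """A synthetic pocket object for comparison/calibration tests."""
    from foldfunc import chem
    from foldfunc.pockets import Pocket

    coords = rng.normal(0.0, spread, (n_res, 3))
    names = [str(rng.choice(chem.AMINO_ACIDS)) for _ in range(n_res)]
    grid = coords.mean(axis=0) + rng.normal(0, 1.5, (30, 3))
    return Pocket(grid_points=grid, spacing=1.0, centroid=grid.mean(axis=0),
                  volume=float(len(grid)), lining_indices=tuple(range(n_res)),
                  lining_names=tuple(names), lining_coords=coords,
                  source_label=label or f"rp{rng.integers(1 << 30)}")
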