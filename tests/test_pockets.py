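"""Pocket detection, PS-like comparison, calibration and clustering."""

import copy
import itertools

import numpy as np
import pytest

from foldfunc import chem
from foldfunc.calibration import CalibrationError
from foldfunc.pockets import (
    Pocket,
    calibrate_pocket_pvalue,
    cluster_pockets,
    compare_pockets,
    detect_pockets,
    largest_pocket,
)
from foldfunc.structure import kabsch_superpose, random_rotation

from conftest import cavity_blob, lattice_ball, random_pocket

MOUTH = np.array([0.0, 0.0, 1.0])


class TestDetection:
    def test_planted_cavity_recovered(self):
        hits = 0
        for seed in range(10):
            s, centre = cavity_blob(seed, r_cavity=5.0, mouth_dir=MOUTH)
            pockets = detect_pockets(s)
            if pockets and np.linalg.norm(pockets[0].centroid - centre) <= 2.0:
                hits += 1
        assert hits >= 9

    def test_convex_solid_has_no_pockets(self):
        assert detect_pockets(lattice_ball()) == []

    def test_min_points_filter_is_monotone(self):
        s, _ = cavity_blob(3, mouth_dir=MOUTH)
        n30 = len(detect_pockets(s, min_points=30))
        n60 = len(detect_pockets(s, min_points=60))
        assert n60 <= n30

    def test_grid_spacing_validated(self):
        s, _ = cavity_blob(0, mouth_dir=MOUTH)
        with pytest.raises(ValueError):
            detect_pockets(s, grid_spacing=0.2)

    def test_rigid_invariance_of_counts_and_volumes(self):
        rng = np.random.default_rng(11)
        s, _ = cavity_blob(5, mouth_dir=MOUTH)
        moved = s.transformed(random_rotation(rng), rng.normal(0, 25, 3))
        p0 = detect_pockets(s)
        p1 = detect_pockets(moved)
        assert len(p0) == len(p1)
        assert [p.volume for p in p0] == [p.volume for p in p1]

    def test_lining_residues_near_grid(self):
        s, _ = cavity_blob(7, mouth_dir=MOUTH)
        inter = s.interaction_coords()
        for p in detect_pockets(s):
            for idx in p.lining_indices:
                d = np.linalg.norm(p.grid_points - inter[idx], axis=1).min()
                assert d <= 5.0
            assert p.volume == pytest.approx(len(p.grid_points) * p.spacing ** 3)


class TestLargestPocket:
    def test_two_cavities_larger_wins(self):
        rng = np.random.default_rng(0)
        ax = np.arange(-22.0, 22.1, 4.3)
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        pts = pts + rng.uniform(-0.4, 0.4, pts.shape)
        c_big = np.array([-10.0, 0.0, 0.0])
        c_small = np.array([12.0, 0.0, 0.0])
        keep = (np.linalg.norm(pts - c_big, axis=1) >= 6.0) & \
               (np.linalg.norm(pts - c_small, axis=1) >= 4.8) & \
               (np.max(np.abs(pts), axis=1) <= 20.0)
        from foldfunc.structure import Structure
        s = Structure.from_arrays(["GLY"] * int(keep.sum()), pts[keep])
        lp = largest_pocket(s)
        assert lp is not None
        assert np.linalg.norm(lp.centroid - c_big) < \
            np.linalg.norm(lp.centroid - c_small)

    def test_none_when_no_pocket(self):
        assert largest_pocket(lattice_ball(radius=8.0)) is None

    def test_equals_detection_maximum(self):
        s, _ = cavity_blob(9, mouth_dir=MOUTH)
        pockets = detect_pockets(s)
        assert pockets
        assert largest_pocket(s).volume == max(p.volume for p in pockets)


def exhaustive_pocket_score(a: Pocket, b: Pocket) -> float:
    """Brute-force maximum of the PS-like score over all correspondences."""
    best = 0.0
    na, nb = a.n_lining, b.n_lining
    nmax = max(na, nb)
    for k in range(3, min(na, nb) + 1):
        for sub_a in itertools.combinations(range(na), k):
            for sub_b in itertools.permutations(range(nb), k):
                try:
                    _, _, rmsd = kabsch_superpose(a.lining_coords[list(sub_a)],
                                                  b.lining_coords[list(sub_b)])
                except Exception:
                    continue
                agree = np.mean([
                    chem.CHEMICAL_CLASS[a.lining_names[i]] ==
                    chem.CHEMICAL_CLASS[b.lining_names[j]]
                    for i, j in zip(sub_a, sub_b)])
                score = (k / nmax) / (1 + (rmsd / 2) ** 2) * agree
                best = max(best, score)
    return best


class TestComparison:
    def test_self_match_is_one(self):
        rng = np.random.default_rng(1)
        p = random_pocket(rng, 12)
        m = compare_pockets(p, p)
        assert m.ps_like_score == pytest.approx(1.0, abs=1e-9)
        assert m.rmsd <= 1e-6

    def test_rigid_copy_scores_near_one(self):
        rng = np.random.default_rng(2)
        for seed in range(5):
            p = random_pocket(np.random.default_rng(seed), 10)
            q = copy.deepcopy(p)
            q.lining_coords = q.lining_coords @ random_rotation(rng).T + \
                rng.normal(0, 15, 3)
            assert compare_pockets(p, q).ps_like_score >= 0.999

    def test_symmetry(self):
        a = random_pocket(np.random.default_rng(3), 9)
        b = random_pocket(np.random.default_rng(4), 11)
        ab = compare_pockets(a, b).ps_like_score
        ba = compare_pockets(b, a).ps_like_score
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_too_few_residues_is_error(self):
        a = random_pocket(np.random.default_rng(5), 2)
        b = random_pocket(np.random.default_rng(6), 8)
        with pytest.raises(ValueError):
            compare_pockets(a, b)

    def test_matches_exhaustive_oracle_on_small_pockets(self):
        """The ICP search finds the brute-force optimum on tiny pockets."""
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            a = random_pocket(rng, int(rng.integers(4, 6)), spread=4.0)
            b = random_pocket(rng, int(rng.integers(4, 6)), spread=4.0)
            heur = compare_pockets(a, b).ps_like_score
            exact = exhaustive_pocket_score(a, b)
            assert heur <= exact + 1e-9
            assert heur == pytest.approx(exact, abs=1e-6)


class TestCalibration:
    def test_rank_bound_and_extremes(self):
        rng = np.random.default_rng(0)
        bg = rng.beta(2, 8, 500)
        cal = calibrate_pocket_pvalue(bg)
        assert cal.pvalue(bg.max()) <= 1 / (500 + 1) + 1e-12
        assert cal.pvalue(0.0) >= 0.99
        assert cal.pvalue(2.0) <= 1 / (500 + 1)

    def test_monotone_decreasing(self):
        rng = np.random.default_rng(1)
        cal = calibrate_pocket_pvalue(rng.beta(2, 8, 400))
        xs = np.linspace(0, 1.2, 200)
        ps = np.array([cal.pvalue(x) for x in xs])
        assert np.all(np.diff(ps) <= 1e-12)

    def test_insufficient_background_is_error(self):
        with pytest.raises(CalibrationError):
            calibrate_pocket_pvalue(np.ones(50))

    def test_null_pvalues_uniform(self):
        """Held-out null scores give uniform p-values (KS)."""
        from scipy import stats
        scores = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            a = random_pocket(rng, int(rng.integers(7, 11)))
            b = random_pocket(rng, int(rng.integers(7, 11)))
            scores.append(compare_pockets(a, b).ps_like_score)
        scores = np.asarray(scores)
        cal = calibrate_pocket_pvalue(scores[:int(len(scores) * 2 / 3)],
                                      min_n=30)
        held = scores[int(len(scores) * 2 / 3):]
        ps = np.array([cal.pvalue(s) for s in held])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestClustering:
    def test_identical_pockets_one_representative(self):
        p = random_pocket(np.random.default_rng(7), 8)
        reps = cluster_pockets([p, copy.deepcopy(p), copy.deepcopy(p)], 0.9)
        assert len(reps) == 1

    def test_cover_and_separation(self):
        pockets = [random_pocket(np.random.default_rng(200 + i), 8)
                   for i in range(12)]
        thr = 0.3
        reps = cluster_pockets(pockets, thr)
        for p in pockets:
            assert any(compare_pockets(p, r).ps_like_score >= thr or p is r
                       for r in reps)
        for r1, r2 in itertools.combinations(reps, 2):
            assert compare_pockets(r1, r2).ps_like_score < thr

    def test_threshold_validation(self):
        p = random_pocket(np.random.default_rng(8), 6)
        with pytest.raises(ValueError):
            cluster_pockets([p], 1.5)
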