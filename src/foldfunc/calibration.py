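"""Score-to-p-value calibration shared by pocket and interface similarity.

Similarity scores (pocket PS-like scores, interface IS-like scores) are
converted to p-values against a background of unrelated-pair scores.  The
calibrator is rank-based over the background sample — ``p(s) =
(1 + #{background >= s}) / (n + 1)`` — which makes held-out null p-values
uniform by construction, with a Gumbel (extreme-value) right tail fitted
to the background and used only beyond the observed maximum, clamped so
extrapolated p-values never exceed the rank bound 1/(n+1).  Both maxima
of similarity searches and finite-sample uniformity favour this hybrid
over a pure parametric fit.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


class CalibrationError(ValueError):
    """Raised when the background sample is too small to calibrate."""


class TailCalibrator:
    """Monotone score -> p-value map calibrated on null scores.

    Parameters
    ----------
    background:
        Scores of unrelated pairs (the null sample); at least ``min_n``.
    min_n:
        Minimum background size (default 100).
    """

    def __init__(self, background: np.ndarray, min_n: int = 100):
        bg = np.asarray(background, dtype=float)
        bg = bg[np.isfinite(bg)]
        if bg.size < min_n:
            raise CalibrationError(
                f"need >= {min_n} background scores, got {bg.size}")
        self._sorted = np.sort(bg)
        self._n = bg.size
        self._max = float(self._sorted[-1])
        # Gumbel right tail for extrapolation beyond the observed maximum
        loc, scale = stats.gumbel_r.fit(bg)
        self._tail = (float(loc), float(max(scale, 1e-12)))

    @property
    def n_background(self) -> int:
        return self._n

    def pvalue(self, score: float | np.ndarray) -> np.ndarray | float:
        """Right-tail p-value(s) of score(s) under the null."""
        s = np.atleast_1d(np.asarray(score, dtype=float))
        n_gt = self._n - np.searchsorted(self._sorted, s, side="right")
        p = (1.0 + n_gt) / (self._n + 1.0)
        beyond = s > self._max
        if np.any(beyond):
            loc, scale = self._tail
            tail_p = stats.gumbel_r.sf(s[beyond], loc=loc, scale=scale)
            p[beyond] = np.minimum(1.0 / (self._n + 1.0), tail_p)
        p = np.clip(p, 0.0, 1.0)
        return p if np.ndim(score) else float(p[0])

    def randomized_pit(self, scores: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
        """Randomized probability integral transform for calibration checks.

        For a null with atoms (e.g. interface-similarity scores with a
        point mass at zero), plain right-tail p-values are conservative at
        the atoms and cannot be uniform.  The standard diagnostic jitters
        within ties: ``u = (n_gt + V (n_eq + 1)) / (n + 1)`` with V ~
        U(0,1), which is uniform under the null regardless of atoms.
        """
        s = np.asarray(scores, dtype=float)
        n_gt = self._n - np.searchsorted(self._sorted, s, side="right")
        n_ge = self._n - np.searchsorted(self._sorted, s, side="left")
        n_eq = n_ge - n_gt
        v = rng.random(s.shape)
        return (n_gt + v * (n_eq + 1)) / (self._n + 1.0)


def percentile_cutoff(background: np.ndarray, percentile: float) -> float:
    """Background percentile used to place scale-dependent thresholds.

    Maps a requested percentile (0-100) of a score/energy background to a
    cutoff value; stricter percentiles give stricter cutoffs.
    """
    bg = np.asarray(background, dtype=float)
    if bg.size < 1:
        raise CalibrationError("empty background")
    return float(np.percentile(bg, percentile))
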