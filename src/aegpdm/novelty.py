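"""One-class novelty detection via the GP predictive mean, for fall alarms.

Normal behaviour is summarized by a set of latent support points (the
samples recycled from auto-encoded-GPDM training).  A zero-mean GP with a
squared-exponential kernel is regressed on these points with *unit
targets*; its predictive mean

    score(x) = k*(x)' (K + s2 I)^{-1} 1

is about 1 inside the normal support and reverts to the prior mean 0 away
from it, giving a smooth membership score without estimating a density.
Frames of a latent trajectory whose score drops below a threshold tau are
flagged; an alarm fires at the first frame that begins a run of at least
``debounce`` consecutive flagged frames, which rejects single-frame score
dips while keeping the alarm within a few hundred milliseconds of a fall
transient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator, OutlierMixin

from .kernels import JITTER, sq_dists

__all__ = [
    "GPNoveltyDetector",
    "DetectionResult",
    "ScoreGrid",
    "fit_novelty",
    "novelty_score",
    "choose_threshold",
    "detect_falls",
    "score_grid",
]


@dataclass
class DetectionResult:
    """Per-frame novelty scores, below-threshold flags and the alarm frame."""

    scores: np.ndarray
    flags: np.ndarray
    alarm_frame: int | None
    threshold: float


@dataclass
class ScoreGrid:
    """Dense novelty-score surface over a bounded 2-D latent plane."""

    x: np.ndarray        # (nx,) axis
    y: np.ndarray        # (ny,) axis
    scores: np.ndarray   # (ny, nx), scores[i, j] = score((x[j], y[i]))


class GPNoveltyDetector(BaseEstimator, OutlierMixin):
    """GP predictive-mean novelty scoring over latent support samples.

    Parameters
    ----------
    lengthscale : float or None
        SE kernel lengthscale; ``None`` uses twice the median distance to
        the 10th nearest neighbour of the support.  This local-density
        scale keeps the score surface tight around the support: a global
        scale (such as the median of *all* pairwise distances) is of the
        order of the support diameter, which flattens the score to ~1
        over the whole occupied region and hides interior novelties.
    noise : float
        Observation noise variance s2 of the unit-target regression.
    threshold_quantile : float
        Lower quantile of held-in normal scores used by
        :meth:`choose_threshold`.
    threshold_margin : float
        The alarm threshold is this fraction of the held-in quantile
        score.  Held-in points sit on the support, so their scores crowd
        the interpolation value ~1/(1+noise); unseen normal data strays
        by up to a few kernel widths and scores lower.  The default 0.5
        grants roughly one lengthscale of slack (an SE score ratio of
        exp(-1/2) ~ 0.61 one lengthscale out).
    debounce : int
        Consecutive below-threshold frames required before an alarm
        (3 frames = 0.3 s at the 10 Hz sampling rate).
    max_support : int
        Supports larger than this are subsampled (cubic fit cost).
    random_state : seed for the subsampling only.
    """

    def __init__(self, lengthscale: float | None = None, noise: float = 0.1,
                 threshold_quantile: float = 0.01,
                 threshold_margin: float = 0.5, debounce: int = 3,
                 max_support: int = 2000, random_state=None):
        self.lengthscale = lengthscale
        self.noise = noise
        self.threshold_quantile = threshold_quantile
        self.threshold_margin = threshold_margin
        self.debounce = debounce
        self.max_support = max_support
        self.random_state = random_state

    def fit(self, X, y=None):
        """Fit the unit-target GP on an (S, m) support point set."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] < 1:
            raise ValueError("support must contain at least one point")
        if X.shape[0] > self.max_support:
            rng = np.random.default_rng(self.random_state)
            idx = rng.choice(X.shape[0], self.max_support, replace=False)
            X = X[np.sort(idx)]
        self.support_ = X
        if self.lengthscale is None:
            if X.shape[0] > 1:
                D = sq_dists(X, X)
                D.sort(axis=1)
                k = min(10, X.shape[0] - 1)
                self.lengthscale_ = 2.0 * float(np.sqrt(np.median(D[:, k])))
                if self.lengthscale_ <= 0:
                    self.lengthscale_ = 1.0
            else:
                self.lengthscale_ = 1.0
        else:
            self.lengthscale_ = float(self.lengthscale)
        K = np.exp(-0.5 * sq_dists(X, X) / self.lengthscale_**2)
        # the noise term regularizes; jitter only as a fallback for noise ~ 0
        K[np.diag_indices_from(K)] += self.noise if self.noise > 0 else JITTER
        L = cho_factor(K, lower=True)
        self.weights_ = cho_solve(L, np.ones(X.shape[0]))
        self.threshold_ = None
        return self

    def score_samples(self, X) -> np.ndarray:
        """Predictive-mean novelty scores, vectorized over query points."""
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            return np.zeros(0)
        X = np.atleast_2d(X)
        if X.shape[1] != self.support_.shape[1]:
            raise ValueError(
                f"query dimension {X.shape[1]} != support dimension "
                f"{self.support_.shape[1]}"
            )
        Ks = np.exp(-0.5 * sq_dists(self.support_, X) / self.lengthscale_**2)
        return Ks.T @ self.weights_

    def choose_threshold(self, normal_scores, quantile: float | None = None,
                         margin: float | None = None) -> float:
        """Set tau from scores on held-in normal points.

        tau = margin * (the given lower quantile of the scores); all-equal
        scores fall back to that value minus 1e-6 before the margin.
        """
        s = np.asarray(normal_scores, dtype=float)
        if s.size == 0:
            raise ValueError("normal_scores must be nonempty")
        q = self.threshold_quantile if quantile is None else quantile
        m = self.threshold_margin if margin is None else margin
        if np.ptp(s) == 0:
            tau = m * (float(s[0]) - 1e-6)
        else:
            tau = m * float(np.quantile(s, q))
        self.threshold_ = tau
        return tau

    def predict(self, X) -> np.ndarray:
        """sklearn outlier convention: +1 normal, -1 novel."""
        if self.threshold_ is None:
            raise RuntimeError("threshold not set; call choose_threshold first")
        return np.where(self.score_samples(X) >= self.threshold_, 1, -1)

    def detect(self, trajectory) -> DetectionResult:
        """Score a latent trajectory and locate the first debounced alarm."""
        if self.threshold_ is None:
            raise RuntimeError("threshold not set; call choose_threshold first")
        scores = self.score_samples(trajectory)
        flags = scores < self.threshold_
        alarm = None
        run = 0
        for i, f in enumerate(flags):
            run = run + 1 if f else 0
            if run >= self.debounce:
                alarm = i - self.debounce + 1
                break
        return DetectionResult(scores, flags, alarm, self.threshold_)

    def score_grid(self, bounds, resolution=(50, 50)) -> ScoreGrid:
        """Novelty-score surface for contour plots (2-D latent space only).

        ``bounds`` is ((xmin, xmax), (ymin, ymax)).
        """
        if self.support_.shape[1] != 2:
            raise ValueError("score grids require a 2-D latent space")
        (x0, x1), (y0, y1) = bounds
        nx, ny = resolution
        gx = np.linspace(x0, x1, nx)
        gy = np.linspace(y0, y1, ny)
        XX, YY = np.meshgrid(gx, gy)
        pts = np.column_stack([XX.ravel(), YY.ravel()])
        return ScoreGrid(gx, gy, self.score_samples(pts).reshape(ny, nx))


# -- thin functional wrappers ----------------------------------------------

def fit_novelty(samples, lengthscale: float | None = None, noise: float = 0.1,
                **kwargs) -> GPNoveltyDetector:
    return GPNoveltyDetector(lengthscale=lengthscale, noise=noise,
                             **kwargs).fit(samples)


def novelty_score(model: GPNoveltyDetector, points) -> np.ndarray:
    return model.score_samples(points)


def choose_threshold(model: GPNoveltyDetector, normal_scores,
                     quantile: float = 0.01,
                     margin: float | None = None) -> float:
    return model.choose_threshold(normal_scores, quantile, margin)


def detect_falls(model: GPNoveltyDetector, trajectory) -> DetectionResult:
    return model.detect(trajectory)


def score_grid(model: GPNoveltyDetector, bounds, resolution=(50, 50)
               ) -> ScoreGrid:
    return model.score_grid(bounds, resolution)
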