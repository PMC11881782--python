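"""Comparison policies for placing new test locations.

The maximum-gradient policy shares MEDTEG's plumbing (Voronoi candidates,
Sibson initialization of the selected point's PMF) but scores a candidate
by the largest difference in estimated threshold between any two of its
natural neighbors, instead of by expected information volume. The random
24-2 policy draws untested locations uniformly from the standard grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import bayes, core, geometry
from .core import MedtegConfig, NoCandidateError
from .geometry import SibsonWeights, TestGrid


@dataclass
class GradientScore:
    """Per-candidate record for the maximum-gradient policy."""

    point: np.ndarray
    pmf: np.ndarray
    gradient: float  # dB: max pairwise |mu_hat_i - mu_hat_j| among neighbors
    omega: float
    sibson: SibsonWeights

    @property
    def final_score(self) -> float:
        return self.gradient * self.omega


def max_gradient_scores(grid: TestGrid, config: MedtegConfig) -> list[GradientScore]:
    """Score every positive-weight candidate by its neighborhood threshold
    gradient. Candidates are compiled exactly as MEDTEG compiles them."""
    if grid.pmfs is None or grid.n < 3:
        raise ValueError("need a grid with >=3 points carrying PMFs")
    vor = geometry.bounded_voronoi(grid, config.region)
    cands = geometry.compile_candidates(vor, grid, config.restrict_to_hull)
    if len(cands) == 0:
        return []
    estimates = np.array([
        bayes.estimate_threshold(p, config.thresh_domain) for p in grid.pmfs])
    omegas = core.combined_weight(cands.points, config.weight_rules)
    out: list[GradientScore] = []
    for pt, om in zip(cands.points, omegas):
        if om <= 0.0:
            continue
        sw = geometry.sibson_weights(pt, grid, config.region, vor=vor,
                                     hemifield_mask=config.hemifield_mask)
        mu_hat = estimates[sw.neighbor_idx]
        grad = float(mu_hat.max() - mu_hat.min()) if len(mu_hat) else 0.0
        pmf = core.interpolate_pmf(pt, grid, sw)
        out.append(GradientScore(pt, pmf, grad, om, sw))
    return out


def max_gradient_select(grid: TestGrid, config: MedtegConfig,
                        rng: np.random.Generator | None = None) -> GradientScore:
    """The maximum-gradient recommendation, with MEDTEG's tie-breaking
    (nearest to fixation, then list order)."""
    scores = max_gradient_scores(grid, config)
    if not scores:
        raise NoCandidateError("all candidates have zero weight")
    final = np.array([s.final_score for s in scores])
    ecc = np.array([np.hypot(*s.point) for s in scores])
    idx = np.arange(len(scores))
    return scores[np.lexsort((idx, ecc, -final))[0]]


def random_24_2_policy(rng: np.random.Generator, tested_points=None,
                       eye: str = "right") -> np.ndarray:
    """Uniform draw (without replacement) from untested 24-2 locations."""
    grid = geometry.build_24_2_grid(eye)
    pts = grid.points
    if tested_points is not None and len(tested_points):
        tested = np.atleast_2d(np.asarray(tested_points, dtype=float))
        d = np.linalg.norm(pts[:, None, :] - tested[None, :, :], axis=2)
        pts = pts[d.min(axis=1) >= geometry.EPS_POINT]
    if len(pts) == 0:
        raise NoCandidateError("24-2 grid exhausted")
    return pts[int(rng.integers(len(pts)))]
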